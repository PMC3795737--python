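"""Gapped-dipeptide features weighted by evolutionary information (TFPSSM).

A protein sequence is treated as a document whose terms are *gapped
dipeptides*: ordered amino-acid pairs ``(a1, a2)`` separated by ``g``
intervening residues.  The weight of each term is computed from a
position-specific scoring matrix (PSSM): per-position amino-acid
probabilities ``q[p, a]`` are derived from the profile and the weight of
``(a1, a2, g)`` is the sum over positions of ``q[p, a1] * q[p+g+1, a2]``.
With one-hot probabilities this reduces to the plain gapped-dipeptide
count, so the scheme is a soft, homology-extended term frequency
("TFPSSM").

Three probability transforms are available:

``sigmoid``
    logistic of the PSI-BLAST log-odds score (default),
``percentage``
    the weighted observed percentages renormalised per position,
``pseudo``
    a smoothed one-hot encoding of the raw sequence, requiring no
    profile at all.
"""

from __future__ import annotations

import re
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

#: canonical amino-acid order used for all feature vectors (alphabetical)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: column order of the PSI-BLAST ASCII PSSM dialect
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: ambiguity / non-standard residue codes tolerated in sequences
AMBIGUITY_CODES = frozenset("XBZUJO")

#: default maximum gap length; vocabulary size is 400 * (GMAX + 1) = 5600
DEFAULT_GMAX = 13

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
# permutation taking a row in PSSM column order to canonical order
_CANON_FROM_PSSM = np.array([PSSM_COLUMN_ORDER.index(a) for a in AA_ALPHABET])
_PSSM_FROM_CANON = np.array([AA_ALPHABET.index(a) for a in PSSM_COLUMN_ORDER])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (upper-cased on construction)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - set(AA_ALPHABET) - AMBIGUITY_CODES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid residue codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """Per-position evolutionary scores for one protein.

    All 20-wide blocks are stored in canonical :data:`AA_ALPHABET` column
    order regardless of the column order of the source file.

    Attributes
    ----------
    protein_id : str
    sequence : str
        Residue letters of the profiled sequence, one per position.
    log_odds : (L, 20) array
        PSI-BLAST log-odds scores.
    percentages : (L, 20) array
        Weighted observed percentages, in [0, 100].
    ipp : (L,) array
        Information per position in bits (second-to-last numeric column
        of the ASCII profile); a conservation measure.
    rel_weight : (L,) array
        Relative weight of gapless real matches (last column).
    """

    protein_id: str
    sequence: str
    log_odds: np.ndarray
    percentages: np.ndarray
    ipp: np.ndarray
    rel_weight: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.percentages = np.asarray(self.percentages, dtype=float)
        self.ipp = np.asarray(self.ipp, dtype=float)
        L = len(self.sequence)
        if L == 0:
            raise ValueError(f"profile {self.protein_id!r} has zero length")
        if self.log_odds.shape != (L, 20) or self.percentages.shape != (L, 20):
            raise ValueError(
                f"profile {self.protein_id!r}: block shapes "
                f"{self.log_odds.shape}/{self.percentages.shape} do not match "
                f"sequence length {L}"
            )
        if self.ipp.shape != (L,):
            raise ValueError(f"profile {self.protein_id!r}: ipp length mismatch")
        if np.any(self.ipp < 0):
            raise ValueError(f"profile {self.protein_id!r}: negative IPP value")
        if self.rel_weight is None:
            self.rel_weight = np.zeros(L)
        else:
            self.rel_weight = np.asarray(self.rel_weight, dtype=float)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GappedDipeptide:
    """Ordered amino-acid pair separated by ``gap`` residues."""

    a1: str
    a2: str
    gap: int

    def __post_init__(self) -> None:
        if self.a1 not in _AA_INDEX or self.a2 not in _AA_INDEX:
            raise ValueError(f"non-standard residues in dipeptide {self}")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def identifier(self) -> str:
        return f"{self.a1}.g{self.gap}.{self.a2}"

    @classmethod
    def from_identifier(cls, ident: str) -> "GappedDipeptide":
        m = re.fullmatch(r"([A-Z])\.g(\d+)\.([A-Z])", ident)
        if m is None:
            raise ValueError(f"malformed gapped-dipeptide identifier {ident!r}")
        return cls(m.group(1), m.group(3), int(m.group(2)))


def vocabulary(gmax: int = DEFAULT_GMAX) -> list[str]:
    """Canonical gapped-dipeptide vocabulary: gap-major, then a1, then a2."""
    if gmax < 0:
        raise ValueError("gmax must be >= 0")
    return [
        f"{a1}.g{g}.{a2}"
        for g in range(gmax + 1)
        for a1 in AA_ALPHABET
        for a2 in AA_ALPHABET
    ]


@dataclass
class FeatureMatrix:
    """Proteins x gapped-dipeptides table of non-negative TFPSSM weights.

    This is the count-like data table handed to correspondence analysis.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("feature matrix shape does not match its labels")
        if np.any(self.values < 0):
            raise ValueError("feature matrix contains negative weights")
        zero = self.values.sum(axis=1) == 0
        if np.any(zero):
            bad = [self.row_ids[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"all-zero feature vectors for proteins: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_columns(self) -> list[str]:
        """Dipeptides absent from every protein (dropped downstream by CA)."""
        mask = self.values.sum(axis=0) == 0
        return [self.col_ids[j] for j in np.flatnonzero(mask)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="protein")

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Raises ``ValueError`` on an empty file, an empty sequence or a
    duplicated identifier.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM parsing
# ---------------------------------------------------------------------------

_INT = r"-?\d+"


def parse_pssm_ascii(path: Union[str, Path], protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM dump.

    The dialect: free-form header lines, a column-header line naming the
    20 residues twice, then one row per position holding the position
    index, the query residue, 20 integer log-odds scores, 20 weighted
    observed percentages, the information per position and the relative
    weight (44 fields).  Header text is skipped by pattern rather than by
    a fixed line count, which tolerates version drift.  Trailing footer
    lines (Lambda/K statistics) are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    column_letters: str | None = None
    rows: list[tuple[int, str, list[float]]] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        # the column-header line: 40 single residue letters
        if column_letters is None and len(tokens) == 40 and all(
            len(t) == 1 and t.isalpha() for t in tokens
        ):
            column_letters = "".join(tokens[:20])
            continue
        # a data row: integer index then a single residue letter
        if re.fullmatch(_INT, tokens[0]) and len(tokens[1]) == 1 and tokens[1].isalpha():
            values: list[float] = []
            for t in tokens[2:]:
                try:
                    values.append(float(t))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric field {t!r} in PSSM row"
                    ) from None
            if len(values) != 42:
                raise ValueError(
                    f"{path}:{lineno}: expected 42 numeric fields "
                    f"(20 scores, 20 percentages, IPP, weight), got {len(values)}"
                )
            rows.append((int(tokens[0]), tokens[1], values))

    if not rows:
        raise ValueError(f"{path}: no PSSM rows found (L = 0)")
    order = column_letters or PSSM_COLUMN_ORDER
    if sorted(order) != sorted(AA_ALPHABET):
        raise ValueError(f"{path}: unexpected residue column set {order!r}")
    perm = np.array([order.index(a) for a in AA_ALPHABET])

    indices = [r[0] for r in rows]
    if indices != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: position indices are not consecutive from 1")

    seq = "".join(r[1] for r in rows)
    data = np.array([r[2] for r in rows], dtype=float)
    log_odds = data[:, :20][:, perm]
    percentages = data[:, 20:40][:, perm]
    ipp = data[:, 40]  # second-to-last numeric column
    rel_weight = data[:, 41]
    return PSSMProfile(
        protein_id=protein_id or path.stem,
        sequence=seq,
        log_odds=log_odds,
        percentages=percentages,
        ipp=ipp,
        rel_weight=rel_weight,
    )


def write_pssm_ascii(profile: PSSMProfile, path: Union[str, Path]) -> None:
    """Write a profile back to the PSI-BLAST ASCII dialect (round-trips)."""
    lo = profile.log_odds[:, _PSSM_FROM_CANON]
    pc = profile.percentages[:, _PSSM_FROM_CANON]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        letters = "  ".join(PSSM_COLUMN_ORDER)
        fh.write("            " + letters + "   " + letters + "\n")
        for p in range(profile.length):
            score_part = " ".join(f"{int(round(v)):3d}" for v in lo[p])
            pct_part = " ".join(f"{v:6.2f}" for v in pc[p])
            fh.write(
                f"{p + 1:5d} {profile.sequence[p]}  {score_part}  {pct_part}"
                f"  {profile.ipp[p]:5.2f} {profile.rel_weight[p]:5.2f}\n"
            )
        fh.write("\n                      K         Lambda\n")


# ---------------------------------------------------------------------------
# probability transforms and TFPSSM weights
# ---------------------------------------------------------------------------

def position_probabilities(
    source: Union[PSSMProfile, ProteinRecord, str],
    mode: str = "sigmoid",
    smoothing: float = 0.2,
) -> np.ndarray:
    """Per-position amino-acid weight matrix ``q`` (L x 20, canonical order).

    Parameters
    ----------
    source
        A :class:`PSSMProfile` (``sigmoid``/``percentage`` modes) or a
        sequence / :class:`ProteinRecord` (``pseudo`` mode).
    mode
        ``sigmoid``: logistic of the log-odds block, ``q = 1/(1+exp(-s))``;
        ``percentage``: percentage block / 100, renormalised per position;
        ``pseudo``: ``(1 - smoothing)`` on the observed residue plus
        ``smoothing / 20`` everywhere (needs no profile).
    smoothing
        Pseudo-count mass in [0, 1] shared uniformly by the 20 residues
        (pseudo mode only).
    """
    if mode in ("sigmoid", "percentage"):
        if not isinstance(source, PSSMProfile):
            raise TypeError(f"{mode!r} mode requires a PSSMProfile")
        if mode == "sigmoid":
            return 1.0 / (1.0 + np.exp(-source.log_odds))
        q = source.percentages / 100.0
        sums = q.sum(axis=1, keepdims=True)
        empty = sums[:, 0] == 0
        if np.any(empty):
            # positions with no observed percentages fall back to uniform
            q[empty] = 1.0 / 20.0
            sums = q.sum(axis=1, keepdims=True)
        return q / sums
    if mode == "pseudo":
        if not 0.0 <= smoothing <= 1.0:
            raise ValueError("smoothing must lie in [0, 1]")
        if isinstance(source, PSSMProfile):
            seq = source.sequence
        elif isinstance(source, ProteinRecord):
            seq = source.sequence
        else:
            seq = str(source).upper()
        L = len(seq)
        q = np.full((L, 20), smoothing / 20.0)
        for p, a in enumerate(seq):
            j = _AA_INDEX.get(a)
            if j is None:
                warnings.warn(
                    f"residue {a!r} at position {p + 1} is outside the standard "
                    "alphabet; using a uniform probability row",
                    stacklevel=2,
                )
                q[p] = 1.0 / 20.0
            else:
                q[p, j] += 1.0 - smoothing
        return q
    raise ValueError(f"unknown probability mode {mode!r}")


def tfpssm_vector(q: np.ndarray, gmax: int = DEFAULT_GMAX) -> np.ndarray:
    """TFPSSM weights over the 400*(gmax+1) gapped-dipeptide vocabulary.

    ``weight(a1, a2, g) = sum_p q[p, a1] * q[p + g + 1, a2]`` for positions
    ``p = 0 .. L - g - 2``.  Gaps too long for the sequence contribute
    all-zero blocks rather than erroring.  Block layout matches
    :func:`vocabulary` (gap-major, a1-major).
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[1] != 20:
        raise ValueError("q must be an L x 20 matrix")
    if gmax < 0:
        raise ValueError("gmax must be >= 0")
    L = q.shape[0]
    blocks = []
    for g in range(gmax + 1):
        span = L - g - 1
        if span <= 0:
            blocks.append(np.zeros((20, 20)))
        else:
            blocks.append(q[:span].T @ q[g + 1 :])
    return np.concatenate([b.ravel() for b in blocks])


def build_feature_matrix(
    inputs: Sequence[Union[PSSMProfile, ProteinRecord, str]],
    mode: str = "sigmoid",
    gmax: int = DEFAULT_GMAX,
    smoothing: float = 0.2,
) -> FeatureMatrix:
    """TFPSSM feature matrix for a collection of proteins.

    Rows follow input order; columns follow the canonical vocabulary.
    Proteins whose whole vector is zero (e.g. single-residue sequences)
    are rejected by name.
    """
    if len(inputs) < 2:
        raise ValueError("need at least 2 proteins to build a feature matrix")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for item in inputs:
        if isinstance(item, PSSMProfile):
            ids.append(item.protein_id)
        elif isinstance(item, ProteinRecord):
            ids.append(item.id)
        else:
            raise TypeError("inputs must be PSSMProfile or ProteinRecord objects")
        q = position_probabilities(item, mode=mode, smoothing=smoothing)
        rows.append(tfpssm_vector(q, gmax=gmax))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in feature matrix input")
    return FeatureMatrix(ids, vocabulary(gmax), np.vstack(rows))


def average_ipp(profile: PSSMProfile) -> float:
    """Mean information per position: a profile-level conservation summary."""
    return float(np.mean(profile.ipp))


# ---------------------------------------------------------------------------
# optional PSI-BLAST wrapper (never exercised by the test suite)
# ---------------------------------------------------------------------------

#: insensitive fast-search preset (BLOSUM80, high word threshold, soft masking)
PSIBLAST_FAST = (
    "-matrix BLOSUM80 -evalue 1e-5 -gapopen 9 -gapextend 2 -threshold 999 "
    "-seg yes -soft_masking true -num_iterations 2"
)
#: conventional sensitive preset: two iterations at e-value 0.001
PSIBLAST_NORMAL = "-evalue 0.001 -num_iterations 2"


def psiblast_command(
    query: Union[str, Path],
    database: str,
    out_pssm: Union[str, Path],
    preset: str = "fast",
) -> list[str]:
    """Argument vector for a PSI-BLAST run producing an ASCII PSSM."""
    flags = {"fast": PSIBLAST_FAST, "normal": PSIBLAST_NORMAL}
    if preset not in flags:
        raise ValueError(f"unknown preset {preset!r}; use 'fast' or 'normal'")
    return (
        ["psiblast", "-query", str(query), "-db", database]
        + flags[preset].split()
        + ["-out_ascii_pssm", str(out_pssm)]
    )


def run_psiblast(
    query: Union[str, Path],
    database: str,
    out_pssm: Union[str, Path],
    preset: str = "fast",
) -> PSSMProfile:
    """Shell out to PSI-BLAST and parse the resulting profile."""
    cmd = psiblast_command(query, database, out_pssm, preset)
    subprocess.run(cmd, check=True)
    return parse_pssm_ascii(out_pssm)
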