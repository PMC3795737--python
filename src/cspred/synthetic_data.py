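"""Seeded synthetic fixtures for every pipeline stage.

Real benchmark corpora for this problem (subcellular-localization and
kinase-family sets) require external databases and profile searches, so
the test bed is built from generators that plant the structures the
method exploits: distance matrices with known compact sets, Gaussian
clusters standing in for CA-embedded classes, and random protein
sequences whose classes are marked by enriched gapped-dipeptides.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compact_sets import DistanceMatrix
from .classifier import LabeledEmbedding
from .sequence_features import AA_ALPHABET, DEFAULT_GMAX, ProteinRecord


# ---------------------------------------------------------------------------
# worked six-item example
# ---------------------------------------------------------------------------

def worked_example_matrix() -> DistanceMatrix:
    """The fixed six-item worked example S1..S6.

    Two tight groups ({S1,S2,S6} and {S3,S4,S5}) separated by distance
    10.  Its nontrivial compact sets are {S1,S6}, {S1,S2,S6} and
    {S3,S4,S5}; the pair {S3,S4} arises as a merge-tree candidate but
    fails verification because its external distance to S5 equals its
    internal diameter (the predicate is strict).
    """
    ids = ("S1", "S2", "S3", "S4", "S5", "S6")
    D = np.full((6, 6), 10.0)
    np.fill_diagonal(D, 0.0)

    def put(a: str, b: str, w: float) -> None:
        i, j = ids.index(a), ids.index(b)
        D[i, j] = D[j, i] = w

    put("S1", "S6", 1.0)
    put("S1", "S2", 3.0)
    put("S2", "S6", 3.0)
    put("S3", "S4", 2.0)
    put("S4", "S5", 2.0)
    put("S3", "S5", 2.5)
    return DistanceMatrix(ids, D)


# ---------------------------------------------------------------------------
# planted compact blocks
# ---------------------------------------------------------------------------

def planted_compact_matrix(
    block_sizes: Sequence[int],
    within: tuple[float, float] = (0.0, 1.0),
    between_floor: float = 5.0,
    seed: int | None = 0,
) -> tuple[DistanceMatrix, list[frozenset[str]]]:
    """Random distance matrix whose blocks are guaranteed compact sets.

    Within-block distances are i.i.d. uniform over ``within``; all
    between-block distances are uniform in ``[floor, 2*floor]``, so every
    block's minimum external distance strictly exceeds its diameter.
    Returns the matrix and the planted nontrivial sets (blocks of size
    >= 2 that are proper subsets).
    """
    lo, hi = within
    if not 0.0 <= lo < hi:
        raise ValueError("within-range must satisfy 0 <= lo < hi")
    if between_floor <= hi:
        raise ValueError("between-floor must exceed the within-range maximum")
    if any(b < 1 for b in block_sizes) or len(block_sizes) < 1:
        raise ValueError("block sizes must be positive")
    rng = np.random.default_rng(seed)
    n = int(sum(block_sizes))
    D = rng.uniform(between_floor, 2 * between_floor, size=(n, n))
    block_of = np.concatenate(
        [np.full(b, i, dtype=int) for i, b in enumerate(block_sizes)]
    )
    same = block_of[:, None] == block_of[None, :]
    D[same] = rng.uniform(lo, hi, size=int(same.sum()))
    D = np.triu(D, 1)
    D = D + D.T
    ids = tuple(f"x{i:03d}" for i in range(n))
    matrix = DistanceMatrix(ids, D)
    expected = [
        frozenset(ids[i] for i in np.flatnonzero(block_of == b))
        for b, size in enumerate(block_sizes)
        if size >= 2 and size < n
    ]
    return matrix, expected


# ---------------------------------------------------------------------------
# Gaussian clusters (a stand-in for CA-embedded classes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """Isotropic Gaussian mixture: K classes at a given centre separation.

    ``separation`` is the minimum distance between class centres in
    units of the (unit) within-class standard deviation.
    """

    n_classes: int = 5
    points_per_class: int = 40
    dim: int = 2
    separation: float = 20.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.points_per_class < 1 or self.dim < 1:
            raise ValueError("invalid cluster sizes")


def gaussian_cluster_dataset(spec: ClusterSpec) -> LabeledEmbedding:
    """Labelled points from K well-defined isotropic Gaussian clusters.

    Centres are placed on a circle (in the first two dimensions) whose
    chord between neighbours equals ``spec.separation``; within-class
    spread is the unit normal.  All items are labelled and marked as
    training; cross-validation re-splits them as needed.
    """
    K = spec.n_classes
    rng = np.random.default_rng(spec.seed)
    centers = np.zeros((K, spec.dim))
    if spec.dim == 1:
        centers[:, 0] = np.arange(K) * spec.separation
    else:
        radius = spec.separation / (2 * np.sin(np.pi / K))
        angles = 2 * np.pi * np.arange(K) / K
        centers[:, 0] = radius * np.cos(angles)
        centers[:, 1] = radius * np.sin(angles)
    coords = []
    labels = []
    for kcls in range(K):
        pts = centers[kcls] + rng.standard_normal((spec.points_per_class, spec.dim))
        coords.append(pts)
        labels.extend([f"class{kcls}"] * spec.points_per_class)
    X = np.vstack(coords)
    n = X.shape[0]
    ids = [f"pt{i:04d}" for i in range(n)]
    return LabeledEmbedding(
        ids=ids, coords=X, is_train=np.ones(n, dtype=bool), labels=labels
    )


# ---------------------------------------------------------------------------
# synthetic sequence classes with dipeptide signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceClassSpec:
    """Random protein classes marked by enriched gapped-dipeptides.

    Each class owns ``signatures_per_class`` gapped-dipeptides (pairs
    with a gap in ``[0, gmax]``); their expected occurrence count per
    sequence is multiplied by ``enrichment`` relative to the background,
    emulating class-specific term preferences in real corpora.
    """

    n_classes: int = 3
    per_class: int = 30
    length_range: tuple[int, int] = (250, 350)
    signatures_per_class: int = 16
    enrichment: float = 8.0
    gmax: int = DEFAULT_GMAX
    seed: int | None = 0
    background: tuple[float, ...] | None = None  # 20 frequencies; uniform default

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment factor must be >= 1")
        if self.length_range[0] < self.gmax + 2:
            raise ValueError("sequences must be at least gmax + 2 long")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if self.background is not None and len(self.background) != 20:
            raise ValueError("background must list 20 frequencies")


def synthetic_protein_classes(
    spec: SequenceClassSpec,
) -> tuple[list[ProteinRecord], list[str], dict[str, list[str]]]:
    """Sequences, labels, and the per-class signature dipeptide lists.

    Residues are drawn i.i.d. from the background (uniform 1/20 by
    default); each class signature ``(a1, a2, g)`` is then over-planted
    at Poisson-many random positions so its expected count reaches
    ``enrichment`` times the background expectation ``(L - g - 1)/400``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = (
        np.asarray(spec.background, dtype=float)
        if spec.background is not None
        else np.full(20, 1 / 20)
    )
    bg = bg / bg.sum()
    letters = np.array(list(AA_ALPHABET))

    # disjoint signature sets across classes
    n_sig = spec.n_classes * spec.signatures_per_class
    total_vocab = 400 * (spec.gmax + 1)
    sig_codes = rng.choice(total_vocab, size=n_sig, replace=False)
    signatures: dict[str, list[tuple[str, str, int]]] = {}
    for kcls in range(spec.n_classes):
        label = f"class{kcls}"
        sigs = []
        for code in sig_codes[
            kcls * spec.signatures_per_class : (kcls + 1) * spec.signatures_per_class
        ]:
            g, rest = divmod(int(code), 400)
            i1, i2 = divmod(rest, 20)
            sigs.append((AA_ALPHABET[i1], AA_ALPHABET[i2], g))
        signatures[label] = sigs

    records: list[ProteinRecord] = []
    labels: list[str] = []
    lo, hi = spec.length_range
    for kcls in range(spec.n_classes):
        label = f"class{kcls}"
        for s in range(spec.per_class):
            L = int(rng.integers(lo, hi + 1))
            seq = rng.choice(letters, size=L, p=bg)
            for a1, a2, g in signatures[label]:
                lam = (spec.enrichment - 1.0) * (L - g - 1) / 400.0
                extra = rng.poisson(lam)
                if extra:
                    positions = rng.integers(0, L - g - 1, size=extra)
                    seq[positions] = a1
                    seq[positions + g + 1] = a2
            records.append(ProteinRecord(f"{label}_seq{s:03d}", "".join(seq)))
            labels.append(label)
    sig_ids = {
        label: [f"{a1}.g{g}.{a2}" for a1, a2, g in sigs]
        for label, sigs in signatures.items()
    }
    return records, labels, sig_ids


# ---------------------------------------------------------------------------
# random count tables (CA fixtures)
# ---------------------------------------------------------------------------

def random_count_table(
    rows: int, cols: int, seed: int | None = 0, lam: float = 3.0
) -> np.ndarray:
    """Poisson integer table with no all-zero row or column."""
    if rows < 2 or cols < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    rng = np.random.default_rng(seed)
    while True:
        N = rng.poisson(lam, size=(rows, cols)).astype(float)
        if N.sum() > 0 and N.sum(axis=1).all() and N.sum(axis=0).all():
            return N
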