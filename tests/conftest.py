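import numpy as np
import pytest

from cspred.sequence_features import AA_ALPHABET, PSSM_COLUMN_ORDER
from cspred.synthetic_data import worked_example_matrix

# hand-crafted 3-position ASCII profile in the PSI-BLAST dialect:
# scores_pssm[p][j] = (j % 7) - 3 + p, percentages uniform 5.0 per residue,
# IPP column 0.82 / 1.50 / 0.30, relative weight 0.10 / 0.20 / 0.30
PSSM_SEQUENCE = "MKT"
PSSM_IPP = [0.82, 1.50, 0.30]
PSSM_RELW = [0.10, 0.20, 0.30]


def _pssm_scores(p: int) -> list[int]:
    return [(j % 7) - 3 + p for j in range(20)]


def make_pssm_text() -> str:
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(PSSM_COLUMN_ORDER) + "   " + "  ".join(PSSM_COLUMN_ORDER),
    ]
    for p, res in enumerate(PSSM_SEQUENCE):
        scores = " ".join(f"{s:3d}" for s in _pssm_scores(p))
        pcts = " ".join("  5.00" for _ in range(20))
        lines.append(
            f"{p + 1:5d} {res}  {scores}  {pcts}  {PSSM_IPP[p]:5.2f} {PSSM_RELW[p]:5.2f}"
        )
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3176"]
    return "\n".join(lines) + "\n"


def expected_log_odds_canonical() -> np.ndarray:
    """The fixture's log-odds block re-ordered to the canonical alphabet."""
    out = np.zeros((3, 20))
    for p in range(3):
        row = _pssm_scores(p)
        for i, a in enumerate(AA_ALPHABET):
            out[p, i] = row[PSSM_COLUMN_ORDER.index(a)]
    return out


@pytest.fixture
def pssm_file(tmp_path):
    path = tmp_path / "query.pssm"
    path.write_text(make_pssm_text())
    return path


@pytest.fixture
def fig1():
    return worked_example_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
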