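"""Correspondence analysis (CA) of a non-negative count-like table.

CA embeds the rows (proteins) and columns (gapped-dipeptides) of a table
``N`` in a shared low-dimensional space where chi-squared distances are
preserved.  The decomposition:

1. divide ``N`` by its grand total ``n`` to get the correspondence
   matrix ``P``;
2. form row and column masses ``r = P 1``, ``c = P^T 1``;
3. compute the standardized residuals
   ``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` and its SVD
   ``S = U diag(sigma) V^T``;
4. row principal coordinates ``F = D_r^{-1/2} U diag(sigma)``, column
   standard coordinates ``Gamma = D_c^{-1/2} V`` and column principal
   coordinates ``G = Gamma diag(sigma)``.

The squared singular values sum to the total inertia, the Pearson
chi-squared statistic of ``N`` divided by ``n``.  The retained dimension
count ``k`` is the smallest number of leading axes explaining at least a
variance fraction ``threshold`` (default 0.95).

New (supplementary) rows are projected into the trained space through
their profiles: ``coords = (row / sum(row)) @ Gamma``, truncated to the
retained axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

#: relative floor under which a singular value counts as numerically zero
SV_RTOL = 1e-12


@dataclass
class CountTable:
    """A validated non-negative table with its correspondence quantities."""

    row_ids: list[str]
    col_ids: list[str]
    N: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if self.N.ndim != 2:
            raise ValueError("count table must be a 2-D matrix")
        if self.N.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("count table shape does not match its labels")
        if np.any(self.N < 0):
            raise ValueError("count table contains negative entries")
        if self.N.sum() <= 0:
            raise ValueError("count table is all zero")

    @property
    def grand_total(self) -> float:
        return float(self.N.sum())

    @property
    def P(self) -> np.ndarray:
        return self.N / self.grand_total

    @property
    def row_masses(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def col_masses(self) -> np.ndarray:
        return self.P.sum(axis=0)


@dataclass
class CAModel:
    """Fitted correspondence-analysis model.

    ``F``, ``G``, ``Gamma`` and ``singular_values`` only carry the axes
    with numerically positive singular value; ``k`` (<= that count) is
    the dimension retained by the variance rule.
    """

    row_ids: list[str]
    col_ids: list[str]          # retained columns, in original order
    dropped_cols: list[str]     # all-zero columns removed before fitting
    r: np.ndarray               # row masses
    c: np.ndarray               # column masses (over retained columns)
    singular_values: np.ndarray
    F: np.ndarray               # row principal coordinates
    G: np.ndarray               # column principal coordinates
    Gamma: np.ndarray           # column standard coordinates
    k: int
    threshold: float

    @property
    def n_axes(self) -> int:
        """Number of axes with positive singular value."""
        return len(self.singular_values)

    @property
    def inertia(self) -> np.ndarray:
        """Per-axis inertia (squared singular values)."""
        return self.singular_values**2

    @property
    def total_inertia(self) -> float:
        return float(np.sum(self.singular_values**2))

    @property
    def inertia_shares(self) -> np.ndarray:
        tot = self.total_inertia
        if tot == 0:
            return np.zeros(0)
        return self.inertia / tot

    # -- serialization ------------------------------------------------------

    def to_json(self, path: Union[str, Path]) -> None:
        """Serialize the model to a single JSON archive."""
        payload = {
            "row_ids": self.row_ids,
            "col_ids": self.col_ids,
            "dropped_cols": self.dropped_cols,
            "r": self.r.tolist(),
            "c": self.c.tolist(),
            "singular_values": self.singular_values.tolist(),
            "F": self.F.tolist(),
            "G": self.G.tolist(),
            "Gamma": self.Gamma.tolist(),
            "k": self.k,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            row_ids=d["row_ids"],
            col_ids=d["col_ids"],
            dropped_cols=d["dropped_cols"],
            r=np.array(d["r"]),
            c=np.array(d["c"]),
            singular_values=np.array(d["singular_values"]),
            F=np.array(d["F"]),
            G=np.array(d["G"]),
            Gamma=np.array(d["Gamma"]),
            k=d["k"],
            threshold=d["threshold"],
        )

    def write_coordinates(self, row_path: Union[str, Path], col_path: Union[str, Path]) -> None:
        """Export row/column principal coordinates as TSV (for plotting)."""
        axes = [f"axis{i + 1}" for i in range(self.n_axes)]
        pd.DataFrame(self.F, index=self.row_ids, columns=axes).to_csv(
            row_path, sep="\t", index_label="id"
        )
        pd.DataFrame(self.G, index=self.col_ids, columns=axes).to_csv(
            col_path, sep="\t", index_label="id"
        )


def pearson_chi2(N: np.ndarray) -> float:
    """Pearson chi-squared statistic of a contingency table.

    ``sum_ij (N_ij - E_ij)^2 / E_ij`` with ``E_ij`` the product of the
    margins over the grand total.  Requires no all-zero row or column.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("table contains negative entries")
    n = N.sum()
    if n <= 0:
        raise ValueError("table is all zero")
    rows = N.sum(axis=1)
    cols = N.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("table has an all-zero row or column")
    E = np.outer(rows, cols) / n
    return float(((N - E) ** 2 / E).sum())


def fit_ca(
    table: Union[CountTable, np.ndarray],
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    threshold: float = 0.95,
) -> CAModel:
    """Fit correspondence analysis on a non-negative table.

    All-zero columns are dropped (and recorded on the model); an
    all-zero row is an error because its profile is undefined.  Axis
    signs are fixed deterministically: on every axis the largest-
    magnitude column standard coordinate is made positive.
    """
    if isinstance(table, CountTable):
        N, row_ids, col_ids = table.N, table.row_ids, table.col_ids
    else:
        N = np.asarray(table, dtype=float)
        if row_ids is None:
            row_ids = [f"row{i}" for i in range(N.shape[0])]
        if col_ids is None:
            col_ids = [f"col{j}" for j in range(N.shape[1])]
    row_ids = list(row_ids)
    col_ids = list(col_ids)
    if N.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(N < 0):
        raise ValueError("table contains negative entries")
    if N.sum() <= 0:
        raise ValueError("cannot fit CA on an all-zero table")

    zero_rows = N.sum(axis=1) == 0
    if np.any(zero_rows):
        bad = [row_ids[i] for i in np.flatnonzero(zero_rows)]
        raise ValueError(f"all-zero rows in CA input: {bad}")
    col_mask = N.sum(axis=0) > 0
    dropped = [col_ids[j] for j in np.flatnonzero(~col_mask)]
    kept_cols = [col_ids[j] for j in np.flatnonzero(col_mask)]
    N = N[:, col_mask]
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise ValueError("CA needs at least 2 nonzero rows and 2 nonzero columns")

    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    # numerical rank: relative floor, plus an absolute eps-scale floor so an
    # exactly-independent (rank-one) table yields zero positive axes
    if sv.size and sv[0] > 0:
        tol = max(SV_RTOL * sv[0], max(S.shape) * np.finfo(float).eps)
        pos = sv > tol
    else:
        pos = np.zeros(sv.shape, dtype=bool)
    U, sv, Vt = U[:, pos], sv[pos], Vt[pos, :]

    Gamma = Vt.T / np.sqrt(c)[:, None]
    # deterministic axis signs: largest |column loading| made positive
    for j in range(Gamma.shape[1]):
        i = int(np.argmax(np.abs(Gamma[:, j])))
        if Gamma[i, j] < 0:
            Gamma[:, j] *= -1
            U[:, j] *= -1
    F = (U * sv) / np.sqrt(r)[:, None]
    G = Gamma * sv

    model = CAModel(
        row_ids=row_ids,
        col_ids=kept_cols,
        dropped_cols=dropped,
        r=r,
        c=c,
        singular_values=sv,
        F=F,
        G=G,
        Gamma=Gamma,
        k=0,
        threshold=threshold,
    )
    model.k = select_dimensions(model, threshold) if sv.size else 0
    return model


def select_dimensions(model: Union[CAModel, np.ndarray, Sequence[float]], threshold: float = 0.95) -> int:
    """Smallest k whose leading axes explain >= ``threshold`` of inertia.

    Accepts a fitted model or a raw vector of singular values.  k is at
    least 1 and never exceeds the number of positive singular values.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if isinstance(model, CAModel):
        sv = model.singular_values
    else:
        sv = np.asarray(model, dtype=float)
    inertia = sv**2
    total = inertia.sum()
    if total <= 0 or sv.size == 0:
        raise ValueError("no positive singular value; dimension undefined")
    shares = np.cumsum(inertia) / total
    k = int(np.searchsorted(shares, threshold - 1e-12) + 1)
    return min(k, len(sv))


def project_supplementary_rows(
    model: CAModel,
    rows: np.ndarray,
    row_ids: Sequence[str] | None = None,
    n_axes: int | None = None,
) -> np.ndarray:
    """Project held-out rows into the trained CA space.

    ``rows`` must be non-negative vectors over the model's *retained*
    columns.  Each row is converted to a profile ``h = row / sum(row)``
    and mapped through the column standard coordinates, ``h @ Gamma``,
    truncated to ``n_axes`` (default: the model's retained ``k``).  A row
    supported entirely on dropped columns has an undefined profile and
    raises, naming the row.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != len(model.col_ids):
        raise ValueError(
            f"rows have {rows.shape[1]} columns; model retains {len(model.col_ids)}"
        )
    if np.any(rows < 0):
        raise ValueError("supplementary rows must be non-negative")
    sums = rows.sum(axis=1)
    if np.any(sums == 0):
        idx = int(np.flatnonzero(sums == 0)[0])
        name = row_ids[idx] if row_ids is not None else f"row {idx}"
        raise ValueError(
            f"supplementary {name} has zero mass over the retained columns"
        )
    if n_axes is None:
        n_axes = model.k
    h = rows / sums[:, None]
    return h @ model.Gamma[:, :n_axes]
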