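"""Hybrid compact-set / nearest-neighbour functional-class prediction.

Training and test points live in the same reduced coordinate space
(typically the retained CA axes).  Prediction proceeds in two tiers:

* **CS** — compact sets are enumerated over the joint embedding; a test
  point lying in a nontrivial compact set takes the strict-majority
  label of the *training* members of the largest such set.  Because the
  verified sets containing a point are nested, "largest" is unique.
  Points in no set, in a set with no training member, or without a
  strict majority stay UNPREDICTED.
* **1-NN fallback** — every point left unpredicted receives the label of
  its Euclidean-nearest training point (ties: lowest training index).

Evaluation follows the precision/recall/accuracy/F conventions of
partial predictors: an UNPREDICTED item counts as a false negative of
its true class but never as anyone's false positive, so the CS-only
precision is computed over predicted items while recall spans all items.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .compact_sets import DistanceMatrix, build_kruskal_tree, verify_compact_sets
from .correspondence_analysis import fit_ca, project_supplementary_rows

UNPREDICTED = None

CS = "CS"
NN = "1NN"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabeledEmbedding:
    """Items embedded in a shared k-dim space, split into train and test.

    ``labels[i]`` must be a string for every training item and may be
    ``None`` for test items (unknown truth).
    """

    ids: list[str]
    coords: np.ndarray
    is_train: np.ndarray
    labels: list[str | None]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.is_train = np.asarray(self.is_train, dtype=bool)
        n = len(self.ids)
        if self.coords.shape[0] != n or self.is_train.shape != (n,):
            raise ValueError("embedding fields have inconsistent lengths")
        if len(self.labels) != n:
            raise ValueError("labels length does not match items")
        for i in np.flatnonzero(self.is_train):
            if self.labels[i] is None:
                raise ValueError(f"training item {self.ids[i]!r} is unlabeled")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate item ids in embedding")

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_train)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_train)

    @classmethod
    def from_split(
        cls,
        train_ids: Sequence[str],
        train_coords: np.ndarray,
        train_labels: Sequence[str],
        test_ids: Sequence[str],
        test_coords: np.ndarray,
    ) -> "LabeledEmbedding":
        train_coords = np.atleast_2d(np.asarray(train_coords, dtype=float))
        test_coords = np.atleast_2d(np.asarray(test_coords, dtype=float))
        if test_coords.size and train_coords.shape[1] != test_coords.shape[1]:
            raise ValueError(
                f"train dimension {train_coords.shape[1]} != test dimension "
                f"{test_coords.shape[1]}"
            )
        n_tr, n_te = len(train_ids), len(test_ids)
        coords = (
            np.vstack([train_coords, test_coords]) if n_te else train_coords
        )
        return cls(
            ids=list(train_ids) + list(test_ids),
            coords=coords,
            is_train=np.array([True] * n_tr + [False] * n_te),
            labels=list(train_labels) + [None] * n_te,
        )


@dataclass(frozen=True)
class Prediction:
    """Outcome for a single test item.

    ``method`` is ``"CS"`` with the voting compact set's members as
    evidence, ``"1NN"`` with the nearest training neighbour and its
    distance, or ``None`` when the item is UNPREDICTED.
    """

    item_id: str
    label: str | None
    method: str | None
    evidence: tuple = ()


@dataclass
class PredictionResult:
    predictions: list[Prediction]

    def __iter__(self):
        return iter(self.predictions)

    def __len__(self) -> int:
        return len(self.predictions)

    def __getitem__(self, item_id: str) -> Prediction:
        for p in self.predictions:
            if p.item_id == item_id:
                return p
        raise KeyError(item_id)

    @property
    def unpredicted_ids(self) -> list[str]:
        return [p.item_id for p in self.predictions if p.label is UNPREDICTED]

    def method_counts(self) -> Counter:
        return Counter(p.method for p in self.predictions if p.label is not None)

    def to_frame(self, truth: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            rows.append(
                {
                    "item": p.item_id,
                    "true_label": truth.get(p.item_id, "") if truth else "",
                    "predicted": p.label if p.label is not None else "UNPREDICTED",
                    "method": p.method or "",
                    "evidence": _format_evidence(p),
                }
            )
        return pd.DataFrame(rows, columns=["item", "true_label", "predicted", "method", "evidence"])

    def write_tsv(self, path: Union[str, Path], truth: dict[str, str] | None = None) -> None:
        self.to_frame(truth).to_csv(path, sep="\t", index=False)


def _format_evidence(p: Prediction) -> str:
    if p.method == CS:
        return "set:" + ",".join(sorted(p.evidence))
    if p.method == NN:
        nb, dist = p.evidence
        return f"nn:{nb}@{dist:.6g}"
    return ""


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)


@dataclass
class EvalReport:
    """Per-class and pooled prediction quality.

    Pooled precision is over predicted items only; pooled recall equals
    accuracy (sum of TP over all items), so the two coincide whenever
    every item receives a prediction.
    """

    per_class: dict[str, ClassMetrics]
    n: int
    n_predicted: int

    @property
    def total_tp(self) -> int:
        return sum(m.tp for m in self.per_class.values())

    @property
    def accuracy(self) -> float:
        return self.total_tp / self.n if self.n else math.nan

    @property
    def precision(self) -> float:
        return self.total_tp / self.n_predicted if self.n_predicted else math.nan

    @property
    def recall(self) -> float:
        return self.accuracy

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in sorted(self.per_class):
            m = self.per_class[label]
            rows.append(
                {
                    "class": label,
                    "n": m.tp + m.fn,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                }
            )
        rows.append(
            {
                "class": "overall",
                "n": self.n,
                "tp": self.total_tp,
                "fp": self.n_predicted - self.total_tp,
                "fn": self.n - self.total_tp,
                "precision": self.precision,
                "recall": self.recall,
                "f_measure": self.f_measure,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_predicted": self.n_predicted,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "per_class": {
                label: {
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                }
                for label, m in sorted(self.per_class.items())
            },
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def _cs_predict_joint(embedding: LabeledEmbedding) -> list[Prediction]:
    D = DistanceMatrix.from_points(embedding.coords, embedding.ids)
    tc = verify_compact_sets(build_kruskal_tree(D), D)
    train_label = {
        embedding.ids[i]: embedding.labels[i] for i in embedding.train_indices
    }
    out: list[Prediction] = []
    for t in embedding.test_indices:
        item = embedding.ids[t]
        out.append(_vote(item, tc.sets_containing(item), train_label))
    return out


def _vote(
    item: str,
    containing_sets: list[frozenset[str]],
    train_label: dict[str, str],
) -> Prediction:
    if not containing_sets:
        return Prediction(item, UNPREDICTED, None)
    largest = containing_sets[0]  # nested by laminarity, so unique maximum
    votes = Counter(
        train_label[m] for m in largest if m != item and m in train_label
    )
    total = sum(votes.values())
    if total == 0:
        return Prediction(item, UNPREDICTED, None)
    label, count = votes.most_common(1)[0]
    if 2 * count <= total:  # no strict majority: ambiguous, fall through
        return Prediction(item, UNPREDICTED, None)
    return Prediction(item, label, CS, tuple(sorted(largest)))


def _cs_predict_per_item(embedding: LabeledEmbedding) -> list[Prediction]:
    tr = embedding.train_indices
    train_ids = [embedding.ids[i] for i in tr]
    train_coords = embedding.coords[tr]
    train_label = {embedding.ids[i]: embedding.labels[i] for i in tr}
    base = squareform(pdist(train_coords))
    out: list[Prediction] = []
    for t in embedding.test_indices:
        item = embedding.ids[t]
        d_to_train = cdist(embedding.coords[t : t + 1], train_coords)[0]
        n = len(train_ids) + 1
        full = np.zeros((n, n))
        full[:-1, :-1] = base
        full[-1, :-1] = d_to_train
        full[:-1, -1] = d_to_train
        D = DistanceMatrix(tuple(train_ids) + (item,), full)
        tc = verify_compact_sets(build_kruskal_tree(D), D)
        out.append(_vote(item, tc.sets_containing(item), train_label))
    return out


def cs_predict(embedding: LabeledEmbedding, per_item: bool = False) -> PredictionResult:
    """Compact-set predictions; items outside any voting set stay UNPREDICTED.

    By default all test points are embedded jointly with the training
    points and compact sets are enumerated once; ``per_item=True``
    instead embeds each test point alone with the training set.
    """
    if len(embedding.train_indices) < 2:
        raise ValueError("compact-set prediction needs at least 2 training items")
    preds = (
        _cs_predict_per_item(embedding) if per_item else _cs_predict_joint(embedding)
    )
    return PredictionResult(preds)


def nn_predict(embedding: LabeledEmbedding, k: int = 1) -> PredictionResult:
    """k-nearest-neighbour prediction (default and recommended k = 1).

    Distance ties are broken by the smallest training-item index; for
    k > 1 the majority label among the k nearest wins, ties resolved in
    favour of the nearest tied label.
    """
    tr = embedding.train_indices
    if len(tr) < 1:
        raise ValueError("nearest-neighbour prediction needs a training item")
    if k < 1 or k > len(tr):
        raise ValueError(f"k must lie in [1, {len(tr)}]")
    train_coords = embedding.coords[tr]
    te = embedding.test_indices
    out: list[Prediction] = []
    if len(te) == 0:
        return PredictionResult(out)
    dists = cdist(embedding.coords[te], train_coords)
    for row, t in enumerate(te):
        order = np.lexsort((np.arange(len(tr)), dists[row]))  # stable in index
        if k == 1:
            j = order[0]
        else:
            top = order[:k]
            votes = Counter(embedding.labels[tr[j]] for j in top)
            best = max(votes.values())
            tied = {lbl for lbl, cnt in votes.items() if cnt == best}
            j = next(jj for jj in top if embedding.labels[tr[jj]] in tied)
        nb = tr[j]
        out.append(
            Prediction(
                embedding.ids[t],
                embedding.labels[nb],
                NN,
                (embedding.ids[nb], float(dists[row, j])),
            )
        )
    return PredictionResult(out)


def predict_cs_plus_nn(
    embedding: LabeledEmbedding, per_item: bool = False, k: int = 1
) -> PredictionResult:
    """Compact sets first; 1-NN for whatever they leave unpredicted."""
    cs = cs_predict(embedding, per_item=per_item)
    nn = nn_predict(embedding, k=k)
    merged = []
    for p_cs, p_nn in zip(cs.predictions, nn.predictions):
        merged.append(p_cs if p_cs.label is not UNPREDICTED else p_nn)
    return PredictionResult(merged)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(predictions: PredictionResult, truth: dict[str, str]) -> EvalReport:
    """Score predictions against known labels.

    UNPREDICTED items count toward the false negatives of their true
    class only.  Per-class precision = TP/(TP+FP), recall = TP/(TP+FN);
    pooled accuracy = sum TP / N.
    """
    classes = set(truth.values())
    for p in predictions:
        if p.item_id not in truth:
            raise ValueError(f"prediction for unknown item {p.item_id!r}")
        if p.label is not None:
            classes.add(p.label)
    counts = {c: ClassMetrics(0, 0, 0) for c in sorted(classes)}
    n_predicted = 0
    for p in predictions:
        true = truth[p.item_id]
        if p.label is UNPREDICTED:
            counts[true].fn += 1
            continue
        n_predicted += 1
        if p.label == true:
            counts[true].tp += 1
        else:
            counts[p.label].fp += 1
            counts[true].fn += 1
    return EvalReport(per_class=counts, n=len(predictions), n_predicted=n_predicted)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """Pooled five-fold (by default) cross-validation outcome.

    ``combined`` scores the full CS+1-NN predictor; ``cs_only`` scores
    the compact-set tier alone (unpredicted items depress its recall,
    never its precision).
    """

    combined: EvalReport
    cs_only: EvalReport
    fold_reports: list[EvalReport]
    fold_of: np.ndarray
    predictions: PredictionResult
    cs_predictions: PredictionResult
    # per fold: (test item ids, their coordinates in that fold's space)
    fold_test_coords: list[tuple[list[str], np.ndarray]]


def make_folds(
    n: int,
    folds: int,
    seed: int | None = 0,
    labels: Sequence[str] | None = None,
    stratified: bool = False,
) -> np.ndarray:
    """Fold index per item: a seeded uniform random partition.

    The default is the plain unstratified split of a random permutation
    into near-equal parts; ``stratified=True`` deals each class
    round-robin instead.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError("more folds than items")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratified:
        if labels is None:
            raise ValueError("stratified folds require labels")
        labels_arr = np.asarray(labels)
        start = 0
        for cls in sorted(set(labels_arr)):
            idx = np.flatnonzero(labels_arr == cls)
            idx = rng.permutation(idx)
            for pos, i in enumerate(idx):
                fold_of[i] = (start + pos) % folds
            start += len(idx)
    else:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            fold_of[chunk] = f
    return fold_of


def cross_validate(
    features,
    labels: Sequence[str],
    ids: Sequence[str] | None = None,
    folds: int = 5,
    seed: int | None = 0,
    reduce: str | None = "ca",
    ca_threshold: float = 0.95,
    per_item: bool = False,
    k: int = 1,
    stratified: bool = False,
) -> CrossValResult:
    """Five-fold (by default) cross-validated CS+1-NN evaluation.

    ``features`` is either a raw coordinate array (``reduce=None``) or a
    count-like feature table (``reduce='ca'``), in which case CA is
    refitted on the training rows of every fold and the test rows are
    projected as supplementary points, so no test information leaks into
    the coordinate system.  Confusion counts are pooled over folds.
    """
    from .sequence_features import FeatureMatrix

    if isinstance(features, FeatureMatrix):
        X = features.values
        if ids is None:
            ids = features.row_ids
    else:
        X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if ids is None:
        ids = [f"item{i}" for i in range(n)]
    ids = list(ids)
    labels = list(labels)
    if len(labels) != n or len(ids) != n:
        raise ValueError("features, labels and ids must have equal length")
    smallest = min(Counter(labels).values())
    if smallest < folds:
        warnings.warn(
            f"a class has only {smallest} items for {folds} folds; "
            "some folds will lack it",
            stacklevel=2,
        )
    fold_of = make_folds(n, folds, seed=seed, labels=labels, stratified=stratified)
    truth = dict(zip(ids, labels))

    all_combined: list[Prediction] = []
    all_cs: list[Prediction] = []
    fold_reports: list[EvalReport] = []
    fold_test_coords: list[tuple[list[str], np.ndarray]] = []
    for f in range(folds):
        test_mask = fold_of == f
        tr = np.flatnonzero(~test_mask)
        te = np.flatnonzero(test_mask)
        if reduce == "ca":
            col_ids_all = (
                features.col_ids
                if isinstance(features, FeatureMatrix)
                else [f"col{j}" for j in range(X.shape[1])]
            )
            model = fit_ca(
                X[tr],
                row_ids=[ids[i] for i in tr],
                col_ids=col_ids_all,
                threshold=ca_threshold,
            )
            col_pos = {cid: j for j, cid in enumerate(col_ids_all)}
            keep = [col_pos[cid] for cid in model.col_ids]
            train_coords = model.F[:, : model.k]
            test_coords = project_supplementary_rows(
                model, X[np.ix_(te, keep)], row_ids=[ids[i] for i in te]
            )
        elif reduce in (None, "none"):
            train_coords = X[tr]
            test_coords = X[te]
        else:
            raise ValueError(f"unknown reduction {reduce!r}")
        emb = LabeledEmbedding.from_split(
            [ids[i] for i in tr],
            train_coords,
            [labels[i] for i in tr],
            [ids[i] for i in te],
            test_coords,
        )
        fold_test_coords.append(([ids[i] for i in te], np.atleast_2d(test_coords)))
        cs = cs_predict(emb, per_item=per_item)
        combined = predict_cs_plus_nn(emb, per_item=per_item, k=k)
        all_cs.extend(cs.predictions)
        all_combined.extend(combined.predictions)
        fold_reports.append(
            evaluate(combined, {ids[i]: labels[i] for i in te})
        )

    combined_res = PredictionResult(all_combined)
    cs_res = PredictionResult(all_cs)
    return CrossValResult(
        combined=evaluate(combined_res, truth),
        cs_only=evaluate(cs_res, truth),
        fold_reports=fold_reports,
        fold_of=fold_of,
        predictions=combined_res,
        cs_predictions=cs_res,
        fold_test_coords=fold_test_coords,
    )
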