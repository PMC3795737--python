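"""End-to-end orchestration: features -> CA -> compact sets -> CS+1-NN.

The pipeline consumes a FASTA file with a tab-separated label table and
either a directory of precomputed PSI-BLAST ASCII profiles (one
``<id>.pssm`` per protein) or no profiles at all, in which case the
smoothed one-hot ("pseudo") probability transform is used.  Profile
generation itself is deliberately decoupled: an optional subcommand can
shell out to PSI-BLAST, but nothing in the pipeline requires it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import classifier, compact_sets, correspondence_analysis, sequence_features
from .classifier import CrossValResult, LabeledEmbedding, PredictionResult
from .sequence_features import DEFAULT_GMAX, FeatureMatrix

log = logging.getLogger("cspred")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults follow the published protocol where stated
    (five folds, 95% CA variance, k = 1)."""

    mode: str = "pseudo"            # pssm-dir | pseudo
    gmax: int = DEFAULT_GMAX
    transform: str = "sigmoid"      # probability transform for PSSM input
    smoothing: float = 0.2          # pseudo-mode smoothing mass
    ca_threshold: float = 0.95
    folds: int = 5
    seed: int = 0
    knn_k: int = 1
    per_item: bool = False
    stratified: bool = False
    outdir: str = "cspred_out"

    def __post_init__(self) -> None:
        if self.mode not in ("pseudo", "pssm-dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 < self.ca_threshold <= 1:
            raise ValueError("ca_threshold must lie in (0, 1]")


def read_labels(path: Union[str, Path]) -> dict[str, str]:
    """Two-column TSV (id, label); an ``id\tlabel`` header line is allowed."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        if lineno == 1 and parts == ["id", "label"]:
            continue
        if parts[0] in table:
            raise ValueError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
        table[parts[0]] = parts[1]
    if not table:
        raise ValueError(f"no labels found in {path}")
    return table


def write_labels(labels: dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for k, v in labels.items():
            fh.write(f"{k}\t{v}\n")


def _load_inputs(config: RunConfig, fasta: Union[str, Path], pssm_dir=None):
    records = sequence_features.read_fasta(fasta)
    if config.mode == "pssm-dir":
        if pssm_dir is None:
            raise ValueError("mode 'pssm-dir' requires a profile directory")
        items = []
        for rec in records:
            path = Path(pssm_dir) / f"{rec.id}.pssm"
            if not path.exists():
                raise FileNotFoundError(f"missing PSSM profile for {rec.id!r}: {path}")
            prof = sequence_features.parse_pssm_ascii(path, protein_id=rec.id)
            if prof.length != len(rec.sequence):
                raise ValueError(
                    f"profile length {prof.length} != sequence length "
                    f"{len(rec.sequence)} for {rec.id!r}"
                )
            items.append(prof)
        transform = config.transform
    else:
        items = records
        transform = "pseudo"
    return records, items, transform


def build_features(
    config: RunConfig, fasta: Union[str, Path], pssm_dir=None
) -> FeatureMatrix:
    """Stage 1–2: read sequences (and profiles) and weight gapped-dipeptides."""
    t0 = time.perf_counter()
    records, items, transform = _load_inputs(config, fasta, pssm_dir)
    fm = sequence_features.build_feature_matrix(
        items, mode=transform, gmax=config.gmax, smoothing=config.smoothing
    )
    log.info(
        "features: %d proteins x %d gapped-dipeptides (%s mode) in %.2fs",
        fm.shape[0], fm.shape[1], transform, time.perf_counter() - t0,
    )
    return fm


def run_crossval(
    config: RunConfig,
    fasta: Union[str, Path],
    labels_path: Union[str, Path],
    pssm_dir: Union[str, Path, None] = None,
) -> CrossValResult:
    """Cross-validated evaluation; writes all artifacts under ``config.outdir``.

    Artifacts: the feature matrix, per-fold test coordinates, the
    compact-set listing of the full training embedding, per-item
    predictions with method provenance, and per-class/pooled reports.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels_map = read_labels(labels_path)
    fm = build_features(config, fasta, pssm_dir)
    missing = [rid for rid in fm.row_ids if rid not in labels_map]
    if missing:
        raise ValueError(f"missing labels for proteins: {missing}")
    labels = [labels_map[rid] for rid in fm.row_ids]

    fm.write_tsv(outdir / "features.tsv")
    t0 = time.perf_counter()
    result = classifier.cross_validate(
        fm,
        labels,
        folds=config.folds,
        seed=config.seed,
        reduce="ca",
        ca_threshold=config.ca_threshold,
        per_item=config.per_item,
        k=config.knn_k,
        stratified=config.stratified,
    )
    log.info("cross-validation (%d folds) in %.2fs", config.folds, time.perf_counter() - t0)

    truth = dict(zip(fm.row_ids, labels))
    result.predictions.write_tsv(outdir / "predictions.tsv", truth)
    result.cs_predictions.write_tsv(outdir / "cs_predictions.tsv", truth)
    result.combined.write_tsv(outdir / "report.tsv")
    result.combined.write_json(outdir / "report.json")
    result.cs_only.write_tsv(outdir / "cs_report.tsv")
    pd.DataFrame({"item": fm.row_ids, "fold": result.fold_of}).to_csv(
        outdir / "folds.tsv", sep="\t", index=False
    )
    for f, (test_ids, coords) in enumerate(result.fold_test_coords):
        axes = [f"axis{i + 1}" for i in range(coords.shape[1])]
        pd.DataFrame(coords, index=test_ids, columns=axes).to_csv(
            outdir / f"fold{f}_test_coordinates.tsv", sep="\t", index_label="id"
        )

    # reference artifacts on the full data: CA coordinates + compact sets
    model = correspondence_analysis.fit_ca(
        fm.values, row_ids=fm.row_ids, col_ids=fm.col_ids, threshold=config.ca_threshold
    )
    model.write_coordinates(outdir / "row_coordinates.tsv", outdir / "col_coordinates.tsv")
    D = compact_sets.DistanceMatrix.from_points(model.F[:, : model.k], fm.row_ids)
    tc = compact_sets.verify_compact_sets(compact_sets.build_kruskal_tree(D), D)
    compact_sets.write_compact_sets_tsv(tc, outdir / "compact_sets.tsv")
    (outdir / "compact_tree.nwk").write_text(
        compact_sets.compact_tree_to_newick(tc) + "\n"
    )
    log.info(
        "overall accuracy %.4f (CS precision %.4f, CS recall %.4f)",
        result.combined.accuracy, result.cs_only.precision, result.cs_only.recall,
    )
    return result


def run_predict(
    config: RunConfig,
    train_fasta: Union[str, Path],
    labels_path: Union[str, Path],
    test_fasta: Union[str, Path],
    pssm_dir: Union[str, Path, None] = None,
    test_pssm_dir: Union[str, Path, None] = None,
) -> PredictionResult:
    """Train on one set, predict another; writes ``predictions.tsv``.

    CA is fitted on the training proteins only; test proteins are
    projected as supplementary rows, then classified by CS+1-NN.  An
    empty test file yields an empty (but valid) predictions table.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels_map = read_labels(labels_path)
    fm = build_features(config, train_fasta, pssm_dir)
    missing = [rid for rid in fm.row_ids if rid not in labels_map]
    if missing:
        raise ValueError(f"missing labels for proteins: {missing}")
    labels = [labels_map[rid] for rid in fm.row_ids]

    try:
        test_records, test_items, transform = _load_inputs(
            config, test_fasta, test_pssm_dir or pssm_dir
        )
    except ValueError as exc:
        if "no FASTA records" in str(exc):
            empty = PredictionResult([])
            empty.write_tsv(outdir / "predictions.tsv")
            log.info("empty test set; wrote empty predictions table")
            return empty
        raise

    model = correspondence_analysis.fit_ca(
        fm.values, row_ids=fm.row_ids, col_ids=fm.col_ids, threshold=config.ca_threshold
    )
    col_pos = {cid: j for j, cid in enumerate(fm.col_ids)}
    keep = [col_pos[cid] for cid in model.col_ids]

    test_vectors = []
    test_ids = []
    for item in test_items:
        rid = item.protein_id if hasattr(item, "protein_id") else item.id
        q = sequence_features.position_probabilities(
            item, mode=transform, smoothing=config.smoothing
        )
        vec = sequence_features.tfpssm_vector(q, gmax=config.gmax)
        if vec.sum() == 0:
            raise ValueError(f"test protein {rid!r} yields an all-zero feature vector")
        test_vectors.append(vec[keep])
        test_ids.append(rid)
    test_coords = correspondence_analysis.project_supplementary_rows(
        model, np.vstack(test_vectors), row_ids=test_ids
    )

    emb = LabeledEmbedding.from_split(
        fm.row_ids, model.F[:, : model.k], labels, test_ids, test_coords
    )
    result = classifier.predict_cs_plus_nn(
        emb, per_item=config.per_item, k=config.knn_k
    )
    result.write_tsv(outdir / "predictions.tsv")
    counts = result.method_counts()
    log.info(
        "predicted %d test proteins (CS %d, 1NN %d)",
        len(result), counts.get("CS", 0), counts.get("1NN", 0),
    )
    return result
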