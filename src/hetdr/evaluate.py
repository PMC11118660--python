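"""Evaluation protocols and metrics.

Two protocols are implemented:

* random masking — labeled drug-cell pairs are partitioned into k folds;
  each fold is hidden from the graph, the model is retrained, and the hidden
  pairs are scored (imputation of randomly masked responses);
* leave-one-out — every labeled pair of a held-out drug (or cell line) is
  hidden and scored after retraining, simulating cold-start prediction for
  an entity with no observed responses; targets with too few or too
  imbalanced labels are screened out first.

AUROC is the Mann-Whitney probability that a random positive outscores a
random negative (ties half credit); AUPR is average precision (the step-wise
precision-recall integral). Both are delegated to scikit-learn, which follows
exactly these conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import MaskMatrix, assemble_graph
from .model import ModelConfig, TrainResult, train_model

__all__ = [
    "FoldPlan",
    "LeaveOutPlan",
    "MetricReport",
    "EvalInputs",
    "labeled_pairs",
    "split_folds_test1",
    "filter_targets_test2",
    "compute_metrics",
    "run_test1",
    "run_test2",
]


def labeled_pairs(labels: pd.DataFrame) -> list[tuple[int, int, float]]:
    """All (drug_idx, cell_idx, label) triples with a 0/1 label, row-major."""
    lab = labels.to_numpy(dtype=float)
    d, c = np.nonzero(np.isfinite(lab))
    return [(int(i), int(j), float(lab[i, j])) for i, j in zip(d, c)]


@dataclass
class FoldPlan:
    """Partition of labeled pairs into k near-equal folds."""

    folds: list[list[tuple[int, int, float]]]
    k: int
    seed: int

    def validate(self) -> None:
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")
        seen = set()
        for f in self.folds:
            for d, c, _ in f:
                if (d, c) in seen:
                    raise ValueError(f"pair ({d},{c}) appears in multiple folds")
                seen.add((d, c))


@dataclass
class LeaveOutPlan:
    """Eligible cold-start targets with their train/test pair splits."""

    target_kind: str  # 'drug' or 'cell'
    eligible_targets: list[str]
    splits: dict[str, tuple[list, list]] = field(default_factory=dict)


@dataclass
class MetricReport:
    """Per-fold or per-target AUROC/AUPR with mean and sd aggregates."""

    rows: pd.DataFrame  # columns: unit, auroc, aupr, n_pos, n_neg
    protocol: str

    @property
    def mean_auroc(self) -> float:
        return float(self.rows["auroc"].mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.rows["auroc"].std(ddof=1)) if len(self.rows) > 1 else 0.0

    @property
    def mean_aupr(self) -> float:
        return float(self.rows["aupr"].mean())

    @property
    def sd_aupr(self) -> float:
        return float(self.rows["aupr"].std(ddof=1)) if len(self.rows) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "protocol": self.protocol,
            "n_units": int(len(self.rows)),
            "auroc_mean": self.mean_auroc,
            "auroc_sd": self.sd_auroc,
            "aupr_mean": self.mean_aupr,
            "aupr_sd": self.sd_aupr,
        }


@dataclass
class EvalInputs:
    """Everything the training/evaluation loop needs, pre-assembled."""

    labels: pd.DataFrame  # drugs x cells, {0, 1, NaN}
    acg: np.ndarray
    adg: np.ndarray
    Sd: np.ndarray
    Sc: np.ndarray
    Sg: np.ndarray
    gene_ids: list[str]


def split_folds_test1(labels: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded shuffle of labeled pairs into k folds of near-equal size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pairs = labeled_pairs(labels)
    if len(pairs) < k:
        raise ValueError(f"need at least k={k} labeled pairs, have {len(pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(pairs[idx])
    plan = FoldPlan(folds=folds, k=k, seed=seed)
    plan.validate()
    return plan


def filter_targets_test2(
    labels: pd.DataFrame,
    target_kind: str = "drug",
    min_entries: int = 10,
    min_class_fraction: float = 0.02,
) -> LeaveOutPlan:
    """Screen cold-start targets: keep a drug/cell only if it has at least
    ``min_entries`` labeled pairs and each class makes up at least
    ``min_class_fraction`` of them."""
    if target_kind not in ("drug", "cell"):
        raise ValueError("target_kind must be 'drug' or 'cell'")
    lab = labels.to_numpy(dtype=float)
    if target_kind == "cell":
        lab = lab.T
        ids = list(labels.columns)
    else:
        ids = list(labels.index)
    all_pairs = labeled_pairs(labels)
    eligible, splits = [], {}
    for i, tid in enumerate(ids):
        row = lab[i]
        finite = np.isfinite(row)
        n = int(finite.sum())
        if n < min_entries:
            continue
        n_pos = int((row[finite] == 1.0).sum())
        n_neg = n - n_pos
        if n_pos < min_class_fraction * n or n_neg < min_class_fraction * n:
            continue
        eligible.append(tid)
        if target_kind == "drug":
            test = [(d, c, y) for d, c, y in all_pairs if d == i]
        else:
            test = [(d, c, y) for d, c, y in all_pairs if c == i]
        test_set = {(d, c) for d, c, _ in test}
        train = [p for p in all_pairs if (p[0], p[1]) not in test_set]
        splits[tid] = (train, test)
    if not eligible:
        warnings.warn("no eligible cold-start targets after screening", stacklevel=2)
    return LeaveOutPlan(target_kind=target_kind, eligible_targets=eligible, splits=splits)


def compute_metrics(y, scores, unit: str = "") -> dict:
    """AUROC and AUPR for one evaluation unit; raises on single-class input."""
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"unit {unit!r}: both classes required for AUROC/AUPR")
    return {
        "unit": unit,
        "auroc": float(roc_auc_score(y, scores)),
        "aupr": float(average_precision_score(y, scores)),
        "n_pos": n_pos,
        "n_neg": n_neg,
    }


def _train_and_score(
    inputs: EvalInputs,
    train: list[tuple[int, int, float]],
    test: list[tuple[int, int, float]],
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray, TrainResult]:
    """Hide the test pairs, retrain from scratch, score the hidden pairs."""
    n, m = inputs.labels.shape
    mask = MaskMatrix.all_visible(n, m).hiding([(d, c) for d, c, _ in test])
    graph = assemble_graph(
        inputs.labels, inputs.acg, inputs.adg, mask=mask, gene_ids=inputs.gene_ids
    )
    result = train_model(
        graph,
        inputs.Sd,
        inputs.Sc,
        inputs.Sg,
        [(d, c) for d, c, _ in train],
        [y for _, _, y in train],
        config,
    )
    from .autodiff import Tensor

    scores = result.model.predict_pairs(
        Tensor(result.embeddings), [(d, c) for d, c, _ in test]
    )
    y_true = np.array([y for _, _, y in test])
    return y_true, scores.data.copy(), result


def run_test1(
    inputs: EvalInputs, config: ModelConfig, k: int = 5, seed: int = 0
) -> MetricReport:
    """k-fold random-mask evaluation: reconstruct hidden response labels."""
    plan = split_folds_test1(inputs.labels, k=k, seed=seed)
    all_pairs = labeled_pairs(inputs.labels)
    rows = []
    for f, test in enumerate(plan.folds):
        test_set = {(d, c) for d, c, _ in test}
        train = [p for p in all_pairs if (p[0], p[1]) not in test_set]
        y_true, scores, _ = _train_and_score(inputs, train, test, config)
        try:
            rows.append(compute_metrics(y_true, scores, unit=f"fold{f}"))
        except ValueError as err:
            warnings.warn(str(err), stacklevel=2)
    return MetricReport(rows=pd.DataFrame(rows), protocol="test1")


def run_test2(
    inputs: EvalInputs,
    config: ModelConfig,
    target_kind: str = "drug",
    min_entries: int = 10,
    min_class_fraction: float = 0.02,
    max_targets: int | None = None,
    seed: int = 0,
) -> MetricReport:
    """Leave-one-out cold-start evaluation over eligible drugs or cells.

    The leave-out plan itself is deterministic (every eligible target is
    held out in id order); ``seed`` is accepted for interface symmetry with
    the random-mask protocol and is unused here.
    """
    plan = filter_targets_test2(
        inputs.labels, target_kind, min_entries, min_class_fraction
    )
    targets = plan.eligible_targets
    if max_targets is not None:
        targets = targets[:max_targets]
    rows = []
    for tid in targets:
        train, test = plan.splits[tid]
        y_true, scores, _ = _train_and_score(inputs, train, test, config)
        try:
            rows.append(compute_metrics(y_true, scores, unit=tid))
        except ValueError as err:
            warnings.warn(str(err), stacklevel=2)
    return MetricReport(rows=pd.DataFrame(rows), protocol=f"test2-{target_kind}")
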