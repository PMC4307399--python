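"""Metrics, cross-validation, window-size scan and resampling protocol.

Peptide-level classification is summarized by sensitivity Sn = TP/(TP+FN),
precision P = TP/(TP+FP), their harmonic mean F, accuracy Acc and the area
under the ROC curve (threshold-free).  Model quality is estimated three
ways:

* stratified 10-fold cross-validation (catalog selection and regression fit
  on the training folds only, by default);
* a self-consistency test (train and evaluate on the same data) whose
  closeness to the CV result is the usual reliability heuristic when
  choosing the sliding-window size;
* a repeated balanced-resampling experiment: because experimentally
  reported non-epitopes are noisy (some may truly be epitopes), many trials
  are run, each pairing the full positive set with a fresh random
  equal-size negative subset, and the mean with a 95% CI is reported
  instead of any single trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .datasets import PeptideDataset, sample_balanced_subset
from .features import PairCatalog, select_top_pairs
from .model import fit, score_dataset
from .scales import PropensityScale, get_scale

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "TrialSummary",
    "confusion_metrics",
    "roc_auc",
    "kfold_cv",
    "self_consistency",
    "window_size_scan",
    "resampling_experiment",
]

METRIC_NAMES = ("sn", "p", "f", "acc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sn, P, F, Acc (fractions in [0, 1]) plus AUC and raw counts."""

    sn: float
    p: float
    f: float
    acc: float
    auc: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {"sn": self.sn, "p": self.p, "f": self.f, "acc": self.acc,
                "auc": self.auc if self.auc is not None else float("nan")}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator computing %s; reporting 0", what)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Sn, P, F and Acc from a confusion table (AUC left unset)."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    sn = _safe_div(counts.tp, counts.tp + counts.fn, "Sn")
    p = _safe_div(counts.tp, counts.tp + counts.fp, "P")
    f = _safe_div(2 * p * sn, p + sn, "F")
    acc = counts.tp + counts.tn
    return MetricSet(sn, p, f, acc / counts.total, None, counts)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray]:
    """AUC and ROC points by threshold sweep over all distinct scores.

    Trapezoidal integration with standard tie handling, so the AUC equals
    the Mann–Whitney statistic P(score_pos > score_neg) + 0.5 * P(tie).
    Returns (auc, curve) with curve rows (FPR, TPR).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.min() == labels.max():
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def _metrics_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> MetricSet:
    pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
    )
    m = confusion_metrics(counts)
    auc, _ = roc_auc(scores, labels)
    return replace(m, auc=auc)


@dataclass
class EvalConfig:
    """Shared knobs for all evaluation entry points."""

    top_k: int = 500
    threshold: float = 0.5
    hydro: PropensityScale = field(default_factory=lambda: get_scale("parker"))
    mass: PropensityScale = field(default_factory=lambda: get_scale("side_chain_mass"))
    fold_aggregation: str = "pooled"  # or "mean"
    refit_catalog: bool = True


def _train_score_fold(
    train: PeptideDataset,
    test: PeptideDataset,
    n: int,
    cfg: EvalConfig,
    catalog: PairCatalog | None,
) -> pd.DataFrame:
    cat = catalog if catalog is not None else select_top_pairs(train, n, cfg.top_k)
    model = fit(train, n, cfg.hydro, cfg.mass, cat)
    return score_dataset(model, test, cfg.threshold)


def kfold_cv(
    dataset: PeptideDataset,
    n: int,
    k: int = 10,
    seed: int = 0,
    config: EvalConfig | None = None,
    return_details: bool = False,
):
    """Stratified k-fold cross-validation at window size n.

    The dataset is partitioned into k stratified folds (seeded shuffle);
    each fold is scored by a model whose pair catalog (unless
    ``config.refit_catalog`` is False) and coefficients are derived from the
    other k-1 folds only.  With the default pooled aggregation, held-out
    scores from all folds are combined into a single confusion table and
    AUC; ``fold_aggregation="mean"`` instead averages per-fold metrics.
    """
    cfg = config or EvalConfig()
    labels = dataset.labels
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class must have >= k={k} records (have {n_pos}/{n_neg})")

    global_catalog = None if cfg.refit_catalog else select_top_pairs(dataset, n, cfg.top_k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_frames = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(dataset)), labels)):
        scored = _train_score_fold(
            dataset.subset(tr), dataset.subset(te), n, cfg, global_catalog
        )
        scored["fold"] = fold
        fold_frames.append(scored)
    pooled = pd.concat(fold_frames, ignore_index=True)

    if cfg.fold_aggregation == "pooled":
        metrics = _metrics_from_scores(
            pooled.score.to_numpy(), pooled.label.to_numpy(), cfg.threshold
        )
        return (metrics, pooled) if return_details else metrics
    if cfg.fold_aggregation == "mean":
        per_fold = [
            _metrics_from_scores(g.score.to_numpy(), g.label.to_numpy(), cfg.threshold)
            for _, g in pooled.groupby("fold")
        ]
        counts = ConfusionCounts(
            tp=sum(m.counts.tp for m in per_fold),
            tn=sum(m.counts.tn for m in per_fold),
            fp=sum(m.counts.fp for m in per_fold),
            fn=sum(m.counts.fn for m in per_fold),
        )
        metrics = MetricSet(
            sn=float(np.mean([m.sn for m in per_fold])),
            p=float(np.mean([m.p for m in per_fold])),
            f=float(np.mean([m.f for m in per_fold])),
            acc=float(np.mean([m.acc for m in per_fold])),
            auc=float(np.mean([m.auc for m in per_fold])),
            counts=counts,
        )
        return (metrics, pooled) if return_details else metrics
    raise ValueError(f"unknown fold_aggregation {cfg.fold_aggregation!r}")


def self_consistency(
    dataset: PeptideDataset, n: int, config: EvalConfig | None = None
) -> MetricSet:
    """Train on the full dataset and evaluate on the same dataset."""
    cfg = config or EvalConfig()
    scored = _train_score_fold(dataset, dataset, n, cfg, None)
    return _metrics_from_scores(scored.score.to_numpy(), scored.label.to_numpy(), cfg.threshold)


def window_size_scan(
    dataset: PeptideDataset,
    sizes: Iterable[int] = range(5, 20),
    k: int = 10,
    seed: int = 0,
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """F-measure of CV and self-consistency across window sizes.

    Sizes exceeding the peptide length are skipped with a warning.  The row
    with the highest cross-validated F is flagged ``best=True``; closeness
    of f_cv and f_self at that size is the usual reliability check.
    """
    cfg = config or EvalConfig()
    pep_len = dataset.peptide_length
    rows = []
    for n in sizes:
        if n > pep_len:
            logger.warning("window size %d > peptide length %d; skipped", n, pep_len)
            continue
        m_cv = kfold_cv(dataset, n, k=k, seed=seed, config=cfg)
        m_self = self_consistency(dataset, n, config=cfg)
        rows.append((n, m_cv.f, m_self.f, m_cv.auc))
    df = pd.DataFrame(rows, columns=["n", "f_cv", "f_self", "auc_cv"])
    df["best"] = False
    if len(df):
        df.loc[df.f_cv.idxmax(), "best"] = True
    return df


@dataclass
class TrialSummary:
    """Per-trial metrics of a resampling experiment plus aggregates."""

    per_trial: list[MetricSet]
    seeds: list[int]
    best: MetricSet  # trial with max F
    worst: MetricSet  # trial with min F
    mean: dict[str, float]
    ci_halfwidth: dict[str, float]  # 1.96 * sd / sqrt(trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, (m, s) in enumerate(zip(self.per_trial, self.seeds)):
            rows.append(
                (t, s, m.counts.tp, m.counts.tn, m.counts.fp, m.counts.fn,
                 m.sn, m.p, m.f, m.acc, m.auc)
            )
        return pd.DataFrame(
            rows,
            columns=["trial", "seed", "TP", "TN", "FP", "FN", "Sn", "P", "F", "Acc", "AUC"],
        )


def resampling_experiment(
    positives: PeptideDataset,
    negatives: PeptideDataset,
    n: int,
    trials: int = 300,
    k: int = 10,
    master_seed: int = 0,
    config: EvalConfig | None = None,
) -> TrialSummary:
    """Repeated balanced-negative resampling with k-fold CV per trial.

    Trial t (seed = master_seed + t) pairs all positives with a fresh
    equal-size random negative subset and runs :func:`kfold_cv`.  Trials are
    summarized by the best and worst F, and per-metric means with 95%
    normal-approximation CIs — the spread across trials is the observable
    footprint of label noise in the negative pool.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    cfg = config or EvalConfig()
    per_trial, seeds = [], []
    for t in range(trials):
        seed_t = master_seed + t
        subset = sample_balanced_subset(positives, negatives, seed_t)
        m = kfold_cv(subset, n, k=k, seed=seed_t, config=cfg)
        per_trial.append(m)
        seeds.append(seed_t)
        logger.info("trial %d (seed %d): F=%.4f AUC=%.4f", t, seed_t, m.f, m.auc)

    fs = [m.f for m in per_trial]
    best = per_trial[int(np.argmax(fs))]
    worst = per_trial[int(np.argmin(fs))]
    mean, ci = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([m.as_dict()[name] for m in per_trial])
        mean[name] = float(vals.mean())
        sd = float(vals.std(ddof=1)) if trials > 1 else 0.0
        ci[name] = 1.96 * sd / np.sqrt(trials)
    return TrialSummary(per_trial, seeds, best, worst, mean, ci)
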