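"""Dataset splitting, metrics, repeated cross-validation, ablation and
external validation.

Splitting follows a 7:2:1 train/validation/test ratio with largest-remainder
rounding so the subset sizes always sum to n (a 5140-compound dataset gives
3598/1028/514).  Cross-validation is stratified 5-fold with each fold
trained independently `repeats` times from fresh seeds, reported as
mean ± SD per fold and pooled over all runs.  AUC is the Mann–Whitney rank
statistic with midrank handling of ties.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .config import TrainingConfig
from .featurize import (
    FEATURE_COLUMNS,
    MoleculeRecord,
    drop_feature_columns,
    featurize_dataset,
)
from .model import HazChemNet

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios plus stratification flag and seed."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("all split ratios must be positive")
        if not math.isclose(sum(self.ratios), 1.0, abs_tol=1e-9):
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    quotas = [n * r for r in ratios]
    sizes = [int(math.floor(q)) for q in quotas]
    remainders = sorted(range(len(ratios)),
                        key=lambda i: (quotas[i] - sizes[i], -i), reverse=True)
    for i in range(n - sum(sizes)):
        sizes[remainders[i]] += 1
    return sizes


def split_dataset(
    labels: np.ndarray | list | int,
    spec: SplitSpec = SplitSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition indices 0..n−1 into train/val/test index arrays.

    `labels` is either the per-record label vector (enables stratification)
    or a bare record count.  Subset sizes are the largest-remainder rounding
    of n·ratio; stratified splits allocate per class the same way and then
    move single records between subsets to restore the exact global sizes.
    """
    if isinstance(labels, (int, np.integer)):
        n = int(labels)
        y = None
    else:
        y = np.asarray(labels)
        n = y.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    targets = _largest_remainder(n, spec.ratios)
    rng = np.random.default_rng(spec.seed)
    if y is None or not spec.stratified:
        order = rng.permutation(n)
        bounds = np.cumsum(targets)[:-1]
        parts = np.split(order, bounds)
    else:
        parts = [[], [], []]
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            sizes = _largest_remainder(idx.size, spec.ratios)
            start = 0
            for s, size in enumerate(sizes):
                parts[s].extend(idx[start:start + size])
                start += size
        parts = [np.array(p, dtype=np.int64) for p in parts]
        # per-class rounding can drift ±1 from the global targets; rebalance
        for _ in range(3 * len(parts)):
            diffs = [len(p) - t for p, t in zip(parts, targets)]
            if all(d == 0 for d in diffs):
                break
            src = int(np.argmax(diffs))
            dst = int(np.argmin(diffs))
            parts[dst] = np.append(parts[dst], parts[src][-1])
            parts[src] = parts[src][:-1]
    train, val, test = (np.sort(np.asarray(p, dtype=np.int64)) for p in parts)
    return train, val, test


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Accuracy/precision/recall/F1/AUC plus confusion counts.

    Metrics that are undefined for the given labels (e.g. recall with no
    actual positives) are NaN and listed in `undefined` — never silent 0.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: ConfusionCounts
    n_runs: int = 1
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def auc_mann_whitney(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """ROC AUC via the Mann–Whitney U statistic (midranks for ties)."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(y_prob)
    u = np.sum(ranks[y_true == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics_from_confusion(c: ConfusionCounts,
                           auc: float = float("nan"),
                           auc_undefined: bool = True) -> MetricsReport:
    """Accuracy = (TP+TN)/total, Precision = TP/(TP+FP), Recall = TP/(TP+FN),
    F1 = 2PR/(P+R)."""
    undefined: list[str] = []
    accuracy = (c.tp + c.tn) / c.total if c.total else float("nan")
    if c.total == 0:
        undefined.append("accuracy")
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = float("nan")
        undefined.append("precision")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = float("nan")
        undefined.append("recall")
    if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
        undefined.append("f1")
    if auc_undefined and not np.isfinite(auc):
        undefined.append("auc")
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, auc=auc, confusion=c,
                         undefined=tuple(undefined))


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Threshold probabilities (ties → positive) and score against labels."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_prob.shape}")
    if not np.all(np.isin(y_true, (0, 1))):
        raise ValueError("y_true must be binary 0/1")
    y_pred = (y_prob >= threshold).astype(np.int64)
    c = confusion_counts(y_true, y_pred)
    auc = auc_mann_whitney(y_true, y_prob)
    return metrics_from_confusion(c, auc=auc)


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-run metrics with per-fold and pooled mean ± SD aggregation."""

    runs: pd.DataFrame       # columns: fold, repeat, seed, accuracy..auc
    k: int
    repeats: int
    seed: int

    def per_fold(self) -> pd.DataFrame:
        """Mean ± SD across the repeat runs within each fold."""
        g = self.runs.groupby("fold")[list(METRIC_NAMES)]
        out = g.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.fillna(0.0)

    def overall(self) -> dict[str, tuple[float, float]]:
        """Pooled mean ± SD across all k×repeats runs."""
        out = {}
        for m in METRIC_NAMES:
            vals = self.runs[m].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out[m] = (float(np.mean(vals)), sd)
        return out

    def to_text(self) -> str:
        """Human-readable table: one row per fold plus an Overall row,
        metrics as percent with one decimal (mean ± SD)."""
        lines = [f"{'Fold':<10}" + "".join(f"{m.capitalize():>18}"
                                           for m in METRIC_NAMES)]
        pf = self.per_fold()
        for fold in pf.index:
            cells = [f"{pf.loc[fold, f'{m}_mean'] * 100:.1f} ± "
                     f"{pf.loc[fold, f'{m}_std'] * 100:.1f}"
                     for m in METRIC_NAMES]
            lines.append(f"{'Fold ' + str(fold):<10}"
                         + "".join(f"{c:>18}" for c in cells))
        ov = self.overall()
        cells = [f"{ov[m][0] * 100:.1f} ± {ov[m][1] * 100:.1f}"
                 for m in METRIC_NAMES]
        lines.append(f"{'Overall':<10}" + "".join(f"{c:>18}" for c in cells))
        return "\n".join(lines) + "\n"

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(d / "cv_runs.csv", index=False)
        self.per_fold().to_csv(d / "cv_per_fold.csv")
        (d / "cv_report.txt").write_text(self.to_text())


def derive_seed(master: int, *tags) -> int:
    """Deterministic sub-seed < 2**31 from a master seed and stream tags."""
    import zlib
    h = zlib.crc32(("/".join(str(t) for t in tags)).encode())
    return int((master * 2654435761 + h) % (2 ** 31))


def _fit_and_score(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
                   test_idx: np.ndarray, cfg: TrainingConfig,
                   seed: int) -> MetricsReport:
    run_cfg = dataclasses.replace(cfg, seed=seed)
    model = HazChemNet.fit(X[train_idx], y[train_idx], cfg=run_cfg)
    proba = model.predict_proba(X[test_idx])
    return compute_metrics(y[test_idx], proba,
                           threshold=cfg.decision_threshold)


def _resolve_xy(data, y=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (records) or (X, y)."""
    if y is None:
        records = list(data)
        if not records or not isinstance(records[0], MoleculeRecord):
            raise TypeError("pass MoleculeRecord list, or X together with y")
        feats = featurize_dataset(records)
        if feats.labels is None:
            raise ValueError("records must be labeled")
        if feats.rejects:
            logger.warning("%d record(s) rejected during featurization",
                           len(feats.rejects))
        return feats.X, feats.labels
    return np.asarray(data, dtype=np.float64), np.asarray(y)


def cross_validate(
    data,
    y: np.ndarray | None = None,
    cfg: TrainingConfig | None = None,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV with `repeats` independent trainings per fold.

    Each run re-fits the whole pipeline (standardizer included) on the
    training folds from a fresh seed derived from `seed`, and scores the
    held-out fold.  `data` is either a list of labeled MoleculeRecords or a
    raw feature matrix with `y`.
    """
    X, y = _resolve_xy(data, y)
    cfg = cfg or TrainingConfig()
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds dataset size {X.shape[0]}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y), start=1):
        for rep in range(1, repeats + 1):
            run_seed = derive_seed(seed, "cv", fold, rep)
            rep_metrics = _fit_and_score(X, y, train_idx, test_idx, cfg,
                                         run_seed)
            rows.append({"fold": fold, "repeat": rep, "seed": run_seed,
                         **rep_metrics.as_dict()})
    return CVReport(runs=pd.DataFrame(rows), k=k, repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# Feature ablation
# ---------------------------------------------------------------------------

#: Named feature-removal variants → dropped column indices of the 516 schema.
ABLATION_VARIANTS: dict[str, tuple[int, ...]] = {
    "full": (),
    "-MolWt": (512,),
    "-MolLogP": (513,),
    "-NumHDonors": (514,),
    "-NumHAcceptors": (515,),
    "-MorganFingerprint": tuple(range(512)),
}


def _normalize_variant(name: str) -> str:
    return name.replace("−", "-").replace("Without ", "-").strip()


@dataclass
class AblationResult:
    """One CV report per feature-removal variant, Table-shaped summary."""

    reports: dict[str, CVReport]
    dims: dict[str, int]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.reports.items():
            ov = rep.overall()
            row = {"variant": name, "n_features": self.dims[name]}
            for m in METRIC_NAMES:
                row[f"{m}_mean"], row[f"{m}_sd"] = ov[m]
            rows.append(row)
        return pd.DataFrame(rows).set_index("variant")


def ablate(
    data,
    y: np.ndarray | None = None,
    cfg: TrainingConfig | None = None,
    variants: list[str] | None = None,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> AblationResult:
    """Retrain the pipeline per feature-removal variant, identical seeds.

    Variants are drawn from ABLATION_VARIANTS; removing a descriptor leaves
    515 columns, removing the fingerprint leaves the 4 descriptors.
    """
    X, y = _resolve_xy(data, y)
    names = [_normalize_variant(v) for v in (variants or
                                             list(ABLATION_VARIANTS))]
    for name in names:
        if name not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {name!r}; "
                             f"choose from {sorted(ABLATION_VARIANTS)}")
    reports, dims = {}, {}
    for name in names:
        Xv, _cols = drop_feature_columns(X, ABLATION_VARIANTS[name],
                                         FEATURE_COLUMNS)
        reports[name] = cross_validate(Xv, y, cfg=cfg, k=k, repeats=repeats,
                                       seed=seed)
        dims[name] = Xv.shape[1]
    return AblationResult(reports=reports, dims=dims)


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

@dataclass
class ExternalValidationReport:
    """Per-class accuracies on held-out hazardous / non-hazardous panels."""

    hazardous_accuracy: float
    nonhazardous_accuracy: float
    false_negative_rate: float
    verdicts: pd.DataFrame     # id, smiles, true label, probability, predicted
    rejects: list[tuple[str, str]]


def external_validate(
    model: HazChemNet,
    hazardous: list[MoleculeRecord],
    nonhazardous: list[MoleculeRecord],
) -> ExternalValidationReport:
    """Score a trained model on two external panels of known class.

    Unfeaturizable compounds are reported and excluded from denominators.
    """
    if not hazardous or not nonhazardous:
        raise ValueError("both external lists must be non-empty")
    frames, rejects = [], []
    for true_label, records in ((1, hazardous), (0, nonhazardous)):
        recs = [dataclasses.replace(r, label=true_label) for r in records]
        feats, proba, classes = model.predict_records(recs)
        rejects.extend(feats.rejects)
        smiles_by_id = {r.id: r.smiles for r in recs}
        frames.append(pd.DataFrame({
            "id": feats.ids,
            "smiles": [smiles_by_id[i] for i in feats.ids],
            "true_label": true_label,
            "probability": proba,
            "predicted": classes,
        }))
    if rejects:
        logger.warning("external validation: %d compound(s) unfeaturizable "
                       "and excluded: %s", len(rejects), rejects)
    verdicts = pd.concat(frames, ignore_index=True)
    haz = verdicts[verdicts.true_label == 1]
    non = verdicts[verdicts.true_label == 0]
    if haz.empty or non.empty:
        raise ValueError("no featurizable compounds in one of the panels")
    haz_acc = float((haz.predicted == 1).mean())
    non_acc = float((non.predicted == 0).mean())
    return ExternalValidationReport(
        hazardous_accuracy=haz_acc,
        nonhazardous_accuracy=non_acc,
        false_negative_rate=float((haz.predicted == 0).mean()),
        verdicts=verdicts,
        rejects=rejects,
    )


def plot_confusion(c: ConfusionCounts, path: str | Path) -> None:
    """Render the 2×2 confusion matrix to an image file (optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.array([[c.tn, c.fp], [c.fn, c.tp]])
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(mat, cmap="Blues")
    for (i, j), val in np.ndenumerate(mat):
        ax.text(j, i, str(val), ha="center", va="center")
    ax.set_xticks([0, 1], ["Non-Hazardous", "Hazardous"])
    ax.set_yticks([0, 1], ["Non-Hazardous", "Hazardous"])
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
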