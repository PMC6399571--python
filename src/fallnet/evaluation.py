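"""Scoring and cross-validation: error rate, logarithmic loss, spherical
payoff, ROC/AUC, and decile calibration.

Conventions: logarithmic loss is the mean negative *natural* log of the
probability assigned to the actual label (0 is perfect). Spherical payoff
is the mean of ``P_correct / sqrt(sum_j P_j^2)`` over the two label states
(1 is perfect); both are proper scoring rules. The error rate thresholds
the predicted fall probability at 0.5 (most-probable state) by default.
Calibration uses equal-count deciles of the sorted predictions with Wilson
95% intervals on the per-bin observed rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .learning import DirichletPrior, fit_cpts, fit_em
from .inference import daily_risk
from .windowing import (
    DailyWindow,
    SplitPlan,
    monte_carlo_folds,
    oversample_positives,
    fold_seed,
)

__all__ = [
    "CalibrationBin",
    "EvaluationReport",
    "error_rate",
    "log_loss",
    "spherical_payoff",
    "roc_auc",
    "auc_concordance",
    "calibration_deciles",
    "evaluate_predictions",
    "cross_validate",
]

_EPS = 1e-12


def _check(predictions, labels):
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if p.size == 0:
        raise ValueError("empty prediction set")
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return np.clip(p, _EPS, 1 - _EPS), y.astype(int)


def error_rate(predictions, labels, threshold: float = 0.5) -> float:
    """Fraction of windows whose thresholded prediction mismatches the label."""
    p, y = _check(predictions, labels)
    return float(np.mean((p >= threshold).astype(int) != y))


def log_loss(predictions, labels) -> float:
    """Mean ``-ln P(actual label)``; natural-log units, 0 is perfect."""
    p, y = _check(predictions, labels)
    return float(-np.mean(np.log(np.where(y == 1, p, 1 - p))))


def spherical_payoff(predictions, labels) -> float:
    """Mean ``P_correct / sqrt(P_yes^2 + P_no^2)``; 1 is perfect."""
    p, y = _check(predictions, labels)
    norm = np.sqrt(p**2 + (1 - p) ** 2)
    return float(np.mean(np.where(y == 1, p, 1 - p) / norm))


def roc_auc(predictions, labels) -> tuple[float, np.ndarray]:
    """AUC plus the ROC polyline as an ``(n, 2)`` array of (FPR, TPR).

    The AUC is the rank (concordance) statistic with ties counted half;
    the curve is a threshold sweep over the distinct predicted values.
    """
    p, y = _check(predictions, labels)
    if y.min() == y.max():
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = _skm.roc_curve(y, p, drop_intermediate=False)
    return auc_concordance(p, y), np.column_stack([fpr, tpr])


def auc_concordance(predictions, labels) -> float:
    """AUC as the Mann-Whitney rank statistic (ties count 1/2)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = stats.rankdata(p)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class CalibrationBin:
    decile: int  # 1..10
    p_lo: float
    p_hi: float
    mean_predicted: float
    observed_rate: float
    ci_low: float
    ci_high: float
    count: int


def _wilson(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


def calibration_deciles(
    predictions, labels, n_bins: int = 10, equal_width: bool = False
) -> list[CalibrationBin]:
    """Observed vs. predicted event rates in prediction deciles.

    Equal-count bins by sorted prediction by default (tied predictions stay
    together, so bins can be unequal under heavy ties); ``equal_width``
    switches to fixed-width probability bins.
    """
    p, y = _check(predictions, labels)
    n = len(p)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} predictions")
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    if equal_width:
        edges = np.linspace(0, 1, n_bins + 1)
        ids = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)
    else:
        ids = (np.arange(n) * n_bins) // n
        # keep ties in one bin: extend each bin to cover runs of equal p
        for i in range(1, n):
            if p[i] == p[i - 1]:
                ids[i] = ids[i - 1]
    bins = []
    for b in range(n_bins):
        mask = ids == b
        cnt = int(mask.sum())
        if cnt == 0:
            bins.append(CalibrationBin(b + 1, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, np.nan, 0))
            continue
        k = int(y[mask].sum())
        lo, hi = _wilson(k, cnt)
        bins.append(
            CalibrationBin(
                decile=b + 1,
                p_lo=float(p[mask].min()),
                p_hi=float(p[mask].max()),
                mean_predicted=float(p[mask].mean()),
                observed_rate=k / cnt,
                ci_low=lo,
                ci_high=hi,
                count=cnt,
            )
        )
    return bins


@dataclass
class EvaluationReport:
    """Per-fold and averaged prediction metrics."""

    error_rate: float
    log_loss: float
    spherical_payoff: float
    auc: float
    n_windows: int
    no_information_rate: float
    roc_points: np.ndarray | None = None
    calibration: list[CalibrationBin] | None = None
    folds: list["EvaluationReport"] = field(default_factory=list)
    sd: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "error_rate": self.error_rate,
            "log_loss": self.log_loss,
            "spherical_payoff": self.spherical_payoff,
            "auc": self.auc,
            "n_windows": self.n_windows,
            "no_information_rate": self.no_information_rate,
        }
        if self.calibration is not None:
            d["calibration"] = [asdict(b) for b in self.calibration]
        if self.roc_points is not None:
            d["roc_points"] = np.asarray(self.roc_points).tolist()
        if self.folds:
            d["folds"] = [f.to_dict() for f in self.folds]
            d["sd"] = self.sd
        return d


def evaluate_predictions(
    predictions, labels, threshold: float = 0.5, with_curves: bool = True
) -> EvaluationReport:
    p, y = _check(predictions, labels)
    if y.min() == y.max():  # degenerate set (e.g. a fold without positives)
        auc, roc = float("nan"), None
    else:
        auc, roc = roc_auc(p, y)
    calib = calibration_deciles(p, y) if (with_curves and len(p) >= 10) else None
    if roc is None:
        with_curves = False
    return EvaluationReport(
        error_rate=error_rate(p, y, threshold),
        log_loss=log_loss(p, y),
        spherical_payoff=spherical_payoff(p, y),
        auc=auc,
        n_windows=len(p),
        no_information_rate=float(max(np.mean(y), 1 - np.mean(y))),
        roc_points=roc if with_curves else None,
        calibration=calib,
    )


_METRICS = ("error_rate", "log_loss", "spherical_payoff", "auc",
            "no_information_rate")


def cross_validate(
    skeleton,
    windows: Sequence[DailyWindow],
    prior: DirichletPrior | None = None,
    k: int = 10,
    seed: int = 0,
    train_fraction: float = 0.9,
    threshold: float = 0.5,
    fall_node: str = "fall",
    mode: str = "subsample",
) -> EvaluationReport:
    """Repeated patient-level 90/10 validation of the full fit/predict loop.

    For each fold: split patients, oversample the *training* positives to
    balance classes (test windows are never resampled), fit CPTs (via EM if
    the training windows have missing evidence), score every test window's
    daily fall risk, and compute the metrics. ``mode="kfold"`` uses a true
    k-way patient partition instead of repeated 90/10 subsampling.
    """
    prior = prior or DirichletPrior()
    windows = list(windows)
    if mode == "subsample":
        plans = monte_carlo_folds(windows, k=k, train_fraction=train_fraction,
                                  seed=seed)
    elif mode == "kfold":
        patients = sorted({w.patient_id for w in windows})
        rng = np.random.default_rng(fold_seed(seed, 0))
        perm = rng.permutation(len(patients))
        chunks = np.array_split(perm, k)
        plans = []
        for c in chunks:
            test = frozenset(patients[i] for i in c)
            train = frozenset(patients) - test
            plans.append(SplitPlan(train, test, seed))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fold_reports = []
    for i, plan in enumerate(plans):
        train = oversample_positives(plan.train_windows(windows),
                                     seed=fold_seed(seed, 100 + i))
        test = plan.test_windows(windows)
        if any(
            n not in w.evidence for w in train for n in skeleton.nodes
            if n != fall_node
        ):
            net = fit_em(skeleton, train, prior, fall_node=fall_node).net
        else:
            net = fit_cpts(skeleton, train, prior, fall_node=fall_node)
        cache: dict = {}
        preds = np.array(
            [daily_risk(net, w, fall_node=fall_node, _cache=cache).risk
             for w in test]
        )
        labels = np.array([w.label for w in test])
        fold_reports.append(
            evaluate_predictions(preds, labels, threshold, with_curves=False)
        )

    # nan-aware: a fold whose test patients happen to include no faller has
    # undefined AUC; other metrics remain defined
    def _agg(fn_, m):
        vals = np.array([getattr(f, m) for f in fold_reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan")
        return float(fn_(vals))

    mean = {m: _agg(np.mean, m) for m in _METRICS}
    sd = {m: _agg(lambda v: np.std(v, ddof=1) if v.size > 1 else 0.0, m)
          for m in _METRICS}
    return EvaluationReport(
        **mean,
        n_windows=int(np.sum([f.n_windows for f in fold_reports])),
        folds=fold_reports,
        sd=sd,
    )


def plot_roc(report: EvaluationReport, path, label: str = "model") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    pts = np.asarray(report.roc_points)
    ax.plot(pts[:, 0], pts[:, 1], label=f"{label} (AUC={report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_calibration(report: EvaluationReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    bins = [b for b in report.calibration if b.count > 0]
    x = [b.decile for b in bins]
    obs = [b.observed_rate for b in bins]
    err = np.array([
        [b.observed_rate - b.ci_low for b in bins],
        [b.ci_high - b.observed_rate for b in bins],
    ])
    ax.errorbar(x, obs, yerr=err, fmt="o-", capsize=3, label="observed")
    ax.plot(x, [b.mean_predicted for b in bins], "s--", label="predicted")
    ax.set_xlabel("risk decile")
    ax.set_ylabel("event rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
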