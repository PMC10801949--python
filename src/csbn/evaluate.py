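"""Discrimination, calibration and clinical-utility metrics.

Horizon AUC uses the censoring-exclusion rule: a patient counts as a case
if the event occurred by the horizon, as a control if followed beyond it,
and is excluded when censored before the horizon. Discrimination over
follow-up uses Harrell's concordance index. Calibration is summarized per
decile of predicted risk, and clinical utility by decision-curve net
benefit, NB(pt) = TP/N - FP/N * pt/(1-pt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricReport",
    "CalibrationTable",
    "DecisionCurveResult",
    "horizon_labels",
    "auc_at_horizon",
    "c_index",
    "calibration_table",
    "decision_curve",
]


@dataclass
class MetricReport:
    auc: float
    auc_ci: tuple[float, float]
    n_evaluated: int
    n_excluded_censored_before_horizon: int


@dataclass
class CalibrationTable:
    table: pd.DataFrame  # columns: bin, mean_predicted, observed, count
    n_evaluated: int


@dataclass
class DecisionCurveResult:
    table: pd.DataFrame  # threshold, nb_model, nb_all, nb_none, snb_model, snb_all
    prevalence: float


def horizon_labels(times, events, horizon: float):
    """Binary labels at a horizon with censoring exclusion.

    Returns (labels, keep_mask): label 1 for an event at or before the
    horizon, 0 for follow-up reaching the horizon; censored-before-horizon
    patients have keep=False.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    case = (events == 1) & (times <= horizon)
    control = times >= horizon
    keep = case | control
    labels = np.where(case, 1, 0)
    return labels, keep


def auc_at_horizon(
    predicted_risk,
    times,
    events,
    horizon: float,
    bootstrap: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Mann-Whitney AUC of predicted risk for horizon status, with a
    percentile-bootstrap 95% CI; ties in risk count one half."""
    risk = np.asarray(predicted_risk, dtype=float)
    labels, keep = horizon_labels(times, events, horizon)
    n_excl = int((~keep).sum())
    y, r = labels[keep], risk[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"AUC undefined: {int(y.sum())} cases / {int((1 - y).sum())} controls"
        )
    auc = float(roc_auc_score(y, r))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(bootstrap):
        idx = rng.integers(0, len(y), size=len(y))
        if len(np.unique(y[idx])) < 2:
            continue
        boots.append(roc_auc_score(y[idx], r[idx]))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = auc
    return MetricReport(auc, (float(lo), float(hi)), int(keep.sum()), n_excl)


def c_index(predicted_risk, times, events) -> float:
    """Harrell's C over comparable pairs (the shorter time carries an
    event); risk ties count one half."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(predicted_risk, dtype=float)
    if events.sum() == 0 or len(times) < 2:
        raise ValueError("no comparable pairs")
    # concordance_index orients by predicted survival time: negate risk
    return float(concordance_index(times, -risk, events))


def calibration_table(predicted_risk, labels, deciles: int = 10) -> CalibrationTable:
    """Observed event fraction per quantile bin of predicted risk.

    Bins with identical quantile edges (fewer distinct risks than bins)
    are merged.
    """
    risk = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(labels, dtype=int)
    edges = np.unique(np.quantile(risk, np.linspace(0, 1, deciles + 1)))
    if len(edges) < 2:
        bins = np.zeros(len(risk), dtype=int)
        n_bins = 1
    else:
        bins = np.clip(np.searchsorted(edges, risk, side="right") - 1, 0, len(edges) - 2)
        n_bins = len(edges) - 1
    rows = []
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        rows.append((b, float(risk[sel].mean()), float(y[sel].mean()), int(sel.sum())))
    table = pd.DataFrame(rows, columns=["bin", "mean_predicted", "observed", "count"])
    return CalibrationTable(table, int(len(y)))


def decision_curve(predicted_risk, labels, thresholds=None) -> DecisionCurveResult:
    """Net benefit of treating at risk >= pt, against treat-all and
    treat-none, plus the standardized (prevalence-scaled) curves.

    Default threshold grid spans 0 to 0.70.
    """
    risk = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 0.701, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds < 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in [0, 1)")
    N = len(y)
    prevalence = float(y.mean())
    rows = []
    for pt in thresholds:
        flag = risk >= pt
        tp = float((flag & (y == 1)).sum()) / N
        fp = float((flag & (y == 0)).sum()) / N
        odds = pt / (1 - pt)
        nb = tp - fp * odds
        nb_all = prevalence - (1 - prevalence) * odds
        rows.append((pt, nb, nb_all, 0.0))
    df = pd.DataFrame(rows, columns=["threshold", "nb_model", "nb_all", "nb_none"])
    if prevalence > 0:
        df["snb_model"] = df["nb_model"] / prevalence
        df["snb_all"] = df["nb_all"] / prevalence
    else:
        df["snb_model"] = np.nan
        df["snb_all"] = np.nan
    return DecisionCurveResult(df, prevalence)
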