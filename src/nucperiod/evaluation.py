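"""Simulation harnesses: accuracy curves, significance curves, ROC/AUC.

These reproduce the package's three standard comparisons on synthetic
panels:

* **accuracy vs degradation** — fraction of replicates per level whose
  dominant period equals the true period, for each estimator;
* **significance vs degradation** — mean of a confirmatory measure's output
  (p-value, deviation or bound) per level;
* **ROC / AUC** — confirmatory detection of degraded-periodic positives
  against permuted negatives, sweeping the decision threshold over all
  observed scores.  Probability-producing measures score ``1 - p`` (more
  significant = more positive); the CRB scores ``-bound``.  AUC is
  threshold-free and invariant under monotone transforms of the scores.

A caveat inherited from the study design: heavily degraded 'positives' may
genuinely behave as negatives, which depresses all measures equally and
does not change their ordering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bootstrap import BootstrapConfig, bwb_pvalue
from .estimators import PeriodRange, profile
from .seqs import IndicatorSequence
from .significance import chi_squared_test, crb_bound, g_statistic, snr_estimate
from .synthetic import PanelItem

__all__ = [
    "AccuracyCurve",
    "ROCCurve",
    "accuracy_curve",
    "significance_curve",
    "roc",
    "measure_scores",
    "dominant_period_histogram",
    "MEASURES",
]

MEASURES = ("g", "bwb", "chisq", "crb")


@dataclass
class AccuracyCurve:
    method: str
    levels: np.ndarray
    accuracy: np.ndarray
    per_level: np.ndarray

    def at(self, level: float) -> float:
        idx = int(np.argmin(np.abs(self.levels - level)))
        return float(self.accuracy[idx])


@dataclass
class ROCCurve:
    measure: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def accuracy_curve(
    method: str,
    panel: Sequence[PanelItem],
    true_period: int = 10,
    prange: PeriodRange = PeriodRange(),
) -> AccuracyCurve:
    """Per-level fraction of replicates whose dominant period is correct."""
    if not panel:
        raise ValueError("empty panel")
    levels = sorted({item.level for item in panel})
    hits: Dict[float, int] = {lv: 0 for lv in levels}
    counts: Dict[float, int] = {lv: 0 for lv in levels}
    for item in panel:
        counts[item.level] += 1
        if profile(item.x, method, prange).dominant == true_period:
            hits[item.level] += 1
    acc = np.array([hits[lv] / counts[lv] for lv in levels])
    return AccuracyCurve(
        method=method,
        levels=np.array(levels),
        accuracy=acc,
        per_level=np.array([counts[lv] for lv in levels]),
    )


def _measure_value(
    measure: str,
    x: IndicatorSequence,
    p_tested: int,
    prange: PeriodRange,
    bwb_config: BootstrapConfig,
    seed: int,
) -> float:
    if measure == "g":
        return g_statistic(profile(x, bwb_config.embedded, prange)).p_value
    if measure == "bwb":
        cfg = BootstrapConfig(
            R=bwb_config.R,
            block_length=bwb_config.block_length,
            embedded=bwb_config.embedded,
            seed=seed,
            alpha=bwb_config.alpha,
        )
        return bwb_pvalue(x, p_tested, cfg).p_value
    if measure == "chisq":
        return chi_squared_test(x, p=p_tested).deviation
    if measure == "crb":
        return crb_bound(snr_estimate(x, p_tested), p_tested, x.N).bound
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


def significance_curve(
    measure: str,
    panel: Sequence[PanelItem],
    p_tested: int = 10,
    prange: PeriodRange = PeriodRange(),
    bwb_config: BootstrapConfig = BootstrapConfig(R=200),
) -> Dict[float, float]:
    """Per-level mean of a measure's output (p-value, deviation, or bound)."""
    if not panel:
        raise ValueError("empty panel")
    sums: Dict[float, float] = {}
    counts: Dict[float, int] = {}
    for item in panel:
        v = _measure_value(measure, item.x, p_tested, prange, bwb_config, item.seed)
        sums[item.level] = sums.get(item.level, 0.0) + v
        counts[item.level] = counts.get(item.level, 0) + 1
    return {lv: sums[lv] / counts[lv] for lv in sorted(sums)}


def measure_scores(
    measure: str,
    panel: Sequence[PanelItem],
    p_tested: int = 10,
    prange: PeriodRange = PeriodRange(),
    bwb_config: BootstrapConfig = BootstrapConfig(R=200),
) -> np.ndarray:
    """Detection scores, oriented so that larger means more positive."""
    vals = np.array(
        [_measure_value(measure, item.x, p_tested, prange, bwb_config, item.seed) for item in panel]
    )
    if measure in ("g", "bwb"):
        return 1.0 - vals
    # crb bound and chisq deviation both shrink as periodicity strengthens
    return -vals


def roc(scores_pos: np.ndarray, scores_neg: np.ndarray, measure: str = "") -> ROCCurve:
    """ROC over all observed score thresholds, AUC by the trapezoid rule."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    y = np.concatenate([np.ones(scores_pos.size), np.zeros(scores_neg.size)])
    s = np.concatenate([scores_pos, scores_neg])
    if np.unique(s).size == 1:  # degenerate: single threshold, two trivial points
        return ROCCurve(measure=measure, fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]), auc=0.5)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return ROCCurve(measure=measure, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def dominant_period_histogram(
    xs: Sequence[IndicatorSequence],
    method: str,
    prange: PeriodRange = PeriodRange(),
) -> Counter:
    """Tabulate dominant periods over a fragment set (None = no periodicity)."""
    return Counter(profile(x, method, prange).dominant for x in xs)
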