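"""Global and individual response-quality analysis.

Global analysis pools normalized RT/RTV samples across all subjects against
the gold-standard mask (periods with an increased catch-trial error rate),
builds the ROC curve over all candidate cut-offs, integrates the AUROC,
selects the operating cut-off at the maximum of the Youden index
J = sensitivity + specificity - 1, and reports the percentile of that
cut-off in the pooled value distribution.  Each subject then gets an
Agreement Index: the Jaccard index between their increased-error-rate mask
and their deviant-predictor-value mask at the global cut-off.

Individual analysis correlates each subject's error-rate series with their
RT and RTV series by Spearman rank correlation, and both branches close
with a "meta-correlation": the per-subject statistic (AI or rho) against the
subject's total error count, across the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .series import ErrorRateSeries, MaskSeries, RTSeries, RTVSeries

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "AgreementResult",
    "CorrelationResult",
    "pooled_roc",
    "auroc",
    "youden_cutoff",
    "deviant_value_mask",
    "agreement_index",
    "spearman",
    "individual_analysis",
    "meta_correlation",
]


@dataclass
class ROCCurve:
    """Pooled ROC curve: one (sensitivity, specificity) pair per candidate
    cut-off, with cut-offs ascending and -inf/+inf sentinels included."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    predictor: str = ""
    n_positive: int = 0
    n_negative: int = 0


@dataclass
class CutoffResult:
    """Youden-optimal operating point of a pooled ROC analysis."""

    predictor: str
    auroc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    percentile: float


@dataclass
class AgreementResult:
    """Per-subject Agreement Index: Jaccard index between the increased-error
    mask and the deviant-value mask, counted in grid seconds."""

    subject_id: str
    ai: float  # NaN when the union is empty (undefined)
    seconds_in_intersection: float
    seconds_in_union: float
    total_errors: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ai)


@dataclass
class CorrelationResult:
    """Per-subject Spearman correlations of the error rate against RT and RTV."""

    subject_id: str
    rho_rt: float
    p_rt: float
    rho_rtv: float
    p_rtv: float
    n: int
    total_errors: int = 0


def pooled_roc(
    predictor_series: Sequence[RTSeries | RTVSeries],
    truth_masks: Sequence[MaskSeries],
    predictor: str = "",
) -> ROCCurve:
    """ROC of a pooled predictor against pooled truth masks.

    All subjects' grid samples are pooled; positives are samples inside a
    truth mask.  For every candidate cut-off c (each distinct pooled value
    plus +-inf sentinels), sensitivity = P(x > c | positive) and
    specificity = P(x <= c | negative).

    Raises if there are no positives or no negatives anywhere (undefined ROC).
    """
    xs, ys = [], []
    for series, mask in zip(predictor_series, truth_masks, strict=True):
        if len(series.values) != len(mask.mask):
            raise ValueError("predictor series and truth mask differ in length")
        xs.append(np.asarray(series.values, float))
        ys.append(np.asarray(mask.mask, bool))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one positive and one negative")

    pos = np.sort(x[y])
    neg = np.sort(x[~y])
    thresholds = np.concatenate(([-np.inf], np.unique(x), [np.inf]))
    # sensitivity: fraction of positives strictly above c
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / n_pos
    # specificity: fraction of negatives at or below c
    spec = np.searchsorted(neg, thresholds, side="right") / n_neg
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        predictor=predictor,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def auroc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve in (1 - specificity, sensitivity).

    Equals the probability that a random positive outranks a random negative
    with ties half-counted (Mann-Whitney statistic).
    """
    if len(curve.thresholds) < 2:
        raise ValueError("need at least two curve points")
    fpr = 1.0 - curve.specificity
    # ties in fpr must be traversed in ascending sensitivity for the
    # trapezoid to integrate the vertical segments correctly
    order = np.lexsort((curve.sensitivity, fpr))
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def youden_cutoff(curve: ROCCurve, pooled_values: np.ndarray) -> CutoffResult:
    """Select the cut-off maximizing Youden's J = sens + spec - 1.

    Ties are broken toward the larger cut-off (fewer samples flagged).  The
    percentile is the inclusive empirical CDF of the cut-off in the pooled
    predictor values, on the 0-100 scale.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    finite = np.isfinite(curve.thresholds)
    j_f = j[finite]
    thr_f = curve.thresholds[finite]
    best = np.flatnonzero(j_f == j_f.max())[-1]
    cutoff = float(thr_f[best])
    pooled = np.asarray(pooled_values, float)
    pct = 100.0 * float(np.mean(pooled <= cutoff)) if pooled.size else float("nan")
    return CutoffResult(
        predictor=curve.predictor,
        auroc=auroc(curve),
        cutoff=cutoff,
        sensitivity=float(curve.sensitivity[finite][best]),
        specificity=float(curve.specificity[finite][best]),
        youden_j=float(j_f[best]),
        percentile=pct,
    )


def deviant_value_mask(
    series: RTSeries | RTVSeries, cutoff: float, source: str = ""
) -> MaskSeries:
    """Samples whose predictor value strictly exceeds the cut-off."""
    return MaskSeries(
        subject_id=series.subject_id,
        t=series.t,
        mask=np.asarray(series.values, float) > cutoff,
        source=source or getattr(series, "source", "rtv"),
        threshold=float(cutoff),
    )


def agreement_index(
    error_mask: MaskSeries,
    deviant_mask: MaskSeries,
    total_errors: int = 0,
) -> AgreementResult:
    """Agreement Index between two binary time masks on a shared grid.

    AI = |A AND B| / |A OR B| in grid samples (Jaccard index); NaN (undefined)
    when the union is empty — such subjects are excluded from cohort medians.
    """
    if len(error_mask.t) != len(deviant_mask.t) or not np.array_equal(
        error_mask.t, deviant_mask.t
    ):
        raise ValueError("masks must share the same time grid")
    a = np.asarray(error_mask.mask, bool)
    b = np.asarray(deviant_mask.mask, bool)
    step = error_mask.t[1] - error_mask.t[0] if len(error_mask.t) > 1 else 1.0
    inter = float(np.sum(a & b)) * step
    union = float(np.sum(a | b)) * step
    ai = inter / union if union > 0 else float("nan")
    return AgreementResult(
        subject_id=error_mask.subject_id,
        ai=ai,
        seconds_in_intersection=inter,
        seconds_in_union=union,
        total_errors=int(total_errors),
    )


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the mid-ranks; the p-value uses the
    large-sample t approximation with n - 2 degrees of freedom.  Returns
    (nan, nan) when either variable has zero rank variance (undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, float(p)


def individual_analysis(
    error_series: Sequence[ErrorRateSeries],
    rt_series: Sequence[RTSeries],
    rtv_series: Sequence[RTVSeries],
    total_errors: Sequence[int] | None = None,
) -> list[CorrelationResult]:
    """Per-subject Spearman correlation of the error rate against RT and RTV.

    Subjects whose error-rate series is constant (typically zero errors) get
    NaN coefficients, flagged rather than dropped.
    """
    totals = list(total_errors) if total_errors is not None else [0] * len(error_series)
    out = []
    for err, rt, rtv, tot in zip(error_series, rt_series, rtv_series, totals, strict=True):
        rho_rt, p_rt = spearman(err.values, rt.values)
        rho_rtv, p_rtv = spearman(err.values, rtv.values)
        out.append(
            CorrelationResult(
                subject_id=err.subject_id,
                rho_rt=rho_rt,
                p_rt=p_rt,
                rho_rtv=rho_rtv,
                p_rtv=p_rtv,
                n=len(err.values),
                total_errors=int(tot),
            )
        )
    return out


def meta_correlation(
    per_subject_stat: Sequence[float], total_errors: Sequence[int]
) -> tuple[float, float]:
    """Spearman correlation of a per-subject statistic (AI or rho) with the
    total error count across the cohort; NaN statistics are dropped pairwise."""
    stat = np.asarray(per_subject_stat, float)
    tot = np.asarray(total_errors, float)
    if stat.shape != tot.shape:
        raise ValueError("statistic and error-count lists must align")
    keep = ~np.isnan(stat)
    if keep.sum() < 3:
        raise ValueError("need at least 3 defined pairs")
    return spearman(stat[keep], tot[keep])
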