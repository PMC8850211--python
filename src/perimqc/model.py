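"""Cohort-level response-quality model.

:class:`ResponseQualityModel` is built from a cohort of perimetric session
records and, on :meth:`~ResponseQualityModel.fit`, runs the full analysis:

1. per subject — interpolated RT series, sliding-window RTV, windowed
   catch-trial error rate, and the gold-standard mask of increased-error
   periods (> 2 errors/min by default);
2. global — pooled ROC / AUROC for normalized RT and RTV against the gold
   standard, Youden-optimal cut-offs with their pooled percentiles, deviant
   RTV-value masks at the cut-off, and per-subject Agreement Indices;
3. individual — per-subject Spearman correlations of the error rate with RT
   and RTV;
4. meta — Spearman correlations of the per-subject AI and rho_RTV with the
   subjects' total error counts.

The fitted :class:`ResponseQualityResults` carries all of it and renders a
summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis as qa
from . import series as rs
from .observer import SessionRecord

__all__ = ["ResponseQualityModel", "ResponseQualityResults"]


@dataclass
class _SubjectSeries:
    subject_id: str
    rt: rs.RTSeries
    rtv: rs.RTVSeries
    rt_norm: rs.RTSeries
    rtv_norm: rs.RTVSeries
    error_rate: rs.ErrorRateSeries
    error_mask: rs.MaskSeries
    total_errors: int


class ResponseQualityModel:
    """Response-quality analysis of a cohort of perimetric sessions.

    Parameters
    ----------
    sessions
        One :class:`~perimqc.observer.SessionRecord` per subject.
    window_s
        Sliding-window length for RTV and the error rate (seconds).
    error_threshold_per_min
        Error-rate threshold defining the gold-standard increased-error mask
        (strictly greater than).
    cutoff_mode
        ``"youden"`` selects the deviant-value cut-off at the Youden optimum
        of the pooled RTV ROC; ``"fixed"`` uses ``fixed_cutoff``.
    fixed_cutoff
        Cut-off on the normalized predictor when ``cutoff_mode="fixed"``.
    """

    def __init__(
        self,
        sessions: Sequence[SessionRecord],
        window_s: float = 60.0,
        error_threshold_per_min: float = 2.0,
        cutoff_mode: str = "youden",
        fixed_cutoff: float | None = None,
    ) -> None:
        if not sessions:
            raise ValueError("need at least one session")
        if cutoff_mode not in ("youden", "fixed"):
            raise ValueError("cutoff_mode must be 'youden' or 'fixed'")
        if cutoff_mode == "fixed" and fixed_cutoff is None:
            raise ValueError("fixed_cutoff required when cutoff_mode='fixed'")
        self.sessions = list(sessions)
        self.window_s = float(window_s)
        self.error_threshold_per_min = float(error_threshold_per_min)
        self.cutoff_mode = cutoff_mode
        self.fixed_cutoff = fixed_cutoff

    def _build_subject(self, session: SessionRecord) -> _SubjectSeries:
        grid = rs.make_grid(session.duration_s)
        onsets, rts = rs.extract_rt_observations(session)
        rt = rs.interpolate_rt(onsets, rts, grid, subject_id=session.subject_id)
        rtv = rs.sliding_rtv(rt, window_s=self.window_s)
        err = rs.error_rate_per_minute(session, grid, window_s=self.window_s)
        mask = rs.flag_increased_error_periods(err, self.error_threshold_per_min)
        return _SubjectSeries(
            subject_id=session.subject_id,
            rt=rt,
            rtv=rtv,
            rt_norm=rs.normalize_unit_interval(rt),
            rtv_norm=rs.normalize_unit_interval(rtv),
            error_rate=err,
            error_mask=mask,
            total_errors=int(len(rs.error_onsets(session))),
        )

    def fit(self) -> "ResponseQualityResults":
        subjects = [self._build_subject(s) for s in self.sessions]
        masks = [s.error_mask for s in subjects]
        totals = [s.total_errors for s in subjects]

        roc_rt = qa.pooled_roc([s.rt_norm for s in subjects], masks, predictor="rt")
        roc_rtv = qa.pooled_roc([s.rtv_norm for s in subjects], masks, predictor="rtv")
        pooled_rt = np.concatenate([s.rt_norm.values for s in subjects])
        pooled_rtv = np.concatenate([s.rtv_norm.values for s in subjects])
        cut_rt = qa.youden_cutoff(roc_rt, pooled_rt)
        cut_rtv = qa.youden_cutoff(roc_rtv, pooled_rtv)

        cutoff = cut_rtv.cutoff if self.cutoff_mode == "youden" else float(self.fixed_cutoff)
        deviant = [
            qa.deviant_value_mask(s.rtv_norm, cutoff, source="rtv") for s in subjects
        ]
        agreement = [
            qa.agreement_index(m, d, total_errors=t)
            for m, d, t in zip(masks, deviant, totals)
        ]
        correlations = qa.individual_analysis(
            [s.error_rate for s in subjects],
            [s.rt_norm for s in subjects],
            [s.rtv_norm for s in subjects],
            totals,
        )

        ai_values = [a.ai for a in agreement]
        rho_rtv = [c.rho_rtv for c in correlations]
        meta_ai = qa.meta_correlation(ai_values, totals)
        meta_rho = qa.meta_correlation(rho_rtv, totals)

        return ResponseQualityResults(
            model=self,
            subjects=subjects,
            roc_rt=roc_rt,
            roc_rtv=roc_rtv,
            cutoff_rt=cut_rt,
            cutoff_rtv=cut_rtv,
            cutoff_used=cutoff,
            deviant_masks=deviant,
            agreement=agreement,
            correlations=correlations,
            meta_rho_ai=meta_ai[0],
            meta_p_ai=meta_ai[1],
            meta_rho_individual=meta_rho[0],
            meta_p_individual=meta_rho[1],
        )


def _median_max(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if not np.isnan(v)], float)
    if arr.size == 0:
        return float("nan"), float("nan")
    return float(np.median(arr)), float(np.max(arr))


@dataclass
class ResponseQualityResults:
    """Fitted cohort analysis: cut-offs, agreement and correlation results."""

    model: ResponseQualityModel
    subjects: list[_SubjectSeries]
    roc_rt: qa.ROCCurve
    roc_rtv: qa.ROCCurve
    cutoff_rt: qa.CutoffResult
    cutoff_rtv: qa.CutoffResult
    cutoff_used: float
    deviant_masks: list[rs.MaskSeries]
    agreement: list[qa.AgreementResult]
    correlations: list[qa.CorrelationResult]
    meta_rho_ai: float
    meta_p_ai: float
    meta_rho_individual: float
    meta_p_individual: float

    @property
    def total_errors(self) -> list[int]:
        return [s.total_errors for s in self.subjects]

    def ai_median_max(self) -> tuple[float, float]:
        """Median/maximum AI over subjects with a non-empty mask union."""
        return _median_max([a.ai for a in self.agreement])

    def rho_median_max(self, predictor: str = "rtv") -> tuple[float, float]:
        attr = {"rt": "rho_rt", "rtv": "rho_rtv"}[predictor]
        return _median_max([getattr(c, attr) for c in self.correlations])

    def agreement_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [a.subject_id for a in self.agreement],
                "ai": [a.ai for a in self.agreement],
                "seconds_in_intersection": [a.seconds_in_intersection for a in self.agreement],
                "seconds_in_union": [a.seconds_in_union for a in self.agreement],
                "total_errors": [a.total_errors for a in self.agreement],
            }
        )

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [c.subject_id for c in self.correlations],
                "rho_rt": [c.rho_rt for c in self.correlations],
                "p_rt": [c.p_rt for c in self.correlations],
                "rho_rtv": [c.rho_rtv for c in self.correlations],
                "p_rtv": [c.p_rtv for c in self.correlations],
                "n": [c.n for c in self.correlations],
                "total_errors": [c.total_errors for c in self.correlations],
            }
        )

    def pooled_median_rt_ms(self) -> float:
        """Median of all raw observed response times across the cohort."""
        rts = np.concatenate(
            [sess.rt_ms[sess.responded] for sess in self.model.sessions]
        )
        return float(np.median(rts))

    def to_dict(self) -> dict:
        ai_med, ai_max = self.ai_median_max()
        rt_med, rt_max = self.rho_median_max("rt")
        rtv_med, rtv_max = self.rho_median_max("rtv")
        err_med, err_max = _median_max([float(t) for t in self.total_errors])
        return {
            "n_subjects": len(self.subjects),
            "pooled_median_rt_ms": self.pooled_median_rt_ms(),
            "total_errors_median": err_med,
            "total_errors_max": err_max,
            "auroc_rt": self.cutoff_rt.auroc,
            "auroc_rtv": self.cutoff_rtv.auroc,
            "cutoff_rtv": self.cutoff_rtv.cutoff,
            "cutoff_rtv_sensitivity": self.cutoff_rtv.sensitivity,
            "cutoff_rtv_specificity": self.cutoff_rtv.specificity,
            "cutoff_rtv_percentile": self.cutoff_rtv.percentile,
            "ai_median": ai_med,
            "ai_max": ai_max,
            "rho_rt_median": rt_med,
            "rho_rt_max": rt_max,
            "rho_rtv_median": rtv_med,
            "rho_rtv_max": rtv_max,
            "meta_rho_ai": self.meta_rho_ai,
            "meta_p_ai": self.meta_p_ai,
            "meta_rho_individual": self.meta_rho_individual,
            "meta_p_individual": self.meta_p_individual,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Response Quality Analysis".center(58),
            "=" * 58,
            f"{'Subjects':34s} {d['n_subjects']:>10d}",
            f"{'Pooled median RT [ms]':34s} {d['pooled_median_rt_ms']:>10.1f}",
            f"{'Total errors (median/max)':34s} {d['total_errors_median']:>6.0f} / {d['total_errors_max']:.0f}",
            "-" * 58,
            f"{'AUROC (RT)':34s} {d['auroc_rt']:>10.4f}",
            f"{'AUROC (RTV)':34s} {d['auroc_rtv']:>10.4f}",
            f"{'RTV cut-off (Youden)':34s} {d['cutoff_rtv']:>10.4f}",
            f"{'  sensitivity / specificity':34s} {d['cutoff_rtv_sensitivity']:>6.2f} / {d['cutoff_rtv_specificity']:.2f}",
            f"{'  percentile of cut-off':34s} {d['cutoff_rtv_percentile']:>10.1f}",
            "-" * 58,
            f"{'AI (median/max)':34s} {d['ai_median']:>6.2f} / {d['ai_max']:.2f}",
            f"{'rho_RT (median/max)':34s} {d['rho_rt_median']:>6.2f} / {d['rho_rt_max']:.2f}",
            f"{'rho_RTV (median/max)':34s} {d['rho_rtv_median']:>6.2f} / {d['rho_rtv_max']:.2f}",
            f"{'Meta-correlation AI vs errors':34s} {d['meta_rho_ai']:>6.2f}  (p={d['meta_p_ai']:.2e})",
            f"{'Meta-correlation rho vs errors':34s} {d['meta_rho_individual']:>6.2f}  (p={d['meta_p_individual']:.2e})",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curves for RT and RTV on one axis (matplotlib)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for curve, cut in ((self.roc_rt, self.cutoff_rt), (self.roc_rtv, self.cutoff_rtv)):
            fpr = 1.0 - curve.specificity
            order = np.argsort(fpr)
            ax.plot(fpr[order], curve.sensitivity[order],
                    label=f"{curve.predictor.upper()} (AUROC={cut.auroc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax
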