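"""Conducting-regime classification on cumulative-charge series.

A trajectory's ``q_tot(t)`` is fit either with one ordinary-least-squares
segment (:func:`fit_single`) or with two independent segments split at a
bifurcation time found by exhaustive grid search (:func:`fit_changepoint`).
:func:`select_model` arbitrates between them by BIC, and
:func:`classify_state` applies the stability and conductance-band criteria
that separate stable low-conducting, open-like and bistable behaviour.
:func:`screen_conformers` implements the fast conductance-threshold triage
of candidate conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import units
from .permeation import ChargeSeries, CurrentEstimate
from .specs import ValidationError


@dataclass
class SegmentFit:
    """One OLS segment of q_tot(t)."""

    t_start: float
    t_end: float
    slope: float            # e/ns
    intercept: float        # e
    r_squared: float
    conductance: float      # nS
    current_ratio: float    # event ratio within the segment (nan if unknown)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegimeFit:
    """Single- or two-segment description of a conducting trajectory."""

    model: str                      # "single" | "two-segment"
    segments: list[SegmentFit]
    bifurcation_time: float | None  # ns
    sse: float
    voltage: float                  # mV
    renorm_factor: float
    n_points: int = 0
    selection_score: float | None = None   # BIC difference vs the rival model

    @property
    def conductances(self) -> list[float]:
        return [s.conductance for s in self.segments]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "bifurcation_time": self.bifurcation_time,
            "segments": [s.to_dict() for s in self.segments],
            "sse": self.sse,
            "voltage": self.voltage,
            "renorm_factor": self.renorm_factor,
            "n_points": self.n_points,
            "selection_score": self.selection_score,
        }


@dataclass
class StateClass:
    """Conducting-state label with the criteria record backing it."""

    label: str              # stable-low | open-like | bistable | unstable
    sigma: float            # nS (single model) or low-segment conductance
    r_squared: float
    fraction_of_open: float
    criteria: dict = field(default_factory=dict)


def _ols(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, R², SSE of an OLS line (R² is nan for flat data)."""
    n = len(t)
    tm, qm = t.mean(), q.mean()
    stt = float(np.sum((t - tm) ** 2))
    stq = float(np.sum((t - tm) * (q - qm)))
    sqq = float(np.sum((q - qm) ** 2))
    if stt == 0:
        raise ValidationError("degenerate time axis")
    slope = stq / stt
    intercept = qm - slope * tm
    sse = max(sqq - stq**2 / stt, 0.0)
    r2 = 1.0 - sse / sqq if sqq > 0 else math.nan
    return slope, intercept, r2, sse


def _segment_conductance(slope: float, voltage: float, renorm: float) -> float:
    return abs(slope * units.E_PER_NS_TO_PA * renorm) / abs(voltage)


def _segment_ratio(series: ChargeSeries, t_lo: float, t_hi: float) -> float:
    n_cat = sum(1 for ev in series.events if ev.valence > 0 and t_lo <= ev.time <= t_hi)
    n_an = sum(1 for ev in series.events if ev.valence < 0 and t_lo <= ev.time <= t_hi)
    return n_an / n_cat if n_cat else math.nan


def fit_single(
    series: ChargeSeries, voltage: float = 40.0, renorm: float = 1.0
) -> RegimeFit:
    """One OLS segment over the full series."""
    t, q = series.times, series.q_tot
    if len(t) < 10:
        raise ValidationError("need at least 10 grid points")
    slope, intercept, r2, sse = _ols(t, q)
    seg = SegmentFit(
        t_start=float(t[0]),
        t_end=float(t[-1]),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        conductance=_segment_conductance(slope, voltage, renorm),
        current_ratio=_segment_ratio(series, t[0], t[-1]),
    )
    return RegimeFit(
        model="single",
        segments=[seg],
        bifurcation_time=None,
        sse=sse,
        voltage=voltage,
        renorm_factor=renorm,
        n_points=len(t),
    )


def fit_changepoint(
    series: ChargeSeries,
    min_segment: float = 50.0,
    voltage: float = 40.0,
    renorm: float = 1.0,
) -> RegimeFit:
    """Best two-segment fit with the bifurcation time found by grid search.

    Every admissible split point on the frame grid is scored by the total
    SSE of two independent OLS segments (no continuity constraint); the
    minimiser is returned. ``min_segment`` (ns) excludes change points
    closer than that to either end.
    """
    t, q = series.times, series.q_tot
    n = len(t)
    if series.duration < 2 * min_segment:
        raise ValidationError("series shorter than twice min_segment")

    # prefix cumulants -> O(1) SSE per candidate split
    c_n = np.arange(1, n + 1, dtype=float)
    c_t = np.cumsum(t)
    c_q = np.cumsum(q)
    c_tt = np.cumsum(t * t)
    c_tq = np.cumsum(t * q)
    c_qq = np.cumsum(q * q)

    def sse_prefix(m):  # SSE of OLS on points [0, m)
        nn = c_n[m - 1]
        st = c_tt[m - 1] - c_t[m - 1] ** 2 / nn
        sq = c_qq[m - 1] - c_q[m - 1] ** 2 / nn
        stq = c_tq[m - 1] - c_t[m - 1] * c_q[m - 1] / nn
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sq - np.where(st > 0, stq**2 / np.maximum(st, 1e-300), 0.0)
        return np.maximum(out, 0.0)

    def sse_suffix(m):  # SSE of OLS on points [m, n)
        nn = c_n[-1] - c_n[m - 1]
        st_ = (c_tt[-1] - c_tt[m - 1]) - (c_t[-1] - c_t[m - 1]) ** 2 / nn
        sq_ = (c_qq[-1] - c_qq[m - 1]) - (c_q[-1] - c_q[m - 1]) ** 2 / nn
        stq_ = (c_tq[-1] - c_tq[m - 1]) - (c_t[-1] - c_t[m - 1]) * (
            c_q[-1] - c_q[m - 1]
        ) / nn
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sq_ - np.where(st_ > 0, stq_**2 / np.maximum(st_, 1e-300), 0.0)
        return np.maximum(out, 0.0)

    lo_t = t[0] + min_segment
    hi_t = t[-1] - min_segment
    candidates = np.flatnonzero((t >= lo_t) & (t <= hi_t))
    candidates = candidates[(candidates >= 2) & (candidates <= n - 2)]
    if len(candidates) == 0:
        raise ValidationError("no admissible change point inside the exclusion window")

    total = sse_prefix(candidates) + sse_suffix(candidates)
    best = candidates[int(np.argmin(total))]
    t_star = float(t[best])

    segs = []
    for sl in (slice(0, best), slice(best, n)):
        slope, intercept, r2, _sse = _ols(t[sl], q[sl])
        segs.append(
            SegmentFit(
                t_start=float(t[sl][0]),
                t_end=float(t[sl][-1]),
                slope=slope,
                intercept=intercept,
                r_squared=r2,
                conductance=_segment_conductance(slope, voltage, renorm),
                current_ratio=_segment_ratio(series, t[sl][0], t[sl][-1]),
            )
        )
    return RegimeFit(
        model="two-segment",
        segments=segs,
        bifurcation_time=t_star,
        sse=float(np.min(total)),
        voltage=voltage,
        renorm_factor=renorm,
        n_points=len(t),
    )


def select_model(
    single: RegimeFit, two: RegimeFit, extra_params: int = 2
) -> RegimeFit:
    """Pick the two-segment fit iff its BIC improves on the single fit.

    BIC = n·ln(SSE/n) + k·ln(n); the two-segment model is charged
    ``extra_params`` additional parameters (the second slope/intercept
    pair). The winning fit carries ``selection_score`` = BIC(single) −
    BIC(two-segment); a positive score favours the two-segment model.
    """
    if single.model != "single" or two.model != "two-segment":
        raise ValidationError("pass (single, two-segment) in that order")
    n = single.n_points
    if n == 0 or n != two.n_points:
        raise ValidationError("fits must come from the same series")
    eps = 1e-300
    bic_single = n * math.log(max(single.sse, eps) / n) + 2 * math.log(n)
    bic_two = n * math.log(max(two.sse, eps) / n) + (2 + extra_params) * math.log(n)
    score = bic_single - bic_two
    winner = two if score > 0 else single
    winner.selection_score = score
    return winner


def classify_state(
    fit: RegimeFit,
    open_reference_ns: float,
    sigma_threshold: float = 2.3,
    r2_threshold: float = 0.99,
    band: tuple[float, float] = (0.40, 0.60),
    open_tolerance: float = 0.15,
) -> StateClass:
    """Label a fitted trajectory as stable-low / open-like / bistable / unstable.

    A single-segment fit is *stable-low* when its conductance σ stays at or
    below ``sigma_threshold`` with R² at or above ``r2_threshold``, and
    *open-like* when σ falls within ``open_tolerance`` of the open-state
    reference. A selected two-segment fit is *bistable* when one segment's
    conductance lies inside ``band`` (as a fraction of the open reference)
    and the other within ``open_tolerance`` of the reference. Anything else
    is *unstable*.
    """
    if open_reference_ns <= 0:
        raise ValidationError("open_reference_ns must be > 0")
    lo, hi = band

    def near_open(g):
        return abs(g - open_reference_ns) <= open_tolerance * open_reference_ns

    if fit.model == "single":
        seg = fit.segments[0]
        sigma, r2 = seg.conductance, seg.r_squared
        frac = sigma / open_reference_ns
        if sigma <= sigma_threshold and r2 >= r2_threshold:
            label = "stable-low"
        elif near_open(sigma):
            label = "open-like"
        else:
            label = "unstable"
    else:
        g_low, g_high = sorted(fit.conductances)
        sigma = g_low
        r2 = min(s.r_squared for s in fit.segments)
        frac = g_low / open_reference_ns
        in_band = lo <= frac <= hi
        label = "bistable" if in_band and near_open(g_high) else "unstable"

    return StateClass(
        label=label,
        sigma=sigma,
        r_squared=r2,
        fraction_of_open=frac,
        criteria={
            "sigma_threshold_nS": sigma_threshold,
            "r2_threshold": r2_threshold,
            "band": list(band),
            "open_reference_nS": open_reference_ns,
            "open_tolerance": open_tolerance,
        },
    )


def rolling_slopes(series: ChargeSeries, window: float) -> np.ndarray:
    """Local OLS slopes of q_tot over sliding windows of ``window`` ns.

    Used to probe for abrupt regime switching: a genuinely bistable series
    yields a bimodal slope distribution with no intermediate plateau.
    """
    t, q = series.times, series.q_tot
    dt = float(t[1] - t[0])
    w = max(2, int(round(window / dt)))
    if w >= len(t):
        raise ValidationError("window longer than the series")
    x = t[:w] - t[:w].mean()
    denom = float(np.sum(x * x))
    # sum(x) == 0, so the window-mean term drops out of the covariance
    return np.correlate(q, x, mode="valid") / denom


def screen_conformers(
    estimates: list[CurrentEstimate],
    threshold_ns: float = 2.5,
    open_reference_ns: float = 3.7,
) -> tuple[list[CurrentEstimate], dict]:
    """Select conformers with conductance below the screening threshold.

    Returns the sub-threshold subset and a summary whose
    ``threshold_percent_of_open`` is the threshold expressed as an integer
    (truncated) percentage of the open-state reference conductance.
    """
    if not estimates:
        raise ValidationError("empty batch")
    selected = [e for e in estimates if e.conductance < threshold_ns]
    summary = {
        "n_total": len(estimates),
        "n_selected": len(selected),
        "threshold_nS": threshold_ns,
        "open_reference_nS": open_reference_ns,
        "threshold_percent_of_open": int(100.0 * threshold_ns / open_reference_ns),
    }
    return selected, summary
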