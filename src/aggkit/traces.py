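"""Trace-level analysis: normalization, replicate averaging, sigmoid fits,
half-time concentration scaling and plateau linearity.

The workhorse is a four-parameter logistic

    F(t) = base + (plateau - base) / (1 + exp(-(t - t_mid)/w))

fitted by least squares to each trace.  The aggregation half time tau_1/2 is
the time at which the *fitted* curve crosses (base+plateau)/2 — i.e. t_mid
for this functional form — which is robust to per-point noise in a way the
raw midpoint crossing is not.  Declining traces (¹⁹F signal decay, CD
extremes) are handled by the sign of (plateau - base); no separate code path
is needed.

Half times over a concentration series obey an approximate power law
tau_1/2 ∝ m0**gamma; gamma is the slope of log tau_1/2 against log m0 and
diagnoses the dominant nucleation mechanism (≈ -(n_2+1)/2 for unsaturated
secondary nucleation, ≈ -1/2 when saturated).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import linregress

__all__ = [
    "AggregationTrace",
    "HalfTimeEstimate",
    "ScalingFit",
    "NormalizationError",
    "SigmoidFitError",
    "normalize_trace",
    "average_replicates",
    "fit_sigmoid",
    "scaling_exponent",
    "plateau_linearity",
]

MODALITIES = ("tht", "f19", "cd_extreme")
DIRECTIONS = ("rising", "declining")


class NormalizationError(ValueError):
    pass


class SigmoidFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class AggregationTrace:
    """One aggregation time series with its experimental context.

    time and signal are equal-length arrays (length >= 10, strictly
    increasing time); m0 is the initial monomer concentration in μM;
    modality is one of tht / f19 / cd_extreme; direction says whether the
    raw signal rises or declines with aggregation.
    """

    time: np.ndarray
    signal: np.ndarray
    m0: float
    replicate_id: str = "r0"
    modality: str = "tht"
    direction: str = "rising"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size < 10:
            raise ValueError("trace needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.m0 > 0:
            raise ValueError("m0 must be > 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class HalfTimeEstimate:
    """tau_1/2 with uncertainty and diagnostics from a logistic fit."""

    tau_half: float
    tau_half_se: float
    width: float
    base: float
    plateau: float
    rss: float
    baseline_slope: float = 0.0  # nonzero only with linear_baseline fits

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be > 0")


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit tau_1/2 ∝ m0**gamma on double-log axes."""

    gamma: float
    gamma_se: float
    log_intercept: float
    r_squared: float


def _logistic(t, base, plateau, t_mid, w):
    z = np.clip(-(t - t_mid) / w, -700.0, 700.0)
    return base + (plateau - base) / (1.0 + np.exp(z))


def _midpoint_crossing(time: np.ndarray, signal: np.ndarray) -> float:
    """First time the signal crosses its own midpoint (linear interpolation)."""
    mid = 0.5 * (signal.min() + signal.max())
    d = signal - mid
    idx = np.nonzero(np.diff(np.signbit(d)))[0]
    if idx.size == 0:
        raise SigmoidFitError("signal never crosses its own midpoint")
    i = idx[0]
    frac = d[i] / (d[i] - d[i + 1])
    return float(time[i] + frac * (time[i + 1] - time[i]))


def _logistic_sloped(t, base, plateau, t_mid, w, slope):
    return _logistic(t, base, plateau, t_mid, w) + slope * t


def fit_sigmoid(
    trace: AggregationTrace, *, linear_baseline: bool = False
) -> HalfTimeEstimate:
    """Fit a four-parameter logistic and report the aggregation half time.

    Multi-start initialization: t_mid is seeded at the raw midpoint crossing
    and w at several fractions of the time span (5% first).  A fitted
    negative width is folded into a base/plateau swap (the logistic is
    symmetric under (w, base, plateau) -> (-w, plateau, base)).  The standard
    error of tau_1/2 comes from the covariance of the fit.  With
    ``linear_baseline=True`` a shared linear drift term is added (off by
    default; plain sigmoids are the norm for these data).
    """
    t, s = trace.time, trace.signal
    span = t[-1] - t[0]
    amp = s.max() - s.min()
    if amp == 0.0:
        raise SigmoidFitError(
            f"trace {trace.replicate_id!r}: constant signal, no transition"
        )
    t_mid0 = _midpoint_crossing(t, s)
    base0 = float(np.mean(s[: max(3, s.size // 20)]))
    plat0 = float(np.mean(s[-max(3, s.size // 20):]))
    if base0 == plat0:
        base0, plat0 = float(s[0]), float(s[-1])
    model = _logistic_sloped if linear_baseline else _logistic

    best = None
    for w_frac in (0.05, 0.02, 0.1, 0.25):
        p0 = [base0, plat0, t_mid0, w_frac * span]
        if linear_baseline:
            p0.append(0.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(model, t, s, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        resid = s - model(t, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        if rss <= 1e-12 * amp * amp * s.size:
            break
    if best is None:
        raise SigmoidFitError(
            f"trace {trace.replicate_id!r}: logistic fit did not converge "
            f"from any start"
        )
    popt, pcov, rss = best
    base, plateau, t_mid, w = popt[:4]
    slope = float(popt[4]) if linear_baseline else 0.0
    if w < 0:  # symmetric reparameterization
        w = -w
        base, plateau = plateau, base
    if not (t[0] <= t_mid <= t[-1]):
        raise SigmoidFitError(
            f"trace {trace.replicate_id!r}: fitted half time {t_mid:g} lies "
            f"outside the observed range [{t[0]:g}, {t[-1]:g}]"
        )
    se = float(np.sqrt(max(pcov[2, 2], 0.0))) if np.all(np.isfinite(pcov)) else math.nan
    return HalfTimeEstimate(
        tau_half=float(t_mid), tau_half_se=se, width=float(w),
        base=float(base), plateau=float(plateau), rss=rss,
        baseline_slope=slope,
    )


def normalize_trace(trace: AggregationTrace) -> AggregationTrace:
    """Map the fitted baseline to 0 and the fitted plateau to 1.

    Declining traces come out rising (aggregation extent), with the original
    orientation retained in ``meta['original_direction']``.  Raises
    :class:`NormalizationError` naming the trace when no sigmoidal
    transition can be resolved.
    """
    try:
        est = fit_sigmoid(trace)
    except SigmoidFitError as exc:
        raise NormalizationError(
            f"cannot normalize trace {trace.replicate_id!r}: {exc}"
        ) from exc
    lo, hi = est.base, est.plateau
    if lo == hi:
        raise NormalizationError(
            f"cannot normalize trace {trace.replicate_id!r}: degenerate fit"
        )
    norm = (trace.signal - lo) / (hi - lo)
    meta = dict(trace.meta)
    meta.setdefault("original_direction", trace.direction)
    meta["normalization"] = {"base": lo, "plateau": hi}
    return replace(trace, signal=norm, direction="rising", meta=meta)


def average_replicates(traces: Sequence[AggregationTrace]) -> AggregationTrace:
    """Pointwise mean of replicate traces on the intersection time grid.

    All traces must share m0 and modality.  Traces are linearly interpolated
    onto the first trace's time points restricted to the overlap of all time
    ranges (no extrapolation); the replicate count is recorded in meta.
    """
    if not traces:
        raise ValueError("no traces to average")
    ref = traces[0]
    for tr in traces[1:]:
        if not math.isclose(tr.m0, ref.m0, rel_tol=1e-9):
            raise ValueError(
                f"mixed concentrations: {tr.m0} vs {ref.m0} μM"
            )
        if tr.modality != ref.modality:
            raise ValueError("mixed modalities")
    t_lo = max(tr.time[0] for tr in traces)
    t_hi = min(tr.time[-1] for tr in traces)
    if t_hi <= t_lo:
        raise ValueError("time ranges do not overlap")
    mask = (ref.time >= t_lo) & (ref.time <= t_hi)
    grid = ref.time[mask]
    if grid.size < 10:
        raise ValueError("intersection grid has fewer than 10 points")
    stack = np.vstack([np.interp(grid, tr.time, tr.signal) for tr in traces])
    meta = {"n_replicates": len(traces),
            "replicates": [tr.replicate_id for tr in traces]}
    return AggregationTrace(
        time=grid, signal=stack.mean(axis=0), m0=ref.m0,
        replicate_id=f"mean_of_{len(traces)}", modality=ref.modality,
        direction=ref.direction, meta=meta,
    )


def scaling_exponent(pairs: Sequence[tuple[float, object]]) -> ScalingFit:
    """OLS fit of log tau_1/2 on log m0; gamma is the slope.

    ``pairs`` holds (m0, tau) where tau may be a float or a
    :class:`HalfTimeEstimate`.  Requires at least three distinct
    concentrations with positive half times.
    """
    m0s, taus = [], []
    for m0, est in pairs:
        tau = getattr(est, "tau_half", est)
        m0s.append(float(m0))
        taus.append(float(tau))
    m0s, taus = np.asarray(m0s), np.asarray(taus)
    if np.unique(m0s).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.any(taus <= 0):
        raise ValueError("all half times must be > 0")
    x, y = np.log(m0s), np.log(taus)
    res = linregress(x, y)
    ss_res = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return ScalingFit(gamma=float(res.slope), gamma_se=se,
                      log_intercept=float(res.intercept), r_squared=r2)


def plateau_linearity(
    finals: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS of final signal intensity against initial monomer concentration.

    Returns (slope, intercept, r_squared).  A linear relation with near-zero
    intercept indicates that essentially all initial monomer converts to
    signal-active fibril mass.
    """
    if len(finals) < 3:
        raise ValueError("need >= 3 points")
    m0s = np.array([f[0] for f in finals], dtype=float)
    vals = np.array([f[1] for f in finals], dtype=float)
    if np.unique(m0s).size < 2:
        raise ValueError("degenerate input: all concentrations identical")
    res = linregress(m0s, vals)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2
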