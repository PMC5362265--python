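"""Time-course analysis of Pol I complex levels: normalization, inter-measurement
assembly/disassembly rates, exponential/logistic fits, and stage labeling.

Levels of each complex are normalized to their highest measurement. Rates are
forward differences between consecutive measurements (level per minute,
positive = assembly). The three-stage structure of the response — fast
adjustment of one complex, then fast adjustment of the other, then slow
consolidation of both — is operationalized by a per-interval rule: an
interval is consolidation when both complexes move slower than a fraction of
the fastest observed rate, otherwise it is labeled by the complex with the
larger rate magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeCourse",
    "RateSeries",
    "StageLabels",
    "KineticFit",
    "normalize_levels",
    "interval_rates",
    "fit_exponential_decay",
    "fit_logistic",
    "classify_stages",
]


@dataclass
class TimeCourse:
    complex_id: str
    timepoints: np.ndarray  # minutes, strictly increasing
    levels: np.ndarray  # non-negative
    normalized: bool = False

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.timepoints.shape != self.levels.shape:
            raise ValueError("timepoints and levels must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.levels < 0):
            raise ValueError("levels must be non-negative")


@dataclass
class RateSeries:
    complex_id: str
    midpoints: np.ndarray  # minutes
    rates: np.ndarray  # level / minute, signed
    timepoints: np.ndarray  # the source grid (len = len(rates) + 1)


@dataclass
class StageLabels:
    interval_labels: list[str]  # per interval, complex_A_fast | complex_B_fast | consolidation
    boundaries: list[float]  # timepoints at which the stage changes
    segments: list[tuple[float, float, str]]  # (t_start, t_end, label), merged


@dataclass
class KineticFit:
    model: str  # exponential_decay | logistic
    params: dict
    rss: float
    converged: bool
    degenerate: bool = False


def normalize_levels(tc: TimeCourse) -> TimeCourse:
    """Divide levels by their maximum so the highest measurement is exactly 1."""
    vmax = tc.levels.max() if tc.levels.size else 0.0
    if vmax <= 0:
        raise ValueError("cannot normalize an all-zero series")
    return TimeCourse(tc.complex_id, tc.timepoints.copy(), tc.levels / vmax,
                      normalized=True)


def interval_rates(tc: TimeCourse) -> RateSeries:
    """Forward-difference rate between consecutive measurements.

    Satisfies the telescoping identity sum(rate_k * dt_k) = v_last - v_first
    exactly.
    """
    if tc.timepoints.size < 2:
        raise ValueError("need >= 2 timepoints")
    dt = np.diff(tc.timepoints)
    rates = np.diff(tc.levels) / dt
    mids = 0.5 * (tc.timepoints[:-1] + tc.timepoints[1:])
    return RateSeries(tc.complex_id, mids, rates, tc.timepoints.copy())


# ---------------------------------------------------------------------------
# kinetic fits (descriptive; the shapes, not mechanistic parameters)
# ---------------------------------------------------------------------------

def _exp_model(t, amplitude, tau, offset):
    return offset + amplitude * np.exp(-t / tau)


def _logistic_model(t, lo, hi, t50, steepness):
    return lo + (hi - lo) / (1.0 + np.exp(-steepness * (t - t50)))


def fit_exponential_decay(tc: TimeCourse) -> KineticFit:
    """Least-squares fit of v(t) = offset + amplitude * exp(-t / tau).

    Initialized from the endpoints (offset ~ last value, amplitude ~ first
    minus last) with tau from a log-linear regression of v - offset.
    """
    t, v = tc.timepoints, tc.levels
    if t.size < 4:
        raise ValueError("need >= 4 points to fit")
    offset0 = float(v[-1])
    amp0 = float(v[0] - v[-1])
    span = float(t[-1] - t[0])
    if abs(amp0) < 1e-12 * max(1.0, abs(v).max()) or np.ptp(v) == 0:
        fit = KineticFit("exponential_decay",
                         {"amplitude": 0.0, "tau": span, "offset": float(v.mean())},
                         float(((v - v.mean()) ** 2).sum()), True, degenerate=True)
        return fit
    resid = v - offset0
    good = resid / amp0 > 1e-9  # same sign as the initial amplitude
    if good.sum() >= 2:
        slope = np.polyfit(t[good], np.log(np.abs(resid[good]) + 1e-30), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else span / 2
    else:
        tau0 = span / 2
    tau0 = float(np.clip(tau0, 1e-3, 100 * span))
    try:
        popt, _ = curve_fit(_exp_model, t, v, p0=[amp0, tau0, offset0],
                            bounds=([-np.inf, 1e-9, -np.inf],
                                    [np.inf, np.inf, np.inf]), maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = [amp0, tau0, offset0], False
    amp, tau, off = (float(x) for x in popt)
    rss = float(((v - _exp_model(t, amp, tau, off)) ** 2).sum())
    return KineticFit("exponential_decay",
                      {"amplitude": amp, "tau": tau, "offset": off},
                      rss, converged)


def fit_logistic(tc: TimeCourse) -> KineticFit:
    """Least-squares 4-parameter logistic fit.

    The steepness is unconstrained in sign, so time-mirrored data fit with
    the same t50 and a flipped sign.
    """
    t, v = tc.timepoints, tc.levels
    if t.size < 4:
        raise ValueError("need >= 4 points to fit")
    lo0, hi0 = float(v.min()), float(v.max())
    span = float(t[-1] - t[0])
    if hi0 - lo0 < 1e-12 * max(1.0, abs(v).max()):
        return KineticFit("logistic",
                          {"lo": lo0, "hi": hi0, "t50": float(t.mean()),
                           "steepness": 0.0},
                          float(((v - v.mean()) ** 2).sum()), True, degenerate=True)
    mid = 0.5 * (lo0 + hi0)
    cross = np.nonzero(np.diff(np.sign(v - mid)))[0]
    t50_0 = float(0.5 * (t[cross[0]] + t[cross[0] + 1])) if cross.size \
        else float(t.mean())
    dvdt = np.diff(v) / np.diff(t)
    k = int(np.argmax(np.abs(dvdt)))
    s0 = float(4 * dvdt[k] / (hi0 - lo0))
    if s0 == 0:
        s0 = 1.0 / span
    try:
        popt, _ = curve_fit(_logistic_model, t, v, p0=[lo0, hi0, t50_0, s0],
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = [lo0, hi0, t50_0, s0], False
    lo, hi, t50, s = (float(x) for x in popt)
    rss = float(((v - _logistic_model(t, lo, hi, t50, s)) ** 2).sum())
    return KineticFit("logistic", {"lo": lo, "hi": hi, "t50": t50,
                                   "steepness": s}, rss, converged)


# ---------------------------------------------------------------------------
# stage labeling
# ---------------------------------------------------------------------------

def classify_stages(rates_a: RateSeries, rates_b: RateSeries,
                    slow_threshold: float = 0.2,
                    label_a: str = "complex_A_fast",
                    label_b: str = "complex_B_fast") -> StageLabels:
    """Label each inter-measurement interval by the dominant complex.

    ``consolidation`` when both |rates| fall below ``slow_threshold`` times
    the maximum |rate| observed across both complexes; otherwise the complex
    with the larger |rate| claims the interval. Contiguous runs are merged.
    """
    if not np.array_equal(rates_a.timepoints, rates_b.timepoints):
        raise ValueError("rate series must share the same interval grid")
    ra, rb = np.abs(rates_a.rates), np.abs(rates_b.rates)
    vmax = max(ra.max(initial=0.0), rb.max(initial=0.0))
    cutoff = slow_threshold * vmax
    labels = []
    for a, b in zip(ra, rb):
        if vmax == 0 or (a < cutoff and b < cutoff):
            labels.append("consolidation")
        elif a >= b:
            labels.append(label_a)
        else:
            labels.append(label_b)
    t = rates_a.timepoints
    segments, boundaries = [], []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            segments.append((float(t[start]), float(t[k]), labels[start]))
            if k < len(labels):
                boundaries.append(float(t[k]))
            start = k
    return StageLabels(labels, boundaries, segments)
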