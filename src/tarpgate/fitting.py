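"""Measurement operations applied to current traces.

Everything an electrophysiologist extracts from macroscopic records:
multi-exponential relaxation fits (desensitization entry, deactivation),
two-pulse recovery fits, the superactivation metric, charge-transfer change
during trains, and Hill fits of concentration-response data.

All fits run a fixed, documented multi-start grid followed by
variable-projection least squares, so repeated calls are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .protocols import SimTrace

__all__ = [
    "ExpFit",
    "RecoveryFit",
    "SuperactivationResult",
    "FitError",
    "fit_exponentials",
    "fit_recovery",
    "fit_suprarecovery",
    "superactivation",
    "charge_transfer_change",
    "fit_hill",
]


class FitError(RuntimeError):
    """A fit failed to converge or the data are degenerate."""


# ---------------------------------------------------------------------------
# Multi-exponential relaxation fitting
# ---------------------------------------------------------------------------

@dataclass
class ExpFit:
    """Sum-of-exponentials fit y(t) = baseline + sum_i a_i exp(-k_i t).

    ``weighted_rate`` is the amplitude-weighted mean rate
    sum(|a_i| k_i) / sum(|a_i|), the conventional summary of multi-component
    relaxations.
    """

    amplitudes: np.ndarray
    rates: np.ndarray
    baseline: float
    residual_norm: float
    window: tuple[float, float]

    @property
    def weighted_rate(self) -> float:
        w = np.abs(self.amplitudes)
        if w.sum() == 0:
            raise FitError("all fitted amplitudes are zero")
        return float((w * self.rates).sum() / w.sum())

    @property
    def weighted_tau(self) -> float:
        """Amplitude-weighted mean time constant (seconds)."""
        w = np.abs(self.amplitudes)
        return float((w / self.rates).sum() / w.sum())

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        return self.baseline + (
            self.amplitudes[None, :]
            * np.exp(-np.outer(t, self.rates))).sum(axis=1)


def _varpro_residual(log_rates, t, y, fit_baseline):
    """Residual after solving amplitudes (and baseline) linearly."""
    rates = np.exp(log_rates)
    cols = [np.exp(-rates[i] * t) for i in range(len(rates))]
    if fit_baseline:
        cols.append(np.ones_like(t))
    a_mat = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
    return a_mat @ coef - y, coef


def fit_exponentials(trace_or_t, current=None, *, window=None,
                     n_components: int = 2,
                     baseline: str = "free") -> ExpFit:
    """Least-squares multi-exponential fit of a relaxation.

    Accepts either a :class:`SimTrace` (with ``window=(t0, t1)`` in trace
    time) or raw ``(t, y)`` arrays. Time is re-zeroed to the window start.
    A fixed log-spaced grid of starting rates makes the result
    deterministic.
    """
    if isinstance(trace_or_t, SimTrace):
        if window is None:
            raise ValueError("window required when fitting a SimTrace")
        mask = trace_or_t.window(*window)
        t = trace_or_t.time[mask]
        y = trace_or_t.current[mask]
    else:
        t = np.asarray(trace_or_t, dtype=float)
        y = np.asarray(current, dtype=float)
        if window is not None:
            mask = (t >= window[0]) & (t <= window[1])
            t, y = t[mask], y[mask]
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1-3")
    if len(t) < 10 * n_components:
        raise FitError(f"window holds {len(t)} samples; "
                       f"need >= {10 * n_components}")
    t0 = t[0]
    t = t - t0
    span = t[-1] if t[-1] > 0 else 1.0
    fit_baseline = baseline == "free"

    # Deterministic multi-start: all sorted combinations from a log grid.
    # Rates are bounded away from zero so no component degenerates into
    # the baseline.
    lo = math.log(0.05 / span)
    hi = math.log(2.0 / max(np.diff(t).min(), 1e-12))
    grid = np.geomspace(0.5 / span, 0.2 / max(np.diff(t).min(), 1e-12), 7)
    from itertools import combinations
    starts = list(combinations(np.log(grid), n_components))

    best = None
    for s in starts:
        r, _ = _varpro_residual(np.array(s), t, y, fit_baseline)
        cost = float(r @ r)
        if best is None or cost < best[0]:
            best = (cost, np.array(s))
    result = least_squares(
        lambda lr: _varpro_residual(lr, t, y, fit_baseline)[0],
        np.clip(best[1], lo, hi), bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, max_nfev=2000)
    if not result.success and result.status <= 0:
        raise FitError(f"exponential fit did not converge: {result.message}")
    _, coef = _varpro_residual(result.x, t, y, fit_baseline)
    rates = np.exp(result.x)
    amps = coef[:n_components]
    base = float(coef[n_components]) if fit_baseline else 0.0
    order = np.argsort(rates)[::-1]
    return ExpFit(amps[order], rates[order], base,
                  float(np.linalg.norm(result.fun)), (t0, t0 + t[-1]))


# ---------------------------------------------------------------------------
# Recovery from desensitization
# ---------------------------------------------------------------------------

#: Exponent of the Hodgkin-Huxley-type recovery function. The squared
#: exponential is the conventional form for AMPA receptor recovery.
HH_EXPONENT = 2


@dataclass
class RecoveryFit:
    """Two-pulse recovery fit.

    ``model = "HH"``: N(t) = N0 + (1 - N0) (1 - exp(-k_rec t))^m.
    ``model = "biexponential"`` (suprarecovery):
    N(t) = 1 + N_sup exp(-k_sup t) - (1 - N0 + N_sup) exp(-k_rec t),
    i.e. a rising recovery exponential plus a decaying superactivation
    component, constrained to N(0) = N0 and N(inf) = 1.
    """

    k_rec: float
    n0: float
    model: str
    n_sup: float | None = None
    k_sup: float | None = None
    residual_norm: float = 0.0
    overshoot: bool = False

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "HH":
            return self.n0 + (1 - self.n0) * (
                1 - np.exp(-self.k_rec * t)) ** HH_EXPONENT
        return (1.0 + self.n_sup * np.exp(-self.k_sup * t)
                - (1 - self.n0 + self.n_sup) * np.exp(-self.k_rec * t))


def fit_recovery(intervals, responses, *, exponent: int = HH_EXPONENT
                 ) -> RecoveryFit:
    """Fit the fractional recovery curve with the HH-type function."""
    t = np.asarray(intervals, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(t) < 4:
        raise FitError("need at least 4 recovery points")
    if np.any(y <= 0):
        raise FitError("responses must be positive")
    if np.ptp(y) < 1e-6:
        raise FitError("responses are constant; recovery rate unidentifiable")
    if y.max() > 1.02:
        raise FitError("responses exceed 1: overshoot present, "
                       "use fit_suprarecovery")

    def model(p):
        k, n0 = p
        return n0 + (1 - n0) * (1 - np.exp(-k * t)) ** exponent

    best = None
    for k0 in np.geomspace(0.1 / t.max(), 10 / t.min(), 12):
        res = least_squares(lambda p: model(p) - y, [k0, max(y.min(), 1e-3)],
                            bounds=([1e-6, 0.0], [np.inf, 1.0]),
                            xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    k, n0 = best.x
    return RecoveryFit(float(k), float(n0), "HH",
                       residual_norm=float(np.linalg.norm(best.fun)))


def fit_suprarecovery(intervals, responses) -> RecoveryFit:
    """Biexponential fit of a recovery curve with an overshoot (hump).

    Falls back to the HH fit (``overshoot=False``) when no response
    exceeds unity.
    """
    t = np.asarray(intervals, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(t) < 6:
        raise FitError("need at least 6 recovery points")
    if y.max() <= 1.0:
        fit = fit_recovery(t, y)
        fit.overshoot = False
        return fit

    def model(p):
        k_rec, n0, n_sup, k_sup = p
        return (1.0 + n_sup * np.exp(-k_sup * t)
                - (1 - n0 + n_sup) * np.exp(-k_rec * t))

    best = None
    for k0 in np.geomspace(0.1 / t.max(), 10 / t.min(), 8):
        for ks in (0.5, 2.0, 8.0):
            p0 = [k0, max(min(y.min(), 0.99), 1e-3),
                  max(y.max() - 1, 1e-3), ks]
            res = least_squares(
                lambda p: model(p) - y, p0,
                bounds=([1e-6, 0.0, 0.0, 1e-6], [np.inf, 1.0, 2.0, np.inf]),
                xtol=1e-14, ftol=1e-14)
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    k_rec, n0, n_sup, k_sup = best.x
    return RecoveryFit(float(k_rec), float(n0), "biexponential",
                       n_sup=float(n_sup), k_sup=float(k_sup),
                       residual_norm=float(np.linalg.norm(best.fun)),
                       overshoot=True)


# ---------------------------------------------------------------------------
# Superactivation
# ---------------------------------------------------------------------------

@dataclass
class SuperactivationResult:
    """Slow activity-dependent current increase during a long application.

    ``magnitude`` is the excess steady-state amplitude over the trough
    following the initial peak, as a percentage of the peak current; in CTZ
    mode (desensitization blocked, no trough) the initial fast peak is the
    reference instead.
    """

    magnitude: float            # %
    rate: float | None          # s^-1, None when magnitude == 0
    reference_mode: str         # "trough" | "initial-peak"
    i_peak: float = float("nan")
    i_trough: float = float("nan")
    i_end: float = float("nan")


#: Trough search: from initial peak + 2 ms to this fraction of the pulse.
TROUGH_SEARCH_FRACTION = 0.5
#: The initial fast peak must occur within this time of agonist onset.
INITIAL_PEAK_WINDOW = 2e-3
#: Boxcar width for extremum detection: averaging suppresses the upward
#: peak / downward trough bias that sample noise otherwise causes.
EXTREMUM_SMOOTHING = 1e-3


def _smoothed(trace: SimTrace, width: float) -> np.ndarray:
    n = max(int(round(width / max(trace.time[1] - trace.time[0], 1e-12))), 1)
    if n <= 1:
        return trace.current
    kernel = np.ones(n) / n
    return np.convolve(trace.current, kernel, mode="same")


def superactivation(trace: SimTrace, *, ctz_mode: bool = False
                    ) -> SuperactivationResult:
    """Measure superactivation on a long (>= 1 s) agonist application."""
    on, off = trace.protocol.agonist_window()
    duration = off - on
    if duration < 1.0:
        raise ValueError("superactivation needs a >= 1 s agonist application")
    smooth = _smoothed(trace, EXTREMUM_SMOOTHING)
    end_mask = trace.window(off - 0.05 * duration, off)
    i_end = float(trace.current[end_mask].mean())

    peak_mask = trace.window(on, on + INITIAL_PEAK_WINDOW)
    i_init = float(smooth[peak_mask].max())
    t_init = float(trace.time[peak_mask][np.argmax(smooth[peak_mask])])
    if i_init <= 0:
        raise FitError("no identifiable initial peak")

    if ctz_mode:
        reference = "initial-peak"
        i_ref = i_init
        magnitude = 100.0 * (i_end - i_init) / i_init
        rise_start = t_init
    else:
        reference = "trough"
        full_peak = float(smooth[trace.window(on, off)].max())
        search = trace.window(t_init + 2e-3,
                              on + TROUGH_SEARCH_FRACTION * duration)
        if not search.any():
            raise FitError("no identifiable trough")
        i_trough = float(smooth[search].min())
        t_trough = float(trace.time[search][np.argmin(smooth[search])])
        i_ref = full_peak
        magnitude = 100.0 * (i_end - i_trough) / full_peak
        rise_start = t_trough

    if magnitude <= 0:
        return SuperactivationResult(0.0, None, reference, i_init,
                                     i_ref if ctz_mode else i_trough, i_end)

    # Rate of the slow rise: single-exponential approach to the plateau.
    fit = fit_exponentials(trace, window=(rise_start, off - 1e-3),
                           n_components=1, baseline="free")
    return SuperactivationResult(
        float(magnitude), float(fit.rates[0]), reference,
        i_init, i_ref if ctz_mode else i_trough, i_end)


# ---------------------------------------------------------------------------
# Charge transfer during trains
# ---------------------------------------------------------------------------

def charge_transfer_change(trace: SimTrace,
                           pulse_onsets=None) -> float:
    """Relative change in charge transfer across a train, in percent.

    Q1 is the charge (time-integral of current) in the first five
    pulse periods, Q2 in the last five; returns (Q2 - Q1)/Q1 * 100.
    """
    if pulse_onsets is None:
        pulse_onsets = trace.protocol.pulse_onsets()
    onsets = np.asarray(pulse_onsets, dtype=float)
    if len(onsets) < 10:
        raise ValueError("need at least 10 pulses for a charge-transfer change")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("pulse windows overlap")
    period = float(np.median(np.diff(onsets)))
    dt = float(trace.time[1] - trace.time[0])
    n_per = int(round(period / dt))
    charges = []
    for t_on in onsets:
        i0 = int(round((t_on - trace.time[0]) / dt))
        seg = trace.current[i0:i0 + n_per + 1]
        charges.append(float(np.trapezoid(seg, dx=dt)))
    q1 = sum(charges[:5])
    q2 = sum(charges[-5:])
    if q1 <= 0:
        raise FitError("no charge in the first pulses")
    return 100.0 * (q2 - q1) / q1


# ---------------------------------------------------------------------------
# Concentration-response
# ---------------------------------------------------------------------------

def fit_hill(concentrations, responses) -> tuple[float, float, float]:
    """Hill fit of a concentration-response relation.

    Returns (EC50, Hill slope, maximal response).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(c) < 5:
        raise FitError("need at least 5 concentrations")
    if np.ptp(y) < 1e-9 * max(abs(y.max()), 1e-30):
        raise FitError("responses are constant; EC50 unidentifiable")

    def model(p):
        log_ec50, n, top = p
        return top / (1.0 + np.exp(n * (log_ec50 - np.log(c))))

    best = None
    for ec0 in np.geomspace(c.min(), c.max(), 8):
        res = least_squares(lambda p: model(p) - y,
                            [math.log(ec0), 1.0, y.max()],
                            bounds=([math.log(c.min()) - 10, 0.1, 0],
                                    [math.log(c.max()) + 10, 6.0, np.inf]),
                            xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    log_ec50, n, top = best.x
    return float(math.exp(log_ec50)), float(n), float(top)
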