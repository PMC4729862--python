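"""Concentration-jump protocols and master-equation simulation.

Protocols are piecewise-constant agonist concentration timelines (the
solution exchange of a fast perfusion system idealized as instantaneous
steps; finite exchange lives in :mod:`tarpgate.synth`). Within each segment
the generator matrix is constant, so occupancies propagate exactly through
the matrix exponential; we use the spectral form of the (reversible,
symmetrizable) generator to evaluate all sample times of a segment in one
vectorized step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .scheme import KineticScheme, equilibrium_occupancy, generator_matrix

__all__ = [
    "Segment",
    "ConcentrationProtocol",
    "SimTrace",
    "make_pulse",
    "make_two_pulse",
    "make_train",
    "simulate",
    "stochastic_simulate",
    "peak_and_steady",
]

#: 20 kHz sampling, as in fast-perfusion patch recordings.
DEFAULT_SAMPLE_INTERVAL = 5e-5

#: Fraction of the agonist segment used for the steady-state window.
STEADY_STATE_FRACTION = 0.05


@dataclass(frozen=True)
class Segment:
    duration: float       # s
    concentration: float  # M

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("segment duration must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class ConcentrationProtocol:
    segments: tuple[Segment, ...]
    label: str = ""
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if not self.sample_interval > 0:
            raise ValueError("sample interval must be > 0")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times."""
        return np.cumsum([s.duration for s in self.segments])

    def concentration_at(self, t: np.ndarray) -> np.ndarray:
        edges = np.concatenate([[0.0], self.boundaries()])
        concs = np.array([s.concentration for s in self.segments])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1,
                      0, len(concs) - 1)
        return concs[idx]

    def agonist_window(self) -> tuple[float, float]:
        """(onset, offset) of the first nonzero-concentration stretch."""
        t0 = 0.0
        for seg in self.segments:
            if seg.concentration > 0:
                return t0, t0 + seg.duration
            t0 += seg.duration
        raise ValueError("protocol has no agonist segment")

    def pulse_onsets(self) -> np.ndarray:
        """Start times of every nonzero-concentration segment."""
        t0, onsets, prev_c = 0.0, [], 0.0
        for seg in self.segments:
            if seg.concentration > 0 and prev_c == 0:
                onsets.append(t0)
            prev_c = seg.concentration
            t0 += seg.duration
        return np.array(onsets)


def make_pulse(duration: float, concentration: float, *,
               pre: float = 0.01, post: float = 0.5,
               sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
               label: str = "") -> ConcentrationProtocol:
    """Baseline / agonist / washout, e.g. the 500 ms desensitization and
    1 ms deactivation protocols at 10 mM glutamate."""
    segs = (Segment(pre, 0.0), Segment(duration, concentration),
            Segment(post, 0.0))
    return ConcentrationProtocol(segs, label or f"pulse {duration*1e3:g} ms",
                                 sample_interval)


def make_two_pulse(conditioning: float, interval: float, test: float,
                   concentration: float, *, pre: float = 0.01,
                   post: float = 0.05,
                   sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
                   label: str = "") -> ConcentrationProtocol:
    """Two-pulse recovery protocol with a variable inter-pulse interval."""
    segs = (Segment(pre, 0.0), Segment(conditioning, concentration),
            Segment(interval, 0.0), Segment(test, concentration),
            Segment(post, 0.0))
    return ConcentrationProtocol(segs, label or "two-pulse", sample_interval)


def make_train(pulse: float, frequency: float, n_pulses: int,
               concentration: float, *, pre: float = 0.01, post: float = 0.2,
               sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
               label: str = "") -> ConcentrationProtocol:
    """Train of brief pulses, mimicking repetitive synaptic activity."""
    period = 1.0 / frequency
    if pulse * frequency >= 1:
        raise ValueError("pulse duration must be shorter than the period")
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    segs = [Segment(pre, 0.0)]
    for i in range(n_pulses):
        segs.append(Segment(pulse, concentration))
        gap = period - pulse if i < n_pulses - 1 else post
        segs.append(Segment(gap, 0.0))
    return ConcentrationProtocol(tuple(segs),
                                 label or f"{frequency:g} Hz train",
                                 sample_interval)


@dataclass
class SimTrace:
    """Simulated macroscopic response.

    ``occupancy[i, j]`` is the probability of state ``j`` at ``time[i]``;
    ``current`` is the conductance-weighted occupancy (normalized units),
    ``popen`` the summed occupancy of open states.
    """

    time: np.ndarray
    occupancy: np.ndarray
    popen: np.ndarray
    current: np.ndarray
    state_names: tuple[str, ...]
    protocol: ConcentrationProtocol
    scheme_variant: str = ""

    def window(self, t0: float, t1: float) -> np.ndarray:
        if t1 <= t0:
            raise ValueError("empty window")
        return (self.time >= t0) & (self.time <= t1)

    def to_frame(self):
        import pandas as pd
        data = {"time": self.time, "current": self.current,
                "popen": self.popen}
        for j, name in enumerate(self.state_names):
            data[f"occ_{name}"] = self.occupancy[:, j]
        return pd.DataFrame(data)


class _Propagator:
    """Spectral propagator for one constant-concentration segment."""

    def __init__(self, q: np.ndarray):
        lam, v = np.linalg.eig(q.T)
        cond = np.linalg.cond(v)
        if cond > 1e8 or np.abs(lam.imag).max() > 1e-6 * max(np.abs(lam.real).max(), 1.0):
            # Defective or heavily non-normal: fall back to expm stepping.
            self.lam = None
            self.q = q
        else:
            self.lam = lam.real
            self.v = v.real
            self.vinv = np.linalg.inv(self.v)

    def at_times(self, p0: np.ndarray, ts: np.ndarray) -> np.ndarray:
        """Occupancy rows at the (segment-relative) times ts."""
        if self.lam is not None:
            coeff = self.vinv @ p0           # (n,)
            # p(t) = V @ (coeff * exp(lam t))
            mat = self.v @ (coeff[:, None] * np.exp(np.outer(self.lam, ts)))
            out = mat.T
        else:
            out = np.empty((len(ts), len(p0)))
            prev_t, p = 0.0, p0.copy()
            for i, t in enumerate(ts):
                if t != prev_t:
                    p = scipy.linalg.expm(self.q.T * (t - prev_t)) @ p
                    prev_t = t
                out[i] = p
        out = np.clip(out, 0.0, None)
        return out / out.sum(axis=1, keepdims=True)


def _initial_vector(scheme: KineticScheme, protocol: ConcentrationProtocol,
                    initial) -> np.ndarray:
    if isinstance(initial, str):
        if initial != "equilibrium":
            raise ValueError(f"unknown initial condition {initial!r}")
        return equilibrium_occupancy(scheme, protocol.segments[0].concentration)
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (scheme.n_states,) or np.any(p0 < -1e-12) \
            or not math.isclose(p0.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("initial occupancy must be a probability vector "
                         f"over {scheme.n_states} states")
    return np.clip(p0, 0.0, None) / p0.sum()


def simulate(scheme: KineticScheme, protocol: ConcentrationProtocol,
             initial="equilibrium", *, require_balanced: bool = True) -> SimTrace:
    """Deterministic macroscopic simulation of a protocol.

    Occupancies are propagated by the exact matrix exponential within each
    constant-concentration segment and sampled on a uniform grid; the
    result is step-size independent by construction.
    """
    if require_balanced and not scheme.balanced:
        raise ValueError("scheme is not balanced; run "
                         "enforce_microscopic_reversibility first "
                         "(or pass require_balanced=False)")
    p0 = _initial_vector(scheme, protocol, initial)

    dt = protocol.sample_interval
    n_samples = int(round(protocol.total_duration / dt)) + 1
    time = np.arange(n_samples) * dt
    occ = np.empty((n_samples, scheme.n_states))

    edges = np.concatenate([[0.0], protocol.boundaries()])
    p = p0
    for k, seg in enumerate(protocol.segments):
        t_start, t_end = edges[k], edges[k + 1]
        mask = (time >= t_start - 1e-12) & (time < t_end - 1e-12)
        if k == len(protocol.segments) - 1:
            mask |= time >= t_end - 1e-12
        ts = time[mask] - t_start
        prop = _Propagator(generator_matrix(scheme, seg.concentration))
        if ts.size:
            occ[mask] = prop.at_times(p, ts)
        p = prop.at_times(p, np.array([seg.duration]))[0]

    g = scheme.conductances
    is_open = np.array([s.state_class == "open" for s in scheme.states])
    current = occ @ g
    popen = occ[:, is_open].sum(axis=1)
    return SimTrace(time, occ, popen, current, scheme.state_names, protocol,
                    scheme.variant)


def stochastic_simulate(scheme: KineticScheme,
                        protocol: ConcentrationProtocol,
                        n_channels: int, seed: int) -> SimTrace:
    """Single-channel ensemble simulation.

    Each channel's state sequence is drawn from the exact jump-process law
    at the protocol's sample times (the per-segment transition kernel
    ``expm(Q dt)`` is the exact distribution of the continuous-time chain
    observed on the grid), vectorized over channels. ``n_channels = 1``
    yields a single-channel record occupying one state per sample; the
    ensemble mean converges to :func:`simulate`.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    dt = protocol.sample_interval
    n_samples = int(round(protocol.total_duration / dt)) + 1
    time = np.arange(n_samples) * dt
    n = scheme.n_states

    p0 = equilibrium_occupancy(scheme, protocol.segments[0].concentration)
    states = rng.choice(n, size=n_channels, p=p0)
    counts = np.zeros((n_samples, n))
    counts[0] = np.bincount(states, minlength=n)

    conc = protocol.concentration_at(time[:-1] + dt / 2)
    kernels: dict[float, np.ndarray] = {}
    for c in np.unique(conc):
        k = scipy.linalg.expm(generator_matrix(scheme, c) * dt)
        k = np.clip(k, 0.0, None)
        kernels[c] = np.cumsum(k / k.sum(axis=1, keepdims=True), axis=1)

    for i in range(1, n_samples):
        cum = kernels[conc[i - 1]]
        u = rng.random(n_channels)
        states = (u[:, None] > cum[states]).sum(axis=1)
        counts[i] = np.bincount(states, minlength=n)

    occ = counts / n_channels
    g = scheme.conductances
    is_open = np.array([s.state_class == "open" for s in scheme.states])
    return SimTrace(time, occ, occ[:, is_open].sum(axis=1), occ @ g,
                    scheme.state_names, protocol, scheme.variant)


def peak_and_steady(trace: SimTrace,
                    window: tuple[float, float] | None = None
                    ) -> tuple[float, float, float]:
    """Peak current, steady-state current and their ratio in percent.

    Steady state is the mean over the final ``STEADY_STATE_FRACTION`` of the
    agonist segment (robust to residual slow relaxations).
    """
    if window is None:
        window = trace.protocol.agonist_window()
    t0, t1 = window
    mask = trace.window(t0, t1)
    if not mask.any():
        raise ValueError("empty window")
    peak = float(trace.current[mask].max())
    ss_start = t1 - STEADY_STATE_FRACTION * (t1 - t0)
    ss_mask = trace.window(ss_start, t1)
    steady = float(trace.current[ss_mask].mean())
    ratio = 100.0 * steady / peak if peak > 0 else float("nan")
    return peak, steady, ratio
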