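"""Synthetic patch-clamp traces from model output.

Emulates what an outside-out patch recording adds on top of the ideal
macroscopic response: finite solution exchange at the pipette tip, the
amplifier's low-pass filter, discrete sampling, additive recording noise
and (optionally) slow rundown across sweeps. The clean model current is
kept alongside, so the full analysis stack can be validated end-to-end by
parameter recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import erf

from . import fitting as ft
from . import protocols as pr
from . import scheme as sc

__all__ = [
    "AcquisitionModel",
    "NoiseModel",
    "SyntheticTrace",
    "synthesize_trace",
    "simulate_with_exchange",
    "make_dataset",
    "parameter_recovery",
]


@dataclass(frozen=True)
class AcquisitionModel:
    """Recording chain: 20 kHz sampling, 10 kHz low-pass, ~300 us
    10-90% solution exchange."""

    sample_rate: float = 20_000.0
    filter_cutoff: float = 10_000.0
    exchange_time: float = 3e-4      # 10-90% solution exchange (s)
    rundown_per_sweep: float = 0.0   # fractional peak loss per sweep

    def __post_init__(self):
        if self.filter_cutoff > self.sample_rate / 2:
            raise ValueError("filter cutoff must be <= Nyquist")
        if self.exchange_time < 0:
            raise ValueError("exchange time must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, sd expressed as a fraction of the clean
    trace's peak; band-limited by the acquisition filter."""

    sd_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sd_fraction < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SyntheticTrace:
    time: np.ndarray
    current: np.ndarray          # noisy, filtered, resampled
    clean_current: np.ndarray    # same processing chain, no noise
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "current": self.current,
                             "clean_current": self.clean_current})


def _exchange_kernel(tau_10_90: float, dt: float) -> np.ndarray:
    """Gaussian smoothing kernel whose step response has the requested
    10-90% rise time (error-function exchange profile)."""
    sigma = tau_10_90 / 2.563103  # 10-90 width of the Gaussian CDF
    if sigma < dt / 10:
        return np.array([1.0])
    half = int(math.ceil(4 * sigma / dt))
    x = np.arange(-half, half + 1) * dt
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _apply_chain(t: np.ndarray, y: np.ndarray,
                 acq: AcquisitionModel) -> tuple[np.ndarray, np.ndarray]:
    """Exchange smoothing + 4-pole Bessel filter + resampling."""
    dt = float(t[1] - t[0])
    out = y
    if acq.exchange_time > 0:
        kernel = _exchange_kernel(acq.exchange_time, dt)
        out = np.convolve(out, kernel, mode="same")
    nyq = 0.5 / dt
    if acq.filter_cutoff < 0.98 * nyq:
        b, a = sps.bessel(4, acq.filter_cutoff / nyq)
        out = sps.lfilter(b, a, out)
    step = max(int(round(1.0 / (acq.sample_rate * dt))), 1)
    return t[::step], out[::step]


def synthesize_trace(trace: pr.SimTrace, acq: AcquisitionModel | None = None,
                     noise: NoiseModel | None = None) -> SyntheticTrace:
    """Turn an ideal simulated trace into a realistic "recorded" one.

    The exchange profile is applied here as a smoothing of the current (a
    cheap, adequate stand-in when the trace was simulated with hard
    concentration steps); for physically consistent exchange use
    :func:`simulate_with_exchange` and set ``acq.exchange_time`` to 0 here.
    Reproducible: a pure function of (trace, acq, noise).
    """
    acq = acq or AcquisitionModel()
    noise = noise or NoiseModel()
    t_s, clean = _apply_chain(trace.time, trace.current, acq)
    rng = np.random.default_rng(noise.seed)
    peak = float(np.abs(clean).max()) or 1.0
    raw_noise = rng.standard_normal(len(trace.time)) * noise.sd_fraction * peak
    dt = float(trace.time[1] - trace.time[0])
    nyq = 0.5 / dt
    if noise.sd_fraction > 0 and acq.filter_cutoff < 0.98 * nyq:
        b, a = sps.bessel(4, acq.filter_cutoff / nyq)
        raw_noise = sps.lfilter(b, a, raw_noise)
        # restore the requested post-filter standard deviation
        raw_noise *= noise.sd_fraction * peak / max(raw_noise.std(), 1e-30)
    step = max(int(round(1.0 / (acq.sample_rate * dt))), 1)
    noisy = clean + raw_noise[::step]
    return SyntheticTrace(t_s, noisy, clean, params={
        "acquisition": asdict(acq), "noise": asdict(noise),
        "scheme_variant": trace.scheme_variant,
        "protocol": trace.protocol.label})


def simulate_with_exchange(scheme_b: sc.KineticScheme,
                           protocol: pr.ConcentrationProtocol,
                           acq: AcquisitionModel,
                           n_ramp_segments: int = 12) -> pr.SimTrace:
    """Re-simulate a protocol with error-function concentration ramps.

    Each concentration step is replaced by a staircase of short segments
    approximating the solution-exchange profile — physically consistent,
    the receptor reacts to the true concentration time course.
    """
    tau = acq.exchange_time
    if tau <= 0:
        return pr.simulate(scheme_b, protocol)
    sigma = tau / 2.563103
    half_span = 3 * sigma
    segs: list[pr.Segment] = []
    prev_c = protocol.segments[0].concentration
    # Build the staircase: at each internal boundary, erf-blend between
    # the neighbouring concentrations.
    for i, seg in enumerate(protocol.segments):
        core = seg.duration - (half_span if i > 0 else 0.0) \
            - (half_span if i < len(protocol.segments) - 1 else 0.0)
        if core <= 0:
            raise ValueError("segment too short for the exchange ramp")
        if i > 0:
            edges = np.linspace(-half_span, half_span, n_ramp_segments + 1)
            mids = 0.5 * (edges[:-1] + edges[1:])
            frac = 0.5 * (1 + erf(mids / (sigma * math.sqrt(2))))
            for j in range(n_ramp_segments):
                c = prev_c + (seg.concentration - prev_c) * frac[j]
                segs.append(pr.Segment(edges[j + 1] - edges[j], max(c, 0.0)))
        segs.append(pr.Segment(core, seg.concentration))
        prev_c = seg.concentration
    ramped = pr.ConcentrationProtocol(tuple(segs),
                                      protocol.label + " (exchange)",
                                      protocol.sample_interval)
    return pr.simulate(scheme_b, ramped)


# ---------------------------------------------------------------------------
# Dataset generation and end-to-end parameter recovery
# ---------------------------------------------------------------------------

#: Protocols covering every analysis operation.
DATASET_PROTOCOLS = {
    "desensitization": lambda: pr.make_pulse(0.5, 0.01, post=0.05),
    "deactivation": lambda: pr.make_pulse(0.001, 0.01, post=0.15),
    "long_pulse": lambda: pr.make_pulse(5.0, 0.01, post=0.1),
    "train_20hz": lambda: pr.make_train(0.001, 20.0, 20, 0.01, post=0.1),
}


def make_dataset(out_dir, *, trial: int = sc.WILD_TYPE_TRIAL,
                 variants=("noTARP", "TARP"), n_sweeps: int = 1,
                 seed: int = 0, acq: AcquisitionModel | None = None,
                 noise_sd: float = 0.02) -> dict:
    """Write a directory of CSV sweeps + JSON ground truth.

    Every sweep is a fresh noise realization of the same clean trace;
    rundown, if configured, scales sweep k by (1 - rundown)^k.
    """
    from .experiments import balanced_scheme, recovery_intervals, \
        recovery_curve

    acq = acq or AcquisitionModel()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"trial": trial, "seed": seed, "noise_sd": noise_sd,
                "acquisition": asdict(acq), "traces": []}
    ss = np.random.SeedSequence(seed)

    for variant in variants:
        scheme_b = balanced_scheme(variant, trial)
        truth = ground_truth(scheme_b)
        for name, make in DATASET_PROTOCOLS.items():
            trace = pr.simulate(scheme_b, make())
            for sweep in range(n_sweeps):
                child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                syn = synthesize_trace(
                    trace, acq, NoiseModel(noise_sd, child_seed))
                factor = (1.0 - acq.rundown_per_sweep) ** sweep
                syn.current = syn.current * factor
                syn.clean_current = syn.clean_current * factor
                fname = f"{variant}_{name}_sweep{sweep}.csv"
                syn.to_frame().to_csv(out / fname, index=False)
                manifest["traces"].append(
                    {"file": fname, "variant": variant, "protocol": name,
                     "sweep": sweep, "seed": child_seed,
                     "rundown_factor": factor})
        # Recovery is a derived curve, not a raw trace.
        ivals = recovery_intervals(scheme_b, 10)
        resp = recovery_curve(scheme_b, ivals)
        pd.DataFrame({"interval": ivals, "response": resp}).to_csv(
            out / f"{variant}_recovery.csv", index=False)
        (out / f"{variant}_ground_truth.json").write_text(
            json.dumps(truth, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def ground_truth(scheme_b: sc.KineticScheme) -> dict:
    """Reference kinetic measurements on the noiseless model output."""
    from .experiments import desensitization_fit, deactivation_fit, \
        fit_trial_recovery

    truth = {
        "variant": scheme_b.variant,
        "k_des": desensitization_fit(scheme_b).weighted_rate,
        "k_deact": deactivation_fit(scheme_b).weighted_rate,
        "k_rec": fit_trial_recovery(scheme_b).k_rec,
    }
    if scheme_b.variant != "noTARP":
        trace = pr.simulate(scheme_b, pr.make_pulse(5.0, 0.01, post=0.1))
        truth["superactivation_pct"] = ft.superactivation(trace).magnitude
    return truth


#: Window offsets for fitting noisy traces: start after the solution
#: exchange has settled (the smoothed step distorts the first ~2 sigma).
EXCHANGE_SETTLE = 4e-4


def measure_synthetic(syn: SyntheticTrace, protocol_name: str,
                      protocol: pr.ConcentrationProtocol,
                      settle: float = EXCHANGE_SETTLE):
    """Apply the matching analysis operation to a synthetic sweep.

    ``settle`` shifts fit windows past the smoothed solution-exchange edge
    (zero when the acquisition chain has no exchange ramp).
    """
    fake = pr.SimTrace(syn.time, np.empty((len(syn.time), 0)),
                       syn.current, syn.current, (), protocol)
    on, off = protocol.agonist_window()
    if protocol_name == "desensitization":
        i_pk = int(np.argmax(syn.current * (syn.time < on + 5e-3)))
        fit = ft.fit_exponentials(fake, window=(syn.time[i_pk], off),
                                  n_components=2)
        return {"k_des": fit.weighted_rate}
    if protocol_name == "deactivation":
        fit = ft.fit_exponentials(
            fake, window=(off + settle, off + 0.1), n_components=2)
        return {"k_deact": fit.weighted_rate}
    if protocol_name == "long_pulse":
        res = ft.superactivation(fake)
        return {"superactivation_pct": res.magnitude}
    return {}


def parameter_recovery(*, trial: int = sc.WILD_TYPE_TRIAL,
                       variant: str = "TARP", n_seeds: int = 20,
                       noise_sd: float = 0.02, seed: int = 0,
                       tolerance: float = 0.10,
                       acq: AcquisitionModel | None = None) -> pd.DataFrame:
    """End-to-end validation: generate noisy sweeps, re-measure, compare.

    For each kinetic parameter the mean estimate across ``n_seeds`` noise
    realizations must lie within ``tolerance`` (relative) of the
    noiseless ground truth. Returns a table with one row per parameter;
    column ``ok`` holds the verdict.
    """
    from .experiments import balanced_scheme, recovery_intervals, \
        recovery_curve

    scheme_b = balanced_scheme(variant, trial)
    truth = ground_truth(scheme_b)
    acq = acq or AcquisitionModel()
    ss = np.random.SeedSequence(seed)

    estimates: dict[str, list[float]] = {}
    proto_names = ["desensitization", "deactivation"]
    if variant != "noTARP":
        proto_names.append("long_pulse")
    clean = {name: pr.simulate(scheme_b, DATASET_PROTOCOLS[name]())
             for name in proto_names}
    settle = EXCHANGE_SETTLE if acq.exchange_time > 0 else 0.0
    for child in ss.spawn(n_seeds):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        for name in proto_names:
            syn = synthesize_trace(clean[name], acq,
                                   NoiseModel(noise_sd, child_seed))
            for key, val in measure_synthetic(
                    syn, name, clean[name].protocol, settle).items():
                estimates.setdefault(key, []).append(val)

    # Recovery: noise the recovery curve points (each point is a peak
    # measurement from a noisy sweep; peak sd ~ noise sd). Same interval
    # series as the ground-truth fit.
    from .experiments import trial_recovery_intervals
    ivals = trial_recovery_intervals(scheme_b)
    resp = recovery_curve(scheme_b, ivals)
    rng = np.random.default_rng(seed + 1)
    for _ in range(n_seeds):
        noisy = resp * (1 + rng.normal(0, noise_sd, len(resp)))
        try:
            if noisy.max() > 1.02:
                k = ft.fit_suprarecovery(ivals, noisy).k_rec
            else:
                k = ft.fit_recovery(ivals, noisy).k_rec
            estimates.setdefault("k_rec", []).append(k)
        except ft.FitError:
            pass

    rows = []
    for key, vals in estimates.items():
        mean = float(np.mean(vals))
        rel = abs(mean - truth[key]) / abs(truth[key])
        rows.append({"parameter": key, "truth": truth[key],
                     "mean_estimate": mean, "rel_error": rel,
                     "n": len(vals), "ok": rel <= tolerance})
    return pd.DataFrame(rows).set_index("parameter")
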