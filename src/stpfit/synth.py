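"""Stochastic generator of experiment-shaped synthetic IPSC datasets.

Emulates the optogenetic stimulation design used to characterize
short-term depression at PV GABAergic synapses: 20-pulse trains at
5/10/20/50 Hz repeated 7 times, plus paired-pulse recovery protocols at
interpulse intervals of 20-3000 ms.  Release is binomial across ``N``
independent sites whose per-pulse probability ``p_n`` comes from the
deterministic depression model; each released quantum contributes a
quantal amplitude drawn with intrasite CV 0.3 (truncated at zero), and
additive Gaussian recording noise is applied to every sweep.  Under this
generative model the amplitude mean is ``N p q`` and the variance is
``N p q^2 (1 + CV^2 - p)`` — exactly the structure assumed by
variance-mean analysis.

Raw current traces can also be synthesized by placing biexponential
kernels at the pulse times, for testing amplitude extraction and kinetics
fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import StimulusProtocol, SynapseParams, simulate_train
from .quantal import AmplitudeTable

__all__ = [
    "QuantalGroundTruth",
    "WaveformSpec",
    "ExperimentDataset",
    "generate_amplitude_table",
    "generate_experiment",
    "synthesize_trace",
]

DEFAULT_FREQUENCIES = (5.0, 10.0, 20.0, 50.0)
DEFAULT_RECOVERY_INTERVALS = (20.0, 50.0, 100.0, 500.0, 1000.0, 3000.0)


@dataclass(frozen=True)
class QuantalGroundTruth:
    """Generating quantal parameters for one synthetic cell.

    Defaults are the population estimates for the septohippocampal PV
    projection synapse (N ~ 15 sites, q ~ 36.4 pA); ``noise_sd_pa`` is a
    typical whole-cell baseline noise level.
    """

    n_sites: int = 15
    q_pa: float = 36.4
    cv_intra: float = 0.3
    noise_sd_pa: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.q_pa <= 0:
            raise ValueError("q_pa must be positive")
        if self.cv_intra < 0 or self.noise_sd_pa < 0:
            raise ValueError("cv_intra and noise_sd_pa must be >= 0")


def _rise_tau_for_1090(decay_tau_ms: float, target_rise_ms: float) -> float:
    """Rise constant of the biexponential kernel whose 10-90% rise time
    matches ``target_rise_ms`` (solved numerically)."""

    def rise_of(tau_r: float) -> float:
        t_peak = math.log(decay_tau_ms / tau_r) * decay_tau_ms * tau_r / (decay_tau_ms - tau_r)
        t = np.linspace(0.0, t_peak, 2001)
        y = np.exp(-t / decay_tau_ms) - np.exp(-t / tau_r)
        y /= y[-1]
        t10 = np.interp(0.1, y, t)
        t90 = np.interp(0.9, y, t)
        return t90 - t10

    return brentq(lambda x: rise_of(x) - target_rise_ms, 1e-3, decay_tau_ms * 0.99)


@dataclass(frozen=True)
class WaveformSpec:
    """Biexponential IPSC kernel plus acquisition settings.

    The kernel is ``exp(-t/decay_tau) - exp(-t/rise_tau)``, peak-normalized
    so a programmed amplitude equals the analytic peak.  Defaults give the
    MS-DBB-like IPSC: 8.5 ms decay and a rise constant chosen so the
    10-90% rise time is 1.0 ms; sampling at 20 kHz.
    """

    rise_tau_ms: float = 0.0  # 0 -> solved from target_rise_ms
    decay_tau_ms: float = 8.5
    sampling_khz: float = 20.0
    baseline_noise_sd_pa: float = 2.0
    target_rise_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_tau_ms == 0.0:
            object.__setattr__(
                self, "rise_tau_ms", _rise_tau_for_1090(self.decay_tau_ms, self.target_rise_ms)
            )
        if not (self.decay_tau_ms > self.rise_tau_ms > 0):
            raise ValueError("need decay_tau_ms > rise_tau_ms > 0")
        if self.sampling_khz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def peak_time_ms(self) -> float:
        td, tr = self.decay_tau_ms, self.rise_tau_ms
        return math.log(td / tr) * td * tr / (td - tr)

    @property
    def peak_value(self) -> float:
        t = self.peak_time_ms
        return math.exp(-t / self.decay_tau_ms) - math.exp(-t / self.rise_tau_ms)


@dataclass
class ExperimentDataset:
    """One synthetic cell: trains per frequency, recovery pairs, ground truth."""

    tables: dict  # frequency_hz -> AmplitudeTable
    recovery: dict  # interval_ms -> repeats x 2 array of (P1, P2) amplitudes, pA
    truth: dict  # generating parameters and per-protocol p_n
    seed: int | None = None


def _draw_amplitudes(
    p: np.ndarray, gt: QuantalGroundTruth, repeats: int, rng: np.random.Generator
) -> np.ndarray:
    """Binomial-quantal amplitude draws: repeats x pulses, pA.

    Per repeat and pulse, each of the N sites releases with probability
    p_n; a released quantum contributes max(0, Normal(q, cv*q)); additive
    recording noise is applied and the measured magnitude floored at 0.
    """
    p = np.asarray(p, dtype=float)
    released = rng.random((repeats, p.size, gt.n_sites)) < p[None, :, None]
    quanta = np.maximum(
        0.0, rng.normal(gt.q_pa, gt.cv_intra * gt.q_pa, size=released.shape)
    )
    amps = (released * quanta).sum(axis=2)
    if gt.noise_sd_pa > 0:
        amps = amps + rng.normal(0.0, gt.noise_sd_pa, size=amps.shape)
    return np.maximum(amps, 0.0)


def generate_amplitude_table(
    params: SynapseParams,
    gt: QuantalGroundTruth,
    protocol: StimulusProtocol,
    repeats: int = 7,
    seed: int | np.random.Generator | None = None,
    p_scale: float = 1.0,
    cell_id: str = "synthetic",
) -> AmplitudeTable:
    """Simulate one protocol: model p_n -> binomial quantal amplitudes.

    ``p_scale`` rescales the release-probability profile, e.g. to emulate
    a cell whose maximum release probability differs from the population
    model's ``p_max_vm`` (the scaled profile must stay within [0, 1]).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else gt.seed
    )
    p = simulate_train(protocol, params).p * p_scale
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ValueError("scaled release probabilities leave [0, 1]")
    amps = _draw_amplitudes(p, gt, repeats, rng)
    return AmplitudeTable(
        amplitudes=amps,
        frequency_hz=1000.0 / protocol.intervals[0] if len(protocol) > 1 else 0.0,
        cell_id=cell_id,
        protocol=protocol,
    )


def generate_experiment(
    params: SynapseParams,
    gt: QuantalGroundTruth,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    n_pulses: int = 20,
    repeats: int = 7,
    recovery_intervals: Sequence[float] = DEFAULT_RECOVERY_INTERVALS,
    seed: int | None = None,
    p_scale: float = 1.0,
    cell_id: str = "synthetic",
) -> ExperimentDataset:
    """Full synthetic experiment for one cell.

    Produces one amplitude table per train frequency plus paired-pulse
    recovery protocols (two pulses from rest per interval, each repeated
    ``repeats`` times), with the generating parameters and per-protocol
    release probabilities stored as ground truth.  Trains start from rest,
    i.e. full recovery is assumed between sweeps.
    """
    seed = seed if seed is not None else gt.seed
    rng = np.random.default_rng(seed)
    tables: dict = {}
    truth_p: dict = {"train": {}, "recovery": {}}
    for freq in frequencies:
        proto = StimulusProtocol.train(freq, n_pulses)
        p = simulate_train(proto, params).p * p_scale
        if np.any(p > 1.0) or np.any(p < 0.0):
            raise ValueError("scaled release probabilities leave [0, 1]")
        tables[float(freq)] = AmplitudeTable(
            amplitudes=_draw_amplitudes(p, gt, repeats, rng),
            frequency_hz=float(freq),
            cell_id=cell_id,
            protocol=proto,
        )
        truth_p["train"][float(freq)] = p.tolist()
    recovery: dict = {}
    for interval in recovery_intervals:
        proto = StimulusProtocol.paired(interval)
        p = simulate_train(proto, params).p * p_scale
        recovery[float(interval)] = _draw_amplitudes(p, gt, repeats, rng)
        truth_p["recovery"][float(interval)] = p.tolist()
    truth = {
        "params": params.to_dict(),
        "quantal": {k: v for k, v in asdict(gt).items() if k != "seed"},
        "p_scale": p_scale,
        "repeats": repeats,
        "p_n": truth_p,
        "seed": seed,
    }
    return ExperimentDataset(tables=tables, recovery=recovery, truth=truth, seed=seed)


def synthesize_trace(
    table: AmplitudeTable,
    waveform: WaveformSpec,
    seed: int | None = None,
    tail_ms: float = 50.0,
) -> tuple:
    """Render raw current sweeps from an amplitude table.

    Each sweep superimposes one peak-normalized biexponential kernel per
    pulse, scaled to the table's amplitude, with linear summation across
    overlapping events and additive Gaussian baseline noise.  Returns
    ``(time_ms, currents)`` with ``currents`` of shape
    ``(n_repeats, n_samples)``, positive-going.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / waveform.sampling_khz
    t_start = min(table.protocol.pulse_times) - 10.0
    t_stop = max(table.protocol.pulse_times) + tail_ms
    time = np.arange(t_start, t_stop, dt)
    currents = np.zeros((table.n_repeats, time.size))
    for j, t0 in enumerate(table.protocol.pulse_times):
        rel = time - t0
        kernel = np.where(
            rel > 0,
            np.exp(-np.maximum(rel, 0.0) / waveform.decay_tau_ms)
            - np.exp(-np.maximum(rel, 0.0) / waveform.rise_tau_ms),
            0.0,
        ) / waveform.peak_value
        amps = np.nan_to_num(table.amplitudes[:, j])
        currents += amps[:, None] * kernel[None, :]
    if waveform.baseline_noise_sd_pa > 0:
        currents += rng.normal(0.0, waveform.baseline_noise_sd_pa, size=currents.shape)
    return time, currents
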