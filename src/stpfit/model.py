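"""Deterministic two-state model of short-term depression (STD) at GABAergic synapses.

The model tracks two presynaptic variables between stimuli:

* ``c`` — residual calcium above baseline, expressed in units of the
  per-stimulus increment ``Delta``.  At each pulse ``c`` jumps by
  ``delta_jump`` and between pulses it decays exponentially with time
  constant ``tau_ca_ms``.
* ``r`` — the fraction of the readily-releasable vesicle pool available
  for release.  Release depletes ``r``; replenishment proceeds at a
  calcium-dependent rate, which is the mechanism of calcium-dependent
  recovery (CDR) from depression.

Both the release probability and the recovery rate are first-order
saturating functions of calcium:

    P(c) = p_max_vm * c / (c + k_half)
    k(c) = k_min + delta_k * c / (c + k_r_half)

At each pulse, in order: calcium jumps, the observable release probability
``p_n = P(c) * r`` is recorded, and the pool is depleted by the released
fraction.  Between pulses both variables relax along closed-form
trajectories, so train simulation needs no numerical integration: with
``c(t) = c0 * exp(-t/tau)`` the recovery integral over an interval ``T`` is

    I_k = k_min*T + delta_k*tau * ln[(c0 + k_r_half)/(c(T) + k_r_half)]

and ``1 - r`` decays by ``exp(-I_k)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "SynapseParams",
    "StimulusProtocol",
    "ModelState",
    "TrainResponse",
    "ConvergenceError",
    "load_params",
    "builtin_params",
    "fold_differences",
    "release_probability",
    "recovery_rate",
    "propagate_interval",
    "simulate_train",
    "simulate_recovery_curve",
    "steady_state_response",
]

#: names of the five kinetic parameters that are free in model fitting
#: (maximum release probability comes from variance-mean analysis and the
#: calcium increment is fixed at 1, so neither is fitted)
FREE_PARAM_NAMES = ("tau_ca_ms", "k_half", "k_min_per_ms", "delta_k_per_ms", "k_r_half")

_JSON_KEYS = (
    "tau_ca_ms",
    "p_max_vm",
    "k_half",
    "k_min_per_ms",
    "delta_k_per_ms",
    "k_r_half",
    "delta_jump",
    "label",
)


class ConvergenceError(RuntimeError):
    """Raised when an iterative routine fails to reach its tolerance."""


@dataclass(frozen=True)
class SynapseParams:
    """Complete parameterization of the depression/recovery model.

    Parameters
    ----------
    tau_ca_ms
        Decay time constant of the residual-calcium transient, ms.
    p_max_vm
        Maximum release probability, dimensionless; fixed from
        variance-mean analysis rather than fitted.
    k_half
        Calcium level (normalized units) at which the release-probability
        function reaches half its maximum.
    k_min_per_ms
        Baseline (calcium-independent) vesicle replenishment rate, per ms.
    delta_k_per_ms
        Calcium-dependent increment of the replenishment rate
        (``k_max - k_min``), per ms.
    k_r_half
        Calcium level at which the recovery-rate function is halfway
        between ``k_min`` and ``k_max``.
    delta_jump
        Per-stimulus calcium increment, normalized units; fixed to 1 so
        calcium is measured in units of one stimulus.
    label
        Free-text identity of the synapse type (e.g. ``"SH"``, ``"HC"``).
    """

    tau_ca_ms: float
    p_max_vm: float
    k_half: float
    k_min_per_ms: float
    delta_k_per_ms: float
    k_r_half: float
    delta_jump: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.tau_ca_ms > 0):
            raise ValueError(f"tau_ca_ms must be positive, got {self.tau_ca_ms}")
        if not (0 < self.p_max_vm <= 1):
            raise ValueError(f"p_max_vm must be in (0, 1], got {self.p_max_vm}")
        if not (self.k_half > 0):
            raise ValueError(f"k_half must be positive, got {self.k_half}")
        if self.k_min_per_ms < 0:
            raise ValueError(f"k_min_per_ms must be >= 0, got {self.k_min_per_ms}")
        if self.delta_k_per_ms < 0:
            raise ValueError(f"delta_k_per_ms must be >= 0, got {self.delta_k_per_ms}")
        if not (self.k_r_half > 0):
            raise ValueError(f"k_r_half must be positive, got {self.k_r_half}")
        if not (self.delta_jump > 0):
            raise ValueError(f"delta_jump must be positive, got {self.delta_jump}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _JSON_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseParams":
        missing = [k for k in _JSON_KEYS if k not in d and k not in ("delta_jump", "label")]
        if missing:
            raise KeyError(f"parameter JSON missing keys: {missing}")
        return cls(**{k: d[k] for k in _JSON_KEYS if k in d})

    def with_free(self, values: Sequence[float]) -> "SynapseParams":
        """Return a copy with the five free kinetic parameters replaced."""
        return replace(self, **dict(zip(FREE_PARAM_NAMES, map(float, values))))

    @property
    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FREE_PARAM_NAMES])


def load_params(path) -> SynapseParams:
    """Load a :class:`SynapseParams` from a JSON file."""
    with open(path) as fh:
        return SynapseParams.from_dict(json.load(fh))


def builtin_params(name: str) -> SynapseParams:
    """Load a shipped parameter set: ``"SH"`` (septohippocampal PV
    projection synapse) or ``"HC"`` (local hippocampal PV synapse)."""
    ref = resources.files("stpfit.data").joinpath(f"{name}.json")
    return SynapseParams.from_dict(json.loads(ref.read_text()))


def fold_differences(a: SynapseParams, b: SynapseParams) -> dict:
    """Parameter-wise fold difference ``a / b`` between two synapse models.

    Covers the six model constants (calcium decay, maximum release
    probability, both half-saturation constants, and the two recovery
    rates).  Used to contrast synapse types, e.g. the septohippocampal
    versus local hippocampal PV models.
    """
    keys = ("tau_ca_ms", "p_max_vm", "k_half", "k_min_per_ms", "delta_k_per_ms", "k_r_half")
    return {k: getattr(a, k) / getattr(b, k) for k in keys}


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered sequence of stimulus onset times, in ms."""

    pulse_times: tuple
    description: str = ""

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.pulse_times)
        if len(times) < 1:
            raise ValueError("protocol needs at least one pulse")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("pulse times must be strictly increasing")
        object.__setattr__(self, "pulse_times", times)

    def __len__(self) -> int:
        return len(self.pulse_times)

    @property
    def intervals(self) -> tuple:
        """Inter-pulse gaps in ms (length ``n_pulses - 1``)."""
        t = self.pulse_times
        return tuple(t2 - t1 for t1, t2 in zip(t, t[1:]))

    @classmethod
    def train(cls, frequency_hz: float, n_pulses: int = 20, start_ms: float = 0.0) -> "StimulusProtocol":
        """Constant-frequency train (the standard 20-pulse protocol)."""
        if frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        period = 1000.0 / frequency_hz
        times = tuple(start_ms + i * period for i in range(n_pulses))
        return cls(times, description=f"{frequency_hz:g} Hz x {n_pulses} pulses")

    @classmethod
    def paired(cls, interval_ms: float, start_ms: float = 0.0) -> "StimulusProtocol":
        """Conditioning/test pulse pair separated by ``interval_ms``."""
        if interval_ms <= 0:
            raise ValueError("interval must be positive")
        return cls((start_ms, start_ms + interval_ms), description=f"pair, {interval_ms:g} ms")


class ModelState(NamedTuple):
    """Instantaneous presynaptic state: calcium elevation and available fraction."""

    c: float
    r: float


REST = ModelState(c=0.0, r=1.0)


@dataclass(frozen=True)
class TrainResponse:
    """Per-pulse model trajectory for one stimulus protocol.

    ``p`` is the observable release probability at each pulse,
    ``P(c_post) * r_pre`` — the quantity that corresponds to IPSC
    amplitude divided by N*q in the data.
    """

    protocol: StimulusProtocol
    c_pre: np.ndarray
    c_post: np.ndarray
    r_pre: np.ndarray
    p: np.ndarray

    @property
    def ppr(self) -> float:
        """Paired-pulse ratio p2/p1 (requires >= 2 pulses)."""
        if len(self.p) < 2:
            raise ValueError("PPR needs at least two pulses")
        return float(self.p[1] / self.p[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pulse_index": np.arange(1, len(self.p) + 1),
                "time_ms": np.asarray(self.protocol.pulse_times),
                "c_pre": self.c_pre,
                "c_post": self.c_post,
                "r_pre": self.r_pre,
                "p_n": self.p,
            }
        )


def release_probability(c, params: SynapseParams):
    """Release probability as a saturating (first-order Hill) function of calcium.

    ``P(c) = p_max_vm * c / (c + k_half)``; rises from 0 at rest toward
    ``p_max_vm``, reaching half-maximum at ``c = k_half``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("calcium must be non-negative")
    out = params.p_max_vm * c / (c + params.k_half)
    return float(out) if out.ndim == 0 else out


def recovery_rate(c, params: SynapseParams):
    """Vesicle replenishment rate (per ms) as a saturating function of calcium.

    ``k(c) = k_min + delta_k * c / (c + k_r_half)``; equals the baseline
    rate ``k_min`` at rest and saturates toward ``k_min + delta_k``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("calcium must be non-negative")
    out = params.k_min_per_ms + params.delta_k_per_ms * c / (c + params.k_r_half)
    return float(out) if out.ndim == 0 else out


def recovery_integral(c0: float, interval_ms: float, params: SynapseParams) -> float:
    """Exact integral of ``k(c(t))`` over an interval with ``c`` decaying from ``c0``."""
    c1 = c0 * math.exp(-interval_ms / params.tau_ca_ms)
    return params.k_min_per_ms * interval_ms + params.delta_k_per_ms * params.tau_ca_ms * math.log(
        (c0 + params.k_r_half) / (c1 + params.k_r_half)
    )


def propagate_interval(state: ModelState, interval_ms: float, params: SynapseParams) -> ModelState:
    """Advance the state through a stimulus-free interval (closed form).

    Calcium decays exponentially; the unavailable fraction ``1 - r``
    decays by the integrated recovery rate along the calcium trajectory.
    """
    if interval_ms < 0:
        raise ValueError("interval must be non-negative")
    c1 = state.c * math.exp(-interval_ms / params.tau_ca_ms)
    ik = recovery_integral(state.c, interval_ms, params)
    r1 = 1.0 - (1.0 - state.r) * math.exp(-ik)
    return ModelState(c=c1, r=r1)


def _pn_sequence(
    gaps: Sequence[float],
    tau: float,
    pmax: float,
    khalf: float,
    kmin: float,
    dk: float,
    krhalf: float,
    delta: float,
    c0: float = 0.0,
    r0: float = 1.0,
) -> list:
    """Lean scalar loop producing p_n for a protocol given as inter-pulse gaps.

    ``gaps[i]`` is the interval between pulse ``i+1`` and pulse ``i+2``;
    the train starts from state ``(c0, r0)``.  This is the hot path for
    fitting and sampling, so it uses plain floats and ``math``.
    """
    exp, log = math.exp, math.log
    c, r = c0, r0
    out = []
    c += delta
    p_rel = pmax * c / (c + khalf)
    out.append(p_rel * r)
    r *= 1.0 - p_rel
    for gap in gaps:
        c1 = c * exp(-gap / tau)
        ik = kmin * gap + dk * tau * log((c + krhalf) / (c1 + krhalf))
        r = 1.0 - (1.0 - r) * exp(-ik)
        c = c1 + delta
        p_rel = pmax * c / (c + khalf)
        out.append(p_rel * r)
        r *= 1.0 - p_rel
    return out


def simulate_train(
    protocol: StimulusProtocol,
    params: SynapseParams,
    initial: ModelState = REST,
) -> TrainResponse:
    """Run the per-pulse map over a stimulus protocol.

    At each pulse: calcium jumps by ``delta_jump``, the observable
    ``p_n = P(c_post) * r_pre`` is recorded, and the available fraction is
    depleted by the released fraction; the state then relaxes to the next
    pulse along the closed-form interval map.
    """
    n = len(protocol)
    c_pre = np.empty(n)
    c_post = np.empty(n)
    r_pre = np.empty(n)
    p = np.empty(n)
    state = initial
    for i in range(n):
        c_pre[i] = state.c
        c_jump = state.c + params.delta_jump
        c_post[i] = c_jump
        r_pre[i] = state.r
        p_rel = release_probability(c_jump, params)
        p[i] = p_rel * state.r
        state = ModelState(c=c_jump, r=state.r * (1.0 - p_rel))
        if i + 1 < n:
            state = propagate_interval(state, protocol.intervals[i], params)
    return TrainResponse(protocol=protocol, c_pre=c_pre, c_post=c_post, r_pre=r_pre, p=p)


def simulate_recovery_curve(intervals_ms: Iterable[float], params: SynapseParams) -> np.ndarray:
    """Paired-pulse ratio p2/p1 for two pulses from rest at each interval.

    Approaches 1 at long intervals, where both calcium and the pool have
    fully recovered.
    """
    out = []
    for t in intervals_ms:
        resp = simulate_train(StimulusProtocol.paired(t), params)
        out.append(resp.ppr)
    return np.array(out)


def steady_state_response(
    frequency_hz: float,
    params: SynapseParams,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple:
    """Fixed point of the per-pulse map under sustained stimulation.

    Returns ``(c_ss_post, r_ss_pre, p_ss)``.  Post-jump calcium has the
    closed geometric-series form ``delta / (1 - exp(-T/tau))``; the
    available fraction is iterated until the relative change of p_n drops
    below ``tol``.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    period = 1000.0 / frequency_hz
    state = REST
    p_prev = None
    for _ in range(max_iter):
        c_jump = state.c + params.delta_jump
        p_rel = release_probability(c_jump, params)
        p_n = p_rel * state.r
        if p_prev is not None and abs(p_n - p_prev) <= tol * max(abs(p_prev), 1e-300):
            return (c_jump, state.r, p_n)
        p_prev = p_n
        state = propagate_interval(ModelState(c=c_jump, r=state.r * (1.0 - p_rel)), period, params)
    raise ConvergenceError(
        f"steady state at {frequency_hz:g} Hz not reached within {max_iter} iterations"
    )
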