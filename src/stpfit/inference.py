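"""Bayesian estimation of the depression-model parameters from release-probability data.

The target data are the observed per-pulse release probabilities from the
short-term-depression protocol (4 train frequencies x 20 pulses = 80
values) together with the paired-pulse recovery protocol (P1 and P2 at 6
interpulse intervals, 12 values).  Five kinetic parameters are free —
calcium decay ``tau_ca``, release half-saturation ``K``, baseline recovery
rate ``k_min``, calcium-dependent recovery increment ``delta_k`` and its
half-saturation ``K_r`` — while the maximum release probability is fixed
from variance-mean analysis and the calcium increment is fixed at 1.

Estimation proceeds in two stages, both in log-parameter space so
positivity is automatic:

1. MAP: derivative-free simplex minimization of the mean squared error
   between model-predicted and observed release probabilities, with the
   convergence criterion on the relative objective change.
2. MCMC: adaptive random-walk Metropolis around the MAP point with a
   Gaussian likelihood whose error variance is Gibbs-sampled from its
   conjugate inverse-gamma conditional; the proposal covariance is adapted
   from the chain history after an initial non-adaptive phase.  Final
   parameters are reported as posterior means and standard deviations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import FREE_PARAM_NAMES, SynapseParams, _pn_sequence
from .quantal import QuantalSummary

__all__ = [
    "FitDataset",
    "FitReport",
    "PosteriorResult",
    "PosteriorSummary",
    "assemble_fit_dataset",
    "objective",
    "fit_map",
    "run_mcmc",
    "posterior_summary",
]

DEFAULT_FREQUENCIES = (5.0, 10.0, 20.0, 50.0)
DEFAULT_INTERVALS = (20.0, 50.0, 100.0, 500.0, 1000.0, 3000.0)

CHAIN_LENGTH_RANGE = (50_000, 150_000)


@dataclass(frozen=True)
class FitDataset:
    """Target vector for model fitting.

    ``std_pr`` maps train frequency (Hz) to the per-pulse observed release
    probabilities; ``recovery`` maps interpulse interval (ms) to the
    observed (p1, p2) pair.  Entries must lie in [0, 1.2] (slightly above
    1 to tolerate noisy normalization by N*q).
    """

    std_pr: dict
    recovery: dict
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        std = {float(f): np.asarray(v, dtype=float) for f, v in self.std_pr.items()}
        rec = {float(t): (float(p1), float(p2)) for t, (p1, p2) in self.recovery.items()}
        for f, v in std.items():
            if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 1.2):
                raise ValueError(f"release probabilities at {f:g} Hz outside [0, 1.2]")
        for t, pair in rec.items():
            if any(not (0 <= p <= 1.2) for p in pair):
                raise ValueError(f"recovery values at {t:g} ms outside [0, 1.2]")
        object.__setattr__(self, "std_pr", std)
        object.__setattr__(self, "recovery", rec)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_points,):
                raise ValueError(f"weights must have length {self.n_points}")
            object.__setattr__(self, "weights", w)

    @property
    def frequencies(self) -> tuple:
        return tuple(sorted(self.std_pr))

    @property
    def intervals(self) -> tuple:
        return tuple(sorted(self.recovery))

    @property
    def n_points(self) -> int:
        return sum(len(v) for v in self.std_pr.values()) + 2 * len(self.recovery)

    def target_vector(self) -> np.ndarray:
        parts = [self.std_pr[f] for f in self.frequencies]
        parts += [np.asarray(self.recovery[t]) for t in self.intervals]
        return np.concatenate(parts)

    def protocol_gaps(self) -> list:
        """Inter-pulse gap sequences, one per protocol, aligned with
        :meth:`target_vector` ordering."""
        gaps = [
            (1000.0 / f,) * (len(self.std_pr[f]) - 1) for f in self.frequencies
        ]
        gaps += [(t,) for t in self.intervals]
        return gaps

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.frequencies:
            for i, p in enumerate(self.std_pr[f], start=1):
                rows.append(("train", f, i, p))
        for t in self.intervals:
            p1, p2 = self.recovery[t]
            rows.append(("recovery", t, 1, p1))
            rows.append(("recovery", t, 2, p2))
        return pd.DataFrame(rows, columns=["kind", "key", "pulse_index", "p_r"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FitDataset":
        std: dict = {}
        rec: dict = {}
        for (kind, key), grp in df.groupby(["kind", "key"]):
            grp = grp.sort_values("pulse_index")
            if kind == "train":
                std[float(key)] = grp["p_r"].to_numpy()
            elif kind == "recovery":
                vals = grp["p_r"].to_numpy()
                rec[float(key)] = (vals[0], vals[1])
            else:
                raise ValueError(f"unknown dataset row kind {kind!r}")
        return cls(std_pr=std, recovery=rec)


def assemble_fit_dataset(
    summary: QuantalSummary,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    intervals: Sequence[float] = DEFAULT_INTERVALS,
    n_pulses: int = 20,
) -> FitDataset:
    """Flatten a :class:`~stpfit.quantal.QuantalSummary` into the fit target.

    Checks that every requested train frequency and recovery interval is
    present, raising an error that names the gaps.
    """
    missing = [f"{f:g} Hz" for f in frequencies if float(f) not in summary.pr]
    missing += [f"{t:g} ms" for t in intervals if float(t) not in summary.recovery_pr]
    if missing:
        raise ValueError(f"summary is missing protocols: {', '.join(missing)}")
    std = {}
    for f in frequencies:
        series = np.asarray(summary.pr[float(f)], dtype=float)
        if len(series) != n_pulses:
            raise ValueError(f"{f:g} Hz series has {len(series)} pulses, expected {n_pulses}")
        std[float(f)] = np.clip(series, 0.0, 1.2)
    rec = {float(t): summary.recovery_pr[float(t)] for t in intervals}
    return FitDataset(std_pr=std, recovery=rec)


def _predict(dataset: FitDataset, theta: Sequence[float], pmax: float, delta: float) -> np.ndarray:
    """Model-predicted release probabilities for every dataset entry.

    ``theta`` is the free-parameter vector (tau_ca, K, k_min, delta_k, K_r).
    """
    tau, khalf, kmin, dk, krhalf = theta
    out = []
    for gaps in dataset.protocol_gaps():
        out.extend(_pn_sequence(gaps, tau, pmax, khalf, kmin, dk, krhalf, delta))
    return np.asarray(out)


def objective(
    free_params: Sequence[float],
    dataset: FitDataset,
    p_max_vm: float,
    delta_jump: float = 1.0,
) -> float:
    """Mean squared error between model and observed release probabilities.

    Invalid (non-positive or non-finite) parameters return ``inf`` so the
    point is rejected by any minimizer or sampler.
    """
    theta = np.asarray(free_params, dtype=float)
    if theta.shape != (5,) or np.any(~np.isfinite(theta)) or np.any(theta <= 0):
        return math.inf
    resid = _predict(dataset, theta, p_max_vm, delta_jump) - dataset.target_vector()
    if dataset.weights is not None:
        resid = resid * np.sqrt(dataset.weights)
    return float(np.mean(resid**2))


@dataclass(frozen=True)
class FitReport:
    iterations: int
    n_evaluations: int
    mse: float
    converged: bool
    message: str = ""


def fit_map(
    dataset: FitDataset,
    init: SynapseParams,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> tuple:
    """Point estimate by derivative-free simplex minimization.

    The search runs over the logarithms of the five free parameters (so
    positivity needs no constraints) and minimizes the log of the MSE,
    which makes the simplex's absolute function tolerance act as a
    relative convergence criterion on the objective itself.  Returns
    ``(params, report)``.
    """
    target_floor = 1e-300

    def f(logx: np.ndarray) -> float:
        return math.log(objective(np.exp(logx), dataset, init.p_max_vm, init.delta_jump) + target_floor)

    x0 = np.log(init.free_values)
    res = minimize(
        f,
        x0,
        method="Nelder-Mead",
        options={"fatol": tol, "xatol": 1e-9, "maxiter": max_iter, "maxfev": 4 * max_iter},
    )
    params = init.with_free(np.exp(res.x))
    mse = objective(params.free_values, dataset, init.p_max_vm, init.delta_jump)
    # an essentially-zero misfit is a perfect self-consistent fit even if the
    # simplex kept shrinking to the iteration cap
    converged = bool(res.success) or mse <= 1e-20
    report = FitReport(
        iterations=int(res.nit),
        n_evaluations=int(res.nfev),
        mse=mse,
        converged=converged,
        message=str(res.message),
    )
    if not converged and res.nit >= max_iter:
        raise ConvergenceWarningError(params, report)
    return params, report


class ConvergenceWarningError(RuntimeError):
    """MAP iteration cap exceeded; carries the best point found so far."""

    def __init__(self, params: SynapseParams, report: FitReport):
        super().__init__(
            f"MAP optimization hit the iteration cap ({report.iterations}); best MSE {report.mse:.3e}"
        )
        self.params = params
        self.report = report


@dataclass
class PosteriorResult:
    """Sampled posterior over the five free kinetic parameters."""

    chains: np.ndarray  # n_samples x 5, natural scale
    param_names: tuple
    sigma2: np.ndarray  # sampled error-variance chain
    map_estimate: SynapseParams
    acceptance_rate: float
    seed: int | None
    chain_length: int


def run_mcmc(
    dataset: FitDataset,
    start: SynapseParams,
    chain_length: int = 50_000,
    seed: int | None = None,
    adapt_start: int = 1000,
    adapt_interval: int = 100,
    prior_span: float = 1000.0,
    initial_step: float = 0.05,
    dr_scale: float = 0.2,
) -> PosteriorResult:
    """Adaptive random-walk Metropolis over the log free parameters.

    The likelihood is Gaussian with unknown error variance, which is
    Gibbs-sampled each iteration from its conjugate inverse-gamma
    conditional (weak prior centred on the starting misfit).  The prior on
    the parameters is flat in log space within ``x/÷ prior_span`` of the
    start.  After ``adapt_start`` iterations the proposal covariance is
    re-estimated from the chain history every ``adapt_interval``
    iterations, scaled by the usual 2.38^2/d factor.  A first-stage
    rejection triggers one delayed-rejection retry from a ``dr_scale``
    narrower proposal (set ``dr_scale=0`` to disable), which keeps the
    sampler moving along the curved ridges this posterior is known for.
    """
    if not (CHAIN_LENGTH_RANGE[0] <= chain_length <= CHAIN_LENGTH_RANGE[1]):
        warnings.warn(
            f"chain_length {chain_length} outside the standard range "
            f"{CHAIN_LENGTH_RANGE[0]}-{CHAIN_LENGTH_RANGE[1]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = dataset.n_points
    target = dataset.target_vector()
    pmax, delta = start.p_max_vm, start.delta_jump
    gaps_list = dataset.protocol_gaps()

    def sse(theta: np.ndarray) -> float:
        out = []
        tau, khalf, kmin, dk, krhalf = theta
        for gaps in gaps_list:
            out.extend(_pn_sequence(gaps, tau, pmax, khalf, kmin, dk, krhalf, delta))
        d = np.asarray(out) - target
        return float(d @ d)

    x = np.log(start.free_values)
    lo, hi = x - math.log(prior_span), x + math.log(prior_span)
    sse_x = sse(np.exp(x))
    # weak conjugate prior on the error variance: one pseudo-observation at
    # the starting mean squared error (floored to keep noiseless data sane)
    n0 = 1.0
    s02 = max(sse_x / n, 1e-12)
    sigma2 = s02

    d = x.size
    scale = 2.38**2 / d
    cov = np.diag(np.full(d, initial_step**2))
    chol = np.linalg.cholesky(cov)
    inv_chol = np.linalg.inv(chol)
    eps = 1e-12 * np.eye(d)

    def log_q1(a: np.ndarray, b: np.ndarray) -> float:
        v = inv_chol @ (b - a)
        return -0.5 * float(v @ v)

    chain = np.empty((chain_length, d))
    sigma2_chain = np.empty(chain_length)
    n_accept = 0
    n_accept_post = 0
    n_post = 0
    neg_inf = -math.inf
    for i in range(chain_length):
        # stage 1: full-scale random-walk proposal
        lp_x = -sse_x / (2.0 * sigma2)
        y1 = x + chol @ rng.standard_normal(d)
        in1 = np.all(y1 >= lo) and np.all(y1 <= hi)
        sse_y1 = sse(np.exp(y1)) if in1 else math.inf
        lp_y1 = -sse_y1 / (2.0 * sigma2) if in1 else neg_inf
        log_a1 = min(0.0, lp_y1 - lp_x)
        if log_a1 > neg_inf and math.log(rng.random()) < log_a1:
            x, sse_x = y1, sse_y1
            n_accept += 1
            if i >= adapt_start:
                n_accept_post += 1
        elif dr_scale > 0:
            # stage 2: delayed-rejection retry from a narrower proposal
            y2 = x + dr_scale * (chol @ rng.standard_normal(d))
            in2 = np.all(y2 >= lo) and np.all(y2 <= hi)
            if in2:
                sse_y2 = sse(np.exp(y2))
                lp_y2 = -sse_y2 / (2.0 * sigma2)
                log_a1_rev = min(0.0, lp_y1 - lp_y2)
                if log_a1_rev < 0:  # else reverse stage-1 move is certain: alpha2 = 0
                    log_num = lp_y2 + log_q1(y2, y1) + math.log1p(-math.exp(log_a1_rev))
                    log_den = lp_x + log_q1(x, y1) + math.log1p(-math.exp(log_a1))
                    if math.log(rng.random()) < log_num - log_den:
                        x, sse_x = y2, sse_y2
                        n_accept += 1
                        if i >= adapt_start:
                            n_accept_post += 1
        if i >= adapt_start:
            n_post += 1
        # Gibbs update of the error variance from its inverse-gamma conditional
        shape = 0.5 * (n0 + n)
        rate = 0.5 * (n0 * s02 + sse_x)
        sigma2 = rate / rng.gamma(shape)
        chain[i] = x
        sigma2_chain[i] = sigma2
        if i >= adapt_start and (i - adapt_start) % adapt_interval == 0 and i > adapt_start:
            hist_cov = np.cov(chain[: i + 1].T)
            try:
                chol = np.linalg.cholesky(scale * hist_cov + eps)
                inv_chol = np.linalg.inv(chol)
            except np.linalg.LinAlgError:
                pass

    acc = n_accept_post / max(n_post, 1)
    if acc < 0.01:
        raise RuntimeError(
            f"MCMC acceptance rate {acc:.4f} after adaptation is below 0.01; "
            "check the starting point and proposal scale"
        )
    return PosteriorResult(
        chains=np.exp(chain),
        param_names=FREE_PARAM_NAMES,
        sigma2=sigma2_chain,
        map_estimate=start,
        acceptance_rate=acc,
        seed=seed,
        chain_length=chain_length,
    )


@dataclass
class PosteriorSummary:
    """Posterior means/SDs per parameter plus the pairwise correlations."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    corr_kr_tau: float
    burn_in: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.table}\n\ncorr(K_r, tau_Ca) = {self.corr_kr_tau:+.3f} "
            f"(burn-in {self.burn_in} samples)"
        )


def posterior_summary(result: PosteriorResult, burn_in_fraction: float = 0.2) -> PosteriorSummary:
    """Posterior mean ± SD per free parameter and the correlation matrix.

    The recovery half-saturation and the calcium decay constant are known
    to be interdependent, so their posterior correlation is reported
    explicitly.
    """
    if not (0 <= burn_in_fraction < 1):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    burn = int(burn_in_fraction * len(result.chains))
    samples = result.chains[burn:]
    table = pd.DataFrame(
        {"mean": samples.mean(axis=0), "sd": samples.std(axis=0, ddof=1)},
        index=list(result.param_names),
    )
    if np.all(samples.std(axis=0) > 0):
        corr = np.corrcoef(samples.T)
    else:
        corr = np.eye(samples.shape[1])
        nz = samples.std(axis=0) > 0
        if nz.sum() > 1:
            corr_nz = np.corrcoef(samples[:, nz].T)
            corr[np.ix_(nz, nz)] = corr_nz
    correlations = pd.DataFrame(corr, index=list(result.param_names), columns=list(result.param_names))
    return PosteriorSummary(
        table=table,
        correlations=correlations,
        corr_kr_tau=float(correlations.loc["k_r_half", "tau_ca_ms"]),
        burn_in=burn,
    )
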