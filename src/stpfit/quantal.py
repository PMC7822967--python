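"""Quantal and train statistics for IPSC amplitude data.

The central object is an :class:`AmplitudeTable` — the repeats x pulses
matrix of evoked IPSC peak amplitudes for one stimulation protocol.  From
tables recorded at several frequencies this module computes:

* the variance-mean (VM) parabola fit
  ``sigma^2 = (1 + CV^2) * q * I - I^2 / N`` giving the quantal amplitude
  ``q`` and the number of functional release sites ``N`` (``CV`` is the
  intrasite quantal coefficient of variation, fixed at 0.3);
* the maximum release probability ``p_max = p_x / (N * q)``;
* per-pulse release-probability and CV series, the paired-pulse ratio,
  steady-state depression normalized to 5 Hz, and the readily-releasable
  pool size from back-extrapolation of cumulative amplitudes;
* IPSC amplitude extraction from raw traces and 10-90% rise /
  single-exponential decay kinetics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .model import StimulusProtocol

__all__ = [
    "AmplitudeTable",
    "VMFit",
    "QuantalSummary",
    "FitError",
    "extract_amplitudes",
    "variance_mean_fit",
    "fit_parabola",
    "p_max_from_fit",
    "pr_series",
    "rrp_from_cumulative",
    "cv_series",
    "ppr",
    "ssd",
    "ipsc_kinetics",
    "summarize_experiment",
]

INTRASITE_CV = 0.3  # intrasite quantal coefficient of variation, fixed


class FitError(RuntimeError):
    """Raised when a quantal fit is degenerate; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class AmplitudeTable:
    """Repeats x pulses matrix of IPSC peak amplitudes (pA, magnitudes).

    Missing entries are NaN and are skipped by all statistics.
    """

    amplitudes: np.ndarray
    frequency_hz: float
    cell_id: str = ""
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        amps = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if np.nanmin(amps, initial=0.0) < 0:
            raise ValueError("amplitudes are peak magnitudes and must be >= 0")
        proto = self.protocol
        if proto is None:
            proto = StimulusProtocol.train(self.frequency_hz, amps.shape[1])
        if len(proto) != amps.shape[1]:
            raise ValueError(
                f"table has {amps.shape[1]} pulses but protocol has {len(proto)}"
            )
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "protocol", proto)

    @property
    def n_repeats(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_pulses(self) -> int:
        return self.amplitudes.shape[1]

    def pulse_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.amplitudes, axis=0)

    def pulse_variances(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanvar(self.amplitudes, axis=0, ddof=1)

    def pulse_counts(self) -> np.ndarray:
        return np.sum(np.isfinite(self.amplitudes), axis=0)


@dataclass(frozen=True)
class VMFit:
    """Result of the variance-mean parabola fit."""

    q_pa: float
    n_vm: float
    cv_intra: float
    p_max_hat: float
    binned_points: tuple  # ((mean_pa, variance_pa2), ...) as fitted

    def __post_init__(self) -> None:
        if not (self.q_pa > 0 and self.n_vm > 0):
            raise ValueError("q and N must be positive")


@dataclass
class QuantalSummary:
    """Derived train statistics for one cell across protocols.

    ``pr`` and ``cv`` map stimulation frequency (Hz) to per-pulse series;
    ``recovery_pr`` maps interpulse interval (ms) to the (p1, p2) pair of
    release probabilities from the paired-pulse recovery protocol.
    """

    pr: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    ppr_train: dict = field(default_factory=dict)
    recovery_pr: dict = field(default_factory=dict)
    ssd: dict = field(default_factory=dict)
    n_rp: float = float("nan")
    fit: VMFit | None = None


# ---------------------------------------------------------------------------
# amplitude extraction and kinetics


def extract_amplitudes(
    time_ms: np.ndarray,
    current_pa: np.ndarray,
    pulse_times: Sequence[float],
    window_ms: float = 2.0,
    baseline_ms: float = 1.0,
    rise_allowance_ms: float = 1.0,
    polarity: int = 1,
) -> np.ndarray:
    """Peak evoked-IPSC amplitude after each stimulus, baseline subtracted.

    For each pulse the baseline is measured over ``baseline_ms``
    immediately before the pulse and extrapolated linearly across the
    detection window, so that the decaying tail of summated earlier
    responses in high-frequency trains is subtracted rather than treated
    as a constant offset.  The amplitude is the absolute peak of the
    baseline-subtracted current in ``(t, t + window_ms +
    rise_allowance_ms]``, truncated at the next pulse so overlapping
    windows stay stimulus-locked.

    ``polarity=-1`` flips inward-negative recordings before measurement.
    """
    t = np.asarray(time_ms, dtype=float)
    i = polarity * np.asarray(current_pa, dtype=float)
    dt = np.median(np.diff(t))
    if dt > 0.1 + 1e-12:
        raise ValueError(f"sampling interval {dt:g} ms too coarse (need <= 0.1 ms)")
    pulse_times = list(pulse_times)
    out = np.empty(len(pulse_times))
    for k, t0 in enumerate(pulse_times):
        if t0 + window_ms > t[-1] + 1e-9:
            raise ValueError(f"detection window for pulse at {t0:g} ms extends past trace end")
        t_end = t0 + window_ms + rise_allowance_ms
        if k + 1 < len(pulse_times):
            t_end = min(t_end, pulse_times[k + 1])
        win = (t > t0) & (t <= t_end)
        base_mask = (t >= t0 - baseline_ms) & (t < t0)
        if base_mask.sum() >= 2:
            slope, offset = np.polyfit(t[base_mask], i[base_mask], 1)
            baseline = slope * t[win] + offset
        elif base_mask.any():
            baseline = float(np.mean(i[base_mask]))
        else:
            baseline = 0.0
        out[k] = float(np.max(np.abs(i[win] - baseline)))
    return out


def ipsc_kinetics(
    time_ms: np.ndarray,
    current_pa: np.ndarray,
    pulse_time: float = 0.0,
    decay_fit_start_ms: float | None = None,
) -> tuple:
    """10-90% rise time and single-exponential decay constant of one IPSC.

    The rise time is measured by linear interpolation of the 10% and 90%
    threshold crossings on the rising phase.  The decay constant comes
    from a least-squares single-exponential fit starting
    ``decay_fit_start_ms`` after the peak; by default the fit starts two
    measured rise times past the peak, where any residual rising
    component has decayed below ~2% and no longer biases the estimate
    (for an instant-rise event this is the peak itself).
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.abs(np.asarray(current_pa, dtype=float))
    post = t >= pulse_time
    t, i = t[post], i[post]
    ipk = int(np.argmax(i))
    peak = i[ipk]
    if peak <= 0:
        raise FitError("no event found in segment")

    def crossing(level: float) -> float:
        above = np.nonzero(i[: ipk + 1] >= level)[0]
        if len(above) == 0:
            return t[0]
        j = above[0]
        if j == 0:
            return t[0]
        # linear interpolation between the straddling samples
        f = (level - i[j - 1]) / (i[j] - i[j - 1])
        return t[j - 1] + f * (t[j] - t[j - 1])

    rise_10_90 = crossing(0.9 * peak) - crossing(0.1 * peak)

    if decay_fit_start_ms is None:
        decay_fit_start_ms = 2.0 * rise_10_90
    mask = t >= t[ipk] + decay_fit_start_ms
    td, yd = t[mask] - t[ipk], i[mask]
    if len(td) < 4:
        raise FitError("too few samples after the peak for a decay fit")
    try:
        popt, _ = curve_fit(
            lambda x, a, tau: a * np.exp(-x / tau),
            td,
            yd,
            p0=(peak, max(td[-1] / 3.0, 1.0)),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitError(f"decay fit failed: {exc}") from exc
    return float(rise_10_90), float(popt[1])


# ---------------------------------------------------------------------------
# variance-mean analysis


def fit_parabola(means_pa: np.ndarray, variances_pa2: np.ndarray, cv_intra: float = INTRASITE_CV) -> tuple:
    """Least-squares fit of the quantal parabola to (mean, variance) points.

    Solves ``sigma^2 = (1 + CV^2) q I - I^2 / N`` for ``(q, N)``; the
    model is linear in ``a = (1 + CV^2) q`` and ``b = 1/N``.  Raises
    :class:`FitError` when the fitted coefficients are non-positive (e.g.
    zero variance everywhere, or variance increasing quadratically).
    """
    mean_i = np.asarray(means_pa, dtype=float)
    var_i = np.asarray(variances_pa2, dtype=float)
    design = np.column_stack([mean_i, -(mean_i**2)])
    coef, *_ = np.linalg.lstsq(design, var_i, rcond=None)
    a, b = coef
    q = a / (1.0 + cv_intra**2)
    if q <= 0 or b <= 0:
        raise FitError(
            "degenerate variance-mean fit (non-positive q or N)",
            {"a": float(a), "b": float(b)},
        )
    return float(q), float(1.0 / b)


def _vm_points(
    tables: Mapping[float, AmplitudeTable],
    bin_fraction: float,
    min_repeats: int,
    min_bin_points: int,
) -> list:
    """Collect (mean, variance) points: P1 per frequency un-binned, later
    pulses pooled across frequencies and binned by ``bin_fraction x`` the
    grand-mean P1 amplitude."""
    p1_means = []
    p1_points = []
    pooled = []
    for freq in sorted(tables):
        tab = tables[freq]
        counts = tab.pulse_counts()
        means = tab.pulse_means()
        variances = tab.pulse_variances()
        if counts[0] >= min_repeats:
            p1_means.append(means[0])
            p1_points.append((means[0], variances[0]))
        for j in range(1, tab.n_pulses):
            if counts[j] >= min_repeats:
                pooled.append((means[j], variances[j]))
    if not p1_points:
        raise FitError("no P1 point with enough repeats")
    bin_width = bin_fraction * float(np.mean(p1_means))
    if bin_width <= 0:
        raise FitError("degenerate bin width (P1 mean amplitude is zero)")
    binned: dict[int, list] = {}
    for m, v in pooled:
        binned.setdefault(int(m // bin_width), []).append((m, v))
    points = list(p1_points)
    for _, grp in sorted(binned.items()):
        if len(grp) >= min_bin_points:
            arr = np.asarray(grp)
            points.append((float(arr[:, 0].mean()), float(arr[:, 1].mean())))
    return points


def variance_mean_fit(
    tables: Mapping[float, AmplitudeTable],
    cv_intra: float = INTRASITE_CV,
    bin_fraction: float = 0.1,
    min_repeats: int = 3,
    min_bin_points: int = 2,
) -> VMFit:
    """Fit the variance-mean parabola across frequencies.

    Per-pulse means and variances are computed across repeats; P1 from each
    frequency enters as its own point; pulses 2 onward are pooled across
    frequencies and binned by ``bin_fraction`` x the grand-mean P1
    amplitude (bins with fewer than ``min_bin_points`` points are
    dropped).  The parabola
    ``sigma^2 = (1 + CV^2) q I - I^2 / N`` is linear in the coefficients
    ``a = (1 + CV^2) q`` and ``b = 1/N``, so the fit is an unweighted
    linear least-squares problem.
    """
    points = _vm_points(tables, bin_fraction, min_repeats, min_bin_points)
    if len(points) < 2:
        raise FitError("need at least two distinct variance-mean points", {"points": points})
    arr = np.asarray(points, dtype=float)
    mean_i, var_i = arr[:, 0], arr[:, 1]
    q, n_vm = fit_parabola(mean_i, var_i, cv_intra)
    fit = VMFit(
        q_pa=float(q),
        n_vm=float(n_vm),
        cv_intra=cv_intra,
        p_max_hat=float(np.clip(mean_i.max() / (n_vm * q), 0.0, 1.0)),
        binned_points=tuple(map(tuple, points)),
    )
    return fit


def p_max_from_fit(fit: VMFit, mean_amplitudes_pa: Sequence[float]) -> float:
    """Maximum release probability from the largest mean amplitude:
    ``p_max = p_x / (N * q)``, clipped to [0, 1] with a warning above 1."""
    p = float(np.max(np.asarray(mean_amplitudes_pa, dtype=float)) / (fit.n_vm * fit.q_pa))
    if p > 1.0:
        warnings.warn(
            f"p_max estimate {p:.3f} exceeds 1; N*q is inconsistent with the amplitudes",
            stacklevel=2,
        )
    return float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# train statistics


def pr_series(table: AmplitudeTable, n_sites: float, q_pa: float) -> np.ndarray:
    """Per-pulse release probability: mean amplitude divided by ``N * q``."""
    if n_sites <= 0 or q_pa <= 0:
        raise ValueError("n_sites and q must be positive")
    out = table.pulse_means() / (n_sites * q_pa)
    if np.nanmax(out) > 1.2:
        warnings.warn(
            f"release probability {np.nanmax(out):.2f} > 1.2; N*q inconsistent with amplitudes",
            stacklevel=2,
        )
    return out


def cv_series(table: AmplitudeTable, min_repeats: int = 3) -> np.ndarray:
    """Per-pulse coefficient of variation across repeats (sample SD / mean).

    Entries with a zero mean or fewer than ``min_repeats`` valid repeats
    are NaN.
    """
    counts = table.pulse_counts()
    means = table.pulse_means()
    sds = np.sqrt(table.pulse_variances())
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((counts >= min_repeats) & (means > 0), sds / means, np.nan)
    return out


def ppr(table: AmplitudeTable) -> float:
    """Paired-pulse ratio: mean P2 amplitude over mean P1 amplitude."""
    if table.n_pulses < 2:
        raise ValueError("PPR needs at least two pulses")
    means = table.pulse_means()
    if not means[0] > 0:
        raise ZeroDivisionError("mean P1 amplitude is zero")
    return float(means[1] / means[0])


def rrp_from_cumulative(table: AmplitudeTable, q_pa: float, tail_pulses: int = 5) -> float:
    """Readily-releasable pool size from cumulative-amplitude back-extrapolation.

    The cumulative mean amplitude is plotted against pulse index; a line
    through the last ``tail_pulses`` points (where release is limited by
    replenishment) is extrapolated back to pulse 0, and the intercept
    divided by ``q`` estimates the number of releasable quanta at train
    onset.
    """
    if table.n_pulses < tail_pulses + 2:
        raise ValueError(f"need at least {tail_pulses + 2} pulses")
    if q_pa <= 0:
        raise ValueError("q must be positive")
    cum = np.cumsum(table.pulse_means())
    x = np.arange(1, table.n_pulses + 1, dtype=float)
    slope, intercept = np.polyfit(x[-tail_pulses:], cum[-tail_pulses:], 1)
    if intercept < 0:
        warnings.warn(f"negative cumulative intercept ({intercept:.1f} pA)", stacklevel=2)
    return float(intercept / q_pa)


def ssd(tables: Mapping[float, AmplitudeTable], reference_hz: float = 5.0) -> dict:
    """Steady-state depression per frequency, normalized to the 5 Hz plateau.

    For each train the plateau is the mean of the P1-normalized amplitudes
    over pulses 16-20; each frequency's plateau is then divided by the
    reference (5 Hz) plateau, which is 1 by construction.
    """
    if reference_hz not in tables:
        raise KeyError(f"missing {reference_hz:g} Hz reference table for SSD normalization")

    def plateau(tab: AmplitudeTable) -> float:
        if tab.n_pulses < 20:
            raise ValueError("SSD needs 20-pulse trains")
        means = tab.pulse_means()
        return float(np.mean(means[15:20]) / means[0])

    ref = plateau(tables[reference_hz])
    return {f: plateau(tab) / ref for f, tab in sorted(tables.items())}


def summarize_experiment(
    tables: Mapping[float, AmplitudeTable],
    recovery_pairs: Mapping[float, np.ndarray] | None = None,
    n_sites: float | None = None,
    q_pa: float | None = None,
    fit: VMFit | None = None,
) -> QuantalSummary:
    """Compute the full battery of train statistics for one cell.

    If ``n_sites``/``q_pa`` are not given, a variance-mean fit is run first
    and its estimates are used to convert amplitudes to release
    probabilities.  ``recovery_pairs`` maps interpulse interval (ms) to a
    repeats x 2 array of (P1, P2) amplitudes.
    """
    if n_sites is None or q_pa is None:
        fit = fit or variance_mean_fit(tables)
        n_sites, q_pa = fit.n_vm, fit.q_pa
    summary = QuantalSummary(fit=fit)
    nq = n_sites * q_pa
    for freq, tab in sorted(tables.items()):
        summary.pr[freq] = pr_series(tab, n_sites, q_pa)
        summary.cv[freq] = cv_series(tab)
        summary.ppr_train[freq] = ppr(tab)
    summary.ssd = ssd(tables) if 5.0 in tables else {}
    if 50.0 in tables:
        summary.n_rp = rrp_from_cumulative(tables[50.0], q_pa)
    if recovery_pairs:
        for interval, pairs in sorted(recovery_pairs.items()):
            arr = np.atleast_2d(np.asarray(pairs, dtype=float))
            summary.recovery_pr[interval] = (
                float(np.nanmean(arr[:, 0]) / nq),
                float(np.nanmean(arr[:, 1]) / nq),
            )
    return summary
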