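"""Spike-density estimation with a forward (EPSP-like) kernel.

Spike trains are convolved with a causal two-exponential kernel

    K(t) = (1 - exp(-t / tau_growth)) * exp(-t / tau_decay),  t >= 0

(growth 1 ms, decay 20 ms by default), normalised to unit area so that
convolution conserves spike count.  Because K(t) = 0 for t < 0, each spike
influences the rate estimate only forward in time — a Gaussian kernel would
smear activity backwards and can make response latencies look impossibly
early.  Rates are evaluated on a 1-ms grid in spikes/s; analyses re-bin
from that grid.  Per-unit rates are normalised by dividing by the mean
baseline rate during the pre-cue fixation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .session import Session, TrialRecord, UnitRecord

__all__ = [
    "KernelParams",
    "RateTrace",
    "epsp_kernel",
    "convolve_density",
    "baseline_rate",
    "normalize_baseline",
    "windowed_rate",
    "fixation_rates",
]

GRID_MS = 1.0  # evaluation grid step


@dataclass(frozen=True)
class KernelParams:
    growth_tau: float = 1.0  # ms
    decay_tau: float = 20.0  # ms

    def __post_init__(self):
        if self.growth_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("kernel time constants must be positive")


@dataclass
class RateTrace:
    """A rate estimate on a uniform time grid (ms)."""

    times: np.ndarray  # ms
    rate: np.ndarray  # spikes/s, or baseline multiples if normalized
    normalized: bool = False
    unit_id: str = ""


def epsp_kernel(params: KernelParams, t_grid: np.ndarray) -> np.ndarray:
    """Unit-area causal kernel sampled on ``t_grid`` (ms).

    Values are zero for t < 0; the discrete samples are normalised so that
    sum(K) * dt = 1, making the convolution conserve spike count on the grid.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2:
        raise ValueError("t_grid must contain at least two samples")
    dt = float(t[1] - t[0])
    span = t[-1]
    if span < 5.0 * params.decay_tau:
        raise ValueError(
            f"t_grid must span at least 5 decay constants ({5 * params.decay_tau} ms)"
        )
    k = np.where(
        t >= 0.0,
        (1.0 - np.exp(-np.maximum(t, 0.0) / params.growth_tau))
        * np.exp(-np.maximum(t, 0.0) / params.decay_tau),
        0.0,
    )
    area = k.sum() * dt
    return k / area


def kernel_support_ms(params: KernelParams) -> float:
    """Truncation point of the kernel tail (relative weight < 1e-13)."""
    return 30.0 * params.decay_tau


def kernel_grid(params: KernelParams) -> np.ndarray:
    return np.arange(0.0, kernel_support_ms(params) + GRID_MS, GRID_MS)


def convolve_density(
    spikes: np.ndarray,
    params: KernelParams = KernelParams(),
    window: tuple[float, float] = (0.0, 1000.0),
) -> RateTrace:
    """Continuous rate estimate over ``window`` (ms) at 1-ms resolution.

    Spikes are binned to the grid and convolved with the unit-area kernel via
    FFT; the result equals the per-spike brute-force summation to machine
    precision.  An empty spike list yields an all-zero trace.
    """
    t0, t1 = window
    times = np.arange(t0, t1 + GRID_MS / 2, GRID_MS)
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    n = times.size
    if spikes.size == 0:
        return RateTrace(times=times, rate=np.zeros(n))
    # pad so spikes well before the window still contribute their full tail
    pad = int(np.ceil(kernel_support_ms(params) / GRID_MS))
    lo = t0 - pad * GRID_MS
    counts = np.zeros(n + pad)
    # floor (not round) so a spike never influences grid points before it
    idx = np.floor((spikes - lo) / GRID_MS + 1e-9).astype(int)
    valid = (idx >= 0) & (idx < counts.size)
    np.add.at(counts, idx[valid], 1.0)
    kernel = epsp_kernel(params, kernel_grid(params))
    conv = fftconvolve(counts, kernel, mode="full")[pad: pad + n]
    return RateTrace(times=times, rate=conv * 1000.0 * GRID_MS)


def snap_to_grid(spikes: np.ndarray) -> np.ndarray:
    """Spike times floored to the evaluation grid (used by oracles)."""
    return np.floor(np.asarray(spikes, dtype=float) / GRID_MS + 1e-9) * GRID_MS


def baseline_rate(unit: UnitRecord, trials: list[TrialRecord],
                  window: tuple[float, float] = (-150.0, 0.0)) -> float:
    """Mean firing rate (Hz) in the baseline window relative to cue onset,
    averaged across trials (spike counts / window duration)."""
    a, b = window
    dur_s = (b - a) / 1000.0
    counts = []
    for t in trials:
        st = unit.spikes.get(t.trial_id)
        if st is None:
            continue
        counts.append(np.count_nonzero((st >= t.cue_on + a) & (st < t.cue_on + b)))
    if not counts:
        return float("nan")
    return float(np.mean(counts) / dur_s)


def normalize_baseline(trace: RateTrace, baseline_hz: float) -> RateTrace:
    """Divide a rate trace by the unit's mean baseline rate.

    Division (not subtraction or z-scoring) is the convention: normalised
    traces are unitless multiples of baseline.  A zero or non-finite baseline
    cannot be normalised; callers flag and exclude such units.
    """
    if not np.isfinite(baseline_hz) or baseline_hz <= 0:
        raise ZeroDivisionError(
            "baseline rate is zero or undefined; unit must be excluded from "
            "normalized analyses"
        )
    return RateTrace(
        times=trace.times,
        rate=trace.rate / baseline_hz,
        normalized=True,
        unit_id=trace.unit_id,
    )


def windowed_rate(unit: UnitRecord, trial: TrialRecord, t0: float, t1: float) -> float:
    """Raw spike rate (Hz) of one unit in an absolute trial window (ms)."""
    st = unit.spikes.get(trial.trial_id)
    if st is None or t1 <= t0:
        return float("nan")
    n = np.count_nonzero((st >= t0) & (st < t1))
    return n / ((t1 - t0) / 1000.0)


def fixation_rates(unit: UnitRecord, session: Session,
                   window: tuple[float, float] = (150.0, 225.0),
                   correct_only: bool = True) -> list[tuple]:
    """Per-fixation mean rates: (fixation, rate_hz) over all (correct) trials."""
    out = []
    for t in session.trials:
        if correct_only and not t.correct:
            continue
        for fx in t.fixations:
            r = windowed_rate(unit, t, fx.onset + window[0], fx.onset + window[1])
            if np.isfinite(r):
                out.append((fx, r))
    return out
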