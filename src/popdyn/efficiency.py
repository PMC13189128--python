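"""Presearch activity and search efficiency.

Search efficiency is indexed by the number of fixations a correct trial
needs.  Per unit, the mean rate during cue presentation (0-500 ms after
cue onset) and cue maintenance (0-200 ms after delay onset) is correlated
(Pearson) with the per-trial fixation count; units are classed positive /
negative / none by the delay-window result.  Correlations are reported
both over trial-level points and over fixation-count group means (the
lowest seven counts by default).  The same trials feed two further
analyses: the divergence of cue-condition population vectors between
search onset and search end, and the correlation of theta-band (4-12 Hz)
LFP power with fixation count per epoch, estimated by Welch's method with
200-ms Hann segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import welch

from .density import baseline_rate, windowed_rate
from .geometry import representational_distance, vector_angle
from .session import Session, UnitRecord

__all__ = [
    "EfficiencyResult",
    "ThetaResult",
    "unit_efficiency_correlation",
    "divergence_at_search_end",
    "theta_power_correlation",
    "band_power",
]

CUE_WINDOW = (0.0, 500.0)  # ms after cue onset
DELAY_WINDOW = (0.0, 200.0)  # ms after delay onset
THETA_BAND = (4.0, 12.0)  # Hz
N_FIX_GROUPS = 7


@dataclass
class EfficiencyResult:
    unit_id: str
    r_cue: float
    p_cue: float
    r_delay: float
    p_delay: float
    r_cue_grouped: float
    r_delay_grouped: float
    r_cue_face: float
    r_cue_house: float
    efficiency_class: str  # positive / negative / none


@dataclass
class ThetaResult:
    epoch: str
    n_fix_values: np.ndarray
    power: np.ndarray  # mean band power per fixation-count group
    r: float
    p: float


def _trial_windows(session: Session, min_trials: int = 20):
    trials = [t for t in session.correct_trials()]
    n_fix = np.array([t.n_fixations for t in trials])
    if len(trials) < min_trials or len(np.unique(n_fix)) < 3:
        raise ValueError(
            f"need >= {min_trials} correct trials spanning >= 3 fixation counts"
        )
    return trials, n_fix


def _safe_pearson(x, y):
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def _grouped_r(n_fix: np.ndarray, rates: np.ndarray, n_groups: int) -> float:
    values = np.unique(n_fix)[:n_groups]
    means = np.array([rates[n_fix == v].mean() for v in values])
    r, _ = _safe_pearson(values.astype(float), means)
    return r


def unit_efficiency_correlation(session: Session, unit: UnitRecord,
                                alpha: float = 0.05,
                                n_groups: int = N_FIX_GROUPS) -> EfficiencyResult:
    """Correlate presearch rate with the trial's fixation count.

    The class label follows the delay-window correlation (sign of r where
    p < alpha, else "none"); cue-window and per-cue-category correlations
    are reported alongside, as are correlations over fixation-count group
    means restricted to the ``n_groups`` lowest counts.
    """
    trials, n_fix = _trial_windows(session)
    cue = np.array([windowed_rate(unit, t, t.cue_on + CUE_WINDOW[0],
                                  t.cue_on + CUE_WINDOW[1]) for t in trials])
    delay = np.array([windowed_rate(unit, t, t.delay_on + DELAY_WINDOW[0],
                                    t.delay_on + DELAY_WINDOW[1]) for t in trials])
    r_cue, p_cue = _safe_pearson(n_fix.astype(float), cue)
    r_delay, p_delay = _safe_pearson(n_fix.astype(float), delay)
    face = np.array([t.cue_category == "face" for t in trials])
    r_cue_face, _ = _safe_pearson(n_fix[face].astype(float), cue[face])
    r_cue_house, _ = _safe_pearson(n_fix[~face].astype(float), cue[~face])
    if np.isnan(r_delay) or p_delay >= alpha:
        cls = "none"
    else:
        cls = "positive" if r_delay > 0 else "negative"
    return EfficiencyResult(
        unit_id=unit.unit_id, r_cue=r_cue, p_cue=p_cue,
        r_delay=r_delay, p_delay=p_delay,
        r_cue_grouped=_grouped_r(n_fix, cue, n_groups),
        r_delay_grouped=_grouped_r(n_fix, delay, n_groups),
        r_cue_face=r_cue_face, r_cue_house=r_cue_house,
        efficiency_class=cls,
    )


@dataclass
class DivergenceResult:
    distance_onset: float
    distance_end: float
    angle_onset: float
    angle_end: float
    t_distance: float
    p_distance: float
    t_angle: float
    p_angle: float
    null_distance_onset: np.ndarray
    null_distance_end: np.ndarray


def divergence_at_search_end(session: Session, unit_ids: list[str],
                             window: tuple[float, float] = (0.0, 225.0),
                             n_subsets: int = 15, n_perm: int = 200,
                             seed: int = 0) -> DivergenceResult:
    """Cue-condition separation at search onset versus search completion.

    Face- and house-cue population vectors (normalized rates in ``window``
    after the first / final fixation onset) are compared by Euclidean
    distance and angle; a paired t-test across random unit subsets tests
    onset-versus-end growth, and cue-label shuffles give a null at each
    time point.
    """
    units = [u for u in session.units if u.unit_id in set(unit_ids)]
    trials = session.correct_trials()
    if len(trials) < 20:
        raise ValueError("too few completed trials for divergence analysis")
    kept, baselines = [], []
    for u in units:
        b = baseline_rate(u, trials)
        if np.isfinite(b) and b > 0:
            kept.append(u)
            baselines.append(b)
    units = kept
    baselines = np.asarray(baselines)
    rng = np.random.default_rng(seed)

    # precompute (trial, unit) normalized rates at onset and end
    def rate_matrix(align: str) -> np.ndarray:
        R = np.zeros((len(trials), len(units)))
        for i, t in enumerate(trials):
            t0 = t.fixations[0].onset if align == "onset" else t.fixations[-1].onset
            for j, u in enumerate(units):
                R[i, j] = windowed_rate(u, t, t0 + window[0], t0 + window[1])
        return R / baselines[None, :]

    R_on, R_end = rate_matrix("onset"), rate_matrix("end")
    is_face = np.array([t.cue_category == "face" for t in trials])

    def dist_angle(R: np.ndarray, face_mask: np.ndarray, cols) -> tuple[float, float]:
        vf = R[np.ix_(face_mask, cols)].mean(axis=0)
        vh = R[np.ix_(~face_mask, cols)].mean(axis=0)
        return representational_distance(vf, vh), vector_angle(vf, vh)

    d_on, d_end, a_on, a_end = (np.zeros(n_subsets) for _ in range(4))
    size = max(5, int(round(0.8 * len(units))))
    for k in range(n_subsets):
        take = rng.choice(len(units), size=size, replace=False)
        d_on[k], a_on[k] = dist_angle(R_on, is_face, take)
        d_end[k], a_end[k] = dist_angle(R_end, is_face, take)

    td, pd_ = stats.ttest_rel(d_end, d_on)
    ta, pa = stats.ttest_rel(a_end, a_on)

    all_cols = np.arange(len(units))
    null_on = np.zeros(n_perm)
    null_end = np.zeros(n_perm)
    for k in range(n_perm):
        perm_mask = rng.permutation(is_face)
        null_on[k], _ = dist_angle(R_on, perm_mask, all_cols)
        null_end[k], _ = dist_angle(R_end, perm_mask, all_cols)

    return DivergenceResult(
        distance_onset=float(d_on.mean()), distance_end=float(d_end.mean()),
        angle_onset=float(a_on.mean()), angle_end=float(a_end.mean()),
        t_distance=float(td), p_distance=float(pd_),
        t_angle=float(ta), p_angle=float(pa),
        null_distance_onset=null_on, null_distance_end=null_end,
    )


def band_power(x: np.ndarray, fs: float, band: tuple[float, float],
               nperseg: int | None = None) -> float:
    """Band-integrated Welch power (Hann segments, 50% overlap)."""
    if len(x) < 8:
        return float("nan")
    if nperseg is None:
        nperseg = min(len(x), int(0.2 * fs))  # 200-ms segments
    f, pxx = welch(x, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2, detrend="constant")
    sel = (f >= band[0]) & (f <= band[1])
    df = f[1] - f[0]
    return float(np.sum(pxx[sel]) * df)  # rectangle-rule band integral


def theta_power_correlation(session: Session, epoch: str,
                            band: tuple[float, float] = THETA_BAND,
                            channel_id: str | None = None,
                            n_groups: int = N_FIX_GROUPS) -> ThetaResult:
    """Theta-band LFP power versus search efficiency for one epoch.

    Per correct trial, band power over the cue or delay epoch is estimated
    by Welch's method; powers are averaged within fixation-count groups
    (the ``n_groups`` lowest counts) and Pearson-correlated with the count.
    """
    import warnings

    if session.lfp is None or not session.lfp:
        raise ValueError("session has no LFP traces")
    trace = session.lfp[0] if channel_id is None else next(
        ch for ch in session.lfp if ch.channel_id == channel_id
    )
    trials, n_fix = _trial_windows(session)
    fs = trace.rate_hz
    powers = []
    for t in trials:
        if epoch == "cue":
            a, b = t.cue_on, t.cue_off
        elif epoch == "delay":
            a, b = t.cue_off, t.array_on
        else:
            raise ValueError(f"unknown epoch {epoch!r}")
        if (b - a) / 1000.0 < 2.0 / band[0]:
            warnings.warn(f"epoch shorter than 2 cycles of {band[0]} Hz")
        x = trace.samples[t.trial_id][int(a):int(b)]
        powers.append(band_power(np.asarray(x, float), fs, band))
    powers = np.asarray(powers)
    values = np.unique(n_fix)[:n_groups]
    group_power = np.array([powers[n_fix == v].mean() for v in values])
    r, p = _safe_pearson(values.astype(float), group_power)
    return ThetaResult(epoch=epoch, n_fix_values=values, power=group_power, r=r, p=p)
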