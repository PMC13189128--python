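"""Synthetic free-gaze search sessions with planted, recorded ground truth.

The generator emulates the task structure the analyses assume: a 400-ms
central fixation, a 500-1300-ms category cue (face or house), a 500-ms
delay, and a free-gaze search over an 11-item array (2 same-category
targets among 20 locations at 5-11 deg eccentricity).  Fixation durations
are log-normal with a 208-ms mean and a small fraction of trials contain
return fixations.  Spiking is inhomogeneous Poisson with piecewise-constant
rates built from per-unit tuning parameters (baseline, category gain,
attention gain, spatial receptive field, cue-maintenance gain, search-
efficiency slope), and LFP traces carry 1/f background noise plus a
theta-band sinusoid whose epoch-specific amplitude depends on the trial's
fixation count.  Every planted parameter is stored in the session's
:class:`~popdyn.session.GroundTruth` so downstream analyses have a
recoverable target.

Randomness is organised as counter-based substreams keyed by
``(seed, stream, unit index, trial index)``; adding units or channels never
perturbs existing trials, and a given config + seed is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .session import (
    ArrayGeometry,
    ArrayItem,
    CATEGORIES,
    FixationEvent,
    GroundTruth,
    LfpTrace,
    Session,
    TrialRecord,
    UnitRecord,
    UnitTruth,
    validate_session,
)

__all__ = [
    "SimConfig",
    "make_array_geometry",
    "simulate_trial",
    "simulate_spikes",
    "simulate_lfp",
    "simulate_session",
    "STIMULUS_TYPES",
    "encoding_vector_for_truth",
]

# substream tags (second entry of the SeedSequence key)
_TRIAL_STREAM = 1
_SPIKE_STREAM = 2
_LFP_STREAM = 3
_TRUTH_STREAM = 4

#: the 6 stimulus types of the peripheral encoding model, in design order
STIMULUS_TYPES = (
    "face_target",
    "face_distractor",
    "house_target",
    "house_distractor",
    "flower_distractor",
    "hand_distractor",
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic generator.

    Defaults encode the task parameters the analyses assume (timeline,
    fixation statistics, tuning strengths); ``seed`` fully determines the
    output.
    """

    n_units: dict[str, int] = field(
        default_factory=lambda: {"V4": 40, "IT": 24, "OFC": 16, "LPFC": 16}
    )
    n_trials: int = 300
    seed: int = 0

    # trial timeline (ms)
    fixation_spot_ms: float = 400.0
    cue_min_ms: float = 500.0
    cue_max_ms: float = 1300.0
    delay_ms: float = 500.0
    search_max_ms: float = 4000.0
    target_hold_ms: float = 800.0

    # fixation / search behaviour
    fix_duration_mean_ms: float = 208.0
    fix_duration_sd_ms: float = 100.0
    fix_duration_min_ms: float = 80.0
    saccade_gap_mean_ms: float = 40.0
    saccade_gap_sd_ms: float = 8.0
    first_saccade_mean_ms: float = 220.0
    first_saccade_sd_ms: float = 30.0
    refixation_prob: float = 0.10
    target_guidance_prob: float = 0.30
    target_hold_prob: float = 0.75
    trial_fail_prob: float = 0.10

    # unit population composition
    rf_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "focal_foveal": 0.35,
            "broad_foveal": 0.15,
            "peripheral_localized": 0.30,
            "peripheral_unlocalized": 0.10,
            "nonresponsive": 0.10,
        }
    )
    p_category_tuned_foveal: float = 0.40
    p_category_tuned_peripheral: float = 0.15
    p_attention_tuned: float = 0.30
    category_gain: float = 2.0
    attention_gain: float = 2.0
    maintenance_exponent: float = 0.5  # maintenance_gain = category_gain ** this
    p_efficiency_positive: float = 0.25
    p_efficiency_negative: float = 0.11
    efficiency_slope: float = 0.06  # |log-rate| change per extra fixation
    peripheral_state_gain: float = 1.5
    refixation_gain_v4_it: float = 0.8
    post_target_gain_v4_it: float = 0.85
    baseline_rate_mean_hz: float = 10.0
    baseline_rate_sd_hz: float = 4.0
    baseline_rate_min_hz: float = 2.0
    evoked_gain_range: tuple[float, float] = (0.6, 1.4)  # evoked = baseline * U(range)
    rf_sigma_deg: float = 2.5
    response_latency_ms: float = 50.0
    # eye-position gain fields on foveal units (the substrate of the spatial
    # layout code): fixation responses scale with proximity of the fixated
    # location to a unit-specific field center
    position_gain_amp: float = 1.0
    position_sigma_deg: float = 3.0

    # LFP
    lfp_enabled: bool = True
    theta_base: float = 1.0
    theta_slope_cue: float = 0.15
    theta_slope_delay: float = -0.15
    theta_ref_nfix: float = 3.0
    theta_freq_hz: float = 8.0
    lfp_noise_sd: float = 1.0

    n_exemplars: int = 40


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def null_sim_config(**overrides) -> SimConfig:
    """A configuration with every planted modulation switched off.

    Useful as the no-signal reference when calibrating false-positive rates:
    units keep their baselines and RF structure but carry no category,
    attention, maintenance, state, history or efficiency modulation.
    """
    cfg = SimConfig(
        category_gain=1.0,
        attention_gain=1.0,
        p_category_tuned_foveal=0.0,
        p_category_tuned_peripheral=0.0,
        p_attention_tuned=0.0,
        maintenance_exponent=0.0,
        p_efficiency_positive=0.0,
        p_efficiency_negative=0.0,
        efficiency_slope=0.0,
        peripheral_state_gain=1.0,
        refixation_gain_v4_it=1.0,
        post_target_gain_v4_it=1.0,
        theta_slope_cue=0.0,
        theta_slope_delay=0.0,
        position_gain_amp=0.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def make_array_geometry(seed: int = 0) -> ArrayGeometry:
    """Twenty array locations: three concentric arcs at 5.5, 8 and 10.5 deg
    eccentricity with three locations per arc per hemifield (mirror symmetric)
    plus two vertical-midline points at 6 deg above and below fixation.

    The layout is deterministic; ``seed`` is accepted for interface symmetry
    with the other generators but does not change the canonical layout.
    """
    del seed
    coords = []
    angles = np.deg2rad([-55.0, 0.0, 55.0])
    for ecc in (5.5, 8.0, 10.5):
        for ang in angles:
            x, y = ecc * math.cos(ang), ecc * math.sin(ang)
            coords.append((x, y))
            coords.append((-x, y))
    coords.append((0.0, 6.0))
    coords.append((0.0, -6.0))
    geom = ArrayGeometry(coordinates=np.array(coords, dtype=float))
    geom.validate()
    return geom


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _draw_fix_duration(config: SimConfig, rng: np.random.Generator) -> float:
    mu, sigma = _lognormal_params(config.fix_duration_mean_ms, config.fix_duration_sd_ms)
    return max(config.fix_duration_min_ms, float(rng.lognormal(mu, sigma)))


def simulate_trial(config: SimConfig, trial_id: int, rng: np.random.Generator) -> TrialRecord:
    """Draw one trial: timeline, array composition and the fixation sequence.

    Correct trials end with an 800-ms hold on one of the two targets; failed
    trials wander among distractors and time out.  Refixation and
    after-first-target flags are computed from the realised sequence.
    """
    cue_on = config.fixation_spot_ms
    cue_off = cue_on + float(rng.uniform(config.cue_min_ms, config.cue_max_ms))
    array_on = cue_off + config.delay_ms

    cue_category = "face" if rng.random() < 0.5 else "house"
    cue_exemplar = int(rng.integers(1, config.n_exemplars + 1))

    locations = rng.choice(np.arange(1, 21), size=11, replace=False)
    target_exemplars = rng.choice(np.arange(1, config.n_exemplars + 1), size=2, replace=False)
    other_cats = [c for c in CATEGORIES if c != cue_category]
    items: list[ArrayItem] = [
        ArrayItem(int(locations[0]), cue_category, int(target_exemplars[0]), True),
        ArrayItem(int(locations[1]), cue_category, int(target_exemplars[1]), True),
    ]
    # nine distractors drawn from the three non-cue categories, three each
    d_cats = [c for c in other_cats for _ in range(3)]
    for k, cat in enumerate(d_cats):
        ex = int(rng.integers(1, config.n_exemplars + 1))
        items.append(ArrayItem(int(locations[2 + k]), cat, ex, False))

    will_fail = rng.random() < config.trial_fail_prob
    items_by_loc = {it.location_index: it for it in items}
    target_locs = [it.location_index for it in items if it.is_target]

    fixations: list[FixationEvent] = []
    t = array_on + max(
        120.0, float(rng.normal(config.first_saccade_mean_ms, config.first_saccade_sd_ms))
    )
    visited: list[int] = []
    target_fixed = False
    correct = False
    ordinal = 0
    deadline = array_on + config.search_max_ms
    while t < deadline:
        ordinal += 1
        current = fixations[-1].location_index if fixations else None
        prior = [loc for loc in visited if loc != current]
        fresh_targets = [l for l in target_locs if l not in visited]
        if prior and rng.random() < config.refixation_prob:
            loc = int(prior[rng.integers(len(prior))])
        elif (not will_fail) and fresh_targets and rng.random() < config.target_guidance_prob:
            loc = int(fresh_targets[rng.integers(len(fresh_targets))])
        else:
            cands = [l for l in items_by_loc if l != current and l not in visited]
            if not cands:
                if config.refixation_prob <= 0 or not prior:
                    break  # everything inspected and revisits disabled
                cands = prior
            loc = int(cands[rng.integers(len(cands))])
        item = items_by_loc[loc]
        is_target = item.is_target and not will_fail
        hold = is_target and rng.random() < config.target_hold_prob
        dur = config.target_hold_ms if hold else _draw_fix_duration(config, rng)
        fixations.append(
            FixationEvent(
                onset=t,
                offset=t + dur,
                location_index=loc,
                item_category=item.category,
                item_exemplar=item.exemplar,
                is_target=item.is_target,
                ordinal=ordinal,
                is_refixation=loc in visited,
                after_first_target_fix=target_fixed,
                trial_id=trial_id,
            )
        )
        visited.append(loc)
        if item.is_target:
            target_fixed = True
        if hold:
            correct = True
            t += dur
            break
        t += dur + max(20.0, float(rng.normal(config.saccade_gap_mean_ms, config.saccade_gap_sd_ms)))
    if not fixations:  # pathological config; keep the record valid
        fixations.append(
            FixationEvent(array_on + 150.0, array_on + 350.0, int(locations[2]),
                          items_by_loc[int(locations[2])].category,
                          items_by_loc[int(locations[2])].exemplar,
                          False, 1, False, False, trial_id)
        )
    trial_end = fixations[-1].offset
    return TrialRecord(
        trial_id=trial_id,
        cue_category=cue_category,
        cue_exemplar=cue_exemplar,
        fixation_spot_on=0.0,
        cue_on=cue_on,
        cue_off=cue_off,
        array_on=array_on,
        trial_end=trial_end,
        array_items=items,
        fixations=fixations,
        correct=correct,
    )


def _catfac(truth: UnitTruth, category: str) -> float:
    if truth.category_gain == 1.0:
        return 1.0
    other = "house" if truth.category_pref == "face" else "face"
    if category == truth.category_pref:
        return truth.category_gain
    if category == other:
        return 1.0 / truth.category_gain
    return 1.0


def _posfac(truth: UnitTruth, location_index: int, geometry: ArrayGeometry) -> float:
    """Spatial gain for a fixation at ``location_index`` (1 when untuned)."""
    if truth.position_amp == 0.0 or truth.position_center is None:
        return 1.0
    d = np.linalg.norm(geometry.coordinates[location_index - 1]
                       - np.asarray(truth.position_center))
    return 1.0 + truth.position_amp * math.exp(-d * d / (2.0 * truth.position_sigma ** 2))


def _maintfac(truth: UnitTruth, category: str) -> float:
    if truth.maintenance_gain == 1.0:
        return 1.0
    if category == truth.category_pref:
        return truth.maintenance_gain
    return 1.0 / truth.maintenance_gain


def rf_locations(truth: UnitTruth, geometry: ArrayGeometry) -> set[int]:
    """Locations within one RF width of the planted center (membership rule)."""
    if truth.rf_center is None:
        return set()
    d = np.linalg.norm(geometry.coordinates - np.asarray(truth.rf_center), axis=1)
    return {int(i + 1) for i in np.where(d <= truth.rf_sigma)[0]}


def _stimulus_type(category: str, is_target: bool) -> str:
    if category in ("face", "house"):
        return f"{category}_{'target' if is_target else 'distractor'}"
    return f"{category}_distractor"


def encoding_vector_for_truth(truth: UnitTruth) -> np.ndarray:
    """The 12 response-strength coefficients implied by a peripheral unit's
    tuning: [on-target block | on-distractor block] x 6 stimulus types."""
    beta = np.zeros(12)
    for b, state in enumerate(("target", "distractor")):
        statefac = truth.state_gain if state == "target" else 1.0
        for s, stype in enumerate(STIMULUS_TYPES):
            cat = stype.split("_")[0]
            attfac = truth.attention_gain if stype.endswith("_target") else 1.0
            beta[b * 6 + s] = truth.evoked_rate * _catfac(truth, cat) * attfac * statefac
    return beta


def _peripheral_drive(truth: UnitTruth, rf_locs: set[int], trial: TrialRecord,
                      on_target_fix: bool) -> float:
    """Additive rate (Hz) from RF-resident array items under a fixation state."""
    drive = 0.0
    statefac = truth.state_gain if on_target_fix else 1.0
    for it in trial.array_items:
        if it.location_index in rf_locs:
            attfac = truth.attention_gain if it.is_target else 1.0
            drive += truth.evoked_rate * _catfac(truth, it.category) * attfac * statefac
    return drive


def rate_segments(truth: UnitTruth, trial: TrialRecord,
                  geometry: ArrayGeometry) -> list[tuple[float, float, float]]:
    """Piecewise-constant firing rate (ms, ms, Hz) for one unit on one trial.

    Foveal units are gated by the fixated item after ``response_latency``;
    peripheral units by RF-resident array items; cue/delay epochs carry the
    category-maintenance and search-efficiency modulations.
    """
    b = truth.baseline_rate
    lat = truth.response_latency
    eff = math.exp(truth.efficiency_slope * (trial.n_fixations - 3.0))
    segs: list[tuple[float, float, float]] = []
    foveal = truth.rf_class in ("focal_foveal", "broad_foveal")
    peripheral = truth.rf_class in ("peripheral_localized", "peripheral_unlocalized")

    segs.append((0.0, trial.cue_on + lat, b))
    if foveal:
        # foveal units respond to any fixated stimulus; category tuning scales
        # the visually evoked rate
        cue_rate = (b + truth.evoked_rate) * _catfac(truth, trial.cue_category) * eff
        delay_rate = b * _maintfac(truth, trial.cue_category) * eff
    else:
        cue_rate = b * eff if truth.rf_class != "nonresponsive" else b
        delay_rate = cue_rate
    segs.append((trial.cue_on + lat, trial.cue_off + lat, cue_rate))
    segs.append((trial.cue_off + lat, trial.array_on + lat, delay_rate))

    t_end = trial.trial_end + lat
    if truth.rf_class == "nonresponsive":
        segs.append((trial.array_on + lat, t_end, b))
    elif foveal:
        cursor = trial.array_on + lat
        if truth.rf_class == "broad_foveal" and trial.fixations:
            first = trial.fixations[0].onset + lat
            segs.append((cursor, first, b + truth.evoked_rate))
            cursor = first
        for fx in trial.fixations:
            a = max(cursor, fx.onset + lat)
            if a > cursor:
                segs.append((cursor, a, b))
            rate = (
                (b + truth.evoked_rate)
                * _catfac(truth, fx.item_category)
                * (truth.attention_gain if fx.is_target else 1.0)
                * (truth.refixation_gain if fx.is_refixation else 1.0)
                * (truth.post_target_gain if fx.after_first_target_fix else 1.0)
                * _posfac(truth, fx.location_index, geometry)
            )
            end = min(fx.offset + lat, t_end)
            segs.append((a, end, rate))
            cursor = end
        if cursor < t_end:
            segs.append((cursor, t_end, b))
    elif peripheral:
        rf = rf_locations(truth, geometry) if truth.rf_class == "peripheral_localized" else set()
        cursor = trial.array_on + lat
        if truth.rf_class == "peripheral_unlocalized":
            segs.append((cursor, t_end, b + truth.evoked_rate))
        else:
            # pre-first-fixation period behaves like an on-distractor state
            bounds = [fx.onset + lat for fx in trial.fixations] + [t_end]
            drive0 = _peripheral_drive(truth, rf, trial, on_target_fix=False)
            segs.append((cursor, bounds[0], b + drive0))
            for i, fx in enumerate(trial.fixations):
                drive = _peripheral_drive(truth, rf, trial, on_target_fix=fx.is_target)
                segs.append((bounds[i], bounds[i + 1], b + drive))
    return [(a, bb, max(r, 0.0)) for a, bb, r in segs if bb > a]


def simulate_spikes(truth: UnitTruth, trial: TrialRecord, geometry: ArrayGeometry,
                    rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (ms) for one unit on one trial.

    The rate is piecewise constant, so the draw is exact: Poisson counts per
    segment, uniform times within each segment.
    """
    times = []
    for a, b, rate in rate_segments(truth, trial, geometry):
        if b > trial.trial_end:
            b = trial.trial_end
        if b <= a or rate <= 0:
            continue
        n = rng.poisson(rate * (b - a) / 1000.0)
        if n:
            times.append(rng.uniform(a, b, size=n))
    if not times:
        return np.zeros(0)
    return np.sort(np.concatenate(times))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude background noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_lfp(config: SimConfig, trial: TrialRecord, gt: GroundTruth,
                 rng: np.random.Generator) -> np.ndarray:
    """One trial of LFP at 1000 Hz: 1/f noise plus a theta sinusoid whose
    amplitude in the cue and delay epochs follows the planted
    amplitude-versus-fixation-count map (opposite signs per epoch)."""
    n = int(round(trial.trial_end))
    t = np.arange(n) / 1000.0  # s
    x = config.lfp_noise_sd * _pink_noise(n, rng)
    nf = trial.n_fixations
    amp_cue = max(0.0, gt.theta_base * (1.0 + gt.theta_slope_cue * (nf - gt.theta_ref_nfix)))
    amp_delay = max(0.0, gt.theta_base * (1.0 + gt.theta_slope_delay * (nf - gt.theta_ref_nfix)))
    amp = np.full(n, gt.theta_base)
    idx = np.arange(n)
    amp[(idx >= trial.cue_on) & (idx < trial.cue_off)] = amp_cue
    amp[(idx >= trial.cue_off) & (idx < trial.array_on)] = amp_delay
    phase = rng.uniform(0, 2 * np.pi)
    x += amp * np.sin(2 * np.pi * gt.theta_freq_hz * t + phase)
    return x


def _draw_unit_truth(config: SimConfig, area: str, geometry: ArrayGeometry,
                     rng: np.random.Generator) -> UnitTruth:
    classes = list(config.rf_fractions)
    probs = np.array([config.rf_fractions[c] for c in classes], dtype=float)
    probs /= probs.sum()
    rf_class = str(rng.choice(classes, p=probs))
    baseline = max(
        config.baseline_rate_min_hz,
        float(rng.normal(config.baseline_rate_mean_hz, config.baseline_rate_sd_hz)),
    )
    evoked = baseline * float(rng.uniform(*config.evoked_gain_range))
    foveal = rf_class in ("focal_foveal", "broad_foveal")
    peripheral = rf_class == "peripheral_localized"

    p_cat = config.p_category_tuned_foveal if foveal else (
        config.p_category_tuned_peripheral if peripheral else 0.0
    )
    cat_tuned = rng.random() < p_cat
    g_cat = config.category_gain if cat_tuned else 1.0
    pref = "face" if rng.random() < 0.5 else "house"
    att_tuned = (foveal or peripheral) and rng.random() < config.p_attention_tuned
    g_att = config.attention_gain if att_tuned else 1.0
    maintenance = g_cat ** config.maintenance_exponent if cat_tuned else 1.0

    u = rng.random()
    if rf_class == "nonresponsive":
        slope = 0.0  # a silent-epoch unit cannot express a presearch slope
    elif u < config.p_efficiency_positive:
        slope = config.efficiency_slope
    elif u < config.p_efficiency_positive + config.p_efficiency_negative:
        slope = -config.efficiency_slope
    else:
        slope = 0.0

    rf_center = rf_sigma = None
    if peripheral:
        loc = int(rng.integers(20))
        center = geometry.coordinates[loc] + rng.normal(0, 0.5, size=2)
        rf_center = (float(center[0]), float(center[1]))
        rf_sigma = config.rf_sigma_deg

    position_center = None
    position_amp = 0.0
    if foveal and config.position_gain_amp > 0:
        loc = int(rng.integers(20))
        center = geometry.coordinates[loc] + rng.normal(0, 0.5, size=2)
        position_center = (float(center[0]), float(center[1]))
        position_amp = config.position_gain_amp * float(rng.uniform(0.5, 1.5))

    attenuate = area in ("V4", "IT") and foveal
    truth = UnitTruth(
        baseline_rate=baseline,
        rf_class=rf_class,
        category_gain=g_cat,
        attention_gain=g_att,
        response_latency=config.response_latency_ms,
        rf_center=rf_center,
        rf_sigma=rf_sigma,
        efficiency_slope=slope,
        maintenance_gain=maintenance,
        evoked_rate=evoked,
        state_gain=config.peripheral_state_gain if peripheral else 1.0,
        category_pref=pref,
        refixation_gain=config.refixation_gain_v4_it if attenuate else 1.0,
        post_target_gain=config.post_target_gain_v4_it if attenuate else 1.0,
        position_center=position_center,
        position_sigma=config.position_sigma_deg,
        position_amp=position_amp,
    )
    if peripheral:
        truth.encoding_coefficients = encoding_vector_for_truth(truth)
    return truth


def simulate_session(config: SimConfig, session_id: str = "synthetic") -> Session:
    """Generate a full validated session under ``config``'s study conditions."""
    seed = config.seed
    geometry = make_array_geometry(seed)

    trials = [
        simulate_trial(config, trial_id, _rng(seed, _TRIAL_STREAM, trial_id))
        for trial_id in range(config.n_trials)
    ]

    gt = GroundTruth(
        theta_base=config.theta_base if config.lfp_enabled else 0.0,
        theta_slope_cue=config.theta_slope_cue,
        theta_slope_delay=config.theta_slope_delay,
        theta_ref_nfix=config.theta_ref_nfix,
        theta_freq_hz=config.theta_freq_hz,
    )

    units: list[UnitRecord] = []
    unit_idx = 0
    for area in ("V4", "IT", "OFC", "LPFC"):
        for _ in range(config.n_units.get(area, 0)):
            uid = f"{area}_{unit_idx:04d}"
            truth = _draw_unit_truth(config, area, geometry, _rng(seed, _TRUTH_STREAM, unit_idx))
            gt.units[uid] = truth
            spikes = {
                t.trial_id: simulate_spikes(
                    truth, t, geometry, _rng(seed, _SPIKE_STREAM, unit_idx, t.trial_id)
                )
                for t in trials
            }
            units.append(UnitRecord(unit_id=uid, area=area, spikes=spikes))
            unit_idx += 1

    lfp = None
    if config.lfp_enabled:
        lfp = []
        for ci, area in enumerate(("V4", "IT", "OFC", "LPFC")):
            if config.n_units.get(area, 0) == 0:
                continue
            samples = {
                t.trial_id: simulate_lfp(config, t, gt, _rng(seed, _LFP_STREAM, ci, t.trial_id))
                for t in trials
            }
            lfp.append(LfpTrace(channel_id=f"lfp_{area}", area=area, samples=samples))

    session = Session(
        session_id=session_id,
        units=units,
        trials=trials,
        array_geometry=geometry,
        lfp=lfp,
        ground_truth=gt,
    )
    validate_session(session)
    return session
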