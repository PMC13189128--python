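"""Receptive-field and selectivity classification of units.

Receptive fields are assigned from rank-sum comparisons of post-stimulus
versus baseline rates for the cue and for the search array: units driven
only by the cue have a focal foveal RF, by both a broad foveal RF, and
only by the array a peripheral RF.  Peripheral units are further split
into localized / unlocalized by whether their array response depends on
which locations are occupied.

Category selectivity combines a rank-sum test on face- versus house-cue
responses with a selectivity index

    SI = (R_face - R_house) / (R_face + R_house)

computed on baseline-subtracted responses, with sign clamps when the two
responses have opposite signs (SI = +1 if R_face > 0 > R_house, -1 for the
mirror case).  Face-selective units need p < alpha and SI > 0.13 (the
"130%" criterion); house-selective need p < alpha and SI < -0.13; a
significant test with |SI| <= 0.13 is "undefined".  Search-epoch activity
is never used for the SI, to avoid interactions with attention.

Attention selectivity compares responses 150-225 ms after fixation onset
on targets versus distractors with a two-tailed Wilcoxon signed-rank test
over per-exemplar paired means (the same stimuli as targets versus as
distractors), falling back to a rank-sum test when no exemplar pairing
exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .density import fixation_rates, windowed_rate
from .session import Session, UnitRecord

__all__ = [
    "SelectionConfig",
    "classify_rf",
    "compute_selectivity_index",
    "select_category_selective",
    "select_attention_selective",
    "overlap_test",
    "classify_units",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    response_window: tuple[float, float] = (50.0, 200.0)  # ms post onset
    baseline_window: tuple[float, float] = (-150.0, 0.0)  # ms re onset
    attention_window: tuple[float, float] = (150.0, 225.0)  # ms post fixation
    alpha: float = 0.05
    si_threshold: float = 0.13
    min_trials: int = 10
    min_fixations: int = 10

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _event_rates(unit: UnitRecord, session: Session, event: str,
                 window: tuple[float, float]) -> np.ndarray:
    """Per-trial rates in a window relative to a named trial event."""
    rates = []
    for t in session.trials:
        t0 = getattr(t, event)
        r = windowed_rate(unit, t, t0 + window[0], t0 + window[1])
        if np.isfinite(r):
            rates.append(r)
    return np.asarray(rates)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _location_effect_p(unit: UnitRecord, session: Session,
                       config: SelectionConfig) -> float:
    """Smallest Bonferroni-corrected p over per-location occupancy tests.

    For each array location, array-onset responses are split by whether an
    item occupied that location; a spatially localized unit responds more
    when its RF locations are filled.
    """
    win = config.response_window
    resp, occupancy = [], []
    for t in session.trials:
        r = windowed_rate(unit, t, t.array_on + win[0], t.array_on + win[1])
        if not np.isfinite(r):
            continue
        resp.append(r)
        occ = np.zeros(20, dtype=bool)
        for it in t.array_items:
            occ[it.location_index - 1] = True
        occupancy.append(occ)
    resp = np.asarray(resp)
    occupancy = np.asarray(occupancy)
    if len(resp) < config.min_trials:
        return 1.0
    best = 1.0
    for loc in range(20):
        a, b = resp[occupancy[:, loc]], resp[~occupancy[:, loc]]
        if len(a) < 3 or len(b) < 3:
            continue
        best = min(best, _ranksum_p(a, b))
    return min(1.0, best * 20)  # Bonferroni over the 20 locations


def classify_rf(unit: UnitRecord, session: Session,
                config: SelectionConfig = SelectionConfig()) -> str:
    """Assign an RF class from cue and array responsiveness.

    Returns one of ``focal_foveal``, ``broad_foveal``,
    ``peripheral_localized``, ``peripheral_unlocalized``, ``nonresponsive``,
    or ``unset`` when there are too few trials.
    """
    cue_base = _event_rates(unit, session, "cue_on", config.baseline_window)
    cue_resp = _event_rates(unit, session, "cue_on", config.response_window)
    arr_base = _event_rates(unit, session, "array_on", config.baseline_window)
    arr_resp = _event_rates(unit, session, "array_on", config.response_window)
    if min(len(cue_base), len(cue_resp), len(arr_base), len(arr_resp)) < config.min_trials:
        log.info("unit %s: too few trials for RF classification", unit.unit_id)
        return "unset"
    cue_p = _ranksum_p(cue_resp, cue_base)
    arr_p = _ranksum_p(arr_resp, arr_base)
    cue_sig = cue_p < config.alpha and cue_resp.mean() > cue_base.mean()
    arr_sig = arr_p < config.alpha and arr_resp.mean() > arr_base.mean()
    if cue_sig and arr_sig:
        return "broad_foveal"
    if cue_sig:
        return "focal_foveal"
    if arr_sig:
        loc_p = _location_effect_p(unit, session, config)
        return "peripheral_localized" if loc_p < config.alpha else "peripheral_unlocalized"
    return "nonresponsive"


def compute_selectivity_index(r_face: float, r_house: float) -> float:
    """SI with the opposite-sign clamp rules; NaN when undefined."""
    if r_face > 0 and r_house < 0:
        return 1.0
    if r_face < 0 and r_house > 0:
        return -1.0
    denom = r_face + r_house
    if denom == 0:
        return float("nan")
    return float(np.clip((r_face - r_house) / denom, -1.0, 1.0))


def _foveal_category_samples(unit: UnitRecord, session: Session,
                             config: SelectionConfig):
    """Cue-evoked baseline-subtracted samples per category (foveal units)."""
    win, base = config.response_window, config.baseline_window
    samples = {"face": [], "house": []}
    baselines = []
    for t in session.trials:
        r = windowed_rate(unit, t, t.cue_on + win[0], t.cue_on + win[1])
        b = windowed_rate(unit, t, t.cue_on + base[0], t.cue_on + base[1])
        if np.isfinite(r) and np.isfinite(b):
            samples[t.cue_category].append(r)
            baselines.append(b)
    return samples, float(np.mean(baselines)) if baselines else float("nan")


def _peripheral_category_samples(unit: UnitRecord, session: Session,
                                 config: SelectionConfig, rf_locs: set[int]):
    """Single-item-in-RF array responses per category (peripheral units).

    Mirrors the single-stimulus mapping condition: only trials where exactly
    one face or house item falls inside the unit's RF contribute.
    """
    win, base = config.response_window, config.baseline_window
    samples = {"face": [], "house": []}
    baselines = []
    for t in session.trials:
        in_rf = [it for it in t.array_items if it.location_index in rf_locs]
        if len(in_rf) != 1 or in_rf[0].category not in ("face", "house"):
            continue
        r = windowed_rate(unit, t, t.array_on + win[0], t.array_on + win[1])
        b = windowed_rate(unit, t, t.array_on + base[0], t.array_on + base[1])
        if np.isfinite(r) and np.isfinite(b):
            samples[in_rf[0].category].append(r)
            baselines.append(b)
    return samples, float(np.mean(baselines)) if baselines else float("nan")


def select_category_selective(unit: UnitRecord, session: Session,
                              config: SelectionConfig = SelectionConfig(),
                              rf_locs: set[int] | None = None) -> tuple[str, float]:
    """Classify category selectivity; returns (category_class, si).

    Foveal units are scored from cue responses, peripheral units from
    single-item-in-RF responses (``rf_locs`` gives the RF membership set);
    search-epoch activity is never used.
    """
    if unit.rf_class in ("focal_foveal", "broad_foveal"):
        samples, baseline = _foveal_category_samples(unit, session, config)
    elif unit.rf_class in ("peripheral_localized", "peripheral_unlocalized"):
        if not rf_locs:
            log.info("unit %s: no RF locations mapped; category class unset", unit.unit_id)
            return "unset", float("nan")
        samples, baseline = _peripheral_category_samples(unit, session, config, rf_locs)
    else:
        return "unset", float("nan")
    face, house = np.asarray(samples["face"]), np.asarray(samples["house"])
    if len(face) < config.min_trials or len(house) < config.min_trials:
        log.info("unit %s: too few category trials (%d face / %d house)",
                 unit.unit_id, len(face), len(house))
        return "unset", float("nan")
    p = _ranksum_p(face, house)
    si = compute_selectivity_index(float(face.mean() - baseline),
                                   float(house.mean() - baseline))
    if p >= config.alpha:
        return "nonselective", si
    if np.isnan(si) or abs(si) <= config.si_threshold:
        return "undefined", si
    return ("face_selective" if si > 0 else "house_selective"), si


def select_attention_selective(unit: UnitRecord, session: Session,
                               config: SelectionConfig = SelectionConfig(),
                               rf_locs: set[int] | None = None
                               ) -> tuple[str, float]:
    """Target-versus-distractor fixation test; returns (tri-state, effect).

    Responses are per-exemplar means of the same stimuli when fixated as
    targets versus as distractors, compared with a two-tailed signed-rank
    test; the attentional effect is the mean paired difference (Hz).  Falls
    back to an unpaired rank-sum across fixations when no exemplar appears
    in both roles.  Peripheral units use the same window but only fixations
    whose fixated location lies in the RF.
    """
    if unit.rf_class == "unset" or unit.rf_class == "nonresponsive":
        return "unset", float("nan")
    peripheral = unit.rf_class.startswith("peripheral")
    if peripheral and not rf_locs:
        return "unset", float("nan")
    by_stim_t: dict[tuple, list[float]] = {}
    by_stim_d: dict[tuple, list[float]] = {}
    tgt, dst = [], []
    for fx, r in fixation_rates(unit, session, config.attention_window):
        if peripheral and fx.location_index not in rf_locs:
            continue
        key = (fx.item_category, fx.item_exemplar)
        if fx.is_target:
            tgt.append(r)
            by_stim_t.setdefault(key, []).append(r)
        else:
            dst.append(r)
            by_stim_d.setdefault(key, []).append(r)
    if len(tgt) < config.min_fixations or len(dst) < config.min_fixations:
        log.info("unit %s: too few fixations for attention test", unit.unit_id)
        return "unset", float("nan")
    shared = sorted(set(by_stim_t) & set(by_stim_d))
    if len(shared) >= 6:
        a = np.array([np.mean(by_stim_t[k]) for k in shared])
        b = np.array([np.mean(by_stim_d[k]) for k in shared])
        effect = float(np.mean(a - b))
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.wilcoxon(a, b, alternative="two-sided",
                                     zero_method="wilcox").pvalue)
    else:  # no usable pairing: unpaired comparison across fixations
        effect = float(np.mean(tgt) - np.mean(dst))
        p = _ranksum_p(np.asarray(tgt), np.asarray(dst))
    return ("selective" if p < config.alpha else "nonselective"), effect


def overlap_test(group_a: np.ndarray, group_b: np.ndarray,
                 bonferroni: int = 1) -> tuple[float, float]:
    """Chi-squared test of whether membership in B is enriched within A.

    Compares the proportion of B-units within A (n_Both / n_A) against the
    base rate (n_B / n_All) over the same unit population.  Returns
    (chi2, p); ``bonferroni`` multiplies p for comparisons across areas.
    """
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must cover the same unit population")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("group A is empty; overlap undefined")
    # 2x2 contingency: rows = in/out of A, cols = in/out of B
    table = np.array([
        [np.sum(a & b), np.sum(a & ~b)],
        [np.sum(~a & b), np.sum(~a & ~b)],
    ], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(min(1.0, p * bonferroni))


def classify_units(session: Session,
                   config: SelectionConfig = SelectionConfig(),
                   rf_locs_by_unit: dict[str, set[int]] | None = None) -> None:
    """Run RF, category and attention classification in place on all units.

    ``rf_locs_by_unit`` supplies RF membership sets for peripheral units;
    for synthetic sessions the planted RF centers are used when available.
    """
    from .simulate import rf_locations

    rf_locs_by_unit = dict(rf_locs_by_unit or {})
    if session.ground_truth is not None:
        for uid, truth in session.ground_truth.units.items():
            if uid not in rf_locs_by_unit and truth.rf_center is not None:
                rf_locs_by_unit[uid] = rf_locations(truth, session.array_geometry)
    for u in session.units:
        u.rf_class = classify_rf(u, session, config)
        locs = rf_locs_by_unit.get(u.unit_id)
        u.category_class, si = select_category_selective(u, session, config, locs)
        u.si = si if u.category_class != "unset" else None
        u.attention_selective, u.attentional_effect = select_attention_selective(
            u, session, config, locs
        )
        if not np.isfinite(u.attentional_effect or np.nan):
            u.attentional_effect = None
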