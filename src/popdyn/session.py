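"""Core data model for free-gaze visual-search recording sessions.

A :class:`Session` bundles everything downstream analyses need: per-unit
spike times aligned to each trial, the trial event timeline, the fixation
sequence with item labels, the search-array geometry, optional LFP traces
and — for synthetic sessions — the planted ground truth.

Conventions
-----------
* All times are in milliseconds, trial-relative, with fixation-spot onset
  at 0.
* Spatial coordinates are degrees of visual angle, x rightward, y upward,
  fixation point at the origin.
* Labels that have not been assigned yet are the explicit string
  ``"unset"`` (or ``None`` for scalars), never a magic number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AREAS",
    "CATEGORIES",
    "RF_CLASSES",
    "CATEGORY_CLASSES",
    "ArrayGeometry",
    "FixationEvent",
    "TrialRecord",
    "UnitRecord",
    "LfpTrace",
    "UnitTruth",
    "GroundTruth",
    "Session",
    "SessionValidationError",
    "validate_session",
]

AREAS = ("V4", "IT", "OFC", "LPFC")
CATEGORIES = ("face", "house", "flower", "hand")
TARGET_CATEGORIES = ("face", "house")
RF_CLASSES = (
    "focal_foveal",
    "broad_foveal",
    "peripheral_localized",
    "peripheral_unlocalized",
    "nonresponsive",
    "unset",
)
CATEGORY_CLASSES = (
    "face_selective",
    "house_selective",
    "nonselective",
    "undefined",
    "unset",
)
ATTENTION_STATES = ("selective", "nonselective", "unset")

N_LOCATIONS = 20
N_ARRAY_ITEMS = 11
N_TARGETS = 2


class SessionValidationError(ValueError):
    """Raised when a session (or one of its parts) violates an invariant."""


@dataclass
class ArrayGeometry:
    """Screen coordinates (degrees of visual angle) of the 20 array locations.

    ``coordinates[i]`` is location index ``i + 1``.  Eighteen locations form
    nine left/right mirror pairs and two sit on the vertical midline; all
    eccentricities lie within 5°-11°.
    """

    coordinates: np.ndarray  # (20, 2) float

    def eccentricities(self) -> np.ndarray:
        return np.linalg.norm(self.coordinates, axis=1)

    def validate(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (N_LOCATIONS, 2):
            raise SessionValidationError(
                f"geometry: expected ({N_LOCATIONS}, 2) coordinates, got {coords.shape}"
            )
        ecc = np.linalg.norm(coords, axis=1)
        bad = np.where((ecc < 5.0 - 1e-9) | (ecc > 11.0 + 1e-9))[0]
        if bad.size:
            raise SessionValidationError(
                f"geometry: location(s) {bad + 1} outside the 5-11 deg eccentricity range"
            )
        on_midline = np.isclose(coords[:, 0], 0.0, atol=1e-9)
        if on_midline.sum() != 2:
            raise SessionValidationError(
                f"geometry: expected 2 vertical-midline locations, found {int(on_midline.sum())}"
            )
        side = coords[~on_midline]
        right = side[side[:, 0] > 0]
        left = side[side[:, 0] < 0]
        if len(right) != 9 or len(left) != 9:
            raise SessionValidationError(
                "geometry: expected 9 locations per hemifield plus 2 midline"
            )
        mirrored = np.stack([-right[:, 0], right[:, 1]], axis=1)
        for pt in mirrored:
            if not np.any(np.all(np.isclose(left, pt, atol=1e-6), axis=1)):
                raise SessionValidationError(
                    f"geometry: right-side location {(-pt[0], pt[1])} has no left mirror"
                )


@dataclass
class FixationEvent:
    """One fixation during search, with item labels and history flags."""

    onset: float
    offset: float
    location_index: int  # 1-20
    item_category: str
    item_exemplar: int  # 1-40 within category
    is_target: bool
    ordinal: int  # 1-based within trial
    is_refixation: bool
    after_first_target_fix: bool
    trial_id: int = -1


@dataclass
class ArrayItem:
    location_index: int
    category: str
    exemplar: int
    is_target: bool


@dataclass
class TrialRecord:
    """One search trial: timeline events, array composition and fixations."""

    trial_id: int
    cue_category: str  # "face" or "house"
    cue_exemplar: int
    fixation_spot_on: float
    cue_on: float
    cue_off: float  # == delay onset
    array_on: float
    trial_end: float
    array_items: list[ArrayItem]
    fixations: list[FixationEvent]
    correct: bool

    @property
    def delay_on(self) -> float:
        return self.cue_off

    @property
    def n_fixations(self) -> int:
        return len(self.fixations)

    def validate(self) -> None:
        t = self
        events = [t.fixation_spot_on, t.cue_on, t.cue_off, t.array_on, t.trial_end]
        names = ["fixation_spot_on", "cue_on", "cue_off", "array_on", "trial_end"]
        for (a, na), (b, nb) in zip(zip(events, names), zip(events[1:], names[1:])):
            if not b > a:
                raise SessionValidationError(
                    f"trial {t.trial_id}: event {nb} ({b}) not after {na} ({a})"
                )
        if t.cue_category not in TARGET_CATEGORIES:
            raise SessionValidationError(
                f"trial {t.trial_id}: cue_category {t.cue_category!r} invalid"
            )
        if len(t.array_items) != N_ARRAY_ITEMS:
            raise SessionValidationError(
                f"trial {t.trial_id}: expected {N_ARRAY_ITEMS} array items, got {len(t.array_items)}"
            )
        locs = [it.location_index for it in t.array_items]
        if len(set(locs)) != N_ARRAY_ITEMS:
            raise SessionValidationError(
                f"trial {t.trial_id}: array items occupy non-distinct locations"
            )
        targets = [it for it in t.array_items if it.is_target]
        if len(targets) != N_TARGETS:
            raise SessionValidationError(
                f"trial {t.trial_id}: expected {N_TARGETS} targets, got {len(targets)}"
            )
        for it in targets:
            if it.category != t.cue_category:
                raise SessionValidationError(
                    f"trial {t.trial_id}: target at location {it.location_index} "
                    f"is {it.category}, cue is {t.cue_category}"
                )
        if targets[0].exemplar == targets[1].exemplar:
            raise SessionValidationError(
                f"trial {t.trial_id}: the two targets share exemplar {targets[0].exemplar}"
            )
        seen: set[int] = set()
        prev_ord = 0
        for fx in t.fixations:
            if fx.offset <= fx.onset:
                raise SessionValidationError(
                    f"trial {t.trial_id}: fixation ordinal {fx.ordinal} has offset <= onset"
                )
            if fx.ordinal <= prev_ord:
                raise SessionValidationError(
                    f"trial {t.trial_id}: fixation ordinals not strictly increasing"
                )
            prev_ord = fx.ordinal
            if fx.is_refixation != (fx.location_index in seen):
                raise SessionValidationError(
                    f"trial {t.trial_id}: fixation ordinal {fx.ordinal} has an "
                    f"inconsistent is_refixation flag"
                )
            seen.add(fx.location_index)
        if len(t.fixations) < 1:
            raise SessionValidationError(f"trial {t.trial_id}: no fixations")


@dataclass
class UnitRecord:
    """One recorded unit: per-trial spike times plus derived labels.

    ``spikes`` maps trial_id -> sorted array of trial-relative spike times
    (ms).  Selectivity labels start out ``"unset"`` and are filled in by the
    selection stage; ``si`` is present iff category classification has run.
    """

    unit_id: str
    area: str
    spikes: dict[int, np.ndarray]
    rf_class: str = "unset"
    category_class: str = "unset"
    attention_selective: str = "unset"  # selective / nonselective / unset
    si: Optional[float] = None
    attentional_effect: Optional[float] = None

    def validate(self, trials_by_id: dict[int, TrialRecord]) -> None:
        if self.area not in AREAS:
            raise SessionValidationError(f"unit {self.unit_id}: unknown area {self.area!r}")
        if self.rf_class not in RF_CLASSES:
            raise SessionValidationError(
                f"unit {self.unit_id}: unknown rf_class {self.rf_class!r}"
            )
        if self.category_class not in CATEGORY_CLASSES:
            raise SessionValidationError(
                f"unit {self.unit_id}: unknown category_class {self.category_class!r}"
            )
        if (self.si is not None) != (self.category_class != "unset"):
            # si present iff category classification has been run; classification
            # may legitimately produce an undefined SI, recorded as NaN
            if self.si is None:
                raise SessionValidationError(
                    f"unit {self.unit_id}: category_class set but si missing"
                )
            raise SessionValidationError(
                f"unit {self.unit_id}: si set but category_class is unset"
            )
        if self.si is not None and np.isfinite(self.si):
            if not -1.0 <= self.si <= 1.0:
                raise SessionValidationError(
                    f"unit {self.unit_id}: si {self.si} outside [-1, 1]"
                )
        for trial_id, st in self.spikes.items():
            if trial_id not in trials_by_id:
                raise SessionValidationError(
                    f"unit {self.unit_id}: spikes reference unknown trial {trial_id}"
                )
            st = np.asarray(st)
            if st.size == 0:
                continue
            if np.any(st < 0):
                raise SessionValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: negative spike time"
                )
            if np.any(np.diff(st) < 0):
                raise SessionValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: spike times not sorted"
                )
            if st[-1] > trials_by_id[trial_id].trial_end + 1e-9:
                raise SessionValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: spike time "
                    f"{st[-1]} beyond trial end"
                )


@dataclass
class LfpTrace:
    """One LFP channel: per-trial sample series at 1000 Hz."""

    channel_id: str
    area: str
    samples: dict[int, np.ndarray]  # trial_id -> samples
    rate_hz: float = 1000.0

    def validate(self, trials_by_id: dict[int, TrialRecord]) -> None:
        if self.area not in AREAS:
            raise SessionValidationError(
                f"lfp {self.channel_id}: unknown area {self.area!r}"
            )
        for trial_id, x in self.samples.items():
            if trial_id not in trials_by_id:
                raise SessionValidationError(
                    f"lfp {self.channel_id}: samples reference unknown trial {trial_id}"
                )
            expected = int(round(trials_by_id[trial_id].trial_end * self.rate_hz / 1000.0))
            if abs(len(x) - expected) > 1:
                raise SessionValidationError(
                    f"lfp {self.channel_id}, trial {trial_id}: {len(x)} samples, "
                    f"expected ~{expected} at {self.rate_hz} Hz"
                )


@dataclass
class UnitTruth:
    """Planted generative parameters for one synthetic unit."""

    baseline_rate: float  # Hz
    rf_class: str
    category_gain: float = 1.0  # g_cat: face gain, house gets 1/g_cat
    attention_gain: float = 1.0  # g_att: gain when the driving item is a target
    response_latency: float = 50.0  # ms
    rf_center: Optional[tuple[float, float]] = None  # peripheral units
    rf_sigma: Optional[float] = None  # deg
    efficiency_slope: float = 0.0  # log-rate change per extra fixation (cue/delay)
    maintenance_gain: float = 1.0  # cue-category gain carried through the delay
    evoked_rate: float = 0.0  # Hz, stimulus-evoked additive drive (peripheral)
    state_gain: float = 1.0  # on-target vs on-distractor fixation gain (peripheral)
    category_pref: str = "face"  # which category gets category_gain
    refixation_gain: float = 1.0  # response scaling on refixated items (foveal)
    post_target_gain: float = 1.0  # scaling after the first target fixation
    # spatial gain field over the fixated location (foveal units): the
    # fixation response scales by 1 + amp * exp(-d^2 / (2 sigma^2)) where d
    # is the distance of the fixated location from the field center
    position_center: Optional[tuple[float, float]] = None
    position_sigma: float = 3.0  # deg
    position_amp: float = 0.0
    encoding_coefficients: Optional[np.ndarray] = None  # (12,) implied lasso betas

    def validate(self, label: str) -> None:
        for name in ("baseline_rate", "category_gain", "attention_gain", "evoked_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SessionValidationError(
                    f"ground truth {label}: {name} must be finite and non-negative"
                )
        if self.rf_class not in RF_CLASSES:
            raise SessionValidationError(
                f"ground truth {label}: unknown rf_class {self.rf_class!r}"
            )


@dataclass
class GroundTruth:
    """Session-level planted structure recorded by the synthetic generator."""

    units: dict[str, UnitTruth] = field(default_factory=dict)
    # theta amplitude model per epoch: amp(n_fix) = base * (1 + slope*(n_fix - ref))
    theta_base: float = 0.0
    theta_slope_cue: float = 0.0
    theta_slope_delay: float = 0.0
    theta_ref_nfix: float = 3.0
    theta_freq_hz: float = 8.0


@dataclass
class Session:
    """A complete recording session — the unit of input for every analysis."""

    session_id: str
    units: list[UnitRecord]
    trials: list[TrialRecord]
    array_geometry: ArrayGeometry
    lfp: Optional[list[LfpTrace]] = None
    ground_truth: Optional[GroundTruth] = None

    def trials_by_id(self) -> dict[int, TrialRecord]:
        return {t.trial_id: t for t in self.trials}

    def units_by_id(self) -> dict[str, UnitRecord]:
        return {u.unit_id: u for u in self.units}

    def correct_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.correct]


def validate_session(session: Session) -> None:
    """Check every structural invariant; raise ``SessionValidationError`` on the
    first violation, naming the offending field and trial/unit."""
    session.array_geometry.validate()
    tb = {}
    for t in session.trials:
        if t.trial_id in tb:
            raise SessionValidationError(f"duplicate trial_id {t.trial_id}")
        t.validate()
        for fx in t.fixations:
            if fx.trial_id not in (-1, t.trial_id):
                raise SessionValidationError(
                    f"trial {t.trial_id}: fixation carries foreign trial_id {fx.trial_id}"
                )
            if fx.location_index not in {it.location_index for it in t.array_items}:
                raise SessionValidationError(
                    f"trial {t.trial_id}: fixation on location {fx.location_index} "
                    f"not in the array"
                )
        tb[t.trial_id] = t
    seen_units: set[str] = set()
    for u in session.units:
        if u.unit_id in seen_units:
            raise SessionValidationError(f"duplicate unit_id {u.unit_id}")
        seen_units.add(u.unit_id)
        u.validate(tb)
    if session.lfp is not None:
        for ch in session.lfp:
            ch.validate(tb)
    if session.ground_truth is not None:
        for uid, truth in session.ground_truth.units.items():
            truth.validate(uid)
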