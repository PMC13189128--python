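"""Versioned HDF5 session container.

Layout (format version 1)
-------------------------
::

    /                     attrs: popdyn_format_version, session_id
    /geometry/coordinates (20, 2) float64
    /units/<unit_id>      attrs: area, rf_class, category_class,
                          attention_selective, si_present, si,
                          attentional_effect_present, attentional_effect
        spike_times       concatenated float64 spike times
        spike_trial_ids   trial_id of each block (int64)
        spike_offsets     block start offsets into spike_times (int64)
    /trials               columnar datasets over trials, plus ragged
        array_items/*     and fixations/* blocks with per-trial offsets
    /lfp/<channel_id>     attrs: area, rate_hz; ragged samples like spikes
    /ground_truth         optional, per-unit parameter table + session attrs

Ragged per-trial data are stored as one concatenated array plus offsets, the
usual HDF5 idiom for jagged lists.  Unknown top-level groups are ignored with
a warning so newer writers stay readable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np

from .session import (
    ArrayGeometry,
    ArrayItem,
    FixationEvent,
    GroundTruth,
    LfpTrace,
    Session,
    SessionValidationError,
    TrialRecord,
    UnitRecord,
    UnitTruth,
    validate_session,
)

__all__ = ["write_session", "read_session", "FORMAT_VERSION", "SessionFormatError"]

log = logging.getLogger(__name__)

FORMAT_VERSION = 1
_KNOWN_GROUPS = {"geometry", "units", "trials", "lfp", "ground_truth"}


class SessionFormatError(IOError):
    """Raised when a file is not a readable session container."""


def _write_ragged(grp: h5py.Group, name: str, ids: list[int], blocks: list[np.ndarray]) -> None:
    offsets = np.zeros(len(blocks) + 1, dtype=np.int64)
    for i, b in enumerate(blocks):
        offsets[i + 1] = offsets[i] + len(b)
    data = np.concatenate([np.asarray(b, dtype=np.float64) for b in blocks]) if blocks else np.zeros(0)
    grp.create_dataset(f"{name}", data=data)
    grp.create_dataset(f"{name[:-1] if name.endswith('s') else name}_trial_ids",
                       data=np.asarray(ids, dtype=np.int64))
    grp.create_dataset(f"{name[:-1] if name.endswith('s') else name}_offsets", data=offsets)


def _read_ragged(grp: h5py.Group, name: str) -> dict[int, np.ndarray]:
    stem = name[:-1] if name.endswith("s") else name
    data = grp[name][()]
    ids = grp[f"{stem}_trial_ids"][()]
    offsets = grp[f"{stem}_offsets"][()]
    return {int(tid): data[offsets[i]: offsets[i + 1]] for i, tid in enumerate(ids)}


def _set_opt(attrs: h5py.AttributeManager, name: str, value) -> None:
    attrs[f"{name}_present"] = value is not None
    attrs[name] = np.float64(value if value is not None else np.nan)


def _get_opt(attrs: h5py.AttributeManager, name: str):
    if not bool(attrs[f"{name}_present"]):
        return None
    return float(attrs[name])


def write_session(session: Session, path: str | Path) -> None:
    """Validate ``session`` and write it to ``path``.

    The file round-trips: :func:`read_session` reproduces the session
    bit-exactly for integers/text and at full float64 precision for reals.
    """
    validate_session(session)
    with h5py.File(path, "w") as f:
        f.attrs["popdyn_format_version"] = FORMAT_VERSION
        f.attrs["session_id"] = session.session_id

        f.create_group("geometry").create_dataset(
            "coordinates", data=np.asarray(session.array_geometry.coordinates, dtype=np.float64)
        )

        tg = f.create_group("trials")
        trials = session.trials
        for name, dtype, getter in [
            ("trial_id", np.int64, lambda t: t.trial_id),
            ("cue_exemplar", np.int64, lambda t: t.cue_exemplar),
            ("fixation_spot_on", np.float64, lambda t: t.fixation_spot_on),
            ("cue_on", np.float64, lambda t: t.cue_on),
            ("cue_off", np.float64, lambda t: t.cue_off),
            ("array_on", np.float64, lambda t: t.array_on),
            ("trial_end", np.float64, lambda t: t.trial_end),
            ("correct", np.int8, lambda t: int(t.correct)),
        ]:
            tg.create_dataset(name, data=np.asarray([getter(t) for t in trials], dtype=dtype))
        tg.create_dataset(
            "cue_category",
            data=np.asarray([t.cue_category for t in trials], dtype=h5py.string_dtype()),
        )

        ig = tg.create_group("array_items")
        item_counts = np.asarray([len(t.array_items) for t in trials], dtype=np.int64)
        ig.create_dataset("offsets", data=np.concatenate([[0], np.cumsum(item_counts)]))
        all_items = [it for t in trials for it in t.array_items]
        ig.create_dataset("location_index", data=np.asarray([it.location_index for it in all_items], dtype=np.int64))
        ig.create_dataset("category", data=np.asarray([it.category for it in all_items], dtype=h5py.string_dtype()))
        ig.create_dataset("exemplar", data=np.asarray([it.exemplar for it in all_items], dtype=np.int64))
        ig.create_dataset("is_target", data=np.asarray([it.is_target for it in all_items], dtype=np.int8))

        fg = tg.create_group("fixations")
        fix_counts = np.asarray([len(t.fixations) for t in trials], dtype=np.int64)
        fg.create_dataset("offsets", data=np.concatenate([[0], np.cumsum(fix_counts)]))
        all_fx = [fx for t in trials for fx in t.fixations]
        fg.create_dataset("onset", data=np.asarray([fx.onset for fx in all_fx], dtype=np.float64))
        fg.create_dataset("offset", data=np.asarray([fx.offset for fx in all_fx], dtype=np.float64))
        fg.create_dataset("location_index", data=np.asarray([fx.location_index for fx in all_fx], dtype=np.int64))
        fg.create_dataset("item_category", data=np.asarray([fx.item_category for fx in all_fx], dtype=h5py.string_dtype()))
        fg.create_dataset("item_exemplar", data=np.asarray([fx.item_exemplar for fx in all_fx], dtype=np.int64))
        fg.create_dataset("is_target", data=np.asarray([fx.is_target for fx in all_fx], dtype=np.int8))
        fg.create_dataset("ordinal", data=np.asarray([fx.ordinal for fx in all_fx], dtype=np.int64))
        fg.create_dataset("is_refixation", data=np.asarray([fx.is_refixation for fx in all_fx], dtype=np.int8))
        fg.create_dataset("after_first_target_fix", data=np.asarray([fx.after_first_target_fix for fx in all_fx], dtype=np.int8))

        ug = f.create_group("units")
        for u in session.units:
            g = ug.create_group(u.unit_id)
            g.attrs["area"] = u.area
            g.attrs["rf_class"] = u.rf_class
            g.attrs["category_class"] = u.category_class
            g.attrs["attention_selective"] = u.attention_selective
            _set_opt(g.attrs, "si", u.si)
            _set_opt(g.attrs, "attentional_effect", u.attentional_effect)
            ids = sorted(u.spikes)
            _write_ragged(g, "spike_times", ids, [np.asarray(u.spikes[i], dtype=np.float64) for i in ids])

        if session.lfp is not None:
            lg = f.create_group("lfp")
            for ch in session.lfp:
                g = lg.create_group(ch.channel_id)
                g.attrs["area"] = ch.area
                g.attrs["rate_hz"] = float(ch.rate_hz)
                ids = sorted(ch.samples)
                _write_ragged(g, "samples", ids, [np.asarray(ch.samples[i], dtype=np.float64) for i in ids])

        if session.ground_truth is not None:
            gt = session.ground_truth
            g = f.create_group("ground_truth")
            for attr in ("theta_base", "theta_slope_cue", "theta_slope_delay",
                         "theta_ref_nfix", "theta_freq_hz"):
                g.attrs[attr] = float(getattr(gt, attr))
            for uid, ut in gt.units.items():
                sub = g.create_group(uid)
                for attr in ("baseline_rate", "category_gain", "attention_gain",
                             "response_latency", "efficiency_slope", "maintenance_gain",
                             "evoked_rate", "state_gain", "refixation_gain",
                             "post_target_gain", "position_sigma", "position_amp"):
                    sub.attrs[attr] = float(getattr(ut, attr))
                sub.attrs["rf_class"] = ut.rf_class
                sub.attrs["category_pref"] = ut.category_pref
                sub.attrs["has_rf"] = ut.rf_center is not None
                if ut.rf_center is not None:
                    sub.attrs["rf_center_x"] = float(ut.rf_center[0])
                    sub.attrs["rf_center_y"] = float(ut.rf_center[1])
                    sub.attrs["rf_sigma"] = float(ut.rf_sigma)
                sub.attrs["has_position_field"] = ut.position_center is not None
                if ut.position_center is not None:
                    sub.attrs["position_center_x"] = float(ut.position_center[0])
                    sub.attrs["position_center_y"] = float(ut.position_center[1])
                if ut.encoding_coefficients is not None:
                    sub.create_dataset("encoding_coefficients",
                                       data=np.asarray(ut.encoding_coefficients, dtype=np.float64))


def read_session(path: str | Path) -> Session:
    """Read and validate a session container written by :func:`write_session`."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SessionFormatError(f"not a readable session container: {path} ({exc})") from exc
    with f:
        version = f.attrs.get("popdyn_format_version")
        if version is None:
            raise SessionFormatError(f"{path}: missing popdyn_format_version header")
        if int(version) != FORMAT_VERSION:
            raise SessionFormatError(
                f"{path}: format version {version} not supported (reader supports {FORMAT_VERSION})"
            )
        for key in f.keys():
            if key not in _KNOWN_GROUPS:
                log.warning("session %s: ignoring unknown block %r", path, key)

        geometry = ArrayGeometry(coordinates=f["geometry/coordinates"][()])

        tg = f["trials"]
        n = len(tg["trial_id"])
        item_off = tg["array_items/offsets"][()]
        fix_off = tg["fixations/offsets"][()]
        ig, fg = tg["array_items"], tg["fixations"]
        item_cols = {k: ig[k][()] for k in ("location_index", "category", "exemplar", "is_target")}
        fix_cols = {k: fg[k][()] for k in ("onset", "offset", "location_index", "item_category",
                                           "item_exemplar", "is_target", "ordinal",
                                           "is_refixation", "after_first_target_fix")}
        cue_cat = tg["cue_category"][()]
        trials = []
        for i in range(n):
            tid = int(tg["trial_id"][i])
            items = [
                ArrayItem(
                    location_index=int(item_cols["location_index"][j]),
                    category=item_cols["category"][j].decode(),
                    exemplar=int(item_cols["exemplar"][j]),
                    is_target=bool(item_cols["is_target"][j]),
                )
                for j in range(item_off[i], item_off[i + 1])
            ]
            fixations = [
                FixationEvent(
                    onset=float(fix_cols["onset"][j]),
                    offset=float(fix_cols["offset"][j]),
                    location_index=int(fix_cols["location_index"][j]),
                    item_category=fix_cols["item_category"][j].decode(),
                    item_exemplar=int(fix_cols["item_exemplar"][j]),
                    is_target=bool(fix_cols["is_target"][j]),
                    ordinal=int(fix_cols["ordinal"][j]),
                    is_refixation=bool(fix_cols["is_refixation"][j]),
                    after_first_target_fix=bool(fix_cols["after_first_target_fix"][j]),
                    trial_id=tid,
                )
                for j in range(fix_off[i], fix_off[i + 1])
            ]
            trials.append(TrialRecord(
                trial_id=tid,
                cue_category=cue_cat[i].decode(),
                cue_exemplar=int(tg["cue_exemplar"][i]),
                fixation_spot_on=float(tg["fixation_spot_on"][i]),
                cue_on=float(tg["cue_on"][i]),
                cue_off=float(tg["cue_off"][i]),
                array_on=float(tg["array_on"][i]),
                trial_end=float(tg["trial_end"][i]),
                array_items=items,
                fixations=fixations,
                correct=bool(tg["correct"][i]),
            ))

        units = []
        for uid in sorted(f["units"].keys()):
            g = f["units"][uid]
            units.append(UnitRecord(
                unit_id=uid,
                area=g.attrs["area"],
                spikes=_read_ragged(g, "spike_times"),
                rf_class=g.attrs["rf_class"],
                category_class=g.attrs["category_class"],
                attention_selective=g.attrs["attention_selective"],
                si=_get_opt(g.attrs, "si"),
                attentional_effect=_get_opt(g.attrs, "attentional_effect"),
            ))

        lfp = None
        if "lfp" in f:
            lfp = []
            for cid in sorted(f["lfp"].keys()):
                g = f["lfp"][cid]
                lfp.append(LfpTrace(
                    channel_id=cid,
                    area=g.attrs["area"],
                    samples=_read_ragged(g, "samples"),
                    rate_hz=float(g.attrs["rate_hz"]),
                ))

        ground_truth = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            ground_truth = GroundTruth(
                theta_base=float(g.attrs["theta_base"]),
                theta_slope_cue=float(g.attrs["theta_slope_cue"]),
                theta_slope_delay=float(g.attrs["theta_slope_delay"]),
                theta_ref_nfix=float(g.attrs["theta_ref_nfix"]),
                theta_freq_hz=float(g.attrs["theta_freq_hz"]),
            )
            for uid in sorted(g.keys()):
                sub = g[uid]
                has_rf = bool(sub.attrs["has_rf"])
                ground_truth.units[uid] = UnitTruth(
                    baseline_rate=float(sub.attrs["baseline_rate"]),
                    rf_class=sub.attrs["rf_class"],
                    category_gain=float(sub.attrs["category_gain"]),
                    attention_gain=float(sub.attrs["attention_gain"]),
                    response_latency=float(sub.attrs["response_latency"]),
                    rf_center=(float(sub.attrs["rf_center_x"]), float(sub.attrs["rf_center_y"])) if has_rf else None,
                    rf_sigma=float(sub.attrs["rf_sigma"]) if has_rf else None,
                    efficiency_slope=float(sub.attrs["efficiency_slope"]),
                    maintenance_gain=float(sub.attrs["maintenance_gain"]),
                    evoked_rate=float(sub.attrs["evoked_rate"]),
                    state_gain=float(sub.attrs["state_gain"]),
                    category_pref=sub.attrs["category_pref"],
                    refixation_gain=float(sub.attrs["refixation_gain"]),
                    post_target_gain=float(sub.attrs["post_target_gain"]),
                    position_center=(
                        (float(sub.attrs["position_center_x"]),
                         float(sub.attrs["position_center_y"]))
                        if bool(sub.attrs["has_position_field"]) else None
                    ),
                    position_sigma=float(sub.attrs["position_sigma"]),
                    position_amp=float(sub.attrs["position_amp"]),
                    encoding_coefficients=sub["encoding_coefficients"][()] if "encoding_coefficients" in sub else None,
                )

        session = Session(
            session_id=str(f.attrs["session_id"]),
            units=units,
            trials=trials,
            array_geometry=geometry,
            lfp=lfp,
            ground_truth=ground_truth,
        )
    validate_session(session)
    return session


def export_unit_labels(session: Session, path: str | Path) -> None:
    """Dump the per-unit label table as JSON for downstream tabulation."""
    import json

    rows = [
        {
            "unit_id": u.unit_id,
            "area": u.area,
            "rf_class": u.rf_class,
            "category_class": u.category_class,
            "si": u.si,
            "attention_selective": u.attention_selective,
            "attentional_effect": u.attentional_effect,
        }
        for u in session.units
    ]
    Path(path).write_text(json.dumps(rows, indent=1))
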