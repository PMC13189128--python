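"""Pipeline orchestration: simulate -> classify -> analyze, reproducibly.

``run_pipeline`` executes the analysis stages in dependency order on a
session (loaded from a container file or generated synthetically), collects
every stage's numeric outputs into a JSON-serialisable results bundle
together with the full configuration and package version, and — given the
same configuration and seed — reproduces every number bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .container import read_session, write_session
from .dpca import binned_samples, trajectory_separation_test
from .efficiency import (
    divergence_at_search_end,
    theta_power_correlation,
    unit_efficiency_correlation,
)
from .encoding import attention_subspace_summary, build_design, fit_lasso_splits
from .geometry import context_comparison, fixation_rate_table, hyperplane_angle
from .rsa import RSA_WINDOWS, neural_dm, physical_dm, rsa_correlation_test, spatial_state_space
from .selection import SelectionConfig, classify_units, overlap_test
from .session import Session
from .simulate import SimConfig, rf_locations, simulate_session
from .subspace import average_fr_axis, build_condition_points, classify_component

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = (
    "selection",
    "state_space",
    "efficiency",
    "orthogonal_subspace",
    "peripheral_encoding",
    "context",
    "spatial_rsa",
    "hyperplanes",
)

# analysis stages all require unit labels
_DEPENDENCIES = {s: ("selection",) for s in STAGES if s != "selection"}


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; serialized into the results bundle."""

    session_path: str | None = None  # load this container, or simulate if None
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    out_dir: str | None = None
    n_perm_trajectory: int = 200
    n_perm_rsa: int = 500
    n_shuffles_hyperplane: int = 100
    n_subsamples_hyperplane: int = 50
    n_lasso_splits: int = 50
    max_encoding_units: int = 20
    save_session: bool = False


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def _foveal_units(session: Session, areas=("V4", "IT", "OFC")) -> list[str]:
    return [u.unit_id for u in session.units
            if u.area in areas and u.rf_class in ("focal_foveal", "broad_foveal")]


def _peripheral_rf_map(session: Session) -> dict[str, set[int]]:
    out = {}
    if session.ground_truth is not None:
        for uid, truth in session.ground_truth.units.items():
            if truth.rf_center is not None:
                out[uid] = rf_locations(truth, session.array_geometry)
    return out


def _stage_selection(session: Session, config: PipelineConfig) -> dict:
    classify_units(session, SelectionConfig())
    counts: dict[str, dict[str, int]] = {}
    for u in session.units:
        area = counts.setdefault(u.area, {})
        for label in (u.rf_class, u.category_class, f"attention_{u.attention_selective}"):
            area[label] = area.get(label, 0) + 1
    cat_mask = np.array([u.category_class in ("face_selective", "house_selective")
                         for u in session.units])
    att_mask = np.array([u.attention_selective == "selective" for u in session.units])
    overlap = {}
    if cat_mask.any():
        chi2, p = overlap_test(cat_mask, att_mask)
        overlap = {"chi2": chi2, "p": p,
                   "prop_attention_in_category": float(att_mask[cat_mask].mean()),
                   "prop_attention_overall": float(att_mask.mean())}
    return {"label_counts": counts, "category_attention_overlap": overlap}


def _stage_state_space(session: Session, config: PipelineConfig) -> dict:
    rng = np.random.default_rng([config.seed, 11])
    unit_ids = _foveal_units(session)
    out = {}
    for epoch, scheme in (("cue", "category"), ("delay", "category"),
                          ("search", "category"), ("search", "attention")):
        samples, labels, times, kept = binned_samples(session, unit_ids, epoch, scheme)
        traj = trajectory_separation_test(
            samples, labels, times, kept,
            n_perm=config.n_perm_trajectory, rng=rng,
        )
        out[f"{epoch}_{scheme}"] = {
            "n_units": len(kept),
            "frac_significant_bins": float(np.mean(traj.significant)),
            "min_p": float(np.min(traj.pvalues)),
        }
    return out


def _stage_efficiency(session: Session, config: PipelineConfig) -> dict:
    results = []
    for u in session.units:
        try:
            results.append(unit_efficiency_correlation(session, u))
        except ValueError:
            continue
    classes = np.array([r.efficiency_class for r in results])
    sig_mask = classes != "none"
    att_mask = np.array([u.attention_selective == "selective" for u in session.units])
    overlap = {}
    if sig_mask.any() and len(att_mask) == len(sig_mask):
        chi2, p = overlap_test(sig_mask, att_mask)
        overlap = {"chi2": chi2, "p": p}
    div = divergence_at_search_end(session, [u.unit_id for u in session.units
                                             if u.area in ("V4", "IT")],
                                   seed=config.seed)
    theta = {}
    if session.lfp:
        for epoch in ("cue", "delay"):
            res = theta_power_correlation(session, epoch)
            theta[epoch] = {"r": res.r, "p": res.p}
    return {
        "n_units_tested": len(results),
        "frac_significant": float(sig_mask.mean()) if len(results) else None,
        "frac_positive": float(np.mean(classes == "positive")) if len(results) else None,
        "frac_negative": float(np.mean(classes == "negative")) if len(results) else None,
        "overlap_with_attention": overlap,
        "divergence": {
            "distance_onset": div.distance_onset, "distance_end": div.distance_end,
            "angle_onset": div.angle_onset, "angle_end": div.angle_end,
            "p_distance": div.p_distance, "p_angle": div.p_angle,
        },
        "theta": theta,
    }


def _stage_orthogonal_subspace(session: Session, config: PipelineConfig) -> dict:
    unit_ids = [u.unit_id for u in session.units
                if u.area in ("V4", "IT")
                and u.rf_class in ("focal_foveal", "broad_foveal")]
    points, meta, coeffs = build_condition_points(session, unit_ids)
    tau = average_fr_axis(coeffs)
    flat = points.reshape(-1, 3)
    out = {"n_conditions": len(meta), "n_time_bins": points.shape[1]}
    for scheme in ("attention", "category"):
        labels = np.repeat([m[scheme] for m in meta], points.shape[1])
        for component in ("parallel", "orthogonal"):
            res = classify_component(flat, labels, component, tau)
            out[f"{scheme}_{component}_accuracy"] = res.accuracy
    return out


def _stage_peripheral_encoding(session: Session, config: PipelineConfig) -> dict:
    rf_map = _peripheral_rf_map(session)
    fits = []
    for u in session.units:
        if u.rf_class != "peripheral_localized":
            continue
        if u.category_class in ("face_selective", "house_selective"):
            continue  # isolate attention effects from intrinsic category tuning
        locs = rf_map.get(u.unit_id)
        if not locs:
            continue
        try:
            X, y, _ = build_design(session, u, locs)
            fits.append(fit_lasso_splits(X, y, n_splits=config.n_lasso_splits,
                                         seed=config.seed, unit_id=u.unit_id))
        except ValueError as exc:
            log.info("encoding: %s", exc)
        if len(fits) >= config.max_encoding_units:
            break
    if len(fits) < 10:
        return {"n_units": len(fits), "note": "too few peripheral units for geometry"}
    summary = attention_subspace_summary(fits, seed=config.seed)
    return {
        "n_units": len(fits),
        "distance_target_state": summary.distance_target_state,
        "distance_distractor_state": summary.distance_distractor_state,
        "angle_target_state": summary.angle_target_state,
        "angle_distractor_state": summary.angle_distractor_state,
        "p_distance": summary.p_distance,
        "p_angle": summary.p_angle,
    }


def _stage_context(session: Session, config: PipelineConfig) -> dict:
    unit_ids = _foveal_units(session)
    out = {}
    for split in ("refixation", "target_found"):
        try:
            cc = context_comparison(session, unit_ids, split)
        except ValueError as exc:
            out[split] = {"note": str(exc)}
            continue
        out[split] = {
            "n_units": len(cc.unit_ids), "t": cc.t_stat, "p": cc.p_value,
            "distance_first": cc.distance_a, "distance_second": cc.distance_b,
            "angle_first": cc.angle_a, "angle_second": cc.angle_b,
        }
    return out


def _stage_spatial_rsa(session: Session, config: PipelineConfig) -> dict:
    rng = np.random.default_rng([config.seed, 17])
    unit_ids = [u.unit_id for u in session.units if u.area in ("V4", "IT")]
    out = {}
    layouts = spatial_state_space(session, unit_ids)
    for window, layout in zip(RSA_WINDOWS, layouts):
        ndm = neural_dm(session, unit_ids, window)
        pdm = physical_dm(session.array_geometry, ndm.labels)
        rho, p, _, sig = rsa_correlation_test(ndm, pdm, n_perm=config.n_perm_rsa,
                                              rng=rng)
        out[f"{int(window[0])}-{int(window[1])}ms"] = {
            "rho": rho, "p": p, "significant": sig,
            "alignment_residual": layout.residual,
        }
    return out


def _stage_hyperplanes(session: Session, config: PipelineConfig) -> dict:
    rng = np.random.default_rng([config.seed, 23])
    unit_ids = _foveal_units(session, areas=("V4", "IT", "OFC"))
    rates, fixations, _ = fixation_rate_table(session, unit_ids)
    cats = np.array([fx.item_category for fx in fixations])
    is_target = np.array([fx.is_target for fx in fixations])
    mask_a = np.isin(cats, ("face", "house")) & ~is_target  # category on distractors
    labels_a = cats
    mask_b = np.isin(cats, ("face", "house"))  # attention on face/house fixations
    labels_b = np.where(is_target, "target", "distractor")
    pair = hyperplane_angle(rates, labels_a, labels_b, mask_a, mask_b,
                            n_subsamples=config.n_subsamples_hyperplane,
                            n_shuffles=config.n_shuffles_hyperplane, rng=rng)
    return {
        "angle": pair.angle,
        "null_mean": float(pair.null_angles.mean()),
        "null_p": float((1 + np.sum(pair.null_angles <= pair.angle))
                        / (len(pair.null_angles) + 1)),
    }


_STAGE_FUNCS = {
    "selection": _stage_selection,
    "state_space": _stage_state_space,
    "efficiency": _stage_efficiency,
    "orthogonal_subspace": _stage_orthogonal_subspace,
    "peripheral_encoding": _stage_peripheral_encoding,
    "context": _stage_context,
    "spatial_rsa": _stage_spatial_rsa,
    "hyperplanes": _stage_hyperplanes,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the bundle.

    The bundle holds every stage report, the fully serialized configuration
    and the package version; with ``out_dir`` set it is also written to
    ``results.json`` there.  Reruns with the same config are byte-identical.
    """
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in _DEPENDENCIES.get(stage, ()):
            if dep not in config.stages:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    if config.session_path is not None:
        session = read_session(config.session_path)
    else:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        session = simulate_session(sim)

    bundle: dict = {
        "popdyn_version": __version__,
        "config": _to_jsonable(config),
        "session_id": session.session_id,
        "n_units": len(session.units),
        "n_trials": len(session.trials),
        "stages": {},
    }
    for stage in STAGES:  # canonical order regardless of request order
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        bundle["stages"][stage] = _to_jsonable(_STAGE_FUNCS[stage](session, config))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
        if config.save_session and config.session_path is None:
            write_session(session, out / "session.h5")
    return bundle
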