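"""Parallel (population-average-rate) axis and orthogonal-plane decomposition.

In the 3-D demixed-component space, a uniform change in population firing
rate moves the state along a single line whose direction is obtained by
summing each component's unit coefficients:

    tau_i = sum_n w_{i,n},   i = 1..3

Every state-space point is split into a signed scalar coordinate along
``tau`` (the parallel, rate-driven component) and a signed 2-D coordinate
in the plane through the origin orthogonal to ``tau`` (the rate-independent
component).  The plane's x axis is seeded by projecting the point
[10, 0, 0] into the plane, and y = tau x x / |tau x x|.  Linear
discriminant classification from each component separately shows whether
category/attention information rides on global rate or on the orthogonal
population pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .density import convolve_density, KernelParams, baseline_rate
from .dpca import PSTHMatrix, fit_dpca
from .session import Session

__all__ = [
    "SubspaceDecomposition",
    "ComponentClassification",
    "average_fr_axis",
    "decompose_point",
    "decompose_points",
    "build_condition_points",
    "classify_component",
]

# 30-ms bins from -60 to 210 ms around fixation onset
CONDITION_BIN_CENTERS = np.array([-45.0, -15.0, 15.0, 45.0, 75.0, 105.0, 135.0, 165.0, 195.0])
CONDITION_WINDOW = (-60.0, 210.0)
CONDITION_BIN_MS = 30.0
X_SEED = np.array([10.0, 0.0, 0.0])
_FALLBACK_SEED = np.array([0.0, 10.0, 0.0])


@dataclass
class SubspaceDecomposition:
    """Parallel/orthogonal coordinates of a set of state-space points."""

    tau: np.ndarray  # (3,) population-average-rate axis
    x_hat: np.ndarray  # in-plane basis
    y_hat: np.ndarray
    parallel: np.ndarray  # (..., ) signed scalar per point
    orthogonal: np.ndarray  # (..., 2) signed plane coordinates


@dataclass
class ComponentClassification:
    component: str  # "parallel" or "orthogonal"
    accuracy: float
    scheme: str
    in_sample_accuracy: float


def average_fr_axis(pc_coefficients: np.ndarray) -> np.ndarray:
    """Population-average-rate axis from the component coefficients.

    ``pc_coefficients`` is (N, 3): column i holds the unit coefficients
    w_{i,n} of component i.  A uniform rate increase across units projects
    along the returned vector.
    """
    w = np.asarray(pc_coefficients, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3:
        raise ValueError("pc_coefficients must be (N, 3)")
    tau = w.sum(axis=0)
    if np.allclose(tau, 0.0):
        raise ValueError("degenerate average-FR axis: coefficient columns sum to zero")
    return tau


def _plane_basis(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tau_hat = tau / np.linalg.norm(tau)
    seed = X_SEED
    in_plane = seed - (seed @ tau_hat) * tau_hat
    if np.linalg.norm(in_plane) < 1e-9 * np.linalg.norm(seed):
        import logging

        logging.getLogger(__name__).info(
            "average-FR axis collinear with the x seed; using fallback seed"
        )
        seed = _FALLBACK_SEED
        in_plane = seed - (seed @ tau_hat) * tau_hat
    x_hat = in_plane / np.linalg.norm(in_plane)
    y = np.cross(tau, x_hat)
    y_hat = y / np.linalg.norm(y)
    return x_hat, y_hat


def decompose_point(P: np.ndarray, tau: np.ndarray) -> tuple[float, np.ndarray]:
    """Split one 3-D point into (parallel coordinate, plane coordinates)."""
    dec = decompose_points(np.asarray(P, dtype=float)[None, :], tau)
    return float(dec.parallel[0]), dec.orthogonal[0]


def decompose_points(points: np.ndarray, tau: np.ndarray) -> SubspaceDecomposition:
    """Vectorised decomposition of (..., 3) points along ``tau``.

    Satisfies Pythagoras: parallel^2 + |orthogonal|^2 = |point|^2, and the
    reconstruction parallel*tau_hat + x*x_hat + y*y_hat recovers each point
    exactly.
    """
    tau = np.asarray(tau, dtype=float)
    if np.allclose(tau, 0.0):
        raise ValueError("tau is the zero vector")
    pts = np.asarray(points, dtype=float)
    tau_hat = tau / np.linalg.norm(tau)
    x_hat, y_hat = _plane_basis(tau)
    par = pts @ tau_hat  # signed length of the projection onto tau
    in_plane = pts - par[..., None] * tau_hat
    ortho = np.stack([in_plane @ x_hat, in_plane @ y_hat], axis=-1)
    return SubspaceDecomposition(tau=tau, x_hat=x_hat, y_hat=y_hat,
                                 parallel=par, orthogonal=ortho)


def _stimulus_sets(session: Session, n_per_category: int = 8) -> list[tuple[str, int]]:
    """Pick the 8 face + 8 house exemplars best covered in *both* attentional
    roles (greedy by the smaller of target / distractor fixation counts), so
    as many units as possible contribute to every condition."""
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for t in session.trials:
        if not t.correct:
            continue
        for fx in t.fixations:
            if fx.item_category in ("face", "house"):
                key = (fx.item_category, fx.item_exemplar)
                role = "target" if fx.is_target else "distractor"
                counts.setdefault(key, {"target": 0, "distractor": 0})[role] += 1
    chosen = []
    for cat in ("face", "house"):
        cands = sorted(
            (k for k in counts if k[0] == cat),
            key=lambda k: -min(counts[k]["target"], counts[k]["distractor"]),
        )
        usable = [k for k in cands if min(counts[k].values()) > 0]
        if len(usable) < n_per_category:
            raise ValueError(
                f"only {len(usable)} {cat} exemplars fixated in both roles; "
                f"need {n_per_category}"
            )
        chosen.extend(usable[:n_per_category])
    return chosen


def build_condition_points(session: Session, unit_ids: list[str],
                           n_components: int = 3,
                           kernel: KernelParams = KernelParams()):
    """32-condition (16 stimuli x 2 attentional states) state-space points.

    PSTHs span -60 to 210 ms around fixation onset in 30-ms bins (nine bins
    centered at -45 ... 195 ms).  Units missing any of the 16 stimuli are
    excluded.  Returns (points (C, T, 3), condition labels, decomposition
    inputs): points come from a dPCA fit across the 32 conditions.
    """
    stimuli = _stimulus_sets(session)
    conds = [(cat, ex, att) for (cat, ex) in stimuli for att in ("target", "distractor")]
    n_bins = len(CONDITION_BIN_CENTERS)

    units = [u for u in session.units if u.unit_id in set(unit_ids)]
    trials = [t for t in session.trials if t.correct]
    baselines = {u.unit_id: baseline_rate(u, trials) for u in units}

    per_unit: dict[str, dict[tuple, list[np.ndarray]]] = {}
    for u in units:
        if not (np.isfinite(baselines[u.unit_id]) and baselines[u.unit_id] > 0):
            continue
        acc: dict[tuple, list[np.ndarray]] = {c: [] for c in conds}
        for t in trials:
            st = u.spikes.get(t.trial_id)
            if st is None:
                continue
            for fx in t.fixations:
                key = (fx.item_category, fx.item_exemplar,
                       "target" if fx.is_target else "distractor")
                if key not in acc:
                    continue
                trace = convolve_density(st - fx.onset, kernel, window=CONDITION_WINDOW)
                r = trace.rate[: n_bins * 30].reshape(n_bins, 30).mean(axis=1)
                acc[key].append(r / baselines[u.unit_id])
        per_unit[u.unit_id] = acc

    kept = [uid for uid, acc in per_unit.items() if all(len(v) > 0 for v in acc.values())]
    if len(kept) < n_components:
        raise ValueError(
            f"only {len(kept)} units saw all 16 stimuli in both states; "
            f"need at least {n_components}"
        )
    values = np.zeros((len(conds) * n_bins, len(kept)))
    for j, uid in enumerate(kept):
        for ci, c in enumerate(conds):
            values[ci * n_bins:(ci + 1) * n_bins, j] = np.mean(per_unit[uid][c], axis=0)
    labels = [f"{cat}{ex}_{att}" for (cat, ex, att) in conds]
    psth = PSTHMatrix(values=values, n_time=n_bins, conditions=labels,
                      times=CONDITION_BIN_CENTERS.copy(), unit_ids=kept)
    fit = fit_dpca(psth, n_components=n_components)
    points = fit.project(psth, n_components)
    coeffs = fit.top_axes(n_components)  # (N, 3) unit coefficients
    meta = [{"category": cat, "exemplar": ex, "attention": att} for (cat, ex, att) in conds]
    return points, meta, coeffs


def classify_component(points: np.ndarray, labels: np.ndarray, component: str,
                       tau: np.ndarray) -> ComponentClassification:
    """LDA classification from one component of the decomposition.

    ``points`` is (n_samples, 3); the classifier sees the 1-D parallel
    coordinate or the 2-D orthogonal-plane coordinates.  Accuracy is
    stratified 5-fold cross-validated (folds capped by the smallest class);
    the in-sample accuracy is reported alongside.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    dec = decompose_points(points, tau)
    if component == "parallel":
        feats = dec.parallel[:, None]
    elif component == "orthogonal":
        feats = dec.orthogonal
    else:
        raise ValueError(f"unknown component {component!r}")
    clf = LinearDiscriminantAnalysis()
    clf.fit(feats, labels)
    in_sample = float(np.mean(clf.predict(feats) == labels))
    n_folds = int(min(5, counts.min()))
    if n_folds < 2:
        raise ValueError("need at least two samples per class for cross-validation")
    correct = 0
    cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
    for train, test in cv.split(feats, labels):
        m = LinearDiscriminantAnalysis().fit(feats[train], labels[train])
        correct += int(np.sum(m.predict(feats[test]) == labels[test]))
    acc = correct / len(labels)
    return ComponentClassification(component=component, accuracy=acc,
                                   scheme=f"stratified {n_folds}-fold",
                                   in_sample_accuracy=in_sample)
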