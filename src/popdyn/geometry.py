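"""Representational geometry: distances, angles, hyperplanes, alignment.

A condition's population response pattern is a "neuronal vector" — a point
in unit space built from time-averaged rates or regression coefficients.
Geometry between conditions is quantified by Euclidean distance and by the
cosine angle between vectors.  Two linear classifiers trained on the same
fixation-level rate matrix under different label schemes (face/house on
distractor fixations; target/distractor on face and house fixations)
define hyperplanes whose angle measures how independent the category and
attention codes are; a label-shuffle null calibrates the angle.  Condition
layouts living in different subspaces are compared after a rotation +
isotropic-scaling (orthogonal Procrustes) alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from .density import fixation_rates
from .session import Session

__all__ = [
    "NeuronalVector",
    "HyperplanePair",
    "representational_distance",
    "vector_angle",
    "mean_pairwise_distance",
    "mean_pairwise_angle",
    "fixation_rate_table",
    "hyperplane_angle",
    "rpca_align",
    "context_comparison",
]

log = logging.getLogger(__name__)


@dataclass
class NeuronalVector:
    condition: str
    values: np.ndarray


@dataclass
class HyperplanePair:
    w1: np.ndarray
    w2: np.ndarray
    b1: float
    b2: float
    angle: float  # degrees
    null_angles: np.ndarray


@dataclass
class AlignmentResult:
    aligned: list[np.ndarray]
    rotations: list[np.ndarray]
    scales: list[float]
    residuals: list[float]
    reflection_needed: list[bool]


def representational_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two neuronal vectors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between neuronal vectors in degrees (arccos of cosine similarity)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero vector")
    c = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def mean_pairwise_distance(vectors: np.ndarray) -> float:
    """Mean Euclidean distance over all condition pairs ((C, N) input)."""
    v = np.asarray(vectors, float)
    d, n = 0.0, 0
    for i in range(len(v)):
        for j in range(i + 1, len(v)):
            d += representational_distance(v[i], v[j])
            n += 1
    return d / max(n, 1)


def mean_pairwise_angle(vectors: np.ndarray) -> float:
    """Mean angle (degrees) over all condition pairs ((C, N) input)."""
    v = np.asarray(vectors, float)
    a, n = 0.0, 0
    for i in range(len(v)):
        for j in range(i + 1, len(v)):
            if np.linalg.norm(v[i]) == 0 or np.linalg.norm(v[j]) == 0:
                continue  # angle undefined for a zero vector; pair skipped
            a += vector_angle(v[i], v[j])
            n += 1
    return a / max(n, 1)


def fixation_rate_table(session: Session, unit_ids: list[str],
                        window: tuple[float, float] = (0.0, 255.0),
                        normalized: bool = True):
    """Fixation-level rate matrix (n_fixations, n_units) plus fixation labels.

    Rates are means over ``window`` after fixation onset; with
    ``normalized`` they are divided by each unit's pre-cue baseline.
    Returns (matrix, fixations, kept_unit_ids).
    """
    from .density import baseline_rate

    units = [u for u in session.units if u.unit_id in set(unit_ids)]
    trials = session.correct_trials()
    cols, kept, fix_ref = [], [], None
    for u in units:
        recs = fixation_rates(u, session, window)
        if fix_ref is None:
            fix_ref = [fx for fx, _ in recs]
        vals = np.array([r for _, r in recs])
        if normalized:
            b = baseline_rate(u, trials)
            if not (np.isfinite(b) and b > 0):
                log.info("unit %s: zero baseline; excluded from rate table", u.unit_id)
                continue
            vals = vals / b
        cols.append(vals)
        kept.append(u.unit_id)
    if not cols:
        raise ValueError("no units with usable baselines")
    return np.stack(cols, axis=1), fix_ref, kept


def _train_mean_classifier(X: np.ndarray, y: np.ndarray, n_subsamples: int,
                           rng: np.random.Generator, C: float = 1.0):
    """Average weight vector/intercept of linear classifiers trained on
    balanced subsamples (min-class count per class, without replacement)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    idx_by_class = [np.where(y == c)[0] for c in classes]
    n_min = min(len(ix) for ix in idx_by_class)
    if n_min < 2:
        counts = {str(c): len(ix) for c, ix in zip(classes, idx_by_class)}
        raise ValueError(f"class imbalance prevents balanced subsampling: {counts}")
    ws, bs = [], []
    for _ in range(n_subsamples):
        take = np.concatenate([rng.choice(ix, size=n_min, replace=False)
                               for ix in idx_by_class])
        clf = LinearSVC(C=C, dual=False, max_iter=10000, tol=1e-4)
        clf.fit(X[take], y[take])
        ws.append(clf.coef_[0])
        bs.append(clf.intercept_[0])
    return np.mean(ws, axis=0), float(np.mean(bs))


def hyperplane_angle(rate_matrix: np.ndarray, labels_a: np.ndarray,
                     labels_b: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                     n_subsamples: int = 100, n_shuffles: int = 1000,
                     rng: np.random.Generator | None = None,
                     null_subsamples: int = 1) -> HyperplanePair:
    """Angle between two classifier hyperplanes with a shuffle null.

    ``rate_matrix`` is fixation x unit; scheme A (e.g. category) uses rows
    ``mask_a`` with ``labels_a``, scheme B (attention) rows ``mask_b`` with
    ``labels_b``.  Each final classifier averages the weights/intercepts of
    ``n_subsamples`` balanced subsamples; the null retrains both classifiers
    on label-shuffled data ``n_shuffles`` times (with ``null_subsamples``
    subsample averages per shuffle to keep the null affordable).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    Xa, ya = rate_matrix[mask_a], np.asarray(labels_a)[mask_a]
    Xb, yb = rate_matrix[mask_b], np.asarray(labels_b)[mask_b]
    w1, b1 = _train_mean_classifier(Xa, ya, n_subsamples, rng)
    w2, b2 = _train_mean_classifier(Xb, yb, n_subsamples, rng)
    angle = vector_angle(w1, w2)
    null = np.zeros(n_shuffles)
    for k in range(n_shuffles):
        wa, _ = _train_mean_classifier(Xa, rng.permutation(ya), null_subsamples, rng)
        wb, _ = _train_mean_classifier(Xb, rng.permutation(yb), null_subsamples, rng)
        null[k] = vector_angle(wa, wb)
    return HyperplanePair(w1=w1, w2=w2, b1=b1, b2=b2, angle=angle, null_angles=null)


def _procrustes_rotation(source: np.ndarray, target: np.ndarray,
                         allow_reflection: bool) -> tuple[np.ndarray, bool]:
    """Best orthogonal map source -> target; returns (R, reflection_needed)."""
    M = target.T @ source
    u, _, vt = np.linalg.svd(M)
    R = u @ vt
    needs_reflection = bool(np.linalg.det(R) < 0)
    if needs_reflection and not allow_reflection:
        d = np.ones(len(u))
        d[-1] = -1.0
        R = u @ np.diag(d) @ vt  # best proper rotation
    return R, needs_reflection


def rpca_align(subspaces: list[np.ndarray], reference: np.ndarray,
               allow_reflection: bool = False) -> AlignmentResult:
    """Align condition layouts to a reference by rotation + isotropic scale.

    Each subspace is a (C, d) matrix of per-condition coordinates over the
    same condition set (d = 2 or 3).  Layouts are centered, rotated
    (orthogonal Procrustes, reflections disabled by default) and scaled to
    best match the centered reference; the residual is the RMS misfit
    normalised by the reference RMS.  For spatial-layout comparisons the
    reference is the physical x-y coordinates of the array locations.
    """
    ref = np.asarray(reference, float)
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 shared conditions to align")
    ref_c = ref - ref.mean(axis=0)
    ref_norm = np.linalg.norm(ref_c)
    aligned, rotations, scales, residuals, reflections = [], [], [], [], []
    for sub in subspaces:
        S = np.asarray(sub, float)
        if S.shape != ref.shape:
            raise ValueError(f"subspace shape {S.shape} != reference {ref.shape}")
        Sc = S - S.mean(axis=0)
        R, needs_ref = _procrustes_rotation(Sc, ref_c, allow_reflection)
        rotated = Sc @ R.T
        denom = float(np.sum(rotated * rotated))
        scale = float(np.sum(rotated * ref_c) / denom) if denom > 0 else 0.0
        fit = scale * rotated
        resid = float(np.linalg.norm(fit - ref_c) / ref_norm) if ref_norm > 0 else 0.0
        aligned.append(fit + ref.mean(axis=0))
        rotations.append(R)
        scales.append(scale)
        residuals.append(resid)
        reflections.append(needs_ref and not allow_reflection)
        if reflections[-1]:
            log.info("rpca_align: reflection would improve fit but is disabled")
    return AlignmentResult(aligned=aligned, rotations=rotations, scales=scales,
                           residuals=residuals, reflection_needed=reflections)


@dataclass
class ContextComparison:
    """Per-unit window means under two task-context splits plus geometry."""

    split: str
    conditions: list[str]
    means_a: np.ndarray  # (n_units, C) e.g. first fixations
    means_b: np.ndarray  # (n_units, C) e.g. refixations
    unit_ids: list[str]
    t_stat: float
    p_value: float
    distance_a: float
    distance_b: float
    angle_a: float
    angle_b: float


def _split_masks(fx, split: str) -> tuple[bool, bool]:
    if split == "refixation":
        return (not fx.is_refixation), fx.is_refixation
    if split == "target_found":
        if fx.is_target:
            return False, False  # distractor fixations only
        return (not fx.after_first_target_fix), fx.after_first_target_fix
    raise ValueError(f"unknown split {split!r}")


def context_comparison(session: Session, unit_ids: list[str], split: str,
                       window: tuple[float, float] = (150.0, 250.0),
                       min_fixations: int = 3) -> ContextComparison:
    """Compare responses and 4-category geometry between two task contexts.

    ``split`` is ``"refixation"`` (first-fixated vs refixated items) or
    ``"target_found"`` (distractor fixations before vs after the first
    fixation on the target).  Per unit, mean normalized rates in the
    150-250-ms window per fixated category per context; a two-tailed paired
    t-test across units compares contexts, and the 4-condition neuronal
    vectors give representational distance and angle per context.
    """
    from .density import baseline_rate

    cats = ["face", "house", "flower", "hand"]
    units = [u for u in session.units if u.unit_id in set(unit_ids)]
    trials = session.correct_trials()
    rows_a, rows_b, kept = [], [], []
    for u in units:
        b = baseline_rate(u, trials)
        if not (np.isfinite(b) and b > 0):
            continue
        acc_a: dict[str, list[float]] = {c: [] for c in cats}
        acc_b: dict[str, list[float]] = {c: [] for c in cats}
        for fx, r in fixation_rates(u, session, window):
            in_a, in_b = _split_masks(fx, split)
            if in_a:
                acc_a[fx.item_category].append(r / b)
            elif in_b:
                acc_b[fx.item_category].append(r / b)
        na = sum(len(v) for v in acc_a.values())
        nb = sum(len(v) for v in acc_b.values())
        if na < min_fixations or nb < min_fixations:
            log.info("unit %s lacks fixations in both %s contexts; excluded",
                     u.unit_id, split)
            continue
        rows_a.append([np.mean(acc_a[c]) if acc_a[c] else np.nan for c in cats])
        rows_b.append([np.mean(acc_b[c]) if acc_b[c] else np.nan for c in cats])
        kept.append(u.unit_id)
    A, B = np.asarray(rows_a), np.asarray(rows_b)
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} units usable for split {split!r}")
    overall_a = np.nanmean(A, axis=1)
    overall_b = np.nanmean(B, axis=1)
    t, p = stats.ttest_rel(overall_a, overall_b)
    # neuronal vectors: per condition across units (NaN cells -> unit mean)
    A_f = np.where(np.isnan(A), overall_a[:, None], A)
    B_f = np.where(np.isnan(B), overall_b[:, None], B)
    return ContextComparison(
        split=split, conditions=cats, means_a=A, means_b=B, unit_ids=kept,
        t_stat=float(t), p_value=float(p),
        distance_a=mean_pairwise_distance(A_f.T), distance_b=mean_pairwise_distance(B_f.T),
        angle_a=mean_pairwise_angle(A_f.T), angle_b=mean_pairwise_angle(B_f.T),
    )
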