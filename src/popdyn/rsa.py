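"""Spatial representational similarity analysis of the search array.

Does population activity preserve the physical layout of the 20 array
locations?  Fixation-aligned responses (0-200 ms in four 50-ms windows)
are grouped by fixated location into per-location population vectors; the
neural dissimilarity matrix is 1 - Pearson's r between location vectors,
the physical one the Euclidean distances between location coordinates.
Spearman correlation over the lower triangles measures correspondence,
with significance from a 1000-run location-label permutation null and
Bonferroni correction across the four windows.  Per-window 2-D PCA layouts
of the location vectors, aligned to the physical coordinates by rotation +
scaling, visualise the recovered geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .density import baseline_rate, windowed_rate
from .geometry import rpca_align
from .session import ArrayGeometry, Session

__all__ = [
    "DissimilarityMatrix",
    "physical_dm",
    "location_vectors",
    "neural_dm",
    "rsa_correlation_test",
    "spatial_state_space",
    "RSA_WINDOWS",
]

log = logging.getLogger(__name__)

RSA_WINDOWS = ((0.0, 50.0), (50.0, 100.0), (100.0, 150.0), (150.0, 200.0))


@dataclass
class DissimilarityMatrix:
    labels: list[int]  # location indices (1-20) or condition ids
    values: np.ndarray  # symmetric, zero diagonal
    metric: str  # "euclidean" or "one_minus_pearson"

    def lower_triangle(self) -> np.ndarray:
        n = len(self.labels)
        ii, jj = np.tril_indices(n, k=-1)
        return self.values[ii, jj]

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity matrix diagonal not zero")
        if self.metric == "one_minus_pearson" and (v.min() < -1e-9 or v.max() > 2 + 1e-9):
            raise ValueError("1 - r entries must lie in [0, 2]")


def physical_dm(geometry: ArrayGeometry,
                labels: list[int] | None = None) -> DissimilarityMatrix:
    """Pairwise Euclidean distances (deg) between array locations."""
    labels = labels or list(range(1, 21))
    coords = np.asarray(geometry.coordinates, float)[[l - 1 for l in labels]]
    diff = coords[:, None, :] - coords[None, :, :]
    return DissimilarityMatrix(labels=list(labels),
                               values=np.linalg.norm(diff, axis=2),
                               metric="euclidean")


def location_vectors(session: Session, unit_ids: list[str],
                     window: tuple[float, float], min_fixations: int = 5,
                     normalized: bool = True):
    """Per-location mean population vectors for one post-fixation window.

    Returns ``(vectors (L, N), kept location labels)``; locations with fewer
    than ``min_fixations`` fixations are dropped (and must be dropped from
    the physical matrix too).
    """
    units = [u for u in session.units if u.unit_id in set(unit_ids)]
    trials = session.correct_trials()
    baselines = {}
    kept_units = []
    for u in units:
        b = baseline_rate(u, trials) if normalized else 1.0
        if np.isfinite(b) and b > 0:
            baselines[u.unit_id] = b
            kept_units.append(u)
    acc = {loc: [] for loc in range(1, 21)}
    for t in trials:
        for fx in t.fixations:
            row = np.array([
                windowed_rate(u, t, fx.onset + window[0], fx.onset + window[1])
                / baselines[u.unit_id]
                for u in kept_units
            ])
            if np.all(np.isfinite(row)):
                acc[fx.location_index].append(row)
    kept_locs = [loc for loc in range(1, 21) if len(acc[loc]) >= min_fixations]
    dropped = [loc for loc in range(1, 21) if loc not in kept_locs]
    if dropped:
        log.info("locations %s dropped (<%d fixations)", dropped, min_fixations)
    vectors = np.stack([np.mean(acc[loc], axis=0) for loc in kept_locs])
    return vectors, kept_locs


def neural_dm(session: Session, unit_ids: list[str],
              window: tuple[float, float],
              min_fixations: int = 5) -> DissimilarityMatrix:
    """1 - Pearson correlation between per-location population vectors."""
    vectors, labels = location_vectors(session, unit_ids, window, min_fixations)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = stats.pearsonr(vectors[i], vectors[j]).statistic
            values[i, j] = values[j, i] = 1.0 - r
    dm = DissimilarityMatrix(labels=labels, values=values, metric="one_minus_pearson")
    dm.validate()
    return dm


def rsa_correlation_test(neural: DissimilarityMatrix, physical: DissimilarityMatrix,
                         n_perm: int = 1000, n_windows: int = 4,
                         rng: np.random.Generator | None = None):
    """Spearman correspondence between neural and physical dissimilarity.

    Returns ``(rho, p, significant)``: rho over the lower-triangle entries;
    p from ``n_perm`` random relabelings of the neural matrix's locations;
    significance requires the observed rho to exceed the null's 95th
    percentile after Bonferroni correction across ``n_windows`` windows.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if neural.labels != physical.labels:
        raise ValueError("neural and physical matrices must share label sets")
    a = neural.lower_triangle()
    b = physical.lower_triangle()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dissimilarity matrix: Spearman rho undefined")
    rho = float(stats.spearmanr(a, b).statistic)
    n = len(neural.labels)
    null = np.zeros(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        shuffled = neural.values[np.ix_(perm, perm)]
        ii, jj = np.tril_indices(n, k=-1)
        null[k] = stats.spearmanr(shuffled[ii, jj], b).statistic
    p = float((1 + np.sum(null >= rho)) / (n_perm + 1))
    significant = bool(p < 0.05 / n_windows)
    return rho, p, null, significant


@dataclass
class SpatialLayout:
    window: tuple[float, float]
    layout: np.ndarray  # (L, 2) aligned to physical coordinates
    residual: float
    labels: list[int]


def spatial_state_space(session: Session, unit_ids: list[str],
                        windows=RSA_WINDOWS,
                        min_fixations: int = 5) -> list[SpatialLayout]:
    """Per-window 2-D layouts of location vectors aligned to the array.

    Each window's location vectors are reduced to 2-D by PCA across
    locations, then rotated and scaled onto the physical x-y coordinates;
    the residual measures how well the neural layout preserves the array's
    geometry.
    """
    out = []
    for window in windows:
        vectors, labels = location_vectors(session, unit_ids, window, min_fixations)
        centered = vectors - vectors.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        layout2d = centered @ vt[:2].T
        ref = np.asarray(session.array_geometry.coordinates)[[l - 1 for l in labels]]
        align = rpca_align([layout2d], ref, allow_reflection=True)
        out.append(SpatialLayout(window=window, layout=align.aligned[0],
                                 residual=align.residuals[0], labels=labels))
    return out
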