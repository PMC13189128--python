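"""Demixed PCA state spaces and trajectory statistics.

Condition-averaged population activity is assembled into a ``(T*C) x N``
matrix (time bins within condition blocks, one column per unit) and
decomposed with demixed PCA (dPCA): the data are split into marginalization
averages — condition, time, and condition x time interaction — and each
marginalization gets its own encoder/decoder axis pairs from a reduced-rank
ridge regression of the marginalized data onto the full data.  Unlike plain
PCA, the leading condition axes then carry condition information unmixed
from condition-independent temporal dynamics.

Trajectories are the per-condition, per-bin projections onto the top three
demixed components.  Separation between condition trajectories is tested
against a shuffle null: condition labels are permuted across trials (or
fixations), the decomposition is refit per permutation, and per-bin
distances are compared to the null with Benjamini-Hochberg FDR control
across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .density import convolve_density, KernelParams, baseline_rate
from .session import Session

__all__ = [
    "PSTHMatrix",
    "DPCAResult",
    "Trajectory",
    "binned_samples",
    "build_psth_matrix",
    "fit_dpca",
    "demixing_from_reference",
    "trajectory_separation_test",
]

EPOCH_WINDOWS = {"cue": (0.0, 500.0), "delay": (0.0, 500.0), "search": (0.0, 225.0)}
MARGINALIZATIONS = ("condition", "time", "condition_time")


@dataclass
class PSTHMatrix:
    """Trial-averaged normalized rates, rows condition-major: row c*T + t."""

    values: np.ndarray  # (T*C, N)
    n_time: int
    conditions: list[str]
    times: np.ndarray  # bin centers (ms)
    unit_ids: list[str]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def tensor(self) -> np.ndarray:
        """View as (C, T, N)."""
        return self.values.reshape(self.n_conditions, self.n_time, -1)


@dataclass
class DPCAResult:
    """Per-marginalization encoder/decoder axes and explained variance."""

    encoders: dict[str, np.ndarray]  # marginalization -> (N, q)
    decoders: dict[str, np.ndarray]
    explained_variance: dict[str, np.ndarray]  # fraction of total variance
    mean: np.ndarray  # (N,) grand mean removed before fitting
    ridge: float

    def top_axes(self, n: int = 3) -> np.ndarray:
        """The ``n`` decoder axes with highest explained variance across all
        marginalizations, as an (N, n) matrix."""
        cands = []
        for m, dec in self.decoders.items():
            for j in range(dec.shape[1]):
                cands.append((self.explained_variance[m][j], m, j))
        cands.sort(key=lambda c: -c[0])
        axes = [self.decoders[m][:, j] for _, m, j in cands[:n]]
        if len(axes) < n:
            raise ValueError(f"only {len(axes)} components available, {n} requested")
        return np.stack(axes, axis=1)

    def project(self, psth: PSTHMatrix, n: int = 3) -> np.ndarray:
        """Project a PSTH matrix onto the top-``n`` axes -> (C, T, n)."""
        pts = (psth.values - self.mean) @ self.top_axes(n)
        return pts.reshape(psth.n_conditions, psth.n_time, n)


@dataclass
class Trajectory:
    """Per-condition state-space paths with a per-bin significance mask."""

    points: np.ndarray  # (C, T, n_components)
    times: np.ndarray
    conditions: list[str]
    significant: np.ndarray | None = None  # (T,) bool
    pvalues: np.ndarray | None = None


_COND_PRIORITY = {"face": 0, "house": 1, "target": 0, "distractor": 1}


def canonical_conditions(labels) -> list[str]:
    """Condition order with face before house and target before distractor,
    so axis-sign conventions are stable across runs."""
    def key(c: str):
        parts = c.split("_")
        return tuple(_COND_PRIORITY.get(p, 9) for p in parts) + (c,)
    return sorted(set(labels), key=key)


def _fixation_condition(fx, trial, scheme: str) -> str | None:
    if scheme == "category":
        return fx.item_category if fx.item_category in ("face", "house") else None
    if scheme == "attention":
        return "target" if fx.is_target else "distractor"
    if scheme == "both":
        if fx.item_category not in ("face", "house"):
            return None
        return f"{fx.item_category}_{'target' if fx.is_target else 'distractor'}"
    raise ValueError(f"unknown condition scheme {scheme!r}")


def binned_samples(session: Session, unit_ids: list[str], epoch: str,
                   conditions: str = "category", bin_ms: float = 10.0,
                   kernel: KernelParams = KernelParams(),
                   correct_only: bool = True):
    """Per-sample binned normalized rates for an epoch.

    A sample is a trial (cue/delay epochs, condition = cue category) or a
    fixation (search epoch, condition from the fixated item).  Returns
    ``(samples, labels, times, kept_unit_ids)`` with ``samples`` of shape
    (S, T, N).  Units whose baseline is zero are excluded (logged upstream).
    """
    if epoch not in EPOCH_WINDOWS:
        raise ValueError(f"unknown epoch {epoch!r}")
    w0, w1 = EPOCH_WINDOWS[epoch]
    n_bins = int(round((w1 - w0) / bin_ms))
    edges = w0 + np.arange(n_bins + 1) * bin_ms
    times = (edges[:-1] + edges[1:]) / 2.0

    units = [u for u in session.units if u.unit_id in set(unit_ids)]
    units.sort(key=lambda u: unit_ids.index(u.unit_id))
    trials = [t for t in session.trials if t.correct or not correct_only]

    baselines = {u.unit_id: baseline_rate(u, trials) for u in units}
    kept = [u for u in units if np.isfinite(baselines[u.unit_id]) and baselines[u.unit_id] > 0]

    events: list[tuple[object, float, str]] = []  # (trial, align_time, label)
    for t in trials:
        if epoch == "cue":
            events.append((t, t.cue_on, t.cue_category))
        elif epoch == "delay":
            events.append((t, t.delay_on, t.cue_category))
        else:
            for fx in t.fixations:
                lab = _fixation_condition(fx, t, conditions)
                if lab is not None:
                    events.append((t, fx.onset, lab))

    samples = np.zeros((len(events), n_bins, len(kept)))
    for j, u in enumerate(kept):
        b = baselines[u.unit_id]
        for i, (t, t0, _) in enumerate(events):
            st = u.spikes.get(t.trial_id)
            if st is None:
                continue
            trace = convolve_density(st - t0, kernel, window=(w0, w1))
            # average the 1-ms density within each bin
            r = trace.rate[: n_bins * int(bin_ms)].reshape(n_bins, int(bin_ms)).mean(axis=1)
            samples[i, :, j] = r / b
    labels = np.array([lab for _, _, lab in events])
    return samples, labels, times, [u.unit_id for u in kept]


def psth_from_samples(samples: np.ndarray, labels: np.ndarray, times: np.ndarray,
                      unit_ids: list[str],
                      condition_order: list[str] | None = None) -> PSTHMatrix:
    """Average per-sample rates into a condition-major PSTH matrix."""
    conds = condition_order or canonical_conditions(labels)
    blocks = []
    for c in conds:
        mask = labels == c
        if not mask.any():
            raise ValueError(f"condition {c!r} has no samples")
        blocks.append(samples[mask].mean(axis=0))
    values = np.concatenate(blocks, axis=0)
    return PSTHMatrix(values=values, n_time=len(times), conditions=list(conds),
                      times=times, unit_ids=list(unit_ids))


def build_psth_matrix(session: Session, unit_ids: list[str], epoch: str,
                      conditions: str = "category", bin_ms: float = 10.0,
                      correct_only: bool = True) -> PSTHMatrix:
    """Condition-averaged normalized-rate matrix for one epoch.

    Epochs: cue (0-500 ms from cue onset), delay (0-500 ms from delay
    onset), search (0-225 ms from fixation onset), in 10-ms bins by default.
    """
    samples, labels, times, kept = binned_samples(
        session, unit_ids, epoch, conditions, bin_ms, correct_only=correct_only
    )
    return psth_from_samples(samples, labels, times, kept)


def _marginalize(tensor: np.ndarray) -> dict[str, np.ndarray]:
    """Split a centered (C, T, N) tensor into its dPCA marginalizations."""
    x_time = tensor.mean(axis=0, keepdims=True)  # condition-independent dynamics
    x_cond = tensor.mean(axis=1, keepdims=True)  # time-independent condition means
    x_ct = tensor - x_time - x_cond
    C, T, _ = tensor.shape
    return {
        "condition": np.broadcast_to(x_cond, tensor.shape).copy(),
        "time": np.broadcast_to(x_time, tensor.shape).copy(),
        "condition_time": x_ct,
    }


def fit_dpca(psth: PSTHMatrix, marginalizations=MARGINALIZATIONS,
             n_components: int = 3, ridge: float | None = None) -> DPCAResult:
    """Least-squares dPCA with ridge regularization.

    For each marginalization the decoder/encoder pair minimizes
    ``||X_phi - X D F^T||_F^2 + ridge * ||D F^T||_F^2`` with rank
    ``n_components``; condition axes are ordered by explained variance.
    ``ridge=None`` picks a small default relative to the data scale.
    """
    X = psth.values
    n_units = X.shape[1]
    if n_units < n_components:
        raise ValueError(
            f"{n_units} units cannot support {n_components} components"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    tensor = Xc.reshape(psth.n_conditions, psth.n_time, n_units)
    margs = _marginalize(tensor)
    total_var = float(np.sum(Xc ** 2))
    if total_var == 0:
        raise ValueError("PSTH matrix has zero variance")
    if ridge is None:
        # a few percent of the mean per-unit variance: enough to keep the
        # decoders from whitening onto low-variance noise directions while
        # leaving genuine marginalization structure untouched
        ridge = 0.05 * total_var / n_units

    gram = Xc.T @ Xc + ridge * np.eye(n_units)
    gram_inv = np.linalg.inv(gram)
    encoders, decoders, evs = {}, {}, {}
    for m in marginalizations:
        Xm = margs[m].reshape(-1, n_units)
        m_full = gram_inv @ (Xc.T @ Xm)  # ridge regression X -> X_m
        u, s, vt = np.linalg.svd(Xc @ m_full, full_matrices=False)
        q = min(n_components, np.sum(s > 1e-12 * max(s[0], 1e-300)))
        q = max(q, 1)
        V = vt[:q].T  # (N, q)
        D = m_full @ V  # decoder axes
        F = V  # encoder axes
        # unit-norm decoders (encoder rescaled to keep D F^T unchanged) so
        # projections are scale-comparable across refits (shuffle nulls)
        norms = np.linalg.norm(D, axis=0)
        norms[norms == 0] = 1.0
        D = D / norms
        F = F * norms
        # fix signs so each encoder axis has positive loading on condition 1
        proj0 = (tensor[0].mean(axis=0) @ D)
        signs = np.where(proj0 >= 0, 1.0, -1.0)
        D, F = D * signs, F * signs
        ev = np.array([
            np.sum((Xc @ D[:, j:j + 1]) ** 2) * np.sum(F[:, j] ** 2) / total_var
            for j in range(q)
        ])
        encoders[m], decoders[m], evs[m] = F, D, ev
    return DPCAResult(encoders=encoders, decoders=decoders,
                      explained_variance=evs, mean=mean, ridge=ridge)


def demixing_from_reference(psth_reference: PSTHMatrix, psth_apply: PSTHMatrix,
                            n_components: int = 3,
                            ridge: float | None = None) -> Trajectory:
    """Fit demixing axes on a reference epoch and re-use them unchanged on
    another epoch's data (e.g. axes from target responses applied to the
    delay, or cue-fit axes applied to search)."""
    if psth_reference.unit_ids != psth_apply.unit_ids:
        raise ValueError("reference and applied PSTHs must share unit set and order")
    fit = fit_dpca(psth_reference, n_components=n_components, ridge=ridge)
    pts = fit.project(psth_apply, n_components)
    return Trajectory(points=pts, times=psth_apply.times,
                      conditions=psth_apply.conditions)


def _condition_distance(points: np.ndarray) -> np.ndarray:
    """Mean pairwise distance between condition points per time bin."""
    C = points.shape[0]
    d = np.zeros(points.shape[1])
    npairs = 0
    for i in range(C):
        for j in range(i + 1, C):
            d += np.linalg.norm(points[i] - points[j], axis=1)
            npairs += 1
    return d / max(npairs, 1)


def trajectory_separation_test(samples: np.ndarray, labels: np.ndarray,
                               times: np.ndarray, unit_ids: list[str],
                               n_perm: int = 1000, alpha: float = 0.05,
                               n_components: int = 3,
                               rng: np.random.Generator | None = None,
                               ridge: float | None = None) -> Trajectory:
    """Shuffle test of condition separation along the trajectory.

    Labels are permuted across samples (trials/fixations, never bins), the
    dPCA projection is refit per permutation, and the per-bin inter-condition
    distance is compared to its null; p-values are Benjamini-Hochberg
    corrected across bins at ``alpha``.
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(0)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; null distribution will be coarse")
    conds = canonical_conditions(labels)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")

    def traj_distance(lab):
        psth = psth_from_samples(samples, lab, times, unit_ids, condition_order=conds)
        fit = fit_dpca(psth, n_components=n_components, ridge=ridge)
        return _condition_distance(fit.project(psth, n_components)), psth, fit

    obs, psth, fit = traj_distance(labels)
    null = np.zeros((n_perm, len(times)))
    lab = np.array(labels)
    for k in range(n_perm):
        null[k] = traj_distance(rng.permutation(lab))[0]
    pvals = (1.0 + np.sum(null >= obs[None, :] - 1e-12, axis=0)) / (n_perm + 1.0)
    reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    return Trajectory(points=fit.project(psth, n_components), times=times,
                      conditions=conds, significant=reject, pvalues=pvals)
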