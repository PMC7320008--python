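"""Phase-based dynamic functional connectivity and brain-state extraction.

Each band-passed ROI trace f(t) is turned into an analytic signal
z(t) = f(t) + i H[f(t)] via the Hilbert transform; its instantaneous phase
phi(t) is the four-quadrant angle of z(t).  The first and last 100 samples
are discarded to absorb filter and Hilbert edge transients (a ten-minute,
1500-frame acquisition keeps 1300 frames = 520 s).  The frame-wise
phase-locking matrix

    M_PL(i, j, t) = cos(phi_i(t) - phi_j(t))

is symmetric with unit diagonal.  Frames from all animals of both groups
are pooled and clustered with k-means under the cityblock (L1) distance —
i.e. k-medians, since the component-wise median is the L1-optimal centroid
— restarted from many random initializations, keeping the replicate with
the smallest sum of within-cluster distances.  Cluster centroids are the
"brain states"; per-animal occurrence rates (fraction of frames assigned
to each state) feed the same normality-gated group statistics as the
static analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import hilbert
from scipy.spatial.distance import cdist

from .preprocess import RoiTimeSeriesSet
from .static_fc import bh_correct, group_compare

__all__ = [
    "PhaseSeries",
    "PhaseLockingTensor",
    "BrainStateModel",
    "hilbert_phase",
    "phase_locking",
    "pool_features",
    "vectorize_matrix",
    "unvectorize_matrix",
    "kmeans_states",
    "match_states",
    "occurrence_group_stats",
    "EDGE_TRIM",
]

#: samples dropped from each end of the phase series
EDGE_TRIM = 100


@dataclass
class PhaseSeries:
    """Instantaneous phases per ROI over the retained frames."""

    phases: np.ndarray
    roi_labels: list[str]
    frame_period: float
    retained: slice
    animal_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.phases.ndim != 2:
            raise ValueError("phases must be 2D [n_roi, n_t_retained]")
        if (self.phases <= -np.pi).any() or (self.phases > np.pi).any():
            raise ValueError("phases must lie in (-pi, pi]")


@dataclass
class PhaseLockingTensor:
    """Cosines of pairwise phase differences, ``mpl[n_roi, n_roi, n_t]``."""

    mpl: np.ndarray
    roi_labels: list[str]
    animal_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        n = len(self.roi_labels)
        if self.mpl.ndim != 3 or self.mpl.shape[0] != n or self.mpl.shape[1] != n:
            raise ValueError("tensor must be [n_roi, n_roi, n_t]")

    @property
    def n_frames(self) -> int:
        return self.mpl.shape[2]


@dataclass
class BrainStateModel:
    """Result of the pooled k-medians brain-state decomposition."""

    k: int
    centroids: np.ndarray  # [k, n_roi, n_roi], symmetric, unit diagonal
    roi_labels: list[str]
    labels: pd.DataFrame  # columns: animal_id, frame, state
    occurrence: pd.DataFrame  # animals x k occurrence rates
    objective: float
    replicate_seeds: list[int]
    replicate_objectives: list[float]

    def centroid_features(self) -> np.ndarray:
        """Strict-upper-triangle vectorization of each centroid."""
        iu = np.triu_indices(len(self.roi_labels), k=1)
        return np.stack([c[iu] for c in self.centroids])


def hilbert_phase(series: RoiTimeSeriesSet, trim: int = EDGE_TRIM) -> PhaseSeries:
    """Analytic-signal phase per ROI, trimmed of edge transients.

    The phase is the four-quadrant arctangent of the imaginary and real
    parts of the analytic signal, giving the full (-pi, pi] range needed
    for cosine phase differences.
    """
    if not series.preprocessed:
        raise ValueError("hilbert_phase expects a band-passed, normalized series")
    if series.n_t <= 2 * trim:
        raise ValueError(
            f"need more than {2 * trim} samples to trim {trim} from each end"
        )
    analytic = hilbert(series.signals, axis=1)
    phases = np.angle(analytic)[:, trim : series.n_t - trim]
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] range
    phases = np.where(phases == -np.pi, np.pi, phases)
    return PhaseSeries(
        phases=phases,
        roi_labels=list(series.roi_labels),
        frame_period=series.frame_period,
        retained=slice(trim, series.n_t - trim),
        animal_id=series.animal_id,
        group=series.group,
    )


def phase_locking(phases: PhaseSeries) -> PhaseLockingTensor:
    """Frame-wise cosine of pairwise phase differences."""
    p = phases.phases
    diff = p[:, None, :] - p[None, :, :]
    mpl = np.cos(diff)
    # enforce exact symmetry / unit diagonal against rounding
    mpl = (mpl + mpl.transpose(1, 0, 2)) / 2.0
    idx = np.arange(p.shape[0])
    mpl[idx, idx, :] = 1.0
    return PhaseLockingTensor(
        mpl=mpl,
        roi_labels=list(phases.roi_labels),
        animal_id=phases.animal_id,
        group=phases.group,
    )


def vectorize_matrix(m: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major."""
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def unvectorize_matrix(v: np.ndarray, n_roi: int) -> np.ndarray:
    """Rebuild a symmetric unit-diagonal matrix from its upper triangle."""
    m = np.eye(n_roi)
    iu = np.triu_indices(n_roi, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


def pool_features(
    tensors: Sequence[PhaseLockingTensor],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack all animals' frames into one feature matrix.

    One row per (animal, retained frame); features are the strict upper
    triangle of the phase-locking matrix (the diagonal is constantly 1 and
    carries no information).  Returns the feature matrix and a frame index
    with columns ``animal_id``, ``group``, ``frame``.
    """
    if not tensors:
        raise ValueError("no tensors to pool")
    labels = tensors[0].roi_labels
    for t in tensors:
        if t.roi_labels != labels:
            raise ValueError("all animals must share the same ROI set")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    blocks = []
    idx_rows = []
    for t in tensors:
        blocks.append(t.mpl[iu].T)  # [n_t, n_pairs]
        idx_rows.append(
            pd.DataFrame(
                {
                    "animal_id": t.animal_id,
                    "group": t.group,
                    "frame": np.arange(t.n_frames),
                }
            )
        )
    features = np.vstack(blocks)
    index = pd.concat(idx_rows, ignore_index=True)
    return features, index


def _kmedians_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One Lloyd-style k-medians run from a random initialization.

    Assignment minimizes cityblock distance; the centroid update is the
    component-wise median (the L1 minimizer).  Empty clusters are repaired
    by reseeding on the point farthest from its current centroid.
    """
    n = x.shape[0]
    # k distinct rows as initial centroids
    for _ in range(100):
        pick = rng.choice(n, size=k, replace=False)
        centroids = x[pick].copy()
        if np.unique(centroids, axis=0).shape[0] == k:
            break
    else:
        raise ValueError(f"could not find {k} distinct rows to initialize")

    labels = np.full(n, -1, dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        d = cdist(x, centroids, metric="cityblock")
        new_labels = d.argmin(axis=1)
        point_d = d[np.arange(n), new_labels]
        for j in range(k):
            if not (new_labels == j).any():
                far = int(point_d.argmax())
                centroids[j] = x[far]
                new_labels[far] = j
                point_d[far] = 0.0
        history.append(float(point_d.sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centroids[j] = np.median(x[labels == j], axis=0)
    objective = float(np.abs(x - centroids[labels]).sum())
    return labels, centroids, objective, history


def kmeans_states(
    features: np.ndarray,
    index: pd.DataFrame,
    roi_labels: Sequence[str],
    k: int,
    n_replicates: int = 200,
    rng: np.random.Generator | int | None = None,
    max_iter: int = 300,
) -> BrainStateModel:
    """Pooled k-means (cityblock distance) brain-state decomposition.

    Runs ``n_replicates`` random initializations and keeps the replicate
    minimizing the total within-cluster L1 distance.  States are relabeled
    in decreasing order of overall occurrence so that state 0 is always the
    most frequent pattern.
    """
    x = np.asarray(features, dtype=float)
    if k < 1:
        raise ValueError("k must be at least 1")
    if x.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("fewer distinct rows than clusters")
    if len(index) != x.shape[0]:
        raise ValueError("frame index must align with the feature rows")

    rng = np.random.default_rng(rng)
    replicate_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_replicates)]

    best = None
    objectives: list[float] = []
    for seed in replicate_seeds:
        run = _kmedians_once(x, k, np.random.default_rng(seed), max_iter)
        objectives.append(run[2])
        if best is None or run[2] < best[2]:
            best = run
    labels, centroids, objective, _ = best

    # canonical ordering: most occupied state first
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centroids = centroids[order]

    n_roi = len(roi_labels)
    cent_mats = np.stack([unvectorize_matrix(c, n_roi) for c in centroids])

    label_table = index.copy()
    label_table["state"] = labels

    occ = (
        label_table.groupby("animal_id", sort=True)["state"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(k), fill_value=0.0)
    )
    occ.columns = [f"state_{j}" for j in range(k)]

    return BrainStateModel(
        k=k,
        centroids=cent_mats,
        roi_labels=list(roi_labels),
        labels=label_table,
        occurrence=occ,
        objective=objective,
        replicate_seeds=replicate_seeds,
        replicate_objectives=objectives,
    )


def match_states(
    model_a: BrainStateModel, model_b: BrainStateModel
) -> pd.DataFrame:
    """Optimal one-to-one state correspondence between two models.

    Minimizes the summed L1 distance between centroid vectors (rectangular
    assignment allowed, so models with different k leave surplus states
    unmatched).  Returns a table ``state_a, state_b, l1_distance``.
    """
    if model_a.roi_labels != model_b.roi_labels:
        raise ValueError("models must share the same ROI set")
    da = model_a.centroid_features()
    db = model_b.centroid_features()
    cost = cdist(da, db, metric="cityblock")
    rows, cols = linear_sum_assignment(cost)
    return pd.DataFrame(
        {
            "state_a": rows,
            "state_b": cols,
            "l1_distance": cost[rows, cols],
        }
    )


def occurrence_group_stats(
    model: BrainStateModel | pd.DataFrame,
    groups: pd.Series | dict,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Group comparison of per-animal state occurrence rates.

    Per state: normality-gated Welch / Mann-Whitney on the occurrence
    rates, then Benjamini-Hochberg correction across the k states.
    ``model`` may be a fitted :class:`BrainStateModel` or a plain
    animals-by-states occurrence table.
    """
    groups = pd.Series(groups)
    occ = model if isinstance(model, pd.DataFrame) else model.occurrence
    missing = occ.index.difference(groups.index)
    if len(missing):
        raise ValueError(f"animals without a group label: {list(missing)}")
    g = groups.loc[occ.index]
    control = occ[g == "control"]
    arthritic = occ[g == "arthritic"]
    if len(control) < 3 or len(arthritic) < 3:
        raise ValueError("each group needs at least 3 animals")

    rows = []
    for col in occ.columns:
        test_used, p_raw = group_compare(control[col], arthritic[col])
        rows.append(
            {
                "state": col,
                "test_used": test_used,
                "p_raw": p_raw,
                "mean_control": float(control[col].mean()),
                "mean_arthritic": float(arthritic[col].mean()),
                "median_control": float(control[col].median()),
                "median_arthritic": float(arthritic[col].median()),
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = bh_correct(table["p_raw"].to_numpy(), fdr=fdr)
    return table
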