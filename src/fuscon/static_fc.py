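"""Static (time-averaged) functional connectivity and its group statistics.

Seed-based correlation maps, ROI-ROI correlation matrices, the Fisher
z-transform, the normality-gated Welch / Mann-Whitney group comparison and
Benjamini-Hochberg false-discovery-rate control used to build the
"significance matrix" of ROI pairs whose connectivity differs between
groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import DopplerMovie, RoiTimeSeriesSet

__all__ = [
    "CorrelationMap",
    "CorrelationMatrix",
    "seed_map",
    "roi_pair_r",
    "correlation_matrix",
    "fisher_z",
    "group_compare",
    "bh_correct",
    "significance_matrix",
    "FISHER_CLIP",
]

#: correlations are clipped to +/- (1 - FISHER_CLIP) before atanh when a
#: pipeline stage transforms measured r values in bulk
FISHER_CLIP = 1e-7


@dataclass
class CorrelationMap:
    """Pixelwise Pearson r against a seed ROI's mean trace.

    ``constant_pixels`` flags pixels whose trace was constant; their r is
    reported as 0 so maps stay renderable, but they must be excluded from
    any statistics.
    """

    values: np.ndarray
    seed_label: str
    constant_pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.constant_pixels.shape:
            raise ValueError("QC mask must match map shape")
        inside = self.values[~self.constant_pixels]
        if inside.size and (np.abs(inside) > 1.0 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal ROI-ROI Pearson correlation matrix."""

    r: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.roi_labels)
        if self.r.shape != (n, n):
            raise ValueError("matrix shape must match ROI labels")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if (np.abs(self.r) > 1.0 + 1e-12).any():
            raise ValueError("correlations must lie in [-1, 1]")

    def pair(self, roi_a: str, roi_b: str) -> float:
        ia = self.roi_labels.index(roi_a)
        ib = self.roi_labels.index(roi_b)
        return float(self.r[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.roi_labels, columns=self.roi_labels)


def seed_map(movie: DopplerMovie, seed_mask: np.ndarray, seed_label: str = "seed") -> CorrelationMap:
    """Correlate every pixel's trace with the mean trace of a seed ROI.

    The movie is expected to be band-pass filtered already; the map is pure
    Pearson correlation, so per-pixel scaling is irrelevant.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != movie.brain_mask.shape:
        raise ValueError("seed mask has the wrong shape")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")

    seed = movie.data[seed_mask].mean(axis=0)
    seed_c = seed - seed.mean()
    seed_norm = np.sqrt(np.sum(seed_c**2))
    if seed_norm == 0.0:
        raise ValueError("seed trace is constant; correlation undefined")

    constant = np.ptp(movie.data, axis=2) == 0.0
    pix = movie.data - movie.data.mean(axis=2, keepdims=True)
    pix_norm = np.sqrt(np.sum(pix**2, axis=2))
    pix_norm[constant] = np.inf  # flagged pixels report r = 0

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.tensordot(pix, seed_c, axes=([2], [0])) / (pix_norm * seed_norm)
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMap(values=r, seed_label=seed_label, constant_pixels=constant)


def roi_pair_r(series: RoiTimeSeriesSet, roi_a: str, roi_b: str) -> float:
    """Pearson correlation between two ROI traces of a preprocessed set."""
    a = series.row(roi_a)
    b = series.row(roi_b)
    for label, x in ((roi_a, a), (roi_b, b)):
        if np.ptp(x) == 0.0:
            raise ValueError(f"ROI {label!r} has a constant trace; r undefined")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(np.dot(ac, bc) / np.sqrt(np.dot(ac, ac) * np.dot(bc, bc)))


def correlation_matrix(series: RoiTimeSeriesSet) -> CorrelationMatrix:
    """All pairwise Pearson correlations of a preprocessed ROI set."""
    if series.n_roi < 2:
        raise ValueError("at least two ROIs are required")
    if (np.ptp(series.signals, axis=1) == 0.0).any():
        bad = [
            lbl
            for lbl, row in zip(series.roi_labels, series.signals)
            if np.ptp(row) == 0.0
        ]
        raise ValueError(f"constant ROI trace(s): {', '.join(bad)}")
    r = np.corrcoef(series.signals)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(r=r, roi_labels=list(series.roi_labels))


def fisher_z(r):
    """Fisher's variance-stabilizing transform, z = atanh(r).

    Rejects |r| >= 1; callers holding measured correlations that may touch
    1 exactly should clip explicitly (see :data:`FISHER_CLIP`).
    """
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1.0).any():
        raise ValueError("|r| must be < 1 for the Fisher transform; clip first")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    normality_alpha: float = 0.05,
    exact_max_n: int = 12,
) -> tuple[str, float]:
    """Two-sided group comparison with a Shapiro-Wilk normality gate.

    If both groups pass Shapiro-Wilk at ``normality_alpha``, Welch's
    unequal-variance t-test is used; otherwise the Mann-Whitney U test
    (exact null distribution when both groups have at most ``exact_max_n``
    observations and no ties, tie-corrected normal approximation
    otherwise).

    Returns ``(test_used, p_raw)`` with ``test_used`` in
    ``{"welch", "mann_whitney"}``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        # identical constants in both groups: no evidence of any difference
        return "mann_whitney", 1.0

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0.0:
            return False
        return stats.shapiro(x).pvalue > normality_alpha

    if _normal(a) and _normal(b):
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        return "welch", float(p)

    if a.size <= exact_max_n and b.size <= exact_max_n and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return "mann_whitney", float(min(p, 1.0))


def bh_correct(p_values: Sequence[float], fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; returns boolean rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def significance_matrix(
    control_matrices: Sequence[CorrelationMatrix],
    arthritic_matrices: Sequence[CorrelationMatrix],
    fdr: float = 0.05,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise group comparison of Fisher-transformed correlations.

    Each animal contributes one correlation matrix; for every ROI pair the
    per-animal r values are Fisher-transformed and compared between groups,
    then Benjamini-Hochberg correction is applied across the pair set of
    this imaging plane.

    Returns a long-format table with one row per ROI pair:
    ``roi_a, roi_b, test_used, p_raw, z_mean_control, z_mean_arthritic,
    z_median_control, z_median_arthritic, significant``.
    """
    if not control_matrices or not arthritic_matrices:
        raise ValueError("both groups need at least one animal")
    labels = control_matrices[0].roi_labels
    for m in list(control_matrices) + list(arthritic_matrices):
        if m.roi_labels != labels:
            raise ValueError("all animals must share the same ROI set")
    if pairs is None:
        pairs = list(combinations(labels, 2))

    clip = 1.0 - FISHER_CLIP
    rows = []
    for roi_a, roi_b in pairs:
        zc = fisher_z(np.clip([m.pair(roi_a, roi_b) for m in control_matrices], -clip, clip))
        za = fisher_z(np.clip([m.pair(roi_a, roi_b) for m in arthritic_matrices], -clip, clip))
        test_used, p_raw = group_compare(zc, za)
        rows.append(
            {
                "roi_a": roi_a,
                "roi_b": roi_b,
                "test_used": test_used,
                "p_raw": p_raw,
                "z_mean_control": float(np.mean(zc)),
                "z_mean_arthritic": float(np.mean(za)),
                "z_median_control": float(np.median(zc)),
                "z_median_arthritic": float(np.median(za)),
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = bh_correct(table["p_raw"].to_numpy(), fdr=fdr)
    return table
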