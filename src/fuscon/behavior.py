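"""Linking connectivity alterations to behavior across individual animals.

Builds the per-animal dataset (selected ROI-pair correlations, brain-state
occurrence rates, behavioral covariates) and the three-block Spearman
correlation matrix over all selected variables: connectivity vs
connectivity, connectivity vs behavior, behavior vs behavior.  Controls
and arthritic animals are pooled by default — the question is whether
individual-level variation in connectivity tracks individual-level
variation in behavior, across the whole severity range.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .static_fc import bh_correct

__all__ = ["SpearmanBlockMatrix", "assemble_dataset", "spearman_blocks"]

_META_COLS = ("group", "cohort")


@dataclass
class SpearmanBlockMatrix:
    """Pairwise Spearman correlations with block structure and BH mask."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    blocks: pd.Series  # variable -> block name ("fc", "state", "behavior")
    excluded: list[str]  # constant columns dropped from testing

    def block_pairs(self, block_a: str, block_b: str) -> pd.DataFrame:
        """Long-format view of one block of the matrix."""
        rows = []
        for va in self.blocks[self.blocks == block_a].index:
            for vb in self.blocks[self.blocks == block_b].index:
                if va == vb:
                    continue
                rows.append(
                    {
                        "var_a": va,
                        "var_b": vb,
                        "rho": self.rho.loc[va, vb],
                        "p": self.p.loc[va, vb],
                        "significant": bool(self.significant.loc[va, vb]),
                    }
                )
        return pd.DataFrame(rows)

    def to_long(self) -> pd.DataFrame:
        rows = []
        cols = list(self.rho.columns)
        for va, vb in combinations(cols, 2):
            pair_blocks = sorted([self.blocks[va], self.blocks[vb]])
            rows.append(
                {
                    "var_a": va,
                    "var_b": vb,
                    "rho": self.rho.loc[va, vb],
                    "p": self.p.loc[va, vb],
                    "significant": bool(self.significant.loc[va, vb]),
                    "block": "-".join(pair_blocks),
                }
            )
        return pd.DataFrame(rows)


def assemble_dataset(
    fc_features: pd.DataFrame | None,
    occurrences: pd.DataFrame | None,
    behavior: pd.DataFrame,
    fc_selection: list[str] | None = None,
    behavior_selection: list[str] | None = None,
) -> pd.DataFrame:
    """Column-align connectivity features, state occurrences and behavior.

    All sources must cover exactly the same animals (index = animal id).
    Returns one row per animal; ``group``/``cohort`` metadata columns are
    carried through from the behavior table when present.
    """
    parts: list[pd.DataFrame] = []
    if fc_features is not None:
        sel = fc_selection if fc_selection is not None else list(fc_features.columns)
        parts.append(fc_features[sel])
    if occurrences is not None:
        parts.append(occurrences)

    if behavior_selection is None:
        behavior_selection = [c for c in behavior.columns if c not in _META_COLS]
    meta = [c for c in _META_COLS if c in behavior.columns]
    parts.append(behavior[behavior_selection + meta])

    ref = parts[-1].index
    if ref.has_duplicates:
        raise ValueError("duplicate animal ids in the behavior table")
    for part in parts:
        if part.index.has_duplicates:
            raise ValueError("duplicate animal ids in an input table")
        missing = ref.symmetric_difference(part.index)
        if len(missing):
            raise ValueError(
                f"input tables cover different animals: {sorted(map(str, missing))}"
            )
    out = pd.concat([p.loc[ref] for p in parts], axis=1)
    data_cols = [c for c in out.columns if c not in _META_COLS]
    if out[data_cols].isna().any().any():
        raise ValueError("missing values in selected columns")
    return out


def _spearman_p_permutation(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_resamples: int
) -> float:
    """Monte-Carlo permutation p-value for Spearman's rho."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(ry)
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def spearman_blocks(
    dataset: pd.DataFrame,
    blocks: pd.Series | dict | None = None,
    alpha: float = 0.05,
    correction: str = "bh",
    p_method: str = "t",
    n_resamples: int = 10000,
    seed: int | None = None,
) -> SpearmanBlockMatrix:
    """Pairwise Spearman correlation matrix with BH-corrected significance.

    Parameters
    ----------
    dataset : DataFrame
        One row per animal; metadata columns ``group``/``cohort`` are
        ignored.  Needs at least 5 animals.
    blocks : mapping, optional
        Variable name -> block label.  Unlabeled variables default to
        ``"behavior"`` if they match a behavior column naming convention is
        not assumed; pass explicit labels for a meaningful block report.
    p_method : {"t", "permutation"}
        Two-sided p-values from the t approximation (default) or a
        Monte-Carlo permutation test (small cohorts).
    correction : {"bh", "none"}
        Multiple-comparison handling over all unique off-diagonal pairs.
    """
    data = dataset[[c for c in dataset.columns if c not in _META_COLS]]
    if len(data) < 5:
        raise ValueError("at least 5 animals are required")
    if p_method not in ("t", "permutation"):
        raise ValueError("p_method must be 't' or 'permutation'")
    if correction not in ("bh", "none"):
        raise ValueError("correction must be 'bh' or 'none'")

    cols = list(data.columns)
    excluded = [c for c in cols if np.ptp(data[c].to_numpy(dtype=float)) == 0.0]
    tested = [c for c in cols if c not in excluded]

    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    rng = np.random.default_rng(seed)

    pair_list = list(combinations(tested, 2))
    pvals = []
    for va, vb in pair_list:
        x = data[va].to_numpy(dtype=float)
        y = data[vb].to_numpy(dtype=float)
        res = stats.spearmanr(x, y)
        r = float(res.statistic)
        p = float(res.pvalue)
        if p_method == "permutation":
            p = _spearman_p_permutation(x, y, rng, n_resamples)
        rho.loc[va, vb] = rho.loc[vb, va] = r
        pmat.loc[va, vb] = pmat.loc[vb, va] = p
        pvals.append(p)

    for c in excluded:
        rho.loc[c, :] = rho.loc[:, c] = np.nan
        rho.loc[c, c] = 1.0
        pmat.loc[c, :] = pmat.loc[:, c] = np.nan
        pmat.loc[c, c] = 0.0

    if correction == "bh":
        flags = bh_correct(np.asarray(pvals), fdr=alpha) if pvals else np.zeros(0, bool)
    else:
        flags = np.asarray(pvals) <= alpha if pvals else np.zeros(0, bool)
    sig = pd.DataFrame(
        np.zeros((len(cols), len(cols)), dtype=bool), index=cols, columns=cols
    )
    for (va, vb), f in zip(pair_list, flags):
        sig.loc[va, vb] = sig.loc[vb, va] = bool(f)

    if blocks is None:
        block_series = pd.Series({c: "behavior" for c in cols})
    else:
        block_series = pd.Series(blocks).reindex(cols).fillna("behavior")
    return SpearmanBlockMatrix(
        rho=rho, p=pmat, significant=sig, blocks=block_series, excluded=excluded
    )
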