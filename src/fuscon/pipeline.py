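"""High-level study drivers gluing the analysis stages together.

These helpers run whole-cohort analyses the way the individual CLI
commands and the reproduction script do: preprocess every animal, build
the static correlation matrices and significance table, extract dynamic
brain states, and assemble the per-animal feature table that feeds the
behavior-correlation and ROC stages.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .dynamic import (
    BrainStateModel,
    hilbert_phase,
    kmeans_states,
    phase_locking,
    pool_features,
)
from .preprocess import DEFAULT_BAND, preprocess
from .simulate import SimulatedCohort
from .static_fc import CorrelationMatrix, correlation_matrix, significance_matrix

__all__ = [
    "preprocess_cohort",
    "static_fc_study",
    "fc_feature_table",
    "dynamic_states_study",
    "pair_column",
]


def pair_column(roi_a: str, roi_b: str) -> str:
    """Canonical column name for a ROI pair feature."""
    return f"r({roi_a},{roi_b})"


def preprocess_cohort(
    cohort: SimulatedCohort,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> dict[str, object]:
    """Band-pass + normalize every animal; returns animal_id -> series."""
    return {
        a.animal_id: preprocess(a.series, f_lo=f_lo, f_hi=f_hi)
        for a in cohort.animals
    }


def _matrices_by_group(
    processed: dict, groups: pd.Series
) -> tuple[list[CorrelationMatrix], list[CorrelationMatrix], dict[str, CorrelationMatrix]]:
    mats = {aid: correlation_matrix(s) for aid, s in processed.items()}
    control = [mats[a] for a in mats if groups[a] == "control"]
    arthritic = [mats[a] for a in mats if groups[a] == "arthritic"]
    return control, arthritic, mats


def static_fc_study(
    cohort: SimulatedCohort,
    fdr: float = 0.05,
    processed: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Static connectivity analysis of a cohort.

    Returns ``(features, significance)`` where ``features`` holds every
    animal's Pearson r for all ROI pairs (plus group/cohort metadata) and
    ``significance`` is the per-pair group-comparison table after
    Benjamini-Hochberg correction over the plane's pair set.
    """
    processed = processed or preprocess_cohort(cohort)
    groups = cohort.groups
    control, arthritic, mats = _matrices_by_group(processed, groups)
    significance = significance_matrix(control, arthritic, fdr=fdr)

    labels = cohort.config.roi_labels
    pairs = list(combinations(labels, 2))
    rows = {}
    for aid, m in mats.items():
        rows[aid] = {pair_column(a, b): m.pair(a, b) for a, b in pairs}
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "animal_id"
    features["group"] = groups.loc[features.index]
    features["cohort"] = cohort.cohorts.loc[features.index]
    return features, significance


def fc_feature_table(cohort: SimulatedCohort, processed: dict | None = None) -> pd.DataFrame:
    """Per-animal ROI-pair correlation features only (no statistics)."""
    features, _ = static_fc_study(cohort, processed=processed)
    return features


def dynamic_states_study(
    cohort: SimulatedCohort,
    k_list: tuple[int, ...] = (5, 6, 7),
    n_replicates: int = 200,
    seed: int | np.random.Generator | None = None,
    processed: dict | None = None,
) -> dict[int, BrainStateModel]:
    """Pooled brain-state decomposition of a cohort for each requested k."""
    processed = processed or preprocess_cohort(cohort)
    tensors = []
    for animal in cohort.animals:
        series = processed[animal.animal_id]
        tensors.append(phase_locking(hilbert_phase(series)))
    features, index = pool_features(tensors)
    rng = np.random.default_rng(seed)
    labels = cohort.config.roi_labels
    return {
        k: kmeans_states(
            features, index, labels, k=k, n_replicates=n_replicates, rng=rng
        )
        for k in k_list
    }
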