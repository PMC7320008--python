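import numpy as np
import pytest

from fuscon.preprocess import RoiTimeSeriesSet, normalize_energy
from fuscon.simulate import CohortConfig, StateSpec, simulate_cohort


def single_state_config(**overrides) -> CohortConfig:
    """A cohort whose animals never switch state: static effects only.

    With one globally synchronous state, the only group difference left is
    the amplitude attenuation of the hind-limb somatosensory ROIs, which
    lowers measured correlations through the noise floor.
    """
    kwargs = dict(
        states=[StateSpec(0, tuple(np.zeros(10)), "sync")],
        occupancy_control=(1.0,),
        occupancy_arthritic=(1.0,),
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def null_config(**overrides) -> CohortConfig:
    """Group-identical cohort: same state dynamics, no attenuation."""
    kwargs = dict(
        subnetwork_attenuation=1.0,
        occupancy_arthritic=(0.5, 0.1, 0.1, 0.15, 0.15),
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def sinusoid_set(
    freqs, phases=None, n_t=1500, frame_period=0.4, labels=None, normalized=True
) -> RoiTimeSeriesSet:
    """Pure sinusoid rows, optionally energy-normalized (flags preprocessed)."""
    freqs = np.atleast_1d(freqs)
    phases = np.zeros(freqs.size) if phases is None else np.atleast_1d(phases)
    t = np.arange(n_t) * frame_period
    rows = [np.cos(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)]
    labels = labels or [f"roi{i}" for i in range(freqs.size)]
    s = RoiTimeSeriesSet(
        signals=np.vstack(rows), roi_labels=labels, frame_period=frame_period
    )
    return normalize_energy(s) if normalized else s


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic study (9 control + 9 arthritic), reused
    across read-only tests."""
    return simulate_cohort(CohortConfig(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
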