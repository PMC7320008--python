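"""Synthetic cohorts with planted ground truth.

Every stage of the pipeline is exercised on simulated cohorts — no raw
data download is needed — whose generative model is exactly the
structure the dynamic-connectivity analysis assumes: each
animal's ROI signals share a band-limited carrier whose pairwise phase
relations switch among a small set of discrete "states" according to a
first-order Markov chain.

Signal model, per ROI i and frame t (frame period dt):

    x_i(t) = A_i * cos(2*pi*f_c*t*dt + theta_{s(t), i}) + e_i(t)

with carrier f_c inside the resting-state band, per-state phase offsets
theta, white noise e ~ N(0, noise_sd^2), and a short cosine-free linear
ramp smoothing offsets across state switches so the band-pass filter sees
no broadband transient.  Group structure is planted twice over:

* the arthritic group's Markov chain has a different stationary occupancy
  (less time in the globally synchronous state, more in the unilateral
  desynchronization states), and
* the carrier amplitude of a designated sub-network (the hind-limb
  somatosensory ROIs by default) is attenuated in arthritic animals, which
  lowers their measured static correlations through the noise floor.

Each arthritic animal carries a latent severity in [0, 1] that scales both
effects and drives the behavioral covariates, so connectivity alterations
and behavior are correlated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .preprocess import DopplerMovie, RoiTimeSeriesSet, _check_masks

__all__ = [
    "StateSpec",
    "CohortConfig",
    "SimulatedAnimal",
    "SimulatedCohort",
    "default_states",
    "build_transition_matrix",
    "stationary_distribution",
    "simulate_state_sequence",
    "simulate_roi_signals",
    "simulate_doppler_movie",
    "simulate_behavior",
    "simulate_cohort",
    "BEHAVIOR_DEFAULTS",
    "DEFAULT_ROI_LABELS",
]

#: bilateral ROI set of the medial coronal imaging plane: hind-limb primary
#: somatosensory, primary/secondary motor, primary/secondary cingulate
DEFAULT_ROI_LABELS = [
    "S1HL_L",
    "S1HL_R",
    "M1_L",
    "M1_R",
    "M2_L",
    "M2_R",
    "Cg1_L",
    "Cg1_R",
    "Cg2_L",
    "Cg2_R",
]


@dataclass(frozen=True)
class StateSpec:
    """One planted brain state: a phase offset per ROI, in radians.

    Offsets live in (-pi, pi] and are expressed relative to the first ROI,
    whose offset must be 0 (a global phase rotation does not change any
    pairwise phase difference, so this is a pure normalization).
    """

    state_id: int
    phase_offsets: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        offs = np.asarray(self.phase_offsets, dtype=float)
        if offs.ndim != 1:
            raise ValueError("phase_offsets must be a flat sequence")
        if (offs <= -np.pi).any() or (offs > np.pi).any():
            raise ValueError("phase offsets must lie in (-pi, pi]")
        if offs[0] != 0.0:
            raise ValueError("the reference ROI (index 0) must have offset 0")

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(self.phase_offsets, dtype=float)


def default_states(n_roi: int = 10) -> list[StateSpec]:
    """Five planted states over the default bilateral 10-ROI plane.

    0. global synchrony of the whole somatomotor/cingulate set;
    1. right sensorimotor block (S1HL_R, M1_R) in antiphase with the rest;
    2. left sensorimotor block in antiphase with the rest (offsets are
       written on the complement so the reference ROI keeps offset 0);
    3. cingulate cortices in antiphase with the sensorimotor cortices;
    4. secondary cingulate a quarter-cycle out of phase with the rest.
    """
    if n_roi != 10:
        raise ValueError("default states are defined for the 10-ROI plane")
    z = np.zeros(10)

    def offs(indices, value):
        o = z.copy()
        o[list(indices)] = value
        return tuple(o)

    return [
        StateSpec(0, tuple(z), "global synchrony"),
        StateSpec(1, offs([1, 3], np.pi), "right SM antiphase"),
        StateSpec(2, offs([1, 3, 4, 5, 6, 7, 8, 9], np.pi), "left SM antiphase"),
        StateSpec(3, offs([6, 7, 8, 9], np.pi), "cingulate antiphase"),
        StateSpec(4, offs([8, 9], np.pi / 2), "Cg2 asynchrony"),
    ]


BEHAVIOR_DEFAULTS: dict[str, dict] = {
    # group means emulate a typical adjuvant-induced-arthritis cohort at
    # three weeks: controls gain 136.00 g vs 49.44 g in arthritics
    # (SEM ~11.7 at N = 9, hence generative SDs near 35 g); median
    # inflammation score 0 vs 22 out of 60.
    # control_sd = 0 for the pathology scores: a healthy animal has no
    # inflammation and no vocalization on paw bending.
    "weight_gain": dict(control=136.00, arthritic=49.44, sd=30.0, control_sd=35.0, loading=0.8, lo=None, hi=None, integer=False),
    "inflammation_score": dict(control=0.0, arthritic=22.0, sd=5.0, control_sd=0.0, loading=0.9, lo=0, hi=60, integer=True),
    "vonfrey_left": dict(control=40.0, arthritic=16.0, sd=5.0, control_sd=5.0, loading=0.8, lo=0, hi=None, integer=False),
    "vonfrey_right": dict(control=40.0, arthritic=16.0, sd=5.0, control_sd=5.0, loading=0.8, lo=0, hi=None, integer=False),
    "bend_left": dict(control=0.0, arthritic=4.0, sd=0.8, control_sd=0.0, loading=0.8, lo=0, hi=5, integer=True),
    "bend_right": dict(control=0.0, arthritic=4.0, sd=0.8, control_sd=0.0, loading=0.8, lo=0, hi=5, integer=True),
}


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    The defaults are the study conditions used throughout the test-suite:
    9 control + 9 arthritic animals (optionally extended by a validation
    cohort), 10 bilateral ROIs, 1500 frames at 0.4 s, a 0.08 Hz carrier
    inside the 0.05-0.2 Hz resting-state band, unit carrier amplitude with
    noise_sd = 0.1, five planted states with a mean dwell around one
    minute, and a 0.5 amplitude attenuation of the hind-limb somatosensory
    ROIs in arthritic animals.
    """

    n_roi: int = 10
    roi_labels: list[str] = field(default_factory=lambda: list(DEFAULT_ROI_LABELS))
    n_control: int = 9
    n_arthritic: int = 9
    n_control_validation: int = 0
    n_arthritic_validation: int = 0
    frame_period: float = 0.4
    n_frames: int = 1500
    carrier_freq: float = 0.08
    amplitude: float = 1.0
    noise_sd: float = 0.1
    states: list[StateSpec] = field(default_factory=default_states)
    occupancy_control: tuple[float, ...] = (0.5, 0.1, 0.1, 0.15, 0.15)
    occupancy_arthritic: tuple[float, ...] = (0.3, 0.2, 0.2, 0.15, 0.15)
    dwell_scale: float = 100.0  # frames; mean dwell ~ dwell_scale/(1-pi_s)
    ramp_frames: int = 2
    subnetwork_rois: tuple[str, ...] = ("S1HL_L", "S1HL_R")
    subnetwork_attenuation: float = 0.5
    severity_range: tuple[float, float] = (0.4, 1.0)
    behavior: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in BEHAVIOR_DEFAULTS.items()}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.roi_labels) != self.n_roi:
            raise ValueError("n_roi must equal len(roi_labels)")
        if not 0.0 <= self.subnetwork_attenuation <= 1.0:
            raise ValueError("subnetwork_attenuation must lie in [0, 1]")
        n_states = len(self.states)
        for name in ("occupancy_control", "occupancy_arthritic"):
            occ = np.asarray(getattr(self, name), dtype=float)
            if occ.size != n_states:
                raise ValueError(f"{name} must have one entry per state")
            if (occ < 0).any() or not np.isclose(occ.sum(), 1.0):
                raise ValueError(f"{name} must be a probability vector")
        for st in self.states:
            if len(st.phase_offsets) != self.n_roi:
                raise ValueError("each state needs one phase offset per ROI")
        for roi in self.subnetwork_rois:
            if roi not in self.roi_labels:
                raise ValueError(f"unknown sub-network ROI {roi!r}")
        if self.dwell_scale < 1:
            raise ValueError("dwell_scale must be at least one frame")

    @property
    def severity_midpoint(self) -> float:
        return 0.5 * (self.severity_range[0] + self.severity_range[1])

    def transition_matrix(self, group: str) -> np.ndarray:
        occ = (
            self.occupancy_control
            if group == "control"
            else self.occupancy_arthritic
        )
        return build_transition_matrix(np.asarray(occ, float), self.dwell_scale)


def build_transition_matrix(occupancy: np.ndarray, dwell_scale: float) -> np.ndarray:
    """Row-stochastic chain with a chosen stationary law and dwell scale.

    ``T = (1 - eps) I + eps 1 pi^T`` with ``eps = 1/dwell_scale``: at each
    frame the chain either stays put or redraws its state from the target
    stationary distribution pi, so pi is exactly stationary and the mean
    dwell in state s is ``dwell_scale / (1 - pi_s)`` frames.
    """
    pi = np.asarray(occupancy, dtype=float)
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
        raise ValueError("occupancy must be a probability vector")
    eps = 1.0 / float(dwell_scale)
    if not 0.0 < eps <= 1.0:
        raise ValueError("dwell_scale must be >= 1 frame")
    t = (1.0 - eps) * np.eye(pi.size) + eps * np.outer(np.ones(pi.size), pi)
    return t


def _check_stochastic(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    return t


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary law of a row-stochastic matrix (left unit eigenvector)."""
    t = _check_stochastic(t)
    vals, vecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_sequence(
    transition_matrix: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    initial: int | None = None,
) -> np.ndarray:
    """Sample a first-order Markov state sequence.

    The initial state is drawn from the chain's stationary distribution
    unless given explicitly.
    """
    t = _check_stochastic(transition_matrix)
    cum = np.cumsum(t, axis=1)
    u = rng.random(n_frames)
    seq = np.empty(n_frames, dtype=np.int64)
    if initial is None:
        pi = stationary_distribution(t)
        state = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
        state = min(state, t.shape[0] - 1)
    else:
        state = int(initial)
        if not 0 <= state < t.shape[0]:
            raise ValueError("initial state out of range")
    seq[0] = state
    for i in range(1, n_frames):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        if state == t.shape[0]:  # guard against u == 1.0 rounding
            state -= 1
        seq[i] = state
    return seq


def simulate_roi_signals(
    config: CohortConfig,
    state_seq: np.ndarray,
    group: str,
    rng: np.random.Generator,
    attenuation: float | None = None,
    animal_id: str | None = None,
    cohort: str | None = None,
) -> RoiTimeSeriesSet:
    """State-switching oscillator traces for one animal.

    Phase offsets follow the planted state sequence, smoothed over
    ``ramp_frames`` frames at each switch; in arthritic animals the
    carrier amplitude of the designated sub-network ROIs is multiplied by
    the attenuation factor (per-animal severity-scaled when provided).
    """
    nyquist = 0.5 / config.frame_period
    if not 0.0 < config.carrier_freq < nyquist:
        raise ValueError(
            f"carrier_freq must lie in (0, {nyquist}) Hz for this frame period"
        )
    state_seq = np.asarray(state_seq, dtype=int)
    if state_seq.min() < 0 or state_seq.max() >= len(config.states):
        raise ValueError("state sequence indexes an unknown state")

    offsets_by_state = np.stack([s.offsets for s in config.states])
    offs = offsets_by_state[state_seq]  # [n_t, n_roi]
    if config.ramp_frames > 1:
        offs = uniform_filter1d(
            offs, size=config.ramp_frames, axis=0, mode="nearest"
        )

    amps = np.full(config.n_roi, config.amplitude, dtype=float)
    if group == "arthritic":
        a = config.subnetwork_attenuation if attenuation is None else attenuation
        if not 0.0 <= a <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        for roi in config.subnetwork_rois:
            amps[config.roi_labels.index(roi)] *= a

    t = np.arange(state_seq.size) * config.frame_period
    carrier_phase = 2.0 * np.pi * config.carrier_freq * t
    clean = amps[None, :] * np.cos(carrier_phase[:, None] + offs)
    noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
    signals = (clean + noise).T
    return RoiTimeSeriesSet(
        signals=signals,
        roi_labels=list(config.roi_labels),
        frame_period=config.frame_period,
        animal_id=animal_id,
        group=group,
        cohort=cohort,
        preprocessed=False,
    )


def simulate_doppler_movie(
    roi_set: RoiTimeSeriesSet,
    roi_masks: Mapping[str, np.ndarray],
    brain_mask: np.ndarray,
    pixel_noise_sd: float,
    rng: np.random.Generator,
) -> DopplerMovie:
    """Expand ROI traces into a pixel movie.

    Every pixel of an ROI carries that ROI's trace plus independent pixel
    noise; brain pixels outside all ROIs carry independent noise alone.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    masks = _check_masks(roi_masks, brain_mask)
    for label in masks:
        if label not in roi_set.roi_labels:
            raise ValueError(f"mask {label!r} has no matching ROI trace")
    n_z, n_x = brain_mask.shape
    n_t = roi_set.n_t
    data = np.zeros((n_z, n_x, n_t))
    if pixel_noise_sd > 0:
        data[brain_mask] = rng.normal(
            0.0, pixel_noise_sd, size=(int(brain_mask.sum()), n_t)
        )
    for label, mask in masks.items():
        data[mask] += roi_set.row(label)[None, :]
    return DopplerMovie(
        data=data, brain_mask=brain_mask, frame_period=roi_set.frame_period
    )


def simulate_behavior(
    config: CohortConfig,
    animal_ids: Sequence[str],
    groups: Sequence[str],
    latent_severity: Sequence[float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Behavioral covariates driven by the latent severity.

    For an arthritic animal with severity s (relative to the severity
    midpoint m), variable v with loading lambda takes

        mu_control + (mu_arthritic - mu_control) * (lambda*s/m + 1-lambda)

    plus Gaussian noise, so the group mean stays at the configured
    arthritic mean while within-group variation tracks severity in
    proportion to the loading.  Controls sit at the control mean plus
    noise.  Bounded scores are clipped and integer scores rounded.
    """
    sev = np.asarray(latent_severity, dtype=float)
    if ((sev < 0) | (sev > 1)).any():
        raise ValueError("latent severity must lie in [0, 1]")
    if not (len(animal_ids) == len(groups) == sev.size):
        raise ValueError("animal_ids, groups and severity must align")
    for g, s in zip(groups, sev):
        if g == "control" and s != 0.0:
            raise ValueError("control animals must have severity 0")

    m = config.severity_midpoint
    table: dict[str, list] = {"animal_id": list(animal_ids), "group": list(groups)}
    for var, spec in config.behavior.items():
        mu_c, mu_a = spec["control"], spec["arthritic"]
        lam = spec["loading"]
        vals = []
        for g, s in zip(groups, sev):
            if g == "arthritic":
                mean = mu_c + (mu_a - mu_c) * (lam * s / m + (1.0 - lam))
                sd = spec["sd"]
            else:
                mean = mu_c
                sd = spec.get("control_sd", spec["sd"])
            v = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            if spec["lo"] is not None:
                v = max(v, spec["lo"])
            if spec["hi"] is not None:
                v = min(v, spec["hi"])
            vals.append(round(v) if spec["integer"] else v)
        table[var] = vals
    return pd.DataFrame(table).set_index("animal_id")


@dataclass
class SimulatedAnimal:
    """One synthetic animal with its planted ground truth."""

    animal_id: str
    group: str
    cohort: str
    series: RoiTimeSeriesSet
    state_sequence: np.ndarray
    severity: float
    attenuation: float


@dataclass
class SimulatedCohort:
    """A full synthetic study: animals, behavior table, planted truth."""

    config: CohortConfig
    animals: list[SimulatedAnimal]
    behavior: pd.DataFrame

    @property
    def animal_ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]

    @property
    def groups(self) -> pd.Series:
        return pd.Series(
            {a.animal_id: a.group for a in self.animals}, name="group"
        )

    @property
    def cohorts(self) -> pd.Series:
        return pd.Series(
            {a.animal_id: a.cohort for a in self.animals}, name="cohort"
        )

    def retained_state_sequence(self, animal: SimulatedAnimal, trim: int = 100) -> np.ndarray:
        return animal.state_sequence[trim : animal.state_sequence.size - trim]


def _severity_occupancy(config: CohortConfig, severity: float) -> np.ndarray:
    """Interpolate the stationary occupancy with severity, then renormalize."""
    pc = np.asarray(config.occupancy_control, float)
    pa = np.asarray(config.occupancy_arthritic, float)
    w = severity / config.severity_midpoint
    pi = pc + w * (pa - pc)
    pi = np.clip(pi, 0.01, None)
    return pi / pi.sum()


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> SimulatedCohort:
    """Generate a complete cohort (and optional validation cohort).

    Identical config + seed gives a bit-identical cohort.  Arthritic
    animals draw a latent severity uniformly from ``severity_range``; it
    scales the sub-network attenuation, shifts the animal's state
    occupancy between the control and arthritic targets, and drives the
    behavioral covariates.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)

    roster: list[tuple[str, str, str]] = []
    for i in range(config.n_control):
        roster.append((f"C{i + 1:02d}", "control", "test"))
    for i in range(config.n_control_validation):
        roster.append((f"C{config.n_control + i + 1:02d}", "control", "validation"))
    for i in range(config.n_arthritic):
        roster.append((f"A{i + 1:02d}", "arthritic", "test"))
    for i in range(config.n_arthritic_validation):
        roster.append(
            (f"A{config.n_arthritic + i + 1:02d}", "arthritic", "validation")
        )

    lo, hi = config.severity_range
    animals: list[SimulatedAnimal] = []
    severities: list[float] = []
    for animal_id, group, cohort in roster:
        if group == "arthritic":
            severity = float(rng.uniform(lo, hi))
            w = severity / config.severity_midpoint
            attenuation = float(
                np.clip(1.0 - (1.0 - config.subnetwork_attenuation) * w, 0.0, 1.0)
            )
            t = build_transition_matrix(
                _severity_occupancy(config, severity), config.dwell_scale
            )
        else:
            severity = 0.0
            attenuation = 1.0
            t = config.transition_matrix("control")
        seq = simulate_state_sequence(t, config.n_frames, rng)
        series = simulate_roi_signals(
            config,
            seq,
            group,
            rng,
            attenuation=attenuation,
            animal_id=animal_id,
            cohort=cohort,
        )
        animals.append(
            SimulatedAnimal(
                animal_id=animal_id,
                group=group,
                cohort=cohort,
                series=series,
                state_sequence=seq,
                severity=severity,
                attenuation=attenuation,
            )
        )
        severities.append(severity)

    behavior = simulate_behavior(
        config,
        [a.animal_id for a in animals],
        [a.group for a in animals],
        severities,
        rng,
    )
    behavior["group"] = [a.group for a in animals]
    behavior["cohort"] = [a.cohort for a in animals]
    return SimulatedCohort(config=config, animals=animals, behavior=behavior)
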