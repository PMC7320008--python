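"""On-disk formats: ROI CSV, behavior CSV, cohort manifests, movies.

ROI time series travel as plain CSV with a leading ``time_s`` column and
one column per ROI label.  Movies use a flat little-endian binary array
(`.bin`, C order) with a JSON sidecar describing shape, dtype and frame
period — deliberately trivial so any environment can read them.
Cohort directories bundle per-animal series CSVs, the behavior table and
a ``manifest.json`` with group/cohort labels and the planted ground truth
of synthetic cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DopplerMovie, RoiTimeSeriesSet
from .simulate import (
    CohortConfig,
    SimulatedAnimal,
    SimulatedCohort,
    StateSpec,
)

__all__ = [
    "write_roi_csv",
    "read_roi_csv",
    "write_movie",
    "read_movie",
    "write_cohort",
    "read_cohort",
    "config_from_mapping",
]


def write_roi_csv(series: RoiTimeSeriesSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(series.signals.T, columns=series.roi_labels)
    df.insert(0, "time_s", series.times)
    df.to_csv(path, index=False)
    return path


def read_roi_csv(
    path: str | Path,
    animal_id: str | None = None,
    group: str | None = None,
    cohort: str | None = None,
    preprocessed: bool = False,
) -> RoiTimeSeriesSet:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("ROI CSV must contain a 'time_s' column")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError("ROI CSV must contain at least two frames")
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("time column must be uniformly sampled")
    labels = [c for c in df.columns if c != "time_s"]
    return RoiTimeSeriesSet(
        signals=df[labels].to_numpy(dtype=float).T,
        roi_labels=labels,
        frame_period=float(steps[0]),
        animal_id=animal_id,
        group=group,
        cohort=cohort,
        preprocessed=preprocessed,
    )


def write_movie(movie: DopplerMovie, path: str | Path) -> Path:
    """Flat binary array + JSON sidecar (``<path>.json``)."""
    path = Path(path)
    data = np.ascontiguousarray(movie.data, dtype="<f4")
    data.tofile(path)
    sidecar = {
        "shape": list(movie.data.shape),
        "dtype": "<f4",
        "order": "C",
        "frame_period": movie.frame_period,
        "brain_mask": movie.brain_mask.astype(int).tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))
    return path


def read_movie(path: str | Path) -> DopplerMovie:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return DopplerMovie(
        data=data.astype(float),
        brain_mask=np.asarray(meta["brain_mask"], dtype=bool),
        frame_period=float(meta["frame_period"]),
    )


def _config_to_mapping(config: CohortConfig) -> dict:
    return {
        "n_roi": config.n_roi,
        "roi_labels": list(config.roi_labels),
        "n_control": config.n_control,
        "n_arthritic": config.n_arthritic,
        "n_control_validation": config.n_control_validation,
        "n_arthritic_validation": config.n_arthritic_validation,
        "frame_period": config.frame_period,
        "n_frames": config.n_frames,
        "carrier_freq": config.carrier_freq,
        "amplitude": config.amplitude,
        "noise_sd": config.noise_sd,
        "states": [
            {
                "state_id": s.state_id,
                "phase_offsets": list(s.phase_offsets),
                "label": s.label,
            }
            for s in config.states
        ],
        "occupancy_control": list(config.occupancy_control),
        "occupancy_arthritic": list(config.occupancy_arthritic),
        "dwell_scale": config.dwell_scale,
        "ramp_frames": config.ramp_frames,
        "subnetwork_rois": list(config.subnetwork_rois),
        "subnetwork_attenuation": config.subnetwork_attenuation,
        "severity_range": list(config.severity_range),
        "behavior": config.behavior,
        "seed": config.seed,
    }


def config_from_mapping(mapping: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain dict (YAML/JSON file)."""
    kwargs = dict(mapping)
    if "states" in kwargs and kwargs["states"] is not None:
        kwargs["states"] = [
            StateSpec(
                state_id=s["state_id"],
                phase_offsets=tuple(s["phase_offsets"]),
                label=s.get("label", ""),
            )
            for s in kwargs["states"]
        ]
    for key in ("occupancy_control", "occupancy_arthritic", "subnetwork_rois", "severity_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return CohortConfig(**kwargs)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write a cohort directory: series CSVs, behavior CSV, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_dir = out / "series"
    series_dir.mkdir(exist_ok=True)
    manifest_animals = []
    for a in cohort.animals:
        write_roi_csv(a.series, series_dir / f"{a.animal_id}.csv")
        manifest_animals.append(
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "cohort": a.cohort,
                "severity": a.severity,
                "attenuation": a.attenuation,
                "state_sequence": a.state_sequence.tolist(),
            }
        )
    cohort.behavior.to_csv(out / "behavior.csv")
    manifest = {
        "config": _config_to_mapping(cohort.config),
        "animals": manifest_animals,
    }
    (out / "manifest.json").write_text(json.dumps(manifest))
    return out


def read_cohort(path: str | Path) -> SimulatedCohort:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    config = config_from_mapping(manifest["config"])
    behavior = pd.read_csv(path / "behavior.csv", index_col="animal_id")
    animals = []
    for entry in manifest["animals"]:
        series = read_roi_csv(
            path / "series" / f"{entry['animal_id']}.csv",
            animal_id=entry["animal_id"],
            group=entry["group"],
            cohort=entry["cohort"],
        )
        animals.append(
            SimulatedAnimal(
                animal_id=entry["animal_id"],
                group=entry["group"],
                cohort=entry["cohort"],
                series=series,
                state_sequence=np.asarray(entry["state_sequence"], dtype=int),
                severity=entry["severity"],
                attenuation=entry["attenuation"],
            )
        )
    return SimulatedCohort(config=config, animals=animals, behavior=behavior)
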