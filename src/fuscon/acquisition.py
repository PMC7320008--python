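"""Ultrafast plane-wave acquisition arithmetic.

A functional-ultrasound scanner insonifies the brain with a fan of tilted
plane waves; the coherent compound of one fan yields a single compound
image, and a power-Doppler frame is the average of the compounds acquired
over one frame period.  Nothing here touches beamforming or clutter
filtering — this module only derives the integer bookkeeping (frames per
acquisition, compounds per frame, number of angles, pulse-repetition
frequency) that the rest of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AcquisitionSpec", "acquisition_geometry"]

_INT_TOL = 1e-9


@dataclass(frozen=True)
class AcquisitionSpec:
    """Complete description of a power-Doppler acquisition.

    Attributes
    ----------
    frame_period : float
        Duration of one power-Doppler frame in seconds.
    duration : float
        Total acquisition time in seconds.
    compound_rate : float
        Compound-image rate in Hz (plane-wave fans per second).
    angle_min, angle_max, angle_step : float
        Plane-wave steering angles in degrees.
    n_frames : int
        Number of Doppler frames, ``duration / frame_period``.
    compounds_per_frame : int
        Compound images averaged into one frame.
    n_angles : int
        Plane-wave angles per compound.
    prf_khz : float
        Pulse repetition frequency in kHz, ``n_angles * compound_rate / 1000``.
    """

    frame_period: float
    duration: float
    compound_rate: float
    angle_min: float
    angle_max: float
    angle_step: float
    n_frames: int
    compounds_per_frame: int
    n_angles: int
    prf_khz: float

    @property
    def sampling_rate(self) -> float:
        """Doppler frame rate in Hz."""
        return 1.0 / self.frame_period

    @property
    def nyquist(self) -> float:
        return 0.5 / self.frame_period


def _exact_int(value: float, field: str) -> int:
    rounded = round(value)
    if abs(value - rounded) > _INT_TOL * max(1.0, abs(value)):
        raise ValueError(
            f"{field} = {value!r} is not an integer; check the acquisition parameters"
        )
    return int(rounded)


def acquisition_geometry(
    frame_period: float = 0.4,
    duration: float = 600.0,
    compound_rate: float = 500.0,
    angle_min: float = -10.0,
    angle_max: float = 10.0,
    angle_step: float = 2.0,
) -> AcquisitionSpec:
    """Derive the integer counts of an acquisition from its timing parameters.

    Defaults describe a ten-minute resting-state acquisition at one Doppler
    frame every 400 ms, each frame compounding 200 plane-wave fans of 11
    angles (-10..+10 degrees, 2 degree step) fired at 5.5 kHz.

    Raises
    ------
    ValueError
        If any parameter is non-positive, the angle range is inverted, or a
        derived count does not come out as an exact integer.
    """
    for name, val in [
        ("frame_period", frame_period),
        ("duration", duration),
        ("compound_rate", compound_rate),
        ("angle_step", angle_step),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val!r}")
    if angle_max <= angle_min:
        raise ValueError("angle_max must exceed angle_min")

    n_frames = _exact_int(duration / frame_period, "n_frames")
    compounds_per_frame = _exact_int(
        compound_rate * frame_period, "compounds_per_frame"
    )
    n_angles = _exact_int((angle_max - angle_min) / angle_step + 1.0, "n_angles")
    prf_khz = n_angles * compound_rate / 1000.0

    return AcquisitionSpec(
        frame_period=frame_period,
        duration=duration,
        compound_rate=compound_rate,
        angle_min=angle_min,
        angle_max=angle_max,
        angle_step=angle_step,
        n_frames=n_frames,
        compounds_per_frame=compounds_per_frame,
        n_angles=n_angles,
        prf_khz=prf_khz,
    )
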