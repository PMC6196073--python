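"""Raw positions -> wrist frame -> low-pass filter -> resultant kinematics.

The chain mirrors standard motion-capture practice for digit kinematics:

1. express every sensor relative to the wrist reference sensor (removes hand
   and forearm translation);
2. zero-lag low-pass Butterworth filter each axis (2nd order, 5 Hz cutoff by
   default, applied forward and backward so there is no phase shift);
3. resultant displacement RD(t) = Euclidean distance from the rest position;
4. resultant velocity RV(t) = Euclidean norm of the per-axis derivatives,
   differentiated with the five-point central stencil (exact for quartics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import TrialRecording, ValidationError

__all__ = [
    "KinematicSeries",
    "to_wrist_frame",
    "lowpass",
    "rest_position",
    "resultant_displacement",
    "five_point_derivative",
    "resultant_velocity",
    "kinematic_series",
]

#: samples averaged to estimate the rest position (0.2 s at 100 Hz)
REST_SAMPLES = 20


@dataclass
class KinematicSeries:
    """Per-effector resultant displacement and speed traces for one trial."""

    effector: str  # "thumb" or "finger"
    rd: np.ndarray  # cm, >= 0
    rv: np.ndarray  # cm/s, >= 0
    fs: float
    rest: np.ndarray  # (x0, y0, z0) in the wrist frame, cm


def to_wrist_frame(rec: TrialRecording) -> TrialRecording:
    """Subtract the reference sensor's simultaneous position from every sensor.

    The reference trace becomes identically zero; all other sensors are then
    expressed in a frame that translates with the wrist.
    """
    if "reference" not in rec.positions:
        raise ValidationError(f"trial {rec.trial_index}: reference sensor absent")
    ref = rec.positions["reference"]
    positions = {name: xyz - ref for name, xyz in rec.positions.items()}
    return TrialRecording(
        participant_id=rec.participant_id,
        trial_index=rec.trial_index,
        task=rec.task,
        fs=rec.fs,
        duration=rec.duration,
        positions=positions,
    )


def lowpass(
    x: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    Forward-backward filtering (``filtfilt``) doubles the effective order and
    cancels the phase response; edges are handled by reflective padding of
    ``3 * order`` samples.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise ValueError(f"series of length {x.shape[0]} too short to filter")
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def rest_position(xyz: np.ndarray, n_rest: int = REST_SAMPLES) -> np.ndarray:
    """Rest position = mean of the first ``n_rest`` pre-movement samples."""
    xyz = np.asarray(xyz, dtype=float)
    return xyz[: max(1, min(n_rest, xyz.shape[0]))].mean(axis=0)


def resultant_displacement(xyz: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """RD(t) = sqrt((x-x0)^2 + (y-y0)^2 + (z-z0)^2), per sample, in cm."""
    xyz = np.asarray(xyz, dtype=float)
    return np.linalg.norm(xyz - np.asarray(rest, dtype=float), axis=-1)


def five_point_derivative(f: np.ndarray, fs: float) -> np.ndarray:
    """Differentiate along axis 0 with the five-point central stencil.

    Interior samples use
    ``f'(t) = (-f(t+2h) + 8 f(t+h) - 8 f(t-h) + f(t-2h)) / (12 h)``
    with ``h = 1/fs`` (fourth-order accurate, exact for degree <= 4).  The
    two samples at each edge fall back to one-sided differences of
    progressively lower order (4-point at the penultimate, 3-point at the
    boundary sample) so the output keeps the input length.
    """
    f = np.asarray(f, dtype=float)
    n = f.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 samples for the five-point stencil, got {n}")
    h = 1.0 / fs
    d = np.empty_like(f)
    d[2:-2] = (-f[4:] + 8.0 * f[3:-1] - 8.0 * f[1:-3] + f[:-4]) / (12.0 * h)
    # one-sided edges: 3-point at the boundary, 4-point one in
    d[0] = (-3.0 * f[0] + 4.0 * f[1] - f[2]) / (2.0 * h)
    d[1] = (-2.0 * f[0] - 3.0 * f[1] + 6.0 * f[2] - f[3]) / (6.0 * h)
    d[-1] = (3.0 * f[-1] - 4.0 * f[-2] + f[-3]) / (2.0 * h)
    d[-2] = (2.0 * f[-1] + 3.0 * f[-2] - 6.0 * f[-3] + f[-4]) / (6.0 * h)
    return d


def resultant_velocity(xyz: np.ndarray, rest: np.ndarray, fs: float) -> np.ndarray:
    """RV(t) = Euclidean norm of the three axis derivatives, in cm/s.

    ``rest`` is accepted for signature symmetry with
    :func:`resultant_displacement`; a constant offset has zero derivative.
    """
    del rest
    v = five_point_derivative(np.asarray(xyz, dtype=float), fs)
    return np.linalg.norm(v, axis=-1)


def kinematic_series(
    rec: TrialRecording,
    sensor_name: str,
    effector: str,
    cutoff: float = 5.0,
    order: int = 2,
    n_rest: int = REST_SAMPLES,
) -> KinematicSeries:
    """Full chain for one sensor of one trial (already in the wrist frame)."""
    if sensor_name not in rec.positions:
        raise ValidationError(f"trial {rec.trial_index}: sensor {sensor_name} absent")
    xyz = lowpass(rec.positions[sensor_name], rec.fs, cutoff=cutoff, order=order)
    rest = rest_position(xyz, n_rest)
    return KinematicSeries(
        effector=effector,
        rd=resultant_displacement(xyz, rest),
        rv=resultant_velocity(xyz, rest, rec.fs),
        fs=rec.fs,
        rest=rest,
    )
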