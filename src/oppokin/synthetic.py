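"""Synthetic opposition-movement sessions with recorded ground truth.

The generator emulates the study protocol — 8 participants, 12 tasks (4
target fingers x 3 target phalanges), 15 trials per task, 3 s trials sampled
at 100 Hz from 16 electromagnetic sensors — with paired bell-shaped
thumb/finger movements whose amplitude split, submovement count, and noise
level are configurable.

Each trial moves the thumb-distal sensor and the instructed phalanx sensor
toward each other along the line joining their rest positions: the thumb
covers a fraction r of the gap and the finger the remaining 1 - r, so r is
the ground-truth displacement ratio D_T.  The default r map is anchored to
the mean ratios reported for this task family (thumb share ~0.54 for distal
targets rising to ~0.88 for proximal ones, and rising from index to little
finger), additive on the Fisher-z scale so that the finger and phalanx
effects do not interact on the analysis scale.  Movements are composed of
one or more overlapping minimum-jerk submovements; more submovements give a
rougher speed profile (lower spectral arc length).  The default roughness
map keeps the thumb at a single submovement and gives the fingers more,
increasing toward ring/little fingers and proximal phalanges.

Ground truth (5%-of-peak onset and end of the noise-free speed profile, true
displacement and ratio, submovement count) is recorded per trial before
noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ALL_TASKS,
    SENSOR_NAMES,
    Digit,
    Finger,
    Phalanx,
    TaskLabel,
    TrialRecording,
)

__all__ = [
    "SimConfig",
    "SyntheticGroundTruth",
    "SENSOR_REST_POSITIONS",
    "minimum_jerk",
    "minimum_jerk_speed",
    "compose_submovements",
    "submovement_specs",
    "composite_speed",
    "threshold_crossings",
    "simulate_trial",
    "simulate_session",
    "default_ratio_map",
    "default_submovement_map",
]


# --------------------------------------------------------------------------
# Hand geometry (wrist-local rest positions, cm; supinated hand, fingers +x)
# --------------------------------------------------------------------------

SENSOR_REST_POSITIONS: dict[str, np.ndarray] = {
    "reference": np.array([0.0, 0.0, 0.0]),
    # fingers: (proximal, middle, distal) x along the finger, y across the palm
    "index_proximal": np.array([7.0, 3.0, 0.0]),
    "index_middle": np.array([9.5, 3.0, 0.0]),
    "index_distal": np.array([11.5, 3.0, 0.0]),
    "middle_proximal": np.array([7.2, 1.0, 0.0]),
    "middle_middle": np.array([10.0, 1.0, 0.0]),
    "middle_distal": np.array([12.5, 1.0, 0.0]),
    "ring_proximal": np.array([7.0, -1.0, 0.0]),
    "ring_middle": np.array([9.5, -1.0, 0.0]),
    "ring_distal": np.array([11.8, -1.0, 0.0]),
    "little_proximal": np.array([6.5, -3.0, 0.0]),
    "little_middle": np.array([8.5, -3.0, 0.0]),
    "little_distal": np.array([10.0, -3.0, 0.0]),
    # thumb, abducted away from the palm plane
    "thumb_proximal": np.array([2.5, 4.5, 1.0]),
    "thumb_middle": np.array([4.0, 5.5, 1.5]),
    "thumb_distal": np.array([5.5, 6.5, 2.0]),
}

#: hand placement relative to the transmitter (cm)
HAND_OFFSET = np.array([9.0, 6.0, 11.0])

THUMB_SENSOR = "thumb_distal"


def default_ratio_map() -> dict[TaskLabel, float]:
    """True thumb share r per task, additive on the Fisher-z scale.

    z(r) = base(phalanx) + delta(finger); the bases and deltas are anchored
    to the reported mean z-transformed ratios (distal 0.62, middle 0.89,
    proximal 1.54; increasing from index to little finger).
    """
    base = {Phalanx.DISTAL: 0.62, Phalanx.MIDDLE: 0.89, Phalanx.PROXIMAL: 1.54}
    delta = {Finger.INDEX: -0.15, Finger.MIDDLE: -0.05, Finger.RING: 0.06, Finger.LITTLE: 0.21}
    return {
        t: float(np.tanh(base[t.phalanx] + delta[t.finger])) for t in ALL_TASKS
    }


def default_submovement_map() -> dict[tuple[TaskLabel, str], int]:
    """Submovement counts per (task, effector).

    The thumb always moves as a single minimum-jerk unit; fingers get more
    submovements toward ring/little fingers and proximal phalanges, mirroring
    the reported smoothness asymmetry (thumb smoother everywhere, finger
    smoothness decreasing index -> little and distal -> proximal).
    """
    f_extra = {Finger.INDEX: 0, Finger.MIDDLE: 0, Finger.RING: 1, Finger.LITTLE: 1}
    p_extra = {Phalanx.DISTAL: 0, Phalanx.MIDDLE: 0, Phalanx.PROXIMAL: 1}
    out: dict[tuple[TaskLabel, str], int] = {}
    for t in ALL_TASKS:
        out[(t, "thumb")] = 1
        out[(t, "finger")] = 2 + f_extra[t.finger] + p_extra[t.phalanx]
    return out


def _default_amplitude_map() -> dict[TaskLabel, float]:
    """Total gap to close per task: thumb-tip to target-sensor distance."""
    thumb = SENSOR_REST_POSITIONS[THUMB_SENSOR]
    return {
        t: float(np.linalg.norm(SENSOR_REST_POSITIONS[t.target_sensor.name] - thumb))
        for t in ALL_TASKS
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic session.

    Defaults follow the recorded protocol: 8 participants x 12 tasks x 15
    trials, 3 s at 100 Hz.  ``noise_sd`` is per-axis Gaussian position noise
    in cm (default on the scale of the tracker's static accuracy after
    accounting for its sub-mm resolution).  Participant and trial variability
    act as Gaussian offsets of the true ratio on the Fisher-z scale.
    """

    n_participants: int = 8
    trials_per_task: int = 15
    fs: float = 100.0
    duration: float = 3.0
    noise_sd: float = 0.005  # cm, per axis per sample
    reference_noise_sd: float = 0.005  # cm; the wrist sensor is mechanically stable
    onset_jitter: float = 0.1  # s, uniform jitter of the movement start
    move_onset: float = 0.6  # s, nominal start of the onward movement
    move_duration: float = 0.6  # s, comfortable-speed opposition movement time
    participant_sd: float = 0.15  # between-participant sd of z(r)
    trial_ratio_sd: float = 0.05  # trial-to-trial sd of z(r)
    amplitude_jitter: float = 0.05  # relative trial-to-trial amplitude scatter
    drift_amplitude: float = 0.1  # cm, common slow hand drift (removed by wrist frame)
    submovement_overlap: float = 0.55  # onset stagger of successive submovements
    seed: int = 0
    ratio_map: dict[TaskLabel, float] = field(default_factory=default_ratio_map)
    submovement_map: dict[tuple[TaskLabel, str], int] = field(
        default_factory=default_submovement_map
    )
    amplitude_map: dict[TaskLabel, float] = field(default_factory=_default_amplitude_map)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def validate(self) -> "SimConfig":
        if abs(self.fs * self.duration - self.n_samples) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")
        for t, r in self.ratio_map.items():
            if not 0.0 < r < 1.0:
                raise ValueError(f"ratio for {t} must lie in (0, 1), got {r}")
        for key, k in self.submovement_map.items():
            if k < 1:
                raise ValueError(f"submovement count for {key} must be >= 1")
        for t, amp in self.amplitude_map.items():
            if not 0.0 < amp < 20.0:
                raise ValueError(
                    f"amplitude {amp} cm for {t} outside plausible hand scale"
                )
        if self.move_onset + self.move_duration + self.onset_jitter > self.duration:
            raise ValueError("movement window does not fit inside the trial")
        return self


@dataclass
class SyntheticGroundTruth:
    """True per-(trial, effector) quantities, recorded before noise."""

    participant: str
    trial: int
    task: TaskLabel
    effector: str
    true_onset_s: float  # 5%-of-peak crossing of the noise-free speed profile
    true_end_s: float
    true_displacement_cm: float
    true_ratio: float  # thumb share r for this trial
    submovements: int


# --------------------------------------------------------------------------
# Minimum-jerk building blocks
# --------------------------------------------------------------------------

def _mj_shape(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _mj_speed_shape(tau: np.ndarray) -> np.ndarray:
    out = np.zeros_like(tau)
    inside = (tau >= 0.0) & (tau <= 1.0)
    ti = tau[inside]
    out[inside] = 30.0 * ti**2 * (1.0 - ti) ** 2
    return out


def minimum_jerk(
    x0: float, xf: float, t0: float, dur: float, fs: float, n_samples: int
) -> np.ndarray:
    """Minimum-jerk point-to-point position profile on the sample grid.

    x(t) = x0 + (xf - x0)(10 tau^3 - 15 tau^4 + 6 tau^5) with
    tau = (t - t0)/dur clipped to [0, 1]; constant outside the window.
    """
    if dur <= 0 or t0 < 0 or t0 + dur > n_samples / fs:
        raise ValueError(
            f"movement window [{t0}, {t0 + dur}] invalid for {n_samples} samples at {fs} Hz"
        )
    t = np.arange(n_samples) / fs
    return x0 + (xf - x0) * _mj_shape((t - t0) / dur)


def minimum_jerk_speed(
    amplitude: float, t0: float, dur: float, t: np.ndarray
) -> np.ndarray:
    """Closed-form speed of one minimum-jerk unit; peaks at 1.875 A / dur."""
    return abs(amplitude) / dur * _mj_speed_shape((t - t0) / dur)


def compose_submovements(
    specs: Sequence[tuple[float, float, float, float]], fs: float, n_samples: int
) -> np.ndarray:
    """Superpose minimum-jerk displacement increments.

    Each spec is (x0, xf, t0, dur); increments beyond each unit's start point
    add linearly, so overlapping submovements blend into one composite
    trajectory starting at the first unit's x0.
    """
    if not specs:
        raise ValueError("need at least one submovement")
    x = np.full(n_samples, specs[0][0], dtype=float)
    for x0, xf, t0, dur in specs:
        x += minimum_jerk(x0, xf, t0, dur, fs, n_samples) - x0
    return x


def submovement_specs(
    amplitude: float, t0: float, total_dur: float, k: int, overlap: float = 0.55
) -> list[tuple[float, float, float, float]]:
    """Split one movement into ``k`` equal overlapping submovements.

    Each unit has duration d = total_dur / (1 + overlap (k - 1)) and starts
    ``overlap * d`` after its predecessor, so the composite spans exactly
    ``total_dur``; each unit carries amplitude / k.
    """
    if k < 1:
        raise ValueError("submovement count must be >= 1")
    d = total_dur / (1.0 + overlap * (k - 1))
    a = amplitude / k
    return [(0.0, a, t0 + i * overlap * d, d) for i in range(k)]


def composite_speed(
    specs: Sequence[tuple[float, float, float, float]], t: np.ndarray
) -> np.ndarray:
    """Speed magnitude of a composite of same-direction submovements."""
    v = np.zeros_like(t)
    for x0, xf, t0, dur in specs:
        v += minimum_jerk_speed(xf - x0, t0, dur, t)
    return v


def threshold_crossings(
    v: np.ndarray, t: np.ndarray, threshold_frac: float = 0.05
) -> tuple[float, float]:
    """Onset/end times where ``v`` crosses ``threshold_frac`` of its peak,
    walking out from the peak on a dense grid (the detection rule's
    continuous-time counterpart)."""
    peak = int(np.argmax(v))
    thr = threshold_frac * v[peak]
    below = np.nonzero(v[:peak] < thr)[0]
    onset = t[below[-1] + 1] if below.size else t[0]
    below = np.nonzero(v[peak + 1 :] < thr)[0]
    end = t[peak + below[0]] if below.size else t[-1]
    return float(onset), float(end)


# --------------------------------------------------------------------------
# Trial and session simulation
# --------------------------------------------------------------------------

def simulate_trial(
    task: TaskLabel,
    cfg: SimConfig,
    rng: np.random.Generator,
    participant_id: str = "P01",
    trial_index: int = 1,
    participant_z_offset: float = 0.0,
) -> tuple[TrialRecording, list[SyntheticGroundTruth]]:
    """Simulate one opposition trial and its ground truth.

    The thumb-distal sensor and the instructed phalanx sensor travel toward
    each other along the line joining their rest positions; every other
    sensor rests at its anatomical offset.  A common slow drift moves the
    whole hand (including the reference sensor) and is removed downstream by
    the wrist-frame transform; independent Gaussian noise is added per axis
    per sample to every sensor.
    """
    cfg.validate()
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    target = task.target_sensor.name

    z = np.arctanh(cfg.ratio_map[task]) + participant_z_offset
    if cfg.trial_ratio_sd > 0:
        z += rng.normal(0.0, cfg.trial_ratio_sd)
    r = float(np.tanh(z))

    amp = cfg.amplitude_map[task]
    if cfg.amplitude_jitter > 0:
        amp *= 1.0 + rng.uniform(-cfg.amplitude_jitter, cfg.amplitude_jitter)
    t0 = cfg.move_onset + rng.uniform(0.0, cfg.onset_jitter)
    dur = cfg.move_duration

    thumb_rest = SENSOR_REST_POSITIONS[THUMB_SENSOR]
    u = SENSOR_REST_POSITIONS[target] - thumb_rest
    u = u / np.linalg.norm(u)

    amps = {"thumb": r * amp, "finger": (1.0 - r) * amp}
    direction = {"thumb": u, "finger": -u}
    moving = {"thumb": THUMB_SENSOR, "finger": target}

    positions = {
        name: np.tile(SENSOR_REST_POSITIONS[name] + HAND_OFFSET, (n, 1))
        for name in SENSOR_NAMES
    }

    truths: list[SyntheticGroundTruth] = []
    t_fine = np.linspace(0.0, cfg.duration, 10 * n)
    for eff in ("thumb", "finger"):
        k = cfg.submovement_map[(task, eff)]
        specs = submovement_specs(amps[eff], t0, dur, k, cfg.submovement_overlap)
        scalar = compose_submovements(specs, cfg.fs, n)
        positions[moving[eff]] = positions[moving[eff]] + scalar[:, None] * direction[eff]
        onset_s, end_s = threshold_crossings(composite_speed(specs, t_fine), t_fine)
        truths.append(
            SyntheticGroundTruth(
                participant=participant_id,
                trial=trial_index,
                task=task,
                effector=eff,
                true_onset_s=onset_s,
                true_end_s=end_s,
                true_displacement_cm=amps[eff],
                true_ratio=r,
                submovements=k,
            )
        )

    if cfg.drift_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        drift = cfg.drift_amplitude * np.sin(
            2.0 * np.pi * 0.2 * t[:, None] + phase[None, :]
        )
        for name in positions:
            positions[name] = positions[name] + drift
    if cfg.noise_sd > 0 or cfg.reference_noise_sd > 0:
        noise = rng.normal(0.0, 1.0, size=(len(SENSOR_NAMES), n, 3))
        for i, name in enumerate(SENSOR_NAMES):
            sd = cfg.reference_noise_sd if name == "reference" else cfg.noise_sd
            positions[name] = positions[name] + sd * noise[i]

    rec = TrialRecording(
        participant_id=participant_id,
        trial_index=trial_index,
        task=task,
        fs=cfg.fs,
        duration=cfg.duration,
        positions=positions,
    )
    return rec, truths


def simulate_session(
    cfg: SimConfig,
) -> tuple[list[TrialRecording], pd.DataFrame, pd.DataFrame]:
    """Simulate a full session: every participant performs every task
    ``trials_per_task`` times in block-randomized order (each block is a
    random permutation of the 12 tasks).

    Returns (recordings, manifest, ground-truth table).  Deterministic for a
    fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    recs: list[TrialRecording] = []
    manifest_rows = []
    truth_rows = []
    trial = 0
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        z_off = rng.normal(0.0, cfg.participant_sd) if cfg.participant_sd > 0 else 0.0
        order: list[TaskLabel] = []
        for _ in range(cfg.trials_per_task):
            block = [ALL_TASKS[i] for i in rng.permutation(len(ALL_TASKS))]
            order.extend(block)
        for task in order:
            trial += 1
            rec, truths = simulate_trial(
                task, cfg, rng, participant_id=pid, trial_index=trial,
                participant_z_offset=z_off,
            )
            recs.append(rec)
            manifest_rows.append({"trial": trial, "participant": pid, "task": task.code})
            for gt in truths:
                truth_rows.append(
                    {
                        "trial": gt.trial,
                        "participant": gt.participant,
                        "task": gt.task.code,
                        "effector": gt.effector,
                        "true_onset_s": gt.true_onset_s,
                        "true_end_s": gt.true_end_s,
                        "true_displacement_cm": gt.true_displacement_cm,
                        "true_ratio": gt.true_ratio,
                        "submovements": gt.submovements,
                    }
                )
    return recs, pd.DataFrame(manifest_rows), pd.DataFrame(truth_rows)
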