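"""Per-trial outcome measures: displacement ratio and spectral arc length.

Displacement ratio (D) quantifies the relative contribution of the two
effectors in an opposition movement:

    D_T = |thumb displacement| / (|thumb displacement| + |finger displacement|)
    D_F = |finger displacement| / (|thumb displacement| + |finger displacement|)

so D_T + D_F = 1 by construction.  Being bounded in [0, 1], the ratios are
Fisher z-transformed (z = 0.5 ln((1+d)/(1-d)) = atanh(d)) before parametric
statistics.

Spectral arc length (SAL) measures movement smoothness: the speed profile of
the onward segment is zero-padded, Fourier transformed, and the magnitude
spectrum normalized in amplitude (by its DC value) and in frequency (to the
analysis band [0, f_max]).  SAL is the negative arc length of that curve;
smoother movements have spectra concentrated at low frequency, hence shorter
arcs and SAL closer to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import MovementSegment

__all__ = [
    "SalConfig",
    "TrialMetrics",
    "effector_displacement",
    "displacement_ratio",
    "fisher_z",
    "spectral_arc_length",
    "compute_trial_metrics",
]

#: clamp for d -> 1 so a zero finger displacement maps to a large finite z
_FISHER_CLAMP = 1.0 - 1e-9


@dataclass(frozen=True)
class SalConfig:
    f_max_hz: float = 10.0  # spectral band; movement content sits below the 5 Hz filter
    pad_factor: int = 16  # zero-pad to next power of two >= pad_factor * length
    adaptive_cutoff: bool = False  # adaptive amplitude-threshold band (SPARC variant)
    amplitude_threshold: float = 0.05  # used only by the adaptive variant


@dataclass
class TrialMetrics:
    thumb_displacement: float  # cm
    finger_displacement: float  # cm
    d_t: float
    d_f: float
    z_d_t: float
    z_d_f: float
    sal_thumb: float
    sal_finger: float
    fallback_used: bool = False


def effector_displacement(rd: np.ndarray, seg: MovementSegment) -> float:
    """Displacement over the onward movement: RD(end) - RD(onset), in cm."""
    rd = np.asarray(rd, dtype=float)
    return float(rd[seg.end] - rd[seg.onset])


def displacement_ratio(thumb_disp: float, finger_disp: float) -> tuple[float, float]:
    """(D_T, D_F) from the two effector displacements (absolute values)."""
    t, f = abs(thumb_disp), abs(finger_disp)
    total = t + f
    if total == 0.0:
        raise ValueError("displacement ratio undefined: both displacements are zero")
    d_t = t / total
    # complement by construction so the pair always sums to exactly 1
    return d_t, 1.0 - d_t


def fisher_z(d: float) -> float:
    """Fisher z-transform of a ratio in [0, 1]; d is clamped just below 1 so
    that a vanishing counterpart displacement yields a large finite value."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {d}")
    d = min(d, _FISHER_CLAMP)
    return float(np.arctanh(d))


def _next_pow2(n: int) -> int:
    return 1 << max(4, int(np.ceil(np.log2(max(1, n)))))


def spectral_arc_length(
    rv_segment: np.ndarray, fs: float, config: SalConfig = SalConfig()
) -> float:
    """Spectral arc length of a speed profile (dimensionless, <= 0).

    Steps: zero-pad to the next power of two >= ``pad_factor * len``; take the
    Fourier magnitude spectrum; divide by the DC magnitude; keep the band
    [0, f_max]; rescale frequency to [0, 1]; sum Euclidean steps between
    adjacent spectrum points; negate.
    """
    v = np.asarray(rv_segment, dtype=float)
    if v.size < 4:
        raise ValueError(f"segment of {v.size} samples too short for a spectrum")
    n_pad = _next_pow2(config.pad_factor * v.size)
    spec = np.abs(np.fft.rfft(v, n=n_pad))
    if spec[0] == 0.0:
        raise ValueError("zero speed profile: spectrum has no DC component")
    spec = spec / spec[0]
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    band = freqs <= config.f_max_hz
    spec, freqs = spec[band], freqs[band]
    if config.adaptive_cutoff:
        above = np.nonzero(spec >= config.amplitude_threshold)[0]
        cut = above[-1] + 1 if above.size else spec.size
        spec, freqs = spec[:cut], freqs[:cut]
    f_hat = freqs / freqs[-1]
    arc = float(np.sum(np.hypot(np.diff(f_hat), np.diff(spec))))
    return -arc


def compute_trial_metrics(
    thumb_rd: np.ndarray,
    thumb_seg: MovementSegment,
    finger_rd: np.ndarray,
    finger_seg: MovementSegment,
    thumb_rv: np.ndarray,
    finger_rv: np.ndarray,
    fs: float,
    sal_config: SalConfig = SalConfig(),
) -> TrialMetrics:
    """Assemble all per-trial measures from the two segmented effectors.

    SAL is computed on the segmented onward speed profile of each effector,
    not the full trial.
    """
    t_disp = effector_displacement(thumb_rd, thumb_seg)
    f_disp = effector_displacement(finger_rd, finger_seg)
    d_t, d_f = displacement_ratio(t_disp, f_disp)
    return TrialMetrics(
        thumb_displacement=t_disp,
        finger_displacement=f_disp,
        d_t=d_t,
        d_f=d_f,
        z_d_t=fisher_z(d_t),
        z_d_f=fisher_z(d_f),
        sal_thumb=spectral_arc_length(
            thumb_rv[thumb_seg.onset : thumb_seg.end + 1], fs, sal_config
        ),
        sal_finger=spectral_arc_length(
            finger_rv[finger_seg.onset : finger_seg.end + 1], fs, sal_config
        ),
        fallback_used=thumb_seg.fallback or finger_seg.fallback,
    )
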