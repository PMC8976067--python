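"""Phasor representation of TCSPC decay data.

The phasor transform maps each pixel's photon-arrival histogram to a point
(g, s) in the first-harmonic Fourier plane:

    g = sum_k c_k cos(w t_k) / sum_k c_k
    s = sum_k c_k sin(w t_k) / sum_k c_k

with w = 2*pi*harmonic/period and t_k the micro-time bin centers.  Mixtures
of decays combine linearly (intensity-weighted), and monoexponential decays
fall on the universal semicircle (g - 1/2)^2 + s^2 = 1/4, at
g = 1/(1 + (w tau)^2), s = w tau/(1 + (w tau)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TCSPCStack",
    "PhasorImage",
    "PhasorPoint",
    "phasor_transform",
    "calibrate",
    "universal_circle_point",
]


@dataclass(frozen=True)
class PhasorPoint:
    """A single point in phasor space."""

    g: float
    s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and np.isfinite(self.s)):
            raise ValueError("phasor coordinates must be finite")

    def as_complex(self) -> complex:
        return complex(self.g, self.s)


@dataclass
class TCSPCStack:
    """Per-pixel photon-count decay histograms with timing metadata.

    counts has shape (H, W, n_bins); period_ns is the laser repetition
    period; bin_width_ns * n_bins must equal the period (periodic binning).
    """

    counts: np.ndarray
    period_ns: float
    bin_width_ns: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D (y, x, bin) array")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")
        if self.period_ns <= 0:
            raise ValueError("laser period must be positive")
        n_bins = self.counts.shape[2]
        if n_bins < 16:
            raise ValueError("need at least 16 micro-time bins")
        if abs(n_bins * self.bin_width_ns - self.period_ns) > 1e-9:
            raise ValueError(
                f"bins ({n_bins}) x bin width ({self.bin_width_ns} ns) "
                f"must equal the laser period ({self.period_ns} ns)"
            )

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[2])

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[0], self.counts.shape[1]

    def bin_centers(self) -> np.ndarray:
        """Micro-time bin centers (k + 1/2) * dt, in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


@dataclass
class PhasorImage:
    """Per-pixel (g, s) phasor coordinates with intensity and validity mask.

    Invalid pixels (zero intensity, or removed by thresholding) carry
    g = s = 0 and must be excluded from statistics via ``valid``.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    omega: float = field(default=np.nan)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.g, self.s, self.intensity, self.valid)}
        if len(shapes) != 1:
            raise ValueError("g, s, intensity, valid must share one shape")
        self.valid = self.valid.astype(bool)

    def copy(self) -> "PhasorImage":
        return PhasorImage(
            self.g.copy(), self.s.copy(), self.intensity.copy(),
            self.valid.copy(), self.omega,
        )


def universal_circle_point(lifetime_ns: float, omega: float) -> PhasorPoint:
    """Phasor of an ideal monoexponential decay with the given lifetime.

    Parameters
    ----------
    lifetime_ns : fluorescence lifetime tau, ns (>= 0)
    omega : angular modulation frequency 2*pi*harmonic/period, rad/ns
    """
    if lifetime_ns < 0:
        raise ValueError("lifetime must be nonnegative")
    wt = omega * lifetime_ns
    d = 1.0 + wt * wt
    return PhasorPoint(1.0 / d, wt / d)


def phasor_transform(stack: TCSPCStack, harmonic: int = 1) -> PhasorImage:
    """Fourier-transform each pixel's decay histogram into phasor space.

    Zero-intensity pixels are marked invalid rather than producing NaNs.
    An all-zero stack yields an image with an empty validity mask.
    """
    if harmonic < 1 or int(harmonic) != harmonic:
        raise ValueError("harmonic must be a positive integer")
    omega = 2.0 * np.pi * harmonic / stack.period_ns
    t = stack.bin_centers()
    cos_w = np.cos(omega * t)
    sin_w = np.sin(omega * t)
    counts = stack.counts.astype(np.float64)
    intensity = counts.sum(axis=2)
    valid = intensity > 0
    denom = np.where(valid, intensity, 1.0)
    g = (counts @ cos_w) / denom
    s = (counts @ sin_w) / denom
    g[~valid] = 0.0
    s[~valid] = 0.0
    return PhasorImage(g=g, s=s, intensity=intensity, valid=valid, omega=omega)


def calibrate(
    image: PhasorImage,
    measured_reference: PhasorPoint,
    reference_lifetime_ns: float,
    omega: float | None = None,
) -> PhasorImage:
    """Correct phasors for the instrument response using a reference decay.

    Each valid pixel's phasor, viewed as a complex number g + i*s, is
    multiplied by expected/measured, where expected is the universal-circle
    phasor of a monoexponential at ``reference_lifetime_ns``.  When the
    measured reference equals the expected one the image is unchanged.
    """
    if omega is None:
        omega = image.omega
    if not np.isfinite(omega):
        raise ValueError("omega must be given when the image carries none")
    zm = measured_reference.as_complex()
    if abs(zm) < 1e-12:
        raise ValueError(
            "measured reference phasor has zero magnitude; calibration unusable"
        )
    ze = universal_circle_point(reference_lifetime_ns, omega).as_complex()
    factor = ze / zm
    z = (image.g + 1j * image.s) * factor
    out = image.copy()
    out.g = np.where(image.valid, z.real, 0.0)
    out.s = np.where(image.valid, z.imag, 0.0)
    return out


def mean_phasor(image: PhasorImage) -> PhasorPoint:
    """Intensity-weighted mean phasor over all valid pixels."""
    v = image.valid
    if not v.any():
        raise ValueError("image has no valid pixels")
    w = image.intensity[v]
    tot = w.sum()
    return PhasorPoint(float((image.g[v] * w).sum() / tot),
                       float((image.s[v] * w).sum() / tot))
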