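"""Normalized-slope complex Fourier descriptors of closed contours.

Each uniformly resampled contour z[n] = x[n] + j y[n] is reduced to its
slope signal ẑ[n] = Δz[n] / ‖Δz[n]‖ — the unit tangent direction at each
step — and transformed with the discrete Fourier transform

    Z[k] = (1/N) Σ_{n=0}^{N-1} ẑ[n] e^{-j 2π k n / N}.

Because ‖ẑ[n]‖ = 1 the full spectrum always carries unit energy
(Σ_k |Z[k]|² = 1), translation drops out when differencing, scale drops
out in the normalization, and rotating the contour by θ multiplies every
coefficient by e^{jθ}.  Low |k| harmonics encode the coarse blade outline;
high |k| encodes fine margin detail.  Retaining the q lowest-frequency
harmonics (default q = 22, the symmetric band k = ±1…±11) yields a compact
descriptor from which the contour can be reconstructed by zero-filling the
spectrum, inverting, renormalizing the slopes to unit modulus, and
integrating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour


@dataclass
class SlopeSignal:
    """Unit-modulus tangent-direction signal of a resampled contour."""

    values: np.ndarray  # complex, length N
    step_length: float  # constant ||Δz[n]|| of the uniform resampling
    start: complex = 0j  # first contour vertex, kept for reconstruction

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class HarmonicDescriptor:
    """Truncated spectrum of a slope signal on an explicit harmonic band."""

    coefficients: np.ndarray  # complex, aligned with `band`
    band: np.ndarray  # signed harmonic indices
    n: int  # source sample count N
    step_length: float
    start: complex = 0j

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.coefficients) ** 2))


def slope_signal(contour: Contour) -> SlopeSignal:
    """Compute ẑ[n] with wraparound (N slopes for N vertices).

    The last slope closes the contour back to the start vertex, which keeps
    the slope sum at exactly zero for a closed polygon.
    """
    v = contour.vertices
    if len(v) < 8:
        raise ValueError("slope signal needs a contour with >= 8 points")
    z = v[:, 0] + 1j * v[:, 1]
    dz = np.roll(z, -1) - z
    norms = np.abs(dz)
    if np.any(norms == 0):
        raise ValueError("coincident consecutive points (zero-length slope)")
    return SlopeSignal(dz / norms, float(norms.mean()), complex(z[0]))


def signed_frequencies(n: int) -> np.ndarray:
    """Signed harmonic indices of an N-point DFT (k > N/2 ≡ k − N)."""
    return np.fft.fftfreq(n, d=1.0 / n).astype(int)


def cft(slopes: SlopeSignal) -> np.ndarray:
    """Full complex Fourier spectrum Z[k], k = 0…N−1, with the 1/N factor.

    Index k of the returned array is the DFT bin; interpret indices above
    N/2 as negative frequencies (see :func:`signed_frequencies`).
    """
    return np.fft.fft(slopes.values) / slopes.n


def truncate(
    spectrum: np.ndarray,
    slopes: SlopeSignal,
    q: int = 22,
    band: str = "symmetric",
) -> HarmonicDescriptor:
    """Retain the q lowest-frequency harmonics of a full spectrum.

    ``band='symmetric'`` (default) keeps k ∈ {±1, …, ±q/2}, excluding
    k = 0 which is ~0 by closure; ``band='one-sided'`` keeps k ∈ {1…q}.
    """
    n = len(spectrum)
    if band == "symmetric":
        if q % 2 != 0 or not 2 <= q <= n - 2:
            raise ValueError("q must be even and in [2, N-2]")
        half = q // 2
        idx = np.concatenate([np.arange(1, half + 1),
                              -np.arange(1, half + 1)[::-1]])
    elif band == "one-sided":
        if not 1 <= q <= n - 1:
            raise ValueError("q must be in [1, N-1]")
        idx = np.arange(1, q + 1)
    else:
        raise ValueError(f"unknown band {band!r}")
    coeffs = spectrum[idx % n]
    return HarmonicDescriptor(coeffs.copy(), idx, n, slopes.step_length,
                              slopes.start)


def reconstruct(descriptor: HarmonicDescriptor) -> Contour:
    """Rebuild a closed contour from a (possibly truncated) descriptor.

    Non-retained harmonics are zero-filled; the inverse transform gives
    slopes which are renormalized to unit modulus (truncation breaks unit
    modulus but the arc-length interpretation should survive) and
    integrated by cumulative sum from the stored start point.
    """
    n = descriptor.n
    full = np.zeros(n, dtype=complex)
    full[descriptor.band % n] = descriptor.coefficients
    zhat = np.fft.ifft(full) * n  # inverse without the 1/N, e^{+j...}
    mods = np.abs(zhat)
    if np.any(mods == 0):
        raise ValueError("reconstructed slope has zero modulus; descriptor "
                         "carries no usable band energy")
    zhat = zhat / mods
    steps = descriptor.step_length * zhat
    z = descriptor.start + np.concatenate([[0.0], np.cumsum(steps)[:-1]])
    return Contour(np.column_stack([z.real, z.imag]))


def rms_difference(original: Contour, reconstructed: Contour) -> float:
    """Radius-normalized RMS positional difference, in percent.

    100 · sqrt(mean ‖p′[n] − p[n]‖²) / R with R the centroid RMS radius of
    the *original* contour (the reference; the measure is asymmetric in
    its arguments by that normalization choice).
    """
    a, b = original.vertices, reconstructed.vertices
    if len(a) != len(b):
        raise ValueError("contours must have equal point counts")
    r = np.sqrt(np.mean(np.sum((a - a.mean(axis=0)) ** 2, axis=1)))
    if r == 0:
        raise ValueError("degenerate reference contour (zero radius)")
    rms = np.sqrt(np.mean(np.sum((b - a) ** 2, axis=1)))
    return float(100.0 * rms / r)


def describe(
    contour: Contour, q: int = 22, band: str = "symmetric",
    align_phase: bool = False,
) -> HarmonicDescriptor:
    """Contour → truncated descriptor in one step."""
    slopes = slope_signal(contour)
    spectrum = cft(slopes)
    if align_phase:
        spectrum = canonical_phase(spectrum)
    return truncate(spectrum, slopes, q=q, band=band)


def canonical_phase(spectrum: np.ndarray) -> np.ndarray:
    """Normalize rotation and start-point phase of a full spectrum.

    Rotation multiplies every Z[k] by e^{jθ}; a start-point shift by n₀
    multiplies Z[k] by e^{-j2πk n₀/N}.  Solving on the fundamental pair
    (Z[1], Z[-1]) fixes both gauge freedoms: after normalization
    arg Z[1] = arg Z[-1] = π/2 (the tangent of an ideal circle at its
    start).  The pair determines (θ, n₀) only up to a simultaneous
    half-turn/half-circuit flip; the flip is resolved so that
    arg Z[1] = +π/2 exactly.  Off by default in the pipeline: aligned
    phases are only needed when inputs are not consistently oriented.
    """
    n = len(spectrum)
    z1, zm1 = spectrum[1], spectrum[-1]
    if z1 == 0 or zm1 == 0:
        return spectrum.copy()
    phi1, phim1 = np.angle(z1), np.angle(zm1)
    theta = np.pi / 2 - 0.5 * (phi1 + phim1)
    alpha = 0.5 * (phi1 - phim1)  # = 2π n₀ / N
    k = signed_frequencies(n)
    out = spectrum * np.exp(1j * (theta - k * alpha))
    if out[1].imag < 0:  # wrong branch of the half-turn ambiguity
        out = -out
    return out
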