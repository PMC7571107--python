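"""Frequency-domain image encoding: normalized log-magnitude 2-D DFT spectra.

A spatial one-hot window f(x, y) is mapped to

    F(u, v) = (1/MN) * sum_x sum_y f(x, y) exp(-j 2 pi (u x / M + v y / N))

the zero-frequency bin is shifted to the matrix centre, the base-10 log of
the magnitude is taken, and the finite values are min-max scaled to
[0, 255].  Zero-magnitude bins (log -> -inf) carry no energy and map to 0,
the darkest value.  The fast path uses an unnormalized FFT: the 1/MN factor
is a constant that cancels under the min-max normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Condition
from .spatial import SpatialImage


class DegenerateSpectrumWarning(UserWarning):
    """Recorded when the finite log-magnitude range collapses to a point."""


@dataclass(frozen=True)
class FrequencyImage:
    """Normalized log-magnitude spectrum of one spatial window, values in [0, 255]."""

    pixels: np.ndarray  # (k, k) float64 in [0, 255], centre = zero frequency
    subject_id: str
    condition: Condition
    start_index: int  # of the source spatial window

    def __post_init__(self) -> None:
        p = np.ascontiguousarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "condition", Condition(self.condition))
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be a square matrix")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixels must be finite")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("pixels must lie in [0, 255]")


def dft2_reference(pixels: np.ndarray) -> np.ndarray:
    """Direct double-sum 2-D DFT with the 1/(MN) normalization.

    Deliberately evaluates the defining sum point by point; it is the slow
    oracle against which the FFT path is verified, never the production path.
    """
    f = np.asarray(pixels, dtype=complex)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError("input must be a square matrix")
    M, N = f.shape
    x = np.arange(M)
    y = np.arange(N)
    out = np.empty((M, N), dtype=complex)
    for u in range(M):
        for v in range(N):
            phase = np.exp(-2j * np.pi * (u * x[:, None] / M + v * y[None, :] / N))
            out[u, v] = (f * phase).sum() / (M * N)
    return out


#: Magnitudes below this fraction of the spectral maximum are FFT round-off
#: of an exact zero and are treated as zero energy.
_ZERO_MAG_RTOL = 1e-12

#: A finite log10-magnitude range narrower than this (relative magnitude
#: spread < 10**tol) is numerically constant.
_DEGENERATE_LOG_RANGE = 1e-9


def normalize_spectrum(pixels: np.ndarray) -> np.ndarray:
    """Shifted log10-magnitude spectrum min-max scaled to [0, 255].

    The extrema are taken over finite entries only.  Non-finite entries
    (log of zero magnitude, i.e. zero energy) map to 0; magnitudes within
    round-off of zero relative to the spectral peak count as zero energy
    too.  If every finite entry is (numerically) equal: with zero-energy
    entries present the finite ones map to 255 (they carry all the energy);
    an entirely constant finite spectrum maps to all zeros with a
    :class:`DegenerateSpectrumWarning`.
    """
    spec = np.fft.fftshift(np.fft.fft2(np.asarray(pixels, dtype=float)))
    mag = np.abs(spec)
    mag[mag < mag.max() * _ZERO_MAG_RTOL] = 0.0
    with np.errstate(divide="ignore"):
        logmag = np.log10(mag)
    finite = np.isfinite(logmag)
    out = np.zeros_like(logmag)
    if not finite.any():
        warnings.warn("spectrum has no finite log-magnitudes", DegenerateSpectrumWarning)
        return out
    lo = logmag[finite].min()
    hi = logmag[finite].max()
    if hi - lo <= _DEGENERATE_LOG_RANGE:
        if finite.all():
            warnings.warn(
                "constant finite spectrum; normalized image is all zeros",
                DegenerateSpectrumWarning,
            )
            return out
        out[finite] = 255.0
        return out
    out[finite] = (logmag[finite] - lo) / (hi - lo) * 255.0
    return out


def to_frequency_image(img: SpatialImage) -> FrequencyImage:
    """Transform one spatial window into its normalized frequency-domain image."""
    return FrequencyImage(
        pixels=normalize_spectrum(img.pixels),
        subject_id=img.subject_id,
        condition=img.condition,
        start_index=img.start_index,
    )
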