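"""Spatial one-hot image encoding of IBI sequences.

Each beat duration is discretised into one of 28 intervals; a 28-beat
sliding window then yields a 28x28 binary matrix whose column *j* one-hot
encodes the bin of beat *j*.  Row 0 is the lowest-IBI interval; a vertical
flip is applied only at PNG export for display.

The interval edges come from the empirical distribution of the filtered
durations (equal-frequency quantile bins by default, equal-width as an
option).  The scheme used for a dataset is stored alongside it so training
and test images always share bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Condition, IBISequence, PHYSIO_HIGH, PHYSIO_LOW

N_BINS = 28


class BinningWarning(UserWarning):
    """Recorded when a quantile scheme falls back to equal width."""


@dataclass(frozen=True)
class BinningScheme:
    """``k`` half-open intervals ``[e_i, e_{i+1})`` (last closed) over IBI durations."""

    edges: np.ndarray  # k+1 strictly increasing values, seconds
    method: str  # "equal_width" | "quantile"
    fallback: bool = False  # True when quantile degraded to equal width

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", e)
        if e.ndim != 1 or e.size < 3:
            raise ValueError("edges must be a 1-D array defining >= 2 intervals")
        if np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.method not in ("equal_width", "quantile"):
            raise ValueError(f"unknown binning method {self.method!r}")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


@dataclass(frozen=True)
class SpatialImage:
    """One 28x28 one-hot window: column *j* encodes the bin of beat ``start_index + j``."""

    pixels: np.ndarray  # (k, window) uint8 in {0, 1}, one nonzero per column
    subject_id: str
    condition: Condition
    start_index: int

    def __post_init__(self) -> None:
        p = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "condition", Condition(self.condition))
        if p.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(p.sum(axis=0) == 1):
            raise ValueError("every column must be one-hot")


def _pad_to_k(edges: np.ndarray, k: int) -> np.ndarray:
    """Deduplicate, then split the widest interval until k intervals remain."""
    e = list(np.unique(edges))
    while len(e) < k + 1:
        widths = np.diff(e)
        j = int(np.argmax(widths))
        e.insert(j + 1, e[j] + widths[j] / 2.0)
    return np.asarray(e)


def fit_bins(
    durations: np.ndarray,
    k: int = N_BINS,
    method: str = "quantile",
    value_range: tuple[float, float] = (PHYSIO_LOW, PHYSIO_HIGH),
) -> BinningScheme:
    """Fit a :class:`BinningScheme` to filtered durations.

    ``equal_width`` spaces ``k`` intervals evenly over ``value_range``;
    ``quantile`` places edges at the 0/k ... k/k empirical quantiles
    (equal-frequency bins).  With fewer distinct values than intervals the
    quantile method falls back to equal width and records a warning.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("cannot fit bins on an empty duration list")
    if k < 2:
        raise ValueError("k must be >= 2")
    lo, hi = value_range
    if np.any((d < lo) | (d > hi)):
        raise ValueError("durations must be filtered to the physiologic range first")

    if method == "equal_width":
        return BinningScheme(np.linspace(lo, hi, k + 1), "equal_width")
    if method != "quantile":
        raise ValueError(f"unknown binning method {method!r}")
    if np.unique(d).size < k:
        warnings.warn(
            f"only {np.unique(d).size} distinct durations for {k} quantile bins; "
            "falling back to equal width",
            BinningWarning,
        )
        return BinningScheme(np.linspace(lo, hi, k + 1), "equal_width", fallback=True)
    edges = np.quantile(d, np.linspace(0.0, 1.0, k + 1))
    edges = _pad_to_k(edges, k)
    return BinningScheme(edges, "quantile")


def encode_beat(duration: float, bins: BinningScheme) -> int:
    """Index of the interval containing ``duration`` (last interval right-closed)."""
    return int(encode_durations(np.asarray([duration]), bins)[0])


def encode_durations(durations: np.ndarray, bins: BinningScheme) -> np.ndarray:
    """Vectorised :func:`encode_beat`; raises on out-of-range values."""
    d = np.asarray(durations, dtype=float)
    e = bins.edges
    if np.any((d < e[0]) | (d > e[-1])):
        bad = d[(d < e[0]) | (d > e[-1])][0]
        raise ValueError(f"duration {bad} outside binning range [{e[0]}, {e[-1]}]")
    idx = np.searchsorted(e, d, side="right") - 1
    return np.minimum(idx, bins.n_bins - 1).astype(np.intp)


def make_images(
    seq: IBISequence,
    bins: BinningScheme,
    window: int = N_BINS,
    stride: int = 1,
) -> list[SpatialImage]:
    """Slide a ``window``-beat window over each unbroken segment of ``seq``.

    Per segment of length L the window yields ``floor((L - window)/stride) + 1``
    images (none when L < window); windows never cross recorded segment
    boundaries.  ``window`` must equal the number of bin rows so images are
    square.
    """
    if window != bins.n_bins:
        raise ValueError(f"window ({window}) must equal the number of bins ({bins.n_bins})")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    images: list[SpatialImage] = []
    for start, stop in seq.segments():
        L = stop - start
        if L < window:
            continue
        rows = encode_durations(seq.durations[start:stop], bins)
        onehot = np.zeros((bins.n_bins, L), dtype=np.uint8)
        onehot[rows, np.arange(L)] = 1
        for w in range(0, L - window + 1, stride):
            images.append(
                SpatialImage(
                    pixels=onehot[:, w : w + window],
                    subject_id=seq.subject_id,
                    condition=seq.condition,
                    start_index=start + w,
                )
            )
    return images


def _pixels_on_scale(img, rendered_scale: float) -> np.ndarray:
    """Pixels of a spatial/frequency image (or raw array) on the rendered scale."""
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    pixels = pixels.astype(float)
    if pixels.size and pixels.max() <= 1.0:  # binary {0,1} matrix -> grayscale
        return pixels * rendered_scale
    return pixels


def image_intensity(img, rendered_scale: float = 255.0) -> float:
    """Mean of all pixel values on the rendered 0-255 scale.

    For a strict one-hot spatial window this is the constant
    ``window * scale / (rows * cols)`` whatever the condition — the
    diagnostic only varies for non-binary renderings.
    """
    return float(_pixels_on_scale(img, rendered_scale).mean())


def quadrant_intensities(img, rendered_scale: float = 255.0) -> dict[str, float]:
    """Mean intensity of the four half-size blocks (lower/upper x left/right).

    "Lower" rows are the low-IBI rows (row index < half).  The four quadrant
    means average to the whole-image mean.
    """
    p = _pixels_on_scale(img, rendered_scale)
    h, w = p.shape[0] // 2, p.shape[1] // 2
    return {
        "lower_left": float(p[:h, :w].mean()),
        "lower_right": float(p[:h, w:].mean()),
        "upper_left": float(p[h:, :w].mean()),
        "upper_right": float(p[h:, w:].mean()),
    }


def export_png(img, path: str | Path, colormap: str | None = None) -> Path:
    """Write a 28x28 grayscale PNG (vertically flipped so low IBIs sit at the bottom).

    ``colormap`` selects a matplotlib colormap rendering for display only;
    colormapped images never feed the classifier.
    """
    from PIL import Image

    p = np.flipud(_pixels_on_scale(img, 255.0))
    if colormap is None:
        arr = np.clip(p, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
    else:
        import matplotlib

        cmap = matplotlib.colormaps[colormap]
        rgba = (cmap(np.clip(p, 0, 255) / 255.0) * 255).astype(np.uint8)
        Image.fromarray(rgba, mode="RGBA").save(path)
    return Path(path)


def save_images_npz(images: list, path: str | Path, bins: BinningScheme | None = None,
                    stride: int = 1, filter_range: tuple[float, float] = (PHYSIO_LOW, PHYSIO_HIGH)) -> Path:
    """Stack images into an NPZ archive with labels, subjects and provenance."""
    path = Path(path)
    pixels = np.stack([np.asarray(i.pixels, dtype=np.float32) for i in images])
    labels = np.array([1 if i.condition is Condition.STRESSED else 0 for i in images], dtype=np.int8)
    subjects = np.array([i.subject_id for i in images])
    starts = np.array([i.start_index for i in images], dtype=np.int64)
    kwargs = dict(images=pixels, labels=labels, subjects=subjects, starts=starts,
                  stride=np.int64(stride), filter_range=np.asarray(filter_range))
    if bins is not None:
        kwargs["bin_edges"] = bins.edges
        kwargs["bin_method"] = np.array(bins.method)
    np.savez_compressed(path, **kwargs)
    return path
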