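"""Render data slices as square wave images.

Time domain: the raw 8 x n array is resized to S x S (default 224 x 224)
by separable, corner-aligned bilinear interpolation and min-max normalised
to [0, 1].  Frequency domain: each channel is replaced by the log-scaled
magnitude of its one-sided DFT before the identical resize/normalise step,
so the two encodings differ only in what the pixels mean — the downstream
classifier sees images of the same shape and intensity range either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .slicing import DataSlice

DEFAULT_SIDE = 224


@dataclass
class WaveImage:
    pixels: np.ndarray  # (side, side), float in [0, 1]
    side: int
    domain: str  # "time" or "frequency"
    subject_id: str
    label: int
    origin_row: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.side, self.side):
            raise ValueError(f"pixels shape {self.pixels.shape} != ({self.side}, {self.side})")
        if self.domain not in ("time", "frequency"):
            raise ValueError(f"domain must be 'time' or 'frequency', got {self.domain!r}")


def bilinear_resize(array: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Separable bilinear resize with corner-aligned coordinates.

    Destination index i on an axis of output length M maps to source
    coordinate i * (N - 1) / (M - 1), so source corners land exactly on
    destination corners.  A singleton source axis is treated as constant.
    When an axis is shrunk by more than 2x the source is first smoothed
    with a half-decimation-width moving average (a light antialias
    prefilter, as library bilinear resizers apply when shrinking); pure
    upsampling is exact two-point interpolation.
    """
    array = np.asarray(array, dtype=np.float64)
    out = array
    for axis, target in enumerate(out_shape):
        n = out.shape[axis]
        if target * 2 <= n:
            out = _moving_average(out, int(np.ceil(n / (2 * target))), axis)
        out = _interp_axis(out, target, axis)
    return out


def _moving_average(array: np.ndarray, width: int, axis: int) -> np.ndarray:
    """Centred moving average with edge replication (antialias prefilter)."""
    if width <= 1:
        return array
    arr = np.moveaxis(array, axis, -1)
    n = arr.shape[-1]
    left = width // 2
    right = width - 1 - left
    padded = np.concatenate(
        [np.repeat(arr[..., :1], left, axis=-1), arr, np.repeat(arr[..., -1:], right, axis=-1)],
        axis=-1,
    )
    csum = np.cumsum(padded, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    smoothed = (csum[..., width:width + n] - csum[..., :n]) / width
    return np.moveaxis(smoothed, -1, axis)


def _interp_axis(array: np.ndarray, target: int, axis: int) -> np.ndarray:
    n = array.shape[axis]
    if n == target:
        return array
    if n == 1:
        reps = [1, 1]
        reps[axis] = target
        return np.tile(array, reps)
    coords = np.arange(target) * (n - 1) / (target - 1) if target > 1 else np.array([0.0])
    lo = np.clip(np.floor(coords).astype(int), 0, n - 2)
    frac = coords - lo
    a = np.take(array, lo, axis=axis)
    b = np.take(array, lo + 1, axis=axis)
    shape = [1, 1]
    shape[axis] = target
    w = frac.reshape(shape)
    return a * (1 - w) + b * w


def _normalise(pixels: np.ndarray) -> np.ndarray:
    lo, hi = pixels.min(), pixels.max()
    if hi - lo <= 0:
        return np.full_like(pixels, 0.5)
    return (pixels - lo) / (hi - lo)


def slice_to_image(sl: DataSlice, side: int = DEFAULT_SIDE) -> WaveImage:
    """Time-domain wave image: resize the 8 x n slice to side x side, then
    min-max normalise to [0, 1] (a constant slice maps to all 0.5)."""
    if side < 16:
        raise ValueError(f"image side must be >= 16, got {side}")
    if not np.all(np.isfinite(sl.data)):
        raise ValueError(f"slice from {sl.subject_id} has non-finite samples")
    pixels = _normalise(bilinear_resize(sl.data, (side, side)))
    return WaveImage(pixels, side, "time", sl.subject_id, sl.label, sl.origin_row)


def slice_to_spectral_image(sl: DataSlice, side: int = DEFAULT_SIDE) -> WaveImage:
    """Frequency-domain wave image.

    Per channel the one-sided DFT magnitude (length n//2 + 1) is computed
    and compressed as log(1 + |X|); the resulting 8 x (n//2 + 1) array goes
    through the same resize and normalisation as the time-domain path.
    """
    if side < 16:
        raise ValueError(f"image side must be >= 16, got {side}")
    if sl.n_rows < 2:
        raise ValueError(f"spectral image needs n_rows >= 2, got {sl.n_rows}")
    spectrum = np.log1p(np.abs(np.fft.rfft(sl.data, axis=1)))
    pixels = _normalise(bilinear_resize(spectrum, (side, side)))
    return WaveImage(pixels, side, "frequency", sl.subject_id, sl.label, sl.origin_row)


def render_slices(slices, side: int = DEFAULT_SIDE, domain: str = "time") -> list[WaveImage]:
    """Render every slice in the given domain."""
    fn = {"time": slice_to_image, "frequency": slice_to_spectral_image}.get(domain)
    if fn is None:
        raise ValueError(f"domain must be 'time' or 'frequency', got {domain!r}")
    return [fn(sl, side) for sl in slices]


def save_png(img: WaveImage, path) -> None:
    """8-bit grayscale PNG export for visual inspection."""
    from PIL import Image

    Image.fromarray(np.round(img.pixels * 255).astype(np.uint8), mode="L").save(path)
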