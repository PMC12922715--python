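"""Stimulus corruption operators for speeded object-recognition experiments.

Images are H x W x 3 float arrays with intensities in [0, 1]; every
operator preserves shape and range.  Two corruptions degrade the stimuli —
additive uniform pixel noise and a Gaussian lowpass — plus a grayscale
conversion and the 1/f ("pink") noise field used as a backward mask.

Quantisation to 8-bit happens only at file I/O, never inside an operator.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "validate_image",
    "add_uniform_noise",
    "lowpass_filter",
    "to_grayscale",
    "pink_noise_mask",
    "read_image",
    "write_image",
    "GRAY_BACKGROUND",
    "LUMA_WEIGHTS",
]

# mid-gray experiment background, in [0,1]
GRAY_BACKGROUND = 0.454
# ITU-R BT.601 luma weights
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return img


def add_uniform_noise(
    img: np.ndarray,
    half_width: float = 0.5,
    seed: int = 0,
    per_channel: bool = False,
) -> np.ndarray:
    """Add uniform noise from [-half_width, half_width] and clip to [0, 1].

    By default one noise value is drawn per pixel location and added
    identically to all three channels (achromatic noise).  Set
    ``per_channel=True`` for independent draws per channel.
    """
    img = validate_image(img)
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    rng = np.random.default_rng(seed)
    h, w, _ = img.shape
    if per_channel:
        noise = rng.uniform(-half_width, half_width, size=(h, w, 3))
    else:
        noise = rng.uniform(-half_width, half_width, size=(h, w))[..., None]
    return np.clip(img + noise, 0.0, 1.0)


def lowpass_filter(
    img: np.ndarray,
    sigma: float = 5.0,
    pad_value: float = GRAY_BACKGROUND,
    truncate: float = 4.0,
) -> np.ndarray:
    """Gaussian lowpass: per-channel 2-D blur with constant gray padding.

    The kernel is truncated at ``truncate`` standard deviations (default 4,
    losing < 1e-4 of its mass) and the result clipped to [0, 1].
    """
    img = validate_image(img)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(
            img[..., c], sigma=sigma, mode="constant", cval=pad_value,
            truncate=truncate,
        )
    return np.clip(out, 0.0, 1.0)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma grayscale (weights 0.299, 0.587, 0.114), replicated to 3 channels."""
    img = validate_image(img)
    luma = img @ LUMA_WEIGHTS
    return np.clip(np.repeat(luma[..., None], 3, axis=2), 0.0, 1.0)


def pink_noise_mask(height: int, width: int, seed: int = 0) -> np.ndarray:
    """Grayscale pink-noise field: amplitude spectrum falling as 1/f.

    Seeded white noise is shaped in the frequency domain by 1/f (radial
    spatial frequency), the DC component is pinned to mid-gray, and the
    field min-max rescaled to [0, 1] and replicated to three channels.
    Used as the backward mask shown immediately after the stimulus.
    """
    if height < 8 or width < 8:
        raise ValueError("mask dimensions must be >= 8")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # placeholder; DC handled below
    shaped = spectrum / f
    shaped[0, 0] = 0.0
    field = np.fft.ifft2(shaped).real
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo) if hi > lo else np.full_like(field, 0.5)
    return np.repeat(field[..., None], 3, axis=2)


def read_image(path) -> np.ndarray:
    """Read a raster image file into a float [0,1] H x W x 3 array."""
    import imageio.v3 as iio

    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.repeat(raw[..., None], 3, axis=2)
    raw = raw[..., :3]
    info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
    img = raw.astype(float) / (info.max if info else 1.0)
    return validate_image(img)


def write_image(path, img: np.ndarray) -> None:
    """Write an image with lossless 8-bit quantisation (PNG)."""
    import imageio.v3 as iio

    img = validate_image(img)
    iio.imwrite(path, np.round(img * 255.0).astype(np.uint8))
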