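"""Training-time augmentation and test-time preprocessing.

The training stack applies, in order: intensity rescale (1/255), a random
x-axis shear with intensity 0.2, a random zoom in ``[1-0.2, 1+0.2]`` about
the image centre, and a horizontal flip with probability 0.5. Test frames
are rescaled, optionally cropped, resized to the model's 150x150 input and
denoised with a mean (box) filter. Geometric transforms use bilinear
interpolation with edge-replicated borders so zoom-out never introduces
artificial black margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, DomainError

__all__ = ["AugmentConfig", "rescale", "resize_to", "denoise_mean", "augment",
           "test_time_pipeline"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation hyperparameters (defaults follow the training recipe)."""

    rescale_factor: float = 1.0 / 255.0
    shear_intensity: float = 0.2
    zoom_range: float = 0.2
    horizontal_flip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rescale_factor <= 0:
            raise ConfigError("rescale_factor must be > 0")
        if self.shear_intensity < 0:
            raise ConfigError("shear_intensity must be >= 0")
        if self.zoom_range < 0:
            raise ConfigError("zoom_range must be >= 0")


def rescale(image: np.ndarray, factor: float = 1.0 / 255.0) -> np.ndarray:
    """Map 8-bit intensities [0, 255] to [0, 1] by multiplying with 1/255."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise DomainError("pixel values must lie in [0, 255]")
    return arr * factor


def resize_to(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize to (height, width); constant images stay constant and
    outputs stay within the input's [min, max]."""
    if height <= 0 or width <= 0:
        raise ConfigError("target dimensions must be positive")
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise DomainError("cannot resize an empty image")
    if arr.shape == (height, width):
        return arr.copy()
    return _sk_resize(arr, (height, width), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def denoise_mean(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Box (mean) filter with an odd kernel and edge-replicated borders."""
    if kernel < 1 or kernel % 2 == 0:
        raise ConfigError(f"kernel must be odd and >= 1, got {kernel}")
    arr = np.asarray(image, dtype=np.float64)
    if kernel == 1:
        return arr.copy()
    return ndimage.uniform_filter(arr, size=kernel, mode="nearest")


def _affine_about_center(image: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Apply a 2x2 output->input pixel transform centred on the image."""
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center
    return ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                    mode="nearest")


def augment(image: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Produce one augmented variant of an 8-bit frame, in [0, 1].

    Order of operations: rescale, random shear, random zoom, horizontal
    flip. The output keeps the input shape; a seeded ``rng`` makes the draw
    reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = rescale(image, cfg.rescale_factor)

    if cfg.shear_intensity > 0:
        s = float(rng.uniform(-cfg.shear_intensity, cfg.shear_intensity))
        # x' = x + s*y in (row, col) index space: col depends on row
        out = _affine_about_center(out, np.array([[1.0, 0.0], [s, 1.0]]))
    if cfg.zoom_range > 0:
        z = float(rng.uniform(1.0 - cfg.zoom_range, 1.0 + cfg.zoom_range))
        # output->input scaling is 1/z: z > 1 magnifies
        out = _affine_about_center(out, np.eye(2) / z)
    if cfg.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0)


def test_time_pipeline(image: np.ndarray, height: int = 150, width: int = 150,
                       denoise_kernel: int = 3,
                       crop_rows: tuple[int, int] | None = None,
                       crop_cols: tuple[int, int] | None = None) -> np.ndarray:
    """Test-time preprocessing: optional annotation-strip crop, rescale,
    resize to the model input size, mean-filter denoising. Returns [0, 1]."""
    arr = np.asarray(image)
    if crop_rows is not None:
        arr = arr[crop_rows[0]:crop_rows[1], :]
    if crop_cols is not None:
        arr = arr[:, crop_cols[0]:crop_cols[1]]
    if arr.size == 0:
        raise DomainError("crop rectangle removed the whole image")
    out = rescale(arr)
    out = resize_to(out, height, width)
    return denoise_mean(out, denoise_kernel)
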