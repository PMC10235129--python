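"""LV-tracing-based cropping.

The crop restricts a frame to the band between two dataset-level midpoints:
``M1 = (X1, Y1)``, the mean midpoint of the LV long axis (mid-cavity), and
``M2 = (X2, Y2)``, the mean midpoint between the LV bottom (mitral end) and
the bottom of the image. Averages run over all training tracings:

    X1 = mean_i (x_t^i + x_b^i) / 2      Y1 = mean_i (y_t^i + y_b^i) / 2
    X2 = mean_i (x_b^i + x_d^i) / 2      Y2 = mean_i (y_b^i + y_d^i) / 2

with ``(x_d^i, y_d^i)`` the point on the last image row directly below the
LV bottom. The retained rows ``[Y1, Y2)`` cover the lower half of the
cavity and the mitral region, the part of the frame that discriminates
between cardiac phases. Midpoints are computed once from the training split
and applied unchanged to held-out frames so no test information leaks into
the preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateCropError, DomainError
from .synthetic import LVTracing

__all__ = ["CropMidpoints", "long_axis", "compute_midpoints", "crop_region"]


@dataclass(frozen=True)
class CropMidpoints:
    """Dataset-level crop midpoints; coordinates kept unrounded."""

    M1: tuple[float, float]
    M2: tuple[float, float]
    n_frames_averaged: int

    def __post_init__(self) -> None:
        if not self.M1[1] < self.M2[1]:
            raise DomainError(
                f"expected Y1 < Y2, got Y1={self.M1[1]}, Y2={self.M2[1]}")


def long_axis(tracing: LVTracing) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Return the long-axis endpoints and their Euclidean length in pixels."""
    top, bottom = tracing.long_axis_top, tracing.long_axis_bottom
    length = math.hypot(bottom[0] - top[0], bottom[1] - top[1])
    if length == 0.0:
        raise DomainError("degenerate long axis: top equals bottom")
    return top, bottom, length


def compute_midpoints(tracings: Sequence[LVTracing],
                      image_height: int | None = None) -> CropMidpoints:
    """Average per-frame long-axis midpoints into dataset-level M1 and M2.

    When ``image_height`` is given, each frame's bottom-of-image point is
    taken as ``(x_b, image_height - 1)``; otherwise the tracing's stored
    ``image_bottom`` is used.
    """
    if len(tracings) == 0:
        raise DomainError("need at least one tracing")
    x1 = y1 = x2 = y2 = 0.0
    for t in tracings:
        x_t, y_t = t.long_axis_top
        x_b, y_b = t.long_axis_bottom
        if image_height is not None:
            x_d, y_d = x_b, float(image_height - 1)
        else:
            x_d, y_d = t.image_bottom
        x1 += (x_t + x_b) / 2.0
        y1 += (y_t + y_b) / 2.0
        x2 += (x_b + x_d) / 2.0
        y2 += (y_b + y_d) / 2.0
    n = len(tracings)
    return CropMidpoints(M1=(x1 / n, y1 / n), M2=(x2 / n, y2 / n),
                         n_frames_averaged=n)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def crop_region(image: np.ndarray, mids: CropMidpoints,
                half_width: int | str = "full") -> np.ndarray:
    """Crop a frame to rows [round(Y1), round(Y2)).

    With ``half_width="full"`` all columns are kept; with an integer, the
    columns [round(X1) - half_width, round(X1) + half_width) are kept.
    Bounds are clipped to the image; an empty result raises. The output is
    a contiguous sub-grid of the input, never resampled.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    r1 = max(0, _round_half_away(mids.M1[1]))
    r2 = min(h, _round_half_away(mids.M2[1]))
    if half_width == "full":
        c1, c2 = 0, w
    else:
        if not isinstance(half_width, (int, np.integer)) or half_width <= 0:
            raise DomainError("half_width must be a positive integer or 'full'")
        cx = _round_half_away(mids.M1[0])
        c1, c2 = max(0, cx - int(half_width)), min(w, cx + int(half_width))
    if r2 <= r1 or c2 <= c1:
        raise DegenerateCropError(
            f"crop rows [{r1}, {r2}) cols [{c1}, {c2}) is empty for a "
            f"{h}x{w} image")
    return arr[r1:r2, c1:c2]
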