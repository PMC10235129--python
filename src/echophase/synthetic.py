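"""Seeded synthetic echocardiogram-like frames, labels and LV tracings.

Real apical-view echocardiograms show a bright cone-shaped scan sector on a
dark background, multiplicative speckle texture, and a dark left-ventricular
(LV) cavity whose cross-sectional area is smallest at end-systole (ES),
largest at end-diastole (ED) and in between for mid-cycle (Non-ESED) frames.
This module draws frames with exactly those properties, together with
EchoNet-style tracing metadata (a long-axis segment plus short-axis chords)
that is consistent with the drawn cavity, so that every downstream stage —
augmentation, cropping, training, evaluation — is testable without clinical
data.

Conventions: coordinates are 0-based ``(x=column, y=row)`` with rows
increasing downward; images are 8-bit grayscale in ``[0, 255]``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError, DomainError, InfeasibleError, MissingMetadataError

__all__ = [
    "Phase",
    "SyntheticConfig",
    "LVTracing",
    "FrameRecord",
    "generate_frame",
    "generate_dataset",
    "select_nonesed_index",
    "add_clutter",
    "write_frames",
    "write_manifest",
    "read_manifest",
    "write_tracings",
    "read_tracings",
]

#: Column order of the EchoNet "VolumeTracings" CSV dialect.
TRACING_COLUMNS = ["FileName", "X1", "Y1", "X2", "Y2", "Frame"]
MANIFEST_COLUMNS = ["file", "source_id", "label", "split"]


class Phase(str, enum.Enum):
    """Cardiac phase label of a frame."""

    ES = "ES"
    ED = "ED"
    NONESED = "NONESED"

    @classmethod
    def coerce(cls, value: "Phase | str") -> "Phase":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError as exc:
            raise DomainError(f"unknown phase {value!r}; expected one of "
                              f"{[p.value for p in cls]}") from exc


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic echo-frame generator.

    Cavity areas are expressed as fractions of the scan-sector area; the
    ES fraction must sit strictly below the Non-ESED band, which must sit
    strictly below the ED fraction, so that pixel counting can recover the
    phase ordering ES < Non-ESED < ED.
    """

    image_height: int = 112
    image_width: int = 112
    cavity_area_fraction_es: float = 0.05
    cavity_area_fraction_ed: float = 0.22
    nonesed_area_range: tuple[float, float] = (0.09, 0.17)
    speckle_scale: float = 0.5
    n_chords: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.n_chords < 1:
            raise ConfigError("n_chords must be >= 1")
        if self.speckle_scale < 0:
            raise ConfigError("speckle_scale must be >= 0")
        lo, hi = self.nonesed_area_range
        if not (self.cavity_area_fraction_es < lo <= hi < self.cavity_area_fraction_ed):
            raise ConfigError(
                "cavity area fractions must satisfy "
                "es < nonesed_low <= nonesed_high < ed; got "
                f"es={self.cavity_area_fraction_es}, range={self.nonesed_area_range}, "
                f"ed={self.cavity_area_fraction_ed}")


@dataclass(frozen=True)
class LVTracing:
    """One frame's LV tracing: a long-axis segment plus short-axis chords.

    ``long_axis_top`` is the apex end ``(x_t, y_t)``, ``long_axis_bottom``
    the mitral end ``(x_b, y_b)``, and ``image_bottom`` the point
    ``(x_d, y_d)`` vertically below the mitral end on the last image row.
    Chords are pairs of endpoints of horizontal short-axis distances.
    """

    long_axis_top: tuple[float, float]
    long_axis_bottom: tuple[float, float]
    image_bottom: tuple[float, float]
    chords: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        y_t = self.long_axis_top[1]
        y_b = self.long_axis_bottom[1]
        y_d = self.image_bottom[1]
        if not (y_t < y_b < y_d):
            raise DomainError(
                f"tracing must satisfy y_t < y_b < y_d, got {y_t}, {y_b}, {y_d}")


@dataclass
class FrameRecord:
    """A grayscale frame plus its phase label and optional tracing."""

    image: np.ndarray
    label: Phase
    tracing: LVTracing | None = None
    source_id: str = "synthetic"
    frame_index: int = 0

    @property
    def file_name(self) -> str:
        return f"{self.source_id}_{self.label.value}.png"


def _sector_mask(height: int, width: int) -> np.ndarray:
    """Boolean mask of the cone-shaped scan sector (apex at top centre)."""
    cx = (width - 1) / 2.0
    apex_y = 0.04 * height
    half_angle = math.radians(33.0)
    radius = 0.93 * height
    yy, xx = np.mgrid[0:height, 0:width]
    dy = yy - apex_y
    dx = xx - cx
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.arctan2(np.abs(dx), dy)  # angle from the downward vertical
    return (dy > 0) & (np.abs(ang) < half_angle) & (dx**2 + dy**2 < radius**2)


def _cavity_fraction(phase: Phase, cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    if phase is Phase.ES:
        return cfg.cavity_area_fraction_es
    if phase is Phase.ED:
        return cfg.cavity_area_fraction_ed
    lo, hi = cfg.nonesed_area_range
    return float(rng.uniform(lo, hi))


def generate_frame(phase: Phase | str, cfg: SyntheticConfig,
                   rng: np.random.Generator | None = None) -> FrameRecord:
    """Draw one synthetic frame of the given cardiac phase.

    The frame shows bright myocardial tissue with multiplicative Rayleigh
    speckle inside the scan sector and a dark elliptical LV cavity whose
    area fraction of the sector is set by the phase. The returned record
    carries a tracing whose long-axis endpoints lie on the drawn cavity's
    vertical long axis. Identical ``(phase, cfg, seed)`` triples produce
    bit-identical images.
    """
    phase = Phase.coerce(phase)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_height, cfg.image_width
    sector = _sector_mask(h, w)
    sector_area = int(sector.sum())
    if sector_area == 0:
        raise ConfigError(f"image {h}x{w} too small to contain a scan sector")

    frac = _cavity_fraction(phase, cfg, rng)
    # ellipse geometry: vertical semi-axis a, horizontal b = ratio * a
    ratio = float(rng.uniform(0.55, 0.70))
    a = math.sqrt(frac * sector_area / (math.pi * ratio))
    b = ratio * a
    cx = (w - 1) / 2.0 + float(rng.uniform(-0.02, 0.02)) * w
    cy = 0.42 * h + float(rng.uniform(-0.02, 0.02)) * h
    # keep the cavity inside the image with one row to spare below
    cy = min(cy, h - 2 - a)
    cy = max(cy, a + 1)

    yy, xx = np.mgrid[0:h, 0:w]
    cavity = (((xx - cx) / b) ** 2 + ((yy - cy) / a) ** 2) <= 1.0
    cavity &= sector

    tissue_level, cavity_level = 170.0, 28.0
    base = np.zeros((h, w), dtype=np.float64)
    base[sector] = tissue_level
    base[cavity] = cavity_level

    if cfg.speckle_scale > 0:
        # multiplicative Rayleigh speckle, normalised to unit mean, blended
        # with the clean image by speckle_scale (0 = clean, 1 = full speckle)
        ray = rng.rayleigh(scale=1.0, size=(h, w)) / math.sqrt(math.pi / 2.0)
        noise = (1.0 - cfg.speckle_scale) + cfg.speckle_scale * ray
        base = base * noise
    image = np.clip(base, 0.0, 255.0).astype(np.uint8)

    y_t, y_b = cy - a, cy + a
    chord_y = np.linspace(y_t, y_b, cfg.n_chords + 2)[1:-1]
    chords = []
    for y in chord_y:
        half = b * math.sqrt(max(0.0, 1.0 - ((y - cy) / a) ** 2))
        chords.append(((cx - half, float(y)), (cx + half, float(y))))
    tracing = LVTracing(
        long_axis_top=(cx, float(y_t)),
        long_axis_bottom=(cx, float(y_b)),
        image_bottom=(cx, float(h - 1)),
        chords=tuple(chords),
    )
    return FrameRecord(image=image, label=phase, tracing=tracing)


def select_nonesed_index(es_index: int, ed_index: int, n_frames: int,
                         rng: np.random.Generator | None = None) -> int:
    """Pick the Non-ESED frame index uniformly among frames that are
    neither the ES nor the ED frame of the video."""
    if n_frames < 3:
        raise InfeasibleError(
            f"need at least 3 frames to pick a Non-ESED frame, got {n_frames}")
    if es_index == ed_index:
        raise DomainError("ES and ED indices must differ")
    if not (0 <= es_index < n_frames and 0 <= ed_index < n_frames):
        raise DomainError("ES/ED indices must lie in [0, n_frames)")
    if rng is None:
        rng = np.random.default_rng()
    candidates = [i for i in range(n_frames) if i not in (es_index, ed_index)]
    return int(candidates[rng.integers(len(candidates))])


def generate_dataset(cfg: SyntheticConfig, n_videos: int,
                     rng: np.random.Generator | None = None,
                     split: str = "train") -> tuple[list[FrameRecord], pd.DataFrame]:
    """Generate ``3 * n_videos`` frames: one ES, one ED and one Non-ESED
    frame per synthetic "video", mirroring the three-frame-per-video
    selection rule, plus a manifest table (file, source_id, label, split)."""
    if n_videos < 1:
        raise ConfigError("n_videos must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    records: list[FrameRecord] = []
    rows = []
    for v in range(n_videos):
        source_id = f"vid{v:04d}"
        # emulate a short cine loop: ES/ED land on fixed indices, the
        # Non-ESED frame index is drawn from the remaining frames
        n_frames = 30
        es_i, ed_i = 10, 20
        non_i = select_nonesed_index(es_i, ed_i, n_frames, rng)
        for phase, idx in ((Phase.ES, es_i), (Phase.ED, ed_i), (Phase.NONESED, non_i)):
            rec = generate_frame(phase, cfg, rng)
            rec.source_id = source_id
            rec.frame_index = idx
            records.append(rec)
            rows.append({"file": rec.file_name, "source_id": source_id,
                         "label": phase.value, "split": split})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return records, manifest


def add_clutter(records: Sequence[FrameRecord], protected_rows: tuple[int, int],
                rng: np.random.Generator, n_blobs: int = 12,
                intensity_range: tuple[float, float] = (60.0, 255.0)) -> list[FrameRecord]:
    """Overlay bright random elliptical distractors outside a protected row
    band.

    Used by the cropping ablation: the phase-discriminative cavity signal
    stays inside ``protected_rows = (row_lo, row_hi)`` while heavy
    label-independent clutter is painted everywhere else, so a model seeing
    the full frame faces nuisance variation that a cropped model does not.
    Tracings and labels are preserved.
    """
    row_lo, row_hi = protected_rows
    out = []
    for rec in records:
        img = rec.image.astype(np.float64).copy()
        h, w = img.shape
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(n_blobs):
            if rng.random() < 0.5:
                cy = rng.uniform(0, max(row_lo, 1))
            else:
                cy = rng.uniform(min(row_hi, h - 1), h)
            cx = rng.uniform(0, w)
            ry = rng.uniform(2, 7)
            rx = rng.uniform(3, 12)
            level = rng.uniform(*intensity_range)
            blob = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2) <= 1.0
            blob[row_lo:row_hi, :] = False
            img[blob] = level
        clipped = np.clip(img, 0, 255).astype(np.uint8)
        out.append(replace_image(rec, clipped))
    return out


def replace_image(rec: FrameRecord, image: np.ndarray) -> FrameRecord:
    """Copy of ``rec`` with a different pixel grid."""
    return FrameRecord(image=image, label=rec.label, tracing=rec.tracing,
                       source_id=rec.source_id, frame_index=rec.frame_index)


# ---------------------------------------------------------------------------
# on-disk formats


def write_frames(records: Sequence[FrameRecord], directory: str | Path) -> list[Path]:
    """Save each frame as an 8-bit grayscale PNG named ``<source>_<label>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        p = directory / rec.file_name
        Image.fromarray(rec.image, mode="L").save(p)
        paths.append(p)
    return paths


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"manifest missing columns {sorted(missing)}")
    return df


def write_tracings(records: Sequence[FrameRecord], path: str | Path) -> None:
    """Write tracings in the EchoNet ``VolumeTracings`` CSV dialect.

    Columns are FileName, X1, Y1, X2, Y2, Frame; the first row for each
    frame is the long axis (top → bottom endpoint), subsequent rows are the
    short-axis chords. Coordinates round-trip exactly through the file.
    """
    rows = []
    for rec in records:
        if rec.tracing is None:
            raise MissingMetadataError(
                f"record {rec.source_id!r} ({rec.label.value}) has no tracing")
        t = rec.tracing
        rows.append({"FileName": rec.file_name,
                     "X1": t.long_axis_top[0], "Y1": t.long_axis_top[1],
                     "X2": t.long_axis_bottom[0], "Y2": t.long_axis_bottom[1],
                     "Frame": rec.frame_index})
        for (x1, y1), (x2, y2) in t.chords:
            rows.append({"FileName": rec.file_name, "X1": x1, "Y1": y1,
                         "X2": x2, "Y2": y2, "Frame": rec.frame_index})
    df = pd.DataFrame(rows, columns=TRACING_COLUMNS)
    # 17 significant digits keep the float round trip exact
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracings(path: str | Path,
                  image_height: int | None = None) -> dict[str, LVTracing]:
    """Read a VolumeTracings-dialect CSV back into per-frame tracings.

    The first row per (FileName, Frame) group is interpreted as the long
    axis; the rest as chords. ``image_bottom`` is reconstructed as the point
    on the last image row below the long-axis bottom when ``image_height``
    is given, otherwise from the stored bottom y plus the deepest chord.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACING_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"tracing file missing columns {sorted(missing)}")
    out: dict[str, LVTracing] = {}
    for (fname, _frame), grp in df.groupby(["FileName", "Frame"], sort=False):
        first = grp.iloc[0]
        top = (float(first.X1), float(first.Y1))
        bottom = (float(first.X2), float(first.Y2))
        chords = tuple((((float(r.X1), float(r.Y1)), (float(r.X2), float(r.Y2))))
                       for r in grp.iloc[1:].itertuples())
        if image_height is not None:
            y_d = float(image_height - 1)
        else:
            y_d = max(bottom[1] + 1.0, float(grp.Y2.max()) + 1.0)
        out[str(fname)] = LVTracing(long_axis_top=top, long_axis_bottom=bottom,
                                    image_bottom=(bottom[0], y_d), chords=chords)
    return out
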