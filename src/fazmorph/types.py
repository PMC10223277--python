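"""Core domain types shared across the pipeline.

Coordinate convention (fixed for serialization): ``x`` is the column index,
``y`` the row index, origin at the top-left corner, ``y`` increasing
downward.  Area and acircularity are invariant to this choice.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import MetadataError


class Plexus(str, enum.Enum):
    """Retinal capillary plexus imaged as an en-face OCTA slab."""

    SCP = "SCP"
    DCP = "DCP"


class Cohort(str, enum.Enum):
    """Patient group: type-1 diabetes, type-2 diabetes, or healthy control."""

    DM1 = "DM1"
    DM2 = "DM2"
    HEALTHY = "HEALTHY"


class Criterion(str, enum.Enum):
    """FAZ delimitation criterion.

    INITIAL: the region within the fovea without blood vessels (observers
    tend to trace the enclosing vessels).  FINAL: the inner boundary of the
    transition zone between the avascular and irrigated areas.
    """

    INITIAL = "INITIAL"
    FINAL = "FINAL"


def _coerce_enum(cls, value, name: str):
    if isinstance(value, cls):
        return value
    try:
        return cls(str(value).upper())
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise MetadataError(
            f"invalid {name} {value!r}; expected one of: {valid}"
        ) from None


@dataclass(frozen=True)
class ContourMeta:
    """Study metadata attached to one segmentation record."""

    eye_id: str
    plexus: Plexus
    cohort: Cohort
    observer: str
    series: int
    criterion: Criterion
    width_mm: float = 3.0
    image_cols: Optional[int] = None
    image_rows: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "plexus", _coerce_enum(Plexus, self.plexus, "plexus"))
        object.__setattr__(self, "cohort", _coerce_enum(Cohort, self.cohort, "cohort"))
        object.__setattr__(
            self, "criterion", _coerce_enum(Criterion, self.criterion, "criterion")
        )
        if self.series < 1:
            raise MetadataError(f"series must be >= 1, got {self.series}")
        if self.width_mm <= 0:
            raise MetadataError(f"width_mm must be > 0, got {self.width_mm}")

    @property
    def record_id(self) -> str:
        return (
            f"{self.eye_id}_{self.plexus.value}_{self.observer}{self.series}"
            f"_{self.criterion.value}"
        )

    def to_dict(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "plexus": self.plexus.value,
            "cohort": self.cohort.value,
            "observer": self.observer,
            "series": self.series,
            "criterion": self.criterion.value,
            "width_mm": self.width_mm,
            "image_cols": self.image_cols,
            "image_rows": self.image_rows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContourMeta":
        required = {"eye_id", "plexus", "cohort", "observer", "series", "criterion"}
        missing = required - set(k for k, v in d.items() if v is not None)
        if missing:
            raise MetadataError(f"missing metadata fields: {sorted(missing)}")
        return cls(
            eye_id=str(d["eye_id"]),
            plexus=d["plexus"],
            cohort=d["cohort"],
            observer=str(d["observer"]),
            series=int(d["series"]),
            criterion=d["criterion"],
            width_mm=float(d.get("width_mm", 3.0)),
            image_cols=None if d.get("image_cols") is None else int(d["image_cols"]),
            image_rows=None if d.get("image_rows") is None else int(d["image_rows"]),
        )


@dataclass
class PointSet:
    """Unordered overlay pixel coordinates extracted from an annotated image.

    ``points`` is an (N, 2) integer array of (x, y) = (column, row) pairs
    with no duplicate rows; real-valued point sets are also accepted for
    purely geometric use.
    """

    points: np.ndarray
    meta: Optional[ContourMeta] = None

    def __post_init__(self):
        pts = np.asarray(self.points)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got shape {pts.shape}")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PointSet):
            return NotImplemented
        return (
            self.meta == other.meta
            and self.points.shape == other.points.shape
            and bool(np.array_equal(self.points, other.points))
        )

    def translated(self, tx, ty) -> "PointSet":
        return PointSet(self.points + np.array([tx, ty]), self.meta)


@dataclass
class AnnotatedImage:
    """An 8-bit RGB en-face image with a FAZ perimeter line drawn over it."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    meta: ContourMeta

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # greyscale promoted to RGB on load
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (rows, cols, 3), got {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError("image must be at least 8x8 pixels")
        self.pixels = px.astype(np.uint8, copy=False)
        rows, cols = px.shape[:2]
        if self.meta.image_rows != rows or self.meta.image_cols != cols:
            self.meta = replace(self.meta, image_rows=rows, image_cols=cols)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class OverlaySpec:
    """Colour rule identifying one observer's drawn perimeter line."""

    target_colour: tuple = (255, 0, 0)
    tolerance: int = 30

    def __post_init__(self):
        if not (0 <= self.tolerance < 128):
            raise ValueError(
                "tolerance must be in [0, 128) to keep the overlay "
                "distinguishable from the background"
            )
        if len(self.target_colour) != 3:
            raise ValueError("target_colour must be an RGB triple")


@dataclass(frozen=True)
class PixelScale:
    """Physical length per pixel step along each image axis."""

    mm_per_px_x: float
    mm_per_px_y: float

    def __post_init__(self):
        if self.mm_per_px_x <= 0 or self.mm_per_px_y <= 0:
            raise ValueError("pixel scale must be strictly positive")

    @classmethod
    def isotropic(cls, mm_per_px: float) -> "PixelScale":
        return cls(mm_per_px, mm_per_px)

    @classmethod
    def from_meta(cls, meta: ContourMeta) -> "PixelScale":
        """Default scale: scan width divided by image dimension per axis."""
        if meta.image_cols is None or meta.image_rows is None:
            raise MetadataError(
                "image dimensions required to derive pixel scale "
                f"(record {meta.record_id})"
            )
        return cls(meta.width_mm / meta.image_cols, meta.width_mm / meta.image_rows)

    @property
    def px_area_mm2(self) -> float:
        return self.mm_per_px_x * self.mm_per_px_y
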