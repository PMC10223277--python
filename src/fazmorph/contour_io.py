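"""Overlay extraction from annotated images and contour file I/O.

Annotated OCTA exports carry the manually drawn FAZ perimeter as a
near-pure-colour line over a greyscale angiogram; the line pixels are
isolated by per-channel colour distance.  Contour coordinates are stored
either as a CSV of (x, y) integer pairs with a JSON metadata sidecar, or as
a single combined JSON file.
"""
from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import AmbiguousOverlayWarning, MetadataError, NoOverlayFound, ParseError
from .types import AnnotatedImage, ContourMeta, OverlaySpec, PointSet

__all__ = [
    "extract_overlay",
    "load_image",
    "read_contour_file",
    "write_contour_file",
]

_8CONN = np.ones((3, 3), dtype=bool)


def extract_overlay(
    image: AnnotatedImage,
    spec: OverlaySpec = OverlaySpec(),
    thin: bool = False,
) -> PointSet:
    """Return every pixel whose colour lies within tolerance of the target.

    Lines thicker than one pixel are kept whole by default — all matching
    pixels enter the point set — because the downstream azimuth sort and
    shoelace area are robust to a thin ring of pixels, while thinning would
    silently change measured areas.  ``thin=True`` applies morphological
    skeletonization for callers who want a 1-px trace.

    Raises :class:`NoOverlayFound` if no pixel matches; emits
    :class:`AmbiguousOverlayWarning` (with the component count) if the
    matching pixels form more than one 8-connected component.
    """
    target = np.asarray(spec.target_colour, dtype=np.int64)
    diff = np.abs(image.pixels.astype(np.int64) - target)
    mask = np.all(diff <= spec.tolerance, axis=-1)
    if not mask.any():
        raise NoOverlayFound(
            f"no pixel within tolerance {spec.tolerance} of colour "
            f"{tuple(spec.target_colour)} (record {image.meta.record_id})"
        )
    _, n_components = ndimage.label(mask, structure=_8CONN)
    if n_components > 1:
        warnings.warn(
            f"overlay colour {tuple(spec.target_colour)} matches "
            f"{n_components} connected components in record "
            f"{image.meta.record_id}",
            AmbiguousOverlayWarning,
            stacklevel=2,
        )
    if thin:
        from skimage.morphology import skeletonize

        mask = skeletonize(mask)
    rows, cols = np.nonzero(mask)
    points = np.column_stack([cols, rows]).astype(np.int64)  # (x, y)
    return PointSet(points, image.meta)


def load_image(path: Union[str, Path], meta: Optional[ContourMeta] = None) -> AnnotatedImage:
    """Load a TIFF/PNG export as 8-bit RGB (greyscale promoted).

    If ``meta`` is None, a JSON sidecar ``<stem>.json`` next to the image is
    required.
    """
    path = Path(path)
    if meta is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise MetadataError(f"no metadata sidecar found for image {path}")
        meta = ContourMeta.from_dict(json.loads(sidecar.read_text()))
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return AnnotatedImage(arr, meta)


def write_contour_file(points: PointSet, path: Union[str, Path]) -> Path:
    """Serialize a point set; inverse of :func:`read_contour_file`.

    A ``.csv`` path writes ``x,y`` rows plus a ``<stem>.json`` metadata
    sidecar; a ``.json`` path writes a single combined file.
    """
    if len(points) == 0:
        raise ValueError("refusing to write an empty point set")
    if points.meta is None:
        raise MetadataError("point set has no metadata to serialize")
    path = Path(path)
    try:
        if path.suffix.lower() == ".csv":
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["x", "y"])
                writer.writerows(np.asarray(points.points, dtype=np.int64).tolist())
            path.with_suffix(".json").write_text(
                json.dumps(points.meta.to_dict(), indent=1)
            )
        else:
            payload = {
                "points": np.asarray(points.points, dtype=np.int64).tolist(),
                "metadata": points.meta.to_dict(),
            }
            path.write_text(json.dumps(payload))
    except OSError as exc:
        raise OSError(f"failed writing contour file {path}: {exc}") from exc
    return path


def read_contour_file(path: Union[str, Path]) -> PointSet:
    """Read a contour file written by :func:`write_contour_file`.

    Accepts CSV (header ``x,y``) with a JSON sidecar, or combined JSON with
    ``points`` and ``metadata`` keys.

    Raises :class:`ParseError` on malformed content and
    :class:`MetadataError` on missing/invalid metadata enum values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"contour file not found: {path}")
    if path.suffix.lower() == ".csv":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise MetadataError(f"metadata sidecar {sidecar} missing for {path}")
        meta = ContourMeta.from_dict(_load_json(sidecar))
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != ["x", "y"]:
                raise ParseError(f"{path}: expected header 'x,y', got {header}")
            pts = []
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                try:
                    pts.append((int(row[0]), int(row[1])))
                except (ValueError, IndexError):
                    raise ParseError(f"{path}:{lineno}: malformed row {row!r}") from None
    else:
        payload = _load_json(path)
        if not isinstance(payload, dict) or "points" not in payload or "metadata" not in payload:
            raise ParseError(f"{path}: expected JSON with 'points' and 'metadata'")
        meta = ContourMeta.from_dict(payload["metadata"])
        try:
            pts = [(int(p[0]), int(p[1])) for p in payload["points"]]
        except (TypeError, ValueError, IndexError):
            raise ParseError(f"{path}: malformed points array") from None
    if not pts:
        raise ParseError(f"{path}: contour file holds no points")
    return PointSet(np.asarray(pts, dtype=np.int64), meta)


def _load_json(path: Path):
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from None
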