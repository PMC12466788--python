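"""Readers and writers for nuclear instance segmentation.

Two input dialects are supported:

* a Hover-Net-style JSON file per tile (or per-slide dictionary of tiles),
  where each instance carries a contour vertex list, a centroid and an
  integer type code;
* a labeled instance mask (2-D integer array, 0 = background) plus a
  label -> cell-type table, for annotated datasets that ship masks.

Both are normalized into :class:`TileSegmentation` records with contours in
0-based pixel coordinates (x rightward, y downward).  Contours are stored
open (last vertex != first) and closed implicitly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage import measure


class CellType(str, Enum):
    """Canonical nucleus classes used throughout the pipeline."""

    CANCER = "cancer"
    IMMUNE = "immune"
    FIBROBLAST = "fibroblast"
    EPITHELIAL = "epithelial"
    DEAD = "dead"
    UNKNOWN = "unknown"


#: Default integer type-code table (common PanNuke-trained convention:
#: 1 = neoplastic, 2 = inflammatory, 3 = connective, 4 = dead, 5 = epithelial,
#: 0 and anything unlisted = unknown).  Fully overridable because checkpoints
#: differ in their code tables.
DEFAULT_TYPE_CODES: dict[int, CellType] = {
    0: CellType.UNKNOWN,
    1: CellType.CANCER,
    2: CellType.IMMUNE,
    3: CellType.FIBROBLAST,
    4: CellType.DEAD,
    5: CellType.EPITHELIAL,
}

#: Inverse of :data:`DEFAULT_TYPE_CODES` used when writing JSON.
DEFAULT_CODE_OF_TYPE: dict[CellType, int] = {
    CellType.UNKNOWN: 0,
    CellType.CANCER: 1,
    CellType.IMMUNE: 2,
    CellType.FIBROBLAST: 3,
    CellType.DEAD: 4,
    CellType.EPITHELIAL: 5,
}


class SegmentationWarning(UserWarning):
    """Non-fatal record-level problems (skipped instances etc.)."""


class SegmentationError(ValueError):
    """Malformed segmentation input."""


def _as_cell_type(value) -> CellType:
    if isinstance(value, CellType):
        return value
    return CellType(str(value).lower())


@dataclass
class NucleusRecord:
    """One segmented nucleus: contour polygon, centroid and cell type."""

    nucleus_id: int
    contour: np.ndarray  # (n, 2) float array of (x, y) vertices
    centroid: tuple[float, float]
    cell_type: CellType = CellType.UNKNOWN

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2:
            raise SegmentationError(
                f"nucleus {self.nucleus_id}: contour must be an (n, 2) array"
            )


@dataclass
class TileSegmentation:
    """All nuclei segmented within one image tile."""

    tile_id: str
    origin: tuple[int, int] = (0, 0)
    size: tuple[int, int] = (512, 512)
    nuclei: list[NucleusRecord] = field(default_factory=list)

    def count(self, cell_type: CellType | None = None) -> int:
        if cell_type is None:
            return len(self.nuclei)
        return sum(1 for n in self.nuclei if n.cell_type == cell_type)


def _shoelace(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _valid_contour(vertices) -> np.ndarray | None:
    """Return an (n, 2) float contour array, or None if degenerate."""
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        return None
    if _shoelace(arr) <= 0.0:
        return None
    return arr


def _parse_instances(
    instances: Mapping, type_map: Mapping[int, CellType], source: str
) -> list[NucleusRecord]:
    def _key_order(k):
        s = str(k)
        return (0, int(s), "") if s.lstrip("-").isdigit() else (1, 0, s)

    records: list[NucleusRecord] = []
    bad: list[str] = []
    for key in sorted(instances, key=_key_order):
        inst = instances[key]
        if not isinstance(inst, Mapping):
            continue
        contour = _valid_contour(inst.get("contour"))
        if contour is None:
            bad.append(str(key))
            continue
        try:
            nucleus_id = int(key)
        except (TypeError, ValueError):
            nucleus_id = len(records) + 1
        centroid = inst.get("centroid")
        if centroid is None:
            centroid = contour.mean(axis=0)
        code = inst.get("type", 0)
        cell_type = type_map.get(int(code), CellType.UNKNOWN)
        records.append(
            NucleusRecord(
                nucleus_id=nucleus_id,
                contour=contour,
                centroid=(float(centroid[0]), float(centroid[1])),
                cell_type=_as_cell_type(cell_type),
            )
        )
    if bad:
        warnings.warn(
            f"{source}: skipped {len(bad)} instance(s) with missing or "
            f"degenerate contour (ids: {', '.join(bad)})",
            SegmentationWarning,
            stacklevel=3,
        )
    return records


def read_hovernet_json(
    path: str | Path,
    type_map: Mapping[int, CellType] | None = None,
    tile_id: str | None = None,
) -> TileSegmentation:
    """Read one tile's instance JSON.

    The file may either wrap instances under a ``"nuc"`` key (with optional
    ``tile_id`` / ``origin`` / ``size`` metadata) or be a flat dictionary
    keyed by instance id.  Instances lacking a usable contour (< 3 vertices
    or zero area) are skipped with a :class:`SegmentationWarning` naming the
    offending ids; valid instances are still returned.
    """
    path = Path(path)
    type_map = dict(DEFAULT_TYPE_CODES if type_map is None else type_map)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SegmentationError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(data, Mapping):
        raise SegmentationError(f"{path}: expected a JSON object at top level")

    if "nuc" in data and isinstance(data["nuc"], Mapping):
        instances = data["nuc"]
        meta_tile = data.get("tile_id")
        origin = tuple(data.get("origin", (0, 0)))
        size = tuple(data.get("size", (512, 512)))
    else:
        instances = {k: v for k, v in data.items() if isinstance(v, Mapping)}
        meta_tile, origin, size = None, (0, 0), (512, 512)

    records = _parse_instances(instances, type_map, str(path))
    return TileSegmentation(
        tile_id=tile_id or meta_tile or path.stem,
        origin=(int(origin[0]), int(origin[1])),
        size=(int(size[0]), int(size[1])),
        nuclei=records,
    )


def write_hovernet_json(
    tile: TileSegmentation,
    path: str | Path,
    code_of_type: Mapping[CellType, int] | None = None,
) -> None:
    """Write a tile back to the JSON dialect (round-trip safe)."""
    path = Path(path)
    path.write_text(json.dumps(_tile_payload(tile, code_of_type), sort_keys=True))


def _tile_payload(
    tile: TileSegmentation, code_of_type: Mapping[CellType, int] | None = None
) -> dict:
    codes = dict(DEFAULT_CODE_OF_TYPE if code_of_type is None else code_of_type)
    return {
        "tile_id": tile.tile_id,
        "origin": list(tile.origin),
        "size": list(tile.size),
        "nuc": {
            str(n.nucleus_id): {
                "contour": n.contour.tolist(),
                "centroid": [float(n.centroid[0]), float(n.centroid[1])],
                "type": codes[n.cell_type],
            }
            for n in tile.nuclei
        },
    }


def write_slide_json(
    path: str | Path,
    tiles: Sequence[TileSegmentation],
    slide_id: str,
    code_of_type: Mapping[CellType, int] | None = None,
) -> None:
    """Write a whole slide (dictionary of tiles) to one JSON file."""
    payload = {
        "slide_id": slide_id,
        "tiles": {t.tile_id: _tile_payload(t, code_of_type) for t in tiles},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_slide_json(
    path: str | Path, type_map: Mapping[int, CellType] | None = None
) -> tuple[str, list[TileSegmentation]]:
    """Read a per-slide dictionary of tiles written by :func:`write_slide_json`."""
    path = Path(path)
    type_map = dict(DEFAULT_TYPE_CODES if type_map is None else type_map)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SegmentationError(f"{path}: malformed JSON ({exc})") from exc
    if "tiles" not in data:
        raise SegmentationError(f"{path}: missing 'tiles' key")
    tiles = []
    for tile_id in sorted(data["tiles"]):
        payload = data["tiles"][tile_id]
        records = _parse_instances(payload.get("nuc", {}), type_map, f"{path}:{tile_id}")
        tiles.append(
            TileSegmentation(
                tile_id=tile_id,
                origin=tuple(payload.get("origin", (0, 0))),
                size=tuple(payload.get("size", (512, 512))),
                nuclei=records,
            )
        )
    return str(data.get("slide_id", path.stem)), tiles


def read_instance_mask(
    label_image: np.ndarray,
    types: Mapping[int, CellType | str] | None = None,
    tile_id: str = "mask",
    origin: tuple[int, int] = (0, 0),
) -> TileSegmentation:
    """Convert a labeled instance mask into a :class:`TileSegmentation`.

    Each positive label is one nucleus; its contour is traced along the 0.5
    iso-level of the label's binary mask (sub-pixel boundary following), so
    the polygon area tracks the label's pixel count closely.  Labels absent
    from ``types`` map to ``unknown``.  Instance labels, not connectivity,
    define nuclei: touching regions with different labels stay distinct.
    """
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer):
        raise TypeError("label image must have an integer dtype")
    if label_image.ndim != 2:
        raise SegmentationError("label image must be 2-D")
    types = types or {}

    records: list[NucleusRecord] = []
    skipped: list[int] = []
    padded = np.pad(label_image, 1)
    for label in np.unique(label_image):
        if label <= 0:
            continue
        binary = (padded == label).astype(float)
        contours = measure.find_contours(binary, 0.5)
        if not contours:
            skipped.append(int(label))
            continue
        boundary = max(contours, key=len)
        if np.allclose(boundary[0], boundary[-1]):
            boundary = boundary[:-1]
        # find_contours returns (row, col) in padded coordinates
        contour = np.column_stack([boundary[:, 1] - 1.0, boundary[:, 0] - 1.0])
        valid = _valid_contour(contour)
        if valid is None:
            skipped.append(int(label))
            continue
        rows, cols = np.nonzero(label_image == label)
        centroid = (float(cols.mean()), float(rows.mean()))
        cell_type = _as_cell_type(types.get(int(label), CellType.UNKNOWN))
        records.append(
            NucleusRecord(
                nucleus_id=int(label),
                contour=valid,
                centroid=centroid,
                cell_type=cell_type,
            )
        )
    if skipped:
        warnings.warn(
            f"{tile_id}: skipped labels with degenerate boundaries: {skipped}",
            SegmentationWarning,
            stacklevel=2,
        )
    height, width = label_image.shape
    return TileSegmentation(
        tile_id=tile_id, origin=origin, size=(width, height), nuclei=records
    )


def tile_image(
    image: np.ndarray, tile_size: int = 512
) -> list[tuple[str, tuple[int, int], np.ndarray]]:
    """Split an image into a non-overlapping grid of square tiles.

    Tiles are emitted in row-major order as ``(tile_id, (x, y) origin,
    pixel block)``; partial tiles at the right/bottom edges are dropped.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise SegmentationError("expected a 2-D or 3-D pixel array")
    height, width = image.shape[:2]
    if height < tile_size or width < tile_size:
        raise SegmentationError(
            f"image {width}x{height} smaller than one {tile_size}px tile"
        )
    tiles = []
    for row in range(height // tile_size):
        for col in range(width // tile_size):
            x, y = col * tile_size, row * tile_size
            block = image[y : y + tile_size, x : x + tile_size]
            tiles.append((f"r{row:03d}_c{col:03d}", (x, y), block))
    return tiles
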