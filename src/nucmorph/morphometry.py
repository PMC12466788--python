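"""Per-nucleus shape descriptors computed from a contour polygon.

Six characteristics are measured for every nucleus: major and minor axis
lengths, perimeter, area, eccentricity and circularity.  Area, perimeter and
the minimum-area rotated bounding rectangle come from shapely; the derived
quantities use the standard definitions

    eccentricity = sqrt(1 - (minor / major)**2)
    circularity  = 4 * pi * area / perimeter**2

so circularity is 1 for a circle and decreases for irregular shapes
(isoperimetric inequality guarantees <= 1 for simple polygons), and
eccentricity is 0 for a shape whose bounding rectangle is square.

Axis lengths default to the side lengths of the minimum-area rotated
bounding rectangle; ``method="moment_ellipse"`` switches to the axes of the
ellipse with the same normalized second central moments as the polygon
(the regionprops convention), since axis conventions differ between
toolkits and neither is canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .segmentation_io import TileSegmentation

AxisMethod = Literal["min_rect", "moment_ellipse"]

#: Feature order used across the pipeline.
MORPHOLOGY_COLUMNS = [
    "major_axis",
    "minor_axis",
    "perimeter",
    "area",
    "eccentricity",
    "circularity",
]


class DegenerateContourError(ValueError):
    """Contour cannot support shape measurement (too few vertices, zero area,
    or self-intersection)."""


@dataclass(frozen=True)
class NucleusMorphology:
    """The six morphological characteristics of one nucleus."""

    major_axis: float
    minor_axis: float
    perimeter: float
    area: float
    eccentricity: float
    circularity: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in MORPHOLOGY_COLUMNS}


def _polygon(contour) -> Polygon:
    arr = np.asarray(contour, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateContourError("contour needs at least 3 (x, y) vertices")
    poly = Polygon(arr)
    if not poly.is_valid:
        raise DegenerateContourError("contour is not a simple polygon")
    if poly.area <= 0.0:
        raise DegenerateContourError("contour has zero area")
    return poly


def polygon_area(contour) -> float:
    """Absolute (orientation-independent) polygon area in px^2."""
    return float(_polygon(contour).area)


def polygon_perimeter(contour) -> float:
    """Sum of Euclidean edge lengths including the closing edge, in px."""
    return float(_polygon(contour).length)


def _min_rect_axes(poly: Polygon) -> tuple[float, float]:
    """Side lengths of the minimum-area rotated bounding rectangle.

    Rotating calipers over the convex-hull edge orientations: the minimal
    rectangle has one side collinear with a hull edge, so scanning every
    edge direction is exact (and stable under rotation/scaling, unlike
    GEOS's oriented envelope, which is approximate in some versions).
    """
    hull = np.asarray(poly.convex_hull.exterior.coords)[:-1]
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    dirs = edges[lengths > 0] / lengths[lengths > 0, None]
    normals = np.column_stack([-dirs[:, 1], dirs[:, 0]])
    along = hull @ dirs.T
    across = hull @ normals.T
    widths = along.max(axis=0) - along.min(axis=0)
    heights = across.max(axis=0) - across.min(axis=0)
    areas = widths * heights
    # ties in minimal area are possible (e.g. symmetric hulls); break them by
    # the scale- and rotation-invariant aspect ratio so the result is stable
    near = areas <= areas.min() * (1.0 + 1e-9)
    aspect = np.maximum(widths, heights) / np.minimum(widths, heights)
    best = int(np.flatnonzero(near)[np.argmax(aspect[near])])
    return (
        float(max(widths[best], heights[best])),
        float(min(widths[best], heights[best])),
    )


def _moment_ellipse_axes(poly: Polygon) -> tuple[float, float]:
    """Axes of the ellipse with the polygon's normalized second moments."""
    coords = np.asarray(poly.exterior.coords)
    x, y = coords[:-1, 0], coords[:-1, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    sxx = ((x**2 + x * x1 + x1**2) * cross).sum() / 12.0 - area * cx**2
    syy = ((y**2 + y * y1 + y1**2) * cross).sum() / 12.0 - area * cy**2
    sxy = (
        (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross
    ).sum() / 24.0 - area * cx * cy
    cov = np.array([[sxx, sxy], [sxy, syy]]) / area
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    minor, major = (4.0 * np.sqrt(eigvals)).tolist()
    return float(major), float(minor)


def axis_lengths(contour, method: AxisMethod = "min_rect") -> tuple[float, float]:
    """(major, minor) axis lengths of the contour, major >= minor."""
    poly = _polygon(contour)
    if method == "min_rect":
        return _min_rect_axes(poly)
    if method == "moment_ellipse":
        return _moment_ellipse_axes(poly)
    raise ValueError(f"unknown axis method: {method!r}")


def compute_morphology(
    contour, method: AxisMethod = "min_rect"
) -> NucleusMorphology:
    """All six shape characteristics of one contour."""
    poly = _polygon(contour)
    area = float(poly.area)
    perimeter = float(poly.length)
    if method == "min_rect":
        major, minor = _min_rect_axes(poly)
    else:
        major, minor = _moment_ellipse_axes(poly)
    ratio = min(minor / major, 1.0) if major > 0 else 1.0
    eccentricity = math.sqrt(max(1.0 - ratio**2, 0.0))
    circularity = 4.0 * math.pi * area / perimeter**2
    return NucleusMorphology(
        major_axis=major,
        minor_axis=minor,
        perimeter=perimeter,
        area=area,
        eccentricity=eccentricity,
        circularity=circularity,
    )


def morphology_table(
    tiles: Iterable[TileSegmentation], method: AxisMethod = "min_rect"
) -> pd.DataFrame:
    """Per-nucleus morphology for every nucleus in the given tiles.

    Returns a DataFrame with columns ``tile_id``, ``nucleus_id``,
    ``cell_type`` and the six morphology columns.  A degenerate contour
    aborts with an error naming the tile and nucleus.
    """
    rows = []
    for tile in tiles:
        for nucleus in tile.nuclei:
            try:
                morph = compute_morphology(nucleus.contour, method=method)
            except DegenerateContourError as exc:
                raise DegenerateContourError(
                    f"tile {tile.tile_id} nucleus {nucleus.nucleus_id}: {exc}"
                ) from exc
            rows.append(
                {
                    "tile_id": tile.tile_id,
                    "nucleus_id": nucleus.nucleus_id,
                    "cell_type": nucleus.cell_type.value,
                    **morph.as_dict(),
                }
            )
    columns = ["tile_id", "nucleus_id", "cell_type", *MORPHOLOGY_COLUMNS]
    return pd.DataFrame(rows, columns=columns)
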