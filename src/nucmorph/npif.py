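"""Tumor-enriched tile selection and slide/patient-level nuclear features.

A whole slide is summarized by 12 nuclear features: the mean and sample
standard deviation of each of the six per-nucleus shape characteristics,
pooled over the nuclei of a target cell type (cancer by default) inside the
most target-enriched tiles.  Tiles with no target nucleus are discarded,
the remainder are ranked by their proportion of target nuclei, the top
fraction (default 25%) is kept, and the nuclei within those tiles are
pooled — not tile-averaged — before taking mean and SD.  Patient-level
features are the unweighted mean of the patient's slide-level features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import AxisMethod, morphology_table
from .segmentation_io import CellType, TileSegmentation

#: Short feature names in the order used for the 12 slide-level features.
FEATURE_NAMES = [
    "MajorAxis",
    "MinorAxis",
    "Perimeter",
    "Area",
    "Eccentricity",
    "Circularity",
]

#: Mapping from feature name to per-nucleus morphology column.
_MORPH_COLUMN = {
    "MajorAxis": "major_axis",
    "MinorAxis": "minor_axis",
    "Perimeter": "perimeter",
    "Area": "area",
    "Eccentricity": "eccentricity",
    "Circularity": "circularity",
}

#: Column names of the 12 features: Mean_MajorAxis ... SD_Circularity.
NPIF_COLUMNS = [f"Mean_{f}" for f in FEATURE_NAMES] + [f"SD_{f}" for f in FEATURE_NAMES]

#: Tile fractions scanned when calibrating the enrichment cutoff.
DEFAULT_SWEEP_FRACTIONS = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2)) + (1.0,)


class EmptyRankingError(ValueError):
    """No tile contains a target nucleus."""


@dataclass(frozen=True)
class TileEnrichment:
    """Target-cell enrichment of one tile."""

    tile_id: str
    n_target: int
    n_total: int

    @property
    def enrichment(self) -> float:
        return self.n_target / self.n_total


@dataclass
class NPIFVector:
    """The 12 mean/SD nuclear features for one slide or patient."""

    values: pd.Series  # indexed by NPIF_COLUMNS
    target: CellType = CellType.CANCER
    fraction: float = 0.25
    n_nuclei: int = 0
    n_tiles: int = 0
    n_slides: int = 1

    def __post_init__(self) -> None:
        self.values = self.values.reindex(NPIF_COLUMNS).astype(float)


def rank_tiles(
    tiles: Sequence[TileSegmentation],
    target: CellType = CellType.CANCER,
    slide_id: str = "",
) -> list[TileEnrichment]:
    """Rank tiles by target-nucleus proportion, descending.

    Tiles with zero target nuclei are removed before ranking.  Ties in
    proportion break by raw target count (descending), then tile id
    (lexicographic), so the ordering is deterministic.
    """
    viable = [
        TileEnrichment(t.tile_id, t.count(target), t.count())
        for t in tiles
        if t.count(target) >= 1
    ]
    if not viable:
        raise EmptyRankingError(
            f"no tile contains a {target.value} nucleus"
            + (f" (slide {slide_id})" if slide_id else "")
        )
    return sorted(viable, key=lambda e: (-e.enrichment, -e.n_target, e.tile_id))


def select_top_fraction(
    ranked: Sequence[TileEnrichment], fraction: float = 0.25
) -> list[TileEnrichment]:
    """First ceil(fraction * n) tiles of a ranking (at least one)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not ranked:
        raise ValueError("empty ranking")
    k = math.ceil(fraction * len(ranked))
    return list(ranked[:k])


def compute_npifs(
    morphology: pd.DataFrame,
    selected: Sequence[TileEnrichment],
    target: CellType = CellType.CANCER,
    fraction: float = 0.25,
) -> NPIFVector:
    """Pool target nuclei across the selected tiles and take mean/SD.

    ``morphology`` is a per-nucleus table as returned by
    :func:`nucmorph.morphometry.morphology_table`.  SD is the sample
    standard deviation (divisor n-1); a single-nucleus pool yields SD = 0
    with a warning.
    """
    tile_ids = {e.tile_id for e in selected}
    pool = morphology[
        morphology["tile_id"].isin(tile_ids)
        & (morphology["cell_type"] == target.value)
    ]
    if pool.empty:
        raise ValueError("no target nuclei in the selected tiles")
    if len(pool) == 1:
        warnings.warn(
            "single-nucleus pool: all SD features set to 0", UserWarning, stacklevel=2
        )
    values = {}
    for name, col in _MORPH_COLUMN.items():
        x = pool[col].to_numpy(dtype=float)
        values[f"Mean_{name}"] = float(x.mean())
        values[f"SD_{name}"] = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return NPIFVector(
        values=pd.Series(values),
        target=target,
        fraction=fraction,
        n_nuclei=len(pool),
        n_tiles=len(tile_ids),
    )


def extract_slide_npifs(
    tiles: Sequence[TileSegmentation],
    target: CellType = CellType.CANCER,
    fraction: float = 0.25,
    morphology: pd.DataFrame | None = None,
    axis_method: AxisMethod = "min_rect",
    slide_id: str = "",
) -> NPIFVector:
    """Full slide-level extraction: rank, select top fraction, pool, summarize."""
    if morphology is None:
        morphology = morphology_table(tiles, method=axis_method)
    ranked = rank_tiles(tiles, target=target, slide_id=slide_id)
    selected = select_top_fraction(ranked, fraction=fraction)
    return compute_npifs(morphology, selected, target=target, fraction=fraction)


def aggregate_patient(slide_vectors: Sequence[NPIFVector]) -> NPIFVector:
    """Average slide-level vectors into one patient-level vector."""
    if not slide_vectors:
        raise ValueError("need at least one slide vector")
    first = slide_vectors[0]
    for v in slide_vectors[1:]:
        if v.target != first.target:
            raise ValueError("slide vectors disagree on target cell type")
        if list(v.values.index) != list(first.values.index):
            raise ValueError("slide vectors have mismatched feature sets")
    stacked = pd.concat([v.values for v in slide_vectors], axis=1)
    return NPIFVector(
        values=stacked.mean(axis=1),
        target=first.target,
        fraction=first.fraction,
        n_nuclei=sum(v.n_nuclei for v in slide_vectors),
        n_tiles=sum(v.n_tiles for v in slide_vectors),
        n_slides=len(slide_vectors),
    )


def npif_table(vectors: Mapping[str, NPIFVector], id_name: str = "slide_id") -> pd.DataFrame:
    """Tabulate a mapping of id -> NPIFVector into one row per id."""
    rows = []
    for key in vectors:
        v = vectors[key]
        rows.append(
            {
                id_name: key,
                **v.values.to_dict(),
                "target_type": v.target.value,
                "fraction": v.fraction,
                "n_nuclei": v.n_nuclei,
                "n_tiles": v.n_tiles,
                "n_slides": v.n_slides,
            }
        )
    return pd.DataFrame(rows)


def cutoff_sweep(
    slides: Mapping[str, Sequence[TileSegmentation]],
    reference: pd.DataFrame,
    target: CellType = CellType.CANCER,
    fractions: Sequence[float] = DEFAULT_SWEEP_FRACTIONS,
    morphology: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Concordance of extracted features with a reference table per cutoff.

    For each tile fraction, slide-level features are extracted and compared
    with ``reference`` (indexed by slide id, columns = feature names) by
    Spearman correlation across the shared slides.  Returns the long-format
    table (fraction, feature, rho, pvalue, n_slides) and the fraction with
    the highest mean rho over features.
    """
    shared = [s for s in slides if s in reference.index]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 slides shared with the reference table, got {len(shared)}"
        )
    if morphology is None:
        morphology = {s: morphology_table(slides[s]) for s in shared}
    features = [c for c in NPIF_COLUMNS if c in reference.columns]

    rows = []
    for fraction in fractions:
        extracted = {}
        for s in shared:
            extracted[s] = extract_slide_npifs(
                slides[s],
                target=target,
                fraction=fraction,
                morphology=morphology[s],
                slide_id=s,
            ).values
        table = pd.DataFrame(extracted).T.loc[shared]
        for feat in features:
            rho, p = stats.spearmanr(table[feat], reference.loc[shared, feat])
            rows.append(
                {
                    "fraction": fraction,
                    "feature": feat,
                    "rho": float(rho),
                    "pvalue": float(p),
                    "n_slides": len(shared),
                }
            )
    result = pd.DataFrame(rows)
    mean_rho = result.groupby("fraction")["rho"].mean()
    best_fraction = float(mean_rho.idxmax())
    return result, best_fraction
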