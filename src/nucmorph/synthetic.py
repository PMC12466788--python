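"""Synthetic tiles, cohorts and survival data with known generative truth.

Nuclei are non-overlapping ellipses placed by rejection sampling; each cell
type in a subtype profile has a Poisson count per tile, a Normal area
distribution (px^2 at nominal 20x, 512x512 tiles) and a Beta-distributed
eccentricity.  The default three profiles encode the qualitative pattern
that aggressive subtypes show stronger nuclear pleomorphism: the HER2+-like
and TNBC-like profiles use large cancer-nucleus area spread (SD 110 px^2,
mean 380), the HR+-like profile a tight one (SD 30, mean 300); the
TNBC-like profile additionally skews toward elongated (high-eccentricity)
nuclei so the two aggressive profiles remain mutually distinguishable.
Marker-status templates make the label-derivation rules reproduce each
profile's intended subtype exactly.

Between-patient heterogeneity enters as a small jitter of each patient's
area mean/SD and eccentricity shape, so classifiers face a realistic
within-subtype spread rather than pure counting noise.

Survival times follow a proportional-hazards exponential model on z-scored
features (betas are log hazard ratios per feature SD); censoring is
independent uniform with its upper bound calibrated to the requested
censoring fraction.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation_io import CellType, NucleusRecord, TileSegmentation

#: Vertices used for the polygonal ellipse approximation of a nucleus.
ELLIPSE_VERTICES = 64


@dataclass(frozen=True)
class CellParams:
    """Generative parameters of one cell type within a subtype profile."""

    rate: float  # expected nuclei per 512x512 tile (Poisson)
    area_mean: float  # px^2
    area_sd: float  # px^2
    ecc_alpha: float  # Beta shape parameters for eccentricity
    ecc_beta: float

    def __post_init__(self) -> None:
        if self.rate < 0 or self.area_sd < 0:
            raise ValueError("rates and SDs must be non-negative")
        if self.ecc_alpha <= 0 or self.ecc_beta <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True)
class SubtypeProfile:
    """Everything needed to simulate one subtype's patients."""

    name: str
    markers: tuple[str, str, str]  # (her2, er, pr) status template
    cells: Mapping[CellType, CellParams]
    log_hazards: Mapping[str, float] = field(default_factory=dict)
    area_mean_jitter: float = 25.0  # patient-level SD of the area mean, px^2
    area_sd_jitter: float = 0.15  # relative patient-level spread of area SD


def default_profiles() -> list[SubtypeProfile]:
    """The three default subtype profiles (see module docstring)."""
    stroma = {
        CellType.IMMUNE: CellParams(8, 80, 15, 2, 2),
        CellType.FIBROBLAST: CellParams(4, 150, 40, 8, 2),
    }
    return [
        SubtypeProfile(
            name="HER2+",
            markers=("positive", "negative", "negative"),
            cells={CellType.CANCER: CellParams(15, 380, 110, 2, 4), **stroma},
            log_hazards={"SD_Area": 0.8},
        ),
        SubtypeProfile(
            name="HR+",
            markers=("negative", "positive", "positive"),
            cells={CellType.CANCER: CellParams(15, 300, 30, 2, 4), **stroma},
            log_hazards={"SD_Area": 0.8},
        ),
        SubtypeProfile(
            name="TNBC",
            markers=("negative", "negative", "negative"),
            cells={CellType.CANCER: CellParams(15, 380, 110, 6, 2), **stroma},
            log_hazards={"SD_Area": 0.8},
        ),
    ]


def _ellipse_contour(
    cx: float, cy: float, a: float, b: float, theta: float, n: int = ELLIPSE_VERTICES
) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    x = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    y = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    return np.column_stack([x, y])


def _ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


@dataclass
class SyntheticTile:
    """One simulated tile: segmentation, generative truth, optional raster."""

    segmentation: TileSegmentation
    truth: pd.DataFrame
    mask: np.ndarray | None = None  # uint16 instance labels
    image: np.ndarray | None = None  # uint8 grayscale render


def generate_tile(
    profile: SubtypeProfile,
    rng: np.random.Generator,
    tile_id: str = "tile",
    tile_size: int = 512,
    render: bool = False,
    max_tries: int = 50,
) -> SyntheticTile:
    """Simulate one tile of non-overlapping elliptical nuclei.

    Placement uses rejection sampling on bounding circles; if a nucleus
    cannot be placed within ``max_tries`` attempts the tile is emitted with
    fewer nuclei and a warning.
    """
    requests: list[tuple[CellType, CellParams]] = []
    for cell_type in sorted(profile.cells, key=lambda c: c.value):
        params = profile.cells[cell_type]
        for _ in range(rng.poisson(params.rate)):
            requests.append((cell_type, params))

    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    nuclei: list[NucleusRecord] = []
    truth_rows = []
    dropped = 0
    for cell_type, params in requests:
        area = max(float(rng.normal(params.area_mean, params.area_sd)), 30.0)
        ecc = 0.95 * float(rng.beta(params.ecc_alpha, params.ecc_beta))
        ratio = np.sqrt(1.0 - ecc**2)  # b/a
        a = np.sqrt(area / (np.pi * ratio))
        b = a * ratio
        theta = float(rng.uniform(0.0, np.pi))
        for _ in range(max_tries):
            cx = float(rng.uniform(a + 1, tile_size - a - 1))
            cy = float(rng.uniform(a + 1, tile_size - a - 1))
            if all(np.hypot(cx - px, cy - py) > a + pr + 1.0 for px, py, pr in placed):
                break
        else:
            dropped += 1
            continue
        placed.append((cx, cy, a))
        nucleus_id = len(nuclei) + 1
        nuclei.append(
            NucleusRecord(
                nucleus_id=nucleus_id,
                contour=_ellipse_contour(cx, cy, a, b, theta),
                centroid=(cx, cy),
                cell_type=cell_type,
            )
        )
        perimeter = _ramanujan_perimeter(a, b)
        truth_rows.append(
            {
                "tile_id": tile_id,
                "nucleus_id": nucleus_id,
                "cell_type": cell_type.value,
                "major_axis": 2.0 * a,
                "minor_axis": 2.0 * b,
                "perimeter": perimeter,
                "area": np.pi * a * b,
                "eccentricity": ecc,
                "circularity": 4.0 * np.pi * (np.pi * a * b) / perimeter**2,
            }
        )
    if dropped:
        warnings.warn(
            f"{tile_id}: dropped {dropped} nucleus(ei) after {max_tries} "
            "placement attempts",
            UserWarning,
            stacklevel=2,
        )

    segmentation = TileSegmentation(
        tile_id=tile_id, size=(tile_size, tile_size), nuclei=nuclei
    )
    truth = pd.DataFrame(truth_rows)
    mask = image = None
    if render:
        from skimage.draw import polygon as draw_polygon

        mask = np.zeros((tile_size, tile_size), dtype=np.uint16)
        for n in segmentation.nuclei:
            rr, cc = draw_polygon(
                n.contour[:, 1], n.contour[:, 0], shape=mask.shape
            )
            mask[rr, cc] = n.nucleus_id
        image = np.full((tile_size, tile_size), 235, dtype=np.uint8)
        image[mask > 0] = 90
    return SyntheticTile(segmentation=segmentation, truth=truth, mask=mask, image=image)


def _patient_profile(
    profile: SubtypeProfile, rng: np.random.Generator
) -> tuple[SubtypeProfile, dict[str, float]]:
    """Perturb the cancer-cell parameters to give each patient its own
    generative distribution; returns the perturbed profile + truth row."""
    cancer = profile.cells[CellType.CANCER]
    mean_p = cancer.area_mean + float(rng.normal(0.0, profile.area_mean_jitter))
    sd_p = cancer.area_sd * float(
        rng.uniform(1.0 - profile.area_sd_jitter, 1.0 + profile.area_sd_jitter)
    )
    alpha_p = cancer.ecc_alpha * float(rng.uniform(0.9, 1.1))
    cells = dict(profile.cells)
    cells[CellType.CANCER] = replace(
        cancer, area_mean=mean_p, area_sd=sd_p, ecc_alpha=alpha_p
    )
    truth = {
        "mean_area": mean_p,
        "sd_area": sd_p,
        "mean_eccentricity": 0.95 * alpha_p / (alpha_p + cancer.ecc_beta),
    }
    return replace(profile, cells=cells), truth


@dataclass
class Cohort:
    """A simulated multi-patient cohort."""

    slides: dict[str, list[TileSegmentation]]  # slide_id -> tiles
    slide_patient: dict[str, str]  # slide_id -> patient_id
    clinical: pd.DataFrame  # patient_id, her2, er, pr, age, subtype
    truth: pd.DataFrame  # per-patient generative parameters


def generate_cohort(
    profiles: Sequence[SubtypeProfile] | None = None,
    n_patients: int = 100,
    tiles_per_slide: int = 6,
    slides_per_patient: int = 1,
    seed: int = 0,
    tile_size: int = 512,
) -> Cohort:
    """Simulate ``n_patients`` patients per subtype profile."""
    profiles = list(default_profiles() if profiles is None else profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 subtype profiles")
    rng = np.random.default_rng(seed)
    slides: dict[str, list[TileSegmentation]] = {}
    slide_patient: dict[str, str] = {}
    clinical_rows = []
    truth_rows = []
    for profile in profiles:
        for i in range(n_patients):
            patient_id = f"{profile.name}_{i:03d}"
            pprofile, truth = _patient_profile(profile, rng)
            for s in range(slides_per_patient):
                slide_id = f"{patient_id}-S{s}"
                tiles = [
                    generate_tile(
                        pprofile,
                        rng,
                        tile_id=f"{slide_id}_t{t:03d}",
                        tile_size=tile_size,
                    ).segmentation
                    for t in range(tiles_per_slide)
                ]
                slides[slide_id] = tiles
                slide_patient[slide_id] = patient_id
            her2, er, pr = profile.markers
            clinical_rows.append(
                {
                    "patient_id": patient_id,
                    "her2": her2,
                    "er": er,
                    "pr": pr,
                    "age": float(np.clip(rng.normal(58.0, 12.0), 30.0, 90.0)),
                    "subtype": profile.name,
                }
            )
            truth_rows.append({"patient_id": patient_id, "subtype": profile.name, **truth})
    return Cohort(
        slides=slides,
        slide_patient=slide_patient,
        clinical=pd.DataFrame(clinical_rows),
        truth=pd.DataFrame(truth_rows),
    )


def generate_survival(
    features: pd.DataFrame,
    betas: Mapping[str, float],
    censoring: float = 0.4,
    seed: int = 0,
    baseline_rate: float = 1.0 / 1000.0,
    id_col: str = "patient_id",
) -> pd.DataFrame:
    """Proportional-hazards exponential survival times for a feature table.

    ``betas`` are log hazard ratios per standard deviation of each named
    feature (features are z-scored internally).  Censoring is independent
    uniform on (0, c_max] with c_max chosen by bisection so the realized
    censoring fraction matches the request.
    """
    if not 0.0 <= censoring <= 0.95:
        raise ValueError("censoring fraction must be in [0, 0.95]")
    missing = [k for k in betas if k not in features.columns]
    if missing:
        raise KeyError(f"betas reference unknown feature(s): {', '.join(missing)}")
    rng = np.random.default_rng(seed)
    n = len(features)
    lp = np.zeros(n)
    for name, beta in betas.items():
        x = features[name].to_numpy(dtype=float)
        sd = x.std()
        if sd > 0:
            lp += beta * (x - x.mean()) / sd
    rate = baseline_rate * np.exp(lp)
    event_times = rng.exponential(1.0 / rate)

    if censoring == 0.0:
        time, event = event_times, np.ones(n, dtype=int)
    else:
        u = rng.uniform(size=n)
        target = int(round(censoring * n))
        lo, hi = 1e-6 * event_times.mean(), 1e4 * event_times.mean()
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            censored = int((mid * u < event_times).sum())
            if censored > target:
                lo = mid
            else:
                hi = mid
        c = np.sqrt(lo * hi) * u
        event = (event_times <= c).astype(int)
        time = np.minimum(event_times, c)

    out = pd.DataFrame(
        {
            id_col: features[id_col] if id_col in features.columns else features.index,
            "time": time,
            "event": event,
        }
    )
    return out.reset_index(drop=True)
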