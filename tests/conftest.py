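"""Shared fixtures: synthetic cohorts and geometry helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from nucmorph import npif, synthetic


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12) -> np.ndarray:
    """Convex hull of random points; always a simple convex polygon."""
    pts = rng.normal(0.0, 5.0, size=(n_points, 2)) + rng.uniform(10, 100, size=2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def extract_cohort_features(cohort: synthetic.Cohort) -> pd.DataFrame:
    """Slide -> patient feature table merged with clinical labels."""
    by_patient: dict[str, list[npif.NPIFVector]] = {}
    for slide_id in sorted(cohort.slides):
        vec = npif.extract_slide_npifs(cohort.slides[slide_id], slide_id=slide_id)
        by_patient.setdefault(cohort.slide_patient[slide_id], []).append(vec)
    patient_vectors = {
        pid: npif.aggregate_patient(vecs) for pid, vecs in by_patient.items()
    }
    table = npif.npif_table(patient_vectors, id_name="patient_id")
    return table.merge(cohort.clinical, on="patient_id")


@pytest.fixture(scope="session")
def cohort300() -> synthetic.Cohort:
    """Default-profile cohort: 3 subtypes x 100 patients."""
    return synthetic.generate_cohort(n_patients=100, seed=11)


@pytest.fixture(scope="session")
def cohort300_features(cohort300) -> pd.DataFrame:
    return extract_cohort_features(cohort300)


@pytest.fixture(scope="session")
def cohort_small() -> synthetic.Cohort:
    """Cheap cohort for structural tests: 3 subtypes x 8 patients."""
    return synthetic.generate_cohort(
        n_patients=8, tiles_per_slide=4, slides_per_patient=2, seed=2
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
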