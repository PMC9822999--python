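"""Shared fixtures: small simulated datasets and brute-force helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytospatial.core import DEFAULT_PALETTE, make_dataset
from cytospatial.synthetic import SimConfig, simulate


def small_config(seed: int = 5, **overrides) -> SimConfig:
    base = dict(
        seed=seed,
        n_patients_per_ie=2,
        images_per_patient=2,
        cells_per_image=600,
        with_genes=False,
        with_markers=False,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate(small_config())


@pytest.fixture(scope="session")
def gene_dataset():
    """Small dataset including gene counts for signature/LR tests."""
    return simulate(small_config(seed=9, cells_per_image=400, with_genes=True))


def random_image(
    rng: np.random.Generator,
    n: int,
    size: float = 400.0,
    types=("tumor", "B", "myeloid", "T_CD8_PD1hi"),
    image_id: str = "rimg1",
) -> pd.DataFrame:
    """A bare random cell table for one image (oracle comparisons)."""
    return pd.DataFrame(
        {
            "cell_id": [f"r{i:05d}" for i in range(n)],
            "image_id": image_id,
            "x_um": rng.uniform(0, size, n),
            "y_um": rng.uniform(0, size, n),
            "radius_um": rng.uniform(2, 10, n),
            "cell_type": rng.choice(list(types), n),
        }
    )


def wrap_image(cells: pd.DataFrame, size: float = 400.0):
    """Embed a single-image cell table in a minimal valid Dataset."""
    images = pd.DataFrame(
        [{"image_id": cells["image_id"].iloc[0], "patient_id": "P1",
          "width_um": size, "height_um": size, "tls_status": "none"}])
    patients = pd.DataFrame([{"patient_id": "P1", "ie_label": "IE1", "grade": 1}])
    return make_dataset(cells, images, patients, palette=DEFAULT_PALETTE)
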