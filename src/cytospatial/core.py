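"""Tabular data model for multiplexed-imaging cell tables.

The universal substrate of the pipeline is a :class:`Dataset`: one row per
segmented cell (centroid in μm, approximate equivalent-circle radius, cell
type, marker intensities, cytokine probe counts including the negative
control probe *DapB*, optional gene counts), plus per-image metadata
(dimensions, TLS status) and per-patient metadata (immune-environment
label, grade).

Conventions
-----------
* Coordinates are continuous μm in an image-local frame, origin top-left,
  y increasing downward; 1 pixel ≡ 1 μm.
* Cells are modelled as disks (centroid + radius); the radius is the proxy
  for segmentation-mask extent used by the contact rule.
* Marker / probe / gene columns are distinguished by name prefix:
  ``mk_<name>`` (marker intensity), ``cy_<name>`` (cytokine probe count,
  ``cy_DapB`` mandatory whenever any probe column is present),
  ``gx_<name>`` (gene count).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MARKER_PREFIX = "mk_"
CYTOKINE_PREFIX = "cy_"
GENE_PREFIX = "gx_"
NEGATIVE_PROBE = "DapB"
NEGATIVE_PROBE_COLUMN = CYTOKINE_PREFIX + NEGATIVE_PROBE

TLS_LEVELS = ("none", "immature", "mature")
IE_LEVELS = ("IE1", "IE2")

CELL_COLUMNS = ("cell_id", "image_id", "x_um", "y_um", "radius_um", "cell_type")
IMAGE_COLUMNS = ("image_id", "patient_id", "width_um", "height_um", "tls_status")
PATIENT_COLUMNS = ("patient_id", "ie_label", "grade")

#: Fixed cell-type palette of the emulated imaging panels.
DEFAULT_PALETTE = (
    "tumor",
    "fibroblast",
    "endothelial",
    "B",
    "plasma",
    "NK",
    "NKT",
    "pDC",
    "migDC",
    "myeloid",
    "T_reg",
    "T_CD4_PD1hi",
    "T_CD4_PD1lo",
    "T_CD8_PD1hi",
    "T_CD8_PD1lo",
)

#: Coarse cell classes used for grouped summaries.
CELL_CLASSES = {
    "tumor": "tumor",
    "fibroblast": "stromal",
    "endothelial": "stromal",
    "B": "B_lineage",
    "plasma": "B_lineage",
    "NK": "T_NK",
    "NKT": "T_NK",
    "T_reg": "T_NK",
    "T_CD4_PD1hi": "T_NK",
    "T_CD4_PD1lo": "T_NK",
    "T_CD8_PD1hi": "T_NK",
    "T_CD8_PD1lo": "T_NK",
    "pDC": "myeloid",
    "migDC": "myeloid",
    "myeloid": "myeloid",
}

T_CELL_TYPES = ("T_reg", "T_CD4_PD1hi", "T_CD4_PD1lo", "T_CD8_PD1hi", "T_CD8_PD1lo")
PD1_HIGH_TYPES = ("T_CD4_PD1hi", "T_CD8_PD1hi")


class SchemaError(ValueError):
    """A mandatory column is missing or of the wrong shape."""


class ReferentialError(ValueError):
    """A foreign key does not resolve (cell→image or image→patient)."""


class UniquenessError(ValueError):
    """Duplicate identifiers where uniqueness is required."""


class ValidationError(ValueError):
    """A field-level invariant is violated."""


class DomainError(ValueError):
    """A parameter is outside its mathematical domain."""


class ConfigurationError(ValueError):
    """An infeasible or inconsistent configuration."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing an upstream output."""


def prefixed_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    return [c for c in df.columns if c.startswith(prefix)]


@dataclass
class Dataset:
    """Cells + images + patients with a declared cell-type palette.

    ``cells`` keeps marker/probe/gene values in prefixed columns exactly as
    they appear on disk, so reading and writing is a plain column-preserving
    CSV round-trip.
    """

    cells: pd.DataFrame
    images: pd.DataFrame
    patients: pd.DataFrame
    palette: tuple[str, ...] = DEFAULT_PALETTE
    cytokines: tuple[str, ...] = ()

    # -- column helpers -------------------------------------------------
    @property
    def marker_columns(self) -> list[str]:
        return prefixed_columns(self.cells, MARKER_PREFIX)

    @property
    def cytokine_columns(self) -> list[str]:
        return prefixed_columns(self.cells, CYTOKINE_PREFIX)

    @property
    def gene_columns(self) -> list[str]:
        return prefixed_columns(self.cells, GENE_PREFIX)

    def cells_of_image(self, image_id: str) -> pd.DataFrame:
        return self.cells[self.cells["image_id"] == image_id]

    def image_ids(self) -> list[str]:
        return list(self.images["image_id"])

    def patient_of_image(self) -> pd.Series:
        """image_id → patient_id."""
        return self.images.set_index("image_id")["patient_id"]

    def ie_of_patient(self) -> pd.Series:
        """patient_id → ie_label."""
        return self.patients.set_index("patient_id")["ie_label"]

    def ie_of_cells(self) -> pd.Series:
        """Per-cell IE label, aligned with ``self.cells``."""
        img2pat = self.patient_of_image()
        pat2ie = self.ie_of_patient()
        return self.cells["image_id"].map(img2pat).map(pat2ie)

    def tls_of_cells(self) -> pd.Series:
        return self.cells["image_id"].map(self.images.set_index("image_id")["tls_status"])

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Raise a typed error on the first violated invariant."""
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise SchemaError(f"cells table missing mandatory column {col!r}")
        for col in IMAGE_COLUMNS:
            if col not in self.images.columns:
                raise SchemaError(f"images table missing mandatory column {col!r}")
        for col in PATIENT_COLUMNS[:2]:
            if col not in self.patients.columns:
                raise SchemaError(f"patients table missing mandatory column {col!r}")

        cy_cols = self.cytokine_columns
        if cy_cols and NEGATIVE_PROBE_COLUMN not in cy_cols:
            raise SchemaError(
                f"cytokine probe columns present but {NEGATIVE_PROBE_COLUMN!r} missing"
            )

        dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()]
        if len(dup):
            raise UniquenessError(f"duplicate cell_id values: {sorted(set(dup))[:5]}")
        dup = self.images["image_id"][self.images["image_id"].duplicated()]
        if len(dup):
            raise UniquenessError(f"duplicate image_id values: {sorted(set(dup))[:5]}")
        dup = self.patients["patient_id"][self.patients["patient_id"].duplicated()]
        if len(dup):
            raise UniquenessError(f"duplicate patient_id values: {sorted(set(dup))[:5]}")

        known_images = set(self.images["image_id"])
        dangling = set(self.cells["image_id"]) - known_images
        if dangling:
            raise ReferentialError(f"cells reference unknown images: {sorted(dangling)[:5]}")
        known_patients = set(self.patients["patient_id"])
        dangling = set(self.images["patient_id"]) - known_patients
        if dangling:
            raise ReferentialError(f"images reference unknown patients: {sorted(dangling)[:5]}")

        if len(self.images):
            bad = self.images[(self.images["width_um"] <= 0) | (self.images["height_um"] <= 0)]
            if len(bad):
                raise ValidationError(f"non-positive image dimensions: {list(bad['image_id'])[:5]}")
            bad = self.images[~self.images["tls_status"].isin(TLS_LEVELS)]
            if len(bad):
                raise ValidationError(f"unknown tls_status: {sorted(set(bad['tls_status']))}")
        if len(self.patients):
            bad = self.patients[~self.patients["ie_label"].isin(IE_LEVELS)]
            if len(bad):
                raise ValidationError(f"unknown ie_label: {sorted(set(bad['ie_label']))}")

        if len(self.cells):
            if not np.all(self.cells["radius_um"].to_numpy(float) > 0):
                raise ValidationError("radius_um must be > 0 for every cell")
            unknown = set(self.cells["cell_type"]) - set(self.palette)
            if unknown:
                raise ValidationError(f"cell types outside declared palette: {sorted(unknown)}")
            dims = self.images.set_index("image_id")[["width_um", "height_um"]]
            w = self.cells["image_id"].map(dims["width_um"]).to_numpy(float)
            h = self.cells["image_id"].map(dims["height_um"]).to_numpy(float)
            x = self.cells["x_um"].to_numpy(float)
            y = self.cells["y_um"].to_numpy(float)
            inside = (x >= 0) & (x <= w) & (y >= 0) & (y <= h)
            if not np.all(inside):
                bad_ids = list(self.cells["cell_id"][~inside])[:5]
                raise ValidationError(f"cell centroids outside image bounds: {bad_ids}")
            for col in cy_cols + self.marker_columns:
                v = self.cells[col].to_numpy(float)
                if np.any(~np.isfinite(v)) or np.any(v < 0):
                    raise ValidationError(f"column {col!r} must be finite and non-negative")

    def area_filter_ids(self, min_area_px: float = 8.0, max_area_px: float = 600.0) -> list[str]:
        """Ids of cells whose disk area (px², 1 px ≡ 1 μm) falls outside
        ``[min_area_px, max_area_px]``.

        This is the optional quality filter applied to segmentation output;
        it is reported, never applied silently.
        """
        area = math.pi * self.cells["radius_um"].to_numpy(float) ** 2
        keep = (area < min_area_px) | (area > max_area_px)
        return list(self.cells["cell_id"][keep])


FLOAT_FORMAT = "%.12g"
_META_FILE = "dataset.json"


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write ``cells.csv``, ``images.csv``, ``patients.csv`` (+ a small JSON
    sidecar holding the declared palette and cytokine order) to ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.cells.to_csv(path / "cells.csv", index=False, float_format=FLOAT_FORMAT)
    ds.images.to_csv(path / "images.csv", index=False, float_format=FLOAT_FORMAT)
    ds.patients.to_csv(path / "patients.csv", index=False, float_format=FLOAT_FORMAT)
    meta = {"palette": list(ds.palette), "cytokines": list(ds.cytokines)}
    (path / _META_FILE).write_text(json.dumps(meta, indent=1) + "\n", encoding="utf-8")


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`SchemaError` / :class:`ReferentialError` /
    :class:`UniquenessError` / :class:`ValidationError` on malformed input.
    """
    path = Path(path)
    for name in ("cells.csv", "images.csv", "patients.csv"):
        if not (path / name).exists():
            raise SchemaError(f"missing table {name!r} in {path}")
    str_cols = {"cell_id": str, "image_id": str, "cell_type": str,
                "patient_id": str, "tls_status": str, "ie_label": str}
    cells = pd.read_csv(path / "cells.csv", dtype=str_cols)
    images = pd.read_csv(path / "images.csv", dtype=str_cols)
    patients = pd.read_csv(path / "patients.csv", dtype=str_cols)

    meta_path = path / _META_FILE
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        palette = tuple(meta["palette"])
        cytokines = tuple(meta["cytokines"])
    else:
        palette = tuple(sorted(set(cells["cell_type"]))) if len(cells) else DEFAULT_PALETTE
        cytokines = tuple(
            c[len(CYTOKINE_PREFIX):]
            for c in prefixed_columns(cells, CYTOKINE_PREFIX)
            if c != NEGATIVE_PROBE_COLUMN
        )
    ds = Dataset(cells=cells, images=images, patients=patients,
                 palette=palette, cytokines=cytokines)
    ds.validate()
    return ds


def make_dataset(
    cells: pd.DataFrame,
    images: pd.DataFrame,
    patients: pd.DataFrame,
    palette: Sequence[str] = DEFAULT_PALETTE,
    cytokines: Sequence[str] = (),
    validate: bool = True,
) -> Dataset:
    """Assemble and (by default) validate a Dataset from in-memory tables."""
    ds = Dataset(
        cells=cells.reset_index(drop=True),
        images=images.reset_index(drop=True),
        patients=patients.reset_index(drop=True),
        palette=tuple(palette),
        cytokines=tuple(cytokines),
    )
    if validate:
        ds.validate()
    return ds
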