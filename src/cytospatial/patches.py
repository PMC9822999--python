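"""Cytokine patches, milieus, and per-image enrichment statistics.

A *cytokine patch* is a connected cluster (chains allowed) of at least
three cells that all express at least one cytokine (general patch) or all
express the same cytokine (cytokine-specific patch), where two cells are
neighbors when their centroids are ≤ 25 μm apart. A *cytokine milieu*
extends a patch by 30 μm: every cell within that distance of some patch
member belongs to the milieu, patch members included.

Per image, enrichment or depletion of a cell type X in milieus of kind Y
is a two-sided Fisher's exact test on the 2×2 table (X/non-X ×
inside/outside milieu) at p < 0.01, evaluated only in images containing
both X cells and Y milieus; the cross-image summary is the percentage of
eligible images with enrichment minus the percentage with depletion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.spatial import cKDTree

from .calling import expressing_any, expression_matrix
from .core import CELL_CLASSES, Dataset, DomainError
from .graphs import NeighborGraph

log = logging.getLogger(__name__)

GENERAL = "general"


@dataclass(frozen=True)
class Patch:
    patch_id: str
    image_id: str
    kind: str  # "general" or a cytokine name
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class Milieu:
    patch_id: str
    image_id: str
    kind: str
    member_ids: tuple[str, ...]  # superset of the patch members


def detect_patches(
    calls: pd.DataFrame,
    graph: NeighborGraph,
    min_size: int = 3,
    kind: str = GENERAL,
) -> list[Patch]:
    """Connected components of qualifying cells in the 25 μm graph.

    Qualifying cells express ≥ 1 cytokine (``kind="general"``) or the
    named cytokine; components smaller than ``min_size`` are dropped.
    """
    if min_size < 1:
        raise DomainError("min_size must be ≥ 1")
    if kind == GENERAL:
        flags = expressing_any(calls)
    else:
        sub = calls[calls["cytokine"] == kind]
        if sub.empty:
            raise DomainError(f"no calls for cytokine {kind!r}")
        flags = sub.set_index("cell_id")["expressed"]
    ids = np.asarray(graph.ids)
    expressed = np.array([bool(flags.get(i, False)) for i in ids])
    qual = np.flatnonzero(expressed)
    if qual.size == 0:
        return []
    pos = {ids[i]: j for j, i in enumerate(qual)}
    rows, cols = [], []
    for j, i in enumerate(qual):
        for nbr in graph.adjacency[ids[i]]:
            jn = pos.get(nbr)
            if jn is not None:
                rows.append(j)
                cols.append(jn)
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(qual.size, qual.size)
    )
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    patches = []
    members_by_comp: dict[int, list[str]] = {}
    for j, lab in enumerate(labels):
        members_by_comp.setdefault(int(lab), []).append(ids[qual[j]])
    comps = sorted(
        (sorted(m) for m in members_by_comp.values() if len(m) >= min_size),
        key=lambda m: m[0],
    )
    for idx, members in enumerate(comps):
        patches.append(
            Patch(
                patch_id=f"{graph.image_id}:{kind}:{idx}",
                image_id=graph.image_id,
                kind=kind,
                member_ids=tuple(members),
            )
        )
    return patches


def build_milieus(
    patches: Sequence[Patch], cells: pd.DataFrame, dilation: float = 30.0
) -> list[Milieu]:
    """Dilate each patch by ``dilation`` μm over the cells of its image."""
    if dilation < 0:
        raise DomainError("dilation must be ≥ 0")
    if not patches:
        return []
    ids = cells["cell_id"].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    pos = {cid: i for i, cid in enumerate(ids)}
    tree = cKDTree(xy)
    milieus = []
    for patch in patches:
        member_pos = [pos[m] for m in patch.member_ids]
        near = set()
        for hits in tree.query_ball_point(xy[member_pos], dilation * (1 + 1e-12)):
            near.update(hits)
        keep = []
        for h in near:
            d = min(np.hypot(*(xy[h] - xy[mp])) for mp in member_pos)
            if d <= dilation:
                keep.append(ids[h])
        members = sorted(set(keep) | set(patch.member_ids))
        milieus.append(
            Milieu(
                patch_id=patch.patch_id,
                image_id=patch.image_id,
                kind=patch.kind,
                member_ids=tuple(members),
            )
        )
    return milieus


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)``. The odds ratio is the sample odds ratio
    ``ad/bc`` with the conventions ``inf`` when ``bc = 0 < ad`` and ``nan``
    when both products vanish; an all-zero table has p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise DomainError("table entries must be non-negative integers")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc
    p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return odds, min(p, 1.0)


def milieu_enrichment(
    ds: Dataset,
    milieus: Sequence[Milieu],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image Fisher enrichment of cell types in milieus, plus summary.

    Milieus of the same kind within one image are merged into a single
    in-milieu indicator so each cell is counted once per (image, kind).
    Only (image, X, Y) combinations where the image contains both X cells
    and Y milieus enter; the summary reports, per (cell_type, kind), the
    percentage of eligible images called enriched minus called depleted.
    """
    member_sets: dict[tuple[str, str], set[str]] = {}
    for m in milieus:
        member_sets.setdefault((m.image_id, m.kind), set()).update(m.member_ids)
    rows = []
    for (image_id, kind), members in sorted(member_sets.items()):
        img_cells = ds.cells_of_image(image_id)
        inside = img_cells["cell_id"].isin(members).to_numpy()
        types = img_cells["cell_type"].to_numpy()
        for cell_type in sorted(set(types)):
            is_x = types == cell_type
            a = int(np.sum(is_x & inside))
            b = int(np.sum(~is_x & inside))
            c = int(np.sum(is_x & ~inside))
            d = int(np.sum(~is_x & ~inside))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                odds, p = (math.nan, 1.0)
            else:
                odds, p = fisher_exact_2x2(a, b, c, d)
            if p >= alpha or math.isnan(odds):
                call = "ns"
            elif odds > 1:
                call = "enriched"
            elif odds < 1:
                call = "depleted"
            else:
                call = "ns"
            rows.append((image_id, cell_type, kind, a, b, c, d, odds, p, call))
    results = pd.DataFrame(
        rows,
        columns=["image_id", "cell_type", "milieu_kind", "a", "b", "c", "d",
                 "odds_ratio", "p", "call"],
    )
    if results.empty:
        summary = pd.DataFrame(
            columns=["cell_type", "milieu_kind", "n_images",
                     "pct_enriched", "pct_depleted", "pct_difference"]
        )
        return results, summary
    grp = results.groupby(["cell_type", "milieu_kind"])
    summary = grp.agg(
        n_images=("image_id", "nunique"),
        pct_enriched=("call", lambda s: 100.0 * np.mean(s == "enriched")),
        pct_depleted=("call", lambda s: 100.0 * np.mean(s == "depleted")),
    ).reset_index()
    summary["pct_difference"] = summary["pct_enriched"] - summary["pct_depleted"]
    return results, summary


def patch_membership_stats(
    calls: pd.DataFrame,
    patches: Sequence[Patch],
    ds: Dataset,
    cell_types: Iterable[str],
    cytokine: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion of cytokine⁺ cells (of the given types) inside specific
    patches of that cytokine, per image and aggregated by TLS status.

    Images with no qualifying cell are excluded from the aggregation.
    """
    cell_types = set(cell_types)
    expr = calls[(calls["cytokine"] == cytokine) & calls["expressed"]]
    expressing = set(expr["cell_id"])
    members: dict[str, set[str]] = {}
    for p in patches:
        if p.kind == cytokine:
            members.setdefault(p.image_id, set()).update(p.member_ids)
    rows = []
    for image_id in ds.image_ids():
        img_cells = ds.cells_of_image(image_id)
        pool = img_cells[img_cells["cell_type"].isin(cell_types)]
        denom_ids = set(pool["cell_id"]) & expressing
        if not denom_ids:
            log.info("image %s has no %s-expressing cells of the filtered types; excluded",
                     image_id, cytokine)
            continue
        num = len(denom_ids & members.get(image_id, set()))
        rows.append((image_id, len(denom_ids), num, num / len(denom_ids)))
    per_image = pd.DataFrame(rows, columns=["image_id", "n_expressing", "n_in_patch", "proportion"])
    if per_image.empty:
        return per_image, pd.DataFrame(columns=["tls_status", "n_images", "mean_proportion"])
    tls = ds.images.set_index("image_id")["tls_status"]
    per_image["tls_status"] = per_image["image_id"].map(tls)
    by_tls = (
        per_image.groupby("tls_status")
        .agg(n_images=("image_id", "nunique"), mean_proportion=("proportion", "mean"))
        .reset_index()
    )
    return per_image, by_tls


def expressing_fractions(
    calls: pd.DataFrame,
    ds: Dataset,
    by_ie: bool = True,
    by_class: bool = False,
) -> pd.DataFrame:
    """Fraction of cells expressing ≥ 1 cytokine, per group.

    Groups are the IE label (default) optionally crossed with coarse
    cell-type class (T and NK / myeloid / stromal / tumor / B lineage).
    """
    any_expr = expressing_any(calls)
    cells = ds.cells[["cell_id", "image_id", "cell_type"]].copy()
    cells["expressing"] = cells["cell_id"].map(any_expr).fillna(False)
    keys = []
    if by_ie:
        cells["ie_label"] = ds.ie_of_cells().to_numpy()
        keys.append("ie_label")
    if by_class:
        cells["cell_class"] = cells["cell_type"].map(CELL_CLASSES)
        keys.append("cell_class")
    if not keys:
        keys = ["image_id"]
    out = (
        cells.groupby(keys)
        .agg(n_cells=("cell_id", "size"), n_expressing=("expressing", "sum"))
        .reset_index()
    )
    out["fraction"] = out["n_expressing"] / out["n_cells"]
    return out


def expressing_fraction_per_image(calls: pd.DataFrame, ds: Dataset) -> pd.DataFrame:
    """Per-image fraction of cells expressing ≥ 1 cytokine (a feature table
    suitable for the patient-averaged IE comparison)."""
    any_expr = expressing_any(calls)
    cells = ds.cells[["cell_id", "image_id"]].copy()
    cells["expressing"] = cells["cell_id"].map(any_expr).fillna(False)
    out = (
        cells.groupby("image_id")
        .agg(n_cells=("cell_id", "size"), n_expressing=("expressing", "sum"))
        .reset_index()
    )
    out["expressing_fraction"] = out["n_expressing"] / out["n_cells"]
    return out[["image_id", "expressing_fraction"]]
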