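"""Neighbor structures over the cells of one image.

Three explicit edge rules drive every spatial analysis:

* **contact**: each cell's circumference is expanded by 8 μm and
  overlapping (expanded) cells are neighbors. On the disk model this is
  ``dist(i, j) ≤ r_i + r_j + 2·expansion``; set ``mode="single"`` to use a
  single 8 μm slack instead of the combined 16 μm.
* **radius**: centroid distance ≤ r (25 μm for cytokine patches).
* **knn**: the k nearest other cells by centroid distance (k = 10 for
  neighborhood composition), optionally restricted to a candidate
  cell-type set and/or excluding types; ties broken by ascending cell_id.

Boundaries are inclusive (≤) everywhere and all constructions are exact
(equal to brute-force all-pairs rules); KD-trees are only an index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import DomainError


@dataclass
class NeighborGraph:
    """Adjacency for one image under one explicit rule.

    For the symmetric rules (contact, radius) ``adjacency[cell_id]`` is a
    tuple of neighbor ids sorted ascending; for knn it is the
    distance-ordered neighbor list (ties by ascending cell_id).
    ``candidate_counts`` is populated for knn only.
    """

    image_id: str
    rule: str
    ids: tuple[str, ...]
    adjacency: dict[str, tuple[str, ...]]
    candidate_counts: dict[str, int] = field(default_factory=dict)

    def neighbors(self, cell_id: str) -> tuple[str, ...]:
        return self.adjacency[cell_id]

    def degree(self, cell_id: str) -> int:
        return len(self.adjacency[cell_id])

    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2

    def edge_list(self, coords: pd.DataFrame | None = None) -> pd.DataFrame:
        """Tidy edge list (each symmetric edge once, source < target)."""
        rows = []
        for src, nbrs in self.adjacency.items():
            for tgt in nbrs:
                if src < tgt or self.rule.startswith("knn"):
                    rows.append((self.image_id, src, tgt))
        df = pd.DataFrame(rows, columns=["image_id", "source", "target"])
        if coords is not None:
            xy = coords.set_index("cell_id")[["x_um", "y_um"]]
            dx = xy.loc[df["source"], "x_um"].to_numpy() - xy.loc[df["target"], "x_um"].to_numpy()
            dy = xy.loc[df["source"], "y_um"].to_numpy() - xy.loc[df["target"], "y_um"].to_numpy()
            df["distance_um"] = np.hypot(dx, dy)
        return df


def _extract(cells: pd.DataFrame):
    ids = cells["cell_id"].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    image_ids = set(cells["image_id"]) if len(cells) else set()
    if len(image_ids) > 1:
        raise DomainError(f"cells span multiple images: {sorted(image_ids)}")
    image_id = next(iter(image_ids)) if image_ids else ""
    return ids, xy, image_id


def _symmetric_graph(ids, pairs, image_id, rule) -> NeighborGraph:
    nbrs: dict[str, list[str]] = {i: [] for i in ids}
    for a, b in pairs:
        nbrs[ids[a]].append(ids[b])
        nbrs[ids[b]].append(ids[a])
    adjacency = {i: tuple(sorted(v)) for i, v in nbrs.items()}
    return NeighborGraph(image_id=image_id, rule=rule, ids=tuple(ids), adjacency=adjacency)


def contact_graph(cells: pd.DataFrame, expansion: float = 8.0, mode: str = "both") -> NeighborGraph:
    """Contact graph: disks overlap after expanding the circumference.

    ``mode="both"`` (default) expands every cell, i.e. edge iff
    ``dist ≤ r_i + r_j + 2·expansion``; ``mode="single"`` uses one slack.
    """
    if expansion < 0:
        raise DomainError("expansion must be ≥ 0")
    if mode not in ("both", "single"):
        raise DomainError(f"unknown expansion mode {mode!r}")
    slack = 2 * expansion if mode == "both" else expansion
    ids, xy, image_id = _extract(cells)
    rule = f"contact{expansion:g}"
    if len(ids) < 2:
        return _symmetric_graph(ids, [], image_id, rule)
    radii = cells["radius_um"].to_numpy(float)
    tree = cKDTree(xy)
    max_dist = 2 * radii.max() + slack
    cand = tree.query_pairs(max_dist, output_type="ndarray")
    if len(cand):
        d = np.hypot(*(xy[cand[:, 0]] - xy[cand[:, 1]]).T)
        keep = d <= radii[cand[:, 0]] + radii[cand[:, 1]] + slack
        cand = cand[keep]
    return _symmetric_graph(ids, cand, image_id, rule)


def radius_graph(cells: pd.DataFrame, r: float = 25.0) -> NeighborGraph:
    """Fixed-radius graph: edge iff centroid distance ≤ r (inclusive)."""
    if r <= 0:
        raise DomainError("radius must be > 0")
    ids, xy, image_id = _extract(cells)
    rule = f"radius{r:g}"
    if len(ids) < 2:
        return _symmetric_graph(ids, [], image_id, rule)
    tree = cKDTree(xy)
    cand = tree.query_pairs(r * (1 + 1e-12), output_type="ndarray")
    if len(cand):
        d = np.hypot(*(xy[cand[:, 0]] - xy[cand[:, 1]]).T)
        cand = cand[d <= r]
    return _symmetric_graph(ids, cand, image_id, rule)


def knn_lists(
    cells: pd.DataFrame,
    k: int = 10,
    restrict_to: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
    queries: Sequence[str] | None = None,
) -> NeighborGraph:
    """k-nearest-neighbor lists by centroid distance.

    Candidates are all cells of the image, optionally restricted to
    ``restrict_to`` types and/or purged of ``exclude`` types; the query
    cell itself is never its own neighbor. Lists are distance-ordered with
    exact ties broken by ascending ``cell_id``; when fewer than ``k``
    candidates exist the list is simply shorter, and the per-query
    candidate count is reported in ``candidate_counts``.
    """
    if k < 1:
        raise DomainError("k must be ≥ 1")
    ids, xy, image_id = _extract(cells)
    rule = f"knn{k}"
    types = cells["cell_type"].to_numpy()
    cand_mask = np.ones(len(ids), dtype=bool)
    if restrict_to is not None:
        cand_mask &= np.isin(types, list(restrict_to))
    if exclude is not None:
        cand_mask &= ~np.isin(types, list(exclude))
    cand_idx = np.flatnonzero(cand_mask)
    cand_ids = ids[cand_idx]

    if queries is None:
        q_positions = np.arange(len(ids))
    else:
        pos = {cid: i for i, cid in enumerate(ids)}
        q_positions = np.array([pos[c] for c in queries], dtype=np.intp)

    adjacency: dict[str, tuple[str, ...]] = {}
    counts: dict[str, int] = {}
    if cand_idx.size:
        tree = cKDTree(xy[cand_idx])
    for qp in q_positions:
        qid = ids[qp]
        self_mask = cand_ids != qid
        n_cand = int(self_mask.sum())
        counts[qid] = n_cand
        if n_cand == 0:
            adjacency[qid] = ()
            continue
        kq = min(k + 1, cand_idx.size)  # +1 absorbs the query itself
        dist, nn = tree.query(xy[qp], k=kq)
        dist = np.atleast_1d(dist)
        nn = np.atleast_1d(nn)
        take = min(k, n_cand)
        # k-th smallest distance among non-self candidates from the initial
        # query; gather every candidate tied at that distance, then apply
        # the deterministic (distance, cell_id) order.
        non_self = nn[cand_ids[nn] != qid]
        if non_self.size >= take:
            dk = np.hypot(*(xy[cand_idx[non_self[take - 1]]] - xy[qp]))
        else:  # initial query saturated by ties; fall back to full scan
            dk = np.inf
        if np.isfinite(dk):
            ball = tree.query_ball_point(xy[qp], dk * (1 + 1e-9) + 1e-12)
            pool = np.asarray(ball, dtype=np.intp)
        else:
            pool = np.arange(cand_idx.size)
        pool = pool[cand_ids[pool] != qid]
        dd = np.hypot(*(xy[cand_idx[pool]] - xy[qp]).T)
        order = np.lexsort((cand_ids[pool], dd))
        chosen = pool[order[:take]]
        adjacency[qid] = tuple(cand_ids[chosen])
    return NeighborGraph(
        image_id=image_id,
        rule=rule,
        ids=tuple(ids[q_positions]),
        adjacency=adjacency,
        candidate_counts=counts,
    )
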