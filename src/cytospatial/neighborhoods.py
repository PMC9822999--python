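"""Permutation-based neighborhood statistics and kNN profiling.

The pairwise interaction test follows the label-permutation formulation
used for multiplexed-imaging contact graphs: for an ordered cell-type
pair (A, B) the statistic is the mean, over A cells, of the number of B
neighbors in the contact graph. The null is generated by permuting the
cell-type labels of the image uniformly (graph fixed) — which conditions
on the relative cell-type frequencies, i.e. the permutation null *is* the
frequency correction — and two one-sided p-values are computed with the
add-one convention ``p = (1 + #extreme) / (1 + n_perm)``. A pair is
called an interaction when ``p_high < α``, avoidance when ``p_low < α``
(α = 0.01, 1000 permutations per image by default).

Also here: k-nearest-neighbor composition profiles stratified by TLS
status, paired direct-neighbor contact fractions, distance-to-nearest
analyses, and flagged-proportion among the k closest candidate cells.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .core import Dataset, DomainError, PD1_HIGH_TYPES, T_CELL_TYPES
from .graphs import NeighborGraph, contact_graph, knn_lists
from .stats import signed_rank_test

log = logging.getLogger(__name__)


def _adjacency_matrix(graph: NeighborGraph) -> tuple[np.ndarray, sparse.csr_matrix]:
    ids = np.asarray(graph.ids)
    pos = {cid: i for i, cid in enumerate(ids)}
    rows, cols = [], []
    for cid, nbrs in graph.adjacency.items():
        i = pos[cid]
        for n in nbrs:
            rows.append(i)
            cols.append(pos[n])
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    )
    return ids, mat


def pairwise_permutation_test(
    cells: pd.DataFrame,
    graph: NeighborGraph,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Permutation interaction/avoidance test for every ordered type pair.

    Returns one row per ordered pair of types present in the image with
    columns ``image_id, type_a, type_b, n_a, n_b, observed, p_high,
    p_low, call``. Pairs involving absent types are simply not evaluable
    and do not appear. Deterministic given ``seed``.
    """
    if statistic not in ("mean", "total"):
        raise DomainError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise DomainError("n_perm must be ≥ 1")
    ids, adj = _adjacency_matrix(graph)
    order = pd.Index(cells["cell_id"]).get_indexer(ids)
    types = cells["cell_type"].to_numpy()[order]
    present = np.array(sorted(set(types)))
    t = present.size
    n = len(ids)
    codes = np.searchsorted(present, types)
    onehot = np.zeros((n, t))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)

    def stat(T: np.ndarray) -> np.ndarray:
        s = T.T @ (adj @ T)  # s[a, b] = Σ_{i of type a} #B-neighbors of i
        if statistic == "mean":
            s = s / counts[:, None]
        return s

    observed = stat(onehot)
    rng = np.random.default_rng(seed)
    ge = np.zeros((t, t))
    le = np.zeros((t, t))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = stat(onehot[perm])
        ge += s >= observed
        le += s <= observed
    p_high = (1.0 + ge) / (1.0 + n_perm)
    p_low = (1.0 + le) / (1.0 + n_perm)

    rows = []
    for a in range(t):
        for b in range(t):
            ph, pl = p_high[a, b], p_low[a, b]
            if ph < alpha and pl < alpha:
                call = "interaction" if ph < pl else ("avoidance" if pl < ph else "ns")
            elif ph < alpha:
                call = "interaction"
            elif pl < alpha:
                call = "avoidance"
            else:
                call = "ns"
            rows.append(
                (graph.image_id, present[a], present[b], int(counts[a]), int(counts[b]),
                 observed[a, b], ph, pl, call)
            )
    return pd.DataFrame(
        rows,
        columns=["image_id", "type_a", "type_b", "n_a", "n_b",
                 "observed", "p_high", "p_low", "call"],
    )


def interaction_summary(results: pd.DataFrame, min_images: int = 1) -> pd.DataFrame:
    """Cross-image summary per ordered pair: fraction of images called
    interaction, fraction called avoidance, and their difference."""
    if results.empty:
        return pd.DataFrame(
            columns=["type_a", "type_b", "n_images",
                     "frac_interaction", "frac_avoidance", "difference"]
        )
    grp = results.groupby(["type_a", "type_b"])
    out = grp.agg(
        n_images=("image_id", "nunique"),
        frac_interaction=("call", lambda s: float(np.mean(s == "interaction"))),
        frac_avoidance=("call", lambda s: float(np.mean(s == "avoidance"))),
    ).reset_index()
    out = out[out["n_images"] >= min_images].reset_index(drop=True)
    out["difference"] = out["frac_interaction"] - out["frac_avoidance"]
    return out


def knn_composition(
    ds: Dataset,
    k: int = 10,
    query_subtypes: Sequence[str] = T_CELL_TYPES,
    stratify_by_tls: bool = True,
) -> pd.DataFrame:
    """Average cell-type composition of the k nearest neighbors, per query
    subtype (and per TLS stratum: non-TLS vs TLS images).

    Each query cell contributes its neighbor-type proportion vector (over
    its ≤ k neighbors) with equal weight; subtypes absent from a stratum
    are omitted.
    """
    tls = ds.images.set_index("image_id")["tls_status"]
    records = []
    for image_id in ds.image_ids():
        img_cells = ds.cells_of_image(image_id)
        if img_cells.empty:
            continue
        queries = img_cells.loc[img_cells["cell_type"].isin(query_subtypes), "cell_id"]
        if queries.empty:
            continue
        graph = knn_lists(img_cells, k=k, queries=list(queries))
        type_of = img_cells.set_index("cell_id")["cell_type"]
        stratum = ("TLS" if tls[image_id] != "none" else "non-TLS") if stratify_by_tls else "all"
        for qid in queries:
            nbrs = graph.adjacency[qid]
            if not nbrs:
                continue
            vec = type_of.loc[list(nbrs)].value_counts(normalize=True)
            records.append(
                {"stratum": stratum, "query_subtype": type_of[qid], **vec.to_dict()}
            )
    if not records:
        return pd.DataFrame(columns=["stratum", "query_subtype", "n_query"])
    df = pd.DataFrame(records).fillna(0.0)
    value_cols = [c for c in df.columns if c not in ("stratum", "query_subtype")]
    out = (
        df.groupby(["stratum", "query_subtype"])[value_cols]
        .mean()
        .reset_index()
    )
    out.insert(2, "n_query", df.groupby(["stratum", "query_subtype"]).size().to_numpy())
    return out


def direct_neighbor_fraction(
    ds: Dataset,
    type_a: str,
    type_b: str,
    target_type: str,
    graphs: Mapping[str, NeighborGraph] | None = None,
    expansion: float = 8.0,
) -> tuple[pd.DataFrame, float]:
    """Per-patient fractions of type-a vs type-b cells with ≥ 1 direct
    (contact-graph) neighbor of the target type, plus the exact two-sided
    paired signed-rank p over patients.

    Cells are pooled over each patient's images; a patient contributes
    only if it has cells of both query types and the target type present
    in at least one of its images. With fewer than 3 contributing
    patients the p-value is undefined (NaN) and fractions are still
    returned.
    """
    img2pat = ds.patient_of_image()
    per_patient: dict[str, dict[str, list[float]]] = {}
    target_seen: dict[str, bool] = {}
    for image_id in ds.image_ids():
        img_cells = ds.cells_of_image(image_id)
        if img_cells.empty:
            continue
        graph = graphs[image_id] if graphs is not None else contact_graph(img_cells, expansion)
        type_of = img_cells.set_index("cell_id")["cell_type"]
        patient = img2pat[image_id]
        rec = per_patient.setdefault(patient, {"a_touch": [], "a_all": [], "b_touch": [], "b_all": []})
        target_seen[patient] = target_seen.get(patient, False) or bool(
            (type_of == target_type).any()
        )
        for key, qtype in (("a", type_a), ("b", type_b)):
            for cid in type_of.index[type_of == qtype]:
                touches = any(type_of[n] == target_type for n in graph.adjacency[cid])
                rec[f"{key}_all"].append(cid)
                if touches:
                    rec[f"{key}_touch"].append(cid)
    rows = []
    for patient, rec in sorted(per_patient.items()):
        n_a, n_b = len(rec["a_all"]), len(rec["b_all"])
        if n_a == 0 or n_b == 0 or not target_seen.get(patient, False):
            log.info("patient %s lacks %s/%s/%s cells; excluded", patient, type_a, type_b, target_type)
            continue
        rows.append(
            (patient, n_a, len(rec["a_touch"]) / n_a, n_b, len(rec["b_touch"]) / n_b)
        )
    df = pd.DataFrame(rows, columns=["patient_id", "n_a", "fraction_a", "n_b", "fraction_b"])
    if len(df) < 3:
        return df, float("nan")
    p = signed_rank_test(df["fraction_a"].to_numpy() - df["fraction_b"].to_numpy())
    return df, p


def distance_to_nearest(
    ds: Dataset, query_ids: Sequence[str], target_type: str
) -> pd.DataFrame:
    """Euclidean centroid distance from each query cell to the nearest
    cell of the target type in the same image.

    Queries in images without any target cell get ``NaN`` distance and
    ``target_present=False`` (excluded from downstream comparisons).
    """
    query_ids = list(query_ids)
    wanted = ds.cells[ds.cells["cell_id"].isin(query_ids)]
    rows = []
    for image_id, grp in wanted.groupby("image_id", sort=True):
        img_cells = ds.cells_of_image(image_id)
        targets = img_cells[img_cells["cell_type"] == target_type]
        q_xy = grp[["x_um", "y_um"]].to_numpy(float)
        if targets.empty:
            for cid in grp["cell_id"]:
                rows.append((cid, image_id, float("nan"), False))
            continue
        t_ids = targets["cell_id"].to_numpy()
        t_xy = targets[["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(t_xy)
        k = min(2, len(t_ids))
        dist, idx = tree.query(q_xy, k=k)
        dist = np.atleast_2d(dist.reshape(len(grp), k))
        idx = np.atleast_2d(idx.reshape(len(grp), k))
        for row, cid in enumerate(grp["cell_id"]):
            # a query that is itself a target: nearest *other* target
            if t_ids[idx[row, 0]] == cid:
                d = dist[row, 1] if k > 1 else float("nan")
                ok = k > 1
            else:
                d, ok = dist[row, 0], True
            rows.append((cid, image_id, float(d), ok))
    out = pd.DataFrame(rows, columns=["cell_id", "image_id", "distance_um", "target_present"])
    return out.set_index("cell_id").loc[[q for q in query_ids if q in out["cell_id"].values]].reset_index()


def knn_target_proportion(
    ds: Dataset,
    query_ids: Sequence[str],
    candidate_types: Sequence[str],
    k: int = 10,
    exclude: Sequence[str] = (),
    flag_types: Sequence[str] = PD1_HIGH_TYPES,
) -> pd.DataFrame:
    """Proportion of flagged cells among the ≤ k nearest candidate cells.

    E.g. the proportion of PD-1^high T cells among each myeloid cell's
    ten closest T cells (T_regs excluded). Queries with zero candidates
    get ``NaN`` and are flagged for exclusion.
    """
    query_ids = list(query_ids)
    flag_set = set(flag_types)
    wanted = ds.cells[ds.cells["cell_id"].isin(query_ids)]
    rows = []
    for image_id, grp in wanted.groupby("image_id", sort=True):
        img_cells = ds.cells_of_image(image_id)
        graph = knn_lists(
            img_cells, k=k, restrict_to=candidate_types, exclude=exclude or None,
            queries=list(grp["cell_id"]),
        )
        type_of = img_cells.set_index("cell_id")["cell_type"]
        for cid in grp["cell_id"]:
            nbrs = graph.adjacency[cid]
            n_cand = graph.candidate_counts[cid]
            if not nbrs:
                rows.append((cid, image_id, 0, float("nan")))
                continue
            prop = float(np.mean([type_of[n] in flag_set for n in nbrs]))
            rows.append((cid, image_id, len(nbrs), prop))
    return pd.DataFrame(rows, columns=["cell_id", "image_id", "n_candidates", "proportion"])
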