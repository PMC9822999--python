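"""Ligand–receptor crosstalk scoring and IE-group enrichment.

Interaction scores between cell types use the regularized geometric-mean
formulation: with ``l`` the mean (library-normalized) ligand expression
in the sender type and ``r`` the mean receptor expression in the
receiver type,

    score = sqrt(l·r) / (μ + sqrt(l·r)),

bounded in [0, 1) and monotone in both means; μ defaults to the global
mean of the expression matrix. A score ≥ 0.4 defines a "true"
interaction for counting. Pair-specific interactions are selected per
type pair as the 5 pairs with the highest coefficient of variation among
its 100 top-scoring interactions. IE1-vs-IE2 enrichment scores each
patient separately and applies an exact two-sided Wilcoxon rank-sum test
per (type pair, LR pair), retaining hits with p < 0.05 (uncorrected, as
prescribed) and overall mean score > 0.4.

The shipped LR list is a small curated table (checkpoint, chemokine and
cytokine axes); users may substitute their own via ``load_lr_pairs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Dataset, DomainError, GENE_PREFIX
from .stats import rank_sum_test

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    annotation: str = ""

    @property
    def label(self) -> str:
        return f"{self.ligand}->{self.receptor}"


def load_lr_pairs(path: str | Path | None = None) -> list[LRPair]:
    """Load (ligand, receptor, annotation) rows; default = packaged list."""
    if path is None:
        path = Path(str(resources.files("cytospatial") / "data" / "lr_pairs.csv"))
    df = pd.read_csv(path)
    pairs = [LRPair(r.ligand, r.receptor, getattr(r, "annotation", "")) for r in df.itertuples()]
    seen = set()
    for p in pairs:
        key = (p.ligand, p.receptor)
        if key in seen:
            raise DomainError(f"duplicate LR pair {key}")
        seen.add(key)
    return pairs


def mean_expression(
    cells: pd.DataFrame,
    cell_types: Sequence[str] | None = None,
    scale: float = 1e4,
    min_cells: int = 10,
    group_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cell-type × gene matrix of mean library-normalized expression.

    Per-cell counts are normalized to ``scale`` total (counts-per-10k by
    default) before averaging within each type; types with fewer than
    ``min_cells`` cells are skipped (logged). ``group_map`` optionally
    collapses fine-grained types into metaclasses (e.g. the T/NK and
    myeloid compartments) before averaging; unmapped types are dropped.
    """
    gene_cols = [c for c in cells.columns if c.startswith(GENE_PREFIX)]
    if not gene_cols:
        raise DomainError("no gene-count (gx_) columns present")
    genes = [c[len(GENE_PREFIX):] for c in gene_cols]
    counts = cells[gene_cols].to_numpy(float)
    totals = counts.sum(axis=1)
    ok = totals > 0
    norm = np.zeros_like(counts)
    norm[ok] = scale * counts[ok] / totals[ok, None]
    types = cells["cell_type"].to_numpy()
    if group_map is not None:
        types = np.array([group_map.get(t, "") for t in types])
        ok = ok & (types != "")
    use_types = sorted(set(types)) if cell_types is None else list(cell_types)
    rows = {}
    for t in use_types:
        mask = (types == t) & ok
        n = int(mask.sum())
        if n < min_cells:
            log.info("cell type %s has %d cells (< %d); skipped", t, n, min_cells)
            continue
        rows[t] = norm[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes)


def lr_score(
    mean_expr: pd.DataFrame,
    pairs: Sequence[LRPair],
    mu: float | None = None,
) -> pd.DataFrame:
    """Score every LR pair over every ordered (sender, receiver) type pair.

    ``mu`` regularizes the score (default: global mean of ``mean_expr``).
    Pairs whose ligand or receptor gene is absent are skipped and logged.
    Mode is autocrine when sender == receiver, else paracrine.
    """
    if mu is None:
        mu = float(mean_expr.to_numpy().mean())
    if mu <= 0:
        raise DomainError("mu must be > 0")
    types = list(mean_expr.index)
    rows = []
    for pair in pairs:
        if pair.ligand not in mean_expr.columns or pair.receptor not in mean_expr.columns:
            log.info("LR pair %s skipped: gene absent from expression table", pair.label)
            continue
        lig = mean_expr[pair.ligand]
        rec = mean_expr[pair.receptor]
        for s in types:
            for r in types:
                root = float(np.sqrt(lig[s] * rec[r]))
                score = root / (mu + root)
                rows.append(
                    (s, r, pair.ligand, pair.receptor, pair.annotation, score,
                     "autocrine" if s == r else "paracrine")
                )
    return pd.DataFrame(
        rows,
        columns=["sender", "receiver", "ligand", "receptor", "annotation", "score", "mode"],
    )


def count_interactions(scores: pd.DataFrame, threshold: float = 0.4) -> pd.DataFrame:
    """Number of LR pairs with score ≥ threshold per (sender, receiver)."""
    out = (
        scores.assign(true_pair=scores["score"] >= threshold)
        .groupby(["sender", "receiver"])["true_pair"]
        .sum()
        .astype(int)
        .reset_index(name="n_interactions")
    )
    return out


def specific_interactions(
    scores: pd.DataFrame, top_n: int = 100, top_cv: int = 5
) -> pd.DataFrame:
    """Type-pair-specific LR pairs by coefficient of variation.

    For each (sender, receiver): take its ``top_n`` highest-scoring pairs
    (ties broken by pair name), compute each pair's CV (sd/mean, across
    all type pairs), and keep the ``top_cv`` pairs with the highest CV.
    A constant score matrix degenerates to name order and is flagged.
    """
    df = scores.copy()
    df["pair"] = df["ligand"] + "->" + df["receptor"]
    cv = (
        df.groupby("pair")["score"]
        .agg(lambda s: float(np.std(s, ddof=1) / np.mean(s)) if np.mean(s) > 0 else 0.0)
        .rename("cv")
    )
    rows = []
    for (s, r), grp in df.groupby(["sender", "receiver"]):
        grp = grp.sort_values(["score", "pair"], ascending=[False, True], kind="stable")
        if len(grp) < top_n:
            log.info("(%s, %s): only %d scored pairs (< top_n=%d); using all", s, r, len(grp), top_n)
        top = grp.head(top_n).copy()
        top["cv"] = top["pair"].map(cv)
        degenerate = bool(np.all(top["cv"].to_numpy() == 0))
        top = top.sort_values(["cv", "pair"], ascending=[False, True], kind="stable")
        sel = top.head(top_cv)
        for rec in sel.itertuples():
            rows.append((s, r, rec.ligand, rec.receptor, rec.score, rec.cv, degenerate))
    return pd.DataFrame(
        rows, columns=["sender", "receiver", "ligand", "receptor", "score", "cv", "degenerate"]
    )


def per_patient_scores(
    ds: Dataset,
    pairs: Sequence[LRPair],
    cell_types: Sequence[str] | None = None,
    scale: float = 1e4,
    min_cells: int = 10,
    mu: float | None = None,
    group_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """LR scores computed for each patient's cells separately.

    ``mu`` defaults to the global mean of the pooled expression matrix so
    patients are scored on a common scale. ``group_map`` collapses types
    into metaclasses first (rare subtypes otherwise fall below
    ``min_cells`` in individual patients).
    """
    cells = ds.cells.copy()
    cells["patient_id"] = ds.cells["image_id"].map(ds.patient_of_image()).to_numpy()
    if mu is None:
        pooled = mean_expression(cells, cell_types=cell_types, scale=scale,
                                 min_cells=min_cells, group_map=group_map)
        if pooled.empty:
            raise DomainError("no cell type reaches min_cells in the pooled data")
        mu = float(pooled.to_numpy().mean())
    frames = []
    for patient, grp in cells.groupby("patient_id", sort=True):
        expr = mean_expression(grp, cell_types=cell_types, scale=scale,
                               min_cells=min_cells, group_map=group_map)
        if expr.empty:
            log.info("patient %s: no scoreable cell types; skipped", patient)
            continue
        sc = lr_score(expr, pairs, mu=mu)
        sc.insert(0, "patient_id", patient)
        frames.append(sc)
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "sender", "receiver", "ligand", "receptor",
                     "annotation", "score", "mode"]
        )
    return pd.concat(frames, ignore_index=True)


def ie_enrichment(
    patient_scores: pd.DataFrame,
    ie_labels: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    min_mean: float = 0.4,
) -> pd.DataFrame:
    """IE1-vs-IE2 enrichment of each (type pair, LR pair).

    Per combination: exact two-sided Wilcoxon rank-sum test on per-patient
    scores between the groups, direction by group-mean difference, and a
    ``retained`` flag for rows with p < alpha and overall mean score >
    min_mean (no multiplicity correction, by design).
    """
    ie = pd.Series(ie_labels)
    df = patient_scores.copy()
    df["ie_label"] = df["patient_id"].map(ie)
    if df["ie_label"].isna().any():
        missing = sorted(set(df.loc[df["ie_label"].isna(), "patient_id"]))
        raise DomainError(f"patients without IE label: {missing}")
    rows = []
    keys = ["sender", "receiver", "ligand", "receptor"]
    for key, grp in df.groupby(keys, sort=True):
        g1 = grp.loc[grp["ie_label"] == "IE1", "score"].to_numpy()
        g2 = grp.loc[grp["ie_label"] == "IE2", "score"].to_numpy()
        if g1.size < 2 or g2.size < 2:
            continue
        if np.ptp(np.concatenate([g1, g2])) == 0:
            p = 1.0
        else:
            p = rank_sum_test(g1, g2)
        mean1, mean2 = float(g1.mean()), float(g2.mean())
        overall = float(grp["score"].mean())
        direction = "IE1" if mean1 > mean2 else ("IE2" if mean2 > mean1 else "none")
        retained = bool(p < alpha and overall > min_mean)
        rows.append((*key, g1.size, g2.size, mean1, mean2, overall, direction, p, retained))
    return pd.DataFrame(
        rows,
        columns=["sender", "receiver", "ligand", "receptor", "n_ie1", "n_ie2",
                 "mean_ie1", "mean_ie2", "mean_overall", "direction", "p", "retained"],
    )
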