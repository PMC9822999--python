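"""LR scoring, specificity selection, and IE enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cytospatial.core import DomainError
from cytospatial.crosstalk import (
    LRPair,
    count_interactions,
    ie_enrichment,
    load_lr_pairs,
    lr_score,
    mean_expression,
    per_patient_scores,
    specific_interactions,
)
from cytospatial.synthetic import SimConfig, simulate

from conftest import small_config


def expr_matrix(data: dict[str, dict[str, float]]):
    return pd.DataFrame(data).T  # index: type, columns: gene


def test_lr_score_worked_examples():
    expr = expr_matrix({"A": {"L": 4.0, "R": 0.0}, "B": {"L": 0.0, "R": 9.0}})
    scores = lr_score(expr, [LRPair("L", "R")], mu=2.0).set_index(["sender", "receiver"])
    # l = 4 (A), r = 9 (B): sqrt(36)/(2+6) = 0.75
    assert scores.loc[("A", "B"), "score"] == pytest.approx(0.75)
    # zero ligand → score 0
    assert scores.loc[("B", "B"), "score"] == 0.0
    assert scores.loc[("A", "A"), "mode"] == "autocrine"
    assert scores.loc[("A", "B"), "mode"] == "paracrine"


def test_lr_score_symmetry_point_half():
    expr = expr_matrix({"A": {"L": 2.0, "R": 2.0}})
    scores = lr_score(expr, [LRPair("L", "R")], mu=2.0)
    assert scores["score"].iloc[0] == pytest.approx(0.5)


def test_lr_score_bounds_and_monotonicity():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 50, size=(30, 2))
    mu = 3.0
    prev = -1.0
    for l, r in sorted(values.tolist(), key=lambda v: v[0] * v[1]):
        expr = expr_matrix({"A": {"L": l, "R": 0.0}, "B": {"L": 0.0, "R": r}})
        s = lr_score(expr, [LRPair("L", "R")], mu=mu).set_index(["sender", "receiver"])
        val = s.loc[("A", "B"), "score"]
        assert 0.0 <= val < 1.0
        assert val >= prev - 1e-12
        prev = val


def test_lr_score_mu_domain():
    expr = expr_matrix({"A": {"L": 1.0, "R": 1.0}})
    with pytest.raises(DomainError):
        lr_score(expr, [LRPair("L", "R")], mu=0.0)


def test_count_interactions_threshold():
    scores = pd.DataFrame({
        "sender": ["A"] * 3, "receiver": ["B"] * 3,
        "ligand": ["L1", "L2", "L3"], "receptor": ["R1", "R2", "R3"],
        "annotation": "", "score": [0.5, 0.45, 0.1], "mode": "paracrine"})
    out = count_interactions(scores).set_index(["sender", "receiver"])
    assert out.loc[("A", "B"), "n_interactions"] == 2
    out0 = count_interactions(scores.assign(score=0.0))
    assert (out0["n_interactions"] == 0).all()


def test_specific_interactions_hand_enumeration():
    """2 type pairs × 3 LR pairs: selection = highest-CV pairs of the top-n."""
    rows = []
    score_table = {  # pair → (score at (A,A), score at (A,B))
        ("L1", "R1"): (0.9, 0.9),   # CV 0
        ("L2", "R2"): (0.8, 0.2),   # high CV
        ("L3", "R3"): (0.5, 0.4),   # low CV
    }
    for (l, r), (s_aa, s_ab) in score_table.items():
        rows.append({"sender": "A", "receiver": "A", "ligand": l, "receptor": r,
                     "annotation": "", "score": s_aa, "mode": "autocrine"})
        rows.append({"sender": "A", "receiver": "B", "ligand": l, "receptor": r,
                     "annotation": "", "score": s_ab, "mode": "paracrine"})
    scores = pd.DataFrame(rows)
    out = specific_interactions(scores, top_n=3, top_cv=2)
    sel_aa = out[(out["sender"] == "A") & (out["receiver"] == "A")]
    # CVs: L1 0; L2 sd/mean of (0.8, 0.2); L3 of (0.5, 0.4) → L2 > L3 > L1
    assert list(sel_aa["ligand"]) == ["L2", "L3"]
    assert not sel_aa["degenerate"].any()


def test_specific_interactions_constant_matrix_degenerate():
    rows = []
    for l in ("L1", "L2", "L3"):
        for recv in ("A", "B"):
            rows.append({"sender": "A", "receiver": recv, "ligand": l,
                         "receptor": "R", "annotation": "", "score": 0.5,
                         "mode": "paracrine"})
    out = specific_interactions(pd.DataFrame(rows), top_n=3, top_cv=2)
    assert out["degenerate"].all()
    sel = out[(out["sender"] == "A") & (out["receiver"] == "A")]
    assert list(sel["ligand"]) == ["L1", "L2"]  # name-order fallback


def rank_sum_oracle(x, y):
    from scipy.stats import rankdata
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, N = len(x), len(pooled)
    obs = ranks[:n].sum()
    mu = n * (N + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        s = sum(ranks[i] for i in combo)
        total += 1
        hits += abs(s - mu) >= abs(obs - mu) - 1e-9
    return hits / total


def test_ie_enrichment_separated_groups_retained():
    g1 = [0.9, 0.8, 0.85, 0.9, 0.8, 0.9, 0.85]
    g2 = [0.1, 0.2, 0.15, 0.1, 0.2, 0.1, 0.15]
    rows = []
    for i, v in enumerate(g1):
        rows.append({"patient_id": f"p1_{i}", "sender": "A", "receiver": "B",
                     "ligand": "L", "receptor": "R", "annotation": "",
                     "score": v, "mode": "paracrine"})
    for i, v in enumerate(g2):
        rows.append({"patient_id": f"p2_{i}", "sender": "A", "receiver": "B",
                     "ligand": "L", "receptor": "R", "annotation": "",
                     "score": v, "mode": "paracrine"})
    labels = {f"p1_{i}": "IE1" for i in range(7)} | {f"p2_{i}": "IE2" for i in range(7)}
    out = ie_enrichment(pd.DataFrame(rows), labels)
    rec = out.iloc[0]
    assert rec["p"] == pytest.approx(rank_sum_oracle(np.array(g1), np.array(g2)))
    assert rec["retained"]
    assert rec["direction"] == "IE1"


def test_ie_enrichment_identical_groups_not_retained():
    rows = []
    for i in range(6):
        rows.append({"patient_id": f"p{i}", "sender": "A", "receiver": "B",
                     "ligand": "L", "receptor": "R", "annotation": "",
                     "score": 0.7, "mode": "paracrine"})
    labels = {f"p{i}": ("IE1" if i < 3 else "IE2") for i in range(6)}
    out = ie_enrichment(pd.DataFrame(rows), labels)
    assert out["p"].iloc[0] == 1.0
    assert not out["retained"].any()


def test_boosted_checkpoint_pairs_recovered():
    """IE1-boosted checkpoint ligands surface as retained IE1-enriched
    myeloid → T/NK metaclass interactions."""
    from cytospatial.core import CELL_CLASSES

    cfg = small_config(seed=41, n_patients_per_ie=4, images_per_patient=1,
                       cells_per_image=1500, with_genes=True)
    ds, _ = simulate(cfg)
    pairs = load_lr_pairs()
    scores = per_patient_scores(ds, pairs, min_cells=10, group_map=CELL_CLASSES)
    out = ie_enrichment(scores, ds.ie_of_patient())
    for ligand, receptor in (("CD274", "PDCD1"), ("CD80", "CTLA4")):
        hit = out[(out["sender"] == "myeloid") & (out["receiver"] == "T_NK")
                  & (out["ligand"] == ligand) & (out["receptor"] == receptor)]
        assert len(hit) == 1
        assert hit["retained"].iloc[0]
        assert hit["direction"].iloc[0] == "IE1"


def test_load_lr_pairs_unique():
    pairs = load_lr_pairs()
    assert len(pairs) == len({(p.ligand, p.receptor) for p in pairs})
    assert any(p.ligand == "CD274" and p.receptor == "PDCD1" for p in pairs)
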