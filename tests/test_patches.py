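"""Patches, milieus, Fisher enrichment, and expressing fractions."""

import math

import numpy as np
import pandas as pd
import pytest

from cytospatial.calling import expressing_any
from cytospatial.core import T_CELL_TYPES
from cytospatial.graphs import radius_graph
from cytospatial.patches import (
    build_milieus,
    detect_patches,
    expressing_fractions,
    fisher_exact_2x2,
    milieu_enrichment,
    patch_membership_stats,
)
from cytospatial.synthetic import (
    calls_from_ground_truth,
    simulate,
    toy_fixture,
)

from conftest import random_image, small_config, wrap_image


# ---------------------------------------------------------------- oracles

def components_oracle(qualifying, adjacency, min_size):
    """Union-find over edges restricted to qualifying cells."""
    parent = {i: i for i in qualifying}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in qualifying:
        for b in adjacency[a]:
            if b in parent:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps = {}
    for i in qualifying:
        comps.setdefault(find(i), set()).add(i)
    return sorted(
        (tuple(sorted(c)) for c in comps.values() if len(c) >= min_size),
        key=lambda c: c[0],
    )


def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {aa: math.comb(r1, aa) * math.comb(n - r1, c1 - aa) / denom
             for aa in range(lo, hi + 1)}
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


# ----------------------------------------------------------------- tests

def test_three_cell_line_forms_one_specific_patch():
    ds, gt = toy_fixture("three_cell_line")
    calls = calls_from_ground_truth(ds, gt)
    graph = radius_graph(ds.cells, r=25)
    patches = detect_patches(calls, graph, kind="CXCL13")
    assert len(patches) == 1
    assert patches[0].member_ids == ("t001", "t002", "t003")


def test_broken_chain_yields_no_patch():
    ds, gt = toy_fixture("three_cell_line")
    flags = gt.expresser_flags.copy()
    flags.loc["t002", "CXCL13"] = False
    gt2 = type(gt)(flags, gt.planted_patch_members, gt.pair_effects, ())
    calls = calls_from_ground_truth(ds, gt2)
    graph = radius_graph(ds.cells, r=25)
    assert detect_patches(calls, graph, kind="CXCL13") == []


def test_two_patch_image_recovers_planted_patches_exactly():
    ds, gt = toy_fixture("two_patch_image")
    calls = calls_from_ground_truth(ds, gt)
    graph = radius_graph(ds.cells, r=25)
    patches = detect_patches(calls, graph, kind="CXCL13")
    found = sorted(sorted(p.member_ids) for p in patches)
    planted = sorted(sorted(m) for m in gt.planted_patch_members["toy_img1"]["CXCL13"])
    assert found == planted


def test_specific_patches_contained_in_general_patches(small_dataset):
    ds, gt = small_dataset
    calls = calls_from_ground_truth(ds, gt)
    for image_id in ds.image_ids():
        cells = ds.cells_of_image(image_id)
        graph = radius_graph(cells, r=25)
        general = detect_patches(calls[calls["cell_id"].isin(cells["cell_id"])], graph)
        gsets = [set(p.member_ids) for p in general]
        for cyt in ds.cytokines:
            for sp in detect_patches(calls[calls["cell_id"].isin(cells["cell_id"])],
                                     graph, kind=cyt):
                assert any(set(sp.member_ids) <= g for g in gsets)


@pytest.mark.parametrize("seed", range(10))
def test_patch_detection_matches_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(50, 250))
    cells = random_image(rng, n, size=300.0)
    expressed = rng.random(n) < 0.3
    calls = pd.DataFrame({
        "cell_id": cells["cell_id"], "cytokine": "CXCL9",
        "d": 0.0, "p": 1.0, "q": 1.0, "expressed": expressed})
    graph = radius_graph(cells, r=25)
    patches = detect_patches(calls, graph, kind="CXCL9")
    found = sorted(tuple(p.member_ids) for p in patches)
    qualifying = set(cells["cell_id"][expressed])
    expected = components_oracle(qualifying, graph.adjacency, 3)
    assert found == sorted(expected)


def test_milieu_includes_cells_within_30um_only():
    """Patch at x = 0, 20, 40: the cell at x = 60 joins the milieu
    (distance 20), the cell at x = 80 does not (distance 40)."""
    rows = []
    for i, x in enumerate([0, 20, 40, 60, 80], start=1):
        rows.append({"cell_id": f"m{i}", "image_id": "img", "x_um": float(x),
                     "y_um": 0.0, "radius_um": 5.0, "cell_type": "B"})
    cells = pd.DataFrame(rows)
    from cytospatial.patches import Patch
    patch = Patch("img:CXCL13:0", "img", "CXCL13", ("m1", "m2", "m3"))
    (milieu,) = build_milieus([patch], cells, dilation=30)
    assert set(milieu.member_ids) == {"m1", "m2", "m3", "m4"}


def test_milieu_is_superset_of_patch(small_dataset):
    ds, gt = small_dataset
    calls = calls_from_ground_truth(ds, gt)
    xy = ds.cells.set_index("cell_id")[["x_um", "y_um"]]
    checked = 0
    for image_id in ds.image_ids():
        cells = ds.cells_of_image(image_id)
        graph = radius_graph(cells, r=25)
        patches = detect_patches(calls[calls["cell_id"].isin(cells["cell_id"])], graph)
        for patch, milieu in zip(patches, build_milieus(patches, cells)):
            assert set(patch.member_ids) <= set(milieu.member_ids)
            for cid in milieu.member_ids:
                dmin = min(
                    np.hypot(*(xy.loc[cid].to_numpy() - xy.loc[m].to_numpy()))
                    for m in patch.member_ids)
                assert dmin <= 30 + 1e-9
            checked += 1
    assert checked > 0


def test_fisher_worked_examples():
    odds, p = fisher_exact_2x2(2, 0, 0, 2)
    assert p == pytest.approx(1 / 3)
    assert odds == math.inf
    _, p = fisher_exact_2x2(0, 0, 0, 0)
    assert p == 1.0
    _, p = fisher_exact_2x2(5, 1, 1, 5)
    assert p == pytest.approx(fisher_oracle(5, 1, 1, 5), rel=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_fisher_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = rng.integers(0, 11, size=4)
    _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
    assert p == pytest.approx(fisher_oracle(int(a), int(b), int(c), int(d)),
                              rel=1e-12, abs=1e-12)


def test_enrichment_degenerate_margins_ns():
    """All cells inside the milieu → no contrast → p = 1, ns."""
    ds, gt = toy_fixture("three_cell_line")
    calls = calls_from_ground_truth(ds, gt)
    graph = radius_graph(ds.cells, r=25)
    patches = detect_patches(calls, graph, kind="CXCL13")
    milieus = build_milieus(patches, ds.cells, dilation=30)
    results, summary = milieu_enrichment(ds, milieus)
    assert (results["p"] == 1.0).all()
    assert (results["call"] == "ns").all()


def test_enrichment_detects_planted_type_concentration():
    """B cells packed inside the milieu, tumor outside → enriched/depleted."""
    rng = np.random.default_rng(2)
    rows = []
    for i in range(30):  # B cluster at (50, 50)
        rows.append({"cell_id": f"b{i:02d}", "image_id": "img",
                     "x_um": 50 + rng.uniform(-15, 15), "y_um": 50 + rng.uniform(-15, 15),
                     "radius_um": 5.0, "cell_type": "B"})
    for i in range(300):
        rows.append({"cell_id": f"t{i:03d}", "image_id": "img",
                     "x_um": rng.uniform(150, 400), "y_um": rng.uniform(150, 400),
                     "radius_um": 5.0, "cell_type": "tumor"})
    cells = pd.DataFrame(rows)
    ds = wrap_image(cells)
    expressed = cells["cell_id"].str.startswith("b")
    calls = pd.DataFrame({"cell_id": cells["cell_id"], "cytokine": "CXCL13",
                          "d": 0.0, "p": 1.0, "q": 1.0, "expressed": expressed})
    graph = radius_graph(cells, r=25)
    patches = detect_patches(calls, graph, kind="CXCL13")
    milieus = build_milieus(patches, cells)
    results, _ = milieu_enrichment(ds, milieus)
    res = results.set_index("cell_type")
    assert res.loc["B", "call"] == "enriched"
    assert res.loc["tumor", "call"] == "depleted"


def test_patch_membership_proportion_two_patch_image():
    """8 patch members / 13 expressing T cells → 8/13."""
    ds, gt = toy_fixture("two_patch_image")
    calls = calls_from_ground_truth(ds, gt)
    graph = radius_graph(ds.cells, r=25)
    patches = detect_patches(calls, graph, kind="CXCL13")
    per_image, by_tls = patch_membership_stats(calls, patches, ds, T_CELL_TYPES, "CXCL13")
    assert per_image["proportion"].iloc[0] == pytest.approx(8 / 13)
    assert by_tls.set_index("tls_status").loc["none", "mean_proportion"] == pytest.approx(8 / 13)


def test_patch_membership_excludes_images_without_expressers():
    ds, gt = toy_fixture("segregated_types")
    calls = calls_from_ground_truth(ds, gt)
    per_image, by_tls = patch_membership_stats(calls, [], ds, T_CELL_TYPES, "CXCL13")
    assert per_image.empty


def test_expressing_fractions_ground_truth_ratio():
    """Planted any-cytokine fraction ratio near the 5:1 design (±20 %)."""
    ds, gt = simulate(small_config(seed=21, cells_per_image=2000))
    calls = calls_from_ground_truth(ds, gt)
    frac = expressing_fractions(calls, ds).set_index("ie_label")["fraction"]
    ratio = frac["IE1"] / frac["IE2"]
    assert 4.0 <= ratio <= 6.0


def test_expressing_fraction_single_cell_zero():
    cells = pd.DataFrame([{"cell_id": "x1", "image_id": "img", "x_um": 1.0,
                           "y_um": 1.0, "radius_um": 5.0, "cell_type": "tumor"}])
    ds = wrap_image(cells)
    calls = pd.DataFrame({"cell_id": ["x1"], "cytokine": "CXCL9", "d": 0.0,
                          "p": 1.0, "q": 1.0, "expressed": False})
    frac = expressing_fractions(calls, ds)
    assert frac["fraction"].iloc[0] == 0.0
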