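"""Permutation interaction tests and kNN/contact statistics."""

import numpy as np
import pandas as pd
import pytest

from cytospatial.graphs import contact_graph, knn_lists
from cytospatial.neighborhoods import (
    direct_neighbor_fraction,
    distance_to_nearest,
    interaction_summary,
    knn_composition,
    knn_target_proportion,
    pairwise_permutation_test,
)
from cytospatial.synthetic import SimConfig, simulate, toy_fixture

from conftest import random_image, small_config, wrap_image


def test_single_type_image_all_p_one():
    rng = np.random.default_rng(0)
    cells = random_image(rng, 60, types=("tumor",))
    graph = contact_graph(cells)
    res = pairwise_permutation_test(cells, graph, n_perm=100, seed=1)
    assert len(res) == 1
    assert res["p_high"].iloc[0] == 1.0
    assert res["p_low"].iloc[0] == 1.0
    assert res["call"].iloc[0] == "ns"


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_segregated_types_called_avoidance_and_self_interaction(seed):
    ds, _ = toy_fixture("segregated_types")
    graph = contact_graph(ds.cells)
    res = pairwise_permutation_test(ds.cells, graph, n_perm=1000, seed=seed)
    r = res.set_index(["type_a", "type_b"])["call"]
    assert r[("tumor", "B")] == "avoidance"
    assert r[("B", "tumor")] == "avoidance"
    assert r[("tumor", "tumor")] == "interaction"
    assert r[("B", "B")] == "interaction"


def test_permutation_p_bounds_and_determinism():
    rng = np.random.default_rng(5)
    cells = random_image(rng, 150)
    graph = contact_graph(cells)
    res1 = pairwise_permutation_test(cells, graph, n_perm=200, seed=42)
    res2 = pairwise_permutation_test(cells, graph, n_perm=200, seed=42)
    pd.testing.assert_frame_equal(res1, res2)
    assert (res1["p_high"] >= 1 / 201).all() and (res1["p_high"] <= 1.0).all()
    assert (res1["p_low"] >= 1 / 201).all() and (res1["p_low"] <= 1.0).all()


def test_interaction_summary_arithmetic():
    rows = []
    for img, call in zip("abcd", ["interaction", "interaction", "interaction", "ns"]):
        rows.append({"image_id": img, "type_a": "x", "type_b": "y", "call": call})
    out = interaction_summary(pd.DataFrame(rows))
    rec = out.iloc[0]
    assert rec["frac_interaction"] == 0.75
    assert rec["frac_avoidance"] == 0.0
    assert rec["difference"] == 0.75


def test_interaction_summary_omits_unevaluable_pairs():
    out = interaction_summary(pd.DataFrame(columns=["image_id", "type_a", "type_b", "call"]))
    assert out.empty


def test_planted_attraction_recovered_across_images():
    cfg = small_config(seed=31, n_patients_per_ie=3, images_per_patient=2,
                       cells_per_image=1200,
                       tls_probabilities={"none": 1.0, "immature": 0.0, "mature": 0.0})
    ds, gt = simulate(cfg)
    frames = []
    for image_id in ds.image_ids():
        cells = ds.cells_of_image(image_id)
        graph = contact_graph(cells)
        frames.append(pairwise_permutation_test(cells, graph, n_perm=500, seed=7))
    res = pd.concat(frames, ignore_index=True)
    summary = interaction_summary(res).set_index(["type_a", "type_b"])
    att = summary.loc[("migDC", "T_CD8_PD1hi")]
    avo = summary.loc[("tumor", "B")]
    assert att["frac_interaction"] >= 0.9
    assert avo["frac_avoidance"] >= 0.9


def knn_composition_oracle(ds, k, query_subtypes):
    """Brute-force recomputation of the composition profile."""
    rows = []
    for image_id in ds.image_ids():
        cells = ds.cells_of_image(image_id)
        xy = cells[["x_um", "y_um"]].to_numpy(float)
        ids = cells["cell_id"].to_numpy()
        types = cells["cell_type"].to_numpy()
        for i in range(len(ids)):
            if types[i] not in query_subtypes:
                continue
            d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
            order = sorted(
                [j for j in range(len(ids)) if j != i], key=lambda j: (d[j], ids[j]))
            nbrs = [types[j] for j in order[:k]]
            vec = pd.Series(nbrs).value_counts(normalize=True)
            rows.append({"query_subtype": types[i], **vec.to_dict()})
    df = pd.DataFrame(rows).fillna(0.0)
    return df.groupby("query_subtype").mean()


def test_knn_composition_matches_bruteforce():
    rng = np.random.default_rng(8)
    cells = random_image(rng, 300)
    ds = wrap_image(cells)
    got = knn_composition(ds, k=10, query_subtypes=("T_CD8_PD1hi", "B"))
    want = knn_composition_oracle(ds, 10, ("T_CD8_PD1hi", "B"))
    got = got.set_index("query_subtype")
    for subtype in want.index:
        for col in want.columns:
            assert got.loc[subtype, col] == pytest.approx(want.loc[subtype, col], abs=1e-12)


def test_knn_composition_rows_sum_to_one(small_dataset):
    ds, _ = small_dataset
    out = knn_composition(ds, k=10)
    value_cols = [c for c in out.columns if c not in ("stratum", "query_subtype", "n_query")]
    sums = out[value_cols].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_planted_migdc_adjacency_raises_pd1hi_composition(small_dataset):
    """PD-1^high CD8 T cells co-clustered with migDCs see more migDC
    neighbors than PD-1^low CD8 T cells."""
    ds, _ = small_dataset
    out = knn_composition(ds, k=10, query_subtypes=("T_CD8_PD1hi", "T_CD8_PD1lo"),
                          stratify_by_tls=False)
    out = out.set_index("query_subtype")
    assert out.loc["T_CD8_PD1hi", "migDC"] > out.loc["T_CD8_PD1lo", "migDC"]


def test_direct_neighbor_fraction_recovers_planted_adjacency(small_dataset):
    ds, _ = small_dataset
    df, p = direct_neighbor_fraction(ds, "T_CD8_PD1hi", "T_CD8_PD1lo", "migDC")
    assert len(df) >= 3
    assert (df["fraction_a"] > df["fraction_b"]).mean() >= 0.9


def test_direct_neighbor_fraction_no_contact_gives_zero():
    ds, _ = toy_fixture("segregated_types")
    df, p = direct_neighbor_fraction(ds, "tumor", "B", "migDC")
    assert df.empty or ((df["fraction_a"] == 0).all() and (df["fraction_b"] == 0).all())


def test_direct_neighbor_fraction_too_few_patients_nan(small_dataset):
    ds, _ = small_dataset
    import dataclasses
    one_pat = ds.patients.iloc[:1]
    keep_imgs = ds.images[ds.images["patient_id"].isin(one_pat["patient_id"])]
    sub = dataclasses.replace(
        ds,
        cells=ds.cells[ds.cells["image_id"].isin(keep_imgs["image_id"])].reset_index(drop=True),
        images=keep_imgs.reset_index(drop=True),
        patients=one_pat.reset_index(drop=True),
    )
    df, p = direct_neighbor_fraction(sub, "T_CD8_PD1hi", "T_CD8_PD1lo", "migDC")
    assert np.isnan(p)


def test_distance_to_nearest_three_cell_line():
    ds, _ = toy_fixture("three_cell_line")
    # middle cell as its own type's query: nearest *other* cell is 20 μm
    out = distance_to_nearest(ds, ["t002"], "T_CD4_PD1lo")
    assert out["distance_um"].iloc[0] == pytest.approx(20.0)


def test_distance_to_nearest_matches_bruteforce():
    rng = np.random.default_rng(9)
    cells = random_image(rng, 400)
    ds = wrap_image(cells)
    queries = list(cells.loc[cells["cell_type"] == "myeloid", "cell_id"])
    out = distance_to_nearest(ds, queries, "T_CD8_PD1hi").set_index("cell_id")
    xy = cells.set_index("cell_id")[["x_um", "y_um"]]
    targets = cells.loc[cells["cell_type"] == "T_CD8_PD1hi", "cell_id"]
    for q in queries:
        want = min(
            np.hypot(*(xy.loc[q].to_numpy() - xy.loc[t].to_numpy())) for t in targets)
        assert out.loc[q, "distance_um"] == pytest.approx(want, abs=1e-9)


def test_distance_to_nearest_flags_missing_target():
    ds, _ = toy_fixture("three_cell_line")
    out = distance_to_nearest(ds, ["t001"], "migDC")
    assert not out["target_present"].iloc[0]
    assert np.isnan(out["distance_um"].iloc[0])


def test_knn_target_proportion_arithmetic():
    """4 candidate T cells, 1 flagged → proportion 0.25 with count 4."""
    rows = [{"cell_id": "q1", "image_id": "img", "x_um": 50.0, "y_um": 50.0,
             "radius_um": 5.0, "cell_type": "myeloid"}]
    coords = [(60, 50, "T_CD8_PD1hi"), (40, 50, "T_CD8_PD1lo"),
              (50, 60, "T_CD4_PD1lo"), (50, 40, "T_CD8_PD1lo")]
    for i, (x, y, t) in enumerate(coords):
        rows.append({"cell_id": f"n{i}", "image_id": "img", "x_um": float(x),
                     "y_um": float(y), "radius_um": 5.0, "cell_type": t})
    ds = wrap_image(pd.DataFrame(rows))
    out = knn_target_proportion(
        ds, ["q1"], candidate_types=("T_CD8_PD1hi", "T_CD8_PD1lo", "T_CD4_PD1lo",
                                     "T_CD4_PD1hi"), k=10, exclude=("T_reg",))
    assert out["n_candidates"].iloc[0] == 4
    assert out["proportion"].iloc[0] == pytest.approx(0.25)


def test_knn_target_proportion_matches_bruteforce():
    rng = np.random.default_rng(10)
    cells = random_image(rng, 300, types=("myeloid", "T_CD8_PD1hi", "T_CD8_PD1lo", "T_reg"))
    ds = wrap_image(cells)
    queries = list(cells.loc[cells["cell_type"] == "myeloid", "cell_id"])[:40]
    out = knn_target_proportion(
        ds, queries, candidate_types=("T_CD8_PD1hi", "T_CD8_PD1lo", "T_reg"),
        k=10, exclude=("T_reg",)).set_index("cell_id")
    oracle_lists = knn_lists(
        cells, k=10, restrict_to=("T_CD8_PD1hi", "T_CD8_PD1lo", "T_reg"),
        exclude=("T_reg",), queries=queries)
    type_of = cells.set_index("cell_id")["cell_type"]
    for q in queries:
        nbrs = oracle_lists.adjacency[q]
        want = np.mean([type_of[n] == "T_CD8_PD1hi" for n in nbrs])
        assert out.loc[q, "proportion"] == pytest.approx(want)
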