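"""End-to-end orchestration: simulate → call → patches → neighborhoods →
signatures → LR → IE comparison.

Every stage parameter defaults to the analysis constants the pipeline is
built around (8 μm contact expansion, 25 μm patch neighbor distance,
30 μm milieu dilation, k = 10, 1000 permutations, α = 0.01 for spatial
tests, LR threshold 0.4 and α = 0.05 for crosstalk enrichment). All
randomness flows from one root seed through stage-name-hashed
substreams, so re-running an identical configuration reproduces every
output byte for byte.

Feature-level IE1-vs-IE2 comparisons average per-image values within
each patient and apply an exact two-sided Wilcoxon rank-sum test across
patients (the ROI-averaged comparison), reporting group medians and
IQRs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import calling, crosstalk, neighborhoods, patches as patches_mod, signatures as sig_mod
from .core import (
    Dataset,
    DependencyError,
    PD1_HIGH_TYPES,
    T_CELL_TYPES,
    read_dataset,
    write_dataset,
)
from .graphs import contact_graph, radius_graph
from .stats import rank_sum_test
from .synthetic import GroundTruth, SimConfig, simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "call", "patches", "neighborhoods", "signatures", "lr", "compare")
FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Serializable run plan: stage toggles plus every stage parameter."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    dataset_path: str | None = None  # read instead of simulating
    alpha_calls: float = 0.01
    per_image_null: bool = False
    contact_expansion: float = 8.0
    contact_mode: str = "both"
    patch_radius: float = 25.0
    patch_min_size: int = 3
    milieu_dilation: float = 30.0
    alpha_enrichment: float = 0.01
    n_perm: int = 1000
    alpha_interactions: float = 0.01
    permutation_statistic: str = "mean"
    knn_k: int = 10
    membership_cytokine: str = "CXCL13"
    direct_neighbor_types: tuple[str, str, str] = ("T_CD8_PD1hi", "T_CD8_PD1lo", "migDC")
    signature_scale: float = 1e4
    random_signature_size: int = 6
    lr_threshold: float = 0.4
    lr_alpha: float = 0.05
    lr_min_mean: float = 0.4
    lr_min_cells: int = 10
    lr_top_n: int = 100
    lr_top_cv: int = 5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["stages"] = list(self.stages)
        d["direct_neighbor_types"] = list(self.direct_neighbor_types)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        kwargs = dict(d)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        for key in ("stages", "direct_neighbor_types"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in kwargs.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def stage_seed(root: int, name: str) -> int:
    """Deterministic sub-seed (< 2^31) for a named stage/substream."""
    ss = np.random.SeedSequence([int(root), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def ie_compare(features: pd.DataFrame, ds: Dataset) -> pd.DataFrame:
    """Patient-averaged Wilcoxon rank-sum comparison of per-image features.

    ``features`` has an ``image_id`` column plus numeric feature columns;
    per-image values are averaged within each patient (images with NaN
    skipped), then IE1 vs IE2 compared by the exact two-sided rank-sum
    test; group medians and IQRs accompany each p-value. Patients with no
    defined value for a feature are excluded (logged).
    """
    img2pat = ds.patient_of_image()
    pat2ie = ds.ie_of_patient()
    df = features.copy()
    df["patient_id"] = df["image_id"].map(img2pat)
    rows = []
    for feature in [c for c in features.columns if c != "image_id"]:
        per_pat = df.dropna(subset=[feature]).groupby("patient_id")[feature].mean()
        missing = set(pat2ie.index) - set(per_pat.index)
        if missing:
            log.info("feature %s undefined for patients %s; excluded", feature, sorted(missing))
        ie = per_pat.index.map(pat2ie)
        g1 = per_pat[ie == "IE1"].to_numpy()
        g2 = per_pat[ie == "IE2"].to_numpy()
        if g1.size < 2 or g2.size < 2:
            p = float("nan")
        elif np.ptp(np.concatenate([g1, g2])) == 0:
            p = 1.0
        else:
            p = rank_sum_test(g1, g2)
        def qt(g, q):
            return float(np.quantile(g, q)) if g.size else float("nan")
        rows.append((feature, g1.size, g2.size,
                     qt(g1, 0.5), qt(g1, 0.75) - qt(g1, 0.25),
                     qt(g2, 0.5), qt(g2, 0.75) - qt(g2, 0.25), p))
    return pd.DataFrame(
        rows, columns=["feature", "n_ie1", "n_ie2", "median_ie1", "iqr_ie1",
                       "median_ie2", "iqr_ie2", "p"])


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_ground_truth(gt: GroundTruth, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    flags = gt.expresser_flags.copy()
    flags.index.name = "cell_id"
    flags.reset_index().to_csv(path / "ground_truth_flags.csv", index=False)
    (path / "planted_patches.json").write_text(
        json.dumps(gt.planted_patch_members, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    _write(gt.pair_effects, path / "pair_effects.csv")
    (path / "signature_positive_cells.txt").write_text(
        "\n".join(gt.signature_positive_cells) + "\n", encoding="utf-8")


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order under ``outdir``.

    Returns a report dict (also written to ``report.json``). Raises
    :class:`DependencyError` when an enabled stage lacks its upstream
    input, either in memory or on disk from a previous invocation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    report: dict = {"seed": cfg.seed}
    t_all = time.perf_counter()

    ds: Dataset | None = None
    calls: pd.DataFrame | None = None

    def need_dataset(stage: str) -> Dataset:
        nonlocal ds
        if ds is None:
            src = Path(cfg.dataset_path) if cfg.dataset_path else outdir / "dataset"
            if not (src / "cells.csv").exists():
                raise DependencyError(
                    f"stage {stage!r} needs a dataset; run 'simulate' first or set dataset_path")
            ds = read_dataset(src)
        return ds

    def need_calls(stage: str) -> pd.DataFrame:
        nonlocal calls
        if calls is None:
            path = outdir / "calls.csv"
            if not path.exists():
                raise DependencyError(f"stage {stage!r} needs calls.csv; run 'call' first")
            calls = pd.read_csv(path, dtype={"cell_id": str})
        return calls

    if "simulate" in cfg.stages:
        t0 = time.perf_counter()
        sim_cfg = dataclasses.replace(cfg.sim, seed=stage_seed(cfg.seed, "simulate"))
        ds, gt = simulate(sim_cfg)
        write_dataset(ds, outdir / "dataset")
        write_ground_truth(gt, outdir / "ground_truth")
        report["n_cells"] = int(len(ds.cells))
        report["n_images"] = int(len(ds.images))
        log.info("simulate: %d cells in %.1fs", len(ds.cells), time.perf_counter() - t0)

    if "call" in cfg.stages:
        t0 = time.perf_counter()
        d = need_dataset("call")
        calls = calling.call_cytokines(d, alpha=cfg.alpha_calls, per_image=cfg.per_image_null)
        _write(calls, outdir / "calls.csv")
        report["n_expressing_cells"] = int(calling.expressing_any(calls).sum())
        log.info("call: %.1fs", time.perf_counter() - t0)

    if "patches" in cfg.stages:
        t0 = time.perf_counter()
        d = need_dataset("patches")
        c = need_calls("patches")
        all_patches, all_milieus = [], []
        for image_id in d.image_ids():
            img_cells = d.cells_of_image(image_id)
            if img_cells.empty:
                continue
            graph = radius_graph(img_cells, r=cfg.patch_radius)
            img_calls = c[c["cell_id"].isin(img_cells["cell_id"])]
            for kind in ("general", *d.cytokines):
                ps = patches_mod.detect_patches(
                    img_calls, graph, min_size=cfg.patch_min_size, kind=kind)
                all_patches.extend(ps)
                all_milieus.extend(
                    patches_mod.build_milieus(ps, img_cells, dilation=cfg.milieu_dilation))
        patch_rows = [(p.patch_id, p.image_id, p.kind, m)
                      for p in all_patches for m in p.member_ids]
        _write(pd.DataFrame(patch_rows, columns=["patch_id", "image_id", "kind", "cell_id"]),
               outdir / "patches.csv")
        milieu_rows = [(m.patch_id, m.image_id, m.kind, cid)
                       for m in all_milieus for cid in m.member_ids]
        _write(pd.DataFrame(milieu_rows, columns=["patch_id", "image_id", "kind", "cell_id"]),
               outdir / "milieus.csv")
        enr, summary = patches_mod.milieu_enrichment(d, all_milieus, alpha=cfg.alpha_enrichment)
        _write(enr, outdir / "enrichment.csv")
        _write(summary, outdir / "enrichment_summary.csv")
        fractions = patches_mod.expressing_fractions(c, d, by_ie=True, by_class=True)
        _write(fractions, outdir / "expressing_fractions.csv")
        per_img, by_tls = patches_mod.patch_membership_stats(
            c, all_patches, d, T_CELL_TYPES, cfg.membership_cytokine)
        _write(per_img, outdir / "patch_membership.csv")
        _write(by_tls, outdir / "patch_membership_by_tls.csv")
        report["n_patches"] = len(all_patches)
        ie_frac = patches_mod.expressing_fractions(c, d, by_ie=True, by_class=False)
        for rec in ie_frac.itertuples():
            report[f"expressing_fraction_{rec.ie_label}"] = float(rec.fraction)
        log.info("patches: %d patches in %.1fs", len(all_patches), time.perf_counter() - t0)

    if "neighborhoods" in cfg.stages:
        t0 = time.perf_counter()
        d = need_dataset("neighborhoods")
        inter_frames = []
        graphs = {}
        for image_id in d.image_ids():
            img_cells = d.cells_of_image(image_id)
            if img_cells.empty:
                continue
            graph = contact_graph(img_cells, expansion=cfg.contact_expansion,
                                  mode=cfg.contact_mode)
            graphs[image_id] = graph
            res = neighborhoods.pairwise_permutation_test(
                img_cells, graph, n_perm=cfg.n_perm, alpha=cfg.alpha_interactions,
                seed=stage_seed(cfg.seed, f"perm:{image_id}"),
                statistic=cfg.permutation_statistic)
            inter_frames.append(res)
        interactions = (pd.concat(inter_frames, ignore_index=True)
                        if inter_frames else pd.DataFrame())
        _write(interactions, outdir / "interactions.csv")
        _write(neighborhoods.interaction_summary(interactions), outdir / "interaction_summary.csv")
        comp = neighborhoods.knn_composition(d, k=cfg.knn_k)
        _write(comp, outdir / "composition.csv")
        ta, tb, tgt = cfg.direct_neighbor_types
        paired, p_paired = neighborhoods.direct_neighbor_fraction(d, ta, tb, tgt, graphs=graphs)
        _write(paired, outdir / "paired_fractions.csv")
        report["direct_neighbor_paired_p"] = None if np.isnan(p_paired) else float(p_paired)
        log.info("neighborhoods: %.1fs", time.perf_counter() - t0)

    if "signatures" in cfg.stages:
        t0 = time.perf_counter()
        d = need_dataset("signatures")
        if not d.gene_columns:
            raise DependencyError("stage 'signatures' needs gene counts (gx_ columns)")
        sigs = list(sig_mod.builtin_signatures().values())
        pool = [c[3:] for c in d.gene_columns]
        sigs.append(sig_mod.random_signature(pool, cfg.random_signature_size,
                                             seed=stage_seed(cfg.seed, "random-signature")))
        wide = sig_mod.score_signatures(d.cells, sigs, scale=cfg.signature_scale)
        long = wide.reset_index().melt(id_vars="cell_id", var_name="signature",
                                       value_name="score")
        _write(long.sort_values(["signature", "cell_id"]), outdir / "scores.csv")
        corr = sig_mod.signature_correlations(wide)
        _write(corr, outdir / "signature_correlations.csv")
        log.info("signatures: %.1fs", time.perf_counter() - t0)

    if "lr" in cfg.stages:
        t0 = time.perf_counter()
        d = need_dataset("lr")
        if not d.gene_columns:
            raise DependencyError("stage 'lr' needs gene counts (gx_ columns)")
        pairs = crosstalk.load_lr_pairs()
        pooled_expr = crosstalk.mean_expression(d.cells, min_cells=cfg.lr_min_cells)
        pooled = crosstalk.lr_score(pooled_expr, pairs)
        _write(pooled, outdir / "lr_scores.csv")
        _write(crosstalk.count_interactions(pooled, threshold=cfg.lr_threshold),
               outdir / "lr_counts.csv")
        _write(crosstalk.specific_interactions(pooled, top_n=cfg.lr_top_n, top_cv=cfg.lr_top_cv),
               outdir / "lr_specific.csv")
        from .core import CELL_CLASSES
        per_pat = crosstalk.per_patient_scores(
            d, pairs, min_cells=cfg.lr_min_cells, group_map=CELL_CLASSES)
        _write(per_pat, outdir / "lr_patient_scores.csv")
        enriched = crosstalk.ie_enrichment(per_pat, d.ie_of_patient(),
                                           alpha=cfg.lr_alpha, min_mean=cfg.lr_min_mean)
        _write(enriched, outdir / "ie_enriched.csv")
        report["n_lr_retained"] = int(enriched["retained"].sum()) if len(enriched) else 0
        log.info("lr: %.1fs", time.perf_counter() - t0)

    if "compare" in cfg.stages:
        t0 = time.perf_counter()
        d = need_dataset("compare")
        c = need_calls("compare")
        features = patches_mod.expressing_fraction_per_image(c, d)
        comparison = ie_compare(features, d)
        _write(comparison, outdir / "ie_comparison.csv")
        for rec in comparison.itertuples():
            report[f"compare_{rec.feature}_p"] = float(rec.p)
        log.info("compare: %.1fs", time.perf_counter() - t0)

    report["runtime_s"] = round(time.perf_counter() - t_all, 2)
    payload = {k: v for k, v in sorted(report.items()) if k != "runtime_s"}
    (outdir / "report.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return report
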