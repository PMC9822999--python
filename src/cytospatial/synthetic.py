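"""Synthetic multiplexed-imaging cell tables with known ground truth.

The generator emulates 1 mm × 1 mm regions of breast-tumor tissue with
~4,000 segmented cells each, a fixed immune/stromal/tumor cell-type
palette, and the statistical structure the downstream analyses assume:

* Poisson probe backgrounds — every cell draws ``cy_DapB ~ Pois(λ0)``
  and, per cytokine, ``Pois(λ0)`` when non-expressing or ``Pois(λ0+Δ)``
  when expressing (Δ additive on the rate scale);
* planted cytokine expressers, partly dispersed and partly in compact
  spatial clusters (the future patches), with an ~5× higher
  expressing-cell fraction in IE1 than in IE2;
* pairwise attraction via a shared-parent (Thomas-type) cluster process
  and avoidance via thinning of one type near clustered cells of the
  other;
* TLS-like B-cell aggregates (mature: dense disc, immature: loose
  Gaussian cloud);
* per-cell gene counts for the signature and ligand–receptor modules,
  with co-elevated attraction/suppression genes in designated myeloid
  cells and checkpoint/chemokine ligand boosts in IE1 patients.

Identical :class:`SimConfig` ⇒ identical output, byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    CELL_CLASSES,
    ConfigurationError,
    DEFAULT_PALETTE,
    Dataset,
    NEGATIVE_PROBE_COLUMN,
    make_dataset,
)
from .crosstalk import load_lr_pairs
from .signatures import builtin_signatures

DEFAULT_CYTOKINES = (
    "CXCL9", "CXCL10", "CXCL13", "CCL2", "CCL4",
    "CCL5", "CCL17", "CCL18", "CCL22", "IL10",
)

#: Cell-type composition per immune environment. IE1 carries the
#: exhaustion-like PD-1^high T-cell compartment; IE2 nearly lacks it.
DEFAULT_TYPE_FREQUENCIES = {
    "IE1": {
        "tumor": 0.40, "fibroblast": 0.15, "endothelial": 0.06, "B": 0.05,
        "plasma": 0.02, "NK": 0.02, "NKT": 0.01, "pDC": 0.01, "migDC": 0.02,
        "myeloid": 0.12, "T_reg": 0.03, "T_CD4_PD1hi": 0.02, "T_CD4_PD1lo": 0.01,
        "T_CD8_PD1hi": 0.05, "T_CD8_PD1lo": 0.03,
    },
    "IE2": {
        "tumor": 0.40, "fibroblast": 0.15, "endothelial": 0.06, "B": 0.05,
        "plasma": 0.02, "NK": 0.02, "NKT": 0.01, "pDC": 0.01, "migDC": 0.02,
        "myeloid": 0.12, "T_reg": 0.03, "T_CD4_PD1hi": 0.005, "T_CD4_PD1lo": 0.04,
        "T_CD8_PD1hi": 0.005, "T_CD8_PD1lo": 0.06,
    },
}

#: Per-cytokine expressing fraction; the planted IE1:IE2 contrast is 5:1.
DEFAULT_EXPRESSER_FRACTION = {
    "IE1": {c: 0.015 for c in DEFAULT_CYTOKINES},
    "IE2": {c: 0.003 for c in DEFAULT_CYTOKINES},
}

DEFAULT_TLS_PROBABILITIES = {"none": 0.75, "immature": 0.125, "mature": 0.125}

#: Mean expression rates (counts) of ligand genes by coarse cell class.
LIGAND_RATES = {
    "CD274": {"myeloid": 0.6, "tumor": 0.4}, "CD80": {"myeloid": 0.6},
    "LGALS9": {"myeloid": 0.6}, "PVR": {"myeloid": 0.5, "tumor": 0.4},
    "CCL3": {"myeloid": 1.0}, "CCL4": {"myeloid": 1.0, "T_NK": 0.8},
    "CCL5": {"T_NK": 1.2, "myeloid": 0.6}, "CXCL9": {"myeloid": 0.8},
    "CXCL10": {"myeloid": 0.8}, "CXCL13": {"T_NK": 0.4, "stromal": 0.5},
    "CCL17": {"myeloid": 0.9}, "CCL22": {"myeloid": 0.9}, "CCL18": {"myeloid": 1.0},
    "CSF1": {"stromal": 0.8, "tumor": 0.6}, "IL15": {"myeloid": 0.6, "stromal": 0.5},
    "IL10": {"myeloid": 0.6, "T_NK": 0.4}, "FLT3LG": {"T_NK": 1.0},
    "IL21": {"T_NK": 0.5}, "IL13": {"T_NK": 0.3},
    "TGFB1": {"myeloid": 0.8, "stromal": 0.8, "tumor": 0.6},
}

RECEPTOR_RATES = {
    "PDCD1": {"T_NK": 2.0}, "CTLA4": {"T_NK": 1.5},
    "HAVCR2": {"T_NK": 1.5, "myeloid": 0.8}, "TIGIT": {"T_NK": 1.5},
    "CCR5": {"T_NK": 1.5, "myeloid": 0.8}, "CXCR3": {"T_NK": 1.8},
    "CXCR5": {"B_lineage": 1.8, "T_NK": 0.6}, "CCR4": {"T_NK": 1.5},
    "CCR8": {"T_NK": 0.8}, "CSF1R": {"myeloid": 2.0}, "IL15RA": {"T_NK": 1.2},
    "IL10RA": {"T_NK": 1.0, "myeloid": 1.0}, "FLT3": {"myeloid": 1.5},
    "IL21R": {"B_lineage": 1.2, "T_NK": 0.8}, "IL13RA1": {"myeloid": 1.0},
    "TGFBR1": {"T_NK": 0.8, "stromal": 0.8},
}

#: Genes whose expression is multiplied in IE1 (checkpoint ligands and
#: chemotactic/activating cytokines) or IE2 (FLT3 ligand) patients.
DEFAULT_IE1_BOOST = {
    "CD274": 4.0, "CD80": 4.0, "LGALS9": 4.0, "PVR": 4.0,
    "CCL3": 3.0, "CCL4": 3.0, "CCL5": 3.0, "CXCL9": 3.0,
    "CSF1": 3.0, "IL15": 3.0, "IL10": 3.0,
}
DEFAULT_IE2_BOOST = {"FLT3LG": 3.0}

#: The checkpoint interactions expected to surface as IE1-enriched
#: myeloid → T-cell crosstalk (used by recovery analyses).
BOOSTED_CHECKPOINT_PAIRS = (
    ("CD274", "PDCD1"), ("CD80", "CTLA4"), ("LGALS9", "HAVCR2"), ("PVR", "TIGIT"),
)


@dataclass
class SimConfig:
    """Full parameterization of the generator; the seed fixes everything."""

    seed: int = 0
    n_patients_per_ie: int = 7
    images_per_patient: int = 4
    image_size: float = 1000.0
    cells_per_image: int = 4000
    type_frequencies: dict = field(default_factory=lambda: {
        ie: dict(v) for ie, v in DEFAULT_TYPE_FREQUENCIES.items()})
    cytokines: tuple[str, ...] = DEFAULT_CYTOKINES
    dapb_rate: float = 1.0           # λ0, background probe rate
    expresser_boost: float = 5.0     # Δ, added rate for expressing cells
    expresser_fraction: dict = field(default_factory=lambda: {
        ie: dict(v) for ie, v in DEFAULT_EXPRESSER_FRACTION.items()})
    patch_rate: float = 2.0          # mean planted clusters / image / cytokine
    patch_sigma: float = 15.0        # nominal spread of a planted cluster (μm)
    patch_size_range: tuple[int, int] = (4, 8)
    attraction_pairs: tuple = (("migDC", "T_CD8_PD1hi", 0.8),)
    avoidance_pairs: tuple = (("tumor", "B", 0.9),)
    attraction_sigma: float = 20.0   # parent-offspring spread (μm)
    attraction_cluster_size: float = 6.0
    avoidance_radius: float = 40.0
    avoidance_cluster_fraction: float = 0.7
    avoidance_cluster_size: float = 40.0
    avoidance_sigma: float = 60.0
    tls_probabilities: dict = field(default_factory=lambda: dict(DEFAULT_TLS_PROBABILITIES))
    mature_tls_radius: float = 80.0
    immature_tls_sigma: float = 120.0
    tls_b_fraction: float = 0.7
    radius_median: float = 5.0
    radius_sigma: float = 0.35
    radius_clip: tuple[float, float] = (2.0, 15.0)
    with_markers: bool = True
    with_genes: bool = True
    n_filler_genes: int = 60
    filler_rate: float = 1.0
    gene_base_rate: float = 0.2
    sig_positive_fraction: float = 0.3
    sig_factor: float = 8.0
    ie1_gene_boost: dict = field(default_factory=lambda: dict(DEFAULT_IE1_BOOST))
    ie2_gene_boost: dict = field(default_factory=lambda: dict(DEFAULT_IE2_BOOST))

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v
        return {k: conv(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        def tup(v):
            return tuple(tup(x) if isinstance(x, list) else x for x in v)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            kwargs[f.name] = tup(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def validate(self) -> None:
        if self.cells_per_image < 1 or self.n_patients_per_ie < 1 or self.images_per_patient < 1:
            raise ConfigurationError("sizes must be positive")
        for ie, freqs in self.type_frequencies.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(f"type frequencies for {ie} sum to {s}, not 1")
            if any(v < 0 for v in freqs.values()):
                raise ConfigurationError("type frequencies must be ≥ 0")
        for rates in (self.dapb_rate, self.expresser_boost, self.patch_rate,
                      self.filler_rate, self.gene_base_rate):
            if rates < 0:
                raise ConfigurationError("rates must be ≥ 0")
        for ie, fr in self.expresser_fraction.items():
            if any(not (0 <= v <= 1) for v in fr.values()):
                raise ConfigurationError("expresser fractions must lie in [0, 1]")
        for a, b, theta in tuple(self.attraction_pairs) + tuple(self.avoidance_pairs):
            if theta < 0:
                raise ConfigurationError("pair strengths must be ≥ 0")
        if self.patch_size_range[0] > self.cells_per_image:
            raise ConfigurationError(
                "requested cluster size exceeds cells_per_image")
        if abs(sum(self.tls_probabilities.values()) - 1.0) > 1e-9:
            raise ConfigurationError("tls probabilities must sum to 1")


@dataclass
class GroundTruth:
    """The planted structure, keyed by the emitted identifiers."""

    expresser_flags: pd.DataFrame  # bool matrix, index cell_id × cytokine
    planted_patch_members: dict    # image_id → cytokine → list of member-id lists
    pair_effects: pd.DataFrame     # type_a, type_b, kind, strength
    signature_positive_cells: tuple[str, ...]


def _gene_palette(cfg: SimConfig) -> list[str]:
    sigs = builtin_signatures()
    genes: list[str] = []
    for s in sigs.values():
        genes.extend(s.genes)
    for p in load_lr_pairs():
        genes.extend([p.ligand, p.receptor])
    genes = sorted(set(genes))
    genes += [f"HK{i:02d}" for i in range(1, cfg.n_filler_genes + 1)]
    return genes


def _gene_rates(cfg: SimConfig, genes: Sequence[str]) -> dict[str, dict[str, float]]:
    """gene → class → Poisson rate (before IE boosts)."""
    classes = sorted(set(CELL_CLASSES.values()))
    rates = {g: {c: cfg.gene_base_rate for c in classes} for g in genes}
    for g in genes:
        if g.startswith("HK"):
            for c in classes:
                rates[g][c] = cfg.filler_rate
    for table in (LIGAND_RATES, RECEPTOR_RATES):
        for g, per_class in table.items():
            if g in rates:
                for c, v in per_class.items():
                    rates[g][c] = v
    return rates


def _place_uniform(rng, n, size):
    return rng.uniform(0.0, size, size=(n, 2))


def _clip(pos, size):
    return np.clip(pos, 0.0, size)


def _simulate_image(cfg, rng, ie, image_id, tls_status, id_start):
    """Positions, types, radii and cytokine flags for one image."""
    palette = list(cfg.type_frequencies[ie].keys())
    probs = np.array([cfg.type_frequencies[ie][t] for t in palette])
    counts = rng.multinomial(cfg.cells_per_image, probs)
    types = np.repeat(palette, counts)
    n = types.size
    size = cfg.image_size
    pos = np.full((n, 2), np.nan)
    placed = np.zeros(n, dtype=bool)

    # TLS-like B-cell aggregate
    if tls_status != "none":
        b_idx = np.flatnonzero(types == "B")
        n_agg = int(round(cfg.tls_b_fraction * b_idx.size))
        agg = rng.choice(b_idx, size=n_agg, replace=False) if n_agg else np.array([], int)
        if agg.size:
            if tls_status == "mature":
                r_tls = cfg.mature_tls_radius
                center = rng.uniform(r_tls, size - r_tls, size=2)
                rr = r_tls * np.sqrt(rng.uniform(0, 1, agg.size))
                th = rng.uniform(0, 2 * np.pi, agg.size)
                pos[agg] = center + np.c_[rr * np.cos(th), rr * np.sin(th)]
            else:
                margin = min(cfg.immature_tls_sigma, size / 4)
                center = rng.uniform(margin, size - margin, size=2)
                pos[agg] = _clip(center + rng.normal(0, cfg.immature_tls_sigma, (agg.size, 2)), size)
            placed[agg] = True

    # attraction: shared-parent Thomas-type clusters
    for type_a, type_b, theta in cfg.attraction_pairs:
        ia = np.flatnonzero((types == type_a) & ~placed)
        ib = np.flatnonzero((types == type_b) & ~placed)
        na_c = int(round(min(theta, 1.0) * ia.size))
        nb_c = int(round(min(theta, 1.0) * ib.size))
        if na_c == 0 or nb_c == 0:
            continue
        k = max(1, int(round(min(na_c, nb_c) / cfg.attraction_cluster_size)))
        margin = min(3 * cfg.attraction_sigma, size / 4)
        parents = rng.uniform(margin, size - margin, size=(k, 2))
        for idx_pool, n_c in ((ia, na_c), (ib, nb_c)):
            chosen = rng.choice(idx_pool, size=n_c, replace=False)
            assign = rng.integers(0, k, size=n_c)
            pos[chosen] = _clip(
                parents[assign] + rng.normal(0, cfg.attraction_sigma, (n_c, 2)), size)
            placed[chosen] = True

    # avoidance: cluster A, thin B proposals near A
    for type_a, type_b, theta in cfg.avoidance_pairs:
        ia = np.flatnonzero((types == type_a) & ~placed)
        if ia.size:
            na_c = int(round(cfg.avoidance_cluster_fraction * ia.size))
            if na_c:
                k = max(1, int(round(na_c / cfg.avoidance_cluster_size)))
                margin = min(2 * cfg.avoidance_sigma, size / 4)
                parents = rng.uniform(margin, size - margin, size=(k, 2))
                chosen = rng.choice(ia, size=na_c, replace=False)
                assign = rng.integers(0, k, size=na_c)
                pos[chosen] = _clip(
                    parents[assign] + rng.normal(0, cfg.avoidance_sigma, (na_c, 2)), size)
                placed[chosen] = True
            rest = np.flatnonzero((types == type_a) & ~placed)
            pos[rest] = _place_uniform(rng, rest.size, size)
            placed[rest] = True
        a_pos = pos[types == type_a]
        ib = np.flatnonzero((types == type_b) & ~placed)
        if ib.size and a_pos.size:
            tree = cKDTree(a_pos)
            pending = ib.copy()
            for _ in range(60):
                if pending.size == 0:
                    break
                prop = _place_uniform(rng, pending.size, size)
                near = np.array([len(h) > 0 for h in
                                 tree.query_ball_point(prop, cfg.avoidance_radius)])
                reject = near & (rng.uniform(size=pending.size) < theta)
                pos[pending[~reject]] = prop[~reject]
                placed[pending[~reject]] = True
                pending = pending[reject]
            if pending.size:  # give up thinning; accept uniform
                pos[pending] = _place_uniform(rng, pending.size, size)
                placed[pending] = True

    rest = np.flatnonzero(~placed)
    pos[rest] = _place_uniform(rng, rest.size, size)

    radii = np.exp(rng.normal(np.log(cfg.radius_median), cfg.radius_sigma, n))
    radii = np.clip(radii, *cfg.radius_clip)

    cell_ids = np.array([f"c{id_start + i:07d}" for i in range(n)])

    # cytokine expresser flags, partly in planted spatial clusters; the
    # cytokines claim disjoint cell sets, so the fraction of cells
    # expressing ≥1 cytokine is exactly the sum of per-cytokine fractions
    # (and the planted IE1:IE2 contrast carries over to the any-cytokine
    # level undiluted)
    flags = np.zeros((n, len(cfg.cytokines)), dtype=bool)
    planted: dict[str, list[list[str]]] = {}
    tree_all = cKDTree(pos)
    lo, hi = cfg.patch_size_range
    total_frac = sum(cfg.expresser_fraction[ie].get(c, 0.0) for c in cfg.cytokines)
    if total_frac > 1:
        raise ConfigurationError(
            f"expresser fractions for {ie} sum to {total_frac} > 1")
    any_flagged = np.zeros(n, dtype=bool)
    for j, cyt in enumerate(cfg.cytokines):
        frac = cfg.expresser_fraction[ie].get(cyt, 0.0)
        n_expr = min(rng.binomial(n, frac), int(np.sum(~any_flagged)))
        if n_expr == 0:
            continue
        n_clusters = rng.poisson(cfg.patch_rate)
        clusters: list[list[str]] = []
        remaining = n_expr
        for _ in range(n_clusters):
            csize = int(rng.integers(lo, hi + 1))
            if csize > remaining:
                break
            center = rng.uniform(0, size, size=2)
            order = tree_all.query(center, k=min(4 * csize + 8, n))[1]
            order = np.atleast_1d(order)
            members = [i for i in order if not any_flagged[i]][:csize]
            if len(members) < csize:
                break
            any_flagged[members] = True
            flags[members, j] = True
            remaining -= csize
            clusters.append([cell_ids[i] for i in sorted(members)])
        if remaining > 0:
            pool = np.flatnonzero(~any_flagged)
            extra = rng.choice(pool, size=min(remaining, pool.size), replace=False)
            any_flagged[extra] = True
            flags[extra, j] = True
        if clusters:
            planted[cyt] = clusters

    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "image_id": image_id,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "radius_um": radii,
            "cell_type": types,
        }
    )
    return df, flags, planted


_MARKER_SPEC = {
    "CD20": ("B", "plasma"),
    "CD3": ("T_reg", "T_CD4_PD1hi", "T_CD4_PD1lo", "T_CD8_PD1hi", "T_CD8_PD1lo", "NKT"),
    "CD68": ("myeloid", "migDC", "pDC"),
    "panCK": ("tumor",),
    "PD1": ("T_CD4_PD1hi", "T_CD8_PD1hi"),
}


def _draw_markers(rng, types: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for marker, positive in _MARKER_SPEC.items():
        base = np.exp(rng.normal(np.log(0.2), 0.5, types.size))
        high = np.exp(rng.normal(np.log(4.0), 0.5, types.size))
        out[f"mk_{marker}"] = np.where(np.isin(types, positive), high, base)
    return out


def simulate(cfg: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a Dataset and its GroundTruth from ``cfg``. Deterministic."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes = _gene_palette(cfg) if cfg.with_genes else []
    rates = _gene_rates(cfg, genes) if cfg.with_genes else {}
    sig_genes = set()
    if cfg.with_genes:
        sigs = builtin_signatures()
        sig_genes = set(sigs["t_attraction"].genes) | set(sigs["t_suppression"].genes)

    cell_frames, image_rows, patient_rows = [], [], []
    flag_blocks, planted_all = [], {}
    sig_positive_all: list[str] = []
    id_start = 0
    tls_levels = list(cfg.tls_probabilities.keys())
    tls_p = np.array([cfg.tls_probabilities[t] for t in tls_levels])

    for ie in ("IE1", "IE2"):
        for p in range(1, cfg.n_patients_per_ie + 1):
            patient_id = f"{ie}_P{p:02d}"
            patient_rows.append((patient_id, ie, int(rng.integers(1, 4))))
            for im in range(1, cfg.images_per_patient + 1):
                image_id = f"{patient_id}_img{im}"
                tls_status = tls_levels[rng.choice(len(tls_levels), p=tls_p)]
                image_rows.append(
                    (image_id, patient_id, cfg.image_size, cfg.image_size, tls_status))
                df, flags, planted = _simulate_image(
                    cfg, rng, ie, image_id, tls_status, id_start)
                id_start += len(df)
                n = len(df)
                types = df["cell_type"].to_numpy()

                # probe counts
                df[NEGATIVE_PROBE_COLUMN] = rng.poisson(cfg.dapb_rate, n).astype(float)
                for j, cyt in enumerate(cfg.cytokines):
                    base = rng.poisson(cfg.dapb_rate, n)
                    extra = np.where(flags[:, j], rng.poisson(cfg.expresser_boost, n), 0)
                    df[f"cy_{cyt}"] = (base + extra).astype(float)

                if cfg.with_markers:
                    for col, vals in _draw_markers(rng, types).items():
                        df[col] = vals

                if cfg.with_genes:
                    cls = np.array([CELL_CLASSES[t] for t in types])
                    myeloid = np.isin(types, ("myeloid", "migDC"))
                    n_pos = int(round(cfg.sig_positive_fraction * myeloid.sum()))
                    pos_idx = (rng.choice(np.flatnonzero(myeloid), size=n_pos, replace=False)
                               if n_pos else np.array([], int))
                    sig_pos = np.zeros(n, dtype=bool)
                    sig_pos[pos_idx] = True
                    sig_positive_all.extend(df["cell_id"].to_numpy()[pos_idx])
                    boost = cfg.ie1_gene_boost if ie == "IE1" else cfg.ie2_gene_boost
                    gene_cols = {}
                    for g in genes:
                        rate = np.array([rates[g][c] for c in cls])
                        if g in boost:
                            rate = rate * boost[g]
                        if g in sig_genes:
                            rate = np.where(sig_pos, rate * cfg.sig_factor, rate)
                        gene_cols[f"gx_{g}"] = rng.poisson(rate).astype(float)
                    df = pd.concat([df, pd.DataFrame(gene_cols, index=df.index)], axis=1)

                cell_frames.append(df)
                flag_blocks.append(
                    pd.DataFrame(flags, index=df["cell_id"], columns=list(cfg.cytokines)))
                if planted:
                    planted_all[image_id] = planted

    cells = pd.concat(cell_frames, ignore_index=True)
    images = pd.DataFrame(
        image_rows, columns=["image_id", "patient_id", "width_um", "height_um", "tls_status"])
    patients = pd.DataFrame(patient_rows, columns=["patient_id", "ie_label", "grade"])
    ds = make_dataset(cells, images, patients,
                      palette=DEFAULT_PALETTE, cytokines=cfg.cytokines)
    effects = [(a, b, "attraction", t) for a, b, t in cfg.attraction_pairs]
    effects += [(a, b, "avoidance", t) for a, b, t in cfg.avoidance_pairs]
    gt = GroundTruth(
        expresser_flags=pd.concat(flag_blocks),
        planted_patch_members=planted_all,
        pair_effects=pd.DataFrame(effects, columns=["type_a", "type_b", "kind", "strength"]),
        signature_positive_cells=tuple(sig_positive_all),
    )
    return ds, gt


def calls_from_ground_truth(ds: Dataset, gt: GroundTruth) -> pd.DataFrame:
    """A noiseless call table taken directly from planted flags (used to
    exercise patch/milieu logic independently of the calling stage)."""
    frames = []
    flags = gt.expresser_flags
    for cyt in ds.cytokines:
        expressed = flags[cyt].reindex(ds.cells["cell_id"]).fillna(False).to_numpy(bool)
        frames.append(pd.DataFrame({
            "cell_id": ds.cells["cell_id"].to_numpy(),
            "cytokine": cyt,
            "d": np.where(expressed, 1.0, 0.0),
            "p": np.where(expressed, 0.0, 1.0),
            "q": np.where(expressed, 0.0, 1.0),
            "expressed": expressed,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# hand-specified micro-datasets with exactly known outputs
# ---------------------------------------------------------------------------

TOY_FIXTURES = ("three_cell_line", "two_patch_image", "segregated_types")


def _toy_tables(cell_specs, cytokine="CXCL13"):
    """cell_specs: list of (x, y, cell_type, expressed)."""
    rows = []
    for i, (x, y, t, expr) in enumerate(cell_specs, start=1):
        rows.append({
            "cell_id": f"t{i:03d}", "image_id": "toy_img1", "x_um": float(x),
            "y_um": float(y), "radius_um": 5.0, "cell_type": t,
            "cy_DapB": 0.0, f"cy_{cytokine}": 50.0 if expr else 0.0,
        })
    cells = pd.DataFrame(rows)
    images = pd.DataFrame([{
        "image_id": "toy_img1", "patient_id": "toy_P1", "width_um": 1000.0,
        "height_um": 1000.0, "tls_status": "none"}])
    patients = pd.DataFrame([{"patient_id": "toy_P1", "ie_label": "IE1", "grade": 2}])
    expressed = np.array([s[3] for s in cell_specs], dtype=bool)
    return cells, images, patients, expressed


def toy_fixture(name: str) -> tuple[Dataset, GroundTruth]:
    """Deterministic micro-datasets from a documented catalogue.

    * ``three_cell_line`` — 3 CXCL13⁺ T cells at (0,0), (20,0), (40,0).
    * ``two_patch_image`` — two planted 4-cell CXCL13 patches 200 μm
      apart, 5 isolated CXCL13⁺ T cells, and 6 non-expressing tumor cells
      (two within 30 μm of the first patch, one within 30 μm of the
      second, three far away).
    * ``segregated_types`` — two 10×10 contact-dense blocks of tumor and
      B cells in opposite image halves.
    """
    if name == "three_cell_line":
        specs = [(0, 0, "T_CD4_PD1lo", True), (20, 0, "T_CD4_PD1lo", True),
                 (40, 0, "T_CD4_PD1lo", True)]
        planted = {"toy_img1": {"CXCL13": [["t001", "t002", "t003"]]}}
    elif name == "two_patch_image":
        patch_a = [(200, 200), (215, 200), (200, 215), (215, 215)]
        patch_b = [(400, 200), (415, 200), (400, 215), (415, 215)]
        isolated = [(700, 100), (760, 160), (700, 300), (100, 700), (300, 700)]
        tumor = [(240, 200), (230, 240), (430, 230), (500, 500), (520, 520), (900, 900)]
        specs = ([(x, y, "T_CD4_PD1lo", True) for x, y in patch_a + patch_b]
                 + [(x, y, "T_CD4_PD1lo", True) for x, y in isolated]
                 + [(x, y, "tumor", False) for x, y in tumor])
        planted = {"toy_img1": {"CXCL13": [
            [f"t{i:03d}" for i in range(1, 5)], [f"t{i:03d}" for i in range(5, 9)]]}}
    elif name == "segregated_types":
        specs = []
        for gx in range(10):
            for gy in range(10):
                specs.append((50 + 20 * gx, 50 + 20 * gy, "tumor", False))
        for gx in range(10):
            for gy in range(10):
                specs.append((750 + 20 * gx, 50 + 20 * gy, "B", False))
        planted = {}
    else:
        raise KeyError(f"unknown toy fixture {name!r}; available: {TOY_FIXTURES}")
    cells, images, patients, expressed = _toy_tables(specs)
    ds = make_dataset(cells, images, patients, cytokines=("CXCL13",))
    flags = pd.DataFrame({"CXCL13": expressed}, index=pd.Index(cells["cell_id"], name="cell_id"))
    gt = GroundTruth(
        expresser_flags=flags,
        planted_patch_members=planted,
        pair_effects=pd.DataFrame(columns=["type_a", "type_b", "kind", "strength"]),
        signature_positive_cells=(),
    )
    return ds, gt


def null_config(**overrides) -> SimConfig:
    """A configuration with no planted structure of any kind: no
    expressers, no attraction/avoidance, no TLS aggregates."""
    base = dict(
        expresser_fraction={"IE1": {c: 0.0 for c in DEFAULT_CYTOKINES},
                            "IE2": {c: 0.0 for c in DEFAULT_CYTOKINES}},
        attraction_pairs=(),
        avoidance_pairs=(),
        tls_probabilities={"none": 1.0, "immature": 0.0, "mature": 0.0},
    )
    base.update(overrides)
    return SimConfig(**base)
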