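"""Per-cell gene-signature scoring and score correlations.

A signature is a plain gene list (T cell attraction, T cell suppression,
M1, M2, plus a seeded random control). The per-cell score is a sum of
library-normalized, log-transformed counts:

    score_c = Σ_{g ∈ signature} log(1 + scale · count_gc / total_c)

with ``scale = 1e4`` (counts-per-10k) and natural log with pseudocount 1.
Normalizing by the total cellular count and log-transforming damps the
relative dominance of highly expressed genes; the score is invariant
under uniform per-cell count scaling and strictly increasing in any
signature-gene count at fixed total.

Scores are compared by Spearman correlation at cell, cluster, or patient
level; a random control signature of matched size should correlate with
neither biological signature.

The shipped ``signatures/*.txt`` gene lists are editable defaults — one
gene symbol per line — and users are expected to substitute their own.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Dataset, DomainError, GENE_PREFIX
from .stats import spearman_corr

log = logging.getLogger(__name__)

BUILTIN_SIGNATURES = ("t_attraction", "t_suppression", "m1", "m2")


@dataclass(frozen=True)
class Signature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise DomainError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DomainError(f"signature {self.name!r} has duplicate genes")


def load_signature(path: str | Path, name: str | None = None) -> Signature:
    """Load a one-gene-per-line text file."""
    path = Path(path)
    genes = tuple(
        line.strip() for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )
    return Signature(name=name or path.stem, genes=genes)


def builtin_signatures() -> dict[str, Signature]:
    """The packaged default signatures."""
    out = {}
    base = resources.files("cytospatial") / "signatures"
    for name in BUILTIN_SIGNATURES:
        out[name] = load_signature(Path(str(base / f"{name}.txt")), name=name)
    return out


def random_signature(gene_pool: Sequence[str], size: int, seed: int) -> Signature:
    """Seeded random control signature drawn from ``gene_pool``."""
    if size < 1 or size > len(set(gene_pool)):
        raise DomainError("random signature size out of range")
    rng = np.random.default_rng(seed)
    genes = tuple(rng.choice(sorted(set(gene_pool)), size=size, replace=False))
    return Signature(name=f"random_{seed}_{size}", genes=genes)


def score_signature(
    cells: pd.DataFrame, sig: Signature, scale: float = 1e4
) -> pd.DataFrame:
    """Score one signature for every cell with gene counts.

    Cells with zero total count are excluded with a warning; signature
    genes absent from the count table contribute 0 and are logged.
    """
    gene_cols = [c for c in cells.columns if c.startswith(GENE_PREFIX)]
    if not gene_cols:
        raise DomainError("no gene-count (gx_) columns present")
    counts = cells[gene_cols].to_numpy(float)
    totals = counts.sum(axis=1)
    ok = totals > 0
    if not np.all(ok):
        log.warning("%d cells with zero total gene count excluded from scoring", (~ok).sum())
    available = {c[len(GENE_PREFIX):]: i for i, c in enumerate(gene_cols)}
    missing = [g for g in sig.genes if g not in available]
    if missing:
        log.warning("signature %s: genes missing from count table: %s", sig.name, missing)
    idx = [available[g] for g in sig.genes if g in available]
    score = np.zeros(len(cells))
    if idx:
        norm = scale * counts[:, idx] / np.where(ok, totals, 1.0)[:, None]
        score = np.log1p(norm).sum(axis=1)
    out = pd.DataFrame(
        {"cell_id": cells["cell_id"].to_numpy(), "signature": sig.name, "score": score}
    )
    return out[ok].reset_index(drop=True)


def score_signatures(
    cells: pd.DataFrame, sigs: Sequence[Signature], scale: float = 1e4
) -> pd.DataFrame:
    """Wide cell_id × signature score table."""
    frames = [score_signature(cells, s, scale=scale) for s in sigs]
    long = pd.concat(frames, ignore_index=True)
    return long.pivot(index="cell_id", columns="signature", values="score")


def signature_correlations(
    scores: pd.DataFrame,
    grouping: pd.Series | None = None,
    exact_limit: int = 9,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between signature scores.

    ``scores`` is the wide cell × signature table; ``grouping`` (optional)
    maps cell_id → group (cluster or patient), in which case unweighted
    group means are correlated instead of single cells. Requires ≥ 3
    units; constant score vectors yield NaN (undefined, reported missing).
    """
    if grouping is not None:
        df = scores.copy()
        df["_group"] = df.index.map(grouping)
        df = df.dropna(subset=["_group"]).groupby("_group").mean()
    else:
        df = scores
    if len(df) < 3:
        raise DomainError("need at least 3 units for correlation")
    rows = []
    for a, b in itertools.combinations(sorted(df.columns), 2):
        rho, p = spearman_corr(df[a].to_numpy(), df[b].to_numpy(), exact_limit=exact_limit)
        rows.append((a, b, len(df), rho, p))
    return pd.DataFrame(rows, columns=["signature_a", "signature_b", "n", "rho", "p"])
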