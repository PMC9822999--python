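"""Negative-probe-calibrated cytokine expression calling.

Each cell carries one count per cytokine mRNA probe plus the count of a
bacterial negative-control probe (*DapB*) that measures per-cell
background. For cytokine *k* and cell *i* the statistic is the raw
difference

    d_ik = count_ik − count_i,DapB.

Under exchangeable probe noise, non-expressing cells have ``d`` symmetric
about zero, so a null distribution is formed per cytokine by reflecting
the non-positive tail of the empirical differences
(``{d ≤ 0} ∪ {−d : d ≤ 0}``). The upper-tail empirical probability of
``d_ik`` under this null — with add-one smoothing so the smallest
attainable p is ``1/(n_null+1)`` — is Benjamini–Hochberg adjusted per
cytokine across all cells, and a cell is called expressing when
``q < alpha`` (default 0.01).

The null is pooled dataset-wide by default; ``per_image=True`` forms it
per image instead (the BH family stays dataset-wide per cytokine either
way, because prevalences differ by probe, not by image).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import (
    CYTOKINE_PREFIX,
    Dataset,
    DomainError,
    NEGATIVE_PROBE_COLUMN,
    SchemaError,
)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j ≥ i} (p_(j) · m / j)`` on the ascending sort, capped
    at 1; stable sort makes tie handling deterministic.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _empirical_upper_p(d: np.ndarray) -> np.ndarray:
    """Upper-tail p under the symmetrized-non-positive-tail null of ``d``."""
    neg = d[d <= 0]
    null = np.sort(np.concatenate([neg, -neg]))
    n_null = null.size
    if n_null == 0:
        # no non-positive differences: null degenerate, nothing callable
        return np.ones_like(d)
    count_ge = n_null - np.searchsorted(null, d, side="left")
    return (count_ge + 1.0) / (n_null + 1.0)


def call_cytokines(ds: Dataset, alpha: float = 0.01, per_image: bool = False) -> pd.DataFrame:
    """Binary cytokine expression status for every (cell, cytokine).

    Returns the call table with columns ``cell_id, cytokine, d, p, q,
    expressed`` (one row per cell × cytokine). Deterministic.
    """
    if NEGATIVE_PROBE_COLUMN not in ds.cells.columns:
        raise SchemaError(f"missing {NEGATIVE_PROBE_COLUMN!r} column")
    if not ds.cytokines:
        raise SchemaError("dataset declares no cytokine probes besides the negative control")
    cells = ds.cells
    dapb = cells[NEGATIVE_PROBE_COLUMN].to_numpy(float)
    image_ids = cells["image_id"].to_numpy()
    frames = []
    for cyt in ds.cytokines:
        col = CYTOKINE_PREFIX + cyt
        if col not in cells.columns:
            raise SchemaError(f"missing probe column {col!r}")
        d = cells[col].to_numpy(float) - dapb
        if d.size and np.ptp(d) == 0:
            warnings.warn(f"cytokine {cyt!r}: zero variance in differences; all p set to 1")
            p = np.ones_like(d)
        elif per_image:
            p = np.empty_like(d)
            for img in np.unique(image_ids):
                mask = image_ids == img
                p[mask] = _empirical_upper_p(d[mask])
        else:
            p = _empirical_upper_p(d)
        q = benjamini_hochberg(p)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cells["cell_id"].to_numpy(),
                    "cytokine": cyt,
                    "d": d,
                    "p": p,
                    "q": q,
                    "expressed": q < alpha,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def expression_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot a call table to a boolean cell_id × cytokine matrix."""
    return calls.pivot(index="cell_id", columns="cytokine", values="expressed").fillna(False)


def expressing_any(calls: pd.DataFrame) -> pd.Series:
    """cell_id → True when the cell expresses at least one cytokine."""
    return calls.groupby("cell_id")["expressed"].any()
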