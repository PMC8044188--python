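"""Genomic relationship (relative kinship) and its near-zero summary.

The estimator is the centered genomic relationship K = Z Z' / (2 Σ p_j q_j)
with Z the column-centered dosage matrix (missing dosages imputed to the
column mean) — the VanRaden form.  For the "relative kinship" report the
off-diagonal entries are floored at 0, matching the non-negative scale on
which most unrelated pairs sit at or near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, alt_freq


@dataclass
class KinshipMatrix:
    raw: np.ndarray         # centered relationship, may be negative
    floored: np.ndarray     # off-diagonals floored at 0
    line_names: list


def kinship_matrix(G: GenotypeMatrix) -> KinshipMatrix:
    p = alt_freq(G.values)
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci for kinship")
    v = G.values[:, poly].astype(float)
    pj = p[poly]
    col_mean = 2.0 * pj
    v = np.where(v == MISSING, col_mean[None, :], v)
    Z = v - col_mean[None, :]
    denom = 2.0 * np.sum(pj * (1.0 - pj))
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2.0
    floored = K.copy()
    off = ~np.eye(K.shape[0], dtype=bool)
    floored[off] = np.maximum(floored[off], 0.0)
    return KinshipMatrix(K, floored, list(G.line_names))


def kinship_histogram(km: KinshipMatrix, bins=None) -> pd.DataFrame:
    """Binned fractions of the off-diagonal upper-triangle floored kinships.

    Always reports `fraction_lt_0.05` and `fraction_ge_0.05` style bands;
    fractions sum to 1.
    """
    if bins is None:
        bins = [0.0, 0.05, 0.10, 0.25, 0.5, 1.0, np.inf]
    iu = np.triu_indices_from(km.floored, k=1)
    vals = km.floored[iu]
    edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    labels = [f"[{edges[i]:g}, {edges[i+1]:g})" if np.isfinite(edges[i + 1])
              else f">= {edges[i]:g}" for i in range(len(edges) - 1)]
    frac = counts / vals.size if vals.size else np.zeros(len(counts))
    return pd.DataFrame({"band": labels, "n_pairs": counts, "fraction": frac})


def near_zero_fraction(km: KinshipMatrix, cut: float = 0.05) -> float:
    """Fraction of pairwise floored kinships below `cut` (the 'near zero'
    share of the panel)."""
    iu = np.triu_indices_from(km.floored, k=1)
    vals = km.floored[iu]
    return float((vals < cut).mean()) if vals.size else np.nan


def kinship_to_frame(km: KinshipMatrix) -> pd.DataFrame:
    return pd.DataFrame(km.floored, index=km.line_names,
                        columns=km.line_names)
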