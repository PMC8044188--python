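"""Per-group allele frequencies and group-specific locus classification.

Given two heterotic groups A and B with het-masked per-group alt-allele
frequencies, loci are classified (flags are independent; a locus may carry
several):

  unique_A        segregating in A (MAF_A >= poly_min) but effectively
                  monomorphic in B (MAF_B < poly_min)  [and vice versa]
  neutralA_fixedB frequency near 0.5 in A (inside the neutral band) while
                  near 0 or 1 in B (inside the fixed band)
  differential    |freq_A - freq_B| >= diff_min

The neutral/fixed band edges are this package's operational choices,
exposed in :class:`LocusClassThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (GenotypeMatrix, VariantTable, alt_freq,
                          subgroup_missing_mask)


@dataclass
class LocusClassThresholds:
    poly_min: float = 0.05
    neutral_low: float = 0.30
    neutral_high: float = 0.70
    fixed_low: float = 0.10      # fixed when freq < fixed_low or > fixed_high
    fixed_high: float = 0.90
    diff_min: float = 0.50

    def __post_init__(self) -> None:
        vals = [self.poly_min, self.neutral_low, self.neutral_high,
                self.fixed_low, self.fixed_high, self.diff_min]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("thresholds must lie in [0, 1]")
        if not (self.neutral_low < self.neutral_high):
            raise ValueError("neutral band must be ordered")
        if not (self.fixed_low < self.fixed_high):
            raise ValueError("fixed band must be ordered")


def group_freqs(G: GenotypeMatrix, assignments: pd.DataFrame, groups,
                min_lines: int = 10, loci_missing_max: float = 0.10,
                use_adjusted: bool = True) -> pd.DataFrame:
    """Het-masked alt-allele frequency per (group, locus).

    Lines are taken by their adjusted ID (Para folded into the base group)
    or default ID; groups with fewer than ``min_lines`` members are excluded
    with a warning.  Returns a loci x groups DataFrame of frequencies (NaN
    where a group has no calls at a locus) with per-group n_used in
    ``.attrs["n_used"]``.
    """
    import logging

    from .assignment import base_group

    log = logging.getLogger(__name__)
    if use_adjusted:
        member_of = assignments["adjusted_id"].map(lambda a: base_group(a))
    else:
        member_of = assignments["default_id"]
    by_line = dict(zip(assignments["line_name"], member_of))
    out = {}
    n_used = {}
    for grp in groups:
        idx = [i for i, ln in enumerate(G.line_names)
               if by_line.get(ln) == grp]
        if len(idx) < min_lines:
            log.warning("group %s has %d lines (< %d); excluded",
                        grp, len(idx), min_lines)
            continue
        sub = subgroup_missing_mask(G.take_lines(idx),
                                    loci_missing_max=loci_missing_max)
        freqs = pd.Series(alt_freq(sub.values), index=sub.locus_ids)
        out[grp] = freqs.reindex(G.locus_ids)
        n_used[grp] = len(idx)
    table = pd.DataFrame(out, index=pd.Index(G.locus_ids, name="locus_id"))
    table.attrs["n_used"] = n_used
    return table


def classify_loci(freq_a, freq_b, thresholds: LocusClassThresholds | None
                  = None) -> pd.DataFrame:
    """Independent class flags per locus for two groups' frequencies."""
    t = thresholds or LocusClassThresholds()
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    maf_a = np.fmin(a, 1 - a)
    maf_b = np.fmin(b, 1 - b)
    seg_a = maf_a >= t.poly_min
    seg_b = maf_b >= t.poly_min
    neutral_a = (a >= t.neutral_low) & (a <= t.neutral_high)
    neutral_b = (b >= t.neutral_low) & (b <= t.neutral_high)
    fixed_a = (a < t.fixed_low) | (a > t.fixed_high)
    fixed_b = (b < t.fixed_low) | (b > t.fixed_high)
    defined = ~(np.isnan(a) | np.isnan(b))
    df = pd.DataFrame({
        "unique_A": seg_a & ~seg_b & defined,
        "unique_B": seg_b & ~seg_a & defined,
        "neutralA_fixedB": neutral_a & fixed_b & defined,
        "neutralB_fixedA": neutral_b & fixed_a & defined,
        "differential": (np.abs(a - b) >= t.diff_min) & defined,
    })
    df["none"] = ~df.any(axis=1) & defined
    return df


def class_counts_by_chromosome(classes: pd.DataFrame,
                               variants: VariantTable) -> pd.DataFrame:
    """Per-chromosome counts of each class flag (plus a Total row)."""
    t = variants.table.reset_index(drop=True)
    classes = classes.reset_index(drop=True)
    merged = pd.concat([t[["chromosome"]], classes], axis=1)
    counts = merged.groupby("chromosome", sort=False).sum(numeric_only=True)
    counts.loc["Total"] = counts.sum()
    return counts.astype(int).reset_index()


def diff_table(freq_a, freq_b, variants: VariantTable,
               label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    """Per-locus frequency-difference records (difference = P_A - P_B),
    sorted by chromosome then position."""
    t = variants.table
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    return pd.DataFrame({
        "locus_id": t["locus_id"].to_numpy(),
        "chromosome": t["chromosome"].to_numpy(),
        "position_bp": t["position_bp"].to_numpy(),
        "allele": t["alt_allele"].to_numpy(),
        f"P_{label_a}": a,
        f"P_{label_b}": b,
        "difference": a - b,
    })
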