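"""Per-locus and windowed diversity statistics.

For a biallelic locus with alt frequency p (hets contributing one copy of
each allele, computed on non-missing calls):

    MAF = min(p, 1 - p)
    GD  = 1 - (p^2 + q^2)            (gene diversity / expected het)
    PIC = GD - 2 p^2 q^2             (polymorphic information content)
    H   = fraction of heterozygous calls among non-missing calls

PIC <= GD always, and GD <= 0.5 for biallelic loci.  All-missing loci are
flagged undefined and excluded from summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, VariantTable, locus_counts

DISTANCE_BANDS_KB = [0.0, 0.1, 1.0, 5.0, 10.0, 25.0, 50.0, 75.0, np.inf]


def locus_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF/GD/PIC/H/missing-rate table, indexed by locus id.

    The `defined` column is False for all-missing columns, whose statistics
    are NaN.
    """
    n_called, alt, n_het = locus_counts(G.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        het = np.where(n_called > 0, n_het / n_called, np.nan)
    q = 1.0 - p
    gd = 1.0 - (p ** 2 + q ** 2)
    pic = gd - 2.0 * p ** 2 * q ** 2
    return pd.DataFrame({
        "maf": np.fmin(p, q),
        "gd": gd,
        "pic": pic,
        "het": het,
        "missing_rate": 1.0 - n_called / G.n_lines,
        "defined": n_called > 0,
    }, index=pd.Index(G.locus_ids, name="locus_id"))


def panel_summary(G: GenotypeMatrix, variants: VariantTable) -> pd.DataFrame:
    """Per-chromosome (plus a "genome" row) means of the locus statistics,
    locus counts, and density = n_loci / spanned bp."""
    stats = locus_stats(G)
    t = variants.table.set_index("locus_id").loc[stats.index]
    rows = []
    for label, sub, tsub in [
        *((c, stats[t["chromosome"].to_numpy() == c],
           t[t["chromosome"] == c]) for c in pd.unique(t["chromosome"])),
        ("genome", stats, t),
    ]:
        ok = sub[sub["defined"]]
        span = int(tsub["position_bp"].max() - tsub["position_bp"].min()) \
            if len(tsub) > 1 else 1
        rows.append({
            "chromosome": label,
            "n_loci": len(sub),
            "density_per_bp": len(sub) / span,
            "mean_maf": ok["maf"].mean(),
            "mean_gd": ok["gd"].mean(),
            "mean_pic": ok["pic"].mean(),
            "mean_het": ok["het"].mean(),
        })
    return pd.DataFrame(rows)


def windowed_gd(G: GenotypeMatrix, variants: VariantTable,
                window_bp: float = 10e6, step_bp: float | None = None
                ) -> pd.DataFrame:
    """Moving-window mean gene diversity per chromosome.

    Windows advance by ``step_bp`` (default window/10, i.e. 1 Mb for the
    10-Mb default window); windows containing no defined locus emit no row.
    """
    step = float(step_bp) if step_bp is not None else window_bp / 10.0
    stats = locus_stats(G)
    gd = stats["gd"].to_numpy()
    defined = stats["defined"].to_numpy()
    chroms = variants.chromosomes
    pos = variants.positions
    rows = []
    for c in pd.unique(chroms):
        sel = (chroms == c) & defined
        if not sel.any():
            continue
        cpos, cgd = pos[sel], gd[sel]
        start = 1
        last = cpos.max()
        while start <= last:
            end = start + window_bp - 1
            inwin = (cpos >= start) & (cpos <= end)
            if inwin.any():
                rows.append({"chromosome": c, "window_start": int(start),
                             "window_end": int(end),
                             "n_loci": int(inwin.sum()),
                             "mean_gd": float(cgd[inwin].mean())})
            start += step
    return pd.DataFrame(rows, columns=["chromosome", "window_start",
                                       "window_end", "n_loci", "mean_gd"])


def snp_density_track(variants: VariantTable, bin_bp: float = 10e6
                      ) -> pd.DataFrame:
    """Locus counts per fixed physical bin along each chromosome."""
    rows = []
    chroms = variants.chromosomes
    pos = variants.positions
    for c in pd.unique(chroms):
        cpos = pos[chroms == c]
        n_bins = int(np.ceil(cpos.max() / bin_bp))
        counts, edges = np.histogram(
            cpos, bins=n_bins, range=(1, n_bins * bin_bp + 1))
        for i, n in enumerate(counts):
            rows.append({"chromosome": c, "bin_start": int(edges[i]),
                         "bin_end": int(edges[i + 1] - 1), "n_loci": int(n)})
    return pd.DataFrame(rows)


def adjacent_distances(variants: VariantTable):
    """Distances between adjacent loci within each chromosome.

    Returns (distances array, banded-fraction DataFrame using the kb bands
    0–0.1, 0.1–1, …, 50–75, >75).  A panel with m loci on c chromosomes has
    m − c distances.
    """
    chroms = variants.chromosomes
    pos = variants.positions
    dists = []
    for c in pd.unique(chroms):
        cpos = pos[chroms == c]
        if len(cpos) > 1:
            dists.append(np.diff(cpos))
    d = np.concatenate(dists) if dists else np.array([], dtype=np.int64)
    kb = d / 1000.0
    edges = np.asarray(DISTANCE_BANDS_KB)
    counts, _ = np.histogram(kb, bins=edges)
    labels = [f"{edges[i]:g}-{edges[i+1]:g} kb" if np.isfinite(edges[i + 1])
              else f">{edges[i]:g} kb" for i in range(len(edges) - 1)]
    frac = counts / d.size if d.size else np.zeros(len(counts))
    hist = pd.DataFrame({"band": labels, "n": counts, "fraction": frac})
    return d, hist
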