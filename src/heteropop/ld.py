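"""Pairwise linkage disequilibrium, segment LD maps, and LD decay.

r^2 is the squared Pearson correlation of dosage vectors over
pairwise-complete lines (composite LD) — the natural statistic for a
near-homozygous panel.  D' requires two-locus haplotype frequencies, which
are estimated by EM: homozygous×homozygous lines contribute two identical
known haplotypes, single hets two half-known ones, and double-het lines are
ambiguous between coupling and repulsion and are resolved iteratively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, VariantTable

# haplotypes ordered (ref,ref), (ref,alt), (alt,ref), (alt,alt)
_HAP_ALLELES = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])


@dataclass
class LDPair:
    locus_i: str
    locus_j: str
    distance_bp: int
    r2: float
    dprime: float
    n: int


def _complete_pair(col_i: np.ndarray, col_j: np.ndarray):
    ok = (col_i != MISSING) & (col_j != MISSING)
    return col_i[ok].astype(float), col_j[ok].astype(float)


def dosage_r2(col_i: np.ndarray, col_j: np.ndarray) -> float | None:
    """Squared Pearson correlation of dosages over pairwise-complete lines;
    None when fewer than 2 complete lines or either locus is monomorphic on
    the complete subset."""
    x, y = _complete_pair(col_i, col_j)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _genotype_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            n[a, b] = np.sum((x == a) & (y == b))
    return n


def hap_freqs_em(col_i: np.ndarray, col_j: np.ndarray,
                 max_iter: int = 100, tol: float = 1e-10) -> np.ndarray | None:
    """EM estimate of the 4 two-locus haplotype frequencies (2n haplotypes
    per n complete lines); None if undefined as in :func:`dosage_r2`."""
    x, y = _complete_pair(col_i, col_j)
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    counts = _genotype_counts(x, y)
    n_hap = 2.0 * x.size
    # unambiguous haplotype counts
    base = np.zeros(4)
    for a in range(3):
        for b in range(3):
            if a == 1 and b == 1:
                continue
            c = counts[a, b]
            if c == 0:
                continue
            ai = [0, 1] if a == 1 else [a // 2] * 2
            bi = [0, 1] if b == 1 else [b // 2] * 2
            # single-het: one hap gets each het allele; hom alleles known
            for h in range(2):
                base[2 * ai[h] + bi[h]] += c
    ndh = counts[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        # double hets split between coupling (00,11) and repulsion (01,10)
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        w = 0.5 if coup + rep == 0 else coup / (coup + rep)
        new = base.copy()
        new[[0, 3]] += ndh * w
        new[[1, 2]] += ndh * (1.0 - w)
        new /= n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def dprime_from_haps(f: np.ndarray) -> float:
    """|D'| from haplotype frequencies."""
    pA = f[2] + f[3]           # alt at locus i
    pB = f[1] + f[3]           # alt at locus j
    D = f[3] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0
    return float(min(abs(D) / dmax, 1.0))


def pair_ld(col_i, col_j, locus_i: str = "", locus_j: str = "",
            distance_bp: int = 0) -> LDPair | None:
    """Compute r^2 and |D'| for one locus pair; None if the pair is
    undefined (monomorphic or <2 complete lines)."""
    r2 = dosage_r2(col_i, col_j)
    if r2 is None:
        return None
    f = hap_freqs_em(col_i, col_j)
    x, _ = _complete_pair(col_i, col_j)
    return LDPair(locus_i, locus_j, int(distance_bp), r2,
                  dprime_from_haps(f), int(x.size))


# ---------------------------------------------------------------------------

def _within_window_pairs(pos: np.ndarray, max_dist: float):
    """Yield (i, j) index pairs with 0 < pos[j]-pos[i] <= max_dist (sorted)."""
    m = pos.size
    j_hi = np.searchsorted(pos, pos + max_dist, side="right")
    for i in range(m):
        for j in range(i + 1, j_hi[i]):
            yield i, j


def segment_ld_map(G: GenotypeMatrix, variants: VariantTable,
                   segment_bp: float = 50_000) -> pd.DataFrame:
    """Mean r^2 over all locus pairs within fixed physical segments.

    Segments with fewer than 2 usable loci (or no defined pairs) emit no
    row; undefined pairs are counted in `n_undefined`.
    """
    chroms = variants.chromosomes
    pos = variants.positions
    v = G.values
    rows = []
    for c in pd.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        seg_id = (pos[sel] - 1) // int(segment_bp)
        for s in np.unique(seg_id):
            idx = sel[seg_id == s]
            if idx.size < 2:
                continue
            vals, n_undef = [], 0
            for a in range(idx.size):
                for b in range(a + 1, idx.size):
                    r2 = dosage_r2(v[:, idx[a]], v[:, idx[b]])
                    if r2 is None:
                        n_undef += 1
                    else:
                        vals.append(r2)
            if vals:
                rows.append({"chromosome": c,
                             "segment_start": int(s * segment_bp + 1),
                             "segment_end": int((s + 1) * segment_bp),
                             "n_pairs": len(vals), "n_undefined": n_undef,
                             "mean_r2": float(np.mean(vals))})
    return pd.DataFrame(rows, columns=["chromosome", "segment_start",
                                       "segment_end", "n_pairs",
                                       "n_undefined", "mean_r2"])


def _isotonic_decreasing(x: np.ndarray, y: np.ndarray, w: np.ndarray
                         ) -> np.ndarray:
    from sklearn.isotonic import IsotonicRegression
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return iso.fit(x, y, sample_weight=w).predict(x)


def ld_decay(G: GenotypeMatrix, variants: VariantTable,
             max_dist_bp: float = 1_000_000, threshold_r2: float = 0.1,
             n_bins: int = 20):
    """Distance-binned LD decay curves and the decay distance.

    Pair r^2 is computed for all within-chromosome pairs up to
    ``max_dist_bp`` apart, binned into log-spaced distance bins, and a
    monotone-decreasing (isotonic) fit of the per-bin mean r^2 is
    thresholded: the decay distance is the first bin midpoint at which the
    fit falls to ``threshold_r2`` (0 when the threshold is 1, since LD
    starts from r^2 = 1 at zero distance; inf when the curve never
    crosses).

    Returns (curve DataFrame with per-chromosome and pooled "genome" rows,
    summary DataFrame with a decay_distance_bp per chromosome).
    """
    chroms = variants.chromosomes
    pos = variants.positions
    v = G.values
    edges = np.geomspace(1.0, float(max_dist_bp), n_bins + 1)
    mids = np.sqrt(edges[:-1] * edges[1:])

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        d_list, r_list = [], []
        for a, b in _within_window_pairs(pos[sel].astype(float), max_dist_bp):
            r2 = dosage_r2(v[:, sel[a]], v[:, sel[b]])
            if r2 is not None:
                d_list.append(pos[sel[b]] - pos[sel[a]])
                r_list.append(r2)
        per_chrom[c] = (np.asarray(d_list, dtype=float), np.asarray(r_list))

    all_d = np.concatenate([d for d, _ in per_chrom.values()]) \
        if per_chrom else np.array([])
    all_r = np.concatenate([r for _, r in per_chrom.values()]) \
        if per_chrom else np.array([])

    curve_rows, summary_rows = [], []
    for label, (d, r) in [*per_chrom.items(), ("genome", (all_d, all_r))]:
        if d.size == 0:
            summary_rows.append({"chromosome": label, "n_pairs": 0,
                                 "mean_r2": np.nan,
                                 "decay_distance_bp": np.nan})
            continue
        which = np.clip(np.searchsorted(edges, d, side="right") - 1,
                        0, n_bins - 1)
        counts = np.bincount(which, minlength=n_bins)
        sums = np.bincount(which, weights=r, minlength=n_bins)
        nonempty = counts > 0
        bx, bw = mids[nonempty], counts[nonempty].astype(float)
        by = sums[nonempty] / counts[nonempty]
        fit = _isotonic_decreasing(bx, by, bw)
        for x, y0, yf, nb in zip(bx, by, fit, bw):
            curve_rows.append({"chromosome": label, "bin_mid_bp": x,
                               "mean_r2": y0, "fit_r2": yf, "n_pairs": int(nb)})
        if threshold_r2 >= 1.0:
            dist = 0.0
        else:
            below = fit <= threshold_r2
            dist = float(bx[np.argmax(below)]) if below.any() else np.inf
        summary_rows.append({"chromosome": label, "n_pairs": int(d.size),
                             "mean_r2": float(r.mean()),
                             "decay_distance_bp": dist})
    return pd.DataFrame(curve_rows), pd.DataFrame(summary_rows)
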