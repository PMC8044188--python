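"""Gabriel-style haplotype blocks and tagSNP selection.

A pair of loci is in "strong LD" when the 90% confidence interval on |D'|
(profile likelihood over a 101-point |D'| grid, allele frequencies held at
their estimates) has lower bound >= 0.70 and upper bound >= 0.98; it shows
"strong recombination" when the upper bound < 0.90.  A span of consecutive
loci is a block when its outermost pair is strong and at least 95% of its
informative pairs are strong.  Maximal non-overlapping blocks are kept
longest-first (ties to the left).  Tags are chosen per block by a greedy
r^2 >= 0.8 cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, VariantTable, MISSING
from .ld import dosage_r2, dprime_from_haps, hap_freqs_em, _complete_pair

_HAPS = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])


@dataclass
class GabrielConfig:
    ci_strong_low: float = 0.70
    ci_strong_high: float = 0.98
    ci_recomb_high: float = 0.90
    strong_fraction: float = 0.95
    min_informative_lines: int = 10
    max_span_loci: int = 50          # cap on candidate block width
    n_grid: int = 101


@dataclass
class HaplotypeBlock:
    chromosome: str
    start_bp: int
    end_bp: int
    member_loci: list = field(default_factory=list)
    tag_loci: list = field(default_factory=list)


@dataclass
class DPrimeCI:
    dprime: float
    ci_low: float
    ci_high: float
    informative: bool = True


# scatter tensor: haplotype pair (h1, h2) -> flat two-locus genotype class
_PAIR_TO_CLASS = np.zeros((4, 4, 9))
for _h1 in range(4):
    for _h2 in range(4):
        _a = _HAPS[_h1, 0] + _HAPS[_h2, 0]
        _b = _HAPS[_h1, 1] + _HAPS[_h2, 1]
        _PAIR_TO_CLASS[_h1, _h2, 3 * _a + _b] = 1.0


def _genotype_probs_from_haps(f: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype probabilities under random union of
    haplotypes."""
    return np.einsum("i,j,ijc->c", f, f, _PAIR_TO_CLASS).reshape(3, 3)


def dprime_ci(col_i: np.ndarray, col_j: np.ndarray,
              cfg: GabrielConfig | None = None) -> DPrimeCI:
    """MLE |D'| with 90% profile-likelihood confidence bounds.

    The likelihood of the observed two-locus genotype counts is evaluated on
    a grid of |D'| values (allele frequencies fixed at their estimates, the
    sign of D fixed at its MLE), normalized, and the 5th/95th percentiles of
    the resulting distribution taken as bounds.  Pairs with fewer than
    ``min_informative_lines`` complete lines, or monomorphic on the complete
    subset, are flagged uninformative.
    """
    cfg = cfg or GabrielConfig()
    f_mle = hap_freqs_em(col_i, col_j)
    x, y = _complete_pair(col_i, col_j)
    if f_mle is None or x.size < cfg.min_informative_lines:
        return DPrimeCI(np.nan, np.nan, np.nan, informative=False)
    counts = np.zeros((3, 3))
    for a, b in zip(x.astype(int), y.astype(int)):
        counts[a, b] += 1
    pA = f_mle[2] + f_mle[3]
    pB = f_mle[1] + f_mle[3]
    D_mle = f_mle[3] - pA * pB
    sign = 1.0 if D_mle >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    grid = np.linspace(0.0, 1.0, cfg.n_grid)
    D = sign * grid * dmax                                  # (n_grid,)
    base = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB,
                     pA * (1 - pB), pA * pB])
    sgn = np.array([1.0, -1.0, -1.0, 1.0])
    F = np.clip(base[None, :] + D[:, None] * sgn[None, :], 1e-12, 1.0)
    M = np.einsum("gi,gj,ijc->gc", F, F, _PAIR_TO_CLASS)    # (n_grid, 9)
    loglik = np.log(np.clip(M, 1e-300, None)) @ counts.ravel()
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    lo = float(grid[int(np.searchsorted(cdf, 0.05))])
    hi = float(grid[min(int(np.searchsorted(cdf, 0.95)), cfg.n_grid - 1)])
    return DPrimeCI(dprime_from_haps(f_mle), lo, hi, informative=True)


def _pair_class(ci: DPrimeCI, cfg: GabrielConfig) -> str:
    if not ci.informative:
        return "uninformative"
    if ci.ci_low >= cfg.ci_strong_low and ci.ci_high >= cfg.ci_strong_high:
        return "strong"
    if ci.ci_high < cfg.ci_recomb_high:
        return "recomb"
    return "inconclusive"


def find_blocks(G: GenotypeMatrix, variants: VariantTable, chromosome: str,
                cfg: GabrielConfig | None = None) -> list[HaplotypeBlock]:
    """Detect Gabriel blocks on one chromosome.

    Expects het-masked input (see genotype_io.subgroup_missing_mask); the
    candidate span width is capped at ``max_span_loci`` consecutive loci.
    """
    cfg = cfg or GabrielConfig()
    chroms = variants.chromosomes
    idx = np.flatnonzero(chroms == str(chromosome))
    pos = variants.positions[idx]
    m = idx.size
    if m < 2:
        return []
    span = min(cfg.max_span_loci, m)
    # pair classes within the span cap
    cls = {}
    for a in range(m):
        for b in range(a + 1, min(a + span, m)):
            ci = dprime_ci(G.values[:, idx[a]], G.values[:, idx[b]], cfg)
            cls[(a, b)] = _pair_class(ci, cfg)

    candidates = []
    for a in range(m):
        for b in range(a + 1, min(a + span, m)):
            if cls[(a, b)] != "strong":
                continue  # outermost pair must be strong
            n_strong = n_inf = 0
            for u in range(a, b + 1):
                for w in range(u + 1, b + 1):
                    c = cls.get((u, w), "uninformative")
                    if c == "strong":
                        n_strong += 1
                        n_inf += 1
                    elif c == "recomb":
                        n_inf += 1
            if n_inf > 0 and n_strong / n_inf >= cfg.strong_fraction:
                candidates.append((a, b))

    # longest-first (bp length), ties leftmost; greedy non-overlap
    candidates.sort(key=lambda ab: (-(pos[ab[1]] - pos[ab[0]]), pos[ab[0]]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for a, b in candidates:
        if taken[a:b + 1].any():
            continue
        taken[a:b + 1] = True
        members = [G.locus_ids[j] for j in idx[a:b + 1]]
        blocks.append(HaplotypeBlock(str(chromosome), int(pos[a]),
                                     int(pos[b]), members))
    blocks.sort(key=lambda blk: blk.start_bp)
    for blk in blocks:
        blk.tag_loci = select_tags(blk, G)
    return blocks


def select_tags(block: HaplotypeBlock, G: GenotypeMatrix,
                r2_min: float = 0.8) -> list[str]:
    """Greedy r^2 cover: repeatedly pick the member tagging the most not-yet
    tagged members (r^2 >= r2_min, a locus tags itself), ties to the lower
    map position, until every member is tagged."""
    members = block.member_loci
    col_of = {lid: G.locus_ids.index(lid) for lid in members}
    k = len(members)
    covers = np.eye(k, dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            r2 = dosage_r2(G.values[:, col_of[members[a]]],
                           G.values[:, col_of[members[b]]])
            if r2 is not None and r2 >= r2_min:
                covers[a, b] = covers[b, a] = True
    untagged = np.ones(k, dtype=bool)
    tags: list[str] = []
    while untagged.any():
        gain = (covers & untagged).sum(axis=1)
        best = int(np.argmax(gain))     # argmax returns first (lowest pos)
        tags.append(members[best])
        untagged &= ~covers[best]
    return sorted(tags, key=members.index)


def blocks_to_frame(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """BED-like table of blocks (chromosome, start, end, members, tags)."""
    return pd.DataFrame([{
        "chromosome": b.chromosome, "start_bp": b.start_bp,
        "end_bp": b.end_bp, "n_members": len(b.member_loci),
        "tag_loci": ",".join(b.tag_loci)} for b in blocks],
        columns=["chromosome", "start_bp", "end_bp", "n_members", "tag_loci"])


def tag_loci_panel(G: GenotypeMatrix, variants: VariantTable,
                   cfg: GabrielConfig | None = None):
    """Find blocks on every chromosome; return (blocks, tag locus ids).

    Loci on no block are their own tags, so the tag set covers the whole
    map (the block-derived tags plus singleton loci outside blocks).
    """
    blocks: list[HaplotypeBlock] = []
    for c in pd.unique(variants.chromosomes):
        blocks.extend(find_blocks(G, variants, c, cfg))
    in_block = {lid for b in blocks for lid in b.member_loci}
    tags = [lid for b in blocks for lid in b.tag_loci]
    singletons = [lid for lid in G.locus_ids if lid not in in_block]
    return blocks, tags + singletons
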