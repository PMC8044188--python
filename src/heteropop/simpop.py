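"""Synthetic structured inbred panels with known admixture truth.

The generator follows the Balding–Nichols construction: each locus has an
ancestral frequency p ~ Uniform(0.05, 0.95); ancestral group k draws its own
frequency from Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), so the drift parameter
F_k is the expected differentiation of group k from the common ancestor.
Line i carries admixture proportions Q[i] ~ Dirichlet(alpha) (or a one-hot
row for "pure" lines) and its allele-draw probability at locus j is
sum_k Q[i,k] * P[k,j].  Inbreds are modeled as a single allele draw doubled
(dosage 0 or 2) except with probability ``residual_het_rate``, where two
independent alleles are drawn — reproducing the {0,2}-dominated matrices
with a small heterozygous residue that the QC rules assume.  Missingness is
MCAR at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, LineRegistry, VariantTable)

__all__ = ["SimConfig", "SimTruth", "plant_map", "simulate_panel",
           "write_truth"]


@dataclass
class SimConfig:
    n_lines: int = 200
    n_loci: int = 2000
    n_chromosomes: int = 10
    chrom_length_bp: int = 200_000_000
    K_true: int = 3
    divergence_F: tuple = (0.3,)          # recycled across groups if shorter
    dirichlet_alpha: tuple = (0.2,)       # recycled to length K_true
    pure_fraction: float = 0.0            # fraction of lines forced one-hot
    residual_het_rate: float = 0.02
    missing_rate: float = 0.05
    telomere_enrichment: float = 3.0      # outer-10% / middle density ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_lines < 1 or self.K_true < 1:
            raise ValueError("n_loci, n_lines and K_true must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for r in (self.residual_het_rate, self.missing_rate, self.pure_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.telomere_enrichment < 1.0:
            raise ValueError("telomere_enrichment must be >= 1")
        F = self.group_F
        if np.any((F <= 0.0) | (F >= 1.0)):
            raise ValueError("divergence_F entries must lie strictly in (0, 1)")
        if np.any(self.alpha <= 0.0):
            raise ValueError("Dirichlet alpha entries must be positive")
        if self.n_loci > self.n_chromosomes * self.chrom_length_bp:
            raise ValueError("n_loci exceeds available integer positions")

    @property
    def group_F(self) -> np.ndarray:
        F = np.resize(np.asarray(self.divergence_F, dtype=float), self.K_true)
        return F

    @property
    def alpha(self) -> np.ndarray:
        return np.resize(np.asarray(self.dirichlet_alpha, dtype=float),
                         self.K_true)


@dataclass
class SimTruth:
    """Generating parameters of a synthetic panel, for recovery tests."""

    true_Q: np.ndarray          # lines x K_true
    true_P: np.ndarray          # K_true x loci
    ancestral_p: np.ndarray     # loci
    group_labels: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.true_Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true_Q rows must sum to 1")
        for a in (self.true_Q, self.true_P, self.ancestral_p):
            if np.any((a < 0) | (a > 1)):
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def true_group(self) -> np.ndarray:
        """Majority ancestry per line (argmax of true_Q)."""
        return self.true_Q.argmax(axis=1)


def _streams(seed: int, n: int):
    """Deterministic per-stage substreams from one root seed."""
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def plant_map(cfg: SimConfig) -> VariantTable:
    """Place loci on chromosomes with telomere-enriched density.

    Density is piecewise constant: the outer 10% at each chromosome end has
    ``telomere_enrichment`` times the density of the middle 80%, so the
    expected outer/middle density ratio equals the enrichment factor exactly
    (uniform when the factor is 1).  Positions are unique 1-based integers,
    sorted within chromosome.
    """
    rng = _streams(cfg.seed, 4)[0]
    L = cfg.chrom_length_bp
    t = cfg.telomere_enrichment
    # per-locus chromosome assignment: equal expected loci per chromosome
    chrom_of = rng.integers(0, cfg.n_chromosomes, size=cfg.n_loci)
    # region weights: [0,0.1L) and [0.9L,L) at density t, middle at 1
    w = np.array([0.1 * t, 0.8, 0.1 * t])
    w = w / w.sum()
    bounds = np.array([0.0, 0.1, 0.9, 1.0]) * L
    rows = []
    for c in range(cfg.n_chromosomes):
        n_c = int((chrom_of == c).sum())
        if n_c == 0:
            continue
        positions: set[int] = set()
        while len(positions) < n_c:
            need = n_c - len(positions)
            region = rng.choice(3, size=need, p=w)
            lo, hi = bounds[region], bounds[region + 1]
            pos = np.floor(lo + rng.random(need) * (hi - lo)).astype(np.int64) + 1
            positions.update(int(x) for x in np.clip(pos, 1, L))
        for p in sorted(positions):
            rows.append((f"S{c + 1}_{p}", str(c + 1), p, "A", "C"))
    return VariantTable(pd.DataFrame(
        rows, columns=["locus_id", "chromosome", "position_bp",
                       "ref_allele", "alt_allele"]))


def simulate_panel(cfg: SimConfig):
    """Draw a full panel; returns (GenotypeMatrix, VariantTable, LineRegistry,
    SimTruth).  Byte-identical for a fixed seed."""
    rng_map, rng_freq, rng_q, rng_geno = _streams(cfg.seed, 4)
    variants = plant_map(cfg)
    m = len(variants)
    K = cfg.K_true

    p = rng_freq.uniform(0.05, 0.95, size=m)
    F = cfg.group_F
    P = np.empty((K, m))
    for k in range(K):
        shape = (1.0 - F[k]) / F[k]
        P[k] = rng_freq.beta(p * shape, (1.0 - p) * shape)
    P = np.clip(P, 1e-9, 1.0 - 1e-9)

    n = cfg.n_lines
    Q = rng_q.dirichlet(cfg.alpha, size=n)
    n_pure = int(round(cfg.pure_fraction * n))
    if n_pure:
        groups = rng_q.integers(0, K, size=n_pure)
        Q[:n_pure] = 0.0
        Q[np.arange(n_pure), groups] = 1.0

    pi = Q @ P                                     # (n, m) allele-draw prob
    u = rng_geno.random((n, m))
    het_line = rng_geno.random((n, m)) < cfg.residual_het_rate
    hom = np.where(u < pi, 2, 0).astype(np.int8)   # one allele doubled
    a1 = (rng_geno.random((n, m)) < pi).astype(np.int8)
    a2 = (rng_geno.random((n, m)) < pi).astype(np.int8)
    geno = np.where(het_line, a1 + a2, hom).astype(np.int8)
    geno[rng_geno.random((n, m)) < cfg.missing_rate] = MISSING

    line_names = [f"L{i:04d}" for i in range(n)]
    truth = SimTruth(true_Q=Q, true_P=P, ancestral_p=p,
                     group_labels=[f"G{k + 1}" for k in range(K)],
                     seed=cfg.seed)
    registry = LineRegistry(pd.DataFrame({
        "line_name": line_names,
        "origin": "synthetic",
        "known_group": [truth.group_labels[g] if Q[i, g] >= 0.99 else None
                        for i, g in enumerate(truth.true_group)],
    }))
    G = GenotypeMatrix(geno, line_names, list(variants.locus_ids))
    return G, variants, registry, truth


def simulate_block_panel(n_lines: int = 100, n_blocks: int = 10,
                         loci_per_block: int = 6,
                         block_length_bp: int = 100_000,
                         gap_bp: int = 0, maf_range=(0.2, 0.5),
                         seed: int = 0):
    """Block-copy panel: perfectly correlated loci within each haplotype
    block, independent blocks.

    Each line draws one allele per block (frequency uniform in
    ``maf_range``) and every locus in the block copies it (dosage 0 or 2),
    so within-block r^2 = 1 and cross-block r^2 is background.  Returns
    (GenotypeMatrix, VariantTable, list of true (start_bp, end_bp) block
    bounds).  Used as the linkage-aware truth for LD-decay and
    block-detection oracles.
    """
    rng = np.random.default_rng(seed)
    rows, cols, bounds = [], [], []
    geno = np.zeros((n_lines, n_blocks * loci_per_block), dtype=np.int8)
    stride = block_length_bp + gap_bp
    for b in range(n_blocks):
        start = b * stride + 1
        pos = np.linspace(start, start + block_length_bp - 1,
                          loci_per_block).astype(np.int64)
        p = rng.uniform(*maf_range)
        z = (rng.random(n_lines) < p).astype(np.int8) * 2
        for k, pp in enumerate(pos):
            j = b * loci_per_block + k
            geno[:, j] = z
            rows.append((f"S1_{pp}", "1", int(pp), "A", "C"))
        bounds.append((int(pos[0]), int(pos[-1])))
    variants = VariantTable(pd.DataFrame(
        rows, columns=["locus_id", "chromosome", "position_bp",
                       "ref_allele", "alt_allele"]))
    G = GenotypeMatrix(geno, [f"L{i:04d}" for i in range(n_lines)],
                       list(variants.locus_ids))
    return G, variants, bounds


def write_truth(prefix, truth: SimTruth, cfg: SimConfig) -> None:
    """Write true Q/P as whitespace matrices plus a TSV of the config."""
    np.savetxt(f"{prefix}.trueQ", truth.true_Q, fmt="%.6f")
    np.savetxt(f"{prefix}.trueP", truth.true_P, fmt="%.6f")
    items = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    pd.DataFrame({"key": list(items), "value": [str(v) for v in items.values()]}
                 ).to_csv(f"{prefix}.config.tsv", sep="\t", index=False)
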