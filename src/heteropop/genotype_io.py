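"""Genotype containers, VCF/HapMap/Q/P readers and writers, and panel QC.

Genotypes are stored as alternate-allele dosages: 0 (ref/ref), 1 (het),
2 (alt/alt) and :data:`MISSING` (-1) for no-calls, in a lines x loci int8
array.  Locus metadata lives in a :class:`VariantTable` (a thin pandas
wrapper) sorted by (chromosome, position); all windowed and LD operations
rely on that ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING: int = -1

_VARIANT_COLS = ["locus_id", "chromosome", "position_bp", "ref_allele", "alt_allele"]

# IUPAC ambiguity codes for heterozygous single-letter HapMap calls
_IUPAC_HET = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}
_IUPAC_DECODE = {v: k for k, v in _IUPAC_HET.items()}


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    """Numeric chromosomes sort numerically, others lexically after them."""
    as_num = pd.to_numeric(chroms, errors="coerce")
    return pd.Series(
        [(0, n, "") if not np.isnan(n) else (1, 0.0, c)
         for n, c in zip(as_num, chroms.astype(str))],
        index=chroms.index,
    )


@dataclass
class VariantTable:
    """Per-locus metadata: id, chromosome, 1-based position, ref/alt allele."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _VARIANT_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"VariantTable missing columns: {missing}")
        t = self.table.copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_bp"] = t["position_bp"].astype(np.int64)
        if (t["position_bp"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        order = _chrom_sort_key(t["chromosome"])
        t = (t.assign(_k=order)
               .sort_values(["_k", "position_bp"], kind="mergesort")
               .drop(columns="_k")
               .reset_index(drop=True))
        if t.duplicated(["chromosome", "position_bp"]).any():
            raise ValueError("duplicate (chromosome, position) in variant table")
        self.table = t

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, locus_ids) -> "VariantTable":
        keep = set(locus_ids)
        return VariantTable(self.table[self.table["locus_id"].isin(keep)].copy())


@dataclass
class LineRegistry:
    """Panel membership: line name, origin label, optional known heterotic group."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "line_name" not in self.table.columns:
            raise ValueError("LineRegistry needs a line_name column")
        t = self.table.copy()
        if t["line_name"].duplicated().any():
            raise ValueError("duplicate line names")
        for col in ("origin", "known_group"):
            if col not in t.columns:
                t[col] = None
        self.table = t.reset_index(drop=True)

    @property
    def line_names(self) -> np.ndarray:
        return self.table["line_name"].to_numpy()


@dataclass
class GenotypeMatrix:
    """Lines x loci alt-allele dosage matrix; -1 encodes a missing call."""

    values: np.ndarray
    line_names: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (lines x loci)")
        bad = ~np.isin(v, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        self.values = v
        if not self.line_names:
            self.line_names = [f"line{i}" for i in range(v.shape[0])]
        if not self.locus_ids:
            self.locus_ids = [f"locus{j}" for j in range(v.shape[1])]
        if len(self.line_names) != v.shape[0] or len(self.locus_ids) != v.shape[1]:
            raise ValueError("index lengths do not match matrix shape")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def take_loci(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            list(self.line_names),
            [self.locus_ids[j] for j in idx],
        )

    def take_lines(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.values[idx, :],
            [self.line_names[i] for i in idx],
            list(self.locus_ids),
        )


@dataclass
class QCThresholds:
    """Locus retention thresholds: MAF >= maf_min, missing <= missing_max,
    heterozygote fraction <= het_max."""

    maf_min: float = 0.05
    missing_max: float = 0.20
    het_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "het_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# per-locus frequency helpers (shared by QC and diversity)

def locus_counts(values: np.ndarray):
    """Return (n_called, alt_copies, n_het) per locus; hets count one copy of
    each allele toward frequencies."""
    v = np.asarray(values)
    called = v != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, v, 0).sum(axis=0)
    n_het = (v == 1).sum(axis=0)
    return n_called, alt, n_het


def alt_freq(values: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per locus over non-missing calls (NaN if none)."""
    n_called, alt, _ = locus_counts(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(path, G: GenotypeMatrix, variants: VariantTable) -> None:
    """Write a minimal VCF 4.2 with a GT FORMAT field ("./." for missing)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    t = variants.table
    if list(t["locus_id"]) != list(G.locus_ids):
        raise ValueError("variant table and genotype matrix loci differ")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(t["chromosome"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.line_names) + "\n")
        for j, row in enumerate(t.itertuples(index=False)):
            calls = "\t".join(gt_map[int(g)] for g in G.values[:, j])
            fh.write(f"{row.chromosome}\t{row.position_bp}\t{row.locus_id}\t"
                     f"{row.ref_allele}\t{row.alt_allele}\t.\t.\t.\tGT\t{calls}\n")


def read_vcf(path):
    """Read biallelic SNP records from a VCF into the panel triple.

    Non-biallelic / non-SNP records are skipped (count logged).  Returns
    (GenotypeMatrix, VariantTable, LineRegistry).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, skipped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        g = np.full(len(samples), MISSING, dtype=np.int8)
        for i, call in enumerate(rec.genotypes):
            a, b = call[0], call[1]
            if a >= 0 and b >= 0:
                g[i] = a + b
        rows.append(g)
        locus_id = rec.ID if rec.ID not in (None, ".") else f"S{rec.CHROM}_{rec.POS}"
        meta.append((locus_id, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if not rows:
        log.warning("read_vcf: no usable biallelic SNP records in %s", path)
        values = np.zeros((len(samples), 0), dtype=np.int8)
        vt = VariantTable(pd.DataFrame(columns=_VARIANT_COLS).astype(
            {"position_bp": np.int64}))
    else:
        values = np.stack(rows, axis=1)
        vt = VariantTable(pd.DataFrame(meta, columns=_VARIANT_COLS))
        # reorder genotype columns to the sorted variant order
        order = {lid: j for j, lid in enumerate(lid for lid, *_ in meta)}
        values = values[:, [order[lid] for lid in vt.locus_ids]]
    G = GenotypeMatrix(values, samples, list(vt.locus_ids))
    reg = LineRegistry(pd.DataFrame({"line_name": samples}))
    return G, vt, reg


# ---------------------------------------------------------------------------
# HapMap (TASSEL dialect)

_HAPMAP_HEADER = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                  "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def write_hapmap(path, G: GenotypeMatrix, variants: VariantTable) -> None:
    """Write TASSEL-style HapMap text with single-letter IUPAC calls."""
    t = variants.table
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + list(G.line_names)) + "\n")
        for j, row in enumerate(t.itertuples(index=False)):
            ref, alt = row.ref_allele, row.alt_allele
            het = _IUPAC_HET.get(frozenset((ref, alt)), "N")
            code = {0: ref, 2: alt, 1: het, MISSING: "N"}
            calls = "\t".join(code[int(g)] for g in G.values[:, j])
            fh.write(f"{row.locus_id}\t{ref}/{alt}\t{row.chromosome}\t"
                     f"{row.position_bp}\t+\tNA\tNA\tNA\tNA\tNA\tNA\t{calls}\n")


def _decode_hapmap_call(call: str, ref: str, alt: str) -> int:
    call = call.strip().upper()
    if call in ("N", "NN", ""):
        return MISSING
    if len(call) == 2:  # two-letter diploid call
        a, b = call[0], call[1]
    elif call in _IUPAC_DECODE:
        a, b = tuple(_IUPAC_DECODE[call])
    elif len(call) == 1:
        a = b = call
    else:
        return MISSING
    alleles = {ref: 0, alt: 1}
    if a not in alleles or b not in alleles:
        return MISSING  # call disagrees with declared alleles
    return alleles[a] + alleles[b]


def read_hapmap(path):
    """Read TASSEL-dialect HapMap text into the panel triple.

    Calls not matching the declared alleles are set missing (count logged).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12 or header[0] not in ("rs#", "rs"):
            raise ValueError("malformed HapMap header")
        samples = header[11:]
        rows, meta, n_bad = [], [], 0
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 11 + len(samples):
                raise ValueError("ragged HapMap row")
            alleles = parts[1].split("/")
            if len(alleles) != 2:
                raise ValueError(f"bad alleles field: {parts[1]}")
            ref, alt = alleles
            g = np.array([_decode_hapmap_call(c, ref, alt) for c in parts[11:]],
                         dtype=np.int8)
            n_bad += int(sum(1 for c in parts[11:]
                             if c.strip().upper() not in ("N", "NN", "")
                             and _decode_hapmap_call(c, ref, alt) == MISSING))
            rows.append(g)
            meta.append((parts[0], parts[2], int(parts[3]), ref, alt))
    if n_bad:
        log.info("read_hapmap: %d calls not matching declared alleles set missing",
                 n_bad)
    values = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int8)
    vt = VariantTable(pd.DataFrame(meta, columns=_VARIANT_COLS))
    order = {lid: j for j, lid in enumerate(lid for lid, *_ in meta)}
    values = values[:, [order[lid] for lid in vt.locus_ids]]
    G = GenotypeMatrix(values, samples, list(vt.locus_ids))
    return G, vt, LineRegistry(pd.DataFrame({"line_name": samples}))


# ---------------------------------------------------------------------------
# Q / P matrices (ADMIXTURE-compatible whitespace text)

def read_q_matrix(path, atol: float = 1e-3) -> np.ndarray:
    """Read a lines x K admixture-proportion matrix; rows renormalized to sum
    to 1 when within `atol` of 1, otherwise an error."""
    Q = np.loadtxt(path, ndmin=2)
    sums = Q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > atol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"Q row {bad} sums to {sums[bad]:.4f}, not 1")
    return Q / sums[:, None]


def write_q_matrix(path, Q: np.ndarray) -> None:
    np.savetxt(path, np.asarray(Q), fmt="%.6f")


def read_p_matrix(path) -> np.ndarray:
    """Read a K x loci ancestral allele-frequency matrix."""
    P = np.loadtxt(path, ndmin=2)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P entries must lie in [0, 1]")
    return P


def write_p_matrix(path, P: np.ndarray) -> None:
    np.savetxt(path, np.asarray(P), fmt="%.6f")


# ---------------------------------------------------------------------------
# QC

def qc_filter(G: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Drop loci failing any of the MAF / missing-rate / heterozygosity rules.

    Returns (filtered GenotypeMatrix, report DataFrame).  The report counts
    removals per criterion; a locus failing several rules is counted under
    each but removed once.  Criteria are evaluated on the raw calls
    independently, so the filter is idempotent and order-free.
    """
    t = thresholds or QCThresholds()
    n_called, alt, n_het = locus_counts(G.values)
    n_lines = G.n_lines
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        het = np.where(n_called > 0, n_het / n_called, np.nan)
    maf = np.fmin(p, 1.0 - p)
    miss = 1.0 - n_called / n_lines

    fail_maf = ~(maf >= t.maf_min)          # NaN (all-missing) fails MAF too
    fail_miss = miss > t.missing_max
    fail_het = het > t.het_max
    keep = ~(fail_maf | fail_miss | fail_het)
    report = pd.DataFrame({
        "criterion": ["maf", "missing", "het", "total_removed", "retained"],
        "n_removed": [int(fail_maf.sum()), int(fail_miss.sum()),
                      int(fail_het.sum()), int((~keep).sum()), int(keep.sum())],
    })
    return G.take_loci(keep), report


def subgroup_missing_mask(G: GenotypeMatrix, loci_missing_max: float = 0.10
                          ) -> GenotypeMatrix:
    """Subgroup-analysis preparation: heterozygous calls become missing, then
    loci whose resulting missing rate exceeds `loci_missing_max` are dropped."""
    v = G.values.copy()
    v[v == 1] = MISSING
    miss = (v == MISSING).mean(axis=0)
    keep = miss <= loci_missing_max
    return GenotypeMatrix(v, list(G.line_names), list(G.locus_ids)).take_loci(keep)
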