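"""End-to-end orchestration: simulate/load -> QC -> diversity -> LD ->
blocks/tags -> kinship -> admixture (CV over K) -> assignment -> Fst ->
group-specific loci -> PCA, with every stage writing its TSV artifacts.

The tagSNP subset (block tags plus off-block singletons), not the full
matrix, feeds the admixture, assignment and Fst stages; all randomness
flows from one seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, assignment, blocks, diversity, group_loci, kinship
from .genotype_io import (GenotypeMatrix, QCThresholds, VariantTable,
                          qc_filter, read_hapmap, read_vcf,
                          subgroup_missing_mask, write_q_matrix,
                          write_p_matrix, write_vcf, write_hapmap)
from .simpop import SimConfig, simulate_panel, write_truth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "heteropop_out"
    input_vcf: str | None = None          # load a panel ...
    input_hapmap: str | None = None
    sim: SimConfig | None = None          # ... or simulate one
    qc: QCThresholds = field(default_factory=QCThresholds)
    assign: assignment.AssignmentThresholds = field(
        default_factory=assignment.AssignmentThresholds)
    locus_class: group_loci.LocusClassThresholds = field(
        default_factory=group_loci.LocusClassThresholds)
    gabriel: blocks.GabrielConfig = field(default_factory=blocks.GabrielConfig)
    ld_max_dist_bp: float = 1_000_000
    ld_segment_bp: float = 50_000
    gd_window_bp: float = 10e6
    k_values: tuple = (1, 2, 3, 4, 5, 6)
    cv_folds: int = 5
    n_restarts: int = 2
    em_max_iter: int = 500
    em_tol: float = 1e-6
    min_group_lines: int = 10
    seed: int = 0
    grouping_map: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Flat key-value YAML; sim.* / qc.* style dotted keys set nested
        fields."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        sim_kwargs, direct = {}, {}
        for k, v in raw.items():
            if k.startswith("sim."):
                sim_kwargs[k[4:]] = v
            elif k.startswith("qc."):
                setattr(cfg.qc, k[3:], v)
            elif k.startswith("assign."):
                setattr(cfg.assign, k[7:], v)
            elif k.startswith("gabriel."):
                setattr(cfg.gabriel, k[8:], v)
            elif k.startswith("locus_class."):
                setattr(cfg.locus_class, k[12:], v)
            else:
                direct[k] = v
        for k, v in direct.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key: {k}")
            if k == "k_values":
                v = tuple(v)
            setattr(cfg, k, v)
        if sim_kwargs:
            cfg.sim = SimConfig(**sim_kwargs)
        return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a report dict of headline numbers.

    Each stage writes its artifacts under ``cfg.outdir`` and logs record
    counts and timing; deterministic for a fixed seed.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    timings = {}

    def stage(name):
        t0 = time.time()

        def done(**kw):
            timings[name] = round(time.time() - t0, 2)
            log.info("stage %s done in %.1fs %s", name, timings[name], kw)
        return done

    # --- input -----------------------------------------------------------
    end = stage("input")
    truth = registry = None
    if cfg.sim is not None:
        G, variants, registry, truth = simulate_panel(cfg.sim)
        write_vcf(out / "panel.vcf", G, variants)
        write_truth(str(out / "truth"), truth, cfg.sim)
    elif cfg.input_vcf:
        if not Path(cfg.input_vcf).exists():
            raise FileNotFoundError(f"input VCF not found: {cfg.input_vcf}")
        G, variants, registry = read_vcf(cfg.input_vcf)
    elif cfg.input_hapmap:
        if not Path(cfg.input_hapmap).exists():
            raise FileNotFoundError(
                f"input HapMap not found: {cfg.input_hapmap}")
        G, variants, registry = read_hapmap(cfg.input_hapmap)
    else:
        raise ValueError("config must give sim.* keys or an input path")
    report["n_lines"] = G.n_lines
    report["n_loci_raw"] = G.n_loci
    end(lines=G.n_lines, loci=G.n_loci)

    # --- QC --------------------------------------------------------------
    end = stage("qc")
    G, qc_report = qc_filter(G, cfg.qc)
    variants = variants.subset(G.locus_ids)
    _write(qc_report, out / "qc_report.tsv")
    report["n_loci_qc"] = G.n_loci
    end(retained=G.n_loci)

    # --- diversity -------------------------------------------------------
    end = stage("diversity")
    _write(diversity.locus_stats(G).reset_index(), out / "locus_stats.tsv")
    summary = diversity.panel_summary(G, variants)
    _write(summary, out / "panel_summary.tsv")
    _write(diversity.windowed_gd(G, variants, cfg.gd_window_bp),
           out / "windowed_gd.tsv")
    _write(diversity.snp_density_track(variants), out / "snp_density.tsv")
    _, hist = diversity.adjacent_distances(variants)
    _write(hist, out / "adjacent_distance_hist.tsv")
    genome = summary[summary["chromosome"] == "genome"].iloc[0]
    report["mean_maf"] = float(genome["mean_maf"])
    report["mean_gd"] = float(genome["mean_gd"])
    report["mean_pic"] = float(genome["mean_pic"])
    end()

    # --- LD --------------------------------------------------------------
    end = stage("ld")
    from .ld import ld_decay, segment_ld_map
    _write(segment_ld_map(G, variants, cfg.ld_segment_bp),
           out / "segment_ld.tsv")
    curve, decay = ld_decay(G, variants, cfg.ld_max_dist_bp)
    _write(curve, out / "ld_decay_curve.tsv")
    _write(decay, out / "ld_decay_summary.tsv")
    gen = decay[decay["chromosome"] == "genome"].iloc[0]
    report["mean_r2"] = float(gen["mean_r2"])
    report["decay_distance_bp"] = float(gen["decay_distance_bp"])
    end()

    # --- blocks and tags -------------------------------------------------
    end = stage("blocks")
    G_masked = subgroup_missing_mask(G)
    v_masked = variants.subset(G_masked.locus_ids)
    blks, tags = blocks.tag_loci_panel(G_masked, v_masked, cfg.gabriel)
    _write(blocks.blocks_to_frame(blks), out / "blocks.tsv")
    (out / "tag_loci.txt").write_text("\n".join(tags) + "\n")
    report["n_blocks"] = len(blks)
    report["n_tags"] = len(tags)
    end(blocks=len(blks), tags=len(tags))

    # --- kinship ---------------------------------------------------------
    end = stage("kinship")
    km = kinship.kinship_matrix(G)
    kinship.kinship_to_frame(km).to_csv(out / "kinship.tsv", sep="\t")
    _write(kinship.kinship_histogram(km), out / "kinship_hist.tsv")
    report["kinship_near_zero_fraction"] = kinship.near_zero_fraction(km)
    end()

    # --- admixture over K, with CV --------------------------------------
    end = stage("admixture")
    tag_idx = [j for j, lid in enumerate(G.locus_ids) if lid in set(tags)]
    G_tag = G.take_loci(np.array(tag_idx, dtype=int)) if tag_idx else G
    cv = admixture.select_k(G_tag, cfg.k_values, seed=cfg.seed,
                            n_folds=cfg.cv_folds)
    _write(cv, out / "cv_error.tsv")
    best_k = int(cv.loc[cv["cv_error"].idxmin(), "K"])
    report["best_K"] = best_k
    Q, P, trace = admixture.fit_admixture(
        G_tag, best_k, seed=cfg.seed, max_iter=cfg.em_max_iter,
        tol=cfg.em_tol, n_restarts=cfg.n_restarts)
    write_q_matrix(out / f"admixture.{best_k}.Q", Q)
    write_p_matrix(out / f"admixture.{best_k}.P", P)
    report["final_loglik"] = trace[-1]
    end(best_k=best_k)

    # --- assignment ------------------------------------------------------
    end = stage("assignment")
    labels = [f"G{k+1}" for k in range(best_k)]
    assigned = assignment.assign_panel(Q, labels, G.line_names, cfg.assign)
    _write(assigned, out / "assignments.tsv")
    _write(assignment.group_shares(assigned, cfg.grouping_map),
           out / "group_shares.tsv")
    end()

    # --- Fst and tree ----------------------------------------------------
    end = stage("fst")
    gf = group_loci.group_freqs(G_tag, assigned, labels,
                                min_lines=cfg.min_group_lines)
    usable = [g for g in labels if g in gf.columns]
    if len(usable) >= 2:
        fst = admixture.fst_matrix(gf[usable].to_numpy().T, usable)
        fst.to_csv(out / "fst_matrix.tsv", sep="\t")
        iu = np.triu_indices(len(usable), k=1)
        report["fst_min"] = float(fst.to_numpy()[iu].min())
        report["fst_max"] = float(fst.to_numpy()[iu].max())
        (out / "fst_tree.nwk").write_text(admixture.fst_tree(fst) + "\n")
    end()

    # --- group-specific loci (two largest groups) ------------------------
    end = stage("grouploci")
    if len(usable) >= 2:
        sizes = assigned["adjusted_id"].map(
            lambda a: assignment.base_group(a)).value_counts()
        top2 = [g for g in sizes.index if g in usable][:2]
        if len(top2) == 2:
            ga, gb = top2
            gf_full = group_loci.group_freqs(
                G, assigned, top2, min_lines=cfg.min_group_lines)
            classes = group_loci.classify_loci(
                gf_full[ga], gf_full[gb], cfg.locus_class)
            _write(group_loci.class_counts_by_chromosome(classes, variants),
                   out / "group_class_counts.tsv")
            dt = group_loci.diff_table(gf_full[ga], gf_full[gb], variants,
                                       ga, gb)
            _write(dt, out / "group_freq_diff.tsv")
            report["n_differential_loci"] = int(classes["differential"].sum())
    end()

    # --- PCA -------------------------------------------------------------
    end = stage("pca")
    pcs = admixture.pca_coordinates(G, n_components=10)
    pcs.reset_index(names="line_name").to_csv(out / "pca.tsv", sep="\t",
                                              index=False)
    end()

    report["timings_s"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
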