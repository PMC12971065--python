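"""Pipeline orchestration, configuration and the run report.

``run_pipeline`` executes the stages in dependency order on a synthetic
dataset generated from the configured seed:

    links -> abc -> starr -> integration -> prioritize -> report

Any stage can be skipped (``PipelineConfig.skip``); criteria that
depend on a skipped stage are set to False and the skip is logged in
the report. All stage outputs are TSV/JSON under the configured output
directory, floats at 6 significant digits, so a rerun with the same
configuration reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abc as abc_mod
from . import links as links_mod
from . import starr as starr_mod
from . import syndata
from . import variants as var_mod
from ._stats import percent
from .formats import write_tsv, write_truth, write_vcf

logger = logging.getLogger("crevar")

SKIPPABLE = ("links", "abc", "starr", "eqtl", "predictions")


def summarize_fraction(numerator: int, denominator: int) -> str:
    """One-decimal percentage string, round half to even ('80.8%')."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return f"{percent(numerator, denominator):.1f}%"


@dataclass
class PipelineConfig:
    """Seed, thresholds and stage toggles of one pipeline run.

    Every threshold defaults to the published decision rule it
    implements; ``sim`` holds overrides for the synthetic-data
    configuration (nested dict mirroring :class:`syndata.SimConfig`).
    """

    seed: int = 0
    outdir: str = "crevar_out"
    sim: dict = field(default_factory=dict)
    skip: list = field(default_factory=list)
    metacell_k: int = 10
    link_cutoff: float = links_mod.DEFAULT_CUTOFF
    link_max_dist: int = links_mod.DEFAULT_MAX_DIST
    abc_threshold: float = abc_mod.DEFAULT_THRESHOLD
    abc_min_dist: int = abc_mod.DEFAULT_MIN_DIST
    starr_min_barcodes: int = 5
    starr_alpha: float = starr_mod.DEFAULT_ALPHA
    starr_lfc_min: float = starr_mod.ENHANCER_LFC_MIN
    starr_quantile: float = starr_mod.CONTROL_QUANTILE
    r2_cutoff: float = var_mod.R2_CUTOFF
    eqtl_fdr_max: float = var_mod.EQTL_FDR_MAX
    pred_lfc_min: float = var_mod.PRED_LFC_MIN
    pred_fdr_max: float = var_mod.PRED_FDR_MAX
    min_criteria: int = var_mod.MIN_CRITERIA

    def __post_init__(self):
        bad = set(self.skip) - set(SKIPPABLE)
        if bad:
            raise ValueError(f"unknown skippable stages: {sorted(bad)}")

    def overrides(self) -> dict:
        """Thresholds that differ from their defaults (recorded in the report)."""
        default = PipelineConfig()
        out = {}
        for f in dataclasses.fields(self):
            if f.name in ("seed", "outdir", "sim", "skip"):
                continue
            if getattr(self, f.name) != getattr(default, f.name):
                out[f.name] = getattr(self, f.name)
        return out


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=True))


@dataclass
class RunReport:
    seed: int
    counts: dict
    percentages: dict
    skipped: list
    overrides: dict
    wall_time_s: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))


def _sim_config(config: PipelineConfig) -> syndata.SimConfig:
    base = dataclasses.asdict(syndata.SimConfig())
    for key, val in config.sim.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key].update(val)
        else:
            base[key] = val
    base["seed"] = config.seed
    return syndata.config_from_dict(base)


def run_pipeline(config: PipelineConfig) -> RunReport:
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    percentages: dict = {}

    ds = syndata.simulate_all(_sim_config(config))
    vs = ds.variant_sets
    write_vcf(vs.variants, outdir / "variants.vcf")
    write_truth(
        {"variants": vs.truth, "multiome": ds.multiome.truth,
         "starr": ds.starr.truth, "abc": ds.abc.truth},
        outdir / "truth.json",
    )

    # ----- links stage ------------------------------------------------
    coacc = p2g = None
    if "links" not in config.skip:
        mo = ds.multiome
        marker_peaks = links_mod.test_features(
            mo.atac, mo.labels, "peaks_marker",
            feature_ids=list(mo.peaks["name"]))
        marker_genes = links_mod.test_features(
            mo.rna, mo.labels, "genes_marker",
            feature_ids=list(mo.genes["name"]))
        norm_atac = links_mod.log2_cpm(mo.atac)
        norm_rna = links_mod.log2_cpm(mo.rna)
        mc_atac = links_mod.make_metacells(norm_atac, mo.labels,
                                           config.metacell_k, config.seed)
        mc_rna = links_mod.MetacellMatrix(
            values=_metacell_means(norm_rna, mc_atac),
            assignments=mc_atac.assignments, k=mc_atac.k)
        coacc = links_mod.coaccessible_promoter_links(
            mc_atac, mo.peaks, mo.genes,
            cutoff=config.link_cutoff, max_dist=config.link_max_dist)
        p2g = links_mod.peak2gene_links(
            mc_atac, mc_rna, mo.peaks, mo.genes,
            cutoff=config.link_cutoff, max_dist=config.link_max_dist)
        write_tsv(marker_peaks, outdir / "marker_peaks.tsv")
        write_tsv(marker_genes, outdir / "marker_genes.tsv")
        write_tsv(coacc, outdir / "links_coaccessibility.tsv")
        write_tsv(p2g, outdir / "links_correlation.tsv")
        counts["marker_peaks_passed"] = int(marker_peaks["passed"].sum())
        counts["marker_genes_passed"] = int(marker_genes["passed"].sum())
        counts["coaccessibility_links"] = len(coacc)
        counts["correlation_links"] = len(p2g)
        logger.info("links: %d co-accessibility, %d correlation",
                    len(coacc), len(p2g))

    # ----- abc stage --------------------------------------------------
    if "abc" not in config.skip:
        ab = ds.abc
        elements = ab.elements.copy()
        elements["activity"] = abc_mod.element_activity(
            elements["atac"], elements["h3k27ac"])
        connections = abc_mod.score_all_genes(
            elements, ab.contacts, ab.genes, ab.bin_size,
            threshold=config.abc_threshold, min_dist=config.abc_min_dist)
        write_tsv(connections, outdir / "abc_connections.tsv")
        counts["abc_connections"] = len(connections)
        logger.info("abc: %d connections", len(connections))

    # ----- starr stage ------------------------------------------------
    starr_enh = starr_fun = None
    if "starr" not in config.skip:
        res = starr_mod.run_starr(
            ds.starr.counts, ds.starr.snp_meta,
            min_barcodes=config.starr_min_barcodes,
            alpha=config.starr_alpha, lfc_min=config.starr_lfc_min,
            quantile=config.starr_quantile)
        starr_enh = res["enhancers"]
        starr_fun = res["allele_effects"]
        write_tsv(starr_enh, outdir / "starr_enhancers.tsv")
        write_tsv(starr_fun, outdir / "starr_allele_effects.tsv")
        counts["starr_snps_total"] = res["qc_report"]["n_total"]
        counts["starr_snps_pass_qc"] = res["qc_report"]["n_pass"]
        percentages["starr_qc"] = summarize_fraction(
            res["qc_report"]["n_pass"], res["qc_report"]["n_total"])
        counts["starr_enhancers"] = int(starr_enh["is_enhancer"].sum())
        counts["functional_snps"] = int(starr_fun["functional"].sum())
        logger.info("starr: %s pass QC", percentages["starr_qc"])

    # ----- integration + prioritization -------------------------------
    risk = var_mod.build_risk_set(vs.index_variants, vs.ld_table,
                                  vs.credible_set, r2_cutoff=config.r2_cutoff)
    risk_full = vs.variants[vs.variants["id"].isin(set(risk["id"]))]
    noncoding = risk_full[risk_full["coding_class"] != "protein-altering"]
    counts["risk_variants"] = len(risk_full)
    counts["noncoding_or_synonymous"] = len(noncoding)
    percentages["noncoding_or_synonymous"] = summarize_fraction(
        len(noncoding), len(risk_full))

    accessibility, acc_summary = var_mod.intersect_accessibility(
        noncoding, vs.peaks_by_celltype)
    counts["accessible_variants"] = acc_summary["n_accessible"]
    percentages["accessible_variants"] = summarize_fraction(
        acc_summary["n_accessible"], acc_summary["n_variants"])

    enrichment = var_mod.peak_enrichment(
        noncoding,
        {"focal": pd.concat(vs.peaks_by_celltype.values()), **vs.control_peaks},
        control_tissues=list(vs.control_peaks))
    write_tsv(enrichment, outdir / "enrichment.tsv")

    eqtls = None if "eqtl" in config.skip else vs.eqtls
    preds = None if "predictions" in config.skip else vs.predictions
    flags = var_mod.assemble_criteria(
        noncoding, accessibility, vs.links, vs.loops, vs.genes,
        eqtls if eqtls is not None else pd.DataFrame(),
        predictions=preds,
        starr_enhancers=starr_enh, starr_functional=starr_fun)
    flags, pr_summary = var_mod.prioritize(flags,
                                           min_criteria=config.min_criteria)
    out_flags = flags.copy()
    out_flags["target_genes"] = out_flags["target_genes"].map(",".join)
    for c in var_mod.CRITERIA + ("prioritized",):
        out_flags[c] = out_flags[c].astype(int)
    write_tsv(out_flags, outdir / "criteria_flags.tsv")
    counts["prioritized_variants"] = pr_summary["n_prioritized"]
    if pr_summary["n_accessible"]:
        percentages["prioritized_of_accessible"] = summarize_fraction(
            pr_summary["n_prioritized"], pr_summary["n_accessible"])
    if len(noncoding):
        percentages["prioritized_of_noncoding"] = summarize_fraction(
            pr_summary["n_prioritized"], len(noncoding))

    report = RunReport(
        seed=config.seed,
        counts=counts,
        percentages=percentages,
        skipped=sorted(config.skip),
        overrides=config.overrides(),
        wall_time_s=round(time.time() - t0, 3),
    )
    report.to_json(outdir / "report.json")
    return report


def _metacell_means(values, metacells: links_mod.MetacellMatrix):
    """Aggregate a second matrix with an existing metacell partition."""
    import numpy as np

    values = np.asarray(values, dtype=float)
    n_mc = metacells.values.shape[0]
    out = np.zeros((n_mc, values.shape[1]))
    grouped = metacells.assignments.groupby("metacell")["cell"]
    for mc_id, cells in grouped:
        out[mc_id] = values[list(cells)].mean(axis=0)
    return out
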