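"""Per-variant evidence assembly and the >=3-of-8 prioritization rule.

A GWAS risk-variant universe is assembled from index variants by LD
expansion (R^2 > 0.5, strict) merged with a 95% credible set, then each
noncoding/synonymous variant accessible in at least one cell-type peak
set is scored on eight boolean evidence criteria:

1. its peak is co-accessible with a gene promoter;
2. its peak's accessibility correlates with a gene's expression;
3. it lies in a HiChIP loop anchor whose partner anchor overlaps a
   gene promoter;
4. its peak is connected to a gene by an ABC call;
5. it lies inside a STARR-seq enhancer;
6. it is a functional SNP by allele-specific STARR-seq;
7. it is a significant eQTL (FDR <= 0.05, either tissue);
8. it is predicted high-effect on chromatin accessibility (fold-
   averaged |log2FC| > 0.25 at FDR < 0.01 in any cell type; one-sided
   Poisson test per cell type, Fisher-combined, BH across variants).

Variants meeting at least three criteria are prioritized. Missense
variants are classified from pathogenicity scores (< 0.34 likely
benign, > 0.565 likely pathogenic, otherwise ambiguous), and variant
enrichment in peak sets is densities per unique merged-peak base,
normalized to control tissues.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._stats import bh_adjust, fisher_combine, percent, signed_poisson_pvalue
from .links import promoter_windows

R2_CUTOFF = 0.5
AM_BENIGN_MAX = 0.34
AM_PATHOGENIC_MIN = 0.565
EQTL_FDR_MAX = 0.05
PRED_LFC_MIN = 0.25
PRED_FDR_MAX = 0.01
MIN_CRITERIA = 3

CRITERIA = (
    "coaccessible_promoter",
    "expression_correlated",
    "hichip_linked",
    "abc_connected",
    "in_starr_enhancer",
    "functional_snp",
    "significant_eqtl",
    "high_effect",
)


# ---------------------------------------------------------------------------
# risk-set assembly and coding classification


def build_risk_set(
    index_variants: pd.DataFrame,
    ld_table: pd.DataFrame,
    credible_set: pd.DataFrame,
    r2_cutoff: float = R2_CUTOFF,
) -> pd.DataFrame:
    """Union of LD-expanded variants (R^2 strictly above cutoff) and the
    credible set, deduplicated by (chrom, pos, ref, alt).

    ``ld_table`` rows carry index_id, variant_id and r2; variant
    coordinates are looked up in ``credible_set`` or carried on the LD
    table itself (chrom/pos/ref/alt columns). Index variants absent from
    the LD table are kept with a warning.
    """
    frames = []
    ld = ld_table[ld_table["r2"] > r2_cutoff].copy()
    missing = set(index_variants["id"]) - set(ld_table["index_id"])
    if missing:
        warnings.warn(
            f"index variants absent from the LD table kept as-is: {sorted(missing)}"
        )
        frames.append(index_variants[index_variants["id"].isin(missing)]
                      .assign(source="index"))
    if {"chrom", "pos", "ref", "alt"}.issubset(ld.columns):
        frames.append(
            ld.rename(columns={"variant_id": "id"})[
                ["id", "chrom", "pos", "ref", "alt"]
            ].assign(source="ld")
        )
    else:
        frames.append(pd.DataFrame({"id": ld["variant_id"], "source": "ld"}))
    frames.append(credible_set.assign(source="credible"))
    merged = pd.concat(frames, ignore_index=True)
    key_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in merged.columns]
    if key_cols == ["chrom", "pos", "ref", "alt"]:
        merged = merged.drop_duplicates(subset=key_cols)
    else:
        merged = merged.drop_duplicates(subset="id")
    return merged.reset_index(drop=True)


def classify_alpha_missense(score):
    """Pathogenicity class from a missense score in [0, 1].

    Strictly below 0.34 is likely benign, strictly above 0.565 likely
    pathogenic, anything else (including the boundaries) ambiguous.
    """
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("scores must lie in [0, 1]")
    out = np.where(
        arr < AM_BENIGN_MAX,
        "likely benign",
        np.where(arr > AM_PATHOGENIC_MIN, "likely pathogenic", "ambiguous"),
    )
    return out.item() if np.isscalar(score) else out


# ---------------------------------------------------------------------------
# interval machinery


def _build_trees(peaks: pd.DataFrame) -> dict:
    trees: dict = {}
    for row in peaks.itertuples(index=False):
        if row.end <= row.start:
            continue
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    return trees


def intersect_accessibility(variants: pd.DataFrame, peaks_by_celltype: dict):
    """Cell types (and hosting peaks) whose peaks contain each variant.

    A variant at position p is inside a peak [start, end) iff
    start <= p < end. Returns a long frame (variant_id, cell_type,
    peak_id) plus a summary with the count and percentage of variants
    accessible in at least one cell type.
    """
    trees = {ct: _build_trees(df) for ct, df in peaks_by_celltype.items()}
    rows = []
    for v in variants.itertuples(index=False):
        for ct, forest in trees.items():
            tree = forest.get(v.chrom)
            if tree is None:
                continue
            for hit in tree.at(v.pos):
                rows.append({"variant_id": v.id, "cell_type": ct,
                             "peak_id": hit.data})
    acc = pd.DataFrame(rows, columns=["variant_id", "cell_type", "peak_id"])
    n_acc = acc["variant_id"].nunique()
    summary = {
        "n_variants": len(variants),
        "n_accessible": n_acc,
        "pct_accessible": percent(n_acc, len(variants)) if len(variants) else 0.0,
    }
    return acc, summary


def merge_intervals(peaks: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals per chromosome."""
    out = []
    for chrom, sub in peaks.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def peak_enrichment(
    variants: pd.DataFrame,
    tissue_peaks: dict,
    control_tissues,
) -> pd.DataFrame:
    """Accessible-variant density per unique peak base, per tissue.

    Constituent peaks of a tissue are merged to a union before counting
    variants and bases, so duplicated peaks change nothing; densities
    are normalized to the mean over the control tissues.
    """
    control_tissues = list(control_tissues)
    if not control_tissues:
        raise ValueError("need at least one control tissue")
    rows = []
    for tissue, peaks in tissue_peaks.items():
        merged = merge_intervals(peaks)
        bases = int((merged["end"] - merged["start"]).sum())
        trees = _build_trees(merged.assign(name=tissue))
        n_acc = sum(
            1 for v in variants.itertuples(index=False)
            if v.chrom in trees and trees[v.chrom].overlaps_point(v.pos)
        )
        density = n_acc / bases if bases > 0 else np.nan
        if bases == 0:
            warnings.warn(f"tissue {tissue!r} has zero peak bases; density missing")
        rows.append({"tissue": tissue, "n_accessible": n_acc,
                     "unique_bases": bases, "density": density})
    df = pd.DataFrame(rows)
    ctrl = df.loc[df["tissue"].isin(control_tissues), "density"]
    ctrl_mean = ctrl.mean()
    df["normalized"] = df["density"] / ctrl_mean if ctrl_mean else np.nan
    return df


# ---------------------------------------------------------------------------
# predicted allelic-effect aggregation


def aggregate_predictions(
    predictions: pd.DataFrame,
    lfc_min: float = PRED_LFC_MIN,
    fdr_max: float = PRED_FDR_MAX,
):
    """Fold-averaged allelic accessibility effects and the high-effect flag.

    Per variant and cell type the log2 fold change is averaged over
    model folds and a one-sided Poisson test compares the fold-averaged
    alternative-allele count against the fold-averaged reference count
    as rate (tail chosen by the sign of the fold change; p = 1 at zero).
    Cell-type p values are combined with Fisher's method, BH-corrected
    across variants; high effect needs any cell type |log2FC| >
    ``lfc_min`` and variant FDR < ``fdr_max``.

    Returns ``(per_variant, per_celltype)`` frames.
    """
    req = {"variant_id", "cell_type", "fold", "ref_count", "alt_count"}
    if not req.issubset(predictions.columns):
        raise ValueError(f"predictions need columns {sorted(req)}")
    if (predictions[["ref_count", "alt_count"]] <= 0).any().any():
        raise ValueError("predicted counts must be positive")
    per_ct = (
        predictions.assign(
            lfc=np.log2(predictions["alt_count"] / predictions["ref_count"])
        )
        .groupby(["variant_id", "cell_type"], as_index=False)
        .agg(log2fc=("lfc", "mean"), ref_avg=("ref_count", "mean"),
             alt_avg=("alt_count", "mean"), n_folds=("fold", "nunique"))
    )
    per_ct["pvalue"] = signed_poisson_pvalue(
        per_ct["alt_avg"].to_numpy(), per_ct["ref_avg"].to_numpy()
    )
    # equal fold-averaged counts carry no directional evidence
    per_ct.loc[per_ct["log2fc"] == 0, "pvalue"] = 1.0
    wide_p = per_ct.pivot(index="variant_id", columns="cell_type", values="pvalue")
    wide_lfc = per_ct.pivot(index="variant_id", columns="cell_type", values="log2fc")
    stat, combined = fisher_combine(wide_p.to_numpy(), axis=1)
    fdr = bh_adjust(combined)
    max_abs = np.abs(wide_lfc.to_numpy()).max(axis=1)
    per_variant = pd.DataFrame(
        {
            "variant_id": wide_p.index,
            "fisher_stat": stat,
            "combined_p": combined,
            "fdr": fdr,
            "max_abs_log2fc": max_abs,
            "high_effect": (max_abs > lfc_min) & (fdr < fdr_max),
        }
    ).reset_index(drop=True)
    return per_variant, per_ct


# ---------------------------------------------------------------------------
# evidence flags


def link_flags(
    accessibility: pd.DataFrame,
    links: pd.DataFrame,
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    variants: pd.DataFrame,
) -> pd.DataFrame:
    """Four linking criteria per variant, with target gene lists.

    ``accessibility`` is the long (variant_id, cell_type, peak_id)
    frame from :func:`intersect_accessibility`; ``links`` is a unified
    link table with a ``method`` column (coaccessibility, correlation,
    abc); the HiChIP criterion holds when the variant lies in a loop
    anchor whose partner anchor overlaps a gene promoter.
    """
    method_to_flag = {
        "coaccessibility": "coaccessible_promoter",
        "correlation": "expression_correlated",
        "abc": "abc_connected",
    }
    peak_methods: dict = {}
    if len(links):
        for row in links.itertuples(index=False):
            peak_methods.setdefault(row.peak_id, {}).setdefault(
                row.method, set()
            ).add(row.gene_id)
    prom = promoter_windows(genes)
    pos_of = variants.set_index("id")[["chrom", "pos"]]
    rows = []
    peaks_of = accessibility.groupby("variant_id")["peak_id"].agg(set) \
        if len(accessibility) else pd.Series(dtype=object)
    for vid in pos_of.index:
        flags = {f: False for f in method_to_flag.values()}
        targets: dict = {f: set() for f in method_to_flag.values()}
        for pk in peaks_of.get(vid, set()):
            for method, flag in method_to_flag.items():
                genes_hit = peak_methods.get(pk, {}).get(method)
                if genes_hit:
                    flags[flag] = True
                    targets[flag] |= genes_hit
        hic_targets = set()
        chrom, pos = pos_of.loc[vid, "chrom"], pos_of.loc[vid, "pos"]
        for lp in loops.itertuples(index=False):
            for (c1, s1, e1, c2, s2, e2) in (
                (lp.chrom1, lp.start1, lp.end1, lp.chrom2, lp.start2, lp.end2),
                (lp.chrom2, lp.start2, lp.end2, lp.chrom1, lp.start1, lp.end1),
            ):
                if c1 == chrom and s1 <= pos < e1:
                    partner = prom[(prom["chrom"] == c2)
                                   & (prom["start"] < e2) & (s2 < prom["end"])]
                    hic_targets |= set(partner["gene"])
        rows.append(
            {
                "variant_id": vid,
                **flags,
                "hichip_linked": bool(hic_targets),
                "target_genes": sorted(
                    set().union(*targets.values()) | hic_targets
                ),
            }
        )
    return pd.DataFrame(rows)


def eqtl_flag(
    variants: pd.DataFrame, eqtls: pd.DataFrame, fdr_max: float = EQTL_FDR_MAX
) -> pd.Series:
    """True when any eQTL row for the variant has FDR <= fdr_max (inclusive)."""
    if len(eqtls):
        sig = set(eqtls.loc[eqtls["fdr"] <= fdr_max, "variant_id"])
    else:
        sig = set()
    return variants["id"].isin(sig).rename("significant_eqtl")


def assemble_criteria(
    variants: pd.DataFrame,
    accessibility: pd.DataFrame,
    links: pd.DataFrame,
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    eqtls: pd.DataFrame,
    predictions: pd.DataFrame | None = None,
    starr_enhancers: pd.DataFrame | None = None,
    starr_functional: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row of the eight boolean criteria per accessible variant.

    Criteria whose input table is absent (None) are set to False for
    every variant, with a warning. STARR flags hold when the SNP is an
    enhancer / functional in ANY condition.
    """
    accessible_ids = (
        accessibility["variant_id"].unique() if len(accessibility) else []
    )
    acc_variants = variants[variants["id"].isin(set(accessible_ids))].copy()
    lf = link_flags(accessibility, links, loops, genes, acc_variants)
    flags = acc_variants[["id"]].rename(columns={"id": "variant_id"}).merge(
        lf, on="variant_id", how="left"
    )
    flags["significant_eqtl"] = eqtl_flag(acc_variants, eqtls).to_numpy()

    if starr_enhancers is not None and len(starr_enhancers):
        enh_ids = set(
            starr_enhancers.loc[starr_enhancers["is_enhancer"], "snp_id"]
        )
    else:
        if starr_enhancers is None:
            warnings.warn("no STARR enhancer table; in_starr_enhancer set to False")
        enh_ids = set()
    flags["in_starr_enhancer"] = flags["variant_id"].isin(enh_ids)

    if starr_functional is not None and len(starr_functional):
        fun_ids = set(
            starr_functional.loc[starr_functional["functional"], "snp_id"]
        )
    else:
        if starr_functional is None:
            warnings.warn("no STARR functional table; functional_snp set to False")
        fun_ids = set()
    flags["functional_snp"] = flags["variant_id"].isin(fun_ids)

    if predictions is not None and len(predictions):
        per_variant, _ = aggregate_predictions(predictions)
        high = set(per_variant.loc[per_variant["high_effect"], "variant_id"])
    else:
        if predictions is None:
            warnings.warn("no prediction table; high_effect set to False")
        high = set()
    flags["high_effect"] = flags["variant_id"].isin(high)
    return flags[["variant_id", *CRITERIA, "target_genes"]]


def prioritize(flags: pd.DataFrame, min_criteria: int = MIN_CRITERIA):
    """Apply the >=3-of-8 rule and summarize criterion frequencies."""
    out = flags.copy()
    crit = out[list(CRITERIA)].astype(bool)
    out["n_criteria"] = crit.sum(axis=1)
    out["prioritized"] = out["n_criteria"] >= min_criteria
    n = len(out)
    summary = {
        "n_accessible": n,
        "n_prioritized": int(out["prioritized"].sum()),
        "pct_prioritized": percent(int(out["prioritized"].sum()), n) if n else 0.0,
        "criterion_counts": {c: int(crit[c].sum()) for c in CRITERIA},
        "criterion_pct": {c: percent(int(crit[c].sum()), n) if n else 0.0
                          for c in CRITERIA},
    }
    return out, summary
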