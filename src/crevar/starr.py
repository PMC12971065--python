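"""Allele-specific STARR-seq statistics.

A STARR-seq experiment measures, per SNP and allele, the number of
unique barcodes observed in an input plasmid library and in output
(RNA) libraries from one or more conditions. This module implements the
published decision rules on such count tables:

* barcode-count QC (a SNP is dropped when any replicate of any allele
  or condition has fewer than 5 unique barcodes);
* median-of-ratios size-factor normalization across samples;
* enhancer calling per condition: alleles are combined, output is
  compared against input with a negative-binomial Wald test using a
  method-of-moments common dispersion, BH-corrected per condition, and
  flagged at |log2FC| > 0.585 (fold change 1.5) and adjusted p < 0.05;
* allelic effects per condition: per-replicate paired log2 ratios
  alt/ref tested with a moderated paired t statistic whose variance is
  shrunk toward the pooled across-SNP variance;
* the functional-SNP rule: inside an enhancer, adjusted p < 0.05, and
  |log2FC| strictly above the 80th percentile of absolute control-SNP
  effects in the same condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import P_FLOOR, bh_adjust, percent

LN2 = np.log(2.0)
ENHANCER_LFC_MIN = 0.585  # log2 of the 1.5 fold-change bound
DEFAULT_ALPHA = 0.05
DEFAULT_EPS = 0.5
CONTROL_QUANTILE = 0.8

REQUIRED_COLUMNS = ["snp_id", "allele", "condition", "replicate", "unique_barcodes"]


def _check_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("empty count table")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    key = table[["snp_id", "allele", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (snp, allele, condition, replicate) rows")


def sum_technical_replicates(table: pd.DataFrame, tech_to_bio: dict) -> pd.DataFrame:
    """Collapse technical replicate indexes into biological replicates."""
    out = table.copy()
    out["replicate"] = out["replicate"].map(tech_to_bio)
    if out["replicate"].isna().any():
        raise ValueError("tech_to_bio does not cover every replicate index")
    return (
        out.groupby(["snp_id", "allele", "condition", "replicate"], as_index=False)
        ["unique_barcodes"].sum()
    )


def qc_filter(table: pd.DataFrame, min_barcodes: int = 5):
    """SNPs whose every measured replicate has >= ``min_barcodes`` barcodes.

    Returns ``(passing_ids, report)``; the report carries the count and
    one-decimal percentage of passing SNPs.
    """
    _check_table(table)
    mins = table.groupby("snp_id")["unique_barcodes"].min()
    passing = set(mins.index[mins >= min_barcodes])
    n_total = len(mins)
    pct = percent(len(passing), n_total)
    report = {
        "n_total": n_total,
        "n_pass": len(passing),
        "pct_pass": pct,
        "summary": f"{len(passing)} ({pct}%) passed quality-control filters",
    }
    return passing, report


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Uses only oligos (rows) with positive counts in every sample, each
    divided by its geometric mean across samples.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no oligo has positive counts in all samples; add a pseudocount "
            "before computing size factors"
        )
    sub = mat[allpos]
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    return pd.Series(np.median(sub / geo, axis=0), index=counts.columns)


def _pivot(table, conditions, combine_alleles):
    sub = table[table["condition"].isin(conditions)]
    index = "snp_id" if combine_alleles else ["snp_id", "allele"]
    mat = sub.pivot_table(
        index=index, columns=["condition", "replicate"],
        values="unique_barcodes", aggfunc="sum", fill_value=0,
    )
    return mat


def estimate_dispersion(norm: np.ndarray, groups) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    For each oligo and replicate group, alpha_i = (var - mean) / mean^2;
    the common value is the median over oligos and groups, floored at 0.
    """
    alphas = []
    for cols in groups:
        sub = norm[:, cols]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        alphas.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not alphas:
        return 0.0
    return float(max(0.0, np.median(np.concatenate(alphas))))


def call_enhancers(
    table: pd.DataFrame,
    condition: str,
    passing=None,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = ENHANCER_LFC_MIN,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Negative-binomial Wald test of one output condition against input.

    Reference and alternative allele counts are combined per SNP; counts
    are normalized by median-of-ratios size factors over the samples
    being compared; the Wald statistic uses a common method-of-moments
    dispersion; BH correction runs across SNPs within the condition.
    """
    _check_table(table)
    mat = _pivot(table, ["input", condition], combine_alleles=True)
    if passing is not None:
        mat = mat.loc[mat.index.isin(set(passing))]
    in_cols = [j for j, c in enumerate(mat.columns) if c[0] == "input"]
    out_cols = [j for j, c in enumerate(mat.columns) if c[0] == condition]
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError("need at least 2 replicates on each side of the test")
    factors = size_factors(mat)
    norm = mat.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    disp = estimate_dispersion(norm, [in_cols, out_cols])
    mu_in = norm[:, in_cols].mean(axis=1)
    mu_out = norm[:, out_cols].mean(axis=1)
    lfc = np.log2(mu_out + eps) - np.log2(mu_in + eps)
    var_ln = ((1.0 / np.maximum(mu_in, eps) + disp) / len(in_cols)
              + (1.0 / np.maximum(mu_out, eps) + disp) / len(out_cols))
    se = np.sqrt(var_ln) / LN2
    z = np.where(se > 0, lfc / np.where(se == 0, 1.0, se), np.inf * np.sign(lfc))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "snp_id": mat.index,
            "condition": condition,
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "is_enhancer": (np.abs(lfc) > lfc_min) & (padj < alpha),
        }
    ).reset_index(drop=True)


def allele_effects(
    table: pd.DataFrame,
    condition: str,
    passing=None,
    eps: float = DEFAULT_EPS,
    shrink_target: float | None = None,
) -> pd.DataFrame:
    """Moderated paired test of alt vs ref expression in one condition.

    Per replicate r the paired log ratio is
    ``d_r = log2((alt_r + eps) / (ref_r + eps))`` on size-factor
    normalized counts; the effect is ``mean(d_r)``. The per-SNP variance
    is shrunk toward the across-SNP pooled variance with weight
    ``d0 / (d0 + n - 1)`` where ``d0`` is the pooled degrees of freedom,
    and the t statistic is referred to ``d0 + n - 1`` df.
    ``shrink_target`` overrides the pooled variance (mainly for tests).
    """
    _check_table(table)
    mat = _pivot(table, [condition], combine_alleles=False)
    if passing is not None:
        mat = mat.loc[mat.index.get_level_values("snp_id").isin(set(passing))]
    ref_df = mat.xs("ref", level="allele")
    alt_df = mat.xs("alt", level="allele")
    both = ref_df.index.intersection(alt_df.index).sort_values()
    n_snps = mat.index.get_level_values("snp_id").nunique()
    if len(both) < n_snps:
        raise ValueError("both alleles must be measured for every SNP")
    if eps == 0 and (mat.to_numpy() == 0).any():
        raise ValueError("zero counts with eps=0 give infinite log ratios; use eps>0")
    factors = size_factors(mat)
    ref = ref_df.loc[both].to_numpy(dtype=float) / factors.to_numpy()[None, :]
    alt = alt_df.loc[both].to_numpy(dtype=float) / factors.to_numpy()[None, :]
    both = list(both)
    n = ref.shape[1]
    if n < 2:
        raise ValueError("need at least 2 replicates")
    d = np.log2(alt + eps) - np.log2(ref + eps)
    effect = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    d_resid = n - 1
    d0 = len(both) * d_resid
    s0 = float(np.mean(s2)) if shrink_target is None else float(shrink_target)
    w = d0 / (d0 + d_resid)
    s2_mod = w * s0 + (1.0 - w) * s2
    se = np.sqrt(s2_mod / n)
    df = d0 + d_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se == 0, 1.0, se), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    pvals[degenerate & (effect != 0)] = P_FLOOR
    pvals[degenerate & (effect == 0)] = 1.0
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "snp_id": both,
            "condition": condition,
            "log2fc": effect,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    )


def control_threshold(effects: pd.DataFrame, q: float = CONTROL_QUANTILE) -> float:
    """Quantile of |log2FC| over control-SNP allelic effects (one condition)."""
    if len(effects) == 0:
        raise ValueError("no control SNPs measured in this condition")
    if len(effects) < 5:
        raise ValueError(f"need at least 5 control SNPs, got {len(effects)}")
    return float(np.quantile(np.abs(effects["log2fc"].to_numpy()), q))


def call_functional(
    effects: pd.DataFrame,
    enhancers: pd.DataFrame,
    threshold: float,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Flag allelic effects that meet the functional-SNP rule.

    functional <=> the SNP is an enhancer in the same condition AND
    adjusted p < alpha AND |log2FC| strictly above ``threshold``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    enh = enhancers.set_index(["snp_id", "condition"])["is_enhancer"]
    out = effects.copy()
    keys = list(zip(out["snp_id"], out["condition"]))
    in_enh = np.array([bool(enh.get(k, False)) for k in keys])
    out["functional"] = (
        in_enh & (out["padj"].to_numpy() < alpha)
        & (np.abs(out["log2fc"].to_numpy()) > threshold)
    )
    return out


def run_starr(
    counts: pd.DataFrame,
    snp_meta: pd.DataFrame,
    conditions=("naive", "complement"),
    min_barcodes: int = 5,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = ENHANCER_LFC_MIN,
    quantile: float = CONTROL_QUANTILE,
) -> dict:
    """QC, enhancer calling, allelic effects and functional flags.

    Control SNPs (``snp_meta.is_control``) set the per-condition
    magnitude threshold of the functional rule and are excluded from the
    reported enhancer/allelic tables.
    """
    passing, report = qc_filter(counts, min_barcodes=min_barcodes)
    controls = set(snp_meta.loc[snp_meta["is_control"], "snp_id"])
    enh_frames, eff_frames, thresholds = [], [], {}
    for cond in conditions:
        enh = call_enhancers(counts, cond, passing=passing,
                             alpha=alpha, lfc_min=lfc_min)
        eff = allele_effects(counts, cond, passing=passing)
        ctrl_eff = eff[eff["snp_id"].isin(controls)]
        thr = control_threshold(ctrl_eff, q=quantile)
        thresholds[cond] = thr
        eff = call_functional(eff[~eff["snp_id"].isin(controls)],
                              enh, thr, alpha=alpha)
        enh_frames.append(enh[~enh["snp_id"].isin(controls)])
        eff_frames.append(eff)
    return {
        "qc_report": report,
        "passing": passing,
        "enhancers": pd.concat(enh_frames, ignore_index=True),
        "allele_effects": pd.concat(eff_frames, ignore_index=True),
        "control_thresholds": thresholds,
    }
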