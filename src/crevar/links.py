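"""Pseudo-bulk statistics and correlation-based enhancer-gene linking.

Implements the single-cell multiome analyses used to nominate candidate
enhancers: per-cell-type pseudo-bulk aggregation, marker/differential
feature testing (two-sided Wilcoxon rank-sum with mode-specific
thresholds and BH correction), metacell construction, the two
correlation-based linking strategies (co-accessibility with a promoter
peak; peak accessibility vs gene expression), and the marker-gene
enrichment of link targets.

Correlations are product-moment correlations computed on metacell
aggregates; the conventional normalization is log2(CPM + 1), applied by
:func:`log2_cpm`. Linking uses the signed correlation (r > cutoff, not
|r|), reflecting the activating semantics of enhancer-promoter links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, log2_fold_change, rank_sum_p_batch
from .formats import gene_tss

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 100
DEFAULT_CUTOFF = 0.3
DEFAULT_MAX_DIST = 250_000

#: per-mode pass thresholds: (min log2FC, max FDR, min fraction, max adj p)
MODE_THRESHOLDS = {
    "peaks_marker": {"lfc": 0.5, "fdr": 0.1},
    "peaks_differential": {"lfc": 0.5, "fdr": 0.25},
    "genes_marker": {"lfc": 1.0, "frac": 0.6},
    "genes_pairwise": {"lfc": 0.5, "frac": 0.3, "padj": 0.05},
}


def log2_cpm(counts: np.ndarray) -> np.ndarray:
    """log2(counts-per-million + 1) per cell (row)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib = np.where(lib == 0, 1.0, lib)
    return np.log2(counts / lib * 1e6 + 1.0)


@dataclass
class PseudoBulkMatrix:
    """Cell-type by feature sums with a log2-CPM normalized layer."""

    raw: pd.DataFrame
    norm: pd.DataFrame

    @property
    def groups(self):
        return list(self.raw.index)


def make_pseudobulk(counts, labels, feature_ids=None, groups=None) -> PseudoBulkMatrix:
    """Sum counts over cells of each label; normalized layer is log2 CPM.

    When ``groups`` is given, cells whose label is outside it raise an
    error naming the offending cells, and empty groups produce all-zero
    rows with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if counts.shape[0] != len(labels):
        raise ValueError("every cell needs a label (lengths differ)")
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(counts.shape[1])]
    if groups is not None:
        unknown = ~np.isin(labels, list(groups))
        if unknown.any():
            raise ValueError(
                f"cells with unknown labels: {np.flatnonzero(unknown).tolist()}"
            )
        groups = list(groups)
    else:
        groups = sorted(set(labels))
    raw = np.zeros((len(groups), counts.shape[1]))
    for gi, g in enumerate(groups):
        mask = labels == g
        if not mask.any():
            warnings.warn(f"cell type {g!r} has no cells; row of zeros emitted")
        raw[gi] = counts[mask].sum(axis=0)
    raw_df = pd.DataFrame(raw, index=groups, columns=feature_ids)
    norm_df = pd.DataFrame(log2_cpm(raw), index=groups, columns=feature_ids)
    return PseudoBulkMatrix(raw=raw_df, norm=norm_df)


def test_features(counts, labels, mode, feature_ids=None, eps=1.0) -> pd.DataFrame:
    """Per-feature per-group Wilcoxon rank-sum tests with pass flags.

    Marker modes compare each group's cells against all other cells;
    pairwise modes require exactly two groups and compare them head to
    head. Values are normalized to log2 CPM before testing; log2 fold
    changes are computed on group means of the normalized values with
    pseudocount ``eps``; BH correction is applied across features within
    each group. Groups with fewer than 3 cells yield p = 1 with a warning.
    """
    if mode not in MODE_THRESHOLDS:
        raise ValueError(f"unknown mode {mode!r}; choose from {list(MODE_THRESHOLDS)}")
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(counts.shape[1])]
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairwise = mode in ("peaks_differential", "genes_pairwise")
    if pairwise and len(groups) != 2:
        raise ValueError(f"mode {mode!r} requires exactly 2 groups, got {len(groups)}")
    # linear CPM: ranks (hence Wilcoxon p) match any monotone transform,
    # and fold changes are taken on group means of the linear values
    lib = counts.sum(axis=1, keepdims=True)
    norm = counts / np.where(lib == 0, 1.0, lib) * 1e6
    thr = MODE_THRESHOLDS[mode]
    results = []
    for g in groups:
        in_g = labels == g
        other = ~in_g if not pairwise else (labels == [h for h in groups if h != g][0])
        x, y = norm[in_g], norm[other]
        if in_g.sum() < 3 or other.sum() < 3:
            warnings.warn(f"group {g!r} comparison has <3 cells; p set to 1")
            pvals = np.ones(counts.shape[1])
        else:
            pvals = rank_sum_p_batch(x, y)
        lfc = log2_fold_change(x.mean(axis=0), y.mean(axis=0), eps=eps)
        frac = (counts[in_g] > 0).mean(axis=0)
        fdr = bh_adjust(pvals)
        passed = np.ones(counts.shape[1], dtype=bool)
        if "lfc" in thr:
            passed &= lfc >= thr["lfc"]
        if "fdr" in thr:
            passed &= fdr <= thr["fdr"]
        if "frac" in thr:
            passed &= frac >= thr["frac"]
        if "padj" in thr:
            passed &= fdr < thr["padj"]
        results.append(
            pd.DataFrame(
                {
                    "feature": feature_ids,
                    "group": g,
                    "log2fc": lfc,
                    "fraction": frac,
                    "pvalue": pvals,
                    "fdr": fdr,
                    "passed": passed,
                }
            )
        )
    return pd.concat(results, ignore_index=True)


@dataclass
class MetacellMatrix:
    """Metacell by feature means plus the cell partition that built them."""

    values: np.ndarray            # metacells x features
    assignments: pd.DataFrame     # cell index, cell type, metacell id
    k: int

    @property
    def n_metacells(self):
        return self.values.shape[0]


def make_metacells(values, labels, k: int, seed: int) -> MetacellMatrix:
    """Group cells within type into seeded random blocks of exactly ``k``.

    Remainder cells (and whole cell types with fewer than ``k`` cells)
    are dropped with a warning; metacell values are member means.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rows, assign = [], []
    mc_id = 0
    for g in sorted(set(labels)):
        idx = np.flatnonzero(labels == g)
        if len(idx) < k:
            warnings.warn(f"cell type {g!r} has fewer than k={k} cells; skipped")
            continue
        perm = rng.permutation(idx)
        n_blocks = len(idx) // k
        for b in range(n_blocks):
            members = perm[b * k:(b + 1) * k]
            rows.append(values[members].mean(axis=0))
            for m in members:
                assign.append({"cell": int(m), "cell_type": g, "metacell": mc_id})
            mc_id += 1
    if not rows:
        raise ValueError("no metacells could be formed")
    return MetacellMatrix(
        values=np.vstack(rows),
        assignments=pd.DataFrame(assign).sort_values("cell").reset_index(drop=True),
        k=k,
    )


def promoter_windows(genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware promoter intervals: -2000/+100 around the TSS."""
    usable = genes[genes["strand"].isin(["+", "-"])]
    skipped = len(genes) - len(usable)
    if skipped:
        warnings.warn(f"{skipped} genes without strand/TSS skipped")
    tss = gene_tss(usable)
    plus = usable["strand"] == "+"
    start = np.where(plus, tss - PROMOTER_UPSTREAM, tss - PROMOTER_DOWNSTREAM + 1)
    end = np.where(plus, tss + PROMOTER_DOWNSTREAM + 1, tss + PROMOTER_UPSTREAM + 1)
    return pd.DataFrame(
        {"chrom": usable["chrom"], "start": start, "end": end,
         "gene": usable["name"], "tss": tss}
    ).reset_index(drop=True)


def _overlaps(a_start, a_end, b_start, b_end):
    return (a_start < b_end) & (b_start < a_end)


def _corr_columns(mat: np.ndarray):
    """Column correlation matrix; constant columns give nan."""
    with np.errstate(invalid="ignore", divide="ignore"):
        centered = mat - mat.mean(axis=0)
        sd = centered.std(axis=0)
        normed = np.where(sd > 0, centered / np.where(sd == 0, 1.0, sd), np.nan)
        return normed.T @ normed / mat.shape[0]


def coaccessible_promoter_links(
    metacell_atac: MetacellMatrix,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Peaks co-accessible with a promoter peak of a gene.

    A peak is linked to gene ``g`` when its metacell correlation with at
    least one peak overlapping ``g``'s promoter exceeds ``cutoff``
    (signed), the peak lies on the gene's chromosome, and the
    peak-midpoint-to-TSS distance is at most ``max_dist``. The promoter
    peak itself is never its own co-accessibility partner.
    """
    prom = promoter_windows(genes)
    corr = _corr_columns(metacell_atac.values)
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    out = []
    for _, pr in prom.iterrows():
        on_chrom = peaks["chrom"].to_numpy() == pr["chrom"]
        pp = np.flatnonzero(
            on_chrom
            & _overlaps(peaks["start"].to_numpy(), peaks["end"].to_numpy(),
                        pr["start"], pr["end"])
        )
        if len(pp) == 0:
            continue
        dist = np.abs(mid - pr["tss"])
        candidates = np.flatnonzero(on_chrom & (dist <= max_dist))
        for ci in candidates:
            partners = pp[pp != ci]
            if len(partners) == 0:
                continue
            r = np.nanmax(corr[ci, partners]) if not np.all(
                np.isnan(corr[ci, partners])) else np.nan
            if np.isnan(r) or r <= cutoff:
                continue
            out.append(
                {
                    "chrom": peaks.iloc[ci]["chrom"],
                    "start": peaks.iloc[ci]["start"],
                    "end": peaks.iloc[ci]["end"],
                    "peak_id": peaks.iloc[ci]["name"],
                    "gene_id": pr["gene"],
                    "score": float(r),
                    "method": "coaccessibility",
                    "distance": int(dist[ci]),
                }
            )
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "peak_id", "gene_id",
                      "score", "method", "distance"]
    )


def peak2gene_links(
    metacell_atac: MetacellMatrix,
    metacell_rna: MetacellMatrix,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Peaks whose accessibility correlates with a nearby gene's expression.

    Both metacell matrices must come from the same barcode-matched cell
    partition. Pairs whose correlation is undefined (a constant vector)
    are omitted with a warning.
    """
    a, b = metacell_atac.assignments, metacell_rna.assignments
    if len(a) != len(b) or not (a[["cell", "metacell"]].to_numpy()
                                == b[["cell", "metacell"]].to_numpy()).all():
        raise ValueError("ATAC and RNA metacells must share one cell partition")
    tss = gene_tss(genes).to_numpy()
    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    am = metacell_atac.values
    rm = metacell_rna.values
    az = am - am.mean(axis=0)
    rz = rm - rm.mean(axis=0)
    asd = az.std(axis=0)
    rsd = rz.std(axis=0)
    n_undefined = 0
    out = []
    for gj in range(len(genes)):
        on_chrom = peaks["chrom"].to_numpy() == genes.iloc[gj]["chrom"]
        dist = np.abs(mid - tss[gj])
        candidates = np.flatnonzero(on_chrom & (dist <= max_dist))
        if len(candidates) == 0:
            continue
        if rsd[gj] == 0:
            n_undefined += len(candidates)
            continue
        for ci in candidates:
            if asd[ci] == 0:
                n_undefined += 1
                continue
            r = float((az[:, ci] @ rz[:, gj]) / (am.shape[0] * asd[ci] * rsd[gj]))
            if r > cutoff:
                out.append(
                    {
                        "chrom": peaks.iloc[ci]["chrom"],
                        "start": peaks.iloc[ci]["start"],
                        "end": peaks.iloc[ci]["end"],
                        "peak_id": peaks.iloc[ci]["name"],
                        "gene_id": genes.iloc[gj]["name"],
                        "score": r,
                        "method": "correlation",
                        "distance": int(dist[ci]),
                    }
                )
    if n_undefined:
        warnings.warn(f"{n_undefined} peak-gene pairs with undefined correlation omitted")
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "peak_id", "gene_id",
                      "score", "method", "distance"]
    )


def marker_enrichment_of_targets(
    target_genes,
    marker_sets: dict,
    control_tissues,
    n_sample: int = 457,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of sampled tissue markers among link target genes.

    For each tissue a random sample of ``n_sample`` marker genes is
    intersected with the target set; the normalized column divides each
    fraction by the mean fraction over the control tissues (missing when
    that mean is zero).
    """
    targets = set(target_genes)
    rng = np.random.default_rng(seed)
    rows = []
    for tissue, markers in marker_sets.items():
        markers = list(markers)
        if len(markers) >= n_sample:
            sampled = rng.choice(markers, size=n_sample, replace=False)
        else:
            warnings.warn(
                f"tissue {tissue!r} has {len(markers)} < {n_sample} markers; using all"
            )
            sampled = np.asarray(markers)
        frac = len(set(sampled) & targets) / len(sampled)
        rows.append({"tissue": tissue, "fraction": frac})
    df = pd.DataFrame(rows)
    ctrl = df[df["tissue"].isin(control_tissues)]["fraction"]
    ctrl_mean = ctrl.mean() if len(ctrl) else np.nan
    if not ctrl_mean or np.isnan(ctrl_mean):
        warnings.warn("control mean fraction is 0 or undefined; normalized missing")
        df["normalized"] = np.nan
    else:
        df["normalized"] = df["fraction"] / ctrl_mean
    return df
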