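"""Synthetic multi-omic data with planted, recoverable ground truth.

Every downstream stage of the pipeline (enhancer linking, ABC scoring,
allele-specific STARR-seq statistics, variant prioritization) is
exercised on data generated here, so each generator plants effects whose
identity is recorded in a truth table:

* ``simulate_multiome`` -- cell-by-peak and cell-by-gene counts with
  planted cell types, marker features, and peak-gene pairs sharing a
  latent factor that sets their target correlation;
* ``simulate_starr_counts`` -- barcode-count tables per SNP x allele x
  condition x replicate with planted enhancer and allelic log2 fold
  changes under a negative-binomial (gamma-Poisson) count model;
* ``simulate_abc_inputs`` -- element activity tracks and a symmetric
  5-kb binned contact matrix with power-law distance decay;
* ``simulate_variant_sets`` -- a GWAS-style variant universe (index
  variants, LD table, credible set, coding classes, pathogenicity
  scores) together with the evidence-channel inputs consumed by the
  prioritization stage (peak sets, link tables, loops, eQTLs, predicted
  allelic accessibility counts), with a configurable number of variants
  planted to satisfy >=3 evidence criteria.

All randomness flows from one seed in ``SimConfig``; each generator
derives its own child stream by a fixed offset so adding one generator
never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import gene_tss

# fixed per-stream seed offsets (see module docstring)
_OFFSET_MULTIOME = 11
_OFFSET_STARR = 23
_OFFSET_ABC = 37
_OFFSET_VARIANTS = 51

CONDITIONS = ("input", "naive", "complement")
OUTPUT_CONDITIONS = ("naive", "complement")

#: the eight evidence criteria of the integration rule
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

#: criteria whose synthetic support records are noise-free tables
DETERMINISTIC_CRITERIA = (
    "coaccessible_promoter",
    "expression_correlated",
    "hichip_linked",
    "abc_connected",
    "significant_eqtl",
    "high_effect",
)


@dataclass(frozen=True)
class MultiomeConfig:
    n_cells: int = 600
    n_cell_types: int = 3
    n_peaks: int = 300
    n_genes: int = 120
    n_marker_peaks: int = 20      # per cell type
    n_marker_genes: int = 15      # per cell type
    marker_fold: float = 4.0
    n_planted_links: int = 50
    link_strength: float = 0.8    # target correlation of planted pairs
    peak_rate: float = 2.0        # baseline mean counts per cell
    gene_rate: float = 5.0
    linked_peak_rate: float = 20.0
    linked_gene_rate: float = 40.0
    latent_sd: float = 1.0        # log-scale sd of the shared factor
    nb_dispersion: float = 0.3
    count_noise: bool = True      # False emits expected rates directly


@dataclass(frozen=True)
class StarrConfig:
    n_snps: int = 1000
    n_control_snps: int = 400
    n_replicates: int = 4
    depth: float = 1000.0         # mean unique barcodes per oligo
    nb_dispersion: float = 0.02
    n_enhancers: int = 0
    enhancer_log2fc: float = 2.0
    n_allelic: int = 0
    allelic_log2fc: float = 1.0
    allelic_in_enhancers: bool = True
    must_detect: bool = True      # planted enhancers must exceed the call bound


@dataclass(frozen=True)
class AbcConfig:
    n_elements: int = 60
    n_genes: int = 3
    contact_decay: float = 1.0
    contact_noise: float = 0.0    # log-sd of multiplicative contact noise
    bin_size: int = 5000
    planted_activity: float = 50.0
    background_activity: float = 0.5


@dataclass(frozen=True)
class PredConfig:
    n_folds: int = 5
    n_cell_types: int = 3
    planted_log2fc: float = 1.0
    noise_sd: float = 0.0         # log2-scale per-fold noise on alt counts
    ref_count: float = 100.0


@dataclass(frozen=True)
class VariantConfig:
    n_loci: int = 6
    n_ld_per_index: int = 8       # R^2 > 0.5, enters the risk set
    n_ld_low_per_index: int = 2   # R^2 <= 0.5, excluded by the filter
    n_credible: int = 20
    n_protein_altering: int = 4
    n_synonymous: int = 2
    n_prioritized: int = 8        # planted with >=3 evidence channels
    n_partial: int = 10           # planted with 1-2 channels
    n_inaccessible: int = 10      # placed outside every peak
    n_cell_types: int = 3
    channel_pool: tuple = CRITERIA


@dataclass(frozen=True)
class SimConfig:
    """Top-level configuration; one seed drives every generator stream."""

    seed: int = 0
    genome: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000))
    multiome: MultiomeConfig = field(default_factory=MultiomeConfig)
    starr: StarrConfig = field(default_factory=StarrConfig)
    abc: AbcConfig = field(default_factory=AbcConfig)
    pred: PredConfig = field(default_factory=PredConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial via gamma-Poisson mixture; dispersion -> 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be positive")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# multiome


@dataclass
class MultiomeData:
    atac: np.ndarray              # cells x peaks
    rna: np.ndarray               # cells x genes
    labels: np.ndarray            # cell-type label per cell
    cell_ids: list
    peaks: pd.DataFrame           # BED6-style, name = peak id
    genes: pd.DataFrame           # BED6-style + tss column
    truth: dict


def simulate_multiome(config: SimConfig) -> MultiomeData:
    mc = config.multiome
    if mc.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if mc.n_cells < 10 * mc.n_cell_types:
        raise ValueError("need at least 10 cells per cell type")
    if min(mc.n_cells, mc.n_peaks, mc.n_genes) <= 0:
        raise ValueError("dimensions must be positive")
    if not 0.0 <= mc.link_strength <= 1.0:
        raise ValueError("link effect strength must lie in [0, 1]")
    need_peaks = 2 * mc.n_planted_links + mc.n_cell_types * mc.n_marker_peaks
    need_genes = mc.n_planted_links + mc.n_cell_types * mc.n_marker_genes
    if mc.n_peaks < need_peaks or mc.n_genes < need_genes:
        raise ValueError(
            "not enough peaks/genes for the planted links (each link needs a "
            "distal and a promoter peak) plus marker features"
        )

    rng = np.random.default_rng(config.seed + _OFFSET_MULTIOME)
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    probs = lengths / lengths.sum()

    # genes: TSS uniform (inside a margin), random strand, 1-kb body
    gi = rng.choice(len(chroms), size=mc.n_genes, p=probs)
    tss = np.array(
        [rng.integers(300_000, int(lengths[i]) - 300_000) for i in gi]
    )
    strand = rng.choice(["+", "-"], size=mc.n_genes)
    start = np.where(strand == "+", tss, tss - 999)
    genes = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in gi],
            "start": start,
            "end": start + 1000,
            "name": [f"gene{i:04d}" for i in range(mc.n_genes)],
            "score": 0,
            "strand": strand,
            "tss": tss,
        }
    )

    # peaks: each linked gene gets a distal peak (indices 0..L-1) plus a
    # promoter peak (indices L..2L-1); remaining peaks are uniform
    peak_chrom, peak_start = [], []
    link_genes = list(range(mc.n_planted_links))
    for g in link_genes:
        d = int(rng.integers(5_000, 100_000)) * int(rng.choice([-1, 1]))
        peak_chrom.append(genes.loc[g, "chrom"])
        peak_start.append(int(np.clip(genes.loc[g, "tss"] + d - 250, 0,
                                      lengths[gi[g]] - 500)))
    for g in link_genes:  # inside the -2000/+100 promoter window
        peak_chrom.append(genes.loc[g, "chrom"])
        peak_start.append(int(genes.loc[g, "tss"]) - 200)
    for _ in range(mc.n_peaks - 2 * mc.n_planted_links):
        i = rng.choice(len(chroms), p=probs)
        peak_chrom.append(chroms[i])
        peak_start.append(int(rng.integers(0, int(lengths[i]) - 500)))
    peaks = pd.DataFrame(
        {
            "chrom": peak_chrom,
            "start": peak_start,
            "end": np.asarray(peak_start) + 500,
            "name": [f"peak{i:04d}" for i in range(mc.n_peaks)],
            "score": 0,
            "strand": ".",
        }
    )

    # cell types and marker features (markers drawn from non-linked features)
    labels = np.array([f"type{i % mc.n_cell_types}" for i in range(mc.n_cells)])
    free_peaks = np.arange(2 * mc.n_planted_links, mc.n_peaks)
    free_genes = np.arange(mc.n_planted_links, mc.n_genes)
    marker_peaks, marker_genes = {}, {}
    pk_pool = rng.permutation(free_peaks)
    gn_pool = rng.permutation(free_genes)
    for t in range(mc.n_cell_types):
        tname = f"type{t}"
        marker_peaks[tname] = pk_pool[t * mc.n_marker_peaks:(t + 1) * mc.n_marker_peaks]
        marker_genes[tname] = gn_pool[t * mc.n_marker_genes:(t + 1) * mc.n_marker_genes]

    # base rates
    peak_base = np.full(mc.n_peaks, mc.peak_rate)
    gene_base = np.full(mc.n_genes, mc.gene_rate)
    peak_base[: 2 * mc.n_planted_links] = mc.linked_peak_rate
    gene_base[:mc.n_planted_links] = mc.linked_gene_rate

    type_mult_peak = np.ones((mc.n_cell_types, mc.n_peaks))
    type_mult_gene = np.ones((mc.n_cell_types, mc.n_genes))
    for t in range(mc.n_cell_types):
        type_mult_peak[t, marker_peaks[f"type{t}"]] = mc.marker_fold
        type_mult_gene[t, marker_genes[f"type{t}"]] = mc.marker_fold
    tcode = np.array([int(l[4:]) for l in labels])

    atac_rate = peak_base[None, :] * type_mult_peak[tcode]
    rna_rate = gene_base[None, :] * type_mult_gene[tcode]

    # planted links: shared latent factor; peak carries it fully, the gene
    # mixes it with independent noise so the log-rate correlation is rho
    rho = mc.link_strength
    sig = mc.latent_sd
    mix = np.sqrt(max(0.0, 1 - rho ** 2))
    z = rng.standard_normal((mc.n_cells, mc.n_planted_links))
    e_gene = rng.standard_normal((mc.n_cells, mc.n_planted_links))
    e_prom = rng.standard_normal((mc.n_cells, mc.n_planted_links))
    peak_mult = np.exp(sig * z)
    gene_mult = np.exp(sig * (rho * z + mix * e_gene))
    prom_mult = np.exp(sig * (rho * z + mix * e_prom))
    atac_rate[:, :mc.n_planted_links] *= peak_mult
    atac_rate[:, mc.n_planted_links: 2 * mc.n_planted_links] *= prom_mult
    rna_rate[:, :mc.n_planted_links] *= gene_mult

    if mc.count_noise:
        atac = _nb_sample(rng, atac_rate, mc.nb_dispersion).astype(float)
        rna = _nb_sample(rng, rna_rate, mc.nb_dispersion).astype(float)
    else:
        atac, rna = atac_rate, rna_rate

    truth = {
        "marker_peaks": {t: peaks["name"].to_numpy()[idx].tolist()
                         for t, idx in marker_peaks.items()},
        "marker_genes": {t: genes["name"].to_numpy()[idx].tolist()
                         for t, idx in marker_genes.items()},
        "links": [
            {
                "peak": f"peak{i:04d}",
                "promoter_peak": f"peak{mc.n_planted_links + i:04d}",
                "gene": f"gene{i:04d}",
                "strength": rho,
            }
            for i in range(mc.n_planted_links)
        ],
        "cell_types": sorted(set(labels)),
    }
    cell_ids = [f"cell{i:05d}" for i in range(mc.n_cells)]
    return MultiomeData(atac, rna, labels, cell_ids, peaks, genes, truth)


# ---------------------------------------------------------------------------
# STARR-seq counts


@dataclass
class StarrData:
    counts: pd.DataFrame          # snp_id, allele, condition, replicate, unique_barcodes
    snp_meta: pd.DataFrame        # snp_id, is_control
    truth: dict


def simulate_starr_counts(
    config: SimConfig,
    snp_ids=None,
    planted_enhancers=None,
    planted_allelic=None,
) -> StarrData:
    sc = config.starr
    if sc.n_snps < 1:
        raise ValueError("need at least one SNP")
    if sc.n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    if sc.nb_dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(config.seed + _OFFSET_STARR)
    if snp_ids is None:
        snp_ids = [f"snp{i:05d}" for i in range(sc.n_snps)]
    elif len(snp_ids) != sc.n_snps:
        raise ValueError("snp_ids length must equal n_snps")
    ctrl_ids = [f"ctrl{i:05d}" for i in range(sc.n_control_snps)]
    all_ids = list(snp_ids) + ctrl_ids

    if planted_enhancers is None:
        enhancers = list(snp_ids[: sc.n_enhancers])
    else:
        enhancers = list(planted_enhancers)
    if planted_allelic is None:
        if sc.allelic_in_enhancers:
            allelic = list(snp_ids[: sc.n_allelic])
        else:
            allelic = list(snp_ids[sc.n_enhancers: sc.n_enhancers + sc.n_allelic])
    else:
        allelic = list(planted_allelic)
    unknown = (set(enhancers) | set(allelic)) - set(snp_ids)
    if unknown:
        raise ValueError(f"planted ids not in the SNP universe: {sorted(unknown)}")
    enh_set, alle_set = set(enhancers), set(allelic)
    if sc.must_detect and enhancers and abs(sc.enhancer_log2fc) <= 0.585:
        raise ValueError(
            "planted enhancer |log2FC| <= 0.585 cannot be detected by the "
            "enhancer call (|log2FC| > 0.585); raise the effect or set "
            "must_detect=False"
        )

    enh_lfc = np.array([sc.enhancer_log2fc if s in enh_set else 0.0 for s in all_ids])
    alle_lfc = np.array([sc.allelic_log2fc if s in alle_set else 0.0 for s in all_ids])

    n = len(all_ids)
    frames = []
    for cond in CONDITIONS:
        for rep in range(1, sc.n_replicates + 1):
            for ai, allele in enumerate(("ref", "alt")):
                mean = np.full(n, sc.depth)
                if cond != "input":
                    mean = mean * 2.0 ** enh_lfc
                    if allele == "alt":
                        mean = mean * 2.0 ** alle_lfc
                counts = _nb_sample(rng, mean, sc.nb_dispersion)
                frames.append(
                    pd.DataFrame(
                        {
                            "snp_id": all_ids,
                            "allele": allele,
                            "condition": cond,
                            "replicate": rep,
                            "unique_barcodes": counts,
                        }
                    )
                )
    counts = pd.concat(frames, ignore_index=True)
    snp_meta = pd.DataFrame(
        {"snp_id": all_ids, "is_control": [s in set(ctrl_ids) for s in all_ids]}
    )
    truth = {
        "enhancers": enhancers,
        "allelic_snps": allelic,
        "controls": ctrl_ids,
        "enhancer_log2fc": sc.enhancer_log2fc,
        "allelic_log2fc": sc.allelic_log2fc,
    }
    return StarrData(counts, snp_meta, truth)


# ---------------------------------------------------------------------------
# ABC inputs


@dataclass
class AbcData:
    elements: pd.DataFrame        # chrom, start, end, name, atac, h3k27ac
    contacts: dict                # chrom -> symmetric bins x bins matrix
    bin_size: int
    genes: pd.DataFrame           # chrom, tss, name
    truth: dict


def simulate_abc_inputs(config: SimConfig) -> AbcData:
    ac = config.abc
    if ac.contact_decay <= 0:
        raise ValueError("contact decay exponent must be > 0")
    rng = np.random.default_rng(config.seed + _OFFSET_ABC)
    chroms = dict(config.genome)

    contacts = {}
    for chrom, length in config.genome:
        n_bins = length // ac.bin_size
        idx = np.arange(n_bins)
        decay = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-ac.contact_decay)
        if ac.contact_noise > 0:
            noise = np.exp(ac.contact_noise * rng.standard_normal(decay.shape))
            noise = np.sqrt(noise * noise.T)  # keep the matrix symmetric
            decay = decay * noise
        contacts[chrom] = decay

    # genes spread over the genome
    chrom_names = list(chroms)
    gene_rows = []
    for g in range(ac.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        n_bins = chroms[chrom] // ac.bin_size
        tss_bin = int(rng.integers(100, n_bins - 100))
        gene_rows.append((chrom, tss_bin * ac.bin_size + ac.bin_size // 2,
                          f"abcgene{g:03d}"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "name"])

    # one planted high-activity element a few bins from each TSS, plus
    # uniform low-activity background elements
    rows, planted = [], []
    eid = 0
    for g, grow in genes.iterrows():
        offset = int(rng.integers(3, 11)) * ac.bin_size
        start = grow["tss"] + offset - 250
        name = f"elem{eid:04d}"
        act = ac.planted_activity
        u = float(np.exp(0.2 * rng.standard_normal()))
        rows.append((grow["chrom"], start, start + 500, name, act * u, act / u))
        planted.append({"element": name, "gene": grow["name"]})
        eid += 1
    n_background = ac.n_elements - len(rows)
    for _ in range(n_background):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(500_000, chroms[chrom] - 500_000))
        act = rng.gamma(2.0, ac.background_activity / 2.0)
        u = float(np.exp(0.2 * rng.standard_normal()))
        rows.append((chrom, start, start + 500, f"elem{eid:04d}", act * u, act / u))
        eid += 1
    elements = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "atac", "h3k27ac"]
    )
    bad = (elements["start"] < 0) | (
        elements["end"] > elements["chrom"].map(chroms)
    )
    if bad.any():
        raise ValueError(
            f"elements outside genome bounds: {elements.loc[bad, 'name'].tolist()}"
        )
    truth = {"connections": planted}
    return AbcData(elements, contacts, ac.bin_size, genes, truth)


# ---------------------------------------------------------------------------
# variant sets and evidence-channel inputs


@dataclass
class VariantData:
    index_variants: pd.DataFrame
    ld_table: pd.DataFrame        # index_id, variant row info, r2
    credible_set: pd.DataFrame
    variants: pd.DataFrame        # the assembled risk-set input universe
    peaks_by_celltype: dict       # cell type -> BED-style frame
    control_peaks: dict           # control tissue -> BED-style frame
    links: pd.DataFrame           # peak/gene link table with a method column
    loops: pd.DataFrame           # BEDPE-style anchors
    genes: pd.DataFrame           # gene annotation for promoter overlap
    eqtls: pd.DataFrame           # variant_id, gene, tissue, fdr
    predictions: pd.DataFrame     # variant_id, cell_type, fold, ref/alt counts
    starr_calls: pd.DataFrame     # snp_id, condition, is_enhancer, functional
    truth: dict


def _random_alleles(rng, n):
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def simulate_variant_sets(config: SimConfig) -> VariantData:
    vc = config.variants
    pc = config.pred
    if vc.n_loci < 1:
        raise ValueError("need at least one locus")
    bad = set(vc.channel_pool) - set(CRITERIA)
    if bad:
        raise ValueError(f"unknown evidence channels: {sorted(bad)}")
    rng = np.random.default_rng(config.seed + _OFFSET_VARIANTS)
    chroms = dict(config.genome)
    chrom_names = list(chroms)

    # loci spread over the genome; variants cluster around their index
    locus_chrom = [chrom_names[i % len(chrom_names)] for i in range(vc.n_loci)]
    locus_pos = [
        int((i // len(chrom_names) + 1) * chroms[locus_chrom[i]]
            / (vc.n_loci / len(chrom_names) + 1))
        for i in range(vc.n_loci)
    ]

    rows = []
    vid = 0

    def new_variant(locus, offset, **kw):
        nonlocal vid
        pos = locus_pos[locus] + offset
        ref, alt = _random_alleles(rng, 1)
        row = {
            "id": f"var{vid:04d}",
            "chrom": locus_chrom[locus],
            "pos": int(pos),
            "ref": ref[0],
            "alt": alt[0],
            "coding_class": "noncoding",
            "locus": locus,
            "is_index": False,
            "credible_set": False,
            "r2": np.nan,
            "am_score": np.nan,
        }
        row.update(kw)
        rows.append(row)
        vid += 1
        return row

    ld_rows = []

    def ld_row(index_id, v):
        return {"index_id": index_id, "variant_id": v["id"], "r2": v["r2"],
                "chrom": v["chrom"], "pos": v["pos"],
                "ref": v["ref"], "alt": v["alt"]}

    for locus in range(vc.n_loci):
        idx = new_variant(locus, 0, is_index=True, r2=1.0)
        ld_rows.append(ld_row(idx["id"], idx))
        for j in range(vc.n_ld_per_index):
            v = new_variant(locus, (j + 1) * 1500,
                            r2=float(rng.uniform(0.55, 0.99)))
            ld_rows.append(ld_row(idx["id"], v))
        for j in range(vc.n_ld_low_per_index):
            v = new_variant(locus, -(j + 1) * 1500,
                            r2=float(rng.uniform(0.05, 0.5)))
            ld_rows.append(ld_row(idx["id"], v))
    # credible-set-only variants (no LD row above 0.5)
    for j in range(vc.n_credible):
        locus = j % vc.n_loci
        new_variant(locus, 200_000 + j * 700, credible_set=True)
    variants = pd.DataFrame(rows)
    if variants["id"].duplicated().any():
        raise ValueError("duplicate variant IDs generated")

    # overlap between the LD expansion and the credible set (dedup exercised)
    in_ld = variants["r2"] > 0.5
    overlap = variants.index[in_ld][: max(2, vc.n_loci)]
    variants.loc[overlap, "credible_set"] = True

    # coding classes and pathogenicity scores on a few risk variants
    risk_idx = variants.index[(variants["r2"] > 0.5) | variants["credible_set"]]
    nonidx = [i for i in risk_idx if not variants.loc[i, "is_index"]]
    pa = nonidx[: vc.n_protein_altering]
    sy = nonidx[vc.n_protein_altering: vc.n_protein_altering + vc.n_synonymous]
    variants.loc[pa, "coding_class"] = "protein-altering"
    variants.loc[sy, "coding_class"] = "synonymous"
    variants.loc[pa, "am_score"] = rng.uniform(0.02, 0.98, size=len(pa))

    # genes (for promoters and link targets): one per locus, strand-aware
    gene_rows = []
    for locus in range(vc.n_loci):
        strand = "+" if locus % 2 == 0 else "-"
        tss = locus_pos[locus] + 60_000
        start = tss if strand == "+" else tss - 9_999
        gene_rows.append(
            {"chrom": locus_chrom[locus], "start": start, "end": start + 10_000,
             "name": f"lgene{locus:03d}", "score": 0, "strand": strand, "tss": tss}
        )
    genes = pd.DataFrame(gene_rows)

    # choose channelled variants among noncoding/synonymous risk variants
    elig = [i for i in risk_idx
            if variants.loc[i, "coding_class"] != "protein-altering"]
    n_chan = vc.n_prioritized + vc.n_partial
    if len(elig) < n_chan + vc.n_inaccessible:
        raise ValueError("not enough risk variants to plant evidence channels")
    chan_idx = elig[:n_chan]
    inacc_idx = elig[n_chan: n_chan + vc.n_inaccessible]

    # a functional SNP is by definition inside an enhancer, so planting
    # 'functional_snp' implies the 'in_starr_enhancer' criterion as well
    pool = list(vc.channel_pool)
    channels = {}
    for k, i in enumerate(chan_idx):
        if k < vc.n_prioritized:
            n_ch = min(3 + (k % (max(1, len(pool) - 2))), len(pool))
            sub_pool = pool
        else:
            n_ch = 1 + (k % 2)
            # keep partial variants at <=2 effective criteria
            sub_pool = [c for c in pool if c != "functional_snp"] \
                if n_ch == 2 else pool
        chosen = {str(c) for c in rng.choice(sub_pool, size=n_ch, replace=False)}
        if "functional_snp" in chosen:
            chosen.add("in_starr_enhancer")
        channels[variants.loc[i, "id"]] = sorted(chosen)

    # peaks: one hosting peak per accessible channelled variant, assigned to
    # a cell type round-robin, plus random background peaks per cell type
    cell_types = [f"ct{t}" for t in range(vc.n_cell_types)]
    peaks_by_celltype = {t: [] for t in cell_types}
    hosting_peak = {}
    for k, i in enumerate(chan_idx):
        v = variants.loc[i]
        pstart = v["pos"] - 250
        pname = f"vpeak{k:04d}"
        ct = cell_types[k % len(cell_types)]
        peaks_by_celltype[ct].append(
            {"chrom": v["chrom"], "start": pstart, "end": pstart + 500,
             "name": pname, "score": 0, "strand": "."}
        )
        hosting_peak[v["id"]] = pname
    for t, ct in enumerate(cell_types):
        for b in range(20):
            chrom = chrom_names[b % len(chrom_names)]
            start = int(rng.integers(100_000, chroms[chrom] - 100_000))
            peaks_by_celltype[ct].append(
                {"chrom": chrom, "start": start, "end": start + 500,
                 "name": f"bg_{ct}_{b:03d}", "score": 0, "strand": "."}
            )
    peaks_by_celltype = {t: pd.DataFrame(v) for t, v in peaks_by_celltype.items()}

    control_peaks = {}
    for cname in ("ctrl_tissue_a", "ctrl_tissue_b"):
        crows = []
        for b in range(40):
            chrom = chrom_names[b % len(chrom_names)]
            start = int(rng.integers(100_000, chroms[chrom] - 100_000))
            crows.append({"chrom": chrom, "start": start, "end": start + 500,
                          "name": f"{cname}_{b:03d}", "score": 0, "strand": "."})
        control_peaks[cname] = pd.DataFrame(crows)

    # evidence-channel support records
    link_rows, loop_rows, eqtl_rows, starr_rows = [], [], [], []
    pred_rows = []
    high_effect_truth = []
    method_of = {
        "coaccessible_promoter": "coaccessibility",
        "expression_correlated": "correlation",
        "abc_connected": "abc",
    }
    for i in chan_idx:
        v = variants.loc[i]
        vid_ = v["id"]
        locus = v["locus"]
        gene = genes.loc[locus]
        chan = channels[vid_]
        for ch in chan:
            if ch in method_of:
                link_rows.append(
                    {"chrom": v["chrom"], "start": v["pos"] - 250,
                     "end": v["pos"] + 250, "peak_id": hosting_peak[vid_],
                     "gene_id": gene["name"], "score": 0.9,
                     "method": method_of[ch],
                     "distance": abs(int(v["pos"]) - int(gene["tss"]))}
                )
            elif ch == "hichip_linked":
                # variant-side anchor narrower than the inter-variant
                # spacing so no neighboring variant is swept in
                loop_rows.append(
                    {"chrom1": v["chrom"], "start1": v["pos"] - 500,
                     "end1": v["pos"] + 500, "chrom2": gene["chrom"],
                     "start2": gene["tss"] - 2500, "end2": gene["tss"] + 2500,
                     "name": f"loop_{vid_}"}
                )
            elif ch == "significant_eqtl":
                eqtl_rows.append({"variant_id": vid_, "gene": gene["name"],
                                  "tissue": "macular", "fdr": 0.01})
        for cond in OUTPUT_CONDITIONS:
            starr_rows.append(
                {"snp_id": vid_, "condition": cond,
                 "is_enhancer": "in_starr_enhancer" in chan
                                or "functional_snp" in chan,
                 "functional": "functional_snp" in chan}
            )
        is_high = "high_effect" in chan
        if is_high:
            high_effect_truth.append(vid_)
        for ct_i in range(pc.n_cell_types):
            lfc = pc.planted_log2fc if (is_high and ct_i == 0) else 0.0
            for fold in range(pc.n_folds):
                ref = pc.ref_count * float(np.exp(0.2 * rng.standard_normal()))
                noise = (pc.noise_sd * rng.standard_normal()
                         if pc.noise_sd > 0 else 0.0)
                pred_rows.append(
                    {"variant_id": vid_, "cell_type": f"ct{ct_i}", "fold": fold,
                     "ref_count": ref, "alt_count": ref * 2.0 ** (lfc + noise)}
                )

    # background eQTL rows (non-significant) and a decoy loop whose partner
    # anchor overlaps no promoter
    for i in list(chan_idx)[:5]:
        eqtl_rows.append({"variant_id": variants.loc[i, "id"],
                          "gene": "lgene000", "tissue": "non-macular",
                          "fdr": float(rng.uniform(0.06, 0.9))})
    loop_rows.append(
        {"chrom1": chrom_names[0], "start1": 9_000_000, "end1": 9_005_000,
         "chrom2": chrom_names[0], "start2": 9_500_000, "end2": 9_505_000,
         "name": "loop_decoy"}
    )

    truth = {
        "channels": channels,
        "hosting_peak": hosting_peak,
        "high_effect": high_effect_truth,
        "inaccessible": variants.loc[inacc_idx, "id"].tolist(),
        "n_risk_expected": int(((variants["r2"] > 0.5)
                                | variants["credible_set"]).sum()),
    }
    return VariantData(
        index_variants=variants[variants["is_index"]].copy(),
        ld_table=pd.DataFrame(ld_rows),
        credible_set=variants[variants["credible_set"]].copy(),
        variants=variants,
        peaks_by_celltype=peaks_by_celltype,
        control_peaks=control_peaks,
        links=pd.DataFrame(link_rows),
        loops=pd.DataFrame(loop_rows),
        genes=genes,
        eqtls=pd.DataFrame(eqtl_rows),
        predictions=pd.DataFrame(pred_rows),
        starr_calls=pd.DataFrame(starr_rows),
        truth=truth,
    )


@dataclass
class Dataset:
    """All synthetic inputs of one study, generated from a single seed."""

    config: SimConfig
    multiome: MultiomeData
    starr: StarrData
    abc: AbcData
    variant_sets: VariantData


def simulate_all(config: SimConfig) -> Dataset:
    variant_sets = simulate_variant_sets(config)
    # STARR SNP universe reuses the channelled variant ids so the pipeline
    # can join assay calls onto the variant table
    chan_ids = list(variant_sets.truth["channels"])
    other = [v for v in variant_sets.variants["id"] if v not in set(chan_ids)]
    snp_ids = (chan_ids + other)[: config.starr.n_snps]
    if len(snp_ids) < config.starr.n_snps:
        snp_ids += [f"snp{i:05d}" for i in range(config.starr.n_snps - len(snp_ids))]
    chan = variant_sets.truth["channels"]
    planted_enh = [v for v, ch in chan.items()
                   if ("in_starr_enhancer" in ch or "functional_snp" in ch)
                   and v in set(snp_ids)]
    planted_alle = [v for v, ch in chan.items()
                    if "functional_snp" in ch and v in set(snp_ids)]
    starr = simulate_starr_counts(
        config, snp_ids=snp_ids,
        planted_enhancers=planted_enh, planted_allelic=planted_alle,
    )
    return Dataset(
        config=config,
        multiome=simulate_multiome(config),
        starr=starr,
        abc=simulate_abc_inputs(config),
        variant_sets=variant_sets,
    )


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    parts = {}
    for key, cls in (
        ("multiome", MultiomeConfig), ("starr", StarrConfig),
        ("abc", AbcConfig), ("pred", PredConfig), ("variants", VariantConfig),
    ):
        sub = dict(d.pop(key, {}) or {})
        if "channel_pool" in sub:
            sub["channel_pool"] = tuple(sub["channel_pool"])
        parts[key] = cls(**sub)
    genome = tuple((c, int(l)) for c, l in d.pop("genome",
                                                SimConfig().genome))
    return SimConfig(seed=int(d.pop("seed", 0)), genome=genome, **parts)
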