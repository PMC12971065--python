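"""Pseudo-bulk, feature tests, metacells and enhancer-gene linking."""

import warnings

import numpy as np
import pandas as pd
import pytest

from crevar import links as lk
from crevar.pipeline import _metacell_means


def _mc(values, k=2):
    """MetacellMatrix directly from a small values array (one per row)."""
    n = values.shape[0]
    assign = pd.DataFrame({"cell": range(n * k), "cell_type": "t",
                           "metacell": np.repeat(range(n), k)})
    return lk.MetacellMatrix(values=values, assignments=assign, k=k)


# ---------------------------------------------------------------------------
# pseudobulk


def test_pseudobulk_sums_counts_within_each_type():
    counts = np.array([[1.0, 0.0], [2.0, 1.0], [5.0, 7.0]])
    pb = lk.make_pseudobulk(counts, ["a", "a", "b"], feature_ids=["p1", "p2"])
    assert pb.raw.loc["a", "p1"] == 3
    assert pb.raw.loc["b", "p2"] == 7
    assert pb.raw.to_numpy().sum() == counts.sum()  # conservation


def test_pseudobulk_empty_group_is_zero_row_with_warning():
    with pytest.warns(UserWarning, match="no cells"):
        pb = lk.make_pseudobulk(np.ones((2, 3)), ["a", "a"], groups=["a", "b"])
    assert (pb.raw.loc["b"] == 0).all()


def test_pseudobulk_unknown_label_raises_naming_cells():
    with pytest.raises(ValueError, match=r"\[1\]"):
        lk.make_pseudobulk(np.ones((2, 3)), ["a", "zzz"], groups=["a"])


# ---------------------------------------------------------------------------
# feature tests


def test_marker_modes_recover_planted_markers_exactly(multiome):
    res = lk.test_features(multiome.atac, multiome.labels, "peaks_marker",
                           feature_ids=list(multiome.peaks["name"]))
    for ctype, names in multiome.truth["marker_peaks"].items():
        hits = set(res[(res["group"] == ctype) & res["passed"]]["feature"])
        assert hits == set(names)
    res_g = lk.test_features(multiome.rna, multiome.labels, "genes_marker",
                             feature_ids=list(multiome.genes["name"]))
    for ctype, names in multiome.truth["marker_genes"].items():
        hits = set(res_g[(res_g["group"] == ctype) & res_g["passed"]]["feature"])
        assert hits == set(names)


def test_identical_distributions_give_zero_lfc_and_no_pass(rng):
    base = rng.poisson(5.0, size=(30, 10)).astype(float)
    counts = np.vstack([base, base])
    labels = ["a"] * 30 + ["b"] * 30
    res = lk.test_features(counts, labels, "peaks_differential")
    assert res["log2fc"].to_numpy() == pytest.approx(0.0, abs=1e-9)
    assert not res["passed"].any()


def test_feature_results_adjusted_p_never_below_raw(multiome):
    res = lk.test_features(multiome.atac[:, :50], multiome.labels, "peaks_marker")
    assert (res["fdr"] >= res["pvalue"] - 1e-15).all()


def test_small_group_yields_p_one_with_warning(rng):
    counts = rng.poisson(5.0, size=(8, 4)).astype(float)
    labels = ["a", "a", "b", "b", "b", "b", "b", "b"]
    with pytest.warns(UserWarning, match="<3 cells"):
        res = lk.test_features(counts, labels, "peaks_differential")
    assert (res.loc[res["group"] == "a", "pvalue"] == 1.0).all()


def test_pairwise_mode_requires_two_groups(rng):
    counts = rng.poisson(5.0, size=(9, 4)).astype(float)
    with pytest.raises(ValueError, match="exactly 2"):
        lk.test_features(counts, ["a", "b", "c"] * 3, "genes_pairwise")


def test_scale_invariance_of_lfc_under_library_scaling(rng):
    counts = rng.poisson(10.0, size=(40, 6)).astype(float)
    labels = ["a"] * 20 + ["b"] * 20
    res1 = lk.test_features(counts, labels, "peaks_marker")
    res2 = lk.test_features(counts * 7.0, labels, "peaks_marker")
    np.testing.assert_allclose(res1["log2fc"], res2["log2fc"], atol=1e-9)
    np.testing.assert_allclose(res1["pvalue"], res2["pvalue"], atol=1e-12)


# ---------------------------------------------------------------------------
# metacells


def test_metacells_partition_four_cells_into_two_blocks():
    values = np.arange(8, dtype=float).reshape(4, 2)
    mc = lk.make_metacells(values, ["a"] * 4, k=2, seed=0)
    assert mc.n_metacells == 2
    assert len(mc.assignments) == 4
    assert mc.assignments["cell"].is_unique  # each cell in at most one metacell


def test_metacells_preserve_constant_features(rng):
    values = np.full((10, 3), 2.5)
    mc = lk.make_metacells(values, ["a"] * 10, k=5, seed=1)
    assert mc.values == pytest.approx(2.5)


def test_metacells_same_seed_same_partition(rng):
    values = rng.normal(size=(30, 4))
    labels = ["a", "b", "c"] * 10
    m1 = lk.make_metacells(values, labels, k=3, seed=9)
    m2 = lk.make_metacells(values, labels, k=3, seed=9)
    pd.testing.assert_frame_equal(m1.assignments, m2.assignments)
    m3 = lk.make_metacells(values, labels, k=3, seed=10)
    assert not m1.assignments.equals(m3.assignments)


def test_metacells_drop_types_smaller_than_k():
    values = np.ones((5, 2))
    with pytest.warns(UserWarning, match="fewer than k"):
        mc = lk.make_metacells(values, ["a", "a", "a", "a", "b"], k=4, seed=0)
    assert mc.n_metacells == 1
    assert set(mc.assignments["cell_type"]) == {"a"}


# ---------------------------------------------------------------------------
# promoter co-accessibility links


def _coacc_setup(distal_tss_distance, profile=None, anti=False):
    """One gene with a promoter peak and one distal candidate peak."""
    tss = 1_000_000
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [tss], "end": [tss + 1000],
                          "name": ["g1"], "score": [0], "strand": ["+"],
                          "tss": [tss]})
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [tss - 200, tss + distal_tss_distance - 250],
            "end": [tss + 300, tss + distal_tss_distance + 250],
            "name": ["prom", "distal"],
        }
    )
    prof = np.arange(10, dtype=float) if profile is None else profile
    distal_prof = -prof if anti else prof
    values = np.column_stack([prof, distal_prof])
    return _mc(values), peaks, genes


def test_identical_profile_at_10kb_is_linked():
    mc, peaks, genes = _coacc_setup(10_000)
    out = lk.coaccessible_promoter_links(mc, peaks, genes)
    assert list(out["peak_id"]) == ["distal"]
    assert out.iloc[0]["score"] == pytest.approx(1.0)
    assert out.iloc[0]["gene_id"] == "g1"


def test_anticorrelated_peak_is_not_linked():
    mc, peaks, genes = _coacc_setup(10_000, anti=True)
    out = lk.coaccessible_promoter_links(mc, peaks, genes)
    assert "distal" not in set(out["peak_id"])


def test_peak_beyond_250kb_is_not_linked():
    mc, peaks, genes = _coacc_setup(300_000)
    out = lk.coaccessible_promoter_links(mc, peaks, genes)
    assert "distal" not in set(out["peak_id"])


def test_promoter_peak_is_not_its_own_partner():
    tss = 1_000_000
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [tss], "end": [tss + 1000],
                          "name": ["g1"], "score": [0], "strand": ["+"],
                          "tss": [tss]})
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [tss - 200],
                          "end": [tss + 300], "name": ["prom"]})
    mc = _mc(np.arange(10, dtype=float)[:, None])
    out = lk.coaccessible_promoter_links(mc, peaks, genes)
    assert out.empty


def test_promoter_window_is_strand_aware():
    tss = 1_000_000
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [tss - 999],
                          "end": [tss + 1], "name": ["gneg"], "score": [0],
                          "strand": ["-"], "tss": [tss]})
    # peak upstream of a minus-strand TSS lies at larger coordinates
    peaks = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [tss + 1500, tss + 50_000],
         "end": [tss + 1900, tss + 50_500], "name": ["prom_up", "distal"]}
    )
    prof = np.arange(10, dtype=float)
    mc = _mc(np.column_stack([prof, prof]))
    out = lk.coaccessible_promoter_links(mc, peaks, genes)
    assert set(out["peak_id"]) == {"distal"}


def test_coaccessibility_correlation_is_symmetric(rng):
    vals = rng.normal(size=(30, 6))
    corr = lk._corr_columns(vals)
    np.testing.assert_allclose(corr, corr.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(corr), 1.0)


# ---------------------------------------------------------------------------
# peak-to-gene links


def test_planted_pair_with_unit_strength_is_linked():
    prof = np.arange(12, dtype=float)
    mc_a = _mc(prof[:, None])
    mc_r = lk.MetacellMatrix(prof[:, None] * 3.0, mc_a.assignments, mc_a.k)
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [990_000],
                          "end": [990_500], "name": ["p"]})
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000],
                          "end": [1_001_000], "name": ["g"], "score": [0],
                          "strand": ["+"], "tss": [1_000_000]})
    out = lk.peak2gene_links(mc_a, mc_r, peaks, genes)
    assert len(out) == 1 and out.iloc[0]["score"] == pytest.approx(1.0)


def test_constant_gene_vector_is_omitted_with_warning():
    prof = np.arange(12, dtype=float)
    mc_a = _mc(prof[:, None])
    mc_r = lk.MetacellMatrix(np.full((12, 1), 5.0), mc_a.assignments, mc_a.k)
    peaks = pd.DataFrame({"chrom": ["chr1"], "start": [990_000],
                          "end": [990_500], "name": ["p"]})
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000],
                          "end": [1_001_000], "name": ["g"], "score": [0],
                          "strand": ["+"], "tss": [1_000_000]})
    with pytest.warns(UserWarning, match="undefined"):
        out = lk.peak2gene_links(mc_a, mc_r, peaks, genes)
    assert out.empty


def test_mismatched_metacell_partitions_raise():
    prof = np.arange(12, dtype=float)
    mc_a = _mc(prof[:, None])
    other = _mc(prof[:, None])
    other.assignments.loc[0, "metacell"] = 5
    with pytest.raises(ValueError, match="partition"):
        lk.peak2gene_links(mc_a, other, pd.DataFrame(), pd.DataFrame())


def test_monte_carlo_link_recovery_and_null_rate(multiome_no_markers):
    """Planted links at strength 0.8 recovered; null pairs rarely linked."""
    mo = multiome_no_markers
    norm_a = lk.log2_cpm(mo.atac)
    norm_r = lk.log2_cpm(mo.rna)
    mc_a = lk.make_metacells(norm_a, mo.labels, k=10, seed=11)
    mc_r = lk.MetacellMatrix(_metacell_means(norm_r, mc_a),
                             mc_a.assignments, mc_a.k)
    links = lk.peak2gene_links(mc_a, mc_r, mo.peaks, mo.genes)
    truth = {(l["peak"], l["gene"]) for l in mo.truth["links"]}
    found = set(zip(links["peak_id"], links["gene_id"]))
    assert len(truth & found) / len(truth) >= 0.9

    # null universe: pairs within range where neither side is planted
    planted_peaks = {l["peak"] for l in mo.truth["links"]} \
        | {l["promoter_peak"] for l in mo.truth["links"]}
    planted_genes = {l["gene"] for l in mo.truth["links"]}
    tss = mo.genes.set_index("name")["tss"]
    gchrom = mo.genes.set_index("name")["chrom"]
    mid = ((mo.peaks["start"] + mo.peaks["end"]) // 2).to_numpy()
    n_null = n_null_linked = 0
    for gname in mo.genes["name"]:
        if gname in planted_genes:
            continue
        near = (mo.peaks["chrom"].to_numpy() == gchrom[gname]) & (
            np.abs(mid - tss[gname]) <= 250_000)
        for pname in mo.peaks["name"].to_numpy()[near]:
            if pname in planted_peaks:
                continue
            n_null += 1
            if (pname, gname) in found:
                n_null_linked += 1
    assert n_null >= 100
    assert n_null_linked / n_null < 0.05


# ---------------------------------------------------------------------------
# marker enrichment of link targets


def test_enrichment_fraction_one_when_all_markers_are_targets(rng):
    markers = [f"g{i}" for i in range(500)]
    res = lk.marker_enrichment_of_targets(
        markers, {"focal": markers, "c1": [f"x{i}" for i in range(500)]},
        control_tissues=["c1"], n_sample=457, seed=0)
    focal = res.set_index("tissue").loc["focal"]
    assert focal["fraction"] == 1.0


def test_enrichment_fraction_zero_for_disjoint_sets():
    res = lk.marker_enrichment_of_targets(
        ["a", "b"], {"t": [f"m{i}" for i in range(600)]},
        control_tissues=["t"], n_sample=457, seed=0)
    assert res.iloc[0]["fraction"] == 0.0


def test_enrichment_normalization_against_control_mean():
    targets = [f"g{i}" for i in range(20)]
    sets = {
        "focal": [f"g{i}" for i in range(100)],      # fraction 0.2
        "c1": [f"g{i}" for i in range(10)] + [f"x{i}" for i in range(90)],
        "c2": [f"g{i}" for i in range(10)] + [f"y{i}" for i in range(90)],
    }
    res = lk.marker_enrichment_of_targets(
        targets, sets, control_tissues=["c1", "c2"], n_sample=100, seed=0)
    res = res.set_index("tissue")
    assert res.loc["focal", "fraction"] == pytest.approx(0.2)
    assert res.loc["focal", "normalized"] == pytest.approx(2.0)


def test_enrichment_small_marker_set_used_whole_with_warning():
    with pytest.warns(UserWarning, match="using all"):
        res = lk.marker_enrichment_of_targets(
            ["a"], {"t": ["a", "b"]}, control_tissues=["t"],
            n_sample=457, seed=0)
    assert res.iloc[0]["fraction"] == pytest.approx(0.5)
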