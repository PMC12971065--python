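"""Risk-set assembly, evidence flags and the prioritization rule."""

import numpy as np
import pandas as pd
import pytest

from crevar import variants as vm


def _variants(rows):
    df = pd.DataFrame(rows)
    for col, default in (("ref", "A"), ("alt", "G")):
        if col not in df:
            df[col] = default
    return df


# ---------------------------------------------------------------------------
# risk set


def test_ld_filter_is_strictly_above_half():
    index = _variants([{"id": "i1", "chrom": "chr1", "pos": 100}])
    ld = pd.DataFrame(
        {
            "index_id": ["i1"] * 3,
            "variant_id": ["i1", "v1", "v2"],
            "r2": [1.0, 0.5, 0.51],
            "chrom": "chr1",
            "pos": [100, 200, 300],
            "ref": "A",
            "alt": "G",
        }
    )
    credible = _variants([]).reindex(columns=["id", "chrom", "pos", "ref", "alt"])
    out = vm.build_risk_set(index, ld, credible)
    assert set(out["id"]) == {"i1", "v2"}  # R^2 = 0.5 exactly is excluded


def test_variant_in_both_sources_appears_once():
    index = _variants([{"id": "i1", "chrom": "chr1", "pos": 100}])
    ld = pd.DataFrame({"index_id": ["i1"], "variant_id": ["v1"], "r2": [0.9],
                       "chrom": ["chr1"], "pos": [200], "ref": ["A"],
                       "alt": ["G"]})
    credible = _variants([{"id": "v1", "chrom": "chr1", "pos": 200}])
    out = vm.build_risk_set(index, ld, credible)
    assert (out["pos"] == 200).sum() == 1


def test_empty_ld_table_returns_credible_set():
    index = _variants([]).reindex(columns=["id", "chrom", "pos", "ref", "alt"])
    ld = pd.DataFrame(columns=["index_id", "variant_id", "r2"])
    credible = _variants(
        [{"id": f"c{i}", "chrom": "chr1", "pos": 1000 + i} for i in range(7)]
    )
    out = vm.build_risk_set(index, ld, credible)
    assert len(out) == 7


def test_index_absent_from_ld_table_kept_with_warning():
    index = _variants([{"id": "i1", "chrom": "chr1", "pos": 100}])
    ld = pd.DataFrame({"index_id": ["other"], "variant_id": ["other"],
                       "r2": [1.0], "chrom": ["chr2"], "pos": [5],
                       "ref": ["A"], "alt": ["G"]})
    credible = _variants([]).reindex(columns=["id", "chrom", "pos", "ref", "alt"])
    with pytest.warns(UserWarning, match="i1"):
        out = vm.build_risk_set(index, ld, credible)
    assert "i1" in set(out["id"])


# ---------------------------------------------------------------------------
# missense classification


@pytest.mark.parametrize(
    "score,expected",
    [
        (0.2, "likely benign"),
        (0.34, "ambiguous"),
        (0.565, "ambiguous"),
        (0.6, "likely pathogenic"),
        (0.0, "likely benign"),
        (1.0, "likely pathogenic"),
    ],
)
def test_missense_classification_thresholds(score, expected):
    assert vm.classify_alpha_missense(score) == expected


def test_missense_classification_rejects_out_of_range():
    with pytest.raises(ValueError):
        vm.classify_alpha_missense(1.2)


# ---------------------------------------------------------------------------
# accessibility intersection


def test_variant_accessibility_uses_half_open_intervals():
    variants = _variants(
        [
            {"id": "at_start", "chrom": "chr1", "pos": 100},
            {"id": "inside", "chrom": "chr1", "pos": 300},
            {"id": "at_end", "chrom": "chr1", "pos": 600},
            {"id": "elsewhere", "chrom": "chr2", "pos": 300},
        ]
    )
    peaks = {"rpe": pd.DataFrame({"chrom": ["chr1"], "start": [100],
                                  "end": [600], "name": ["pk"]})}
    acc, summary = vm.intersect_accessibility(variants, peaks)
    assert set(acc["variant_id"]) == {"at_start", "inside"}
    assert summary["n_accessible"] == 2
    assert summary["pct_accessible"] == 50.0


# ---------------------------------------------------------------------------
# enrichment


def _tissue(intervals):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in intervals]
    )


def test_enrichment_density_arithmetic():
    variants = _variants(
        [{"id": f"v{i}", "chrom": "chr1", "pos": 1000 + i} for i in range(5)]
    )
    peaks = {
        "focal": _tissue([("chr1", 0, 500_000)]),
        "ctrl": _tissue([("chr2", 0, 1_000_000)]),
    }
    res = vm.peak_enrichment(variants, peaks, ["ctrl"]).set_index("tissue")
    assert res.loc["focal", "density"] == pytest.approx(1e-5)
    assert res.loc["focal", "unique_bases"] == 500_000


def test_enrichment_invariant_under_peak_duplication():
    variants = _variants([{"id": "v", "chrom": "chr1", "pos": 10}])
    once = {"t": _tissue([("chr1", 0, 100)]), "c": _tissue([("chr2", 0, 100)])}
    twice = {"t": _tissue([("chr1", 0, 100), ("chr1", 0, 100)]),
             "c": once["c"]}
    r1 = vm.peak_enrichment(variants, once, ["c"])
    r2 = vm.peak_enrichment(variants, twice, ["c"])
    pd.testing.assert_frame_equal(r1, r2)


def test_enrichment_normalization_worked_example():
    # density 1e-5 against control densities 2e-6 and 3e-6 -> 4.0
    variants = _variants(
        [{"id": f"v{i}", "chrom": "chr1", "pos": 1000 + i} for i in range(5)]
        + [{"id": "c1", "chrom": "chr2", "pos": 10},
           {"id": "c2", "chrom": "chr2", "pos": 20},
           {"id": "c3", "chrom": "chr3", "pos": 10},
           {"id": "c4", "chrom": "chr3", "pos": 20},
           {"id": "c5", "chrom": "chr3", "pos": 30}]
    )
    peaks = {
        "focal": _tissue([("chr1", 0, 500_000)]),
        "ctrl1": _tissue([("chr2", 0, 1_000_000)]),
        "ctrl2": _tissue([("chr3", 0, 1_000_000)]),
    }
    res = vm.peak_enrichment(variants, peaks, ["ctrl1", "ctrl2"])
    res = res.set_index("tissue")
    assert res.loc["ctrl1", "density"] == pytest.approx(2e-6)
    assert res.loc["ctrl2", "density"] == pytest.approx(3e-6)
    assert res.loc["focal", "normalized"] == pytest.approx(4.0)


def test_enrichment_invariant_under_chromosome_relabeling():
    variants = _variants([{"id": "v", "chrom": "chrA", "pos": 10}])
    peaks = {"t": _tissue([("chrA", 0, 100)]), "c": _tissue([("chrB", 0, 100)])}
    relabel = {"chrA": "chr9", "chrB": "chr11"}
    v2 = variants.assign(chrom=variants["chrom"].map(relabel))
    p2 = {k: df.assign(chrom=df["chrom"].map(relabel)) for k, df in peaks.items()}
    r1 = vm.peak_enrichment(variants, peaks, ["c"]).drop(columns="tissue")
    r2 = vm.peak_enrichment(v2, p2, ["c"]).drop(columns="tissue")
    pd.testing.assert_frame_equal(r1, r2)


# ---------------------------------------------------------------------------
# predicted-effect aggregation


def _pred_rows(vid, lfc, cell_types=("ct0", "ct1"), folds=5, ref=100.0):
    return [
        {"variant_id": vid, "cell_type": ct, "fold": f,
         "ref_count": ref, "alt_count": ref * 2.0 ** (lfc if ct == "ct0" else 0)}
        for ct in cell_types for f in range(folds)
    ]


def test_equal_predictions_are_null():
    preds = pd.DataFrame(_pred_rows("v0", 0.0))
    per_variant, per_ct = vm.aggregate_predictions(preds)
    assert (per_ct["pvalue"] == 1.0).all()
    assert per_variant.iloc[0]["max_abs_log2fc"] == 0.0
    assert not per_variant.iloc[0]["high_effect"]


def test_strong_predicted_effect_is_high_effect_among_nulls():
    rows = _pred_rows("v_hot", 1.0)
    for i in range(30):
        rows += _pred_rows(f"v{i}", 0.0)
    per_variant, _ = vm.aggregate_predictions(pd.DataFrame(rows))
    res = per_variant.set_index("variant_id")
    assert bool(res.loc["v_hot", "high_effect"])
    assert not res.drop("v_hot")["high_effect"].any()


def test_aggregation_rejects_nonpositive_counts():
    preds = pd.DataFrame(_pred_rows("v0", 0.5))
    preds.loc[0, "ref_count"] = 0.0
    with pytest.raises(ValueError, match="positive"):
        vm.aggregate_predictions(preds)


def test_fold_averaging_of_log2fc():
    rows = [
        {"variant_id": "v", "cell_type": "ct0", "fold": f,
         "ref_count": 100.0, "alt_count": 100.0 * 2.0 ** lfc}
        for f, lfc in enumerate([0.2, 0.4, 0.6])
    ]
    _, per_ct = vm.aggregate_predictions(pd.DataFrame(rows))
    assert per_ct.iloc[0]["log2fc"] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# link flags, eQTL flag, prioritization


def _flag_setup():
    variants = _variants(
        [
            {"id": "v_link", "chrom": "chr1", "pos": 1000},
            {"id": "v_loop", "chrom": "chr1", "pos": 5000},
            {"id": "v_decoy_loop", "chrom": "chr1", "pos": 9000},
            {"id": "v_nopeak", "chrom": "chr2", "pos": 1000},
        ]
    )
    acc = pd.DataFrame(
        {
            "variant_id": ["v_link", "v_loop", "v_decoy_loop"],
            "cell_type": "ct0",
            "peak_id": ["pkA", "pkB", "pkC"],
        }
    )
    links = pd.DataFrame(
        {"peak_id": ["pkA"], "gene_id": ["G"], "method": ["coaccessibility"]}
    )
    loops = pd.DataFrame(
        {
            "chrom1": ["chr1", "chr1"],
            "start1": [4500, 8500],
            "end1": [5500, 9500],
            "chrom2": ["chr1", "chr1"],
            "start2": [100_000, 300_000],
            "end2": [101_000, 301_000],
            "name": ["good", "no_promoter_partner"],
        }
    )
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100_500], "end": [101_500],
         "name": ["G"], "score": [0], "strand": ["+"], "tss": [100_500]}
    )
    return variants, acc, links, loops, genes


def test_link_flags_from_containing_peak_and_loops():
    variants, acc, links, loops, genes = _flag_setup()
    out = vm.link_flags(acc, links, loops, genes, variants).set_index("variant_id")
    assert bool(out.loc["v_link", "coaccessible_promoter"])
    assert out.loc["v_link", "target_genes"] == ["G"]
    assert bool(out.loc["v_loop", "hichip_linked"])
    assert not bool(out.loc["v_decoy_loop", "hichip_linked"])
    row = out.loc["v_nopeak"]
    assert not any(row[f] for f in ("coaccessible_promoter",
                                    "expression_correlated", "abc_connected",
                                    "hichip_linked"))


def test_eqtl_flag_inclusive_boundary_and_tissues():
    variants = _variants(
        [{"id": v, "chrom": "chr1", "pos": i} for i, v in
         enumerate(["at_bound", "above", "macular_only"])]
    )
    eqtls = pd.DataFrame(
        {
            "variant_id": ["at_bound", "above", "above", "macular_only"],
            "gene": "G",
            "tissue": ["macular", "macular", "non-macular", "macular"],
            "fdr": [0.05, 0.051, 0.051, 0.001],
        }
    )
    flag = vm.eqtl_flag(variants, eqtls)
    assert list(flag) == [True, False, True]


def test_prioritize_requires_three_of_eight():
    rows = []
    for n_true in (0, 2, 3, 8):
        row = {"variant_id": f"v{n_true}", "target_genes": []}
        for i, c in enumerate(vm.CRITERIA):
            row[c] = i < n_true
        rows.append(row)
    out, summary = vm.prioritize(pd.DataFrame(rows))
    got = out.set_index("variant_id")["prioritized"]
    assert not got["v0"] and not got["v2"]
    assert got["v3"] and got["v8"]
    assert summary["n_prioritized"] == 2
    assert summary["pct_prioritized"] == 50.0


def test_prioritization_monotone_in_criteria():
    row = {"variant_id": "v", "target_genes": []}
    for i, c in enumerate(vm.CRITERIA):
        row[c] = i < 3
    out1, _ = vm.prioritize(pd.DataFrame([row]))
    assert bool(out1.iloc[0]["prioritized"])
    row2 = dict(row)
    row2[vm.CRITERIA[5]] = True  # adding evidence never removes priority
    out2, _ = vm.prioritize(pd.DataFrame([row2]))
    assert bool(out2.iloc[0]["prioritized"])
    assert out2.iloc[0]["n_criteria"] == out1.iloc[0]["n_criteria"] + 1


def test_end_to_end_deterministic_channel_recovery(variant_sets_deterministic):
    """Variants planted with >=3 evidence channels emerge prioritized."""
    vs = variant_sets_deterministic
    noncoding = vs.variants[vs.variants["coding_class"] != "protein-altering"]
    acc, _ = vm.intersect_accessibility(noncoding, vs.peaks_by_celltype)
    flags = vm.assemble_criteria(
        noncoding, acc, vs.links, vs.loops, vs.genes, vs.eqtls,
        predictions=vs.predictions, starr_enhancers=vs.starr_calls,
        starr_functional=vs.starr_calls)
    flags, _ = vm.prioritize(flags)
    flags = flags.set_index("variant_id")
    for vid, channels in vs.truth["channels"].items():
        assert flags.loc[vid, "n_criteria"] == len(channels)
        assert flags.loc[vid, "prioritized"] == (len(channels) >= 3)
    planted = set(vs.truth["channels"])
    assert not flags.drop(index=planted & set(flags.index))["prioritized"].any()
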