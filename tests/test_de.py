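import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plaquescape.config import AnalysisThresholds, Genotype
from plaquescape.de import (
    Comparison, Pseudobulk, bh_adjust, build_pseudobulk,
    continuous_distance_de, filter_de_results, fit_group_de,
    pairwise_genotype_de, proximal_vs_distal_de, region_vs_rest_de,
)


def _toy_cells(n_per, genotypes=("WT", "FAD"), batches=("b1", "b2", "b3"),
               cell_type="Micro"):
    rows = []
    i = 0
    for b in batches:
        for g in genotypes:
            for _ in range(n_per):
                rows.append({"cell_id": f"c{i:05d}", "x": 0.0, "y": 0.0,
                             "volume": 500.0, "sample_id": f"{g}_{b}",
                             "batch_id": b, "genotype": g,
                             "cell_type": cell_type})
                i += 1
    cells = pd.DataFrame(rows)
    cells["total_transcripts"] = 0
    return cells


def test_pseudobulk_sums_and_thresholds():
    cells = _toy_cells(60)
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.poisson(2.0, (len(cells), 4)),
                          index=cells["cell_id"], columns=list("wxyz"))
    pb = build_pseudobulk(counts, cells)
    # exact conservation: pseudobulk sums equal member-cell sums
    total = pb.counts.to_numpy().sum()
    assert total == counts.to_numpy().sum()
    one = pb.meta.iloc[0]
    member = cells[cells["sample_id"] == one["sample_id"]]["cell_id"]
    np.testing.assert_array_equal(
        pb.counts.iloc[0].to_numpy(), counts.loc[member].sum(axis=0).to_numpy())


def test_pseudobulk_drops_small_strata_and_rare_genes():
    cells = pd.concat([_toy_cells(60, genotypes=("WT",)),
                       _toy_cells(49, genotypes=("FAD",))], ignore_index=True)
    cells["cell_id"] = [f"c{i:05d}" for i in range(len(cells))]
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.poisson(2.0, (len(cells), 3)),
                          index=cells["cell_id"], columns=list("abc"))
    counts["rare"] = 0
    counts.loc[counts.index[:10], "rare"] = 1  # detected in ~3% of cells
    pb = build_pseudobulk(counts, cells)
    # 49-cell strata dropped
    assert (pb.meta["n_cells"] >= 50).all()
    assert set(pb.meta["genotype"]) == {"WT"}
    assert "rare" not in pb.genes_tested["Micro"]
    assert set("abc") <= set(pb.genes_tested["Micro"])


def test_pseudobulk_no_surviving_stratum_errors():
    cells = _toy_cells(10)
    counts = pd.DataFrame(np.ones((len(cells), 2), dtype=int),
                          index=cells["cell_id"], columns=["a", "b"])
    with pytest.raises(ValueError, match="stratum"):
        build_pseudobulk(counts, cells)


def _simple_pb(y_by_group, batches=("b1", "b2", "b3"), gene="g"):
    """Pseudobulk with one gene whose log2 CPM is controlled via counts."""
    rows, meta = [], []
    for b in batches:
        for gname, vals in y_by_group.items():
            for v in vals:
                rows.append({gene: v, "other": 1000})
                meta.append({"cell_type": "Micro", "sample_id": f"{gname}_{b}",
                             "genotype": gname, "batch_id": b, "n_cells": 100})
    counts = pd.DataFrame(rows)
    return Pseudobulk(counts, pd.DataFrame(meta),
                      {"Micro": [gene, "other"]})


def test_identical_groups_give_zero_log2fc():
    pb = _simple_pb({"WT": [40], "FAD": [40]})
    res = fit_group_de(pb, Comparison(("FAD",), ("WT",), cell_type="Micro"))
    assert res.loc[res["gene"] == "g", "log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert not res["significant"].any()


def test_group_label_swap_negates_log2fc():
    rng = np.random.default_rng(2)
    pb = _simple_pb({"WT": [int(v) for v in rng.poisson(30, 1)],
                     "FAD": [int(v) for v in rng.poisson(90, 1)]})
    a = fit_group_de(pb, Comparison(("FAD",), ("WT",), cell_type="Micro"))
    b = fit_group_de(pb, Comparison(("WT",), ("FAD",), cell_type="Micro"))
    np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-9)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)


def test_reml_matches_statsmodels_mixedlm():
    """The package's closed-form REML agrees with MixedLM on random designs."""
    import statsmodels.formula.api as smf
    from plaquescape._lmm import fit_random_intercept

    rng = np.random.default_rng(7)
    for _ in range(6):
        n_b = int(rng.integers(2, 5))
        reps = int(rng.integers(2, 4))
        rows = []
        for b in range(n_b):
            u = rng.normal(0, 0.5)
            for g in (0, 1):
                for _ in range(reps):
                    rows.append({"y": 3 + 0.8 * g + u + rng.normal(0, 0.4),
                                 "g": g, "b": b})
        df = pd.DataFrame(rows)
        X = np.column_stack([np.ones(len(df)), df["g"]])
        fit = fit_random_intercept(df["y"].to_numpy(), X, df["b"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm("y ~ g", df, groups=df["b"]).fit(reml=True)
        assert fit["beta"][1] == pytest.approx(ref.params["g"], abs=1e-4)
        if ref.converged:
            assert fit["se"][1] == pytest.approx(ref.bse["g"], abs=1e-3)


def test_single_batch_falls_back_to_ols():
    pb = _simple_pb({"WT": [40, 42], "FAD": [90, 88]}, batches=("b1",))
    res = fit_group_de(pb, Comparison(("FAD",), ("WT",), cell_type="Micro"))
    assert (res["model_flag"] == "ols").all()


def test_insufficient_replicates_named_in_error():
    pb = _simple_pb({"WT": [40, 42], "FAD": [90, 88]}, batches=("b1",))
    with pytest.raises(ValueError, match="group_b"):
        fit_group_de(pb, Comparison(("FAD",), ("R47H",), cell_type="Micro",
                                    label="x"))


def test_pairwise_runs_five_comparisons(small_null_qc):
    _, cells, counts, _ = small_null_qc
    pb = build_pseudobulk(counts, cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pairwise_genotype_de(pb, cell_types=["Micro"])
    assert res["comparison"].nunique() == 5
    assert set(res["comparison"]) == {
        "FAD_vs_WT", "R47H_FAD_vs_R47H", "R47H_vs_WT",
        "R47H_FAD_vs_FAD", "R47H_FAD_vs_WT"}


def test_pairwise_skips_missing_genotype(small_null_qc):
    _, cells, counts, _ = small_null_qc
    keep = cells["genotype"] != "R47H"
    pb = build_pseudobulk(counts.loc[cells.loc[keep, "cell_id"]], cells[keep])
    with pytest.warns(UserWarning):
        res = pairwise_genotype_de(pb, cell_types=["Micro"])
    assert set(res["comparison"]) == {"FAD_vs_WT", "R47H_FAD_vs_FAD",
                                      "R47H_FAD_vs_WT"}


def test_region_vs_rest_recovers_planted_region_effect():
    from plaquescape.simulate import RegionEffect, simulate_cohort
    from plaquescape.preprocess import qc_filter_cells
    from plaquescape.validation import null_config, uniform_densities

    cfg = null_config(6, cell_type_densities={
        r: {"Micro": 0.6e-4} for r in ("cortex", "corpus_callosum",
                                       "hippocampus", "thalamus")})
    cfg.region_effects = [RegionEffect("G0000", "Micro", "cortex", 1.5)]
    design = [(Genotype.WT, f"b{i}") for i in (1, 2, 3)]
    ds, _ = simulate_cohort(cfg, design, seed=6)
    cells, counts = qc_filter_cells(ds.cells, ds.counts)
    pb = build_pseudobulk(counts, cells, extra_keys=("region",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = region_vs_rest_de(pb)
    hit = res[(res["gene"] == "G0000") & (res["cell_type"] == "Micro")
              & (res["comparison"] == "cortex_vs_rest:WT")]
    assert hit["significant"].iloc[0]
    assert hit["log2fc"].iloc[0] > 0.5
    # nominal-significance flag recorded
    assert hit["model_flag"].str.contains("nominal").all()


def test_proximal_vs_distal_recovers_planted_decay():
    from plaquescape.simulate import DistanceEffect, simulate_cohort
    from plaquescape.preprocess import qc_filter_cells
    from plaquescape.spatial import nearest_plaque_distance
    from plaquescape.validation import null_config

    cfg = null_config(7, cell_type_densities={
        r: {"Micro": 0.6e-4} for r in ("cortex", "corpus_callosum",
                                       "hippocampus", "thalamus")})
    cfg.distance_effects = [DistanceEffect("Itgax", "Micro", 1.5, 50.0)]
    design = [(Genotype.FAD, "b1"), (Genotype.FAD, "b2"),
              (Genotype.R47H_FAD, "b1"), (Genotype.R47H_FAD, "b2")]
    ds, _ = simulate_cohort(cfg, design, seed=7)
    cells, counts = qc_filter_cells(ds.cells, ds.counts)
    parts = []
    for sid in cells["sample_id"].unique():
        sub = cells[cells["sample_id"] == sid]
        prox = nearest_plaque_distance(sub, ds.sample_plaques(sid))
        parts.append(sub.merge(prox, on="cell_id"))
    cells = pd.concat(parts, ignore_index=True)
    zoned = cells[cells["zone"].isin(["proximal", "distal"])]
    pb = build_pseudobulk(counts, zoned, extra_keys=("zone",))
    res = proximal_vs_distal_de(pb, cell_types=["Micro"]).set_index("gene")
    assert res.loc["Itgax", "significant"]
    assert res.loc["Itgax", "log2fc"] > 0.35
    # a zone missing for the cell type is an error naming the zone
    pb_p = build_pseudobulk(counts, zoned[zoned["zone"] == "proximal"],
                            extra_keys=("zone",))
    with pytest.raises(ValueError, match="distal"):
        proximal_vs_distal_de(pb_p, cell_types=["Micro"])


def test_continuous_distance_requires_enough_cells():
    cells = _toy_cells(5, genotypes=("FAD",))
    cells["distance_to_nearest_plaque"] = 50.0
    counts = pd.DataFrame(np.ones((len(cells), 2), dtype=int),
                          index=cells["cell_id"], columns=["a", "b"])
    with pytest.raises(ValueError, match="30"):
        continuous_distance_de(counts, cells, "Micro")


def test_bh_hand_computed_and_identity():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.05]), [0.05])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_bruteforce_and_is_monotone(p):
    from plaquescape.validation import _bh_bruteforce

    p = np.asarray(p)
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, _bh_bruteforce(p), atol=1e-12)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def _atlas():
    return pd.DataFrame({
        "gene": ["Gfap", "P2ry12", "Itgax", "Slc17a7", "G0001"],
        "expressed_in": ["Astro", "Micro", "Micro", "ExN", "ExN|Micro|Astro"],
        "exclusive_to": ["Astro", "Micro", "Micro", "ExN", ""],
        "dam_marker": [False, False, True, False, False],
        "daa_marker": [True, False, False, False, False],
    })


def _de_rows():
    return pd.DataFrame({
        "cell_type": ["ExN", "Micro", "ExN", "Micro"],
        "comparison": ["FAD_vs_WT"] * 4,
        "gene": ["Gfap", "P2ry12", "G0001", "G0001"],
        "log2fc": [1.0, -0.5, 0.4, 0.4],
        "se": [0.1] * 4, "p": [1e-4] * 4, "p_adj": [1e-3] * 4,
        "significant": [True] * 4, "model_flag": ["reml"] * 4,
    })


def test_filter_neuronal_removes_astrocyte_gene():
    out = filter_de_results(_de_rows(), _atlas(), mode="neuronal")
    reasons = dict(zip(out["gene"] + ":" + out["cell_type"], out["filtered_reason"]))
    assert reasons["Gfap:ExN"] == "glial_or_disease_marker"
    assert reasons["G0001:ExN"] == ""  # pan-expressed gene survives
    assert len(out) == len(_de_rows())  # raw rows preserved alongside


def test_filter_glial_keeps_annotated_genes_only():
    out = filter_de_results(_de_rows(), _atlas(), mode="glial")
    reasons = dict(zip(out["gene"] + ":" + out["cell_type"], out["filtered_reason"]))
    assert reasons["P2ry12:Micro"] == ""
    assert reasons["Gfap:ExN"] == "not_expressed_in_type"
    with pytest.raises(ValueError):
        filter_de_results(_de_rows(), None, mode="glial")


def test_filter_exclusion_list_overrides_everything():
    out = filter_de_results(_de_rows(), _atlas(), mode="neuronal",
                            exclusion_genes=["G0001"])
    assert (out.loc[out["gene"] == "G0001", "filtered_reason"]
            == "exclusion_list").all()
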