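"""End-to-end validation benchmarks on synthetic ground truth.

Each function regenerates its own data from a seed, runs the relevant part
of the pipeline, and returns summary numbers: detector accuracy against
rendered ground truth, type-I error and recovery of the differential
expression procedures, geometric accuracy of the area estimators, recovery
of the planted microglial plaque attraction, and exact agreement of the
bias classifier and BH adjustment with independent brute-force
implementations.  The benchmark problem sizes (cohorts of 4 genotypes x 3
batches at roughly 200 cells per type per section, 300-gene panel) mirror
the cohort structure the pipeline is designed for at a scale where each
suite runs in seconds to a couple of minutes.
"""

from __future__ import annotations

import io as _io
import warnings

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, Genotype, GENOTYPE_ORDER
from .de import (
    Comparison, bh_adjust, build_pseudobulk, continuous_distance_de,
    fit_group_de, pairwise_genotype_de,
)
from .bias import ALLOWED_PAIRS, classify_bias, genotype_proportion_matrix
from .plaques import (
    ConfusionCounts, PlaqueMask, detect_plaques_threshold, detection_metrics,
    match_predictions, transcript_density_contrast, two_sample_contrast,
)
from .preprocess import qc_filter_cells
from .simulate import (
    DistanceEffect, GenotypeEffect, SimConfig, TYPE_MARKERS,
    random_fov_tables, render_dapi_image, simulate_cohort, simulate_section,
)
from .spatial import (
    alpha_shape_area, convex_hull_area, nearest_plaque_distance,
    proximal_distal_density, union_disk_area,
)

FULL_DESIGN = tuple(
    (g, f"b{i + 1}") for i in range(3) for g in GENOTYPE_ORDER
)


def uniform_densities(per_type: float = 0.25e-4) -> dict:
    """Flat per-region, per-type density giving ~225 cells/type/section."""
    return {
        r: {ct: per_type for ct in ("ExN", "InN", "Astro", "Micro", "Oligo")}
        for r in ("cortex", "corpus_callosum", "hippocampus", "thalamus")
    }


def null_config(seed: int, **kw) -> SimConfig:
    """Cohort config with no planted effects (exchangeable genotypes)."""
    kw.setdefault("cell_type_densities", uniform_densities())
    return SimConfig(seed=seed, genotype_effects=[], distance_effects=[],
                     biased_subpopulations=[], **kw)


# ---------------------------------------------------------------------------
# detector validation
# ---------------------------------------------------------------------------

def f1_worked_example() -> dict:
    """Worked F1 example on hold-out plaque-validation confusion counts.

    73 annotated plaques of which 76% were detected (tp=56, fn=17) plus one
    false positive give F1 = 112/130.
    """
    conf = ConfusionCounts(tp=56, fp=1, fn=17)
    return detection_metrics(conf)


def detector_benchmark(seed: int, n_images: int = 20) -> dict:
    """Threshold detector vs rendered ground truth over random fields of view.

    Aggregates object-level confusion counts over ``n_images`` rendered
    images and also contrasts transcript density of detected plaques vs
    cells on a simulated amyloid section (plaques carry no RNA, so their
    density should be significantly lower; rank-sum test).
    """
    rng = np.random.default_rng(seed)
    tp = fp = fn = 0
    for i in range(n_images):
        cells, plaques = random_fov_tables(int(rng.integers(2**31)))
        img, gt = render_dapi_image(cells, plaques, seed=int(rng.integers(2**31)))
        det = detect_plaques_threshold(img, 0.108)
        conf = match_predictions(det, PlaqueMask(gt, 0.108))
        tp, fp, fn = tp + conf.tp, fp + conf.fp, fn + conf.fn
    metrics = detection_metrics(ConfusionCounts(tp, fp, fn))

    cfg = SimConfig(seed=seed, cell_type_densities=uniform_densities(0.5e-4))
    cells, _counts, plaques, _r, _t = simulate_section(
        cfg, Genotype.FAD, "b1", seed, "s00")
    contrast = transcript_density_contrast(plaques, cells)
    return {
        "f1": metrics["f1"], "tp": tp, "fp": fp, "fn": fn,
        "n_images": n_images,
        "density_contrast_p": contrast["p"],
        "plaque_density_median": float(np.median(contrast["plaque_density"])),
        "cell_density_median": float(np.median(contrast["cell_density"])),
    }


# ---------------------------------------------------------------------------
# differential expression calibration and recovery
# ---------------------------------------------------------------------------

def null_de_calibration(seed: int, n_seeds: int = 5) -> dict:
    """Fraction of significant (gene, comparison) rows on null cohorts.

    With no planted effects the four genotypes are exchangeable, so the
    pairwise genotype contrasts should flag (almost) nothing.
    """
    tot = sig = 0
    for k in range(n_seeds):
        s = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        cfg = null_config(s)
        ds, _ = simulate_cohort(cfg, list(FULL_DESIGN), seed=s)
        cells, counts = qc_filter_cells(ds.cells, ds.counts)
        pb = build_pseudobulk(counts, cells)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_genotype_de(pb)
        tot += len(res)
        sig += int(res["significant"].sum())
    return {"significant_fraction": sig / tot, "n_rows": tot, "n_seeds": n_seeds}


def planted_filler_genes(n: int = 20, cell_type: str = "Micro") -> list:
    """Filler genes with comfortably detectable baselines, for planting."""
    cfg = null_config(0)
    base = 2.0 ** cfg.baseline_log2()
    fillers = [g for g in cfg.genes if g.startswith("G")]
    ranked = base.loc[cell_type, fillers].sort_values(ascending=False)
    return list(ranked.index[10:10 + n])


def de_recovery(seed: int, n_planted: int = 20, log2fc: float = 1.5,
                n_cohorts: int = 4) -> dict:
    """Sensitivity and empirical FDR for planted genotype effects.

    Plants |log2FC| = ``log2fc`` in ``n_planted`` of the 300 genes for
    microglia in the amyloid genotypes and tests the 5xFAD vs WT contrast
    at the standard thresholds (BH p < 0.05, |log2FC| >= 0.35).  Discovery
    and miss counts are pooled over ``n_cohorts`` replicate cohorts: a
    single cohort yields only ~20 discoveries, so its FDR estimate is
    dominated by Poisson noise in the handful of false calls.
    """
    planted = planted_filler_genes(n_planted)
    effects = [
        GenotypeEffect(g, "Micro", (Genotype.FAD, Genotype.R47H_FAD), log2fc)
        for g in planted
    ]
    tp = fp = n_tested = 0
    lfc_sum = 0.0
    for k in range(n_cohorts):
        s = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        cfg = SimConfig(seed=s, genotype_effects=effects, distance_effects=[],
                        biased_subpopulations=[],
                        cell_type_densities=uniform_densities())
        ds, _ = simulate_cohort(cfg, list(FULL_DESIGN), seed=s)
        cells, counts = qc_filter_cells(ds.cells, ds.counts)
        pb = build_pseudobulk(counts, cells)
        res = fit_group_de(
            pb, Comparison(("FAD",), ("WT",), cell_type="Micro")
        ).set_index("gene")
        tested_planted = [g for g in planted if g in res.index]
        called = set(res.index[res["significant"]])
        tp += len(called & set(tested_planted))
        fp += len(called - set(planted))
        n_tested += len(tested_planted)
        lfc_sum += float(res.loc[tested_planted, "log2fc"].sum())
    return {
        "sensitivity": tp / n_tested,
        "fdr": fp / max(tp + fp, 1),
        "n_called": tp + fp,
        "n_planted_tested": n_tested,
        "mean_log2fc_planted": lfc_sum / n_tested,
    }


def continuous_de_recovery(seed: int, slope_ln: float = -0.02) -> dict:
    """Recovery of a planted log-linear distance decay at the single-cell level.

    Plants a natural-log slope of ``slope_ln`` per um (per-um log2 slope
    slope_ln/ln2 ~ -0.0289) on the microglial marker genes, simulates two
    amyloid sections, and fits the NB distance regression on microglia
    within the proximal radius.
    """
    ln2 = float(np.log(2.0))
    planted = TYPE_MARKERS["Micro"] + ["Apoe"]
    slope_log2 = slope_ln / ln2
    cfg = SimConfig(
        seed=seed, genotype_effects=[], biased_subpopulations=[],
        distance_effects=[
            DistanceEffect(g, "Micro", slope_log2, kind="linear") for g in planted
        ],
    )
    ds, _ = simulate_cohort(
        cfg, [(Genotype.FAD, "b1"), (Genotype.R47H_FAD, "b2")], seed=seed)
    cells, counts = qc_filter_cells(ds.cells, ds.counts)
    parts = []
    for sid in cells["sample_id"].unique():
        sub = cells[cells["sample_id"] == sid]
        prox = nearest_plaque_distance(sub, ds.sample_plaques(sid))
        parts.append(sub.merge(prox, on="cell_id"))
    cells = pd.concat(parts, ignore_index=True)
    n_cells = int(((cells["cell_type"] == "Micro")
                   & (cells["distance_to_nearest_plaque"] < 100)).sum())
    res = continuous_distance_de(counts, cells, "Micro").set_index("gene")
    est = res.loc[[g for g in planted if g in res.index], "log2fc"]
    nonplanted = res.drop(index=est.index)
    within = float(((est - slope_log2).abs() <= 0.3 * abs(slope_log2)).mean())
    return {
        "slope_log2_per_um_true": slope_log2,
        "slope_log2_per_um_mean": float(est.mean()),
        "fraction_within_30pct": within,
        "fraction_sign_correct": float((np.sign(est) == np.sign(slope_log2)).mean()),
        "planted_significant_fraction": float(res.loc[est.index, "significant"].mean()),
        "nonplanted_significant_fraction": float(nonplanted["significant"].mean()),
        "n_cells": n_cells,
    }


# ---------------------------------------------------------------------------
# geometry oracles
# ---------------------------------------------------------------------------

def geometry_oracles(seed: int = 0) -> dict:
    """Disk-union and alpha-shape areas vs closed forms and a hull oracle."""
    from shapely.geometry import box

    big = box(-1e4, -1e4, 1e4, 1e4)
    disk = np.pi * 100.0**2
    single = union_disk_area([(0.0, 0.0)], 100.0, big)
    disjoint = union_disk_area([(0.0, 0.0), (400.0, 0.0)], 100.0)
    coincident = union_disk_area([(0.0, 0.0), (0.0, 0.0)], 100.0)
    gx, gy = np.meshgrid(np.linspace(0, 100, 50), np.linspace(0, 100, 50))
    square = alpha_shape_area(np.column_stack([gx.ravel(), gy.ravel()]), 0.015)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 100, (200, 2))
    hull_gap = abs(alpha_shape_area(pts, 0.0) - convex_hull_area(pts))
    return {
        "disk_rel_err": abs(single - disk) / disk,
        "disjoint_rel_err": abs(disjoint - 2 * disk) / (2 * disk),
        "coincident_rel_err": abs(coincident - disk) / disk,
        "alpha_square_area": square,
        "alpha0_vs_hull_gap": hull_gap,
    }


def microglia_attraction_recovery(seed: int) -> dict:
    """Proximal/distal microglia density ratio vs the planted attraction (2x)."""
    cfg = SimConfig(
        seed=seed, genotype_effects=[], distance_effects=[],
        biased_subpopulations=[],
        cell_type_densities={
            r: {"Micro": 1.8e-4}
            for r in ("cortex", "corpus_callosum", "hippocampus", "thalamus")
        },
    )
    cells, _counts, plaques, regions, _t = simulate_section(
        cfg, Genotype.FAD, "b1", seed, "s00")
    res = proximal_distal_density(cells, plaques, regions.total_polygon())
    return {
        "ratio": res["proximal"] / res["distal"],
        "proximal_density": res["proximal"],
        "distal_density": res["distal"],
        "n_cells": int(res["n_proximal"] + res["n_distal"]),
    }


# ---------------------------------------------------------------------------
# exact oracles: bias classifier and BH
# ---------------------------------------------------------------------------

def _bias_oracle_call(row: np.ndarray, thresholds: AnalysisThresholds) -> tuple:
    """Independent re-derivation of the bias rule for one composition.

    Deliberately written as a direct transcription of the rule: check the
    four single-genotype shares in fixed order, then the allowed pair sums
    in fixed order.
    """
    names = [g.value for g in GENOTYPE_ORDER]
    for i in range(4):
        if row[i] > thresholds.single_genotype_bias:
            return ("single", names[i])
    pairs = [(0, 1), (2, 3), (1, 3), (0, 2)]  # WT+R47H, FAD+cross, R47H+cross, WT+FAD
    for a, b in pairs:
        if row[a] + row[b] > thresholds.pair_bias:
            return ("pair", names[a] + "+" + names[b])
    return ("none", "")


def bias_grid_agreement(step: int = 1) -> dict:
    """classify_bias vs brute-force enumeration over the 4-part simplex grid.

    Enumerates every composition of 4 nonnegative integers summing to 100
    (176,851 compositions at step 1) and compares calls.
    """
    thresholds = AnalysisThresholds()
    grid = []
    rng_vals = range(0, 101, step)
    for a in rng_vals:
        for b in range(0, 101 - a, step):
            for c in range(0, 101 - a - b, step):
                grid.append((a, b, c, 100 - a - b - c))
    arr = np.asarray(grid, dtype=float) / 100.0
    props = pd.DataFrame(arr, columns=[g.value for g in GENOTYPE_ORDER])
    calls = classify_bias(props, thresholds)
    agree = 0
    for (_, row), arr_row in zip(calls.iterrows(), arr):
        call, members = _bias_oracle_call(arr_row, thresholds)
        agree += (call == row["call"]) and (members == row["genotypes"])
    return {
        "agreement_fraction": agree / len(arr),
        "n_compositions": len(arr),
    }


def _bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal step-up BH: sort, scale by n/rank, running min from the top."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def bh_oracle_check(seed: int, n_vectors: int = 100) -> dict:
    """bh_adjust vs the literal brute-force procedure on random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(1, 60))
        p = rng.uniform(size=n)
        if rng.uniform() < 0.3:  # exercise ties
            p = np.round(p, 1)
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - _bh_bruteforce(p)))))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


# ---------------------------------------------------------------------------
# end-to-end determinism
# ---------------------------------------------------------------------------

def _small_pipeline_tables(seed: int) -> dict:
    """One compact end-to-end run: cohort -> QC -> spatial -> DE -> bias."""
    cfg = SimConfig(seed=seed, cell_type_densities=uniform_densities(0.3e-4))
    design = [
        (g, f"b{i + 1}") for i in range(2) for g in GENOTYPE_ORDER
    ]
    ds, _truth = simulate_cohort(cfg, design, seed=seed)
    cells, counts = qc_filter_cells(ds.cells, ds.counts)
    parts = []
    for sid in cells["sample_id"].unique():
        sub = cells[cells["sample_id"] == sid]
        plq = ds.sample_plaques(sid)
        if len(plq) == 0:
            continue
        parts.append(sub.merge(nearest_plaque_distance(sub, plq), on="cell_id"))
    dist = pd.concat(parts, ignore_index=True)
    pb = build_pseudobulk(counts, cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        de = pairwise_genotype_de(pb, cell_types=["Micro"])
        from .bias import subcluster_cell_type
        labels, _excl = subcluster_cell_type(cells, counts, "Micro", seed=seed)
    props = genotype_proportion_matrix(labels, cells)
    calls = classify_bias(props)
    return {
        "cells": cells, "distances": dist, "de": de,
        "proportions": props.reset_index(), "bias_calls": calls,
    }


def pipeline_determinism(seed: int) -> dict:
    """Two identical-seed end-to-end runs must be byte-identical as CSV."""
    def as_bytes(tables: dict) -> dict:
        out = {}
        for name, t in tables.items():
            buf = _io.StringIO()
            t.to_csv(buf, index=False)
            out[name] = buf.getvalue()
        return out

    a = as_bytes(_small_pipeline_tables(seed))
    b = as_bytes(_small_pipeline_tables(seed))
    identical = set(a) == set(b) and all(a[k] == b[k] for k in a)
    return {"identical": bool(identical), "n_tables": len(a)}
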