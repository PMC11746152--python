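"""Per-cell-type subclustering and genotype-bias classification.

Subclusters of one cell type are found with the same normalize / embed /
cluster pipeline applied to the subset.  The genotype composition of each
subcluster is first normalized by the number of cells each genotype
contributes to the type (so unequal cohort sizes cancel) and then
row-normalized; a subcluster is called biased toward a single genotype when
its normalized share exceeds 1/3 (uniform would be 1/4), or toward an
allowed genotype pair when the combined share exceeds 0.60 (uniform 1/2).
Pairs mixing a plaque-free control with the double mutant (WT with
R47H;5xFAD, or R47H with 5xFAD alone on the other diagonal) are never
called, since they do not correspond to a single driving mutation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, Genotype, GENOTYPE_ORDER
from .preprocess import cluster_cells, embed_cells, normalize_log

__all__ = [
    "subcluster_cell_type", "genotype_proportion_matrix", "classify_bias",
    "regional_subtype_composition", "ALLOWED_PAIRS",
]

#: pairs eligible for a combined-proportion call, in fixed order
ALLOWED_PAIRS = (
    (Genotype.WT, Genotype.R47H),
    (Genotype.FAD, Genotype.R47H_FAD),
    (Genotype.R47H, Genotype.R47H_FAD),
    (Genotype.WT, Genotype.FAD),
)


def subcluster_cell_type(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    cell_type: str,
    seed: int = 0,
    thresholds: AnalysisThresholds | None = None,
    resolution: float = 1.0,
    n_pcs: int = 20,
):
    """Subcluster one cell type; flag subclusters under the 5% size floor.

    Returns ``(labels, excluded)``: a Series of subcluster labels (e.g.
    ``Micro_s0``) indexed by cell_id, and the set of labels excluded for
    holding less than min_subcluster_fraction of the type's cells.
    """
    thresholds = thresholds or AnalysisThresholds()
    sub = cells[cells["cell_type"] == cell_type]
    if len(sub) < 2 * thresholds.min_cells_per_pseudobulk:
        raise ValueError(
            f"only {len(sub)} {cell_type!r} cells; too few to subcluster"
        )
    mat = counts.loc[sub["cell_id"]]
    norm = normalize_log(mat)
    emb = embed_cells(norm, sub, n_pcs=min(n_pcs, mat.shape[1] - 1))
    raw = cluster_cells(emb, seed=seed, resolution=resolution)
    labels = pd.Series(
        [f"{cell_type}_s{k}" for k in raw], index=sub["cell_id"], name="subcluster"
    )
    frac = labels.value_counts(normalize=True)
    excluded = set(frac.index[frac < thresholds.min_subcluster_fraction])
    return labels, excluded


def genotype_proportion_matrix(
    labels: pd.Series,
    cells: pd.DataFrame,
    within_cell_type: bool = True,
) -> pd.DataFrame:
    """Normalized genotype composition of each subcluster.

    r(g, s) = n(g, s) / N(g) with N(g) the total cells the genotype
    contributes (within the analyzed cell type when ``within_cell_type``),
    then each subcluster row is normalized to sum to 1.  Genotypes
    contributing no cells are dropped with a warning.
    """
    geno = cells.set_index("cell_id")["genotype"].reindex(labels.index)
    if within_cell_type:
        totals = geno.value_counts()
    else:
        totals = cells["genotype"].value_counts()
    cols = [g.value for g in GENOTYPE_ORDER if totals.get(g.value, 0) > 0]
    missing = [g.value for g in GENOTYPE_ORDER if totals.get(g.value, 0) == 0]
    if missing:
        warnings.warn(f"genotypes with no cells dropped from proportions: {missing}")
    tab = pd.crosstab(labels, geno).reindex(columns=cols, fill_value=0)
    r = tab / totals.reindex(cols)
    props = r.div(r.sum(axis=1), axis=0)
    props.index.name = "subcluster"
    return props


def classify_bias(
    props: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
    allowed_pairs: tuple = ALLOWED_PAIRS,
) -> pd.DataFrame:
    """Bias call per subcluster from its normalized genotype proportions.

    Single-genotype calls (share > single_genotype_bias) take precedence
    over pair calls (combined share of an allowed pair > pair_bias); ties
    break by the fixed genotype order WT, R47H, FAD, R47H;FAD.  Rows must
    sum to 1.
    """
    thresholds = thresholds or AnalysisThresholds()
    vals = props.to_numpy(dtype=float)
    if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("proportion rows must sum to 1")
    col = {c: j for j, c in enumerate(props.columns)}
    singles = [(g.value, col[g.value]) for g in GENOTYPE_ORDER if g.value in col]
    pair_list = [
        (f"{a.value}+{b.value}", col[a.value], col[b.value])
        for a, b in allowed_pairs
        if a.value in col and b.value in col
    ]
    rows = []
    for sub, row in zip(props.index, vals):
        call, members, prop = "none", "", np.nan
        for name, j in singles:
            if row[j] > thresholds.single_genotype_bias:
                call, members, prop = "single", name, float(row[j])
                break
        if call == "none":
            for name, ja, jb in pair_list:
                s = float(row[ja] + row[jb])
                if s > thresholds.pair_bias:
                    call, members, prop = "pair", name, s
                    break
        rows.append({"subcluster": sub, "call": call,
                     "genotypes": members, "proportion": prop})
    return pd.DataFrame(rows)


def regional_subtype_composition(
    labels: pd.Series,
    cells: pd.DataFrame,
    grouping: dict,
    group_a: tuple = (Genotype.FAD, Genotype.R47H_FAD),
    group_b: tuple = (Genotype.WT, Genotype.R47H),
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region class proportions (e.g. DAM vs homeostatic) with a
    permutation test of the genotype-group difference.

    ``grouping`` maps each non-excluded subcluster label to a class name.
    For every (region, class): the overall class proportion, the per-sample
    proportions averaged within the two genotype groups, and a permutation
    p-value obtained by shuffling sample-level group assignments
    (>= ``n_permutations`` draws, seeded).  Regions without cells of the
    analyzed type are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    meta = cells.set_index("cell_id").loc[labels.index, ["region", "sample_id", "genotype"]]
    cls = labels.map(grouping)
    keep = cls.notna()
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} cells in ungrouped subclusters ignored")
    df = pd.DataFrame({
        "region": meta["region"].to_numpy(),
        "sample_id": meta["sample_id"].to_numpy(),
        "genotype": meta["genotype"].to_numpy(),
        "cls": cls.to_numpy(),
    })[keep.to_numpy()]
    a_set = {g.value for g in group_a}
    b_set = {g.value for g in group_b}
    out = []
    for region, sub in df.groupby("region"):
        if len(sub) == 0:
            warnings.warn(f"region {region!r} has no cells of the analyzed type")
            continue
        samples = sub.groupby("sample_id").agg(genotype=("genotype", "first"))
        in_a = samples["genotype"].isin(a_set).to_numpy()
        in_b = samples["genotype"].isin(b_set).to_numpy()
        for cname in sorted(df["cls"].unique()):
            per_sample = (
                sub.assign(hit=sub["cls"] == cname)
                .groupby("sample_id")["hit"].mean()
                .reindex(samples.index)
                .to_numpy()
            )
            prop = float((sub["cls"] == cname).mean())
            if in_a.sum() and in_b.sum():
                obs = abs(per_sample[in_a].mean() - per_sample[in_b].mean())
                n_a = int(in_a.sum())
                idx_pool = np.flatnonzero(in_a | in_b)
                vals = per_sample[idx_pool]
                more = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(len(vals))
                    stat = abs(vals[perm[:n_a]].mean() - vals[perm[n_a:]].mean())
                    if stat >= obs - 1e-15:
                        more += 1
                p = (more + 1) / (n_permutations + 1)
                mean_a = float(per_sample[in_a].mean())
                mean_b = float(per_sample[in_b].mean())
            else:
                p, mean_a, mean_b = np.nan, np.nan, np.nan
            out.append({
                "region": region, "class": cname, "proportion": prop,
                "mean_group_a": mean_a, "mean_group_b": mean_b, "p_perm": p,
            })
    return pd.DataFrame(out)
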