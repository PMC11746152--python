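"""Pseudobulk construction and the four differential-expression procedures.

Counts are summed per (cell type, sample) stratum — optionally further split
by plaque zone or region — and modeled on the log2(CPM+1) scale with a
linear mixed model carrying a random intercept per imaging batch.  The four
procedures are: pairwise genotype contrasts (five pairs), region vs the
pooled remaining regions within genotype, plaque-proximal vs distal in
amyloid samples, and a single-cell negative-binomial regression on distance
to the nearest plaque.  BH adjustment runs within each (cell type,
comparison) family.  Significance requires |log2FC| >= 0.35 at adjusted
p < 0.05 for the group contrasts (unadjusted p for the region procedure,
flagged nominal; adjusted p alone for the continuous procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from scipy.stats import t as st_t

from ._lmm import fit_random_intercept, moderate_variances
from .config import AnalysisThresholds, Genotype, GENOTYPE_ORDER

__all__ = [
    "Pseudobulk", "Comparison", "build_pseudobulk", "fit_group_de",
    "pairwise_genotype_de", "region_vs_rest_de", "proximal_vs_distal_de",
    "continuous_distance_de", "bh_adjust", "filter_de_results",
    "PAIRWISE_COMPARISONS",
]

DE_COLUMNS = ["cell_type", "comparison", "gene", "log2fc", "se", "p", "p_adj",
              "significant", "model_flag"]

#: the five genotype contrasts, each "a vs b" with log2FC = a relative to b
PAIRWISE_COMPARISONS = (
    (Genotype.FAD, Genotype.WT),
    (Genotype.R47H_FAD, Genotype.R47H),
    (Genotype.R47H, Genotype.WT),
    (Genotype.R47H_FAD, Genotype.FAD),
    (Genotype.R47H_FAD, Genotype.WT),
)


@dataclass
class Comparison:
    """Two disjoint groups of metadata values within one cell type."""

    group_a: tuple
    group_b: tuple
    key: str = "genotype"
    cell_type: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.group_a = tuple(str(v) for v in np.atleast_1d(self.group_a))
        self.group_b = tuple(str(v) for v in np.atleast_1d(self.group_b))
        if not self.group_a or not self.group_b:
            raise ValueError("comparison groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("comparison groups must be disjoint")
        if not self.label:
            self.label = "+".join(self.group_a) + "_vs_" + "+".join(self.group_b)


@dataclass
class Pseudobulk:
    """Summed counts per stratum plus stratum metadata.

    ``counts``: strata x genes integer frame; ``meta``: aligned frame with
    cell_type, sample_id, genotype, batch_id, n_cells and any extra
    stratification keys; ``genes_tested``: per cell type, the genes passing
    the 15% detection filter.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    genes_tested: dict = field(default_factory=dict)


def build_pseudobulk(
    counts: pd.DataFrame,
    cells: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
    extra_keys: tuple = (),
) -> Pseudobulk:
    """Sum counts per (cell_type, sample_id, *extra_keys) stratum.

    Strata with fewer than min_cells_per_pseudobulk cells are dropped.  Per
    cell type, genes detected (count > 0) in fewer than
    min_gene_cell_fraction of that type's cells are excluded from testing.
    """
    thresholds = thresholds or AnalysisThresholds()
    keys = ["cell_type", "sample_id", *extra_keys]
    typed = cells[cells["cell_type"].astype(str) != ""].reset_index(drop=True)
    if typed.empty:
        raise ValueError("no typed cells for pseudobulk construction")
    mat = counts.loc[typed["cell_id"]]

    genes_tested = {}
    for ct, sub in typed.groupby("cell_type"):
        detected = (mat.loc[sub["cell_id"]] > 0).mean(axis=0)
        genes_tested[ct] = list(detected.index[detected >= thresholds.min_gene_cell_fraction])

    groups = typed.groupby(keys, sort=True)
    rows, meta_rows = [], []
    dropped = []
    for key_vals, sub in groups:
        if len(sub) < thresholds.min_cells_per_pseudobulk:
            dropped.append(key_vals)
            continue
        rows.append(mat.loc[sub["cell_id"]].sum(axis=0))
        m = dict(zip(keys, np.atleast_1d(key_vals)))
        m["genotype"] = str(sub["genotype"].iloc[0])
        m["batch_id"] = str(sub["batch_id"].iloc[0])
        m["n_cells"] = int(len(sub))
        meta_rows.append(m)
    if not rows:
        raise ValueError(
            f"no pseudobulk stratum reaches {thresholds.min_cells_per_pseudobulk} "
            f"cells; failed strata: {dropped}"
        )
    pb_counts = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame(meta_rows)
    return Pseudobulk(counts=pb_counts, meta=meta, genes_tested=genes_tested)


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors per pseudobulk row.

    Composition-robust depth estimate: a handful of strongly regulated
    genes can carry a sizable share of a 300-gene library, and dividing by
    the raw total would shift every other gene in the opposite direction.
    Falls back to total counts when too few genes are positive everywhere.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    lib[lib == 0] = 1.0
    allpos = (counts > 0).all(axis=0)
    if allpos.sum() < 10:
        s = lib
    else:
        sub = counts[:, allpos]
        ref = np.exp(np.mean(np.log(sub), axis=0))
        s = np.median(sub / ref, axis=1)
        s[s <= 0] = 1.0
    return s / np.exp(np.mean(np.log(s)))


def _log2cpm(counts: np.ndarray, sf_cols=None) -> np.ndarray:
    """log2(1 + normalized counts) on a CPM-like scale.

    Depth uses median-of-ratios size factors, optionally estimated on a
    column subset (``sf_cols``); the common rescaling constant puts values
    on the counts-per-million scale of the mean library so the pseudocount
    behaves like it would for CPM.
    """
    counts = np.asarray(counts, dtype=float)
    s = _size_factors(counts if sf_cols is None else counts[:, sf_cols])
    q = counts / s[:, None]
    scale = 1e6 / max(np.median(q.sum(axis=1)), 1.0)
    return np.log2(1.0 + q * scale)


def fit_group_de(
    pb: Pseudobulk,
    comparison: Comparison,
    thresholds: AnalysisThresholds | None = None,
    adjusted_significance: bool = True,
) -> pd.DataFrame:
    """Mixed-model contrast of two pseudobulk groups for one cell type.

    Per gene: log2(CPM+1) ~ group with a random intercept per batch, fitted
    by REML; the group coefficient is the log2 fold change (a vs b) and is
    Wald-tested against a t reference.  Residual variances are moderated
    across genes with an empirical-Bayes inverse-chi2 prior (limma-style)
    before the test — with a handful of pseudobulk replicates the raw
    per-gene variances are noisy and the occasional underestimate would
    yield spuriously tiny standard errors; the prior degrees of freedom add
    to the residual ones.  Falls back to ordinary least squares (flagged
    ``ols``) when only one batch is present.  BH adjustment across the
    tested genes.
    """
    thresholds = thresholds or AnalysisThresholds()
    meta = pb.meta
    sel = meta["cell_type"] == comparison.cell_type if comparison.cell_type else np.ones(len(meta), bool)
    vals = meta[comparison.key].astype(str)
    in_a = sel & vals.isin(comparison.group_a)
    in_b = sel & vals.isin(comparison.group_b)
    for name, m in (("group_a", in_a), ("group_b", in_b)):
        if m.sum() < 2:
            raise ValueError(
                f"{name} ({comparison.label}) has {int(m.sum())} pseudobulk "
                "replicates; need at least 2"
            )
    use = in_a | in_b
    sub_counts = pb.counts.loc[use.to_numpy()].to_numpy(dtype=float)
    sub_meta = meta.loc[use.to_numpy()]
    all_genes = list(pb.counts.columns)
    genes = pb.genes_tested.get(comparison.cell_type, all_genes)
    col_of = {g: j for j, g in enumerate(all_genes)}
    tested_cols = [col_of[g] for g in genes]

    X = np.column_stack([
        np.ones(len(sub_meta)),
        in_a.loc[use].to_numpy(dtype=float),
    ])
    batches = sub_meta["batch_id"].to_numpy()
    single_batch = len(np.unique(batches)) < 2
    n_obs, n_par = X.shape
    df_resid = n_obs - n_par

    def run_pass(sf_cols) -> pd.DataFrame:
        Y = _log2cpm(sub_counts, sf_cols=sf_cols)[:, tested_cols]
        rows, sigma2, c_factor = [], [], []
        for j, gene in enumerate(genes):
            fit = fit_random_intercept(Y[:, j], X, batches)
            # floor keeps degenerate (near-perfect-fit) genes well-defined
            sigma2.append(max(fit["sigma2"], 1e-12))
            c_factor.append(fit["cov_unit"][1])
            rows.append({
                "cell_type": comparison.cell_type,
                "comparison": comparison.label,
                "gene": gene,
                "log2fc": float(fit["beta"][1]),
                "model_flag": "ols" if single_batch else fit["method"],
            })
        out = pd.DataFrame(rows)
        s2_post, d0 = moderate_variances(np.asarray(sigma2), df_resid)
        se = np.sqrt(s2_post * np.asarray(c_factor))
        lfc = out["log2fc"].to_numpy()
        stat = np.divide(lfc, se, out=np.zeros_like(lfc), where=se > 0)
        df_total = df_resid + (d0 if np.isfinite(d0) else 1e6)
        out["se"] = se
        out["p"] = 2.0 * st_t.sf(np.abs(stat), df=df_total)
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        p_used = out["p_adj"] if adjusted_significance else out["p"]
        out["significant"] = (
            (p_used < thresholds.alpha_fdr)
            & (out["log2fc"].abs() >= thresholds.abs_log2fc)
        )
        if not adjusted_significance:
            out["model_flag"] = out["model_flag"] + "+nominal_p"
        return out[DE_COLUMNS]

    # two passes: regulated genes can carry enough of a 300-gene library to
    # drag the size factors along the contrast, so the depth estimate is
    # recomputed without first-pass hits and the model refitted
    first = run_pass(None)
    hits = set(first.loc[first["significant"], "gene"])
    if not hits:
        return first
    stable = [j for j, g in enumerate(all_genes) if g not in hits]
    if len(stable) < len(all_genes) // 2:
        return first
    return run_pass(stable)


def pairwise_genotype_de(
    pb: Pseudobulk,
    thresholds: AnalysisThresholds | None = None,
    cell_types: list | None = None,
) -> pd.DataFrame:
    """The five genotype contrasts for every cell type in the pseudobulk.

    Comparisons lacking two replicates per group are skipped with a warning.
    """
    thresholds = thresholds or AnalysisThresholds()
    cell_types = cell_types or sorted(pb.meta["cell_type"].unique())
    out = []
    for ct in cell_types:
        for a, b in PAIRWISE_COMPARISONS:
            comp = Comparison((a.value,), (b.value,), key="genotype", cell_type=ct)
            try:
                out.append(fit_group_de(pb, comp, thresholds))
            except ValueError as e:
                warnings.warn(f"skipping {ct} {comp.label}: {e}")
    if not out:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.concat(out, ignore_index=True)


def region_vs_rest_de(
    pb: Pseudobulk,
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Each region vs the pooled other regions, within genotype and cell type.

    The pseudobulk must be stratified by region (``extra_keys=('region',)``).
    Significance uses the unadjusted p-value with the fold-change cutoff,
    flagged as nominal in ``model_flag``; adjusted p-values are still
    reported.
    """
    thresholds = thresholds or AnalysisThresholds()
    if "region" not in pb.meta.columns:
        raise ValueError("pseudobulk is not stratified by region")
    out = []
    for ct in sorted(pb.meta["cell_type"].unique()):
        for geno in sorted(pb.meta.loc[pb.meta["cell_type"] == ct, "genotype"].unique()):
            sub = pb.meta[(pb.meta["cell_type"] == ct) & (pb.meta["genotype"] == geno)]
            regions = sorted(sub["region"].unique())
            if len(regions) < 2:
                warnings.warn(
                    f"skipping {ct}/{geno}: only {len(regions)} region(s) with "
                    "surviving pseudobulk rows"
                )
                continue
            geno_rows = pb.meta["genotype"] == geno
            pb_g = Pseudobulk(pb.counts.loc[geno_rows.to_numpy()].reset_index(drop=True),
                              pb.meta.loc[geno_rows.to_numpy()].reset_index(drop=True),
                              pb.genes_tested)
            for region in regions:
                rest = tuple(r for r in regions if r != region)
                comp = Comparison((region,), rest, key="region", cell_type=ct,
                                  label=f"{region}_vs_rest:{geno}")
                try:
                    out.append(fit_group_de(pb_g, comp, thresholds,
                                            adjusted_significance=False))
                except ValueError as e:
                    warnings.warn(f"skipping {ct} {comp.label}: {e}")
    if not out:
        raise ValueError("no (cell type, genotype) block has two or more "
                         "regions with surviving pseudobulk rows")
    return pd.concat(out, ignore_index=True)


def proximal_vs_distal_de(
    pb: Pseudobulk,
    thresholds: AnalysisThresholds | None = None,
    cell_types: list | None = None,
) -> pd.DataFrame:
    """Plaque-proximal vs distal pseudobulk contrast in amyloid samples.

    The pseudobulk must be stratified by zone (``extra_keys=('zone',)``) and
    built from amyloid-genotype cells with a zone column; cells beyond the
    distal radius are excluded by construction of the zones.
    """
    thresholds = thresholds or AnalysisThresholds()
    if "zone" not in pb.meta.columns:
        raise ValueError("pseudobulk is not stratified by zone")
    amyloid = pb.meta["genotype"].map(lambda g: Genotype.parse(g).amyloid)
    pb_a = Pseudobulk(pb.counts.loc[amyloid.to_numpy()].reset_index(drop=True),
                      pb.meta.loc[amyloid.to_numpy()].reset_index(drop=True),
                      pb.genes_tested)
    out = []
    cell_types = cell_types or sorted(pb_a.meta["cell_type"].unique())
    for ct in cell_types:
        zones = set(pb_a.meta.loc[pb_a.meta["cell_type"] == ct, "zone"])
        for z in ("proximal", "distal"):
            if z not in zones:
                raise ValueError(f"zone {z!r} absent for cell type {ct!r}")
        comp = Comparison(("proximal",), ("distal",), key="zone", cell_type=ct,
                          label="proximal_vs_distal")
        out.append(fit_group_de(pb_a, comp, thresholds))
    return pd.concat(out, ignore_index=True)


def continuous_distance_de(
    counts: pd.DataFrame,
    cells: pd.DataFrame,
    cell_type: str,
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Single-cell NB regression of expression on distance to plaque.

    Restricted to amyloid-genotype cells of the given type within the
    proximal radius.  Per gene: counts ~ NB(mu, alpha) with log mu =
    intercept + beta * distance + log(size factor); the dispersion comes
    from a method-of-moments estimate (floored at 1e-8) and beta is
    Wald-tested.  The reported effect is the per-um log2 change beta / ln 2.
    Genes failing the detection filter among the analyzed cells are not
    tested.  Significance uses the adjusted p-value alone.

    Size factors are estimated robustly in two passes: cell library size
    over its median first, then — because strongly distance-responsive
    genes can be a large fraction of the library and would drag the size
    factor along the distance axis, biasing every other gene — the library
    is recomputed excluding genes called significant in the first pass and
    the model is refitted.
    """
    thresholds = thresholds or AnalysisThresholds()
    if "distance_to_nearest_plaque" not in cells.columns:
        raise ValueError("cells need a distance_to_nearest_plaque column")
    amyloid = cells["genotype"].map(lambda g: Genotype.parse(g).amyloid)
    sel = (
        amyloid
        & (cells["cell_type"] == cell_type)
        & (cells["distance_to_nearest_plaque"] < thresholds.proximal_radius)
    )
    sub = cells[sel]
    if len(sub) < 30:
        raise ValueError(
            f"only {len(sub)} {cell_type} cells within the proximal radius; need >= 30"
        )
    mat = counts.loc[sub["cell_id"]]
    detected = (mat > 0).mean(axis=0)
    genes = list(detected.index[detected >= thresholds.min_gene_cell_fraction])
    d = sub["distance_to_nearest_plaque"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d)), d])
    ln2 = np.log(2.0)

    def run_pass(size: np.ndarray) -> pd.DataFrame:
        offset = np.log(size)
        rows = []
        for gene in genes:
            y = mat[gene].to_numpy(dtype=float)
            q = y / size
            m, v = q.mean(), q.var(ddof=1)
            alpha = max((v - m) / m**2 if m > 0 else 0.0, 1e-8)
            try:
                fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                             offset=offset).fit()
                beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
                flag = "nb_glm"
            except Exception:
                beta, se, p, flag = 0.0, np.nan, 1.0, "failed"
            rows.append({
                "cell_type": cell_type,
                "comparison": "distance_continuous",
                "gene": gene,
                "log2fc": float(beta / ln2),  # per-um log2 change
                "se": float(se / ln2) if np.isfinite(se) else np.nan,
                "p": float(p),
                "model_flag": flag,
            })
        out = pd.DataFrame(rows)
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < thresholds.alpha_fdr
        return out[DE_COLUMNS]

    lib = mat[genes].sum(axis=1).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    first = run_pass(lib / np.median(lib))
    hits = set(first.loc[first["significant"], "gene"])
    if not hits:
        return first
    stable = [g for g in genes if g not in hits]
    lib2 = mat[stable].sum(axis=1).to_numpy(dtype=float)
    if len(stable) < len(genes) // 2 or np.median(lib2) <= 0 or (lib2 == 0).any():
        return first
    return run_pass(lib2 / np.median(lib2))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_de_results(
    results: pd.DataFrame,
    atlas: pd.DataFrame | None,
    mode: str,
    exclusion_genes=(),
    glial_types: tuple = ("Micro", "Astro", "Oligo", "OPC"),
) -> pd.DataFrame:
    """Post-hoc DE filters against atlas annotation and exclusion lists.

    ``mode='glial'`` keeps only genes annotated as expressed in the result
    row's cell type (spillover from neighbouring cells otherwise produces
    spurious calls).  ``mode='neuronal'`` removes glial-exclusive markers
    and DAM/DAA program genes.  Genes on ``exclusion_genes`` (e.g. an
    anterior-posterior gradient list) are removed in both modes.  The
    returned table preserves every input row and marks removals in a
    ``filtered_reason`` column; downstream consumers subset to rows with an
    empty reason.
    """
    if mode not in ("glial", "neuronal"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if mode == "glial" and atlas is None:
        raise ValueError("glial mode requires an atlas annotation")
    out = results.copy()
    out["filtered_reason"] = ""
    excl = set(exclusion_genes)
    if excl.intersection(out["gene"]):
        out.loc[out["gene"].isin(excl), "filtered_reason"] = "exclusion_list"
    if mode == "glial":
        expressed = {
            r["gene"]: set(str(r["expressed_in"]).split("|"))
            for _, r in atlas.iterrows()
        }
        not_expr = [
            reason == "" and ct not in expressed.get(g, set())
            for g, ct, reason in zip(out["gene"], out["cell_type"], out["filtered_reason"])
        ]
        out.loc[not_expr, "filtered_reason"] = "not_expressed_in_type"
    else:
        bad = set()
        if atlas is not None:
            bad |= set(atlas.loc[atlas["exclusive_to"].isin(glial_types), "gene"])
            for col in ("dam_marker", "daa_marker"):
                if col in atlas.columns:
                    bad |= set(atlas.loc[atlas[col].astype(bool), "gene"])
        hit = (out["filtered_reason"] == "") & out["gene"].isin(bad)
        out.loc[hit, "filtered_reason"] = "glial_or_disease_marker"
    return out
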