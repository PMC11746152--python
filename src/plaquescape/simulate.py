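"""Synthetic MERFISH-like coronal sections with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: four genotypes (WT, Trem2-R47H, 5xFAD, R47H;5xFAD) imaged in
batches with unbalanced genotype composition, a ~300-gene panel, polygonal
regions with region-dependent cell-type densities, plaque point fields
present only in amyloid genotypes with region- and genotype-dependent
intensity, negative-binomial counts with library-size variation, and three
kinds of planted signal: genotype effects, distance-to-plaque decay effects
(DAM/DAA-like programs), and genotype-biased latent subpopulations.  Every
planted assignment is recorded in a :class:`SimTruth` for recovery testing.

All randomness flows from one root seed: per-section generators are spawned
from ``SeedSequence([root_seed, section_index])`` and per-batch gene effects
from ``SeedSequence([root_seed, crc32(batch)])``, so a cohort is bit
reproducible and batch effects are shared by sections of the same batch.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from shapely.geometry import box

from .config import AnalysisThresholds, Genotype
from .io import Dataset
from .spatial import RegionMap

__all__ = [
    "SimConfig", "SimTruth", "GenotypeEffect", "DistanceEffect", "RegionEffect",
    "BiasedSubpopulation", "simulate_section", "simulate_cohort",
    "render_dapi_image", "build_atlas", "gene_panel", "random_fov_tables",
]

CELL_TYPES = ("ExN", "InN", "Astro", "Micro", "Oligo")

#: marker genes expressed per cell type (Apoe is shared Micro/Astro)
TYPE_MARKERS = {
    "Micro": ["P2ry12", "Tmem119", "Cx3cr1", "Hexb",
              "Itgax", "Cst7", "Csf1", "Ccl6", "Cd74"],
    "Astro": ["Slc1a2", "Aqp4", "Gja1", "Gfap", "C4b", "Clu"],
    "Oligo": ["Plp1", "Mbp", "Ptgds", "Sox10"],
    "ExN": ["Slc17a7", "Fos", "Bdnf", "Ntrk2", "Sulf2", "Cplx1", "Cdh12", "Wfs1"],
    "InN": ["Gad1", "Gad2", "Pvalb", "Sst"],
}
SHARED_MARKERS = {"Apoe": ("Micro", "Astro")}
DAM_MARKERS = ("Itgax", "Cst7", "Csf1", "Ccl6", "Cd74", "Apoe")
DAA_MARKERS = ("Gfap", "C4b", "Clu")


def gene_panel(n_genes: int = 300) -> list[str]:
    """Panel gene names: the named markers followed by filler genes."""
    named = [g for ms in TYPE_MARKERS.values() for g in ms] + list(SHARED_MARKERS)
    if n_genes < len(named):
        raise ValueError(f"n_genes must be >= {len(named)}")
    return named + [f"G{i:04d}" for i in range(n_genes - len(named))]


def default_region_layout() -> RegionMap:
    """Four rectangular regions standing for the major structures."""
    return RegionMap({
        "cortex": box(0, 1500, 3000, 3000),
        "corpus_callosum": box(0, 1200, 3000, 1500),
        "hippocampus": box(0, 0, 1500, 1200),
        "thalamus": box(1500, 0, 3000, 1200),
    })


def default_cell_type_densities() -> dict:
    """cells/um^2 per (region, cell type)."""
    return {
        "cortex":          {"ExN": 4.0e-4, "InN": 0.8e-4, "Astro": 1.2e-4, "Micro": 0.8e-4, "Oligo": 0.4e-4},
        "corpus_callosum": {"ExN": 0.2e-4, "InN": 0.1e-4, "Astro": 1.5e-4, "Micro": 1.0e-4, "Oligo": 4.0e-4},
        "hippocampus":     {"ExN": 4.0e-4, "InN": 0.6e-4, "Astro": 1.2e-4, "Micro": 0.8e-4, "Oligo": 0.4e-4},
        "thalamus":        {"ExN": 3.0e-4, "InN": 0.6e-4, "Astro": 1.2e-4, "Micro": 0.8e-4, "Oligo": 1.0e-4},
    }


def default_plaque_intensity() -> dict:
    """plaques/um^2 per (region, genotype); nonzero only for amyloid genotypes.

    Values follow the per-region plaque densities of 12-month amyloid-model
    brains: highest in the corpus callosum, then cortex/hippocampus, lowest
    subcortically, with the R47H;5xFAD cross carrying a lower burden than
    5xFAD outside the CC.
    """
    fad = {"corpus_callosum": 5.61e-5, "cortex": 3.92e-5,
           "hippocampus": 2.89e-5, "thalamus": 2.71e-5}
    cross = {"corpus_callosum": 6.23e-5, "cortex": 2.08e-5,
             "hippocampus": 2.04e-5, "thalamus": 0.32e-5}
    out: dict = {}
    for region in fad:
        out[region] = {
            Genotype.WT: 0.0, Genotype.R47H: 0.0,
            Genotype.FAD: fad[region], Genotype.R47H_FAD: cross[region],
        }
    return out


@dataclass(frozen=True)
class GenotypeEffect:
    """Planted log2 shift of one gene in one cell type for given genotypes."""
    gene: str
    cell_type: str
    genotypes: tuple
    log2fc: float


@dataclass(frozen=True)
class DistanceEffect:
    """Planted distance-to-plaque effect on one gene in one cell type.

    ``kind='exp'``: log2 mean gains amplitude_log2 * exp(-d / decay_um).
    ``kind='linear'``: log2 mean gains amplitude_log2 * min(d, clamp_um),
    i.e. amplitude_log2 is a per-um log2 slope (clamped far from plaques to
    keep means bounded).  Cells in plaque-free sections get no effect.
    """
    gene: str
    cell_type: str
    amplitude_log2: float
    decay_um: float = 50.0
    kind: str = "exp"
    clamp_um: float = 500.0


@dataclass(frozen=True)
class RegionEffect:
    """Planted log2 shift of one gene in one cell type within one region."""
    gene: str
    cell_type: str
    region: str
    log2fc: float


@dataclass(frozen=True)
class BiasedSubpopulation:
    """A latent subtype of one cell type enriched in specific genotypes.

    ``marker_genes`` gain ``shift_log2``; ``down_genes`` lose it.  Real
    activation states are bidirectional (e.g. disease-associated microglia
    gain Itgax/Cst7 while losing P2ry12/Tmem119), which also keeps the
    subtype's library size close to its parent's.
    """
    cell_type: str
    genotypes: tuple
    marker_genes: tuple
    fraction: float
    shift_log2: float = 2.0
    down_genes: tuple = ()
    name: str = ""


def default_genotype_effects() -> list[GenotypeEffect]:
    amyloid = (Genotype.FAD, Genotype.R47H_FAD)
    r47h = (Genotype.R47H, Genotype.R47H_FAD)
    eff = []
    for g, fc in [("Itgax", 3.3), ("Cst7", 2.5), ("Csf1", 1.5),
                  ("Ccl6", 1.5), ("Cd74", 1.8), ("Apoe", 1.0)]:
        eff.append(GenotypeEffect(g, "Micro", amyloid, fc))
    for g in ("P2ry12", "Tmem119"):
        eff.append(GenotypeEffect(g, "Micro", amyloid, -0.5))
    for g, fc in [("Gfap", 1.5), ("C4b", 1.2), ("Clu", 0.8)]:
        eff.append(GenotypeEffect(g, "Astro", amyloid, fc))
    for g, fc in [("Ntrk2", 0.8), ("Bdnf", 0.6)]:
        eff.append(GenotypeEffect(g, "ExN", r47h, fc))
    eff.append(GenotypeEffect("Fos", "ExN",
                              (Genotype.R47H, Genotype.FAD, Genotype.R47H_FAD), -0.7))
    return eff


def default_distance_effects() -> list[DistanceEffect]:
    eff = [DistanceEffect(g, "Micro", a) for g, a in
           [("Itgax", 1.5), ("Cst7", 1.2), ("Csf1", 1.0), ("Apoe", 0.8)]]
    eff.append(DistanceEffect("P2ry12", "Micro", -0.8))
    eff += [DistanceEffect("Gfap", "Astro", 1.0), DistanceEffect("C4b", "Astro", 0.8)]
    return eff


def default_biased_subpopulations() -> list[BiasedSubpopulation]:
    return [
        BiasedSubpopulation("Micro", (Genotype.FAD, Genotype.R47H_FAD),
                            ("Itgax", "Cst7", "Csf1"), 0.5, 2.0,
                            down_genes=("P2ry12", "Tmem119"), name="DAM"),
        BiasedSubpopulation("ExN", (Genotype.WT, Genotype.R47H),
                            ("Sulf2", "Cplx1"), 0.3, 2.0, name="wt_enriched"),
    ]


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_genes: int = 300
    region_layout: RegionMap = field(default_factory=default_region_layout)
    cell_type_densities: dict = field(default_factory=default_cell_type_densities)
    genotype_plaque_intensity: dict = field(default_factory=default_plaque_intensity)
    #: log-normal parameters of plaque area in um^2 (mean/sigma of ln area)
    plaque_area_log_mu: float = float(np.log(150.0))
    plaque_area_log_sigma: float = 0.6
    nb_dispersion: float = 0.3  # var = mu + alpha mu^2
    library_size_lognormal_sigma: float = 0.35
    batch_effect_sigma: float = 0.15  # per-(batch, gene) log2 sd
    genotype_effects: list = field(default_factory=default_genotype_effects)
    distance_effects: list = field(default_factory=default_distance_effects)
    region_effects: list = field(default_factory=list)
    biased_subpopulations: list = field(default_factory=default_biased_subpopulations)
    microglia_plaque_attraction: float = 2.0
    volume_exceed_fraction: float = 0.02  # fraction of cells failing the QC cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        for region, dd in self.cell_type_densities.items():
            for ct, v in dd.items():
                if v < 0:
                    raise ValueError(f"negative density for ({region}, {ct})")
        for region, dd in self.genotype_plaque_intensity.items():
            for g, v in dd.items():
                if v < 0:
                    raise ValueError(f"negative plaque intensity for ({region}, {g})")
        genes = set(self.genes)
        for e in self.genotype_effects + self.distance_effects + self.region_effects:
            if e.gene not in genes:
                raise ValueError(f"effect references unknown gene {e.gene!r}")
            if e.cell_type not in self.cell_types:
                raise ValueError(f"effect references unknown cell type {e.cell_type!r}")
        for s in self.biased_subpopulations:
            if s.cell_type not in self.cell_types:
                raise ValueError(f"subpopulation references unknown cell type {s.cell_type!r}")
            for g in tuple(s.marker_genes) + tuple(s.down_genes):
                if g not in genes:
                    raise ValueError(f"subpopulation references unknown gene {g!r}")

    @property
    def genes(self) -> list[str]:
        return gene_panel(self.n_genes)

    @property
    def cell_types(self) -> tuple:
        types = set()
        for dd in self.cell_type_densities.values():
            types.update(dd)
        return tuple(t for t in CELL_TYPES if t in types) + tuple(sorted(types - set(CELL_TYPES)))

    def baseline_log2(self) -> pd.DataFrame:
        """Per-(cell type, gene) baseline log2 mean counts.

        Deterministic: background means are drawn from a fixed internal
        stream so the panel baseline does not depend on the run seed.
        """
        genes = self.genes
        rng = np.random.default_rng(20240805)
        background = np.exp(rng.normal(np.log(0.3), 0.8, size=len(genes)))
        base = {}
        for ct in self.cell_types:
            mult = np.exp(rng.normal(0.0, 0.2, size=len(genes)))
            base[ct] = background * mult
        df = pd.DataFrame(base, index=genes).T
        for ct, markers in TYPE_MARKERS.items():
            if ct not in df.index:
                continue
            for g in markers:
                df.loc[:, g] = 0.03
                df.loc[ct, g] = 6.0
        for g, cts in SHARED_MARKERS.items():
            df.loc[:, g] = 0.03
            for ct in cts:
                if ct in df.index:
                    df.loc[ct, g] = 4.0
        return np.log2(df)


@dataclass
class SimTruth:
    """Ground truth of one simulated section or cohort."""

    genotype_effects: list
    distance_effects: list
    subpopulations: list
    cell_truth: pd.DataFrame  # cell_id, sample_id, cell_type, region, subpopulation
    plaque_truth: pd.DataFrame

    @staticmethod
    def concat(parts: list["SimTruth"]) -> "SimTruth":
        plq = [p.plaque_truth for p in parts if len(p.plaque_truth)]
        return SimTruth(
            genotype_effects=parts[0].genotype_effects,
            distance_effects=parts[0].distance_effects,
            subpopulations=parts[0].subpopulations,
            cell_truth=pd.concat([p.cell_truth for p in parts], ignore_index=True),
            plaque_truth=(pd.concat(plq, ignore_index=True) if plq
                          else parts[0].plaque_truth),
        )


def _batch_effect_log2(config: SimConfig, batch) -> np.ndarray:
    """Per-gene multiplicative batch effect (log2), shared across a batch."""
    if config.batch_effect_sigma == 0:
        return np.zeros(config.n_genes)
    key = zlib.crc32(str(batch).encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, key, 7]))
    return rng.normal(0.0, config.batch_effect_sigma, size=config.n_genes)


def _sample_in_polygon(rng, poly, n: int) -> np.ndarray:
    """Uniform points in a polygon by rejection from its bounding box."""
    x0, y0, x1, y1 = poly.bounds
    out = np.empty((0, 2))
    from shapely import contains_xy
    while len(out) < n:
        m = max(int((n - len(out)) * 2.5), 16)
        pts = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
        ok = contains_xy(poly, pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[ok]])
    return out[:n]


def _draw_plaques(rng, config: SimConfig, genotype: Genotype,
                  sample_id: str, thresholds: AnalysisThresholds) -> pd.DataFrame:
    rows = []
    k = 0
    for region, poly in config.region_layout.polygons.items():
        dd = config.genotype_plaque_intensity.get(region)
        if dd is None or genotype not in dd:
            raise ValueError(f"no plaque intensity entry for ({region}, {genotype})")
        lam = dd[genotype] * poly.area
        n = rng.poisson(lam) if genotype.amyloid and lam > 0 else 0
        if n == 0:
            continue
        xy = _sample_in_polygon(rng, poly, n)
        area = np.exp(rng.normal(config.plaque_area_log_mu,
                                 config.plaque_area_log_sigma, n))
        for i in range(n):
            k += 1
            rows.append({
                "plaque_id": f"{sample_id}_p{k:04d}",
                "x": xy[i, 0], "y": xy[i, 1],
                "area": area[i],
                "equivalent_diameter": 2.0 * np.sqrt(area[i] / np.pi),
                "volume": area[i] * thresholds.section_thickness,
                "sample_id": sample_id,
                "region": region,
            })
    cols = ["plaque_id", "x", "y", "area", "equivalent_diameter",
            "volume", "sample_id", "region"]
    return pd.DataFrame(rows, columns=cols)


def _draw_cells(rng, config: SimConfig, genotype: Genotype,
                plaque_xy: np.ndarray, thresholds: AnalysisThresholds):
    """Cell positions per region/type (inhomogeneous Poisson by thinning).

    Microglia intensity is multiplied by ``microglia_plaque_attraction``
    within proximal_radius of a plaque centroid; implemented by simulating at
    the ceiling intensity and thinning with probability lambda(x)/lambda_max.
    """
    tree = cKDTree(plaque_xy) if len(plaque_xy) else None
    attract = config.microglia_plaque_attraction
    xs, types, regions = [], [], []
    for region, poly in config.region_layout.polygons.items():
        for ct, dens in config.cell_type_densities.get(region, {}).items():
            if dens <= 0:
                continue
            boosted = ct == "Micro" and tree is not None and attract != 1.0
            lam_max = dens * max(attract, 1.0) if boosted else dens
            n = rng.poisson(lam_max * poly.area)
            if n == 0:
                continue
            xy = _sample_in_polygon(rng, poly, n)
            if boosted:
                d, _ = tree.query(xy, k=1)
                near = d < thresholds.proximal_radius
                lam = np.where(near, dens * attract, dens)
                keep = rng.uniform(size=n) < lam / lam_max
                xy = xy[keep]
            xs.append(xy)
            types += [ct] * len(xy)
            regions += [region] * len(xy)
    xy = np.vstack(xs) if xs else np.empty((0, 2))
    return xy, np.array(types, dtype=object), np.array(regions, dtype=object)


def simulate_section(
    config: SimConfig,
    genotype: Genotype,
    batch,
    seed,
    sample_id: str = "s00",
    thresholds: AnalysisThresholds | None = None,
):
    """Simulate one coronal section.

    Returns ``(cells, counts, plaques, regions, truth)``.  ``seed`` may be an
    int or a ``numpy.random.SeedSequence``.
    """
    thresholds = thresholds or AnalysisThresholds()
    rng = np.random.default_rng(seed)
    genes = config.genes
    n_genes = len(genes)

    plaques = _draw_plaques(rng, config, genotype, sample_id, thresholds)
    plaque_xy = plaques[["x", "y"]].to_numpy(dtype=float)
    xy, types, regions = _draw_cells(rng, config, genotype, plaque_xy, thresholds)
    n = len(xy)

    # latent subpopulations (enriched genotypes only)
    subpop = np.full(n, "", dtype=object)
    for i_s, s in enumerate(config.biased_subpopulations):
        if genotype not in s.genotypes:
            continue
        mask = types == s.cell_type
        pick = mask & (rng.uniform(size=n) < s.fraction)
        subpop[pick] = s.name or f"{s.cell_type}_sub{i_s}"

    # per-cell log2 mean matrix
    baseline = config.baseline_log2()
    log2mu = np.empty((n, n_genes))
    type_order = list(baseline.index)
    base_arr = baseline.to_numpy()
    for i_t, ct in enumerate(type_order):
        log2mu[types == ct] = base_arr[i_t]
    log2mu += _batch_effect_log2(config, batch)[None, :]

    gi = {g: i for i, g in enumerate(genes)}
    for e in config.genotype_effects:
        if genotype in e.genotypes:
            log2mu[types == e.cell_type, gi[e.gene]] += e.log2fc
    for e in config.region_effects:
        mask = (types == e.cell_type) & (regions == e.region)
        log2mu[mask, gi[e.gene]] += e.log2fc
    if len(plaque_xy):
        d, _ = cKDTree(plaque_xy).query(xy, k=1)
        for e in config.distance_effects:
            mask = types == e.cell_type
            if e.kind == "exp":
                contrib = e.amplitude_log2 * np.exp(-d[mask] / e.decay_um)
            elif e.kind == "linear":
                contrib = e.amplitude_log2 * np.minimum(d[mask], e.clamp_um)
            else:
                raise ValueError(f"unknown distance effect kind {e.kind!r}")
            log2mu[mask, gi[e.gene]] += contrib
    for i_s, s in enumerate(config.biased_subpopulations):
        name = s.name or f"{s.cell_type}_sub{i_s}"
        mask = subpop == name
        for g in s.marker_genes:
            log2mu[mask, gi[g]] += s.shift_log2
        for g in s.down_genes:
            log2mu[mask, gi[g]] -= s.shift_log2

    lib = np.exp(rng.normal(0.0, config.library_size_lognormal_sigma, n))
    mu = (2.0 ** log2mu) * lib[:, None]
    alpha = config.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(1.0 / alpha, alpha * mu)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    # volumes: a configurable fraction exceeds the QC cutoff by construction
    vol = np.exp(rng.normal(np.log(700.0), 0.35, n))
    vol = np.minimum(vol, thresholds.max_cell_volume * 0.97)
    n_over = rng.binomial(n, config.volume_exceed_fraction)
    if n_over:
        over = rng.choice(n, n_over, replace=False)
        vol[over] = rng.uniform(thresholds.max_cell_volume * 1.03,
                                thresholds.max_cell_volume * 1.5, n_over)

    cell_ids = np.array([f"{sample_id}_c{i:05d}" for i in range(n)])
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "x": xy[:, 0], "y": xy[:, 1],
        "volume": vol,
        "total_transcripts": counts.sum(axis=1),
        "sample_id": sample_id,
        "batch_id": str(batch),
        "genotype": genotype.value,
        "cell_type": types.astype(str),
        "subcluster": "",
        "region": regions.astype(str),
    })
    counts_df = pd.DataFrame(counts, index=cell_ids, columns=genes)
    truth = SimTruth(
        genotype_effects=list(config.genotype_effects),
        distance_effects=list(config.distance_effects),
        subpopulations=list(config.biased_subpopulations),
        cell_truth=pd.DataFrame({
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "cell_type": types.astype(str),
            "region": regions.astype(str),
            "subpopulation": subpop.astype(str),
        }),
        plaque_truth=plaques.copy(),
    )
    return cells, counts_df, plaques.drop(columns=["region"]), config.region_layout, truth


def simulate_cohort(
    config: SimConfig,
    design: list,
    seed: int | None = None,
    thresholds: AnalysisThresholds | None = None,
):
    """Simulate one section per (genotype, batch) design row and concatenate.

    Returns ``(dataset, truth)``.  Per-section seeds derive from the root
    seed and the section index, so cohorts are reproducible and individual
    sections are independent.
    """
    if not design:
        raise ValueError("design must be nonempty")
    root = config.seed if seed is None else seed
    cells_l, counts_l, plaques_l, truths = [], [], [], []
    for i, (genotype, batch) in enumerate(design):
        if isinstance(genotype, str):
            genotype = Genotype.parse(genotype)
        sid = f"s{i:02d}_{genotype.value}"
        c, m, p, _, t = simulate_section(
            config, genotype, batch, np.random.SeedSequence([root, i]),
            sample_id=sid, thresholds=thresholds,
        )
        cells_l.append(c)
        counts_l.append(m)
        plaques_l.append(p)
        truths.append(t)
    cells = pd.concat(cells_l, ignore_index=True)
    counts = pd.concat(counts_l)
    nonempty = [p for p in plaques_l if len(p)]
    plaques = (pd.concat(nonempty, ignore_index=True) if nonempty
               else plaques_l[0])
    ds = Dataset(cells=cells, counts=counts, plaques=plaques,
                 regions={"*": config.region_layout}, atlas=build_atlas(config))
    return ds.validate(), SimTruth.concat(truths)


def build_atlas(config: SimConfig) -> pd.DataFrame:
    """Expression-annotation table for the panel.

    One row per gene: which cell types express it (pipe separated), whether
    it is exclusive to a single type, and whether it is on the DAM / DAA
    disease-program marker lists.  Mirrors the role of a curated reference
    atlas annotation; here derived from the generator's own baselines.
    """
    genes = config.genes
    marker_of: dict[str, list] = {}
    for ct, ms in TYPE_MARKERS.items():
        for g in ms:
            marker_of.setdefault(g, []).append(ct)
    for g, cts in SHARED_MARKERS.items():
        marker_of[g] = list(cts)
    rows = []
    all_types = list(config.cell_types)
    for g in genes:
        expressed = marker_of.get(g, all_types)
        rows.append({
            "gene": g,
            "expressed_in": "|".join(expressed),
            "exclusive_to": expressed[0] if len(expressed) == 1 else "",
            "dam_marker": g in DAM_MARKERS,
            "daa_marker": g in DAA_MARKERS,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DAPI-like rendering for the plaque detector
# ---------------------------------------------------------------------------

#: lobe geometry of the multi-lobed plaque footprint, calibrated so the union
#: of 4 lobes has the requested equivalent diameter
_LOBE_RADIUS_F = 0.62
_LOBE_OFFSET_F = 0.45
NUCLEUS_DIAMETER = 8.5  # um
PLAQUE_PEAK = 1.0
NUCLEUS_PEAK = 0.45
DEFAULT_PIXEL_SIZE = 0.108  # um/px


def _rasterize_disk(grid: np.ndarray, cx: float, cy: float, r: float) -> None:
    ny, nx = grid.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, nx)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, ny)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    grid[y0:y1, x0:x1] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def render_dapi_image(
    cells: pd.DataFrame,
    plaques: pd.DataFrame,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    window: tuple = (0.0, 0.0, 216.0, 216.0),
    seed: int = 0,
    noise_sigma: float = 0.02,
    noise_mean: float = 0.05,
):
    """Render a DAPI-like intensity image plus a ground-truth plaque mask.

    Nuclei become round blobs of diameter 8.5 um at moderate brightness;
    plaques become brighter (>= 2x nucleus peak) multi-lobed blobs of the
    diameter given by their ``equivalent_diameter``, with a fibril-like
    internal texture.  The label mask marks plaque footprints only.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    x0, y0, x1, y1 = window
    nx = int(round((x1 - x0) / pixel_size))
    ny = int(round((y1 - y0) / pixel_size))
    if nx <= 0 or ny <= 0:
        raise ValueError("empty rendering window")
    rng = np.random.default_rng(seed)

    nuc_fp = np.zeros((ny, nx), dtype=bool)
    r_nuc = NUCLEUS_DIAMETER / 2.0 / pixel_size
    for _, c in cells.iterrows():
        cx, cy = (c["x"] - x0) / pixel_size, (c["y"] - y0) / pixel_size
        if -r_nuc <= cx <= nx + r_nuc and -r_nuc <= cy <= ny + r_nuc:
            _rasterize_disk(nuc_fp, cx, cy, r_nuc)

    mask = np.zeros((ny, nx), dtype=np.uint16)
    label = 0
    for _, p in plaques.iterrows():
        R = p["equivalent_diameter"] / 2.0 / pixel_size
        cx, cy = (p["x"] - x0) / pixel_size, (p["y"] - y0) / pixel_size
        if not (-2 * R <= cx <= nx + 2 * R and -2 * R <= cy <= ny + 2 * R):
            continue
        label += 1
        fp = np.zeros((ny, nx), dtype=bool)
        rot = rng.uniform(0, 2 * np.pi)
        for t in rot + np.arange(4) * (np.pi / 2):
            off = _LOBE_OFFSET_F * R * rng.uniform(0.9, 1.1)
            _rasterize_disk(fp, cx + off * np.cos(t), cy + off * np.sin(t),
                            _LOBE_RADIUS_F * R)
        mask[fp] = label
    plq_fp = mask > 0

    img = np.clip(rng.normal(noise_mean, noise_sigma, (ny, nx)), 0, None)
    texture = 1.0 + 0.25 * np.tanh(gaussian_filter(rng.normal(0, 1, (ny, nx)), 3.0) * 2)
    obj = NUCLEUS_PEAK * nuc_fp.astype(float)
    obj = np.where(plq_fp, PLAQUE_PEAK * texture, obj)
    img += gaussian_filter(obj, sigma=max(1.0, 0.3 / pixel_size))
    # relabel mask contiguously in case off-window plaques were skipped
    labels = np.unique(mask)
    labels = labels[labels > 0]
    relabel = np.zeros(int(mask.max()) + 1, dtype=np.uint16)
    relabel[labels] = np.arange(1, len(labels) + 1, dtype=np.uint16)
    return img, relabel[mask]


def random_fov_tables(
    seed: int,
    window: tuple = (0.0, 0.0, 216.0, 216.0),
    n_nuclei: int = 35,
    n_plaques_mean: float = 3.0,
    plaque_diameter_log_mu: float = float(np.log(22.4)),
    plaque_diameter_log_sigma: float = 0.15,
):
    """Small random cell/plaque tables for one rendered field of view.

    Plaque centers keep a margin of one radius from the window edge so the
    ground-truth footprint is fully inside the image.
    """
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window
    cells = pd.DataFrame({
        "cell_id": [f"c{i:03d}" for i in range(n_nuclei)],
        "x": rng.uniform(x0, x1, n_nuclei),
        "y": rng.uniform(y0, y1, n_nuclei),
    })
    n_p = max(1, rng.poisson(n_plaques_mean))
    d = np.exp(rng.normal(plaque_diameter_log_mu, plaque_diameter_log_sigma, n_p))
    margin = d.max()
    # plaques are distinct annotated objects: keep centers separated so
    # footprints do not merge into one connected component
    xs, ys = [], []
    for i in range(n_p):
        for _ in range(200):
            px = rng.uniform(x0 + margin, x1 - margin)
            py = rng.uniform(y0 + margin, y1 - margin)
            sep = [np.hypot(px - a, py - b) for a, b in zip(xs, ys)]
            req = [(d[i] + d[j]) / 2 + 5.0 for j in range(len(xs))]
            if all(s > r for s, r in zip(sep, req)):
                break
        xs.append(px)
        ys.append(py)
    plaques = pd.DataFrame({
        "plaque_id": [f"p{i:03d}" for i in range(n_p)],
        "x": xs,
        "y": ys,
        "equivalent_diameter": d,
        "area": np.pi * (d / 2) ** 2,
    })
    return cells, plaques
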