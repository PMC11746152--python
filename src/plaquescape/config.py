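"""Analysis thresholds and the four-level genotype code.

Every numeric cutoff used anywhere in the pipeline lives in
:class:`AnalysisThresholds` so a run is fully reproducible from one config
object plus a seed.  Defaults are the values used throughout the analysis:
cells above 1800 um^3 or below 50 transcripts are discarded, pseudobulk
strata need 50 cells, differential expression calls need |log2FC| >= 0.35 at
BH-adjusted p < 0.05, plaque-proximal means within 100 um of a plaque
centroid and distal means 100-500 um, and so on.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from dataclasses import dataclass


class Genotype(enum.Enum):
    """The four mouse genotypes: wild-type, Trem2-R47H, 5xFAD, and the cross.

    ``amyloid`` is True for the two genotypes carrying the 5xFAD transgenes,
    which are the only ones that develop A-beta plaques.
    """

    WT = "WT"
    R47H = "R47H"
    FAD = "FAD"
    R47H_FAD = "R47H_FAD"

    @property
    def amyloid(self) -> bool:
        return self in (Genotype.FAD, Genotype.R47H_FAD)

    @classmethod
    def parse(cls, s: str) -> "Genotype":
        key = str(s).strip().replace(" ", "")
        aliases = {
            "WT": cls.WT,
            "wild-type": cls.WT,
            "wildtype": cls.WT,
            "R47H": cls.R47H,
            "Trem2R47H": cls.R47H,
            "FAD": cls.FAD,
            "5xFAD": cls.FAD,
            "R47H_FAD": cls.R47H_FAD,
            "R47H;FAD": cls.R47H_FAD,
            "Trem2R47H;5xFAD": cls.R47H_FAD,
            "5xFAD;Trem2R47H": cls.R47H_FAD,
        }
        if key in aliases:
            return aliases[key]
        raise ValueError(f"unknown genotype string: {s!r}")


#: Fixed genotype order used for tie-breaking and column order everywhere.
GENOTYPE_ORDER = (Genotype.WT, Genotype.R47H, Genotype.FAD, Genotype.R47H_FAD)


@dataclass(frozen=True)
class AnalysisThresholds:
    """All tunable analysis cutoffs (units in field names / docs)."""

    max_cell_volume: float = 1800.0  # um^3, strict >
    min_transcripts_per_cell: int = 50  # strict <
    min_gene_cell_fraction: float = 0.15
    min_cells_per_pseudobulk: int = 50
    abs_log2fc: float = 0.35
    alpha_fdr: float = 0.05
    min_subcluster_fraction: float = 0.05
    single_genotype_bias: float = 1.0 / 3.0
    pair_bias: float = 0.60
    proximal_radius: float = 100.0  # um
    distal_radius: float = 500.0  # um
    annulus_width: float = 25.0  # um
    neighborhood_radius: float = 50.0  # um
    alpha_shape_alpha: float = 0.015  # 1/um
    knn_k: int = 5
    section_thickness: float = 10.0  # um

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"threshold {f.name} must be strictly positive, got {v}")
        if not self.proximal_radius < self.distal_radius:
            raise ValueError("proximal_radius must be < distal_radius")
        for name in ("min_gene_cell_fraction", "alpha_fdr", "min_subcluster_fraction",
                     "single_genotype_bias", "pair_bias"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisThresholds":
        return cls(**d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
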