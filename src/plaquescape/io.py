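"""Reading and writing of all on-disk tables, plus run manifests.

Formats are deliberately plain: counts as Matrix Market (with row/column
name sidecars) or dense CSV, every metadata table as headered CSV, region
polygons as JSON of nested coordinate lists, label masks as 16-bit TIFF.
Coordinates are 2-D (x, y) in um; sections are planar, the 10 um thickness
only enters when areas are converted to volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .config import AnalysisThresholds, Genotype
from .spatial import RegionMap

__all__ = ["Dataset", "load_dataset", "save_results", "SchemaError", "ConsistencyError"]

CELL_COLUMNS = ["cell_id", "x", "y", "volume", "total_transcripts",
                "sample_id", "batch_id", "genotype"]
OPTIONAL_CELL_COLUMNS = ["cell_type", "subcluster", "region"]
PLAQUE_COLUMNS = ["plaque_id", "x", "y", "area", "equivalent_diameter",
                  "volume", "sample_id"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ConsistencyError(ValueError):
    """Cross-table identifiers disagree (e.g. counts vs cell metadata)."""


@dataclass
class Dataset:
    """One loaded cohort: cells, counts, plaques, regions, optional atlas.

    ``counts`` is a cells x genes integer DataFrame indexed by cell_id whose
    row order matches ``cells``.  ``regions`` maps sample_id to a RegionMap
    (a single shared map may be stored under the key ``'*'``).
    """

    cells: pd.DataFrame
    counts: pd.DataFrame
    plaques: pd.DataFrame
    regions: dict[str, RegionMap] = field(default_factory=dict)
    atlas: pd.DataFrame | None = None

    def validate(self) -> "Dataset":
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"cell table missing required column(s): {missing}")
        for c in OPTIONAL_CELL_COLUMNS:
            if c not in self.cells.columns:
                self.cells[c] = ""
        if self.cells["cell_id"].duplicated().any():
            raise ConsistencyError("duplicate cell_id in cell table")
        if len(self.cells) != len(self.counts):
            raise ConsistencyError(
                f"counts has {len(self.counts)} rows but cell table has {len(self.cells)}"
            )
        if not np.array_equal(
            self.counts.index.to_numpy().astype(str),
            self.cells["cell_id"].to_numpy().astype(str),
        ):
            raise ConsistencyError("cell ids in counts and cell table do not agree 1:1")
        # normalizes genotype strings to the 4-level enum codes
        self.cells["genotype"] = [Genotype.parse(g).value for g in self.cells["genotype"]]
        if len(self.plaques):
            missing = [c for c in PLAQUE_COLUMNS if c not in self.plaques.columns]
            if missing:
                raise SchemaError(f"plaque table missing required column(s): {missing}")
            known = set(self.cells["sample_id"].astype(str))
            bad = set(self.plaques["sample_id"].astype(str)) - known
            if bad:
                raise ConsistencyError(f"plaque sample ids not present in cell table: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        return self

    def region_map(self, sample_id: str) -> RegionMap:
        if sample_id in self.regions:
            return self.regions[sample_id]
        if "*" in self.regions:
            return self.regions["*"]
        raise KeyError(f"no region map for sample {sample_id!r}")

    def sample_plaques(self, sample_id: str) -> pd.DataFrame:
        return self.plaques[self.plaques["sample_id"] == sample_id].reset_index(drop=True)

    def sample_cells(self, sample_id: str) -> pd.DataFrame:
        return self.cells[self.cells["sample_id"] == sample_id].reset_index(drop=True)

    def sort_by_cell_id(self) -> "Dataset":
        """Canonical row order (ascending cell_id) for order-independence."""
        order = np.argsort(self.cells["cell_id"].astype(str).to_numpy(), kind="stable")
        cells = self.cells.iloc[order].reset_index(drop=True)
        counts = self.counts.iloc[order]
        return Dataset(cells, counts, self.plaques, self.regions, self.atlas)


def _read_counts(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = (path.parent / (path.stem + ".rows.txt")).read_text().split()
        cols = (path.parent / (path.stem + ".cols.txt")).read_text().split()
        return pd.DataFrame(np.asarray(mat, dtype=np.int64), index=rows, columns=cols)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(np.int64)


def load_dataset(paths: dict, thresholds: AnalysisThresholds | None = None) -> Dataset:
    """Load and validate a Dataset from a mapping of role -> file path.

    Recognized roles: ``counts`` (MTX with ``.rows.txt``/``.cols.txt``
    sidecars, or dense CSV with cell ids in the first column), ``cells``,
    optional ``plaques``, ``regions`` (JSON), ``atlas`` (CSV).
    """
    counts = _read_counts(Path(paths["counts"]))
    cells = pd.read_csv(paths["cells"])
    if "genotype" not in cells.columns:
        raise SchemaError("cell table missing required column(s): ['genotype']")
    cells["cell_id"] = cells["cell_id"].astype(str)
    plaques = (
        pd.read_csv(paths["plaques"]) if "plaques" in paths and paths["plaques"]
        else pd.DataFrame(columns=PLAQUE_COLUMNS)
    )
    regions: dict[str, RegionMap] = {}
    if paths.get("regions"):
        with open(paths["regions"]) as fh:
            raw = json.load(fh)
        # either one shared map, or {sample_id: map}
        if raw and isinstance(next(iter(raw.values())), dict):
            regions = {sid: RegionMap.from_json_dict(m) for sid, m in raw.items()}
        else:
            regions = {"*": RegionMap.from_json_dict(raw)}
    atlas = pd.read_csv(paths["atlas"]) if paths.get("atlas") else None
    ds = Dataset(cells=cells, counts=counts, plaques=plaques, regions=regions, atlas=atlas)
    return ds.validate()


def save_counts(counts: pd.DataFrame, path: Path) -> None:
    """Write a counts table as Matrix Market with name sidecars."""
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
    (path.parent / (path.stem + ".rows.txt")).write_text(
        "\n".join(map(str, counts.index)) + "\n")
    (path.parent / (path.stem + ".cols.txt")).write_text(
        "\n".join(map(str, counts.columns)) + "\n")


def save_results(
    results: dict[str, pd.DataFrame],
    out_dir,
    thresholds: AnalysisThresholds | None = None,
    seed: int | None = None,
) -> dict:
    """Write result tables as CSV and a JSON manifest describing the run.

    The manifest records file names, row counts, the thresholds hash and
    the seed, so any output can be traced back to its exact configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in results.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False)
        entries.append({"file": fname, "row_count": int(len(table))})
    manifest = {
        "files": entries,
        "config_hash": (thresholds or AnalysisThresholds()).config_hash(),
        "seed": seed,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
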