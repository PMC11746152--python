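"""Plaque detection in DAPI-like images and confusion-count validation.

Amyloid plaques appear in DAPI images as bright, large (mean diameter
~22 um), irregular multi-lobed objects, whereas nuclei are dimmer, round
and small (~8.5 um).  The detector here is a transparent threshold-and-
filter pipeline: global intensity quantile threshold, connected components,
a minimum-diameter filter that rejects nuclei, and a maximum-circularity
filter that rejects round objects.  Validation counts true/false positives
by object overlap and summarizes them as F1, false-negative rate and two
false-positive-rate conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .config import AnalysisThresholds

__all__ = [
    "PlaqueMask", "ConfusionCounts", "detect_plaques_threshold",
    "mask_to_table", "match_predictions", "detection_metrics",
    "two_sample_contrast", "transcript_density_contrast",
]


@dataclass
class PlaqueMask:
    """Integer label image (0 background, k>0 plaque k) with pixel size."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            # relabel to contiguous positive integers
            lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int32)
            lut[present] = np.arange(1, len(present) + 1)
            self.labels = lut[self.labels]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def save(self, path) -> None:
        """Write the label image as 16-bit TIFF (pixel size in the header)."""
        import tifffile

        tifffile.imwrite(path, self.labels.astype(np.uint16),
                         metadata={"pixel_size_um": self.pixel_size})

    @classmethod
    def load(cls, path, pixel_size: float | None = None) -> "PlaqueMask":
        import json as _json

        import tifffile

        with tifffile.TiffFile(path) as tif:
            labels = tif.asarray()
            if pixel_size is None:
                meta = tif.shaped_metadata or ({},)
                pixel_size = float(meta[0].get("pixel_size_um", 1.0))
        return cls(labels.astype(np.int32), pixel_size)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def detect_plaques_threshold(
    image: np.ndarray,
    pixel_size: float,
    intensity_quantile: float = 0.90,
    min_diameter: float = 15.0,
    max_circularity: float = 0.90,
) -> PlaqueMask:
    """Threshold detector for bright irregular plaque-like objects.

    Pixels above the global intensity quantile are labeled by 8-connectivity;
    components with equivalent diameter below ``min_diameter`` (um) are
    removed (nuclei and noise specks), and components with circularity
    4*pi*A/P^2 above ``max_circularity`` are removed (round somata).  A
    constant image yields an empty mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or not np.isfinite(image).all():
        raise ValueError("image must be a finite 2-D array")
    thr = np.quantile(image, intensity_quantile)
    binary = image > thr
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return PlaqueMask(np.zeros_like(labels, dtype=np.int32), pixel_size)
    out = np.zeros_like(labels, dtype=np.int32)
    k = 0
    for region in measure.regionprops(labels):
        d_eq = region.equivalent_diameter_area * pixel_size
        if d_eq < min_diameter:
            continue
        perim = region.perimeter_crofton
        circ = 4.0 * np.pi * region.area / perim**2 if perim > 0 else 1.0
        if circ > max_circularity:
            continue
        k += 1
        out[labels == region.label] = k
    return PlaqueMask(out, pixel_size)


def mask_to_table(
    mask: PlaqueMask,
    sample_id: str = "s00",
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Geometry table of a label mask (centroid, area, diameter, volume).

    Centroids are mean pixel positions scaled by pixel size, areas are pixel
    counts times pixel area, and volumes assume the section thickness.
    """
    thresholds = thresholds or AnalysisThresholds()
    ps = mask.pixel_size
    rows = []
    for region in measure.regionprops(mask.labels):
        area = region.area * ps * ps
        cy, cx = region.centroid
        rows.append({
            "plaque_id": f"{sample_id}_p{region.label:04d}",
            "x": cx * ps,
            "y": cy * ps,
            "area": area,
            "equivalent_diameter": 2.0 * np.sqrt(area / np.pi),
            "volume": area * thresholds.section_thickness,
            "sample_id": sample_id,
        })
    cols = ["plaque_id", "x", "y", "area", "equivalent_diameter", "volume", "sample_id"]
    return pd.DataFrame(rows, columns=cols)


def match_predictions(
    predicted: PlaqueMask,
    annotated: PlaqueMask,
    min_overlap_fraction: float = 0.5,
) -> ConfusionCounts:
    """Object-level confusion counts between predicted and annotated masks.

    An annotated object is a true positive when its greedily matched
    predicted object covers at least ``min_overlap_fraction`` of its area,
    otherwise a false negative.  A predicted object overlapping zero
    annotated pixels is a false positive.  Matching is greedy by overlap,
    ties broken by lower label, and each predicted object matches at most
    one annotated object.
    """
    P, A = predicted.labels, annotated.labels
    if P.shape != A.shape:
        raise ValueError(f"mask shapes differ: {P.shape} vs {A.shape}")
    n_p, n_a = int(P.max()), int(A.max())
    both = (P > 0) & (A > 0)
    pairs: dict[tuple, int] = {}
    if both.any():
        pair_ids = P[both].astype(np.int64) * (n_a + 1) + A[both].astype(np.int64)
        uniq, cnt = np.unique(pair_ids, return_counts=True)
        for u, c in zip(uniq, cnt):
            pairs[(int(u // (n_a + 1)), int(u % (n_a + 1)))] = int(c)
    area_a = np.bincount(A.ravel(), minlength=n_a + 1)

    order = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    matched_p: set = set()
    matched_a: dict = {}
    for (p, a), ov in order:
        if p in matched_p or a in matched_a:
            continue
        matched_p.add(p)
        matched_a[a] = ov
    tp = sum(
        1 for a, ov in matched_a.items()
        if ov >= min_overlap_fraction * area_a[a]
    )
    fn = n_a - tp
    overlapping_p = {p for (p, _a) in pairs}
    fp = n_p - len(overlapping_p)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def detection_metrics(conf: ConfusionCounts) -> dict:
    """F1, false-negative rate, and both false-positive-rate conventions.

    F1 = 2 tp / (2 tp + fp + fn).  Because the false-positive rate of an
    object detector has no single established denominator, it is reported
    under both conventions: against predictions (fp / (fp + tp)) and
    against annotated objects (fp / (tp + fn)).
    """
    tp, fp, fn = conf.tp, conf.fp, conf.fn
    if tp + fp + fn == 0:
        raise ValueError("all confusion counts are zero")
    return {
        "f1": 2.0 * tp / (2.0 * tp + fp + fn),
        "fnr": fn / (tp + fn) if tp + fn else 0.0,
        "fpr_predicted": fp / (fp + tp) if fp + tp else 0.0,
        "fpr_annotated": fp / (tp + fn) if tp + fn else 0.0,
    }


def two_sample_contrast(values_a, values_b, test: str = "t") -> dict:
    """Two-sided two-sample test (Welch t or Wilcoxon rank-sum).

    The rank-sum test is computed exactly when both samples have at most 20
    observations and no ties span the pooled sample; otherwise the normal
    approximation is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return {"statistic": float(res.statistic), "p": float(res.pvalue)}
    if test == "rank_sum":
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        if len(a) <= 20 and len(b) <= 20 and no_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return {"statistic": float(res.statistic), "p": float(res.pvalue)}
        res = stats.ranksums(a, b)
        return {"statistic": float(res.statistic), "p": float(res.pvalue)}
    raise ValueError(f"unknown test {test!r}")


def transcript_density_contrast(
    plaques: pd.DataFrame,
    cells: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
) -> dict:
    """Transcript density of plaque objects vs cells (plaques carry no RNA).

    Plaque density: summed transcripts of cells whose centroid falls within
    the plaque's equivalent radius, divided by plaque area.  Cell density:
    the cell's transcript count divided by its footprint area (volume over
    section thickness).  Returns both samples and the rank-sum p-value.
    """
    thresholds = thresholds or AnalysisThresholds()
    if len(plaques) == 0 or len(cells) == 0:
        raise ValueError("need at least one plaque and one cell")
    from scipy.spatial import cKDTree

    xy = cells[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    tx = cells["total_transcripts"].to_numpy(dtype=float)
    plaque_density = []
    for _, p in plaques.iterrows():
        r = p["equivalent_diameter"] / 2.0
        inside = tree.query_ball_point([p["x"], p["y"]], r)
        plaque_density.append(tx[inside].sum() / p["area"])
    cell_area = cells["volume"].to_numpy(dtype=float) / thresholds.section_thickness
    cell_density = tx / cell_area
    res = two_sample_contrast(plaque_density, cell_density, test="rank_sum")
    return {
        "plaque_density": np.asarray(plaque_density),
        "cell_density": cell_density,
        "statistic": res["statistic"],
        "p": res["p"],
    }
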