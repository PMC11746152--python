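import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from plaquescape.config import AnalysisThresholds
from plaquescape.spatial import (
    alpha_shape_area, annulus_composition, closest_cell_composition,
    convex_hull_area, knn_distances, knn_outlier_filter,
    nearest_plaque_distance, plaque_neuron_distance_contrast,
    proximal_distal_density, regional_density, union_disk_area, RegionMap,
)


def _cells(xy, types=None, ids=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame({
        "cell_id": ids or [f"c{i:03d}" for i in range(n)],
        "x": xy[:, 0], "y": xy[:, 1],
        "cell_type": types if types is not None else ["Micro"] * n,
    })


def _plaques(xy, ids=None):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return pd.DataFrame({
        "plaque_id": ids or [f"p{i}" for i in range(len(xy))],
        "x": xy[:, 0], "y": xy[:, 1],
    })


def test_nearest_plaque_distance_and_zones():
    cells = _cells([(0, 0), (0, 100), (0, 600)])
    prox = nearest_plaque_distance(cells, _plaques([(30, 40)]))
    assert prox["distance_to_nearest_plaque"].iloc[0] == pytest.approx(50.0)
    assert prox["zone"].iloc[0] == "proximal"
    # exactly 100 um is distal (proximal is a strict inequality)
    d0 = nearest_plaque_distance(_cells([(100, 0)]), _plaques([(0, 0)]))
    assert d0["zone"].iloc[0] == "distal"
    d5 = nearest_plaque_distance(_cells([(501, 0)]), _plaques([(0, 0)]))
    assert d5["zone"].iloc[0] == "beyond"


def test_nearest_plaque_takes_minimum_and_empty_errors():
    prox = nearest_plaque_distance(_cells([(0, 0)]), _plaques([(30, 40), (6, 8)]))
    assert prox["distance_to_nearest_plaque"].iloc[0] == pytest.approx(10.0)
    with pytest.raises(ValueError, match="no plaques"):
        nearest_plaque_distance(_cells([(0, 0)]), _plaques(np.empty((0, 2))))


def test_closest_cell_composition_hand_counts():
    cells = _cells([(0, 0), (100, 0), (200, 0)], types=["A", "A", "B"])
    plaques = _plaques([(1, 0), (99, 0), (201, 0)])
    props = closest_cell_composition(plaques, cells)
    assert props["A"] == pytest.approx(2 / 3)
    assert props["B"] == pytest.approx(1 / 3)
    assert props.sum() == pytest.approx(1.0)


def test_closest_cell_tie_breaks_by_cell_id():
    cells = _cells([(0, 10), (0, -10)], types=["A", "B"], ids=["c2", "c1"])
    props = closest_cell_composition(_plaques([(0, 0)]), cells)
    assert props.idxmax() == "B"  # c1 < c2 wins the exact tie


def test_closest_cell_errors():
    with pytest.raises(ValueError):
        closest_cell_composition(_plaques(np.empty((0, 2))), _cells([(0, 0)]))
    untyped = _cells([(0, 0)], types=[""])
    with pytest.raises(ValueError):
        closest_cell_composition(_plaques([(0, 0)]), untyped)


def test_annulus_composition_two_step_normalization():
    """Annulus counts A:30, B:10 with section totals A:300, B:50: raw
    proportions (0.75, 0.25); abundance-normalized (1/3, 2/3)."""
    rng = np.random.default_rng(0)
    # annulus [0, 25): 30 A at r=10, 10 B at r=12
    ang = rng.uniform(0, 2 * np.pi, 400)
    xs, ys, types = [], [], []
    for i in range(30):
        xs.append(10 * np.cos(ang[i])); ys.append(10 * np.sin(ang[i])); types.append("A")
    for i in range(30, 40):
        xs.append(12 * np.cos(ang[i])); ys.append(12 * np.sin(ang[i])); types.append("B")
    # remaining cells far beyond the distal radius
    for i in range(40, 310):
        xs.append(5000 + i); ys.append(5000.0); types.append("A")
    for i in range(310, 350):
        xs.append(6000 + i); ys.append(6000.0); types.append("B")
    cells = _cells(np.column_stack([xs, ys]), types=types)
    out = annulus_composition(_plaques([(0, 0)]), cells)
    first = out[(out["annulus_lo"] == 0.0)].set_index("cell_type")
    assert first.loc["A", "proportion"] == pytest.approx(0.75)
    assert first.loc["B", "proportion"] == pytest.approx(0.25)
    assert first.loc["A", "proportion_normalized"] == pytest.approx(1 / 3)
    assert first.loc["B", "proportion_normalized"] == pytest.approx(2 / 3)


def test_annulus_composition_single_type_simplex():
    rng = np.random.default_rng(1)
    r = rng.uniform(0, 500, 300)
    t = rng.uniform(0, 2 * np.pi, 300)
    cells = _cells(np.column_stack([r * np.cos(t), r * np.sin(t)]))
    out = annulus_composition(_plaques([(0, 0)]), cells)
    assert (out["proportion"] == 1.0).all()
    sums = out.groupby("annulus_lo")["proportion"].sum()
    assert np.allclose(sums, 1.0)


@pytest.mark.parametrize("centers, expected", [
    ([(0, 0)], np.pi * 1e4),
    ([(0, 0), (400, 0)], 2 * np.pi * 1e4),
    ([(0, 0), (0, 0)], np.pi * 1e4),
])
def test_union_disk_area_closed_forms(centers, expected):
    big = box(-1e4, -1e4, 1e4, 1e4)
    assert union_disk_area(centers, 100.0, big) == pytest.approx(expected, rel=0.01)


def test_union_disk_area_monotone_and_empty():
    assert union_disk_area([], 100.0) == 0.0
    a50 = union_disk_area([(0, 0), (60, 0)], 50.0)
    a80 = union_disk_area([(0, 0), (60, 0)], 80.0)
    assert a80 > a50


def test_knn_filter_matches_bruteforce_oracle():
    """10x10 grid at 10 um spacing, k=5: brute-force 5th-NN distances are
    14.14 um except 20 um at the 4 corners, so the IQR window keeps 96."""
    grid = np.column_stack([
        np.repeat(np.arange(10) * 10.0, 10), np.tile(np.arange(10) * 10.0, 10)])

    def brute_kth(points, k):
        out = []
        for p in points:
            d = np.sort(np.linalg.norm(points - p, axis=1))
            out.append(d[k])  # d[0] is the self-distance
        return np.asarray(out)

    np.testing.assert_allclose(knn_distances(grid, 5), brute_kth(grid, 5))
    kept = knn_outlier_filter(grid, 5)
    assert len(kept) == 96
    corners = {(0.0, 0.0), (0.0, 90.0), (90.0, 0.0), (90.0, 90.0)}
    assert corners.isdisjoint({tuple(p) for p in kept})

    with_outlier = np.vstack([grid, [[1000.0, 1000.0]]])
    kept = knn_outlier_filter(with_outlier, 5)
    assert not any((p == [1000.0, 1000.0]).all() for p in kept)

    with pytest.raises(ValueError):
        knn_outlier_filter(grid[:5], 5)


def test_alpha_shape_triangle_and_square():
    assert alpha_shape_area([(0, 0), (100, 0), (0, 100)], 0.0) == pytest.approx(5000.0)
    gx, gy = np.meshgrid(np.linspace(0, 100, 50), np.linspace(0, 100, 50))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    assert alpha_shape_area(pts, 0.015) == pytest.approx(10000.0, rel=0.05)


def test_alpha_zero_equals_convex_hull_oracle():
    rng = np.random.default_rng(2)
    for _ in range(5):
        pts = rng.uniform(0, 200, (rng.integers(10, 80), 2))
        assert alpha_shape_area(pts, 0.0) == pytest.approx(convex_hull_area(pts))


def test_alpha_shape_degenerate_inputs():
    with pytest.raises(ValueError):
        alpha_shape_area([(0, 0), (1, 1)], 0.015)
    with pytest.raises(ValueError):
        alpha_shape_area([(0, 0), (1, 1), (2, 2)], 0.015)  # collinear


def test_proximal_distal_density_uniform_cells():
    """Uniform random cells give matching proximal and distal densities."""
    rng = np.random.default_rng(3)
    section = box(0, 0, 2000, 2000)
    cells = _cells(rng.uniform(0, 2000, (3000, 2)))
    plaques = _plaques(rng.uniform(500, 1500, (5, 2)))
    res = proximal_distal_density(cells, plaques, section)
    assert res["proximal"] == pytest.approx(res["distal"], rel=0.2)
    # hand-checked division
    assert res["proximal"] == pytest.approx(res["n_proximal"] / res["proximal_area"])


def test_density_rigid_motion_invariance():
    rng = np.random.default_rng(4)
    section = box(0, 0, 1000, 1000)
    xy = rng.uniform(0, 1000, (1500, 2))
    pxy = rng.uniform(300, 700, (3, 2))
    res0 = proximal_distal_density(_cells(xy), _plaques(pxy), section)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = np.array([123.0, -45.0])
    from shapely import affinity
    sec2 = affinity.translate(affinity.rotate(section, theta, origin=(0, 0),
                                              use_radians=True), *shift)
    res1 = proximal_distal_density(_cells(xy @ R.T + shift),
                                   _plaques(pxy @ R.T + shift), sec2)
    assert res1["proximal"] == pytest.approx(res0["proximal"], rel=1e-6)
    assert res1["distal"] == pytest.approx(res0["distal"], rel=1e-6)


def test_regional_density_uniform_and_empty():
    rng = np.random.default_rng(5)
    rm = RegionMap({"r1": box(0, 0, 1000, 1000), "r2": box(2000, 0, 3000, 1000)})
    cells = _cells(rng.uniform(0, 1000, (100, 2)))
    out = regional_density(cells, rm, by="all").set_index("region")
    assert out.loc["r1", "density"] == pytest.approx(1e-4)
    assert out.loc["r2", "density"] == 0.0


def test_regional_density_recovers_planted_type_density():
    rng = np.random.default_rng(6)
    rm = RegionMap({"r": box(0, 0, 1000, 1000)})
    n = 2000  # density 2e-3 over 1e6 um^2; dense enough for the alpha shape
    cells = _cells(rng.uniform(0, 1000, (n, 2)), types=["Micro"] * n)
    out = regional_density(cells, rm, by="Micro").set_index("region")
    assert out.loc["r", "density"] == pytest.approx(2e-3, rel=0.15)


def test_plaque_neuron_distance_grid_geometry():
    """Neurons on a 20-um grid with plaques at cell centers: each plaque sits
    sqrt(2)*10 um from its nearest neuron."""
    g = np.arange(0, 200, 20.0)
    gx, gy = np.meshgrid(g, g)
    neurons = _cells(np.column_stack([gx.ravel(), gy.ravel()]), types=["ExN"] * 100)
    plaques = _plaques([(30.0, 30.0), (90.0, 110.0)])
    res = plaque_neuron_distance_contrast(plaques, neurons)
    np.testing.assert_allclose(res["plaque_to_neuron"], np.sqrt(2) * 10)
    np.testing.assert_allclose(res["neuron_to_neuron"], 20.0)
    coincident = plaque_neuron_distance_contrast(_plaques([(0.0, 0.0)]), neurons)
    assert coincident["plaque_to_neuron"][0] == 0.0
    with pytest.raises(ValueError):
        plaque_neuron_distance_contrast(plaques, neurons.iloc[:1])
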