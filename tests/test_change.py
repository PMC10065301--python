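"""Temporal overlays, class transitions, centroids and spherical displacement."""

import numpy as np
import pytest

import nichecast as nc
from nichecast.suitability import ClassifiedMap, area_grid


def _classified(values, P=0.2, nodata=-9999.0):
    g = nc.RasterGrid(100.0, 20.0, 0.5, nodata, np.asarray(values, dtype=float))
    return ClassifiedMap(g, P)


# ---------------------------------------------------------------------------
# binary mask + overlay
# ---------------------------------------------------------------------------

def test_binary_suitable_semantics():
    cm = _classified([[0, 1, 2, 3]])
    np.testing.assert_array_equal(nc.binary_suitable(cm), [[False, True, True, True]])
    counts = cm.counts()
    assert nc.binary_suitable(cm).sum() == counts[1] + counts[2] + counts[3]


def test_binary_all_unsuitable():
    cm = _classified([[0, 0], [0, 0]])
    assert nc.binary_suitable(cm).sum() == 0


def test_overlay_identity_and_disjoint(small_grid):
    rng = np.random.default_rng(0)
    cur = small_grid.mask & (rng.random(small_grid.values.shape) < 0.4)
    same = nc.overlay(cur, cur, small_grid)
    c = same.counts()
    assert c["stable"] == cur.sum() and c["shrink"] == 0 and c["expand"] == 0
    disjoint = small_grid.mask & ~cur
    d = nc.overlay(cur, disjoint, small_grid).counts()
    assert d["stable"] == 0


def test_overlay_matches_per_cell_brute_force():
    """Random 30x30 masks: per-class counts equal a truth-table evaluation,
    and the conservation identities hold exactly."""
    rng = np.random.default_rng(7)
    vals = rng.random((30, 30))
    vals[rng.random((30, 30)) < 0.05] = -9999.0
    grid = nc.RasterGrid(100.0, 20.0, 0.1, -9999.0, vals)
    cur = grid.mask & (rng.random((30, 30)) < 0.5)
    fut = grid.mask & (rng.random((30, 30)) < 0.5)
    change = nc.overlay(cur, fut, grid)
    brute = {"stable": 0, "shrink": 0, "expand": 0, "never": 0}
    for i in range(30):
        for j in range(30):
            if not grid.mask[i, j]:
                continue
            key = ("stable" if cur[i, j] and fut[i, j]
                   else "shrink" if cur[i, j]
                   else "expand" if fut[i, j] else "never")
            brute[key] += 1
    assert change.counts() == brute
    c = change.counts()
    assert c["stable"] + c["shrink"] == cur.sum()
    assert c["stable"] + c["expand"] == fut.sum()


def test_overlay_geometry_mismatch():
    g = nc.RasterGrid(0.0, 0.0, 1.0, -9999.0, np.zeros((2, 2)))
    with pytest.raises(nc.errors.AlignmentError):
        nc.overlay(np.zeros((2, 2), bool), np.zeros((3, 3), bool), g)


def test_overlay_on_toy_fixture(toy):
    stack, _, suit, expected = toy
    cm = nc.classify(suit, expected["maxsss_threshold"])
    cur = nc.binary_suitable(cm)
    fut = np.zeros_like(cur)
    for i, j in expected["future_mask_cells"]:
        fut[i, j] = True
    change = nc.overlay(cur, fut, suit)
    assert change.counts() == expected["overlay_counts"]


# ---------------------------------------------------------------------------
# change proportions
# ---------------------------------------------------------------------------

def test_proportions_identity_case(small_grid):
    cur = small_grid.mask.copy()
    props = nc.change_proportions(nc.overlay(cur, cur, small_grid))
    assert props["stable_pct_of_current"] == pytest.approx(100.0)
    assert props["shrink_pct_of_current"] == pytest.approx(0.0)
    assert props["expand_pct_of_future"] == pytest.approx(0.0)


def test_proportions_four_cell_hand_case():
    """Equal-area cells, current={a,b,c}, future={b,c,d} -> (66.67, 33.33, 33.33)."""
    # one row at the equator: all four cells have identical area
    grid = nc.RasterGrid(0.0, -0.05, 0.1, -9999.0, np.zeros((1, 4)))
    cur = np.array([[True, True, True, False]])
    fut = np.array([[False, True, True, True]])
    props = nc.change_proportions(nc.overlay(cur, fut, grid))
    assert props["stable_pct_of_current"] == pytest.approx(200 / 3, rel=1e-9)
    assert props["shrink_pct_of_current"] == pytest.approx(100 / 3, rel=1e-9)
    assert props["expand_pct_of_future"] == pytest.approx(100 / 3, rel=1e-9)
    assert props["stable_pct_of_current"] + props["shrink_pct_of_current"] == pytest.approx(100.0)


def test_proportions_zero_denominator():
    grid = nc.RasterGrid(0.0, 0.0, 1.0, -9999.0, np.zeros((1, 2)))
    none_mask = np.zeros((1, 2), bool)
    props = nc.change_proportions(nc.overlay(none_mask, none_mask, grid))
    assert props["stable_pct_of_current"] is None


# ---------------------------------------------------------------------------
# class transitions
# ---------------------------------------------------------------------------

def test_transition_identity_is_diagonal():
    cm = _classified([[0, 1], [2, 3]])
    M = nc.class_transition(cm, cm)
    assert np.all(M[~np.eye(4, dtype=bool)] == 0.0)
    assert M[3, 3] > 0


def test_transition_marginals_and_brute_force():
    rng = np.random.default_rng(11)
    a = _classified(rng.integers(0, 4, (3, 3)))
    b = _classified(rng.integers(0, 4, (3, 3)))
    M = nc.class_transition(a, b)
    areas = area_grid(a.classes)
    brute = np.zeros((4, 4))
    for i in range(3):
        for j in range(3):
            brute[int(a.classes.values[i, j]), int(b.classes.values[i, j])] += areas[i, j]
    np.testing.assert_allclose(M, brute / 1e4, rtol=1e-12)
    for c in range(4):
        assert M[c].sum() == pytest.approx(areas[a.classes.values == c].sum() / 1e4)
        assert M[:, c].sum() == pytest.approx(areas[b.classes.values == c].sum() / 1e4)


# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------

def test_centroid_single_cell():
    cm = _classified([[0, 0], [0, 3]])
    lon, lat = nc.centroid(cm)
    expect = cm.classes.cell_center(1, 1)
    assert (lon, lat) == (pytest.approx(expect[0]), pytest.approx(expect[1]))


def test_centroid_meridian_symmetry():
    # top class symmetric about the middle meridian, all in one row
    cm = _classified([[3, 0, 3]])
    lon, lat = nc.centroid(cm)
    assert lon == pytest.approx(100.75)  # the middle cell's meridian
    assert lon == pytest.approx(sum(cm.classes.cell_center(0, j)[0] for j in (0, 2)) / 2)


def test_centroid_five_cell_hand_weighted():
    vals = np.zeros((3, 5))
    cells = [(0, 0), (0, 4), (1, 2), (2, 1), (2, 3)]
    for i, j in cells:
        vals[i, j] = 3
    cm = _classified(vals)
    areas = area_grid(cm.classes)
    w = np.array([areas[i, j] for i, j in cells])
    lons = np.array([cm.classes.cell_center(i, j)[0] for i, j in cells])
    lats = np.array([cm.classes.cell_center(i, j)[1] for i, j in cells])
    lon, lat = nc.centroid(cm)
    assert lon == pytest.approx(np.sum(w * lons) / w.sum(), rel=1e-12)
    assert lat == pytest.approx(np.sum(w * lats) / w.sum(), rel=1e-12)


def test_centroid_invariant_to_other_classes():
    a = _classified([[3, 1, 0], [2, 3, 1]])
    b = _classified([[3, 0, 0], [0, 3, 0]])
    assert nc.centroid(a) == nc.centroid(b)


def test_centroid_empty_class_raises():
    with pytest.raises(nc.errors.NichecastError):
        nc.centroid(_classified([[0, 1]]), target_class=3)


def test_centroid_on_toy_fixture(toy):
    _, _, suit, expected = toy
    cm = nc.classify(suit, expected["maxsss_threshold"])
    lon, lat = nc.centroid(cm)
    assert (lon, lat) == (pytest.approx(expected["centroid_most"][0]),
                          pytest.approx(expected["centroid_most"][1]))


# ---------------------------------------------------------------------------
# displacement
# ---------------------------------------------------------------------------

def test_displacement_identity():
    d, b, c = nc.displacement((105.9, 26.68), (105.9, 26.68))
    assert d == 0.0 and c is None


def test_displacement_due_north_closed_form():
    """One degree due north is ~111.2 km with bearing 0 (compass N)."""
    d, b, c = nc.displacement((105.9, 26.68), (105.9, 27.68))
    assert d == pytest.approx(np.pi * nc.EARTH_RADIUS_KM / 180.0, rel=1e-9)
    assert d == pytest.approx(111.2, abs=0.05)
    assert b == pytest.approx(0.0, abs=1e-9)
    assert c == "N"


def test_displacement_northeast_sector():
    """The current-to-2050s move under a low-emission analogue heads NE."""
    d, b, c = nc.displacement((105.9, 26.68), (106.22, 27.23))
    assert c == "NE"


@pytest.mark.parametrize("bearing,sector", [
    (0, "N"), (22.4, "N"), (22.6, "NE"), (45, "NE"), (90, "E"), (135, "SE"),
    (180, "S"), (225, "SW"), (270, "W"), (315, "NW"), (359, "N"),
])
def test_compass_sectors(bearing, sector):
    assert nc.compass_8(bearing) == sector


def test_haversine_symmetric_triangle_inequality():
    rng = np.random.default_rng(17)
    for _ in range(50):
        pts = [(float(rng.uniform(-179, 179)), float(rng.uniform(-89, 89)))
               for _ in range(3)]
        d01 = nc.haversine_km(pts[0], pts[1])
        assert d01 == pytest.approx(nc.haversine_km(pts[1], pts[0]), rel=1e-12)
        d02 = nc.haversine_km(pts[0], pts[2])
        d12 = nc.haversine_km(pts[1], pts[2])
        assert d02 <= d01 + d12 + 1e-9


# ---------------------------------------------------------------------------
# centroid track
# ---------------------------------------------------------------------------

def test_track_single_map():
    cm = _classified([[3, 0]])
    track = nc.centroid_track([("current", cm)])
    assert len(track.points) == 1 and track.segments == []
    assert track.overall[0] == 0.0


def test_track_identical_maps_zero_segments():
    cm = _classified([[3, 0], [0, 3]])
    track = nc.centroid_track([("a", cm), ("b", cm), ("c", cm)])
    assert len(track.segments) == 2
    assert all(seg[0] == pytest.approx(0.0, abs=1e-9) for seg in track.segments)


def test_track_names_empty_scenario():
    good = _classified([[3]])
    bad = _classified([[1]])
    with pytest.raises(nc.errors.NichecastError, match="2050s"):
        nc.centroid_track([("current", good), ("2050s", bad)])


def test_eastward_truth_shift_gives_eastward_centroid(small_suite):
    """An eastward habitat displacement built from a coordinate-ramp niche
    yields an overall bearing in the eastern sector (45-135 degrees)."""
    from nichecast.synthetic import default_geometry, gradient_layer

    geom = default_geometry(40, 40)
    ramp = gradient_layer(geom, "east")
    stack = nc.EnvStack({"ramp": ramp}, "current")
    spec = nc.TruthSpec(true_weights={"ramp": 6.0}, optimum_style="unimodal",
                        optima={"ramp": 0.0}, warming_shift={"ramp": -0.8})
    fut = nc.make_future_stack(stack, spec, "future")
    d_cur = nc.true_suitability(stack, spec)
    d_fut = nc.true_suitability(fut, spec)

    def topclass(d):
        vals = d.values.copy()
        cut = np.quantile(d.valid_values, 0.9)
        vals[d.mask] = np.where(d.valid_values >= cut, 3.0, 0.0)
        return ClassifiedMap(nc.RasterGrid(d.x_ll, d.y_ll, d.cell_size,
                                           d.nodata_value, vals), 0.5)

    track = nc.centroid_track([("current", topclass(d_cur)), ("future", topclass(d_fut))])
    dist, bearing, compass = track.overall
    assert dist > 0
    assert 45.0 < bearing < 135.0
    assert compass == "E"
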