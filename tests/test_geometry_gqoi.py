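"""Landmarks, edge curves, planes and gQOIs: closed-form cases, brute-force
voxel oracles, and phantom ground-truth recovery at coarse resolution."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from valvegeom import geometry_gqoi as gg
from valvegeom.synthetic_valve import (
    ValvePhantomParams, generate_valve_phantom, murine_preset,
)

VOX = 10.0  # fast-phantom voxel size (µm)


# ---------------------------------------------------------------------------
# commissure detection
# ---------------------------------------------------------------------------

def _toy_volume():
    """Tiny hand-built 3-label volume: wall slab at x >= 15, two leaflet
    slabs meeting on the plane y = 9|10, a third leaflet apart."""
    grid = np.zeros((20, 20, 20), np.uint8)
    grid[15:, :, :] = 1                       # wall
    grid[3:15, 0:10, 5:8] = 2                 # anterior
    grid[3:15, 10:20, 5:8] = 3                # left
    grid[3:15, 0:20, 12:15] = 4               # right (touches wall only)
    return gg.LabeledValveVolume(grid=grid, voxel_size=1.0,
                                 origin=np.zeros(3))


def _brute_force_contacts(volume, la, lb):
    """Exhaustive voxel scan: voxels of label a/b with a 26-neighbour of the
    other label and a 26-neighbour of the wall."""
    g = volume.grid
    wall = volume.label_map["wall"]
    out = []
    nx, ny, nz = g.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                v = g[i, j, k]
                if v not in (la, lb):
                    continue
                other = lb if v == la else la
                nbrs = g[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2,
                         max(k - 1, 0):k + 2]
                if np.any(nbrs == other) and np.any(nbrs == wall):
                    out.append((i, j, k))
    return volume.voxel_centers(np.array(out))


def test_pair_contact_set_matches_brute_force_scan():
    volume = _toy_volume()
    fast = gg._pair_contact_points(volume, "anterior", "left")
    brute = _brute_force_contacts(volume, 2, 3)
    fast_set = {tuple(np.round(p, 6)) for p in fast}
    assert fast_set == {tuple(np.round(p, 6)) for p in brute}


def test_missing_pair_contact_raises():
    volume = _toy_volume()
    with pytest.raises(gg.LandmarkError):
        gg._pair_contact_points(volume, "anterior", "right")


def test_missing_leaflet_label_raises():
    volume = _toy_volume()
    volume.grid[volume.grid == 3] = 0
    with pytest.raises(gg.LandmarkError):
        gg.find_commissures(volume)


def test_commissures_recovered_on_symmetric_phantom(symmetric_phantom):
    volume, _, truth = symmetric_phantom
    found = gg.find_commissures(volume)
    err = np.linalg.norm(found - truth.landmarks_true.commissures, axis=1)
    # the apex voxel itself carries the wall label, so the detected contact
    # set tops out a couple of voxels below the analytic commissure
    assert np.all(err <= 3.5 * VOX)


# ---------------------------------------------------------------------------
# edge extraction
# ---------------------------------------------------------------------------

def test_edge_chains_endpoints_and_wall_adjacency(fast_phantom):
    volume, _, _ = fast_phantom
    commissures = gg.find_commissures(volume)
    wall = volume.mask("wall")
    wall_idx = np.argwhere(wall)
    from scipy.spatial import cKDTree
    wall_tree = cKDTree(volume.voxel_centers(wall_idx))
    for leaflet in gg.LEAFLETS:
        free, basal = gg.extract_leaflet_edges(volume, leaflet, commissures)
        ca, cb = (commissures[i] for i in gg.LEAFLET_COMMISSURES[leaflet])
        for chain in (free, basal):
            ends = {tuple(chain[0]), tuple(chain[-1])}
            assert min(np.linalg.norm(chain[0] - ca),
                       np.linalg.norm(chain[0] - cb)) <= 2 * VOX
            assert min(np.linalg.norm(chain[-1] - ca),
                       np.linalg.norm(chain[-1] - cb)) <= 2 * VOX
        # basal nodes hug the wall (26-adjacency reaches √3 voxels); interior
        # free-edge nodes stay off it
        d_basal, _ = wall_tree.query(basal)
        assert np.median(d_basal) <= 2.0 * VOX
        d_free, _ = wall_tree.query(free[3:-3])
        assert np.all(d_free >= 2.0 * VOX)


def test_basal_node_classification_matches_wall_adjacency(fast_phantom):
    """Each basal node must sit on the wall-attached band of leaflet voxels
    as defined by the brute per-voxel 26-adjacency test."""
    volume, _, _ = fast_phantom
    commissures = gg.find_commissures(volume)
    leaflet = "left"
    _, basal = gg.extract_leaflet_edges(volume, leaflet, commissures)
    band = volume.mask(leaflet) & ndi.binary_dilation(volume.mask("wall"),
                                                      gg._STRUCT26)
    band_pts = volume.voxel_centers(np.argwhere(band))
    from scipy.spatial import cKDTree
    d, _ = cKDTree(band_pts).query(basal[1:-1])
    assert np.all(d <= 1.0 * VOX)


# ---------------------------------------------------------------------------
# spline curves and lengths
# ---------------------------------------------------------------------------

def test_straight_line_length_exact():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
    c = gg.fit_curve_and_length(nodes)
    assert c.length == pytest.approx(3.0, abs=1e-9)


def test_semicircle_length_closed_form():
    r = 1000.0
    t = np.linspace(0.0, np.pi, 32)
    nodes = np.stack([r * np.cos(t), r * np.sin(t), np.zeros_like(t)], axis=1)
    c = gg.fit_curve_and_length(nodes, smoothing=0.0)
    assert c.length == pytest.approx(np.pi * r, rel=0.005)


def test_quadrature_length_matches_dense_polyline():
    rng = np.random.default_rng(11)
    nodes = np.cumsum(rng.normal(size=(25, 3)), axis=0) * 50.0
    c = gg.fit_curve_and_length(nodes, smoothing=0.0)
    dense = c.sample(100_001)
    poly = np.linalg.norm(np.diff(dense, axis=0), axis=1).sum()
    assert c.length == pytest.approx(poly, rel=1e-3)


def test_too_few_nodes_raises():
    with pytest.raises(gg.InsufficientDataError):
        gg.fit_curve_and_length(np.zeros((3, 3)))


def test_arc_point_midpoint_of_straight_segment():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [4, 0, 0.0]])
    c = gg.fit_curve_and_length(nodes)
    assert c.arc_point(0.5) == pytest.approx([2.0, 0.0, 0.0], abs=1e-3)


# ---------------------------------------------------------------------------
# planes, height, tilt
# ---------------------------------------------------------------------------

def test_plane_through_unit_points_closed_form():
    plane = gg._plane_through(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                              np.array([0, 0, 1.0]))
    assert np.allclose(np.abs(plane.normal), 1 / np.sqrt(3))
    assert plane.signed_distance(np.array([[1.0, 0, 0]]))[0] == pytest.approx(0.0, abs=1e-12)


def test_collinear_plane_points_raise():
    with pytest.raises(gg.DegeneratePlaneError):
        gg._plane_through(np.zeros(3), np.array([1.0, 0, 0]),
                          np.array([2.0, 0, 0]))


def test_valve_height_constant_and_mean_cases():
    anl = gg.Plane(point=np.zeros(3), normal=np.array([0, 0, 1.0]))
    same = np.array([[0, 0, 700.0], [100, 0, 700.0], [0, 100, 700.0]])
    assert gg.valve_height(same, anl) == pytest.approx(700.0)
    mixed = np.array([[0, 0, 600.0], [1, 0, 700.0], [0, 1, 800.0]])
    assert gg.valve_height(mixed, anl) == pytest.approx(700.0)


def test_tilt_angle_closed_forms():
    z = gg.Plane(point=np.zeros(3), normal=np.array([0, 0, 1.0]))
    assert gg.tilt_angle(z, z) == pytest.approx(0.0, abs=1e-9)
    t10 = gg.Plane(point=np.zeros(3),
                   normal=np.array([np.sin(np.deg2rad(10)), 0,
                                    np.cos(np.deg2rad(10))]))
    assert gg.tilt_angle(z, t10) == pytest.approx(10.0, abs=1e-9)
    flipped = gg.Plane(point=np.zeros(3), normal=-t10.normal)
    assert gg.tilt_angle(z, flipped) == pytest.approx(10.0, abs=1e-9)


def test_untilted_phantom_planes_parallel(symmetric_phantom):
    volume, _, _ = symmetric_phantom
    record, landmarks = gg.compute_gqoi(volume, seed=0)
    assert record.beta <= 1.5          # coarse voxel jitter only
    # and the tilted phantom recovers its tilt (ground truth comparison)


def test_tilted_phantom_recovers_tilt_angle(fast_gqoi):
    record, _, truth = fast_gqoi
    assert record.beta == pytest.approx(truth.gqoi_true.beta, abs=1.0)


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def test_uniform_slab_mid_surface_and_thickness():
    """A flat slab of known thickness: the EDT ridge sits at the slab centre
    and the local thickness estimate converges to the true value."""
    h = 1.0
    t = 15.0
    grid = np.zeros((40, 40, 30), np.uint8)
    grid[:, :, 5:20] = 2                      # slab z ∈ [5, 20) voxels
    vol = gg.LabeledValveVolume(grid=grid, voxel_size=h, origin=np.zeros(3))
    idx, edt = gg._mid_surface_indices(vol, "anterior")
    centers = vol.voxel_centers(idx)
    interior = (centers[:, 0] > 5) & (centers[:, 0] < 35) \
        & (centers[:, 1] > 5) & (centers[:, 1] < 35)
    assert np.all(np.abs(centers[interior, 2] - 12.5) <= 0.5 * h + 1e-9)
    sites = centers[interior][::50]
    est = [gg._column_thickness(vol, "anterior", s, np.array([0, 0, 1.0]),
                                reach=2 * t) for s in sites]
    assert np.mean(est) == pytest.approx(t, abs=0.5 * h)


def test_phantom_thickness_within_one_voxel(fast_gqoi):
    record, _, truth = fast_gqoi
    assert record.thickness == pytest.approx(truth.gqoi_true.thickness,
                                             abs=VOX)


def test_thickness_insensitive_to_site_seed(fine_phantom, fine_gqoi):
    """The belly is near-uniform in thickness, so different random site
    draws agree closely at the study's working resolution."""
    volume, _, _ = fine_phantom
    _, landmarks, _ = fine_gqoi
    w1 = gg.leaflet_thickness(volume, landmarks, seed=1)
    w2 = gg.leaflet_thickness(volume, landmarks, seed=2)
    assert abs(w1 - w2) / w1 < 0.10


# ---------------------------------------------------------------------------
# perimeter
# ---------------------------------------------------------------------------

def _circle_curves(r=1000.0):
    """Three 120° arcs of a circle in the z=0 plane as 'basal curves'."""
    curves = {}
    spans = {"anterior": (np.pi / 3, -2 * np.pi / 3),
             "left": (np.pi / 3, 2 * np.pi / 3),
             "right": (-np.pi / 3, -2 * np.pi / 3)}
    for leaflet, (a0, da) in spans.items():
        t = np.linspace(0, 1, 41)
        ang = a0 + da * t
        nodes = np.stack([r * np.cos(ang), r * np.sin(ang),
                          np.zeros_like(ang)], axis=1)
        curves[leaflet] = gg.fit_curve_and_length(nodes)
    return curves


def test_perimeter_of_circle_closed_form():
    r = 1000.0
    anl = gg.Plane(point=np.zeros(3), normal=np.array([0, 0, 1.0]))
    l_gamma, contour = gg.valve_perimeter(_circle_curves(r), anl)
    assert l_gamma == pytest.approx(2 * np.pi * r, rel=0.005)


def test_perimeter_projection_idempotent():
    anl = gg.Plane(point=np.zeros(3), normal=np.array([0, 0, 1.0]))
    curves = _circle_curves()
    l1, contour = gg.valve_perimeter(curves, anl)
    reproj = {l: gg.fit_curve_and_length(anl.project(curves[l].nodes))
              for l in gg.LEAFLETS}
    l2, _ = gg.valve_perimeter(reproj, anl)
    assert l2 == pytest.approx(l1, abs=1e-9)


# ---------------------------------------------------------------------------
# record assembly and normalization
# ---------------------------------------------------------------------------

def test_assemble_gqoi_normalization():
    rec = gg.assemble_gqoi("s", 10.0, {"anterior": 1347.3, "left": 1672.6,
                                       "right": 1672.6},
                           {"anterior": 1904.9, "left": 2276.5,
                            "right": 2276.5},
                           650.4, 19.0, 4646.0, 10.0)
    assert round(rec.l_fe_norm["anterior"], 2) == 0.29
    assert rec.l_gamma / rec.l_gamma == 1.0
    for leaflet in gg.LEAFLETS:
        assert rec.l_fe_norm[leaflet] * rec.l_gamma == pytest.approx(rec.l_fe[leaflet])
    with pytest.raises(gg.NormalizationError):
        gg.assemble_gqoi("s", 10.0, rec.l_fe, rec.l_ba, 1.0, 1.0, 0.0, 0.0)


def test_phantom_gqoi_recovery_coarse(fast_gqoi):
    """Coarse-voxel recovery stays within 10% of analytic ground truth
    (the fine-resolution 5% contract is exercised at 2.8 µm)."""
    record, _, truth = fast_gqoi
    g = truth.gqoi_true
    assert record.l_gamma == pytest.approx(g.l_gamma, rel=0.05)
    assert record.height == pytest.approx(g.height, rel=0.10)
    for leaflet in gg.LEAFLETS:
        assert record.l_fe[leaflet] == pytest.approx(g.l_fe[leaflet], rel=0.10)
        assert record.l_ba[leaflet] == pytest.approx(g.l_ba[leaflet], rel=0.10)
        assert record.l_fe_norm[leaflet] == pytest.approx(
            g.l_fe_norm[leaflet], rel=0.10)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

def test_scale_equivariance_of_gqois():
    """Scaling the phantom by s = 2 (voxel size included) doubles every
    dimensional gQOI and leaves normalized ones and β unchanged."""
    base = murine_preset(tvp=10.0, voxel_size=12.0, leaflet_thickness=40.0)
    s = 2.0
    scaled = murine_preset(tvp=10.0, voxel_size=12.0 * s,
                           leaflet_thickness=40.0 * s)
    for f in ("wall_radius_at_anl", "wall_radius_at_stj", "valve_height_true",
              "belly_sag_depth", "wall_thickness"):
        setattr(scaled, f, getattr(base, f) * s)
    r1, _ = gg.compute_gqoi(generate_valve_phantom(base)[0], seed=0)
    r2, _ = gg.compute_gqoi(generate_valve_phantom(scaled)[0], seed=0)
    assert r2.l_gamma == pytest.approx(s * r1.l_gamma, rel=0.02)
    assert r2.height == pytest.approx(s * r1.height, rel=0.04)
    assert r2.height_norm == pytest.approx(r1.height_norm, rel=0.04)
    assert r2.beta == pytest.approx(r1.beta, abs=0.7)
    for leaflet in gg.LEAFLETS:
        assert r2.l_fe_norm[leaflet] == pytest.approx(
            r1.l_fe_norm[leaflet], rel=0.04)


def test_rigid_motion_invariance_of_gqois():
    """A rotated and translated phantom yields the same gQOIs up to voxel
    resampling error."""
    base = murine_preset(tvp=10.0, voxel_size=12.0, leaflet_thickness=40.0)
    moved = murine_preset(tvp=10.0, voxel_size=12.0, leaflet_thickness=40.0)
    moved.axis_direction = np.array([0.3, -0.2, 0.93])
    moved.axis_direction /= np.linalg.norm(moved.axis_direction)
    moved.axis_origin = np.array([310.0, -170.0, 95.0])
    r1, _ = gg.compute_gqoi(generate_valve_phantom(base)[0], seed=0)
    r2, _ = gg.compute_gqoi(generate_valve_phantom(moved)[0], seed=0)
    assert r2.l_gamma == pytest.approx(r1.l_gamma, rel=0.02)
    assert r2.height == pytest.approx(r1.height, rel=0.04)
    assert r2.beta == pytest.approx(r1.beta, abs=1.2)
    for leaflet in gg.LEAFLETS:
        assert r2.l_fe[leaflet] == pytest.approx(r1.l_fe[leaflet], rel=0.04)
        assert r2.l_ba[leaflet] == pytest.approx(r1.l_ba[leaflet], rel=0.04)
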