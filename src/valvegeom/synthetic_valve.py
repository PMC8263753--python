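"""Synthetic tri-leaflet valve phantoms with closed-form ground truth.

The phantom emulates a segmented murine pulmonary valve fixed at a
transvalvular pressure: an arterial wall shaped as a ruled tube between the
annulus circle and a (possibly tilted) commissure circle, and three leaflets,
each a thickened analytic patch spanned between its basal attachment arc on
the wall and a sagging free-edge chord between its two commissures.  The
anterior leaflet is smaller than the left and right ones (scale ≈ 0.8), the
commissure circle is tilted ~10° about the anterior direction, and the
default preset reproduces the gross anatomy of a 1-year-old C57BL/6J mouse
valve (perimeter ≈ 4.6 mm, leaflet thickness ≈ 19 µm, height/perimeter
≈ 0.14).

Every geometric quantity of interest is available in closed form (evaluated
by dense sampling of the analytic curves, never by the voxel pipeline), which
makes the phantom a ground-truth oracle for the measurement code.

The module also generates synthetic collagen-fiber sets (axial von
Mises-Fisher directions, truncated-normal diameters) and linear-in-pressure
gQOI series for exercising the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .geometry_gqoi import (
    LEAFLETS, LEAFLET_COMMISSURES, DEFAULT_LABEL_MAP,
    LabeledValveVolume, Plane, ValveLandmarks, GQOIRecord,
    ResolutionError, assemble_gqoi,
)
from .fiber_frame import FiberSet, fold_axial

__all__ = [
    "ValvePhantomParams",
    "GroundTruth",
    "murine_preset",
    "generate_valve_phantom",
    "generate_fiber_set",
    "generate_gqoi_series",
    "generate_gqoi_records",
]

#: concentration above which fiber directions are treated as exactly aligned
KAPPA_CAP = 1e7


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ValvePhantomParams:
    """Parameters of the analytic valve phantom (lengths in µm, angles deg)."""

    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    wall_radius_at_anl: float = 730.0
    wall_radius_at_stj: float = 760.0
    valve_height_true: float = 775.0
    leaflet_scale: dict = field(default_factory=lambda: {"anterior": 0.8, "left": 1.0, "right": 1.0})
    leaflet_thickness_true: float = 19.0
    tilt_angle_true: float = 10.0
    belly_sag_depth: float = 180.0
    voxel_size: float = 2.8
    tvp: float = 10.0
    seed: int = 0
    wall_thickness: float = 50.0
    #: free-edge midpoint rests this fraction of the belly sag *below* the ANL
    free_edge_drop_frac: float = 0.05

    def validate(self) -> None:
        for name in ("wall_radius_at_anl", "wall_radius_at_stj",
                     "valve_height_true", "leaflet_thickness_true",
                     "belly_sag_depth", "voxel_size", "wall_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(0 < s <= 1 for s in self.leaflet_scale.values()):
            raise ValueError("leaflet scales must lie in (0, 1]")
        if not (0 <= self.tilt_angle_true < 30):
            raise ValueError("tilt angle must lie in [0°, 30°)")
        if self.voxel_size > self.leaflet_thickness_true / 3:
            raise ResolutionError(
                "voxel grid too coarse to separate labels: voxel_size must be "
                "<= leaflet_thickness_true / 3")


def murine_preset(tvp: float = 10.0, voxel_size: float = 2.8, seed: int = 0,
                  jitter: float = 0.0,
                  leaflet_thickness: float = 19.0) -> ValvePhantomParams:
    """Murine pulmonary-valve preset at a stated transvalvular pressure.

    The dimensional parameters are backed out from published normalized
    murine morphometry (perimeter ≈ 4646 µm, height/perimeter ≈ 0.14,
    thickness ≈ 19 µm, tilt ≈ 10°) and are therefore approximate.  ``jitter``
    adds seeded multiplicative sample-to-sample variability (fractional s.d.)
    for cohort generation; the pressure dependence mimics arterial distention
    (radii grow ~12% from 10 to 20 mmHg, then level off).
    """
    distend = {10.0: 1.0, 20.0: 1.12, 30.0: 1.123}.get(float(tvp), 1.0)
    rng = np.random.default_rng(seed)

    def j(x, frac=1.0):
        return x * (1.0 + frac * jitter * rng.standard_normal()) if jitter else x

    return ValvePhantomParams(
        wall_radius_at_anl=j(730.0 * distend),
        wall_radius_at_stj=j(760.0 * distend),
        valve_height_true=j(775.0 * distend ** 0.9),
        leaflet_thickness_true=j(leaflet_thickness, 0.5),
        tilt_angle_true=float(np.clip(j(10.0, 2.0), 0.0, 29.0)),
        belly_sag_depth=j(180.0 * (10.0 / float(tvp)) ** 0.3),
        voxel_size=voxel_size,
        tvp=float(tvp),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# analytic phantom geometry
# ---------------------------------------------------------------------------

def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Right-handed rotation mapping +z onto ``direction`` (Rodrigues)."""
    b = np.asarray(direction, float)
    b = b / np.linalg.norm(b)
    a = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


class ValvePhantom:
    """Closed-form valve geometry in the posed (world) frame.

    Curves are parameterized on t ∈ [0,1] running from the leaflet's first
    commissure to its second (the P1→P2 circumferential convention); surfaces
    on (t, u) ∈ [0,1]² with u = 0 on the basal attachment and u = 1 on the
    free edge.
    """

    def __init__(self, params: ValvePhantomParams):
        params.validate()
        self.params = params
        p = params
        scales = np.array([p.leaflet_scale[l] for l in LEAFLETS], float)
        widths = 2 * np.pi * scales / scales.sum()
        w_a, w_l, w_r = widths
        # anterior sector centred on azimuth 0
        self.psi_commissure = np.array([w_a / 2,              # P1 anterior/left
                                        -w_a / 2,             # P2 anterior/right
                                        w_a / 2 + w_l])       # P3 left/right
        # azimuth paths psi(t), first -> second commissure
        self._psi_path = {
            "anterior": (w_a / 2, -w_a),     # P1 -> P2 (through 0)
            "left": (w_a / 2, w_l),          # P1 -> P3
            "right": (-w_a / 2, -w_r),       # P2 -> P3 (through the back)
        }
        beta = np.deg2rad(p.tilt_angle_true)
        self._m = np.tan(beta)
        self._e1 = np.array([np.cos(beta), 0.0, np.sin(beta)])
        self._e2 = np.array([0.0, 1.0, 0.0])
        self._stj_center = np.array([0.0, 0.0,
                                     p.valve_height_true - self._m * p.wall_radius_at_stj])
        self._rot = _rotation_to(p.axis_direction)
        self._org = np.asarray(p.axis_origin, float)
        self.commissures = self._pose(np.array([self._stj_rim(psi)
                                                for psi in self.psi_commissure]))

    # -- canonical-frame pieces ------------------------------------------
    def _pose(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self._rot.T + self._org

    def _stj_rim(self, psi):
        psi = np.asarray(psi, float)
        return (self._stj_center
                + self.params.wall_radius_at_stj
                * (np.cos(psi)[..., None] * self._e1 + np.sin(psi)[..., None] * self._e2))

    def _anl_circle(self, psi):
        psi = np.asarray(psi, float)
        r = self.params.wall_radius_at_anl
        return np.stack([r * np.cos(psi), r * np.sin(psi),
                         np.zeros_like(psi)], axis=-1)

    def _wall_canonical(self, psi, s):
        """Ruled inner wall surface between the ANL circle (s=0) and the
        commissure circle (s=1); s extrapolates linearly outside [0,1]."""
        a = self._anl_circle(psi)
        c = self._stj_rim(psi)
        s = np.asarray(s, float)[..., None]
        return (1.0 - s) * a + s * c

    def wall(self, psi, s):
        return self._pose(self._wall_canonical(psi, s))

    def _leaflet_psi(self, leaflet, t):
        psi0, span = self._psi_path[leaflet]
        return psi0 + span * np.asarray(t, float)

    def _basal_canonical(self, leaflet, t):
        t = np.asarray(t, float)
        return self._wall_canonical(self._leaflet_psi(leaflet, t), (2 * t - 1) ** 2)

    def _free_canonical(self, leaflet, t):
        t = np.asarray(t, float)
        ia, ib = LEAFLET_COMMISSURES[leaflet]
        pa = self._stj_rim(self.psi_commissure[ia])
        pb = self._stj_rim(self.psi_commissure[ib])
        chord = (1 - t)[..., None] * pa + t[..., None] * pb
        dip = 0.5 * (pa[2] + pb[2]) + self.params.free_edge_drop_frac * self.params.belly_sag_depth
        out = chord.copy()
        out[..., 2] -= dip * 4 * t * (1 - t)
        return out

    def basal(self, leaflet, t):
        return self._pose(self._basal_canonical(leaflet, t))

    def free(self, leaflet, t):
        return self._pose(self._free_canonical(leaflet, t))

    def surface(self, leaflet, t, u):
        """Leaflet mid-surface S(t, u): ruled between basal arc and free edge
        with an additional quadratic belly sag along the valve axis."""
        t = np.asarray(t, float)
        u = np.asarray(u, float)
        b = self._basal_canonical(leaflet, t)
        f = self._free_canonical(leaflet, t)
        s = (1 - u)[..., None] * b + u[..., None] * f
        s[..., 2] -= (self.params.belly_sag_depth
                      * (4 * t * (1 - t)) * (4 * u * (1 - u)))
        return self._pose(s)


# ---------------------------------------------------------------------------
# ground truth (dense sampling of the closed forms; pipeline-independent)
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic reference values for one phantom."""

    params: ValvePhantomParams
    landmarks_true: ValveLandmarks
    gqoi_true: GQOIRecord
    mid_surfaces_true: dict            # leaflet -> callable S(t, u)
    free_curves_true: dict             # leaflet -> callable F(t)
    basal_curves_true: dict            # leaflet -> callable B(t)
    phantom: "ValvePhantom | None" = None

    def azimuthal_xi(self, leaflet: str, points: np.ndarray) -> np.ndarray:
        """Exact normalized azimuth of points about the valve axis, measured
        from the leaflet's first commissure toward its second — the analytic
        counterpart of the pipeline's circumferential coordinate ξ."""
        ph = self.phantom
        q = (np.atleast_2d(points) - ph._org) @ ph._rot
        ang = np.arctan2(q[:, 1], q[:, 0])
        psi0, span = ph._psi_path[leaflet]
        rel = (np.sign(span) * (ang - psi0)) % (2 * np.pi)
        rel = np.where(rel > 1.5 * np.pi, rel - 2 * np.pi, rel)
        return rel / abs(span)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _arc_midpoint(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    i = int(np.searchsorted(cum, cum[-1] / 2))
    f = (cum[-1] / 2 - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-30)
    return pts[i - 1] + f * (pts[i] - pts[i - 1])


def _plane_from_points(p0, p1, p2, ref) -> Plane:
    n = np.cross(p1 - p0, p2 - p0)
    n = n / np.linalg.norm(n)
    if n @ ref < 0:
        n = -n
    return Plane(point=(p0 + p1 + p2) / 3.0, normal=n)


def compute_ground_truth(phantom: ValvePhantom, n_dense: int = 100_001) -> GroundTruth:
    """Evaluate every gQOI from the phantom's closed-form curves by dense
    polyline sampling (independent of the voxel pipeline)."""
    p = phantom.params
    t = np.linspace(0.0, 1.0, n_dense)
    basal_pts = {l: phantom.basal(l, t) for l in LEAFLETS}
    free_pts = {l: phantom.free(l, t) for l in LEAFLETS}

    l_ba = {l: _polyline_length(basal_pts[l]) for l in LEAFLETS}
    l_fe = {l: _polyline_length(free_pts[l]) for l in LEAFLETS}
    p5 = {l: _arc_midpoint(basal_pts[l]) for l in LEAFLETS}
    p4 = {l: _arc_midpoint(free_pts[l]) for l in LEAFLETS}

    commissures = phantom.commissures
    ref = commissures.mean(axis=0) - np.mean(list(p5.values()), axis=0)
    anl = _plane_from_points(*(p5[l] for l in LEAFLETS), ref=ref)
    stj = _plane_from_points(*commissures, ref=ref)

    height = float(np.mean(np.abs(anl.signed_distance(commissures))))
    cosb = abs(float(anl.normal @ stj.normal))
    beta = float(np.degrees(np.arccos(np.clip(cosb, -1.0, 1.0))))

    # perimeter: projected basal chains concatenated into the closed contour
    l_gamma = sum(_polyline_length(anl.project(basal_pts[l])) for l in LEAFLETS)

    gqoi = assemble_gqoi("phantom", p.tvp, l_fe, l_ba, height,
                         p.leaflet_thickness_true, l_gamma, beta)
    landmarks = ValveLandmarks(commissures=commissures,
                               free_edge_midpoints=p4, basal_midpoints=p5,
                               anl_plane=anl, stj_plane=stj)
    return GroundTruth(
        params=p, landmarks_true=landmarks, gqoi_true=gqoi,
        mid_surfaces_true={l: (lambda tt, uu, _l=l: phantom.surface(_l, tt, uu))
                           for l in LEAFLETS},
        free_curves_true={l: (lambda tt, _l=l: phantom.free(_l, tt))
                          for l in LEAFLETS},
        basal_curves_true={l: (lambda tt, _l=l: phantom.basal(_l, tt))
                           for l in LEAFLETS},
        phantom=phantom,
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _stamp(grid: np.ndarray, origin: np.ndarray, h: float,
           points: np.ndarray, label: int) -> None:
    """Mark the voxels containing ``points`` with ``label`` where still empty."""
    idx = np.floor((points.reshape(-1, 3) - origin) / h).astype(np.int64)
    ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
    flat = np.ravel_multi_index(tuple(idx[ok].T), grid.shape)
    g = grid.ravel()
    sel = flat[g[flat] == 0]
    g[sel] = label


def _stamp_slab(grid: np.ndarray, origin: np.ndarray, h: float,
                surface_xyz: np.ndarray, normals: np.ndarray,
                half_width: float, label: int, step: float) -> None:
    """Voxelize a thickened surface with centre-in-solid semantics: a voxel
    is marked only when its *centre* lies within ``half_width`` of the
    mid-surface along the local normal, which keeps the voxelized slab
    thickness unbiased regardless of orientation."""
    shape = np.array(grid.shape)
    g = grid.ravel()
    base = surface_xyz.reshape(-1, 3)
    nrm = normals.reshape(-1, 3)
    for d in np.arange(-(half_width + 0.6 * h), half_width + 0.6 * h + step,
                       step):
        pts = base + d * nrm
        idx = np.floor((pts - origin) / h).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx, p, n = idx[ok], pts[ok], nrm[ok]
        centers = origin + (idx + 0.5) * h
        proj = np.abs(np.einsum("ij,ij->i", centers - (p - d * n), n))
        sel = proj <= half_width
        flat = np.ravel_multi_index(tuple(idx[sel].T), grid.shape)
        sel2 = flat[g[flat] == 0]
        g[sel2] = label


def _surface_grid_normals(xyz: np.ndarray) -> np.ndarray:
    """Unit normals of a surface sampled on a 2D parameter grid."""
    du = np.gradient(xyz, axis=0)
    dv = np.gradient(xyz, axis=1)
    n = np.cross(du, dv)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    return n / np.maximum(norm, 1e-30)


def generate_valve_phantom(params: ValvePhantomParams):
    """Voxelize the analytic phantom.

    Returns ``(volume, meshes, truth)``: the labeled voxel volume (labels
    0 background, 1 wall, 2 anterior, 3 left, 4 right), per-leaflet
    mid-surface triangle meshes, and the analytic :class:`GroundTruth`.
    """
    params.validate()
    h = params.voxel_size
    phantom = ValvePhantom(params)
    truth = compute_ground_truth(phantom)

    step = 0.45 * h
    half_w = params.leaflet_thickness_true / 2.0

    # --- sample the surfaces ------------------------------------------------
    psi = np.linspace(0.0, 2 * np.pi,
                      int(np.ceil(2 * np.pi * (params.wall_radius_at_stj
                                               + params.wall_thickness) / step)) + 1)
    s_lo, s_hi = -0.08, 1.12
    span = np.linalg.norm(phantom.wall(0.0, s_hi) - phantom.wall(0.0, s_lo))
    s = np.linspace(s_lo, s_hi, int(np.ceil(span / step)) + 1)
    wall_xyz = phantom.wall(psi[:, None], s[None, :])
    # outward horizontal offset direction (posed)
    out_dir = phantom._pose(np.stack([np.cos(psi), np.sin(psi),
                                      np.zeros_like(psi)], axis=-1)) - phantom._pose(np.zeros((len(psi), 3)))

    leaf_xyz, leaf_nrm = {}, {}
    for l in LEAFLETS:
        nt = int(np.ceil(truth.gqoi_true.l_ba[l] / step)) + 1
        nu = int(np.ceil((np.linalg.norm(
            phantom.surface(l, 0.5, 1.0) - phantom.surface(l, 0.5, 0.0))
            + 2 * params.belly_sag_depth) / step)) + 1
        tt = np.linspace(0.0, 1.0, nt)
        uu = np.linspace(0.0, 1.0, nu)
        xyz = phantom.surface(l, tt[:, None], uu[None, :])
        leaf_xyz[l] = xyz
        leaf_nrm[l] = _surface_grid_normals(xyz)

    # --- bounds -------------------------------------------------------------
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for xyz in [wall_xyz, *leaf_xyz.values()]:
        pts = xyz.reshape(-1, 3)
        lo = np.minimum(lo, pts.min(axis=0))
        hi = np.maximum(hi, pts.max(axis=0))
    pad = params.wall_thickness + half_w + 4 * h
    lo -= pad
    hi += pad
    shape = tuple(np.ceil((hi - lo) / h).astype(int))
    grid = np.zeros(shape, np.uint8)
    origin = lo

    # --- stamp wall then leaflets (first label wins) ------------------------
    # offsets stop half a voxel short of the analytic boundary so that the
    # set of marked voxels has centre-in-solid semantics: a voxel containing
    # a sample at offset ±(w/2 − h/2) has its centre within ±w/2
    for d in np.arange(0.0, params.wall_thickness - 0.49 * h, step):
        _stamp(grid, origin, h,
               wall_xyz + d * out_dir[:, None, :], DEFAULT_LABEL_MAP["wall"])
    for l in LEAFLETS:
        _stamp_slab(grid, origin, h, leaf_xyz[l], leaf_nrm[l], half_w,
                    DEFAULT_LABEL_MAP[l], step)
    del wall_xyz, out_dir, leaf_nrm, leaf_xyz

    # where adjacent leaflets compete for voxels near the commissures the
    # losing label can leave stray fragments; keep one 6-connected component
    # (labelled on the leaflet's bounding box to bound memory)
    from scipy import ndimage as ndi
    from .geometry_gqoi import _bbox_slices
    for l in LEAFLETS:
        sl = _bbox_slices(grid == DEFAULT_LABEL_MAP[l], 1, grid.shape)
        sub = grid[sl]
        mask = sub == DEFAULT_LABEL_MAP[l]
        lab, n = ndi.label(mask)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            sub[mask & (lab != np.argmax(sizes))] = 0
        del lab, mask

    volume = LabeledValveVolume(grid=grid, voxel_size=h, origin=origin)

    # --- mid-surface meshes ---------------------------------------------
    meshes = {}
    for l in LEAFLETS:
        tt = np.linspace(0.0, 1.0, 97)
        uu = np.linspace(0.0, 1.0, 49)
        xyz = phantom.surface(l, tt[:, None], uu[None, :])
        nt, nu = xyz.shape[:2]
        verts = xyz.reshape(-1, 3)
        i, j = np.meshgrid(np.arange(nt - 1), np.arange(nu - 1), indexing="ij")
        v00 = (i * nu + j).ravel()
        v10 = ((i + 1) * nu + j).ravel()
        v01 = (i * nu + j + 1).ravel()
        v11 = ((i + 1) * nu + j + 1).ravel()
        faces = np.concatenate([np.stack([v00, v10, v11], axis=1),
                                np.stack([v00, v11, v01], axis=1)])
        meshes[l] = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    return volume, meshes, truth


# ---------------------------------------------------------------------------
# fiber and series generators
# ---------------------------------------------------------------------------

def generate_fiber_set(mean_direction, concentration: float, n_fibers: int,
                       diameter_mean_nm: float = 90.0,
                       diameter_sd_nm: float = 5.0,
                       frame_name: str = "sem", seed: int = 0,
                       length_mean_um: float = 6.0,
                       length_sd_um: float = 2.0,
                       region_center=(0.0, 0.0, 0.0),
                       region_size: float = 50.0) -> FiberSet:
    """Draw an axial fiber set: directions from a von Mises-Fisher
    distribution about ±``mean_direction`` (antipodally symmetrized, stored
    as the z ≥ 0 hemisphere representative), diameters and lengths from
    truncated normals, centroids uniform in a cube.
    """
    from scipy.stats import truncnorm

    if concentration < 0:
        raise ValueError("concentration κ must be >= 0")
    if n_fibers < 1:
        raise ValueError("need at least one fiber")
    mu = np.asarray(mean_direction, float)
    nmu = np.linalg.norm(mu)
    if abs(nmu - 1.0) > 1e-6:
        raise ValueError("mean_direction must be a unit vector")
    mu = mu / nmu

    rng = np.random.default_rng(seed)
    kappa = float(concentration)
    if kappa >= KAPPA_CAP:
        w = np.ones(n_fibers)
    elif kappa == 0.0:
        w = rng.uniform(-1.0, 1.0, n_fibers)
    else:
        u = rng.uniform(size=n_fibers)
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2 * np.pi, n_fibers)
    sw = np.sqrt(np.clip(1.0 - w ** 2, 0.0, None))
    local = np.stack([sw * np.cos(phi), sw * np.sin(phi), w], axis=1)
    directions = fold_axial(local @ _rotation_to(mu).T)

    def trunc(mean, sd, lo):
        if sd <= 0:
            return np.full(n_fibers, mean)
        a = (lo - mean) / sd
        return truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                             size=n_fibers, random_state=rng)

    diameters = trunc(diameter_mean_nm, diameter_sd_nm, 0.0)
    lengths = trunc(length_mean_um, length_sd_um, 0.1)
    centroids = (np.asarray(region_center, float)
                 + rng.uniform(-0.5, 0.5, (n_fibers, 3)) * region_size)
    return FiberSet(centroids=centroids, directions=directions,
                    diameters_nm=diameters, lengths_um=lengths,
                    frame=frame_name)


def generate_gqoi_series(intercept: float, slope: float, noise_sd: float,
                         n_per_tvp: dict | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Linear-in-pressure scalar gQOI series: value = intercept + slope·TVP
    + N(0, noise_sd).  Default design n = (3, 5, 3) at 10/20/30 mmHg."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_per_tvp is None:
        n_per_tvp = {10: 3, 20: 5, 30: 3}
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for tvp in sorted(n_per_tvp):
        for _ in range(int(n_per_tvp[tvp])):
            val = intercept + slope * tvp
            if noise_sd:
                val += noise_sd * rng.standard_normal()
            rows.append({"sample_id": f"s{k:02d}", "tvp": float(tvp),
                         "value": float(val)})
            k += 1
    return pd.DataFrame(rows)


_DEFAULT_ROW_TRENDS = {
    # (intercept, slope per mmHg) on the normalized scale
    "fe_anterior": (0.29, 0.0003), "fe_left": (0.38, -0.002),
    "fe_right": (0.38, -0.002),
    "ba_anterior": (0.41, 0.0001), "ba_left": (0.49, -0.0011),
    "ba_right": (0.49, -0.0011),
    "height": (0.15, -0.0008), "thickness": (0.0039, 0.0),
    "beta": (10.0, 0.0), "l_gamma": (4554.0, 26.0),
}


def generate_gqoi_records(n_per_tvp: dict | None = None, noise_frac: float = 0.0,
                          seed: int = 0,
                          trends: dict | None = None) -> list[GQOIRecord]:
    """Full synthetic gQOI records with known row-wise linear trends,
    suitable for exercising the table/statistics layer end to end."""
    if n_per_tvp is None:
        n_per_tvp = {10: 3, 20: 5, 30: 3}
    trends = dict(_DEFAULT_ROW_TRENDS, **(trends or {}))
    rng = np.random.default_rng(seed)
    records = []
    k = 0
    for tvp in sorted(n_per_tvp):
        for _ in range(int(n_per_tvp[tvp])):
            def val(key):
                a, b = trends[key]
                v = a + b * tvp
                if noise_frac:
                    v *= 1.0 + noise_frac * rng.standard_normal()
                return v
            lg = val("l_gamma")
            rec = assemble_gqoi(
                f"synth{k:02d}", float(tvp),
                {"anterior": val("fe_anterior") * lg,
                 "left": val("fe_left") * lg, "right": val("fe_right") * lg},
                {"anterior": val("ba_anterior") * lg,
                 "left": val("ba_left") * lg, "right": val("ba_right") * lg},
                val("height") * lg, val("thickness") * lg, lg, val("beta"))
            records.append(rec)
            k += 1
    return records
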