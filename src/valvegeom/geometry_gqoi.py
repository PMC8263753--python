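"""Landmark detection and geometric quantities of interest (gQOIs) for a
labeled tri-leaflet pulmonary-valve segmentation.

The valve is represented as a voxel volume in which the arterial wall and the
three leaflets (anterior, left, right) carry distinct integer labels.  From
this the module identifies the three commissure points P1-P3, splits each
leaflet edge into its free edge and basal attachment, builds the annulus (ANL)
and sino-tubular-junction (STJ) planes, and measures

* ``L_FE`` / ``L_BA`` -- free-edge and basal-attachment arc lengths per leaflet,
* ``H``   -- valve height (mean commissure distance to the ANL plane),
* ``w``   -- leaflet thickness at random belly sites,
* ``L_Γ`` -- valve perimeter (closed contour of the basal attachments
  projected onto the ANL plane), used to normalize all dimensional gQOIs,
* ``β``   -- tilt angle between the ANL and STJ planes.

All coordinates are physical micrometres in a right-handed frame; voxel
indices are 0-based and cell-centred (index ``i`` maps to
``origin + (i + 0.5) * voxel_size``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import interpolate
from scipy.spatial import cKDTree

__all__ = [
    "LabeledValveVolume",
    "Plane",
    "Curve3D",
    "ValveLandmarks",
    "GQOIRecord",
    "LEAFLETS",
    "LEAFLET_COMMISSURES",
    "DEFAULT_LABEL_MAP",
    "ValveGeomError",
    "LandmarkError",
    "TopologyError",
    "ResolutionError",
    "InsufficientDataError",
    "DegeneratePlaneError",
    "NormalizationError",
    "ParametrizationError",
    "find_commissures",
    "extract_leaflet_edges",
    "fit_curve_and_length",
    "fit_closed_curve_and_length",
    "build_planes",
    "valve_height",
    "leaflet_thickness",
    "valve_perimeter",
    "tilt_angle",
    "assemble_gqoi",
    "compute_gqoi",
]

LEAFLETS = ("anterior", "left", "right")

#: Commissure naming convention: P1 = anterior/left, P2 = anterior/right,
#: P3 = left/right.  Each leaflet is bounded by two commissures, listed in
#: (first, second) order; circumferential coordinates run first -> second.
LEAFLET_COMMISSURES = {"anterior": (0, 1), "left": (0, 2), "right": (1, 2)}

DEFAULT_LABEL_MAP = {"wall": 1, "anterior": 2, "left": 3, "right": 4}

_STRUCT26 = np.ones((3, 3, 3), bool)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class ValveGeomError(Exception):
    """Base class for valve-geometry errors."""


class LandmarkError(ValveGeomError):
    """A landmark (commissure, midpoint) could not be detected."""


class TopologyError(ValveGeomError):
    """Edge chains or contours are disconnected or cannot be closed."""


class ResolutionError(ValveGeomError):
    """The voxel grid is too coarse to resolve the requested structure."""


class InsufficientDataError(ValveGeomError):
    """Too few points for the requested fit."""


class DegeneratePlaneError(ValveGeomError):
    """Three defining points are (near-)collinear."""


class NormalizationError(ValveGeomError):
    """A normalization scale is zero or negative."""


class ParametrizationError(ValveGeomError):
    """Points fall outside the leaflet's azimuthal sector."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabeledValveVolume:
    """Labeled voxel segmentation of one valve.

    ``grid`` is indexed ``[ix, iy, iz]`` so that integer index axes coincide
    with the physical x/y/z axes; ``origin`` is the physical position of the
    corner of voxel (0,0,0).
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, float)

    def mask(self, name: str) -> np.ndarray:
        return self.grid == self.label_map[name]

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical centres (µm) of an (N,3) array of voxel indices."""
        return self.origin + (np.asarray(indices, float) + 0.5) * self.voxel_size


@dataclass
class Plane:
    """Oriented plane; the positive side is the arterial (STJ) side."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        n = np.asarray(self.normal, float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise DegeneratePlaneError("zero plane normal")
        self.normal = n / nn

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points).astype(float)
        d = self.signed_distance(pts)
        return pts - d[:, None] * self.normal


@dataclass
class Curve3D:
    """A fitted 3D curve: ordered nodes, smoothing-spline handle, arc length."""

    nodes: np.ndarray
    tck: tuple
    length: float
    role: str = "curve"
    closed: bool = False

    def evaluate(self, u) -> np.ndarray:
        return np.asarray(interpolate.splev(np.asarray(u, float), self.tck)).T

    def sample(self, n: int = 2001) -> np.ndarray:
        return self.evaluate(np.linspace(0.0, 1.0, n))

    def arc_point(self, s: float) -> np.ndarray:
        """Point at arc-length fraction ``s`` in [0, 1] along the curve."""
        pts = self.sample(4001)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        u = np.interp(s * cum[-1], cum, np.linspace(0.0, 1.0, len(pts)))
        return self.evaluate(np.atleast_1d(u))[0]


@dataclass
class ValveLandmarks:
    """Commissures, per-leaflet edge midpoints, and the two valve planes."""

    commissures: np.ndarray                      # (3,3): rows P1, P2, P3
    free_edge_midpoints: dict                    # leaflet -> P4 (3,)
    basal_midpoints: dict                        # leaflet -> P5 (3,)
    anl_plane: Plane
    stj_plane: Plane
    free_curves: dict | None = None              # leaflet -> Curve3D
    basal_curves: dict | None = None             # leaflet -> Curve3D

    @property
    def valve_axis(self) -> np.ndarray:
        """Unit valve axis: the ANL normal, pointing to the arterial side."""
        return self.anl_plane.normal

    @property
    def center(self) -> np.ndarray:
        """Centroid of the three basal midpoints (on the ANL plane)."""
        return np.mean([self.basal_midpoints[l] for l in LEAFLETS], axis=0)

    @property
    def axis_center(self) -> np.ndarray:
        """Circumcenter of the three commissures: for commissures on a circle
        about the valve axis this point lies exactly on the axis, making it
        the natural origin for azimuthal coordinates."""
        a, b, c = self.commissures
        ab, ac = b - a, c - a
        n = np.cross(ab, ac)
        n2 = n @ n
        if n2 < 1e-18:
            return self.center
        rel = ((ac @ ac) * np.cross(n, ab)
               + (ab @ ab) * np.cross(ac, n)) / (2 * n2)
        return a + rel


@dataclass
class GQOIRecord:
    """All gQOIs of one valve at one transvalvular pressure.

    ``l_fe``/``l_ba`` map leaflet id -> µm; normalized twins are the
    dimensional values divided by the valve perimeter ``l_gamma``.
    """

    sample_id: str
    tvp: float
    l_fe: dict
    l_ba: dict
    height: float
    thickness: float
    l_gamma: float
    beta: float
    l_fe_norm: dict = field(default_factory=dict)
    l_ba_norm: dict = field(default_factory=dict)
    height_norm: float = 0.0
    thickness_norm: float = 0.0


# ---------------------------------------------------------------------------
# voxel helpers
# ---------------------------------------------------------------------------

def _bbox_slices(mask: np.ndarray, margin: int, shape) -> tuple:
    # per-axis projections avoid materializing the full index list
    sl = []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        hit = np.flatnonzero(mask.any(axis=other))
        if hit.size == 0:
            raise LandmarkError("empty label mask")
        sl.append(slice(max(int(hit[0]) - margin, 0),
                        min(int(hit[-1]) + margin + 1, shape[ax])))
    return tuple(sl)


def estimate_valve_axis(volume: LabeledValveVolume) -> tuple[np.ndarray, np.ndarray]:
    """Rough (center, unit axis) of the valve before planes are known.

    The wall label forms a short, wide tube, so the tube axis is the
    direction of *least* coordinate variance of the wall voxels.  The sign is
    chosen so the axis points from the sagging leaflet bellies toward the
    arterial side (wall centroid above leaflet centroid).  The result is
    cached on the volume.
    """
    cached = getattr(volume, "_axis_cache", None)
    if cached is not None:
        return cached
    flat = np.flatnonzero(volume.grid.ravel() == volume.label_map["wall"])
    if len(flat) == 0:
        raise LandmarkError("wall label missing")
    flat = flat[:: max(1, len(flat) // 100_000)]
    pts = volume.voxel_centers(
        np.stack(np.unravel_index(flat, volume.grid.shape), axis=1))
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, 0]  # smallest variance

    leaf_pts = []
    for name in LEAFLETS:
        li = np.argwhere(volume.mask(name))
        if len(li) == 0:
            raise LandmarkError(f"leaflet label '{name}' missing")
        leaf_pts.append(volume.voxel_centers(li[:: max(1, len(li) // 30_000)]).mean(axis=0))
    leaf_center = np.mean(leaf_pts, axis=0)
    if axis @ (center - leaf_center) < 0:
        axis = -axis
    volume._axis_cache = (center, axis)
    return center, axis


def _pair_contact_points(volume: LabeledValveVolume, name_a: str, name_b: str) -> np.ndarray:
    """Physical centres of voxels where leaflets a/b are mutually 26-adjacent
    and also 26-adjacent to the wall label."""
    union = volume.mask(name_a) | volume.mask(name_b)
    sl = _bbox_slices(union, 2, volume.grid.shape)
    sub = volume.grid[sl]
    a = sub == volume.label_map[name_a]
    b = sub == volume.label_map[name_b]
    w = sub == volume.label_map["wall"]
    da = ndi.binary_dilation(a, _STRUCT26)
    db = ndi.binary_dilation(b, _STRUCT26)
    dw = ndi.binary_dilation(w, _STRUCT26)
    contact = ((a & db) | (b & da)) & dw
    idx = np.argwhere(contact)
    if len(idx) == 0:
        raise LandmarkError(f"no wall-adjacent contact between leaflets "
                            f"'{name_a}' and '{name_b}'")
    offset = np.array([s.start for s in sl])
    return volume.voxel_centers(idx + offset)


def find_commissures(volume: LabeledValveVolume) -> np.ndarray:
    """Locate the three commissure points P1 (anterior/left), P2
    (anterior/right), P3 (left/right).

    For each leaflet pair, the contact set is the voxels where the two labels
    touch while also touching the wall; the commissure is taken at the
    arterial-most end of that set (centroid of the contact voxels within one
    voxel of the extreme projection onto the valve axis).
    """
    center, axis = estimate_valve_axis(volume)
    pairs = [("anterior", "left"), ("anterior", "right"), ("left", "right")]
    out = []
    for name_a, name_b in pairs:
        pts = _pair_contact_points(volume, name_a, name_b)
        proj = pts @ axis
        sel = proj >= proj.max() - volume.voxel_size
        top = pts[sel]
        # lexicographic sort makes the centroid order-independent and the
        # selection reproducible under permutations of the voxel scan
        top = top[np.lexsort(top.T[::-1])]
        out.append(top.mean(axis=0))
    return np.array(out)


# ---------------------------------------------------------------------------
# mid-surface extraction (shared with the NURBS module)
# ---------------------------------------------------------------------------

def _leaflet_crop(volume: LabeledValveVolume, leaflet: str, margin: int = 4):
    mask = volume.mask(leaflet)
    sl = _bbox_slices(mask, margin, volume.grid.shape)
    offset = np.array([s.start for s in sl])
    return volume.grid[sl], offset


def _chunked_edt(mask: np.ndarray, voxel_size: float,
                 max_voxels: int = 40_000_000, overlap: int = 24) -> np.ndarray:
    """Euclidean distance transform in float32, computed blockwise along the
    longest axis for large volumes.

    Valid for thin structures: a block overlap of ``overlap`` voxels keeps
    every distance up to ``overlap``·voxel exact, far above any leaflet
    half-thickness.  Blockwise evaluation bounds the float64 temporaries of
    the exact EDT to one block at a time.
    """
    if mask.size <= max_voxels:
        return ndi.distance_transform_edt(
            mask, sampling=voxel_size).astype(np.float32)
    axis = int(np.argmax(mask.shape))
    n = mask.shape[axis]
    n_blocks = int(np.ceil(mask.size / max_voxels))
    step = int(np.ceil(n / n_blocks))
    out = np.empty(mask.shape, np.float32)
    for start in range(0, n, step):
        stop = min(start + step, n)
        lo = max(start - overlap, 0)
        hi = min(stop + overlap, n)
        sl = [slice(None)] * 3
        sl[axis] = slice(lo, hi)
        block = ndi.distance_transform_edt(mask[tuple(sl)],
                                           sampling=voxel_size)
        core = [slice(None)] * 3
        core[axis] = slice(start - lo, stop - lo)
        dst = [slice(None)] * 3
        dst[axis] = slice(start, stop)
        out[tuple(dst)] = block[tuple(core)]
        del block
    return out


def _mid_surface_indices(volume: LabeledValveVolume, leaflet: str):
    """Voxel indices (global) and EDT values (µm) of the leaflet mid-surface.

    The mid-surface is the ridge of the Euclidean distance transform of the
    leaflet mask: voxels whose EDT is within half a voxel of the local 3^3
    maximum, i.e. local maxima along the thickness direction.  Cached per
    volume and leaflet.
    """
    cache = getattr(volume, "_midsurface_cache", None)
    if cache is None:
        cache = volume._midsurface_cache = {}
    if leaflet in cache:
        return cache[leaflet]
    sub, offset = _leaflet_crop(volume, leaflet)
    mask = sub == volume.label_map[leaflet]
    edt = _chunked_edt(mask, volume.voxel_size)
    if edt.max() < 1.5 * volume.voxel_size:
        raise ResolutionError(
            f"leaflet '{leaflet}' thinner than 3 voxels at "
            f"voxel size {volume.voxel_size} µm")
    ridge = mask & (edt >= ndi.maximum_filter(edt, size=3) - 0.5 * volume.voxel_size)
    idx = np.argwhere(ridge)
    cache[leaflet] = (idx + offset, edt[tuple(idx.T)])
    return cache[leaflet]


def _rim_mask(leaf_mask: np.ndarray, ridge_local: np.ndarray,
              window: int = 5, threshold: float = 0.65) -> np.ndarray:
    """Boolean rim flag per mid-surface ridge voxel of a thin slab.

    A ridge voxel lies on the slab rim when the local leaflet-voxel
    occupancy (count in a ``window``³ box) drops below ``threshold`` times
    the median occupancy of the ridge: at the rim roughly half of the
    neighbourhood hangs outside the slab.  Counted by direct window sums at
    the ridge voxels only, to avoid filtering the whole crop.
    """
    half = window // 2
    shape = np.array(leaf_mask.shape)
    counts = np.zeros(len(ridge_local), np.int32)
    rng = range(-half, half + 1)
    for dx in rng:
        for dy in rng:
            for dz in rng:
                idx = ridge_local + np.array([dx, dy, dz])
                ok = np.all((idx >= 0) & (idx < shape), axis=1)
                counts[ok] += leaf_mask[tuple(idx[ok].T)]
    return counts < threshold * np.median(counts)


def _decimate(nodes: np.ndarray, spacing: float) -> np.ndarray:
    """Keep nodes at least ``spacing`` apart along the chain; endpoints stay."""
    keep = [0]
    acc = 0.0
    for i in range(1, len(nodes)):
        acc += float(np.linalg.norm(nodes[i] - nodes[i - 1]))
        if acc >= spacing:
            keep.append(i)
            acc = 0.0
    if keep[-1] != len(nodes) - 1:
        keep.append(len(nodes) - 1)
    return nodes[keep]


def _basal_band_points(volume, leaflet, sub, offset):
    """Scattered candidate points of the basal attachment: all leaflet
    voxels 26-adjacent to the wall (1-voxel dilation defines "attached").

    The band is asymmetric — the leaflet separates from the wall only
    gradually on the ventricular side, so the band trails far down the wall
    — but its arterial-side edge tracks the attachment line to within about
    a voxel; the chain builder therefore keeps the top layer per azimuthal
    bin (see :func:`_order_chain` with ``select='top'``).
    """
    leaf = sub == volume.label_map[leaflet]
    wall = sub == volume.label_map["wall"]
    band = leaf & ndi.binary_dilation(wall, _STRUCT26)
    if not band.any():
        raise TopologyError(f"leaflet '{leaflet}' has no wall attachment")
    return volume.voxel_centers(np.argwhere(band) + offset)


def extract_leaflet_edges(volume: LabeledValveVolume, leaflet: str,
                          commissures: np.ndarray,
                          node_spacing: float | None = None):
    """Split the leaflet edge into free-edge and basal-attachment node chains.

    The basal attachment is traced through the wall-adjacent band of leaflet
    voxels (attachment = 26-adjacency to the wall within a 1-voxel dilation);
    the free edge is the non-wall-adjacent rim of the extracted mid-surface.
    Both chains are ordered from the leaflet's first commissure to its second
    (azimuthal order about the valve axis), decimated to ``node_spacing``
    (default: max(10 µm, one voxel)) and anchored exactly at the two
    commissure points.

    Returns ``(free_nodes, basal_nodes)`` as (N,3) µm arrays.
    """
    ca, cb = (commissures[i] for i in LEAFLET_COMMISSURES[leaflet])
    center, axis = estimate_valve_axis(volume)

    sub, offset = _leaflet_crop(volume, leaflet)
    leaf = sub == volume.label_map[leaflet]
    wall = sub == volume.label_map["wall"]
    wall_d1 = ndi.binary_dilation(wall, _STRUCT26)
    if not (leaf & wall_d1).any():
        raise TopologyError(f"leaflet '{leaflet}' has no wall attachment")
    mid_idx, ridge_edt = _mid_surface_indices(volume, leaflet)
    mid_pts = volume.voxel_centers(mid_idx)
    mid_local = mid_idx - offset
    rim = _rim_mask(leaf, mid_local)
    half_w = float(ridge_edt.max())
    if node_spacing is None:
        # keep the node spacing above the rim-band half-thickness: node
        # jitter amplitude scales with the band width, and sampling it at a
        # finer wavelength turns it into arc-length inflation
        node_spacing = max(10.0, 3.0 * volume.voxel_size, 1.1 * half_w)
    n_dil = max(2, int(np.ceil(half_w / volume.voxel_size)) + 2)
    wall_far = ndi.binary_dilation(wall, _STRUCT26, iterations=n_dil)
    near_wall = wall_far[tuple(mid_local.T)]

    basal_pts = _basal_band_points(volume, leaflet, sub, offset)
    # rim voxels where the slab is truncated by a *neighbouring leaflet*
    # (label competition near the commissures) are not free edge either
    others = np.zeros_like(leaf)
    for other in LEAFLETS:
        if other != leaflet:
            others |= sub == volume.label_map[other]
    if others.any():
        others = ndi.binary_dilation(others, _STRUCT26, iterations=2)
        near_other = others[tuple(mid_local.T)]
    else:
        near_other = np.zeros(len(mid_local), bool)
    free_sel = rim & ~near_wall & ~near_other
    if free_sel.sum() < 4:
        raise TopologyError(f"free-edge rim of leaflet '{leaflet}' not found")
    free_pts = mid_pts[free_sel]

    free_nodes = _order_chain(free_pts, ca, cb, center, axis, node_spacing)
    basal_nodes = _order_chain(basal_pts, ca, cb, center, axis, node_spacing,
                               select="top", voxel_size=volume.voxel_size)
    return free_nodes, basal_nodes


def _azimuth_frame(center, axis, ref_point):
    """In-plane basis with azimuth 0 at ``ref_point``."""
    e1 = ref_point - center
    e1 = e1 - (e1 @ axis) * axis
    n = np.linalg.norm(e1)
    if n < 1e-9:
        raise LandmarkError("reference point on the valve axis")
    e1 /= n
    e2 = np.cross(axis, e1)
    return e1, e2


def _sector_angles(points, center, axis, ca, cb):
    """Azimuths of points measured from commissure ``ca`` toward ``cb``,
    returned together with the (signed) sector width."""
    e1, e2 = _azimuth_frame(center, axis, ca)
    rel = points - center
    ang = np.arctan2(rel @ e2, rel @ e1)        # in (-pi, pi], 0 at ca
    rel_b = cb - center
    ang_b = float(np.arctan2(rel_b @ e2, rel_b @ e1)) % (2 * np.pi)
    # decide sector orientation: points should fall between 0 and the second
    # commissure; pick the direction (ccw/cw) that contains the point median
    ang_pos = ang % (2 * np.pi)
    med = np.median(ang_pos)
    if med <= ang_b + 1e-9:
        out, width = ang_pos, ang_b
    else:
        out = (-ang) % (2 * np.pi)
        width = (2 * np.pi - ang_b) % (2 * np.pi)
    # angles just past azimuth 0 wrap to ~2π; map them back to small negatives
    out = np.where(out > width + 0.5 * (2 * np.pi - width), out - 2 * np.pi, out)
    return out, width


def _order_chain(points, ca, cb, center, axis, spacing, select="median",
                 voxel_size=0.0):
    """Order scattered chain points from commissure ca to cb by azimuth,
    reduce them to one node per azimuthal bin, decimate, and anchor the
    endpoints.

    ``select='median'`` takes the component-wise bin median (robust to
    stray rim points); ``select='top'`` takes the median of the bin's
    arterial-most layer (within 1.5 voxels of the maximal axis projection),
    which recovers the basal attachment from its asymmetric contact band.
    """
    ang, width = _sector_angles(points, center, axis, ca, cb)
    inside = (ang > -0.05) & (ang < width + 0.05)
    pts, ang = points[inside], ang[inside]
    if len(pts) < 4:
        raise TopologyError("edge chain too short")
    r_mean = np.mean(np.linalg.norm(pts - center - ((pts - center) @ axis)[:, None] * axis, axis=1))
    nbins = max(8, int(np.ceil(width * r_mean / max(spacing, 1e-9))))
    edges = np.linspace(0.0, width, nbins + 1)
    which = np.clip(np.digitize(ang, edges) - 1, 0, nbins - 1)
    nodes = []
    for i in range(nbins):
        m = which == i
        if not np.any(m):
            continue
        p = pts[m]
        if select == "top":
            proj = p @ axis
            p = p[proj >= proj.max() - 1.5 * voxel_size]
        nodes.append(np.median(p, axis=0))
    nodes = np.array(nodes)
    # azimuth orders bins globally, but where the edge runs steeply many
    # nodes share one azimuth and their relative order is arbitrary;
    # re-ordering by foot position on a heavily smoothed reference spline
    # restores the along-curve order without permitting global jumps
    nodes = _reorder_along_reference(nodes)
    # drop nodes that leave the local chain (mis-detected bins)
    for _ in range(2):
        if len(nodes) < 5:
            break
        mids = 0.5 * (nodes[:-2] + nodes[2:])
        dev = np.linalg.norm(nodes[1:-1] - mids, axis=1)
        keep = np.concatenate([[True], dev <= 3.0 * spacing, [True]])
        if keep.all():
            break
        nodes = nodes[keep]
    nodes = _decimate(nodes, spacing)
    # anchor endpoints at the exact commissure points
    if np.linalg.norm(nodes[0] - ca) > np.linalg.norm(nodes[-1] - ca):
        nodes = nodes[::-1]
    return np.vstack([ca, nodes, cb])


def _reorder_along_reference(nodes: np.ndarray) -> np.ndarray:
    """Re-order approximately ordered chain nodes by their foot position on
    a heavily smoothed spline through them (stable for azimuth ties)."""
    if len(nodes) < 8:
        return nodes
    length = float(np.linalg.norm(np.diff(nodes, axis=0), axis=1).sum())
    try:
        rough = fit_curve_and_length(nodes,
                                     smoothing=len(nodes) * (0.04 * length) ** 2)
    except Exception:
        return nodes
    ref = rough.sample(4001)
    _, foot = cKDTree(ref).query(nodes)
    return nodes[np.argsort(foot, kind="stable")]


# ---------------------------------------------------------------------------
# spline curves and lengths
# ---------------------------------------------------------------------------

def _dedupe(nodes: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    keep = np.concatenate([[True], d > 1e-12])
    return nodes[keep]


_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)


def _spline_arclength(tck) -> float:
    """Arc length of a parametric spline on [0,1] by per-knot-span 16-point
    Gauss-Legendre quadrature of the parametric speed."""
    knots = np.unique(np.clip(tck[0], 0.0, 1.0))
    total = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        if b <= a:
            continue
        u = 0.5 * (b - a) * _GL_X + 0.5 * (a + b)
        der = np.asarray(interpolate.splev(u, tck, der=1))
        speed = np.linalg.norm(der, axis=0)
        total += 0.5 * (b - a) * float(_GL_W @ speed)
    return total


def fit_curve_and_length(nodes: np.ndarray, smoothing: float = 0.0,
                         role: str = "curve") -> Curve3D:
    """Fit a cubic smoothing spline through ordered nodes (chord-length
    parameterized) and measure its arc length by adaptive Gauss quadrature.

    ``smoothing`` is the scipy ``splprep`` residual budget; 0 interpolates.
    """
    nodes = _dedupe(np.asarray(nodes, float))
    if len(nodes) < 4:
        raise InsufficientDataError(f"need >= 4 nodes, got {len(nodes)}")
    chord = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    tck, _ = interpolate.splprep(nodes.T, u=u, s=smoothing, k=3)
    return Curve3D(nodes=nodes, tck=tck, length=_spline_arclength(tck), role=role)


def fit_closed_curve_and_length(nodes: np.ndarray, smoothing: float = 0.0,
                                role: str = "perimeter_contour") -> Curve3D:
    """Fit a periodic cubic spline through an ordered closed node loop."""
    nodes = _dedupe(np.asarray(nodes, float))
    if np.linalg.norm(nodes[0] - nodes[-1]) < 1e-9:
        nodes = nodes[:-1]
    if len(nodes) < 4:
        raise InsufficientDataError("need >= 4 distinct nodes for a closed curve")
    loop = np.vstack([nodes, nodes[0]])
    chord = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    tck, _ = interpolate.splprep(loop.T, u=u, s=smoothing, k=3, per=1)
    return Curve3D(nodes=loop, tck=tck, length=_spline_arclength(tck),
                   role=role, closed=True)


# ---------------------------------------------------------------------------
# planes and scalar gQOIs
# ---------------------------------------------------------------------------

def _plane_through(p0, p1, p2) -> Plane:
    n = np.cross(p1 - p0, p2 - p0)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(p1 - p0), np.linalg.norm(p2 - p0), 1.0)
    if nn < 1e-9 * scale * scale:
        raise DegeneratePlaneError("three defining points are collinear")
    return Plane(point=(p0 + p1 + p2) / 3.0, normal=n / nn)


def build_planes(commissures: np.ndarray, basal_curves: dict,
                 free_curves: dict) -> ValveLandmarks:
    """Build the ANL and STJ planes and the full landmark set.

    P5 (basal midpoint) and P4 (free-edge midpoint) are arc-length midpoints
    of the fitted edge curves; the ANL plane passes through the three P5
    points, the STJ plane through the commissures.  Both normals are oriented
    toward the arterial side (from the annulus toward the commissures).
    """
    p5 = {l: basal_curves[l].arc_point(0.5) for l in LEAFLETS}
    p4 = {l: free_curves[l].arc_point(0.5) for l in LEAFLETS}
    anl = _plane_through(*(p5[l] for l in LEAFLETS))
    stj = _plane_through(*commissures)
    ref = commissures.mean(axis=0) - np.mean(list(p5.values()), axis=0)
    if np.linalg.norm(ref) < 1e-9:
        ref = anl.normal
    if anl.normal @ ref < 0:
        anl.normal = -anl.normal
    if stj.normal @ ref < 0:
        stj.normal = -stj.normal
    return ValveLandmarks(commissures=np.asarray(commissures, float),
                          free_edge_midpoints=p4, basal_midpoints=p5,
                          anl_plane=anl, stj_plane=stj,
                          free_curves=free_curves, basal_curves=basal_curves)


def valve_height(commissures: np.ndarray, anl: Plane) -> float:
    """Mean unsigned distance of the three commissures to the ANL plane (µm)."""
    return float(np.mean(np.abs(anl.signed_distance(commissures))))


def tilt_angle(anl: Plane, stj: Plane) -> float:
    """Dihedral angle β between the ANL and STJ planes, in degrees ∈ [0, 90]."""
    c = abs(float(anl.normal @ stj.normal))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def parametrize_leaflet_points(points: np.ndarray, landmarks: ValveLandmarks,
                               leaflet: str, tol: float = 0.05):
    """Chart (ξ, η) ∈ [0,1]² for points of one leaflet.

    ξ is the normalized azimuth about the valve axis between the leaflet's
    two commissures (0 at the first, 1 at the second); η is the fractional
    position from the basal attachment (0) to the free edge (1), measured as
    d_basal / (d_basal + d_free) with distances to the fitted edge curves.
    """
    points = np.atleast_2d(points)
    ca, cb = (landmarks.commissures[i] for i in LEAFLET_COMMISSURES[leaflet])
    center, axis = landmarks.axis_center, landmarks.valve_axis
    ang, width = _sector_angles(points, center, axis, ca, cb)
    xi = ang / width
    if np.any(xi < -tol) or np.any(xi > 1 + tol):
        raise ParametrizationError(
            f"points outside azimuthal sector of leaflet '{leaflet}'")
    xi = np.clip(xi, 0.0, 1.0)

    basal = landmarks.basal_curves[leaflet].sample(801)
    free = landmarks.free_curves[leaflet].sample(801)
    d_b, _ = cKDTree(basal).query(points)
    d_f, _ = cKDTree(free).query(points)
    eta = d_b / np.maximum(d_b + d_f, 1e-12)
    return xi, eta


def _column_thickness(volume: LabeledValveVolume, leaflet: str,
                      site: np.ndarray, normal: np.ndarray,
                      reach: float) -> float:
    """Local slab thickness: extent of the contiguous run where the
    trilinearly interpolated leaflet indicator exceeds 1/2 along the line
    through ``site`` in the local normal direction, sampled at a fifth of a
    voxel.  Interpolation places the boundary halfway between the last
    labeled and first unlabeled voxel centre, which keeps the estimate
    sub-voxel accurate for oblique and curved slabs."""
    h = volume.voxel_size
    step = h / 5.0
    s = np.arange(-reach, reach + 0.5 * step, step)
    pos = site + s[:, None] * normal
    # local crop of the label mask around the column
    lo = np.floor((pos.min(axis=0) - volume.origin) / h).astype(int) - 2
    hi = np.ceil((pos.max(axis=0) - volume.origin) / h).astype(int) + 3
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, volume.grid.shape)
    crop = (volume.grid[tuple(slice(a, b) for a, b in zip(lo, hi))]
            == volume.label_map[leaflet]).astype(np.float32)
    # voxel-centre coordinates of the samples within the crop
    coords = ((pos - volume.origin) / h - 0.5 - lo).T
    vals = ndi.map_coordinates(crop, coords, order=1, mode="constant", cval=0.0)
    inside = vals >= 0.5
    mid = len(s) // 2
    if not inside[mid]:
        return 0.0
    a = mid
    while a > 0 and inside[a - 1]:
        a -= 1
    b = mid
    while b + 1 < len(s) and inside[b + 1]:
        b += 1
    return (b - a + 1) * step


def leaflet_thickness(volume: LabeledValveVolume, landmarks: ValveLandmarks,
                      n_sites_per_leaflet: int = 3, seed: int = 0) -> float:
    """Mean local leaflet thickness ``w`` (µm) at seeded random belly sites.

    The belly region is the part of each leaflet mid-surface with radial
    coordinate η ∈ [0.35, 0.65] and circumferential coordinate ξ in the
    central half [0.25, 0.75].  At each site the local thickness is measured
    by column integration: the extent of the leaflet label along the local
    surface normal (PCA of the neighbouring mid-surface points), sampled at
    a fifth of a voxel, which stays sub-voxel accurate for oblique and
    curved leaflets.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for leaflet in LEAFLETS:
        idx, edt = _mid_surface_indices(volume, leaflet)
        pts = volume.voxel_centers(idx)
        xi, eta = parametrize_leaflet_points(pts, landmarks, leaflet, tol=0.2)
        belly = (eta >= 0.35) & (eta <= 0.65) & (xi >= 0.25) & (xi <= 0.75)
        if belly.sum() < n_sites_per_leaflet:
            raise ResolutionError(
                f"belly region of leaflet '{leaflet}' unresolved")
        sites = rng.choice(np.flatnonzero(belly), size=n_sites_per_leaflet,
                           replace=False)
        tree = cKDTree(pts)
        reach = 2.0 * float(edt.max()) + 2.0 * volume.voxel_size
        for site_i in sites:
            _, nbr = tree.query(pts[site_i], k=min(16, len(pts)))
            rel = pts[nbr] - pts[nbr].mean(axis=0)
            _, vecs = np.linalg.eigh(rel.T @ rel)
            w = _column_thickness(volume, leaflet, pts[site_i], vecs[:, 0],
                                  reach)
            if w > 0:
                vals.append(w)
    if not vals:
        raise ResolutionError("no valid thickness sites")
    return float(np.mean(vals))


def valve_perimeter(basal_curves: dict, anl: Plane,
                    commissures: np.ndarray | None = None):
    """Valve perimeter length L_Γ: arc length of the closed contour formed by
    projecting all basal attachments onto the ANL plane.

    Returns ``(l_gamma_um, contour)``.  The three projected chains are joined
    at their shared commissure projections into one closed loop; a
    :class:`TopologyError` is raised when chain endpoints do not meet.
    """
    proj = {l: anl.project(basal_curves[l].nodes) for l in LEAFLETS}
    # loop: anterior P1->P2, right P2->P3, left reversed P3->P1
    segs = [proj["anterior"], proj["right"], proj["left"][::-1]]
    scale = sum(basal_curves[l].length for l in LEAFLETS)
    loop = [segs[0]]
    for seg in segs[1:]:
        prev_end = loop[-1][-1]
        if np.linalg.norm(seg[0] - prev_end) > np.linalg.norm(seg[-1] - prev_end):
            seg = seg[::-1]
        if np.linalg.norm(seg[0] - prev_end) > 1e-3 * scale:
            raise TopologyError("basal chains do not meet at a shared commissure")
        loop.append(seg[1:])
    nodes = np.vstack(loop)
    contour = fit_closed_curve_and_length(nodes)
    return contour.length, contour


def assemble_gqoi(sample_id: str, tvp: float, l_fe: dict, l_ba: dict,
                  height: float, thickness: float, l_gamma: float,
                  beta: float) -> GQOIRecord:
    """Assemble a gQOI record, normalizing every dimensional quantity by the
    valve perimeter length L_Γ."""
    if l_gamma <= 0:
        raise NormalizationError("valve perimeter length must be positive")
    return GQOIRecord(
        sample_id=sample_id, tvp=tvp, l_fe=dict(l_fe), l_ba=dict(l_ba),
        height=height, thickness=thickness, l_gamma=l_gamma, beta=beta,
        l_fe_norm={k: v / l_gamma for k, v in l_fe.items()},
        l_ba_norm={k: v / l_gamma for k, v in l_ba.items()},
        height_norm=height / l_gamma,
        thickness_norm=thickness / l_gamma,
    )


def compute_gqoi(volume: LabeledValveVolume, sample_id: str = "valve",
                 tvp: float = float("nan"), seed: int = 0,
                 node_spacing: float | None = None,
                 smoothing: float | None = None,
                 measure_thickness: bool = True):
    """Full gQOI pipeline on one labeled valve volume.

    Returns ``(record, landmarks)``.  ``smoothing=None`` gives each edge
    spline a residual budget matched to the node jitter: one voxel per basal
    node (the wall band averages across the whole leaflet thickness) and
    max(voxel, half the mid-surface ridge half-thickness) per free-edge node
    (free nodes scatter across the rounded rim band, whose width scales with
    the leaflet thickness).  An interpolating spline would turn that jitter
    into arc-length inflation; pass 0 for strict interpolation.
    ``measure_thickness=False`` skips the belly thickness measurement (used
    by the coarse-voxel convergence study where the leaflet is only a few
    voxels thick).
    """
    commissures = find_commissures(volume)
    free_curves, basal_curves = {}, {}
    for leaflet in LEAFLETS:
        fn, bn = extract_leaflet_edges(volume, leaflet, commissures,
                                       node_spacing=node_spacing)
        if smoothing is None:
            _, ridge_edt = _mid_surface_indices(volume, leaflet)
            sigma_free = max(volume.voxel_size, 0.6 * float(ridge_edt.max()))
            budget_free = len(fn) * sigma_free ** 2
            budget_basal = len(bn) * volume.voxel_size ** 2
        else:
            budget_free = budget_basal = smoothing
        free_curves[leaflet] = fit_curve_and_length(fn, budget_free,
                                                    role="free_edge")
        basal_curves[leaflet] = fit_curve_and_length(bn, budget_basal,
                                                     role="basal_attachment")
    landmarks = build_planes(commissures, basal_curves, free_curves)
    h = valve_height(commissures, landmarks.anl_plane)
    beta = tilt_angle(landmarks.anl_plane, landmarks.stj_plane)
    l_gamma, _ = valve_perimeter(basal_curves, landmarks.anl_plane)
    if measure_thickness:
        w = leaflet_thickness(volume, landmarks, seed=seed)
    else:
        w = float("nan")
    record = assemble_gqoi(
        sample_id, tvp,
        {l: free_curves[l].length for l in LEAFLETS},
        {l: basal_curves[l].length for l in LEAFLETS},
        h, w, l_gamma, beta)
    return record, landmarks
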