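"""Tensor-product B-spline (NURBS with unit weights) leaflet mid-surfaces,
central cross-sections, and representative-shape normalization.

Each leaflet mid-surface is fitted as

    S(ξ, η) = Σ_i Σ_j R^{p,q}_{i,j}(ξ, η) P_{i,j},

with open (clamped) knot vectors on [0,1]², cubic orders p = q = 3 and an
8×8 control net by default.  All weights are fixed at one, so the basis is a
plain tensor-product B-spline and the fit reduces to a linear least-squares
problem for the control-point positions, stabilized by a small ridge penalty
on second differences of the control net.

From the fitted surface the central circumferential (c2, η = 0.5) and radial
(r2, through the free-edge midpoint P4) cross-sections are extracted,
projected onto the best-fitted vertical plane (the plane containing the
valve axis closest to the curve), and normalized: the circumferential
abscissa c̄ spans [−1, 1], the radial abscissa r̄ spans [0, 1] with r̄ = 0 at
the basal attachment, and the height h̄ is the signed distance to the ANL
plane divided by the same normalization scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry_gqoi import (
    LEAFLETS, Curve3D, Plane, ValveLandmarks, LabeledValveVolume,
    ValveGeomError, ResolutionError, NormalizationError,
    fit_curve_and_length, parametrize_leaflet_points, _mid_surface_indices,
)

__all__ = [
    "LeafletNURBS",
    "CrossSection",
    "MeanCrossSection",
    "CentralSections",
    "IllPosedFitError",
    "open_uniform_knots",
    "basis_matrix",
    "basis_derivative_matrix",
    "extract_mid_surface",
    "parametrize_points",
    "fit_surface",
    "evaluate_surface",
    "surface_derivative",
    "central_cross_sections",
    "normalize_cross_section",
    "average_cross_sections",
]


class IllPosedFitError(ValveGeomError):
    """The collocation matrix is rank deficient (try a ridge penalty > 0)."""


# ---------------------------------------------------------------------------
# B-spline basis (Cox-de Boor)
# ---------------------------------------------------------------------------

def open_uniform_knots(n_ctrl: int, degree: int) -> np.ndarray:
    """Open (clamped) uniform knot vector on [0,1] for ``n_ctrl`` control
    points of the given degree."""
    if n_ctrl <= degree:
        raise ValueError("need more control points than the degree")
    interior = np.linspace(0.0, 1.0, n_ctrl - degree + 1)[1:-1]
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def basis_matrix(knots: np.ndarray, degree: int, u: np.ndarray) -> np.ndarray:
    """All B-spline basis functions N_{i,degree} evaluated at ``u``.

    Iterative Cox-de Boor recursion, vectorized over evaluation points;
    returns an (len(u), n_basis) matrix with n_basis = len(knots)-degree-1.
    """
    knots = np.asarray(knots, float)
    u = np.atleast_1d(np.asarray(u, float))
    m = len(knots) - 1
    # degree-0 indicators over the m spans; the last nonempty span is closed
    left = knots[:-1][None, :]
    right = knots[1:][None, :]
    N = ((u[:, None] >= left) & (u[:, None] < right)).astype(float)
    at_end = u >= knots[-1] - 0.0
    if np.any(at_end):
        nonempty = np.flatnonzero(knots[1:] > knots[:-1])
        N[at_end] = 0.0
        N[at_end, nonempty[-1]] = 1.0
    for d in range(1, degree + 1):
        nb = m - d
        new = np.zeros((len(u), nb))
        for i in range(nb):
            den1 = knots[i + d] - knots[i]
            den2 = knots[i + d + 1] - knots[i + 1]
            if den1 > 0:
                new[:, i] += (u - knots[i]) / den1 * N[:, i]
            if den2 > 0:
                new[:, i] += (knots[i + d + 1] - u) / den2 * N[:, i + 1]
        N = new
    return N


def basis_derivative_matrix(knots: np.ndarray, degree: int,
                            u: np.ndarray) -> np.ndarray:
    """First derivatives N'_{i,degree}(u), same layout as :func:`basis_matrix`."""
    knots = np.asarray(knots, float)
    u = np.atleast_1d(np.asarray(u, float))
    if degree == 0:
        return np.zeros((len(u), len(knots) - 1))
    lower = basis_matrix(knots, degree - 1, u)
    nb = len(knots) - degree - 1
    out = np.zeros((len(u), nb))
    for i in range(nb):
        den1 = knots[i + degree] - knots[i]
        den2 = knots[i + degree + 1] - knots[i + 1]
        if den1 > 0:
            out[:, i] += degree / den1 * lower[:, i]
        if den2 > 0:
            out[:, i] -= degree / den2 * lower[:, i + 1]
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LeafletNURBS:
    """Fitted tensor-product B-spline mid-surface of one leaflet."""

    degree_xi: int
    degree_eta: int
    knots_xi: np.ndarray
    knots_eta: np.ndarray
    control_points: np.ndarray        # (n, m, 3) µm
    weights: np.ndarray               # (n, m), all ones here
    leaflet_id: str = ""
    rms_residual: float = float("nan")

    def __post_init__(self):
        self.knots_xi = np.asarray(self.knots_xi, float)
        self.knots_eta = np.asarray(self.knots_eta, float)
        self.control_points = np.asarray(self.control_points, float)
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights <= 0):
            raise ValueError("NURBS weights must be positive")

    @property
    def shape(self):
        return self.control_points.shape[:2]


@dataclass
class CrossSection:
    """One normalized central cross-section of one leaflet."""

    direction: str                     # "circumferential" | "radial"
    abscissa: np.ndarray               # c̄ ∈ [-1,1] or r̄ ∈ [0,1]
    height: np.ndarray                 # h̄ (0 at the ANL plane)
    plane: Plane                       # best-fitted vertical plane
    normalization_scale: float         # µm
    leaflet_id: str = ""
    tvp: float = float("nan")


@dataclass
class MeanCrossSection:
    """Pointwise mean ± sd of several sections on a shared abscissa grid."""

    direction: str
    abscissa: np.ndarray
    mean_height: np.ndarray
    sd_height: np.ndarray
    n_samples: int
    tvp: float = float("nan")


class CentralSections(NamedTuple):
    c2: Curve3D
    r2: Curve3D
    xi_star: float
    eta_star: float


# ---------------------------------------------------------------------------
# mid-surface extraction and parametrization
# ---------------------------------------------------------------------------

def extract_mid_surface(volume: LabeledValveVolume, leaflet: str,
                        k_normals: int = 12):
    """Mid-surface point cloud of a leaflet with local surface normals.

    The mid-surface is the ridge of the leaflet's Euclidean distance
    transform; normals are the smallest-variance PCA axes of the
    ``k_normals`` nearest ridge points.
    """
    idx, _ = _mid_surface_indices(volume, leaflet)
    points = volume.voxel_centers(idx)
    if len(points) < 100:
        raise ResolutionError(
            f"only {len(points)} mid-surface points for leaflet '{leaflet}'")
    k = min(k_normals, len(points) - 1)
    tree = cKDTree(points)
    _, nbr = tree.query(points, k=k + 1)
    rel = points[nbr[:, 1:]] - points[:, None, :]
    cov = np.einsum("nki,nkj->nij", rel, rel) / k
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    return points, normals


def parametrize_points(points: np.ndarray, landmarks: ValveLandmarks,
                       leaflet: str):
    """(ξ, η) ∈ [0,1]² chart of leaflet points: ξ is the normalized azimuth
    between the leaflet's two commissures about the valve axis, η the
    fractional basal→free-edge position."""
    return parametrize_leaflet_points(points, landmarks, leaflet)


# ---------------------------------------------------------------------------
# fitting and evaluation
# ---------------------------------------------------------------------------

def _second_difference_penalty(n: int, m: int) -> np.ndarray:
    """Stacked second-difference operators over an (n, m) control net acting
    on the row-major flattened net."""
    def d2(k):
        d = np.zeros((max(k - 2, 0), k))
        for i in range(k - 2):
            d[i, i:i + 3] = (1.0, -2.0, 1.0)
        return d
    blocks = []
    if n > 2:
        blocks.append(np.kron(d2(n), np.eye(m)))
    if m > 2:
        blocks.append(np.kron(np.eye(n), d2(m)))
    if not blocks:
        return np.zeros((0, n * m))
    return np.vstack(blocks)


def fit_surface(points: np.ndarray, params_uv, degree_xi: int = 3,
                degree_eta: int = 3, n_ctrl_xi: int = 8, n_ctrl_eta: int = 8,
                ridge: float = 1e-3, leaflet_id: str = "",
                point_weights: np.ndarray | None = None) -> LeafletNURBS:
    """Least-squares fit of the control net to scattered mid-surface points.

    ``params_uv`` is the (ξ, η) pair per point.  ``ridge`` is a dimensionless
    relative weight on the squared second differences of the control net (it
    multiplies a penalty with the same units as the data misfit, so the fit
    is exactly equivariant under uniform scaling and rigid motion).  With
    ``ridge = 0`` a rank-deficient collocation matrix raises
    :class:`IllPosedFitError`.
    """
    points = np.asarray(points, float)
    xi, eta = (np.asarray(a, float) for a in params_uv)
    npts = len(points)
    if npts < n_ctrl_xi * n_ctrl_eta:
        raise IllPosedFitError("fewer points than control points")
    ku = open_uniform_knots(n_ctrl_xi, degree_xi)
    kv = open_uniform_knots(n_ctrl_eta, degree_eta)
    bu = basis_matrix(ku, degree_xi, xi)
    bv = basis_matrix(kv, degree_eta, eta)
    a = np.einsum("ki,kj->kij", bu, bv).reshape(npts, -1)

    if point_weights is not None:
        w = np.asarray(point_weights, float)[:, None]
        ata = a.T @ (w * a)
        atx = a.T @ (w * points)
    else:
        ata = a.T @ a
        atx = a.T @ points
    if ridge > 0:
        d = _second_difference_penalty(n_ctrl_xi, n_ctrl_eta)
        lam = ridge * npts / max(len(d), 1)
        ata = ata + lam * (d.T @ d)
    else:
        if np.linalg.matrix_rank(ata) < ata.shape[0]:
            raise IllPosedFitError(
                "collocation matrix is rank deficient; use ridge > 0")
    ctrl = np.linalg.solve(ata, atx)
    resid = a @ ctrl - points
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return LeafletNURBS(degree_xi=degree_xi, degree_eta=degree_eta,
                        knots_xi=ku, knots_eta=kv,
                        control_points=ctrl.reshape(n_ctrl_xi, n_ctrl_eta, 3),
                        weights=np.ones((n_ctrl_xi, n_ctrl_eta)),
                        leaflet_id=leaflet_id, rms_residual=rms)


def _check_domain(xi, eta):
    xi = np.atleast_1d(np.asarray(xi, float))
    eta = np.atleast_1d(np.asarray(eta, float))
    if np.any(xi < -1e-12) or np.any(xi > 1 + 1e-12) \
            or np.any(eta < -1e-12) or np.any(eta > 1 + 1e-12):
        raise ValueError("(ξ, η) outside the parametric domain [0,1]²")
    return np.clip(xi, 0, 1), np.clip(eta, 0, 1)


def evaluate_surface(surface: LeafletNURBS, xi, eta) -> np.ndarray:
    """Evaluate S(ξ, η) by the Cox-de Boor recursion (paired ξ/η arrays)."""
    scalar = np.ndim(xi) == 0 and np.ndim(eta) == 0
    xi, eta = _check_domain(xi, eta)
    bu = basis_matrix(surface.knots_xi, surface.degree_xi, xi)
    bv = basis_matrix(surface.knots_eta, surface.degree_eta, eta)
    num = np.einsum("ki,kj,ijc->kc", bu, bv,
                    surface.control_points * surface.weights[:, :, None])
    den = np.einsum("ki,kj,ij->k", bu, bv, surface.weights)
    pts = num / den[:, None]
    return pts[0] if scalar else pts


def surface_derivative(surface: LeafletNURBS, xi, eta,
                       direction: str = "xi") -> np.ndarray:
    """Partial derivative ∂S/∂ξ or ∂S/∂η (unit weights assumed)."""
    scalar = np.ndim(xi) == 0 and np.ndim(eta) == 0
    xi, eta = _check_domain(xi, eta)
    if direction == "xi":
        bu = basis_derivative_matrix(surface.knots_xi, surface.degree_xi, xi)
        bv = basis_matrix(surface.knots_eta, surface.degree_eta, eta)
    elif direction == "eta":
        bu = basis_matrix(surface.knots_xi, surface.degree_xi, xi)
        bv = basis_derivative_matrix(surface.knots_eta, surface.degree_eta, eta)
    else:
        raise ValueError("direction must be 'xi' or 'eta'")
    out = np.einsum("ki,kj,ijc->kc", bu, bv, surface.control_points)
    return out[0] if scalar else out


def project_parameters(surface: LeafletNURBS, points: np.ndarray,
                       xi0, eta0, n_iter: int = 3):
    """Foot-point projection: refine (ξ, η) per point by damped Gauss-Newton
    minimization of ‖S(ξ, η) − x‖², clipped to the domain."""
    xi = np.asarray(xi0, float).copy()
    eta = np.asarray(eta0, float).copy()
    pts = np.asarray(points, float)
    for _ in range(n_iter):
        s = evaluate_surface(surface, xi, eta)
        sx = surface_derivative(surface, xi, eta, "xi")
        se = surface_derivative(surface, xi, eta, "eta")
        r = pts - s
        a11 = np.einsum("ij,ij->i", sx, sx)
        a12 = np.einsum("ij,ij->i", sx, se)
        a22 = np.einsum("ij,ij->i", se, se)
        b1 = np.einsum("ij,ij->i", sx, r)
        b2 = np.einsum("ij,ij->i", se, r)
        det = np.maximum(a11 * a22 - a12 ** 2, 1e-12)
        dxi = np.clip((a22 * b1 - a12 * b2) / det, -0.05, 0.05)
        deta = np.clip((a11 * b2 - a12 * b1) / det, -0.1, 0.1)
        xi = np.clip(xi + dxi, 0.0, 1.0)
        eta = np.clip(eta + deta, 0.0, 1.0)
    return xi, eta


def fit_leaflet_surface(points: np.ndarray, landmarks: ValveLandmarks,
                        leaflet: str, degree: int = 3, n_ctrl: int = 8,
                        ridge: float = 1e-3, n_param_iters: int = 2,
                        edge_trim: float = 0.03,
                        anchor_weight: float = 0.15) -> LeafletNURBS:
    """Fit a leaflet mid-surface with edge anchoring and parameter
    correction.

    Two voxel-scale artefacts are handled here.  First, the extracted ridge
    bends up the arterial wall near the basal attachment (the medial locus
    of the leaflet-wall wedge follows the wedge bisector), so cloud points
    with η below ``edge_trim`` are discarded and the η = 0 / η = 1 surface
    edges are instead anchored to the fitted basal and free-edge curves with
    a combined ``anchor_weight`` share of the total least-squares weight.
    Second, the initial (ξ, η) chart inherits edge-curve noise, which
    inflates the residual in the near field of the edges; each correction
    round projects every cloud point onto the current surface (foot-point
    parameters) and refits.  The reported RMS residual is over the retained
    cloud points only.
    """
    points = np.asarray(points, float)
    xi, eta = parametrize_leaflet_points(points, landmarks, leaflet)
    keep = (eta > edge_trim) & (eta < 1.0 - edge_trim)
    if keep.sum() >= 100:
        points, xi, eta = points[keep], xi[keep], eta[keep]

    n_anchor = 150
    s = np.linspace(0.0, 1.0, n_anchor)
    basal_pts = landmarks.basal_curves[leaflet].evaluate(s)
    free_pts = landmarks.free_curves[leaflet].evaluate(s)
    a_xi_b, _ = parametrize_leaflet_points(basal_pts, landmarks, leaflet, tol=0.2)
    a_xi_f, _ = parametrize_leaflet_points(free_pts, landmarks, leaflet, tol=0.2)
    anchor_pts = np.vstack([basal_pts, free_pts])
    anchor_xi = np.concatenate([a_xi_b, a_xi_f])
    anchor_eta = np.concatenate([np.zeros(n_anchor), np.ones(n_anchor)])
    w_anchor = anchor_weight * len(points) / ((1 - anchor_weight) * 2 * n_anchor)

    def refit(xi_c, eta_c):
        all_pts = np.vstack([points, anchor_pts])
        all_xi = np.concatenate([xi_c, anchor_xi])
        all_eta = np.concatenate([eta_c, anchor_eta])
        weights = np.concatenate([np.ones(len(points)),
                                  np.full(2 * n_anchor, w_anchor)])
        return fit_surface(all_pts, (all_xi, all_eta), degree_xi=degree,
                           degree_eta=degree, n_ctrl_xi=n_ctrl,
                           n_ctrl_eta=n_ctrl, ridge=ridge,
                           leaflet_id=leaflet, point_weights=weights)

    surf = refit(xi, eta)
    for _ in range(n_param_iters):
        xi, eta = project_parameters(surf, points, xi, eta)
        surf = refit(xi, eta)
    resid = evaluate_surface(surf, xi, eta) - points
    surf.rms_residual = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return surf


# ---------------------------------------------------------------------------
# central cross-sections
# ---------------------------------------------------------------------------

def central_cross_sections(surface: LeafletNURBS, landmarks: ValveLandmarks,
                           leaflet: str, n_samples: int = 201) -> CentralSections:
    """Extract the central radial (r2) and circumferential (c2) sections.

    r2 = S(ξ*, ·) with ξ* chosen so the η = 1 endpoint is nearest the
    free-edge midpoint P4; c2 = S(·, η*) through the belly point S(ξ*, 0.5),
    i.e. η* = 0.5.
    """
    p4 = landmarks.free_edge_midpoints[leaflet]
    xi_grid = np.linspace(0.0, 1.0, 1001)
    edge = evaluate_surface(surface, xi_grid, np.ones_like(xi_grid))
    xi_star = float(xi_grid[np.argmin(np.linalg.norm(edge - p4, axis=1))])
    eta_star = 0.5

    tt = np.linspace(0.0, 1.0, n_samples)
    r2_pts = evaluate_surface(surface, np.full_like(tt, xi_star), tt)
    c2_pts = evaluate_surface(surface, tt, np.full_like(tt, eta_star))
    r2 = fit_curve_and_length(r2_pts, role="cross_section")
    c2 = fit_curve_and_length(c2_pts, role="cross_section")
    return CentralSections(c2=c2, r2=r2, xi_star=xi_star, eta_star=eta_star)


def _best_vertical_plane(points: np.ndarray, axis: np.ndarray) -> Plane:
    """Plane containing the valve-axis direction that minimizes the sum of
    squared distances to the points (1-D eigenproblem over in-plane normals)."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal basis of the plane perpendicular to the axis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ axis) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    center = points.mean(axis=0)
    rel = points - center
    q = np.stack([rel @ e1, rel @ e2], axis=1)
    cov = q.T @ q / len(q)
    evals, evecs = np.linalg.eigh(cov)
    nu2 = evecs[:, 0]                       # smallest in-plane variance
    normal = nu2[0] * e1 + nu2[1] * e2
    return Plane(point=center, normal=normal)


def normalize_cross_section(curve, anl: Plane, valve_axis: np.ndarray,
                            direction: str, leaflet_id: str = "",
                            tvp: float = float("nan"),
                            n_samples: int = 201) -> CrossSection:
    """Project a cross-section onto its best-fitted vertical plane and
    normalize to the representative-shape coordinates.

    The abscissa is the in-plane horizontal coordinate, the height the
    signed distance to the ANL plane; both are divided by the normalization
    scale (half the abscissa extent for circumferential sections, the full
    extent for radial ones), so c̄ spans [−1, 1] and r̄ spans [0, 1] with
    r̄ = 0 at the basal end (the first sample of the curve).
    """
    pts = curve.sample(n_samples) if isinstance(curve, Curve3D) \
        else np.asarray(curve, float)
    plane = _best_vertical_plane(pts, valve_axis)
    proj = plane.project(pts)
    axis = np.asarray(valve_axis, float)
    axis = axis / np.linalg.norm(axis)
    horiz = np.cross(axis, plane.normal)
    horiz /= np.linalg.norm(horiz)
    a = (proj - proj.mean(axis=0)) @ horiz
    if a[-1] < a[0]:                        # abscissa increases along the curve
        a = -a
    h = anl.signed_distance(pts)
    extent = a.max() - a.min()
    if extent < 1e-6 * max(np.abs(h).max(), 1.0):
        raise NormalizationError("near-vertical cross-section cannot be "
                                 "normalized in the abscissa direction")
    if direction == "circumferential":
        scale = extent / 2.0
        abscissa = (a - (a.max() + a.min()) / 2.0) / scale
    elif direction == "radial":
        scale = extent
        abscissa = (a - a.min()) / scale
        if abscissa[0] > 0.5:               # basal end must sit at r̄ = 0
            abscissa = 1.0 - abscissa
    else:
        raise ValueError("direction must be 'circumferential' or 'radial'")
    return CrossSection(direction=direction, abscissa=abscissa,
                        height=h / scale, plane=plane,
                        normalization_scale=scale, leaflet_id=leaflet_id,
                        tvp=tvp)


def average_cross_sections(sections: list, n_grid: int = 101) -> MeanCrossSection:
    """Resample sections of one direction/TVP onto a common abscissa grid and
    take the pointwise mean and standard deviation."""
    if len(sections) < 2:
        raise ValueError("need at least two sections to average")
    directions = {s.direction for s in sections}
    tvps = {s.tvp for s in sections if not np.isnan(s.tvp)}
    if len(directions) != 1 or len(tvps) > 1:
        raise ValueError("cannot average sections of mixed direction or TVP")
    direction = sections[0].direction
    lo, hi = (-1.0, 1.0) if direction == "circumferential" else (0.0, 1.0)
    grid = np.linspace(lo, hi, n_grid)
    heights = []
    for s in sections:
        order = np.argsort(s.abscissa)
        heights.append(np.interp(grid, s.abscissa[order], s.height[order]))
    h = np.array(heights)
    return MeanCrossSection(direction=direction, abscissa=grid,
                            mean_height=h.mean(axis=0),
                            sd_height=h.std(axis=0, ddof=1),
                            n_samples=len(sections),
                            tvp=(tvps.pop() if tvps else float("nan")))
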