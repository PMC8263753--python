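"""Collagen-fiber frame transforms and orientation statistics.

Fiber sets (centroid, direction, diameter, length per fiber) are measured in
a local electron-microscopy frame and mapped into the valve (µCT) frame by a
given rigid transform, mirroring the manual registration of the two imaging
modalities.  Fibers are *axial* quantities (v ≡ −v); directions are stored as
the z ≥ 0 hemisphere representative, ties on the equator broken by v_y ≥ 0,
then v_x ≥ 0.

Orientation is summarized by the polar/azimuth histogram (θ = arccos|v_z| ∈
[0°, 90°], φ = atan2(v_y, v_x) mod 180°), by the principal eigenvector of the
second-moment (dyadic) orientation tensor Σ v vᵀ / N — the vector mean
vanishes for axial data — and by the angle between that mean axis and a
reference direction, typically the circumferential tangent ∂S/∂ξ of the
NURBS-fitted leaflet surface at the imaged location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FiberSet",
    "RigidTransform",
    "OrientationSummary",
    "FrameError",
    "fold_axial",
    "apply_transform",
    "spherical_angles",
    "spherical_to_cartesian",
    "orientation_summary",
    "circumferential_reference",
    "diameter_summary",
]


class FrameError(ValueError):
    """A fiber set and transform disagree on the coordinate frame."""


def fold_axial(v: np.ndarray) -> np.ndarray:
    """Canonical axial representative: flip each vector into the z ≥ 0
    hemisphere; equator ties (v_z = 0) resolved by v_y ≥ 0, then v_x ≥ 0."""
    v = np.atleast_2d(np.asarray(v, float)).copy()
    eps = 1e-12
    z0 = np.abs(v[:, 2]) <= eps
    y0 = z0 & (np.abs(v[:, 1]) <= eps)
    flip = (v[:, 2] < -eps) \
        | (z0 & (v[:, 1] < -eps)) \
        | (y0 & (v[:, 0] < 0))
    v[flip] *= -1.0
    return v


@dataclass
class FiberSet:
    """Axial fiber bundle in a named coordinate frame (µm / nm units)."""

    centroids: np.ndarray       # (N,3) µm
    directions: np.ndarray      # (N,3) unit, z>=0 representative
    diameters_nm: np.ndarray    # (N,)
    lengths_um: np.ndarray      # (N,)
    frame: str

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, float))
        self.directions = fold_axial(self.directions)
        self.diameters_nm = np.asarray(self.diameters_nm, float)
        self.lengths_um = np.asarray(self.lengths_um, float)
        if not self.frame:
            raise FrameError("frame name must be non-empty")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("fiber directions must be unit vectors")
        if np.any(self.diameters_nm <= 0):
            raise ValueError("fiber diameters must be positive")

    def __len__(self):
        return len(self.directions)

    def to_frame_df(self) -> pd.DataFrame:
        n = len(self)
        return pd.DataFrame({
            "fiber_id": np.arange(n),
            "cx_um": self.centroids[:, 0], "cy_um": self.centroids[:, 1],
            "cz_um": self.centroids[:, 2],
            "dx": self.directions[:, 0], "dy": self.directions[:, 1],
            "dz": self.directions[:, 2],
            "diameter_nm": self.diameters_nm, "length_um": self.lengths_um,
            "frame": self.frame,
        })

    @classmethod
    def from_frame_df(cls, df: pd.DataFrame) -> "FiberSet":
        frames = df["frame"].unique()
        if len(frames) != 1:
            raise FrameError("fiber table mixes coordinate frames")
        return cls(centroids=df[["cx_um", "cy_um", "cz_um"]].to_numpy(),
                   directions=df[["dx", "dy", "dz"]].to_numpy(),
                   diameters_nm=df["diameter_nm"].to_numpy(),
                   lengths_um=df["length_um"].to_numpy(),
                   frame=str(frames[0]))


@dataclass
class RigidTransform:
    """Proper rigid transform x ↦ R x + t between two named frames."""

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str
    to_frame: str

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def inverse(self) -> "RigidTransform":
        return RigidTransform(rotation=self.rotation.T,
                              translation=-self.rotation.T @ self.translation,
                              from_frame=self.to_frame, to_frame=self.from_frame)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m, from_frame: str, to_frame: str) -> "RigidTransform":
        m = np.asarray(m, float)
        return cls(rotation=m[:3, :3], translation=m[:3, 3],
                   from_frame=from_frame, to_frame=to_frame)


@dataclass
class OrientationSummary:
    """θ/φ histograms, mean axis, and alignment with a reference direction."""

    theta_histogram: np.ndarray
    theta_edges_deg: np.ndarray
    phi_histogram: np.ndarray
    phi_edges_deg: np.ndarray
    mean_axis: np.ndarray
    alignment_angle_to_reference_deg: float
    second_moment_eigvals: np.ndarray = field(default_factory=lambda: np.zeros(3))


def apply_transform(fibers: FiberSet, transform: RigidTransform) -> FiberSet:
    """Map a fiber set into another frame: centroids affinely, directions by
    rotation only (then re-folded to the canonical hemisphere); diameters and
    lengths are frame-independent."""
    if fibers.frame != transform.from_frame:
        raise FrameError(
            f"fiber set is in frame '{fibers.frame}', transform expects "
            f"'{transform.from_frame}'")
    return FiberSet(
        centroids=fibers.centroids @ transform.rotation.T + transform.translation,
        directions=fold_axial(fibers.directions @ transform.rotation.T),
        diameters_nm=fibers.diameters_nm.copy(),
        lengths_um=fibers.lengths_um.copy(),
        frame=transform.to_frame)


def spherical_angles(direction) -> tuple[float, float]:
    """Axial spherical angles of a unit vector: θ = arccos|v_z| ∈ [0°, 90°]
    and φ = atan2(v_y, v_x) mod 180°; the pole (θ=0) reports φ=0."""
    v = np.asarray(direction, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero vector has no orientation")
    v = v / n
    theta = float(np.degrees(np.arccos(np.clip(abs(v[2]), 0.0, 1.0))))
    if abs(v[0]) < 1e-12 and abs(v[1]) < 1e-12:
        phi = 0.0
    else:
        phi = float(np.degrees(np.arctan2(v[1], v[0]))) % 180.0
    return theta, phi


def spherical_to_cartesian(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector with polar angle θ from +z and azimuth φ from +x."""
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                     np.cos(th)])


def orientation_summary(fibers: FiberSet, reference_direction,
                        n_bins: int = 18) -> OrientationSummary:
    """Histogram θ/φ, the dyadic mean axis, and its angle to a reference."""
    if len(fibers) < 1:
        raise ValueError("need at least one fiber")
    v = fibers.directions
    angles = np.array([spherical_angles(d) for d in v])
    theta_edges = np.linspace(0.0, 90.0, n_bins + 1)
    phi_edges = np.linspace(0.0, 180.0, n_bins + 1)
    # np.histogram closes the right edge of the last bin, so θ = 90° counts
    th_hist, _ = np.histogram(angles[:, 0], bins=theta_edges)
    ph_hist, _ = np.histogram(angles[:, 1], bins=phi_edges)

    moment = v.T @ v / len(v)
    evals, evecs = np.linalg.eigh(moment)
    mean_axis = fold_axial(evecs[:, -1])[0]

    ref = np.asarray(reference_direction, float)
    ref = ref / np.linalg.norm(ref)
    align = float(np.degrees(np.arccos(np.clip(abs(mean_axis @ ref), 0.0, 1.0))))
    return OrientationSummary(theta_histogram=th_hist, theta_edges_deg=theta_edges,
                              phi_histogram=ph_hist, phi_edges_deg=phi_edges,
                              mean_axis=mean_axis,
                              alignment_angle_to_reference_deg=align,
                              second_moment_eigvals=evals)


def circumferential_reference(surface, xi: float, eta: float) -> np.ndarray:
    """Circumferential direction of a fitted leaflet surface: the normalized
    partial derivative ∂S/∂ξ at (ξ, η)."""
    from .nurbs_shape import surface_derivative

    d = surface_derivative(surface, xi, eta, direction="xi")
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("degenerate circumferential tangent")
    return d / n


def diameter_summary(fibers: FiberSet, bin_width_nm: float = 5.0,
                     band_nm: tuple[float, float] = (80.0, 100.0)):
    """Diameter histogram and the fraction of fibers inside ``band_nm``.

    Returns ``(counts, bin_edges_nm, fraction_in_band)``.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    d = fibers.diameters_nm
    lo = np.floor(d.min() / bin_width_nm) * bin_width_nm
    hi = np.ceil(d.max() / bin_width_nm) * bin_width_nm
    if hi <= lo:
        hi = lo + bin_width_nm
    edges = np.arange(lo, hi + 0.5 * bin_width_nm, bin_width_nm)
    counts, _ = np.histogram(d, bins=edges)
    frac = float(np.mean((d >= band_nm[0]) & (d <= band_nm[1])))
    return counts, edges, frac
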