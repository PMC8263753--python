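# Methods

`valvegeom` quantifies the shape and fibrous structure of the murine
pulmonary valve (PV) from labeled 3D segmentations: three leaflet labels
(anterior Aℓ, left Lℓ, right Rℓ) plus the arterial wall, on an isotropic
voxel grid in physical micrometres.  This note records the models, the
estimators, the numerical choices, and what the synthetic phantom does and
does not establish about real data.

## Geometric quantities of interest (gQOIs)

For a valve fixed at a transvalvular pressure (TVP), the pipeline measures:

* **Commissures P1–P3** — for each leaflet pair, the set of voxels where the
  two labels touch (26-adjacency) while also touching the wall; the
  commissure is the arterial-most end of that set (centroid of the contact
  voxels within one voxel of the extreme projection onto the valve axis).
  The rough valve axis used here is the least-variance principal direction
  of the wall voxels (the wall is a short wide tube), oriented from the
  sagging leaflet bellies toward the artery.
* **Free edge / basal attachment** — the leaflet edge is split into the part
  attached to the wall and the free part.  Attachment is defined by a
  1-voxel dilation of the wall label.  The basal chain is traced through
  the *arterial-side edge* of the wall-adjacent voxel band: because a
  closed leaflet separates from the wall only gradually, the band trails
  far down the wall on the ventricular side, while its upper edge tracks
  the attachment line to within about a voxel.  The free chain is the rim
  of the extracted mid-surface away from the wall (and away from
  neighbouring leaflets).  Both chains are reduced to one node per
  azimuthal bin (component-wise median, with an outlier pass that removes
  nodes leaving the local chain), decimated to a node spacing of
  max(10 µm, 3 voxels), and anchored exactly at the two commissures.
* **Edge lengths L_FE, L_BA** — cubic smoothing splines through the node
  chains, parameterized by chord length; arc length by per-knot-span
  16-point Gauss–Legendre quadrature.  The default smoothing budget is
  matched to the node jitter (one voxel per basal node; max(voxel, half the
  ridge half-thickness) per free-edge node) — an interpolating spline would
  convert that jitter into a several-percent arc-length inflation.
* **ANL / STJ planes, H, β** — P5/P4 are arc-length midpoints of the
  basal/free splines; the annulus (ANL) plane passes through the three P5,
  the sino-tubular-junction (STJ) plane through P1–P3; valve height H is
  the mean unsigned commissure distance to the ANL plane and the tilt β is
  the dihedral angle arccos|n_ANL·n_STJ|.
* **Perimeter L_Γ** — the basal chains are projected orthogonally onto the
  ANL plane, concatenated at the shared commissure projections into one
  closed loop, and measured as a periodic-spline arc length.  L_Γ
  normalizes every dimensional gQOI.
* **Thickness w** — at three seeded random mid-surface sites per leaflet in
  the belly region (η ∈ [0.35, 0.65], central circumferential half
  ξ ∈ [0.25, 0.75]), local thickness is measured by *column integration*:
  the extent of the contiguous run where the trilinearly interpolated
  leaflet indicator exceeds ½ along the local surface normal (PCA of
  neighbouring mid-surface points), sampled at a fifth of a voxel.  This
  estimator stays sub-voxel accurate for oblique and curved slabs, where a
  value read off the distance transform carries an orientation-dependent
  half-voxel bias.

Mid-surfaces are extracted as the ridge of the leaflet's Euclidean distance
transform (voxels within half a voxel of the local 3³ EDT maximum).  For
volumes above ~4·10⁷ voxels the EDT runs blockwise along the longest axis
with a 24-voxel overlap — exact for every distance below the overlap, far
above any leaflet half-thickness — which bounds peak memory.

## Leaflet surface model

Each leaflet mid-surface is fitted by a tensor-product B-spline

S(ξ, η) = Σᵢ Σⱼ N⁽ᵖ⁾ᵢ(ξ) N⁽q⁾ⱼ(η) P᠎ᵢⱼ,

a NURBS surface with all weights fixed at one; the fit then stays a linear
least-squares problem for the control points.  Defaults: p = q = 3, 8×8
control net, open uniform knots — enough to resolve the belly sag without
chasing voxel noise; all configurable.  A dimensionless ridge weight
λ = 10⁻³ on the squared second differences of the control net regularizes
the sparsely sampled corners; because the penalty carries the same units as
the data misfit, the fit is exactly equivariant under rigid motion and
uniform scaling.

The fitting chart assigns ξ as the normalized azimuth about the valve axis
between the leaflet's two commissures (origin at the circumcenter of
P1–P3, which lies on the axis) and η as the relative distance between the
basal and free-edge curves.  Two voxel-scale artefacts are handled
explicitly: the EDT ridge bends along the leaflet–wall wedge bisector near
the attachment (those points are trimmed and the η = 0 / η = 1 surface
edges are instead anchored to the extracted edge curves with a 15% weight
share), and the chart inherits edge-curve noise (two rounds of foot-point
projection re-parameterize every point on the current surface and refit).

Central cross-sections: r2 = S(ξ*, ·) with ξ* chosen so the η = 1 endpoint
is nearest the free-edge midpoint P4; c2 = S(·, 0.5).  Each section is
projected onto its best-fitted *vertical* plane (the plane containing the
valve-axis direction minimizing the summed squared distances — a 1-D
eigenproblem over in-plane normals) and normalized: circumferential
abscissa c̄ spans [−1, 1] (scale = half the abscissa extent), radial
abscissa r̄ spans [0, 1] with r̄ = 0 at the basal end (scale = full
extent), and h̄ is the signed ANL distance divided by the same scale.  One
scale per curve.  Sections from different valves at one TVP are averaged
on a common 101-point abscissa grid.

## Collagen fiber statistics

Fibers are axial quantities (v ≡ −v); the canonical representative lies in
the z ≥ 0 hemisphere (equator ties resolved by v_y ≥ 0 then v_x ≥ 0, with a
10⁻¹² tolerance).  A given rigid transform maps a fiber set from its local
SEM frame into the valve frame: centroids affinely, directions by rotation
only; no automatic registration is attempted, mirroring the manual
alignment of the two imaging modalities.  Orientation is summarized by θ =
arccos|v_z| ∈ [0°, 90°], φ = atan2(v_y, v_x) mod 180°, and by the principal
eigenvector of the second-moment tensor Σ v vᵀ/N (the vector mean vanishes
for axial data); the alignment angle is measured against the
circumferential direction ∂S/∂ξ of the fitted surface at the imaged
location.  Diameters are binned at 5 nm with the fraction inside
[80, 100] nm reported.

## Statistics

Valves are fixed at a single pressure each (design n = 3, 5, 3 at
10/20/30 mmHg).  Per TVP: mean ± s.e.m (sample sd / √n).  Each normalized
gQOI is regressed against TVP by OLS over *individual* points, with the
two-sided t-test on the slope (n−2 df); normalized thickness and tilt use
a degenerate constant model (slope ≡ 0, intercept = grand mean) because
their pressure trend is below measurement error.  Left and right leaflets
are pooled with each valve contributing both values (so the pooled row has
up to 2n points).  Regressing on per-TVP means weighted by group size
reproduces the all-points slope exactly (algebraic identity, tested).
Whether the original analysis fitted individual valves or per-TVP means is
not stated; the two differ in the slope's standard error, which is why
only the slope itself is checked against the published table.  Derived
quantities: anterior / left&right mean ratios per TVP, relative perimeter
change between pressures, and the dimensional thickness (constant-model w̄
× group-size-weighted mean L_Γ).

## Synthetic phantom

The phantom is an analytic valve with closed-form ground truth: a ruled
wall between the annulus circle (radius ~730 µm) and a commissure circle
(radius ~760 µm) tilted 10° about the anterior direction; three leaflets
with sector widths proportional to scales (anterior 0.8, left = right =
1.0); basal arcs on the wall dipping to the annulus plane; free-edge chords
sagging so the coaptation midpoint rests just below the annulus; and a
quadratic belly sag (180 µm).  Leaflets are thickened to 19 µm and
voxelized with centre-in-solid semantics (a voxel is labeled only when its
centre lies within half a thickness of the mid-surface), which keeps the
voxelized slab thickness unbiased at any orientation.  Dimensional preset
values are backed out from published normalized murine morphometry
(perimeter ≈ 4646 µm, H/L_Γ ≈ 0.14, w ≈ 19 µm, β ≈ 10°) and are
approximate; ground truth is computed by densely sampling the closed-form
curves (10⁵ points), never by the pipeline under test.

Fiber sets draw axial directions from a von Mises–Fisher distribution about
±μ (antipodally symmetrized; κ ≥ 10⁷ is treated as perfectly aligned) and
diameters/lengths from truncated normals; gQOI series are linear in TVP
with Gaussian noise.  All generators are bit-reproducible under a fixed
seed.

What the phantom does *not* emulate: scanner noise and PSF (volumes arrive
"segmented"), pressure-dependent tissue mechanics (the pressure series only
rescales the geometry), coaptation contact between leaflets, local
thickness variation, and the full anterior asymmetry — the 0.8 scale acts
on the azimuthal sector width, while both edge lengths are dominated by the
commissure-to-annulus vertical excursion, so the phantom's anterior/left&
right length ratios sit near one rather than at the ~0.8–0.9 of real
valves.  Passing the phantom checks therefore demonstrates
correctness of the geometric estimators under voxelization, not robustness
to segmentation error in real µCT data.

## Problem sizes and reproducibility

Accuracy checks run the murine preset at the study's 2.8 µm voxel
(~1.5·10⁸ voxels; every gQOI recovered within 5%, tilt within 1°);
grid-refinement convergence uses a 30 µm-leaflet variant at {8, 4, 2} µm —
the 19 µm preset would be under three voxels thick at 8 µm — and checks
that the absolute error of L_Γ, H and the valve-total free-edge and basal
lengths decreases monotonically.  Surface-fitting and cross-section checks
run at 5 µm, where fits must stay under one voxel RMS.  Unit tests use a
coarse 10 µm / 35 µm fixture for speed, with correspondingly wider
tolerances.  Every stochastic step (thickness sites, fiber draws, cohort
jitter) takes an explicit integer seed recorded in output metadata, and
pipeline reruns with an identical configuration are byte-identical.

## Known limitations

* Commissure detection tops out a couple of voxels below the analytic
  commissure (the apex voxel itself carries the wall label).
* The basal attachment of a leaflet that leaves the wall tangentially is
  intrinsically ill-conditioned at voxel resolution; the arterial-edge rule
  keeps the bias at the one-voxel scale but it does not vanish faster than
  the voxel size.
* The free-edge rim of the mid-surface ends about half a leaflet thickness
  short of the true edge (a medial-axis property), shortening free-edge
  estimates by a fraction of a percent.
* The η chart is not arc-length fractional position; only ξ is compared
  against the phantom's analytic chart.
* Histogram θ-bins close the right edge at 90° (vectors in the equator
  count in the last bin).
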