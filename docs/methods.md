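# Methods

This note records the models, conventions and numerical choices behind
`tissuecarto`, and what the synthetic fixtures do and do not establish
about real microscopy data.

## Coordinate conventions

Image arrays are `(channel, z, y, x)` with voxel spacing `(dz, dy, dx)` in
μm; voxel `(iz, iy, ix)` is centred at the physical point
`(x, y, z) = (ix·dx, iy·dy, iz·dz)`. All meshes live in this μm frame, so
a mesh extracted from a mask and the volume it came from can be combined
without further registration. UV maps occupy the unit square; pixel `(i, j)`
of an R×C projection is the point `u = (j+0.5)/C`, `v = 1 − (i+0.5)/R`
(image row 0 is the top of the square). Triangles that face outward in 3D
have positive signed area in UV; this pins the mirror ambiguity of every
chart so projections are comparable across frames. Positive layer offsets
point along the outward normal — a layer "20 μm inward" is offset −20.

## Extraction

`binarize_volume` thresholds one channel (optional Gaussian pre-smoothing,
off by default so a binary input is reproduced exactly), applies
morphological closing with a ball footprint, and keeps the largest
connected component — the pipeline assumes a single surface of interest
per frame. `refine_mask_levelset` is morphological Chan–Vese with the mask
as the initial level set and a fixed iteration count; region-based level
sets assume roughly bimodal intensity between object and background, which
holds for solid-object segmentations but not for thin-shell images (use
the solid mask for those).

`mask_to_mesh` runs marching cubes at level 0.5 on a Gaussian-smoothed
(σ = 1 voxel) copy of the binary mask. Raw binary marching cubes
overestimates areas by the staircase factor (~6% on a sphere); the
pre-smoothing removes this and is why the extracted 20 μm sphere's area and
volume land within 1% of the closed forms. Orientation is enforced
globally: if the signed (divergence-theorem) volume is negative the face
winding is flipped, guaranteeing outward normals for closed surfaces.
Taubin smoothing uses the uniform-weight (λ, μ) = (0.5, −0.53) pair;
`mu=0` degenerates to pure Laplacian smoothing (which shrinks — exposed
mainly for comparison).

## Unwrapping

The spherical chart is `u = φ/2π` from a chosen meridian, `v = 1 − θ/π`
(v = 1 at the +pole); cylindrical is the analogue on angle × axial
position. Faces straddling the u = 0/1 wrap are cut by duplicating their
minority-side corners *in UV only* (the 3D mesh stays watertight, which
the projection stage needs for normals); the duplicated coordinates are
shifted across the seam and clamped into the square, choosing the side
that clamps the least. The residual distortion is confined to the one ring
of seam-adjacent faces; quantitative measurements should mask the seam
band, as the tests do. Chart slivers (e.g. pole-adjacent faces of noisy
meshes) can have zero UV area; they cover no pixels and are skipped by the
rasterizer with a warning.

`uv_harmonic_disk` maps the boundary loop to a circle by arc length
(starting at the lowest boundary vertex index, for determinism) and solves
the Laplace equation per coordinate with cotangent weights clamped at
zero. Clamping sacrifices a little conformality on obtuse triangles but
buys the Tutte guarantee: with a convex boundary the map is a bijection,
and the flat-disk and hemisphere tests confirm zero flipped triangles.

`conformal_sphere_map` uses conformalized mean-curvature flow: implicit
Euler steps of the diffusion `(M_k − dt·L₀) V_{k+1} = M_k V_k` with the
*initial* cotangent Laplacian L₀ held fixed, recentring and rescaling each
step (dt = 0.05 on the unit-scaled mesh, stop at max |‖v‖−1| < 1e-4 or
300 steps). The flow converges to a conformal spherical embedding; a
damped Möbius-centering iteration (sphere inversions
`T_a(p) = (1−|a|²)(p+a)/|p+a|² + a`, step `a = −½·centroid`) then fixes
the inversion freedom by driving the area-weighted centroid of the image
to the sphere centre, and the result is projected exactly to unit norm.
Median corner-angle distortion on the 2:1:1 ellipsoid is ~0.7°.

`cut_mesh_along_seams` duplicates seam vertices per side by splitting each
cut vertex's face umbrella into components connected through non-cut
edges, then verifies every resulting patch is a disk via its Euler
characteristic (errors name the characteristic found).

## Projection

Rasterization assigns each pixel centre the containing UV triangle and its
barycentric weights; faces are scanned in ascending index order and claim
only unassigned pixels, so overlapping UV resolves deterministically to
the lowest face index (with a warning). Per valid pixel the 3D position
and angle-weighted outward normal are interpolated barycentrically
(normals renormalized), and each layer samples the volume trilinearly at
`position + offset · normal`. Out-of-volume samples get fill value 0 and a
per-layer in-volume flag; background is 0 plus a validity mask, never NaN,
because downstream 2D tooling chokes on NaN. Because geometry is
interpolated from the mesh but intensity from the grid, output resolution
is set by the grid, not the mesh — a 162-vertex and a 2562-vertex sphere
give projections agreeing to 0.6% RMS.

## Alignment and UV transfer

All aligners move only 3D vertices; the UV layer is carried over
bit-identically, which is the whole point of UV transfer: a fixed (u, v)
indexes homologous material across frames.

*Rigid*: similarity ICP. Initialization tries the current pose plus the
four proper principal-axes sign combinations and keeps the lowest
closest-point RMS; the current pose is preferred on ties because for
near-symmetric shapes (spheres, ellipsoids) the PCA pose is ambiguous and
a time-series step should stay near the identity. Closest points are
exact point-to-triangle minima over cKDTree-pruned candidates. The
residual is non-increasing across iterations; non-convergence returns the
best transform with a warning.

*Shrink-wrap*: optional rigid pre-alignment, then `iterations` rounds of
closest-point projection interleaved with `smooth_per_iter` Taubin steps
(defaults 10 and 2), ending with a pure projection so the output lies
exactly on the target. Interleaved smoothing is what removes projection
creases; the defaults are a schedule choice, not a fitted value.

*Möbius*: both meshes are conformally mapped to the unit sphere; after
Möbius centering the residual freedom is a sphere rotation. It is resolved
by matching the smoothed log conformal area factor (zero-mean,
area-weighted) between the two sphere images: a deterministic
super-Fibonacci grid of rotations (default 128) is scored, the best eight
basins are refined by Nelder–Mead with barycentric descriptor
interpolation (nearest-vertex lookup would make the cost piecewise
constant and kill the refinement), and the winner maps each reference
vertex through sphere → target-sphere barycentric lift → 3D, with a final
closest-point projection. The descriptor is this package's choice of
intrinsic, rotation-invariant quantity; published Möbius-registration
objectives differ in detail. On shapes with (near-)symmetries the
recovered rotation is only defined up to the symmetry group.

*Propagation* walks outward from the reference frame in both directions,
aligning each previous deformed mesh onto the next frame, and logs
per-frame RMS residuals. On the 5-frame sphere(r = 10 μm) →
ellipsoid(12, 10, 8 μm) fixture — a 20–25% shape change chosen as a
realistic per-movie deformation — every frame lands on its target surface
to <1% of the radius and fixed-(u, v) points track the exact material
correspondence to ~0.7 μm mean (tolerance 1.5 μm, 15% of the radius).
Closest-point transfer has no notion of material motion, so tangential
drift of this order is inherent to geometry-only alignment, not a bug.

## Cartographic analysis

Area distortion is the per-face ratio of 3D to UV area, normalized so its
UV-area-weighted mean is 1 (the raw ratio is recovered via the stored
scale). With this definition the lat-long sphere chart has distortion
∝ sin(colatitude): polar faces are stretched wide in UV, so their 3D/UV
ratio is small. Per-pixel distortion uses the containing face's constant
value with no smoothing, consistent with the piecewise-linear map; the
raster therefore converges first order under mesh refinement.
`corrected_label_areas` integrates pixel UV area × raw distortion over
each label's valid pixels; a 30° spherical cap comes out within ~1% of
2πR²(1−cos θ) while the uncorrected projected area is off by >150% — the
Jacobian matters.

Surface calculus uses standard linear FEM: per-face gradients of the PL
interpolant (exact on linear functions), divergence as the negative
adjoint of the gradient under barycentric lumped vertex masses (so the
discrete divergence theorem holds to machine precision on closed meshes
and div∘grad equals the cotangent Laplacian), and curl as the divergence
of the in-plane 90°-rotated field, with positive sign for
counter-clockwise circulation about the outward normal (verified against
the rigid-rotation field on the sphere, curl = 2 cos θ).

## Tension inference

Under the assumption that stress is concentrated on cell-cell interfaces,
the tensions at a tricellular vertex balance: Σᵢ Tᵢ tᵢ = 0 in the local
tangent plane (the normal component of any imbalance is discarded —
stresses are assumed in-plane). Tensions are relative; the gauge is fixed
by mean(T) = 1 per connected component. The solve is an equality-
constrained least squares (KKT system via `lstsq`, so leftover gauge
freedom yields the minimum-norm solution); components with fewer balance
equations than free tensions are flagged underdetermined and set to T = 1;
negative solutions are clipped to a small floor and flagged. The vertex
stress Σᵢ Tᵢ tᵢ⊗tᵢ in the 2D tangent basis gives the anisotropy
|λ₁−λ₂|/(λ₁+λ₂) ∈ [0, 1].

Junction extraction finds pixel corners where ≥3 labels meet (merging
adjacent candidates), lifts them through the UV map and estimates endpoint
tangents from the mean of the nearest 8 interface boundary pixels. Eight
rather than a shorter step is a deliberate trade-off: very short steps are
dominated by the ±0.5 px staircase quantization of rasterized interfaces
(4–7° tangent bias at 3 px), while long windows chord-bias curved
interfaces; 8 px keeps the 120° honeycomb junction within ±2°. Tension
recovery through the full pixel path remains quantization-limited — exact
recovery is demonstrated on the generator's analytic network, and the
pixel path is validated on junction counts, positions (<1 px) and angles.

## Synthetic ground truth

`make_shell_volume` emulates a fluorescently labelled surface: intensity
is a Gaussian profile in signed distance to the implicit surface
(σ = thickness/2, signed distance via Newton projection, exact near the
surface where sampling happens) times a texture (uniform, angular
checkerboard, or Voronoi "cells"), plus additive Gaussian noise. The noise
model is additive only — no Poisson shot noise, PSF blur, anisotropic
optics or bleaching — so passing tests demonstrate pipeline correctness,
not robustness to real microscope physics. Defaults (20 μm radius, 1 μm
voxels, 2 μm shell) mirror a small embryo imaged at moderate resolution.

`make_sequence` interpolates ellipsoid semi-axes linearly and carries the
exact material correspondence (shared unit-sphere preimage), so alignment
can be scored against truth rather than against itself.

`make_cell_labels` builds foams whose tensions are *exactly* recoverable,
via the reciprocal-diagram principle: cells are the Voronoi tessellation
of a (possibly jittered) triangular lattice, junctions are the
circumcenters of the dual Delaunay triangles, and each interface's tension
is the length of its dual Delaunay edge. Because Voronoi edges are
perpendicular bisectors of Delaunay edges, the weighted tangents at every
junction are the 90°-rotation of a closed triangle of edge vectors — force
balance holds to machine precision for any seed configuration, with no
relaxation step that could fail to converge. The perfect lattice gives the
uniform honeycomb (T ≡ 1, 120°, zero anisotropy); jitter with relative
amplitude `sigma` spreads tensions by roughly that factor.

All generators draw randomness from a single `numpy` Generator seeded per
call; identical seeds give bit-identical fixtures.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: icospheres at
subdivision 3–4 (642–2562 vertices), volumes ≤ 48³ voxels, projection
grids ≤ 256², 5-frame sequences, ~56-cell foams — sizes at which every
closed-form oracle in the suite is sharp while the full suite stays fast.
None of the aligners is stochastic; the only random inputs are generator
seeds, which the acceptance script derives from `--seed`.

## Known limitations

- Level-set refinement assumes solid-object (not shell) intensity.
- Seam-adjacent faces of angular charts carry clamp distortion; multi-patch
  UV layouts are read from OBJ but not generated.
- Möbius alignment requires closed genus-0 surfaces and inherits the
  symmetry ambiguity of its descriptor.
- Geometry-only UV transfer drifts tangentially where the true tissue
  motion has a tangential component the shapes do not constrain.
- Pixel-path tension inference is limited by rasterization; sub-pixel
  interface fitting is out of scope.
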