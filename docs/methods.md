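# Methods

`efeg` simulates what an array of electric-field sensors (EFEG) would measure
above a human head, compared with a conventional scalp-potential (EEG)
montage, and quantifies two downstream consequences: how many uncorrelated
signals each modality can resolve at a given noise floor, and how accurately
a distributed inverse solver can localize cortical sources from each. This
note documents the models, the synthetic data they run on, the numerical
choices, and what the results do and do not demonstrate.

## Volume conduction models

### Anisotropic concentric-shell model

The reference forward model is a quasi-static 4-shell sphere: brain, CSF,
skull and scalp with outer radii 9.1 / 9.2 / 9.7 / 10.2 cm and radial
conductivities 0.3 / 1.5 / 0.006 / 0.3 S/m. The skull's tangential
conductivity is 10 times its radial one (0.06 S/m), modeling the conductive
diploe between the skull tables. In a shell with radial conductivity
`sigma_r` and tangential conductivity `sigma_t` the potential separates into
spherical harmonics with radial power laws `r**alpha`, where

    alpha (alpha + 1) = n (n + 1) sigma_t / sigma_r,

giving two real exponents per harmonic degree `n` per shell (reducing to
`n` and `-(n+1)` in the isotropic limit). Coefficients are fixed by
regularity at the center, continuity of the potential and of the radial
current density at the interfaces, zero current into the air outside the
scalp, and the free-space multipole expansion of the dipole's primary
source. The exterior potential is continued harmonically
(`r**-(n+1)` terms matched at the scalp) and the field in air is the
negative gradient of that continuation; "scalp" field values are air-side
limits, which is where a contactless sensor would sit.

Numerics: all radii are scaled by the scalp radius and each shell's power
basis is normalized at the shell's boundary, so the per-harmonic interface
systems stay well conditioned to degree 400 (the hard truncation; the series
is cut adaptively when a bound on the term magnitude falls below a relative
tolerance of 1e-8 — the bound is used rather than the potential increment
because the potential vanishes identically on the dipole axis while the
field does not). A general dipole is decomposed into a radial and a
tangential moment at its location; on-axis evaluation points use the closed
pole limit of the order-1 angular terms. The solver is validated four
independent ways: the exact free-space dipole potential (outer boundary
pushed to 100 m), the classical closed-form single-sphere solution, an
independently coded isotropic transfer-matrix solver, and a dense
finite-difference radial boundary-value oracle for the anisotropic stack
(first order at material interfaces, Richardson extrapolated). The E-field
is checked against a central-difference gradient of the potential.

### Boundary-element model

The BEM variant solves the same problem for three nested isotropic
compartments (CSF+brain / skull / scalp, 0.3 / 0.006 / 0.3 S/m) on
triangulated surfaces, so non-spherical geometry can be represented. The
double-layer operator uses per-vertex collocation: triangle solid angles are
exact (van Oosterom–Strackee), lumped one third per vertex for far
triangles; for observers within four median edge lengths of a triangle the
linear shape functions are integrated by 4- or 8-fold triangle subdivision
with exact sub-triangle solid angles. Diagonals come from the closed-surface
identity (2 pi on the surface), the constant null space is removed by
deflation, and the isolated-skull reformulation (exact algebra: an insulated
inner-skull solve plus modified source terms) is applied whenever the skull
is less than a tenth as conductive as the brain. Tangential field components
are obtained exactly as a surface sensor triplet would measure them: forward
differences of the interpolated scalp potential over 1 mm steps along the
local azimuthal and inclinational tangents, with displaced points projected
back to the surface. The radial component is not computed in the BEM — a
boundary solve does not provide the air-side normal derivative directly, and
the comparison deliberately mirrors a surface triplet measurement.

Default meshing puts the inner skull one subdivision finer than the outer
shells (level 4 vs 3: 5,120 vs 1,280 triangles), because discretization
error on the inner skull is amplified by the resistive skull; at that
resolution the scalp potential of a mid-depth radial dipole agrees with the
analytic isotropic solution to better than 5% relative RMS, and halving the
mesh size roughly halves the error. Accuracy degrades for sources within
about one inner-skull edge length of the surface; the spherical model, which
has no such limit, is used for all quantitative anchors.

## Synthetic cortex and sources

Real group-averaged cortical surfaces cannot be redistributed here, so the
source space is synthetic. Each hemisphere is a closed icosphere (the same
topology as a FreeSurfer hemisphere surface) at subdivision 5 (10,242
vertices), centered at the head origin, with its radius modulated by a
band-limited random fold field: a seeded superposition of 32 plane waves
restricted to the sphere, 70% of the power at angular wavenumber 12 and 30%
one octave up (secondary folds), normalized to unit RMS and soft-saturated
at 3 RMS so the surface stays inside the brain shell for every seed. The
left hemisphere is the mirror image of the right. Defaults: base radius
66 mm (crests reach ~86 mm; the real pial surface fits a 90 mm sphere),
RMS fold depth 8 mm. Dipoles sit at every vertex, oriented along the
analytic surface normal. With the defaults about two thirds of the normals
are tangential-dominant with respect to the scalp, close to the ~71%
expected for uniformly random orientations (the solid-angle fraction beyond
45 degrees from the radial direction) and to real cortical statistics.

A source patch is one vertex of the nested subdivision-4 grid (2,562 per
hemisphere, 5,124 in all) together with its third-ring neighborhood: 37
dipoles in the regular case, 31 at the 24 pentagonal grid vertices, 36 where
the ring grazes a pentagonal vertex — an unavoidable feature of any
subdivided icosahedron. All member dipoles share one global amplitude,
calibrated so the strongest patch produces a 10 microvolt peak over the
scalp potential montage (a typical evoked-response magnitude); the
calibrated amplitude is ~2.6 nAm per dipole.

What the generator does not emulate: spatially organized gyri and sulci
(smooth superficial crowns vs steep deep banks — the random field mixes
depth and steepness independently), cortical thickness and area variations,
inter-hemispheric asymmetry, and any physiological correlation structure
between patches (observations are single active patches). Consequently
patch-level fields on this cortex are somewhat weaker and less radial than
on a real pial surface: the strongest patch carries a ~0.3 mV/m peak radial
field after the 10 uV calibration, whereas a single superficial radial
dipole with the same calibration gives ~0.6 mV/m (the order-of-magnitude
anchor of ~1 mV/m is a single-dipole statement). Passing tests therefore
show that the EFEG/EEG comparisons are robust to this class of folded
geometry, not that per-patch amplitudes match any specific brain.

## Sensor montages

Electrode positions of a real 128-channel net are not available, so sensors
are synthesized as a Fibonacci spiral over the spherical cap of polar
half-angle 120 degrees (crown coverage without face and neck). The 128-site
cap has a minimum spacing of 2.4 cm, consistent with high-density EEG; the
485-site variant refines the same cap. Field montages attach the local
radial / inclinational / azimuthal unit frame at each site (3 channels per
site, 384 total); off-scalp montages shift every site radially. Standoffs of
0 / 1 / 10 / 30 mm are used for signal counting and 0–10 cm for
localization.

## Signal counting

For each montage the channels-by-patches data matrix (one column per active
patch) is reduced to its channel covariance (mean-centered across
observations; an uncentered toggle exists), whose eigenvalues are sorted and
normalized by the largest. Read as noise-to-signal power levels, the number
of eigenvalues strictly above a level is the number of uncorrelated signals
detectable at that noise floor. Counts are compared over the realistic band
1e-4..1e-3. Because each montage is normalized by its own largest
eigenvalue, counts are not monotone under channel addition — adding
redundant channels raises the normalizer as much as the spectrum — which is
why the tangential-only pair can match or slightly exceed the full
three-component field, and the radial-only subset trails both.

## Inverse solvers and scoring

Both solvers are linear operators for fixed gain, noise covariance and
regularization. `mne` is the classical regularized minimum norm
`s = R G' (G R G') + N)^-1 d` with an isotropic source prior `R`; the prior
scale is set to the calibrated patch amplitude so the regularization
parameter `lambda` is dimensionless. `harmony` solves the same problem in
the span of the first 64 graph-Laplacian eigenvectors of each hemisphere
mesh (a low-spatial-frequency surface basis), then maps coefficients back to
dipoles; the rationale is that the skull low-pass filters spatial detail, so
high-frequency components of the solution cannot be inferred from the data.
The noise covariance is `N = lambda (C + eps I)` with `C` the simulated
signal covariance and `eps` pinning the identity term to 3% of the mean
channel signal power — emulating irrelevant background cortical activity
plus internal sensor noise. Potential channels are average-referenced (gain
and data); field channels need no reference. `lambda` is tuned per solver
and channel type by minimizing the mean corrected localization error on a
seeded 200-patch subsample over a 7-point log grid (1e-3..1e3), without
masking; masking is applied to the final solutions only. Solutions are
probability-masked: a dipole is kept when a two-sided z-test of its
amplitude against its operator-propagated noise standard deviation is
significant at alpha = 0.05 Bonferroni-corrected by the channel count.

Localization error: the true source location is the member-position mean
re-projected to the nearest cortex vertex; the raw error is the
amplitude-weighted mean geodesic distance from there to the 37
largest-amplitude dipoles of the solution restricted to the source's
hemisphere (a fully masked hemisphere scores "undefined" and is reported,
not dropped); the corrected error subtracts the same measure applied to the
true patch itself and floors at zero (the unfloored value is kept for
audit), so a perfect reconstruction scores exactly zero. Geodesics are
Dijkstra shortest paths over the mesh edge graph augmented with unfolded
cross-edge connections, accurate to ~1–2% of true surface geodesics at
these resolutions — ample for centimeter-scale errors.

## Problem sizes and determinism

Default experiments use the full 5,124-patch source space with 128 potential
and 384 field channels on the spherical model; localization scores a seeded
500-patch subsample with Harmony. BEM experiments default to the reduced
spherical-shell meshes and are primarily used for cross-validation and
qualitative pattern checks (ring-shaped tangential-field magnitude for
radial sources, dumbbell-shaped for tangential ones). Every random draw
descends from one master seed recorded in the experiment config, whose YAML
serialization and content hash accompany all outputs; reruns are
bit-identical.

## Known limitations

- The fold field is statistically, not anatomically, cortex-like; per-patch
  field magnitudes are conservative relative to a real pial surface.
- The falloff of the peak field with sensor distance approaches the
  inverse-cube dipole law only beyond ~1 m from the head; between 10 and
  30 cm standoff the measured log-log slope against distance from the head
  center is ~ -3.7, i.e. steeper than the asymptote, because the source sits
  at 80% of the brain radius and higher multipoles still contribute there.
- Noise enters only through the eigenvalue threshold and the
  `lambda (C + eps I)` covariance; no sensor noise is injected into the
  data themselves, so localization errors are smaller than would be seen
  with noisy measurements, and only their potential-vs-field *ratio* is
  interpreted.
- BEM accuracy is not reliable for sources closer than about one inner-skull
  edge length to the surface; anisotropy cannot be represented in a BEM at
  all.
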