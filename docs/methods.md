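# Methods

This note documents the models, numerical choices and limitations behind
`nrbrt`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physical model and assumptions

A cuboid sample carries spatially varying intrinsic scattering and absorption
at two wavelengths and a fluorophore concentration n with absorption
cross-section σ.  Total attenuations are μe = μa;e + μs;e + nσ at the
excitation wavelength and μf = μa;f + μs;f at the fluorescence wavelength;
reabsorption of fluorescence light by the fluorophore is neglected, as are
refraction and reflection at the boundary (index-matched), polarization, and
finite spectral bandwidth (delta-function absorption/emission spectra,
quantum yield one).  Elastic scattering is isotropic.  These assumptions are
shared by the analytic model and the Monte Carlo engine, so the two can be
compared configuration by configuration.

The inverse problem is two-dimensional: every broken ray lies in a slice
plane (y, z), with z running into the sample from the illuminated face.
Reconstruction proceeds slice by slice.

## Geometry

The three scan directions are represented by unit vectors û₁, û₂, û₃
pointing *from the vertex toward* the source/detector stations.  Direction 1
is normal to the illuminated face; for the transmission scan directions 2 and
3 point to the opposite face at ±45° (mutually orthogonal, 135° from
direction 1); for the backscattering scan all three point back to the
illuminated face, at 0°, 45° and −70°.  A measurement for the ordered pair
(l, k) sends light down −û_l and detects along +û_k; both orderings of a
pair share the same two surface stations, which is what "interchanging
sources and detectors" means operationally.

**Acceptance-cone window.**  The finite detector integrates the
single-scattered intensity over arrival directions within β of its
collimation axis; the admissible polar-angle window Δθ at an observation
point is computed in closed form by intersecting the cone with the set of
directions that back-project onto the source ray.  The window is derived
directly from the defining step functions as an exact 2D arc intersection,
with one degenerate branch
(observation point on the source line, where the full cone of measure 2β is
admissible through a zero-length detector leg).  The implementation is
certified against a brute-force scan of 10⁶ directions on 1000 random
configurations (`validation.window_oracle_check`); the acceptance suite
requires endpoint agreement below the scan resolution.

**Finite-detector factor.**  f̄_lk integrates Δθ/(|r−r_s| sin θ_l) over the
detector footprint on the sample face: a rectangle Δd × Δd/cos α in
"same-detector" mode or a square Δd × Δd in "per-direction-square" mode.
The out-of-plane (x) extent is collapsed to a multiplicative length Δd; the
in-plane integral uses 21-node Gauss–Legendre quadrature (configurable).
The collapse is exact only when the fluorescence leg L2 exceeds roughly
Δd/(2β) — for shorter legs the 3D acceptance cone clips the out-of-plane
footprint.  This matters only where absolute signal shapes are compared with
Monte Carlo data (see Validation below); it cancels identically in the data
function and hence in reconstruction.

## Forward models

**Analytic (single scattering).**  δW = (η₀W/2πσ)·f̄·ñ(R)·exp(−∫μe−∫μf)
with exact Siddon-style voxel traversal for the line integrals and
nearest-voxel sampling of ñ at the vertex (consistent with the
piecewise-constant phantom).  All physical constants default to 1: the
attenuation reconstruction is provably independent of them and
concentrations are reported max-normalized.  A footprint- and cone-resolved
variant (`signal_area_integrated`) integrates ñ·exp over the probed region
instead of evaluating it at the central vertex; it serves as a validation
mode and documents where the point-vertex approximation degrades (near the
detector face and wherever the optical parameters vary across the probed
segment).  Both signal expressions share the 1/(2π) normalization so that
the footprint-resolved form reduces exactly to the point-vertex form in the
constant-field limit — the absolute scale is immaterial throughout.

**Monte Carlo (all scattering orders).**  Analog transport on the voxel
grid: exponential free paths against the local total attenuation at the
photon's current wavelength, sampled by exact voxel-by-voxel chord
accumulation (Woodcock delta-tracking against the majorant is available as
an option; the two agree statistically and Woodcock is ~3× faster on these
phantoms).  At an interaction the channel is chosen proportionally to μa
(termination), μs (isotropic redirect) or, at the excitation wavelength
only, nσ (conversion to the fluorescence wavelength with isotropic
re-emission).  Photon conservation (absorbed + exited = N) holds exactly.
Exit positions are continuous (no scoring mesh).  Scoring follows the
angularly selective detector definition: fluorescence hits within the
surface footprint and within β of the collimation axis contribute
(ŝ_k·ŝ_j)·E_f each.

Randomness: per-source independent streams derived from a master seed via
`numpy.random.SeedSequence(seed, source_index)`; the kernel seeds numpy's
generator once per run, so results are reproducible and independent of
evaluation order.  Full-budget runs of 10¹¹ photons per source are expressed
as a single configurable N; desk-scale experiments use 10⁵–10⁷.

## Projection assembly

For every vertex pixel and direction, station positions are found by inverse
geometry and snapped to a 0.1 mm station grid anchored per direction.  The
snap is exact for the 0°/±45° transmission geometry (stations coincide with
the exact positions); for the −70° backscattering direction the residual
vertex offset is below half a pixel and is accepted — backscattering
reconstructions are correspondingly slightly degraded even before photon
noise.  Nonpositive (photon-starved) measurements are
masked, never propagated as −∞; masked vertices are median-filled before the
Φ assembly and excluded from quality metrics.

## Inversion

From φ_lk = −ln ñ + I_l^e + I_k^f, the symmetric/antisymmetric combinations
satisfy φ_lk(+) = −ln ñ + I_l(+) + I_k(+) and φ_lk(−) = I_l(−) − I_k(−),
where I_l(±) integrates μ(±) along leg l, with μ(+) = (μe+μf)/2 the average
and μ(−) = μe−μf the difference.  Using û_l·∇I_l = −μ(±) at the vertex, the
vector
fields

    Φ(+) = Σ_{l<k} ½(σ_lû_l + σ_kû_k − σ_mû_m) φ_lk(+)
    Φ(−) = Σ_{l<k} ⅓(σ_lû_l − σ_kû_k) φ_lk(−)

give each integral family I_l the total coefficient σ_lû_l, so that
∇·Φ(±) = −(σ₁+σ₂+σ₃)μ(±) pointwise (a *local* formula).  The −ln ñ terms
cancel in Φ(+) because the coefficients sum to zero — which is exactly why
the constraint Σσ_lû_l = 0 defines the weights.  The coefficient
construction was re-derived from these requirements; the overall sign is
fixed by requiring positive attenuation from noiseless homogeneous data
(under our û-toward-source convention both branches take the same sign).
The weights are (1, 1/√2, 1/√2) for the transmission geometry and mixed-sign
for backscattering (all legs exit one face, so a positive combination cannot
vanish).

**Differentiation.**  ∇·Φ uses TV-regularized differentiation: minimize
½‖Ku − g‖² + λ·TV(u) (lagged-diffusivity fixed point, ≤100 iterations,
relative-change tolerance 1e-6, TV smoothing ε=1e-8), where K is the running
sum matching the forward or backward difference; the forward- and
backward-based derivatives are averaged, giving a second-order centered
estimate.  Inputs are median-filtered (3×3 default) and padded by
duplicating 10 edge rows/columns on all sides (cropped after), which moves
the method's boundary artefacts outside the region of interest.  λ is a
per-run setting: tens to hundreds for photon-limited data (per-sample
presets are shipped), and vanishingly small (1e-8) for noise-free data,
where the scheme reduces to plain centered differences and the median
prefilter — a denoising stage — is disabled.  With those noise-free
settings the end-to-end inversion is exact to discretization; with the
prefilter on, sharp inclusions produce localized streaks along their
tangent lines (the same artefact family seen in photon-limited
reconstructions).

**Concentration.**  ln ñ = 2I₁(+) − φ₁₂(+) + φ₃₂(+) − φ₁₃(+), with I₁(+)
integrated along direction 1 so the line never leaves the reconstructed
region.  The formula follows by eliminating I₂, I₃ among the three pairwise
identities ln ñ = I_l(+) + I_k(+) − φ_lk(+), which also fix its overall
sign (verified by noiseless recovery tests).  A pairwise mode and a conventional
fluorescence-tomography mode (known μe, μf, one ordered pair, no
interchange; full-slice maps integrated in absolute coordinates) are also
provided.  Outputs are max-normalized to [0, 1]; the absolute scale would
require calibration of the instrument constants.  If the contrast agent is
absent along the required lines (agent confined to an inclusion), ñ cannot
be reconstructed — the maps are masked accordingly, while μ(±) remain
reconstructable wherever the agent is present (locality).

## Phantoms

Cuboid background plus non-overlapping spherical inclusions, rasterized at
0.1 mm pitch by a voxel-center-in-sphere test (sharp boundaries, no partial
volume).  Inclusions are specified by intrinsic scattering plus
total-attenuation contrasts; intrinsic absorption absorbs the difference and
is validated nonnegative.  The 13-sample reference catalog is encoded by its
dimensionless products (optical depths Lz·μ̄s, absorption ratio μ̄a/μ̄s,
concentration ratio σn̄/μ̄a, inclusion products D·μs and contrasts), which
are unambiguous; several absolute dimensions are not uniquely determined by
those products and are encoded as documented best-effort values, overridable
per field.  Inclusion centers default to the sample center.

## What the generator emulates — and what it does not

The synthetic phantoms reproduce homogeneous backgrounds with step-like
spherical inhomogeneities across weak-to-moderate optical regimes (depths
0.7–4).  Real tissue differs: smoother parameter variations (which would
*reduce* the streak artefacts driven by sharp boundaries), anisotropic
scattering (g ≠ 0), finite quantum yield, spectral bandwidth, refractive
mismatch, detector dark counts and nonlinearity.  Passing tests therefore
demonstrate correctness of the reconstruction mathematics and transport
physics under the stated assumptions, not performance on experimental data.

## Validation experiments (desk scale)

Problem sizes are chosen so the whole suite runs in minutes on one CPU:

1. Window geometry: 1000 random configurations vs a 10⁶-direction scan.
2. Projection identity: 100 random broken rays through a random
   heterogeneous slice, residual < 1e-8 (independent crossing-based
   integrator).
3. Reciprocity null: μe ≡ μf ⟹ max|φ(−)| < 1e-10, |μ(−)|/μ(+) < 1e-6.
4. Parameter recovery: noiseless 51×101 transmission scan with an inclusion;
   interior (≥5 px from edges and inclusion boundary) relative errors below
   5% for μ(±), μe, μf; concentration contrast within 10%.
5. Monte Carlo physics: Beer–Lambert at N=10⁶ (3 binomial σ); full-physics
   MC vs the analytic model at N=10⁷ per source on a Sample-1-like phantom
   (optical depth 0.7, Lz = 8.1 mm) with an enlarged detector (β = 2°,
   Δd = 0.3 mm) to boost counts.  Vertices are restricted to the model's
   validity domain: fluorescence legs > Δd/(2β) (out-of-plane cone
   clipping) and ≥ 0.4 mm from the inclusion boundary (point-vertex
   approximation).  Consistency is assessed per point at 3σ Poisson with a
   single multiple-comparison allowance plus an ensemble χ² test, so the
   check is stable under reseeding.  The backscattering pair is additionally
   required to be noisier than the transmission pair at the deepest probed
   vertices, with noise increasing with separation (the geometry's known
   asymmetry).
6. Noise scaling: one source, nine detectors, N ∈ {10⁵, 10⁶, 10⁷} with
   {64, 16, 8} independent repeats; rms of std/mean across repeats follows
   a log-log slope of −0.5 ± 0.05.

Full-budget error tables (10⁹–10¹¹ photons per source over hundreds of
stations) are outside desk scale; the same pipeline and the per-sample λ/β/Δd
presets support such runs unchanged.

## Known limitations

- The in-plane (x-collapsed) finite-detector factor overestimates signals
  whose fluorescence leg is shorter than ≈ Δd/(2β); reconstruction is
  unaffected (the factor cancels in φ), but absolute signal comparisons must
  respect the validity domain.
- Backscattering station snapping for the −70° direction leaves sub-pixel
  vertex offsets; backscattering μ maps are correspondingly less accurate
  than transmission maps even before noise.
- The TV solver's λ is not calibrated to any physical noise model; presets
  are per-sample empirical values for full-budget runs.
- 3D regularization across slices, anisotropic phase functions and
  iterative/statistical reconstruction are out of scope.
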