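# nrbrt — non-reciprocal broken-ray fluorescence tomography

`nrbrt` implements tomographic image reconstruction for fluorescence imaging
of weakly scattering media (epithelial layers, engineered tissue, small model
organisms) from **angularly selective surface measurements**.  A collimated
source excites a fluorescent contrast agent; the light detected by a
collimated, finite detector has traveled a *broken ray* — two straight legs
joined at the fluorescence vertex, with the wavelength (and hence the
attenuation coefficient) changing at the vertex.  Because the two legs are
attenuated differently, interchanging source and detector changes the
measurement: the broken-ray transform is *non-reciprocal*, and this asymmetry
is what makes simultaneous reconstruction possible.

The package is aimed at researchers developing or evaluating single-scattering
optical tomography: it provides the full numerical chain used to validate the
method — voxelized phantoms, a noise-free analytic forward model, an analog
Monte Carlo photon-transport engine (all scattering orders), projection
assembly, local inversion, and image-quality evaluation.

## The method in brief

For a source in direction l and a detector in direction k with acceptance
half-angle β and side Δd, the single-scattering signal is

    δW_lk = (η₀ W / 2πσ) · f̄_lk · ñ(R) · exp(−∫_leg1 μe − ∫_leg2 μf),

with ñ = σ^{3/2} n the scaled fluorophore concentration, μe, μf the total
attenuations at the excitation and fluorescence wavelengths (μ = μa + μs + nσ
at excitation), and f̄_lk a purely geometric finite-detector factor.  The data
function

    φ_lk(R) = −ln[ δW_lk / (η₀ W f̄_lk / 2πσ) ]
            = −ln ñ(R) + ∫_leg-l μe + ∫_leg-k μf

is measured for all six ordered pairs of three fixed coplanar directions
(sources and detectors are interchanged to complete the scan).  Writing
μ(±) for (μe+μf)/2 and μe−μf, the symmetric/antisymmetric combinations
φ(±) = (φ_lk ± φ_kl)-type averages feed a **local** inversion formula

    μ(±)(R) = −(σ₁+σ₂+σ₃)⁻¹ ∇·Φ(±)(R),

where Φ(±) are vector-weighted combinations of the φ(±) maps and the
constants σ_l solve σ₁û₁ + σ₂û₂ + σ₃û₃ = 0.  Derivatives are computed with
total-variation-regularized differentiation (median prefilter and edge
padding for noisy data).  The concentration follows from
ln ñ = 2 I₁(+) − φ₁₂(+) + φ₃₂(+) − φ₁₃(+), with I₁(+) the integral of the
reconstructed μ(+) along the surface normal, and is reported max-normalized.

## Worked example

A noiseless transmission scan of a 51 × 101-pixel slice (0.1 mm pitch,
optical depth 0.7) containing a spherical inclusion with twofold contrast in
μe, μf and n, reconstructed and compared against the model:

```python
from nrbrt.validation import parameter_recovery_check
res = parameter_recovery_check()
for k in ("mu_plus_max_rel", "mu_minus_max_rel", "n_contrast_ratio"):
    print(k, round(res[k], 5))
```

prints

```
mu_plus_max_rel 1e-05
mu_minus_max_rel 2e-05
n_contrast_ratio 1.99456
```

i.e. the average attenuation μ(+) and the spectral difference μ(−) are
recovered to about 1e-5 maximum interior relative error from noise-free data
(discretization accuracy), and the inclusion-to-background concentration
ratio (true value 2) is recovered to 0.3%.  With Monte Carlo data the
accuracy is photon-budget limited; the validation experiments quantify
exactly how (noise ∝ 1/√N).

The thirteen-sample reference catalog is available as
`nrbrt.phantoms.sample_library()`, and a configuration-driven pipeline as a
CLI:

```bash
nrbrt pipeline --config run.yaml --out results/run1
```

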