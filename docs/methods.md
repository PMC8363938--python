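# Methods

## The model

Iron in nigral tissue accelerates transverse relaxation through two
mechanisms that act on very different scales and are treated as statistically
independent, so the gradient-echo (GE) and spin-echo (SE) magnitude decays
factor into per-mechanism envelopes:

    S_GE(TE) = exp(-R2*_nano TE) * S*_micro(TE) * exp(-R2*_other TE)
    S_SE(TE) = exp(-R2_nano  TE) * S_micro(TE)  * exp(-R2_other  TE)

**Nanoscale.** Water protons exchange past iron-loaded ferritin and
neuromelanin on nanosecond timescales, far below any echo time, so the
contribution is a plain exponential that affects R2 and R2* equally:

    R2_nano = R2*_nano = r2_FT <c_FT>_V + r2_NM <c_NM>_V

with empirical relaxivities per iron load (defaults r2_FT = 0.02,
r2_NM = 0.8 s^-1 per ug/g at 7 T). Two presets ship: the printed rounded
literature values, and values back-derived from the reported compartment
rates (7.54 s^-1 at 8.9 ug/g NM; 1.14 s^-1 at 51.1 ug/g FT). Tests pin the
formula; the relaxivities themselves are configuration.

**Microscale.** Iron-rich neuromelanin clusters inside dopaminergic somata
perturb the local Larmor frequency. Concentration maps (ug iron / g tissue)
scale to a volume susceptibility chi(r) = rho (c_NM chi_NM + c_FT chi_FT)
with chi_NM = 3.3 and chi_FT = 1.3 ppb per ug/g, and the frequency shift is
the dipole-kernel convolution evaluated in k-space,
df = f0 F^-1[(1/3 - kz^2/k^2) F[chi]], B0 along z, f0 = gamma B0 / 2 pi.

Two solvers consume the field:

* *Static dephasing*: the GE microscale decay is the magnitude of the
  Fourier transform of the intravoxel frequency density rho(df); the SE
  microscale rate is zero. For dilute spherical perturbers of volume fraction
  zeta and excess susceptibility dchi the decay is asymptotically exponential
  with R2* = (2 pi / 9 sqrt 3) gamma B0 zeta dchi, valid beyond
  tau = 1/(2 gamma B0 dchi) (about 0.2 ms at nigral iron loads at 7 T).
* *Monte Carlo*: protons random-walk with per-axis step SD sqrt(2 D dt) and
  accrue phase 2 pi df(r(t)) dt; the SE channel negates the phase of the
  first half-echo. D = 0.3 um^2/ms models post mortem tissue, 1.0 in vivo;
  dt = 0.1 ms.

**Biomarkers.** Dividing the sphere rate by the cluster iron load gives an
effective microscale relaxivity r2*_NM = (2 pi / 9 sqrt 3) gamma B0 chi_NM
(about 2.5 s^-1 per ug/g at 7 T), from which two estimators of the
volume-averaged NM-bound iron concentration follow:

    c_NM,1 = (R2* - R2) / r2*_NM                   (~0.4 (R2*-R2) s ug/g)
    c_NM,2 = (R2*|N1 - R2*|S) / (r2_NM + r2*_NM)   (~0.3 dR2* s ug/g)

In vivo extrapolation applies Curie-law susceptibility scaling (about a 5 %
reduction from 293 K to 310 K) and reruns the Monte Carlo stage at the in
vivo diffusion coefficient.

## The synthetic phantom

No real 3D iron map is shipped; the phantom module generates one with the
measured statistics of nigrosome 1: non-overlapping spheres (default radii
5-15 um, a free parameter — soma-scale, below the ~50 um perturber bound
inferred from granular image hypointensities) packed to a target volume
fraction (default 1.97 %), each carrying a log-normal per-cluster iron
concentration (default mean 387, SD 150 ug/g; tissue measurements
give only a mean +/- SEM plus a right-skewed per-neuron histogram spanning
roughly 85-1400 ug/g, so the SD is a configuration choice), over a ferritin
background of 56 ug/g (scalar or linear z-gradient), on a 0.88 um isotropic
grid. Ferritin is zeroed inside clusters (clusters displace the diffuse
pool). Spheres are rasterized by voxel-center inclusion without
partial-volume antialiasing (voxel size << radius) and placed wholly inside
the grid.

What the phantom does *not* emulate: neurites, vessels, myelinated fibers,
the anterior-posterior iron gradient of the whole substantia nigra,
sub-voxel (~100 nm) iron texture, and compartment boundaries (walkers
diffuse freely through clusters with a single D). Passing tests therefore
demonstrate the internal consistency of the forward model and estimators
under these idealized conditions, not their accuracy on real tissue.

## Numerical choices

* **Dipole kernel**: (1/3 - kz^2/k^2) with the k=0 term zeroed; the
  convolution leaves the constant offset undefined, so the output is demeaned
  over the ROI. Default x2 zero-padding per axis suppresses wrap-around; a
  periodic mode (padding=1) serves phantoms meant to tile space. A uniform
  susceptibility map produces an exactly zero field only in periodic mode —
  under zero-padding the volume itself becomes a perturber.
* **Frequency histograms** are trapezoid-normalized probability densities;
  a constant field degenerates to a single-bin point mass. The
  static-dephasing transform integrates the histogram by trapezoid
  quadrature (default 512 bins when built from a map).
* **Monte Carlo**: positions wrap periodically; frequency sampling is
  trilinear by default (nearest available); the phase integral is
  left-Riemann with a fractional final step, so GE echoes need not sit on
  the step grid (the standard multi-echo protocol's 3.34 ms spacing does
  not). SE refocusing is an exact phase sign inversion at a step boundary,
  so SE echo times must be even multiples of dt. One sequential RNG stream
  per run seed makes runs reproducible and independent across seeds.
* **Rate fitting**: `loglinear` is an OLS fit of log S; `rician_floor` fits
  S = sqrt((s0 e^{-R TE})^2 + floor^2) by nonlinear least squares seeded
  from a log-linear fit of the early echoes, with non-convergence returned
  as a flagged fit. ROI statistics use the population SD (ddof=0);
  differences propagate SDs in quadrature.
* **Optical density** uses base-10 logarithms (Beer-Lambert convention).
  Negative biomarker differences are clipped to zero and flagged.
* **Units**: susceptibility in ppb (1e-9 SI), concentrations in ug/g,
  lengths in um, dt in ms, echo times in s, rates in s^-1. NIfTI headers
  store voxel size in mm (um values written as mm x 1e-3).

## Problem sizes and validation

Deterministic constants are validated against hand evaluation; stochastic
stages against closed forms: the FFT field against the analytic sphere
dipole field (<5 % of peak outside a 2-voxel surface shell), the D=0 Monte
Carlo against the Fourier transform of the same field's histogram, SE
attenuation in a uniform gradient against exp(-(2 pi g)^2 D TE^3 / 12), and
the fitted static-dephasing rate of dilute sphere phantoms against the
closed-form rate (within 15 %; at least ~30 perturbers are needed, since
few-sphere phantoms truncate the far-field frequency tail and bias the
fitted rate low). Test phantoms run at 32^3-128^3 voxels with 1e4-2e5
walkers; the acceptance script's convergence figure runs the full 1e6-walker,
128^3 configuration.

End-to-end recovery of the volume-averaged NM iron concentration through
(R2* - R2)/r2*_NM is validated within 25 % over a 2x range of zeta
(0.01-0.02) and cluster load (194-387 ug/g) at D = 0.3 um^2/ms with echoes
up to 16 ms. The estimator assumes static dephasing; its systematic error is
the diffusion-driven microscale SE rate, so recovery degrades at higher
susceptibility contrast, longer echo trains, or faster diffusion (to
~0.6-0.7x at 774 ug/g over the full 4-40.74 ms echo train) and approaches
unity as D -> 0. This mirrors the modest (tens of percent) agreement the
estimator achieves against histology and is a documented limitation, not a
defect of the implementation.

## Known limitations

* The sphere closed form and the effective relaxivity assume dilute,
  uniform-susceptibility spherical perturbers; warnings (not errors) are
  emitted outside zeta <= 0.1.
* Relaxivities and susceptibilities per iron load are literature-derived
  configuration, not fitted; no temperature or pH dependence beyond the
  scalar Curie correction.
* No background-field removal or susceptibility inversion (forward model
  only); no B0/B1 corrections, multi-compartment fitting, membrane
  permeability, or intermediate-length-scale (~100 nm) structure.
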