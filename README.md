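# ironrelax

A generative biophysical model of iron-induced transverse (R2) and effective
transverse (R2\*) MRI relaxation in nigrosome 1, the dopaminergic-neuron-rich
subregion of substantia nigra that degenerates first in Parkinson's disease.
It is aimed at quantitative-MRI researchers who want to link R2/R2\* contrast
to the cellular iron distribution: how much of the relaxation is driven by
iron chelated in the neuromelanin (NM) of dopaminergic neurons versus the
diffuse ferritin (FT) pool, and how well relaxometry can recover the NM iron
load.

## The model

GE and SE magnitude decays factor into independent mechanism envelopes:

```
S_GE(TE) = exp(-R2*_nano TE) · S*_micro(TE) · exp(-R2*_other TE)
S_SE(TE) = exp(-R2_nano  TE) · S_micro(TE)  · exp(-R2_other  TE)
```

* nanoscale (equal in R2 and R2\*): `R2_nano = r2_FT ⟨c_FT⟩ + r2_NM ⟨c_NM⟩`
* microscale: iron maps → susceptibility `Δχ(r) = ρ(c_NM χ_NM + c_FT χ_FT)`
  → Larmor shift `Δf = f0 · F⁻¹[(1/3 − k_z²/k²) F[Δχ]]` → signal decay,
  either in the static-dephasing approximation (Fourier transform of the
  intravoxel frequency histogram; SE contribution zero) or by Monte Carlo
  random-walk diffusion simulation (GE and SE)
* for dilute spherical perturbers: `R2*_micro = (2π/9√3) γ B0 ζ Δχ`, giving
  an effective NM relaxivity `r2*_NM = (2π/9√3) γ B0 χ_NM ≈ 2.5 s⁻¹/(µg/g)`
  at 7 T and the biomarkers
  `c_NM,1 = (R2* − R2)/r2*_NM` and `c_NM,2 = ΔR2*/(r2_NM + r2*_NM)`.

Since no real 3D iron map is distributed, a phantom module generates
synthetic nigrosome patches with the measured statistics (≈2 % NM volume
fraction, cluster iron of a few hundred µg/g over a ≈56 µg/g ferritin
background, 0.88 µm isotropic grid). See `docs/methods.md` for assumptions,
parameters and limitations.

## Worked example

```python
import json
import ironrelax as ir

cfg = ir.RunConfig(
    phantom=ir.PhantomSpec(grid_shape=(64, 64, 64), zeta_nm=0.02,
                           sphere_radius_range=(4.0, 8.0), seed=1),
    mc=ir.McConfig(n_protons=50_000, te=tuple(0.004 * k for k in range(1, 9)), seed=2),
    seed=0,
)
report = ir.run_pipeline(cfg)
print(json.dumps(report, indent=2, sort_keys=True))
```

prints (abridged):

```
"phantom":      {"zeta_achieved": 0.0206, "c_nm_vol_ug_per_g": 7.50,
                 "c_ft_vol_ug_per_g": 54.85, "nm_iron_fraction": 0.120, ...}
"nano_s^-1":    {"nm": 6.00, "ft": 1.10, "total": 7.10}
"micro_sd_s^-1":{"all_iron": 13.20, "nm": 13.09, "ft_by_subtraction": 0.11}
"mc":           {"r2s_micro_s^-1": 13.39, "r2_micro_s^-1": 5.36, ...}
"totals_s^-1":  {"r2s": 20.49, "r2": 12.46}
```

Reading it: the generated patch reached a 2.06 % NM volume fraction, and only
12 % of its iron sits in neuromelanin — yet NM dominates both the nanoscale
rate (6.0 of 7.1 s⁻¹, its relaxivity is 40× ferritin's) and the microscale
R2\* (13.1 of 13.2 s⁻¹ in static dephasing: the uniform ferritin background
produces no field perturbation). The Monte Carlo R2\*_micro (13.4 s⁻¹) agrees
with the static-dephasing prediction, while diffusion leaves a smaller
microscale R2 (5.4 s⁻¹) in the spin-echo channel.

The same stages are available from a shell:

```
ironrelax make-phantom --seed 1 --out run/
ironrelax field --iron run/ --out run/
ironrelax simulate mc --field run/df_hz.nii.gz --n 100000 --out run/
ironrelax fit --decay run/decay_mc_ge.csv --model rician
```

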