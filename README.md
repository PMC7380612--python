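# nozzleflow

Exact flow, shear-rate and shear-stress profiles of shear-thinning bioinks
in cylindrical printing nozzles — plus capillary rheometry: recovering a
bioink's viscosity parameters from flow-rate-versus-pressure measurements
made with nothing but a bioprinter and a laboratory scale.

## Who this is for

In extrusion bioprinting, the survival of cells suspended in a hydrogel ink
depends on the hydrodynamic shear stress inside the nozzle. Predicting that
stress — and the velocity and shear-rate profiles that come with it —
requires solving pipe flow for a *generalized Newtonian* fluid, whose
viscosity η(γ̇) falls with shear rate. `nozzleflow` computes that solution
exactly from the experimentally controlled quantities: the nozzle radius
*A*, and either the driving pressure or the imposed flow rate.

## The method

Any positive viscosity law η(γ̇) — a Carreau–Yasuda model or a measured
table — is interpolated by continuous power-law segments
η<sub>i</sub>(γ̇) = K<sub>i</sub> γ̇<sup>n<sub>i</sub>−1</sup> on a
log-spaced shear-rate grid Γ̇₀ … Γ̇<sub>N</sub>. For stationary, laminar,
pressure-driven flow with gradient G = Δp/L < 0, the momentum balance then
integrates exactly in every radial shell where one segment applies:

- shear rate γ̇<sub>i</sub>(r) = (−G r / 2K<sub>i</sub>)<sup>1/n<sub>i</sub></sup>,
- shear stress σ(r) = −G r / 2 — *independent of the material law*,
- velocity u(r) by matching shells from the no-slip wall inward,

with closed-form flow rate Q and cross-sectional averages. Supported laws:

| law | η(γ̇) |
|---|---|
| Newtonian | η |
| power law | K γ̇ⁿ⁻¹ |
| simplified Carreau–Yasuda | η̃₀ / (1 + Kγ̇) |
| 3-parameter Carreau–Yasuda | η̃₀ [1 + (γ̇/γ̇<sub>c</sub>)<sup>α</sup>]⁻¹ |
| 5-parameter Carreau–Yasuda | η̃<sub>∞</sub> + (η̃₀ − η̃<sub>∞</sub>)[1 + (Kγ̇)<sup>a₁</sup>]<sup>−a₂/a₁</sup> |
| tabulated | log-log interpolation of rheometer data |

The inverse problem — *capillary rheometry* — fits the 3-parameter
Carreau–Yasuda law to measured (pressure, flow rate) pairs by
Levenberg–Marquardt least squares, with the forward solver as the model
function. Independent validation oracles (an exact global solution for the
simplified law, and a brute-force stress-inversion/quadrature solver for
everything else) are part of the package.

## Worked example

Flow of a 2.5% alginate solution (η̃₀ = 6.8 Pa s, γ̇<sub>c</sub> = 27.9 s⁻¹,
α = 0.78) through a 21G needle (radius 275.5 µm, length 28 mm) at 100 kPa:

```sh
nozzleflow profile --model cy3 --eta0 6.8 --gammadot-c 27.9 --alpha 0.78 \
    --radius 275.5um --length 28mm --dp 100kPa
```

```json
{
  "G_Pa_per_m": -3571428.5714285714,
  "flow_rate_m3_per_s": 2.325044430772555e-08,
  "wall_shear_rate_per_s": 2433.295259831285,
  "wall_shear_stress_Pa": 491.96428571428567,
  "u_avg_m_per_s": 0.09750753497273969,
  "gammadot_avg_per_s": 836.3789618635964,
  "eta_avg_Pa_s": 0.9350734217426999,
  "sigma_avg_Pa": 327.9761904761904,
  "u_max_m_per_s": 0.14187323754724288
}
```

(abridged) — the ink extrudes at 23.3 µl/s with a peak velocity of
14 cm/s; a cell near the wall experiences ~492 Pa of shear stress, the
cross-section average is 328 Pa (= ⅔ of the wall value, exactly, for any
material). Doubling the pressure multiplies Q by ~19, not 2 — the signature
of shear thinning.

The same from Python, including the inverse fit on synthetic noisy data:

```python
import nozzleflow as nf

ink = nf.CarreauYasuda3(eta_0=6.8, gammadot_c=27.9, alpha=0.78)
data = nf.generate_flow_curve_data(ink, noise=nf.NoiseSpec(cv=0.01, seed=42))
result = nf.CapillaryRheometry(data, relative_residuals=True).fit()
print(result.summary())
```

```
Capillary rheometry fit (3-parameter Carreau-Yasuda)
========================================================
needle radius         0.0002755 m
needle length         0.028 m
data points           10
grid                  150 intervals, 1e-06..1e+08 1/s
--------------------------------------------------------
parameter           estimate  rel. std err  unit
eta_0                6.78112        0.0129  Pa s
gammadot_c           28.0593        0.0219  1/s
alpha               0.780074       0.00114  -
--------------------------------------------------------
RSS                   0.000747262 (relative)
converged             True
function evals        7
```

All three parameters come back within the noise level of their true values.

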