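# selfthin

Climate-sensitive self-thinning analysis for even-aged forest stands.

In an even-aged stand, carrying capacity — the maximum number of trees of a
given mean size per hectare — is set by the self-thinning line

    log N = intercept + slope · log D,

where *D* is the quadratic mean diameter (cm) and *N* the stocking
(trees ha⁻¹). As stands grow, suppressed trees die and the stand tracks this
line. Because the line reflects resource supply, warming and drying should
push it down — turning a forest from carbon sink to carbon source as excess
trees die. `selfthin` estimates how the line shifts with climate from
permanent-plot inventories, and projects what that shift means for stand
density and carbon stock. It is aimed at forest biometricians and ecologists
working with long-term remeasured plot networks (the motivating system is
tall, mono-specific *Eucalyptus regnans* stands censused every 2–3 years).

Two complementary estimates of the line are implemented:

* **Static allometry** — a linear mixed model on control plots,
  `log N_ij ~ N(α₀ⱼ + α₁ log D_ij + α₂ MATⱼ, σ)` with plot random intercepts
  `α₀ⱼ ~ N(α₀, σ_α₀)`; the covariate (long-term mean annual temperature by
  default, alternatively precipitation, AHMI or VPD) shifts the intercept
  across space.
* **Growth–mortality allocation** — a negative-binomial GLMM for per-period
  dead-tree counts,

      ΔN_ij ~ NB(μ_ij, θ)
      log μ_ij = β₀ij + β₁ log D_ij + β₂ log N_ij + log ΔD_ij + log N_raw_ij

  with the QMD increment ΔD and the live count N_raw entering as fixed
  offsets, and the intercept carrying a plot random effect plus MAT terms
  (either separate spatial/temporal effects, or their composite MAT_ij).
  The thinning line follows in closed form:
  `intercept = β₀/(−β₂) + (log β₂ − log(β₁+1))/(−β₂)`,
  `slope = (1+β₁)/(−β₂)`, and a climate coefficient β_k shifts the intercept
  by β_k/(−β₂) per °C — so a ΔT warming multiplies carrying capacity by
  `exp(ΔT · β_k/(−β₂))`.

The package also quantifies the relative size of dying trees (the *k*
factor, dead-tree QMD over live-tree QMD), cross-validates both models
plot-wise, simulates transient-versus-permanent warming trajectories, and
ships a synthetic stand-dynamics generator with known truth parameters so
every stage can be validated end to end without field data.

## Worked example

Generate a synthetic 112-plot study (40 unthinned controls, a 9.5–12.5 °C
spatial MAT gradient, a 0.71 °C warming trend over 1947–2000), fit the
composite mortality model, derive the thinning line, and project a +3 °C
warming:

```python
import selfthin as st

ds = st.gen_dataset(seed=1, tree_level=False)
fit = st.MortalityModel.from_dataframe(ds.model_frame(), variant="eq_composite",
                                       mat_center=11.0).fit(seed=0)
print(fit.summary())
line = fit.thinning_line()
print(line.summary())
proj = st.project_capacity(line.climate_effect, 3.0, draws=line.draws)
imp = st.carbon_impact(-proj.percent_change / 100, 450.0, 1_000_000.0)
```

which prints

```
Mortality GLMM (eq_composite), NB family, log link
observations: 1568   plots: 112
converged: True   -loglik: 4581.86
MAT centred at 11.000 degC
       param   estimate       mean       2.5%      97.5%
       beta0   -29.8700   -29.8838   -31.7170   -27.9914
       beta1     2.9823     2.9849     2.7416     3.2207
       beta2     2.4177     2.4189     2.2549     2.5819
       beta5     0.2985     0.2966     0.2035     0.3899
 sigma_beta0     0.8944     0.8962     0.7778     1.0239
       theta     9.0701     9.0809     7.9042    10.4102

Self-thinning line (derived from mortality model)
  intercept       12.5609  [12.3646, 12.7735]
  slope           -1.6471  [-1.7022, -1.5977]
  MAT effect/C    -0.1235  [-0.1608, -0.0831]

+3 C capacity multiplier: 0.690 [0.617, 0.779] (-31.0 %)
carbon loss over 1 Mha at 450 t C/ha: 139 Mt (= 309,546 ha of mature forest)
pooled k factor: 0.622 from 1110 events
```

Reading this: β₅ ≈ 0.30 means each +1 °C multiplies mortality rates by
e^0.30 ≈ 1.35 on this synthetic realisation (whose truth composites a
spatial effect of 0.15 and a temporal effect of 0.28); dividing by −β₂
converts it into a per-degree intercept drop of the thinning line (−0.12),
so +3 °C multiplies carrying capacity by e^(−0.37) ≈ 0.69. The slope ≈ −1.65
is the classic size-density exponent. Applying the decline to a carbon-dense
forest estate (450 t C ha⁻¹ over 10⁶ ha) converts the capacity drop into a
stock loss. The k factor near 0.62 says trees that die are about 62 % of the
size of their neighbours — self-thinning removes the suppressed, not the
dominant.

The same pipeline runs from the shell:

```bash
selfthin simulate --out study/ --seed 1
selfthin fit-mortality --data study/ --variant eq_composite --out fit.json
selfthin derive --fit fit.json --out stl.json
selfthin project --fit fit.json --delta-t 3 --out projection.json
selfthin kfactor --data study/ --out kfactor.json
selfthin crossval --data study/ --model eq_composite --out cv.json
selfthin trajectory --scenario permanent --delta-t 3 --out traj.csv
```

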