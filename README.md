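# thermodive

Tools for studying **body-temperature controllability in regionally
endothermic fishes** from biologging tag data.

Large pelagic predators such as mako sharks, bigeye tuna and swordfish keep
their swimming muscle warmer than the water through vascular countercurrent
heat exchangers. Beyond simple insulation, some of these species appear to
*modulate* their heat-exchange rate between dive phases — absorbing heat
quickly in the warm mixed layer while losing it slowly below the
thermocline. `thermodive` implements the full analysis chain used to
quantify that ability:

1. **Heat-exchange model.** Muscle temperature follows Newtonian heat
   exchange plus constant metabolic heat production,

   ```
   dTb/dt = k (Ta(t) − Tb(t)) + Ṫm
   ```

   with `k` (min⁻¹) the whole-body heat transfer coefficient and `Ṫm`
   (°C min⁻¹) internal heat production. Two variants are fitted to each
   deployment by bounded least squares on the fully simulated trace: a
   constant-`k` model, and a two-regime model with `k_warm` (Ta ≥ Tb) and
   `k_cool` (Ta < Tb). The ratio `k_warm/k_cool` measures thermoregulatory
   control; AIC plus a mean-absolute-error guard selects between models.

2. **Segmentation.** The thermocline is detected per deployment from
   1-m-binned, 20-m-smoothed ambient temperature (steepest gradient), and
   deep dives are extracted as maximal below-thermocline excursions longer
   than 10 min.

3. **Comparative allometry.** Across species, `log10 k` is regressed on
   `log10 Mass`, endothermy and their interaction with a phylogenetic mixed
   model: Brownian species covariance on a Grafen-scaled tree plus an
   independent species effect, sampled by a conjugate Gibbs sampler and
   ranked by DIC. Fitted group lines are compared as fold-differences at a
   reference body mass.

4. **Synthetic data.** A generator produces stratified water columns,
   trapezoidal dive tracks, tag deployments driven by the heat model, and
   comparative datasets with known allometric, phylogenetic and
   intraspecific structure — so every stage is testable with exact ground
   truth.

## Worked example

```python
from thermodive import (HeatModelParams, SimConfig, WaterColumn,
                        fit_heat_model, select_heat_model, thermal_summary, synth)
from thermodive.segment import build_profile, detect_thermocline, extract_dives

truth = HeatModelParams(kind="variable", k_warm=0.052, k_cool=0.0036, tm_dot=0.0062)
series = synth.simulate_deployment(SimConfig(seed=1, noise_sd=0.1),
                                   WaterColumn(), truth)

profile = build_profile(series)
thermocline = detect_thermocline(profile)
dives = extract_dives(series, thermocline)
summary = thermal_summary(series)

fit_c = fit_heat_model(series, kind="constant")
fit_v = fit_heat_model(series, kind="variable")
choice = select_heat_model(fit_c, fit_v)
```

Formatted, the results read:

```
thermocline: 100.0 m; dives: 3; mean elevation 2.85 C; above ambient 83%
constant: k=0.0017, MAE=0.625
variable: k_warm=0.0513, k_cool=0.0036, tm_dot=0.0062, ratio=14.2, MAE=0.080
selection: variable | lower AIC and MAE improvement above guard
```

The detected thermocline (100 m) and the three >10-min deep dives match the
generating schedule; the two-regime fit recovers the generating coefficients
to within the noise (ratio ≈ 14), and the model comparison correctly
prefers it: a fish like this warms ~14× faster than it cools, the signature
of active heat-exchange control.

The same stages are available from the shell:

```sh
thermodive simulate --seed 1 --out run/sim
thermodive segment  --input run/sim/tag_series.csv --out run/seg
thermodive fit-heat --input run/sim/tag_series.csv --out run/fit
thermodive simulate --seed 1 --kind comparative --out run/comp
thermodive compare  --table run/comp/species_k.csv --tree run/comp/tree.nwk \
                    --response k_warm --out run/cmp
thermodive report   --run run/seg --run run/fit --run run/cmp --out run/report.json
```

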