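# sorghum-iwue

Leaf-level water-use-efficiency analysis for sorghum genotype × watering-treatment
trials: partitioning intrinsic water-use efficiency into stomatal and
photosynthetic-capacity components, evaporative-flux hydraulics, phenotypic-change
vectors, and ANOVA-based quantitative genetics — with a ground-truthed synthetic-trial
generator so every stage is testable without field data.

## The scientific problem

Intrinsic water-use efficiency, **iWUE = A_n / g_s** (µmol CO₂ mol⁻¹ H₂O), trades off
against carbon assimilation: raising it by closing stomata usually costs photosynthesis.
Because the A_n–g_s relation is curvilinear and saturating, two genotypes can reach the
same iWUE by very different routes — operating lower on the g_s axis, or assimilating
more CO₂ at a given g_s. Distinguishing those routes, and asking which is heritable, is
the core of screening C₄ germplasm for drought performance. This package implements that
workflow for a nested-association-mapping (NAM) style design: many closely related
genotypes, two watering treatments (well-watered WW, water-stressed WS), a few pot
replicates each, and RP/NRP haplotype labels for candidate aquaporin loci.

The central quantities:

- **iWUE partition.** A reference curve iWUE = f(g_s) is fitted across all retained
  observations of both treatments (default: power law `iWUE = a·g_s^b` on the log–log
  scale; alternative: constant-assimilation hyperbola `iWUE = A_ref / g_s`). For each
  genotype × treatment mean, `ΔiWUE_gs = f(g_s) − iWUE_trt` is the deviation explained by
  stomatal behaviour alone and `ΔiWUE_pc = iWUE_obs − f(g_s)` is the non-stomatal
  (photosynthetic-capacity) remainder, where `iWUE_trt` is the treatment-population mean.
  By construction `ΔiWUE_gs + ΔiWUE_pc = iWUE_obs − iWUE_trt` exactly.
- **Hydraulics.** From the evaporative-flux method, `K_leaf = E / (Ψ_stem − Ψ_midday)`
  and `K_plant = E / (Ψ_pre-dawn − Ψ_midday)` (mmol m⁻² s⁻¹ MPa⁻¹), with the serial
  resistance split `R_leaf = 1/K_leaf`, `R_rest = 1/K_plant − R_leaf`.
- **Change vectors.** Per genotype, the WW→WS shift in the (C_i, A_n) plane:
  `θ = atan2(ΔA_n, ΔC_i)` in degrees (WW − WS deltas). Small θ means C_i fell much more
  than A_n — capacity maintained under stomatal closure.
- **Quantitative genetics.** Balanced two-way genotype × treatment ANOVA; broad-sense
  heritability `H_b² = σ_g²/σ_p²` with
  `σ_p² = σ_g² + σ_g×t²/n_treatments + σ_e²/n_replicates_std` (replicates standardized
  at 5); `GCV = 100·σ_g/mean` and `PCV = 100·σ_p/mean`. Both the mean-squares-as-components
  convention used in published summary tables and the standard expected-mean-squares
  estimators are available.
- **Haplotype contrasts.** RP vs NRP genotype groups per aquaporin, crossed with
  treatment, tested at the genotype level (the biological unit of replication), with
  Tukey HSD letter groups from a from-scratch studentized-range CDF.

## Worked example

```python
import numpy as np
import sorghum_iwue as si

records, truth = si.simulate_trial(si.SimulationConfig(), seed=1)   # 89 × 2 × 3
derived = si.derive_traits(records)                                 # iWUE, K_leaf, ...
means, excluded = si.apply_exclusion_filter(si.aggregate_means(derived))

curve = si.ReferenceCurveModel(means["g_s"], means["iwue"]).fit()
print(curve.summary())
# Reference curve (power): a = 62.272, b = -0.496514
# fit domain g_s in [0.03191, 0.3706], n = 178, R^2 = 0.8706

part = si.partition_iwue(means, curve)
print(part.head(3).round(2).to_string(index=False))
# genotype_id treatment  g_s  iwue_obs  iwue_calc  treatment_mean_iwue  delta_iwue_gs  delta_iwue_pc  extrapolated
#        G001        WS 0.11    196.79     188.25               240.48         -52.23           8.55         False
#        G001        WW 0.23    128.09     129.32               143.11         -13.79          -1.23         False
#        G002        WS 0.08    251.71     219.19               240.48         -21.29          32.52         False

res = si.TwoWayAnova(derived.assign(log_gs=np.log(derived["g_s"])), "log_gs").fit()
vc = res.variance_components("ems")
print(round(vc.heritability, 3))   # 0.72  (realized simulation truth: 0.705)
```

Reading the partition rows: G001 under WS sits below the stress population mean almost
entirely through its stomatal term (ΔiWUE_gs = −52.2: its g_s is high for WS), while
G002 gains +32.5 µmol mol⁻¹ from photosynthetic capacity — the drought-resilient route.
The heritability of log g_s estimated from the ANOVA (0.72) recovers the value implied
by the generator's sampled effects (0.705).

The same pipeline runs from a shell:

```bash
iwue simulate --seed 1 --out records.csv
iwue run --in records.csv --out results/
```

producing `derived.csv`, `means.csv`, `partition.csv` + `curve.json`, `vectors.csv`,
`table3_like.csv` (heritability/GCV/PCV per trait), `table2_like.csv` + `letters.csv`
(haplotype ANOVA and Tukey letters), `correlations.csv`, and a `run.json` log. Identical
config and seed give byte-identical outputs.

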