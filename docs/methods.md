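# Methods

This note documents the models, conventions and design choices behind
`sorghum_iwue`, in the order the pipeline applies them.

## Data model and exclusion rule

The canonical table is long-format: one row per pot replicate under one watering
treatment, with gas exchange (A_n µmol m⁻² s⁻¹, g_s mol m⁻² s⁻¹, C_i µmol mol⁻¹,
E mmol m⁻² s⁻¹), water potentials in signed (negative) MPa, leaf-disc weights in g and
disc area in m², SPAD, ΦPSII, morphology and above-ground biomass. Wide or renamed files
are ingested through a column-mapping config. Missing values propagate per trait: a
genotype × treatment group contributes to a trait's analysis only where its mean is
defined, because different traits are routinely measured on different leaves or plants.
Physiologically implausible rows (pre-dawn below midday potential, disc weights out of
order, ΦPSII outside [0, 1]) are flagged with warnings, never silently dropped.

Failed stressed plants are removed by an explicit two-threshold rule rather than by
name: a genotype × treatment mean is excluded iff its g_s mean < 0.02 mol m⁻² s⁻¹ AND
its A_n mean < 2.0 µmol m⁻² s⁻¹. The conjunction generalizes the single published
instance of a shut-down genotype (A_n 1.79, g_s 0.01 under stress) while retaining every
functional stressed mean; both thresholds are configurable, and the filter runs before
all downstream stages (including the treatment means used by the iWUE partition). All
exclusions are logged to a sidecar CSV with reasons.

## Synthetic-trial generator

The generator emulates an 89-genotype × 2-treatment × 3-replicate glasshouse screen with
a known effect structure, so that parameter recovery can be tested against realized
(sample) truths rather than asymptotic parameters.

Generative model, with all randomness from one seed:

- `log g_s = log(gs_base · ws_gs_factor^[WS]) + G_i + GT_it + ε_ijt`, with
  G_i ~ N(0, σ_g²), GT_it ~ N(0, σ_g×t²), ε ~ N(0, σ_e²). The lognormal scale keeps g_s
  positive and right-skewed, as screens report.
- capacity multiplier `c_i = exp(pc_i)`, pc_i ~ N(0, pc_σ_g²), optionally scaled under
  WS by a per-genotype `ws_capacity_factor` (1 = capacity maintained; < 1 = capacity
  lost under stress);
- `A_n = c_i · A_max · g_s/(g_s + K_half)` — a saturating A_n–g_s curve;
- `C_i = 400 − 1.6·A_n/g_s`, floored at 5 µmol mol⁻¹ — the CO₂ supply function with the
  H₂O:CO₂ diffusivity ratio, keeping A_n, g_s and C_i mutually coherent so the θ
  analysis is internally consistent;
- `E = g_s · VPD/P_atm` in mmol m⁻² s⁻¹; `Ψ_midday = Ψ_pre-dawn − E/K_plant` and
  `Ψ_stem = Ψ_midday + E/K_leaf`, with `K_leaf = K_plant / K_leaf_fraction`, so the
  evaporative-flux equations recover the configured conductances exactly (to rounding)
  when measurement noise is off;
- morphology, SPAD, ΦPSII and biomass from genotype-level normals; haplotype groups are
  labels with an optional additive NRP shift on log g_s.

Defaults (chosen once to emulate the published ranges and means of this kind of screen,
and not revisited): gs_base = 0.20 mol m⁻² s⁻¹, ws_gs_factor = 0.35, A_max = 45 µmol m⁻²
s⁻¹, K_half = 0.12 mol m⁻² s⁻¹, σ_g = 0.22, σ_g×t = 0.13, σ_e = 0.18 on log g_s (these
imply an Eq.-style H_b² near 0.77, close to published g_s heritability), pc_σ_g = 0.12,
Ψ_pre-dawn −0.15 / −0.70 MPa (WW/WS), K_plant_base = 4.0 mmol m⁻² s⁻¹ MPa⁻¹,
K_leaf_fraction = 0.4, WS K_plant factor 0.6, VPD 2.0 kPa. Measurement noise is off by
default: oracle tests verify algorithms exactly, and noise is switched on only for
robustness checks.

What the generator does **not** emulate: instrument error structure, diurnal and
chamber-position effects, genetic linkage (haplotypes are labels, not simulated
genomes), leaf-age covariates, and any correlation between capacity and hydraulic
effects. Tests passing on this generator therefore certify the algorithms and their
calibration, not field-data robustness.

## Physiology

iWUE, the conductances, LMA (DW/area) and RWC ((FW−DW)/(TW−DW)) are plain arithmetic at
fixed units; converters are never implicit, since silent unit mixing is the dominant bug
class here. Reversed or zero water-potential gradients yield missing conductances with
warnings rather than exceptions — field data contain such rows and batch analyses must
survive them. Transpiration at the PPFD of leaf excision is interpolated
piecewise-linearly from the plant's light-response points; extrapolation beyond the
measured PPFD range is refused unless explicitly enabled, because the curve model
outside the data is unknown.

## iWUE partition

The reference curve is fitted across **all retained observations of both treatments**.
Two forms are implemented because the method's verbal description ("iWUE versus g_s,
i.e. constant A_n") admits both readings:

- `power` (default): iWUE = a·g_s^b by least squares on log iWUE vs log g_s; a fit with
  b ≥ 0 is rejected as non-decreasing. R² is reported on the fitting (log–log) scale.
- `constant_A_hyperbola`: iWUE = A_ref/g_s with A_ref the grand-mean A_n. The power law
  nests this at b = −1.

The treatment-mean iWUE is the mean over retained genotype × treatment means of that
treatment (replicate-level averaging is available); the partition itself is computed on
genotype × treatment means, matching genotype-mean plotting conventions. Means with g_s
outside the fit domain are still evaluated (preserving the additivity identity) but
flagged as extrapolated.

Identifiability caveat: when the reference curve is instead fitted to a **single
reference genotype**, the power exponent is poorly constrained by that genotype's narrow
g_s range, and the capacity components under genotype-referenced and global curves can
decorrelate (R as low as ~0.6 in simulation). The single-parameter constant-A form is
well identified from few points and reproduces the near-complete agreement between
reference choices (R ≥ 0.98 in simulation); use it for genotype-referenced partitions.

## Change vectors

Deltas are signed WW − WS so that stress reducing both A_n and C_i gives positive
components; θ is the two-argument arctangent in degrees, which handles sign reversals
without discontinuity (genotypes whose C_i rises under stress are flagged). The raw
Euclidean magnitude mixes µmol m⁻² s⁻¹ with µmol mol⁻¹ exactly as the underlying
vector-analysis method does; a z-scored variant (each axis divided by its across-genotype
SD) is provided for a unit-free reading. Deltas are not standardized by default.

## Variance components, heritability, GCV/PCV

The two-way genotype × treatment ANOVA is the classical balanced fixed-effects
decomposition; unbalanced tables fall back to the unweighted-means analysis (cell means
scaled by the harmonic mean cell size, residual pooled within cells) with a warning
rather than Type I/II/III machinery, because the target design is balanced. Exactly
constant responses yield all-zero sums of squares (cancellation dust is clipped), so
degenerate trials give H_b² = 0 rather than numerical noise.

Two component conventions coexist deliberately:

- `paper_literal` (default for summary tables): mean squares taken directly as
  σ_g² = MS_G, σ_g×t² = MS_G×T, σ_e² = MS_E, and
  σ_p² = σ_g² + σ_g×t²/n_treatments + σ_e²/n_replicates_std with the replicate count
  standardized at 5. This reproduces published summary tables built that way, and it
  bounds H_b² in [0, 1] by construction.
- `ems`: standard expected-mean-squares estimators (σ_e² = MS_E,
  σ_g×t² = (MS_G×T − MS_E)/r, σ_g² = (MS_G − MS_G×T)/(r·t), truncated at 0 with a flag).
  This is the statistically consistent choice and the one used for simulation-recovery
  tests, where it recovers the realized-truth heritability with |bias| < 0.01 over
  100-seed panels.

Published phenotypic variances of the reference table are **not** reconstructible from
its printed components with the stated divisors (e.g. A_n: 127.2 + 61.6/2 + 61.49/5 =
170.30 against a printed 160.03); the interaction divisor is therefore exposed as a
parameter, and when reproducing published H_b²/PCV the printed σ_p² is taken as given.
For centred traits whose mean is near zero (the iWUE deviation components), GCV/PCV
require a caller-supplied substitute mean on the natural scale — conventionally the iWUE
mean.

## Haplotype inference

The Population (RP vs NRP) comparison uses the genotype, not the pot, as the unit of
replication: replicates share their genotype's effect, and a genotype's two treatment
cells share it too, so pooling either level into a fixed-effects ANOVA inflates the
Population F-statistic whenever genotypic variance is nonzero. The default analysis
therefore collapses to genotype-level summaries — Population is tested on per-genotype
averages across treatments (between-genotype stratum), Treatment and
Population × Treatment on per-genotype WS − WW differences (within-genotype stratum).
In a balanced design this is the analysis a random-genotype mixed model reduces to, and
simulation confirms nominal type-I error (≈0.05 over hundreds of null trials). The
pooled replicate-level two-way ANOVA remains available (`level="replicate"`) with an
explicit anticonservativeness warning.

Tukey HSD uses a studentized-range CDF computed by quadrature of its integral definition
(inner z-integral by 160-node Gauss–Legendre over the effective support, outer scale
integral by adaptive quadrature), accurate to ~1e-6 and validated against the k = 2
closed form q = √2·z; critical values come from root-finding on that CDF. Unequal group
sizes use the Tukey–Kramer harmonic-mean standard error. Letter groups are assembled by
the insert-and-absorb algorithm, giving a transitively consistent compact letter display
independent of input order. P-values across traits/aquaporins are reported raw
(per-test), matching common reporting practice; a Benjamini–Hochberg option is not
applied by default.

Pearson correlations use the product-moment formula with two-sided p from the t
transform on n − 2 df, pairwise-complete missing handling, and a least-squares line.
Zero-variance series give a missing r with a warning.

## Problem sizes and numerical choices

Simulation-based checks use the study geometry (89 × 2 × 3 ≈ 534 rows per trial) with
panel sizes chosen for stable Monte-Carlo summaries: 100 seeds for heritability
recovery, 200 null seeds for type-I calibration, 20 seeds for direction-of-effect sign
tests. A full pipeline run completes in a few seconds on one CPU. Curve fits use
closed-form least squares (no iterative optimizers); ANOVA sums of squares are computed
from cell means with exact-zero clipping only for identically constant responses;
the exclusion filter requires both thresholds to fail jointly so that borderline but
functional plants are never dropped.

## Known limitations

- No REML/mixed-model variance estimation, narrow-sense heritability, or marker-based
  analysis; haplotype groups are labels only.
- The fixed-effects haplotype analysis assumes a balanced treatment structure within
  genotype; heavily unbalanced field data would warrant the mixed model it approximates.
- The reference-curve forms are empirical; no mesophyll-conductance or C₄ biochemical
  model is fitted, and the partition inherits any misspecification of the curve.
- The change-vector magnitude mixes units by construction; compare magnitudes only
  within a dataset, or use the standardized variant.
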