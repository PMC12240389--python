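# Methods

This note documents the model implemented by `estromix`, the default
parameter values, the numerical conventions, and the main design
decisions. Symbols: concentrations `C` in µg/L water-equivalents,
potency `ACC5` in µg/L, estradiol equivalency factor `EEF`
(dimensionless relative to 17β-estradiol).

## 1. Model

### 1.1 e-EDC identification (bioactivity)

A chemical is treated as an estrogenic endocrine-disrupting chemical
(e-EDC) when it is called active in at least one of the 18 curated
estrogen-receptor agonist assays (transactivation, binding, and
dimerization endpoints from a public high-throughput screening battery)
*and* its ER-pathway AUC score exceeds 0.01. The AUC gate removes
assay-interference false positives ("decoys"): chemicals with
individual active calls but negligible integrated pathway response.
Possible statuses:

- `active_eedc` — active in ≥ 1 retained assay and AUC > 0.01;
- `excluded_low_auc` — active call(s) but AUC ≤ 0.01;
- `inactive` — screened, no active call;
- `insufficient_information` — never screened in the battery.

Manual overrides (`force_active` / `force_inactive`) take precedence;
an active call with a missing AUC is an error rather than a silent
default. Assay rows carrying disqualifying quality flags (borderline
activity, only-highest-concentration-active, gain ACC below the lowest
tested concentration, biochemical assay interference, fewer than two
replicates) are removed before any aggregation.

### 1.2 Potency aggregation

For an active chemical, the per-assay activity concentration at cutoff
(ACC, log₁₀ µM) values from the retained active assays are reduced to
their 5th percentile (linear interpolation, index `q·(n−1)`), then
converted to mass units:

```
ACC5 [µg/L] = 10^(P5(log10 ACC [µM])) × MW [g/mol]
```

The 5th percentile is a deliberately sensitive summary: it tracks the
most responsive end of the assay battery without being the single
minimum.

### 1.3 Exposure–activity ratios

Each measured concentration is first converted to a water-equivalent:

| matrix | unit | conversion |
|---|---|---|
| marine_water, wwtp_effluent | ng/L | ÷ 1000 → µg/L |
| mussel_tissue, fish_tissue | ng/g | ÷ BCF [L/kg] → µg/L |
| bile | ng/mL | used directly (numerically µg/L on the bile scale) |

Then `EAR = C / ACC5` per chemical, and per sample

```
EAR_mix = Σ over detected active e-EDCs of EAR_i
```

under the concentration-addition model for same-mode-of-action
mixtures. Non-detects contribute zero (no ½-LOQ substitution), so
EAR_mix is a lower bound under censoring. Bile from female fish is
excluded because endogenous estrogens dominate the female signal.
Bile EARs are *not* comparable to water EARs; they live on their own
scale and are screened against bile-specific thresholds (§1.5).

### 1.4 EEQ calibration

The classical estradiol-equivalency view is computed in parallel:
`EEQ_i = C_i × EEF_i`, `EEQ_mix = Σ EEQ_i`. The calibration ratio is
the median over samples of `EAR_mix / EEQ_mix` (samples with zero EEQ
excluded), with a Spearman rank correlation reported as a coherence
check. The original survey found a median ratio of ~27 with ρ ≈ 0.98;
27 is therefore the default bridging constant. When
`recompute_calibration_ratio` is enabled the pipeline estimates the
ratio from the supplied data instead.

### 1.5 Screening thresholds

In-vivo vitellogenin-induction benchmarks for estradiol in water —
NOEC 0.005 µg/L and LOEC 0.025 µg/L — are mapped into EAR space by the
calibration ratio and into bile-EAR space by a bile-to-water
bioconcentration range:

```
NOEC_EAR      = 0.005 × 27                 = 0.135   (reported 0.14)
LOEC_EAR      = 0.025 × 27                 = 0.675   (reported 0.68)
NOEC_bEAR     = NOEC_EAR × [4000, 13000]   = [540, 1755]   (reported 540–1800)
LOEC_bEAR     = LOEC_EAR × [4000, 13000]   = [2700, 8775]  (reported 2700–8800)
```

Reported values are rounded to two significant figures (half-up), but
**classification always uses the unrounded values** — sites with p95
EAR_mix of 546 and 548 fall in the medium class only against the exact
540 bound.

### 1.6 Classification

Site class is assigned from the 95th percentile of the site's sample
EAR_mix values (same interpolation convention as §1.2), with all lower
bounds inclusive:

| p95 EAR_mix (bile) | class |
|---|---|
| ≥ 8775 | high_high_certainty |
| [2700, 8775) | high_low_certainty |
| [540, 2700) | medium |
| < 540 | low |

Individual samples are graded low / medium / high against the governing
(NOEC, LOEC) pair for their matrix — the lowest bile pair for bile, the
water pair otherwise; a sensitivity mode substitutes the highest bile
LOEC. Concordance with field biology joins site classes against
fraction of males with measurable vitellogenin and altered female
spawning timing: an elevated class (≥ medium) counts as aligned when
any male vitellogenin was observed or spawning timing exceeds the
cohort median; a low class counts as aligned when no male vitellogenin
was observed.

### 1.7 Prioritization

Within each medium/high sample, using the governing thresholds:

- **high sample**: single-chemical EAR ≥ LOEC → driver, provisional
  high_priority; else ≥ 1% of EAR_mix → major contributor,
  high_priority; else minor contributor — watch_list if its own EAR ≥
  NOEC, otherwise low_priority.
- **medium sample**: EAR ≥ NOEC → driver, watch_list; ≥ 1% → major
  contributor, watch_list; else minor contributor, low_priority.

Per-sample provisional categories are resolved per chemical by taking
the maximum across samples. Detected active e-EDCs that never reach any
elevated sample get low_priority; detected never-screened chemicals get
insufficient_information; inactive or AUC-excluded chemicals get no
assignment.

## 2. Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| AUC cutoff | 0.01 | – | separates genuine pathway response from interference |
| excluded assay flags | 5 flags (§1.1) | – | standard HTS reliability screens |
| potency percentile q | 0.05 | – | sensitive but not minimum-driven summary |
| vitellogenin NOEC / LOEC | 0.005 / 0.025 | µg/L E2 | published in-vivo benchmarks |
| calibration ratio | 27 | – | survey median EAR/EEQ |
| bile BCF range | 4000–13000 | – | measured bile-to-water estrogen concentration factors |
| site percentile | 0.95 | – | upper-bound screening exposure per site |
| major-contribution cut | 1 | % of EAR_mix | de-minimis contribution bound |
| rounding | 2 sig figs, half-up | – | matches reported threshold precision |

## 3. Synthetic campaign generator

The generator (`estromix.synthetic`) produces a chemical registry
(true e-EDCs, inactive chemicals, decoys with active calls but
AUC ≤ 0.01, and never-screened chemicals), an assay table with Gaussian
log-potency noise (σ = 0.3 by default) and random disqualifying flags
(p = 0.1; at least two rows per screened chemical are always kept so
truth remains well defined), and sample tables with lognormal
concentrations (chemical-specific medians, σ = 1.0) scaled by lognormal
site multipliers (σ = 0.5) and left-censored at a fixed LOQ
(10⁻⁴ µg/L). Censored values are withheld (`value = None`) exactly as a
laboratory report would. `driver_spec` forces a chemical's median EAR
to a chosen target by setting its concentration median to
`target × ACC5`. EEFs are generated as `noise / (k × ACC5)` so that
with zero EEF noise every sample satisfies `EAR_mix / EEQ_mix = k`
exactly — the closed-form calibration check. Ground truth (statuses,
ACC5 values, per-sample true EAR_mix, site multipliers) is returned
alongside for recovery tests.

Realism limits: concentrations are independent across chemicals (no
co-occurrence structure from shared sources), LOQ is global rather than
per analyte/batch, and bile is the default matrix; the generator is a
validation instrument, not an emulator of any specific survey.

## 4. Numerical conventions

- Percentiles: linear interpolation at fractional index `q·(n−1)`
  (NumPy's default "linear" method); verified in tests against an
  independent sort-and-interpolate oracle for all n ≤ 8.
- All class/threshold lower bounds are inclusive (`≥`).
- Rounding for display: two significant figures, half-up
  (`floor(x/scale + 0.5)`), never used in decisions.
- Spearman ρ via `scipy.stats.spearmanr`, cross-checked in tests
  against a from-first-principles average-rank implementation;
  requires n ≥ 3 and non-constant vectors.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the campaign config; identical seeds reproduce byte-equal
  CSV outputs.
- CSV round-trips are lossless: writers use `%.17g` float formatting
  and readers use round-trip float parsing.

## 5. Design decisions

- **Unrounded thresholds in decisions** (§1.5): required to reproduce
  the published medium classifications at p95 values of 546/548.
- **Non-detects as zero**: avoids fabricating mass below the LOQ; the
  resulting EAR_mix is a conservative lower bound, appropriate for a
  screening tool whose exceedances trigger follow-up.
- **Concordance rule** (§1.6): "any male vitellogenin or
  later-than-median spawning" as the field signal for elevated sites —
  the simplest operationalization that matches the published 8-of-10
  alignment with misses at Nisqually and Commencement Bay-Thea Foss
  Waterway.
- **Category resolution by maximum**: a chemical's final priority
  reflects its worst observed behavior, making the list robust to
  dilution by many quiet samples.
- **Long-format sample CSVs**: analyte panels differ across studies and
  matrices; a wide table would be mostly missing values with ambiguous
  semantics (not analyzed vs. not detected).

## 6. Problem sizes exercised

Tests run campaigns up to 10 sites × 20 samples × 15 chemicals
(200 samples, ~3000 measurements) in seconds; the full suite (167
tests, including property-based suites with hundreds of generated
cases) completes in a few seconds on a single core. The pipeline is
vectorized over pandas frames and comfortably handles
surveys orders of magnitude larger than the bundled 18-site summary.

## 7. Limitations

- Concentration addition assumes a shared mode of action; antagonism,
  synergy, and non-ER pathways are out of scope.
- The bile scale depends on a literature bioconcentration range, not
  per-fish toxicokinetics; bile EARs are screening quantities only.
- The default calibration ratio (27) is survey-specific; new datasets
  should recompute it (`recompute_calibration_ratio`).
- Censoring-as-zero biases EAR_mix downward where LOQs are high
  relative to potency.
- Field-concordance statistics require external data and are not
  desk-reproducible (see `external_repro.md`).
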