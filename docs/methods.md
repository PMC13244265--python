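# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, the synthetic-data model
used for validation, and the limits of what the test suite demonstrates.

## The classification procedure

### Criterion catalog

The unit of analysis is a per-mouse table of behavioral endpoints. The
default catalog maps the five behaviorally measurable DSM-V criteria to
parameters of a standard trauma battery:

| Criterion | Construct | Parameters |
|---|---|---|
| B | intrusive thoughts | pre-CS % inactivity (log), post-CS % inactivity (log) |
| C | avoidance | EPM open/closed duration ratio (sqrt), light/dark dark-side duration |
| D | negative alterations in cognition | Barnes probe pass/fail (binary), water consumed 48 h, sucrose consumed 24 h |
| E | altered arousal/reactivity | EPM open/closed duration ratio (sqrt), light/dark dark-side duration |
| G | social impairment | duration with novel mouse (trial 2), latency to approach novel mouse (trial 3, log) |

Criteria A, F, H are satisfied by design (trauma exposure; testing ≥ 30
days post-exposure; no confounding condition) and are recorded as notes,
not scored. Two structural facts matter downstream:

* **C and E share the identical parameter pair.** One exceedance on the
  EPM ratio or the dark-side duration therefore awards *two* points. This
  raises the null probability of reaching five points relative to five
  disjoint parameter sets (the catalog exposes
  `distinct_parameter_sets()`, and the test suite measures the inflation
  directly). Users composing their own catalogs should be aware that
  sharing parameter sets is a real modeling decision, not bookkeeping.
* **Criterion D contains the only binary parameter.** The catalog places
  water consumption under D as listed in the standard battery; the package
  follows the catalog literally and takes no position on the construct
  mapping.

Open-field average velocity rides along as an *auxiliary* parameter — in
the cohort, outside the point system — because the subtype stage needs it.

### Transforms

All statistics (effect sizes, control moments, z-scores) are computed on
the transformed scale. Two policies:

* `catalog_fixed` (default): use each parameter's declared transform.
* `auto`: D'Agostino–Pearson omnibus test per sex on the pooled
  (controls + exposed) sample at α = 0.05; if non-normal, try log then
  sqrt and adopt the first transform whose post-transform p ≥ 0.05 for
  every analyzed sex, else keep identity and flag the parameter.

Choices made where reasonable alternatives exist:

* **Normality scope** is the pooled per-sex sample, configurable to
  control-only. A single transform is chosen per parameter because a
  per-group transform would make control-SD units incomparable across
  groups.
* **Log of zero**: the column is offset by half its smallest positive
  observed value, and the offset is recorded in the transform plan.
  Inactivity durations and latencies can legitimately be zero.
* **Minimum n** for the omnibus test is 8 (the mathematical minimum for
  the kurtosis component); n < 20 attaches a small-sample warning.
* Transforms are monotone, so rank-based statements survive them — but
  z-cutoff exceedance does **not** (the tails compress differently), which
  is why the transform policy is part of the analysis contract. The suite
  demonstrates this with an explicit counterexample.

### Effect sizes and selection

Continuous parameters: Glass's delta, Δ = (μ_T − μ_C)/σ_C, with the sample
SD (n − 1) of controls only. The control-only denominator is the point of
the statistic: trauma frequently inflates group variance, and a pooled SD
would shrink exactly the effects one is trying to detect. Binary
parameters: φ = √(χ²/N) from the uncorrected Pearson chi-square of the
2×2 group × outcome table; φ equals the absolute Pearson correlation of
the two indicator variables (tested against that identity).

Selection is per sex and per criterion: parameters with |effect| strictly
greater than 0.5 are kept, ordered by descending magnitude with the name
as a deterministic tie-break. An effect of exactly 0.5 is *not* selected.
Magnitude, not sign, drives selection, because pathology can point either
way (more freezing, but also paradoxically more open-arm time). A
criterion with fewer than two survivors is flagged as a shortfall — fatal
in strict mode, otherwise the survivors (or, with zero survivors, the
single strongest parameter) carry the criterion. No p-values and no
multiple-testing correction enter selection; the rule is effect-size-only
by design.

### Scoring and labels

Per mouse and selected parameter, z = (χ − μ_C)/σ_C on the analysis scale;
a parameter is extreme when |z| > cutoff. The cutoff is the two-sided
standard-normal critical value at 85% coverage. Numerically this is
1.4395…; the package defaults to the conventional two-decimal value
**1.44** and offers the exact quantile behind a flag — the two differ only
for |z| landing inside (1.4395, 1.44], which the suite verifies with a
constructed case. Exceedance is strict: |z| equal to the cutoff scores
nothing.

The binary probe has no z-score. It counts as extreme when the mouse shows
the pathological outcome (fail) *and* the outcome's control prevalence is
at most 1 − coverage (0.15), keeping the binary evidence roughly as rare
under the null as a two-sided z-exceedance. A catalog whose binary
parameter is common in controls triggers an "uninformative" warning and
never awards points. This rarity rule is this package's explicit
construction for folding a categorical outcome into a z-based point
system.

One point per criterion if ≥ 1 selected parameter is extreme (never more,
regardless of how many exceed). Exposed mice: susceptible iff all five
points, else resilient. Control mice are scored with the same control
statistics (all controls included — no leave-one-out) and a full-scoring
control is labeled `control_flagged`; controls never enter incidence
numerators or denominators. A mouse missing *every* parameter of some
criterion is `unclassifiable` and leaves the denominator; a mouse missing
some parameters is scored on the rest.

Incidence is reported per sex and pooled; pooled = pooled counts, never an
average of percentages. Every reported percentage sits beside its
numerator and denominator (rounding is half-away-from-zero to 2 dp).

### Subtyping resilient mice

Resilient mice are re-scored on two axes against same-sex controls:
sucrose consumed per gram body weight (identity scale) and open-field
velocity (sqrt scale). Consumption is judged two-sided with the direction
annotated — decreased consumption is canonical anhedonia, but trauma
cohorts have shown the increase instead — while hyperlocomotion is
one-sided (z > +1.44) by the meaning of "hyper". The four-way subtype is
{neither, increased_consumption, hyperlocomotive, both}; decreased
variants are reported as their own labels when they occur. Mice missing
body weight or either axis are excluded with a logged reason.

## The synthetic-data model

`simulate` generates cohorts with planted ground truth:

* **Design**: 19 controls and 42 exposed per sex (38/84 pooled — the
  scale of the reference cohort), susceptible fraction 0.30.
* **Marginals**: on the transformed scale each continuous parameter is
  normal; the raw scale is lognormal for inactivity/latency parameters,
  sqrt-normal for ratio/velocity parameters, normal otherwise — so the
  catalog's declared transforms are exactly the normalizing ones and the
  `auto` policy has something real to find. Locations and scales are
  chosen as plausible assay values (e.g. dark-side duration 180 ± 35 s of
  a 300 s trial, sucrose 5 ± 1.2 mL, velocity ≈ 4 cm/s).
* **Susceptible mice** are shifted +2.5 control-SD (transformed scale) on
  every criterion parameter — freezing, dark-side time, consumption and
  novel-mouse latency up, time with the novel mouse down, the EPM ratio up
  (the paradoxical risk-taking direction). 2.5 SD makes per-criterion
  exceedance probable but not certain, so sensitivity is a meaningful
  measurement rather than 1.0 by construction.
* **Probe failure**: 0.10 in controls (below the 0.15 rarity bound), 0.45
  in resilient, 0.90 in susceptible mice.
* **Resilient subtypes** per sex: females {both 0.52, increased 0.30,
  hyper 0.04, neither 0.14}, males {neither 0.80, increased 0.16, hyper
  0.04, both 0.00}; subtype shifts are +2.5 SD on the relevant axis.
  The consumption shift is planted on the sucrose column itself; since
  the subtype axis is the ratio sucrose/body-weight, body-weight
  variability attenuates the realized ratio shift by a few percent —
  immaterial for label recovery, but worth knowing when reading the
  planted-vs-recovered comparisons. It also means consumption-subtype
  resilient mice genuinely carry an extreme criterion-D parameter, as
  their real counterparts would.
* **Determinism**: every draw comes from a generator keyed by (seed,
  purpose, mouse id, parameter name). Cohorts are byte-reproducible, and
  adding a mouse or a parameter never reshuffles other draws. An optional
  equicorrelation knob (latent Gaussian copula, default off) exists
  because no correlation structure is published for such batteries;
  parameters are independent within mouse by default.

What the generator does *not* emulate: within-trial dynamics (freezing
bouts, trajectories), realistic cross-assay correlation structure,
batch/cohort effects, or missingness mechanisms. Passing tests therefore
demonstrate that the pipeline recovers what it plants under clean
conditions — not that any particular real cohort satisfies these
distributional assumptions.

## Validation design

* Closed-form oracles: hand-computed Glass delta, chi-square and phi
  values to 1e-12; scipy's uncorrected chi-square as an independent route.
* A brute-force scorecard enumerator (plain loops, statistics stdlib — no
  shared code) reproduces every point, total and label bit-exactly on
  small cohorts.
* Null false-positive structure: on large no-shift cohorts, the
  susceptible-label rate matches the product of per-criterion-set
  exceedance rates measured on an independent cohort (within 3 SE), and
  the shared C/E parameter set measurably inflates the rate over a
  five-disjoint-set catalog (a strict nesting argument makes the
  comparison one-sided).
* Parameter recovery: at 200 exposed / 100 control per sex with the
  default 2.5-SD shifts, over 20 seeds, label sensitivity against latent
  truth exceeds 0.8 and the mean incidence agrees with an independently
  seeded calibration run. At the study scale itself (42 exposed per sex)
  effect-size estimates are noisy enough that selection occasionally drops
  a true parameter, and single-cohort incidence estimates spread widely
  (roughly 10–35% across seeds at a true 30% × sensitivity) — an honest
  property of the method at that n, visible in the acceptance script's
  study-scale entry.
* Monotonicity: criterion points and incidence are non-increasing in the
  cutoff over {1.0, 1.44, 2.0, 2.5}.

## Known limitations

* "At least two independent parameters" per criterion is enforced as
  *distinct* parameters only; no correlation screen is applied between
  parameters of a criterion.
* The binary rarity rule is a construction choice; other reasonable rules
  (e.g. exact binomial tail tests) would score borderline prevalences
  differently.
* Whether z-scores should be computed on the raw or transformed scale is
  a genuine fork; this package defaults to transformed (the only reading
  under which control-SD units are scale-consistent) and exposes the raw
  option through a custom transform plan with identity entries.
* Incidence confidence intervals are not emitted; at n ≤ 100 per sex the
  binomial noise dominates, and users should interval their own estimates
  (the counts needed are always printed).
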