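# Methods

## Model

For country *i* the pipeline computes

1. an exposure distribution `D_i` over blood lead levels (BLL, µg/dL) of
   0–19-year-olds,
2. the mean cognitive damage `L_i = E_{D_i}[f(B)]` in IQ points, where
   `f` is the dose–response function,
3. the relative IQ cost `rel_i = min(cap, 100 · L_i · e_US · r_i/r_US)` in
   percent of lifetime earnings,
4. the absolute cost `abs_i = rel_i/100 · gdp_pc_i · pop_i` in constant
   2021 international dollars per year,

then aggregates: the global total is `Σ_i abs_i`; continent rows report the
mean of `rel_i` (population-weighted by default, simple mean optional — the
weighting is recorded in every run summary). The absolute cost is an annual
flow for the current 0–19 cohort only; discounting, future cohorts, adult
health effects and behavioural costs are deliberately out of scope.

### Exposure distributions

Country inputs are summaries, not samples: a mean BLL with lower/upper
interval bounds, and optionally the shares above 5 and 10 µg/dL. Three
families represent `D_i`:

* **degenerate** — point mass at the mean. The baseline: the dose–response
  evaluated at the country mean.
* **lognormal(μ, σ)** — the standard right-skewed model for biomarker
  concentrations; mean `exp(μ + σ²/2)`, exceedance
  `P(B > t) = Φ(−(ln t − μ)/σ)`.
* **normal** — included for completeness; truncated at 0 and renormalized
  wherever it is integrated or its exceedance evaluated, since BLL is
  non-negative. Its `distribution_mean` reports the pre-truncation
  location, i.e. the summary statistic it was built from.

Two closed-form log-normal fits invert the summaries (`z_k = Φ⁻¹(1−p_k)`):

* **mean + one exceedance**: σ solves `σ²/2 − zσ + ln(t/m) = 0` and
  `μ = ln t − σz`. Feasible iff the discriminant `z² + 2 ln(m/t) ≥ 0`; the
  error message reports the admissible range of *p* for the given mean.
  When `m < t` both roots can be positive and the data cannot distinguish
  them. The `root_policy` makes the choice explicit: `smaller_sigma`
  (default — less dispersion, conservative mean loss under the concave
  default dose–response), `larger_sigma`, or `match_second_exceedance`,
  which picks the root whose implied share above 10 µg/dL is closest to the
  reported one. When a second exceedance is available the last policy is
  the information-complete choice and is what the end-to-end recovery
  analyses use. Discriminants within −1e−10 of zero are clamped to the
  double root σ = z, so boundary inputs fit exactly.
* **two exceedances**: `σ = ln(t₂/t₁)/(z₂ − z₁)`, `μ = ln t₁ − σz₁` —
  exact two-quantile inversion, used as fallback when the mean-based fit is
  infeasible.

A country with `p_gt5 = 0` and mean below 5 µg/dL (or zero mean) has no
representable dispersion; the log-normal scenario degrades to the
degenerate limit there, which also makes a fully lead-free world evaluate
to exactly zero cost under every scenario.

Inverse-normal quantiles come from `scipy.special.ndtri` (accurate to
~1e−15). Round-trip inversion to 1e−8 is only possible while the
exceedances stay in roughly (1e−7, 1−1e−7); beyond ±5.2σ the share stored
as a double no longer carries the information, and tests and the acceptance
script skip such tails rather than pretend to verify them.

### Dose–response

`DoseResponseSpec` supports `linear` (slope in IQ pts per µg/dL),
`loglinear` (`β ln(1 + b)`, IQ pts per log-unit) and `piecewise_linear`
(segment slopes between increasing knots, integrated cumulatively), plus a
no-effect `threshold` t₀ that shifts the argument: `f(max(b − t₀, 0))`. All
forms are continuous, non-decreasing and 0 at b = 0.

The default is `loglinear` with β = 6.9/ln(30/2.4) ≈ 2.73 and no threshold.
The slope is anchored to the magnitude reported by pooled analyses of the
childhood lead/IQ literature — about 6.9 IQ points lost over the 2.4 to
30 µg/dL range — with `ln(1+b)` rather than `ln b` so the function is
defined and zero at zero exposure. It is configuration, not a constant
wired into the engine: any coefficients, knots and threshold can be set in
the run config, and each scenario may carry its own variant.

Expectations `E[f(B)]`:

* degenerate — direct evaluation;
* lognormal — Gauss–Hermite quadrature in the log domain
  (`E[f(exp(μ + σZ))]` against the standard normal weight), 128 nodes by
  default via `scipy.special.roots_hermite` (stable at high order, unlike
  numpy's rule above ~400 nodes). The estimate is accepted when doubling
  the nodes moves it by less than `rel_tol` (default 1e−8); otherwise an
  adaptive quadrature over z ∈ [−12, 12] takes over, and a
  `QuadratureError` carrying the achieved error estimate is raised if even
  that fails;
* truncated normal — adaptive quadrature on [0, loc + 12·scale],
  renormalized by the positive-mass fraction.

### Monetization parameters

The earnings parameters are implementer-supplied defaults, visible and
overridable in configuration:

| parameter | default | meaning |
|---|---|---|
| `e_us` | 0.02 | fractional lifetime-earnings loss per IQ point, US reference economy |
| `r_us` | 0.10 | US returns to education, per year of schooling |
| `cap_pct` | 100 | ceiling on the relative cost (earnings lost cannot exceed earnings) |

`e_us = 2 %` per IQ point is the magnitude used in US EPA regulatory
analyses of earnings effects of cognitive ability; `r_us = 10 %` per year
of schooling is the conventional Mincerian return for the US. The
returns-to-education scaling is applied as the multiplicative ratio
`r_i/r_US` on `e_us` — the most literal reading of "relative returns to
cognitive skills"; it is a single point where a different mapping could be
swapped in.

### Scenarios

| name | definition |
|---|---|
| `baseline` | degenerate at the country mean |
| `log-normal` | full distributional integration, fitted from (mean, p>5) with two-exceedance fallback |
| `lower_bound` | dose–response variant with a 2 µg/dL no-effect threshold and slope 1.4 (≈ half the default) |
| `lower_ci` / `upper_ci` | degenerate at the lower / upper interval bound of the mean |
| `increase_5` / `increase_10` | BLL location ×1.05 / ×1.10 before the distribution is built |

The multiplier acts on exposure, not on the final cost, because under a
nonlinear dose–response the two differ. The baseline is the point-mass
model, with the log-normal integration listed as a deviation: a suite in
which "log-normal" names a sensitivity cannot have it as the baseline. The
`lower_bound` numbers are explicit stand-ins for an otherwise undefined
label; both are config keys. For every monotone dose–response the suite
satisfies, per country, `lower_ci ≤ baseline ≤ upper_ci` and
`baseline ≤ +5% ≤ +10%` — a structural ordering the tests enforce across
100 random worlds.

## Synthetic worlds

`generate_countries(n=199, seed, …)` emits a country table with the
statistical structure the analysis assumes, from a known truth:

* country mean BLLs are log-normally spread across countries
  (median ≈ 3.5 µg/dL, log-sd 0.75, clipped to [0.5, 20] µg/dL) — many
  low-exposure countries and a right tail of high-exposure ones, the
  LMIC/high-income asymmetry;
* within-country log-sd σ ~ U(0.3, 0.9); GDP per capita log-uniform on
  [$2,000, $70,000]; cohort population log-uniform on [2×10⁵, 2×10⁸];
  returns to education U(0.05, 0.15); interval bounds mean ∓ 20 %;
* the emitted summaries (mean, p>5, p>10) are **analytic** functions of the
  truth, so fitting-stage tests measure numerical error only; a
  `summary_noise` mode adds relative perturbation for robustness tests;
* 199 countries by default, continents assigned cyclically over the six
  reporting regions; a single seeded `numpy` generator, the seed recorded
  in the truth block.

`truth_costs` computes the true costs by an independent path: the closed
form `slope · exp(μ + σ²/2)` for a linear dose–response, seeded Monte Carlo
otherwise (10⁶ draws per country by default in the end-to-end checks, which
puts the Monte-Carlo standard error of the global total near 6×10⁻⁵
relative — well under the 10⁻³ recovery tolerance; the single-distribution
quadrature oracle uses 10⁷ draws). The generator does not emulate the
upstream exposure-estimation machinery (no age/sex structure, no spatial
correlation, no reporting bias), so passing tests demonstrate that the
pipeline's numerics and bookkeeping are correct — not that any particular
real-world total is.

## Numerical choices and edge cases

* Exceedance thresholds must be strictly positive; boundary exceedance
  shares (0 or 1) are rejected by the fitters — the p→0 limit is the
  degenerate distribution, handled explicitly at the scenario layer.
* Result tables are written with ≥ 10 significant digits (`%.12g`);
  read/write round-trips are lossless at that precision.
* Continent labels are a closed vocabulary of the six reporting regions;
  aggregation raises on any key mismatch between records and results
  rather than silently dropping countries.
* Scenario runs are pure: identical inputs give bit-identical outputs, and
  per-country failures are collected into one aggregate error naming every
  failing country.
* Run outputs carry a manifest (config hash, seed, scenario list,
  weighting, version, timestamp); all files except the manifest are
  byte-reproducible across reruns.

## Limitations

* The monetization parameters and the dose–response coefficients are
  defaults chosen from the literature's magnitudes, not estimates produced
  by this package; real-data use should set them deliberately.
* Interval bounds are treated as scenario inputs, not as a posterior to be
  propagated; the suite brackets rather than quantifies uncertainty.
* The human-capital approach prices cognition only through earnings;
  mortality, morbidity, behavioural and cardiovascular channels are out of
  scope, so totals are best read as lower bounds of the full burden.
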