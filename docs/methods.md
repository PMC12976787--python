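# Methods

## The measure

Let m(x, t) be the central death rate at single age x in calendar year
t for one sex, on 1×1 age–period Lexis cells (closed–open on both
axes). For a data window [t0, T] the cohort aged x at the terminal
year T has observed survival

    l_c(x, T) = ∏_{a = a_min(x)}^{x−1} exp(−m(a, T−x+a)),
    a_min(x) = max(0, x − (T − t0)),

i.e. rates are read along the cohort's diagonal, and ages lived before
the window opened contribute a factor of 1 — truncation treats
unobserved early mortality as survival. The truncated cross-sectional
average length of life is the trapezoidal age-integral of l_c(·, T)
over 0..ω. With ω = 110 and a null hazard TCAL equals ω; with
time-invariant rates and a window at least ω years long it equals the
period life expectancy computed with exp-based survival, and with a
shorter window W it equals the closed form Σ trapezoid of
l(x)/l(x−W) — both identities are enforced in the test suite against
implementations that do not share the Lexis code path.

Conventions: a window [t0, T] reads rate cells in years t0..T−1; the
terminal-year column t = T is used only by the period life-expectancy
comparator. A 1955–2020 window therefore spans 65 observed
person-year columns on a 66-column file.

### Discretisation choices

* **Per-cell survival factor `exp(−m)`** rather than a q-type
  conversion. Exponential factors are multiplicative along diagonals,
  so log-survival is exactly additive over Lexis cells — the property
  the decomposition's exactness rests on. The difference from
  (1−m/2)/(1+m/2) is O(m²) per cell and cancels almost entirely in
  between-sex differences.
* **1×1 period–cohort squares, no Lexis-triangle split.** Triangle
  (death-by-triangle) data are not universally available; the square
  approximation assigns the cohort aged x at T to cells (a, T−x+a).
* **Trapezoidal age integration at integer ages**, no within-interval
  a(x) correction: symmetric, simple, and the decomposition then
  telescopes exactly with the same weights.
* The **period life table** comparator uses q(x) = m/(1 + (1−a)m) with
  a(x) = 0.5 at all ages including age 0, and L(ω) = l(ω)/m(ω) in the
  open interval. `ax` is an override point; sex differences are
  insensitive to infant-a(x) refinements.

## Decomposition

For each cohort, the difference of the two sexes' survival products is
allocated over the cohort's cells by stepwise replacement. Writing
p_s(a) for the per-cell factors, either replacement order telescopes
exactly:

    ∏p_f − ∏p_m = Σ_a (∏_{b<a} p_f) (p_f(a) − p_m(a)) (∏_{b>a} p_m).

Each cell receives the average of the two orders (F-first and M-first),
which removes the order asymmetry while keeping the telescoping exact;
the paper-trail alternative — a one-directional formula — differs only
in how second-order interaction terms are shared between cells, not in
any cell's sign or the total. Cohort allocations are combined with the
same trapezoidal weights TCAL uses (½ for the oldest cohort, 1
otherwise), so the cell sums reproduce TCAL_f − TCAL_m to machine
precision; the suite enforces 1e-10 over randomized surfaces and 1e-12
on small ones.

Within a cell, cause i receives the share (m_i^m − m_i^f)/(m^m − m^f)
of the cell's contribution — the standard cause-of-death decomposition
step. Where |m^m − m^f| < 1e-12 the cell's contribution (itself ≈ 0)
is assigned 0 to every cause rather than dividing by a vanishing
denominator. A cause with higher female than male rates inside an
overall female-advantage cell gets a negative (male-favoring)
contribution — this is exactly the midlife neoplasm band the analysis
is designed to expose.

Cause-elimination scenarios subtract the cause's rate surface from the
all-cause surface of **both** sexes (independent competing risks /
associated single decrement), floor at zero, and recompute. Deleting a
female-only cause with positive rates strictly widens the gap; a
male-only cause strictly narrows it.

## Data model and combination rule

All-cause rates come from an HMD-style `Mx_1x1` table; cause counts
from a WHO-style long table harmonised into eight categories (breast,
gynecological, lung/larynx/trachea/bronchus, prostate, other cancers,
cardiovascular, external, residual) via a declarative ICD mapping.
"Female reproductive cancers" is always the derived union breast ∪
gynecological. Defaults ship for ICD-9/10 as coarse 3-character ranges
(breast = C50/174, gynecological = C51–C58/179–184, …); ICD-7/8 data
require user-supplied rules and fail loudly otherwise. Under ICD-9 the
male-breast code 175 is deliberately left in `other_cancers` so that
`breast` matches the female reproductive definition.

Cause-specific rates are built by scaling the HMD-side all-cause rate
with the WHO-side cause fraction, m_i = m·D_i/D, never by dividing WHO
counts by a population: this keeps the all-cause TCAL identical to the
rate source regardless of denominator differences between the two
databases. Cells with D = 0 but m > 0 (source discordance) assign
their whole rate to `residual` with a logged warning, preserving the
all-cause surface. WHO five-year age bands are expanded to single ages
proportionally to the same sex/year's all-cause death distribution
(uniform fallback), conserving band totals exactly via
largest-remainder rounding.

## Bootstrap

Confidence intervals are percentile intervals from a stratified
bootstrap (default 1000 iterations, level 0.95): independently within
each (age, year) cell, the cause composition is redrawn from a
multinomial conditional on the cell's deaths. Two modes:

* **poisson** (default): the cell total is first redrawn
  D\* ~ Poisson(D) and all-cause rates rescaled by D\*/D for the
  replicate. Without this layer the all-cause quantities would be
  bootstrap-invariant and their intervals degenerate; adding it gives
  the TCAL and gap intervals genuine width.
* **conditional**: totals held fixed; only the cause composition (and
  hence the decomposition, not the all-cause TCAL) varies. Provided
  for fidelity experiments.

The multinomial draw is implemented as the sequential
conditional-binomial factorisation, vectorised over the grid, so a
full-surface redraw is a handful of array operations. One base seed
governs everything; sub-streams per (iteration, population) are derived
through `numpy.random.SeedSequence`, making results independent of
evaluation order and bitwise reproducible. Calibration is verified by
simulation: across 200 synthetic datasets with known truth (reduced
grid, ages 0–60, window 2000–2020, 200 iterations each — sizes chosen
to keep the check a couple of minutes), the 95% interval for the TCAL
gap covers the truth at an observed rate inside [0.90, 0.99].

## Synthetic generator

The generator emulates the statistical structure of a low-mortality
country pair of sexes, not any specific country:

* Hazards are Gompertz–Makeham with multiplicative period decline on
  the senescent term, m(x,t) = a + b·e^{βx}·e^{−ρ(t−t0)}. Defaults
  (per person-year): female a = 2·10⁻⁴, b = 3·10⁻⁵; male a = 4·10⁻⁴,
  b = 4.5·10⁻⁵; β = 0.095 per year of age and ρ = 0.01 per calendar
  year for both sexes. These give life expectancies in the high-70s to
  mid-80s, a male excess at every age, and ~1%/year improvement —
  typical of the populations the method targets.
* Cause fractions per age are renormalised weighted age profiles:
  Gaussian bumps (breast modal age 52, gynecological 54, smoking-related
  cancers 66, prostate 76, other cancers 63, cardiovascular 78
  female / 74 male), a young-adult hump for external causes (heavier
  for males), and a uniform residual. Weights put the female midlife
  neoplasm excess at ages 35–60 with ≥11% margin while keeping male
  all-cause rates above female everywhere.
* Exposure defaults to 150 000 person-years per (age, year, sex) cell,
  the order implied by a mid-size national population spread over ~111
  ages.
* Two modes: `expected` (counts = rate × exposure, real-valued,
  deterministic — the oracle for exactness tests) and `sampled`
  (Poisson totals, multinomial cause split — the input for bootstrap
  and coverage tests). One seed, per-sex sub-streams.

What the generator does **not** emulate: cohort-specific effects beyond
the age × period structure (no smoking epidemics travelling with
cohorts), revision breaks or coding-practice changes in cause
assignment, migration, age misstatement, or war/pandemic shocks.
Passing tests therefore demonstrate the correctness of the estimators
and the pipeline on well-behaved surfaces, not robustness to real-data
artefacts; with registered HMD/WHO extracts the same pipeline runs
unchanged through the file-based pathway.

## Degenerate inputs and numerical guards

Missing rate cells are explicit flags; a needed diagonal cell that is
missing raises with the (age, year) named, never treated as zero. A
zero-length window returns TCAL = ω (no observed mortality). Cause
deletion refuses to remove more rate than exists (1e-9 slack, floored
at 0). The cause-share guard at |Δm| < 1e-12 and the largest-remainder
tie-break toward the youngest age are the only tolerance decisions
inside the estimators; both are documented at the call sites.

## Known limitations

* The exp(−m) cell factor slightly understates survival at very high
  rates (m ≳ 0.5) relative to q-based conventions; comparisons between
  discretisations matter more for levels than for sex gaps, and the
  sensitivity command (`tcalkit sensitivity`) quantifies window-choice
  effects directly.
* Truncation makes TCAL depend on the window: values are comparable
  only across equal windows, which is why the pipeline carries
  (t0, T) on every result object and output row.
* The Poisson layer on cell totals is a modelling choice for the
  all-cause sampling variability of registered count data; where
  totals are considered design-fixed, conditional mode gives narrower,
  composition-only intervals.
* ICD default mappings are coarse 3-character ranges adequate for the
  eight analysis categories; sub-type analyses need a user mapping.
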