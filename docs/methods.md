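# Methods

This note records the statistical conventions the package implements,
the choices made where the field literature leaves latitude, and what
the synthetic-data tests do and do not establish.

## Census data model

A stand is a fixed set of contiguous plots (default 300 m² each) in
which every stem with DBH ≥ an inclusion threshold (default 4.99 cm) is
tagged at first detection and followed until death. A tree's life
course across the census series is constrained to be monotone,

    not_yet_recruited* → alive+ → dead*,

and ingestion validates this: a tree can never return to `alive` after
`dead`, and a live observation must carry a DBH at or above the
threshold. Multi-stemmed trees carry a single equivalent diameter,
√(Σ dᵢ²), which preserves total cross-sectional area; the inclusion
rule is applied to this aggregate, not to any individual stem, so a
tree with three 3 cm stems (aggregate 5.2 cm) is recruited while a tree
with one 4 cm stem is not.

Darwin Core Archives are read with a purpose-built minimal reader
(meta.xml descriptor, tab-separated occurrence core, MeasurementOrFact
extension). Trees are matched across censuses by `occurrenceID` and the
census calendar is taken from `eventDate` years, because deposited
archives carry no explicit census field. DBH is taken from measurement
rows whose type mentions diameter/DBH — basal-area measurement rows,
which some deposits also carry, are ignored — and `measurementUnit`
(cm/mm/m) is honoured. Rows with unparseable event dates are skipped
with a logged warning rather than aborting the ingest.

## Rates

All annual rates use the compound-interest convention (see the formulas
in the README). Two consequences worth noting:

* at t = 1 the mortality rate reduces exactly to the simple annual
  fraction 100·D/N₀ (tested as a closed-form limit);
* the net change rate compounds exactly: x₀(1 + Ch/100)ᵗ = xₜ.

Interval lengths t are explicit configuration, defaulting to
census-year differences. When reproducing published tables whose
printed rates are numerically consistent with a nominal interval rather
than the calendar difference, set `interval_years` explicitly; the
configuration always wins over the calendar.

Survivor basal-area change is split by sign into a decrement (trees
that shrank — buttress erosion, stem damage, measurement height drift)
and an increment, so the identity

    BAₜ = BA₀ − BA_dead − BA_decr + BA_recr + BA_incr

holds exactly and is checked after every interval tally.

The loss/gain rates L and G use the same compound form as m and r with
basal-area components in place of counts. Published loss rates computed
with other software may disagree with this formula by a few hundredths
of a percent per year; this implementation states its formula and
applies it uniformly.

## Count comparisons

The dead-vs-recruit comparison treats deaths and recruits as two
Poisson event streams and conditions on the total: under equal
intensities, D | (D+R = n) ~ Binomial(n, ½). We report the exact
two-sided binomial p (minimum-likelihood method, via
`scipy.stats.binomtest`), the signed normal-approximation
Z = (D − R)/√n, and its two-sided p. The identical contract applies to
per-class total ingrowth vs total outgrowth. For small n the exact p is
the one to quote; the Z statistic is reported because published tables
conventionally print it.

## Diameter classes

Classes have increasing amplitude (default breaks 5, 10, 20, 40,
80 cm) to compensate for the reverse-J decline of abundance with size.
The boundary convention is: first class lower-closed at the inclusion
threshold, every class upper-closed — 10.0 cm is in class 1, 10.01 cm
in class 2. Stems beyond the last break fall into an overflow class
that is tallied and logged, never silently dropped; report tables omit
it only when empty.

Per class and interval the four flows are: deaths D (among trees in
the class at the first census), absolute outgrowth O (survivors leaving
the class by growth in either direction — shrinkage across a boundary
counts), recruits R (by first recorded class), and absolute ingrowth I
(survivors arriving from another class). Conservation
Nₜ = N₀ − D − O + R + I holds exactly per class, and globally
Σ O = Σ I; both are asserted after every tally, so a violation is an
error, not a warning.

Expected class frequencies under the size-independence null scale the
first-census value by the ratio of classed totals,
exp_k = value_k · (Nₜ_total/N₀_total), applied to class counts and to class
death counts alike. This operational definition reproduces published
"expected" columns cell-for-cell, which is why it is used rather than a
proportions-under-multinomial construction. Observed-vs-expected dead
frequencies are tested with the G-test, G = 2 Σ O ln(O/E) with the
0·ln 0 = 0 convention, df = k − 1, upper chi-square tail, and no
Williams small-sample correction (matching the default of the R
implementations commonly cited). Note that when every expected value is
the observed value times one constant c, G collapses to
2 (Σ O) ln(1/c) regardless of the distribution across classes — a
useful closed-form check, but also a caution about how much the test
can say in that design.

## Diversity

Shannon H′ uses natural logarithms (nats per individual); Pielou
J = H′/ln S is undefined for S < 2 and the package says so rather than
returning 0. The Hutcheson t-test equips H′ with the analytic variance

    var(H) = [Σ p (ln p)² − (Σ p ln p)²]/N + (S − 1)/(2N²),

including the finite-sample correction term, because that is the form
implemented by the classic software; t = (H₁ − H₂)/√(var₁ + var₂) with
Welch-style effective degrees of freedom and a two-sided Student-t
p-value. The test is antisymmetric in its arguments by construction.

## Synthetic censuses

The generator emulates the structure the analysis assumes — and only
that structure:

| parameter | default | meaning |
|---|---|---|
| `n_plots`, `plot_area_m2` | 26, 300 | ~0.78 ha of contiguous plots |
| `n_initial_trees` | 1500 | stand size at first census |
| `n_species`, `abundance_k` | 118, 0.05 | geometric-series abundances |
| `dbh_scale_cm` | 5.0 | shifted-exponential initial DBH (reverse-J) |
| `annual_death_prob` q | 0.03 | per-tree, per-year |
| `annual_recruit_rate` λ | 1.0 | recruits · plot⁻¹ · yr⁻¹, Poisson |
| `growth_median_cm`, `growth_sigma` | 0.15, 0.6 | lognormal annual increment |
| `measurement_sd_cm` | 0.05 | additive jitter, allows negative change |
| `p_multistem` | 0.05 | fraction recorded as 2–3 stems |
| `census_years` | (0, 5, 11) | census calendar |

Defaults were chosen once to resemble a surveyed semi-deciduous
tropical stand of ≈0.8 ha: ~52 stems per plot, ≈3 %/yr mortality,
~1 recruit·plot⁻¹·yr⁻¹, a median increment of 1.5 mm/yr, and an
exponential DBH scale of 5 cm (placing ≈36 % of stems above 10 cm, as
in reverse-J stands of this type). The dominance parameter 0.05 gives
H′ ≈ 3.9 at S = 118.

Deliberate simplifications: no spatial structure or gap dynamics, no
density dependence, mortality and growth independent of size and
species, recruits entering just above the threshold. Surviving trees'
DBH is floored at the inclusion threshold — tagged trees stay in the
survey, and the floor keeps every survivor assignable to a class while
negative increments above the floor still produce downward class moves.
A green test on synthetic data therefore establishes the bookkeeping
and the estimators, not the realism of any ecological covariance.

The recovery experiment closes the loop: with per-year death
probability q, the compound mortality estimator targets 100q at the
annual scale, and 200 replicates at q = 0.03 recover 3.0 %/yr with
|bias| far below the Monte-Carlo standard error of the mean (the
Jensen curvature bias of the ^(1/t) transform is O(10⁻³) at these
sample sizes).

## Numerical conventions

* Report rounding: half away from zero at 2 dp (2.705 → 2.71), because
  that is how published inventory tables round; Python's banker's
  rounding would disagree on exact halves. Implemented with `decimal`.
* Basal-area identities are checked with a relative tolerance of 1e-6;
  count identities exactly.
* Species tie-breaks in `top_abundant` are alphabetical, making reports
  deterministic.
* Guild matching keys on the binomial (genus + epithet, accents
  stripped) so author strings do not block a match; unmatched species
  are `unknown` and logged. The packaged guild table normalises the
  shade-bearing code "Sb" to shade-tolerant.
* Identical seeds give byte-identical simulated registries and
  byte-identical pipeline reports.

## Known limitations

* The DwC-A reader targets the occurrence + MeasurementOrFact layout
  described above; archives with event cores or other extensions are
  out of scope.
* No confidence intervals on rates, and no census-interval
  standardisation corrections for comparing rates measured over
  different interval lengths.
* Basal area is used as the biomass proxy throughout; no allometric
  biomass estimation.
* Published tables produced by other software can embed choices (exact
  census dates, alternative loss-rate formulas, different two-sided
  p-value conventions) that are not recoverable from the tables
  themselves; this package documents its own conventions and applies
  them uniformly instead of reverse-engineering each cell.
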