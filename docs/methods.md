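# Methods

## Model

The package evaluates a multiplicative benefit chain per crime category
(sexual assault; all other violent and property crimes combined; murder):
a pool of searchable forensic profiles is converted into investigative
leads, leads into prevented victims via a recidivism/victim-reduction
rate, and victims into tangible and intangible cost savings using
per-case crime-cost estimates. The chain assumes:

* leads scale linearly with the pool, the category's share of database
  profiles, the upload-increase fraction a more sensitive assay brings,
  and the kinship lead rate — no saturation, no interaction between
  categories;
* every input is statistically independent of the others;
* a lead prevents future victims only through earlier identification of
  serial offenders (benefits to non-recidivist case resolution are
  deliberately excluded, making savings conservative);
* all money is nominal USD with no deflation or discounting — the source
  estimates mix 2014–2022 figures and the model keeps them as printed.

Scopes. The **lifetime** scope applies the chain separately to the stock
of profiles that never produced a hit (total forensic profiles minus
lifetime hits) and the stock that did, then sums. The **annual** scope
applies it to one year of uploads with no hit/no-hit split — the split
describes the accumulated stock, not the flow. **Murder** has its own
front end: reported murders × (1 − clearance rate) unsolved cases per
year, times an assumed DNA-profile yield, accumulated over a 10-year
horizon; annual murder figures are the horizon totals divided by the
horizon, exactly.

## Parameters

All defaults live in three packaged JSON fixtures and are the published
input tables verbatim:

* `paper_tables_2_4` — per-category rows: tangible/intangible cost per
  case (USD), upload increase (fraction, 0.05–0.20, base 0.10), upload
  ratio, category share of profiles (sexual assault uniform 0.135–0.20;
  other crimes uniform 0.80–0.865), total cases per year, investigative
  lead rate (0.59–0.88, base 0.76), reduction rate (0.30–0.67 sexual
  assault, 0.30–0.65 other, 0.05–0.15 murder), extra investigation hours
  (10–50, base 30) and police hourly rate ($24–$71, base $46); plus the
  murder front end (17,284 reported murders, 61.4% clearance, 30–50%
  profile yield, 10-year horizon).
* `paper_database_state` — NDIS/SAKI tallies: 1,144,255 forensic
  profiles, 587,773 lifetime hits, 114,426 uploads/year, 80,325 completed
  kits, 33,398 uploaded, 15,784 hits, 10,550 serial hits, $2–3B funding.
* `paper_costs` — reagent run configurations (e.g. 12-library panel kit
  at $11,499 with a $1,500 run kit; hypothetical 96-library kit at
  $23,000; $120 flat library price; $2,737 high-output flow cell),
  caseload volumes (330,000–400,000 requests/year × 5 samples), database
  build-out (1,000,000 samples/year), and capital lines (sequencers
  $73.5M, robots $60M, validation $20M over 10 years; $50M/year
  miscellaneous).

Distribution conventions. Ranged inputs with a stated base case are
triangular (min, base, max); the base case may sit on an endpoint, giving
a valid degenerate triangular (e.g. the sexual-assault reduction rate
0.30/0.67/0.67). Inputs given only as ranges (the category shares) are
uniform; their base case for deterministic evaluations is the midpoint.
Known constants are point masses.

## Deterministic bounds

The `low`/`high` settings move the *rate* inputs (upload increase, share,
lead rate, reduction rate, murder profile yield and serial reduction) to
their endpoints simultaneously; per-case costs and labor inputs stay at
their base-case values. That is how the published bounds are constructed
— the weighted per-case costs appear in both the lowest and highest
figures — and it is what the bounding tables here reproduce.

Two reproduction conventions deserve note:

* **Intermediates are never rounded.** The published chains demonstrably
  carry unrounded intermediates (20,015 profiles = 6,671.624 unsolved ×
  0.30 × 10); rounding happens only at display. All reproduced dollar
  figures agree with print within 0.1%, integer counts within ±1.
* **Hit-pool upload increase.** For the lifetime *hit* pool the
  upload-increase term is allocated with a configurable share
  (`hit_increase_share`). In the packaged other-crimes parameters it is
  the sexual-assault share, which is the allocation the published
  workbook used (verified by inverting its printed hit-pool dollar
  figures, which match this composition to <0.001% at both endpoints and
  no other tested composition within 4%). For sexual assault the field
  coincides with the category share, reducing to the plain
  `(1+u)·p·h` chain.

One published value is internally inconsistent and is not reproduced as
printed: the other-crimes annual low victim count appears as 17,103, but
the same paragraph's tangible saving ($140,543,217 = victims × $8,261)
pins the value at 17,013; the package produces 17,013.

## Monte Carlo

Each trial samples all inputs independently; triangular draws use the
generator's closed-form two-branch inverse CDF, uniform draws an affine
transform. Each named input has its own substream derived from the run
seed and a stable hash of the input name, so results are bit-reproducible
for a given seed and unaffected by input reordering. The default trial
count is 1,000 (the published run size); convergence tests use 100,000.

Two wirings are shipped because the published workbook's composition is
not stated:

* `annual_uploads` (default) — the chain consistent with the published
  static annual arithmetic, driven by the 114,426 uploads/year figure
  (murder by its unsolved-case front end). Its simulated outcome means
  agree with the published simulation's reported means within the
  published run's own sampling error (checked by test at 2%).
* `total_cases` — the input tables read verbatim: total cases × share ×
  upload ratio × (1+u) × lead rate × reduction.

Police labor is computed per trial as its own outcome, not netted from
savings. Histograms are equal-width over [min, max] with 30 bins by
default. Tornado sensitivity evaluates the deterministic model with one
input at each endpoint and all others at base case; rows are sorted by
descending swing. Because the chain is monotone non-decreasing in every
input, all trial outcomes lie inside the all-low/all-high deterministic
envelope, which the tests assert.

## Cost model conventions

Per-sample reagent cost = per-library price + run-kit price / plexity.
The per-library price (kit cost / kit size, or a flat price) is a catalog
price and is rounded to the cent before the run share is added; the total
is again rounded to the cent. Cost per lead and per hit are carried at
full precision and rounded to whole dollars only for display, so
cost-per-lead × leads recovers the budget exactly. Capital lines use
straight-line 10-year amortization. The published budget table prints
$298,580,000 for database work where its narrative implies $289,580,000
(1,000,000 × $289.58); the fixture defaults to the table value — the only
one consistent with the printed $943,090,000 total reused downstream —
and records the discrepancy in a note field.

## Synthetic scenarios and what the tests show

`generate_scenario` emulates the structure the analysis assumes — and
only that: independent triangular/uniform inputs with plausible bounds,
internally consistent database tallies, a multiplicative chain. Modes are
drawn uniformly inside each range, collapsing onto the maximum with 10%
probability to exercise the degenerate-triangular edge. It does **not**
emulate correlated inputs, heavy-tailed cost distributions, reporting or
clearance-rate drift over time, or category overlap; a passing test
matrix therefore validates the propagation machinery, not the realism of
any particular input range. Two independent oracles close the loop: the
closed-form chain expectation (product of analytic input means) for
simulated means, and exhaustive enumeration on finite-support inputs for
the sampler's empirical distribution (total-variation distance < 0.02 at
50,000 draws).

## Limitations

* Benefits are restricted to serial-recidivism prevention; resolution of
  non-recidivist cases, deterrence, wrongful-conviction avoidance and
  missing-persons benefits (costed only at the reagent level) are out of
  scope, as in the source analysis.
* The category shares of database profiles are assumed equal in the hit
  and no-hit pools, which the serial-hit-rate evidence only partially
  supports.
* Inputs are US-centric and nominal; transferring the analysis elsewhere
  means replacing every fixture value, which the config layer is designed
  to make straightforward.
* The two Monte Carlo wirings bracket the published workbook's unstated
  composition; the default reproduces both the published static annual
  arithmetic and the published simulation means, but the workbook itself
  was not available for inspection.
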