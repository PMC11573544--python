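# Methods

This note documents the model implemented by `uccea`, its assumptions, the
numerical choices made where the design was open, and what the synthetic
data generator does and does not emulate.

## Decision model

A three-state Markov cohort model — progression-free survival (PFS),
progressed disease (PD), death — evaluates first-line nivolumab +
gemcitabine–cisplatin against gemcitabine–cisplatin alone in advanced
urothelial carcinoma from a Chinese payer perspective. The cycle length is
1 week; the horizon is 10 years (522 cycles = round(10 × 365.25/7)); costs
and utilities are discounted at 5% per year; state membership is valued at
cycle midpoints (trapezoidal half-cycle correction). The cohort starts
fully progression-free at age 65 (configurable; the source trial does not
state a cohort starting age).

### Transition probabilities

Survival curves are fitted in months; the weekly grid is converted at
1 month = 365.25/84 weeks, fixed in one place (`transitions.WEEKS_PER_MONTH`)
to avoid unit drift. Per cycle of length *u* ending at *t*, the exit
probability from a fitted curve is `1 − S(t)/S(t−u)`.

The composition of the 3×3 matrix is not derivable from survival curves
alone (OS and PFS do not identify the PFS→Death vs PD→Death split), so the
model uses a partitioned-survival-consistent construction:

* **PFS→Death** `d = max(OS cycle probability, background death)`. The
  background floor, converted from an annual life-table probability via
  `1 − (1−q)^(u·7/365.25)` with age advancing along model time, prevents
  extrapolated trial hazards from dipping below general-population
  mortality.
* **PFS→PD** `max(0, PFS-exit − d)`; the PFS row is renormalized to sum
  to 1.
* **PD→Death** is back-solved each cycle from the running occupancy so
  that the fraction alive tracks the fitted OS curve exactly (floored at
  `d`, clipped into [0,1] with a logged diagnostic). Wherever the
  background floor is not binding, the cohort's all-state survival
  therefore reproduces S_OS to machine precision — this is asserted in the
  tests.
* Death is absorbing.

Extrapolated PFS can cross OS; S_PFS is clipped to S_OS on the grid with a
logged warning.

### Accrual

Life years accrue (alive occupancy) × (7/365.25 years) per cycle, QALYs
weight PFS/PD occupancy by utilities 0.80/0.71, and costs accrue the
per-cycle state costs of the ledger — all on half-cycle-corrected occupancy
and discounted at cycle midpoints. Terminal care attaches to each cycle's
death increment as an event cost: by default discounted at cycle end and
not half-cycle corrected (a switch enables midpoint treatment; whether the
original analysis corrected event costs is unstated). One-off
adverse-event costs land at cycle 0 undiscounted. Traces are propagated at
full precision with no early truncation.

A patient-level microsimulation with identical accrual rules serves as a
validation oracle only; the cohort trace is its n→∞ limit (checked at
200,000 paths within 3 Monte Carlo SEs).

## Costs

All prices in 2022 US$ (conversion for CNY inputs at $1 = ¥7.1470):
nivolumab $1249.072/100 mg vial, gemcitabine $5.596/200 mg, cisplatin
$1.059/10 mg, $41 per administration unit, $278.21 terminal care, plus
grade ≥3 AE unit costs (anemia $500.78, neutropenia $434.57, decreased
neutrophil count $534.40, decreased white-cell count $622.5231).

Dosing follows the trial: nivolumab 360 mg + gemcitabine 1000 mg/m² (days
1, 8) + cisplatin 70 mg/m² (day 1) every 3 weeks for six blocks, then
maintenance nivolumab 480 mg every 4 weeks from week 18 through week 104
(2-year stopping rule); the comparator receives the chemotherapy alone.
Second-line treatment is gemcitabine–cisplatin for both arms (six blocks,
configurable). A 21-day block maps onto weekly cycles with day-1 costs in
its first week and day-8 costs in its second.

Open choices, with defaults:

* **BSA formula**: Du Bois, `0.007184·cm^0.725·kg^0.425` (unstated in the
  source; the most common choice in Chinese CEA practice). Body 65 kg /
  1.65 m → 1.716 m².
* **Vial wastage**: whole-vial rounding by default (gemcitabine
  1716 mg → 9 vials); a `linear` policy is available for sensitivity and
  never costs more per cycle.
* **Administration unit**: co-administered chemotherapy counts as one
  infusion unit and nivolumab adds its own, so a combination day-1 visit
  bills 2 units and a day-8 visit 1. "Per unit" is ambiguous in the source
  table; this convention is localized in one helper.
* **AE incidences are synthetic placeholders.** The source prices the AEs
  but does not print their incidences; the shipped per-arm profiles
  (e.g. anemia 0.22/0.18) are plausible myelosuppression rates for
  platinum-based regimens and are prominently flagged. Override them for
  any substantive re-analysis. AE costs enter once at cycle 0, the common
  convention for on-treatment toxicity in cohort models.
* **Terminal care** applies to all deaths, not only disease deaths.
* **Second-line costs** are a per-model-cycle PD-state schedule (six
  blocks from model start, then zero). A memoryless cohort cannot index
  costs by time-in-state without tunnel states, so patients progressing
  after week 18 accrue no second-line drug cost; with median PFS around
  8 months this understates comparator costs somewhat. Tunnel states are
  out of scope.

## Survival analysis

Five families in standard parameterizations (time in months): exponential
(rate), Weibull (shape, scale), lognormal (μ, σ), log-logistic (α scale,
β shape), Gompertz (shape a>0, rate b). Fitting maximizes the
right-censored log-likelihood by Nelder–Mead on log-transformed positive
parameters from five deterministic moment-style starts (the exponential
MLE is closed-form). Requiring a positive Gompertz shape keeps S(t)→0.
Model choice minimizes AIC = 2k − 2logL among converged fits; ties break
toward fewer parameters, then a fixed family order. Fits agree with
lifelines' fitters to ~4 significant figures where both exist (test-only
cross-check; lifelines has no Gompertz fitter, one reason the MLE is
implemented here).

Medians use closed forms for all five families (Gompertz:
`log1p(a·ln2/b)/a`), verified against a brute-force grid in tests.

## Pseudo-IPD reconstruction

Digitized (time, survival) read points plus the numbers-at-risk table are
converted to patient-level records by interval accounting in the style of
the Guyot algorithm: within each at-risk interval, the censoring count is
iterated until the implied at-risk count at the next table time matches the
printed one, with events at the read times recovered through the
product-limit recursion and censorings spread uniformly over the interval.
Events precede censorings at ties. Beyond the last table time no censoring
is assumed except administrative censoring of everyone still at risk at the
last read time, so the record count always equals n at risk at 0. An
optional published total-events count re-labels final administrative
censorings to match.

Integer rounding and boundary reads need care: a drop read exactly at an
interval boundary aggregates events that truly occurred just before it.
When the previous interval has censorings available, they are re-labelled
as events just before the boundary, keeping every at-risk count exact and
the KM curve faithful; when it has none, curve and table are genuinely
inconsistent at read-grid resolution, the curve wins, and the residual
(a few subjects at isolated rows) is absorbed by the next interval's
censoring solve. Measured on jitter-free emulated curves (n₀=300, monthly
reads, 3-month risk tables, 40 seeds): max |KM − read| = 0.007, 96% of
table rows exact, worst row off by 5.

## Synthetic data generator

The generator defines the study conditions for everything downstream.

* **Calibration.** For each arm/endpoint the family is fixed (log-logistic
  for OS in both arms and PFS in the chemotherapy arm; lognormal for PFS in
  the combination arm — the families favoured by AIC on the reconstructed
  trial data) and its median is pinned exactly to the printed value
  (log-logistic median = α; lognormal median = e^μ). The shape comes from
  the printed 95% CI width: the sample median of n uncensored draws is
  asymptotically normal with sd 1/(2·f(m)·√n), so the density at the median
  is solved from `width = 1.96/(f(m)·√n)` at a reference n = 300 (arm sizes
  are not printed; 300 is of the order of the trial's arms) and mapped to
  the shape (log-logistic f(m) = β/4α; lognormal f(m) = 1/(mσ√2π)). The
  closed form replaces a Monte-Carlo bisection because it is deterministic
  and exact for the same target; a 10,000-replicate simulation oracle in
  the tests confirms the reproduced width is within 30% of the printed one.
* **Simulation.** Inverse-CDF event times; censoring is uniform on
  [0, max follow-up] for a `censor_rate` fraction plus administrative
  censoring at max follow-up (default 36 months, a trial-length window);
  the source says nothing about censoring structure. Bit-reproducible
  given a seed.
* **Curve emulation.** KM of a simulated cohort sampled at the read grid,
  with truncated Gaussian jitter (default σ = 0.002 survival units,
  monotonicity preserved — plot-reading error is small but nonzero) and an
  at-risk table every 3 months.
* **Life table.** Gompertz–Makeham,
  `q(age) = 1 − exp(−(a + b·e^(c·age)))` with a = 5·10⁻⁴, b = 5·10⁻⁵,
  c = 0.09 per year, giving q(65) ≈ 0.018 — a plausible general-population
  all-cause rate. Real census rates can be supplied as a CSV with the same
  schema.

**What the synthetic stand-in does not capture.** Calibrating to medians
and CI widths alone cannot reproduce the real trial's sustained hazard
separation: the comparator arm's relatively wider CI yields a flatter
shape, so the synthetic OS curves cross at about 5 years and the
incremental effect (≈ 0.07 QALY discounted) is far smaller than an analysis
of the actual curves would give. Qualitative conclusions are unaffected —
the combination still gains QALYs at an ICER several times the
willingness-to-pay threshold, nivolumab price still dominates the tornado,
and no PSA draw is cost-effective — but absolute ΔLY/ΔQALY/ICER values from
the synthetic inputs should not be quoted as estimates for the real
regimen, and the required price reduction is correspondingly deeper than a
real-data analysis would find.

## Economics and sensitivity analysis

ICERs are reported only in the north-east quadrant (ΔE > 0, ΔC > 0);
dominance cases carry labels instead of ratios, and the south-west quadrant
reads the ratio as savings per QALY forgone (cost-effective when ≥ WTP).
WTP = $38,223/QALY (3× China's 2022 per-capita GDP).

One-way sensitivity re-runs the pipeline at each parameter's published
bounds (the published ranges are exactly ±20% for the drug prices and
administration; utilities carry their own CIs), all else at base, sorted by
ICER spread; dominance at a bound is recorded as a signed sentinel, never
dropped. The PSA draws all parameters jointly and independently
(n = 5,000, seeded): Gamma for costs and Beta for utilities by method of
moments with mean = base and sd = (high − low)/3.92 (range read as a 95%
CI; divisor configurable); zero-width ranges are point masses; a failing
draw is redrawn with a logged count so n stays exact. Survival-parameter
uncertainty is off by default (the published parameter table lists no
distributions for survival parameters); an optional switch draws
multivariate-normal log-parameters using the finite-difference Hessian at
the MLE. The CEAC reports, per WTP, the fraction of draws with positive
incremental net monetary benefit.

Because the PSA and tornado vary only costs and utilities, the transition
schedules — and hence the cohort traces — are identical across draws; the
implementation computes the traces once and re-runs ledger assembly and
accrual per draw, which is numerically identical to a full re-run.

The price-threshold search bisects the nivolumab unit-price multiplier
until the ICER is within $1/QALY of the target (any drug can be selected;
the bracket must straddle the target or the search errors with both
endpoint ICERs). It matches the closed form to 1e−6 on a model whose cost
is linear in price.

## Problem sizes and tolerances

Default analysis sizes: 522 weekly cycles; PSA n = 5,000; generator
validation at n = 50,000 (KM medians within 1.5% of printed values);
microsimulation validation at n = 200,000 paths (3 SE agreement);
AIC-selection study at 50 replicates of n = 2,000 with 20% censoring
(generating family selected in ≥ 80%). Optimizer tolerances: Nelder–Mead
xatol 1e−8 / fatol 1e−10; transition row sums within 1e−12; closed-form
identities asserted to 1e−9; threshold bisection to $1/QALY.

## Known limitations

* No tunnel states: PD costs are indexed by model time, not time in state
  (see Costs above); time-to-treatment-discontinuation is proxied by PFS.
* AE incidences are placeholders (flagged above).
* The PFS→Death / PD→Death split is a modelling construction, not a
  published quantity; alternatives (e.g. additive background mortality)
  would change state-specific occupancy but not total survival.
* Two strategies only; no efficiency frontier, EVPI, or crossover
  modelling.
* The subgroup analysis (PD-L1 ≥ 1%) is supported as an alternate
  calibration input set, not shipped as data.
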