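# Methods

## Model structure and assumptions

The model is a three-level decision tree evaluated as a cohort
expectation. Every patient has a first breast-conserving surgery; a
positive margin report (probability `p_pos_st` = 0.30 under standard
techniques, `p_pos_ifmi` = 0.10 under fluorescence guidance) triggers a
re-excision; a positive report after the second surgery
(`p_pos_second` = 0.10, identical in both arms because fluorescence
guidance is applied in the first surgery only) triggers a third surgery,
which is final regardless of outcome. The time horizon runs from the
first surgery to return to work after the last one; later disease course,
recurrence and quality of life are deliberately outside the model.

Expected surgeries per patient are `E[N] = 1 + p1(1 + p2)`; both
incremental endpoints are affine in the relative risk
`RR = p_pos_ifmi/p_pos_st`, which is what makes exact linear
interpolation across the effectiveness range valid.

## Cost model

Costs take a hospital perspective plus lost productivity. Per surgery:
the DRG lump sum (`drg_cost`, €3,508) plus `lost_productivity` (€521,
representing 14 working days lost per surgery episode valued at average
wages and female employment rates — carried as a single per-surgery euro
amount; its wage-side derivation is not part of this package). Once per
IFMI patient, the add-on:

| component | base value |
|---|---|
| fluorescent agent (Bevacizumab-IRDye800CW) | €500 |
| camera system, amortized | €182 per surgery |
| sterile draping | €23 |
| additional staff | €107 |
| operating-time delta | −€588.62 |

The camera amortization is `price/(lifespan × volume) +
maintenance_rate × price/volume` = €182.14 for €150,000, 10 % p.a.,
7 years, 200 surgeries/year; the model carries the whole-euro €182 as
the per-case materials price (it is also the centre of that parameter's
PSA distribution). The operating-time delta is
`(prolongation − s × fsa_duration) × c − F`: fluorescence inspection
adds 10 minutes, skipping frozen section analysis (FSA, 27 minutes)
saves staff waiting time scaled by the staff time saving factor
`s = 0.64` (the senior physician cannot leave, so only part of the
staff cost is avoided).

### Calibration of the time-cost parameters

The per-minute cost of surgery used in the source setting was derived
from an unpublished DRG cost-centre matrix, so it cannot be recomputed
from printed inputs. The model therefore carries two explicit
parameters — `cost_per_minute` (c) and `fsa_fixed_saving` (F) — and
fixes them by requiring the model to reproduce two published
incremental-cost results simultaneously: −€663 at `s = 0.64` and +€516
at `s = 0`. Incremental cost is affine in `s`, so the two anchors give a
2×2 linear system with the unique solution c = 68.229 €/min,
F = 91.91 € (`calibrate_time_cost`). As a plausibility check,
c is numerically close to the principled non-calibrated fallback
`(drg_cost + lost_productivity)/st_duration` = 68.29 €/min
(`derived_cost_per_minute`).

Where c is needed away from the base case, two modes exist: the
calibrated fixed value (base case, sweeps, scenarios — this reproduces
both anchors exactly), and the derived ratio recomputed from the current
DRG, lost-productivity and ST-duration values (per draw in the PSA, per
variation in the tornado — so that those three inputs propagate through
the operating-time channel; a fixed c would make the ST-duration bar
vanish, contradicting its observed influence).

Monetary reporting truncates expected costs to whole euros (floor),
which reproduces the printed €5,358 / €4,695; increments are rounded.
Internal arithmetic is full precision.

## Probabilistic sensitivity analysis

Each of 10,000 draws samples every uncertain parameter: beta
distributions for the three margin proportions (moment-matched to mean
and SE: `shape_sum = mean(1−mean)/se² − 1`), gammas for the cost items
(`shape = (mean/se)²`, `scale = se²/mean`), triangulars for the three
durations with the printed min/max and the mode at the base-case value,
and the staff time saving factor held fixed (it carries no
distribution). The second-surgery proportion is sampled once per draw
and applied to both arms (perfectly correlated — it is one shared
parameter). Intervals are empirical 2.5th/97.5th percentiles with linear
interpolation between order statistics.

Two sampling modes for the IFMI margin proportion are implemented
because the inputs support both: `fixed_rr` (default) ties it to the
sampled ST proportion via the base-case relative risk — the mode
consistent with the relative-risk sweep construction and with the
reported surgery interval (−0.30, −0.15) — and `independent` samples it
from its own beta (mean 0.10, SE 0.018). In `fixed_rr` mode the unused
IFMI beta is not sampled at all; this keeps the random streams common
across relative risks, making sweep point estimates *and* the surgery
interval bounds exactly affine in RR under a shared seed. Cost-interval
bounds interpolate only approximately (each draw's add-on enters the
ordering), which is the expected behaviour for interpolated intervals in
this model class.

Seeding: `numpy.random.default_rng(seed)` drives each analysis;
`spawn_rng(seed, label)` derives independent substreams when several
analyses share a master seed. Identical (seed, n, mode, parameters) give
bit-identical results.

## Deterministic sensitivity analyses

* **RR sweep** over relative risks 0, 1/6, 1/3, 1/2, 2/3, 5/6, 1
  (IFMI margin levels 0–30 % in 5 % steps); per-node PSA intervals with
  a common seed; `interpolate` for off-grid values.
* **Tornado**: each parameter with a Table row is set to 0.75× and
  1.25× its base value, one at a time, against the incremental cost at
  the base relative risk; entries sorted by descending range, ties
  broken by name. The ST margin proportion is varied directly (the IFMI
  proportion stays at 0.10 — one-at-a-time semantics).
* **Scenarios**: named override sets for the published one-way analyses
  (DRG €2,201/€5,047, agent €800, ST margins 18.3 % with SE 0.035,
  ST duration 35/83 min, FSA duration 13/53 min, staff factor 0/1),
  each adjusting the matching PSA spec. Overriding the ST margin
  proportion preserves the prevailing relative risk unless the IFMI
  proportion is set explicitly.
* **Thresholds** for the staff time saving factor: the point criterion
  solves the affine `delta_cost(s) = 0` in closed form (0.280 with
  calibrated defaults); the significance criterion finds the smallest s
  where the PSA's 97.5th percentile of incremental cost reaches zero,
  by bisection (default tolerance 0.005) with one fixed seed for every
  evaluation so the bracketing function is deterministic and monotone.

## Structural variants

Variant A replaces deterministic re-excision after the first surgery
with probabilities by margin status; `(1, 0)` reduces to the base tree
to machine precision (tested). Variant B replaces the tree with
per-strategy probability vectors over total surgery counts {1, 2, 3, 4}.
The variant probabilities observed in surgical practice registries are
not part of this package's inputs; defaults are illustrative
placeholders and the variants are property-tested, not value-tested.

## Synthetic patient-level data

`microsim.simulate_cohort` draws individual trajectories: Bernoulli
margin outcomes with the configured proportions, costs attached
deterministically given the realized path (lump sum per surgery, add-on
once for IFMI). It emulates exactly the stochastic structure the cohort
model takes expectations over — and nothing more: no patient-level cost
noise, no casemix heterogeneity, no coding variation in repeated DRG
billing, no correlation between margin outcomes and operating times.
Passing oracle tests therefore demonstrate internal consistency between
the simulator and the closed forms, not fidelity to real surgical
registries. Cohort sizes in the test suite (50,000–100,000 patients;
20 random parameterizations) were chosen so that 3-standard-error checks
are sharp enough to catch arithmetic errors while the whole suite stays
fast.

## Numerical choices and degenerate inputs

* Beta fits require `se² < mean(1−mean)`; gamma fits require positive
  mean and SE; violations raise a validation error naming the key.
* Auto-generated PSA specs degrade to `fixed` when a point estimate sits
  at the edge of the family's support (a proportion of exactly 0 or 1, a
  cost of 0, a duration outside the printed triangular bounds) — such
  values arise legitimately at sweep boundaries and in scenarios, and
  are treated as known exactly.
* The triangular mode equals the base-case point estimate, so the
  asymmetric FSA triangular (13, 27, 53) has analytic mean 31 ≠ 27; the
  PSA mean of incremental cost accordingly sits below the deterministic
  point estimate. This is a property of the stated input distributions,
  not a bug; quantities that are exactly mean-matched (the surgery
  endpoint) converge to their point estimates.
* Equal tornado ranges order alphabetically (stable, reproducible).
* Probabilities are validated into [0, 1]; the staff factor into [0, 1];
  durations must be positive.

## Known limitations

* The calibrated (c, F) pair is a linear-model completion of two printed
  results, not an independent costing of operating-room minutes.
* Lost productivity and the DRG lump sum are setting-specific (German,
  2017-era); transferring the model requires re-parameterization, which
  the configuration schema supports.
* The cost interval and the significance threshold are sensitive to
  distributional details the inputs do not pin down (notably the FSA
  triangular's skew and the per-draw cost-per-minute recomputation);
  they should be read as orders of magnitude, unlike the deterministic
  endpoints and the surgery interval, which are sharp.
* No quality-of-life or survival modelling; the endpoints are surgeries
  and euros only.
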