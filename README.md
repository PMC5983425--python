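# ifmiecon

Early decision-analytic assessment of **intra-operative fluorescence
molecular imaging (IFMI)** versus **standard techniques of
breast-conserving surgery (ST)** with frozen section analysis (FSA) for
margin assessment.

Successful breast-conserving surgery requires tumour-free resection
margins; positive margins trigger re-excision. IFMI injects a fluorescent
agent (Bevacizumab-IRDye800CW) so the surgeon can see malignant tissue
during the operation, which is expected to lower the proportion of
positive margins — and with it the number of repeat surgeries and their
costs. This package implements the early, model-based evaluation of that
trade-off for the German DRG setting: a decision tree for up to three
surgeries, an itemized cost model, probabilistic and deterministic
sensitivity analyses, structural tree variants, and a patient-level
microsimulation that serves as a brute-force oracle for the cohort model.
It is aimed at health-economics researchers and modellers who want a
tested, configurable, reproducible version of this class of
early-assessment model.

## Model

Each patient enters a decision tree. After the first surgery the margin
is positive with probability $p_1$ ($p_1^{ST} = 0.30$;
$p_1^{IFMI} = RR \cdot p_1^{ST} = 0.10$ at the base-case relative risk
$RR = 1/3$). Positive margins trigger a re-excision; after the second
surgery margins are positive with probability $p_2 = 0.10$ in both arms,
and a third surgery is always final. Hence

$$E[N] = 1 + p_1 (1 + p_2), \qquad
\Delta N = (p_1^{IFMI} - p_1^{ST})(1 + p_2) = -0.22 .$$

Costs per surgery are the DRG lump sum (€3,508) plus lost productivity
(€521). IFMI adds, once per patient: the agent (€500), the amortized
camera system (€182/surgery from €150,000 purchase, 10 % p.a.
maintenance, 7-year life, 200 surgeries/year), sterile draping (€23),
additional staff (€107), and the operating-time delta
$(t_{prolong} - s \cdot t_{FSA})\,c - F$, where $s = 0.64$ is the staff
time saving factor applied to the avoided FSA waiting time. The
per-minute cost $c$ and fixed FSA saving $F$ are calibrated so the model
reproduces two published incremental-cost anchors simultaneously
(−€663 at $s=0.64$, +€516 at $s=0$), giving $c = 68.23$ €/min and
$F = 91.91$ € (see `docs/methods.md`).

Uncertainty propagates by Monte Carlo: betas (moment-matched to mean and
SE) for the margin proportions, gammas for the cost items, triangulars
for the durations; 10,000 draws give percentile intervals. Deterministic
machinery covers the relative-risk sweep with exact linear interpolation,
a ±25 % tornado analysis, one-way scenarios, and break-even thresholds
for the staff time saving factor.

## Worked example

```python
from ifmiecon import expected_cost, incremental, load_parameters, run_psa

params = load_parameters()          # packaged base-case configuration
m, c = params.margins, params.costs

for strategy in ("IFMI", "ST"):
    r = expected_cost(strategy, m, c)
    print(strategy, round(r.expected_surgeries, 2), r.expected_cost_eur)

inc = incremental(m, c)
print("delta:", round(inc.delta_surgeries, 2), round(inc.delta_cost))

res = run_psa(params)               # 10,000 draws, seeded
print("95% CI surgeries:", [round(x, 2) for x in res.ci_surgeries])
```

prints

```
IFMI 1.11 4695
ST 1.33 5358
delta: -0.22 -663
95% CI surgeries: [-0.3, -0.15]
```

IFMI avoids 0.22 surgeries per patient (95 % CI −0.30 to −0.15, i.e. a
significant reduction) and saves €663 per patient in expectation; costs
fall from €5,358 (ST) to €4,695 (IFMI), truncated to whole euros.

The `examples/` directory holds one short script per capability
(base case, PSA, sweep, tornado, thresholds, structural variants,
microsimulation oracle). A thin CLI wraps the same functions:

```sh
ifmiecon base --out run/        # strategies.csv, incremental.json, manifest.json
ifmiecon psa --draws 10000 --seed 42 --out run/
ifmiecon tornado --out run/
ifmiecon sweep --scenario agent_800 --out run/
```

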