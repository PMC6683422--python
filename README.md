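# stepcea

Trial-based cost-effectiveness analysis of four depression-care strategies in
primary care, rebuilt as a tested, reusable Python pipeline.

A large randomized trial in Alberta primary care compared four ways of
managing depression after universal PHQ-9 screening: **SC** (standard care,
screening results withheld), **TAU** (treatment as usual, results shared with
the physician), **ICBT** (TAU plus online cognitive behavioural therapy), and
**SCP** (a protocolized stepped-care pathway). Clinically the arms were
indistinguishable; the economic question — does any strategy deliver the same
health at lower cost to the payer? — is what this package answers. The
patient-level administrative data are not publicly deposited, so the package
ships (a) the trial's published summary tables as machine-readable constants
and (b) a seeded synthetic-cohort generator calibrated to those tables, which
makes every stage of the analysis testable end to end.

## The model

**Costs.** Each participant's service use over the year after randomization
falls into one of five combinations: none, physician only,
physician + outpatient, physician + inpatient, or all three sectors. The
expected one-year cost per participant in an arm is the decision-tree sum

```
E[cost] = p_phys·C_p + p_phys_out·(C_p + C_o) + p_phys_inp·(C_p + C_i) + p_all·(C_p + C_o + C_i)
```

where the `p` are the arm's service-mix probabilities and `C_p, C_o, C_i` are
mean sector costs among users (2017 CAD). On patient-level data the sector
means are gamma-GLM (identity link) predictions adjusted for age, sex and
baseline PHQ-9, after per-arm × period × sector boxplot trimming (1.5 × IQR;
inpatient costs are never trimmed) and multiple imputation of missing 12-week
outcomes (chained equations, Rubin's rules).

**Effects.** QALYs are the area under the piecewise-linear EQ-5D-5L utility
path over 52 weeks. The base case carries the 12-week utility forward:
`QALY = (12/52)·(u0+u12)/2 + (40/52)·u12`; two sensitivity scenarios return
the effect to baseline linearly or immediately after week 12.

**Uncertainty.** A probabilistic sensitivity analysis samples each arm's total
cost (gamma) and QALY (truncated normal) for 10,000 iterations, yielding
ICERs with dominance classification, net-monetary-benefit based
cost-effectiveness acceptability curves (CEACs) over willingness-to-pay
0–200,000 $/QALY, and incremental cost-effectiveness scatterplots.

## Worked example

Reproduce the headline table directly from the published summaries:

```python
import stepcea as sc

tr = sc.table_reproduction(population="all", n_iter=10_000, seed=1)
for arm in ("SC", "TAU", "ICBT", "SCP"):
    print(f"{arm:5s} expected cost ${tr.expected_costs[arm].total:8.2f}"
          f"   QALY {tr.qalys[arm]:.4f}")
print(f"SCP vs iCBT: {100*tr.scatter_fraction:.1f}% of PSA points "
      "below $50,000/QALY")
```

prints

```
SC    expected cost $ 2392.49   QALY 0.8777
TAU   expected cost $ 2770.05   QALY 0.8665
ICBT  expected cost $ 2486.92   QALY 0.8777
SCP   expected cost $ 2197.74   QALY 0.8777
SCP vs iCBT: 56.9% of PSA points below $50,000/QALY
```

SCP is the cheapest arm with the equal-best QALY: it *dominates* TAU outright
and costs ~$190–290 less than SC/iCBT for the same health, which is why its
acceptability curve leads at every willingness-to-pay. The 56.9% is the share
of Monte Carlo draws in which SCP is cost-effective against iCBT at
$50,000/QALY — close to a coin flip, i.e. genuine decision uncertainty.

The same analysis runs end to end on patient-level data (here, a synthetic
cohort with the trial's structure — missing outcomes, cost outliers and all):

```python
report = sc.run_full_analysis(sc.AnalysisConfig(seed=7))
print(report.summary_frame())
report.write("results/", plots=True)   # CSVs + CEAC/scatter PNGs
```

or from the shell:

```bash
stepcea generate --seed 7 --out cohort.csv
stepcea report --cohort cohort.csv --seed 7 --subgroup --out results/
```

## Layout

| module | role |
| --- | --- |
| `stepcea.published` | the trial's printed summary tables as constants |
| `stepcea.cohort` | calibrated synthetic cohort generator (+ CSV dialect) |
| `stepcea.preprocessing` | service-combination classification, IQR trimming, multiple imputation, depressed subgroup |
| `stepcea.adjustment` | OLS outcome adjustment, gamma-identity-GLM cost adjustment, Rubin pooling |
| `stepcea.effectiveness` | QALY area-under-curve and persistence scenarios |
| `stepcea.cost_tree` | service-mix decision-tree expected costs |
| `stepcea.psa` | Monte Carlo PSA: ICER, NMB, CEAC, scatterplots |
| `stepcea.pipeline` | end-to-end orchestration and table-reproduction mode |
| `stepcea.cli` | `stepcea` command with generate/preprocess/adjust/tree/psa/report |

Methodological details, parameter defaults and known limitations are in
[docs/methods.md](docs/methods.md).
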