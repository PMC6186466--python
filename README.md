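# strokecoi

Prevalence-based cost-of-illness (COI) estimation for stroke, built as a
reusable, tested Python pipeline. It takes claim-level records (one row per
outpatient visit or inpatient admission for ischemic stroke, ICD-10 I63, or
hemorrhagic stroke, ICD-10 I61), an age-stratified mortality table, and an
economic parameter file, and produces the full cost ledger — direct medical,
direct non-medical and indirect costs per subtype with subtotals and
percentage shares — plus per-case costs and cohort descriptives.

It is aimed at health economists and health-services researchers who work
with single-payer claims aggregates (the data model mirrors South Korea's
2015 national stroke analysis) and need the whole chain from raw claim lines
to a publishable burden-of-disease table, with every arithmetic step unit
tested. Because national claims databases are not public, the package
includes a seeded synthetic claims generator calibrated to the published
2015 cohort structure, so the entire pipeline runs and is testable without
any restricted data.

## The cost model

Costs for all cases treated in one calendar year (prevalence-based COI):

**Direct medical** — covered inpatient and outpatient treatment summed off
the claim lines; the non-covered out-of-pocket allotment as ratios
*r*<sub>in</sub>, *r*<sub>out</sub> applied to the covered totals per
disposition; medication incl. pharmacy use; and assistive devices, an
annual per-patient cost CPI-adjusted from its 2010 base
(241 512 KRW × CPI<sub>2015</sub>/CPI<sub>2010</sub> × patients).

**Direct non-medical** — transportation, 21 000 KRW round trip per
outpatient visit-claim; and caregiver cost, a CPI-adjusted daily rate times
total inpatient days.

**Indirect (human-capital approach)** — morbidity loss: work time absorbed
by care, valued per age band *a* as

&nbsp;&nbsp;Σ<sub>a</sub> (days<sub>a</sub> + ⅓ · visits<sub>a</sub>) ·
(income<sub>a</sub>/365) · employment<sub>a</sub>,

one outpatient visit costing one third of a work day; and premature-death
loss: deaths<sub>a</sub> · lost-years<sub>a</sub> · income<sub>a</sub> ·
employment<sub>a</sub> summed over bands, with zero income below age 20 and
at or above 70. A discounted present-value convention for the death loss is
also provided (see `docs/methods.md`). The cost per stroke case is
(grand total − premature-death loss) / patients.

## Worked example

Feeding the nine published 2015 component cost rows (million KRW, per
subtype) through the breakdown builder:

```python
from strokecoi import datasets, build_cost_breakdown, per_case_cost

bd = build_cost_breakdown(datasets.reference_components())
print(f"total cost (all stroke): {bd.amount('grand_total', 'all'):,.0f} million KRW")
print(f"premature-death share:   {bd.share('mortality_loss', 'all'):.2f} %")
pc = per_case_cost(bd.amount("grand_total", "all") * 1e6,
                   bd.amount("mortality_loss", "all") * 1e6,
                   datasets.N_PATIENTS)
print(f"cost per stroke case:    {pc} million KRW")
```

```
total cost (all stroke): 7,472,822 million KRW
premature-death share:   45.53 %
cost per stroke case:    7.9 million KRW
```

The grand total is about 7.47 trillion KRW (≈ US$6.85 billion at the 2015
rate of 1090.14 KRW/USD); lost productivity from premature death is the
largest single item at 45.53 % of the total; and the average case costs
7.9 million KRW once the death loss (not a treatment cost of the cases
themselves) is excluded. The reconstructed total differs from the published
7 472 828 by 6 million KRW — exactly the footprint of the source having
rounded each cell to the million before summing; `strokecoi
check-reference` replays all 51 such checks and prints a pass/fail line for
each.

## Command line

```bash
strokecoi simulate --n-patients 10000 --seed 7 --out claims.csv --mortality-out deaths.csv
strokecoi estimate --claims claims.csv --mortality deaths.csv \
    --params params.yaml --out report/
strokecoi check-reference
```

`estimate` writes `table1_cohort.csv`, `table2_costs.csv`,
`table3_per_case.csv`, `report.md` and a machine-readable `results.json`.
Exit codes: 0 success, 2 input validation error, 3 parameter error.

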