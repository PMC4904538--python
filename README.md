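# mesoapportion

Apportionment of mesothelioma risk among asbestos exposure sources.

When a patient's mesothelioma is judged to be asbestos-related, a physician
or expert witness may be asked how much of the risk each asbestos-containing
product, workplace, or time period contributed. That share is not simply
proportional to exposure dose: it depends jointly on how much fiber was
inhaled, how mesotheliogenic the fiber type was, and — dominantly — how long
before diagnosis the exposure occurred. `mesoapportion` performs this
calculation for an arbitrary above-background exposure history and renders a
grouped, subtotaled report.

## Model

Each exposure period (one calendar year, or part of one) contributes an
absolute mesotheliogenic risk

```
risk = c × p × (m / 12) × T^e,   T = max(0, Y − (y + L))
```

where `c` is the relative 8-hour TWA fiber concentration, `p` the relative
mesotheliogenic potency of the fiber mix (commercial chrysotile ≡ 1), `m`
the months of exposure, `y` the exposure year, `Y` the diagnosis year, `L`
the latency lag (default 10 years — the window after exposure carrying
essentially no mesothelioma risk) and `e` the time exponent (default 2; an
exposure twice as far in the past, after lagging, carries a fourfold risk).
An optional plateau caps `T` at `M − L` to reflect cohort evidence that
pleural mesothelioma rates stop rising roughly 40–45 years after exposure.
The percentage contribution of entry *i* is `risk_i / Σ_j risk_j × 100`;
because this is a ratio, only *relative* concentrations and potencies
matter — any common scale factor cancels.

Literature-derived potency presets are included (chrysotile : amosite :
crocidolite ≈ 1 : 100 : 500 lifetime, 1 : 35 : 200 occupational; generic
amphibole 50), along with a fraction-weighted mixture calculator, but the
operator always supplies the potency values explicitly.

## Worked example

The package ships an 8-entry example history: a worker handled "Product A"
(potency 6, ≈90% chrysotile + 10% amphibole) in 1965, 1966 and briefly in
1969, and worked around chrysotile-only materials (potency 1) from 1966 to
1970; mesothelioma was diagnosed in 2013.

```
$ mesoapportion example
Mesothelioma diagnosis year: 2013
Lag: 10 y | time exponent: 2 | mode: paper_truncate

Year  Months  Conc.  Potency  Description  Group           Result  Percent
Group description: Product A
1965  4       1      6        Plant A      Product A       2888    27.76%
1966  2       1      6        Plant A      Product A       1369    13.16%
1969  0.5     1      6                     Product A       289     2.78%
                                           subtotal        4546    43.70%

Group description: misc. products
1966  10      1      1                     misc. products  1140    10.96%
1967  12      1      1                     misc. products  1296    12.46%
1968  12      1      1                     misc. products  1225    11.78%
1969  11.5    1      1                     misc. products  1107    10.64%
1970  12      1      1                     misc. products  1089    10.47%
                                           subtotal        5857    56.30%

                                           total           10403   100.00%
```

Reading the output: the 1965 stint alone contributes 27.76% of the total
risk despite lasting only 4 months, because it is both early (lagged
elapsed time 38 years, squared) and high-potency; "Product A" as a whole
is apportioned ≈44% of the mesothelioma. The `Result` column is the
absolute risk `c·p·(m/12)·T²`, truncated to an integer in `paper` mode.

The same run from a CSV file:

```
mesoapportion run --input history.csv --diagnosis-year 2013 --mode paper
```

with columns `year,months,concentration,potency,description,group` and an
optional `end_year` column that expands a constant multi-year exposure into
one entry per year. Programmatic use mirrors the CLI:

```python
from mesoapportion import CaseConfig, ExposureEntry, apportion

config = CaseConfig(diagnosis_year=2013)
entries = [ExposureEntry(1965, 4, 1, 6, group="Product A"), ...]
report = apportion(entries, config)
report.group("Product A").subtotal_percent
```

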