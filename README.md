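# cantrend

Nowcasting yearly cancer incidence from public search interest.

Official cancer-registry counts lag the current year by two to four
years, which complicates resource planning for diagnosis, treatment and
rehabilitation. `cantrend` implements a deliberately simple nowcasting
model for epidemiologists and health planners who need a short-term
estimate before registry data arrive: it scales the latest observed case
count of a region by the year-over-year change in the region's relative
search volume index (RSVI) — the 0–100 popularity score a search-trends
service assigns to a topic such as "cancer".

## Model

For a region with observed count $Ac_t$ in year $t$ and search indices
$RSVI_t$, $RSVI_{t+1}$, the one-step prediction is

$$Pr_{t+1} = Ac_t \cdot \frac{RSVI_{t+1}}{RSVI_t}$$

and each prediction is validated with the signed percentage error

$$\%Error = \frac{Pr - Ac}{Ac} \times 100 .$$

When actuals stop (registry lag), forecasts are *chained*: each step's
base is the previous step's unrounded prediction, so the $k$-step
forecast telescopes to $Ac_t \cdot RSVI_{t+k}/RSVI_t$. Chained outputs
are flagged `predicted`, because their deviation from reality compounds
with horizon.

The package ships, as packaged CSV fixtures, the published 50-US-state
validation tables this model was originally scored on (2017 one-step
validation with all inputs; 2018–2020 predicted/actual/%error triples;
2021–2023 US and 54-country projections), together with a seeded
synthetic generator of coupled incidence/RSVI series so every operation
is testable without any download.

## Worked example

Reconstruct the packaged 2017 validation run end to end:

```python
from cantrend import table1_inputs
from cantrend.io import write_incidence_csv, write_rsvi_csv

incidence, rsvi = table1_inputs()       # inputs printed in the 2017 table
write_incidence_csv(incidence, "incidence.csv")
write_rsvi_csv(rsvi, "rsvi.csv")
```

```console
$ cantrend validate --incidence incidence.csv --rsvi rsvi.csv --years 2017 --out table1_check.csv
year=2017 n=50 mean_pct_error=-0.983 median_pct_error=-1.584 min=-7.6 max=12.1 prop_within_6pct=0.840
wrote 50 record(s) to table1_check.csv
```

All 50 states are predicted; the mean %error is −0.98, the median −1.58,
and 84 % of states land within the ±6 % band. The report's first rows:

```text
region,base_year,target_year,base_count,base_provenance,rsvi_base,rsvi_target,ratio,predicted_raw,predicted,actual,pct_error
AK,2016,2017,3008.0,actual,67.0,70.0,1.045,3142.686567164179,3143,3067.0,2.5
AL,2016,2017,27550.0,actual,89.0,86.0,0.966,26621.34831460674,26621,27409.0,-2.9
```

Reading the Alabama row: 27,550 actual 2016 cases were scaled by the
full-precision ratio 86/89 = 0.96629… to a raw prediction of 26,621.35,
reported as 26,621; against the 27,409 actual 2017 cases that is a
−2.87 % error, shown as −2.9 at print precision. (The 3-decimal ratio
column is display only — multiplying by 0.966 would give 26,613, which
is wrong.)

The same model is available programmatically:

```python
>>> from cantrend import predict_one_step
>>> rec = predict_one_step(27550, 89, 86, region="AL", base_year=2016, actual=27409)
>>> rec.predicted, round(rec.percent_error, 2)
(26621, -2.87)
```

Other subcommands: `cantrend predict` (one-step predictions without
requiring actuals), `cantrend forecast` (chained projection past the
last observed year), `cantrend simulate` (synthetic coupled data sets),
`cantrend fixtures` (dump a packaged table). Exit codes: 0 success,
2 input/validation error, 3 configuration error.

## Scope

File-based input only: no live querying of any search-trends service
(there is no stable programmatic contract), no registry API clients, no
age/sex/site stratification, no age-standardisation, no prediction
intervals, and no map rendering — region→value exports are designed to
feed external mapping tools.
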