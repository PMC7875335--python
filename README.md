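# snakerisk

Municipality-level snakebite risk analysis: descriptive surveillance
statistics, spatial cluster detection, driver regression, and a four-level
risk-grading instrument for antivenom-allocation decisions.

Snakebite envenoming is a major neglected tropical disease; in Brazil about
27,000 cases a year are reported to the national surveillance system and
treated with publicly distributed antivenom. Deciding *which* municipalities
to prioritise requires combining the epidemiological record with
environmental and socioeconomic drivers of risk. This package implements
that analysis chain for anyone working with municipality-aggregated
surveillance tables (epidemiologists, state health departments, spatial
analysts):

- **`surveillance`** — annual averages, annualised incidence per 100,000,
  case-fatality percentages, state/region/country aggregation, and exact
  Fisher–Jenks natural-breaks classification for choropleth mapping.
- **`moran`** — queen-contiguity spatial weights, Anselin's Local Moran's I
  `I_i = (z_i/m2) Σ_j w_ij z_j`, conditional-permutation pseudo p-values
  (floor `1/(n_perm+1)`), and HH/LL/HL/LH cluster labelling.
- **`regression`** — per-1-SD rate-ratio screening, VIF and Pearson
  collinearity filters, Poisson and negative-binomial count models with Wald
  intervals, and DIC/AIC model selection (overdispersed counts select NB).
- **`flowchart`** — the decision instrument: within-state quartiles classify
  the epidemiological situation High/Low, national driver quartiles count
  high-risk drivers `d_i` (≥ 4 = "many"), and a 2×2 table yields the grade
  High / MediumHigh / MediumLow / Low.
- **`synthetic`** — a synthetic-country generator (lattice municipalities,
  spatially autocorrelated covariates, NB counts with known ground-truth
  coefficients) so the full pipeline is testable without restricted data.
- **`gis`** / **`cli`** — CSV/GeoJSON readers and writers with validation
  and rejection reports, zonal statistics, and a subcommand CLI.

## Worked example

The published Brazilian state-level table for 2013–2017 ships with the
package; the derived columns are recomputed, not stored:

```python
>>> from snakerisk import surveillance as sv
>>> ref = sv.load_reference_table().set_index("unit_id")
>>> br = ref.loc["Brazil"]
>>> sv.annual_average(br.cases, 5)          # cases per year, country level
27120
>>> sv.fatality_rate(br.deaths, br.cases)   # case-fatality, percent
0.38
>>> para = ref.loc["Para"]
>>> sv.incidence_rate(para.cases, 5, para.population)   # per 100,000/year
61.67
>>> sv.mean_per_unit(br.cases, 5564)        # mean bites per municipality
24.37
```

27,120 cases a year nationwide with 0.38% fatality; Pará, the most affected
state, reports 61.67 annual cases per 100,000 inhabitants.

The full pipeline on a synthetic country:

```sh
snakerisk run-all --rows 30 --cols 30 --states 9 --seed 17 --out results/
```

which chains simulation → description → clustering → driver models → risk
grading and ends with

```
graded 900 municipalities: High=94, MediumHigh=236, MediumLow=86, Low=484 -> results/stratify
pipeline complete -> results
```

Every output directory carries a `provenance.json` (parameters, seed, config
hash); rerunning with the same seed reproduces every file byte for byte.

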