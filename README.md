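# hwfplan

Needs-based health workforce planning as an open, tested simulation engine.

Health ministries and planners need to decide how many midwives, doctors or
other cadres to train and employ. `hwfplan` implements the population
needs-based approach: instead of extrapolating utilisation or applying
facility staffing norms, it derives workforce requirements from what the
population actually needs — demography × health status × planned service
levels — and compares them with a stock-and-flow projection of supply.

## The model

**Supply.** For each cadre *n*, the registered stock evolves annually by

```
T[n,t] = T[n,t-1] · (1 − a[n]) + I[n,t]
S[n,t] = T[n,t] · P[n]
```

where `a` is the attrition rate, `I` the inflow of newly licensed entrants
(enrolment cohort lagged by the training duration, net of dropout, plus
immigrants, adjusted by the licensure pass rate), and `P` the
labour-participation rate giving the effective (practising) supply `S`.

**Need.** The needed volume of service *y* in year *t* sums over population
strata (age cohort *i*, gender *j*, location *g*):

```
NHS[y,t] = Σ  P[i,j,g,t] · H[t] · L[y]        with  H[t] = H[t-1] · (1 + R_h)
```

`H` is the proportion of the stratum in need (prevalence or coverage gap),
compounded by its annual rate of change `R_h` estimated from two survey
waves and clamped to [0, 1]; `L` is the planned per-person service
frequency. Volumes convert to full-time-equivalent requirements through the
WISN-style standard workload `SW = AWT / SS` (annual available working
hours over hours per service), a work-division split `W` across cadres, and
the support-activities adjustment factor

```
N[n,t] = Σ_y ( NHS[y,t] · W[y,n] / SW[n,y] ) · SAAF ,   SAAF = 1 / (1 − Σ SAS)
```

which inflates direct-care requirements to cover indirect work (handovers,
meetings) taking a share `SAS` of working time.

**Integration.** Gap = `S − N` on whole-person (half-up rounded)
headcounts, staff availability ratio `SAR = S / N` (1 = equilibrium, < 1 =
shortage), and wage bills `headcount × income` with income compounding at
an annual inflation rate.

## Worked example

A bundled synthetic demo scenario (two cadres sharing four maternal and
new-born care services over 2020–2030) runs end-to-end from the command
line:

```
$ hwfplan demo --out demo_out
demo scenario 'synthetic-demo': wrote 6 files to demo_out
  midwife 2030: need 11044, supply 14729, gap 3685, SAR 133.4%
  obstetrician_gynaecologist 2030: need 1031, supply 440, gap -591, SAR 42.7%
```

The midwife workforce starts just short of need (gap −74, SAR 99.1 % in
2020, see `demo_out/gaps.csv`), crosses into needs-based oversupply as
training output outpaces attrition, and ends 2030 at 133 % of need — a
signal to consolidate rather than expand training. The specialist cadre
stays in deep shortage throughout (SAR 28.9 % → 42.7 %), i.e. the gap of
591 specialists by 2030 is the number to be trained above the current rate
of production. `need.csv`, `supply.csv`, `costs.csv` and `services.csv`
carry the full annual series; `summary.md` a compact digest.

The same engine is scriptable:

```python
from importlib import resources
from hwfplan import load_scenario, run_scenario, apply_variant, compare_scenarios

scenario = load_scenario(str(resources.files("hwfplan") / "data" / "synthetic_demo" / "scenario.yaml"))
base = run_scenario(scenario)
frozen = run_scenario(apply_variant(scenario, "no-rate-change"))
print(compare_scenarios(base, frozen).head())
```

Built-in what-if variants mirror the standard sensitivity analyses:
`no-rate-change` (hold health status at baseline), `no-support-adjustment`
(drop the SAAF) and `tertiary-standards` (switch activity standards to the
tertiary-facility practice setting); `hwfplan sweep` draws seeded uniform
samples over parameter ranges for best/worst-case envelopes.

## Layout

- `hwfplan.scenario_model` — validated domain types (`Scenario` and friends)
- `hwfplan.needs_engine` — health-status projection, service volumes,
  standard workloads, SAAF, FTE requirements
- `hwfplan.supply_engine` — stock-and-flow recursion and education pipeline
- `hwfplan.gap_cost_engine` — gaps, SAR, income and wage-bill series, growth
- `hwfplan.scenario_runner` — full runs, variants, comparisons, sweeps
- `hwfplan.io` / `hwfplan.cli` — YAML + CSV scenario format, result tables,
  `hwfplan` command
- `hwfplan.fixtures` — printed-series fixture, synthetic-scenario
  generator, known-answer scenario

See `docs/methods.md` for modelling assumptions, defaults and limitations.
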