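# Methods

This note documents the model implemented by `hwfplan`, the defaults it
chooses where conventions differ, what the bundled synthetic data does and
does not emulate, and the package's known limitations.

## Model structure

The engine is a deterministic annual cohort simulation with two independent
sides integrated at the end.

**Supply side.** Each cadre's registered stock follows the stock-and-flow
recursion `T_t = T_{t-1}(1 − a) + I_t`. Order of operations matters and is
fixed: attrition applies to the previous year's stock first, then inflows
enter, so new graduates are never attrited in their entry year. Inflow is
`I_t = (E_{t−d}(1 − dropout) + M_t) · pass_rate`, where `E` is the
enrolment series, `d` the whole-year training duration and `M_t`
immigration: immigrants are assumed to sit the same licensure examination
as domestic graduates and share the pass-rate adjustment. The registered /
professionally-active / practising distinction is collapsed to two levels:
a single attrition rate converts registered stock year over year, and a
single participation rate `P ∈ (0, 1]` converts registered stock to
effective (practising) supply. The training lag defaults to 0 years
because aggregate "annual output" series are often already expressed at the
point of graduation; a nonzero `training_duration` shifts the enrolment
lookup. Missing lagged cohorts contribute zero with a logged warning rather
than an error, so short enrolment histories remain usable.

**Need side.** An indicator is the proportion of a selected set of
population strata in need; the engine is agnostic about whether it encodes
prevalence, incidence-derived need or a coverage gap — interpretation
belongs to the scenario author. Its level compounds annually,
`H_t = H_{t−1}(1 + R_h)`, clamped to [0, 1] each year (the model is silent
on proportions above 100 %, and clamping is the only defensible choice for
a proportion). When `R_h` is not given directly it is estimated from two
survey waves. Two conventions are implemented:

- `geometric` (default): `R_h = (H₂/H₁)^{1/Δt} − 1`. Chosen as the default
  because the projection applies the rate via *discrete annual
  compounding* `(1 + R_h)`, and the geometric rate is the exact inverse of
  that operation — simulate-then-estimate round-trips to machine precision.
- `continuous`: `R_h = ln(H₂/H₁)/Δt`, the instantaneous-rate convention,
  selectable per run (`rate_method`).

Service volumes are `Σ_strata P · H_t · L` with `L` the per-person annual
frequency. Workforce requirements divide each service volume, after the
work-division split `W`, by the standard workload `SW = AWT/SS`, then
multiply by `SAAF = 1/(1 − ΣSAS)`. AWT follows the WISN convention:
(possible working days − public holidays − annual leave − sick leave −
other absences) × hours per day; the invariant "available days > 0" is
enforced at validation. Work division is time-invariant by default (the
applied examples we know of use fixed splits) with a per-year override hook
on each service norm. A service may carry one service standard per practice
setting (e.g. `primary` vs `tertiary`); the scenario's `practice_setting`
selects one standard set for the whole run.

**Integration.** Gaps and SARs are computed on headcounts rounded half-up
to whole persons — this choice reproduces published gap tables exactly from
published whole-person need/supply series — while all internal series stay
real-valued. The wage bill of need uses rounded need (one employs whole
people); the wage bill of supply follows the un-rounded supply path, since
the supply series is an expectation rather than an employment decision.
Both conventions are simple to override by passing pre-rounded series to
the cost functions. Income compounds at a constant annual inflation rate
from the baseline; currency is an opaque label.

## Parameters that matter

| parameter | units | default | notes |
|---|---|---|---|
| `attrition_rate` | fraction/year | — (required) | exits ÷ opening stock; `compute_attrition_rate` derives it from counts |
| `participation_rate` | fraction | 1.0 | practising ÷ registered |
| `training_duration` | whole years | 0 | shifts enrolment lookup |
| `dropout_rate`, `pass_rate` | fractions | 0.0 / 1.0 | education-pipeline losses |
| `rate_of_change` / two waves | per year | estimated, geometric | see above |
| `service_standard` | hours/service | — (required) | per practice setting optional |
| AWT components | days, hours | 8 h/day | WISN convention |
| `sas` per support activity | fraction of AWT | — | Σ < 1 enforced |
| `income_inflation` | fraction/year | 0.0 | applied to both cost series |
| flags | booleans | both true | `apply_rate_of_change`, `apply_support_adjustment` |

Proportions are stored as fractions everywhere; percent notation (`"4.5%"`)
is accepted only at the I/O boundary and converted on read, which prevents
double-scaling bugs. Years are calendar integers and series must be dense
over the horizon — missing years are validation errors, never silently
interpolated.

## Scenario validation

`check_scenario` collects every invariant breach as a `(path, message)`
record (k injected defects ⇒ k violations) rather than failing fast, so a
planner fixing a configuration sees all problems at once. Strata are
free-form labels joined by exact match; `"all"` is an ordinary label
conventionally used for composite (non-disaggregated) analysis.

## Sensitivity tooling

Variants are deep-copied scenarios with dotted-path overrides (list items
addressed by their identifying label, e.g.
`cadres.midwife.attrition_rate`). Three ship as built-ins: `no-rate-change`,
`no-support-adjustment`, `tertiary-standards`. The sweep draws each swept
parameter independently and uniformly over its range with a
`numpy.random.default_rng(seed)` stream — a deliberate design choice (the
requirement is only "vary inputs across their plausible range"); the
envelope is the per-cadre-year min/max of need, supply and gap over all
samples plus the base run, so base containment holds by construction.
Everything downstream of the seed is deterministic; two runs with the same
scenario and seed are bit-identical.

## Synthetic data: what it emulates, what it does not

The published national application this engine generalises did not print
its raw inputs (population tables, indicator levels, enrolments); only its
output series are public. The package therefore splits testing in two:

- the **printed-values fixture** stores the published need/supply/cost/
  support-allowance series digit-for-digit and feeds them through the gap,
  SAR, SAAF, growth and aggregation operations, which must return the
  published gaps, ratios and totals at printed precision (three 2030-column
  entries and one supply-growth percentage reflect rounding of unpublished
  underlying reals and are asserted at ±1 person / ±0.1 point);
- the **synthetic generator** draws complete, valid scenarios shaped like
  that application (11-year horizon, two cadres, age × gender × location
  strata, indicator trends of a few percent a year, sub-hour activity
  standards, support allowances of 2–12 %) for property-based testing of
  the needs and supply engines against independent brute-force loop
  oracles, and a hand-derivable known-answer scenario pins the full
  pipeline arithmetic.

Synthetic populations grow smoothly at constant stratum-specific rates and
indicator trends are exact geometric series, so passing tests demonstrate
arithmetic correctness of the engines, not forecasting skill: real
populations, disease trends and labour markets are not this well behaved,
and nothing here validates the behavioural realism of any particular
scenario's inputs. The bundled demo scenario is likewise synthetic — a
plausible, internally consistent illustration, not country data.

## Numerical choices

- Work-division sums are checked to an absolute tolerance of 1e-9;
  normalised random splits pass, hand-entered splits that are off by a
  rounding step fail loudly.
- Half-up rounding (0.5 → 1, away from zero for negatives) is used for
  headcounts, matching how published tables reconcile.
- Oracle-equivalence tests use 1e-9 relative tolerance; structural
  identities (SAAF ratio, homogeneity, inverse-linearity in service
  standards) are asserted at 1e-12 relative.
- Degenerate inputs fail with explicit errors: zero need for SAR, zero
  baseline for rate estimation, non-positive available working days,
  support allowances summing to ≥ 1, exits exceeding stock.
- Test and acceptance problem sizes (scenarios up to ~50 strata × 10
  services, 100 random scenarios for the oracle sweep, 3–8 year synthetic
  horizons) were chosen as the smallest sizes that exercise every code
  path and stratum-join combination; the whole suite runs in seconds.

## Known limitations

- No demand weighting: this is a full (unweighted) needs-based analysis;
  translating need into funded demand against a budget envelope is out of
  scope beyond the wage-bill series.
- No behavioural feedback: supply does not respond to wages or working
  conditions, and health-status trends are deterministic compounding, not
  epidemiological dynamics. Long-range projections should be revisited as
  data arrive.
- Attrition and participation are scalar per cadre; age-structured
  workforce stocks (retirement waves) are not modelled.
- The published sensitivity-analysis magnitudes of the national application
  (e.g. the ~17–23 % long-run effect of freezing health-status trends)
  depend on its unpublished inputs and cannot be re-derived here; the
  package asserts the corresponding directional and structural properties
  instead.
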