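# Methods

## Model and assumptions

The engine scores each above-background asbestos exposure period with an
absolute mesotheliogenic risk

    risk = concentration × potency × (months / 12) × T^e

and apportions by normalising these scores into percentages. `T` is the
elapsed time from the exposure year to the diagnosis year minus a latency
lag `L` (floored at zero), and `e` is the time exponent.

Assumptions baked into this form:

- **Linearity in dose.** Risk scales linearly with concentration, potency
  and duration. Supralinear concentration effects and threshold doses are
  deliberately not modelled: no above-background exposure can be shown to
  contribute zero risk, so all are scored proportionally.
- **Power-law time dependence.** Mesothelioma incidence grows roughly as a
  power of time since exposure. The default is lag 10 years then square
  (`L=10, e=2`); the unlagged cube (`L=0, e=3`) is a recognised variant
  that produces very similar apportionments, and both are reachable through
  `CaseConfig`. With `e=2` an exposure with twice the lagged elapsed time
  carries exactly four times the risk.
- **Relative scales only.** Because percentages are ratios, the absolute
  calibration of concentration and potency cancels; only ratios between
  entries matter. Genetic and host factors are assumed to multiply all
  entries equally and therefore cancel as well.
- **No causation judgement.** The engine never decides whether a
  mesothelioma is asbestos-related; it only apportions among the entries it
  is given, on the premise that the case has already been attributed to
  asbestos.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `diagnosis_year` | calendar year | — | required |
| `lag_years` | years | 10 | latency window with essentially no risk |
| `time_exponent` | — | 2 | power on the lagged elapsed time |
| `max_years` | years since exposure | none | plateau; lagged term saturates at `max_years − lag_years` |
| `rounding_mode` | — | `exact` | `paper_truncate` floors each entry risk to an integer |
| entry `months` | months | — | 0 < m ≤ 12, fractional allowed |
| entry `concentration` | relative 8-h TWA (or fiber/cc·yr dose with months=12) | — | > 0 |
| entry `potency` | relative to commercial chrysotile = 1 | — | > 0 |

Potency presets: chrysotile/amosite/crocidolite 1:100:500 (lifetime basis)
and 1:35:200 (occupational basis), plus a generic-amphibole 50:1 working
figure kept as a separate "example" scenario rather than averaged into the
others, since it is an operator's illustrative choice rather than a
literature estimate. `mixed_potency` blends component potencies by mass
fraction (0.9·1 + 0.1·50 = 5.9 ≈ 6). Presets are advisory only: the engine
never substitutes them silently; the operator enters every potency.

## Numerical choices

- **Truncation convention.** In `paper_truncate` mode each entry risk is
  floored to an integer *before* subtotaling and normalisation, so
  percentages are ratios of truncated integers. This reproduces the
  reference printout cell for cell (e.g. an exact risk of 1140.833…
  reports as 1140 and 1140/10403 → 10.96%). Floor was chosen over
  round-half-down; both are consistent with the reference output. The
  default `exact` mode keeps full double precision and is what real
  analyses should use.
- **Display rounding.** Percentages render with exactly two decimals,
  half-up, applied only at rendering; displayed percents may sum to
  100 ± 0.02 and are not force-balanced, so each cell remains individually
  reproducible.
- **Plateau semantics.** `max_years` is applied per entry: each entry's
  lagged term saturates at `max_years − lag_years`. The alternative —
  anchoring the plateau to the earliest exposure year of the whole
  history — was considered and rejected because the risk formula itself is
  per-entry and a per-entry cap keeps entries independent of one another.
- **Lag-window entries.** An exposure inside the latency window gets risk 0
  with a logged warning rather than an error: such periods are legitimate
  history. If *every* entry is inside the window the total is zero and
  apportionment is refused.
- **Group identity.** Labels are matched case-sensitively after trimming
  surrounding whitespace; blank labels collect under `(ungrouped)`. Groups
  report in order of first appearance in the input (the printout layout is
  consistent with either this or alphabetical order; `--sort label` gives a
  case-insensitive alphabetical ordering). Entries within a group sort by
  year, ties by input order.
- **Degenerate inputs.** Empty histories, exposures dated after diagnosis,
  nonpositive concentrations/potencies, months outside (0, 12] and inverted
  year ranges are rejected with errors naming the offending field (and, for
  CSV input, the row and column).

## Synthetic history generator

`generate_history` produces deterministic (per-seed) random exposure
histories for property testing: years uniform over the requested range,
months in half-month steps on (0, 12], concentrations lognormal(0, 1)
(spanning roughly two orders of magnitude, matching the relative-TWA entry
convention), and potencies drawn from the preset-like set
{1, 6, 35, 50, 100, 200, 500} weighted 3:1 toward chrysotile, reflecting
its dominant historical share of use. Group labels cycle through a small
set of product names.

What it emulates: the *shape* of a plausible occupational history — mixed
fiber types, uneven durations, widely varying concentrations. What it does
not: correlation structure of real careers (consecutive years at one job
with one product), recall error, or dose-reconstruction uncertainty.
Passing property tests therefore demonstrate the algebraic guarantees of
the engine (conservation, scale/permutation/shift invariance, agreement
with brute-force recomputation) on valid inputs, not the epidemiological
accuracy of any particular apportionment — which, as with the model
itself, is bounded by the quality of the operator's inputs.

Test problem sizes: property suites run on seeded histories of up to 50
entries, 200 histories in the end-to-end suite — ample for an engine whose
per-history cost is linear in the number of entries.

## Known limitations

- The time term uses whole calendar years; sub-year timing of an exposure
  within its year is not resolved (a 0.5-month stint in January and one in
  December of the same year score identically).
- The plateau interpretation ("time since exposure", per entry) is one of
  two defensible readings; see Numerical choices.
- No uncertainty quantification: percentages are point apportionments with
  no confidence intervals.
- The engine deliberately has no opinion on whether the disease is
  asbestos-related, on actual exposure reconstruction, or on the correct
  potency ratios — those are operator inputs, and results are only as good
  as they are.
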