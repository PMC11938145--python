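# agrocycle

Multi-objective allocation of irrigation water, nitrogen fertilizer and
straw in a two-stage circular agroecosystem (tomato–corn–soybean style
rotations).  The model composes:

* **production** — Jensen multiplicative crop-water production with a
  concave quadratic nitrogen response, field water balance, irrigation
  quotas from soil moisture, straw biomass, and quadratic biochar/straw
  amendment effects on the recycling stage;
* **straw** — splitting collected biomass into field return, biochar
  preparation, power generation (combustion + gasification) and sale;
* **economics** — net economic benefit from crop, straw and electricity
  revenues minus material, electricity and water costs;
* **quality** — a weighted comprehensive crop-quality objective, with AHP,
  entropy and game-theoretic combination weighting machinery;
* **footprints** — a CO2/CH4/N2O inventory (GWP 28 / 298) minus carbon
  sequestration, and green/blue/gray water footprints, both per kg of
  production;
* **optimize** — fuzzy max-min scalarization of the four objectives
  (NEB, TCQ, WF, CF) anchored to a payoff table of single-objective
  optima, solved with multistart SLSQP, plus a brute-force grid oracle;
* **hydro** — triangular intuitionistic fuzzy parameters with accuracy
  defuzzification, and Pearson-III precipitation frequency analysis with
  wet/normal/dry hydrological-year classification and Monte-Carlo
  sampling;
* **synthetic** — seeded generation of parameter bundles, the 9-treatment
  factorial trial design, noisy observations and precipitation records,
  with inverse fitting helpers for validation;
* **evaluation** — R², nRMSE, Willmott consistency index and the coupling
  coordination degree model for scenario comparison.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` carries the acceptance criteria (GHG conversion
factors, AHP consistency of the five shipped allocation scenarios,
hydrological-year classification, solver-vs-oracle dominance on 20 seeded
toys, parameter recovery, end-to-end validation metrics, Monte-Carlo class
proportions, invariant suites, and the directional coordination check).
The full suite runs in roughly five minutes on one CPU.

## CLI

```bash
agrocycle generate --seed 1 --out results/          # synthetic study instance
agrocycle optimize --scenario Sw2 --hydro normal --seed 1 --out results/
agrocycle evaluate --table pairs.csv                # R2 / nRMSE / WCI
agrocycle report --config config.yaml --out results/run1
```

A minimal config:

```yaml
seed: 1
study: {n_crops: 3, n_stages: 5, noise_cv: 0.05}
precip: {mean_mm: 553.2, cv: 0.25, cs: 0.5}
optimize:
  n_starts: 4
  scenarios: [Sw1, Sw2, Sw3, Sw4, Sw5]
  hydro_years: [wet, normal, dry]
```

`report` runs generate → optimize (each scenario × hydrological year) →
coordination evaluation, and writes CSV summaries, scenario rankings and a
run manifest.  The full default report (15 optimizations over the 3-crop
instance) takes several minutes; shrink `scenarios`/`hydro_years` or the
crop count for quick runs.

## Straw-allocation scenarios

Shipped in `src/agrocycle/data/scenarios.csv`:

| scenario | return | biochar | electricity | sale |
|----------|--------|---------|-------------|------|
| Sw1      | 0.25   | 0.25    | 0.25        | 0.25 |
| Sw2      | 0.55   | 0.20    | 0.15        | 0.10 |
| Sw3      | 0.05   | 0.60    | 0.20        | 0.15 |
| Sw4      | 0.14   | 0.06    | 0.50        | 0.30 |
| Sw5      | 0.26   | 0.20    | 0.14        | 0.40 |
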