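# lungcea

A Markov cohort state-transition model for evaluating the
cost-effectiveness of lung-cancer screening strategies in a Chinese
population: annual or one-time low-dose CT (LDCT), alone or with a
plasma micro-RNA signature classifier (MSC) triaging CT-positive
nodules, at 20 or 30 pack-year eligibility thresholds.

The model tracks 12 health states (healthy, carcinoma in situ, stages
I–IV, five post-treatment maintenance states, death) over 1-year cycles
from screening entry (ages 50–74) to age 79, and reports discounted
costs (2018 CNY), life-years, and QALYs per strategy, pairwise ICERs
with dominance labels, efficiency frontiers, one-way (tornado)
sensitivity analyses, probabilistic sensitivity analysis with
beta/gamma parameter distributions, cost-effectiveness acceptability
curves, and test-characteristic threshold searches.

## Layout

| module                     | role                                                        |
| -------------------------- | ----------------------------------------------------------- |
| `lungcea.parameters`       | typed, validated input vector + PSA sampling distributions  |
| `lungcea.natural_history`  | age/sex/smoking-adjusted 12-state transition matrices       |
| `lungcea.screening`        | the 8-strategy catalog and the per-cycle screening overlay  |
| `lungcea.engine`           | cohort trace propagation and discounted payoff accrual      |
| `lungcea.cea`              | ICERs, dominance, frontier, net monetary benefit, CEAC      |
| `lungcea.sensitivity`      | one-way sweeps, tornado, PSA, threshold search              |
| `lungcea.fixtures`         | toy chains + independent oracles (fundamental matrix, microsimulation) |
| `lungcea.refdata`          | published population-level base-case table (regression anchor) |
| `lungcea.cli` / `reporting`| command-line workflow and table writers                     |

All default inputs ship in `src/lungcea/data/defaults.yaml`, each value
tagged `[published]` (verbatim from the published input table) or
`[fixture]` (needed but never printed; clearly-labelled, overridable
defaults).

## CLI

```sh
lungcea validate                            # check a parameter file
lungcea run --start-age 65 --out out/       # base-case CEA table
lungcea dsa --start-age 65 --out out/       # tornado data (8 default sweeps)
lungcea psa --start-age 65 --n-iter 10000 --seed 1 --out out/
lungcea threshold --start-age 65 --path spec_msc_conj \
    --intervention 6 --vs 2 --target -27000 --bounds 0.81 0.99
```

Machine outputs are tab-separated text with a commented header carrying
the seed, parameter digest and schema version; pretty tables use the
published presentation units (cost in CNY millions, LY/QALY in
10,000s, 2 decimals).

## Notes on fidelity

Exact numeric reproduction of the published population-level outcomes
is not attainable: the original model was built in a proprietary GUI
environment and several mechanisms (clinical-presentation stage
distribution, false-positive workup depth, PSA standard errors) are
unreported. Those gaps are filled with explicit, overridable fixture
defaults, and fidelity is asserted at the level the published data
supports: arithmetic identities on the printed table, dominance
structure (the annual 20-pack-year strategies dominate the 30-pack-year
reference), and engine correctness against independent oracles.
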