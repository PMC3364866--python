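# suprapop

Tools for deciding whether the polymorphisms two related species share are
compatible with neutral genetic drift alone, or require ongoing
hybridisation — built around the dabbling ducks (genus *Anas*), where a
SNP panel developed in the mallard stays polymorphic in congeners that
diverged more than six million years ago at rates an order of magnitude
above comparable species pairs.

The package has four working parts:

- **`suprapop.drift`** — the closed-form persistence-time calculus. A
  neutral polymorphism at initial minor-allele frequency *p* in a
  population of effective size *N*<sub>e</sub> segregates on average for

  *t*(*p*) = −4 *N*<sub>e</sub> [(1 − *p*) ln(1 − *p*) + *p* ln *p*]

  generations. With *N*<sub>e</sub> = 0.1 *N*<sub>c</sub> and one-year
  generations this turns census counts into My-scale persistence times,
  retention thresholds (3.8 *N*<sub>e</sub> generations), sensitivity
  scenarios, and pooled "supra-population" gene pools for hybridising
  species complexes.
- **`suprapop.wright_fisher`** — a forward Wright–Fisher simulator
  (binomial resampling of 2*N* allele copies) plus an exact Markov-chain
  oracle that validates it, and a two-population island model in which
  gametes migrate at rate *m* per generation — hybridisation opposing
  drift.
- **`suprapop.genotypes`** — genotype-matrix I/O (a simple TSV dialect and
  biallelic VCF), per-species QC (MAF, observed heterozygosity,
  missingness, an exact Hardy–Weinberg test by full enumeration), and
  cross-species polymorphism-sharing reports with full Venn decomposition.
- **`suprapop.synth`** — a generator for synthetic study-shaped panels
  (focal-species ascertainment, star-shaped divergence with gene flow,
  per-species sample sizes and missingness, F1 hybrids), so the entire
  pipeline is testable without any data download.

A `suprapop` command line (`simulate-panel`, `qc`, `share`, `persist`,
`wf-sim`, `run-all`) orchestrates the stages from a YAML config with
seeded, byte-reproducible outputs.

## Worked example

```python
from suprapop.pipeline import RunConfig, run, render_report
from suprapop.drift import ScenarioConfig
from suprapop.synth import PanelConfig

cfg = RunConfig(
    out_dir="demo", seed=1,
    panel_recipe=PanelConfig(seed=1),          # study-shaped synthetic panel
    scenarios=(
        ("Anas platyrhynchos", ScenarioConfig(1.0, divergence_time=6.4e6)),
        ("Anas acuta",         ScenarioConfig(3.0, divergence_time=6.4e6)),
        ("Anas penelope",      ScenarioConfig(3.0, divergence_time=8.0e6)),
    ),
    wf_diploid_size=50, wf_replicates=5000,
)
print(render_report(run(cfg)))
```

prints (abridged):

```
Polymorphism sharing:
  acuta: 182 polymorphic loci (50% of panel)
  ...
  fuligula: 1 polymorphic loci (0% of panel)

Persistence table (generations):
  Anas platyrhynchos: Ne=1,900,000; p=0.5: 5,267,919, p=0.1: 2,470,631
  Anas acuta: Ne=540,000; p=0.5: 1,497,198, p=0.1: 702,179
  Anas strepera: Ne=380,000; p=0.5: 1,053,584, p=0.1: 494,126  [literature cell flagged]
  ...
  scenario Anas platyrhynchos x1: threshold 7.2 My vs divergence 6.4 My -> retained
  scenario Anas penelope x3: threshold 3.8 My vs divergence 8 My -> not retained
  supra-population (Anas platyrhynchos, Anas acuta, Anas crecca):
    Ne = 3.1 million; mean persistence at p=0.5 8.68 My

Wright-Fisher check (N=50): simulated mean absorption 136.7 +/- 1.4 gen;
    oracle 136.6; diffusion 138.6
  gene flow m=0: joint shared fraction 0.293
  gene flow m=0.1: joint shared fraction 0.837
```

Reading it: mallard-scale populations (*N*<sub>e</sub> ≈ 1.9 M) can hold a
balanced polymorphism for ~5.3 My on drift alone, but the smaller species
cannot cover their ≥ 6.4 My divergences even with a threefold
*N*<sub>e</sub> allowance — while the synthetic panel, generated *with*
gene flow, still shows a mallard-like sharing gradient, and the simulator
shows joint shared polymorphism rising steeply with the hybridisation
rate. The flagged table cell is a known typesetting duplication in the
published species table; the formula value is printed instead. Pooling the
three hybridising species lifts *N*<sub>e</sub> to 3.1 M and persistence
to ~8.7 My — past their common ancestor.

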