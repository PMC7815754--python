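# guteco

Ecological process inference for host-associated microbiota succession.

`guteco` is a Python library for quantifying the processes — selection,
dispersal and drift — that govern how gut microbial communities assemble and
turn over across host development, treating the host gut and its surrounding
water as one metacommunity. It is aimed at microbial ecologists working with
rarefied OTU/zOTU tables, a reference 16S phylogeny and per-sample metadata
from longitudinal rearing designs (e.g. fish hatched and reared under
manipulated water environments and sampled from larva to adult).

## What it computes

For every pair of communities within a developmental stage:

* **βMNTD / βNTI** — abundance-weighted beta mean nearest taxon distance,
  z-scored against a tip-label-shuffle null on the study phylogeny.
  βNTI < −2 signals homogeneous selection, βNTI > +2 heterogeneous selection.
* **RC_bray** — Raup–Crick on Bray–Curtis from a richness-preserving,
  occupancy-weighted null assembly of the metacommunity, in [−1, 1].
  When |βNTI| < 2, RC > 0.95 signals dispersal limitation and RC < −0.95
  homogenizing dispersal; everything else is undominated.
* **Process profiles** — per-stage fractions of the five assembly processes.
* **Selection strength** — excess of observed within-stage similarity over an
  α/γ-preserving null, with a permutation p-value.

Around the core inference: alpha diversity (richness, Shannon, Faith PD),
Bray–Curtis/Jaccard distances, Venn-style shared-OTU fractions, Rao
quadratic-entropy partitioning of ecosystem diversity
(γ = α_local + β_intra-habitat + β_inter-habitat, equivalent-numbers
corrected), PERMANOVA, Mantel and partial Mantel tests, one-way ANOVA with
LSD letters, and Chevan–Sutherland hierarchical partitioning of
alpha-diversity variance.

A first-class **synthetic metacommunity generator** emulates the
hatch/transition rearing design (three environments with mostly-unique
species pools, a 3×3 hatch×rearing transition at 12 dph, seven timepoints in
three developmental stages, stage-dependent Gaussian trait filtering on a
Brownian trait with phylogenetic signal, immigration and drift), with a
recorded truth block so the whole pipeline is verifiable end to end.

## Worked example

```python
from guteco import (NullModelConfig, SimulationConfig, pairwise_turnover,
                    process_profile, simulate_study)
from guteco.data import rarefy

cfg = SimulationConfig(n_otus=800, dph_schedule=(12, 20, 27, 42, 56, 98),
                       replicates=1, depth=500, seed=8)
study = simulate_study(cfg)                      # 54 gut + 45 water samples
table = rarefy(study.table, cfg.depth, seed=0)
turnover = pairwise_turnover(table, study.tree, study.metadata,
                             NullModelConfig(n_null=199, seed=0))
print((100 * process_profile(turnover)).round(1))
```

prints (percentages of within-stage pairs per process):

```
       heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated
group
S1                        36.6                    0.0                  28.8                    26.1          8.5
S2                         2.6                    5.2                  11.1                    30.7         50.3
S3                         0.7                   39.2                   1.3                    34.0         24.8
```

Reading the table: homogeneous selection rises from 0% of pairs at the
larval stage to 39% in adults — the pipeline recovers the generator's
stage-increasing selection schedule s = (0.3, 0.6, 0.8), the signature of
host filtering compounding with development. Early stages instead show
heterogeneous selection and dispersal signatures (fish still carry their
distinct hatching-environment communities), and dispersal limitation fades
from 29% to 1% as host selection takes over.

The `examples/` directory holds one short narrative script per capability:
study simulation, diversity partitioning, process classification, selection
strength and community statistics. A thin CLI (`succession-proc`) exposes
the same stages (`simulate`, `diversity`, `processes`, `selection-strength`,
`stats`, `run`) for shell pipelines; `run` executes the full
simulate → rarefy → diversity → processes → stats chain and writes every
intermediate as TSV plus a JSON summary, byte-identically under a fixed
seed.

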