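# tmtboot

Bootstrap inference for **bridged multi-plex TMT proteomics**: differential
protein abundance between groups that were measured in *separate* TMT plexes
linked only through a pooled-reference channel.

## The problem

In isobaric-labelling (TMT) proteomics, reporter-ion intensities are directly
comparable only within one plex. Studies that need more samples than a plex
holds — here, a post-exercise plasma extracellular-vesicle study with 10
ME/CFS cases and 12 sedentary controls, each sampled pre-exercise, 15 min and
24 h after a maximal cycling test — spread subjects over several plexes and
load one channel per plex with a pooled reference so each sample can be
expressed as a ratio to it. Cases and controls still sit in different plexes,
so group comparisons are only valid inside a *block*: a case plex bridged to
a control plex (compositions 3:3, 3:3, 2:3, 2:3 here).

`tmtboot` implements the full statistical chain this design requires:

1. **Preprocessing** — loading normalization, reference ratios, contaminant
   (lipoprotein/keratin) exclusion, a 75 %-of-experiments **and**
   75 %-of-samples detection filter, and iterative ensemble (random-forest
   style) imputation with group/time/block covariates.
2. **Differential abundance** — per protein and contrast, every
   case × control log2 fold-change pair within each block (9 per 3:3 block,
   6 per 2:3); the bootstrap draws `n_case(b)` pairs per block with
   replacement, pools across blocks and takes the median, B = 10,000 times.
   The 95 % nearest-rank percentile interval is then **false-coverage-rate
   adjusted** (Benjamini–Yekutieli, q = 0.1): with R of m nominal CIs
   excluding 0, all intervals are re-cut at level 1 − Rq/m, and a protein is
   differentially abundant iff its adjusted CI still excludes 0. Within-group
   change over time uses one-sample t-tests of subject log2 fold changes
   with BH correction.
3. **Enrichment** — one-sided hypergeometric over-representation with BH,
   and classical preranked GSEA (weighted-KS enrichment score, gene-set
   permutation null, NES, minSize 5 / maxSize 500) on the bootstrapped
   median log2 fold-change ranking.
4. **Clinical screening** — per group, Spearman correlation of each
   protein's fold change against clinical/exercise parameters (Bell scale,
   SF-36, symptom-score changes, VO₂peak, VAT, …) with 2000-resample
   bootstrap CIs, BH within parameter, and the |ρ| > 0.8 & q < 0.1
   "significant and strong" rule. Welch-from-summary and Wilcoxon utilities
   cover the cohort-table and particle-level comparisons.
5. **Synthetic cohorts** — a generator that reproduces the exact block
   design, log-normal abundances with subject random effects, planted
   group×time effects, block-structured missingness, and clinical covariates
   rank-linked to protein fold changes via a Gaussian copula — with ground
   truth, so every stage is verifiable end to end.

## Worked example

```python
from tmtboot import (SimulationConfig, simulate_cohort, timepoint_log2,
                     between_group_pairs, bootstrap_ci_table)
from tmtboot.simulate import Effect

effects = tuple(Effect(f"PROT{i:04d}", "T15m", 1.0) for i in range(1, 6))
matrix, meta, design, _, truth = simulate_cohort(
    SimulationConfig(n_proteins=100, effects=effects), seed=7)

values = timepoint_log2(matrix, meta, "T15m")
pairs = [between_group_pairs(values.loc[p], meta, design, p, "T15m")
         for p in values.index]
results = bootstrap_ci_table(pairs, B=10_000, ci_level=0.95, fcr_q=0.1, seed=7)
for r in results:
    if r.significant:
        print(r.protein_id, round(r.median_log2fc, 2), r.ci_adjusted)
```

prints (see `examples/02_differential_abundance.py` for the full script):

```
significant proteins (adjusted CI excludes 0): 6 of 100
  PROT0001: median log2 FC +0.92, adjusted CI (+0.20, +1.45)  [planted]
  PROT0002: median log2 FC +1.22, adjusted CI (+0.70, +1.56)  [planted]
  PROT0003: median log2 FC +0.99, adjusted CI (+0.50, +1.40)  [planted]
  PROT0004: median log2 FC +1.28, adjusted CI (+0.97, +1.77)  [planted]
  PROT0005: median log2 FC +1.10, adjusted CI (+0.80, +1.56)  [planted]
  PROT0037: median log2 FC +0.34, adjusted CI (+0.09, +0.55)  [FALSE POSITIVE]
null proteins: mean estimate +0.009 (should be ~0)
```

All five proteins simulated with a doubled abundance in cases at 15 min are
recovered with estimates near +1; the adjusted intervals of null proteins
almost all cover 0.

The `examples/` directory has one short script per capability (simulation,
differential abundance, enrichment, clinical screening, full pipeline), and
the `tmtboot` console command exposes the same stages as subcommands
(`simulate`, `preprocess`, `diffabund`, `enrich`, `correlate`, `run`).

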