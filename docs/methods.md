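# Methods

## The comparability structure

All inference respects one constraint: reporter-ion quantities are
comparable only within a TMT plex, and across plexes only as ratios to the
pooled-reference channel. A **block** pairs one case plex with one control
plex; case:control fold changes are formed inside blocks and never across
them. The default design is four blocks with compositions 3:3, 3:3, 2:3 and
2:3 (10 cases, 12 controls), each subject contributing three samples
(pre-exercise, 15 min, 24 h post-exercise) within a single plex.

## Preprocessing

* `normalize_total` equalizes each sample's non-missing column total to the
  across-sample mean total (loading normalization for raw S/N data).
* `to_reference_ratios` divides each sample by its plex's reference column;
  a ratio is missing if either operand is.
* `filter_contaminants` removes proteins annotated as lipoproteins or
  keratins, the standard contaminant classes of EV proteomics.
* `filter_detection` keeps a protein iff it is detected (≥ 1 non-missing
  sample) in ≥ 75 % of blocks **and** in ≥ 75 % of all samples. Both
  fractions are compared with ≥ on exact rationals so that 3 of 4 blocks
  passes a 0.75 threshold; "detected in an experiment" means at least one
  sample of the block observes the protein, since whole-run dropout is the
  dominant TMT missingness pattern. Both rules are evaluated on the input
  matrix simultaneously (conjunction), not sequentially.
* `impute` fills the remainder. The `forest` method is iterative ensemble
  regression (scikit-learn `IterativeImputer` with `ExtraTreesRegressor`):
  samples are rows, each protein is regressed on all other proteins plus
  one-hot group, time-point and block covariates, sweeping until the change
  in imputed values plateaus or `max_iter` is reached. Ratio-scale data are
  imputed on log2 and mapped back; observed cells are restored bitwise.
  `knn` and `column_median` are deterministic baselines used by the tests.
  `mask_and_score` measures NRMSE = RMSE/SD on deliberately masked cells;
  a mean-type imputer scores ≈ 1 on structureless data, and the forest
  imputer scores well below 1 when proteins are correlated.

## Bootstrapped median fold-change inference

For a contrast (a time point, or a within-subject ratio of two time points)
the subject-level quantity is the log2 reference ratio (or log2 fold
change). Within each block, all case-minus-control differences are formed:
n_case × n_control values (9 for 3:3, 6 for 2:3; 30 in the default design).
Each bootstrap replicate draws, with replacement, k_b = n_case(b) values
from block b's pair list — 3 from 9 and 2 from 6 in the default design,
generalizing "one third of the pairs" to arbitrary compositions — pools the
draws (10 values) and records the median. The point estimate is the median
of the B = 10,000 bootstrap medians.

Intervals are **nearest-rank percentile**: with α = 1 − level, the order
statistics at 1-based ranks ⌈(α/2)B⌉ and ⌈(1−α/2)B⌉ (an epsilon-guarded
ceil keeps e.g. 0.025·1000 at rank 25). False-coverage-rate adjustment
(Benjamini–Yekutieli's CI analogue of FDR) uses the selection rule "nominal
CI excludes 0": with R of m selected, every interval is re-cut at level
1 − Rq/m ≥ the nominal level, so adjusted intervals contain nominal ones;
significance requires the adjusted interval to exclude 0. With R = 0
nothing is significant and intervals stay nominal. An alternative reading —
widening CIs to match BY-adjusted bootstrap p-values — was considered and
not implemented; the FCR construction is the standard CI-side procedure.

All arithmetic is on the log2 scale, where "ratio = 1" becomes "log2 FC =
0" and group-swap antisymmetry is exact. Pair lists are ordered by the
unordered subject-id pair, so exchanging case/control roles negates every
drawn value under the same seed stream (bitwise mirror for symmetric
compositions). The RNG uses one master seed with per-protein substreams
keyed by a CRC-32 hash of the protein id, making results independent of
protein ordering and parallelization.

Within-group change over time needs no bootstrap (a subject's three samples
share one plex): subject log2 fold changes are tested against 0 with a
two-sided one-sample t-test, BH-adjusted across proteins. Zero-variance
inputs are flagged degenerate (p = 1 when the mean is also 0, else p = 0).

`bh_adjust` / `by_adjust` implement the step-up q-values directly
(q_i = min_{j≥i} m·p_(j)/j, BY multiplying by Σ 1/i, capped at 1); the test
suite checks them against statsmodels as an independent reference.

## Enrichment

* **Over-representation** (`fisher_ora`): one-sided hypergeometric upper
  tail of the overlap between a hit list and each set, both intersected
  with the background first; BH across tested sets. The background defaults
  to the post-filter protein universe, not a genome-wide list — a narrower,
  more conservative choice than web-service defaults.
* **Preranked GSEA** (`gsea_preranked`): weighted Kolmogorov–Smirnov
  running sum with weight exponent 1 — each hit adds |r|/Σ_set|r|, each
  miss subtracts 1/(N−|set|); ES is the maximal absolute deviation (ties
  between the positive and negative extremum resolve positive, with a
  1e-12 relative guard so float summation order cannot flip the choice).
  The null is gene-set permutation: nperm uniformly drawn same-size
  subsets. Subsets are drawn as gene identities and mapped to ranking
  positions, which makes the entire result antisymmetric under metric
  negation, seed for seed. p is the add-one-smoothed one-sided tail among
  permutation scores of matching sign; NES divides ES by the mean
  |permutation ES| of that sign; BH across retained sets (sizes 5–500
  after universe intersection). This is classical permutation preranked
  GSEA; adaptive multilevel p-estimation (which differs in the deep tail)
  is deliberately out of scope. Ranking ties keep input order (stable
  sort); duplicate gene symbols keep the entry with the largest |metric|.

## Clinical screening

Per group separately, each protein's within-subject log2 fold change is
correlated (Spearman, average ranks) with each clinical parameter. A pairs
bootstrap (B = 2000) yields a nearest-rank 95 % CI; degenerate replicates
(zero rank variance) are redrawn. The p-value is the two-sided tail count
p = 2·(1 + min(#{ρ* ≤ 0}, #{ρ* ≥ 0}))/(B + 1), capped at 1 — add-one
smoothing prevents p = 0. BH is applied within each parameter across
proteins, never pooled across parameters. `passes_rule` marks |ρ| > 0.8 and
q < 0.1.

A consequence worth knowing: the smoothed p floor is 2/(B+1) ≈ 10⁻³ at
B = 2000, so a *single* true correlation among m screened proteins can pass
q < 0.1 only when m ≲ 100; larger families need several co-significant
proteins to share the floor rank. The recovery tests therefore screen a
50-protein family.

ΔSSS is the symptom score at 24 h minus at 0 h (positive = worsened; the
post-exertional-malaise readout). Cohort-table comparisons use Welch's
unequal-variance t-test from summary statistics (the printed p-values are
reproduced under Welch but not under the pooled-variance test); particle
size/concentration comparisons use Wilcoxon rank-sum (unpaired) and
signed-rank (paired, zeros dropped), exact for small tie-free samples.

## Synthetic cohort generator

Log2 abundance of protein p in subject s at time t:
μ_p + u_s + δ_{p,g(s),t} + ε, with u_s ~ N(0, subject_sd²) and
ε ~ N(0, residual_sd²). The reference channel of a plex carries the mean of
the plex's baseline generative means (μ_p + u_s), so reference division
cancels baseline and subject structure exactly: a noise-free cohort returns
planted contrasts without bias, which is what makes the recovery tests
sharp. Output values are linear-scale sample/reference ratios.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| blocks | 3:3, 3:3, 2:3, 2:3 | the study design (10 cases, 12 controls) |
| baseline mean / SD (log2) | 7.0 / 1.5 | typical reporter S/N spread |
| subject SD (log2) | 0.25 | moderate between-subject biology |
| residual SD (log2) | 0.30 | chosen so planted \|δ\| = 1 effects are recoverable at the study's n; a calibration, overridable |
| n_proteins | 500 | desk-scale stand-in for the ~865-protein post-filter set |

Planted effects shift cases additively at a time point (ratio contrasts act
on the numerator time point). Block missingness masks whole protein×block
stripes with probability p_block plus independent cell dropout — the two
regimes real multi-plex data mixes. Clinical covariates are linked to
realized fold changes by a Gaussian copula: latent Pearson 2·sin(πρ/6)
yields population Spearman ρ; monotone marginal transforms preserve ranks;
symptom scores are binned to integers 0–10, producing realistic ties.
Unlinked covariates follow marginals centred on the published cohort
summaries. Sample Spearman at n = 10 is attenuated (≈ 0.85 for ρ = 0.9) —
tests budget for this.

What the generator does **not** emulate: peptide/PSM-level noise, reporter
ion interference and ratio compression, intensity-dependent (MNAR)
missingness, and correlated protein modules beyond the shared subject
effect. Passing tests therefore validate the statistical machinery under
the stated design, not the instrument physics.

## Problem sizes and numerical choices

Simulation-backed tests run at 500 proteins, B = 2000 bootstrap replicates
and 20 seeds for type-I/recovery checks, B = 100,000 for the enumeration
comparison, 200 simulations for CI coverage, and nperm = 500 over 200
random sets for the GSEA null — sizes at which the Monte-Carlo error is
well below each assertion's margin. Determinism contracts are bitwise:
fixed config + seed reproduce matrices, masks, clinical values and pipeline
output files byte-for-byte (the run manifest's wall-times are the only
exception, and are excluded from the comparison).

## Known limitations

* The FCR selection rule ("nominal CI excludes 0") is the standard
  construction but not the only reading of a "BY-adjusted CI"; see above.
* Permutation GSEA p-values are floor-limited at 1/(nperm+1); very deep
  tails need larger nperm.
* The forest imputer inherits scikit-learn's iterative-imputer stopping
  rule (tolerance or max_iter) rather than the exact missForest
  out-of-bag criterion; observed values are unaffected either way.
* No moderated-variance (limma-style) alternative for the within-group
  tests; with n = 10/12 subjects the plain t-test is the specified method.
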