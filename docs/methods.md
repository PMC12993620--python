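# Methods

This note documents the models and procedures implemented in `rivertide`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmarks do and do not demonstrate.

## Detection and compartment model

Input is a genome × sample coverage summary (read count, breadth of coverage,
mean depth) produced upstream by a read mapper at ≥ 95% identity. Presence
requires breadth ≥ 0.75 **and** mean depth ≥ 3.0, both inclusive; depth is
mean depth over the whole genome length, the common mapper-summary convention
and the conservative reading of a 3× floor. Occupancy above 10% of a
compartment's samples (strict `>`) assigns the genome to that compartment;
genomes above the threshold in both compartments are `both` and appear in both
per-compartment matrices; genomes below it everywhere are removed. The strict
reading of the occupancy threshold against the inclusive reading of the
mapping thresholds follows the wording conventions of the protocols they come
from ("at least" vs ">").

## TMM normalization

Between-sample scaling uses the trimmed mean of M-values. The reference sample
is the one whose 75th-percentile count/library-size statistic is closest to
the mean of that statistic across samples. For sample *k* against reference
*r*, over genomes with nonzero counts in both: M-values
`M_g = log2((y_gk/N_k)/(y_gr/N_r))` and intensities
`A_g = ½ log2((y_gk/N_k)(y_gr/N_r))` are doubly trimmed (drop the top and
bottom 30% quantiles of M and 5% of A); the factor is the precision-weighted
mean `f_k = 2^(Σ w_g M_g / Σ w_g)` with the binomial delta-method weights
`w_g = (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr)`. Factors are rescaled
to geometric mean 1 and abundances reported as counts per million,
`y_gk/(N_k f_k) × 10⁶`. A sample sharing no nonzero genome with the reference
(possible when compartments are nearly disjoint and the community is small)
gets factor 1 with a warning. TMM assumes most genomes are not changing
between samples; the module-detection benchmark deliberately stresses this
assumption (60% of genomes latent-driven) and the trimming is what keeps the
factors anchored to the unmodulated majority by count.

## Persistence and stability

Persistence classes partition detection fractions at ≥ 0.75 (persistent) and
≤ 0.25 (ephemeral), boundaries inclusive. Stability is scored only for
persistent genomes on TMM abundances: the genome's median is taken over *all*
samples of the compartment, zeros included (a persistent genome can have
up to 25% missing samples), and a sample fluctuates when its abundance leaves
the ±25% band around that median — strictly, so the band boundary itself is
non-fluctuating. Class cut-offs mirror persistence: stable ≤ 0.25 of samples
fluctuating, unstable ≥ 0.75. Since persistence requires detection in more
than half the samples, the median is always positive (asserted).

Consecutive Bray–Curtis dissimilarities (each sample against its prior
timepoint, `BC = Σ|x−y| / Σ(x+y)`) are compared between compartments with the
Welch unequal-variance t test; the equal-variance variant can be recovered
from the reported statistic and degrees of freedom if needed. Stability
class-count tables are tested with Fisher's exact test: 2×2 via the standard
hypergeometric two-sided rule, 2×3 by complete enumeration of the conditional
distribution (feasible up to a grand total of 500; beyond that a seeded
Monte Carlo estimate with 10⁵ draws is used, and the two agree within
Monte-Carlo error on enumerable tables).

## Virus–host linkage

Three independent evidence channels are combined:

* **d2\*** — k = 6 words counted on both strands of each genome; each genome's
  expected word counts come from an order-2 Markov model fitted to its own
  3-mer frequencies; `d2* = ½(1 − D2*/√(Σ X̃²/E_a · Σ Ỹ²/E_b))` over words
  with positive expected probability in both genomes. 0 means identical
  composition, 1 maximally dissimilar. Word length and Markov order are
  parameters, not constants; sequences shorter than 10·4^k trigger a warning
  because word-count estimates get noisy.
* **Shared k-mers** — distinct canonical 25-mers (lexicographic min of word
  and reverse complement, N-containing words dropped); significance is the
  upper-tail hypergeometric probability of the observed overlap when drawing
  the virus's k-mer set from a universe equal to the union of all host-panel
  k-mer sets. That universe definition makes the test panel-relative: with
  very few hosts the expected overlap is large and the test loses power,
  which is the correct behaviour for an exact-match screen. P-values are
  Benjamini–Hochberg adjusted across all virus × host pairs.
* **CRISPR arrays** — a seed-and-extend direct-repeat finder: a 21-bp seed
  occurring ≥ 3 times with successive gaps inside the spacer range (20–60 bp)
  is extended while all copies agree; arrays are kept when the final repeat
  length is 21–48 bp. Spacers hit a virus when they (or their reverse
  complement) occur with ≤ 1 mismatch. The finder is a deliberately simple
  reimplementation validated against planted arrays and an empirical
  false-positive bound on Markov-random sequence, not a port of any specific
  tool.

A pair is accepted with evidence `crispr` on any spacer hit, or with evidence
`consensus` when the host is the virus's best (minimum, ties by host id) d2\*
hit with d2\* < 0.2 and adjusted shared-k-mer p < 0.05. Best-hit status is
applied to the composition channel only.

## Ordination and multivariate tests

NMDS minimizes Kruskal stress-1 by majorization: configuration distances are
isotonically regressed (weak ties averaged) on the observed dissimilarity
order, then a Guttman transform updates the configuration; the first start is
classical metric scaling and the remaining 19 are random; the lowest-stress
solution is returned centred and principal-axis rotated. PERMANOVA computes
`SS_total = Σ_{i<j} d²_ij / n` and within-group sums analogously per group;
the p-value permutes labels (999 by default) or enumerates all distinct
assignments exactly at small n. The sequential two-factor variant reports the
compartment R² first and the additional R² of time after it (Type-I order),
using hat-matrix projection of the Gower-centred matrix. Procrustes centres
and unit-scales both configurations, takes the optimal rotation from the SVD
of the cross-product, and reports `m² = 1 − (Σσ)²` with
`correlation = √(1−m²)`; the permutation test permutes the row order of one
configuration. Species accumulation reports both the permutation mean and the
exact rarefaction expectation `E[S_k] = Σ_g [1 − C(n−n_g,k)/C(n,k)]`. Shannon
diversity uses the natural log, the ecology default.

## Co-occurrence networks

Correlations are computed per compartment on log₁₀ TMM abundance over
**jointly detected** samples only (pairwise-complete): zeros in these data are
non-detections, not measured zeros, and treating them as values destroys
genuine member correlations while manufacturing spurious ones. Pairs with
fewer than 10 joint detections get correlation 0 — below that, sample
correlations at 15–17 timepoints are dominated by chance. (A `raw` transform
and Spearman option exist for sensitivity analysis.) The signed-hybrid
adjacency zeroes negative correlations and raises positives to the power β
(14 for SW, 8 for PW); the topological overlap is
`t_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.

Module detection clusters 1−TOM by average linkage and traverses the
dendrogram from the root: merges at height ≥ 0.995 are always split (genuine
modules coalesce well below, noise merges pile up near 1); below the cut a
node is still split when its two subtrees' eigengenes are dissimilar by at
least the merge cut height (0.3) — the same criterion the subsequent merge
step uses, so a split is never undone — and a heterogeneous side too small to
be a module (< 20) is pruned to unassigned rather than absorbed. This static
rule replaces the dynamic tree-cut algorithm of the reference implementation;
it is validated against planted module truth, not against that tool. Module
eigengenes are first principal components of the standardized member
profiles, unit variance, sign-oriented to correlate positively with members;
modules with eigengene dissimilarity < 0.3 are merged iteratively. Labels are
deterministic under input order (canonical id sorting; naming by size then
smallest member id). Genome significance is |cor(genome, trait)| and module
membership cor(genome, own eigengene). The scale-free fit R² is reported
diagnostically; β is never auto-selected.

## Sparse PLS and VIP

One chemistry variable is regressed on one module's genome abundances
(standardized). Per component, the weight vector keeps the `keep_x`
largest-magnitude entries of `X'y` on the deflated residuals (default half
the module size, floor 5), unit norm; scores deflate X and y. The fit reports
in-sample R² over all components (2 by default) and a permutation p-value
from refitting on y permuted across samples — distribution-free and matched
to the statistic, since no parametric null for sparse in-sample R² is
available. `VIP_j = √(p · Σ_h SS_h (w_jh/‖w_h‖)² / Σ_h SS_h)`, so
Σ VIP² = p exactly. In-sample R² with few samples and many predictors is
optimistic; the permutation null carries the same optimism, which is what
makes the test calibrated (verified type-I 0.03–0.07 at α = 0.05).

## AMG scoring

A candidate is any gene with a metabolic function id. Flanks are everything
to each side on the contig (no distance bound; a distance-bounded variant is
a parameter). Score 1 = viral hallmark on both flanks; 2 = hallmark on one
and viral-like on the other; 3 = viral-like on both; the best (lowest)
applicable score wins. Contig-end or transposon-like candidates never pass
filtering but keep their score for reporting. Enrichment per group and
compartment reports both hypergeometric tails (the enrichment direction is
ambiguous a priori), plus an overall 2×2 Fisher test of AMG vs non-AMG genes
by compartment.

## The synthetic-data generator

The generator emulates a 48-hour, 3-hourly, two-compartment river time
series: 17 pore-water samples and 15 surface-water samples (two fixed SW
timepoints absent — failed libraries are routine in field campaigns and the
analysis must tolerate unequal compartment coverage). Default per-compartment
persistence-class fractions are SW 0.70/0.25/0.05 and PW 0.11/0.26/0.63 for
persistent/intermittent/ephemeral — a strongly persistent surface community
against a largely ephemeral hyporheic one — with class occupancy probabilities
0.90/0.50/0.12 chosen so expected detection fractions fall inside the class
intervals with margin at 15–17 timepoints.

Choices the generator makes where no external value exists, with rationale:

* **Abundance model** — log-normal with log₁₀-mean ~ U(1,3) and σ = 0.15;
  the log-normal form is a modelling choice (field-typical rank-abundance
  skew), not inferred from any dataset.
* **Cross-compartment zeros are real zeros** — a surface genome never occurs
  in pore water; this matches the interpretation that between-compartment
  zeros are biological.
* **Modules** — each module has an AR(1) latent (coefficient 0.7, innovation
  sd 1) over the timepoint grid; latents are orthogonalized across modules
  because independent AR(1) draws at 17 points frequently correlate strongly
  by chance, which would make planted modules unidentifiable in principle.
  Members add `b_g·z_m(t)` to log₁₀ abundance with `b_g ~ U(0.5, 0.8)` —
  strong enough that member correlations survive count noise and the
  compositional pathway, weak enough that TMM's trimmed majority stays
  anchored. Modules are planted among persistent genomes of one compartment
  (alternating, subject to pool availability).
* **Chemistry** — variable j is `Σ_m c_jm z_m(t) + N(0, 0.25)` with identity
  loadings for the first `n_modules` variables plus two pure-noise variables;
  variables carry field-realistic names (nitrate, sulfate, …).
* **Counts and coverage** — reads ~ Poisson(relative abundance × library
  size); relative abundance includes a stable unmodeled background mass
  (3× the mean foreground total) standing for the unbinned community fraction
  that real reads also map against, which damps compositional swings of the
  total. Library sizes are log-uniform over one decade centred near 10⁸ reads
  (the per-sample scale of deeply sequenced river metagenomes); mean depth is
  `count × 150 / genome_length` with nominal lengths 25 kb (viral) and 50 kb
  (microbial contig scale), and breadth follows the Lander–Waterman-style
  stand-in `1 − exp(−depth)`.
* **Genome sequences** — hosts are 100 kb order-2 Markov chains (Dirichlet(1)
  transition rows); a linked virus is 25 kb from its host's chain, carries a
  1 kb window copied verbatim from the host (≥ 976 shared 25-mers guaranteed)
  and the host carries a planted CRISPR array (4 × 28 bp repeat, three 32 bp
  spacers, the middle spacer copied from the virus). Unlinked viruses come
  from independent chains.
* **Seeding** — one integer seed drives named substreams (CRC-keyed), so
  adding genomes does not perturb chemistry draws and regression tests stay
  stable.

**What passing the synthetic benchmarks shows** — that every stage implements
its stated rule exactly (oracle agreement), that the permutation machinery is
calibrated, and that the pipeline recovers truth planted under the generative
assumptions above. **What it does not show** — robustness to real-data
features the generator omits: assembly chimerism and strain mixtures, mapping
bias and shared reads between related genomes, non-stationary or bursty
dynamics beyond AR(1), chemistry measurement structure beyond iid noise, and
genome-length heterogeneity. Real occupancy is also not Bernoulli-independent
across time; autocorrelated presence would make persistence classes easier to
recover than this benchmark implies.

## Problem sizes and numerical choices

The default synthetic dataset is 500 genomes × 32 samples; module recovery is
benchmarked on 3 planted modules of 30 plus 60 noise genomes; host linkage on
10 hosts with 10 linked and 10 unlinked 25 kb viruses; sparse-PLS sparse-signal
recovery on 64 samples × 100 predictors with 10 true. Permutation tests use
999 permutations in the pipeline and 99–199 in the calibration benchmarks
(500 null replicates each), which leaves the validity of the p-values
untouched. NMDS stops when stress improves by less than 1e-7 or at 500
iterations, with 20 restarts; Procrustes and PERMANOVA p-value floors are
1/(n_perm+1). Ties in best-hit selection and module naming break
lexicographically for determinism. Degenerate inputs (all-zero samples,
constant traits, empty margins) raise validation errors naming the offender
rather than propagating NaNs.

## Known limitations

* The shared-k-mer significance model (hypergeometric over the host-panel
  k-mer universe) is a stated approximation; exact-match tools define their
  own null. Acceptance of the consensus rule is defined against planted
  truth, not against any external tool's output.
* The CRISPR finder requires exact repeat copies; diverged repeats or arrays
  at contig boundaries are missed.
* The static tree cut with eigengene splitting approximates dynamic tree
  cutting; very small or strongly overlapping modules below the size floor
  are left unassigned.
* Sparse-PLS R² is in-sample and reported as such; no cross-validation is
  performed.
* PERMANOVA's sequential time term treats time as a linear predictor; cyclic
  diel structure is not modelled.
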