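# rivertide

Temporal analysis of viral and microbial communities in river compartments.

Rivers exchange water between the flowing channel (surface water, SW) and the
sediment pore water (PW) of the hyporheic zone. Genome-resolved metagenomic
time series from both compartments — viral genomes (vMAGs) and bacterial or
archaeal genomes (MAGs) sampled every few hours — make it possible to ask how
persistent each genome is over a diel cycle, how stable its abundance is, which
viruses infect which hosts, and how groups of co-occurring organisms track
water chemistry. `rivertide` implements that analysis chain as a tested,
reusable library with a synthetic-data generator that plants known truth for
every stage, so the whole pipeline can be exercised and validated without any
external downloads.

## What it computes

* **Presence and compartment calling** — a genome is present in a sample when
  read-mapping breadth ≥ 75% of its length and mean depth ≥ 3×; occupancy
  above 10% of a compartment's samples (strict) assigns it to that
  compartment (`pore`, `surface`, `both`, or `removed`).
* **TMM normalization** — trimmed mean of M-values between-sample scaling
  factors (two-sided trims of 0.30 on M and 0.05 on A, precision-weighted,
  factors rescaled to geometric mean 1), reported as counts per million:
  `x_gk = y_gk / (N_k f_k) × 10⁶`.
* **Persistence and stability** — persistent (detected in ≥ 75% of samples),
  intermittent (25–75%), ephemeral (≤ 25%); persistent genomes are *stable*
  when their TMM abundance leaves the ±25%-of-median band in ≤ 25% of samples
  and *unstable* at ≥ 75%. Consecutive Bray–Curtis dissimilarities per
  compartment are compared by a Welch unpaired t test; class-count tables by
  Fisher's exact test (2×2 closed form; 2×3 exact enumeration).
* **Virus–host linkage** — three alignment-free evidence channels:
  d2\* oligonucleotide dissimilarity (k = 6 words, order-2 Markov centring,
  both strands), shared canonical 25-mers with a hypergeometric tail p-value
  (Benjamini–Hochberg adjusted across all pairs), and CRISPR direct-repeat
  arrays with spacer-to-virus matching (≤ 1 mismatch, either strand). A pair
  is accepted on a spacer hit, or when the host is the virus's best d2\* hit
  with d2\* < 0.2 **and** adjusted shared-k-mer p < 0.05.
* **Ecology toolbox** — Shannon H′, Bray–Curtis matrices (genomes present in
  > 3 samples), non-metric multidimensional scaling (Kruskal stress-1,
  isotonic regression, majorized updates, multiple restarts), PERMANOVA
  (pseudo-F, R², permutation or exhaustive p), envfit vector fitting,
  Procrustes superimposition (m², correlation = √(1 − m²)), species
  accumulation with the exact rarefaction expectation, ANOSIM.
* **Co-occurrence modules** — signed-hybrid weighted network
  (`a_ij = r_ij^β` for positive correlations, β = 14 SW / 8 PW), topological
  overlap, average-linkage tree with a static cut plus eigengene-based
  subtree splitting, minimum module size 20, eigengene merging at
  dissimilarity 0.3.
* **Module–chemistry coupling** — sparse PLS of one chemistry variable on a
  module's genome abundances with permutation p-values and variable
  importance in projection (VIP) scores; a module is significantly related
  when R² > 0.3 and p < 0.05, and VIP > 1 flags influential genomes.
* **AMG scoring** — auxiliary metabolic gene scores 1–3 from viral hallmark /
  viral-like context on both flanks, with contig-end and transposon filters,
  plus per-compartment hypergeometric enrichment.

## Worked example

Simulate the default study design (350 vMAGs + 150 MAGs across 15 SW and 17 PW
samples at 3-hour spacing over 48 h) and run every stage:

```bash
rivertide run --seed 1 --out results/demo
```

which prints (abbreviated):

```
persistence_recovery: 0.9417
sw_persistent_fraction: 0.6582
pw_persistent_fraction: 0.1463
permanova_r2: 0.4719
permanova_p: 0.001
procrustes_corr: 0.8779
module_ari_sw: 0.9436
n_significant_module_chem: 3
hostlink_precision: 1
hostlink_recall: 1
amg_score_accuracy: 1
```

Reading this: 94% of genomes recover their planted persistence class from the
coverage thresholds alone; the surface-water community is far more persistent
than the pore water (66% vs 15% of genomes), mirroring the strong
compartment contrast the design plants; compartment identity explains 47% of
community variance (PERMANOVA, p = 0.001); viral and microbial ordinations are
congruent (Procrustes correlation 0.88); the three planted co-occurrence
modules are recovered (adjusted Rand index 0.94 in SW) and three
module–chemistry couplings are significant by sparse PLS; all ten planted
virus–host pairs are recovered with no false positives; and every planted
auxiliary-score configuration is scored exactly.

The same stages are available individually (`rivertide simulate`, `detect`,
`normalize`, `temporal`, `hostlink`, `amg`) and as library functions
(`rivertide.abundance`, `rivertide.temporal`, `rivertide.hostlink`,
`rivertide.ecology`, `rivertide.network`, `rivertide.spls`, `rivertide.amg`).

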