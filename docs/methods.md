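# Methods

## Model and procedure

The pipeline targets a two-genotype (WT, KO), two-condition (sham, DMM),
two-timepoint (weeks 2, 4) bulk RNA-seq design in which each design cell
is a single pooled sample.  Pooling removes replicate-level variance, so
no dispersion is estimated anywhere; all inference is combinatorial
(hypergeometric) over deterministic per-gene rules.

Stages, in order:

1. **Expression filter.** Keep genes with TPM strictly greater than
   `tpm_min` (default 1) in at least one sample.  This set is *the
   universe* for the DIF quartile, the overlap test and the enrichment
   background — changing the filter changes every downstream statistic.
2. **Contrasts.** Per genotype and week,
   `L = log2((E_DMM + ε)/(E_sham + ε))` with cell values the pooled
   sample's TPM (or the cell mean when a matrix carries replicates).
3. **DIF score.** `DIF = L_KO − L_WT`.  Negative DIF means the DMM
   response seen in WT is suppressed in the knockout.  The score is
   exactly antisymmetric under swapping the genotype labels.
4. **Threshold.** `DIF₂₅%` is the lower quartile of DIF over the whole
   universe, computed per week by default.
5. **Selection.** At each week keep genes with `L_KO < 0`, `L_WT > 0`
   and `DIF < DIF₂₅%`; *common* genes pass at both weeks.  All
   inequalities are strict, so boundary genes (including any tied with
   the quartile value) are excluded, and each week's selection can never
   exceed ⌈N/4⌉ genes.
6. **Overlap significance.** Upper-tail hypergeometric probability
   `P(X ≥ k)` of the observed intersection `k`, with the two per-week
   selection sizes as marginals and the filtered universe as the
   population.
7. **Scaling.** For heat-map-style reporting, each selected gene's TPM
   row is z-scored across the 8 samples (sample sd, ddof = 1); constant
   rows are emitted as zeros with a warning rather than an error.
8. **Enrichment.** The common genes and the universe are translated
   mouse → human through an ortholog map (union semantics for
   many-to-many pairs; unmapped genes are dropped and counted in the
   log).  Each gene set in a GMT collection is tested by the same
   upper-tail hypergeometric statistic against the translated universe;
   p-values are Benjamini–Hochberg step-up adjusted across the
   collection and each set scores `−log10(q)`, with q floored at the
   smallest positive normal double so scores stay finite.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `tpm_min` | 1 | TPM | conventional expressed/not-expressed cut for TPM matrices |
| `pseudocount` (ε) | 1 | TPM | keeps ratios finite at zero counts and shrinks low-expression fold changes; 0 is allowed when all used cells are positive |
| `quantile_rule` | `linear` | — | linear interpolation between order statistics (numpy's default, the common "type 7" convention); `lower`, `higher`, `midpoint`, `nearest` available |
| `quartile_scope` | `per_week` | — | each week's threshold from that week's DIF distribution; `pooled` shares one threshold, exposed because the published description does not fix this |
| `week_policy` | `per_week` | — | node-attribute export: per-week DIF columns or their mean |

## Synthetic data

`simulate_study` builds log2 TPM as
`baseline + effect·[condition = DMM] + N(0, noise_sd)` per sample and
exponentiates.  Gene classes:

* **attenuated** (default 5%): WT effect `+|N(2, 0.5)|`, KO effect
  `−|N(1, 0.5)|`, identical at both weeks — the signal the rule selects;
* **shared_de** (10%): one effect per week, same in both genotypes,
  random sign, drawn independently across weeks — responders the rule
  must reject;
* **null** (remainder): no condition effect;
* **unexpressed** (10%): baseline near 2⁻⁶ TPM, removed by the filter.

Defaults: 2000 genes, `noise_sd = 0.25` on log2 TPM, baselines
`N(4, 2)` truncated below at 0.5 so that with noise off the filter
removes exactly the unexpressed class.  Noise is multiplicative on TPM,
matching the ratio-based statistic.  Column sums are not re-normalised
after simulation: the contrasts are per-gene ratios and are invariant to
a per-gene scale.

What the simulation does **not** emulate: count-level (Poisson/NB)
sampling noise, library-size and gene-length coupling between genes,
correlated co-expression modules, and real ortholog ambiguity (the
fixture map is one-to-one).  Green tests therefore demonstrate that the
implementation applies the stated rules exactly and recovers planted
structure under log-normal noise; they do not validate the biological
sensitivity of the rule on real cartilage data.

## Numerical choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, …)`;
  tests check them against an exact rational enumeration oracle on all
  margins with N ≤ 25 to 10 significant digits.
* BH-FDR is the plain step-up `q(i) = min_{j≥i} p(j)·m/j` clipped at 1,
  order-preserving; tests compare against statsmodels on 1,000 random
  vectors.
* Duplicate gene symbols at load collapse to the row with the largest
  total TPM, ties broken by the lexicographically largest row vector, so
  the result is independent of input row order.  Gene order is
  canonicalised by sorting after load.
* Enrichment rows sort by score descending with ties broken by set name,
  making the ranking independent of collection order.
* Zero-TPM cells with ε = 0 are a hard error naming the gene and cell;
  the deposited-data reproduction sweep instead drops genes with any
  zero in a used cell when ε = 0.

## Design choices that were genuinely open

* **Threshold scope.** The published rule defines the lower quartile
  over "DIF values for a total of 12,597 genes" and applies the rule at
  both weeks; whether the quartile is per week or pooled across weeks is
  not stated.  Per-week is the default (each week's distribution sets
  its own bar); pooled is a config switch.
* **Pseudocount.** Unstated in the published description.  ε = 1 TPM is
  the default; the reproduction sweep covers ε ∈ {0 with zero-genes
  dropped, 0.01, 1} × {linear, lower} quartile conventions and reports
  which configuration matches the printed counts.
* **Enrichment background.** Taken as the filtered universe translated
  to human symbols (configurable in principle to all collection genes);
  the overlap test's population is likewise the filtered universe, the
  only population the filtering step defines.
* **Ortholog direction.** Queries are translated mouse → human because
  hallmark collections are human-annotated; operating on translated
  universes makes the direction immaterial to the margins.
* **FDR estimator.** "False discovery rate estimation" admits several
  estimators; Benjamini–Hochberg step-up is used, and the function seam
  (`bh_fdr`) keeps alternatives pluggable.

## Problem sizes

The default test suite and the acceptance script run entirely on
simulated studies of 200–2000 genes × 8 samples, with oracle sweeps of
500–1000 randomized instances; the full suite completes in a few seconds
on one CPU.  These sizes were chosen so the combinatorial oracles
(exhaustive hypergeometric enumeration, per-gene brute-force rule
checks) remain exact and fast while the 2000-gene default matches the
order of magnitude of a filtered transcriptome quartile computation.

## Known limitations

* With a single pooled sample per cell, the selection rule has no
  within-cell error model; its false-positive behaviour depends entirely
  on the quartile threshold and the two-timepoint consistency
  requirement.
* Reproducing the deposited study's exact printed counts (12,597 / 1270)
  requires the GEO GSE147529 processed table, which must be downloaded
  by the user; the reproduction sweep is implemented but cannot run
  without it.
* The enrichment stage assumes symbol-keyed inputs; identifier-keyed
  matrices need the optional ID-to-symbol map at load time.
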