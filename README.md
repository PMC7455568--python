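# difsel

Selection of genotype-dependent treatment-response genes from pooled bulk
RNA-seq designs, built around the **DIF attenuation statistic**, with
hypergeometric overlap testing and hallmark-style gene-set enrichment.

## The problem

In a surgical osteoarthritis model (destabilization of the medial
meniscus, DMM), articular cartilage from wild-type (WT) and *Oscar*
knockout (KO) mice was profiled at 2 and 4 weeks after sham or DMM
surgery — one pooled sample per (genotype × surgery × week) cell, 8
samples, no replicates.  The question: which genes respond to surgery in
WT but have that response *attenuated* by the knockout, consistently at
both timepoints?

With no replicates there is no dispersion to estimate, so the analysis is
a deterministic rule over per-genotype contrasts.  For each gene, with
`E_x` the TPM under condition x and ε a pseudocount,

```
L_g   = log2((E_DMM + ε) / (E_sham + ε))        for genotype g ∈ {WT, KO}
DIF   = L_KO − L_WT
DIF₂₅% = lower quartile of DIF over the filtered gene universe (per week)
```

A gene is selected at a week when (strict inequalities throughout)

1. `L_KO < 0` — the knockout's response is downward,
2. `L_WT > 0` — the wild type responds upward,
3. `DIF < DIF₂₅%` — the attenuation is in the strongest quartile,

and a **common gene** satisfies all three at *both* weeks.  The universe
is all genes with TPM > 1 in at least one sample.  The significance of
the two-week overlap, and of each gene set's overlap with the common
genes (after mouse→human ortholog translation), is an upper-tail
hypergeometric probability; gene-set p-values are Benjamini–Hochberg
adjusted and reported as an enrichment score `−log10(FDR)`.

A synthetic-data module generates study-shaped matrices with planted
attenuated / shared-response / null / unexpressed gene classes so that
every stage is testable without downloading anything.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_select_attenuated_genes.py
python analysis/03_hallmark_enrichment.py
```

prints (abridged):

```
simulated 2000 genes x 8 samples -> results/synthetic_study
planted classes: {'null': 1500, 'shared_de': 200, 'unexpressed': 200, 'attenuated': 100}
universe 1800; week 2: 334, week 4: 334, common: 125 (overlap p = 3.64e-20)
planted-class recovery: recall 0.880, precision 0.704
                        set  k  K            p            q     score
PLANTED_ATTENUATED_RESPONSE 32 49 3.871906e-27 3.871906e-26 25.412075
              RANDOM_SET_01  8 42 6.846158e-03 3.423079e-02  1.465583
```

Reading the numbers: the TPM filter keeps 1800 of 2000 genes (the 200
planted unexpressed genes drop out); each week's quartile rule selects
334 genes; 125 pass at both weeks — far more than the ~62 expected by
chance, hence the vanishing overlap p.  Of the 125, 88 are truly planted
attenuated genes (recall 0.88, precision 0.70), and the gene set salted
with attenuated members dominates the enrichment ranking.

The same pipeline runs from the shell on any matrix + sample sheet:

```bash
difsel simulate --out study/
difsel run --matrix study/matrix.tsv --samples study/samples.tsv \
           --gmt study/sets.gmt --orthologs study/orthologs.tsv --out out/
```

Exit codes: 0 success, 2 input/format error, 3 computation error.  Every
run writes a `manifest.json` (config echo, input SHA-256 digests, stage
summary numbers) that fully determines a re-run.

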