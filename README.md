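# rtturnover

Statistics for cis-regulatory element turnover across DNA replication
timing.

Enhancers are fast-evolving: most are lineage-specific, and their gain and
loss ("turnover") is not uniform across the genome. Because de novo mutation
rates are elevated at late-replicating domains, the DNA replication-timing
(RT) program is a natural organizing axis for where new enhancers emerge —
across mammalian evolution and, on a much shorter clock, between healthy and
tumor cell states. `rtturnover` implements the quantitative machinery to
test that relationship, for computational biologists working with Repli-seq
tracks, multi-species histone-mark peak sets, population variant tables,
JASPAR motifs and expression matrices.

## What it computes

* **Replication domains** — z-scored RT tracks averaged onto 200 kb bins;
  cluster number chosen by Gaussian-mixture BIC, assignment by k-means;
  constitutive classification (early: RT > 0.5 in every cell type; late:
  RT < −0.5; else dynamic).
* **Enhancer age and turnover** — conserved vs recent from an
  element × species mark matrix (≥2 other species), per-group turnover
  log(n_recent / n_conserved), its regression on mean RT, the summary ratio

      P(recent | late RT) / P(recent | early RT),

  tissue-difference interaction tests, Fisher-exact interval enrichment
  (TEs, eQTLs, accessibility), homology-graph singleton fractions and
  lineage divergence expectations (e.g. ~15 substitutions/kb since the
  human-macaque split at 29 Myr, 25 yr generations, μ = 1.28e-8).
* **Selection scan** — derived-allele-frequency profile in 10 bp windows
  around motif centers, rare (DAF < 1.5 %) vs common (> 5 %) odds ratios
  normalized by 2–4 kb flanks, exact Fisher p values and confidence
  intervals, bootstrap bands over motif centers.
* **Motif composition** — PWM consensus (> 0.5 rule) and GC content,
  two-strand log-odds scanning, early/late motif enrichment
  log2((present_early/absent_early)/(present_late/absent_late)),
  substitution spectra with CpG masking, tissue-specificity
  τ = Σ(1 − x_i)/(N − 1), and a 2-component Gaussian mixture (EM) on
  binding-site RT.
* **Cancer turnover** — gained/lost/unchanged classification between
  healthy and tumor peak sets, width-normalized somatic mutation burden,
  gain/loss proportions across RT quintiles.
* **Synthetic genomes** — a generator producing RT landscapes, age-labeled
  enhancers, sequences, variants, TE insertions, cancer peak sets and
  expression matrices with ground truth, so the whole pipeline is testable
  without any external downloads.

## Worked example

Everything is available as a library (`import rtturnover`) and through the
`rtt` command. A complete synthetic run:

```bash
echo "genome_size=10000000" > sim.cfg
rtt simulate --seed 11 --config sim.cfg --outdir sim
rtt domains --tracks sim/rt_celltype_*.bedgraph --kmax 8 --out domains.tsv
rtt turnover --elements sim/enhancers.bed --marks sim/marks.tsv \
    --track sim/rt_germline_mean.bedgraph --out turnover.tsv
rtt cancer --healthy sim/cancer_healthy.bed --tumor sim/cancer_tumor.bed \
    --somatic sim/somatic.tsv --track sim/rt_germline_mean.bedgraph --out fates.tsv
```

prints

```
wrote synthetic dataset to sim
clustered 50 bins into 5 clusters -> domains.tsv
turnover slope vs RT = -0.4629 (R^2 = 0.925, p = 0.00892); P(recent|late)/P(recent|early) = 1.830
fates: gained=135, lost=133, unchanged=689 -> fates.tsv
```

Reading the numbers: the 50 × 200 kb bins of the 10 Mb synthetic genome fall
into 5 RT clusters. The turnover log-ratio *decreases* with RT (slope −0.46,
R² = 0.93) — since higher RT means earlier replication, recent enhancers
concentrate at late-replicating domains — and a recent enhancer is 1.83×
more probable among late- than early-replicating elements, consistent with
the generator's lateness-driven birth model. In the matched cancer peak
sets, 135 enhancers were gained and 133 lost relative to 689 unchanged.

The first lines of `turnover.tsv` (quintile 1 = latest):

```
group  n_recent  n_conserved  log_ratio  mean_rt
1      110       89            0.2118    -0.8657
2      88        111          -0.2322    -0.0307
```

`rtt daf` writes the motif-centered DAF odds-ratio profile with bootstrap
bands, and `rtt motifs` the per-motif consensus, GC and early/late
enrichment table. See `docs/methods.md` for the models, defaults and
numerical conventions behind each statistic.

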