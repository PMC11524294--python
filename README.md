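# nucredit

Nuclear RNA-editing analysis for transcriptome-aligned RNA-seq: call editing
sites from per-position pileups with an exact-test error model, characterize
them (substitution type, region, codon position, synonymy, editing degree and
density), test functional enrichment, group PPR genes with their C-to-U edited
targets by shared-coexpression-matrix decomposition, and discover the
flanking-base motif around edited C residues by positional chi-square.

The package is aimed at plant transcriptomics work where editing is called in
*transcript space* (reads aligned to primary transcripts of a sequenced
genotype, so DNA–RNA differences are not confounded by strain polymorphisms).
Every input it consumes can also be produced by its built-in synthetic-data
generator with planted ground truth, so the whole pipeline is testable without
any sequencing data.

## The statistics at the core

**Site calling.** At a candidate position with coverage *n* and *k* reads
carrying one specific non-reference base, sequencing error alone produces that
base at rate ε/3 (ε = per-base error probability, derived from the column's
mean Phred quality as 10^(−q/10), split uniformly over the three alternative
bases). A one-sided Fisher's exact test compares the observed split
(*k*, *n*−*k*) against the expected-under-error split
(round(*n*·ε/3), rest); Benjamini–Hochberg adjusted p-values are thresholded
strictly below α = 0.05. Only columns with ≥ 50 high-quality reads are tested.
The **editing degree** of a called site is *k*/*n* — the fraction of reads
carrying the edited base.

**Characterization.** Sites are placed in 5'UTR/CDS/3'UTR, CDS sites get codon
position, ref/alt codons and synonymy under the standard genetic code;
**editing density** is sites per kilobase of each region class; per-amino-acid
rates divide event counts by codon-table degeneracy; transcripts are grouped
by the combination of edited regions (A = 5'UTR, B = CDS, C = 3'UTR, so "AC"
means edited in both UTRs).

**Enrichment.** GO terms are tested by the upper-tail hypergeometric
P(X ≥ k | N, K, n); editing enrichment among endosymbiont-derived genes by a
one-sided Fisher's exact test on the edited × endosymbiont 2×2 table.

**Coexpression clustering.** Edited genes' expression is multiplied by their
mean editing degree (approximating the abundance of *edited* transcripts,
which is what a PPR protein binds), a Spearman network is built
(edge iff ρ ≥ 0.7, p ≤ 0.05), and its Shared Coexpression Matrix —
scm(i,j) = number of genes coexpressed with both i and j — is greedily
decomposed: the pair with the largest entry seeds a cluster, a third gene with
hypergeometrically significant shared-neighbour overlap joins, then any gene
significant with ≥ 3 members joins to a fixpoint; members are removed and the
process repeats. Also available as a scikit-learn style estimator
(`SCMCluster().fit(expr)` with `labels_`).

**Motif scan.** For each cluster's C-to-U sites the ±5 flanks are tallied into
a 4 × 11 composition matrix, compared position-wise (chi-square
goodness-of-fit, df 3) against a background built from *all* C residues in the
supplied transcripts; significant purine-dominated positions at −1/+1 yield
the core motif R-C-R (R = A/G).

## Worked example

```bash
nucredit run --seed 7 --outdir demo
```

simulates 80 transcripts with 400 planted editing events (degrees 0.20–0.65,
coverage ~100×, error rate 10⁻³, purine bias 0.8 at the −1/+1 flanks of C-to-U
sites), then calls, annotates, clusters and scans. With seed 7 it calls **399
sites** (of 400 planted; region split 83 / 215 / 101 across 5'UTR / CDS /
3'UTR), recovers **3 coexpression clusters**, and the pooled motif report
(`demo/motif_report.tsv`) shows exactly the planted signal:

```
position  A  C  G  T      chi2            p label
      -2 17 17  8 22  5.875352 1.178346e-01     N
      -1 22  3 37  2 54.200598 1.016796e-11     R
       1 29  3 30  2 44.882323 9.801149e-10     R
       2 13 18 19 14  1.605098 6.582345e-01     N
```

i.e. the −1 and +1 columns are overwhelmingly purine (A+G) and deviate from
the transcriptome background at p < 10⁻⁹, while the other flanking positions
do not — the core motif is reported as **RCR**. The same analyses are exposed
stage-by-stage (`nucredit simulate/call/annotate/enrich/cluster/motif`) and as
library functions.

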