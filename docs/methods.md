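# Methods

This note documents the models, parameter choices and numerical conventions of
`nucredit`, and what the synthetic-data generator does and does not emulate.

## Coordinate and alphabet conventions

All in-memory positions are 0-based with half-open intervals; every file
format (GFF3, pileup TSV, sites TSV/VCF, evidence TSV) is 1-based inclusive,
and the ±1 conversion happens only in `nucredit.io`. Alignment space is the
transcript (sense) strand — reads are assumed aligned to primary-transcript
templates, one primary transcript per gene — so substitution labels need no
reverse-complement logic. Sequences are stored in the DNA alphabet;
substitution labels report U on both sides ("C-to-U"), giving the 12 ordered
types over {A, C, G, U}. Reference columns on N are skipped with a logged
count.

## The editing caller

Per-read filters (perfect 22 nt seed, ≤ 3 candidate edits per read, handled by
`filter_read`) apply to alignment records; when the input is already a
pileup, those filters are assumed applied upstream. Per-column filters:
mean base quality ≥ 20 (Phred; conventional default, exposed as a flag) and
coverage ≥ 50 reads, counted after the quality cut. Each (column,
non-reference base with ≥ 1 read) pair becomes a candidate.

The error model: under sequencing error alone, a specific alternative base
appears at rate ε/3, with ε = 10^(−q/10) from the column's mean quality (a
global `--error-rate` can override). The test is a one-sided (greater)
Fisher's exact test on

```
[[ alt_count, coverage − alt_count ],
 [ round(coverage·ε/3), coverage − round(coverage·ε/3) ]]
```

with round-half-to-even on the expected count (documented for bit-exactness).
This is the minimal 2×2 reading of "observed vs expected under error"; the
one-sided direction reflects that only an excess of the alternative base is
evidence of editing. p-values are Benjamini–Hochberg adjusted (standard
step-up cumulative minimum handles ties) and sites require q strictly below
α = 0.05. Degree = alt_count/coverage.

Measured properties (the acceptance suite recomputes these): on 1,000 null
replicates with matched ε the fraction of runs with ≥ 1 call is ~0;
planted sites with degree ≥ 0.2 at ~100× coverage are recovered at ≥ 95%
sensitivity with mean signed degree error ≈ 0.001 over 500 sites.

## Characterization

Region by half-open interval membership. Codon position is
((pos − cds_start) mod 3) + 1; the alt codon substitutes the edited base;
translation uses the standard code with `*` for stop; synonymy is ref_aa ==
alt_aa; codons containing N leave the codon fields unset (logged).

Editing density divides per-region site counts by the summed region length
(kb) over *all supplied* transcripts (the template space); `edited_only`
restricts the denominator to edited transcripts. Per-amino-acid rates divide
event counts by codon-table degeneracy (stop treated as a 21st residue with
degeneracy 3); the words "number of degenerate codons" force this reading, but
a `usage` denominator (codon occurrences in the supplied CDS) is available.
RPKM uses the supplied library size; log2 is taken only where rpkm +
pseudocount > 0 (pseudocount default 0). Cross-validation against EST-style
evidence counts a site *covered* if any observation exists at its position and
*confirmed* if any observation equals the edited base; the fraction is
undefined (None) with zero coverage.

## Enrichment

GO terms: upper-tail hypergeometric per term present on ≥ 1 gene, universe =
exactly the supplied label table (explicit is better than a guessed genome
size), no multiple-testing correction by default because enrichment is
reported at raw p < 0.05 (a `fdr` flag adds BH). The endosymbiont test is a
one-sided (greater) Fisher's exact test; all tests are one-sided because the
claims under test are over-representation claims. Reported p-values are the
true tiny values, never clamped to 0.

## Coexpression clustering

Expression of each edited gene is multiplied by its mean editing degree
(averaged over its sites); unedited genes (e.g. PPRs) keep factor 1. Note a
constant per-gene factor does not change Spearman ranks — the adjustment
matters for magnitude-based interpretation and mirrors "number of edited
transcripts" semantics.

The network uses tie-corrected Spearman correlation (average-rank transform +
Pearson, t-distribution p-values with df = n−2; computed directly because
`scipy.stats.spearmanr` collapses to a scalar NaN when any profile is
constant — constant genes instead get NaN correlations and no edges, logged).
Edge iff ρ ≥ 0.7 and p ≤ 0.05; both thresholds are configuration. At least 5
samples are required (rank correlations are unstable below that).

SCM(i,j) = |neighbours(i) ∩ neighbours(j)|, computed as A² with zeroed
diagonal. Decomposition is greedy: (1) the unassigned pair with the largest
SCM entry seeds (ties: higher ρ, then lexicographically smallest ids); (2) the
third gene minimizing the larger of its two overlap p-values joins, both
p ≤ 0.05 required — a pair that cannot recruit a third gene is dissolved and
masked; (3) genes with significant overlap with ≥ 3 current members join, all
qualifying genes per sweep, to a fixpoint; (4) the cluster closes and its
members are removed. Minimum cluster size is 3 by construction.

The shared-neighbour null is Hypergeometric: observed overlap k between genes
with a and b neighbours (*excluding the partner edge*) drawn from the N − 2
other genes of the *full* network. Two deliberate choices here: degrees
exclude the partner (the partner cannot be its own shared neighbour), and the
universe stays the full gene set across rounds even though removed members no
longer count as shared neighbours — this keeps late clusters tested against
the same null as early ones and avoids the degenerate case where a pure
remaining clique has forced overlap and p = 1 on the shrunken support. Only
PPR genes and C-to-U edited genes enter the matrix.

Recovery, measured: with 3 planted blocks (target within-block Spearman 0.9,
200 samples, 27 genes), memberships are recovered with adjusted Rand = 1.0
across 20 seeds.

## Motif scan

Flanks are the 11-mers centred on edited C residues (sites within 5 nt of a
transcript end are skipped, counted). The background matrix aggregates the ±5
context of every C residue with a full flank in *all* supplied transcripts,
column-normalized over A/C/G/T (N neighbours excluded). Each flanking position
is tested by chi-square goodness-of-fit of the cluster's observed 4-vector
against n × background proportions, df 3 (an independence variant on the 2×4
table is available behind a flag). A zero background proportion with a nonzero
observation gets a continuity floor of 1/(4n) so the statistic stays finite;
zero-zero cells contribute nothing.

Position labels: R when significant *and* purine fraction ≥ 0.6; significance
for labelling uses α = 0.05 with a Bonferroni correction across the 10 tested
positions (the package's multiplicity choice — ten positions are always
tested, and uncorrected labelling would mark a spurious outer position in
~40% of scans). Raw per-position p-values are always reported and are what the
null-calibration property checks (measured false-positive rate at α = 0.05
under motif_prob 0: ~5.6% over 500 position tests). An all-N label set yields
an empty core motif. The per-cluster minimum of 20 sites for testing is a
chi-square-validity guardrail, not a biological threshold.

## The synthetic-data generator

What it emulates, and the defaults chosen as the study conditions:

* **Transcripts** — ATG-led CDS of 300–900 nt (multiple of 3, no internal
  in-frame stop, stop-terminated), UTRs of 100–300 / 150–400 nt, i.i.d.
  uniform base composition.
* **Editing events** — 400 sites over 80 transcripts by default; type weights
  put 61.3% of mass on the four dominant types (C-to-U, U-to-C, A-to-G,
  G-to-A) and split the rest evenly; degrees uniform on [0.20, 0.65] (mean
  0.425, matching the observed 41–43% mean degrees); sites avoid the first and
  last 5 bases so every site has a full motif flank.
* **Pileups** — coverage Poisson(100) truncated at ≥ 1; one multinomial draw
  per column with uniform error ε = 10⁻³ over the three non-reference bases
  (+ the planted degree on the alt base), so counts sum to coverage exactly.
  The uniform error model is the minimal assumption; no published per-base
  error rate exists for the motivating data, so ε is a free parameter. The
  column's mean quality is set to −10·log₁₀(ε) so a caller reading qualities
  is exactly matched to the generator.
* **Motif context** — with probability 0.8 both immediate neighbours of a
  planted C-to-U site are rewritten to A or G (equal odds); rewrites never
  touch another planted site's base and are resampled if they would create an
  in-frame internal stop.
* **Expression** — log-normal around a per-cluster latent sample profile
  (positive scale, RPKM-like); the latent loading uses the Gaussian identity
  ρ_s = (6/π)·arcsin(ρ/2) so the *expected Spearman* correlation within a
  block equals the configured target (default 0.8; 30 samples, matching the
  30-library design the pipeline emulates); between-block correlation is
  centred at 0.
* **Labels** — endosymbiont flag Bernoulli(0.17); edited flags Bernoulli with
  per-stratum fractions 0.273 / 0.195 so the planted odds ratio is recoverable;
  GO terms assigned independently of everything, making term-level enrichment
  null-calibrated by construction.
* **Evidence** — one EST-style observation per planted site with probability
  0.1, carrying the edited base with probability equal to the true degree.

Reproducibility: every operation draws from its own stream seeded as
`seed + fixed offset`, so adding operations never perturbs existing outputs,
and identical seeds give byte-identical files.

What it does **not** emulate — and hence what passing tests do not show about
real data: read-level artefacts (alignment bias, strand bias, indel slippage,
PCR duplicates), genotype polymorphism, splice isoforms and multi-isoform
collapsing, non-uniform base composition and codon usage, dependence between
GO membership and editing, and library-size variation across samples. The
caller's error control on real data additionally depends on upstream read
filtering that the pileup format assumes already happened.

## Problem sizes and budgets in the test/acceptance suites

Sizes were chosen to make the measured properties statistically meaningful at
desk scale: 1,000 null replicates for the caller's false-call rate; 500
planted sites for sensitivity and degree bias; exhaustive exact-test
enumeration (Fisher tables to coverage 200, hypergeometric universes to
N = 60); 20 seeds for cluster recovery; 100 seeded motif scans at 220 sites
each for detection/specificity and 50 null scans (500 position tests) for
calibration.

## Known limitations

* The decomposition is greedy and order-dependent by design; ties are broken
  deterministically (documented above) but a different tie policy can change
  late clusters.
* The hypergeometric shared-neighbour null ignores degree correlation between
  linked genes; in very dense networks it is conservative.
* The chi-square motif test treats the background as fixed; when a cluster
  contributes a large fraction of all C residues the test becomes slightly
  conservative (cluster and background overlap).
* VCF output is a minimal dialect (INFO keys ED/ET/RG) intended for
  interchange, not a full-featured VCF writer; BAM/SAM ingestion is out of
  scope (the pileup TSV is the boundary where a pysam-based adapter would
  plug in).
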