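# Methods

This note documents the models implemented in `stopscan`, the conventions
and defaults that matter, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Sequence model and filtering

A CDS enters analysis only if it (1) has length a multiple of three,
(2) contains only A/C/G/T, (3) has no internal stop codon under its
genome's translation table, and (4) ends in a stop codon of that table.
Rejection reports the first failed rule (`length`, `alphabet`,
`internal_stop`, `invalid_stop`).  Ambiguity codes are not resolved; any
non-ACGT character rejects the CDS.  Translation tables are NCBI tables 11
(standard bacterial) and 4 (TGA reassigned to tryptophan), taken from
Biopython.  Optional cohort-level filters mirror common practice for
phylogenetic non-independence: keep the first genome per genus, and drop
genomes below 500 kb when size metadata is present.

Frames are defined 1-based: +1 codons start at nucleotide positions
2, 5, 8, …, +2 codons at 3, 6, 9, …; a CDS of n codons yields exactly n−1
complete codons per off-frame.  The scan covers the whole CDS including
the start and terminal stop codons, and the density denominator is the
total codon count (start and stop included):

    density(c, f) = 100 · Σ_CDS count(c, f) / Σ_CDS n_codons.

Whether terminal codons belong in the denominator is a convention; it is
applied identically to real and simulated sequences, so Z scores are
unaffected.  −1/−2 frames are not scanned (they mirror +2/+1 one codon
away from the boundary).

## Null models

All four simulators regenerate every CDS independently in each of the
`n_reps` (default 200) replicates, and every replicate genome is scored
with the same density contract as the real genome.

**Codon shuffle.** Start and stop codons are held fixed; internal codons
are uniformly permuted per CDS.  Preserves length, GC, and the exact codon
and amino-acid multisets; destroys codon order.  Because the real
arrangement is one permutation among equals, this null is exactly
calibrated for any generator with exchangeable internal codons.

**Synonymous site.** A *coding block* is the set of an amino acid's codons
sharing their first two nucleotides; the 6-fold amino acids (Leu, Ser,
Arg) split into a 2-fold and a 4-fold block, and under table 4 tryptophan
forms the 2-fold block {TGA, TGG}.  Genome-wide third-site frequencies are
tabulated per block and each internal codon is resampled within its block.
Preserves the amino-acid sequence and per-position block membership.

**Synonymous codon.** As above but with blocks pooled: each internal codon
is resampled from its amino acid's full synonym set using genome-wide
synonym frequencies.  Preserves only the amino-acid sequence.

**Markov chains (orders 2 and 5).** Transition counts are collected over
the internal region of every CDS (start and stop codons discounted),
keyed by the context string *and* the codon positions of its nucleotides,
sliding one nucleotide at a time.  Simulation copies the real start codon
and the first `order` internal nucleotides as seed, then samples
nucleotide-by-nucleotide — codon positions tracked on the simulated
sequence's own frame — until the real length minus the stop codon, which
is appended verbatim.  Contexts never observed in training back off to the
(k−1)-nucleotide context, recursively down to the codon-position-specific
mononucleotide distribution.  Backoff was chosen over add-one smoothing to
avoid inventing unobserved transitions; since each genome is simulated
under its own model, full-order contexts almost always exist.  The seed
nucleotides are copied verbatim in every replicate.

The synonymous-site and synonymous-codon tables are also trained on
internal codons only, matching the Markov convention of discounting start
and stop codons from training.

## Excess statistics

Z = (real − mean)/sd over the replicate densities, with the n−1 sd
estimator; ensembles with zero spread yield a flagged NaN rather than an
infinite score.  p = 2·Φ(−|Z|) (two-tailed; the analyses report both
positive and negative excesses).  Benjamini–Hochberg correction is applied
across genomes within one (codon set, frame, model) family, and a genome
counts as having excess when Z > 0 and q < α (default 0.05); negative
excesses (Z < 0, q < α) are reported alongside.  Tracked codon sets are
the eight TAN/TGN codons analysed individually (TAA, TAG, TGA, TAC, TAT,
TGC, TGG, TGT) plus the genome's pooled stop set; frames +1, +2 and their
sum ("both") share one denominator.  Cohort-level GC correlations use
tie-aware Spearman ranks.

A calibration subtlety worth knowing: models whose null is *estimated from
the genome being scored* (synonymous site/codon, Markov) are mildly
conservative under a generator that matches them — the fitted frequencies
partially absorb the genome's idiosyncrasies, shrinking the Z spread below
1 (measured sd(Z) ≈ 0.7 for the synonymous-site model on i.i.d.-codon
genomes, roughly independent of genome size).  The shuffle null has no
fitted parameters and is exact.  Reported rejection rates at α = 0.05 are
therefore at or below nominal for the fitted nulls; this biases against
declaring excess, not toward it.

## Dicodon repeat-context test

In a repeat of two identical amino acids followed by a codon starting with
C or T, only the first codon's third site can complete an off-frame stop:
isoleucine repeats (ATH|ATH|YNN) can encode +1 TAA, valine repeats
(GTN|GTN|YNN) +1 TAG.  Per genome, all qualifying codon triples are pooled
(overlapping repeats each count; runs of three contribute both windows)
and the proportions of A at site 3 and site 6 are compared across genomes
with a two-sided paired Wilcoxon signed-rank test (zero differences
dropped; genomes without contexts excluded listwise).  The A/T-ending
restriction limits both repeat codons to A/T-ending synonyms, controlling
the GC3 difference between the compared sites.  log(A3/A6) is correlated
against genome GC3 with Spearman ranks; genomes with a zero proportion
have an undefined log-ratio and are dropped from that correlation.  The
test cannot control the residual mutational-context difference between
sites 3–4 and 6–7; that limitation is inherited from the design.

## Genetic-code comparison

Raw density differences between table-4 and table-11 genomes are
confounded by GC content (table-4 genomes are strongly AT-rich), so a
single loess curve of density against whole-CDS GC is fitted on the pooled
cohort — the fit is label-blind — and groups are compared on residuals
with a tie-corrected Kruskal–Wallis test, reported with group mean
residuals.  The loess is classic locally weighted regression: tricube
kernel over the span fraction of nearest neighbours, local polynomial of
degree 2, no robustness iterations; span defaults to 0.75 and is
configurable.  It is implemented in-package because the commonly available
`lowess` routines are local-linear only.  Kruskal–Wallis is retained even
for two groups (rather than Mann–Whitney) to keep one test across all
group layouts.

## Expression stratification (CAI)

CAI (Sharp & Li) is the geometric mean of per-codon relative adaptiveness
w against a highly expressed reference set — ribosomal-protein genes
matching rplA–rplF, rplI–rplU, rpsB–rpsU (case-insensitive; a warning is
issued below 20 matches, an error at zero).  Within each amino acid,
w = count / max synonymous count over the reference; codons absent from an
otherwise observed amino acid are floored at w = 0.01 (CodonW-compatible),
and amino acids entirely absent are uninformative (w = 1).  Stops and
single-synonym amino acids are excluded from the geometric mean — note
that under table 4 tryptophan has two codons and is therefore informative.

To keep the expression proxy independent of the density measurement, each
CDS is split into disjoint halves: the first 30 nt are removed (5′ ends
are biased for ribosome binding), CAI is computed on codons 11..⌊n/2⌋, and
off-frame densities on codons ⌊n/2⌋+1..n.  CDSs shorter than 22 codons
leave no CAI codons and are excluded.  Per genome, CAI and second-half
density are associated across CDSs with tie-aware Spearman ranks.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not real genomes.  Each CDS is ATG + internal codons + a stop drawn
uniformly from the table's stop set.  Amino acids are drawn i.i.d. from a
fixed average bacterial composition (embedded constants, overridable);
synonyms are drawn i.i.d. from a genome-specific usage table.  That table
is built by drawing per-amino-acid synonym weights from a symmetric
Dirichlet (`concentration` per synonym; default 50 gives mild genome-to-
genome usage variation) and exponentially tilting them toward or away from
G/C third sites so the *expected* GC3 of the codon stream hits the target
(solved by bisection; targets outside the code's feasible range — e.g.
below the floor set by Met/Trp — are clamped with a warning).  Realized
GC3 of a ≥50k-codon genome lands within ±0.02 of target.  Because internal
codons are i.i.d., codon order is exchangeable and the shuffle null is
calibrated by construction; in-frame stops cannot arise (only sense codons
are sampled), so no redraws are needed.

Two planted-signal operators create alternative hypotheses:

* `inject_osc_bias(stop, frame, δ)` — one left-to-right pass; at every
  internal codon whose downstream neighbour (read from the original
  sequence) completes the target stop and whose amino acid has an
  OSC-forming synonym, that synonym is adopted with probability δ
  (same-block synonyms preferred).  δ=0 is the identity, δ=1 saturates
  every eligible site; the amino-acid sequence is never changed.
* `inject_dicodon_bias(config, δ)` — at every qualifying repeat context,
  the first codon's third site is set to the target nucleotide with
  probability δ when the swap is synonymous (a δ-weighted mixture with a
  point mass, shifting E[A3] by δ·(1−p_A)).

What the generator does **not** emulate: operonic/positional codon-usage
gradients, amino-acid autocorrelation along proteins, motif or
secondary-structure constraints, mutational context dependence, length/
expression covariation, or phylogenetic relatedness between genomes.
Passing calibration and recovery tests on these cohorts therefore
demonstrates correctness of the machinery under its stated assumptions,
not that real genomes satisfy those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale analogues of a full
genome-database cohort: genomes of 15–100 CDSs with CDSs of 60–250 codons,
cohorts of 50–200 genomes, 200 replicates throughout (the replicate count
follows the analysis convention; variance gains beyond 200 are marginal).
These sizes are the package's chosen study conditions and are what the
documented calibration and power figures refer to.  Other conventions:
densities are per 100 codons; sd uses n−1; BH families are
(codon set, frame, model); undefined values (zero sd, zero proportions,
constant vectors) are flagged NaN and excluded listwise rather than
propagated; random streams are split per genome and per replicate from a
master seed, so results are independent of evaluation order.

## Limitations

* Programmed frameshifting sites, pseudogenes that survive the four
  filters, and annotation errors are not modelled or detected.
* The normal approximation for p from Z inherits the finite-replicate
  spread of the 200-simulation estimate; empirical-rank p values are not
  provided.
* OSC *efficiency* (termination context effects) is outside scope; an OSC
  is counted, not weighted by its likely effectiveness.
* The frameshift cost/probability machinery that would connect excesses to
  tRNA repertoires is exposed only as a hook (`per_codon_score` aggregates
  a caller-supplied per-codon probability per CDS and per genome); no cost
  model is implemented.
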