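# stopscan

Out-of-frame stop codon (OSC) excess analysis for bacterial coding
sequences.

A stop trinucleotide read in the +1 or +2 frame of a CDS spans two in-frame
codons and can terminate an accidentally frameshifted translation early.
The *ambush hypothesis* proposes such OSCs are selectively maintained.
Testing this requires a careful null: stop codons are AT-rich, so raw OSC
counts mostly reflect nucleotide composition.  `stopscan` is a toolkit for
molecular evolution researchers that quantifies OSC excess against four
null-sequence models which preserve increasingly strict layers of coding
structure:

| model      | preserves                                             |
|------------|-------------------------------------------------------|
| `markov2`/`markov5` | local nucleotide context (codon-position-aware Markov chains) |
| `shuffle`  | exact codon multiset per CDS (internal codons permuted) |
| `synsite`  | amino-acid sequence + coding-block membership (third sites resampled within blocks) |
| `syncodon` | amino-acid sequence (synonyms resampled with blocks pooled) |

For each genome and tracked codon set *c* in frame *f*, the excess is the
standard score against *n* = 200 replicate simulations,

```
Z = (D_real − mean(D_sim)) / sd(D_sim)
```

where densities *D* are OSC counts per 100 in-frame codons.  Two-tailed
p values come from the normal approximation, corrected across genomes by
Benjamini–Hochberg FDR within each (codon, frame, model) family; a genome
"has excess" when Z > 0 and q < 0.05.  Supporting analyses include:
Spearman correlations of Z against genome GC; the dicodon repeat-context
test (A use at site 3 vs site 6 of ATH|ATH|YNN and GTN|GTN|YNN repeats,
paired Wilcoxon signed-rank across genomes); loess-detrended density
comparisons between translation-table-11 and table-4 (TGA→Trp) genomes via
Kruskal–Wallis on residuals; and CAI-based expression stratification with a
disjoint half-split per CDS.  A built-in synthetic-genome generator with
controllable GC3, codon usage, genetic code, and injectable OSC enrichment
makes every stage testable without downloads.

## Worked example

Generate a small AT-rich cohort with a planted +1 TAA enrichment
(15% of eligible synonymous sites switched to the OSC-forming synonym) and
test it against the synonymous-site null:

```python
import stopscan as ss

spec = ss.CohortSpec(
    n_genomes=12, n_cds=(25, 35), cds_length=(80, 200), gc3=(0.2, 0.3),
    enrichment=ss.EnrichmentSpec(stop="TAA", frame="+1", delta=0.15),
)
genomes, truth = ss.generate_cohort(spec, seed=42)

ensembles = [
    ss.run_ensemble(g, "synsite", n_reps=200, seed=1000 + i)
    for i, g in enumerate(genomes)
]
results = ss.apply_fdr(ss.ensembles_to_results(ensembles))
taa = [r for r in results if r.codon_set == "TAA" and r.frame == "+1"]
print(ss.summarize_excess(taa).to_string(index=False))
r = taa[0]
print(f"\n{r.genome_id}: density={r.real_density:.2f} per 100 codons, "
      f"null {r.sim_mean:.2f} +/- {r.sim_sd:.2f}, Z={r.z:.2f}, q={r.q:.2g}")
```

Output:

```
codon_set frame   model  n_genomes  n_excess  pct_excess  n_negative_excess  pct_negative_excess
      TAA    +1 synsite         12         6        50.0                  0                  0.0

synth0000: density=3.87 per 100 codons, null 3.29 +/- 0.17, Z=3.44, q=0.0043
```

Half of the genomes reach FDR-significant +1 TAA excess even in this small
cohort; the first genome's real density sits 3.4 null standard deviations
above its 200-replicate synonymous-site expectation.

The same pipeline runs from the shell on FASTA cohorts (one multi-FASTA of
CDSs per genome plus a `metadata.tsv` sidecar; GenBank flat files are also
read):

```sh
stopscan synth --n-genomes 20 --gc3 0.2 0.5 --seed 7 --out cohort/
stopscan simulate --cohort cohort/ --models shuffle,synsite --reps 200 \
    --seed 7 --out excess/
stopscan dicodon --cohort cohort/ --repeat ile-taa --out dicodon/
```

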