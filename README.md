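# sortramp

Sort-seq reporter scoring and early-elongation analysis for randomized
N-terminal coding sequences.

## The problem

The first few codons of a bacterial open reading frame have an outsized
effect on protein yield: randomizing ORF nucleotides 7–15 (protein
residues 3–5) of an otherwise fixed eGFP reporter changes expression by
orders of magnitude, largely through early-elongation arrest rather
than initiation or mRNA stability. The experimental design behind this
package is a *sort-and-sequence* screen: a library of up to
4⁹ = 262,144 nine-nucleotide windows is expressed in *E. coli*, cells
are FACS-sorted into five fluorescence bins (bins 1–4 ≈ 24% of cells
each, bin 5 the brightest 2.5%, bin medians 20 / 120 / 600 / 3600 /
12,000 RFU), and each bin is deep-sequenced. Complementary
single-molecule experiments follow individual ribosomes through the
first codons and measure how often translation aborts.

`sortramp` implements the complete analysis as a tested, reusable
library, plus a generative simulator so that every stage is exercisable
without any sequencing download.

## What it computes

**GFP score.** For variant *v* with read counts *c<sub>vb</sub>* in bins
*b* = 1..5, counts are first normalized within each bin by its total
depth, *n<sub>vb</sub>* = *c<sub>vb</sub>* / Σ<sub>v'</sub>
*c<sub>v'b</sub>*; the score is the bin-index-weighted mean

> GFP score(v) = Σ_b (n_vb / Σ_b' n_vb') · b  ∈ [1, 5],

after removing variants with fewer than 10 total reads. Replicate
agreement is quantified by the Pearson correlation of scores over
variants with >100 reads.

**Sequence and peptide features.** Tripeptide translation with
amber/ochre/opal stop taxonomy and optional amber (supE44) suppression;
A/U content; tRNA adaptation index (tAI, dos Reis wobble rules with an
*E. coli* K-12 gene-copy table); Kyte–Doolittle hydropathy; net
side-chain charge; rare-codon flags; externally computed RNA folding
energies joined by variant.

**Motif enrichment.** Degenerate IUPAC hexamers (e.g. AADUAU, AAVAUU)
and amino-acid class motifs (K|N followed by Y|I) are scanned across the
window; enrichment between "high" (score > 4) and "low" (score < 3)
strata is the presence-fraction ratio with a two-sided Fisher exact
test, plus positional and synonymous-codon profiles.

**Single-molecule elongation.** Traces of alternating non-rotated /
rotated ribosome conformations with labeled-tRNA binding events are
simulated (irreversible per-codon abort branches), classified
(completed / aborted with or without ≥100 ms tRNA sampling), and
summarized: processivity *p* = completed/total with binomial s.e.
√(p(1−p)/n), and exponential state lifetimes by maximum likelihood with
an exact chi-square CI and an optional correction for 10 Hz frame
discretization. Bulk helpers quantify end-point peptide accumulation
ratios and gradient-method relative quantum yields.

## Worked example

```python
from sortramp import SimConfig, simulate_experiment, score_pipeline
from sortramp import motifs as mot
from sortramp.scoring import replicate_correlation

sim = SimConfig(n_variants=5000, seed=1)          # default study conditions
exp = simulate_experiment(sim)                     # library -> sort -> sequence
scores = score_pipeline(exp.replicates[0])
print(scores.head(3).round(4).to_string(index=False))

r, n = replicate_correlation(score_pipeline(exp.replicates[0]),
                             score_pipeline(exp.replicates[1]))
print(f"replicate Pearson r = {r:.3f} over {n} variants")

high, low = mot.stratify_scores(scores)
res = mot.enrichment(mot.KNYI, high, low, "pooled", scores)
print(f"K|N-Y|I: {res.n_high_with}/{res.n_high_with + res.n_high_without} high vs "
      f"{res.n_low_with}/{res.n_low_with + res.n_low_without} low carry the motif, "
      f"Fisher p = {res.p_value:.2e}")
```

prints

```
  variant  total_reads  frac1  frac2  frac3  frac4  frac5  gfp_score
ACTGGCACA          940 0.1351 0.2617 0.2713 0.2447 0.0872     2.8872
GGCTTTGGG          895 0.1765 0.2972 0.2190 0.1955 0.1117     2.7687
GGTCACAGG          913 0.1676 0.3067 0.2727 0.2114 0.0416     2.6528
replicate Pearson r = 0.965 over 5000 variants
K|N-Y|I: 54/95 high vs 0/2821 low carry the motif, Fisher p = 4.03e-89
```

Each row is one 9-nt window: its raw read total, its renormalized share
of each bin, and the resulting score. The simulator plants a +0.8 log10
expression effect on windows encoding K|N at residue 3/4 followed by
Y|I, and the enrichment stage recovers exactly that motif from the
scored counts.

A command-line interface mirrors the library
(`sortramp simulate|extract|score|features|motifs|smfret|quant|run`);
see `sortramp --help`.

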