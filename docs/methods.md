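# Methods

## Scoring model

The per-variant expression statistic is a weighted mean of FACS bin
indices. Counts are normalized within each bin by that bin's total
sequencing depth (removing depth differences between bins), each
variant's five normalized abundances are renormalized to sum to one,
and the score is Σ_b w_b·b ∈ [1, 5]. Properties relied on throughout:
the score is invariant to positive rescaling of a variant's row, equals
the bin index when all mass sits in one bin, and is monotone under
shifting mass toward brighter bins. Variants with fewer than 10 total
raw reads are removed **before** normalization; the alternative order
(normalize on unfiltered depths) differs only through the removed
variants' contribution to bin depths and is available by composing
`normalize_bins` manually. No pseudocounts are used: a variant absent
from a bin contributes zero weight there. When `score_pipeline` meets a
bin with zero depth it treats that column as contributing no weight;
calling `normalize_bins` directly on such data is an error, since a
zero-depth bin usually signals a malformed input rather than a design
choice.

Replicate reproducibility is the Pearson correlation of scores over
variants with strictly more than 100 raw reads in each replicate.
Replicate aggregation is an unweighted per-variant mean (and sd);
pooled-count scoring (`pool_counts` then `score_pipeline`) is available
but not the default, since the within-replicate depth normalization is
not exchangeable with pooling.

## Generative simulator

The simulator exists so every downstream stage has ground truth. It is
additive in log10 fluorescence:

* baseline (default 2.6 log10 RFU, placing a typical variant between
  the bin-3 and bin-4 medians of the emulated gate design);
* +0.05 per A/U nucleotide in the window (a mild downstream-box-like
  composition effect: 0–9 A/U spans 0.45 log10);
* +0.8 for windows whose residues 3–4 or 4–5 realize K|N then Y|I (the
  planted motif recovered by the enrichment stage);
* stop handling: the first UAA/UGA forces the stop floor (default 2
  log10 below baseline); each UAG before any hard stop is suppressed
  with probability 0.85 (an efficient amber-suppressor host), and the
  variant's expected value is the read-through-probability-weighted
  mixture of read-through expression and floor. A per-cell Bernoulli
  read-through would be more physical (bimodal fluorescence); the
  scalar mixture keeps one expected value per variant, which is all the
  sorting model consumes, and still produces the qualitative ordering
  hard stop < amber < stop-free.

Cell-to-cell spread is log-normal (log10 sd 0.25), consistent with
log-spaced bin medians in flow data. Sorting assigns each cell a bin by
the *empirical quantiles* of the pooled fluorescence distribution,
implemented by ranking with random tie-breaks; this realizes the gate
fractions even in degenerate pools (cv = 0). Default gates are
contiguous: cumulative boundaries (0.24, 0.48, 0.72, 0.975), i.e. bins
of 24/24/24/25.5/2.5% of cells. An optional `unsorted_gap` quantile
band models designs that discard cells between the bin-4 and bin-5
gates. Sequencing is multinomial per bin at configured depth; PCR
jackpotting, sequencing error and growth competition are deliberately
out of scope. Library representation across cells is uniform.

Default problem sizes — 5,000 distinct windows, 10⁶ cells, 10⁶ reads
per bin, two replicates — give ≈200 cells and ≈950 reads per variant,
enough that score noise is dominated by cell sampling rather than read
sampling. All randomness flows from one top-level seed through numpy
`SeedSequence` spawning in fixed order (library; then per replicate a
sort stream and a sequencing stream), so replicates share truth but
re-run the experiment.

What passing recovery tests shows — and does not. The simulator
reproduces the statistical *structure* the analysis assumes (quantile
gates, multinomial sampling, additive effects, stop truncation); it
does not reproduce real-library phenomena such as uneven variant
representation, PCR duplicates, misreads into the constant flanks, or
expression effects beyond the additive model. Recovery statistics
(Spearman ≈ 0.95, replicate r ≈ 0.96 at default depth) are therefore
upper bounds on what identical analysis would achieve on real data, and
the screen's own data-dependent constants (library mean ≈ 3, replicate
r = 0.74, particular wild-type scores) are treated as loose qualitative
bands, not targets.

## Sequence features

Translation uses the standard genetic code with '*' as the stop symbol;
the 262,144 windows encode exactly 21³ = 9,261 distinct tripeptides.
Amber suppression (optional) decodes UAG as Gln while preserving the
amber classification for provenance. Hydropathy is the mean
Kyte–Doolittle index and charge the integer side-chain charge at
neutral pH (K/R +1, D/E −1, His 0); stop symbols are excluded from both
rather than assigned values, and an all-stop tripeptide has no defined
value. Both scales are pluggable. Rare codons default to the classical
*E. coli* set AGG, AGA, CGA (Arg), ATA (Ile), CTA (Leu), configurable.

tAI follows the standard construction: raw weight W(codon) = Σ over
recognizing anticodons of (1 − s)·tGCN, with the dos Reis selective
constraints (Watson–Crick 0; G:U 0.41; I:C 0.28; I:A 0.9999; U:G 0.68)
and bacterial special cases — AUG keeps only its cognate reader, and
AUA is read by the lysidine-modified ileX tRNA (s = 0.89, one gene
copy, tracked separately because its genomic anticodon CAU collides
with Met). Weights are normalized to max 1; zero-weight codons receive
the geometric mean of the nonzero weights; a sequence's tAI is the
geometric mean of its codon weights and is undefined for stops. The
shipped tGCN table is a GtRNAdb-derived *E. coli* K-12 MG1655 anticodon
copy-number fixture, overridable via TSV (`anticodon, copies`); no
result in this package is sensitive to its exact values.

RNA folding energies are consumed, never computed: an external
`variant → ΔG` table (e.g. from RNAfold over the window ±30 nt) is
left-joined, with missing variants kept explicitly absent.

## Motif analysis

Motifs are stored in the DNA alphabet (RNA input normalized). Matching
is positionwise IUPAC containment for nucleotide patterns and
residue-class membership for peptide patterns (any stop in the
tripeptide fails a peptide match, mirroring the screen's stop
filtering). For hexamers in a 9-nt window the valid offsets are 1–4;
offsets 1 and 4 are in-frame (codons 3–4 and 4–5).

The discovery tool the screen used internally is a discriminative
regression whose statistic is not reconstructible; enrichment is
therefore reported as the quantities actually interpretable from strata
— the high/low presence-fraction ratio and a two-sided Fisher exact
p-value — with "high" = score strictly above 4 and "low" strictly below
3 (boundary placement is a measure-zero choice; thresholds are
configurable). A zero low-stratum fraction yields an infinite ratio
with the exact p still computed. Exhaustive scans of the 4,096 literal
hexamers apply Benjamini–Hochberg control. `permutation_null_pvalues`
exposes the test's null calibration; with large balanced strata and a
prevalent pattern the p-values are approximately uniform (the exact
test's discreteness sets the floor on this approximation).

## Single-molecule model and estimators

Arrest is modeled as an irreversible branch before decoding each codon
(probability q_k), not a graded slow-down: completion probability is
Π(1 − q_k), and recovered per-codon abort rates are survival-curve
decrements. State dwells are exponential; durations are floored to the
10 Hz frame grid with a one-frame minimum (an event shorter than a
frame is still seen for one frame). This discretization biases the
plain exponential MLE low by up to half a frame; the optional
correction inverts the exact expectation of the floored-and-clamped
observation (a geometric-tail relation solved by bisection), bringing
the bias below 0.2 frames for lifetimes of a few frames or more. The
95% CI uses the exact chi-square pivot 2n·mean/τ ~ χ²(2n) and achieves
nominal coverage on continuous data (≥93% observed across 200
replicates in the acceptance suite). Lifetimes may be fit pooled across
codons or per codon (both modes provided, since reference experiments
are ambiguous on this point); terminal arrest dwells are excluded.

Aborted traces are subclassified by post-arrest A-site tRNA sampling:
any binding strictly longer than 100 ms (configurable) counts as
sampling. Manual trace curation in the reference workflow (two-
fluorophore presence, single-step photobleaching) is replaced by
explicit fields on `Trace` so filtering is programmatic and
reproducible. The named presets KIH/IGK/TVG (84/54/27% completion)
encode measured reference processivities as simulator targets — the
preset splits the total abort probability evenly over codons 4–5, where
arrests concentrated — and are *not* desk-reproductions of those
measurements, which require real traces.

`relative_accumulation` normalizes each species' band intensity to the
total lane intensity at the same time point, averages the last three
time points, and reports ratios to a reference species (ratio 1 by
construction). `relative_quantum_yield` is the gradient-method closed
form Q = Q_R·(Grad/Grad_R)·(n²/n_R²).

## Numerical and interface choices

* User-facing coordinates are 1-based inclusive ("nucleotides 7–15");
  internal arrays are 0-based half-open.
* Window extraction from reads uses exact constant-flank anchoring
  (upstream flank plus the first 6 nt of the downstream flank by
  default); every read is accounted for as retained or one discard
  reason, and the tallies sum to the total.
* All writers emit provenance comment lines (package version, seed,
  config hash); identical configurations produce byte-identical
  outputs. The config hash excludes the output directory and log level.
* Acceptance-scale computations are sized to run in seconds-to-minutes:
  exhaustive checks enumerate all 262,144 windows; stochastic checks
  use 5,000-variant libraries, 200-replicate calibrations, and
  1,000–2,000-trace ensembles, sizes at which the asserted tolerances
  (3 binomial s.d., 15% s.e.-vs-s.d. agreement, 2% survival-product
  error) are comfortably resolvable.

## Known limitations

* The expression model is additive in log10 with independent terms; it
  cannot represent epistasis between the motif and composition effects.
* The amber mixture is a per-variant expectation, not per-cell
  bimodality (see above).
* tAI values depend on the fixture's copy numbers and the bacterial
  wobble conventions; organisms other than *E. coli* require a
  different table.
* The enrichment p-value is exact but conditional on the observed
  margins; for tiny strata its discreteness makes "uniformity" a poor
  description of the null, and the permutation helper should be used
  for calibration instead.
* FASTQ extraction tolerates no anchor mismatches by default
  (configurable downstream anchor length only); heavily error-prone
  reads would need fuzzy matching that is deliberately not implemented.
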