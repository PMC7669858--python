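# Methods

This note documents the models, parameter choices and numerical
conventions behind `clonalkit`, and what the synthetic-data generator
does and does not emulate.

## Barcode design (`barcode_design`)

A WS barcode of `k` repeats is a `2k`-mer with odd (1-based) positions
in {A, T} and even positions in {C, G}; GC content is therefore exactly
50% by construction, which equalizes amplicon melting behavior and PCR
efficiency across clones. The designer rejection-samples random WS
strings and accepts a candidate only if its Hamming distance to every
accepted barcode is at least `min_hamming` (default 8 for 30-mers).
Matching downstream is positional and exact, so Hamming distance — not
edit distance — is the relevant separation: at distance ≥ 8, no
plausible number of substitution errors converts one whitelisted barcode
into another, and error-carrying reads fall into the design-fail or
whitelist-unmatched bins instead of being miscounted. Sampling is
bounded (default 10⁶ draws) and fails loudly when the requested library
is combinatorially infeasible (e.g. five distinct 2-mers). At the scale
used here (tens of barcodes, 2¹⁵ weak × 2¹⁵ strong patterns available)
rejection sampling accepts almost every draw.

## Synthetic data (`synthetic_data`)

All generators are pure functions of (config, seed) built on
`numpy.random.default_rng`; the same seed yields byte-identical output.

**Clone trajectories.** The default mixture holds ten clones in three
classes — one dominant grower (weekly rate 2.0), one weak grower (1.4),
four persisters (≈ 1.0) and four decliners (0.4–0.6) — mirroring the
qualitative behavior of barcoded clone mixtures in vivo: a dramatic
first-week die-off (default survival 0.1) followed by class-specific
exponential growth. An 11th library barcode (CL11) carries no cells and
serves as the background control for detection calls.

**Amplicon reads.** Reads are a fixed-offset sample index (default 6 nt)
followed by the 30-nt barcode. Source barcodes are drawn multinomially
from the clone fractions; substitution errors are i.i.d. per base
(default 0.005, the right order for Illumina amplicon data); Phred
scores are drawn from N(35, 3) clipped to [2, 40], independent of the
error process. Reads are held as numpy code matrices so 10⁵-read
samples simulate and quantify in fractions of a second; standard
Phred+33 FASTQ is materialized on demand. Not modeled: PCR amplification
bias, indels, paired ends, quality–error coupling. Consequently, passing
recovery tests demonstrate correctness of the counting and filtering
logic under multinomial sampling with substitution noise — not
robustness to PCR jackpotting or indel-rich platforms.

**Mutation tables.** The clone tree is a nested tuple; every branch
(clade) receives a fixed number of heterozygous mutations. Expected VAF
is 0.5 in carriers and 0 elsewhere — the diploid heterozygous model,
appropriate for a mainly diploid line — and the parental sample is a
cell mixture with expected VAF 0.5 × Σ(proportions of carrying clones).
Observed alt counts are Binomial(depth, VAF) with per-sample depth =
configured depth + Poisson(10) jitter, so the depth floor is respected.
Trinucleotide contexts are drawn from a configurable 96-channel
distribution (uniform by default), and half the records are emitted on
the purine strand to exercise downstream strand normalization. An
optional germline outgroup sample (zero VAF everywhere) roots the
inferred topology; without it, the two clades adjacent to the root share
one unrooted edge and their stem mutations (and parental VAFs) merge.
Copy-number alterations, subclonal mutations within a clone, and
contamination are not modeled.

**Expression counts.** Counts are negative binomial via gamma–Poisson
mixing with variance μ + φμ²; φ = 0 degenerates to Poisson. The default
φ = 0.002 is deliberately near-Poisson: the downstream depletion test is
a dispersion-free conditional binomial, and the generator's role is to
emulate the operating conditions under which such a screen is valid
(one library per clone, technical-level noise). Real between-clone
biological dispersion is far larger (φ ≈ 0.01–0.1), and under it the
conditional binomial is anti-conservative — a known limitation of
single-replicate screens, inherited by design here and worth remembering
when interpreting hits on real data. The planted ligand's mean (default
20 counts) is divided by 100 in the target clone; its receptor (mean
200) is expressed everywhere. Decoy pairs (default 49, a desk-scale
version of a several-hundred-pair screen) have equal ligand means across
samples, and each decoy receptor is silent with probability 0.5,
reflecting that most receptor genes are off in any one clone — the
situation the screen's receptor-expression gate exists to filter.

**Luciferase series.** Per-mouse readings are scale × burden ×
exp(N(0, σ)) — multiplicative log-normal assay noise around strict
proportionality to tumor burden, with the first time point the 24 h
baseline.

## Barcode quantification (`barcode_quant`)

Filtering order per read: exact index match (demultiplexing), WS design
match, quality thresholds, exact whitelist match. The quality rule is
applied to the barcode region only: every base Phred ≥ 10 (inclusive)
and mean Phred strictly > 30, mirroring the asymmetric wording of the
protocol it implements. Each read lands in exactly one bin (matched,
index-unmatched, design-fail, quality-fail, whitelist-unmatched), and
the accounting identity `matched + discarded = input reads` is enforced
by the count-table type itself. No error correction is attempted:
1-mismatch rescue would be safe given the Hamming-separated whitelist
but is unnecessary at amplicon error rates and is therefore omitted;
exactness keeps the estimator unbiased (errors remove reads uniformly
across barcodes rather than transferring them).

Fractions divide each barcode's count by the sample's whitelist-matched
total; a zero-total sample yields flagged NaN fractions rather than an
error. T0 normalization divides each fraction by the barcode's mean
fraction across the designated T = 0 reference samples; barcodes absent
from all T0 samples are excluded from the normalized output with a
warning. Both raw and normalized values are reported. Background per
sample is the observed fraction of a barcode known to be absent from the
inoculum; detection of any other barcode requires its fraction to
*strictly* exceed that level.

## Growth summaries (`growth_dynamics`)

Fold change is reading / 24 h baseline, with points at or below the
background level flagged but still reported. The background level from
negative-control readings is mean + 2 SD (exposed as a parameter; the
choice of 2 SD is a convention, not a fitted quantity). Doubling time
assumes exponential growth: generations = log₂(N₂/N₁), doubling time =
duration / generations, undefined (an error) when the culture did not
grow. The linear fit is ordinary least squares via
`scipy.stats.linregress` with R² = squared Pearson r and a two-tailed
slope t-test; a constant response returns R² = 0 by convention. The
mesothelial clearance ratio is the cleared area at 24 h divided by the
initial (1 h) cluster area — a scalar operation; image segmentation is
out of scope.

## Clonal phylogeny (`phylogeny`)

**Characters.** A mutation is retained only if depth ≥ 30 in every
sample (including the parental and any outgroup) and VAF ≥ 0.25 in at
least one taxon; retained VAFs map to present (≥ 0.25), absent (< 0.10)
or ambiguous ([0.10, 0.25)). Ambiguous (and missing) taxa enter Fitch
scoring as the full state set {present, absent}, so they never force a
change; an alternative would be to excise them per character, which is
exposed at the matrix level by recoding, but full-uncertainty scoring is
the default because it uses all rows without inventing certainty.

**Search.** Fitch small parsimony is computed vectorized across
characters in one post-order pass (a change whenever two child state
sets have empty intersection). For ≤ 7 taxa the search enumerates all
(2n−5)!! unrooted topologies by stepwise addition and returns every
minimum-score topology; above that, 10 random-addition starts each
climb to an NNI local optimum, with ties broken by lexicographic Newick
string so results are deterministic given the seed. Exhaustive search
is exact; the heuristic is adequate for the ≤ 13-taxon matrices this
package targets but carries the usual local-optimum caveat.

**Bootstrap.** Characters are resampled with replacement; support for
each internal split of the reference best tree is the fraction of
replicate best trees containing it. In exhaustive mode, per-topology
character lengths are computed once and each replicate reduces to a
weighted sum, making 1000 replicates on 7 taxa sub-second. Support is
attached to the reference tree's splits (not a consensus), matching
common maximum-parsimony practice; replicate ties are broken by the same
lexicographic rule as the search.

**Branch assignment.** Each mutation is placed on the edge(s) where one
deterministic minimal Fitch reconstruction changes state: the down-pass
uses the union-on-empty-intersection rule, and the top-down refinement
keeps the parent's state when allowed, preferring *absent* otherwise
(mutations arise rather than revert in a typical clone history).
Zero-change characters are assigned to no branch; characters needing
more than one change (homoplasy) are assigned to all of their change
edges and flagged rather than silently attributed. Branch summaries
report the mean parental VAF over assigned mutations, NaN for empty
branches.

**Rank-sum comparison.** Branch VAF sets are compared with a two-sided
Wilcoxon rank-sum test: exact permutation enumeration on midranks (ties
handled) when both n ≤ 10, otherwise the normal approximation with tie
correction (`scipy.stats.mannwhitneyu`). The exact two-sided rule counts
labelings whose rank-sum deviates from its null mean at least as much as
observed, which coincides with the standard exact test in the untied
case.

## Mutational signatures (`signatures`)

Channels follow the conventional lexicographic 96-channel layout
(substitution type C>A … T>G major, then 5′ and 3′ flanks); purine
-reference records are reverse-complemented to the pyrimidine strand
before binning, and non-SNV rows are skipped and counted. Refitting is
per-sample NNLS — the standard signature-refit estimator whose
reconstruction quality the cosine similarity then measures; exposures
are in mutation-count units, nonnegative by construction, and
scale-equivariant. The catalog reader accepts any conforming
channels × signatures TSV whose columns sum to 1 (within 10⁻⁶) and
reorders rows to the canonical layout, so any catalog version with this
shape can be used. The attribution filter keeps signatures contributing
≥ 200 mutations across all samples (inclusive at the boundary) and
re-runs the refit on the reduced catalog. De novo extraction (NMF) is
out of scope.

## Crosstalk screen (`crosstalk`)

cpm = count × 10⁶ / library size, with library sizes defaulting to
column sums. The depletion test is an exact conditional binomial, target
versus pooled rest with a library-size offset: given the ligand's total
count n, the target count is Binomial(n, L_t/L_total) under the null,
one-sided p = P(X ≤ k). This is a deliberate design choice over a
negative-binomial exact test: with one library per clone there are no
replicates from which to estimate dispersion, and the conditional
binomial is the dispersion-free exact analog (its anti-conservatism
under real biological dispersion is documented above). BH correction
runs across tested ligands only; receptors act as a gate (strict
cpm > 2 in the target), and a hit additionally requires the target to
have the minimum cpm among samples for that ligand. Hits report the raw
p, FDR, passing receptors and the target's cpm.

## Contingency statistics (`stats`)

Fisher's exact two-sided p uses the minimum-likelihood rule (sum of
probabilities of margin-consistent tables no more probable than the
observed one), the common software default; the double-one-tail
convention is available by flag. The Monte-Carlo chi-square samples
tables uniformly under fixed margins (Patefield's algorithm via
`scipy.stats.random_table`) and uses the add-one estimator
(1 + B)/(1 + N), which cannot return zero and is mildly conservative;
degenerate margins return p = 1.

## Problem sizes and defaults used in the checks

The shipped tests and acceptance checks run the pipeline at the scale it
was designed around: 11-barcode libraries; 10⁵-read amplicon samples at
0.5% substitution error over 100 seeds; 6–7-taxon trees with 5–30
mutations per branch at 200–500× depth, 200–1000 bootstrap replicates;
2000-mutation spectra against 2–5-signature catalogs over 100 seeds; and
1000–2000-gene expression matrices with 50 ligand–receptor pairs over
100 seeds. These sizes were chosen so each property is measured with
comfortable statistical margin while any single check completes in
seconds.

## Known limitations

* Exact matching only (no index or barcode error correction); fine for
  Hamming-separated whitelists, lossy for degenerate libraries.
* The heuristic tree search (NNI from random-addition starts) can stop
  in local optima on large, conflicted matrices; the exhaustive mode is
  the reference behavior.
* The crosstalk test ignores biological dispersion (see above); treat
  real-data hits as candidates for orthogonal validation, as the
  original screen did.
* The expression generator plants a single depleted ligand; correlated
  gene modules, batch effects and compositional artifacts are not
  simulated.
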