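# Methods

## Model

Each base *i* of the reference genome carries, for every non-reference
species *j* of an N-way alignment, one of three observations: the species
aligns with a nucleotide identical to the reference (1), aligns with a
different nucleotide (2), or contributes no nucleotide (3). A K-state
hidden Markov model generates these vectors: initial probabilities
*a<sub>k</sub>* at the first base of each modelled sequence, transitions
*b<sub>t,u</sub>* between adjacent bases, and emissions that factor over
species as independent three-way multinomials
(p<sub>k,j,1</sub>, p<sub>k,j,2</sub>, p<sub>k,j,3</sub>).

Internally the multinomial is represented by two Bernoulli variables per
species: an align flag *y* with success probability *f<sub>k,j</sub>* and a
match flag *z* with conditional probability *g<sub>k,j</sub>*, where *z* is
missing whenever *y* = 0 and then contributes no factor to the emission.
This is exactly equivalent to the multinomial via p₁ = f·g, p₂ = f·(1−g),
p₃ = 1−f, and it lets the M-step re-estimate *g* only from positions with
expected alignment. The package exposes the multinomial form as `model.p`;
its residual construction (p₂ = f − p₁, p₃ = 1 − (p₁+p₂)) makes each triple
sum to exactly 1.0 in float64 while differing from the algebraic values by
at most one ulp.

Independence assumptions worth keeping in mind: emissions are independent
across species given the state (no phylogenetic tree structure), and each
genome slice is modelled as an independent chain started from *a*. Whether a
chain should instead persist across adjacent slices of one chromosome is a
genuinely open design point; independence was chosen because slices are also
the unit of training subsampling and of the train/test split, and because
with sticky transitions the effect of the boundary condition decays within
tens of bases.

## Numerics

Forward–backward runs in linear space with per-position scaling constants.
Per-position log-emission vectors are accumulated in log space (a product of
~100 species factors underflows float64 long before scaling could help) and
shifted by their per-position maximum before exponentiation. Boundary
parameters (f or g exactly 0 or 1) are admitted by replacing infinite logs
with a −1e30 penalty. The recursions are numba-compiled; posteriors are
renormalised per base and agree with brute-force path enumeration to ~1e−15
relative error (the contract is 1e−9).

After every M-step, probabilities are clamped to [1e−10, 1−1e−10] and the
initial/transition rows renormalised: a state that a subsampled iteration
never visits must not acquire an absorbing zero. Decoding ties break to the
lowest state index. Degenerate inputs are errors, not silent results: empty
slice lists, inconsistent (y, z) pairs, constant feature vectors in
correlation clustering, segmentations with different state counts.

## Training regime

Baum–Welch runs a fixed number of iterations (default 200) with a random
subset of genome slices (default 150 of the 200 kb slices) drawn without
replacement each iteration from a seeded generator. There is no
likelihood-based stopping rule: with per-iteration resampling the sampled
likelihood fluctuates by design. Full-data mode (`segments_per_iteration =
None`, or `--segments-per-iter 0` on the CLI) restores classical EM with its
monotonicity guarantee, which the test suite checks to 1e−8 per step.
Initialisation is seeded random: f, g ~ Uniform(0.2, 0.8), uniform *a*, and
transitions with 0.9 on the diagonal — enough to break symmetry while
starting in the sticky-transition regime the data exhibit. Identical seeds
and inputs give bitwise-identical parameter trajectories.

EM converges to local optima, and with few states a single random start can
collapse two true states into one. Where a single canonical fit matters (the
acceptance script's recovery experiment), several short pre-runs from
independent random initialisations are scored by their data likelihood and
only the best is continued — restart selection uses the likelihood alone,
which is the standard multi-start EM recipe.

## Synthetic data

The simulator draws state paths from (a, b) per slice, then per species an
align flag from f and, if aligned, a match flag from g — precisely the
annotator's generative assumptions. `emit_maf` renders observations as MAF
text (uniform reference nucleotides, mismatches uniform over the other three
bases, unaligned species as gaps or omitted rows, blocks broken at
all-unaligned runs and every 10 kb) such that parsing and re-encoding the
text reproduces the observation matrices bit-exactly. MAF emission never
produces an 'N', keeping the round trip exact under the rule that ambiguity
codes encode as not-aligned.

The `preset_clade_model` builds deterministic states that mimic the broad
families seen in vertebrate alignments: a prefix of the divergence-ordered
species list aligns and matches (the prefix shrinking with the state index),
plus an align-without-match state (high f, g = 0.1) for K ≥ 4 and an
artifact-like state (proximal and most-distal species align, the middle of
the tree does not) for K ≥ 5. Defaults: f = 0.95/0.05 inside/outside the
pattern, g = 0.9 where matching, self-transition 0.99 (segments of ~100
bases, long enough that transitions are informative at the 200 kb slice
scale, short enough that a 500 kb simulation holds thousands of them).

What the simulator does **not** emulate: phylogenetic correlation between
species, substitution-rate heterogeneity along the genome, indel structure
beyond per-base presence/absence, and assembly artifacts with positional
structure. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-alignment model misspecification.

Recovery is judged after minimum-cost bipartite matching of states on the L1
distance between multinomial emission vectors, since EM state labels are
arbitrary. At the default experiment scale (500 kb, 4 states, 8 species, 300
full-data iterations) the maximum absolute error on f, g and b is well below
0.05 and decoding agrees with the true path on far more than 95% of bases.
The initial distribution *a* is excluded from that criterion: a 500 kb
genome contains only a handful of slice starts, so *a* is estimated from
almost no data.

## Enrichment and evaluation conventions

Fold enrichment of a state for an annotation is (fraction of annotation
bases in the state) / (fraction of the background universe in the state),
computed on merged interval sets so a base counts once. The universe
defaults to the whole segmented genome; passing a restricted universe
implements background-relative analyses, and `relative_enrichment` divides a
foreground column by a background column. Positional enrichment normalises,
at each signed offset, by the anchors still in bounds at that offset;
minus-strand anchors mirror their offsets so positive offsets are downstream
5'→3'. The promoter-window gene ranking uses a closed ±2 kb window (4001
bases including the TSS base) and a top set of floor(fraction × n_genes)
genes with lexicographic tie-breaks.

Precision–recall: states (or score bins) are ranked by fold enrichment for
the target among training-slice bases and added cumulatively, with precision
and recall measured on test-slice bases only. Score tracks are partitioned
into 400 bins — one bin for bases where the score is undefined, the rest
equalised to within one base by descending score; a tied score increment
straddling bin boundaries is split proportionally to the overlap of its rank
interval with each bin, with a seeded uniform choice of which bases land
where. Top-percent score sets pick the distinct-value threshold whose set
size is closest to the requested fraction of the universe (ties to the
smaller set, which makes sets nested across fractions); undefined bases rank
below every value but count toward the universe size. Multi-sample targets
are pooled by concatenation: each (chromosome, sample) pair becomes a
pseudo-chromosome `chrom#sample` with the segmentation and splits replicated
across samples.

## State clustering

States are clustered on the concatenation [f<sub>k,·</sub>,
(f·g)<sub>k,·</sub>] with distance 1 − Pearson correlation and complete
linkage (the cited clustering routine's default; the linkage method is
recorded in output metadata by virtue of being fixed here). Leaf order is
the exact optimal leaf ordering: a dynamic program over (subtree, leftmost
leaf, rightmost leaf) triples minimising the summed distance between
adjacent leaves over all 2^(K−1) tree-consistent orders. The DP is
implemented in this package because the installed scipy's
`optimal_leaf_ordering` returned verifiably suboptimal orders on small
instances where exhaustive search is feasible; the test suite checks the DP
against exhaustive search for K ≤ 8. Enrichment matrices are filtered to
states with ≥ 2-fold enrichment in some sample, log2-transformed with folds
floored at 0.01 (finite and rank-preserving), row z-normalised, and
bi-clustered the same way.

## Problem sizes

The bundled experiments run on simulated genomes of 30–500 kb with 4–12
species and 2–8 states — sizes at which brute-force oracles (path
enumeration up to K^T ≈ 6 × 10³ paths, exhaustive leaf-order search up to
2⁷ orders, per-base counting) are exact and fast, chosen so the full test
suite and the acceptance script each complete in minutes on one CPU. The
algorithms themselves stream slice-by-slice and have no genome-size-specific
constants beyond the 200 kb slice default.

## Known limitations

- No Viterbi decoding; per-base maximum-posterior assignment only.
- Reverse-strand reference rows in MAF are rejected rather than
  reverse-complemented.
- Per-allele score files must be reduced to per-base tracks upstream (e.g.
  max over alternate alleles); the evaluation machinery consumes per-base
  values only.
- The positional-enrichment normalisation (anchors in bounds at each offset)
  is one of two defensible conventions; the alternative (all anchors)
  differs only at offsets that leave the segmented extent.
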