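# Methods

This note records the models, conventions, parameter choices and known
limitations behind `equimsy`. Coordinates are 0-based half-open throughout;
printed 1-based coordinate pairs from assembly reports are interpreted as
half-open when reproducing printed segment lengths (so Y:429,056–554,227 is
125,171 bp).

## Synthetic data generator (`equimsy.synth`)

The generator emulates the input classes an MSY study consumes, each with a
`TruthSet` holding exact planted coordinates and values. A single global
seed feeds independent sub-streams (reference, gametologs, calls, counts),
so adding one output never perturbs another and identical configs give
byte-identical outputs.

**Reference.** A uniform-random A/C/G/T background with planted features
laid left-to-right, separated by equal single-copy spacers. An ampliconic
array is a random master unit copied `copies` times, each copy mutated
independently at per-site rate `m` solving `2m − (4/3)m² = d` so the
*expected pairwise divergence between copies* equals the configured `d`
(uniform alternative bases). A transposition emits a separate "X-PAR"
source sequence and plants a copy of its central segment mutated at rate
`1 − identity` (every mutation changes the base, so expected identity is
exact), reverse-complemented when inverted.

**Gametologs.** Each gene starts from a random stop-free CDS, duplicated
and evolved independently along the X and Y branches for `t/2` each, where
`t` = target Ks, under an exact Kimura two-parameter site process with a
2:1 transition:transversion ratio (closed-form substitution probabilities,
not small-rate approximations). The Li/Pamilo–Bianchi estimator is
consistent for `t` under this process, so the expected estimated Ks equals
the target; codons that become stops are re-evolved. Targets above 2.0 are
rejected — the estimator's log corrections saturate there. Because all
sites evolve at one rate, expected Ka equals Ks; the generator makes no
attempt to emulate purifying selection, only synonymous divergence.

**Calls.** Per sample, depth at each site is Poisson(mean depth × CNV copy
factor), a site is called when depth ≥ 1, and the called base is the sample
haplotype base. Haplotypes carry two SNP layers: group-level variants
shared by all samples of a group (`group_snp_rates`, emulating clade stem
branches so call sets carry phylogenetic structure) and sample-specific
variants. No read-level simulation, sequencing error, or ancient-DNA
deamination is modelled; "called" is an input-level concept here, standing
in for an external genotyping pipeline's callability.

**Counts.** Gene × sample negative-binomial counts with group means
`base_mean × fold(gene, group)` and size parameter `dispersion`
(variance `μ + μ²/size`). Defaults `base_mean = 3000`,
`dispersion = 20` (biological CV ≈ 22%) describe a well-expressed testis
gene in a controlled same-tissue comparison; at 20 replicates per group
these give the CPM fold-ratio a relative SD of ~10%, which is the precision
the fold-recovery checks assume. Pooling-level library composition effects
are not simulated.

**What passing recovery tests show — and don't.** The generator's features
are clean by construction: no indels, no repeat families overlapping
feature boundaries, no GC or coverage bias, independent sites. Recovery at
the stated tolerances demonstrates the algorithms are correct on the model
they assume; real-assembly performance additionally depends on indels,
interspersed repeats and mapping artefacts that are out of scope here.

## Sequence classes (`equimsy.seqclass`)

Windows are anchored at 0, step, 2·step, … (defaults 100/20, matching
fixed-motif dot-plot semantics); a trailing partial window is ignored.
Exact-identity hits are found by hashing window strings; sub-1.0 identity
by a dense one-hot window comparison, chunked for memory. Windows
containing N never match at identity 1.0 (ambiguity is not identity); below
1.0 an N counts as a mismatch.

Ampliconic blocks: per-window off-diagonal hit counts thresholded at
`min_density` (default 1), qualifying windows merged when ≤ `merge_gap`
(default 2000 bp) apart. The copy estimate is 1 + the modal hit
multiplicity; the repeat unit is the modal hit lag, used to extract
consecutive copies for an unbiased mean pairwise divergence (computed from
the sequence, not from the thresholded hits). The density and merge-gap
defaults were chosen to recover planted arrays cleanly; they are the
module's own parameters, not published values.

Transposed segments: the cross-sequence scan cannot use two step-anchored
window grids directly — a diagonal whose offset is not a multiple of the
step would never have in-register window pairs. Candidate diagonals are
therefore seeded by exact shared 24-mers (offset voting, high-copy seeds
excluded), and each candidate diagonal is verified by a base-aligned
windowed identity scan on the y-side grid; qualifying-window runs merge
across gaps ≤ 1000 bp, runs shorter than `min_length` (5 kb) are dropped,
and the segment identity is recomputed base-by-base. The model is
indel-free: segments pair equal-length intervals.

Class partition paints precedence XY-array > PAR-transposed > ampliconic >
single-copy onto a per-base label array; the output is an exact partition
and fractions sum to 1. Overlapping same-precedence inputs merge with a
warning.

## Gametolog evolution (`equimsy.gametolog`)

Degeneracy classification counts synonymous single-base alternatives per
codon position under the standard code (0 → class 0; 1–2 → class 2, which
folds the isoleucine 3-fold site into class 2; 3 → class 4), the LWL/LPB
convention. Each sequence's codon is classified with its own degeneracy and
site counts averaged; a difference contributes ½ to each sequence's class.
Codon columns with gaps, N, or stops in either sequence are dropped before
counting (no fractional sites). The estimator implements the
Pamilo–Bianchi–Li forms (what PAML's yn00 reports for its "LPB93" output);
the combination formulas are in the module docstring. Saturation (any log
argument ≤ 0) raises an explicit undefined flag, never a silent NaN.

Strata are an exact dynamic-programming segmentation of the X-ordered Ks
series minimising within-segment SSE; ties break toward the smaller first
segment for determinism. `auto` mode grows the number of strata while each
extra boundary at least halves the residual SSE — an interpretable elbow
that picks 1 for flat series and the visually obvious count for plateaued
series. (`auto` is this package's own addition; published strata counts are typically chosen by inspection.)

Topology classification reports monophyly of Y-labelled tips and the number
of maximal Y-only clades (a single Y tip is monophyletic by convention);
unrooted trees must supply an outgroup tip.

The gene-conversion scan follows Sawyer: restrict to polymorphic columns;
per sequence pair, score +1 per matching column and −penalty per mismatch,
with the default penalty `(1−q)/q` for pair mismatch fraction `q`, chosen
so a random stretch has expected score zero and only match-dense tracts
accumulate score (the formula is documented in code). The maximal-scoring
run per pair is compared against a global null from `n_perm` (default
10,000) permutations of polymorphic-column order, one shared permutation
across pairs per iteration; `p = (1 + #{null max ≥ observed})/(1 + n_perm)`.
Results are deterministic for a fixed seed and invariant to input order.

`clock_date` is a deliberate simplification: a strict molecular clock
(`T = Ks/2r`, or proportional scaling through a calibration pair), not a
Bayesian relaxed-clock analysis. It provides plumbing-level dating only.

## Block diagnostics (`equimsy.popblocks`)

Mappability is 1/occurrences of each k-mer (default k = 100) counted on
both strands, computed with dual 64-bit rolling hashes (forward and
reverse-complement) for genome-scale speed; a brute-force occurrence
counting oracle guards correctness in tests. N-containing k-mers score 1
but are flagged — ambiguity must not masquerade as multi-mapping.

Blocks are fixed-width in reference coordinates (default 50 kbp; the
called-site restriction applies inside the block — a deliberate deviation
from a convention where blocks stretch to hold a fixed number of called
sites). Block coverage is the mean depth over called sites; blocks with no
called site are NaN, never 0, because zero is a biological signal
(deletion) and missing is not. Normalization divides by the sample's mean
raw coverage over blocks with mean mappability ≥ 0.9 (the same cutoff used
for 1 kbp block selection, kept as a single coherent threshold), which
fixes the mean of high-mappability blocks at exactly 1. Note the normalizer
includes any planted CNV blocks, so a ×2 duplication covering fraction `f`
of high-mappability blocks reads out at `2/(1+f)`; at realistic scale
(9.5 Mb reference, 200 kb duplication) this is ≈ 1.96.

Mismatch rates are non-reference called sites over called sites per
high-mappability block, averaged within sample groups. CNV flagging
reports maximal runs of ≥ 3 consecutive blocks above 1.5 or below 0.5
normalized coverage; these thresholds are operational defaults for the
synthetic diagnostics, not published values.

## Supermatrix and tree (`equimsy.blocktree`)

1 kbp blocks with mean mappability ≥ 0.9 (inclusive) are selected in
coordinate order; per sample, called positions contribute their called base
and uncalled positions N. Distances use pairwise deletion — sites with N in
either row are excluded per pair — because sample-level missingness would
otherwise erase most columns under complete-column deletion; models are
p-distance and Jukes–Cantor (`d = −¾ln(1−4p/3)`, an error rather than NaN
at `p ≥ 0.75`). Tree building is canonical Saitou–Nei neighbor joining with
deterministic lexicographic tie-breaking and negative branch lengths
clamped to zero (flagged). NJ replaces a maximum-likelihood search
deliberately: it is deterministic, exact on additive distances, and
sufficient for the split-level comparisons this package makes. Canonical
Newick output orders children by smallest descendant tip label with branch
lengths to 6 significant digits.

## Catalog and expression (`equimsy.catalog`)

The catalog summary counts genes and copies by origin category,
single/multi-copy status and expression profile, with per-Mb densities
rounded to one decimal, half away from zero (the printed-value convention).
The packaged fixture `data/table1_catalog_synthetic.tsv` transcribes
published marginal totals exactly but fills unnamed rows with placeholder
genes — it is marked synthetic in its name and header, and only
marginal-level conclusions should be drawn from it.

The annotation filter accepts a gene-model hit iff sequence similarity
≥ 80%, exon recovery ≥ 75%, exon order preserved and exon–intron boundaries
conserved, all thresholds inclusive; rejections carry their failed
criteria. The comparative matrix computes union size, species-specific
genes (non-absent in exactly one species) and the universal set
(non-absent, non-pseudogene everywhere) by plain set arithmetic.

Expression comparison computes `CPM = (count + c)/(libsize + c·G)·1e6` with
pseudocount `c = 0.5` over `G` genes, and the fold change of group CPM
means, flagged at ≥ 4-fold either way. Additive-pseudocount CPM was chosen
over trimmed-mean normalization because few-replicate designs make robust
normalization unstable; the pseudocount bounds fold estimates for
weakly-expressed genes (a planted 395-fold depletion of a
moderately-expressed gene reads out slightly low). No formal differential
test is reported — no single canonical test fits a two-replicate cross-species design, and fabricating one would misrepresent it.

## Problem sizes

The test and acceptance runs use: 120–200 kb references for dot-plot-scan
recovery, the full 125,171 bp planted transposition in a 160 kb reference,
a 9.5 Mb reference (a realistic full-assembly scale) for block
normalization and CNV recovery, 50 gametologs of 1200 codons for strata
recovery, 10,000 permutations for the planted conversion tract plus 200
null alignments at 300 permutations for the type-I check, and 20
RNA-seq replicates per group. These sizes were chosen so every stochastic
recovery band holds with a wide margin under the generator's model.
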