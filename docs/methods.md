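# Methods

This note records the models, conventions and numerical choices behind
mitokit, and what the synthetic-data tests do and do not establish.

## Records and coordinates

Internally all coordinates are 0-based half-open on the forward (J)
strand; GenBank I/O converts to and from 1-based inclusive positions, and
a `join()` across the file origin becomes a `wraps_origin` annotation.
The circular origin is treated as a file artifact throughout: spacer and
overlap accounting, gene-order extraction and composition statistics are
invariant under rotation (property-tested). The gene alphabet is the
37-gene insect mitochondrial complement; Leu/Ser isoacceptors are
disambiguated by the precedence explicit name > anticodon qualifier >
codon-recognised note, because annotation dialects differ in which they
provide. Unknown control-region spellings (D-loop, misc_feature notes)
map to `AT_rich` via a synonym table.

## Composition

Skews are (A−T)/(A+T) and (G−C)/(G+C); a zero denominator yields NaN
rather than a value. Ambiguity codes are excluded from all counts.
Codon-position composition is computed on the coding-sense PCG
concatenation in each gene's own frame, not on the genomic strand, since
position-specific base biases (T bias at position 2, G bias at position
1) are reading-frame properties. The genetic code is fixed to NCBI
translation table 5 (invertebrate mitochondrial). RSCU is count ×
family degeneracy / family total, with empty families reported as 0;
averages across genomes are arithmetic means of per-genome RSCU. Stop
inference uses length mod 3: a 1-residue overhang ending in T is the
partial stop `T-`, a 2-residue overhang ending in TA is `TA-` (completed
to TAA by polyadenylation in vivo); anything else is reported verbatim.

## Rearrangement inference

A gene order is a signed circular permutation anchored at cox1
(reflection is not considered: strand identity is meaningful). The event
vocabulary is transposition, in-place inversion, and reverse
transposition; each gene participates in at most one event, and
tandem-duplication–random-loss is deliberately out of vocabulary (it
surfaces as `unresolved_block` when the event budget is exceeded).

The optimisation target is the number of *relocated* genes: inference
finds a maximum *stationary backbone* — the largest set of genes forming
a common subsequence of the two orders, signs free — by dynamic
programming, then reads events off the complement. Backbone genes whose
strand differs are in-place inversions; relocated genes are
transpositions or reverse transpositions, merged into block events when
they stay contiguous, ordered and uniformly flipped. Ties between
equally large backbones are resolved in favour of genes that keep their
ancestral index. This tie-break is what makes the classic MQI pattern
(I(+) Q(−) M(+) → M(+) Q(+) I(+)) come out as "trnQ inverted in place,
trnM and trnI transposed around it" rather than as a two-move
description that relocates trnQ: the gene that never left its slot is
treated as the anchor. Counting events instead of relocated genes would
prefer the two-move description; the relocated-gene objective matches
how the rearrangement literature narrates these hotspot states.

Correctness is checked two ways: replaying the inferred events on the
reference must reproduce the query exactly, and the relocated-gene count
must equal exhaustive search over all stationary-backbone subsets — run
over every signed permutation of up to 4 genes in the test suite and up
to 6 genes (46,080 states) by `scripts/oracle_sweep.py`.

## Distances and saturation

The GTR generator is built from exchangeabilities (GT ≡ 1) and
stationary frequencies, normalised so that the expected rate over the
non-invariant mixture is 1; rate heterogeneity uses k = 4
mean-preserving discrete-gamma categories (category means via the
regularised incomplete gamma function) plus a point mass at rate 0 with
weight p_inv. Transition matrices come from the symmetrised
eigendecomposition. The pairwise distance maximises the likelihood of
the 4×4 site-pattern counts (pairwise deletion of gaps/ambiguity) by
bounded scalar search on [1e−9, 10] to xatol 1e−8; distances at the cap
are flagged saturated. In the equal-frequency, equal-rate, α→∞, p_inv=0
limit this reproduces the Jukes–Cantor closed form −(3/4)·ln(1−4p/3) to
well under 1e−3 (tested on a grid p = 0.05…0.70).

Model fitting maximises the sum of pairwise profile log-likelihoods
(each pair's distance optimised inside the objective) over
(log exchangeabilities, log α, logit p_inv) with empirical base
frequencies, by Nelder–Mead from two fixed starts, each polished by
restarting the simplex from the incumbent until the objective stops
improving (the α/p_inv ridge is nearly flat, and a single simplex run
can terminate far up the ridge); for large taxon sets the pair list is
subsampled (seeded) to at most 60 pairs to keep the composite likelihood
tractable. α and p_inv are partially confounded in pairwise fits —
recovered α absorbs some invariant-site signal, and replicate-to-
replicate spread of α̂ at 20 taxa × 10 kb is roughly ±0.1 around a value
slightly below truth — but on the standard recovery configuration the α
estimate lands within 25% of truth. One model is estimated per partition and then held fixed for
all pairwise distances in it, mirroring standard practice of selecting a
single model per data block.

The saturation screen computes the Pearson correlation (Spearman
available) between the lower triangles of the corrected and p-distance
matrices per partition, and flags partitions below a configurable
threshold (default 0.9) *or* in the bottom ranks (default 3); the
rank-based rule surfaces the fastest partitions even when everything
correlates well. Partitions with fewer than three usable pairs or
constant distances are excluded with a warning — note that a partition
saturated so badly that every corrected distance hits the cap becomes
constant and is excluded rather than flagged.

A caution from testing: correcting distances with a badly mis-specified
single model (e.g. protein-coding frequencies applied to a mixed
PCG+RNA supermatrix with a small α) can distort deep distances enough to
break tree recovery even when uncorrected distances succeed. The
pipeline therefore always estimates the model from the data being
analysed.

## Supermatrices

Genes concatenate in a fixed canonical order (PCGs alphabetical, then
tRNAs, then rRNAs), recorded in the supermatrix's gene-span metadata.
PCG alignments must be frame-0 with whole codons; `trim_to_frame` drops
the 1–2 trailing columns left by partial stop codons before
concatenation. The P12 variants drop every third position (the emitted
charset stride is then `\2`, since the retained positions interleave);
the exc3genes variants drop atp8, nad4l and nad6 entirely. Missing taxa
are padded with `-`. Block counts follow from the rule: 63 (13×3 + 22 +
2), 50, 54 and 44 for the four variants.

## Trees

Neighbor joining is implemented directly so that ties in the Q criterion
are broken deterministically (lexicographic pair order, clusters
labelled by their smallest leaf) and negative branch estimates are
clamped to zero with the deficit moved to the sibling. NJ rather than
ML/Bayesian inference is a deliberate scope choice: clade-recovery
checks on synthetic data need a consistent, fast, deterministic
estimator, not a full inference stack. Monophyly is evaluated after
rerooting on the outgroup; singleton sets are monophyletic by
convention. Robinson–Foulds counts bipartitions present in exactly one
tree and is cross-checked against dendropy's implementation.

## Synthetic data generator

The generator emulates the statistical structure of a small sawfly-type
mitogenome study; defaults are study conditions, not tuning knobs:

- **Tree.** Yule (pure birth), 20 ingroup taxa, scaled to 0.3
  substitutions/site root-to-tip at relative rate 1; one backbone leaf
  is expanded into a planted 4-taxon clade (clade depth capped at a
  quarter of the tree depth), and an outgroup attaches below a new root
  on a long branch.
- **Model.** GTR+Γ+I shared across partitions: exchangeabilities
  (AC,AG,AT,CG,CT,GT) = (1.5, 8, 1.5, 1, 10, 1) — transition-heavy, as
  in mitochondrial DNA — with α = 0.5 and p_inv = 0.15.
- **Composition.** Coding-sense stationary frequencies per gene class
  and strand; PCGs ≈ 81.5% AT with T-skew, RNAs ≈ 85% AT, control
  region ≈ 92% AT. N-strand PCGs are more T-rich in coding sense than
  J-strand ones, so the assembled forward strand ends up mildly A-skewed
  (≈ +0.01 to +0.03) while the pooled PCG partition is T-skewed
  (≈ −0.11): the two-sided skew pattern real sawfly genomes show.
  Rejection of stop codons during PCG simulation slightly depletes
  pos-1 T and pos-2 A, which is why realized position-specific skews
  (pos-2 T bias, pos-1 G bias) emerge without being imposed.
- **Rates.** Codon-position multipliers (1.0, 0.6, 20): third positions
  saturate at the default tree depth. Three fast-gene analogues (atp8,
  nad4l, nad6) carry an extra ×2.5; RNAs evolve at ×0.8.
- **Genes.** Realistic per-gene lengths (~15.5 kb genomes at scale 1);
  PCGs get a fixed ATN start and a TAA stop, with planted partial stops
  on cob (`T-`) and nad4 (`TA-`); internal stop codons are removed by
  re-evolving offending codon columns (codon-level rejection). tRNA
  lengths are drawn from 60–71 bp; no secondary structure is simulated.
- **Assembly.** Genes are laid on the ring in the ancestral
  pancrustacean order — clade members instead receive the derived
  MQI + ANS1ERF arrangement — with sparse random spacers (zero with
  probability 0.5, else 1–12 bp) and an A+T-rich region of 600–1000 bp
  after rrnS. With default settings this yields ~110–130 bp of
  intergenic spacer at ~17–20 locations per genome.
- **Determinism.** All randomness flows from one integer seed through
  named substreams; fixed seed ⇒ byte-identical files.

What the generator does *not* emulate: indels and alignment uncertainty
(alignments are emitted gap-free; gap handling is tested with separately
mutated inputs), tRNA/rRNA secondary structure, gene overlaps (spacers
are non-negative), within-gene composition heterogeneity, and
among-lineage compositional non-stationarity. Passing recovery tests on
these data therefore show the pipeline's machinery is correct and
consistent, not that real data meet its assumptions.

## Problem sizes in the standard runs

The test suite simulates at full genome scale for composition and
recovery checks (20 taxa, ~15.5 kb, 20-seed clade-recovery sweep); the
acceptance script runs the same sweep at half gene lengths and reports
every quantity it computes. Model fits use at most 40–60 subsampled
pairs and capped Nelder–Mead iterations; these sizes are the package's
standard configuration for a single-CPU run and are recorded in the
emitted JSON alongside each value.

## Known limitations

- Pairwise composite-likelihood model estimation is statistically less
  efficient than tree-based ML and confounds α with p_inv; only α is
  held to a recovery tolerance.
- The rearrangement model assumes each gene moves at most once between
  the two orders compared; histories with repeated movement of the same
  gene collapse to their net effect, and duplication/loss events are out
  of vocabulary.
- The CLI's saturation stage fits one model per pooled partition; very
  short partitions (single tRNAs) are better pooled, as the pipeline
  does, than screened individually.
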