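# Methods

## Coordinate projection by syntenic interpolation

The model assumes conserved synteny: between two alignable anchor blocks,
the order of loci is preserved across species, so an unalignable position
can be mapped by transferring its relative position within the flanking
inter-anchor gap. Anchor blocks are ungapped aligned segments between two
assemblies, stored 0-based half-open in forward-strand coordinates with
the orientation of the target segment recorded as a strand. Inside a block
the mapping is base-wise proportional; between blocks the fraction
`(x − up.end) / (down.start − up.end)` on the source side is applied to the
target-side gap. Reversed-orientation flank pairs interpolate with the
target axis reversed. Interpolated fractions are rounded half-to-even —
deterministic and unbiased over an ensemble of queries.

Projection is refused (rather than extrapolated) when the flanks are
one-sided (chromosome ends), when the two flanking blocks disagree on
target chromosome or orientation, or when their target intervals are not
collinear. Refusals surface as "unprojectable" results rather than errors
in all higher-level operations.

### The anchor-distance score

Confidence decays exponentially with the distance to the nearest flanking
anchor edge:

    f(d) = exp(−d / (g·s)),   s = −d_h / (g·log 0.5)

`g` is the genome size of the species in which the distance is measured
and `d_h` the *distance half-life*, the distance at which `f` = 0.5.
Because `g·s = d_h / ln 2`, the score simplifies to `f(d) = 2^(−d/d_h)`
and is independent of genome size; the scaling factor is kept in the API
because it is how the parameterization is conventionally written.

`d_h` defaults to 10,000 bp. The value is a unit-bearing design choice,
exposed as `--half-life` everywhere: with `d_h` = 10 kb, a path score of
0.99 corresponds to a summed anchor distance of `10000·log₂(1/0.99)` ≈
145 bp, which is what makes the 0.99 conservation threshold (below) mean
"on or within ~150 bp of an anchor". Users comparing genomes with very
different anchor densities may reasonably halve or double it; the score is
monotone in `d/d_h`, so rankings within a run are unaffected.

### Bridging species and the shortest path

The species graph has one node per species and a directed edge wherever a
pairwise anchor set exists. A path projects the query stepwise; each step
contributes the anchor distance measured in the species the step leaves
from (the terminal species contributes nothing — its coordinate is the
interpolation output, which makes a two-node path score equal the single
pairwise score). The path score is `∏ᵢ 2^(−dᵢ/d_h) = 2^(−Σdᵢ/d_h)`, its
length `l_p = 1 − score`, and the optimum minimizes `l_p`, i.e. the summed
distance.

The optimum is found with Dijkstra's algorithm over accumulated distance,
with one label per species. Because the coordinate reached in an
intermediate species depends on the path taken to it, the edge weights are
path-dependent and this single-label search is a greedy strategy, not a
guaranteed global optimum. The package therefore ships an exhaustive
simple-path enumerator (`enumerate_paths_project`, graphs ≤ 8 nodes); on
hundreds of seeded coordinate-consistent fixtures the two agree exactly,
which is the regime the method is designed for (anchors that are mutually
consistent up to local scale distortion). Ties between equal-score paths
are broken by fewer nodes, then lexicographic species order, in both
implementations.

Numerical notes: scores are computed in closed form from the summed
distance (no repeated multiplication), agree with the per-step product to
1e-12 relative, and distances are exact integers until the final
exponential.

## Conservation classes

A query element is **DC** if its interval overlaps ≥ 1 bp of a direct
source–target anchor block; otherwise its midpoint is projected through
the graph and the element is **IC** if the score strictly exceeds the
threshold (default 0.99) and **NC** otherwise, including unprojectable
queries. The three labels partition any input set, and raising the
threshold can only move elements IC → NC. The midpoint is used because the
score is defined on a single reference point; an `endpoints` mode (project
both ends, keep the better score) exists for long elements. Overlap of the
projected point with a target-species peak set is emitted as an annotation
column only — it never affects the label, keeping the classification a
pure function of the anchors.

## Epigenomic profile comparison

Regions (typically regulatory-block TADs) are tiled with fixed 1-kb
windows; a terminal partial window is kept iff it is at least half a
window wide, so arbitrary region lengths bin deterministically. Window
centers are projected; the target signal is read from the 1-kb bin of the
*fixed target grid* that contains the projected point (not a window
centered on it), mirroring how a binned target track is actually indexed.

Coverage is compared on quantiles: each species' per-bin means are
replaced by average-tie ranks divided by the bin count, making the
comparison invariant under any strictly monotone transform of either
track — library size, dynamic range and background level drop out. A bin
pair is *mutually enriched* when both quantiles reach the enrichment
quantile `q_e` (default 0.8, matching the "signal ≥ 80th percentile"
convention for enhancer-ensemble analysis; the appropriate value for other
marks is data-dependent and exposed as `--enrichment-quantile`),
source-/target-specific when only one does. The log₂ ratio of quantiles
(floored at ε = 0.01 before division) is capped to [−1, 1]; amplitude is
`max(q_source, q_target)¹⁰`, a display weight that suppresses
low-signal bins.

A consequence of rank quantiles worth knowing: thresholding at `q_e`
labels exactly the top `1 − q_e` fraction of bins per species, whatever
the signal. Planted-domain recovery is therefore crisp only when true
enrichment covers at most that fraction (high sensitivity, near-zero
background) and specific-domain purity is crisp when it covers at least
that fraction; the test fixtures are constructed on each side of this
boundary deliberately.

Association tests are Fisher's exact test (two-sided, hypergeometric
tail): shared enrichment × direct alignability of the source bin center,
and target-bin enrichment × membership in projected enhancer ensembles.
Tables with an empty margin are flagged degenerate rather than
interpreted. Odds ratios are the sample value `ad/bc` (∞ when only `bc` is
zero, undefined for 0/0).

## The synthetic fixture generator

The simulator emulates the projection setting, not genomes: a master
coordinate axis stands for the ancestral collinear layout, and each
species gets a strictly increasing piecewise-linear map from master to
species coordinates (segment length 50 kb, per-segment scale = global
scale × lognormal jitter, default σ = 0.1). Default species scales 1×,
1.5× and 2× mirror the roughly two-fold size difference of orthologous
TADs between zebrafish and mouse. Anchors are placed once on the master
axis as a jittered lattice at the highest per-pair density (default
0.1/kb, widths 20–60 bp); each pair keeps an independent subset (thinning
to its own density, then dropout), so a bridging species can be given much
denser anchors to both endpoints than they share directly. Optional
inversions mark blocks '−' purely to exercise the unprojectable pathway.
The exact maps are retained as a `TruthMap` oracle, so projection error
can be measured without circularity.

Signal tracks are Poisson counts over 100-bp steps (background mean 5),
with planted rectangular domains at `snr ×` background (default 4); shared
domains occupy truth-corresponding coordinates in both species. The
marginal coverage distribution is deliberately unrealistic — the
comparator is rank-based, so only the ordering matters, and a Poisson
step function orders exactly like real coverage would at matched SNR.

What the fixtures do *not* emulate: rearrangements other than single-block
inversions, lineage-specific insertions that break the shared master axis,
chromosome fissions (single-chromosome genomes), mappability artifacts,
and replicate-level assay noise. Passing tests therefore demonstrate the
correctness of the algorithms under conserved synteny, not performance on
real genome pairs; genome-wide figures (e.g. the fold reduction in anchor
distance achievable by bridging) depend on real alignment densities and
are only qualitatively reproduced here (≥ 5× on the sparse-direct /
dense-bridge fixture).

## Problem sizes and defaults used in the shipped checks

The test fixtures use 0.2–1 Mb master axes (hundreds of anchors and 1-kb
bins, 500 random projections for the Dijkstra/enumeration comparison), the
Fisher implementation is verified against exact-arithmetic enumeration on
every 2×2 table with margins ≤ 30, and planted-domain recovery uses SNR 4
with shared domains covering ~15% of bins. These sizes exercise every code
path while keeping the whole suite fast; all of them scale up by changing
the fixture configs.

## Known limitations

- Interval projection is endpoint-based; an interval spanning an inversion
  or a split is reported unprojectable rather than decomposed.
- One-sided flanks are never extrapolated; queries beyond the outermost
  anchor of a chromosome are unprojectable by design.
- Dijkstra's one-label-per-species state is greedy under path-dependent
  coordinates (see above); use the enumerator to audit small graphs.
- Quantile normalization is pairwise only; comparing more than two species
  requires a common reference or repeated pairwise runs.
- Chain parsing expects the reference ('t') side on the '+' strand, as
  UCSC chains are emitted.
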