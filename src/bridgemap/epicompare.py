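"""Cross-species epigenomic profile comparison over projected bins.

Regions of interest in the source genome (typically regulatory-block TADs)
are split into fixed-width windows (default 1 kb); each window's center is
projected to the target genome with the bridging-species approach, and the
signal of the enclosing target window on the fixed 1-kb grid is retrieved.
Coverage in each species is represented as empirical quantiles after
quantile normalization of the two distributions, so the comparison is
invariant to monotone differences between the two assays. Each bin pair is
then categorized (mutually enriched / source-specific / target-specific /
neither) by thresholding both quantiles, annotated with a capped log2
signal ratio in [-1, 1] and a signal amplitude max(q)^10, and flagged as
alignable when the source bin center overlaps a direct alignment.
Enrichment contrasts (shared signal vs alignability; target enrichment in
vs out of projected ensembles) are tested with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .genome_model import AnchorSet, GenomicInterval, SignalTrack
from .projection import ScoringParams, SpeciesGraph, shortest_path_project

__all__ = [
    "Bin",
    "BinComparison",
    "EnrichmentTest",
    "bin_regions",
    "quantile_transform",
    "compare_bins",
    "compare_regions",
    "fisher_exact_2x2",
    "shared_enrichment_by_alignability",
    "ensemble_enrichment",
]

DEFAULT_BIN_SIZE = 1000
DEFAULT_ENRICH_Q = 0.8   # enrichment quantile threshold (>= 80th percentile)
DEFAULT_RATIO_FLOOR = 0.01
DEFAULT_RATIO_CAP = 1.0

Category = Literal[
    "mutually-enriched", "source-specific", "target-specific",
    "neither", "unprojectable",
]


@dataclass(frozen=True)
class Bin:
    """One fixed-width window with its region of origin and center."""

    chrom: str
    start: int
    end: int
    region_name: str | None = None

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class BinComparison:
    """Comparison of one source bin with its projected target bin."""

    source_bin: Bin
    target_chrom: str | None
    target_start: int | None
    target_end: int | None
    q_source: float
    q_target: float
    category: Category
    ratio: float
    amplitude: float
    alignable: bool
    projection_score: float = 0.0


@dataclass(frozen=True)
class EnrichmentTest:
    """A 2x2 contingency table with Fisher's exact test result.

    ``table`` rows are the first factor, columns the second. ``degenerate``
    marks tables with an empty margin, for which the test is uninformative
    (p = 1, odds ratio undefined).
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Binning and normalization
# ---------------------------------------------------------------------------


def bin_regions(
    regions: Iterable[GenomicInterval], bin_size: int = DEFAULT_BIN_SIZE
) -> list[Bin]:
    """Tile each region with consecutive fixed-width windows.

    The final partial window is kept iff it is at least half the bin width;
    a region shorter than half the bin width yields no bins.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    bins: list[Bin] = []
    half = bin_size / 2
    for region in regions:
        pos = region.start
        while pos + bin_size <= region.end:
            bins.append(Bin(region.chrom, pos, pos + bin_size, region.name))
            pos += bin_size
        remainder = region.end - pos
        if remainder >= half and remainder > 0:
            bins.append(Bin(region.chrom, pos, region.end, region.name))
    return bins


def quantile_transform(track: SignalTrack, bins: Sequence[Bin]) -> np.ndarray:
    """Per-bin mean coverage replaced by its empirical quantile rank.

    Ranks are averaged over ties and divided by the number of bins, so the
    output lies in (0, 1] and is uniform up to ties; any strictly monotone
    transform of the signal leaves it unchanged.
    """
    if not bins:
        raise ValueError("no bins to transform")
    values = _bin_means(track, bins)
    return stats.rankdata(values, method="average") / len(values)


def _bin_means(track: SignalTrack, bins: Sequence[Bin]) -> np.ndarray:
    values = np.empty(len(bins))
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        by_chrom.setdefault(b.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        starts = np.array([bins[i].start for i in idx])
        ends = np.array([bins[i].end for i in idx])
        values[idx] = track.means(chrom, starts, ends)
    return values


def compare_bins(
    q_source: float,
    q_target: float,
    enrich_q: float = DEFAULT_ENRICH_Q,
    cap: float = DEFAULT_RATIO_CAP,
    floor: float = DEFAULT_RATIO_FLOOR,
) -> tuple[Category, float, float]:
    """Category, capped log2 ratio and amplitude for one quantile pair.

    Category thresholds both quantiles at ``enrich_q``; the ratio is
    log2(max(q_source, floor) / max(q_target, floor)) clamped to
    [-cap, cap]; the amplitude is max(q_source, q_target) ** 10.
    """
    for q in (q_source, q_target):
        if not 0 <= q <= 1:
            raise ValueError(f"quantile {q} outside [0, 1]")
    s_enriched = q_source >= enrich_q
    t_enriched = q_target >= enrich_q
    if s_enriched and t_enriched:
        category: Category = "mutually-enriched"
    elif s_enriched:
        category = "source-specific"
    elif t_enriched:
        category = "target-specific"
    else:
        category = "neither"
    ratio = math.log2(max(q_source, floor) / max(q_target, floor))
    ratio = max(-cap, min(cap, ratio))
    amplitude = max(q_source, q_target) ** 10
    return category, ratio, amplitude


# ---------------------------------------------------------------------------
# Region comparison
# ---------------------------------------------------------------------------


def _grid_bin(pos: int, bin_size: int, chrom_length: int) -> tuple[int, int]:
    """The fixed-grid window containing ``pos``, clipped to the chromosome."""
    start = (pos // bin_size) * bin_size
    return start, min(start + bin_size, chrom_length)


def compare_regions(
    regions: Iterable[GenomicInterval],
    track_source: SignalTrack,
    track_target: SignalTrack,
    graph: SpeciesGraph,
    source_species: str,
    target_species: str,
    direct_anchor_set: AnchorSet | None = None,
    params: ScoringParams | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    enrich_q: float = DEFAULT_ENRICH_Q,
    cap: float = DEFAULT_RATIO_CAP,
    floor: float = DEFAULT_RATIO_FLOOR,
) -> tuple[list[BinComparison], dict[str, float]]:
    """Compare source and target signal over projected region bins.

    Splits the regions into bins, projects each bin center through the
    species graph, reads the target signal from the enclosing fixed-grid
    target window, quantile-normalizes both per-bin signal distributions,
    and emits one :class:`BinComparison` per bin (category "unprojectable"
    where no path exists). The second return value maps region name to its
    fraction of mutually enriched bins among projectable ones — the shared
    signal ordering key.

    ``direct_anchor_set`` defaults to the graph's direct (source, target)
    edge and drives the ``alignable`` flag (bin center inside a direct
    alignment block).
    """
    params = params or ScoringParams()
    if direct_anchor_set is None:
        direct_anchor_set = graph.anchor_set(source_species, target_species)
    bins = bin_regions(regions, bin_size)
    if not bins:
        return [], {}
    q_source = quantile_transform(track_source, bins)
    target_assembly = graph.assemblies[target_species]

    projections = [
        shortest_path_project(graph, source_species, target_species,
                              b.chrom, b.center, params)
        for b in bins
    ]
    proj_idx = [i for i, p in enumerate(projections) if p.projectable]
    target_bins: dict[int, tuple[str, int, int]] = {}
    for i in proj_idx:
        p = projections[i]
        start, end = _grid_bin(p.pos, bin_size,
                               target_assembly.chrom_lengths[p.chrom])
        target_bins[i] = (p.chrom, start, end)
    # quantile-normalize the retrieved target signal against itself so both
    # per-bin distributions are uniform and comparable
    q_target = np.full(len(bins), np.nan)
    if proj_idx:
        tbins = [Bin(*target_bins[i]) for i in proj_idx]
        q_target[proj_idx] = quantile_transform(track_target, tbins)

    comparisons: list[BinComparison] = []
    for i, b in enumerate(bins):
        alignable = bool(
            direct_anchor_set is not None
            and direct_anchor_set.block_at(b.chrom, b.center) is not None
        )
        p = projections[i]
        if not p.projectable:
            comparisons.append(
                BinComparison(b, None, None, None, float(q_source[i]),
                              float("nan"), "unprojectable", float("nan"),
                              float("nan"), alignable, 0.0)
            )
            continue
        tchrom, tstart, tend = target_bins[i]
        category, ratio, amplitude = compare_bins(
            float(q_source[i]), float(q_target[i]), enrich_q, cap, floor
        )
        comparisons.append(
            BinComparison(b, tchrom, tstart, tend, float(q_source[i]),
                          float(q_target[i]), category, ratio, amplitude,
                          alignable, p.score)
        )

    summary: dict[str, float] = {}
    by_region: dict[str, list[BinComparison]] = {}
    for c in comparisons:
        by_region.setdefault(c.source_bin.region_name or ".", []).append(c)
    for name, cs in by_region.items():
        projectable = [c for c in cs if c.category != "unprojectable"]
        shared = sum(c.category == "mutually-enriched" for c in projectable)
        summary[name] = shared / len(projectable) if projectable else 0.0
    return comparisons, summary


# ---------------------------------------------------------------------------
# Fisher's exact tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> EnrichmentTest:
    """Two-sided Fisher's exact test of the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one. The
    odds ratio is the sample value a*d / (b*c); inf when only b*c is zero,
    nan for the doubly degenerate 0/0 case.
    """
    table = ((int(a), int(b)), (int(c), int(d)))
    for row in table:
        for x in row:
            if x < 0:
                raise ValueError(f"negative count {x} in contingency table")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    degenerate = min(a + b, c + d, a + c, b + d) == 0
    return EnrichmentTest(table, odds, float(p), degenerate)


def shared_enrichment_by_alignability(
    bin_comparisons: Sequence[BinComparison],
) -> EnrichmentTest:
    """Is shared (mutually enriched) signal associated with alignability?

    Builds the 2x2 table of (alignable vs non-alignable) x (mutually
    enriched vs not) over projectable bins and applies Fisher's exact test.
    An empty margin (e.g. no alignable bin at all) is flagged degenerate.
    """
    usable = [c for c in bin_comparisons if c.category != "unprojectable"]
    if not usable:
        raise ValueError("no projectable bin comparisons")
    a = sum(c.alignable and c.category == "mutually-enriched" for c in usable)
    b = sum(c.alignable and c.category != "mutually-enriched" for c in usable)
    c2 = sum((not c.alignable) and c.category == "mutually-enriched" for c in usable)
    d = sum((not c.alignable) and c.category != "mutually-enriched" for c in usable)
    return fisher_exact_2x2(a, b, c2, d)


def ensemble_enrichment(
    ensembles: Iterable[GenomicInterval],
    signal_target: SignalTrack,
    graph: SpeciesGraph,
    source_species: str,
    target_species: str,
    params: ScoringParams | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    enrich_q: float = DEFAULT_ENRICH_Q,
) -> EnrichmentTest:
    """Is target signal enriched inside projected source ensembles?

    Projects each ensemble's endpoints to the target genome; target-genome
    grid bins falling inside a projected ensemble are "inside". Bins are
    "enriched" when their signal quantile (over all target grid bins) is
    >= ``enrich_q``. Fisher's exact test on the resulting 2x2 table.
    """
    params = params or ScoringParams()
    target_assembly = graph.assemblies[target_species]
    projected: list[tuple[str, int, int]] = []
    for ens in ensembles:
        left = shortest_path_project(graph, source_species, target_species,
                                     ens.chrom, ens.start, params)
        right = shortest_path_project(graph, source_species, target_species,
                                      ens.chrom, ens.end - 1, params)
        if not (left.projectable and right.projectable):
            continue
        if left.chrom != right.chrom:
            continue
        lo, hi = sorted((left.pos, right.pos))
        projected.append((left.chrom, lo, hi + 1))
    if not projected:
        raise ValueError("no ensemble could be projected to the target genome")
    grid: list[Bin] = []
    for chrom, length in sorted(target_assembly.chrom_lengths.items()):
        for start in range(0, length - bin_size // 2 + 1, bin_size):
            grid.append(Bin(chrom, start, min(start + bin_size, length)))
    q = quantile_transform(signal_target, grid)
    inside = np.zeros(len(grid), dtype=bool)
    for i, b in enumerate(grid):
        center = b.center
        inside[i] = any(
            chrom == b.chrom and lo <= center < hi for chrom, lo, hi in projected
        )
    enriched = q >= enrich_q
    a = int(np.sum(inside & enriched))
    b_ = int(np.sum(inside & ~enriched))
    c = int(np.sum(~inside & enriched))
    d = int(np.sum(~inside & ~enriched))
    return fisher_exact_2x2(a, b_, c, d)
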