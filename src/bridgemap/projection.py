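"""Anchor-distance scoring, syntenic interpolation and bridged projection.

A genomic position that is not itself alignable between two species can,
under conserved synteny, still be projected by interpolating its relative
position between the two nearest alignable anchor blocks. The confidence of
such a projection decays exponentially with the distance to the nearest
anchor:

    f(d) = exp(-d / (g * s)),    s = -d_h / (g * log 0.5)

where ``g`` is the genome size and ``d_h`` the *distance half-life*, the
distance at which f returns 0.5. Substituting s shows f(d) = 2^(-d/d_h):
the genome size cancels, leaving a single interpretable parameter.

For distant species pairs, anchors are sparse; routing the projection
through one or more *bridging species* with denser pairwise alignments can
shorten the anchor distances. A path p through the species graph scores
prod_i f(d_i) and has length l_p = 1 - prod_i f(d_i); the best bridge
combination is the shortest path, found with Dijkstra's algorithm over
accumulated -log f. An exhaustive simple-path enumerator is provided as an
oracle for small graphs.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx

from .genome_model import AnchorBlock, AnchorSet, GenomeAssembly

__all__ = [
    "ScoringParams",
    "scaling_factor",
    "score_distance",
    "flanking_anchors",
    "project_point_pairwise",
    "path_score",
    "SpeciesGraph",
    "shortest_path_project",
    "enumerate_paths_project",
    "PairwiseProjection",
    "ProjectionResult",
    "Unprojectable",
]

DEFAULT_HALF_LIFE = 10_000.0  # bp; f(d_h) = 0.5


class Unprojectable(Exception):
    """Raised when a coordinate cannot be projected through a species pair."""


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the anchor-distance scoring function.

    d_h : distance half-life in bp — the query-to-anchor distance at which
    the score is 0.5. The per-species scaling factor
    s = -d_h / (g * log 0.5) is derived from it; g * s = d_h / ln 2 for
    every genome, which is why scores are genome-size independent.
    """

    d_h: float = DEFAULT_HALF_LIFE

    def __post_init__(self) -> None:
        if not self.d_h > 0:
            raise ValueError(f"distance half-life must be > 0, got {self.d_h}")

    def scaling_factor(self, g: float) -> float:
        return scaling_factor(self.d_h, g)


def scaling_factor(d_h: float, g: float) -> float:
    """Per-species scaling factor s = -d_h / (g * log 0.5)."""
    if not d_h > 0:
        raise ValueError(f"distance half-life must be > 0, got {d_h}")
    if not g > 0:
        raise ValueError(f"genome size must be > 0, got {g}")
    return -d_h / (g * math.log(0.5))


def score_distance(d: float, g: float, params: ScoringParams) -> float:
    """Anchor-distance score f(d) = exp(-d / (g * s)) in (0, 1].

    1.0 when the position overlaps an anchor (d = 0); 0.5 at d = d_h.
    Strictly decreasing in d and identical for every genome size g.
    """
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    s = scaling_factor(params.d_h, g)
    return math.exp(-d / (g * s))


def path_score(step_distances: Iterable[float], params: ScoringParams) -> tuple[float, float]:
    """Score of a projection path and its length l_p = 1 - score.

    The score is the product of per-step anchor-distance scores,
    prod_i 2^(-d_i/d_h) = 2^(-sum(d_i)/d_h); only the summed distance
    matters.
    """
    distances = list(step_distances)
    if not distances:
        raise ValueError("empty path")
    total = 0.0
    for d in distances:
        if d < 0:
            raise ValueError(f"distance must be >= 0, got {d}")
        total += d
    score = math.exp(-total * math.log(2.0) / params.d_h)
    return score, 1.0 - score


# ---------------------------------------------------------------------------
# Pairwise interpolation
# ---------------------------------------------------------------------------

ProjectionMode = Literal["inside-block", "interpolated", "one-sided"]


@dataclass(frozen=True)
class PairwiseProjection:
    """A single-species-pair projection of one position."""

    chrom: str
    pos: int
    anchor_distance: float
    mode: ProjectionMode
    upstream: AnchorBlock | None = None
    downstream: AnchorBlock | None = None


def flanking_anchors(
    anchor_set: AnchorSet, chrom: str, pos: int
) -> tuple[AnchorBlock | None, AnchorBlock | None]:
    """Nearest anchor ending at/before ``pos`` and nearest starting after it.

    Raises :class:`Unprojectable` if the chromosome carries no anchors at
    all. Either side may be None at chromosome extremes (one-sided).
    """
    if chrom not in anchor_set.source:
        raise ValueError(
            f"unknown chromosome {chrom!r} for {anchor_set.source.species_id!r}"
        )
    inside = anchor_set.block_at(chrom, pos)
    if inside is not None:
        return (inside, inside)
    up, down = anchor_set.flanking(chrom, pos)
    if up is None and down is None:
        raise Unprojectable(
            f"no anchors on {chrom} for pair {anchor_set.species_pair}"
        )
    return (up, down)


def _round_half_even(x: float) -> int:
    # banker's rounding: deterministic and unbiased over fixture ensembles
    return int(round(x))


def project_point_pairwise(
    anchor_set: AnchorSet, chrom: str, pos: int, params: ScoringParams
) -> PairwiseProjection:
    """Project one position through a single species pair by interpolation.

    Inside an anchor block the mapping is base-wise proportional within the
    block (anchor distance 0). Between blocks the relative position within
    the source inter-anchor gap is transferred to the target gap, and the
    anchor distance is the distance to the nearer of the two flanking inner
    edges. One-sided flanks (chromosome ends) and inconsistent flanks
    (different target chromosome, discordant strands, or non-collinear
    target order) raise :class:`Unprojectable` — no extrapolation is done.
    """
    source = anchor_set.source
    source.check_interval(chrom, pos, pos + 1)
    inside = anchor_set.block_at(chrom, pos)
    if inside is not None:
        frac = (pos - inside.start_a) / inside.width_a
        if inside.strand == "+":
            tpos = inside.start_b + _round_half_even(frac * inside.width_b)
        else:
            tpos = inside.end_b - _round_half_even(frac * inside.width_b)
        return PairwiseProjection(inside.chrom_b, tpos, 0.0, "inside-block",
                                  inside, inside)
    up, down = anchor_set.flanking(chrom, pos)
    if up is None and down is None:
        raise Unprojectable(
            f"no anchors on {chrom} for pair {anchor_set.species_pair}"
        )
    if up is None or down is None:
        raise Unprojectable(
            f"one-sided flanking anchors at {chrom}:{pos} for pair "
            f"{anchor_set.species_pair}"
        )
    if up.chrom_b != down.chrom_b or up.strand != down.strand:
        raise Unprojectable(
            f"inconsistent flanking anchors at {chrom}:{pos} for pair "
            f"{anchor_set.species_pair} (target chromosome or strand differs)"
        )
    src_gap = down.start_a - up.end_a
    frac = (pos - up.end_a) / src_gap
    if up.strand == "+":
        tgt_gap = down.start_b - up.end_b
        if tgt_gap < 0:
            raise Unprojectable(
                f"non-collinear flanking anchors at {chrom}:{pos} for pair "
                f"{anchor_set.species_pair}"
            )
        tpos = up.end_b + _round_half_even(frac * tgt_gap)
    else:
        # reversed orientation: the source gap maps to the target interval
        # between the downstream block's end and the upstream block's start
        tgt_gap = up.start_b - down.end_b
        if tgt_gap < 0:
            raise Unprojectable(
                f"non-collinear flanking anchors at {chrom}:{pos} for pair "
                f"{anchor_set.species_pair}"
            )
        tpos = up.start_b - _round_half_even(frac * tgt_gap)
    distance = float(min(pos - up.end_a, down.start_a - pos))
    tpos = min(max(tpos, 0), anchor_set.target.chrom_lengths[up.chrom_b] - 1)
    return PairwiseProjection(up.chrom_b, tpos, distance, "interpolated", up, down)


# ---------------------------------------------------------------------------
# Species graph and bridged projection
# ---------------------------------------------------------------------------


class SpeciesGraph:
    """Directed graph of species connected by available anchor sets.

    An edge (u, v) exists iff an AnchorSet with source u and target v was
    registered; reciprocal anchor sets give both directions.
    """

    def __init__(self, assemblies: Iterable[GenomeAssembly] = ()):
        self.assemblies: dict[str, GenomeAssembly] = {
            a.species_id: a for a in assemblies
        }
        self.edges: dict[tuple[str, str], AnchorSet] = {}

    def add_assembly(self, assembly: GenomeAssembly) -> None:
        self.assemblies[assembly.species_id] = assembly

    def add_anchor_set(self, anchor_set: AnchorSet) -> None:
        src, tgt = anchor_set.species_pair
        self.assemblies.setdefault(src, anchor_set.source)
        self.assemblies.setdefault(tgt, anchor_set.target)
        self.edges[(src, tgt)] = anchor_set

    @property
    def nodes(self) -> list[str]:
        return sorted(self.assemblies)

    def anchor_set(self, source: str, target: str) -> AnchorSet | None:
        return self.edges.get((source, target))

    def successors(self, species: str) -> list[str]:
        return sorted(t for (s, t) in self.edges if s == species)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ProjectionResult:
    """Outcome of a (possibly bridged) projection of one position.

    ``score`` = prod of per-step anchor-distance scores in [0, 1];
    ``path_length`` l_p = 1 - score. An unprojectable query yields score 0,
    empty path and chrom None.
    """

    chrom: str | None
    pos: int | None
    score: float
    path: tuple[str, ...]
    step_distances: tuple[float, ...]

    @property
    def path_length(self) -> float:
        return 1.0 - self.score

    @property
    def projectable(self) -> bool:
        return self.chrom is not None

    @property
    def total_distance(self) -> float:
        return float(sum(self.step_distances))


_UNPROJECTABLE = ProjectionResult(None, None, 0.0, (), ())


def shortest_path_project(
    graph: SpeciesGraph,
    source_species: str,
    target_species: str,
    chrom: str,
    pos: int,
    params: ScoringParams | None = None,
) -> ProjectionResult:
    """Project a position along the best bridging-species path (Dijkstra).

    Each traversed edge (u, v) projects the coordinate currently held in u
    through the (u, v) anchor set; the edge weight is the anchor distance of
    that step (equivalently -log f up to the constant ln2/d_h, so minimizing
    the summed distance minimizes the path length l_p). The coordinate
    reached in v is propagated along relaxed edges. Dijkstra keeps one label
    per species — the greedy strategy; the exhaustive enumerator below
    serves as its oracle on small graphs. Ties are broken by fewer path
    nodes, then lexicographic species order.

    Returns an unprojectable result (score 0, empty path) when no usable
    path exists.
    """
    params = params or ScoringParams()
    if source_species not in graph.assemblies:
        raise ValueError(f"unknown source species {source_species!r}")
    if target_species not in graph.assemblies:
        raise ValueError(f"unknown target species {target_species!r}")
    # label: (total_distance, n_nodes, path) per species; coordinate alongside
    best: dict[str, tuple[float, int, tuple[str, ...]]] = {}
    coord: dict[str, tuple[str, int]] = {source_species: (chrom, pos)}
    dist: dict[str, tuple[float, ...]] = {source_species: ()}
    start_key = (0.0, 1, (source_species,))
    best[source_species] = start_key
    heap: list[tuple[float, int, tuple[str, ...]]] = [start_key]
    settled: set[str] = set()
    while heap:
        total, n_nodes, path = heapq.heappop(heap)
        u = path[-1]
        if u in settled or best.get(u) != (total, n_nodes, path):
            continue
        settled.add(u)
        if u == target_species:
            tchrom, tpos = coord[u]
            score, _ = path_score(dist[u], params) if dist[u] else (1.0, 0.0)
            return ProjectionResult(tchrom, tpos, score, path, dist[u])
        uchrom, upos = coord[u]
        for v in graph.successors(u):
            if v in settled:
                continue
            aset = graph.edges[(u, v)]
            try:
                proj = project_point_pairwise(aset, uchrom, upos, params)
            except Unprojectable:
                continue
            cand = (total + proj.anchor_distance, n_nodes + 1, path + (v,))
            if v not in best or cand < best[v]:
                best[v] = cand
                coord[v] = (proj.chrom, proj.pos)
                dist[v] = dist[u] + (proj.anchor_distance,)
                heapq.heappush(heap, cand)
    return _UNPROJECTABLE


def enumerate_paths_project(
    graph: SpeciesGraph,
    source_species: str,
    target_species: str,
    chrom: str,
    pos: int,
    params: ScoringParams | None = None,
    max_nodes: int = 8,
) -> ProjectionResult:
    """Exhaustively evaluate every simple path and return the best result.

    Brute-force oracle for :func:`shortest_path_project`; refuses graphs
    with more than ``max_nodes`` species. Ties are broken the same way
    (fewer nodes, then lexicographic path order).
    """
    params = params or ScoringParams()
    if len(graph.assemblies) > max_nodes:
        raise ValueError(
            f"graph has {len(graph.assemblies)} nodes, oracle limit is {max_nodes}"
        )
    g = graph.to_networkx()
    if source_species not in g or target_species not in g:
        raise ValueError("source or target species not in graph")
    best: tuple[float, int, tuple[str, ...]] | None = None
    best_result: ProjectionResult | None = None
    for path in nx.all_simple_paths(g, source_species, target_species):
        cur_chrom, cur_pos = chrom, pos
        distances: list[float] = []
        ok = True
        for u, v in zip(path, path[1:]):
            try:
                proj = project_point_pairwise(
                    graph.edges[(u, v)], cur_chrom, cur_pos, params
                )
            except Unprojectable:
                ok = False
                break
            distances.append(proj.anchor_distance)
            cur_chrom, cur_pos = proj.chrom, proj.pos
        if not ok:
            continue
        key = (sum(distances), len(path), tuple(path))
        if best is None or key < best:
            best = key
            score, _ = path_score(distances, params)
            best_result = ProjectionResult(
                cur_chrom, cur_pos, score, tuple(path), tuple(distances)
            )
    if best_result is None:
        if source_species == target_species:
            return ProjectionResult(chrom, pos, 1.0, (source_species,), ())
        return _UNPROJECTABLE
    return best_result
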