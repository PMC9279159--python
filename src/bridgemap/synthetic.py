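"""Synthetic multi-species synteny and signal fixtures with known truth.

Emulates the projection setting end to end without any real sequence: a
shared *master coordinate* axis stands for the ancestral collinear layout;
each simulated species carries a strictly increasing piecewise-linear map
from master to species coordinates (its genome may be larger or smaller
overall, e.g. a 2x scale mirrors the roughly two-fold size difference of
orthologous regulatory-block TADs, with local jitter so inter-anchor
distortion is non-trivial). Anchor blocks are placed on the master axis and
realized in every species through its map; each species pair keeps an
independent random subset (dropout), so a "bridging" species can be given
much denser anchors to either endpoint than the endpoints share directly.
The exact master map is retained as a :class:`TruthMap` oracle for
projection error measurement, and paired signal tracks with planted
shared / species-specific enrichment domains provide ground truth for the
epigenome comparator. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .genome_model import AnchorBlock, AnchorSet, GenomeAssembly, SignalTrack
from .projection import SpeciesGraph

__all__ = [
    "SpeciesSpec",
    "SyntenyConfig",
    "TruthMap",
    "SyntenyFixture",
    "simulate_synteny",
    "truth_projection",
    "PlantedDomain",
    "SignalConfig",
    "SimulatedSignal",
    "simulate_signal",
    "build_species_graph",
]

CHROM = "chr1"  # simulated genomes are single-chromosome


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated species: label and overall genome-size scale factor."""

    species_id: str
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class SyntenyConfig:
    """Configuration of the synthetic synteny fixture.

    anchors_per_kb maps a species pair (either order) to its anchor density
    on the master axis; pairs absent from the map get default_density, and
    pairs absent from both carry no anchor set (no graph edge). dropout is
    the per-pair probability of omitting an individual anchor.
    scale_jitter_sd > 0 makes each species' master map piecewise linear
    with lognormal per-segment scales, so interpolation between anchors is
    approximate rather than exact.
    """

    seed: int = 0
    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("zeb", 1.0),
        SpeciesSpec("bridge", 1.5),
        SpeciesSpec("mus", 2.0),
    )
    master_length: int = 1_000_000
    default_density: float = 0.1           # anchors per kb of master axis
    anchors_per_kb: Mapping[frozenset[str], float] = field(default_factory=dict)
    dropout: float = 0.0
    dropout_per_pair: Mapping[frozenset[str], float] = field(default_factory=dict)
    anchor_width: tuple[int, int] = (20, 60)
    inversion_prob: float = 0.0
    scale_jitter_sd: float = 0.1
    segment_length: int = 50_000

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        for dens in self.anchors_per_kb.values():
            if not dens > 0:
                raise ValueError("anchor densities must be > 0")
        if not self.default_density > 0:
            raise ValueError("default_density must be > 0")
        if len({s.species_id for s in self.species}) != len(self.species):
            raise ValueError("duplicate species ids")

    def density_for(self, a: str, b: str) -> float:
        return self.anchors_per_kb.get(frozenset((a, b)), self.default_density)

    def dropout_for(self, a: str, b: str) -> float:
        return self.dropout_per_pair.get(frozenset((a, b)), self.dropout)


class TruthMap:
    """The exact monotone master -> species coordinate maps (the oracle)."""

    def __init__(self, master_length: int,
                 maps: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.master_length = master_length
        self._maps = maps  # species -> (master breakpoints, species coords)

    def species(self) -> list[str]:
        return sorted(self._maps)

    def forward(self, species: str, master_pos: float) -> float:
        """Species coordinate of a master position (exact, unrounded)."""
        mb, sc = self._maps[species]
        if not 0 <= master_pos <= self.master_length:
            raise ValueError(f"master position {master_pos} outside [0, "
                             f"{self.master_length}]")
        return float(np.interp(master_pos, mb, sc))

    def inverse(self, species: str, species_pos: float) -> float:
        """Master coordinate of a species position (exact, unrounded)."""
        mb, sc = self._maps[species]
        if not sc[0] <= species_pos <= sc[-1]:
            raise ValueError(
                f"position {species_pos} outside genome of {species!r}"
            )
        return float(np.interp(species_pos, sc, mb))

    def genome_length(self, species: str) -> int:
        return int(round(self._maps[species][1][-1]))


def truth_projection(truth_map: TruthMap, species_a: str, species_b: str,
                     pos: float) -> int:
    """Exact projection of a position from species_a to species_b.

    Composes the inverse map of a with the forward map of b; the oracle
    against which interpolation error is measured.
    """
    master = truth_map.inverse(species_a, pos)
    return int(round(truth_map.forward(species_b, master)))


@dataclass(frozen=True)
class SyntenyFixture:
    """Output of :func:`simulate_synteny`."""

    config: SyntenyConfig
    assemblies: dict[str, GenomeAssembly]
    anchor_sets: dict[tuple[str, str], AnchorSet]
    truth: TruthMap

    def graph(self) -> SpeciesGraph:
        return build_species_graph(self.assemblies.values(),
                                   self.anchor_sets.values())


def build_species_graph(assemblies: Iterable[GenomeAssembly],
                        anchor_sets: Iterable[AnchorSet]) -> SpeciesGraph:
    graph = SpeciesGraph(assemblies)
    for aset in anchor_sets:
        graph.add_anchor_set(aset)
    return graph


def _species_map(spec: SpeciesSpec, config: SyntenyConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_seg = max(1, int(np.ceil(config.master_length / config.segment_length)))
    master_bp = np.minimum(
        np.arange(n_seg + 1, dtype=float) * config.segment_length,
        config.master_length,
    )
    seg_lengths = np.diff(master_bp)
    if config.scale_jitter_sd > 0:
        jitter = rng.lognormal(0.0, config.scale_jitter_sd, size=n_seg)
    else:
        jitter = np.ones(n_seg)
    coords = np.concatenate([[0.0], np.cumsum(seg_lengths * spec.scale * jitter)])
    return master_bp, coords


def _master_anchors(density: float, config: SyntenyConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Anchor (start, end) intervals on the master axis: jittered lattice.

    Generated once at the highest per-pair density; sparser pairs keep a
    random subset, so anchors are shared master positions across pairs.
    """
    spacing = 1000.0 / density
    n = int(config.master_length / spacing)
    if n < 2:
        raise ValueError(
            f"anchor density {density}/kb yields {n} anchors on a "
            f"{config.master_length} bp master axis; need >= 2"
        )
    wmin, wmax = config.anchor_width
    centers = (np.arange(n) + 0.5) * spacing
    centers = centers + rng.uniform(-0.25 * spacing, 0.25 * spacing, size=n)
    widths = rng.integers(wmin, wmax + 1, size=n)
    starts = np.clip(np.round(centers - widths / 2), 0,
                     config.master_length - widths).astype(np.int64)
    ends = starts + widths
    # enforce source-side separation so every anchor survives validation
    for i in range(1, n):
        if starts[i] <= ends[i - 1]:
            shift = ends[i - 1] + 1 - starts[i]
            starts[i] += shift
            ends[i] += shift
    keep = ends <= config.master_length
    return np.stack([starts[keep], ends[keep]], axis=1)


def simulate_synteny(config: SyntenyConfig) -> SyntenyFixture:
    """Simulate assemblies, per-pair anchor sets and the truth map.

    Anchors live on the master axis per unordered species pair and are
    realized in each species through its monotone map; reciprocal anchor
    sets (both directions) are emitted for every pair. Deterministic for a
    fixed config.
    """
    rng = np.random.default_rng(config.seed)
    maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in config.species:
        maps[spec.species_id] = _species_map(spec, config, rng)
    truth = TruthMap(config.master_length, maps)
    assemblies = {
        sid: GenomeAssembly(sid, {CHROM: truth.genome_length(sid)})
        for sid in (s.species_id for s in config.species)
    }

    def realize(sid: str, m_start: int, m_end: int) -> tuple[int, int]:
        s = int(round(truth.forward(sid, m_start)))
        e = int(round(truth.forward(sid, m_end)))
        e = max(e, s + 1)
        length = assemblies[sid].chrom_lengths[CHROM]
        s = min(s, length - 1)
        e = min(max(e, s + 1), length)
        return s, e

    anchor_sets: dict[tuple[str, str], AnchorSet] = {}
    ids = [s.species_id for s in config.species]
    base_density = max(
        [config.default_density] + [config.density_for(a, b)
                                    for i, a in enumerate(ids)
                                    for b in ids[i + 1:]]
    )
    lattice = _master_anchors(base_density, config, rng)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            density = config.density_for(a, b)
            # shared master lattice thinned to this pair's density,
            # then per-pair dropout applied on top
            keep_prob = (density / base_density) * (1 - config.dropout_for(a, b))
            if keep_prob < 1:
                master = lattice[rng.random(len(lattice)) < keep_prob]
            else:
                master = lattice
            if len(master) < 2:
                raise ValueError(
                    f"pair ({a}, {b}) has {len(master)} anchors after "
                    f"dropout; need >= 2"
                )
            strands = np.where(
                rng.random(len(master)) < config.inversion_prob, "-", "+"
            )
            blocks_ab = []
            for (ms, me), strand in zip(master, strands):
                sa, ea = realize(a, int(ms), int(me))
                sb, eb = realize(b, int(ms), int(me))
                blocks_ab.append(AnchorBlock(CHROM, sa, ea, CHROM, sb, eb,
                                             str(strand)))
            anchor_sets[(a, b)] = AnchorSet(
                assemblies[a], assemblies[b], blocks_ab
            )
            anchor_sets[(b, a)] = AnchorSet(
                assemblies[b], assemblies[a],
                [blk.flipped() for blk in blocks_ab],
            )
    return SyntenyFixture(config, assemblies, anchor_sets, truth)


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

DomainKind = Literal["shared", "source-specific", "target-specific"]


@dataclass(frozen=True)
class PlantedDomain:
    """A rectangular enrichment domain on the master axis."""

    master_start: int
    master_end: int
    kind: DomainKind

    def __post_init__(self) -> None:
        if self.master_start >= self.master_end:
            raise ValueError("empty planted domain")


@dataclass(frozen=True)
class SignalConfig:
    """Paired-track simulation: Poisson background plus planted domains.

    snr is the fold enrichment of domain coverage over background; the
    marginal coverage distribution is irrelevant to the rank-based
    comparator, only the ordering it induces matters.
    """

    source_species: str
    target_species: str
    domains: tuple[PlantedDomain, ...] = ()
    background_mean: float = 5.0
    snr: float = 4.0
    step: int = 100

    def __post_init__(self) -> None:
        if not self.background_mean > 0:
            raise ValueError("background_mean must be > 0")
        if not self.snr >= 1:
            raise ValueError("snr must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")


@dataclass(frozen=True)
class SimulatedSignal:
    """Paired tracks plus ground truth for the comparator."""

    config: SignalConfig
    source_track: SignalTrack
    target_track: SignalTrack
    truth: TruthMap

    def domain_kind_at(self, species_pos: float, *, species: str | None = None
                       ) -> DomainKind | None:
        """Ground-truth domain kind at a source-species position (or None)."""
        species = species or self.config.source_species
        master = self.truth.inverse(species, species_pos)
        for dom in self.config.domains:
            if dom.master_start <= master < dom.master_end:
                return dom.kind
        return None


def _domain_active(kind: DomainKind, role: str) -> bool:
    return kind == "shared" or kind == f"{role}-specific"


def simulate_signal(
    signal_config: SignalConfig,
    truth_map: TruthMap,
    seed: int = 0,
    assemblies: Mapping[str, GenomeAssembly] | None = None,
) -> SimulatedSignal:
    """Simulate paired coverage tracks with planted enrichment domains.

    Coverage is emitted as Poisson counts over fixed ``step``-bp windows;
    windows inside an active domain draw from mean background_mean * snr.
    Shared domains occupy truth-corresponding coordinates in both species.
    """
    rng = np.random.default_rng(seed)
    for dom in signal_config.domains:
        if dom.master_end > truth_map.master_length:
            raise ValueError(
                f"domain {dom} extends past the master axis "
                f"({truth_map.master_length} bp)"
            )
    tracks: dict[str, SignalTrack] = {}
    for role in ("source", "target"):
        sid = getattr(signal_config, f"{role}_species")
        length = (assemblies[sid].chrom_lengths[CHROM] if assemblies
                  else truth_map.genome_length(sid))
        edges = np.arange(0, length + signal_config.step, signal_config.step)
        edges[-1] = min(edges[-1], length)
        edges = np.unique(edges)
        starts, ends = edges[:-1], edges[1:]
        means = np.full(len(starts), signal_config.background_mean)
        for dom in signal_config.domains:
            if not _domain_active(dom.kind, role):
                continue
            lo = truth_map.forward(sid, dom.master_start)
            hi = truth_map.forward(sid, dom.master_end)
            centers = (starts + ends) / 2
            means[(centers >= lo) & (centers < hi)] = (
                signal_config.background_mean * signal_config.snr
            )
        values = rng.poisson(means).astype(float)
        assembly = (assemblies[sid] if assemblies
                    else GenomeAssembly(sid, {CHROM: int(length)}))
        tracks[role] = SignalTrack(
            assembly,
            [(CHROM, int(s), int(e), v) for s, e, v in zip(starts, ends, values)],
        )
    return SimulatedSignal(signal_config, tracks["source"], tracks["target"],
                           truth_map)
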