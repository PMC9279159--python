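"""Genome assemblies, alignment anchors, intervals and signal tracks.

All coordinates are 0-based half-open (BED convention). Every downstream
module (projection, conservation classification, epigenome comparison)
consumes only the types defined here; file I/O for the supported plain-text
formats (chrom.sizes, anchor TSV, UCSC chain, BED, bedGraph) lives here too.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("bridgemap")


class FormatError(ValueError):
    """A malformed input file (bad line, inconsistent record, bad coordinate)."""


# ---------------------------------------------------------------------------
# Assemblies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """A genome assembly: a species label and its chromosome lengths.

    ``genome_size`` (the total assembly length ``g``) scales the
    anchor-distance scoring function in :mod:`bridgemap.projection`.
    """

    species_id: str
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError(f"assembly {self.species_id!r} has no chromosomes")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(
                    f"assembly {self.species_id!r}: chromosome {name!r} has "
                    f"non-positive length {length}"
                )

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        """Validate a half-open interval against this assembly."""
        if chrom not in self.chrom_lengths:
            raise ValueError(
                f"unknown chromosome {chrom!r} in assembly {self.species_id!r}"
            )
        if not (0 <= start < end <= self.chrom_lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds for "
                f"{self.species_id!r} (length {self.chrom_lengths[chrom]})"
            )


def read_chrom_sizes(path: str | Path, species_id: str | None = None) -> GenomeAssembly:
    """Read a UCSC chrom.sizes two-column TSV into a :class:`GenomeAssembly`.

    ``species_id`` defaults to the file's stem.
    """
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if name in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise FormatError(
                    f"{path}:{lineno}: non-positive length {length} for {name!r}"
                )
            lengths[name] = length
    if not lengths:
        raise FormatError(f"{path}: no chromosomes found")
    return GenomeAssembly(species_id or path.stem, lengths)


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchorBlock:
    """One collinear aligned block between two assemblies ("anchor point").

    ``strand`` is the orientation of the target interval relative to the
    source; both intervals are stored in forward-strand coordinates.
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (self.start_a < self.end_a and self.start_b < self.end_b):
            raise ValueError(f"inverted or empty interval in anchor block {self}")

    @property
    def width_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def width_b(self) -> int:
        return self.end_b - self.start_b

    def flipped(self) -> "AnchorBlock":
        """The same alignment viewed from the target side."""
        return AnchorBlock(
            self.chrom_b, self.start_b, self.end_b,
            self.chrom_a, self.start_a, self.end_a, self.strand,
        )


class _ChromIndex:
    """Sorted per-chromosome arrays over anchor blocks for flanking queries."""

    __slots__ = ("blocks", "starts", "ends")

    def __init__(self, blocks: list[AnchorBlock]):
        self.blocks = sorted(blocks, key=lambda b: b.start_a)
        self.starts = [b.start_a for b in self.blocks]
        self.ends = [b.end_a for b in self.blocks]


class AnchorSet:
    """A validated, indexed collection of anchor blocks for one species pair.

    Within each source chromosome the blocks are non-overlapping on the
    source side; overlaps in the input are resolved by keeping the longer
    block (a warning is logged for each dropped block).
    """

    def __init__(
        self,
        source: GenomeAssembly,
        target: GenomeAssembly,
        blocks: Iterable[AnchorBlock],
        *,
        validate: bool = True,
    ):
        self.source = source
        self.target = target
        by_chrom: dict[str, list[AnchorBlock]] = {}
        for blk in blocks:
            if validate:
                source.check_interval(blk.chrom_a, blk.start_a, blk.end_a)
                target.check_interval(blk.chrom_b, blk.start_b, blk.end_b)
            by_chrom.setdefault(blk.chrom_a, []).append(blk)
        self._index: dict[str, _ChromIndex] = {}
        for chrom, blks in by_chrom.items():
            blks.sort(key=lambda b: (b.start_a, -(b.end_a - b.start_a)))
            kept: list[AnchorBlock] = []
            for blk in blks:
                if kept and blk.start_a < kept[-1].end_a:
                    # source-side overlap: keep the longer block
                    if blk.width_a > kept[-1].width_a:
                        dropped, kept[-1] = kept[-1], blk
                    else:
                        dropped = blk
                    logger.warning(
                        "dropping source-overlapping anchor %s:%d-%d "
                        "(%s -> %s); longer block kept",
                        dropped.chrom_a, dropped.start_a, dropped.end_a,
                        source.species_id, target.species_id,
                    )
                else:
                    kept.append(blk)
            self._index[chrom] = _ChromIndex(kept)

    @property
    def species_pair(self) -> tuple[str, str]:
        return (self.source.species_id, self.target.species_id)

    def __len__(self) -> int:
        return sum(len(ix.blocks) for ix in self._index.values())

    def __iter__(self) -> Iterator[AnchorBlock]:
        for chrom in sorted(self._index):
            yield from self._index[chrom].blocks

    def chromosomes(self) -> list[str]:
        return sorted(self._index)

    def blocks_on(self, chrom: str) -> Sequence[AnchorBlock]:
        ix = self._index.get(chrom)
        return ix.blocks if ix else []

    def block_at(self, chrom: str, pos: int) -> AnchorBlock | None:
        """The block whose source interval contains ``pos``, if any."""
        ix = self._index.get(chrom)
        if ix is None or not ix.blocks:
            return None
        i = bisect_right(ix.starts, pos) - 1
        if i >= 0 and pos < ix.ends[i]:
            return ix.blocks[i]
        return None

    def overlapping(self, chrom: str, start: int, end: int) -> list[AnchorBlock]:
        """All blocks whose source interval overlaps [start, end)."""
        ix = self._index.get(chrom)
        if ix is None:
            return []
        lo = bisect_right(ix.ends, start)  # first block with end_a > start
        hi = bisect_left(ix.starts, end)   # first block with start_a >= end
        return ix.blocks[lo:hi]

    def flanking(
        self, chrom: str, pos: int
    ) -> tuple[AnchorBlock | None, AnchorBlock | None]:
        """Nearest block ending at/before ``pos`` and nearest starting after.

        Either side may be ``None`` at chromosome extremes. A block
        containing ``pos`` is reported via :meth:`block_at`, not here.
        """
        ix = self._index.get(chrom)
        if ix is None or not ix.blocks:
            return (None, None)
        i = bisect_right(ix.ends, pos) - 1  # last block with end_a <= pos
        up = ix.blocks[i] if i >= 0 else None
        j = bisect_right(ix.starts, pos)  # first block with start_a > pos
        down = ix.blocks[j] if j < len(ix.blocks) else None
        return (up, down)


ANCHOR_TSV_COLUMNS = (
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "strand"
)


def read_anchor_table(
    path: str | Path,
    source_assembly: GenomeAssembly,
    target_assembly: GenomeAssembly,
) -> AnchorSet:
    """Read the canonical 7-column anchor TSV.

    Columns: chrom_a start_a end_a chrom_b start_b end_b strand.
    Lines starting with '#' are comments.
    """
    path = Path(path)
    blocks: list[AnchorBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            try:
                blk = AnchorBlock(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3], int(fields[4]), int(fields[5]), fields[6],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                source_assembly.check_interval(blk.chrom_a, blk.start_a, blk.end_a)
                target_assembly.check_interval(blk.chrom_b, blk.start_b, blk.end_b)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            blocks.append(blk)
    return AnchorSet(source_assembly, target_assembly, blocks, validate=False)


def write_anchor_table(anchor_set: AnchorSet, path: str | Path) -> None:
    """Write the canonical anchor TSV with a commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ANCHOR_TSV_COLUMNS) + "\n")
        for blk in anchor_set:
            fh.write(
                f"{blk.chrom_a}\t{blk.start_a}\t{blk.end_a}\t"
                f"{blk.chrom_b}\t{blk.start_b}\t{blk.end_b}\t{blk.strand}\n"
            )


def read_chain(
    path: str | Path,
    source_assembly: GenomeAssembly,
    target_assembly: GenomeAssembly,
) -> AnchorSet:
    """Read a UCSC chain file; each ungapped chain segment becomes one block.

    The chain's "target" side (tName, listed first in the header) is taken as
    the source assembly, matching UCSC liftover chain naming
    (sourceToTarget.over.chain). Minus-strand query coordinates are converted
    to forward-strand 0-based half-open.
    """
    path = Path(path)
    blocks: list[AnchorBlock] = []
    with open(path) as fh:
        header: list[str] | None = None
        t_cur = q_cur = 0
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if header is not None and not line:
                    header = None
                continue
            fields = line.split()
            if fields[0] == "chain":
                if len(fields) < 12:
                    raise FormatError(f"{path}:{lineno}: short chain header")
                header = fields
                t_cur = int(fields[5])
                q_cur = int(fields[10])
                continue
            if header is None:
                raise FormatError(f"{path}:{lineno}: alignment line outside a chain")
            chain_id = header[12] if len(header) > 12 else "?"
            t_name, t_strand = header[2], header[4]
            q_name, q_size, q_strand = header[7], int(header[8]), header[9]
            if t_strand != "+":
                raise FormatError(
                    f"{path}: chain {chain_id}: reference strand must be '+'"
                )
            size = int(fields[0])
            if size > 0:
                if q_strand == "+":
                    qs, qe = q_cur, q_cur + size
                else:
                    qs, qe = q_size - (q_cur + size), q_size - q_cur
                blocks.append(
                    AnchorBlock(t_name, t_cur, t_cur + size,
                                q_name, qs, qe, q_strand)
                )
            if len(fields) == 3:
                t_cur += size + int(fields[1])
                q_cur += size + int(fields[2])
            elif len(fields) == 1:
                # terminal line: verify declared extents were consumed
                t_end, q_end = int(header[6]), int(header[11])
                if t_cur + size != t_end or q_cur + size != q_end:
                    raise FormatError(
                        f"{path}: chain {chain_id}: declared block lengths do "
                        f"not sum to the chain extent"
                    )
                header = None
            else:
                raise FormatError(f"{path}:{lineno}: malformed alignment line")
    return AnchorSet(source_assembly, target_assembly, blocks)


# ---------------------------------------------------------------------------
# Intervals (peaks, TADs, ensembles)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A named half-open interval (an ATAC peak, a TAD, an ensemble...)."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval {self}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path, assembly: GenomeAssembly | None = None) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals, validating against ``assembly`` if given."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3] if len(fields) > 3 else None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if assembly is not None:
                try:
                    assembly.check_interval(iv.chrom, iv.start, iv.end)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


class SignalTrack:
    """Step-function coverage over an assembly (bedGraph semantics).

    Intervals are non-overlapping with non-negative values; positions not
    covered by any record have value 0. Interval means are computed from a
    cumulative integral, so querying many windows is O(log n) each.
    """

    def __init__(
        self,
        assembly: GenomeAssembly,
        records: Iterable[tuple[str, int, int, float]] = (),
    ):
        self.assembly = assembly
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            assembly.check_interval(chrom, start, end)
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}")
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        # per chrom: (starts, ends, values, cum) with cum[i] = integral before record i
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping signal records on {chrom} near position "
                    f"{int(starts[i + 1])}"
                )
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._data[chrom] = (starts, ends, values, cum)

    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the step function over [0, pos) for each pos."""
        if chrom not in self._data:
            return np.zeros(len(pos))
        starts, ends, values, cum = self._data[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        i = np.clip(i, 0, len(starts) - 1)
        inside = np.minimum(pos, ends[i]) - starts[i]
        inside = np.maximum(inside, 0)
        base = np.searchsorted(starts, pos, side="right") - 1
        out = np.where(base >= 0, cum[np.maximum(base, 0)] + values[i] * inside, 0.0)
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.means(chrom, np.array([start]), np.array([end]))[0])

    def means(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Mean coverage over each half-open window; uncovered bases count 0."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("empty window in means() query")
        total = self._integral(chrom, ends) - self._integral(chrom, starts)
        return total / (ends - starts)


def read_signal_bedgraph(path: str | Path, assembly: GenomeAssembly) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    path = Path(path)
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed record") from None
    try:
        return SignalTrack(assembly, records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_signal_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tvalue\n")
        for chrom in track.chromosomes():
            starts, ends, values, _ = track._data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")
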