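"""DC / IC / NC conservation classification of regulatory elements.

A query element (for example an open-chromatin peak) is *directly
conserved* (DC) if it overlaps a direct alignment anchor between the source
and target genomes; *indirectly conserved* (IC) if it does not, but its
reference point projects through the bridging-species graph with a score
above the threshold (default 0.99, i.e. within ~145 bp total anchor
distance at the default 10 kb half-life); *non-conserved* (NC) otherwise,
including unprojectable elements. The three labels partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .genome_model import AnchorBlock, AnchorSet, GenomicInterval
from .projection import ProjectionResult, ScoringParams, SpeciesGraph, shortest_path_project

__all__ = ["ConservationCall", "classify_interval", "classify_all", "summarize_calls"]

Label = Literal["DC", "IC", "NC"]

DEFAULT_THRESHOLD = 0.99


@dataclass(frozen=True)
class ConservationCall:
    """One element's conservation label with its evidence.

    DC calls carry the overlapping direct anchor block; IC and NC calls
    carry the projection result (NC also covers unprojectable elements,
    whose projection has score 0). ``target_peak_overlap`` is an optional
    annotation — whether the projected point falls inside a target-species
    peak — and never influences the label.
    """

    interval: GenomicInterval
    label: Label
    direct_anchor: AnchorBlock | None = None
    projection: ProjectionResult | None = None
    target_peak_overlap: bool | None = None

    @property
    def score(self) -> float | None:
        return self.projection.score if self.projection is not None else None


def _reference_point(peak: GenomicInterval, mode: str) -> list[int]:
    if mode == "midpoint":
        return [peak.center]
    if mode == "endpoints":
        return [peak.start, peak.end - 1]
    raise ValueError(f"unknown reference-point mode {mode!r}")


def classify_interval(
    peak: GenomicInterval,
    direct_anchor_set: AnchorSet,
    graph: SpeciesGraph,
    params: ScoringParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    target_peaks: Sequence[GenomicInterval] | None = None,
    reference_point: str = "midpoint",
) -> ConservationCall:
    """Classify one element as DC, IC or NC.

    DC requires >= 1 bp overlap with a direct source-target anchor block.
    Otherwise the peak's reference point (midpoint by default; "endpoints"
    projects both ends and keeps the better score) is projected through the
    graph: IC if score > threshold (strict), NC otherwise.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    params = params or ScoringParams()
    source_id, target_id = direct_anchor_set.species_pair
    overlapping = direct_anchor_set.overlapping(peak.chrom, peak.start, peak.end)
    if overlapping:
        return ConservationCall(peak, "DC", direct_anchor=overlapping[0])
    best: ProjectionResult | None = None
    for point in _reference_point(peak, reference_point):
        res = shortest_path_project(graph, source_id, target_id,
                                    peak.chrom, point, params)
        if best is None or res.score > best.score:
            best = res
    assert best is not None
    overlap_flag: bool | None = None
    if target_peaks is not None and best.projectable:
        overlap_flag = any(
            tp.chrom == best.chrom and tp.start <= best.pos < tp.end
            for tp in target_peaks
        )
    label: Label = "IC" if best.score > threshold else "NC"
    return ConservationCall(peak, label, projection=best,
                            target_peak_overlap=overlap_flag)


def classify_all(
    peaks: Iterable[GenomicInterval],
    direct_anchor_set: AnchorSet,
    graph: SpeciesGraph,
    params: ScoringParams | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    target_peaks: Sequence[GenomicInterval] | None = None,
    reference_point: str = "midpoint",
) -> list[ConservationCall]:
    """Classify every peak; the labels partition the input exhaustively."""
    return [
        classify_interval(
            peak, direct_anchor_set, graph, params, threshold,
            target_peaks=target_peaks, reference_point=reference_point,
        )
        for peak in peaks
    ]


def summarize_calls(calls: Sequence[ConservationCall]) -> dict[str, dict[str, float]]:
    """Counts and fractions per label; fractions sum to 1 for non-empty input."""
    counts = {"DC": 0, "IC": 0, "NC": 0}
    for call in calls:
        counts[call.label] += 1
    n = len(calls)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "total": {"n": n}}
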