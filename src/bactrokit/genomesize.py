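"""Genome-size estimation from read coverage of single-copy transcript-like
segments.

The logic mirrors the classic single-copy coverage argument: if reads
totalling T bases map to putative single-copy sequence at modal (peak)
depth c, the genome size is T / c.  The filter cascade removes segments
that would bias the peak: an initial quality-filtered mapping, removal of
the low-coverage (< 10, fragmented/erroneous models) and high-coverage
(> 60, repeat-contaminated) bands, retention of the median 50% of segments
ranked by coverage, removal of segments with runs of >= 5 Ns or a poor
annotation-quality (AED-like) score > 0.2, and a final unique-mapping pass;
per-segment depth is summarised by the median with the 100 bp flanks
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import ReferenceIndex, map_reads
from .pileup import CoverageTrack


class InsufficientSegments(ValueError):
    """Fewer than the minimum usable single-copy segments after filtering."""


class AmbiguousPeak(ValueError):
    """The per-segment coverage histogram has no dominant mode."""


@dataclass
class TranscriptSegment:
    """A genomic segment for one transcript, including ``flank`` bp on each
    side (flanks are excluded from coverage summaries)."""

    id: str
    sequence: str
    flank: int = 100
    aed: float = 0.0
    median_coverage: float = float("nan")

    @property
    def has_n_run(self) -> bool:
        return "N" * 5 in self.sequence

    @property
    def core_length(self) -> int:
        return len(self.sequence) - 2 * self.flank


def segments_from_truth(
    genome: str, truth, flank: int = 100, aed: float = 0.05
) -> list[TranscriptSegment]:
    """Extract planted gene segments (with flanks) from a synthetic genome."""
    out = []
    for f in truth.by_type("gene"):
        s, e = max(0, f.start - flank), min(len(genome), f.end + flank)
        out.append(TranscriptSegment(f.name, genome[s:e], flank=flank, aed=aed))
    return out


def _median_coverages(
    segments: list[TranscriptSegment], reads, min_q: int, alignments=None
) -> dict[str, float]:
    ref = {seg.id: seg.sequence for seg in segments}
    if alignments is None:
        index = ReferenceIndex(ref, seed_len=19)
        alignments = map_reads(reads, index)
    else:
        alignments = [a for a in alignments if a.ref_id in ref]
    track = CoverageTrack.from_alignments(
        alignments, {n: len(s) for n, s in ref.items()}, min_q=min_q
    )
    out: dict[str, float] = {}
    for seg in segments:
        depth = track.depth[seg.id]
        core = depth[seg.flank : len(depth) - seg.flank]
        out[seg.id] = float(np.median(core)) if core.size else 0.0
    return out


def coverage_filter_cascade(
    segments: list[TranscriptSegment],
    reads,
    low: float = 10.0,
    high: float = 60.0,
    q_initial: int = 29,
    q_final: int = 55,
    aed_max: float = 0.2,
    min_retained: int = 10,
) -> list[TranscriptSegment]:
    """Apply the full filter cascade; returns retained segments with their
    final median coverage filled in.

    Order: initial mapping (alignments at or below ``q_initial`` excluded)
    -> drop the < ``low`` and > ``high`` coverage bands -> keep the median
    50% of segments ranked by coverage (ties broken by id) -> drop N-run
    and AED > ``aed_max`` segments -> final pass at ``q_final``.  Reads are
    mapped once; the two passes re-filter the same alignments by quality.
    """
    ref = {seg.id: seg.sequence for seg in segments}
    index = ReferenceIndex(ref, seed_len=19)
    alignments = map_reads(reads, index)
    med0 = _median_coverages(segments, reads, min_q=q_initial, alignments=alignments)
    banded = [s for s in segments if low <= med0[s.id] <= high]
    banded.sort(key=lambda s: (med0[s.id], s.id))
    n = len(banded)
    keep = banded[n // 4 : n - n // 4] if n >= 4 else banded
    keep = [s for s in keep if not s.has_n_run and s.aed <= aed_max]
    if len(keep) < min_retained:
        raise InsufficientSegments(
            f"insufficient single-copy set: {len(keep)} segments retained"
        )
    med1 = _median_coverages(keep, reads, min_q=q_final, alignments=alignments)
    for s in keep:
        s.median_coverage = med1[s.id]
    return keep


@dataclass
class SizeEstimate:
    peak_coverage: float
    total_bases: int
    retained_segments: int
    size_bp: float = field(init=False)

    def __post_init__(self) -> None:
        self.size_bp = self.total_bases / self.peak_coverage

    @property
    def size_mbp(self) -> float:
        return self.size_bp / 1e6


def coverage_peak(medians) -> float:
    """Mode of per-segment median coverages: histogram with bin width 1,
    bin-centre interpolation (+0.5).  Adjacent tied modes are averaged;
    separated ties raise :class:`AmbiguousPeak`."""
    vals = np.asarray(list(medians), dtype=float)
    if vals.size == 0:
        raise InsufficientSegments("no segments to estimate a peak from")
    bins = np.bincount(np.floor(vals).astype(int))
    top = bins.max()
    cands = np.flatnonzero(bins == top)
    if cands.size > 1 and cands.max() - cands.min() > 2:
        raise AmbiguousPeak(f"no dominant coverage peak; candidates at {cands + 0.5}")
    return float(cands.mean()) + 0.5


def estimate_genome_size(
    retained: list[TranscriptSegment] | None,
    total_bases: int,
    peak: float | None = None,
) -> SizeEstimate:
    """Genome size = total sequenced bases / peak single-copy coverage.

    ``peak`` may be given directly (worked-arithmetic use); otherwise it is
    the histogram mode of the retained segments' median coverages.
    """
    if peak is None:
        if not retained:
            raise InsufficientSegments("no retained segments")
        peak = coverage_peak(s.median_coverage for s in retained)
    return SizeEstimate(
        peak_coverage=peak,
        total_bases=total_bases,
        retained_segments=len(retained) if retained else 0,
    )
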