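"""Turn an alignment stream into filtered 5'-end break events.

The fragmentation signal lives entirely in where aligned reads *start*:
each kept alignment contributes one ``ReadStartEvent`` at the 0-based
genomic coordinate of its 5'-terminal aligned base, the putative point of
mechanochemical cleavage.  The default :class:`FilterPolicy` mirrors the
standard protocol ``samtools view -f 35 -F 4`` restricted to autosomes:
paired, properly paired, mate-on-reverse (hence read on forward strand),
mapped reads only.

A plain two-column TSV (contig, 0-based position) is accepted as an
alignment-free event source, which is what the simulator emits.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

from .genome_io import GenomicInterval, InputError, _open_text, merge_intervals

logger = logging.getLogger(__name__)

#: Contig-name spellings of the 22 human autosomes, both with and without
#: the "chr" prefix.
DEFAULT_AUTOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
)

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_DUPLICATE = 0x400


@dataclass(frozen=True, slots=True)
class ReadStartEvent:
    """One filtered alignment's 5'-end break coordinate (0-based)."""

    contig: str
    pos: int
    sample_id: str = ""
    strand: str = "+"


@dataclass
class FilterPolicy:
    """Which alignments count as break observations.

    Defaults follow the forward-strand autosome protocol: required flag
    bits 35 (paired + proper pair + mate reverse), excluded bit 4
    (unmapped), contigs restricted to autosomes, duplicates kept, no
    mapping-quality floor.  ``allowed_contigs=None`` admits every contig.
    Reads whose alignment begins with a soft clip longer than
    ``max_leading_clip`` are dropped: the clip hides the true fragment end.
    """

    require_flags: int = 35
    exclude_flags: int = 4
    allowed_contigs: frozenset[str] | None = field(default=DEFAULT_AUTOSOMES)
    drop_duplicates: bool = False
    min_mapq: int = 0
    max_leading_clip: int = 0
    strand: str = "forward"  # forward | reverse | both

    def __post_init__(self):
        if self.require_flags & self.exclude_flags:
            raise ValueError(
                "required and excluded flag bitmasks must be disjoint "
                f"({self.require_flags:#x} & {self.exclude_flags:#x})"
            )
        if self.strand not in ("forward", "reverse", "both"):
            raise ValueError(f"strand must be forward/reverse/both, got {self.strand!r}")


class MaskIndex:
    """Membership queries against a merged interval set, O(log n) each."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.contig, []).append(iv.start)
            self._ends.setdefault(iv.contig, []).append(iv.end)

    def __contains__(self, key: tuple[str, int]) -> bool:
        contig, pos = key
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[contig][i]

    def __bool__(self) -> bool:
        return bool(self._starts)


def iter_alignments(path) -> Iterator[pysam.AlignedSegment]:
    """Stream alignments from SAM/BAM/CRAM."""
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        yield from bam.fetch(until_eof=True)


def _leading_clip(aln: pysam.AlignedSegment, reverse: bool) -> int:
    cigar = aln.cigartuples
    if not cigar:
        return 0
    op, length = cigar[-1] if reverse else cigar[0]
    return length if op == 4 else 0  # 4 = soft clip


def extract_read_starts(
    alignments: Iterable[pysam.AlignedSegment],
    policy: FilterPolicy | None = None,
    mask: Iterable[GenomicInterval] | MaskIndex | None = None,
    sample_id: str = "",
) -> Iterator[ReadStartEvent]:
    """Yield one break event per alignment passing the filter policy.

    A record is emitted iff its flag contains every required bit and no
    excluded bit, its contig is allowed, its mapping quality clears the
    threshold, its leading soft clip is within bounds, and its 5'-end
    position does not fall inside a mask interval.  Input order is
    preserved; the stream is order-agnostic.
    """
    policy = policy or FilterPolicy()
    mask_index = mask if isinstance(mask, MaskIndex) else MaskIndex(mask or ())
    for aln in alignments:
        flag = aln.flag
        if flag & policy.require_flags != policy.require_flags:
            continue
        if flag & policy.exclude_flags:
            continue
        contig = aln.reference_name
        if contig is None:
            continue
        if policy.allowed_contigs is not None and contig not in policy.allowed_contigs:
            continue
        if aln.mapping_quality < policy.min_mapq:
            continue
        if policy.drop_duplicates and flag & FLAG_DUPLICATE:
            continue
        reverse = bool(flag & FLAG_REVERSE)
        if reverse and policy.strand == "forward":
            continue
        if not reverse and policy.strand == "reverse":
            continue
        if _leading_clip(aln, reverse) > policy.max_leading_clip:
            continue
        pos = (aln.reference_end - 1) if reverse else aln.reference_start
        if (contig, pos) in mask_index:
            continue
        yield ReadStartEvent(contig, pos, sample_id, "-" if reverse else "+")


def count_events(stream: Iterable[ReadStartEvent]) -> int:
    """N of the cleavage-rate statistic: total kept break events."""
    return sum(1 for _ in stream)


# ---------------------------------------------------------------------------
# Alignment-free event TSV (contig, 0-based position[, strand])


def load_events_tsv(source, sample_id: str = "") -> list[ReadStartEvent]:
    events: list[ReadStartEvent] = []
    with _open_text(source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"{source}:{lineno}: expected >= 2 TSV columns")
            strand = fields[2] if len(fields) > 2 else "+"
            events.append(ReadStartEvent(fields[0], int(fields[1]), sample_id, strand))
    return events


def write_events_tsv(events: Iterable[ReadStartEvent], path) -> None:
    with open(path, "wt") as out:
        for ev in events:
            out.write(f"{ev.contig}\t{ev.pos}\t{ev.strand}\n")
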