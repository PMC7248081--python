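"""Readers, writers and validation for the pipeline's external formats.

Everything downstream works in a single coordinate convention: 0-based,
half-open intervals, with CpG sites indexed by the position of the C on the
forward strand.  BED input is native to this convention; the methylation-call
TSV dialect stores 1-based positions and is converted on load; SAM positions
are converted by :mod:`cleavescan.read_extraction` via pysam.

Formats handled here:

* reference genome — FASTA, plain or gzipped (via Biopython);
* CpG-island and low-complexity-mask intervals — BED3+;
* per-CpG bisulfite calls — 4-column TSV (contig, 1-based position of the C,
  read coverage, methylated-read count), a minimal methylation-map dialect;
* derived methylation status maps — 3-column TSV (contig, 1-based position,
  status), round-trippable;
* sample labels — 2-column TSV (sample id, TUMOR/NORMAL).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_ILLEGAL = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """A file violates its declared format."""


class InputError(ValueError):
    """Inputs are well-formed but mutually inconsistent."""


def _open_text(source) -> TextIO:
    """Open a path as text, transparently handling gzip."""
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Genome


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig, upper-case over the alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = _ILLEGAL.search(self.sequence)
        if bad:
            raise FormatError(
                f"contig {self.name!r}: illegal character {bad.group()!r} "
                f"at offset {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


Genome = dict[str, GenomeSequence]


def load_genome(source, ambiguous: str = "error") -> Genome:
    """Load a FASTA reference into a mapping of contig name -> sequence.

    Parameters
    ----------
    source
        Path to a FASTA file (optionally gzipped).
    ambiguous
        ``"error"`` rejects IUPAC ambiguity codes other than N with a
        :class:`FormatError` naming the contig and offset; ``"n"`` maps
        them to N.
    """
    if ambiguous not in ("error", "n"):
        raise ValueError(f"ambiguous must be 'error' or 'n', got {ambiguous!r}")
    genome: Genome = {}
    with _open_text(source) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in genome:
                raise FormatError(f"duplicate contig name {record.id!r}")
            seq = str(record.seq).upper()
            if ambiguous == "n":
                seq = _ILLEGAL.sub("N", seq)
            genome[record.id] = GenomeSequence(record.id, seq)
    if not genome:
        raise FormatError(f"no FASTA records found in {source}")
    logger.info("loaded %d contig(s) from %s", len(genome), source)
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence], path, width: int = 70) -> None:
    with open(path, "wt") as out:
        for name, contig in genome.items():
            out.write(f">{name}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a contig, 0-based."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise FormatError(f"negative coordinate in {self.contig}:{self.start}")
        if self.start >= self.end:
            raise FormatError(
                f"empty or inverted interval {self.contig}:{self.start}-{self.end}"
            )

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def load_intervals(
    source,
    genome: Mapping[str, GenomeSequence] | None = None,
    merge: bool = False,
) -> list[GenomicInterval]:
    """Load BED3+ intervals, optionally validated against contig lengths.

    Mask files should be loaded with ``merge=True`` (overlaps unioned);
    island files keep their input order and stay distinct.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{source}:{lineno}: expected >= 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{source}:{lineno}: non-integer coordinate") from exc
            try:
                interval = GenomicInterval(contig, start, end)
            except FormatError as exc:
                raise FormatError(f"{source}:{lineno}: {exc}") from exc
            if genome is not None:
                if contig not in genome:
                    raise FormatError(
                        f"{source}:{lineno}: contig {contig!r} absent from genome"
                    )
                if end > len(genome[contig]):
                    raise FormatError(
                        f"{source}:{lineno}: interval end {end} exceeds contig "
                        f"length {len(genome[contig])}"
                    )
            intervals.append(interval)
    logger.info("loaded %d interval(s) from %s", len(intervals), source)
    return merge_intervals(intervals) if merge else intervals


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping or abutting intervals, per contig, sorted."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and iv.contig == merged[-1].contig and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.contig, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as out:
        for iv in intervals:
            out.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Methylation calls and maps


class MethylStatus(str, Enum):
    METHYLATED = "METHYLATED"
    UNMETHYLATED = "UNMETHYLATED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class MethylationCall:
    """Bisulfite read counts for one forward-strand CpG cytosine."""

    contig: str
    position: int  # 0-based position of the C
    coverage: int
    methylated_count: int

    def __post_init__(self):
        if not (0 <= self.methylated_count <= self.coverage):
            raise FormatError(
                f"{self.contig}:{self.position}: methylated count "
                f"{self.methylated_count} outside [0, coverage={self.coverage}]"
            )


def load_methylation_calls(
    source,
    genome: Mapping[str, GenomeSequence] | None = None,
    validate: str = "error",
) -> list[MethylationCall]:
    """Parse the 4-column bisulfite-call TSV (positions are 1-based on disk).

    When a genome is supplied, each call is checked to sit on a CpG
    (C at the position, G at the next); ``validate`` selects whether a
    mismatch raises (``"error"``), warns (``"warn"``) or is ignored
    (``"off"``) — the lenient modes exist for assembly-version mismatches.
    """
    if validate not in ("error", "warn", "off"):
        raise ValueError(f"validate must be error/warn/off, got {validate!r}")
    calls: list[MethylationCall] = []
    rejected = 0
    with _open_text(source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{source}:{lineno}: expected 4 TSV columns")
            contig = fields[0]
            try:
                pos1, cov, meth = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{source}:{lineno}: non-integer field") from exc
            if pos1 < 1:
                raise FormatError(f"{source}:{lineno}: position must be >= 1")
            try:
                call = MethylationCall(contig, pos1 - 1, cov, meth)
            except FormatError as exc:
                raise FormatError(f"{source}:{lineno}: {exc}") from exc
            if genome is not None and validate != "off":
                seq = genome.get(contig)
                ok = (
                    seq is not None
                    and call.position + 1 < len(seq)
                    and seq.sequence[call.position : call.position + 2] == "CG"
                )
                if not ok:
                    msg = f"{source}:{lineno}: call at {contig}:{pos1} is not on a CpG"
                    if validate == "error":
                        raise FormatError(msg)
                    logger.warning(msg)
                    rejected += 1
                    continue
            calls.append(call)
    logger.info(
        "loaded %d methylation call(s) from %s (%d rejected)",
        len(calls), source, rejected,
    )
    return calls


def write_methylation_calls(calls: Iterable[MethylationCall], path) -> None:
    with open(path, "wt") as out:
        for c in calls:
            out.write(f"{c.contig}\t{c.position + 1}\t{c.coverage}\t{c.methylated_count}\n")


class MethylationMap:
    """Per-CpG methylation status, keyed by (contig, forward-strand C position).

    Any position absent from the map is UNKNOWN; explicit UNKNOWN entries
    (assayed but ambiguous CpGs) are retained so audits can distinguish
    "excluded" from "never measured".
    """

    def __init__(self, statuses: Mapping[tuple[str, int], MethylStatus] | None = None):
        self._statuses: dict[tuple[str, int], MethylStatus] = dict(statuses or {})

    def status(self, contig: str, position: int) -> MethylStatus:
        return self._statuses.get((contig, position), MethylStatus.UNKNOWN)

    def __len__(self) -> int:
        return len(self._statuses)

    def __eq__(self, other) -> bool:
        return isinstance(other, MethylationMap) and self._statuses == other._statuses

    def items(self):
        return self._statuses.items()

    def counts(self) -> dict[MethylStatus, int]:
        out = {s: 0 for s in MethylStatus}
        for status in self._statuses.values():
            out[status] += 1
        return out

    def to_tsv(self, path) -> None:
        """Write the 3-column status TSV (contig, 1-based position, status)."""
        with open(path, "wt") as out:
            for (contig, pos), status in sorted(self._statuses.items()):
                out.write(f"{contig}\t{pos + 1}\t{status.value}\n")

    @classmethod
    def from_tsv(cls, source) -> "MethylationMap":
        statuses: dict[tuple[str, int], MethylStatus] = {}
        with _open_text(source) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"{source}:{lineno}: expected 3 TSV columns")
                try:
                    status = MethylStatus(fields[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{source}:{lineno}: unknown status {fields[2]!r}"
                    ) from exc
                statuses[(fields[0], int(fields[1]) - 1)] = status
        return cls(statuses)


def build_methylation_map(
    calls: Iterable[MethylationCall],
    min_coverage: int = 10,
    concordance: float = 0.9,
) -> MethylationMap:
    """Threshold bisulfite calls into METHYLATED / UNMETHYLATED / UNKNOWN.

    A CpG is assigned a determined status only when its coverage is
    *strictly greater than* ``min_coverage`` and *strictly more than* a
    fraction ``concordance`` of its reads agree; everything else —
    under-covered sites and intermediate methylation ratios — is UNKNOWN
    and excluded from the cleavage-rate contrast downstream.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    if not (0.5 < concordance <= 1):
        raise ValueError("concordance must be in (0.5, 1]")
    seen: dict[tuple[str, int], MethylationCall] = {}
    statuses: dict[tuple[str, int], MethylStatus] = {}
    for call in calls:
        key = (call.contig, call.position)
        if key in seen:
            prev = seen[key]
            if (prev.coverage, prev.methylated_count) != (
                call.coverage,
                call.methylated_count,
            ):
                raise InputError(
                    f"conflicting duplicate call at {call.contig}:{call.position + 1}"
                )
            continue
        seen[key] = call
        status = MethylStatus.UNKNOWN
        if call.coverage > min_coverage:
            if call.methylated_count / call.coverage > concordance:
                status = MethylStatus.METHYLATED
            elif (call.coverage - call.methylated_count) / call.coverage > concordance:
                status = MethylStatus.UNMETHYLATED
        statuses[key] = status
    return MethylationMap(statuses)


# ---------------------------------------------------------------------------
# Sample labels


def load_labels(source) -> dict[str, str]:
    """Load the 2-column sample-label TSV (sample id, TUMOR/NORMAL)."""
    labels: dict[str, str] = {}
    with _open_text(source) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{source}:{lineno}: expected 2 TSV columns")
            if fields[0] in labels:
                raise FormatError(f"{source}:{lineno}: duplicate sample {fields[0]!r}")
            labels[fields[0]] = fields[1]
    return labels


def write_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "wt") as out:
        for sample, label in labels.items():
            out.write(f"{sample}\t{label}\n")
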