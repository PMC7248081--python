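"""Dinucleotide cleavage rates from break events.

The statistic: for each dinucleotide class XY,

    r(XY) = n(XY) / (N * p(XY))

where n(XY) counts break events whose 5'-end base is the second base of an
XY pair in the reference, N is the total number of classified events, and
p(XY) is the fraction of XY among the informative dinucleotide positions in
the 200-bp genomic windows centred on those same events.  The local window
normalisation absorbs composition and mappability bias around read starts;
r = 1 means no cleavage preference.

When a methylation map is supplied the CG class is split three ways —
CmG (methylated), CuG (unmethylated), CxG (status unknown) — giving 18
classes; without a map there are the 16 standard dinucleotides.  All three
CG sub-classes are informative for both numerator and background; CxG is
simply not used in the methylated-vs-unmethylated contrast downstream.

Accounting rules (applied identically to n and p):

* events whose 200-bp window is truncated by a contig edge are excluded
  from both;
* an event whose break pair contains N or a masked base (or sits at
  position 0) is DISCARDed: excluded from N and its window from p;
* a dinucleotide overlapping any masked or N base is uninformative for p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    FormatError,
    GenomeSequence,
    GenomicInterval,
    InputError,
    MethylationMap,
    MethylStatus,
)
from .read_extraction import MaskIndex, ReadStartEvent

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: The 16 standard dinucleotides in lexicographic order; class code 4*x + y.
DINUCLEOTIDES = [a + b for a in BASES for b in BASES]
CG_CODE = DINUCLEOTIDES.index("CG")  # 6

CMG, CUG, CXG = "CmG", "CuG", "CxG"
CMG_CODE, CUG_CODE, CXG_CODE = 16, 17, 18
N_CODES = 19

#: Class labels by mode. Annotated mode replaces CG with its three
#: methylation-status sub-classes (18 labels).
UNANNOTATED_LABELS = list(DINUCLEOTIDES)
ANNOTATED_LABELS = [d for d in DINUCLEOTIDES if d != "CG"] + [CMG, CUG, CXG]

_CODE_TO_LABEL = {i: d for i, d in enumerate(DINUCLEOTIDES)}
_CODE_TO_LABEL.update({CMG_CODE: CMG, CUG_CODE: CUG, CXG_CODE: CXG})

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i

CG_FAMILY_CODES = (CG_CODE, CMG_CODE, CUG_CODE, CXG_CODE)


class EmptyResultError(InputError):
    """Every event was discarded; no rate table can be formed."""


def class_labels(annotated: bool) -> list[str]:
    return ANNOTATED_LABELS if annotated else UNANNOTATED_LABELS


def _codes_for(annotated: bool) -> list[int]:
    if annotated:
        return [c for c in range(16) if c != CG_CODE] + [CMG_CODE, CUG_CODE, CXG_CODE]
    return list(range(16))


def _mask_bool(contig: str, length: int, mask: MaskIndex | None,
               intervals: Sequence[GenomicInterval] | None = None) -> np.ndarray | None:
    """Boolean per-base masked array for one contig, or None if unmasked."""
    if intervals is None:
        return None
    arr = np.zeros(length, dtype=bool)
    any_hit = False
    for iv in intervals:
        if iv.contig == contig:
            arr[iv.start : min(iv.end, length)] = True
            any_hit = True
    return arr if any_hit else None


def dinucleotide_classes(
    contig: GenomeSequence,
    methylmap: MethylationMap | None = None,
    mask: Sequence[GenomicInterval] | None = None,
) -> np.ndarray:
    """Per-position class codes for one contig.

    The returned int16 array ``D`` has length len(contig); ``D[i]`` is the
    class code of the pair (i-1, i) — the pair a break *at* i falls on —
    or -1 where the pair is undefined (i = 0), contains N, or overlaps a
    masked base.  With a methylation map, CG positions are re-coded to
    CmG/CuG/CxG by the status of the C at i-1.
    """
    seq = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
    b = _BASE_CODE[seq].astype(np.int16)
    L = len(seq)
    D = np.full(L, -1, dtype=np.int16)
    if L >= 2:
        valid = (b[:-1] >= 0) & (b[1:] >= 0)
        D[1:] = np.where(valid, 4 * b[:-1] + b[1:], -1)
    masked = _mask_bool(contig.name, L, None, mask)
    if masked is not None and L >= 2:
        pair_masked = masked[:-1] | masked[1:]
        D[1:][pair_masked] = -1
    if methylmap is not None:
        status_code = {
            MethylStatus.METHYLATED: CMG_CODE,
            MethylStatus.UNMETHYLATED: CUG_CODE,
            MethylStatus.UNKNOWN: CXG_CODE,
        }
        for i in np.flatnonzero(D == CG_CODE):
            D[i] = status_code[methylmap.status(contig.name, int(i) - 1)]
    return D


def classify_break_site(
    genome: Mapping[str, GenomeSequence],
    event: ReadStartEvent,
    methylmap: MethylationMap | None = None,
    mask: MaskIndex | Iterable[GenomicInterval] | None = None,
) -> str | None:
    """Class label of one break site, or None (DISCARD).

    For a forward-strand event at i the class is read from reference bases
    (i-1, i); reverse-strand events read the reverse complement of
    (i, i+1), so a reverse break on a CpG still maps to the CG family with
    the status of the forward-strand C at i.  DISCARD when the flanking
    base does not exist, either base is N, or either base is masked.
    """
    if event.contig not in genome:
        raise InputError(f"event contig {event.contig!r} absent from genome")
    contig = genome[event.contig]
    seq = contig.sequence
    mask_index = mask if isinstance(mask, MaskIndex) or mask is None else MaskIndex(mask)
    i = event.pos
    if not (0 <= i < len(seq)):
        raise InputError(f"event position {i} outside contig {event.contig!r}")
    if event.strand == "-":
        if i + 1 >= len(seq):
            return None
        first, second = i, i + 1
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        pair = "".join(comp.get(c, "N") for c in reversed(seq[first : second + 1]))
        c_pos = first  # forward-strand C of a CpG hit on the reverse strand
    else:
        if i == 0:
            return None
        first, second = i - 1, i
        pair = seq[first : second + 1]
        c_pos = first
    if "N" in pair:
        return None
    if mask_index is not None and (
        (event.contig, first) in mask_index or (event.contig, second) in mask_index
    ):
        return None
    if pair == "CG" and methylmap is not None:
        return {
            MethylStatus.METHYLATED: CMG,
            MethylStatus.UNMETHYLATED: CUG,
            MethylStatus.UNKNOWN: CXG,
        }[methylmap.status(event.contig, c_pos)]
    return pair


@dataclass
class CleavageRateTable:
    """n(XY), p(XY), r(XY) per class, plus sample-level accounting.

    ``table`` is indexed by class label with columns ``n`` (break counts),
    ``p`` (pooled background fraction) and ``r`` (cleavage rate; NaN where
    p = 0).  ``N`` is the number of events that entered a class;
    ``exclusions`` tallies events dropped for truncated windows or
    DISCARDed break pairs.
    """

    table: pd.DataFrame
    N: int
    half_width: int
    annotated: bool
    exclusions: dict[str, int] = field(default_factory=dict)

    def rate(self, label: str) -> float:
        return float(self.table.loc[label, "r"])

    def write_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write(f"# N={self.N}\n")
            out.write(f"# half_width={self.half_width}\n")
            out.write(f"# annotated={self.annotated}\n")
            for key, val in sorted(self.exclusions.items()):
                out.write(f"# excluded_{key}={val}\n")
            out.write("class\tn\tp\tr\n")
            for label, row in self.table.iterrows():
                out.write(f"{label}\t{int(row.n)}\t{row.p:.10g}\t{row.r:.10g}\n")

    @classmethod
    def read_tsv(cls, source) -> "CleavageRateTable":
        meta: dict[str, str] = {}
        rows = []
        with open(source, "rt") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("# "):
                    key, _, val = line[2:].partition("=")
                    meta[key] = val
                elif line and not line.startswith("class\t"):
                    label, n, p, r = line.split("\t")
                    rows.append((label, int(n), float(p), float(r)))
        table = pd.DataFrame(rows, columns=["class", "n", "p", "r"]).set_index("class")
        exclusions = {
            k.removeprefix("excluded_"): int(v)
            for k, v in meta.items()
            if k.startswith("excluded_")
        }
        return cls(
            table=table,
            N=int(meta["N"]),
            half_width=int(meta["half_width"]),
            annotated=meta["annotated"] == "True",
            exclusions=exclusions,
        )


def _events_by_contig(
    events: Iterable[ReadStartEvent], genome: Mapping[str, GenomeSequence]
) -> dict[str, np.ndarray]:
    grouped: dict[str, list[int]] = {}
    for ev in events:
        if ev.contig not in genome:
            raise InputError(f"event contig {ev.contig!r} absent from genome")
        if ev.strand == "-":
            raise InputError(
                "reverse-strand events are not supported by the streaming rate "
                "computation; classify them via classify_break_site"
            )
        grouped.setdefault(ev.contig, []).append(ev.pos)
    return {c: np.asarray(p, dtype=np.int64) for c, p in grouped.items()}


def compute_cleavage_rates(
    genome: Mapping[str, GenomeSequence],
    events: Iterable[ReadStartEvent],
    methylmap: MethylationMap | None = None,
    mask: Sequence[GenomicInterval] | None = None,
    half_width: int = 100,
) -> CleavageRateTable:
    """Compute the full per-class cleavage-rate table for one sample.

    The default ``half_width`` of 100 gives the 200-bp background window
    [i - 100, i + 100), i.e. 199 overlapping dinucleotide positions per
    event.  Background fractions are pooled: summed pair counts over all
    windows divided by summed informative positions.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if genome and all(2 * half_width > len(c) for c in genome.values()):
        raise InputError(
            f"window width {2 * half_width} exceeds the length of every contig"
        )
    annotated = methylmap is not None
    grouped = _events_by_contig(events, genome)

    n = np.zeros(N_CODES, dtype=np.int64)
    bg = np.zeros(N_CODES, dtype=np.int64)
    truncated = 0
    discarded = 0

    for contig_name, positions in grouped.items():
        contig = genome[contig_name]
        L = len(contig)
        D = dinucleotide_classes(contig, methylmap, mask)
        full = (positions - half_width >= 0) & (positions + half_width <= L)
        truncated += int((~full).sum())
        pos = positions[full]
        cls = D[pos]
        keep = cls >= 0
        discarded += int((~keep).sum())
        pos = pos[keep]
        n += np.bincount(cls[keep], minlength=N_CODES)
        # window pair positions t in [i - hw + 1, i + hw): prefix-sum lookup
        lo = pos - half_width + 1
        hi = pos + half_width
        for code in _codes_for(annotated):
            prefix = np.concatenate(([0], np.cumsum(D == code, dtype=np.int64)))
            bg[code] += int((prefix[hi] - prefix[lo]).sum())

    N = int(n.sum())
    if N == 0:
        raise EmptyResultError(
            "no events survived classification "
            f"(truncated={truncated}, discarded={discarded})"
        )
    bg_total = int(bg.sum())
    codes = _codes_for(annotated)
    p = bg[codes] / bg_total
    counts = n[codes]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(p > 0, counts / (N * p), np.nan)
    table = pd.DataFrame(
        {"n": counts, "p": p, "r": r}, index=pd.Index(class_labels(annotated), name="class")
    )
    logger.info(
        "rate table: N=%d, truncated=%d, discarded=%d", N, truncated, discarded
    )
    return CleavageRateTable(
        table=table,
        N=N,
        half_width=half_width,
        annotated=annotated,
        exclusions={"truncated_window": truncated, "discarded_pair": discarded},
    )


# ---------------------------------------------------------------------------
# Island-restricted CpG cleavage rates


@dataclass(frozen=True)
class IslandScore:
    """Island-restricted CpG cleavage rate for one sample.

    ``rate`` is n / (N * p_island) with n the CG-family break count inside
    the island, p_island the CG fraction among the island's own informative
    dinucleotide positions, and N the *sample-wide* event total so scores
    are depth-comparable across samples.  ``status`` is "ok" or a reason
    code ("no_cg", "low_cg") when the score is missing (rate = NaN).
    """

    island_id: str
    contig: str
    start: int
    end: int
    n: int
    p_island: float
    rate: float
    status: str


def island_cleavage_rate(
    genome: Mapping[str, GenomeSequence],
    events: Iterable[ReadStartEvent],
    island: GenomicInterval,
    N: int,
    mask: Sequence[GenomicInterval] | None = None,
    min_cg_positions: int = 5,
) -> IslandScore:
    """Score one CpG island; see :class:`IslandScore`.

    CG breaks of any methylation status count — the samples being scored
    (e.g. tumours) typically carry no bisulfite map.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    score = _score_islands_impl(genome, list(events), [island], N, mask, min_cg_positions)
    return score[0]


def score_islands(
    genome: Mapping[str, GenomeSequence],
    events: Iterable[ReadStartEvent],
    islands: Sequence[GenomicInterval],
    N: int | None = None,
    mask: Sequence[GenomicInterval] | None = None,
    min_cg_positions: int = 5,
) -> list[IslandScore]:
    """Score every island for one sample; N defaults to the event count."""
    events = list(events)
    if N is None:
        N = len(events)
    if N <= 0:
        raise ValueError("N must be positive")
    return _score_islands_impl(genome, events, islands, N, mask, min_cg_positions)


def _score_islands_impl(
    genome: Mapping[str, GenomeSequence],
    events: list[ReadStartEvent],
    islands: Sequence[GenomicInterval],
    N: int,
    mask: Sequence[GenomicInterval] | None,
    min_cg_positions: int,
) -> list[IslandScore]:
    grouped = _events_by_contig(events, genome)
    class_cache: dict[str, np.ndarray] = {}
    sorted_pos: dict[str, np.ndarray] = {
        c: np.sort(p) for c, p in grouped.items()
    }
    scores: list[IslandScore] = []
    for island in islands:
        if island.contig not in genome:
            raise InputError(f"island contig {island.contig!r} absent from genome")
        if island.contig not in class_cache:
            class_cache[island.contig] = dinucleotide_classes(
                genome[island.contig], None, mask
            )
        D = class_cache[island.contig]
        # pairs fully inside the island: positions t in [start+1, end)
        t_lo, t_hi = island.start + 1, min(island.end, len(D))
        window = D[t_lo:t_hi]
        informative = int((window >= 0).sum())
        cg = int((window == CG_CODE).sum())
        if cg == 0:
            scores.append(
                IslandScore(island.id, island.contig, island.start, island.end,
                            0, 0.0, float("nan"), "no_cg")
            )
            continue
        if cg < min_cg_positions:
            scores.append(
                IslandScore(island.id, island.contig, island.start, island.end,
                            0, cg / informative, float("nan"), "low_cg")
            )
            continue
        p_island = cg / informative
        pos = sorted_pos.get(island.contig, np.empty(0, dtype=np.int64))
        lo = np.searchsorted(pos, t_lo, side="left")
        hi = np.searchsorted(pos, t_hi, side="left")
        inside = pos[lo:hi]
        n = int((D[inside] == CG_CODE).sum()) if inside.size else 0
        rate = n / (N * p_island)
        scores.append(
            IslandScore(island.id, island.contig, island.start, island.end,
                        n, p_island, rate, "ok")
        )
    return scores


def island_scores_frame(scores: Sequence[IslandScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.island_id, s.contig, s.start, s.end, s.n, s.p_island, s.rate, s.status)
            for s in scores
        ],
        columns=["island_id", "contig", "start", "end", "n", "p_island", "rate", "status"],
    ).set_index("island_id")


def write_island_scores(scores: Sequence[IslandScore], path) -> None:
    island_scores_frame(scores).to_csv(path, sep="\t", float_format="%.10g")


def read_island_scores(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", index_col="island_id")
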