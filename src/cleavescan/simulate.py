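"""Synthetic genomes, methylation maps and break events with known truth.

The generative model is the exact inverse of the cleavage-rate estimator:
every informative genome position i (one with a defined dinucleotide pair
(i-1, i)) carries a sampling weight given by its class, and break events
are drawn independently with probability proportional to that weight.
Under this model the estimated rate ratios r(XY)/r(X'Y') converge to the
weight ratios w(XY)/w(X'Y'), which makes the simulator the ground-truth
oracle for the estimator, the island scorer and the classifier.

Defaults emulate the study conditions at desk scale: a 100-kb genome with
20 CpG islands of 500 bp, a methylated CpG cleaving 1.5x more readily than
an unmethylated one, cohorts of 20 tumor + 20 normal samples at 1e5 reads
each, and tumor demethylation modelled as a weight multiplier on the CG
positions of a few affected islands.

No fragment-length model and no read sequences: only 5'-start coordinates
matter to the method, so independent per-position sampling is the minimal
sufficient generative model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cleavage import (
    ANNOTATED_LABELS,
    CG_FAMILY_CODES,
    CMG_CODE,
    CUG_CODE,
    CXG_CODE,
    CG_CODE,
    DINUCLEOTIDES,
    dinucleotide_classes,
)
from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    MethylationCall,
    MethylationMap,
    MethylStatus,
    write_bed,
    write_fasta,
    write_labels,
    write_methylation_calls,
)
from .read_extraction import ReadStartEvent, write_events_tsv

logger = logging.getLogger(__name__)

BASES = "ACGT"


def default_weights(cmg: float = 1.5) -> dict[str, float]:
    """Uniform break weights except a configurable methylated-CpG boost."""
    weights = {d: 1.0 for d in DINUCLEOTIDES}
    weights.update({"CmG": cmg, "CuG": 1.0, "CxG": 1.0})
    return weights


@dataclass
class FragmentationModel:
    """Per-class break weights plus a read budget and seed.

    Weights are relative propensities (all strictly positive); the
    probability of a break at position i is weight(class(i)) divided by
    the total weight over informative positions.
    """

    weights: dict[str, float] = field(default_factory=default_weights)
    n_reads: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for label, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"break weight for {label} must be > 0, got {w}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")

    def weight_vector(self) -> np.ndarray:
        """Weights indexed by class code (19 slots; CG falls back to the
        mean of its annotated sub-classes if not given explicitly)."""
        vec = np.zeros(19)
        for code in range(16):
            label = DINUCLEOTIDES[code]
            vec[code] = self.weights.get(label, 1.0)
        vec[CMG_CODE] = self.weights.get("CmG", 1.0)
        vec[CUG_CODE] = self.weights.get("CuG", 1.0)
        vec[CXG_CODE] = self.weights.get("CxG", 1.0)
        if "CG" in self.weights:
            vec[CG_CODE] = self.weights["CG"]
        else:
            vec[CG_CODE] = (vec[CMG_CODE] + vec[CUG_CODE]) / 2
        return vec


@dataclass
class SyntheticGenomeSpec:
    """Layout of a synthetic genome with CG-enriched islands.

    ``base_composition`` gives (A, C, G, T) background frequencies;
    ``island_cg_enrichment`` multiplies the chance CpG-start density
    inside islands.  Methylation ground truth: island CpGs are
    unmethylated and background CpGs methylated, with small noise
    fractions flipped or set to unknown.
    """

    length: int = 100_000
    n_islands: int = 20
    island_length: int = 500
    island_cg_enrichment: float = 4.0
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    island_meth_noise: float = 0.05
    background_unmeth_noise: float = 0.05
    unknown_frac: float = 0.05
    edge_margin: int = 200
    contig_name: str = "sim1"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.island_cg_enrichment < 1:
            raise ValueError("island_cg_enrichment must be >= 1")


def _island_sequence(rng: np.random.Generator, length: int, comp: np.ndarray,
                     enrichment: float) -> str:
    """CG-enriched sequence: emit a CG block with probability q per step,
    a composition-drawn base otherwise; q targets the enriched density."""
    p_cg = comp[1] * comp[2]  # chance CG-start density of the background
    d = enrichment * p_cg
    if d >= 0.5:
        raise ValueError(
            f"island CG target density {d:.3f} unreachable (enrichment too high)"
        )
    q = d / (1 - d)
    chars: list[str] = []
    while len(chars) < length:
        if rng.random() < q:
            chars.extend("CG")
        else:
            chars.append(BASES[rng.choice(4, p=comp)])
    return "".join(chars[:length])


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, GenomeSequence], list[GenomicInterval], MethylationMap]:
    """Generate a genome, its island annotation and its methylation map.

    Islands are placed without overlap in evenly spaced slots (jittered
    within each slot) at least ``edge_margin`` bases from the contig ends,
    so default background windows are never truncated at islands.  With
    enrichment factor 1, island sequence is drawn exactly like background.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition)
    codes = rng.choice(4, size=spec.length, p=comp)
    seq = np.frombuffer("ACGT".encode(), dtype="S1")[codes].tobytes().decode()
    seq_list = list(seq)

    islands: list[GenomicInterval] = []
    if spec.n_islands > 0:
        span = spec.length - 2 * spec.edge_margin
        slot = span // spec.n_islands
        if slot < spec.island_length + 1:
            raise ValueError(
                f"cannot place {spec.n_islands} non-overlapping islands of "
                f"{spec.island_length} bp in {span} usable bases"
            )
        for k in range(spec.n_islands):
            offset = int(rng.integers(0, slot - spec.island_length + 1))
            start = spec.edge_margin + k * slot + offset
            end = start + spec.island_length
            islands.append(GenomicInterval(spec.contig_name, start, end))
            if spec.island_cg_enrichment > 1:
                seq_list[start:end] = _island_sequence(
                    rng, spec.island_length, comp, spec.island_cg_enrichment
                )

    sequence = "".join(seq_list)
    genome = {spec.contig_name: GenomeSequence(spec.contig_name, sequence)}

    # methylation truth: island CpGs unmethylated, background methylated,
    # with noise flips and unknowns
    statuses: dict[tuple[str, int], MethylStatus] = {}
    island_starts = np.array([iv.start for iv in islands], dtype=np.int64)
    island_ends = np.array([iv.end for iv in islands], dtype=np.int64)

    def in_island(pos: int) -> bool:
        if not len(island_starts):
            return False
        k = np.searchsorted(island_starts, pos, side="right") - 1
        return k >= 0 and pos < island_ends[k]

    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    cpg_positions = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    u = rng.random(len(cpg_positions))
    for pos, roll in zip(cpg_positions.tolist(), u):
        island = in_island(pos)
        base = MethylStatus.UNMETHYLATED if island else MethylStatus.METHYLATED
        noise = spec.island_meth_noise if island else spec.background_unmeth_noise
        if roll < spec.unknown_frac:
            status = MethylStatus.UNKNOWN
        elif roll < spec.unknown_frac + noise:
            status = (
                MethylStatus.METHYLATED if island else MethylStatus.UNMETHYLATED
            )
        else:
            status = base
        statuses[(spec.contig_name, pos)] = status
    methylmap = MethylationMap(statuses)
    logger.info(
        "simulated genome: %d bp, %d islands, %d CpGs",
        spec.length, len(islands), len(statuses),
    )
    return genome, islands, methylmap


def simulate_breaks(
    genome: Mapping[str, GenomeSequence],
    model: FragmentationModel,
    methylmap: MethylationMap | None = None,
    mask: Sequence[GenomicInterval] | None = None,
    interval_weight_multipliers: Sequence[tuple[GenomicInterval, float]] = (),
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> list[ReadStartEvent]:
    """Draw ``model.n_reads`` break events with class-proportional weights.

    ``interval_weight_multipliers`` rescales the weight of CG-family
    positions inside given intervals (the tumor-demethylation knob used by
    :func:`simulate_cohort`).  Deterministic for a given seed/rng.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    wvec = model.weight_vector()
    contig_names: list[str] = []
    weight_chunks: list[np.ndarray] = []
    lengths: list[int] = []
    for name, contig in genome.items():
        D = dinucleotide_classes(contig, methylmap, mask)
        w = np.where(D >= 0, wvec[np.clip(D, 0, None)], 0.0)
        for iv, factor in interval_weight_multipliers:
            if iv.contig != name:
                continue
            t = np.arange(iv.start + 1, min(iv.end, len(D)))
            cg_family = np.isin(D[t], CG_FAMILY_CODES)
            w[t[cg_family]] *= factor
        contig_names.append(name)
        weight_chunks.append(w)
        lengths.append(len(w))
    weights = np.concatenate(weight_chunks)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no informative positions to sample breaks from")
    draws = rng.choice(len(weights), size=model.n_reads, p=weights / total)
    offsets = np.cumsum([0] + lengths[:-1])
    which = np.searchsorted(offsets, draws, side="right") - 1
    local = draws - offsets[which]
    return [
        ReadStartEvent(contig_names[k], int(pos), sample_id, "+")
        for k, pos in zip(which.tolist(), local.tolist())
    ]


@dataclass
class SyntheticCohortSpec:
    """A two-group cohort differing only through island weight multipliers.

    ``tumor_island_multiplier`` rescales CG-family break weights inside the
    ``n_affected_islands`` designated islands for tumor samples; 0.5
    emulates demethylation (methylated islands losing their elevated
    cleavage propensity).
    """

    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    model: FragmentationModel = field(default_factory=FragmentationModel)
    n_affected_islands: int = 3
    tumor_island_multiplier: float = 0.5
    samples_per_group: int = 20
    reads_per_sample: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if self.n_affected_islands > self.genome.n_islands:
            raise ValueError("more affected islands than islands")
        if not self.tumor_island_multiplier > 0:
            raise ValueError("tumor_island_multiplier must be > 0")


@dataclass
class SyntheticCohort:
    """Everything a downstream experiment needs, plus the ground truth."""

    genome: dict[str, GenomeSequence]
    islands: list[GenomicInterval]
    methylmap: MethylationMap
    events: dict[str, list[ReadStartEvent]]
    labels: dict[str, str]
    affected_islands: list[str]
    spec: SyntheticCohortSpec


def simulate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Simulate per-sample break events for a tumor/normal cohort.

    All samples share the genome, methylation map and base fragmentation
    model; tumor samples additionally apply the island weight multiplier
    to the affected islands.  Group labels are TUMOR / NORMAL.
    """
    master = np.random.SeedSequence(spec.seed)
    genome_seed, pick_seed, *_ = master.spawn(2)
    genome_spec = SyntheticGenomeSpec(
        **{**asdict(spec.genome), "seed": int(genome_seed.generate_state(1)[0] % 2**31)}
    )
    genome, islands, methylmap = simulate_genome(genome_spec)

    pick_rng = np.random.default_rng(pick_seed)
    affected_idx = sorted(
        pick_rng.choice(len(islands), size=spec.n_affected_islands, replace=False).tolist()
    )
    affected = [islands[i] for i in affected_idx]

    events: dict[str, list[ReadStartEvent]] = {}
    labels: dict[str, str] = {}
    n_groups = spec.samples_per_group
    sample_seeds = master.spawn(2 * n_groups)
    model = FragmentationModel(
        weights=dict(spec.model.weights), n_reads=spec.reads_per_sample
    )
    k = 0
    for group, multiplier in (("NORMAL", 1.0), ("TUMOR", spec.tumor_island_multiplier)):
        for j in range(n_groups):
            sample_id = f"{group.lower()}_{j:02d}"
            rng = np.random.default_rng(sample_seeds[k])
            k += 1
            mult = (
                [(iv, multiplier) for iv in affected] if multiplier != 1.0 else []
            )
            events[sample_id] = simulate_breaks(
                genome,
                model,
                methylmap,
                interval_weight_multipliers=mult,
                rng=rng,
                sample_id=sample_id,
            )
            labels[sample_id] = group
    return SyntheticCohort(
        genome=genome,
        islands=islands,
        methylmap=methylmap,
        events=events,
        labels=labels,
        affected_islands=[iv.id for iv in affected],
        spec=spec,
    )


# ---------------------------------------------------------------------------
# On-disk dataset in the pipeline's native formats


def synthetic_calls_from_map(
    methylmap: MethylationMap, coverage: int = 50
) -> list[MethylationCall]:
    """Bisulfite-call rows whose thresholded statuses reproduce the map.

    Synthetic counts: METHYLATED -> coverage/coverage, UNMETHYLATED ->
    0/coverage, UNKNOWN -> intermediate ratio (coverage/2).
    """
    calls = []
    for (contig, pos), status in sorted(methylmap.items()):
        meth = {
            MethylStatus.METHYLATED: coverage,
            MethylStatus.UNMETHYLATED: 0,
            MethylStatus.UNKNOWN: coverage // 2,
        }[status]
        calls.append(MethylationCall(contig, pos, coverage, meth))
    return calls


def save_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort in the formats the pipeline consumes, plus a
    manifest JSON recording the spec, seed and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.genome, outdir / "genome.fa")
    write_bed(cohort.islands, outdir / "islands.bed")
    cohort.methylmap.to_tsv(outdir / "methylation_map.tsv")
    write_methylation_calls(
        synthetic_calls_from_map(cohort.methylmap), outdir / "methylation_calls.tsv"
    )
    events_dir = outdir / "events"
    events_dir.mkdir(exist_ok=True)
    for sample_id, events in cohort.events.items():
        write_events_tsv(events, events_dir / f"{sample_id}.tsv")
    write_labels(cohort.labels, outdir / "labels.tsv")
    manifest = {
        "spec": asdict(cohort.spec),
        "affected_islands": cohort.affected_islands,
        "samples": sorted(cohort.events),
    }
    with open(outdir / "manifest.json", "wt") as out:
        json.dump(manifest, out, indent=1)
    logger.info("cohort written to %s", outdir)
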