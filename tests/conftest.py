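"""Shared fixtures: tiny hand-built genomes and session-scoped simulations."""

from collections import Counter

import numpy as np
import pytest

from cleavescan import (
    GenomeSequence,
    MethylationMap,
    MethylStatus,
)
from cleavescan.simulate import SyntheticCohortSpec, simulate_cohort


def naive_cleavage_rates(genome, events, methylmap=None, mask_intervals=None,
                         half_width=100):
    """Independent brute-force oracle for the streaming rate computation.

    Explicit Python loops over every event and every window position; shares
    no code with cleavescan.cleavage.compute_cleavage_rates.
    Returns (n, p, r, N) as dicts keyed by class label.
    """
    masked = set()
    for iv in mask_intervals or ():
        for pos in range(iv.start, iv.end):
            masked.add((iv.contig, pos))

    status_label = {
        MethylStatus.METHYLATED: "CmG",
        MethylStatus.UNMETHYLATED: "CuG",
        MethylStatus.UNKNOWN: "CxG",
    }

    def pair_label(contig_name, t):
        seq = genome[contig_name].sequence
        if t < 1 or t >= len(seq):
            return None
        a, b = seq[t - 1], seq[t]
        if "N" in (a, b):
            return None
        if (contig_name, t - 1) in masked or (contig_name, t) in masked:
            return None
        pair = a + b
        if pair == "CG" and methylmap is not None:
            return status_label[methylmap.status(contig_name, t - 1)]
        return pair

    n = Counter()
    bg = Counter()
    N = 0
    for ev in events:
        L = len(genome[ev.contig])
        if ev.pos - half_width < 0 or ev.pos + half_width > L:
            continue
        label = pair_label(ev.contig, ev.pos)
        if label is None:
            continue
        N += 1
        n[label] += 1
        for t in range(ev.pos - half_width + 1, ev.pos + half_width):
            wlabel = pair_label(ev.contig, t)
            if wlabel is not None:
                bg[wlabel] += 1
    total = sum(bg.values())
    p = {label: count / total for label, count in bg.items()}
    r = {label: n[label] / (N * p[label]) for label in p if p[label] > 0}
    return dict(n), p, r, N


@pytest.fixture
def toy_genome():
    return {"c1": GenomeSequence("c1", "AACGT")}


@pytest.fixture
def toy_methylmap():
    return MethylationMap({("c1", 2): MethylStatus.METHYLATED})


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (20 + 20 samples,
    1e5 reads each, 2x island break-weight shift on 3 affected islands).
    Session-scoped: it backs both classifier and ranking checks."""
    return simulate_cohort(SyntheticCohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_cohort_matrix(default_cohort):
    from cleavescan import build_matrix, score_islands

    cohort = default_cohort
    tables = {}
    for sample_id, events in cohort.events.items():
        scores = score_islands(cohort.genome, events, cohort.islands)
        tables[sample_id] = {s.island_id: s.rate for s in scores}
    return build_matrix(tables, cohort.labels)
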