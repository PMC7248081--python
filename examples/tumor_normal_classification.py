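"""Tumor/normal classification from island cleavage-rate vectors.

Simulates a cohort of 8 tumor + 8 normal samples in which three designated
islands lose half their CpG break weight in tumours (demethylation), builds
the samples x islands feature matrix, evaluates a linear SVM by balanced
jack-knife and ranks islands by group difference.
"""

from cleavescan import build_matrix, jackknife_evaluate, rank_islands, score_islands
from cleavescan.simulate import SyntheticCohortSpec, simulate_cohort

spec = SyntheticCohortSpec(samples_per_group=8, reads_per_sample=100_000, seed=5)
cohort = simulate_cohort(spec)
print(f"affected islands (ground truth): {cohort.affected_islands}")

tables = {}
for sample_id, events in cohort.events.items():
    scores = score_islands(cohort.genome, events, cohort.islands)
    tables[sample_id] = {s.island_id: s.rate for s in scores}
matrix = build_matrix(tables, cohort.labels)

report = jackknife_evaluate(matrix, rounds=50, seed=1)
s = report.summary()
print(
    f"jack-knife ({s['rounds']} rounds, {s['holdout_per_class']}/class held out): "
    f"TP%={s['tp_pct']:.1f} TN%={s['tn_pct']:.1f} accuracy={s['accuracy_pct']:.1f}%"
)

ranking = rank_islands(matrix, k=5)
print("\ntop 5 islands by |tumor - normal| cleavage-rate difference:")
print(ranking.round(4))
print(
    "\nNegative differences mean lower CpG cleavage in tumours, the signature\n"
    "of island demethylation; the truly affected islands should lead the list."
)
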