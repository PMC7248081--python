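# Methods

## Model and estimator

DNA shearing during library preparation breaks the backbone with a
dinucleotide-dependent propensity; in particular cytosine methylation
raises the cleavage rate of CpG. The observable is the 0-based genomic
coordinate *i* of each aligned read's 5′-terminal base, taken as the break
point; the dinucleotide of a break is the reference pair at (i−1, i).

For each class XY the cleavage rate is estimated as

r(XY) = n(XY) / (N · p(XY))

with n(XY) the break count on XY, N the total classified break count, and
p(XY) the *local background*: the fraction of XY among informative
dinucleotide positions in the 200-bp windows [i−100, i+100) centred on the
same events. Normalising against event-centred windows rather than the
whole genome cancels composition and mappability biases of read placement.
Under a model in which breaks occur independently with per-position weight
w(class), the expectation of r(XY) is w(XY)/w̄ (w̄ the weight averaged
over informative positions), so **ratios** of rates estimate ratios of
weights; the uniform model gives r ≡ 1.

### Classes

Without methylation information there are the 16 standard dinucleotides.
With a methylation map, CG is split by the status of its C into CmG
(methylated), CuG (unmethylated) and CxG (undetermined), for 18 classes.
All three CG sub-classes are fully informative — they enter both n and the
background p — which keeps the estimator unbiased for every class; CxG is
simply never used in the methylated-vs-unmethylated contrast. Sites are
keyed by the forward-strand C; the paired reverse-strand CpG is not
tracked separately (CpG is treated as a strand-symmetric unit and the
default read filter is forward-strand only).

### Accounting rules

Applied identically to numerator and denominator so both are drawn from
the same event set:

* an event whose window is truncated by a contig edge is excluded from
  both n and p;
* an event whose break pair is undefined (i = 0), contains N, or overlaps
  a masked base is discarded (tallied for audit) and contributes no
  window;
* a dinucleotide containing N or overlapping a masked base is
  uninformative for the background;
* p is *pooled*: summed pair counts over all windows divided by summed
  informative positions (with full windows and no masking this equals the
  mean of per-window fractions, and it remains well-behaved when masking
  makes windows unequal).

### Methylation map

Bisulfite calls (contig, C position, coverage, methylated count) are
thresholded: a CpG is METHYLATED when coverage is strictly greater than 10
reads and strictly more than 90% of them are methylated, UNMETHYLATED
symmetrically, otherwise UNKNOWN. Both thresholds are deliberate strict
inequalities. Calls are validated against the reference (C at the
position, G next) to catch assembly mismatches; validation is downgradable
to a warning.

### Read filtering

The default policy keeps alignments with flag bits 35 set (paired, proper
pair, mate reverse — hence read on the forward strand) and bit 4 clear
(mapped), on the 22 autosomes, with no mapping-quality floor and
duplicates kept — the estimator is insensitive to these choices, and the
minimal filter is the most reproducible. Reads whose alignment begins
with a soft clip are dropped (the clip hides the true fragment end). A
reverse-strand mode exists (5′ end = rightmost aligned base, dinucleotide
read as reverse complement); average rates do not depend on the strand
choice, and forward-only is the default.

## Island scoring

An island's score is r restricted to the island: n counts CG-family breaks
at positions whose dinucleotide lies fully inside the island
([start+1, end)), p is the CG fraction among the island's own informative
pairs (the same position universe as n), and N is the **sample-wide**
event total, which makes scores comparable across samples of different
depth. The absolute scale therefore carries an island-length/genome-length
factor; only contrasts across samples and islands are interpreted. Islands
with fewer than 5 informative CG positions (configurable) are reported as
missing with a reason code rather than as noisy zeros; zero breaks in a
scoreable island is a true 0, distinct from missing.

## Classification and evaluation

Per-sample island scores are assembled into a samples × islands matrix
(outer union of islands; islands missing in > 20% of samples dropped;
remaining gaps imputed with the column median — island coverage gaps are
the method's main practical failure mode, and the filter keeps them from
dominating). Features are z-scored from the training rows (margin
classifiers are scale-sensitive and island rates vary with CG density),
and a linear-kernel SVM with C = 1.0 (the conventional default) is fitted
after equalising class counts by seeded down-sampling. Decision values
> 0 predict TUMOR; an exact 0 predicts NORMAL (arbitrary, documented,
stable). The persisted model carries feature order, scaling constants and
training medians, so prediction is self-contained and missing features are
imputed consistently.

Evaluation is a balanced jack-knife: each round removes a seeded random
holdout of equal size per class (default 20% of the smaller class, at
least 1), trains on the remainder and scores the holdout. Reported
percentages follow sensitivity/specificity conventions: TP% + FN% = 100
over held-out tumours, TN% + FP% = 100 over held-out normals. Identical
inputs and seed reproduce the report exactly. Because rounds reuse the
same samples, aggregated percentages are not independent Bernoulli draws;
chance-level bands should be computed at the number of independent
samples per class, not at rounds × holdout.

Island ranking orders islands by |mean(tumor) − mean(normal)| of their
scores, reporting the signed difference so demethylation (negative) is
distinguishable from hypermethylation; ties break lexicographically by
island id.

## The simulator

The generator inverts the estimator's model exactly: every informative
position carries a weight given by its class and breaks are drawn
independently in proportion — the minimal generative model sufficient for
a statistic that only uses 5′-start counts. Defaults define the study
conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| genome length | 100 kb | full pipeline in seconds |
| base composition (A,C,G,T) | 0.30, 0.20, 0.20, 0.30 | mild AT richness, human-like |
| islands | 20 × 500 bp, CpG density 4× background | CpG-island-like enrichment |
| methylation truth | island CpGs unmethylated, background methylated | CpG-island biology |
| methylation noise | 5% flipped, 5% unknown per stratum | imperfect bisulfite maps |
| CmG weight | 1.5 (others 1.0) | the observed methylated/unmethylated cleavage contrast |
| cohort | 20 + 20 samples, 1e5 reads each | balanced two-group design |
| tumor effect | CG-family weight × 0.5 in 3 affected islands | island demethylation |

Island sequence is generated by emitting CG blocks with a probability
chosen so the expected CpG-start density is the enrichment factor times
the background's chance density (at factor 1 the island is drawn exactly
like background, so equality is exact, not approximate). Methylation
statuses are written both as a status map and as synthetic bisulfite call
rows whose thresholded statuses reproduce the map, making the on-disk
dataset a full round-trip fixture for the whole pipeline.

What the simulator does **not** emulate: coverage variation and mapping
error, fragment-length structure and two-ended fragments, sequencing
error, strand asymmetries, chromosome structure, or the heterogeneity of
real tumours. Passing tests demonstrate estimator correctness and
end-to-end statistical behaviour under the stated generative model — not
performance on real WGS data, for which `docs/replication.md` gives the
protocol.

## Numerical and design choices

* The background window is symmetric, [i−100, i+100), giving 199
  overlapping pairs; symmetry is the least-informative reading of "around
  the read start".
* The streaming implementation uses per-class prefix sums over the contig,
  so window tallies are O(1) per event; tests pin it to an explicit
  brute-force loop at 1e-12 relative error.
* Rates with p = 0 are reported as missing (NaN), never as 0 or infinity;
  n = 0 with p > 0 is a true rate of 0.
* Zero-variance features z-score with scale 1 (constant columns carry no
  information either way).
* Jack-knife sub-seeds derive from one master generator, so a single seed
  reproduces every round.
* All randomness flows through numpy `SeedSequence`/`default_rng`; the
  same seed gives byte-identical outputs everywhere.

## Problem sizes

The test and acceptance workloads use the defaults above: brute-force
oracle comparisons on a 10-kb genome with 1e4 events, null and
weight-recovery checks at 1e6 events on 100-kb genomes, and the cohort
experiment at 40 × 1e5 events — the full suite runs in well under a
minute of compute for the estimator checks and a few seconds for the
classifier experiment.

## Known limitations

* Coverage is the binding constraint on real data: islands with few
  informative CpGs or shallow coverage yield unstable scores (hence the
  min-CG threshold and the matrix missingness filter).
* The method estimates *relative* cleavage preferences; absolute rates
  depend on the overall weight scale and are only meaningful as ratios.
* The 18-class contrast requires a methylation map from a matched cell
  type for the reference/control side; scored samples need none.
* Only 5′ ends of (by default) forward-strand reads are used; fragment 3′
  ends and longer sequence context are out of scope.
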