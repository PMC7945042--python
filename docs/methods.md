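# Methods

## Scaffold model

A scaffold graph is a directed graph of oriented contigs; edges carry a
signed gap estimate (negative = overlap) and a paired-end support count.
Orientations are assumed already resolved by the upstream scaffolder, so
edges read head-to-tail on the oriented sequences and a reverse-oriented
contig simply occupies its interval with sequence and depth reversed.
Scaffolds are the weakly connected components, ordered by smallest contig
id so every run enumerates them identically.

### Cycle breaking

Coordinates need an entry point (an in-degree-0 node), which cyclic
components lack. Minimum feedback arc set is NP-hard, so we use a greedy
heuristic: while any strongly connected subcomponent of size ≥ 2 remains,
take the vertex on a cycle with the lowest in-degree (ties to the
lexicographically smallest contig id — the tie rule is our choice, made
for determinism) and remove all its incoming edges. One removal pass per
offending vertex; iteration handles components with several cycles. The
heuristic may remove more edges than the optimum (measured mean excess
≈ 1 edge on dense 6-node graphs) but never edits an already-acyclic
component.

### Coordinates and span

All in-degree-0 contigs are seeded at provisional coordinate 0 and
relaxed in Kahn topological order (queue seeded lexicographically —
"breadth-first" made deterministic). Each edge u→v proposes
end(u) + gap(u,v) for start(v); v keeps the maximum proposal. On a DAG
this is exactly the longest path from any source, which we verify in
tests against exhaustive path enumeration. The maximum rule is what keeps
the two arms of a bubble pinned to the same reconvergence point: any
other tie-break would compress the layout and stack coverage that
belongs side by side. Because overlaps can push starts negative, the
frame is shifted so the minimum start is 0; span = maximum end.
Seeding *all* sources at 0 (rather than a single one) plus the shift
generalizes the single-source description deterministically to components
with several entry points.

Intervals are 0-based half-open everywhere, matching bedGraph, so no
coordinate convention changes hands at the coverage interface.

## Coverage

Depth enters as 4-column bedGraph per contig (the `genomecov -bga -split`
layout, with explicit zero intervals; missing positions are tolerated and
zero-filled with a warning). The scaffold track sums, at each span
position, the depth of every contig whose interval covers it. Gap
positions covered by no contig carry depth 0 and **are included** in the
mean/variance of the span: the change-point scan runs over the full span
signal, so its summary moments must describe the same signal. Variance is
the population variance (divide by n), matching its plug-in use in the Z
statistic.

Multi-sample abundance projects each sample's depth map independently
onto the final scaffold coordinates and reports (mean, variance) per
scaffold per sample. A sample lacking every contig of a scaffold gets
(0, 0) — absence of an organism from a sample is signal, not error. The
MetaBAT2-style writer reports `totalAvgDepth` as the sum of per-sample
means (the jgi_summarize convention); MaxBin 2.0 and CONCOCT writers
derive from the same table.

## Change-point detection

Per-base coverage of one organism is modelled as Poisson, approximated
Gaussian(μ, σ²). For each position i, the predecessor window covers
[i−|w|, i) and the successor [i, i+|w|), and

    Z(i) = (μ_{i−1} − μ_i) / √(σ²_{i−1} + σ²_i),   i ∈ [w, span − w].

Defaults: |w| = 1500 bp; for spans < 2|w| the window is divided by 5
(floor division) until it fits, and scaffolds whose window would drop
below 10 bp are passed through unexamined (a 0-width window is
meaningless; the floor value only decides when to give up on very short
scaffolds).

Implementation: means and variances come from cumulative sums of the
mean-centred track — centring bounds the cancellation error of the
E[x²] − μ² variance form, and the result agrees with naive per-window
recomputation to ≲1e−9 relative at every position.

### Candidate selection

The selection loop is where a published sliding-Z description leaves the
most freedom; our choices:

* **Two-tailed empirical percentiles.** Z ≤ α-th or Z ≥ (100−α)-th
  percentile of the scaffold's own empirical Z distribution (default
  α = 1). Tails are two-sided because a mis-join can step coverage in
  either direction. A perfectly flat Z distribution has no tails and
  yields no candidates.
* **Significance gate.** Percentile tails are *relative*: they flag
  ~2α% of positions of every scaffold, homogeneous or not. Under the
  model's own null (both windows sampling one Poisson organism),
  Var(Z) ≈ 1/|w|, and one scaffold scans ≈ span/|w| effectively
  independent window pairs; a candidate must therefore also satisfy
  |Z| ≥ z_{1−α/(200·n_eff)} / √|w| with n_eff = span/|w| — the two-sided
  level-(α/100) test of equal window means, Bonferroni-corrected for the
  scan. The gate is derived entirely from α, |w| and the span; it keeps
  the empirical false-split rate on homogeneous scaffolds at the few-
  percent level while leaving genuine junctions (|Z| of order 1)
  untouched.
* **Degenerate windows.** If both variances are 0 the statistic is
  undefined: equal means give Z = 0; unequal means are a certain
  discontinuity and become automatic candidates.
* **Merging.** Candidates within |w| of one another collapse onto the
  position of maximal |Z| (non-maximum suppression; degenerate flags rank
  above any finite |Z|). The radius is our choice — window-overlapping
  candidates describe the same discontinuity.

### Boundary matching and delinking

A candidate at p matches the nearest contig boundary b with |p − b| ≤ β
(default β = 150 bp, standing in for the read length; ties go to the
lexicographically smaller contig id, then start before end). A start
match removes the contig's incoming edges; an end match its outgoing
edges. Unmatched candidates are logged as `unresolved` and never edited:
mid-contig change points may be assembly errors, whose handling is out of
scope. Correction is a single pass — detect on the original layout, edit,
then re-extract components, coordinates and tracks once (an
iterate-to-convergence mode exists behind `ChangePointParams(iterate=True)`
but is off by default). Delinking only ever removes edges, so the contig
set is conserved and the final edge set is a subset of the input's.

## Synthetic communities

`simulate_community` emulates exactly what the pipeline consumes, with
recorded truth: random genomes with planted Poisson abundances, fragmented
into overlapping contigs (edge gap = −overlap, so a clean genome is a path
scaffold whose span equals the genome length), occasional reverse
orientations, and bubbles — two variant contigs over the same interval,
each at half the genome rate so the summed track matches the backbone.
Depth is drawn i.i.d. Poisson per base directly; reads are never
simulated because the pipeline only ever sees bedGraph. `plant_chimera`
appends a false edge from the end of one genome to the start of another
and records the junction; it warns when both genomes have equal depth,
since such a junction produces no discontinuity and is undetectable by
construction.

What the generator does **not** model: sequencing error and mappability
biases, GC-dependent coverage waves, repeat-induced coverage pileups,
gradual (non-step) abundance changes, and inter-genome homology. Passing
tests therefore demonstrate correctness of the algorithms under the
stated coverage model, not performance on real libraries — on real data
coverage is over-dispersed relative to Poisson, which widens the Z null
and makes detection conservative rather than anticonservative.

Study conditions used by the whole-method tests and the acceptance
script, chosen once as representative desk-scale sizes: 200 random DAGs
(≤ 10 nodes) for the coordinate oracle; 200 digraphs (≤ 50 nodes) for
cycle breaking; 100 coverage-conservation fixtures; 100 chimeric
replicates (10× joined to 50×, segments ≥ 6000 bp i.e. ≥ 4|w|) and 100
homogeneous replicates (constant rate 20×, span 14 kb) for the
detection rates; and an end-to-end community of 10 genomes × 15 kb with
abundances 10–65× (chimera partners differing ≥ 2-fold) and 5 planted
chimeras.

## Bin evaluation

Bins are assigned to the genome receiving the majority of aligned base
pairs (ties: lexicographically first, with a warning). Completeness
= 100 · (distinct genome bases covered by the bin's alignments to the
assigned genome)/genome length — genome-side intervals are merged before
counting, the only reading under which the metric stays ≤ 100%.
Contamination = 100 · (bin bp not aligned to the assigned genome)/bin bp,
a bin-side count without deduplication, clipped to [0, 100]. "Aligned bp"
is the target-interval length of each PAF record (not the match count);
the choice matters only for gapped alignments and is recorded here.

## Known limitations

* **Overlap double-counting.** Where two contigs overlap, both carry the
  full read depth, so the summed track spikes by ~2× over the overlap —
  and overlaps sit exactly at contig boundaries, where the matcher looks.
  Strong overlap spikes can occasionally delink a correct join; the
  significance gate suppresses most, and a false split merely shortens a
  scaffold without polluting bins.
* Change points inside contigs are reported but never acted on.
* Multiple strains through a bubble are summed, not resolved; the span
  model represents the longest consistent layout, not a haplotype path.
* The feedback-arc heuristic is not optimal; it only guarantees
  acyclicity with at least one entry point.
* One organism = one abundance: the Poisson-rate model has no within-
  genome coverage trend, so a genuinely uneven genome may trigger
  boundary-coincident candidates on real data.
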