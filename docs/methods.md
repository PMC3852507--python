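# Methods

## Model and assumptions

`mran` treats miRNA cooperativity as condition-specific target sharing.
The inputs are (a) per-condition miRNA and mRNA expression matrices with
matched sample columns, assumed already normalized to a log-intensity
scale (only finiteness is validated; normalization is an upstream
concern), and (b) a static sequence-based miRNA→target table, consumed
as a file and never recomputed. Identifiers are joined
case-insensitively after trimming; species prefixes are kept verbatim
and no orthology mapping is attempted. When a sample-metadata map is
supplied, replicate columns are collapsed to per-cell means
(`collapse_replicates`) so unbalanced replication between the miRNA and
mRNA arrays still yields matched columns.

### Inverse-expression filter

A static pair survives in condition *c* iff both members are measured
and the sample Pearson correlation is strictly below `r_max` (default
0, i.e. plain `r < 0`). An optional one-sided correlation t-test at
`alpha_corr` tightens this for stricter runs; the default imposes no
p-value cut because the sign criterion alone defines the filter.
Zero-variance features make the correlation undefined and are skipped
(counted, as are unmeasured pairs). At least three matched samples are
required (correlation df ≥ 1).

### Overlap score and significance

The target overlap score is the Jaccard coefficient of two miRNAs'
condition-specific target sets (defined as 1 on the diagonal). Its
significance is the probability that two uniformly drawn sets of the
observed sizes, from the condition's target universe, overlap at least
as much — the hypergeometric upper tail, which is exactly the exhaustive
randomization of set membership at fixed sizes. The universe is the
union of all condition target sets in that condition (the analysis is
scoped to condition-active genes), overridable via the `universe`
argument when a larger gene background is preferred. A Monte-Carlo
permutation mode (explicit random-set sampling, add-one estimator
`(hits + 1)/(n_perm + 1)`, default `n_perm = 1000`) serves as a
cross-check; the exact tail is the default because it is deterministic
and testable against enumeration. Edges require `t > 0` and
`p < alpha_edge` (strict, default 0.05); weights are `1 − p`, a bounded
monotone transform of significance; both `t` and `p` are stored so any
other transform is recoverable.

### Module extraction

Condition networks are merged into a simple graph whose edges carry the
per-condition `(condition, t, p)` records — clustering runs on the
collapsed simple view, so duplicated condition edges never double
connectivity, while condition multiplicity stays available as
annotation. Module detection re-implements the molecular-complex
procedure: vertex weight = `k_max ×` density of the highest k-core of
the closed neighborhood (loop-free density `2E/(n(n−1))`; isolated
vertices weigh 0); seeds processed in descending weight; breadth-first
expansion admits unvisited neighbors with weight `> seed × (1 − vwp)`;
each vertex joins at most one complex during prediction. Post-processing
applies haircut (iterative removal of degree-<2 members), drops
complexes lacking a 2-core, and optionally "fluffs" boundary neighbors
whose closed-neighborhood density exceeds `fluff_density`. Defaults are
the canonical published ones: `vwp = 0.2`, haircut on, fluff off,
2-core filter. Ties in vertex weight and in module score
(`density × size`) break lexicographically on miRNA ids, making runs
bit-reproducible; edge weighting inside the detector is unweighted.
Module annotation pools each member's condition-specific targets over
every condition that contributes an intra-module edge.

### Regulator co-occurrence and pathway enrichment

Motif pairs are tested with the cumulative hypergeometric tail
`P(C ≥ c') = Σ_{i=c'}^{min(m1,m2)} C(m1,i) C(N−m1, m2−i) / C(N, m2)`
where `N` is the scope size (one condition's network nodes, tested per
condition so results carry the condition label), Bonferroni-corrected by
the number of tested pairs in that scope (recorded in the output for
auditability), default α = 1e-5. Pathway enrichment uses the same tail
on module target sets, uncorrected at α = 0.05 — the asymmetry between
the two regimes is deliberate: a genome-scale motif-pair screen needs
stringent family-wise control, while the pathway readout is an
exploratory display. The enrichment background defaults to the genes measured in
the contributing conditions' mRNA matrices (the conservative choice),
configurable to the pathway-collection universe. The heat-map matrix of
`−log10 p` drops modules and pathways with no significant cell.

### Sequence and structure comparison

Sequence similarity is global-alignment identity (match 1, mismatch 0,
linear gap −1; identity = matches / alignment length along a
deterministic traceback, computed in canonical argument order so it is
symmetric). This replaces consistency-based multiple alignment with a
self-contained exact pairwise method; the scoring parameters are stated
in every report header. Structure distance is the ordered tree edit
distance (Zhang–Shasha dynamic program; unit insert/delete/relabel
costs, pair-vs-unpaired relabel costs 1) on the standard tree encoding
of dot-bracket strings — pairs are internal nodes, unpaired positions
leaves, under a virtual root. `base_pair_distance` (symmetric difference
of pair sets) is provided as a fast alternative for equal-length
structures. The within/between/random comparison pools all member pairs
within modules, all pairs spanning two modules (subsampled to
`n_random_pairs` when larger, seeded), and uniformly drawn record pairs
(matched in count to the within set, seeded); the structure layer is
negated so "more similar" is one test direction across layers, and
p-values come from the one-sided rank-sum test. With a single module the
between comparison is reported absent. Records carrying species
prefixes (hsa-, mmu-, …) are analyzed per species; otherwise pooled.

The rank-sum test enumerates the exact distribution when `n + m ≤ 12`
without ties, otherwise uses the normal approximation with tie
correction and no continuity correction (so a fully tied comparison
reports p = 1, and so does the degenerate all-equal case). The unpaired
rank-sum test is used throughout: the comparisons are between
independent pools of pairwise scores, for which a signed-rank (paired)
test has no defined pairing.

## Synthetic studies and what they show

The generator plants, per group of co-regulated miRNAs: a shared target
pool (`shared_target_fraction` of each member's `targets_per_mirna`
targets, default 0.8 × 20, plus private targets), anti-correlated
expression, a TF-motif pair, and a hairpin structure family. Defaults:
3 groups of 5 among 60 miRNAs, 400 genes, 12 samples, 2 conditions,
planted correlation −0.8, gene and miRNA noise sd 0.3, baseline 8 (log2
intensity scale). Each group is active in one condition
(`g mod n_conditions`), so cooperativity is condition-specific.

Shared genes are driven by a per-group latent activity (members =
baseline + latent + noise; gene = baseline − β·latent + noise) because
one shared gene cannot be simultaneously anti-correlated with five
*independent* miRNAs; private genes follow the member-driven form
gene = baseline − β′·(member − baseline) + noise. Both slopes are solved
in closed form so the expected pair correlation equals
`anti_corr_strength`; a side effect is within-group miRNA–miRNA
correlation ≈ 0.92, in line with tightly co-regulated families. Planted
target pools are group-exclusive: background miRNAs draw their targets
from the remaining genes, so background target sharing is mutual noise
rather than systematic linkage into planted modules. Planted TF pairs
are additionally carried (co-occurring) by five background miRNAs,
putting the planted co-occurrence signal past the Bonferroni bar while
group-only carriage would sit just above it.

Hairpin families are structure families: each group has a skeleton
(outer stem 10–14 bp, internal loop, inner stem 5–8 bp, terminal loop
4–7 nt) and members receive structure-preserving point mutations —
paired positions resampled as Watson–Crick pairs, loop positions
resampled from a non-pairing alphabet — at `resample_fraction` (default
1.0, i.e. full resampling). Unconstrained point mutations cannot
produce the structure-similar / sequence-dissimilar regime: a mutation
rate high enough to erase sequence identity also destroys the fold.
`conserve_seed=True` optionally keeps the template's seed block
(residues 2–8 plus pairing partners) for seed-layer studies, at the
cost of measurable precursor-sequence similarity. Background miRNAs get
independent random skeletons. Precursors are folded by base-pair
maximization (Watson–Crick + GU wobble, minimum loop 3, deterministic
traceback preferring pairing, then the leftmost partner).

What passing tests show — and do not. The generator is linear-Gaussian
with exclusive target pools and exact hairpin families; it contains no
probe effects, saturation, batch structure, correlated background
biology, or imperfect target predictions. Recovery of planted modules
(score ≥ 0.9 in ≥ 9/10 seeds at the defaults; ≤ 0.2 when sharing is
removed) therefore validates the machinery — filtering, scoring,
significance, clustering — not the method's power on real microarray
data, where the signal-to-noise is unknowable without the original
arrays.

## Numerical choices and degenerate inputs

- p-values are compared to thresholds with strict `<` throughout.
- Floats are serialized with `repr` (17 significant digits), so network
  round-trips are exact to well past 12 digits.
- Unbalanced dot-brackets report the first offending position; a string
  left open at the end reports position = string length.
- Fewer than two miRNAs with condition targets yields a valid edgeless
  network with a warning, not an error.
- Jaccard on an empty set is an error by contract: such miRNAs must
  have been dropped by the filter.
- All stochastic routines (permutation significance, pair subsampling,
  the generator) take explicit seeds; the pipeline writes its seed into
  `run_log.yaml` and `summary.json`, and identical config + seed gives
  byte-identical outputs.

## Problem sizes

Default study and test sizes (60 miRNAs, 400 genes, 12 samples, 2
conditions; 10 replicate seeds for recovery; ~60 folded precursors of
45–60 nt; enumeration oracles at N ≤ 12, trees ≤ 7 nodes, alignments to
length 12) were chosen so every property is checkable by exhaustive or
replicated computation while remaining comfortably interactive.

## Known limitations

- "Exact randomization" is realized as the closed-form hypergeometric
  tail; for universes so small that the null is lumpy, the permutation
  cross-check is the honest comparator.
- The inverse filter uses the sign of the correlation only (by default);
  with few samples, half of all null pairs pass it. Downstream overlap
  significance absorbs most of this, but some background edges are
  expected and visible in every run.
- The folder maximizes base pairs, not free energy; folded structures
  are surrogates adequate for distance comparisons, not thermodynamic
  predictions.
- Alignment identity depends on the stated scoring scheme; it is not a
  substitute for consistency-based multiple alignment when alignments
  themselves are the object of study.
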