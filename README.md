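# mran — miRNA association networks and cooperative miRNA modules

MicroRNAs repress their target mRNAs post-transcriptionally, and most of
them do so cooperatively: several miRNAs share target genes and act
together in a condition-dependent way. `mran` identifies such
cooperating miRNAs from paired miRNA/mRNA expression profiles plus a
static (sequence-based) miRNA→target prediction table, without any
external web service or binary tool.

The method, per condition *c*:

1. **Condition-specific targets.** A predicted pair (miRNA *i*, gene
   *g*) is kept when the two are inversely co-expressed across matched
   samples, `PCC(i, g) < 0` (Pearson). The retained genes form the
   condition-specific target set `Targets_c(i)`.
2. **Target overlap score.** Each miRNA pair is scored by the Jaccard
   coefficient

   `t_ij = |Targets(i) ∩ Targets(j)| / |Targets(i) ∪ Targets(j)|` (and 1
   for *i* = *j*),

   with significance from the exact randomization null: two sets of the
   observed sizes drawn uniformly from the condition's target universe,
   i.e. the hypergeometric upper tail `P(K ≥ k)` (a Monte-Carlo
   permutation mode is available as a cross-check).
3. **Network.** Nodes are miRNAs with non-empty condition target sets;
   edges join pairs with `t_ij > 0` and `p < 0.05`, weighted by
   `a_ij = 1 − p_ij`. Per-condition networks are merged into a global
   miRNA association network (MRAN) whose edges remember every
   contributing condition.
4. **Cooperative miRNA modules (CMMs).** A from-scratch MCODE
   implementation (core-clustering-coefficient vertex weights, greedy
   seed expansion with the default vertex-weight percentage 0.2,
   haircut, 2-core filter) extracts densely connected modules.
5. **Characterization.** TF-motif pairs are tested for co-occurrence on
   the network's miRNAs (cumulative hypergeometric, Bonferroni,
   α = 1e-5); module target genes for pathway enrichment (hypergeometric,
   uncorrected α = 0.05, −log10 p heat-map matrix); and module members
   for sequence similarity (Needleman–Wunsch global-alignment identity
   of seed / mature / precursor sequences) and precursor secondary-
   structure similarity (Zhang–Shasha ordered tree edit distance on
   dot-bracket structures), compared within vs between modules vs random
   pairs with one-sided Wilcoxon rank-sum tests.

A seeded generator (`mran.simulate`) produces complete synthetic studies
with planted ground truth — co-regulated miRNA groups with shared
targets, latent-driven anti-correlation, planted TF-motif pairs, and
hairpin structure families — so the whole pipeline is testable end to
end. A base-pair-maximization (Nussinov) folder is included for the
synthetic precursors.

## Worked example

```sh
mran simulate --outdir demo --seed 1
mran run-all --config demo/config.yaml
```

prints

```
fixtures written to demo (3 planted groups)
global network: 60 miRNAs, 84 connections; 5 modules; outputs in demo/results
```

The simulated study has 60 miRNAs, 400 genes, 2 conditions and 3 planted
groups of 5 co-regulated miRNAs. The run recovers a 60-node, 84-edge
global MRAN and five modules (`demo/results/modules.tsv`):

```
module_id  n_mirnas  n_links  n_targets  members
1          5         10       36         mir-0001,...,mir-0005
2          5         10       36         mir-0006,...,mir-0010
3          5         10       36         mir-0011,...,mir-0015
4          4         5        49         mir-0025,mir-0034,mir-0038,mir-0046
5          3         3        33         mir-0056,mir-0058,mir-0059
```

Modules 1–3 are exactly the three planted groups (each a 5-clique with
10 links and 36 pooled condition-specific targets); modules 4–5 are
small background complexes arising from chance target sharing. The
sequence/structure report (`seqstruct_report.tsv`) shows the
structure-vs-sequence contrast the pipeline is designed to expose —
precursor *structures* within modules are far more similar than between
modules, while precursor *sequences* are not:

```
layer             p_within_vs_between   p_within_vs_random
seed              5.63e-01              3.19e-01
mature            1.86e-01              3.72e-01
precursor_seq     8.29e-01              6.06e-01
precursor_struct  4.22e-07              5.90e-05
```

and `cooccurrence.tsv` lists the planted TF-motif pairs, e.g.
`TF-g1a / TF-g1b` carried by 10 of 60 miRNAs with all 10 co-occurring
(p = 1.33e-11, Bonferroni 1.21e-09 < 1e-5).

Each stage is also available as its own subcommand (`build-net`,
`merge`, `modules`, `cooccur`, `enrich`, `seqstruct`) over the same
file formats: expression TSV (features × samples), two-column target and
motif TSVs, GMT gene sets, FASTA + Vienna dot-bracket hairpins, and
edge-list/GraphML networks.

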