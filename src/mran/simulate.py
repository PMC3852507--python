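"""Seeded synthetic study generator with planted ground truth.

The generator emulates the statistical structure of a paired
miRNA/mRNA co-transcriptomic study: groups of co-regulated miRNAs share
a large fraction of their predicted targets, their shared targets are
anti-correlated with every member through a per-group latent activity
(active in a subset of conditions only), TF-motif pairs are planted on
group members, and each group's precursors share a hairpin skeleton.
Everything is a deterministic function of the seed, so the full pipeline
can be benchmarked against the planted truth without any external data.

The expression model is linear-Gaussian on a log-intensity scale: the
standard surrogate for normalized microarray data.  It does not model
probe effects, saturation or batch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, GeneSetCollection, HairpinRecord,
                 MotifAnnotation, TargetMap, write_hairpins)
from .seqstruct import nussinov_fold, parse_dotbracket

__all__ = [
    "HairpinTemplate",
    "PlantedTruth",
    "SimulatedStudy",
    "make_truth",
    "simulate_dataset",
    "simulate_hairpins",
    "truth_recovery_score",
    "write_fixtures",
]

_WC_PAIRS = ("AU", "UA", "GC", "CG")
#: loop alphabet that cannot form canonical or wobble pairs with itself
_LOOP_BASES = "AC"


@dataclass(frozen=True)
class HairpinTemplate:
    """A group's precursor skeleton: dot-bracket shape plus a reference
    sequence compatible with it."""

    structure: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("template sequence/structure length mismatch")


@dataclass
class PlantedTruth:
    """Ground truth planted into a simulated study."""

    groups: list[list[str]]
    shared_target_fraction: float
    anti_corr_strength: float
    planted_motif_pairs: list[tuple[str, str]]
    structure_templates: list[HairpinTemplate]
    rng_seed: int
    active_conditions: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            overlap = seen & set(group)
            if overlap:
                raise ValueError(f"planted groups overlap on {sorted(overlap)}")
            seen |= set(group)
        if not 0 < self.shared_target_fraction <= 1:
            raise ValueError("shared_target_fraction must be in (0, 1]")
        if not -1 < self.anti_corr_strength < 0:
            raise ValueError("anti_corr_strength must be in (-1, 0)")


@dataclass
class SimulatedStudy:
    """A complete synthetic study in the pipeline's native types."""

    expression: dict[str, tuple[ExpressionMatrix, ExpressionMatrix]]
    targets: TargetMap
    motifs: MotifAnnotation
    hairpins: list[HairpinRecord]
    gene_sets: GeneSetCollection
    truth: PlantedTruth

    @property
    def conditions(self) -> list[str]:
        return sorted(self.expression)


def _mirna_ids(n: int) -> list[str]:
    return [f"mir-{i:04d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"gene-{i:04d}" for i in range(1, n + 1)]


def _random_template(rng: np.random.Generator) -> HairpinTemplate:
    """Sample a hairpin skeleton (outer stem, internal loop, inner stem,
    terminal loop) and fill it with a compatible random sequence."""
    a = int(rng.integers(10, 15))       # outer stem pairs
    b1 = int(rng.integers(1, 4))        # internal loop, 5' side
    c = int(rng.integers(5, 9))         # inner stem pairs
    loop = int(rng.integers(4, 8))      # terminal loop
    b2 = int(rng.integers(1, 4))        # internal loop, 3' side
    structure = ("(" * a + "." * b1 + "(" * c + "." * loop
                 + ")" * c + "." * b2 + ")" * a)
    sequence = _fill_structure(structure, rng)
    return HairpinTemplate(structure, sequence)


def _fill_structure(structure: str, rng: np.random.Generator,
                    base: str | None = None,
                    keep: frozenset[int] = frozenset()) -> str:
    """Assign bases compatible with a dot-bracket skeleton.

    Paired positions get random Watson-Crick pairs, unpaired positions
    non-pairing loop bases.  Positions in ``keep`` (1-based, pairs keep
    both partners) retain the bases of ``base``.
    """
    _, pairs = parse_dotbracket(structure)
    seq = list(base) if base is not None else [""] * len(structure)
    paired = {i for ij in pairs for i in ij}
    for (i, j) in sorted(pairs):
        if i in keep or j in keep:
            continue
        pair = _WC_PAIRS[rng.integers(0, len(_WC_PAIRS))]
        seq[i - 1], seq[j - 1] = pair[0], pair[1]
    for pos in range(1, len(structure) + 1):
        if pos in paired or pos in keep:
            continue
        seq[pos - 1] = _LOOP_BASES[rng.integers(0, len(_LOOP_BASES))]
    return "".join(seq)


def make_truth(
    n_groups: int = 3,
    group_size: int = 5,
    n_mirnas: int = 60,
    n_conditions: int = 2,
    shared_target_fraction: float = 0.8,
    anti_corr_strength: float = -0.8,
    rng_seed: int = 0,
) -> PlantedTruth:
    """Build the planted truth for the default study conditions.

    Groups occupy the first n_groups * group_size miRNA ids; group g is
    active (anti-correlated with its targets) in condition g mod
    n_conditions, so cooperativity is condition-specific.
    """
    if n_groups * group_size > n_mirnas:
        raise ValueError("planted groups exceed the miRNA population")
    rng = np.random.default_rng(rng_seed)
    ids = _mirna_ids(n_mirnas)
    groups = [ids[g * group_size:(g + 1) * group_size]
              for g in range(n_groups)]
    templates = [_random_template(rng) for _ in range(n_groups)]
    motif_pairs = [(f"TF-g{g + 1}a", f"TF-g{g + 1}b")
                   for g in range(n_groups)]
    active = {g: (g % n_conditions,) for g in range(n_groups)}
    return PlantedTruth(
        groups=groups,
        shared_target_fraction=shared_target_fraction,
        anti_corr_strength=anti_corr_strength,
        planted_motif_pairs=motif_pairs,
        structure_templates=templates,
        rng_seed=rng_seed,
        active_conditions=active,
    )


def _slopes(r: float, mirna_noise_sd: float,
            gene_noise_sd: float) -> tuple[float, float]:
    """Solve the regression slopes so planted pairs have expected
    Pearson correlation r (latent-driven shared genes, member-driven
    private genes)."""
    r = abs(r)
    var_mir = 1.0 + mirna_noise_sd ** 2
    if r ** 2 * var_mir >= 1.0:
        raise ValueError(
            f"anti_corr_strength {r} unreachable with miRNA noise sd "
            f"{mirna_noise_sd}: member-to-latent coupling is too weak")
    beta_shared = (r * np.sqrt(var_mir) * gene_noise_sd
                   / np.sqrt(1.0 - r ** 2 * var_mir))
    beta_private = (r * gene_noise_sd
                    / (np.sqrt(var_mir) * np.sqrt(1.0 - r ** 2)))
    return float(beta_shared), float(beta_private)


def simulate_dataset(
    n_mirnas: int = 60,
    n_genes: int = 400,
    n_samples: int = 12,
    n_conditions: int = 2,
    truth: PlantedTruth | None = None,
    targets_per_mirna: int = 20,
    noise_sd: float = 0.3,
    mirna_noise_sd: float = 0.3,
    baseline: float = 8.0,
    with_hairpins: bool = True,
    rng_seed: int | None = None,
) -> SimulatedStudy:
    """Generate a complete synthetic study with planted ground truth.

    Group members share ``shared_target_fraction`` of a group target pool
    plus private targets; in each group's active condition the shared
    genes follow gene = baseline - beta * latent + noise and private
    genes gene = baseline - beta' * (member - baseline) + noise, giving
    expected pair correlation anti_corr_strength.  Background miRNAs and
    genes are independent Gaussians.  The same seed reproduces the study
    byte for byte.
    """
    if truth is None:
        truth = make_truth(n_mirnas=n_mirnas, n_conditions=n_conditions,
                           rng_seed=rng_seed if rng_seed is not None else 0)
    seed = truth.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    mirnas = _mirna_ids(n_mirnas)
    genes = _gene_ids(n_genes)
    for group in truth.groups:
        if not set(group) <= set(mirnas):
            raise ValueError("planted group members outside the miRNA ids")

    n_shared = int(round(truth.shared_target_fraction * targets_per_mirna))
    n_private = targets_per_mirna - n_shared
    needed = sum(n_shared + n_private * len(g) for g in truth.groups)
    if needed > n_genes:
        raise ValueError(f"planted target pools need {needed} genes, only "
                         f"{n_genes} available")

    # --- static target map ------------------------------------------------
    cursor = 0
    shared_pool: dict[int, list[str]] = {}
    targets: dict[str, set[str]] = {}
    for gi, group in enumerate(truth.groups):
        shared = genes[cursor:cursor + n_shared]
        cursor += n_shared
        shared_pool[gi] = shared
        for member in group:
            private = genes[cursor:cursor + n_private]
            cursor += n_private
            targets[member] = set(shared) | set(private)
    planted_members = {m for g in truth.groups for m in g}
    background_genes = genes[cursor:]  # planted pools stay group-exclusive
    if len(background_genes) < targets_per_mirna:
        raise ValueError("not enough background genes for background "
                         "miRNA target sets")
    for mirna in mirnas:
        if mirna in planted_members:
            continue
        pick = rng.choice(len(background_genes), size=targets_per_mirna,
                          replace=False)
        targets[mirna] = {background_genes[i] for i in sorted(pick)}
    target_map = TargetMap({m: frozenset(g) for m, g in targets.items()})

    # --- expression -------------------------------------------------------
    beta_shared, beta_private = _slopes(truth.anti_corr_strength,
                                        mirna_noise_sd, noise_sd)
    expression: dict[str, tuple[ExpressionMatrix, ExpressionMatrix]] = {}
    for cond_idx in range(n_conditions):
        label = f"cond{cond_idx + 1}"
        mir_vals = rng.normal(baseline, 1.0, size=(n_mirnas, n_samples))
        gene_vals = rng.normal(baseline, 1.0, size=(n_genes, n_samples))
        gene_row = {g: i for i, g in enumerate(genes)}
        mir_row = {m: i for i, m in enumerate(mirnas)}
        for gi, group in enumerate(truth.groups):
            if cond_idx not in truth.active_conditions.get(gi, ()):
                continue
            latent = rng.normal(0.0, 1.0, size=n_samples)
            for member in group:
                mir_vals[mir_row[member]] = (
                    baseline + latent
                    + rng.normal(0.0, mirna_noise_sd, size=n_samples))
            for g in shared_pool[gi]:
                gene_vals[gene_row[g]] = (
                    baseline - beta_shared * latent
                    + rng.normal(0.0, noise_sd, size=n_samples))
            for member in group:
                for g in sorted(targets[member] - set(shared_pool[gi])):
                    centered = mir_vals[mir_row[member]] - baseline
                    gene_vals[gene_row[g]] = (
                        baseline - beta_private * centered
                        + rng.normal(0.0, noise_sd, size=n_samples))
        samples = [f"{label}-s{k + 1:02d}" for k in range(n_samples)]
        expression[label] = (
            ExpressionMatrix(label, pd.DataFrame(mir_vals, index=mirnas,
                                                 columns=samples)),
            ExpressionMatrix(label, pd.DataFrame(gene_vals, index=genes,
                                                 columns=samples)),
        )

    # --- motif annotations ------------------------------------------------
    motifs: dict[str, set[str]] = {m: set() for m in mirnas}
    background_motifs = [f"TF-bg{k + 1}" for k in range(8)]
    for mirna in mirnas:
        motifs[mirna].add(background_motifs[int(rng.integers(0, 8))])
        for tf in background_motifs:
            if rng.random() < 0.25:
                motifs[mirna].add(tf)
    background_mirnas = sorted(set(mirnas) - planted_members)
    for gi, group in enumerate(truth.groups):
        a, b = truth.planted_motif_pairs[gi]
        carriers = list(group)
        # the planted TF pair also co-regulates a few background miRNAs,
        # deepening the co-occurrence signal beyond the module itself
        extra = rng.choice(len(background_mirnas), size=5, replace=False)
        carriers += [background_mirnas[i] for i in sorted(extra)]
        for member in carriers:
            motifs[member] |= {a, b}
    motif_ann = MotifAnnotation({m: frozenset(v) for m, v in motifs.items()},
                                universe_size=n_mirnas)

    # --- hairpins ---------------------------------------------------------
    hairpins: list[HairpinRecord] = []
    if with_hairpins:
        hairpins = simulate_hairpins(mirnas, truth, rng)

    # --- pathway sets -----------------------------------------------------
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for gi in range(len(truth.groups)):
        extra = rng.choice(n_genes, size=10, replace=False)
        members = set(shared_pool[gi]) | {genes[i] for i in sorted(extra)}
        pid = f"path-g{gi + 1}"
        sets[pid] = frozenset(members)
        descriptions[pid] = f"pathway enriched for planted group {gi + 1}"
    for k in range(8):
        pick = rng.choice(n_genes, size=30, replace=False)
        pid = f"path-bg{k + 1}"
        sets[pid] = frozenset(genes[i] for i in sorted(pick))
        descriptions[pid] = "background pathway"
    gene_sets = GeneSetCollection(sets, descriptions)

    return SimulatedStudy(expression=expression, targets=target_map,
                          motifs=motif_ann, hairpins=hairpins,
                          gene_sets=gene_sets, truth=truth)


def simulate_hairpins(
    mirnas: list[str],
    truth: PlantedTruth,
    rng: np.random.Generator,
    resample_fraction: float = 1.0,
    conserve_seed: bool = False,
    mature_length: int = 22,
    fold: bool = True,
) -> list[HairpinRecord]:
    """Generate precursor hairpins: group members share their group's
    skeleton (structure-preserving resampling of the template sequence),
    background miRNAs get independent random skeletons.

    ``resample_fraction`` is the probability that each template stem pair
    or loop base is redrawn for a member: at the default 1.0 member
    sequences share only the skeleton, so within-group similarity is
    structural, not sequential -- mirroring modules whose members come
    from unrelated precursors.  ``conserve_seed`` additionally keeps the
    template's seed block (residues 2-8 and their pairing partners)
    identical across members, planting seed-level similarity at the cost
    of some precursor-sequence similarity.  Folding uses base-pair
    maximization; set ``fold=False`` to keep the designed structures.
    """
    member_group = {m: gi for gi, group in enumerate(truth.groups)
                    for m in group}
    records = []
    for mirna in mirnas:
        gi = member_group.get(mirna)
        if gi is None:
            template = _random_template(rng)
            seq = template.sequence
            structure = template.structure
        else:
            template = truth.structure_templates[gi]
            structure = template.structure
            keep: set[int] = set()
            if conserve_seed:
                _, pairs = parse_dotbracket(structure)
                partner = {}
                for i, j in pairs:
                    partner[i] = j
                    partner[j] = i
                for pos in range(2, 9):  # seed block, residues 2-8
                    keep.add(pos)
                    if pos in partner:
                        keep.add(partner[pos])
            seq = _mutate_template(template, rng, resample_fraction,
                                   frozenset(keep))
        folded = nussinov_fold(seq) if fold else structure
        records.append(HairpinRecord(
            mirna_id=mirna,
            mature_seq=seq[:mature_length],
            precursor_seq=seq,
            precursor_struct=folded,
            mature_start=1,
            mature_end=mature_length,
        ))
    return records


def _mutate_template(template: HairpinTemplate, rng: np.random.Generator,
                     resample_fraction: float,
                     keep: frozenset[int]) -> str:
    """Structure-preserving point mutations of a template sequence."""
    _, pairs = parse_dotbracket(template.structure)
    seq = list(template.sequence)
    paired = {i for ij in pairs for i in ij}
    for (i, j) in sorted(pairs):
        if i in keep or j in keep:
            continue
        if rng.random() < resample_fraction:
            pair = _WC_PAIRS[rng.integers(0, len(_WC_PAIRS))]
            seq[i - 1], seq[j - 1] = pair[0], pair[1]
    for pos in range(1, len(seq) + 1):
        if pos in paired or pos in keep:
            continue
        if rng.random() < resample_fraction:
            seq[pos - 1] = _LOOP_BASES[rng.integers(0, len(_LOOP_BASES))]
    return "".join(seq)


def truth_recovery_score(detected, truth: PlantedTruth) -> float:
    """Mean best-match Jaccard between planted groups and detected
    modules (1 = every group recovered exactly, 0 = nothing detected)."""
    if not truth.groups:
        return 0.0
    modules = [frozenset(getattr(m, "mirnas", m)) for m in detected]
    total = 0.0
    for group in truth.groups:
        gset = frozenset(group)
        best = 0.0
        for module in modules:
            j = len(gset & module) / len(gset | module)
            best = max(best, j)
        total += best
    return total / len(truth.groups)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fixtures(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study in the pipeline's native file dialects plus a
    machine-readable truth manifest; returns the path map."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cond in study.conditions:
        mir, mrna = study.expression[cond]
        for tag, em in (("mirna", mir), ("mrna", mrna)):
            p = outdir / f"{tag}_{cond}.tsv"
            em.data.to_csv(p, sep="\t", float_format="%.10g")
            paths[f"{tag}_{cond}"] = p
    p = outdir / "targets.tsv"
    with open(p, "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mirna in sorted(study.targets.targets_of):
            for gene in sorted(study.targets.targets_of[mirna]):
                fh.write(f"{mirna}\t{gene}\n")
    paths["targets"] = p
    p = outdir / "motifs.tsv"
    with open(p, "w") as fh:
        fh.write("mirna_id\tmotif_id\n")
        for mirna in sorted(study.motifs.motifs_of):
            for motif in sorted(study.motifs.motifs_of[mirna]):
                fh.write(f"{mirna}\t{motif}\n")
    paths["motifs"] = p
    p = outdir / "gene_sets.gmt"
    with open(p, "w") as fh:
        for pid in sorted(study.gene_sets.sets):
            desc = study.gene_sets.descriptions.get(pid, "")
            genes = "\t".join(sorted(study.gene_sets.sets[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")
    paths["gene_sets"] = p
    if study.hairpins:
        fa = outdir / "hairpins.fa"
        db = outdir / "hairpins.db"
        co = outdir / "mature_coords.tsv"
        write_hairpins(study.hairpins, fa, db, co)
        paths.update(hairpins_fasta=fa, hairpins_struct=db, mature_coords=co)
    manifest = {
        "groups": [sorted(g) for g in study.truth.groups],
        "shared_target_fraction": study.truth.shared_target_fraction,
        "anti_corr_strength": study.truth.anti_corr_strength,
        "planted_motif_pairs": [list(p) for p in
                                study.truth.planted_motif_pairs],
        "active_conditions": {str(k): list(v) for k, v in
                              sorted(study.truth.active_conditions.items())},
        "rng_seed": study.truth.rng_seed,
    }
    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = p
    return paths
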