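"""End-to-end orchestration of the association-network workflow.

Stages run in the order: per-condition network construction, merging,
module extraction, regulator co-occurrence, pathway enrichment,
sequence/structure comparison.  Every stage writes its artifact to the
output directory, and the whole run is a pure function of
(inputs, config, seed): re-running with the same seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .io import (read_expression, read_gene_sets, read_hairpins,
                 read_motif_annotations, read_target_map, write_network)
from .mcode import annotate_modules, mcode_complexes, merge_condition_mrans
from .network import build_condition_mran, inverse_pair_filter
from .seqstruct import LAYERS, compare_similarity_distributions, split_by_species
from .stats import enrichment_matrix, motif_cooccurrence_graph, pathway_enrichment

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    conditions maps a condition label to {"mirna": path, "mrna": path};
    optional inputs (motifs, gene sets, hairpins) switch their stages on.
    """

    conditions: dict[str, dict[str, str]]
    targets_path: str
    outdir: str
    motifs_path: str | None = None
    gene_sets_path: str | None = None
    hairpins_fasta: str | None = None
    hairpins_struct: str | None = None
    mature_coords: str | None = None
    r_max: float = 0.0
    alpha_corr: float | None = None
    alpha_edge: float = 0.05
    sig_method: str = "exact"
    n_perm: int = 1000
    mcode_vwp: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    mcode_fluff_density: float = 0.2
    mcode_min_core: int = 2
    enrich_alpha: float = 0.05
    enrich_background: str = "measured"
    cooccur_alpha: float = 1.0e-05
    cooccur_correction: str = "bonferroni"
    seed_window: tuple[int, int] = (2, 8)
    n_random_pairs: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("config needs at least one condition")
        if not 0 < self.alpha_edge <= 1:
            raise ValueError(f"alpha_edge outside (0, 1]: {self.alpha_edge}")
        if self.r_max > 0:
            raise ValueError("r_max must be <= 0")
        if not 0 <= self.mcode_vwp < 1:
            raise ValueError(f"mcode_vwp outside [0, 1): {self.mcode_vwp}")
        if not 0 < self.enrich_alpha <= 1:
            raise ValueError("enrich_alpha outside (0, 1]")
        if not 0 < self.cooccur_alpha <= 1:
            raise ValueError("cooccur_alpha outside (0, 1]")
        if self.sig_method not in ("exact", "permutation"):
            raise ValueError(f"unknown sig_method {self.sig_method!r}")
        if self.enrich_background not in ("measured", "gene_sets"):
            raise ValueError("enrich_background must be 'measured' or "
                             "'gene_sets'")
        self.seed_window = tuple(self.seed_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["seed_window"] = list(self.seed_window)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the run summary (also written to
    summary.json).  A stage error aborts with the stage name; artifacts
    of completed stages persist."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"conditions": {}, "seeds": {"rng_seed": config.rng_seed}}

    targets = _stage("read-inputs")(read_target_map)(config.targets_path)

    nets = []
    measured_genes: set[str] = set()
    for cond in sorted(config.conditions):
        net, cond_summary, genes = _build_condition(config, cond, targets,
                                                    outdir)
        nets.append(net)
        measured_genes |= genes
        summary["conditions"][cond] = cond_summary

    global_net = _stage("merge")(merge_condition_mrans)(nets)
    write_network(global_net, outdir / "global_network.tsv", "edgelist")
    summary["global"] = {
        "n_mirnas": global_net.graph.number_of_nodes(),
        "n_connections": global_net.graph.number_of_edges(),
    }

    modules = _stage("modules")(_extract_modules)(config, global_net, nets,
                                                  outdir)
    summary["modules"] = {
        "n_modules": len(modules),
        "sizes": [m.size for m in modules],
        "links": [m.links for m in modules],
        "targets": [len(m.target_union) for m in modules],
    }

    if config.motifs_path:
        summary["cooccurrence"] = _stage("cooccur")(_cooccurrence)(
            config, nets, outdir)
    if config.gene_sets_path:
        summary["enrichment"] = _stage("enrich")(_enrichment)(
            config, modules, measured_genes, outdir)
    if config.hairpins_fasta:
        summary["seqstruct"] = _stage("seqstruct")(_seqstruct)(
            config, modules, outdir)

    run_log = {
        "package_version": __version__,
        "config": {**asdict(config), "seed_window": list(config.seed_window)},
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


@_stage("build-net")
def _build_condition(config: RunConfig, cond: str, targets, outdir: Path):
    paths = config.conditions[cond]
    mirna = read_expression(paths["mirna"], cond)
    mrna = read_expression(paths["mrna"], cond)
    res = inverse_pair_filter(mirna, mrna, targets, r_max=config.r_max,
                              alpha_corr=config.alpha_corr)
    net = build_condition_mran(res, cond, alpha_edge=config.alpha_edge,
                               sig_method=config.sig_method,
                               n_perm=config.n_perm,
                               rng_seed=config.rng_seed)
    write_network(net, outdir / f"network_{cond}.tsv", "edgelist")
    n_genes = len(frozenset().union(*res.cond_targets.values())) \
        if res.cond_targets else 0
    cond_summary = {
        "n_mirnas": len(res.cond_targets),
        "n_genes": n_genes,
        "n_pairs": len(res.pairs),
        "n_edges": net.n_edges,
        "n_skipped_unmeasured": res.n_skipped_unmeasured,
    }
    return net, cond_summary, set(mrna.feature_ids)


def _extract_modules(config: RunConfig, global_net, nets, outdir: Path):
    modules = mcode_complexes(
        global_net.simple_view,
        vwp=config.mcode_vwp,
        haircut=config.mcode_haircut,
        fluff=config.mcode_fluff,
        fluff_density=config.mcode_fluff_density,
        min_core=config.mcode_min_core,
    )
    modules = annotate_modules(modules, nets)
    with open(outdir / "modules.tsv", "w") as fh:
        fh.write("module_id\tn_mirnas\tn_links\tn_targets\tmembers\n")
        for m in modules:
            fh.write(f"{m.module_id}\t{m.size}\t{m.links}\t"
                     f"{len(m.target_union)}\t"
                     + ",".join(sorted(m.mirnas)) + "\n")
    return modules


def _cooccurrence(config: RunConfig, nets, outdir: Path) -> dict:
    ann = read_motif_annotations(config.motifs_path)
    rows = []
    totals = {"n_significant": 0, "n_tested": 0}
    for net in nets:
        scope = sorted(set(net.graph.nodes) & set(ann.motifs_of))
        if len(scope) < 2:
            log.warning("condition %r: co-occurrence scope < 2 annotated "
                        "miRNAs; skipped", net.condition)
            continue
        results, n_tested = motif_cooccurrence_graph(
            ann, scope, alpha=config.cooccur_alpha,
            correction=config.cooccur_correction)
        totals["n_significant"] += len(results)
        totals["n_tested"] += n_tested
        for r in results:
            rows.append((r.motif_a, r.motif_b, net.condition, r.m1, r.m2,
                         r.c_obs, r.N, repr(r.p), repr(r.p_bonferroni)))
    with open(outdir / "cooccurrence.tsv", "w") as fh:
        fh.write("motif_a\tmotif_b\tcondition\tm1\tm2\tc_obs\tN\t"
                 "p\tp_bonferroni\n")
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    return totals


def _enrichment(config: RunConfig, modules, measured_genes: set[str],
                outdir: Path) -> dict:
    sets = read_gene_sets(config.gene_sets_path)
    if config.enrich_background == "measured":
        background = frozenset(measured_genes)
    else:
        background = frozenset().union(*sets.sets.values())
    cells = []
    for m in modules:
        genes = frozenset(m.target_union) & background
        if not genes:
            continue
        module_cells, _ = pathway_enrichment(genes, background, sets,
                                             alpha=config.enrich_alpha,
                                             module_id=m.module_id)
        cells.extend(module_cells)
    with open(outdir / "enrichment_long.tsv", "w") as fh:
        fh.write("module_id\tpathway_id\tk\tK\tn\tN_bg\tp\tneglog10p\n")
        for c in sorted(cells, key=lambda c: (str(c.module_id), c.pathway_id)):
            fh.write(f"{c.module_id}\t{c.pathway_id}\t{c.k}\t{c.K}\t{c.n}\t"
                     f"{c.N_bg}\t{c.p!r}\t{c.neglog10p!r}\n")
    matrix = enrichment_matrix(cells, alpha=config.enrich_alpha)
    matrix.to_csv(outdir / "enrichment_matrix.tsv", sep="\t",
                  float_format="%.10g")
    n_sig = sum(1 for c in cells if c.p < config.enrich_alpha)
    return {"n_cells": len(cells), "n_significant": n_sig,
            "n_modules_mapped": int(matrix.shape[0]) if not matrix.empty else 0}


def _seqstruct(config: RunConfig, modules, outdir: Path) -> dict:
    records = read_hairpins(config.hairpins_fasta, config.hairpins_struct,
                            config.mature_coords)
    by_species = split_by_species(records)
    covered = [m for m in modules
               if all(any(mem == r.mirna_id for r in records)
                      for mem in m.mirnas)]
    rows = []
    out: dict = {}
    for species in sorted(by_species):
        recs = by_species[species]
        ids = {r.mirna_id for r in recs}
        sp_modules = [m for m in covered if set(m.mirnas) <= ids]
        if not sp_modules:
            continue
        for layer in LAYERS:
            rep = compare_similarity_distributions(
                sp_modules, recs, layer,
                n_random_pairs=config.n_random_pairs,
                rng_seed=config.rng_seed,
                seed_window=config.seed_window)
            rows.append((layer, species,
                         "NA" if rep.p_within_vs_between is None
                         else repr(rep.p_within_vs_between),
                         "NA" if rep.p_within_vs_random is None
                         else repr(rep.p_within_vs_random),
                         len(rep.within), len(rep.between)))
            out[f"{species}:{layer}"] = {
                "p_within_vs_between": rep.p_within_vs_between,
                "p_within_vs_random": rep.p_within_vs_random,
            }
    with open(outdir / "seqstruct_report.tsv", "w") as fh:
        fh.write("# similarity: global-alignment identity "
                 "(match 1, mismatch 0, gap -1); structure distance: "
                 "ordered tree edit distance (unit costs), negated for "
                 "the one-sided test\n")
        fh.write("layer\tspecies\tp_within_vs_between\tp_within_vs_random\t"
                 "n_within\tn_between\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return out
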