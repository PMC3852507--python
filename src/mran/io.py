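"""Readers and writers for the external formats the pipeline touches.

Expression matrices are tab-separated feature x sample tables; static
miRNA->target maps, motif annotations and mature coordinates are small
TSVs; pathway collections are GMT; precursor sequences are FASTA with
Vienna dot-bracket structure files.  Networks round-trip through an edge
list dialect or GraphML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqstruct import parse_dotbracket

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "TargetMap",
    "GeneSetCollection",
    "MotifAnnotation",
    "HairpinRecord",
    "read_expression",
    "collapse_replicates",
    "read_target_map",
    "read_gene_sets",
    "read_motif_annotations",
    "read_hairpins",
    "write_hairpins",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_id(identifier: str) -> str:
    """Canonical comparison key: trimmed, case-folded.

    Species prefixes (hsa-, mmu-) are kept verbatim; only the case is
    folded so array probe ids and target-map ids can be joined.
    """
    return identifier.strip().casefold()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """One condition's normalized feature x sample expression matrix.

    Values are assumed already normalized (log-scale intensities);
    only finiteness is validated here.
    """

    condition: str
    data: pd.DataFrame  # features x samples

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r} "
                              f"in condition {self.condition!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.data.shape[1] < 3:
            raise FormatError(
                f"insufficient samples: correlation needs >= 3 matched "
                f"columns, got {self.data.shape[1]}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise FormatError("non-finite expression values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TargetMap:
    """Static miRNA -> target-gene sets (sequence-based predictions)."""

    targets_of: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets_of.items():
            if not mirna or not isinstance(mirna, str):
                raise FormatError("empty or non-string miRNA id in target map")
            if not genes:
                raise FormatError(f"miRNA {mirna!r} has an empty target set")
            if any(not g for g in genes):
                raise FormatError(f"empty gene id for miRNA {mirna!r}")

    @property
    def n_pairs(self) -> int:
        """Number of unique miRNA-gene pairs."""
        return sum(len(g) for g in self.targets_of.values())

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets_of)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise FormatError(f"pathway {pid!r} has no genes")


@dataclass
class MotifAnnotation:
    """miRNA -> TF-motif (TFBS) sets plus the annotated-universe size N."""

    motifs_of: dict[str, frozenset[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < len(self.motifs_of):
            raise FormatError("universe_size smaller than the number of "
                              "annotated miRNAs")
        carriers: dict[str, int] = {}
        for motifs in self.motifs_of.values():
            for m in motifs:
                carriers[m] = carriers.get(m, 0) + 1
        if carriers and max(carriers.values()) > self.universe_size:
            raise FormatError("motif carrier count exceeds universe_size")


@dataclass
class HairpinRecord:
    """Precursor hairpin with its mature product.

    Coordinates are 1-based inclusive positions of the mature miRNA on
    the precursor; the dot-bracket structure must be balanced and as long
    as the precursor sequence.
    """

    mirna_id: str
    mature_seq: str
    precursor_seq: str
    precursor_struct: str
    mature_start: int
    mature_end: int

    def __post_init__(self) -> None:
        if len(self.precursor_struct) != len(self.precursor_seq):
            raise FormatError(
                f"{self.mirna_id}: structure length "
                f"{len(self.precursor_struct)} != sequence length "
                f"{len(self.precursor_seq)}")
        try:
            parse_dotbracket(self.precursor_struct)
        except ValueError as exc:
            raise FormatError(f"{self.mirna_id}: unbalanced structure "
                              f"({exc})") from exc
        if not (1 <= self.mature_start <= self.mature_end
                <= len(self.precursor_seq)):
            raise FormatError(f"{self.mirna_id}: mature coordinates "
                              f"({self.mature_start}, {self.mature_end}) "
                              "outside precursor")
        if len(self.mature_seq) < 8:
            raise FormatError(f"{self.mirna_id}: mature sequence shorter "
                              "than 8 nt")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Read a feature x sample expression TSV.

    The header row holds sample ids, the first column feature ids.  Rows
    containing any non-numeric cell are dropped (the count is logged);
    duplicate feature ids and fewer than three sample columns are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"insufficient samples in {path}: need >= 3 "
                          f"sample columns, got {df.shape[1]}")
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    good = numeric.notna().all(axis=1)
    n_bad = int((~good).sum())
    if n_bad:
        log.warning("%s: dropped %d rows with non-numeric cells", path, n_bad)
    return ExpressionMatrix(condition, numeric.loc[good].astype(float))


def collapse_replicates(matrix: ExpressionMatrix,
                        groups: dict[str, str]) -> ExpressionMatrix:
    """Average replicate columns into per-cell means.

    ``groups`` maps sample id -> cell label (e.g. time point); columns
    sharing a label are averaged, so miRNA and mRNA matrices with
    unbalanced replication can be matched cell-by-cell.
    """
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise FormatError(f"samples without replicate labels: {missing}")
    labels = [groups[s] for s in matrix.sample_ids]
    collapsed = matrix.data.T.groupby(pd.Index(labels, name="cell"),
                                      sort=False).mean().T
    return ExpressionMatrix(matrix.condition, collapsed)


_HEADERISH = {"mirna", "mirna_id", "mir", "gene", "gene_id", "target",
              "target_id", "motif", "motif_id", "tf", "start", "end",
              "mature_start", "mature_end"}


def _read_pair_rows(path: str | Path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}: malformed {what} row at line {lineno}: "
                    f"{line!r}")
            if lineno == 1 and (fields[0].casefold() in _HEADERISH
                                or fields[1].casefold() in _HEADERISH):
                continue  # optional header
            rows.append((fields[0], fields[1]))
    if not rows:
        raise FormatError(f"{path}: empty {what} file")
    return rows


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column (miRNA id, gene id) TSV into a TargetMap.

    Duplicate rows are collapsed into sets; an optional header line is
    skipped; empty files and malformed rows are errors.
    """
    pairs = _read_pair_rows(path, "target")
    mapping: dict[str, set[str]] = {}
    for mirna, gene in pairs:
        mapping.setdefault(mirna, set()).add(gene)
    return TargetMap({m: frozenset(g) for m, g in mapping.items()})


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...; tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line {lineno} has fewer "
                                  "than 3 fields")
            name, desc, *genes = fields
            name = name.strip()
            if name in sets:
                raise FormatError(f"{path}: duplicate pathway id {name!r} "
                                  f"at line {lineno}")
            genes = frozenset(g.strip() for g in genes if g.strip())
            if not genes:
                raise FormatError(f"{path}: pathway {name!r} at line "
                                  f"{lineno} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, descriptions)


def read_motif_annotations(path: str | Path) -> MotifAnnotation:
    """Read a two-column (miRNA id, motif id) TSV.

    The annotated universe N is the number of distinct miRNA ids present.
    """
    pairs = _read_pair_rows(path, "motif")
    mapping: dict[str, set[str]] = {}
    for mirna, motif in pairs:
        mapping.setdefault(mirna, set()).add(motif)
    return MotifAnnotation({m: frozenset(v) for m, v in mapping.items()},
                           universe_size=len(mapping))


_STRUCT_CHARS = frozenset("().")


def _read_vienna(path: str | Path) -> dict[str, str]:
    """Parse a Vienna-style file: '>id', optional sequence line, then the
    dot-bracket line (a trailing energy in parentheses is not expected)."""
    structures: dict[str, str] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
            elif current is not None and set(line) <= _STRUCT_CHARS:
                structures[current] = line
                current = None
    return structures


def read_hairpins(fasta_path: str | Path, struct_path: str | Path,
                  coords_path: str | Path) -> list[HairpinRecord]:
    """Join precursor FASTA, Vienna dot-bracket and mature-coordinate
    files into HairpinRecords.

    T residues are transliterated to U; ids present in only some of the
    three inputs are reported via a logged count and skipped.  Unbalanced
    structures and sequence/structure length mismatches are errors.
    """
    seqs = {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    structs = _read_vienna(struct_path)
    coords: dict[str, tuple[int, int]] = {}
    with open(coords_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(f"{coords_path}: malformed coordinate row "
                                  f"at line {lineno}")
            if lineno == 1 and fields[1].casefold() in _HEADERISH:
                continue
            coords[fields[0]] = (int(fields[1]), int(fields[2]))
    shared = sorted(set(seqs) & set(structs) & set(coords))
    unmatched = (set(seqs) | set(structs) | set(coords)) - set(shared)
    if unmatched:
        log.warning("read_hairpins: %d ids present in only some inputs: %s",
                    len(unmatched), sorted(unmatched)[:10])
    records = []
    for mid in shared:
        start, end = coords[mid]
        seq = seqs[mid]
        records.append(HairpinRecord(
            mirna_id=mid,
            mature_seq=seq[start - 1:end],
            precursor_seq=seq,
            precursor_struct=structs[mid],
            mature_start=start,
            mature_end=end,
        ))
    return records


def write_hairpins(records: list[HairpinRecord], fasta_path: str | Path,
                   struct_path: str | Path, coords_path: str | Path) -> None:
    """Write hairpin records in the dialects read_hairpins consumes."""
    records = sorted(records, key=lambda r: r.mirna_id)
    with open(fasta_path, "w") as fa:
        for rec in records:
            fa.write(f">{rec.mirna_id}\n{rec.precursor_seq}\n")
    with open(struct_path, "w") as db:
        for rec in records:
            db.write(f">{rec.mirna_id}\n{rec.precursor_seq}\n"
                     f"{rec.precursor_struct}\n")
    with open(coords_path, "w") as co:
        co.write("mirna_id\tmature_start\tmature_end\n")
        for rec in records:
            co.write(f"{rec.mirna_id}\t{rec.mature_start}\t{rec.mature_end}\n")


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

_FORMATS = ("edgelist", "graphml")


def _float_repr(x: float) -> str:
    return repr(float(x))


def write_network(net, path: str | Path, format: str = "edgelist") -> None:
    """Serialize a condition-specific or global association network.

    Edge attributes t (overlap score), p (significance) and the condition
    labels round-trip losslessly; the edge-list dialect stores the node
    set in a header comment so isolated nodes survive.
    """
    from .network import ConditionMRAN
    from .mcode import GlobalMRAN

    if format not in _FORMATS:
        raise ValueError(f"unknown network format {format!r}; "
                         f"expected one of {_FORMATS}")
    if isinstance(net, ConditionMRAN):
        _write_condition(net, Path(path), format)
    elif isinstance(net, GlobalMRAN):
        _write_global(net, Path(path), format)
    else:
        raise TypeError(f"cannot serialize {type(net).__name__}")


def _write_condition(net, path: Path, format: str) -> None:
    g = net.graph
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# mran-edgelist v1\n# kind: condition\n")
            fh.write(f"# condition: {net.condition}\n")
            fh.write("# nodes: " + "\t".join(sorted(g.nodes)) + "\n")
            fh.write("source\ttarget\tt\tp\tweight\n")
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                d = g.edges[u, v]
                fh.write(f"{u}\t{v}\t{_float_repr(d['t'])}\t"
                         f"{_float_repr(d['p'])}\t"
                         f"{_float_repr(d['weight'])}\n")
    else:
        out = nx.Graph(kind="condition", condition=net.condition)
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, t=float(d["t"]), p=float(d["p"]),
                         weight=float(d["weight"]))
        nx.write_graphml(out, str(path))


def _write_global(net, path: Path, format: str) -> None:
    g = net.graph
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# mran-edgelist v1\n# kind: global\n")
            fh.write("# nodes: " + "\t".join(sorted(g.nodes)) + "\n")
            fh.write("source\ttarget\tcondition\tt\tp\n")
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                for cond, t, p in sorted(g.edges[u, v]["records"]):
                    fh.write(f"{u}\t{v}\t{cond}\t{_float_repr(t)}\t"
                             f"{_float_repr(p)}\n")
    else:
        out = nx.Graph(kind="global")
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            records = sorted((c, float(t), float(p))
                             for c, t, p in d["records"])
            out.add_edge(u, v,
                         conditions=",".join(c for c, _, _ in records),
                         records=json.dumps(records))
        nx.write_graphml(out, str(path))


def read_network(path: str | Path, format: str = "edgelist"):
    """Read back a network written by write_network."""
    from .network import ConditionMRAN
    from .mcode import GlobalMRAN

    if format not in _FORMATS:
        raise ValueError(f"unknown network format {format!r}; "
                         f"expected one of {_FORMATS}")
    if format == "edgelist":
        return _read_edgelist(Path(path))
    g = nx.read_graphml(str(path))
    kind = g.graph.get("kind")
    if kind == "condition":
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, t=float(d["t"]), p=float(d["p"]),
                         weight=float(d["weight"]))
        return ConditionMRAN(condition=g.graph["condition"], graph=out)
    if kind == "global":
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            records = [(c, float(t), float(p))
                       for c, t, p in json.loads(d["records"])]
            out.add_edge(u, v, records=records)
        return GlobalMRAN(graph=out)
    raise FormatError(f"{path}: unknown network kind {kind!r}")


def _read_edgelist(path: Path):
    from .network import ConditionMRAN
    from .mcode import GlobalMRAN

    kind = condition = None
    nodes: list[str] = []
    edges: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
            elif line.startswith("# condition:"):
                condition = line.split(":", 1)[1].strip()
            elif line.startswith("# nodes:"):
                rest = line.split(":", 1)[1]
                nodes = [n for n in rest.strip().split("\t") if n]
            elif line.startswith("#") or not line.strip():
                continue
            elif line.startswith("source\t"):
                continue
            else:
                edges.append(line.split("\t"))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if kind == "condition":
        for u, v, t, p, w in edges:
            g.add_edge(u, v, t=float(t), p=float(p), weight=float(w))
        return ConditionMRAN(condition=condition or "", graph=g)
    if kind == "global":
        for u, v, cond, t, p in edges:
            if g.has_edge(u, v):
                g.edges[u, v]["records"].append((cond, float(t), float(p)))
            else:
                g.add_edge(u, v, records=[(cond, float(t), float(p))])
        return GlobalMRAN(graph=g)
    raise FormatError(f"{path}: missing or unknown '# kind:' header")
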