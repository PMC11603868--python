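"""Readers and writers for the pipeline's external inputs.

Differential-expression (DEG) tables, GMT gene-set collections, gene
annotations, undirected protein-protein interaction (PPI) edge lists and
term parent/child graphs are all consumed as local delimited text.  Each
reader validates its domain invariants on the way in and raises
:class:`~laminadiv.errors.FormatError` / ``ValidationError`` with a line
number where one is known; nothing is fetched from the network.

Gene identifiers are upper-cased by default before any join, following the
HGNC-symbol convention used when crossing symbol-keyed resources (DEG
tables, gene sets, STRING exports, annotations).  Delimiters are explicit
configuration, never sniffed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Closed biotype vocabulary for gene annotations.
BIOTYPES = ("protein_coding", "ncRNA", "rRNA", "other")

#: Marker returned for genes absent from an annotation.
UNKNOWN_BIOTYPE = "unknown"

#: Default header-name mapping for DEG tables: logical role -> column name.
DEFAULT_DEG_COLUMNS = {"gene": "gene_id", "lfc": "lfc", "pvalue": "p_value"}


def normalize_gene_id(gene_id: str, case_fold: bool = True) -> str:
    gene_id = str(gene_id).strip()
    return gene_id.upper() if case_fold else gene_id


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

@dataclass
class DEGTable:
    """One lamina's differential-expression result.

    ``data`` has columns ``gene_id`` (unique), ``lfc`` (log2 fold change,
    finite) and ``p_value`` (in (0, 1]).
    """

    lamina_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "lfc", "p_value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"DEG table missing columns {missing}")
        if len(self.data) == 0:
            raise ValidationError("DEG table is empty")
        if self.data["gene_id"].duplicated().any():
            dupes = sorted(self.data.loc[self.data["gene_id"].duplicated(), "gene_id"].unique())
            raise ValidationError(f"duplicate gene identifiers: {dupes[:10]}")
        p = self.data["p_value"]
        if ((p <= 0) | (p > 1) | p.isna()).any():
            raise ValidationError("p_value outside (0, 1]")
        if (~self.data["lfc"].apply(math.isfinite)).any():
            raise ValidationError("non-finite LFC")
        self.data = self.data.reset_index(drop=True)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene_id"])

    def __len__(self) -> int:
        return len(self.data)


def read_deg_table(
    path: str | Path,
    lamina_label: str,
    *,
    delimiter: str = "\t",
    columns: Mapping[str, str] | None = None,
    case_fold: bool = True,
) -> DEGTable:
    """Read a delimited DEG table with a header row.

    ``columns`` maps the logical roles ``gene``, ``lfc`` and ``pvalue`` to the
    file's header names (defaults: ``gene_id``, ``lfc``, ``p_value``).  Rows
    failing validation are reported with their 1-based file line number
    (header = line 1).
    """
    colmap = dict(DEFAULT_DEG_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    for role, name in colmap.items():
        if name not in raw.columns:
            raise FormatError(f"missing required column {name!r} (role {role!r}) in {path}")
    df = pd.DataFrame(
        {
            "gene_id": raw[colmap["gene"]].map(lambda g: normalize_gene_id(g, case_fold)),
            "lfc": pd.to_numeric(raw[colmap["lfc"]], errors="coerce"),
            "p_value": pd.to_numeric(raw[colmap["pvalue"]], errors="coerce"),
        }
    )
    # data row i sits on file line i + 2 (header is line 1)
    for col, role in (("lfc", colmap["lfc"]), ("p_value", colmap["pvalue"])):
        bad = df.index[df[col].isna()]
        if len(bad):
            i = int(bad[0])
            raise FormatError(
                f"non-numeric value {raw[role].iloc[i]!r} in column {role!r}", line=i + 2
            )
    bad_p = df.index[(df["p_value"] <= 0) | (df["p_value"] > 1)]
    if len(bad_p):
        i = int(bad_p[0])
        raise ValidationError(
            f"p_value {df['p_value'].iloc[i]} outside (0, 1]", line=i + 2
        )
    dup = df.index[df["gene_id"].duplicated(keep=False)]
    if len(dup):
        genes = sorted(df.loc[dup, "gene_id"].unique())
        raise ValidationError(f"duplicate gene identifier(s) after normalization: {genes[:10]}")
    return DEGTable(lamina_label=lamina_label, data=df)


def write_deg_table(table: DEGTable, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a DEG table so that :func:`read_deg_table` round-trips it."""
    table.data.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets keyed by ``set_id``."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self.sets:
            raise ValidationError(f"duplicate set id {gs.set_id!r}")
        if not gs.members:
            raise ValidationError(f"gene set {gs.set_id!r} has no members")
        self.sets[gs.set_id] = gs

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def names(self) -> dict[str, str]:
        return {s.set_id: s.name for s in self}


def read_gmt(path: str | Path, *, case_fold: bool = True) -> GeneSetCollection:
    """Read a GMT file: tab-separated lines ``name<TAB>description<TAB>member...``.

    The set name doubles as the set id.  Lines with fewer than three fields
    (i.e. no members) are format errors.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line has {len(fields)} field(s); expected name, description "
                    "and at least one member",
                    line=lineno,
                )
            name = fields[0].strip()
            members = frozenset(
                normalize_gene_id(g, case_fold) for g in fields[2:] if g.strip()
            )
            if not members:
                raise FormatError("GMT line has no non-empty members", line=lineno)
            try:
                coll.add(GeneSet(set_id=name, name=name, members=members))
            except ValidationError as err:
                raise ValidationError(str(err), line=lineno) from err
    if len(coll) == 0:
        raise ValidationError(f"GMT file {path} contains no gene sets")
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Maps gene id -> (chromosome, biotype); lookups of unannotated genes
    return the explicit ``unknown`` marker rather than raising."""

    table: dict[str, tuple[str, str]] = field(default_factory=dict)

    def chromosome(self, gene_id: str) -> str | None:
        entry = self.table.get(gene_id)
        return entry[0] if entry else None

    def biotype(self, gene_id: str) -> str:
        entry = self.table.get(gene_id)
        return entry[1] if entry else UNKNOWN_BIOTYPE

    def genes_on(self, chromosome: str) -> set[str]:
        return {g for g, (c, _) in self.table.items() if c == chromosome}

    def __len__(self) -> int:
        return len(self.table)


def read_annotation(
    path: str | Path, *, delimiter: str = "\t", case_fold: bool = True
) -> GeneAnnotation:
    """Read a gene annotation TSV with columns gene_id, chromosome, biotype."""
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ("gene_id", "chromosome", "biotype"):
        if col not in raw.columns:
            raise FormatError(f"annotation missing column {col!r}")
    ann = GeneAnnotation()
    for i, row in raw.iterrows():
        bt = str(row["biotype"]).strip()
        if bt not in BIOTYPES:
            raise ValidationError(
                f"biotype {bt!r} not in {BIOTYPES}", line=int(i) + 2
            )
        ann.table[normalize_gene_id(row["gene_id"], case_fold)] = (
            str(row["chromosome"]).strip(),
            bt,
        )
    return ann


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "chromosome": c, "biotype": b}
        for g, (c, b) in sorted(ann.table.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "chromosome", "biotype"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path, *, delimiter: str = "\t", case_fold: bool = True
) -> nx.Graph:
    """Read a STRING-style undirected edge list.

    Two or three whitespace/``delimiter``-separated columns per line:
    ``nodeA nodeB [confidence]``.  Edges are deduplicated as unordered pairs
    (first confidence wins); self-loops are dropped and counted in a logged
    warning.  Confidence, when present, must lie in [0, 1].
    """
    graph = nx.Graph()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter != " " else line.split()
            if len(fields) < 2:
                raise FormatError("edge line needs at least two columns", line=lineno)
            a = normalize_gene_id(fields[0], case_fold)
            b = normalize_gene_id(fields[1], case_fold)
            conf: float | None = None
            if len(fields) >= 3 and fields[2].strip():
                try:
                    conf = float(fields[2])
                except ValueError as err:
                    raise FormatError(f"non-numeric confidence {fields[2]!r}", line=lineno) from err
                if not 0.0 <= conf <= 1.0:
                    raise ValidationError(f"confidence {conf} outside [0, 1]", line=lineno)
            if a == b:
                n_self_loops += 1
                continue
            if graph.has_edge(a, b):
                continue
            if conf is None:
                graph.add_edge(a, b)
            else:
                graph.add_edge(a, b, confidence=conf)
    if n_self_loops:
        logger.warning("dropped %d self-loop edge(s) from %s", n_self_loops, path)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, attrs in sorted(graph.edges(data=True)):
            if "confidence" in attrs:
                fh.write(f"{a}\t{b}\t{attrs['confidence']:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Term graphs (ontology child -> parent)
# ---------------------------------------------------------------------------

def _validate_dag(graph: nx.DiGraph) -> nx.DiGraph:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(f"term graph contains a cycle: {cycle}")
    return graph


def read_term_graph(path: str | Path, *, delimiter: str = "\t") -> nx.DiGraph:
    """Read an ontology as a child->parent DAG.

    ``.obo`` files are parsed with :mod:`obonet` and reduced to their
    ``is_a`` edges; anything else is read as a two-column child/parent
    delimited file with a header.
    """
    path = Path(path)
    if path.suffix == ".obo":
        import obonet

        obo = obonet.read_obo(str(path))
        graph = nx.DiGraph()
        graph.add_nodes_from(obo.nodes())
        for child, parent, key in obo.edges(keys=True):
            if key == "is_a":
                graph.add_edge(child, parent)
        return _validate_dag(graph)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"term graph file {path} needs child and parent columns")
    graph = nx.DiGraph()
    for _, row in raw.iterrows():
        graph.add_edge(str(row.iloc[0]).strip(), str(row.iloc[1]).strip())
    return _validate_dag(graph)


def term_graph_from_edges(edges: Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Build and validate a child->parent DAG from in-memory edges."""
    graph = nx.DiGraph()
    graph.add_edges_from(edges)
    return _validate_dag(graph)


def write_term_graph(graph: nx.DiGraph, path: str | Path) -> None:
    pd.DataFrame(sorted(graph.edges()), columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False
    )
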