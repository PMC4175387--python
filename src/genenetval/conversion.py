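"""Conversion of KEGG pathways into undirected gene association networks.

A metabolic pathway mixes genes/enzymes with chemical compounds; a gene
network has only genes.  The conversion lifts the pathway to the gene
association level:

* gene-gene relations (PPrel, ECrel, GErel) become undirected edges;
* compound nodes are removed and every pair of genes that touched the same
  compound — through a protein-compound relation or through a reaction in
  which the compound is a substrate or product — is connected (a clique
  over the compound's gene neighbourhood);
* compounds linked to each other by compound-compound relations are merged
  into one bridging component first, so genes joined by a chain of
  compounds are also connected;
* group entries are expanded to their member genes;
* all direction information is discarded.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx

from .pathway_model import (
    GENE_RELATION_TYPES,
    Pathway,
    canonical_gene_id,
)

__all__ = [
    "GeneNetwork",
    "convert_pathway",
    "relation_only_network",
    "read_network",
    "write_network",
    "NetworkParseError",
]

logger = logging.getLogger(__name__)


class NetworkParseError(ValueError):
    """Raised when an edge-list file has an unparseable line."""


class GeneNetwork:
    """An undirected simple graph over canonical gene identifiers.

    Edges are stored canonically (each unordered pair once, as a sorted
    tuple); self-loops are rejected.  ``label`` records provenance — the
    pathway accession or the input file name.
    """

    __slots__ = ("genes", "edges", "label")

    def __init__(
        self,
        genes: set[str] | frozenset[str] | list[str] = (),
        edges=(),
        label: str = "",
    ) -> None:
        self.genes: set[str] = set(genes)
        self.edges: set[tuple[str, str]] = set()
        self.label = label
        for a, b in edges:
            self.add_edge(a, b)

    @staticmethod
    def canonical_edge(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_gene(self, g: str) -> None:
        self.genes.add(g)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on gene {a!r} is not allowed")
        self.genes.add(a)
        self.genes.add(b)
        self.edges.add(self.canonical_edge(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return self.canonical_edge(a, b) in self.edges

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, label: str = "") -> "GeneNetwork":
        net = cls(label=label)
        net.genes.update(str(n) for n in g.nodes)
        for a, b in g.edges:
            if a != b:
                net.edges.add(cls.canonical_edge(str(a), str(b)))
        return net

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.genes, self.edges, self.label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self.genes == other.genes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"GeneNetwork(label={self.label!r}, genes={self.n_genes}, "
            f"edges={self.n_edges})"
        )


def _entry_gene_names(pathway: Pathway, entry_id: str) -> list[str]:
    """Canonical gene names of an entry, expanding groups recursively."""
    entry = pathway.entries[entry_id]
    if entry.kind == "gene":
        return [canonical_gene_id(n) for n in entry.names]
    if entry.kind == "group":
        names: list[str] = []
        for m in entry.members:
            names.extend(_entry_gene_names(pathway, m))
        return names
    return []


def _entry_compound_ids(pathway: Pathway, entry_id: str) -> list[str]:
    entry = pathway.entries[entry_id]
    if entry.kind == "compound":
        return [entry_id]
    if entry.kind == "group":
        out: list[str] = []
        for m in entry.members:
            out.extend(_entry_compound_ids(pathway, m))
        return out
    return []


def relation_only_network(pathway: Pathway) -> GeneNetwork:
    """Gold standard built from gene-gene relations only.

    This is the "classical" reading of a pathway: PPrel/ECrel/GErel edges
    with groups expanded, but no compound bridging and no reaction-derived
    edges.  All pathway genes are kept as nodes so pruning behaves the same
    as for the full conversion.
    """
    pathway.validate()
    net = GeneNetwork(label=pathway.pathway_id)
    for entry in pathway.entries.values():
        if entry.kind == "gene":
            for n in entry.names:
                net.add_gene(canonical_gene_id(n))
    for rel in pathway.relations:
        if rel.rel_type not in GENE_RELATION_TYPES:
            continue
        for a in _entry_gene_names(pathway, rel.source):
            for b in _entry_gene_names(pathway, rel.target):
                if a != b:
                    net.add_edge(a, b)
    return net


def convert_pathway(pathway: Pathway) -> GeneNetwork:
    """Convert a pathway into its undirected gene association network.

    Returns an empty network (not an error) for a pathway without gene
    entries.  Raises if the pathway has dangling references.
    """
    pathway.validate()
    net = relation_only_network(pathway)

    # compound components: compounds chained by compound-compound relations
    # act as a single bridge
    comp_graph = nx.Graph()
    for entry in pathway.entries.values():
        if entry.kind == "compound":
            comp_graph.add_node(entry.entry_id)
    for rel in pathway.relations:
        if rel.rel_type == "compound_compound":
            src = _entry_compound_ids(pathway, rel.source)
            tgt = _entry_compound_ids(pathway, rel.target)
            for c1 in src:
                for c2 in tgt:
                    if c1 != c2:
                        comp_graph.add_edge(c1, c2)

    component_of: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(comp_graph)):
        for cid in comp:
            component_of[cid] = i
    neighbours: dict[int, set[str]] = {i: set() for i in set(component_of.values())}

    def attach(compound_id: str, genes) -> None:
        comp = component_of.get(compound_id)
        if comp is not None:
            neighbours[comp].update(genes)

    # genes adjacent to a compound through PCrel (or any relation pairing a
    # gene entry with a compound entry)
    for rel in pathway.relations:
        if rel.rel_type in GENE_RELATION_TYPES or rel.rel_type in ("maplink", "compound_compound"):
            continue
        src_genes = _entry_gene_names(pathway, rel.source)
        tgt_genes = _entry_gene_names(pathway, rel.target)
        src_comps = _entry_compound_ids(pathway, rel.source)
        tgt_comps = _entry_compound_ids(pathway, rel.target)
        for c in src_comps:
            attach(c, tgt_genes)
        for c in tgt_comps:
            attach(c, src_genes)

    # genes adjacent to a compound through reactions (enzyme consumes or
    # produces the compound)
    for rx in pathway.reactions:
        enzyme_genes: set[str] = set()
        for eid in rx.enzymes:
            enzyme_genes.update(_entry_gene_names(pathway, eid))
        for cid in list(rx.substrates) + list(rx.products):
            for c in _entry_compound_ids(pathway, cid):
                attach(c, enzyme_genes)

    # clique over each compound component's gene neighbourhood
    for genes in neighbours.values():
        ordered = sorted(genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                net.add_edge(a, b)

    return net


# --- edge-list I/O ----------------------------------------------------------


def _iter_edge_lines(path: Path, fmt: str):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 1:
                # isolated gene (SIF convention: a one-column line)
                yield lineno, fields[0], None
                continue
            if fmt == "sif":
                if len(fields) == 3:
                    yield lineno, fields[0], fields[2]
                    continue
            else:
                if len(fields) >= 2:
                    yield lineno, fields[0], fields[1]
                    continue
            raise NetworkParseError(
                f"{path}:{lineno}: cannot parse {fmt.upper()} line: {raw.rstrip()!r}"
            )


def read_network(path: str | Path, format: str = "tsv") -> GeneNetwork:
    """Read an undirected gene network from a SIF or two-column TSV file.

    Identifiers are canonicalised; duplicate lines collapse to one edge;
    self-loops are dropped with a warning.
    """
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown network format {format!r}")
    path = Path(path)
    net = GeneNetwork(label=path.name)
    for lineno, a, b in _iter_edge_lines(path, format):
        if b is None:
            net.add_gene(canonical_gene_id(a))
            continue
        a, b = canonical_gene_id(a), canonical_gene_id(b)
        if a == b:
            logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
            net.add_gene(a)
            continue
        net.add_edge(a, b)
    return net


def write_network(net: GeneNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write a gene network as a SIF or TSV edge list (isolated genes kept).

    Round-trips with :func:`read_network`.
    """
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown network format {format!r}")
    path = Path(path)
    connected = {g for e in net.edges for g in e}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# gene network: {net.label or path.stem}\n")
        for a, b in sorted(net.edges):
            if format == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        # isolated genes: one-column lines (SIF convention)
        for g in sorted(net.genes - connected):
            fh.write(f"{g}\n")
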