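"""Synthetic pathway and benchmark generation.

Everything the package needs for testing and benchmarking can be generated
locally: KGML pathway files exercising each conversion motif (direct
gene-gene relations, gene–compound–gene bridges, multi-gene compounds,
compound chains, two-enzyme transfer reactions, group entries), inferred
networks derived from them with controlled corruption, and size-matched
null networks.

:func:`make_pathway` also returns the *expected* converted network, built
by a deliberately naive constructor (plain loops and a union-find — no
shared code with the conversion module) so conversion can be tested
against an independent oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .conversion import GeneNetwork, convert_pathway, write_network
from .evaluation import random_network
from .pathway_model import (
    GENE_RELATION_TYPES,
    Pathway,
    PathwayEntry,
    PathwayReaction,
    PathwayRelation,
    canonical_gene_id,
    write_kgml,
)

__all__ = ["FixtureSpec", "BenchmarkBundle", "make_pathway", "make_benchmark",
           "naive_expected_network", "make_worked_example"]

_GENE_REL_CYCLE = ("PPrel", "ECrel", "GErel")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic pathway."""

    gene_count: int = 10
    compound_count: int = 3
    relation_density: float = 0.25
    reaction_count: int = 1
    group_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gene_count, self.compound_count, self.reaction_count,
               self.group_count) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 < self.relation_density <= 1:
            raise ValueError("relation_density must be in (0, 1]")
        if self.gene_count < 2 and (
            self.compound_count or self.reaction_count or self.group_count
        ):
            raise ValueError("motifs need at least 2 genes")
        if self.reaction_count and not self.compound_count:
            raise ValueError("reactions need at least one compound")
        if self.group_count and self.gene_count < 2 * self.group_count:
            raise ValueError("each group needs 2 distinct member genes")


def make_pathway(spec: FixtureSpec) -> tuple[Pathway, GeneNetwork]:
    """Generate a synthetic pathway and its expected converted network.

    Deterministic given ``spec`` (which includes the seed).  When the
    counts permit, the pathway contains at least one of each motif class:
    a direct gene-gene relation, a two-gene compound bridge, a compound
    shared by three genes, a two-enzyme transfer reaction, and a compound
    chain.  The expected network is produced by
    :func:`naive_expected_network`, not by the conversion module.
    """
    rng = np.random.default_rng(spec.seed)
    pw = Pathway(pathway_id=f"syn{spec.seed:05d}", organism="syn")

    gene_ids = []
    for i in range(spec.gene_count):
        eid = str(i + 1)
        names = [f"syn:G{i + 1:03d}"]
        # one multi-gene entry to exercise name expansion
        if i == 0 and spec.gene_count >= 6:
            names.append(f"syn:G{i + 1:03d}B")
        pw.add_entry(PathwayEntry(entry_id=eid, kind="gene", names=names))
        gene_ids.append(eid)

    compound_ids = []
    for j in range(spec.compound_count):
        eid = f"c{j + 1}"
        pw.add_entry(
            PathwayEntry(entry_id=eid, kind="compound", names=[f"cpd:C{j + 1:05d}"])
        )
        compound_ids.append(eid)

    group_ids = []
    free = list(gene_ids)
    for k in range(spec.group_count):
        members = [free.pop(0), free.pop(0)]
        eid = f"grp{k + 1}"
        pw.add_entry(PathwayEntry(entry_id=eid, kind="group", members=members))
        group_ids.append(eid)

    # direct gene-gene relations
    rel_count = 0
    if spec.gene_count >= 2:
        for a in range(spec.gene_count):
            for b in range(a + 1, spec.gene_count):
                if rng.random() < spec.relation_density:
                    pw.relations.append(
                        PathwayRelation(
                            source=gene_ids[a],
                            target=gene_ids[b],
                            rel_type=_GENE_REL_CYCLE[rel_count % 3],
                        )
                    )
                    rel_count += 1
        if rel_count == 0:
            pw.relations.append(
                PathwayRelation(source=gene_ids[0], target=gene_ids[1],
                                rel_type="PPrel")
            )
    if group_ids and spec.gene_count > 2 * spec.group_count:
        # a relation through a group entry, to exercise expansion
        pw.relations.append(
            PathwayRelation(source=group_ids[0], target=gene_ids[-1],
                            rel_type="PPrel")
        )

    def pick_genes(k: int) -> list[str]:
        idx = rng.choice(spec.gene_count, size=k, replace=False)
        return [gene_ids[int(i)] for i in idx]

    # compound motifs
    cursor = 0
    if spec.compound_count >= 1 and spec.gene_count >= 2:
        a, b = pick_genes(2)
        cid = compound_ids[cursor]
        pw.relations.append(PathwayRelation(source=a, target=cid, rel_type="PCrel"))
        pw.relations.append(PathwayRelation(source=cid, target=b, rel_type="PCrel"))
        cursor += 1
    if spec.compound_count >= 2 and spec.gene_count >= 3:
        cid = compound_ids[cursor]
        for g in pick_genes(3):
            pw.relations.append(PathwayRelation(source=g, target=cid, rel_type="PCrel"))
        cursor += 1
    if spec.compound_count - cursor >= 2 and spec.gene_count >= 2:
        # compound chain: gene - c_i - c_{i+1} - gene
        c1, c2 = compound_ids[cursor], compound_ids[cursor + 1]
        a, b = pick_genes(2)
        pw.relations.append(PathwayRelation(source=a, target=c1, rel_type="PCrel"))
        pw.relations.append(
            PathwayRelation(source=c1, target=c2, rel_type="compound_compound")
        )
        pw.relations.append(PathwayRelation(source=c2, target=b, rel_type="PCrel"))
        cursor += 2
    for cid in compound_ids[cursor:]:
        # leftover compounds get a random gene neighbourhood of size 0-2
        for g in pick_genes(int(rng.integers(0, min(3, spec.gene_count)))):
            pw.relations.append(PathwayRelation(source=g, target=cid, rel_type="PCrel"))

    # transfer reactions: two enzymes moving a compound
    for r in range(spec.reaction_count):
        enzymes = pick_genes(2) if spec.gene_count >= 2 else gene_ids[:1]
        sub = compound_ids[int(rng.integers(spec.compound_count))]
        prod = compound_ids[int(rng.integers(spec.compound_count))]
        pw.reactions.append(
            PathwayReaction(
                reaction_id=f"rn{r + 1}",
                enzymes=sorted(enzymes),
                substrates=[sub],
                products=[prod] if prod != sub else [],
            )
        )

    pw.validate()
    return pw, naive_expected_network(pw)


def naive_expected_network(pathway: Pathway) -> GeneNetwork:
    """Reference conversion by brute force; the oracle for convert_pathway.

    Uses only plain dictionaries, nested loops and a hand-rolled union-find
    so it shares no machinery with the conversion module.
    """
    entry_genes: dict[str, list[str]] = {}

    def genes_of(eid: str) -> list[str]:
        e = pathway.entries[eid]
        if e.kind == "gene":
            return [canonical_gene_id(x) for x in e.names]
        if e.kind == "group":
            out = []
            for m in e.members:
                out.extend(genes_of(m))
            return out
        return []

    def compounds_of(eid: str) -> list[str]:
        e = pathway.entries[eid]
        if e.kind == "compound":
            return [eid]
        if e.kind == "group":
            out = []
            for m in e.members:
                out.extend(compounds_of(m))
            return out
        return []

    for eid in pathway.entries:
        entry_genes[eid] = genes_of(eid)

    net = GeneNetwork(label=pathway.pathway_id)
    for e in pathway.entries.values():
        if e.kind == "gene":
            for name in e.names:
                net.add_gene(canonical_gene_id(name))

    for rel in pathway.relations:
        if rel.rel_type in GENE_RELATION_TYPES:
            for a in entry_genes[rel.source]:
                for b in entry_genes[rel.target]:
                    if a != b:
                        net.add_edge(a, b)

    # union-find over compounds joined by compound-compound relations
    parent = {e.entry_id: e.entry_id for e in pathway.entries.values()
              if e.kind == "compound"}

    def find(x: str) -> str:
        while parent[x] != x:
            x = parent[x]
        return x

    for rel in pathway.relations:
        if rel.rel_type == "compound_compound":
            for c1 in compounds_of(rel.source):
                for c2 in compounds_of(rel.target):
                    parent[find(c1)] = find(c2)

    adjacent: dict[str, set[str]] = {}
    for rel in pathway.relations:
        if rel.rel_type in GENE_RELATION_TYPES or rel.rel_type in (
            "maplink", "compound_compound",
        ):
            continue
        for c in compounds_of(rel.source):
            adjacent.setdefault(find(c), set()).update(entry_genes[rel.target])
        for c in compounds_of(rel.target):
            adjacent.setdefault(find(c), set()).update(entry_genes[rel.source])
    for rx in pathway.reactions:
        rx_genes = set()
        for eid in rx.enzymes:
            rx_genes.update(entry_genes[eid])
        for cid in list(rx.substrates) + list(rx.products):
            for c in compounds_of(cid):
                adjacent.setdefault(find(c), set()).update(rx_genes)

    for genes in adjacent.values():
        for a in genes:
            for b in genes:
                if a < b:
                    net.add_edge(a, b)
    return net


def make_worked_example() -> tuple[GeneNetwork, GeneNetwork]:
    """The two-edge textbook comparison used throughout the docs and tests.

    The input network has edges (3,2) and (3,7); the gold standard connects
    3-2 directly and 3-7 through gene 5, so the input scores one hit at
    level 1 and one at level 2.
    """
    g_i = GeneNetwork(edges=[("G3", "G2"), ("G3", "G7")], label="worked-input")
    g_p = GeneNetwork(
        edges=[("G3", "G2"), ("G3", "G5"), ("G5", "G7")], label="worked-gold"
    )
    return g_i, g_p


# --- benchmark bundles ------------------------------------------------------


@dataclass
class BenchmarkBundle:
    """File layout of one generated benchmark directory."""

    root: Path
    pathway_files: list[Path]
    real_file: Path
    null_files: list[Path]
    manifest_file: Path


def make_benchmark(
    real_spec: FixtureSpec,
    null_count: int = 5,
    topology: str = "pure_random",
    seed: int = 0,
    out_dir: str | Path = "benchmark",
    n_pathways: int = 3,
    sample_fraction: float = 0.8,
    noise_fraction: float = 0.1,
) -> BenchmarkBundle:
    """Write a self-contained benchmark: pathways, a "real" network, nulls.

    The "real" network keeps ``sample_fraction`` of the union gold-standard
    edges and adds ``noise_fraction`` (of the kept count) random non-edges,
    so it is biologically structured but imperfect; null networks share its
    size but none of its structure beyond chance.  Reproducible: the same
    seed yields byte-identical files.
    """
    if null_count < 1:
        raise ValueError("null_count must be >= 1")
    out = Path(out_dir)
    (out / "pathways").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    pathway_files = []
    converted = []
    for i in range(n_pathways):
        sub_seed = int(rng.integers(2**31))
        spec_i = FixtureSpec(
            gene_count=real_spec.gene_count,
            compound_count=real_spec.compound_count,
            relation_density=real_spec.relation_density,
            reaction_count=real_spec.reaction_count,
            group_count=real_spec.group_count,
            seed=sub_seed,
        )
        pw, _ = make_pathway(spec_i)
        path = out / "pathways" / f"{pw.pathway_id}.xml"
        write_kgml(pw, path)
        pathway_files.append(path)
        converted.append(convert_pathway(pw))

    gold = GeneNetwork(label="gold-union")
    for c in converted:
        gold.genes.update(c.genes)
        gold.edges.update(c.edges)

    # sample the real network from the gold standard, then corrupt mildly
    edges = sorted(gold.edges)
    keep_n = max(1, round(sample_fraction * len(edges)))
    keep_idx = rng.choice(len(edges), size=keep_n, replace=False)
    real = GeneNetwork(gold.genes, label="real")
    for i in sorted(int(x) for x in keep_idx):
        real.add_edge(*edges[i])
    genes = sorted(gold.genes)
    gold_edge_set = set(edges)
    non_edges = [
        (genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
        if (genes[i], genes[j]) not in gold_edge_set
    ]
    add_n = min(round(noise_fraction * keep_n), len(non_edges))
    if add_n:
        for i in rng.choice(len(non_edges), size=add_n, replace=False):
            real.add_edge(*non_edges[int(i)])
    real_file = out / "real.tsv"
    write_network(real, real_file, format="tsv")

    null_files = []
    null_seeds = []
    for i in range(null_count):
        null_seed = int(rng.integers(2**31))
        null = random_network(real, topology=topology, seed=null_seed)
        null.label = f"null_{i:03d}"
        path = out / f"null_{i:03d}.tsv"
        write_network(null, path, format="tsv")
        null_files.append(path)
        null_seeds.append(null_seed)

    manifest_file = out / "manifest.json"
    manifest = {
        "seed": seed,
        "topology": topology,
        "null_count": null_count,
        "n_pathways": n_pathways,
        "sample_fraction": sample_fraction,
        "noise_fraction": noise_fraction,
        "real_spec": asdict(real_spec),
        "null_seeds": null_seeds,
        "pathways": [p.name for p in pathway_files],
        "real": real_file.name,
        "nulls": [p.name for p in null_files],
    }
    manifest_file.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return BenchmarkBundle(
        root=out,
        pathway_files=pathway_files,
        real_file=real_file,
        null_files=null_files,
        manifest_file=manifest_file,
    )
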