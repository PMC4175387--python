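import numpy as np
import pytest

from genenetval import GeneNetwork
from genenetval.fixtures import make_worked_example
from genenetval.pathway_model import (
    Pathway,
    PathwayEntry,
    PathwayRelation,
)


def build_pathway_m() -> Pathway:
    """A small mixed pathway in the style of a textbook conversion example.

    Eight genes connected by direct relations plus two compound nodes:
    genes 3 and 8 each touch compound c1, genes 6 and 7 each touch
    compound c2 — so conversion must bridge (3,8) and (6,7).
    """
    pw = Pathway(pathway_id="pathwayM", organism="syn")
    for i in range(1, 9):
        pw.add_entry(
            PathwayEntry(entry_id=str(i), kind="gene", names=[f"syn:G{i}"])
        )
    pw.add_entry(PathwayEntry(entry_id="c1", kind="compound", names=["cpd:C00001"]))
    pw.add_entry(PathwayEntry(entry_id="c2", kind="compound", names=["cpd:C00002"]))
    direct = [("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("5", "6"), ("1", "7")]
    for k, (a, b) in enumerate(direct):
        pw.relations.append(
            PathwayRelation(source=a, target=b,
                            rel_type=("PPrel", "ECrel", "GErel")[k % 3])
        )
    for gene, comp in [("3", "c1"), ("8", "c1"), ("6", "c2"), ("7", "c2")]:
        pw.relations.append(
            PathwayRelation(source=gene, target=comp, rel_type="PCrel")
        )
    return pw


@pytest.fixture
def pathway_m() -> Pathway:
    return build_pathway_m()


@pytest.fixture
def worked_example() -> tuple[GeneNetwork, GeneNetwork]:
    """Two-edge input vs a path-shaped gold standard (one hit per level)."""
    return make_worked_example()


def random_gene_network(
    rng: np.random.Generator, n_genes: int = 8, p: float = 0.3, label: str = ""
) -> GeneNetwork:
    genes = [f"G{i}" for i in range(n_genes)]
    net = GeneNetwork(genes, label=label)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                net.add_edge(genes[i], genes[j])
    return net
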