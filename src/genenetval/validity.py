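"""The level-weighted validity measure for gene networks.

Given an inferred network G_I and a gold-standard gene association network
G_P (typically a converted KEGG pathway), each input edge (a, b) is looked
up in G_P at its *level*: the shortest-path edge count between a and b.
An edge at level l ≤ n is a hit with weight 1/l; everything else is a
failure.  With ``hits[l]`` the number of input edges at level l:

    H_n = sum_{l=1..n} hits[l] / l          (cumulative hits)
    F_n = ||E_I|| - H_n                     (cumulative failures)
    V_n = H_n / ||E_I||                     (validity, in [0, 1])

Pathway-specific *pruning* first restricts G_I to edges whose two endpoints
are both genes of G_P: interactions among genes a pathway knows nothing
about are neither hits nor failures for that pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .conversion import GeneNetwork, relation_only_network
from .pathway_model import Pathway

__all__ = ["ValidityResult", "level", "prune", "score", "classical_precision"]


@dataclass
class ValidityResult:
    """Outcome of scoring one input network against one gold standard.

    ``validity`` is ``None`` when the (pruned) input network has no edges —
    the measure is undefined rather than zero, and such results sort last
    in functional rankings.
    """

    level_cap: int
    hits_per_level: dict[int, int] = field(default_factory=dict)
    cumulative_hits: float = 0.0
    failures: float = 0.0
    validity: Optional[float] = None
    evaluated_edges: int = 0
    label: str = ""

    @property
    def defined(self) -> bool:
        return self.validity is not None

    def hit(self, l: int) -> int:
        """Hit count at level ``l`` (0 when no input edge sits at that level)."""
        return self.hits_per_level.get(l, 0)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n": self.level_cap,
            "edges": self.evaluated_edges,
            "H_n": self.cumulative_hits,
            "F_n": self.failures,
            "V_n": self.validity,
        }
        for l in range(1, self.level_cap + 1):
            d[f"hit_{l}"] = self.hit(l)
        return d


def level(net: GeneNetwork, a: str, b: str) -> Optional[int]:
    """Shortest-path edge count between genes ``a`` and ``b`` in ``net``.

    Returns ``None`` if either gene is absent or the genes are disconnected.
    ``a == b`` is a usage error: an input edge cannot be a self-loop.
    """
    if a == b:
        raise ValueError("level is undefined for a gene paired with itself")
    if a not in net.genes or b not in net.genes:
        return None
    try:
        return nx.shortest_path_length(net.to_networkx(), a, b)
    except nx.NetworkXNoPath:
        return None


def prune(input_net: GeneNetwork, pathway_net: GeneNetwork) -> GeneNetwork:
    """Restrict ``input_net`` to edges with both endpoints in ``pathway_net``.

    Genes the pathway does not mention carry no information for this
    evaluation, so edges touching them are removed; isolated genes are
    dropped as well.
    """
    pruned = GeneNetwork(label=input_net.label)
    keep = pathway_net.genes
    for a, b in input_net.edges:
        if a in keep and b in keep:
            pruned.add_edge(a, b)
    return pruned


def score(
    input_net: GeneNetwork,
    pathway_net: GeneNetwork,
    n: int = 2,
    do_prune: bool = True,
) -> ValidityResult:
    """Score ``input_net`` against the gold standard ``pathway_net`` at level cap ``n``.

    Every (optionally pruned) input edge is assigned exactly one level — its
    shortest distance in the gold standard — and counts as a hit only when
    that level is at most ``n``.  Edges between disconnected or absent genes
    contribute only to the edge total, i.e. they are failures at every
    level.
    """
    if n < 1:
        raise ValueError(f"level cap n must be >= 1, got {n}")
    evaluated = prune(input_net, pathway_net) if do_prune else input_net

    total = evaluated.n_edges
    hits: dict[int, int] = {}
    if total:
        gp = pathway_net.to_networkx()
        for a, b in evaluated.edges:
            if a not in pathway_net.genes or b not in pathway_net.genes:
                continue
            try:
                l = nx.shortest_path_length(gp, a, b)
            except nx.NetworkXNoPath:
                continue
            if 1 <= l <= n:
                hits[l] = hits.get(l, 0) + 1

    h_n = sum(count / l for l, count in hits.items())
    result = ValidityResult(
        level_cap=n,
        hits_per_level=hits,
        cumulative_hits=h_n,
        failures=total - h_n,
        validity=(h_n / total) if total else None,
        evaluated_edges=total,
        label=pathway_net.label,
    )
    return result


def classical_precision(input_net: GeneNetwork, pathway: Pathway) -> Optional[float]:
    """Precision of the input against the relation-only reading of a pathway.

    The classical use of KEGG takes only direct gene-gene relations
    (PPrel/ECrel/GErel) as the gold standard — no compound bridging, no
    reaction-derived edges — and counts the fraction of (pruned) input
    edges present in it.  Equivalent to V_1 against the relation-only
    network.  ``None`` when no input edge survives pruning.
    """
    gold = relation_only_network(pathway)
    return score(input_net, gold, n=1, do_prune=True).validity
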