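"""Independent brute-force oracles used to cross-check the implementation.

Nothing here calls into genenetval's graph machinery: levels come from
exhaustive simple-path enumeration, scores from a direct transcription of
the defining formulas on top of that enumeration.
"""

from __future__ import annotations

from typing import Iterable, Optional


def adjacency(edges: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def brute_level(
    nodes: Iterable[str], edges: Iterable[tuple[str, str]], a: str, b: str
) -> Optional[int]:
    """Shortest simple-path edge count by exhaustive DFS enumeration."""
    nodes = set(nodes)
    if a not in nodes or b not in nodes:
        return None
    adj = adjacency(edges)
    best: list[Optional[int]] = [None]

    def dfs(current: str, visited: set[str], length: int) -> None:
        if best[0] is not None and length >= best[0]:
            return  # no simple path extension can beat the best
        if current == b:
            best[0] = length
            return
        for nxt in adj.get(current, ()):
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, visited, length + 1)
                visited.remove(nxt)

    dfs(a, {a}, 0)
    return best[0]


def brute_score(
    input_edges: Iterable[tuple[str, str]],
    gold_nodes: Iterable[str],
    gold_edges: Iterable[tuple[str, str]],
    n: int,
    do_prune: bool = True,
) -> dict:
    """Direct transcription of the hit/failure/validity formulas."""
    gold_nodes = set(gold_nodes)
    gold_edges = list(gold_edges)
    edges = list(input_edges)
    if do_prune:
        edges = [e for e in edges if e[0] in gold_nodes and e[1] in gold_nodes]
    hits: dict[int, int] = {}
    for a, b in edges:
        l = brute_level(gold_nodes, gold_edges, a, b)
        if l is not None and 1 <= l <= n:
            hits[l] = hits.get(l, 0) + 1
    h_n = sum(c / l for l, c in hits.items())
    total = len(edges)
    return {
        "hits": hits,
        "H": h_n,
        "F": total - h_n,
        "V": (h_n / total) if total else None,
        "edges": total,
    }
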