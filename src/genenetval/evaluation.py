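"""Evaluation machinery: null models, ROC study, noise study, global network.

Three reusable procedures characterise the validity measure:

* **ROC study** — real networks and size-matched null networks (pure random
  or scale-free) are each scored against every pathway; sweeping a
  threshold T over the validity values yields a confusion matrix per T,
  a TPR/FPR point per T, and an AUC.  The default grid is the 101 values
  0.00, 0.01, ..., 1.00.
* **Noise study** — a fraction k·10% of a network's edges is replaced by
  random non-edges (fresh from the original at every iteration k = 1..10);
  the mean validity per iteration tracks how the measure degrades with
  loss of real structure.
* **Global network / functional assignment** — the union of all converted
  pathway networks gives one organism-wide gold standard; ranking pathways
  by validity assigns the input network its best-fitting biological
  function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .conversion import GeneNetwork
from .validity import ValidityResult, score

__all__ = [
    "ConfusionCounts",
    "RocResult",
    "NoiseProfile",
    "DEFAULT_THRESHOLDS",
    "random_network",
    "sample_size",
    "roc_study",
    "noise_study",
    "build_kgn",
    "functional_assignment",
]

#: default threshold grid: 0.00 to 1.00 in steps of 0.01 (101 values)
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(round(t * 0.01, 2) for t in range(101))


@dataclass
class ConfusionCounts:
    """Confusion matrix at one validity threshold.

    Positives are evaluations whose validity strictly exceeds the
    threshold; whether a positive is true or false depends on whether the
    evaluated network was real or null.
    """

    threshold: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else 0.0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocResult:
    """ROC curve from a threshold sweep: one (FPR, TPR) point per threshold."""

    thresholds: tuple[float, ...]
    confusion: list[ConfusionCounts]
    points: list[tuple[float, float]]  # sorted by ascending FPR
    auc: float

    def to_rows(self) -> list[dict]:
        return [
            {
                "threshold": c.threshold,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "tpr": c.tpr,
                "fpr": c.fpr,
            }
            for c in self.confusion
        ]


@dataclass
class NoiseRecord:
    iteration: int
    noise_fraction: float
    mean_validity: float
    sd_validity: float
    replicates: int


@dataclass
class NoiseProfile:
    """Mean validity per noise iteration (fraction = iteration x 10%)."""

    records: list[NoiseRecord] = field(default_factory=list)

    def mean_series(self) -> list[float]:
        return [r.mean_validity for r in self.records]

    def to_rows(self) -> list[dict]:
        return [vars(r) for r in self.records]


# --- null models ------------------------------------------------------------


def random_network(
    template: GeneNetwork,
    topology: str = "pure_random",
    seed: int = 0,
) -> GeneNetwork:
    """Sample a null network over the template's gene set.

    ``pure_random`` draws exactly ``template.n_edges`` distinct unordered
    gene pairs uniformly.  ``scale_free`` grows a preferential-attachment
    (Barabási–Albert) graph over the same genes, with the attachment
    parameter chosen so the expected edge count is closest to the
    template's.  Deterministic given ``seed``.
    """
    genes = sorted(template.genes)
    n = len(genes)
    if n < 2:
        raise ValueError("template must have at least 2 genes")
    m_edges = template.n_edges
    max_edges = n * (n - 1) // 2
    if m_edges > max_edges:
        raise ValueError(
            f"{m_edges} edges requested but only {max_edges} possible over {n} genes"
        )
    rng = np.random.default_rng(seed)

    null = GeneNetwork(genes, label=f"{topology}:{template.label}")
    if topology == "pure_random":
        # sample distinct pairs by index into the C(n,2) enumeration
        chosen = rng.choice(max_edges, size=m_edges, replace=False)
        for k in sorted(int(c) for c in chosen):
            i, j = _pair_from_index(k, n)
            null.add_edge(genes[i], genes[j])
    elif topology == "scale_free":
        # BA with parameter m yields m*(n-m) edges; pick m closest to target
        best_m = min(
            range(1, n),
            key=lambda m: (abs(m * (n - m) - m_edges), m),
        )
        import networkx as nx

        g = nx.barabasi_albert_graph(n, best_m, seed=int(rng.integers(2**31)))
        perm = rng.permutation(n)
        for a, b in g.edges:
            null.add_edge(genes[perm[a]], genes[perm[b]])
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return null


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """Map an index in [0, C(n,2)) to the k-th unordered pair (i < j)."""
    # row i starts at offset i*n - i*(i+1)/2 - i in the lexicographic listing
    i = 0
    row = n - 1
    while k >= row:
        k -= row
        i += 1
        row -= 1
    return i, i + 1 + k


def sample_size(
    confidence: float = 0.95, margin: float = 0.05, proportion: float = 0.5
) -> int:
    """Sample size for estimating a proportion in an infinite population.

    ``ceil(z^2 p (1-p) / margin^2)`` with z the two-sided normal quantile —
    385 for 95% confidence, 5% margin and p = 0.5.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if not 0 < margin < 1:
        raise ValueError(f"margin must be in (0, 1), got {margin}")
    if not 0 < proportion < 1:
        raise ValueError(f"proportion must be in (0, 1), got {proportion}")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    return math.ceil(z * z * proportion * (1 - proportion) / (margin * margin))


# --- ROC study --------------------------------------------------------------


def _validity_values(
    nets: Sequence[GeneNetwork],
    pathways: Sequence[GeneNetwork],
    n: int,
) -> list[float]:
    """V_n of every (network, pathway) pair after pruning; undefined -> 0."""
    values = []
    for net in nets:
        for pw in pathways:
            v = score(net, pw, n=n, do_prune=True).validity
            values.append(v if v is not None else 0.0)
    return values


def roc_from_scores(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> RocResult:
    """Threshold sweep over precomputed validity values.

    An evaluation is classified positive when its validity strictly exceeds
    the threshold.  The AUC is the trapezoidal integral over the achieved
    (FPR, TPR) points sorted by FPR — no anchor points are added, so a
    degenerate sweep whose negatives never fire spans zero FPR width.
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ValueError("threshold grid must be non-empty")
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)

    confusion = []
    for t in thresholds:
        tp = int((pos > t).sum())
        fp = int((neg > t).sum())
        confusion.append(
            ConfusionCounts(
                threshold=t,
                tp=tp,
                fn=len(pos) - tp,
                fp=fp,
                tn=len(neg) - fp,
            )
        )
    points = sorted((c.fpr, c.tpr) for c in confusion)
    fpr = [p[0] for p in points]
    tpr = [p[1] for p in points]
    auc = float(np.trapezoid(tpr, fpr)) if len(points) > 1 else 0.0
    return RocResult(thresholds=thresholds, confusion=confusion, points=points, auc=auc)


def roc_study(
    real_nets: GeneNetwork | Sequence[GeneNetwork],
    pathways: Sequence[GeneNetwork],
    null_nets: Sequence[GeneNetwork],
    n: int = 2,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> RocResult:
    """ROC analysis of validity scores: real vs null networks over pathways.

    Every (network, pathway) pair is scored at level cap ``n`` after
    pruning; real-network evaluations form the positive class and
    null-network evaluations the negative class.
    """
    if isinstance(real_nets, GeneNetwork):
        real_nets = [real_nets]
    if not pathways:
        raise ValueError("at least one pathway network is required")
    if not real_nets or not null_nets:
        raise ValueError("at least one real and one null network are required")
    pos = _validity_values(real_nets, pathways, n)
    neg = _validity_values(null_nets, pathways, n)
    return roc_from_scores(pos, neg, thresholds)


# --- noise study ------------------------------------------------------------


def perturb_network(
    net: GeneNetwork, fraction: float, rng: np.random.Generator
) -> GeneNetwork:
    """Replace ``round(fraction * ||E||)`` edges by uniformly chosen non-edges.

    Removal and addition are sampled independently; added edges are drawn
    from the current non-edges over the same gene set, so the result stays
    a simple graph with the original edge count (unless the complement is
    exhausted).
    """
    genes = sorted(net.genes)
    n = len(genes)
    edges = sorted(net.edges)
    k = min(round(fraction * len(edges)), len(edges))
    if k == 0:
        return net.copy()

    removed_idx = set(rng.choice(len(edges), size=k, replace=False).tolist())
    kept = [e for i, e in enumerate(edges) if i not in removed_idx]

    edge_set = set(edges)
    non_edges = [
        (genes[i], genes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if (genes[i], genes[j]) not in edge_set
    ]
    add_k = min(k, len(non_edges))
    added_idx = rng.choice(len(non_edges), size=add_k, replace=False) if add_k else []
    perturbed = GeneNetwork(genes, kept, label=f"noisy:{net.label}")
    for i in added_idx:
        perturbed.add_edge(*non_edges[int(i)])
    return perturbed


def noise_study(
    net: GeneNetwork,
    pathway_net: GeneNetwork,
    n: int = 2,
    iterations: int = 10,
    replicates: int = 50,
    seed: int = 0,
    do_prune: bool = True,
) -> NoiseProfile:
    """Degradation of validity under increasing random edge replacement.

    At iteration k (k = 1..``iterations``) each replicate swaps a fraction
    k·10% of the *original* edges for random non-edges (perturbation is not
    cumulative across iterations) and is scored against ``pathway_net``;
    the profile stores the mean and SD of validity per iteration.
    Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    profile = NoiseProfile()
    for k in range(1, iterations + 1):
        fraction = min(k * 0.10, 1.0)
        values = []
        for _ in range(replicates):
            noisy = perturb_network(net, fraction, rng)
            v = score(noisy, pathway_net, n=n, do_prune=do_prune).validity
            values.append(v if v is not None else 0.0)
        profile.records.append(
            NoiseRecord(
                iteration=k,
                noise_fraction=fraction,
                mean_validity=float(np.mean(values)),
                sd_validity=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                replicates=replicates,
            )
        )
    return profile


# --- global network & functional assignment ---------------------------------


def build_kgn(pathway_nets: Sequence[GeneNetwork]) -> GeneNetwork:
    """Union of converted pathway networks: one organism-wide gold standard."""
    if not pathway_nets:
        raise ValueError("at least one pathway network is required")
    kgn = GeneNetwork(label="KGN")
    for pw in pathway_nets:
        kgn.genes.update(pw.genes)
        kgn.edges.update(pw.edges)
    return kgn


def functional_assignment(
    input_net: GeneNetwork,
    pathway_nets: Sequence[GeneNetwork],
    n: int = 2,
) -> list[tuple[str, ValidityResult]]:
    """Rank pathways by how well the input network matches each of them.

    The input is pruned and scored per pathway; pathways are sorted by
    descending V_n (undefined validity last), ties broken by the larger
    pruned edge count, then label.  The top pathway is the biological
    function that best fits the input network.
    """
    if not pathway_nets:
        raise ValueError("at least one pathway network is required")
    results = []
    for pw in pathway_nets:
        res = score(input_net, pw, n=n, do_prune=True)
        results.append((pw.label, res))

    def sort_key(item: tuple[str, ValidityResult]):
        label, res = item
        v = res.validity if res.validity is not None else -1.0
        return (-v, -res.evaluated_edges, label)

    return sorted(results, key=sort_key)
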