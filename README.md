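# genenetval

Score the biological validity of an inferred gene network against KEGG
metabolic pathways.

Gene-network inference methods (Bayesian networks, co-expression, rule
mining, ...) produce graphs whose edges claim a functional relationship
between two genes. Judging whether such a network carries real biology is
hard: curated pathways mix genes with chemical compounds, and a naive
edge-overlap precision ignores indirect but biologically meaningful
relationships. This package addresses both problems for anyone evaluating
network-inference output:

1. **Pathway conversion.** A KEGG pathway (KGML file) is converted into an
   undirected *gene association network*: gene–gene relations (PPrel,
   ECrel, GErel) become edges; compound nodes are removed and every pair of
   genes that touched the same compound — through a protein–compound
   relation, a chain of compound–compound relations, or a reaction in which
   the compound is a substrate or product — is connected.
2. **Level-weighted validity.** Let `G_I = (N_I, E_I)` be the input network
   and `G_P = (N_P, E_P)` a converted pathway. The *level* of a gene pair
   is its shortest-path edge count in `G_P`. With `Hit_l` the number of
   input edges whose endpoints sit at level `l`,

   ```
   H_n = Σ_{l=1..n} Hit_l / l        cumulative hits
   F_n = ‖E_I‖ − H_n                 cumulative failures
   V_n = H_n / ‖E_I‖  ∈ [0, 1]       validity
   ```

   A direct match weighs 1, a two-step (indirect) match 1/2, and so on up
   to the level cap `n` (default 2). Before scoring, the input network is
   *pruned* to edges whose endpoints both occur in the pathway — a pathway
   cannot judge genes it does not contain.

On top of the scorer sit the evaluation procedures: ROC analysis of real
vs. null networks (pure-random or scale-free, 101 thresholds), a
noise-degradation study, the organism-wide union network, per-pathway
functional ranking, and a synthetic KGML/benchmark generator so everything
runs without any KEGG download.

## Worked example

The canonical two-edge comparison: the input claims edges (3,2) and (3,7);
the gold standard connects 3–2 directly and 3–7 through gene 5.

```python
from genenetval import GeneNetwork, level, score

g_i = GeneNetwork(edges=[("G3", "G2"), ("G3", "G7")])
g_p = GeneNetwork(edges=[("G3", "G2"), ("G3", "G5"), ("G5", "G7")])

print(level(g_p, "G3", "G7"))          # 2
print(score(g_i, g_p, n=1).failures)   # 1.0
r = score(g_i, g_p, n=2)
print(r.cumulative_hits, r.failures, r.validity)   # 1.5 0.5 0.75
```

Edge (3,2) is a hit at level 1 (weight 1) and edge (3,7) a hit at level 2
(weight 1/2), so `H_2 = 1.5`; of the two input edges, `F_2 = 2 − 1.5 =
0.5` failure mass remains and the network's validity is `V_2 = 0.75`. At
level cap 1 the (3,7) edge is a plain failure: `F_1 = 1`.

## Command line

```sh
genenetval fixture --out-dir bench --seed 7       # synthetic benchmark bundle
genenetval convert bench/pathways/*.xml --out-dir nets --format sif
genenetval score bench/real.tsv bench/pathways/*.xml -n 2
genenetval roc bench -n 2                         # 101-threshold sweep + AUC
genenetval noise bench/real.tsv bench/pathways/<file>.xml --replicates 50
```

`score` prints one row per pathway, ranked by validity — the top pathway is
the biological function that best fits the input network. `roc` prints the
per-threshold confusion matrices and the trapezoidal AUC.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the worked-example comparison from scratch with the public API and
writes the recomputed reference quantities (the level-2 cumulative failures
and the 3–7 level) as JSON.
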