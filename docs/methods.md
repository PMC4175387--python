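# Methods

## The measure

The package evaluates an inferred gene network `G_I` against a
gold-standard gene association network `G_P` derived from a curated
metabolic pathway. The *level* of a gene pair is the number of edges on
the shortest undirected path between them in `G_P`. Each input edge is
assigned exactly one level — its shortest distance — and contributes to at
most one hit count; this keeps the hit mass bounded by `‖E_I‖` so that the
cumulative failures `F_n = ‖E_I‖ − H_n` can never go negative. Input
edges whose endpoints are disconnected in `G_P` (or absent, when pruning is
off) are failures at every level cap.

Validity `V_n = H_n / ‖E_I‖` is undefined — reported as `None`, never 0 —
when the (pruned) input network has no edges. Rankings place undefined
results last; they are "no information", not "bad network". Ties in
functional rankings break by larger pruned edge count, then
lexicographically by pathway label, so rankings are deterministic.

### Pruning

Per-pathway evaluation first removes every input edge with at least one
endpoint the pathway does not mention (both endpoints must be present).
The rationale: a pathway carries no information about foreign genes, so
those edges are neither hits nor failures *for that pathway*. Pruning
defaults to on for per-pathway scoring and can be disabled for
whole-network comparisons against a user-supplied gold standard.

## Pathway conversion

KGML entries, relations and reactions are modeled; graphics, coordinates,
BRITE and map-link entries are ignored. Gene identifiers are
canonicalised by stripping the organism prefix and uppercasing, which is
how KGML names (`sce:YBR160W`) line up with the ORF identifiers inferred
networks typically use. An entry naming several genes expands to all of
them.

Conversion rules, in order:

1. every PPrel/ECrel/GErel relation adds undirected edges between all gene
   names of its two entries (groups expanded first; direction discarded);
2. compounds linked by compound–compound relations are merged into one
   *compound component* (a chain of metabolites is a single bridge);
3. for each compound component, the set of adjacent genes — via
   protein–compound relations or via reactions that consume/produce a
   member compound — is connected as a clique, then all compound nodes are
   dropped.

An ECrel that carries a compound subtype still contributes its direct
gene–gene edge (it is a gene relationship; the mediating compound may
*additionally* bridge other genes). Co-enzymes of one reaction are
connected only through the shared substrate/product compounds — no extra
enzyme–enzyme rule is needed, since the shared compound's clique already
joins them. Map-link relations are ignored: they point to other pathways,
not to molecular interactions.

The *classical* baseline keeps only rule 1 (no compound bridging, no
reactions) and scores plain precision, which equals `V_1` against that
relation-only network. Because the full conversion's edge set is a
superset of the relation-only one, `V_1 ≥ classical precision` always — a
property test enforces this.

## Evaluation procedures

**ROC study.** Every (network, pathway) pair gets a pruned validity score;
real-network evaluations are the positive class, null-network evaluations
the negative class. At threshold `T`, an evaluation is positive iff its
validity *strictly exceeds* `T` (equality is negative). The default grid
is 0.00–1.00 in steps of 0.01 (101 thresholds). The AUC is the
trapezoidal integral over the achieved (FPR, TPR) points sorted by FPR; no
anchor points are added. Consequences worth knowing: with `T = 1` in the
grid the point (0,0) always occurs (no validity exceeds 1), and with
`T = 0` the point (1,1) occurs whenever every null evaluation has positive
validity — the usual case, since random edges occasionally fall within the
level cap. In the degenerate case where no negative evaluation ever fires
(all null validities exactly 0), all points sit at FPR = 0 and the
trapezoid spans zero width, yielding AUC 0 rather than 1; benchmark
generation avoids this regime and the behaviour is deliberate rather than
patched with synthetic anchors. The internal AUC agrees with
scikit-learn's `auc` to 1e-9 on random score sets (tested).

**Null models.** Pure-random nulls draw exactly `‖E‖` distinct unordered
pairs uniformly over the template's gene set (index-mapped sampling, no
rejection). Scale-free nulls grow a Barabási–Albert graph over the same
genes with attachment parameter `m` chosen to minimise
`|m·(n−m) − ‖E‖|`, i.e. the expected edge count closest to the
template's; node labels are randomly permuted so hub placement is not tied
to lexicographic order. All stochastic operations take an explicit seed.

**Sample size.** `ceil(z² p(1−p)/ε²)` with `z` the two-sided normal
quantile: 385 networks at 95% confidence, 5% margin, p = 0.5 — the
classical infinite-population proportion formula.

**Noise study.** At iteration `k = 1..10`, a fraction `k·10%` of the
*original* edges is removed (perturbation is fresh from the original each
iteration, not cumulative) and the same number of uniformly chosen
non-edges over the same gene set is added, keeping the graph simple and
the edge count constant. Removal and addition are sampled independently
per replicate. The default replicate count is 50 (desk scale); 385
reproduces the sample-size-driven design at full scale.

## Synthetic data

The fixture generator emits KGML files containing every conversion motif:
direct gene–gene relations at a configurable density, a two-gene compound
bridge, a compound shared by three genes, a two-compound chain, group
entries, one multi-gene entry, and two-enzyme transfer reactions. Each
generated pathway is accompanied by the expected converted network built
by an independent naive constructor (plain loops plus a hand-rolled
union-find, no shared code with the conversion module), so conversion is
tested against a genuine oracle rather than against itself.

Benchmark bundles build a "real" network by sampling 80% of the union
gold-standard edges and adding 10% (of the kept count) random non-edges,
then pair it with size-matched nulls. Defaults for the benchmark regime
are 40 genes per pathway, relation density 0.05 (≈2 direct relations per
gene), 6 compounds and 2 reactions — chosen to match the sparsity of real
metabolic pathways, where a gene has a handful of direct partners and
distance-2 neighbourhoods are small relative to the graph.

What a green synthetic benchmark does *not* establish: the generator does
not mimic real pathway size distributions, enzyme multi-functionality
across pathways, or the evidence heterogeneity of curated interaction
networks; absolute AUC values on it say nothing about AUC on real data.

## Known limitations

* The advantage of level-2 scoring over the classical precision baseline
  is regime-dependent: it holds for sparse gold standards (the realistic
  case) but inverts on small dense graphs, where most gene pairs sit
  within distance 2 and null networks score high at level 2. The level
  cap should be chosen with the gold standard's density in mind.
* Levels are computed on the undirected gold standard; no edge-type-aware
  or direction-aware matching is provided.
* How enzyme identifiers (EC numbers) map to genes is outside the model;
  fixtures emit gene entries directly, and real KGML files are expected to
  name genes.
* An empty pruned network yields "undefined validity" and is excluded from
  rankings; whether to treat it as 0 is a policy the caller can implement
  on top.
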