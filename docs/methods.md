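# Methods

## Scope and model

`comorbnet` re-implements, as a reusable and tested pipeline, a common
systems-biology workflow for dissecting the molecular basis of disease
comorbidity from two curated susceptibility gene lists, a pathway
collection (GMT), and a merged protein–protein interactome. The four
stages — gene-set assembly, over-representation analysis (ORA), pathway
cross-talk, and guilt-by-association candidate prediction — are pure
set/graph computations; there is no model fitting. The stages that the
original web-tool-based analyses leave implicit are made explicit and
configurable here.

## Gene sets

Genes are keyed by positive integer Entrez ID; symbols are metadata
(symbol matching is ambiguity-prone). Records carry a provenance set
and an optional gene–disease-association (GDA) score in [0, 1].
`filter_by_gda` keeps records with score **strictly** greater than the
threshold (default 0.2, the DisGeNET "strong association" convention);
a flag switches to ≥. Records without a score are outside its domain
and are dropped by it. The pipeline-level policy (`apply_gda_policy`)
is the union semantics implied by merging a score-filtered database
list with an unscored literature list: unscored records pass, scored
records must exceed the threshold. Merging unions provenance per gene
and keeps the maximum score; all outputs are sorted by ascending gene
ID so reruns are byte-identical.

## Over-representation analysis

The statistic is the one-sided upper hypergeometric tail
P(X ≥ k | N, K, n) (over-representation only), computed with
`scipy.stats.hypergeom.sf`; k = 0 returns exactly 1. The background
universe defaults to the union of all pathway members — the least
presumptuous choice when a collection ships without an explicit
universe — and can be set explicitly (the synthetic generator sets it
to the full gene universe). Query genes outside the background are
dropped before testing; an empty restricted query is a named error, not
a silent zero. BH adjustment (statsmodels `fdr_bh`) runs across the
whole collection, separately per disease — mirroring two independent
enrichment runs rather than pooling. Significance is FDR < alpha
(default 0.05). Classification into shared / A-specific / B-specific
follows from the two significance sets and satisfies the partition
identities |sig_A| = |shared| + |A-specific| by construction.

Reproducing the published AD/MDD term counts (311 GO BP terms, 153/146
significant KEGG pathways, 102 shared) is out of scope: they depend on
2021 GO/KEGG snapshots and unpublished web-tool settings (background,
pathway-size filters). The counts are recorded in
`comorbnet.reference` with a `REPRODUCIBLE = False` flag and only their
internal arithmetic is asserted.

## Pathway cross-talk

Coefficients are computed on **disease-gene-restricted** memberships
(pathway members ∩ disease-associated genes) by default, since the
cross-talk network is built by integrating the two diseases' genes and
per-pathway disease-gene counts; `use_full_members` switches to full
memberships — the source analyses are ambiguous on this point, so both
are first-class. The edge criterion, never stated numerically in the
motivating work, follows the cross-talk literature's convention: both
pathways hold ≥ `min_genes` (default 3) considered genes and share ≥
`min_shared` (default 2). Edge weight is the arithmetic mean of JC and
OC (both are computed; no combination rule is ever stated, and the mean
is the common convention). Edges are canonicalized (lexicographically
ordered pathway pair), so the network is independent of input order,
and raising either threshold can only remove edges.

The tripartite (pathway–pathway–gene) network attaches each retained
pathway's considered member genes from a chosen gene set (shared genes
for the shared-pathway network; all disease genes, with
AD-/MDD-/shared-class labels, for the disease-specific network).
GraphML export keeps every attribute and round-trips exactly; SIF and
TSV are flat Cytoscape-friendly exports.

## Interactome and candidate prediction

Cleaning guarantees: canonical min–max edge storage, no self-loops, no
duplicates, exclusion list applied to merges (default UBC = 7316,
UBB = 7314, UBD = 10537; configurable). Node sets are always derived
from edge endpoints — isolated nodes are never carried.

Disease-network extraction uses the **edge-incident** rule by default:
keep every edge with at least one endpoint in the seed set. This is the
only rule consistent with the published stage sizes (650 seeds cannot
induce a 9,089-node subgraph under the induced rule) and it yields a
useful theorem: for any node of the overlap network (the edge-set
intersection of the two disease networks) that belongs to neither seed
set, every incident overlap edge must lead to a gene in *both* seed
sets — hence such a node's overlap degree equals its count of
shared-gene neighbors. The `induced` rule stays available behind a
switch. The overlap network's node set is defined as the endpoints of
the common edges, not the intersection of node sets.

The candidate score is the number of distinct shared-gene neighbors in
the overlap network (equal, by the theorem, to overlap degree for
non-disease nodes — resolving the ambiguous "node degree with the
disease network as background"); degree in the union disease network is
reported as a secondary column. The published "node degrees > 5.0" call
is the integer threshold ≥ 6. Known disease genes are excluded from
novel calls; ties rank by ascending gene ID for determinism. The
published overlap-network edge count (4,900) violates edge
inclusion–exclusion by exactly one against its own stage counts
(32,065 + 18,221 − 45,385 = 4,901); the package records and surfaces
this discrepancy rather than absorbing it, and asserts the identity
exactly on everything it computes itself.

## Synthetic data

The generator emulates the data regime above with planted, constructive
ground truth. Defaults are the package's benchmark study conditions:
5,000-gene universe; Erdős–Rényi background at mean degree 6 (G(n, m)
with m = 3n; a Barabási–Albert option exists for heavy-tailed degrees);
disease sets of 100 and 100 sharing exactly 30 (the shared subset is
sampled first, so the overlap is exact); 20 candidate genes sampled
from the non-disease remainder, each wired by added edges to exactly 8
distinct shared genes; 50 pathways with sizes uniform on [10, 60], of
which 4 per disease are planted by drawing ⌈0.8·size⌉ members from that
disease's gene set and the rest from the remaining universe, the others
uniform from the universe. With these parameters the planted
hypergeometric signal is overwhelming (k ≈ 24, K = 30, n = 100,
N = 5,000) while the chance that a background node accrues ≥ 6
shared-gene neighbors (Binomial(30, ~0.0012) tail) is ~10⁻¹²: the
noise-free recovery guarantee is constructive, not statistical luck.
One integer seed drives a single `numpy.random.Generator` stream; file
outputs are sorted and byte-identical across runs.

What the generator does **not** emulate: the human interactome's degree
distribution and clustering, gene-family structure in pathways,
correlated annotation (pathway overlap in real KEGG is far from
uniform), or literature-curation biases in gene lists. Passing tests
therefore validate the pipeline's *semantics and statistics* — set
algebra, extraction rules, error control, recovery of planted signal —
not the biological conclusions one would draw on real data.

The `rewire` noise model replaces round(rate·|E|) uniformly chosen
edges with uniform random non-self, non-duplicate pairs; the edge count
is conserved, the degree sequence is not. It degrades candidate wiring
roughly binomially, so mean recall at threshold 6 with wiring 8 falls
from 1.0 (rate 0) to ≈ 0.97 / 0.6 / 0.16 at rates 0.1 / 0.3 / 0.5.

## Numerical and design choices

- Hypergeometric p-values come from scipy's `sf`; the test suite checks
  them against exhaustive draw enumeration (all parameter combinations,
  N ≤ 12) and exact rational combinatorial sums (N ≤ 200, 1e-10
  relative).
- BH adjustment delegates to statsmodels; the suite checks the literal
  step-up definition, monotonicity, and permutation invariance.
- All orderings (gene IDs, pathway IDs, edges, rankings) are total and
  deterministic; no output file contains a timestamp.
- Degenerate inputs raise named errors (empty restricted query, empty
  sets for JC/OC, empty seed set, candidate absent from the network,
  malformed GMT/TSV lines) rather than returning sentinel values.
- Simulation sizes in the test suite and acceptance script (10–100
  seeds, 500 null replicates, 5,000-gene universe) were chosen as the
  smallest sizes at which the binomial/hypergeometric error bars are
  far narrower than the effects being asserted.

## Known limitations

- ORA treats genes as exchangeable; no gene-length, expression, or LD
  bias correction (none is claimed by the approach it implements).
- Direct-neighbor counting only; no diffusion or shortest-path
  prioritization.
- The cross-talk edge criterion and the full-vs-restricted membership
  choice are conventions, exposed as parameters, not inferences.
- Pathway module labels (immune / neurodevelopment / cancer /
  endocrine) in the motivating analyses are manual curation and are out
  of scope; the exports carry node classes so such annotation can be
  done downstream.
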