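# Methods

## Model

`lion` scores lncRNA–disease associations by network proximity under the
guilt-by-association premise: molecules involved in the same disease tend to
interact and to concentrate in a common neighborhood of the interactome, so
a lncRNA whose protein partners sit close to a disease's genes is a
plausible candidate for that disease.

The input is a tripartite network with node classes {lncRNA, protein,
disease} and edge layers lncRNA–protein, protein–protein (PPI) and
disease–protein. All layers are unweighted; the PPI is undirected
(reversed duplicates are one edge, self-loops are dropped). Identifiers are
normalized by uppercasing and stripping surrounding whitespace, since gene
symbols and lncRNA names are case-inconsistent across source databases; the
same string may name both a protein and a lncRNA (distinct nodes, logged as
a warning).

### Disease subnetwork

For disease *d*, seeds are its disease genes present in the PPI (absent
genes are dropped with a warning; zero seeds aborts extraction for that
disease). The walk graph contains the seeds, their first PPI neighbors, the
PPI edges between member proteins, and the lncRNA–protein edges from any
lncRNA into the member set. Disease nodes themselves never enter the walk
graph — the disease acts only through the restart distribution.

Which PPI edges qualify is governed by `edge_rule`:

* `induced` (default): all PPI edges with both endpoints in the member set,
  including neighbor–neighbor edges. Chosen because it preserves the local
  topology (triangles, dense cores) that the walker exploits.
* `star`: only edges incident to a seed — a stricter reading of
  "interactions between the disease genes and their nearest neighbors".

A subnetwork is *eligible* for diffusion iff its walk graph is connected
and non-bipartite and the seed set is non-empty — the classical condition
for a plain random walk to have a unique limit. With restart probability
r > 0 the iteration is a contraction and converges on any graph, but the
filter is applied as stated; `lion rank --force` overrides it with a
prominent warning.

### Diffusion

With node order fixed (lexicographic by (kind, identifier), lncRNAs before
proteins), `W` is the column-normalized adjacency (`W[i,j] = 1/deg(j)`),
`p^0` uniform over the seeds, and

    p^(k+1) = (1 − r) W p^k + r p^0 ,   starting at p^0.

Defaults: `r = 0.5`, L1 tolerance `1e-6`, `max_iter = 1000`. Since `W` is
column-stochastic, mass is conserved (Σp^k = 1) and the map contracts in L1
with factor (1 − r), so at r = 0.5 and tol 1e-6 convergence needs at most
ceil(log(tol/2)/log(1−r)) = 21 iterations regardless of graph size, and the
starting vector is immaterial to the fixed point. lncRNAs are ranked by
their raw p^∞ entries (no renormalization over lncRNAs), ties broken by
identifier, ranks 1-based. `diffuse_closed_form` solves
(I − (1−r)W) p = r p^0 directly and serves as the testing oracle; the
system is nonsingular for any r > 0.

Numerical choices: matrices are scipy CSR; the power iteration materializes
a dense copy for graphs of ≤ 500 nodes (identical results to ≤ 1e-12 — the
threshold only trades memory for speed). Scores are written as shortest
round-trip decimal representations so LDN files re-read bit-identically.

### LDN assembly

`predict_all` processes diseases in lexicographic order, recomputing each
subnetwork independently (no cross-disease caching) so runs are
deterministic and per-disease failures are isolated. Ineligible or failing
diseases are skipped, never fatal, with a machine-readable reason
(`no_seeds`, `disconnected`, `bipartite`, `not_converged`). Each eligible
disease contributes one weighted edge per ranked lncRNA; per-disease edge
weights therefore sum to ≤ 1 (lncRNA mass is a sub-vector of a probability
vector). Medians in the LDN summary use the mean-of-central-values rule for
even counts.

## Evaluation

ROC curves sweep the predicted edge weights as thresholds. The ground truth
never defines negatives, so the negative set is all predicted edges absent
from the truth file — consistent with sweeping the whole predicted edge
set. With every operating point retained, the trapezoidal area equals the
tie-corrected rank statistic (concordant + ½·tied)/(n_pos·n_neg); the tests
verify this against exhaustive pairwise counting. Group evaluation pools
all edges of the group's diseases into one curve; `--per-disease`
macro-averages per-disease AUCs instead (provided as an alternative,
without a validated reference behavior).

The null model permutes lncRNA labels among lncRNA nodes and disease labels
among disease nodes of the bipartite LDN — one global permutation per
class, never across classes — preserving the unlabeled graph: degree
sequences and the weights attached to graph positions are unchanged while
identities are randomized. A single seeded generator (`numpy` PCG64) drives
the shuffle; a fixed seed reproduces the null byte-for-byte.

Rank-sum comparisons use the two-sided Wilcoxon/Mann–Whitney test: the
classical exact distribution for tie-free samples with both sizes ≤ 20,
full enumeration of the C(n1+n2, n1) group assignments for small tied
samples (≤ 20,000 combinations; this makes identical samples yield p = 1
under the doubled-tail rule), and otherwise the normal approximation with
tie and continuity corrections.

## Synthetic benchmarks

The generator emulates the structure the method assumes: an Erdős–Rényi
PPI background (`background_edge_prob`) overlaid with dense planted disease
modules (`module_edge_prob` within each module's `genes_per_disease`
proteins, sampled without replacement within a module, overlapping across
modules as real disease genes do); each disease's genes are exactly its
module; each planted lncRNA attaches to its module's proteins with
probability `attach_true` and to all other proteins at `attach_background`;
non-planted lncRNAs attach everywhere at the background rate.

Defaults are the strong-planting regime: 300 proteins, background edge
probability 0.02 (mean PPI degree ≈ 6, the sparse-but-connected regime of
curated interactomes), 10 diseases × 15 genes, module density 0.5, 100
lncRNAs with 2 planted per disease, attachment 0.8 vs 0.02. Connectivity
floor: isolated lncRNAs are re-drawn (up to 100 attempts) and a protein
absent from all three layers receives one background PPI edge, so node
counts always equal the config and every planted pair is scoreable.

`recovery_experiment` draws `n_seeds` replicate benchmarks (child seeds of
the config seed), runs the full pipeline on each, scores the LDN against
the planted truth, and scores `n_null_per_seed` label-shuffled copies as
the control; it reports means and standard deviations of both AUCs. The
test suite uses 10 replicates; the acceptance script additionally averages
5 shuffles per replicate to report a lower-variance null estimate (the
analytic null-AUC standard deviation at ~20 positives / ~900 negatives is
≈ 0.065 per shuffle).

What the benchmark does *not* emulate: scale-free or
duplication-divergence PPI topology, literature ascertainment bias toward
well-studied lncRNAs, weighted or directed interactions, and disease gene
sets that straddle several network neighborhoods. Passing the recovery
tests therefore shows the pipeline recovers a planted local-neighborhood
signal, not that real-data AUCs of any particular magnitude are expected.

## Degenerate inputs and edge cases

* Empty layers: warning, empty network; empty disease layer yields an
  empty LDN (warning) whose summary medians are NaN.
* A walk graph with an isolated node cannot be column-normalized
  (named error); this cannot arise from an eligible subnetwork.
* AUC is undefined (error) when a restriction leaves zero positives or
  zero negatives; truth pairs with no predicted edge are logged as
  unscored positives and contribute nothing.
* `r = 1` is allowed and returns the restart distribution after one step;
  `r = 0` is rejected (no contraction guarantee).

## Known limitations

* Full-scale published interaction layers are external downloads; the
  package only validates against synthetic benchmarks and user-supplied
  files, which it takes as-is (no alias resolution beyond exact normalized
  matching, no disease-ontology mapping).
* Seeds are unweighted; association strength, expression and edge weights
  are ignored by design.
* Only first PPI neighbors enter the subnetwork; multi-hop neighborhoods
  and symmetric (degree-½) normalization variants are out of scope.
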