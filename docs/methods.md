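# Methods

`pcnfold` computes network observables of native protein structures that
discriminate two-state (TS) from multi-state (MS) folding kinetics, and
evaluates them with a homology-aware discriminant-analysis protocol.
This note records the models, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Protein contact networks

A protein is reduced to its C-alpha trace; the protein contact network
(PCN) joins residues *i*, *j* whenever their C-alpha distance satisfies
0 < d_ij ≤ 8 Å. The threshold is inclusive — the common convention when
a cutoff is stated as an upper bound — and is exposed as `--threshold`
for sensitivity analysis. Backbone contacts (|i−j| = 1, peptide-bond
distance 3–4 Å) are part of the full PCN; they are removed only where
the spectral observables require it (below).

Parsing policy for real PDB files (the source gives no guidance on
these, so the package fails loudly rather than guessing):

* chain: first polymer chain by default, `--chain` to override; first
  model only;
* altLoc duplicates: highest occupancy wins, ties broken by altLoc
  letter;
* MSE → M and SEC → C are accepted; any other nonstandard residue is an
  error naming the residue;
* sequence-number gaps: residues are renumbered consecutively in order
  of appearance and a warning with the gap count is logged. Dropping
  positions keeps every matrix well-formed; users who prefer otherwise
  can pre-process.

## Weighted networks and the entropy ratio S_R

Link weights are statistical contact potentials: for a link (i, j) the
raw weight is M[r_i, r_j] from a 20×20 residue contact-energy table,
shifted per protein by a constant so the smallest link weight is exactly
1 (entropies need positive weights). Only the shifted weights enter any
computation, so the observables are insensitive to the table's additive
normalisation. The shipped table
(`data/mj_contact_potentials.tsv`) is a Miyazawa–Jernigan-style contact
energy matrix transcribed to two decimals; because only shifted weights
matter and all correctness tests use synthetic potential tables, no
result in the test suite depends on that transcription. Any 20×20
symmetric TSV can be supplied with `--potentials`.

Two canonical maximum-entropy ensembles over integer link weights
w ∈ {0, 1, 2, …} are fitted to each weighted PCN:

* **strength-constrained** (entropy S_s): expected node strengths
  ⟨s_i⟩ (weighted contact sums) are enforced. Pair weights are
  geometric: π_ij(w) = (1 − x_i x_j)(x_i x_j)^w.
* **strength-and-degree-constrained** (S_ks): expected strengths and
  expected degrees ⟨k_i⟩ are enforced jointly;
  π_ij(0) = 1/Z_ij, π_ij(w ≥ 1) = y_i y_j (x_i x_j)^w / Z_ij.

Integer support follows the standard network-ensemble formalism; the
entropy sum runs over all N(N−1)/2 pairs (required for the degree
constraints to be meaningful), entropies are reported in nats, and the
ratio S_R = S_s / S_ks ≥ 1 is base-independent. S_R near 1 means the
strength sequence alone pins down the ensemble; large S_R means many
contact topologies (degree sequences) are compatible with the observed
strengths — the physical picture being that such native states coexist
with many network configurations, as expected for MS folders.

### Solver

The dual (Lagrange-multiplier) problem is solved by coordinate-wise
exact minimisation: per node, the multiplier is solved with a bracketed
root finder (brentq, xtol 1e-300 so roots may span hundreds of orders of
magnitude) while all others are held fixed; sweeps repeat until the
maximum constraint residual is ≤ 1e-8 (default `tolerance`). Because
each coordinate solve is an exact coordinate minimisation of a convex
function, the dual objective is non-increasing across sweeps — a
property the test suite asserts. A damped Newton step on the free
log-multipliers (analytic Jacobian, step accepted only if it reduces the
residual norm) accelerates the linear tail; it is attempted at sweeps
40, 200 and 600.

Parametrisation matters at the boundaries of the constraint set:

* the joint fit uses (t_i = x_i y_i, x_i) rather than (x_i, y_i), which
  turns the all-unit-weight case s_i = k_i (where x and y diverge
  jointly) into an ordinary interior point — the binary configuration
  model;
* a node whose degree constraint saturates (it must link to every
  available partner, as in the two-node reference case) has a divergent
  multiplier; t is capped at 1e100, which perturbs the entropy only at
  O(1/t);
* constraint vectors on a *facet* of the realisable polytope — degree
  sequences attaining an Erdős–Gallai equality (a subset of nodes whose
  mutual links are all forced), or strengths that push a
  vanishing-probability link to carry finite expected weight — have no
  finite dual solution at all, and the sweeps stall at a sub-geometric
  rate. When that is detected (less than 2× residual reduction per 100
  sweeps), the fit falls back to the equivalent *primal* convex program
  in the pairwise link probabilities p_ij and excess weights
  e_ij = ⟨w_ij⟩ − p_ij, where the pair entropy
  h(p, e) = −(1−p)ln(1−p) − 2p ln p + (p+e)ln(p+e) − e ln e
  is concave, the constraints are linear, and facets are ordinary
  boundary points. The primal program is solved by an augmented
  Lagrangian (method of multipliers) with L-BFGS-B inner solves to the
  same residual tolerance. Realistic PCNs sit well inside the polytope
  and never need the fallback; it exists so that arbitrary valid
  constraint sets — including adversarial random networks used in the
  property suite — are fitted exactly rather than rejected.

Entropies are evaluated in chain-rule form, H(link indicator) +
p · H(weight | link present), which is free of the catastrophic
cancellation the naive ln Z expansion suffers when a constraint
saturates; this is what lets the two-node fits agree with their symbolic
closed forms to better than 1e-10, and in practice to ~1e-14.

Non-convergent constraint sets (e.g. two nodes with unequal strengths,
which share a single pair) raise a fit error carrying the residuals;
clearly unrealisable inputs (strength below degree, degree exceeding the
partner count) are rejected up front.

## Spectral observables

The combinatorial Laplacian L = D − A of a contact network is positive
semi-definite; by the membrane analogy its largest eigenvalues are the
highest vibrational frequencies, with the corresponding modes tending to
localise on specific chain regions. To emphasise long-range structure,
the backbone is removed protein-specifically: b is the smallest number
of leading diagonals (chain separations 1..b) whose removal disconnects
the PCN, found by incremental removal with a connected-components check;
then diagonals 1..b−1 are removed, leaving the largest
backbone-stripped network that is still one component (so the spectrum
is that of a single connected graph). The observables λ_N, λ_{N−1},
λ_{N−2} are the three largest eigenvalues divided by the residue count
N_C — the rescaling that removes the observed linear size dependence of
the raw eigenvalues. Eigenvalues come from a dense symmetric
decomposition (deterministic; fine for chains up to a few thousand
residues).

Note the b-reduction is defined by chain order: relabelling nodes
changes the diagonals, so these features are deliberately *not*
graph-isomorphism invariants — the suite asserts this.

## Inter-residue link density R_0

The d-diagonal of the adjacency matrix holds the contacts at chain
separation d (d = 1..N_C−1). R_0 is the number of empty diagonals
divided by N_C — kept as N_C, not N_C−1, so the maximum attainable
value is (N_C−1)/N_C. Low R_0 = contacts at many separations = diffuse,
cooperative interactions; high R_0 = interactions concentrated in a few
bands. R_0 is computed on the full PCN (not the b-reduced one).

## Classical comparators

* mean Kyte–Doolittle hydropathy ⟨h⟩ (shipped 20-entry scale,
  pluggable via `--hydropathy`);
* relative contact order CO = (L_C · N_C)^{-1} Σ_{contacts} |i−j|,
  over the full PCN with no separation floor;
* long-range order LRCO = |{contacts with |i−j| > 12}| / N_C. The
  count form (rather than a separation-weighted sum) follows the
  long-range-order definition this statistic descends from; `min_sep`
  is configurable so the sensitivity to this reconstruction choice can
  be measured rather than assumed.

## Classification protocol

Features (any subset: singles, pairs, triples, quadruples) feed Gaussian
discriminant analysis — quadratic (per-class covariance) by default,
with linear (pooled covariance) available; priors are training
frequencies. The default is quadratic because the reference protocol's
performance tables are QDA-based even where the surrounding text says
"Fisher"; both modes are exposed so the distinction is testable.
Covariance regularisation uses scikit-learn's reg_param = 1e-9
(a convex shrink toward identity-scaled variance) to guard tiny folds.

Performance is estimated by k-fold cross-validation (k = 10) in which
homology groups are atomic: every resampling shuffles the groups and
deals them greedily into the currently smallest fold, so homologs never
appear on both sides of a train/test split (which would inflate
performance). Per resampling, predictions are pooled over the k test
folds before computing overall accuracy, per-class accuracies and the
Matthews correlation coefficient (zero-denominator convention: MCC = 0);
the report gives means and standard deviations over resamplings
(default 10000) and is bit-reproducible from the seed. The sd across
resamplings measures fold-assignment variability and does not shrink
with more resamplings — it is the *mean* that stabilises as
1/√n_resamplings, and that is what the suite verifies. Homology groups
are an input column; the package does not infer homology.

## Synthetic fixtures

Generators make every stage testable offline, as pure functions of
their parameters and seed:

* banded networks (exact separations) — exercise the diagonal
  machinery, R_0 and b against hand-computable oracles;
* ideal α-helix traces (rise 1.5 Å, radius 2.3 Å, turn 100°) — the 8 Å
  contact pattern is exactly the separations {1,2,3,4}, independent of
  length;
* self-avoiding random globules: 3.8 Å consecutive spacing, ≥ 3.5 Å
  clash distance, confined to a sphere of radius c·n^{1/3} with
  c = 3.0 Å by default (≈ 0.009 residues/Å³, protein-like packing);
  chain growth with rejection and full restarts;
* two-class Gaussian feature clouds with homology groups of fixed size
  and known Bayes error — the classifier acceptance harness (default
  class means 4σ apart per axis, Bayes error ≈ 0.2%).

These fixtures emulate the *geometry* and *statistics* the pipeline
consumes, not protein physics: globules have no secondary structure,
helices no tertiary contacts, and feature clouds are exactly Gaussian.
Green tests therefore establish numerical and algorithmic correctness —
oracle agreement, invariants, classifier recovery at known Bayes error —
not biological performance on real structures; the latter requires real
PDB inputs and a curated TS/MS label table, which the `features` +
`classify` commands accept unchanged.

## Problem sizes and determinism

The test and acceptance runs use networks of 5–60 nodes, 100-network
property sweeps, and 1000-resampling cross-validation on 100-sample
datasets — sizes chosen so the full suite completes in a few minutes
while every guarantee (residual ≤ 1e-8, closed forms to 1e-10,
exhaustive b-oracle agreement for bands ⊆ {1..5}, N ≤ 20) is exercised
at full strength. All randomness flows through explicit
`numpy.random.default_rng` seeds; CLI feature tables embed the package
version and a hash of the resolved configuration, and identical
configurations produce byte-identical outputs.

## Known limitations

* The contact-potential transcription is approximate (two decimals,
  from-memory); swap in `--potentials` for exact published values.
  Shift-invariance makes the entropies robust to this in practice.
* Raw-network inputs (`--input-format matrix|edges`) have no residue
  identities: entropies use unit weights and ⟨h⟩ is NaN.
* The primal fallback is exact but slower than the dual path; an
  adversarial large network on a polytope facet could take minutes.
* CLI exit codes: 0 success, 1 usage, 2 data error.
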