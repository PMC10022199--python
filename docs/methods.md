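# Methods

## Model

The package reconstructs clonal evolution from a longitudinal single-cell
experiment as a Boolean matrix factorization with constraints. A rooted
mutation tree over the `m` post-filter mutations encodes a perfect
phylogeny under the infinite sites assumption (ISA): each mutation occurs
once and is never lost, so the mutation set of a clone is the union of the
mutations on its root path. We use the mutation-tree convention — exactly
one clone per mutation, no explicit wild-type clone — which is forced by
the root rule used in clonal-tree reconstruction (the root clone is the
unique row of the phylogenetic matrix `B` with L1 norm 1; a wild-type row
would have norm 0).

Observations `G` (cells × mutations, entries 0/1/NA) deviate from the
noiseless genotypes `D = C·B` through per-sample error rates: a false
positive rate `α_s` (a mutation observed where none exists — sequencing
error, mapping artifact) and a false negative rate `β_s` (a mutation
missed — chiefly allelic dropout). NA entries denote insufficient read
depth and contribute a likelihood factor of 1 (no evidence either way).
The likelihood factorizes completely over samples, cells and mutations,
which makes it time-agnostic and cheap to evaluate; all time structure
enters post hoc through the longitudinal augmentation.

The prior over `(B, C)` is uniform, so posterior maximization reduces to
likelihood maximization.

### Sample weights

Each sample's log-likelihood contribution is scaled by `w_s`. The default
is `w_s = (N/S)/n_s`: every time point contributes equally regardless of
how many cells it happened to yield, and `Σ_s w_s n_s = N`. Users can
override the weights (e.g. `w_s = 1` to weight cells, not samples,
equally).

### Attachment handling

Two likelihood modes are available per fit:

- **MAP attachments** (default): each cell contributes the maximum over
  clones of its attachment log-likelihood. Ties break toward the clone
  with the smaller mutation set, then the lexicographically smaller
  mutation id, making attachments deterministic (an all-NA cell lands on
  the root).
- **Marginalized**: each cell contributes the log-mean over clones
  (uniform 1/m attachment prior), computed with log-sum-exp. We chose the
  uniform prior as the least informative option; an empirical
  (prevalence-weighted) prior would couple cells and break the clean
  factorization.

## Search

The tree space is explored by MCMC with restarts. Moves: prune-and-reattach
(probability 0.6) — detach a non-root subtree and reattach it under a
uniformly chosen node outside it — and label swap (0.4) — exchange two
mutations' positions. Both preserve rootedness and acyclicity and both are
reversible, so the chain is irreducible over the `m^(m−1)` rooted labeled
trees. A proposed tree is accepted with probability
`min(1, exp(ΔlogL / λ))` where `λ` is the learning rate (default 1): a
temperature. As `λ → 0` the search degenerates to hill climbing; larger
`λ` accepts more downhill moves and escapes local maxima at the cost of
slower concentration.

Candidate error rates are supplied as per-sample grids; the search is run
for every rate combination and the best scoring solution across
combinations is returned, compared on raw weighted log-likelihood (no
penalty for the rate values themselves). With rate estimation enabled,
every 10th iteration perturbs one sample's `α` or `β` by a Gaussian step
(σ = 0.2) in logit space instead of proposing a tree move, accepted by the
same rule.

Chains stop early after `early_stopping` iterations (default 500) without
strict improvement of the chain's best score. Each restart derives its own
seed from the master seed via `numpy.random.SeedSequence.spawn`, so
results are bit-identical regardless of the process count used to run
restarts.

Mutations with byte-identical observation columns (NA pattern included)
are collapsed to one representative before the search — no likelihood can
order them — and re-expanded in reports. A column differing only by an
NA ↔ 0 exchange is *not* collapsed: the NA carries no evidence but the 0
does.

Equivalent solutions: trees within 1e-9 absolute log-likelihood of the
optimum are retained when requested; at machine precision a looser
tolerance would conflate genuinely different scores.

## Clonal and longitudinal tree construction

From the fitted `B`, the clonal tree is rebuilt directly: root = the
norm-1 row; every other clone's parent is the argmin, over clones with
strictly smaller mutation sets, of the L1 distance between the rows — an
immediate consequence of the ISA (the parent's set is the child's set
minus one mutation). Ties, which can only arise on noisy or malformed
`B`, break toward the larger parent set and then the lexicographically
smaller clone id, so reconstruction is deterministic. On any `B` derived
from a valid mutation tree the rule recovers the generating topology
exactly (property-tested over 1000 random trees up to m = 10).

Clone prevalences are cell fractions per sample from the MAP attachments;
each sample's column sums to 1 by construction.

The longitudinal tree duplicates each clone at every time point from its
first observation (prevalence > 0) to the final one, with persistence
edges between consecutive copies. Because sampling can miss a
low-prevalence parent, a child may be observed first; the correction
propagates earliest-observation times from the leaves toward the root in
one pass (handling cascaded reversals through grandparents), inserting
zero-prevalence parent copies at the earlier time. Parental edges are
anchored at the child's first time tag — the natural choice, since that is
the earliest time at which both endpoints exist. Clones never observed in
any sample acquire the minimum first time of their observed descendants;
a never-observed clone with no observed descendants is dropped from the
longitudinal view (kept in the clonal tree) with a warning.

## Filter cascade

The cascade runs in a fixed order: binarize → MAF → exonic function →
cell frequency → depth-NA → missing fraction → median depths → known
genes. Decisions where the natural reading was open:

- **Binarization threshold** is inclusive (ALT reads ≥ `min_alt_reads`,
  default 2); a strict `>` mode is available behind a flag.
- **MAF rule**: keep when the population minor-allele frequency is ≤ the
  cutoff (default 0.01) *or unrecorded* — absence from population
  databases is evidence of somatic status, not grounds for removal.
- **Cell frequency** (default 0.01) is satisfied when *any* sample reaches
  the fraction; an all-samples mode exists behind a flag. The any-sample
  reading keeps mutations private to one time point, which is precisely
  the longitudinal signal of interest.
- **Median ALT depth** (default 4) is computed over the cells carrying the
  mutation; the all-cells alternative (available behind a flag) would be
  dominated by the zeros of non-carrier cells and reject almost
  everything.
- **Missing fraction** (default 0.4) is evaluated per variant site.
- Medians of even-length samples are the arithmetic mean of the middle
  pair; threshold comparisons are ≥ (ties pass).

Each filter is a projection (idempotent, never adds variants or flips
0 ↔ 1), and the pure annotation-based filters commute; both properties are
asserted in the test suite.

## Synthetic data

The generator emulates the statistical structure the model assumes, with
defaults describing a small longitudinal design: m = 8 mutations, three
time points of 50 cells, α = 0.05, β = 0.15, 10% NA, mean mapped depth
20×. Trees are uniform over rooted labeled trees (Prüfer sequence plus a
uniform root). Per-sample clone prevalences are symmetric-Dirichlet
(concentration 1 by default — occasionally near-degenerate compositions,
which is realistic for clonal sweeps); cells attach i.i.d. by prevalence.

Read depths are generated so the cascade, not a flag, reproduces the
intended matrix on ingestion: NA entries are realized as sites with total
depth below the depth threshold, observed 1-entries carry ALT support at
or above the binarization threshold, observed 0-entries stay below it.
Totals are Poisson at the mean depth, truncated below at the depth
threshold for measured sites; ALT counts are binomial given the entry
state. Each variant column is conditioned to retain at least one observed
non-NA 1 — a variant observed nowhere would be absent from any real call
set — touching at most one entry per variant, a negligible perturbation of
the configured rates at the matrix sizes used.

What the generator does **not** emulate: doublets, copy-number variation
and allelic imbalance, site-specific or cell-specific error rates,
correlated dropout along transcripts, and germline contamination. Tests
passing on this generator therefore certify the estimator under its own
model assumptions, not robustness to these real-data effects.

## Numerical choices

- All likelihoods in log space; per-clone tables computed as two matrix
  products per sample, so no underflow for any practical matrix size.
- Equivalence tolerance 1e-9 absolute log-likelihood; enumeration
  cross-checks agree to ~1e-15.
- Problem sizes in tests and the acceptance script (m ≤ 8, ≤ 150 cells,
  10 replicates; exhaustive enumerations at m = 4) were chosen as the
  smallest instances that exercise every code path and still give the
  stochastic checks comfortable margins; all complete in seconds thanks to
  early stopping.

## Known limitations

- Variant keys are kept verbatim (`chrom:pos:ref:alt`, 1-based); indels
  are not left-aligned or normalized, so the same indel written two ways
  is two variants.
- No doublet, copy-number or back-mutation (finite-sites) modeling.
- Maximization only: the search returns the best tree (and ties), not a
  posterior sample, so no credible sets.
- Per-cell BAM pileups are not computed; depths are consumed as a table.
- The rate-grid search is exhaustive over per-sample combinations and its
  cost grows multiplicatively with grid sizes.
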