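"""Generative model: D = C·B with per-sample false positive/negative noise.

A mutation tree over m mutations defines m clones (one per introduced
mutation) and hence a clones x mutations Boolean phylogenetic matrix B
whose row i is the mutation set accumulated on the root->i path — the
perfect-phylogeny encoding under the infinite sites assumption (no back
mutations).  An attachment matrix C assigns each cell to one clone, and
the noiseless genotype matrix is D = C·B.  Observations G deviate from D
through per-sample false positive (alpha_s) and false negative (beta_s)
rates; NA entries carry no evidence.  The weighted log-likelihood
factorizes over samples, cells and mutations:

    log P(G | B, C) = sum_s w_s sum_{i in s} sum_j log P(G_ij | D_ij)

with P(1|0)=alpha, P(0|0)=1-alpha, P(0|1)=beta, P(1|1)=1-beta and
P(NA|.)=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .matrix import CellMetadata, MutationMatrix

__all__ = [
    "MutationTree",
    "NoiseModel",
    "entry_log_prob",
    "genotypes_from",
    "weighted_log_likelihood",
    "map_attachments",
    "marginal_log_likelihood",
    "LikelihoodEngine",
]

ROOT = -1


class TreeError(ValueError):
    """Raised for structurally invalid mutation trees."""


@dataclass(frozen=True)
class MutationTree:
    """Rooted tree over mutations, stored as a parent array.

    ``parent[i]`` is the index of mutation i's parent, or -1 for the
    single root mutation.  ``mutations`` are the column labels of the
    matrix the tree was built for.
    """

    mutations: tuple[str, ...]
    parent: tuple[int, ...]

    def __post_init__(self) -> None:
        m = len(self.mutations)
        if m == 0:
            raise TreeError("a mutation tree needs at least one mutation")
        if len(self.parent) != m:
            raise TreeError("parent array length mismatch")
        roots = [i for i, p in enumerate(self.parent) if p == ROOT]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        # acyclicity + connectivity: walk to root from every node
        for i in range(m):
            seen = set()
            j = i
            while j != ROOT:
                if j in seen or not (0 <= j < m):
                    raise TreeError(f"cycle or invalid parent reached from node {i}")
                seen.add(j)
                j = self.parent[j]

    @property
    def m(self) -> int:
        return len(self.mutations)

    @property
    def root(self) -> int:
        return self.parent.index(ROOT)

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.m)]
        for i, p in enumerate(self.parent):
            if p != ROOT:
                out[p].append(i)
        return out

    def topological_order(self) -> list[int]:
        """Nodes ordered root first, every parent before its children."""
        order = [self.root]
        kids = self.children()
        stack = list(reversed(kids[self.root]))
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(kids[v]))
        return order

    def phylogenetic_matrix(self) -> np.ndarray:
        """Clones x mutations Boolean matrix B (clone i <-> mutation i)."""
        m = self.m
        B = np.zeros((m, m), dtype=bool)
        for v in self.topological_order():
            p = self.parent[v]
            if p != ROOT:
                B[v] = B[p]
            B[v, v] = True
        return B

    def ancestor_matrix(self) -> np.ndarray:
        """A[i, j] = True iff mutation i is a strict ancestor of mutation j."""
        B = self.phylogenetic_matrix()
        A = B.T.copy()
        np.fill_diagonal(A, False)
        return A

    def with_parent(self, node: int, new_parent: int) -> "MutationTree":
        p = list(self.parent)
        p[node] = new_parent
        return MutationTree(self.mutations, tuple(p))


def validate_phylogenetic_matrix(B: np.ndarray) -> None:
    """Check the perfect-phylogeny invariants of a clones x mutations B."""
    norms = B.sum(axis=1)
    if (norms == 1).sum() != 1:
        raise TreeError(
            f"phylogenetic matrix must have exactly one row of L1 norm 1, "
            f"found {(norms == 1).sum()}"
        )


@dataclass
class NoiseModel:
    """Per-sample error rates and likelihood weights.

    alpha: false positive rate (spurious observed mutation),
    beta: false negative rate (missed mutation, e.g. allelic dropout),
    both strictly inside (0, 1).  weights default to ``(N/S)/n_s`` so
    every time point contributes equally.
    """

    alpha: dict[str, float]
    beta: dict[str, float]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rates in (("alpha", self.alpha), ("beta", self.beta)):
            for s, r in rates.items():
                if not (0.0 < r < 1.0):
                    raise ValueError(f"{name}[{s!r}] = {r} outside (0, 1)")

    @classmethod
    def uniform(
        cls, metadata: CellMetadata, alpha: float, beta: float,
        weights: dict[str, float] | None = None,
    ) -> "NoiseModel":
        w = metadata.default_weights() if weights is None else weights
        return cls(
            alpha={s: alpha for s in metadata.sample_order},
            beta={s: beta for s in metadata.sample_order},
            weights=w,
        )

    def resolved_weights(self, metadata: CellMetadata) -> dict[str, float]:
        return self.weights if self.weights else metadata.default_weights()


def entry_log_prob(observed: float, true: int, alpha: float, beta: float) -> float:
    """Log probability of one observed entry given its true genotype.

    NA observations (NaN) are uninformative and contribute 0.
    """
    if isinstance(observed, float) and math.isnan(observed):
        return 0.0
    if true == 0:
        return math.log(alpha) if observed == 1 else math.log1p(-alpha)
    return math.log1p(-beta) if observed == 1 else math.log(beta)


def genotypes_from(tree: MutationTree, attachments: np.ndarray) -> np.ndarray:
    """Noiseless genotype matrix D = C·B for one-hot attachments C.

    ``attachments`` may be a one-hot cells x clones matrix or a vector
    of clone indices; returns a cells x mutations 0/1 array.
    """
    B = tree.phylogenetic_matrix()
    att = np.asarray(attachments)
    if att.ndim == 2:
        if att.shape[1] != tree.m:
            raise ValueError("attachment matrix clone dimension mismatch")
        if not (att.sum(axis=1) == 1).all():
            raise ValueError("attachment matrix rows must be one-hot")
        idx = att.argmax(axis=1)
    else:
        idx = att.astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= tree.m):
            raise ValueError("clone index out of range")
    return B[idx].astype(int)


class LikelihoodEngine:
    """Vectorized per-clone log-likelihood evaluation for one matrix G.

    Precomputes per-sample indicator matrices so that, for any candidate
    phylogenetic matrix B, the cells x clones table of per-cell
    attachment log-likelihoods is two matrix products per sample.
    """

    def __init__(self, matrix: MutationMatrix, noise: NoiseModel):
        self.matrix = matrix
        self.noise = noise
        meta = matrix.metadata
        vals = matrix.values()
        self.m = matrix.n_variants
        self.n = matrix.n_cells
        self.sample_rows = matrix.sample_indices()
        self.weights = noise.resolved_weights(meta)
        self._per_sample: list[tuple[str, np.ndarray, np.ndarray, float]] = []
        for s in meta.sample_order:
            rows = self.sample_rows[s]
            if rows.size == 0:
                continue
            sub = vals[rows]
            g1 = (sub == 1.0).astype(float)
            g0 = (sub == 0.0).astype(float)
            self._per_sample.append((s, g1, g0, self.weights[s]))
        self._cell_order = np.concatenate(
            [self.sample_rows[s] for s, *_ in self._per_sample]
        ) if self._per_sample else np.empty(0, dtype=int)

    def cell_clone_logliks(self, B: np.ndarray) -> np.ndarray:
        """Unweighted cells x clones log-likelihood table (matrix row order)."""
        out = np.zeros((self.n, B.shape[0]))
        Bt = B.T.astype(float)  # mutations x clones
        for s, g1, g0, _w in self._per_sample:
            a = self.noise.alpha[s]
            b = self.noise.beta[s]
            w1 = Bt * math.log1p(-b) + (1.0 - Bt) * math.log(a)
            w0 = Bt * math.log(b) + (1.0 - Bt) * math.log1p(-a)
            out[self.sample_rows[s]] = g1 @ w1 + g0 @ w0
        return out

    def _collapse(self, per_cell: np.ndarray) -> float:
        total = 0.0
        for s, _g1, _g0, w in self._per_sample:
            total += w * per_cell[self.sample_rows[s]].sum()
        return float(total)

    def map_loglik(self, B: np.ndarray) -> float:
        """Weighted log-likelihood with each cell at its best clone."""
        L = self.cell_clone_logliks(B)
        return self._collapse(L.max(axis=1))

    def marginal_loglik(self, B: np.ndarray) -> float:
        """Weighted log-likelihood with attachments marginalized.

        Uniform attachment prior 1/m over clones; log-sum-exp in
        log-space for stability.
        """
        L = self.cell_clone_logliks(B)
        per_cell = logsumexp(L, axis=1) - math.log(B.shape[0])
        return self._collapse(per_cell)

    def loglik(self, B: np.ndarray, marginalize: bool) -> float:
        return self.marginal_loglik(B) if marginalize else self.map_loglik(B)


def enumerate_rooted_trees(mutations: tuple[str, ...] | list[str]):
    """Yield every rooted labeled tree on the given mutations.

    There are m^(m-1) of them; practical only for m <= 6 or so, where
    it supports exhaustive likelihood maximization as a ground truth
    for the stochastic search.
    """
    import itertools

    muts = tuple(mutations)
    m = len(muts)
    if m == 1:
        yield MutationTree(muts, (ROOT,))
        return
    for root in range(m):
        others = [i for i in range(m) if i != root]
        for parents in itertools.product(range(m), repeat=m - 1):
            assign = [ROOT] * m
            for node, p in zip(others, parents):
                assign[node] = p
            try:
                yield MutationTree(muts, tuple(assign))
            except TreeError:
                continue


def ancestor_descendant_accuracy(true_tree: MutationTree,
                                 inferred_tree: MutationTree) -> float:
    """Fraction of ordered mutation pairs whose ancestor relation agrees.

    Pairs are matched by mutation label, so the trees may order their
    mutation lists differently.
    """
    order = [inferred_tree.mutations.index(mu) for mu in true_tree.mutations]
    A_true = true_tree.ancestor_matrix()
    A_inf = inferred_tree.ancestor_matrix()[np.ix_(order, order)]
    m = true_tree.m
    if m < 2:
        return 1.0
    off = ~np.eye(m, dtype=bool)
    return float((A_true == A_inf)[off].mean())


def _clone_tie_order(tree: MutationTree) -> np.ndarray:
    """Clone preference order: fewer mutations first, then mutation id."""
    B = tree.phylogenetic_matrix()
    sizes = B.sum(axis=1)
    order = sorted(range(tree.m), key=lambda c: (sizes[c], tree.mutations[c]))
    return np.array(order)


def map_attachments(
    matrix: MutationMatrix, tree: MutationTree, noise: NoiseModel
) -> np.ndarray:
    """One-hot MAP attachment matrix C.

    Each cell attaches to the clone maximizing its log-likelihood; ties
    go to the clone with the smaller mutation count, then the
    lexicographically smaller mutation id.
    """
    engine = LikelihoodEngine(matrix, noise)
    L = engine.cell_clone_logliks(tree.phylogenetic_matrix())
    order = _clone_tie_order(tree)
    ordered = L[:, order]
    # argmax returns the first maximal entry, i.e. the preferred clone
    best = order[ordered.argmax(axis=1)]
    C = np.zeros((matrix.n_cells, tree.m), dtype=int)
    C[np.arange(matrix.n_cells), best] = 1
    return C


def weighted_log_likelihood(
    matrix: MutationMatrix,
    tree: MutationTree,
    attachments: np.ndarray,
    noise: NoiseModel,
) -> float:
    """Weighted log-likelihood at a fixed attachment matrix."""
    att = np.asarray(attachments)
    idx = att.argmax(axis=1) if att.ndim == 2 else att.astype(int)
    if att.ndim == 2 and not (att.sum(axis=1) == 1).all():
        raise ValueError("attachment matrix rows must be one-hot")
    engine = LikelihoodEngine(matrix, noise)
    L = engine.cell_clone_logliks(tree.phylogenetic_matrix())
    return engine._collapse(L[np.arange(matrix.n_cells), idx])


def marginal_log_likelihood(
    matrix: MutationMatrix, tree: MutationTree, noise: NoiseModel
) -> float:
    """Weighted log-likelihood with cell attachments marginalized out."""
    return LikelihoodEngine(matrix, noise).marginal_loglik(
        tree.phylogenetic_matrix()
    )
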