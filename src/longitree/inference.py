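"""MCMC maximization of the weighted likelihood over mutation trees.

The search runs independent restart chains for every combination of
candidate per-sample error rates, proposing prune-and-reattach and
label-swap moves on the mutation tree and accepting with probability
min(1, exp(dlogL / learning_rate)).  The learning rate acts as a
temperature: small values reduce the search to hill climbing, large
values to a random walk over tree space, which helps escape local
maxima at the cost of accuracy.  Chains stop early after a configurable
number of iterations without improving their best score; the overall
best tree, rates and attachments are returned, together with all trees
tied with the optimum when requested.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import MutationMatrix
from .model import (
    LikelihoodEngine,
    MutationTree,
    NoiseModel,
    ROOT,
    map_attachments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "InferenceResult",
    "collapse_indistinguishable",
    "initialize_tree",
    "propose_move",
    "mcmc_search",
]

#: absolute log-likelihood tolerance for "equivalent" solutions
EQUIVALENCE_TOL = 1e-9


class InferenceConfigError(ValueError):
    """Raised for invalid inference parameters."""


GridLike = "float | list[float] | dict[str, list[float]]"


@dataclass
class InferenceConfig:
    """Parameters of the MCMC search.

    ``alpha_grid`` / ``beta_grid`` accept a single rate, a list of
    candidates applied to every sample, or a per-sample dict of lists;
    the search maximizes the likelihood for every rate combination and
    keeps the best.
    """

    learning_rate: float = 1.0
    alpha_grid: object = 0.01
    beta_grid: object = 0.05
    n_iterations: int = 10000
    n_restarts: int = 50
    early_stopping: int = 500
    n_processes: int = 1
    seed: int = 0
    random_init: bool = True
    marginalize: bool = False
    keep_equivalent: bool = False
    collapse_indistinguishable: bool = True
    estimate_rates: bool = False
    weights: dict[str, float] | None = None

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise InferenceConfigError("learning_rate must be > 0")
        if self.n_iterations <= 1:
            raise InferenceConfigError("n_iterations must be > 1")
        if self.n_restarts < 1:
            raise InferenceConfigError("n_restarts must be >= 1")
        if self.early_stopping <= 1:
            raise InferenceConfigError("early_stopping must be > 1")

    def rate_grid(self, which: str, samples: list[str]) -> dict[str, list[float]]:
        raw = self.alpha_grid if which == "alpha" else self.beta_grid
        if isinstance(raw, (int, float)):
            grid = {s: [float(raw)] for s in samples}
        elif isinstance(raw, dict):
            grid = {s: [float(x) for x in raw[s]] for s in samples}
        else:
            grid = {s: [float(x) for x in raw] for s in samples}
        for s, values in grid.items():
            if not values:
                raise InferenceConfigError(f"empty {which} grid for sample {s!r}")
            for v in values:
                if not (0.0 < v < 1.0):
                    raise InferenceConfigError(
                        f"{which} candidate {v} for sample {s!r} outside (0, 1)"
                    )
        return grid


@dataclass
class InferenceResult:
    """Best tree, rates and attachments found by the search."""

    best_tree: MutationTree
    best_attachments: np.ndarray
    best_rates: dict[str, tuple[float, float]]  # sample -> (alpha, beta)
    best_loglik: float
    equivalent_trees: list[MutationTree] = field(default_factory=list)
    collapsed_groups: dict[str, list[str]] = field(default_factory=dict)
    trace: list[list[tuple[int, float]]] = field(default_factory=list)
    matrix: MutationMatrix | None = None  # post-collapse matrix searched over

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(
            alpha={s: ab[0] for s, ab in self.best_rates.items()},
            beta={s: ab[1] for s, ab in self.best_rates.items()},
        )

    def expanded_mutation_count(self) -> int:
        """Mutation count with collapsed indistinguishable groups re-expanded."""
        if not self.collapsed_groups:
            return self.best_tree.m
        return sum(len(g) for g in self.collapsed_groups.values())


# ---------------------------------------------------------------------------
# preparation


def collapse_indistinguishable(
    matrix: MutationMatrix,
) -> tuple[MutationMatrix, dict[str, list[str]]]:
    """Merge mutations with identical observation columns.

    Columns must match exactly, NA pattern included — no likelihood can
    separate such events, so one representative (first in input order)
    stands for the group.  The returned mapping (representative ->
    group members, representative first) allows re-expansion in
    reports.
    """
    vals = matrix.values()
    groups: dict[bytes, list[int]] = {}
    for j in range(matrix.n_variants):
        col = vals[:, j]
        key = np.where(np.isnan(col), 2.0, col).tobytes()
        groups.setdefault(key, []).append(j)
    reps = sorted(idx[0] for idx in groups.values())
    mapping: dict[str, list[str]] = {}
    for idx in groups.values():
        rep = matrix.variants[idx[0]]
        mapping[rep] = [matrix.variants[j] for j in idx]
    keep = [matrix.variants[j] for j in reps]
    return matrix.subset_variants(keep), mapping


def _frequency_order(matrix: MutationMatrix) -> list[int]:
    """Mutation indices by decreasing observed frequency, ties by input order."""
    freq = matrix.observed_frequencies()
    return sorted(range(matrix.n_variants), key=lambda j: (-freq[j], j))


def initialize_tree(
    matrix: MutationMatrix,
    random_init: bool = True,
    rng: np.random.Generator | None = None,
) -> MutationTree:
    """Initial tree respecting the observed mutation-frequency order.

    The most frequently observed mutation is the root (ties broken by
    input order).  Random initialization draws each mutation's parent
    uniformly among mutations preceding it in the frequency order,
    which guarantees acyclicity; the deterministic variant builds the
    linear chain in frequency order.
    """
    if matrix.n_variants == 0:
        raise InferenceConfigError("cannot initialize a tree with no mutations")
    order = _frequency_order(matrix)
    parent = [ROOT] * matrix.n_variants
    if random_init:
        if rng is None:
            rng = np.random.default_rng()
        for k in range(1, len(order)):
            parent[order[k]] = order[int(rng.integers(k))]
    else:
        for k in range(1, len(order)):
            parent[order[k]] = order[k - 1]
    return MutationTree(tuple(matrix.variants), tuple(parent))


# ---------------------------------------------------------------------------
# moves


def _subtree(parent: tuple[int, ...], v: int) -> set[int]:
    kids: dict[int, list[int]] = {}
    for i, p in enumerate(parent):
        if p != ROOT:
            kids.setdefault(p, []).append(i)
    out = set()
    stack = [v]
    while stack:
        u = stack.pop()
        out.add(u)
        stack.extend(kids.get(u, ()))
    return out


def propose_move(tree: MutationTree, rng: np.random.Generator) -> MutationTree:
    """Propose a neighboring tree.

    With probability 0.6, prune a non-root node's subtree and reattach
    it under a uniformly chosen node outside the subtree; otherwise
    swap the tree positions of two mutations (relabeling).  Both moves
    always yield a valid rooted tree and both are reversible.  With a
    single mutation the move is a no-op.
    """
    m = tree.m
    if m < 2:
        return tree
    parent = list(tree.parent)
    if rng.random() < 0.6:
        root = tree.root
        candidates = [i for i in range(m) if i != root]
        v = candidates[int(rng.integers(len(candidates)))]
        sub = _subtree(tree.parent, v)
        targets = [i for i in range(m) if i not in sub]
        t = targets[int(rng.integers(len(targets)))]
        parent[v] = t
    else:
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        swap = {i: j, j: i}
        new_parent = [ROOT] * m
        for v in range(m):
            p = tree.parent[v]
            new_parent[swap.get(v, v)] = swap.get(p, p) if p != ROOT else ROOT
        parent = new_parent
    return MutationTree(tree.mutations, tuple(parent))


def _perturb_rates(
    noise: NoiseModel, samples: list[str], rng: np.random.Generator,
    sigma: float = 0.2,
) -> NoiseModel:
    """Logit-space Gaussian perturbation of one sample's alpha or beta."""
    s = samples[int(rng.integers(len(samples)))]
    which = "alpha" if rng.random() < 0.5 else "beta"
    rates = dict(noise.alpha) if which == "alpha" else dict(noise.beta)
    r = rates[s]
    logit = math.log(r / (1.0 - r)) + sigma * rng.standard_normal()
    rates[s] = 1.0 / (1.0 + math.exp(-logit))
    if which == "alpha":
        return NoiseModel(alpha=rates, beta=dict(noise.beta), weights=noise.weights)
    return NoiseModel(alpha=dict(noise.alpha), beta=rates, weights=noise.weights)


# ---------------------------------------------------------------------------
# search


def _run_chain(
    matrix: MutationMatrix,
    noise: NoiseModel,
    config: InferenceConfig,
    chain_seed: np.random.SeedSequence,
):
    """One restart chain; returns (best_tree, best_noise, best_loglik,
    improvement trace, equivalent trees seen)."""
    rng = np.random.default_rng(chain_seed)
    engine = LikelihoodEngine(matrix, noise)
    samples = matrix.metadata.sample_order
    tree = initialize_tree(matrix, config.random_init, rng)
    cur_noise = noise
    cur = engine.loglik(tree.phylogenetic_matrix(), config.marginalize)
    best_tree, best_noise, best = tree, cur_noise, cur
    trace = [(0, best)]
    equivalents: dict[tuple[int, ...], MutationTree] = {tree.parent: tree}
    since_improve = 0
    lr = config.learning_rate
    for it in range(1, config.n_iterations + 1):
        accepted = False
        if config.estimate_rates and it % 10 == 0:
            cand_noise = _perturb_rates(cur_noise, samples, rng)
            cand_engine = LikelihoodEngine(matrix, cand_noise)
            cand = cand_engine.loglik(tree.phylogenetic_matrix(), config.marginalize)
            delta = cand - cur
            if delta >= 0 or rng.random() < math.exp(delta / lr):
                cur_noise, engine, cur = cand_noise, cand_engine, cand
                accepted = True
        else:
            cand_tree = propose_move(tree, rng)
            cand = engine.loglik(cand_tree.phylogenetic_matrix(), config.marginalize)
            delta = cand - cur
            if delta >= 0 or rng.random() < math.exp(delta / lr):
                tree, cur = cand_tree, cand
                accepted = True
        if accepted and cur > best + EQUIVALENCE_TOL:
            best, best_tree, best_noise = cur, tree, cur_noise
            trace.append((it, best))
            equivalents = {tree.parent: tree}
            since_improve = 0
        else:
            if config.keep_equivalent and abs(cur - best) <= EQUIVALENCE_TOL:
                equivalents.setdefault(tree.parent, tree)
            since_improve += 1
        if since_improve >= config.early_stopping:
            break
    return best_tree, best_noise, best, trace, list(equivalents.values())


def mcmc_search(matrix: MutationMatrix, config: InferenceConfig) -> InferenceResult:
    """Maximize the weighted likelihood over trees (and optionally rates).

    Runs ``n_restarts`` chains of ``n_iterations`` for every per-sample
    (alpha, beta) rate combination and returns the overall best
    solution.  Fully reproducible given ``config.seed``: every chain
    derives its own seed deterministically, so results do not depend on
    ``n_processes``.
    """
    config.validate()
    if config.collapse_indistinguishable:
        matrix, groups = collapse_indistinguishable(matrix)
    else:
        groups = {}
    if matrix.n_variants == 0:
        raise InferenceConfigError("matrix has no mutations after collapsing")

    meta = matrix.metadata
    samples = meta.sample_order
    alpha_grid = config.rate_grid("alpha", samples)
    beta_grid = config.rate_grid("beta", samples)
    weights = config.weights or meta.default_weights()

    combos = []
    for alphas in itertools.product(*(alpha_grid[s] for s in samples)):
        for betas in itertools.product(*(beta_grid[s] for s in samples)):
            combos.append(NoiseModel(
                alpha=dict(zip(samples, alphas)),
                beta=dict(zip(samples, betas)),
                weights=weights,
            ))

    root_seed = np.random.SeedSequence(config.seed)
    chain_seeds = root_seed.spawn(len(combos) * config.n_restarts)

    jobs = []
    for ci, noise in enumerate(combos):
        for r in range(config.n_restarts):
            jobs.append((noise, chain_seeds[ci * config.n_restarts + r]))

    if config.n_processes > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=config.n_processes)(
            delayed(_run_chain)(matrix, noise, config, seed)
            for noise, seed in jobs
        )
    else:
        outcomes = [_run_chain(matrix, noise, config, seed) for noise, seed in jobs]

    best = None
    equivalents: dict[tuple[int, ...], MutationTree] = {}
    trace = []
    for tree, noise, loglik, chain_trace, chain_equiv in outcomes:
        trace.append(chain_trace)
        if best is None or loglik > best[2] + EQUIVALENCE_TOL:
            best = (tree, noise, loglik)
            equivalents = {t.parent: t for t in chain_equiv}
        elif config.keep_equivalent and abs(loglik - best[2]) <= EQUIVALENCE_TOL:
            for t in chain_equiv:
                equivalents.setdefault(t.parent, t)
    assert best is not None
    best_tree, best_noise, best_loglik = best

    attachments = map_attachments(matrix, best_tree, best_noise)
    rates = {
        s: (best_noise.alpha[s], best_noise.beta[s]) for s in samples
    }
    equivalent_trees = (
        [t for t in equivalents.values() if t.parent != best_tree.parent]
        if config.keep_equivalent else []
    )
    return InferenceResult(
        best_tree=best_tree,
        best_attachments=attachments,
        best_rates=rates,
        best_loglik=best_loglik,
        equivalent_trees=equivalent_trees,
        collapsed_groups=groups,
        trace=trace,
        matrix=matrix,
    )
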