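"""Clonal tree construction and its longitudinal (time-tagged) augmentation.

From the phylogenetic matrix B a clonal tree is rebuilt: the root is
the unique clone carrying a single mutation, and each clone's parent is
the smaller-mutation-set clone at minimal L1 distance — under the
infinite sites assumption parent sets are subsets of child sets, so the
rule recovers the generating topology exactly on valid B.

The longitudinal clonal tree duplicates each clone at every sampling
time from its first observation to the end of the experiment, joining
consecutive copies with persistence edges.  Because a child clone can
be sampled before its parent (sampling noise, low prevalence), a
time-reversal correction inserts zero-prevalence parent copies at the
earlier time so that no parental edge ever points backwards in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellMetadata, MutationMatrix
from .model import MutationTree, TreeError, validate_phylogenetic_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClonalTree",
    "LongitudinalNode",
    "LongitudinalEdge",
    "LongitudinalClonalTree",
    "build_clonal_tree",
    "compute_prevalences",
    "build_longitudinal_tree",
    "make_summary_table",
    "make_fishplot_table",
]


@dataclass
class ClonalTree:
    """Rooted tree over clones; clone i is identified by the mutation it
    introduces and carries the mutation set of row i of B."""

    clones: list[str]                    # clone ids (distinguishing mutation)
    mutation_sets: dict[str, tuple[str, ...]]
    parent: dict[str, str | None]        # clone -> parent clone (None = root)

    @property
    def root(self) -> str:
        for c, p in self.parent.items():
            if p is None:
                return c
        raise TreeError("clonal tree has no root")

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.clones}
        for c, p in self.parent.items():
            if p is not None:
                out[p].append(c)
        return out

    def topological_order(self) -> list[str]:
        order = [self.root]
        kids = self.children()
        stack = list(reversed(kids[self.root]))
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(kids[v]))
        return order


@dataclass(frozen=True)
class LongitudinalNode:
    clone: str
    time_tag: int
    prevalence: float
    mutations: tuple[str, ...]

    @property
    def node_id(self) -> str:
        return f"{self.clone}@{self.time_tag}"


@dataclass(frozen=True)
class LongitudinalEdge:
    parent: tuple[str, int]  # (clone, time_tag)
    child: tuple[str, int]
    kind: str                # "parental" | "persistence"

    @property
    def parent_id(self) -> str:
        return f"{self.parent[0]}@{self.parent[1]}"

    @property
    def child_id(self) -> str:
        return f"{self.child[0]}@{self.child[1]}"


@dataclass
class LongitudinalClonalTree:
    nodes: list[LongitudinalNode]
    edges: list[LongitudinalEdge]
    first_time: dict[str, int] = field(default_factory=dict)

    def node(self, clone: str, time_tag: int) -> LongitudinalNode:
        for n in self.nodes:
            if n.clone == clone and n.time_tag == time_tag:
                return n
        raise KeyError((clone, time_tag))

    def parental_edges(self) -> list[LongitudinalEdge]:
        return [e for e in self.edges if e.kind == "parental"]

    def persistence_edges(self) -> list[LongitudinalEdge]:
        return [e for e in self.edges if e.kind == "persistence"]


# ---------------------------------------------------------------------------


def build_clonal_tree(
    B: np.ndarray, mutations: list[str] | tuple[str, ...]
) -> ClonalTree:
    """Rebuild the clonal tree from a clones x mutations matrix B.

    The root is the unique row of L1 norm 1.  Each other clone's parent
    is the argmin over smaller-norm rows of the L1 distance; ties are
    broken toward the larger parent mutation set, then the
    lexicographically smaller clone id.
    """
    B = np.asarray(B, dtype=bool)
    validate_phylogenetic_matrix(B)
    m = B.shape[0]
    norms = B.sum(axis=1)
    # clone id: the clone's own label under the one-clone-per-mutation
    # convention (its distinguishing mutation)
    clone_ids = [mutations[i] for i in range(m)]
    parent: dict[str, str | None] = {}
    mutation_sets = {
        clone_ids[i]: tuple(mutations[j] for j in np.flatnonzero(B[i]))
        for i in range(m)
    }
    root_idx = int(np.flatnonzero(norms == 1)[0])
    for i in range(m):
        if i == root_idx:
            parent[clone_ids[i]] = None
            continue
        candidates = [k for k in range(m) if norms[k] < norms[i]]
        if not candidates:
            raise TreeError(f"clone {clone_ids[i]} has no candidate parent")
        dists = [(int(np.abs(B[i].astype(int) - B[k].astype(int)).sum()),
                  -int(norms[k]), clone_ids[k], k) for k in candidates]
        dists.sort()
        parent[clone_ids[i]] = clone_ids[dists[0][3]]
    return ClonalTree(clones=clone_ids, mutation_sets=mutation_sets, parent=parent)


def clonal_tree_from_mutation_tree(tree: MutationTree) -> ClonalTree:
    """Shortcut: the clonal tree implied directly by a mutation tree."""
    return build_clonal_tree(tree.phylogenetic_matrix(), list(tree.mutations))


def compute_prevalences(
    attachments: np.ndarray,
    metadata: CellMetadata,
    clones: list[str],
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Clone x sample table of cell fractions (columns sum to 1)."""
    att = np.asarray(attachments)
    idx = att.argmax(axis=1) if att.ndim == 2 else att.astype(int)
    cells = metadata.cells if cells is None else cells
    if len(cells) != len(idx):
        raise ValueError("attachment rows do not match cells")
    out = pd.DataFrame(
        0.0, index=pd.Index(clones, name="clone"), columns=metadata.sample_order
    )
    counts = metadata.counts()
    for cell, c in zip(cells, idx):
        s = metadata.sample_of[cell]
        out.loc[clones[c], s] += 1.0
    for s in metadata.sample_order:
        if counts[s]:
            out[s] /= counts[s]
    return out


def build_longitudinal_tree(
    tree: ClonalTree,
    prevalences: pd.DataFrame,
    metadata: CellMetadata,
) -> LongitudinalClonalTree:
    """Augment the clonal tree with time tags and correct time reversals.

    Each clone gets a node copy at every time from its first observation
    to the final time, joined by persistence edges.  Corrections
    propagate leaf-to-root so a grandparent observed after a grandchild
    is pulled back in a single pass; inserted correction nodes have
    prevalence 0.  Clones never observed and without observed
    descendants are dropped with a warning.
    """
    S = metadata.n_samples
    INF = S + 1
    first: dict[str, int] = {}
    for c in tree.clones:
        observed = [
            t + 1 for t, s in enumerate(metadata.sample_order)
            if prevalences.loc[c, s] > 0.0
        ]
        first[c] = observed[0] if observed else INF

    # leaf-to-root propagation of earliest observation
    for c in reversed(tree.topological_order()):
        p = tree.parent[c]
        if p is not None and first[c] < first[p]:
            first[p] = first[c]

    dropped = [c for c in tree.clones if first[c] >= INF]
    if dropped:
        logger.warning(
            "clones never observed and without observed descendants "
            "dropped from the longitudinal tree: %s", dropped,
        )
    kept = [c for c in tree.clones if first[c] < INF]

    nodes = []
    for c in kept:
        for t in range(first[c], S + 1):
            prev = float(prevalences.loc[c, metadata.sample_order[t - 1]])
            nodes.append(LongitudinalNode(
                clone=c, time_tag=t, prevalence=prev,
                mutations=tree.mutation_sets[c],
            ))

    edges = []
    for c in kept:
        for t in range(first[c], S):
            edges.append(LongitudinalEdge((c, t), (c, t + 1), "persistence"))
    for c in kept:
        p = tree.parent[c]
        if p is None:
            continue
        t = first[c]
        edges.append(LongitudinalEdge((p, t), (c, t), "parental"))

    return LongitudinalClonalTree(
        nodes=nodes, edges=edges, first_time={c: first[c] for c in kept}
    )


def make_fishplot_table(
    tree: ClonalTree, prevalences: pd.DataFrame, metadata: CellMetadata
) -> pd.DataFrame:
    """TimeScape-compatible long table: timepoint, clone_id, parent, clonal_prev."""
    rows = []
    for t, s in enumerate(metadata.sample_order, start=1):
        for c in tree.clones:
            rows.append({
                "timepoint": t,
                "clone_id": c,
                "parent": tree.parent[c] if tree.parent[c] is not None else "ROOT",
                "clonal_prev": float(prevalences.loc[c, s]),
            })
    return pd.DataFrame(rows)


def make_summary_table(
    result,
    matrix: MutationMatrix,
    metadata: CellMetadata,
) -> pd.DataFrame:
    """Per-time-point summary: optimal rates, mutation and cell counts.

    ``n_mutations`` is the post-filter, post-collapse count searched by
    inference; ``n_mutations_expanded`` re-expands collapsed
    indistinguishable groups.
    """
    counts = metadata.counts()
    n_collapsed = result.best_tree.m
    n_expanded = result.expanded_mutation_count()
    rows = []
    for t, s in enumerate(metadata.sample_order, start=1):
        alpha, beta = result.best_rates[s]
        rows.append({
            "sample": s,
            "time": t,
            "alpha": alpha,
            "beta": beta,
            "n_mutations": n_collapsed,
            "n_mutations_expanded": n_expanded,
            "n_cells": counts[s],
        })
    return pd.DataFrame(rows)
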