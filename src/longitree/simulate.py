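"""Synthetic longitudinal single-cell experiments with known ground truth.

The generator draws a uniform random rooted mutation tree, per-sample
clone prevalences from a symmetric Dirichlet, i.i.d. cell attachments,
and corrupts the noiseless genotypes with per-sample false positive /
false negative flips plus missing (NA) entries.  Read depths are
generated so the downstream filters reproduce the intended matrix: NA
entries are realized as genuinely low-coverage sites (below the depth
threshold), not as a flag, and observed entries carry enough ALT
support to survive binarization.  Fixture emission writes per-cell
VCFv4.2 files, metadata/annotation/depth tables and a JSON sidecar with
the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EXONIC_FUNCTIONS
from .matrix import CellMetadata, MutationMatrix
from .model import MutationTree, ROOT
from .preprocess import FilterConfig

__all__ = [
    "SimulationConfig",
    "Simulation",
    "simulate_tree",
    "simulate_experiment",
    "emit_fixture_files",
    "load_truth_sidecar",
]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic longitudinal experiment.

    Defaults describe a small longitudinal design: three time points of
    50 cells each, moderate dropout (beta) and low false positive rate,
    10% missing entries, and a mean mapped read depth of 20x typical of
    targeted single-cell sequencing.
    """

    m: int = 8                      # mutations
    S: int = 3                      # samples (time points)
    n_per_sample: tuple[int, ...] = (50, 50, 50)
    alpha: tuple[float, ...] | float = 0.05   # per-sample false positive rate
    beta: tuple[float, ...] | float = 0.15    # per-sample false negative rate
    na_rate: float = 0.1
    prevalence_concentration: float = 1.0     # symmetric Dirichlet parameter
    mean_depth: float = 20.0                  # mean mapped read depth C
    min_depth: int = 3              # depth threshold NA entries fall below
    min_alt_reads: int = 2          # ALT support observed 1-entries exceed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.S < 1:
            raise ValueError("m and S must be >= 1")
        if len(self.n_per_sample) != self.S:
            raise ValueError("n_per_sample length must equal S")
        if any(n < 1 for n in self.n_per_sample):
            raise ValueError("every sample needs at least one cell")
        if not (0.0 <= self.na_rate < 1.0):
            raise ValueError("na_rate must be in [0, 1)")

    def rate(self, which: str, s: int) -> float:
        raw = self.alpha if which == "alpha" else self.beta
        return float(raw[s]) if isinstance(raw, (tuple, list)) else float(raw)

    @property
    def sample_names(self) -> list[str]:
        return [f"T{t}" for t in range(1, self.S + 1)]


@dataclass
class Simulation:
    """A generated experiment: truth plus observable tables."""

    config: SimulationConfig
    tree: MutationTree
    attachments: np.ndarray          # clone index per cell
    prevalences: np.ndarray          # S x m
    D: np.ndarray                    # noiseless genotypes, cells x m
    G: MutationMatrix                # observed matrix (0/1/NA)
    total_depth: np.ndarray
    alt_depth: np.ndarray
    annotation: pd.DataFrame
    metadata: CellMetadata
    variant_info: pd.DataFrame = field(repr=False, default=None)

    def recorded_filter_config(self) -> FilterConfig:
        """Thresholds under which ingestion + filtering reproduces G.

        Binarization and depth thresholds are the generating ones; the
        relevance filters (MAF, exonic class, cell frequency, missing
        fraction, medians) are set at their permissive ends because the
        generator plants no casualties for them.
        """
        max_n = max(self.config.n_per_sample)
        return FilterConfig(
            min_alt_reads=self.config.min_alt_reads,
            max_maf=0.49,
            min_cell_freq=min(0.01, 1.0 / (2 * max_n)),
            min_depth=self.config.min_depth,
            max_missing=1.0,
            min_median_depth=1,
            min_median_alt_depth=1,
        )


def simulate_tree(m: int, seed: int | np.random.Generator = 0) -> MutationTree:
    """Uniform random rooted labeled tree on m mutations.

    Decodes a uniform Prüfer sequence into an unrooted labeled tree
    (uniform over the m^(m-2) Cayley trees) and roots it at a uniform
    node; the (tree, root) pairs biject onto the m^(m-1) rooted labeled
    trees, so every rooted tree is equally likely.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = tuple(f"chr1:{100 + j}:A:T" for j in range(m))
    if m == 1:
        return MutationTree(labels, (ROOT,))
    # Prüfer decode
    edges: list[tuple[int, int]] = []
    if m == 2:
        edges = [(0, 1)]
    else:
        prufer = [int(rng.integers(m)) for _ in range(m - 2)]
        degree = [1] * m
        for x in prufer:
            degree[x] += 1
        import heapq

        leaves = [i for i in range(m) if degree[i] == 1]
        heapq.heapify(leaves)
        for x in prufer:
            leaf = heapq.heappop(leaves)
            edges.append((leaf, x))
            degree[x] -= 1
            if degree[x] == 1:
                heapq.heappush(leaves, x)
        u, v = heapq.heappop(leaves), heapq.heappop(leaves)
        edges.append((u, v))
    root = int(rng.integers(m))
    adj: dict[int, list[int]] = {i: [] for i in range(m)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    parent = [ROOT] * m
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                stack.append(v)
    return MutationTree(labels, tuple(parent))


def _draw_depths(
    G_vals: np.ndarray, rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Total/ALT depths consistent with the observed matrix.

    Observed 1-entries get total >= max(min_depth, min_alt_reads) and
    ALT >= min_alt_reads; observed 0-entries keep ALT below the
    binarization threshold; NA entries get total < min_depth.
    """
    n, m = G_vals.shape
    floor = max(cfg.min_depth, cfg.min_alt_reads)
    tot = rng.poisson(cfg.mean_depth, size=(n, m)).astype(int)
    tot = np.maximum(tot, cfg.min_depth)  # truncated: measured sites are covered
    alt = np.zeros_like(tot)

    ones = G_vals == 1.0
    zeros = G_vals == 0.0
    nas = np.isnan(G_vals)

    tot[ones] = np.maximum(tot[ones], floor)
    extra = rng.binomial(np.maximum(tot[ones] - cfg.min_alt_reads, 0), 0.75)
    alt[ones] = cfg.min_alt_reads + extra

    noise_alt = rng.binomial(tot[zeros], 0.02)
    alt[zeros] = np.minimum(noise_alt, cfg.min_alt_reads - 1)

    tot[nas] = rng.integers(0, cfg.min_depth, size=nas.sum()) if cfg.min_depth > 0 else 0
    alt[nas] = rng.binomial(tot[nas], 0.5)
    return tot, alt


def _draw_annotation(
    variants: tuple[str, ...], rng: np.random.Generator
) -> pd.DataFrame:
    """Synthetic gene symbols, exonic classes and MAFs (rare and common mix)."""
    rows = []
    for j, v in enumerate(variants):
        common = rng.random() < 0.2
        maf = float(rng.uniform(0.05, 0.4)) if common else float(rng.uniform(0, 0.005))
        if rng.random() < 0.1:
            maf_str = ""  # unrecorded in the population database
        else:
            maf_str = f"{maf:.6f}"
        rows.append({
            "variant_key": v,
            "gene": f"GENE{j + 1}",
            "exonic_function": EXONIC_FUNCTIONS[int(rng.integers(len(EXONIC_FUNCTIONS)))],
            "maf": maf_str,
        })
    return pd.DataFrame(rows)


def simulate_experiment(
    tree: MutationTree, config: SimulationConfig
) -> Simulation:
    """Generate one longitudinal experiment from a known mutation tree.

    Per sample: clone prevalences ~ symmetric Dirichlet, attachments
    i.i.d. by prevalence, genotypes D = C·B, observations G by flipping
    0->1 w.p. alpha_s and 1->0 w.p. beta_s, then NA i.i.d. at na_rate.
    Every variant column is conditioned to retain at least one observed
    non-NA 1 (an everywhere-unobserved variant could not enter any real
    call set); the adjustment touches at most one entry per variant.
    """
    rng = np.random.default_rng(config.seed)
    m = tree.m
    B = tree.phylogenetic_matrix()

    samples = config.sample_names
    cells: list[str] = []
    sample_of: dict[str, str] = {}
    clone_idx: list[int] = []
    prevalences = np.zeros((config.S, m))
    for s_i, s in enumerate(samples):
        prev = rng.dirichlet([config.prevalence_concentration] * m)
        prevalences[s_i] = prev
        n_s = config.n_per_sample[s_i]
        draws = rng.choice(m, size=n_s, p=prev)
        for k, c in enumerate(draws):
            cell = f"{s}_cell{k + 1}"
            cells.append(cell)
            sample_of[cell] = s
            clone_idx.append(int(c))

    metadata = CellMetadata(cells=cells, sample_of=sample_of, sample_order=samples)
    att = np.array(clone_idx)
    D = B[att].astype(float)

    G_vals = D.copy()
    for s_i, s in enumerate(samples):
        rows = [i for i, c in enumerate(cells) if sample_of[c] == s]
        a = config.rate("alpha", s_i)
        b = config.rate("beta", s_i)
        sub = G_vals[rows]
        flip0 = (sub == 0.0) & (rng.random(sub.shape) < a)
        flip1 = (sub == 1.0) & (rng.random(sub.shape) < b)
        sub[flip0] = 1.0
        sub[flip1] = 0.0
        G_vals[rows] = sub
    if config.na_rate > 0:
        G_vals[rng.random(G_vals.shape) < config.na_rate] = np.nan

    # condition: each variant observed (non-NA 1) in at least one cell
    for j in range(m):
        col = G_vals[:, j]
        if not np.any(col == 1.0):
            carriers = np.flatnonzero(D[:, j] == 1.0)
            pick = int(carriers[rng.integers(carriers.size)]) if carriers.size \
                else int(rng.integers(len(cells)))
            G_vals[pick, j] = 1.0

    tot, alt = _draw_depths(G_vals, rng, config)
    idx = pd.Index(cells, name="cell_id")
    cols = list(tree.mutations)
    G = MutationMatrix(
        data=pd.DataFrame(G_vals, index=idx, columns=cols),
        metadata=metadata,
        total_depth=pd.DataFrame(tot.astype(float), index=idx, columns=cols),
        alt_depth=pd.DataFrame(alt.astype(float), index=idx, columns=cols),
    )
    annotation = _draw_annotation(tree.mutations, rng)
    return Simulation(
        config=config,
        tree=tree,
        attachments=att,
        prevalences=prevalences,
        D=D,
        G=G,
        total_depth=tot,
        alt_depth=alt,
        annotation=annotation,
        metadata=metadata,
        variant_info=annotation,
    )


# ---------------------------------------------------------------------------
# fixture emission


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cell}
"""


def emit_fixture_files(sim: Simulation, out_dir: str | Path) -> dict[str, Path]:
    """Write the experiment as the standard input file set.

    Produces per-cell VCFs (records for sites with ALT-supporting
    reads), a metadata TSV, the annotation TSV, the per-cell depth TSV
    and a ``truth.json`` sidecar carrying the generating tree,
    attachments, rates and the thresholds under which ingestion
    reproduces the observed matrix exactly.
    """
    out = Path(out_dir)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)

    variants = list(sim.tree.mutations)
    parsed = [v.split(":") for v in variants]
    for i, cell in enumerate(sim.metadata.cells):
        lines = [_VCF_HEADER.format(cell=cell)]
        for j, (chrom, pos, ref, alt_allele) in enumerate(parsed):
            a = int(sim.alt_depth[i, j])
            t = int(sim.total_depth[i, j])
            if a < 1:
                continue  # no ALT evidence -> not a call
            gt = "0/1"
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt_allele}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{t - a},{a}:{t}\n"
            )
        (vcf_dir / f"{cell}.vcf").write_text("".join(lines))

    meta_path = out / "metadata.tsv"
    pd.DataFrame({
        "cell_id": sim.metadata.cells,
        "sample": [sim.metadata.sample_of[c] for c in sim.metadata.cells],
    }).to_csv(meta_path, sep="\t", index=False)

    ann_path = out / "annotation.tsv"
    sim.annotation.to_csv(ann_path, sep="\t", index=False)

    depth_path = out / "depths.tsv"
    rows = []
    for i, cell in enumerate(sim.metadata.cells):
        for j, v in enumerate(variants):
            rows.append({
                "cell_id": cell,
                "variant_key": v,
                "total_depth": int(sim.total_depth[i, j]),
                "alt_depth": int(sim.alt_depth[i, j]),
            })
    pd.DataFrame(rows).to_csv(depth_path, sep="\t", index=False)

    truth_path = out / "truth.json"
    truth = {
        "tree": {
            "mutations": list(sim.tree.mutations),
            "parent": list(sim.tree.parent),
        },
        "attachments": [int(c) for c in sim.attachments],
        "prevalences": sim.prevalences.tolist(),
        "alpha": [sim.config.rate("alpha", s) for s in range(sim.config.S)],
        "beta": [sim.config.rate("beta", s) for s in range(sim.config.S)],
        "sample_order": sim.metadata.sample_order,
        "filter_config": sim.recorded_filter_config().to_dict(),
        "simulation_config": asdict(sim.config),
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")

    return {
        "vcf_dir": vcf_dir,
        "metadata": meta_path,
        "annotation": ann_path,
        "depths": depth_path,
        "truth": truth_path,
    }


def planted_cascade_fixture():
    """Demo call set with one planted casualty per thresholded filter stage.

    Two samples of 120 cells each; seven variants of which, under the
    default thresholds, exactly one is removed at binarization (ALT
    support below 2 everywhere), one at the MAF stage (population MAF
    0.05), one at the cell-frequency stage (one carrier per sample,
    1/120 < 0.01), one at the missing-fraction stage (half the cells
    below the depth threshold), and two at the median-depth stage (one
    failing the locus median, one the ALT-support median).  Returns
    ``(calls, annotation, metadata, expected_counts)`` where
    ``expected_counts`` maps each cascade stage to the variant count
    surviving it.
    """
    from .io import CallTable, VariantAnnotation

    n_per = 120
    samples = ["T1", "T2"]
    cells = [f"{s}_c{i}" for s in samples for i in range(1, n_per + 1)]
    metadata = CellMetadata(
        cells=cells,
        sample_of={c: c.split("_")[0] for c in cells},
        sample_order=samples,
    )
    variants = {
        "chr1:101:A:T": "keep",
        "chr1:102:A:T": "binarize",
        "chr1:103:A:T": "maf",
        "chr1:104:A:T": "cell_frequency",
        "chr1:105:A:T": "missing_fraction",
        "chr1:106:A:T": "median_total",
        "chr1:107:A:T": "median_alt",
    }
    calls = CallTable()
    for v, fate in variants.items():
        for k, cell in enumerate(cells):
            within = k % n_per  # position within the cell's sample
            total, alt = 10, 0
            if fate == "keep":
                alt = 5 if within < 30 else 0
            elif fate == "binarize":
                alt = 1  # never reaches the 2-read threshold
            elif fate == "maf":
                alt = 5 if within < 30 else 0
            elif fate == "cell_frequency":
                alt = 5 if within == 0 else 0  # single carrier per sample
            elif fate == "missing_fraction":
                if within < 30:
                    alt = 5
                elif within >= 60:
                    total = 2  # below min_depth -> NA in half the cells
            elif fate == "median_total":
                total = 5  # locus median 5 < 8
                alt = 4 if within < 30 else 0
            elif fate == "median_alt":
                alt = 2 if within < 30 else 0  # support median 2 < 4
            calls.add(cell, v, total, alt)
    annotation = VariantAnnotation()
    for j, v in enumerate(variants):
        annotation.gene[v] = f"GENE{j + 1}"
        annotation.exonic_function[v] = "Nonsynonymous SNV"
        annotation.maf[v] = 0.05 if variants[v] == "maf" else 0.001
    expected_counts = {
        "binarize": 6,
        "maf": 5,
        "exonic_function": 5,
        "cell_frequency": 4,
        "depth_na": 4,
        "missing_fraction": 3,
        "median_depths": 1,
        "known_genes": 1,
    }
    return calls, annotation, metadata, expected_counts


def load_truth_sidecar(path: str | Path) -> dict:
    """Reload the truth sidecar; reconstructs the MutationTree object."""
    truth = json.loads(Path(path).read_text())
    truth["tree_object"] = MutationTree(
        tuple(truth["tree"]["mutations"]), tuple(truth["tree"]["parent"])
    )
    return truth
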