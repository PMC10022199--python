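"""Quality- and variant-filter cascade producing the binarized matrix.

The cascade turns raw per-cell calls into the time-indexed 0/1/NA
mutation matrix consumed by inference, applying in order: binarization
on alt-read support, population-MAF filtering, exonic-function
selection, per-sample cell-frequency filtering, low-depth NA setting,
missing-fraction filtering, median-depth filtering and an optional
known-gene subset.  A FilterReport records the variant count surviving
each stage.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CallTable, VariantAnnotation, EXONIC_FUNCTIONS, UNANNOTATED
from .matrix import CellMetadata, MutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "binarize_calls",
    "filter_by_maf",
    "filter_by_exonic_function",
    "filter_by_cell_frequency",
    "apply_depth_na",
    "filter_by_missing_fraction",
    "filter_by_median_depths",
    "subset_known_genes",
    "run_filter_cascade",
]


class FilterConfigError(ValueError):
    """Raised for filter parameters outside their validity range."""


class NoVariantsError(RuntimeError):
    """Raised when no variant survives the full cascade."""


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade with their validity ranges.

    Defaults assume a mean mapped read depth of a typical targeted /
    full-length RNA single-cell experiment; alt-read and depth
    thresholds should stay well below half the mean coverage to avoid
    biasing toward high copy-number or highly expressed loci.
    """

    min_alt_reads: int = 2          # reads supporting ALT for a 1 call
    max_maf: float = 0.01           # population MAF above which a site is deemed germline
    min_cell_freq: float = 0.01     # per-sample cell fraction supporting the site
    allowed_exonic_functions: tuple[str, ...] = tuple(EXONIC_FUNCTIONS) + (UNANNOTATED,)
    min_depth: int = 3              # below -> entry set to NA
    max_missing: float = 0.4        # max NA fraction per site
    min_median_depth: int = 8       # median total depth over all cells
    min_median_alt_depth: int = 4   # median ALT depth over mutated cells
    known_genes: tuple[str, ...] = ()
    strict_alt_threshold: bool = False   # use > instead of >= on min_alt_reads
    cell_freq_all_samples: bool = False  # require the frequency in every sample
    median_alt_over_all_cells: bool = False  # literal all-cells median variant

    def validate(self) -> None:
        if self.min_alt_reads < 1:
            raise FilterConfigError("min_alt_reads must be >= 1")
        if not (0.0 <= self.max_maf < 0.5):
            raise FilterConfigError("max_maf must be in [0, 0.5)")
        if not (0.0 < self.min_cell_freq <= 1.0):
            raise FilterConfigError("min_cell_freq must be in (0, 1]")
        if self.min_depth < 0:
            raise FilterConfigError("min_depth must be >= 0")
        if not (0.0 <= self.max_missing <= 1.0):
            raise FilterConfigError("max_missing must be in [0, 1]")
        if self.min_median_depth < 1 or self.min_median_alt_depth < 1:
            raise FilterConfigError("median depth thresholds must be >= 1")
        vocab = set(EXONIC_FUNCTIONS) | {UNANNOTATED}
        unknown = [c for c in self.allowed_exonic_functions if c not in vocab]
        if unknown:
            raise FilterConfigError(f"unknown exonic function classes: {unknown}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterReport:
    """Variant counts surviving each cascade stage, in order."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, stage: str, matrix: MutationMatrix) -> None:
        self.stages.append((stage, matrix.n_variants))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "variants_remaining"])

    def counts(self) -> dict[str, int]:
        return dict(self.stages)


# ---------------------------------------------------------------------------
# individual filters


def binarize_calls(
    calls: CallTable,
    metadata: CellMetadata,
    min_alt_reads: int = 2,
    strict: bool = False,
) -> MutationMatrix:
    """Binarize alt-read support into a cells x variants 0/1 matrix.

    An entry is 1 when the cell's alt-supporting reads reach
    ``min_alt_reads`` (>= by default; strict > behind the flag), else 0.
    Variants with no qualifying cell anywhere are dropped.  Read depths
    from the calls are carried along for the later depth-based filters.
    """
    if min_alt_reads < 1:
        raise FilterConfigError("min_alt_reads must be >= 1")
    variants = calls.variants()
    cells = metadata.cells
    data = np.zeros((len(cells), len(variants)))
    tot = np.zeros_like(data)
    alt = np.zeros_like(data)
    for j, v in enumerate(variants):
        for i, c in enumerate(cells):
            a = calls.get_alt(c, v)
            alt[i, j] = a
            tot[i, j] = calls.get_total(c, v)
            hit = a > min_alt_reads if strict else a >= min_alt_reads
            if hit:
                data[i, j] = 1.0
    keep = data.sum(axis=0) > 0
    idx = pd.Index(cells, name="cell_id")
    return MutationMatrix(
        data=pd.DataFrame(data[:, keep], index=idx, columns=np.array(variants)[keep]),
        metadata=metadata,
        total_depth=pd.DataFrame(tot[:, keep], index=idx, columns=np.array(variants)[keep]),
        alt_depth=pd.DataFrame(alt[:, keep], index=idx, columns=np.array(variants)[keep]),
    )


def filter_by_maf(
    matrix: MutationMatrix, annotation: VariantAnnotation, max_maf: float = 0.01
) -> MutationMatrix:
    """Keep variants rare in the reference population.

    A site survives when its population minor-allele frequency is at
    most ``max_maf`` or unrecorded — absence from population databases
    is itself evidence for somatic status.
    """
    keep = [
        v for v in matrix.variants
        if (annotation.maf_of(v) is None or annotation.maf_of(v) <= max_maf)
    ]
    return matrix.subset_variants(keep)


def filter_by_exonic_function(
    matrix: MutationMatrix,
    annotation: VariantAnnotation,
    allowed_classes: tuple[str, ...] | list[str],
) -> MutationMatrix:
    """Keep variants whose exonic functional class is selected."""
    vocab = set(EXONIC_FUNCTIONS) | {UNANNOTATED}
    unknown = [c for c in allowed_classes if c not in vocab]
    if unknown:
        raise FilterConfigError(f"unknown exonic function classes: {unknown}")
    allowed = set(allowed_classes)
    keep = [v for v in matrix.variants if annotation.class_of(v) in allowed]
    if not keep:
        logger.warning("exonic-function filter removed every variant")
    return matrix.subset_variants(keep)


def filter_by_cell_frequency(
    matrix: MutationMatrix,
    min_cell_freq: float = 0.01,
    all_samples: bool = False,
) -> MutationMatrix:
    """Drop variants supported by too small a cell fraction.

    For each sample s, ``f_s`` = fraction of s's cells with entry 1.
    Default keeps a variant when max_s f_s >= threshold (support in any
    one sample suffices); the all-samples mode requires it everywhere.
    """
    if not (0.0 < min_cell_freq <= 1.0):
        raise FilterConfigError("min_cell_freq must be in (0, 1]")
    vals = matrix.values()
    rows = matrix.sample_indices()
    freqs = []
    for s, idx in rows.items():
        if idx.size == 0:
            continue
        freqs.append((vals[idx] == 1.0).sum(axis=0) / idx.size)
    f = np.vstack(freqs)
    agg = f.min(axis=0) if all_samples else f.max(axis=0)
    keep = [v for v, ok in zip(matrix.variants, agg >= min_cell_freq) if ok]
    return matrix.subset_variants(keep)


def apply_depth_na(
    matrix: MutationMatrix,
    depths: CallTable | None = None,
    min_depth: int = 3,
) -> MutationMatrix:
    """Set entries with insufficient total read depth to NA.

    Depths come from the provided table or, when omitted, from the
    depths carried on the matrix since binarization; pairs absent from
    the table count as depth 0.
    """
    if min_depth < 0:
        raise FilterConfigError("min_depth must be >= 0")
    if min_depth == 0:
        return matrix.with_data(matrix.data.copy())
    if depths is not None:
        tot = np.array([
            [depths.get_total(c, v) for v in matrix.variants]
            for c in matrix.cells
        ], dtype=float)
    elif matrix.total_depth is not None:
        tot = matrix.total_depth.to_numpy(dtype=float)
    else:
        raise ValueError("no depth information available for the NA filter")
    data = matrix.data.copy()
    vals = data.to_numpy(dtype=float)
    vals[tot < min_depth] = np.nan
    out = pd.DataFrame(vals, index=data.index, columns=data.columns)
    return matrix.with_data(out)


def filter_by_missing_fraction(
    matrix: MutationMatrix, max_missing: float = 0.4
) -> MutationMatrix:
    """Drop variants whose NA fraction across cells exceeds the cap."""
    if not (0.0 <= max_missing <= 1.0):
        raise FilterConfigError("max_missing must be in [0, 1]")
    vals = matrix.values()
    frac = np.isnan(vals).sum(axis=0) / matrix.n_cells
    keep = [v for v, f in zip(matrix.variants, frac) if f <= max_missing]
    return matrix.subset_variants(keep)


def filter_by_median_depths(
    matrix: MutationMatrix,
    depths: CallTable | None = None,
    min_median_depth: int = 8,
    min_median_alt_depth: int = 4,
    alt_over_all_cells: bool = False,
) -> MutationMatrix:
    """Keep variants with sufficient median coverage and ALT support.

    The locus test takes the median total depth over all cells; the
    support test takes the median ALT depth over the cells carrying the
    mutation (entry == 1) — a variant with no mutated cell fails it.
    The literal all-cells ALT median is available behind a flag.
    """
    if min_median_depth < 1 or min_median_alt_depth < 1:
        raise FilterConfigError("median depth thresholds must be >= 1")
    if depths is not None:
        tot = np.array([
            [depths.get_total(c, v) for v in matrix.variants]
            for c in matrix.cells
        ], dtype=float)
        alt = np.array([
            [depths.get_alt(c, v) for v in matrix.variants]
            for c in matrix.cells
        ], dtype=float)
    elif matrix.total_depth is not None and matrix.alt_depth is not None:
        tot = matrix.total_depth.to_numpy(dtype=float)
        alt = matrix.alt_depth.to_numpy(dtype=float)
    else:
        raise ValueError("no depth information available for the median filters")
    vals = matrix.values()
    keep = []
    for j, v in enumerate(matrix.variants):
        if statistics.median(tot[:, j]) < min_median_depth:
            continue
        if alt_over_all_cells:
            support = alt[:, j]
        else:
            support = alt[vals[:, j] == 1.0, j]
        if support.size == 0:
            continue
        if statistics.median(support) < min_median_alt_depth:
            continue
        keep.append(v)
    return matrix.subset_variants(keep)


def subset_known_genes(
    matrix: MutationMatrix,
    annotation: VariantAnnotation,
    known_genes: tuple[str, ...] | list[str],
) -> MutationMatrix:
    """Restrict to variants hitting user-supplied genes (no-op if empty)."""
    if not known_genes:
        return matrix
    wanted = set(known_genes)
    present = {annotation.gene_of(v) for v in matrix.variants}
    absent = sorted(wanted - {g for g in present if g})
    if absent:
        logger.warning("known genes absent from the data: %s", absent)
    keep = [v for v in matrix.variants if annotation.gene_of(v) in wanted]
    return matrix.subset_variants(keep)


# ---------------------------------------------------------------------------
# cascade


def run_filter_cascade(
    calls: CallTable,
    annotation: VariantAnnotation,
    metadata: CellMetadata,
    config: FilterConfig | None = None,
    depths: CallTable | None = None,
) -> tuple[MutationMatrix, FilterReport]:
    """Apply the full filter cascade in its fixed order.

    ``depths`` supplies total/ALT read depths for the NA and median
    filters; when omitted the depths present in ``calls`` are used.
    Raises :class:`NoVariantsError` when nothing survives.
    """
    config = config or FilterConfig()
    config.validate()
    report = FilterReport()

    matrix = binarize_calls(
        calls, metadata, config.min_alt_reads, strict=config.strict_alt_threshold
    )
    report.record("binarize", matrix)
    matrix = filter_by_maf(matrix, annotation, config.max_maf)
    report.record("maf", matrix)
    matrix = filter_by_exonic_function(
        matrix, annotation, config.allowed_exonic_functions
    )
    report.record("exonic_function", matrix)
    matrix = filter_by_cell_frequency(
        matrix, config.min_cell_freq, all_samples=config.cell_freq_all_samples
    )
    report.record("cell_frequency", matrix)
    matrix = apply_depth_na(matrix, depths, config.min_depth)
    report.record("depth_na", matrix)
    matrix = filter_by_missing_fraction(matrix, config.max_missing)
    report.record("missing_fraction", matrix)
    matrix = filter_by_median_depths(
        matrix, depths, config.min_median_depth, config.min_median_alt_depth,
        alt_over_all_cells=config.median_alt_over_all_cells,
    )
    report.record("median_depths", matrix)
    matrix = subset_known_genes(matrix, annotation, config.known_genes)
    report.record("known_genes", matrix)

    if matrix.n_variants == 0:
        raise NoVariantsError("no variants survive the filter cascade")
    return matrix, report
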