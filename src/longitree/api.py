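"""High-level modelling interface.

:class:`LongitudinalCloneModel` holds a time-indexed mutation matrix
(built in memory, from a filtered TSV, or straight from the raw input
file set) and ``fit()`` runs the MCMC likelihood maximization.  The
returned :class:`CloneTreeResults` carries the best tree, rates and
attachments, and derives the longitudinal clonal tree, the prevalence
(fishplot) table and the per-time-point summary.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .inference import InferenceConfig, InferenceResult, mcmc_search
from .longitudinal import (
    build_clonal_tree,
    build_longitudinal_tree,
    compute_prevalences,
    make_fishplot_table,
    make_summary_table,
)
from .matrix import CellMetadata, MutationMatrix
from .preprocess import FilterConfig, FilterReport, run_filter_cascade

__all__ = ["LongitudinalCloneModel", "CloneTreeResults"]


class LongitudinalCloneModel:
    """Clonal-tree model for a longitudinal single-cell experiment.

    Parameters
    ----------
    matrix
        Observed mutation matrix G (cells x variants, entries 0/1/NA)
        with its chronological sample partition.
    annotation
        Optional variant annotation used to attach gene symbols to
        clones in the exported tree.

    Examples
    --------
    >>> model = LongitudinalCloneModel(matrix)
    >>> res = model.fit(alpha=[0.01, 0.05], beta=0.1, seed=7)
    >>> res.summary()
    """

    def __init__(self, matrix: MutationMatrix,
                 annotation: lio.VariantAnnotation | None = None,
                 filter_report: FilterReport | None = None):
        self.matrix = matrix
        self.annotation = annotation
        self.filter_report = filter_report

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_matrix_tsv(cls, path: str | Path, sample_order: list[str]):
        """Build from a pre-built 0/1/NA matrix TSV (cell_id + sample columns)."""
        return cls(lio.read_matrix_tsv(path, sample_order))

    @classmethod
    def from_files(
        cls,
        metadata_path: str | Path,
        vcf_dir: str | Path,
        annotation_path: str | Path,
        depth_path: str | Path,
        sample_order: list[str],
        cell_column: str = "cell_id",
        sample_column: str = "sample",
        filter_config: FilterConfig | None = None,
    ):
        """Build from the raw input file set, running the filter cascade."""
        metadata = lio.read_cell_metadata(
            metadata_path, cell_column, sample_column, sample_order
        )
        calls = lio.read_variant_calls(vcf_dir, metadata)
        annotation = lio.read_annotation_table(annotation_path)
        depths = lio.read_depth_table(depth_path)
        matrix, report = run_filter_cascade(
            calls, annotation, metadata, filter_config, depths=depths
        )
        return cls(matrix, annotation=annotation, filter_report=report)

    @property
    def metadata(self) -> CellMetadata:
        return self.matrix.metadata

    # -- fitting ---------------------------------------------------------

    def fit(self, config: InferenceConfig | None = None, **overrides
            ) -> "CloneTreeResults":
        """Run the MCMC search and wrap the result.

        Keyword overrides map onto :class:`InferenceConfig` fields, with
        ``alpha`` / ``beta`` accepted as aliases for the rate grids.
        """
        config = config or InferenceConfig()
        renames = {"alpha": "alpha_grid", "beta": "beta_grid"}
        fields = {renames.get(k, k): v for k, v in overrides.items()}
        if fields:
            config = replace(config, **fields)
        result = mcmc_search(self.matrix, config)
        return CloneTreeResults(self, result, config)


class CloneTreeResults:
    """Fitted longitudinal clonal tree with its derived views."""

    def __init__(self, model: LongitudinalCloneModel,
                 result: InferenceResult, config: InferenceConfig):
        self.model = model
        self.result = result
        self.config = config
        self.tree = result.best_tree
        self.attachments = result.best_attachments
        self.rates = result.best_rates
        self.loglik = result.best_loglik
        self._matrix = result.matrix if result.matrix is not None else model.matrix
        self.clonal_tree = build_clonal_tree(
            self.tree.phylogenetic_matrix(), list(self.tree.mutations)
        )
        self.prevalences = compute_prevalences(
            self.attachments, self._matrix.metadata, self.clonal_tree.clones,
            cells=self._matrix.cells,
        )
        self.longitudinal_tree = build_longitudinal_tree(
            self.clonal_tree, self.prevalences, self._matrix.metadata
        )

    def summary(self) -> pd.DataFrame:
        """Per-time-point table: optimal alpha/beta, mutation and cell counts."""
        return make_summary_table(self.result, self._matrix, self._matrix.metadata)

    def fishplot_table(self) -> pd.DataFrame:
        return make_fishplot_table(
            self.clonal_tree, self.prevalences, self._matrix.metadata
        )

    def genotypes(self) -> np.ndarray:
        """Fitted noiseless genotype matrix D = C·B."""
        from .model import genotypes_from

        return genotypes_from(self.tree, self.attachments)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the full output bundle (matrix, tree, fishplot, summary)."""
        return lio.write_outputs(
            out_dir,
            self._matrix,
            self.longitudinal_tree,
            self.fishplot_table(),
            self.summary(),
            annotation=self.model.annotation,
        )
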