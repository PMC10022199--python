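"""Core containers: cell metadata and the time-indexed mutation matrix.

The central object downstream of preprocessing is the observed mutation
matrix ``G``: cells x variants with entries 1 (mutation observed),
0 (not observed) or NA (insufficient read support, uninformative).
Cells are partitioned into chronologically ordered samples (time points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellMetadata", "MutationMatrix", "NA"]

#: sentinel used in the float-valued matrix for "not available"
NA = np.nan


class MetadataError(ValueError):
    """Raised for inconsistent cell metadata."""


@dataclass
class CellMetadata:
    """Cell-to-sample assignment plus the chronological order of samples.

    Parameters
    ----------
    cells
        Cell identifiers, unique, in input order.
    sample_of
        Mapping cell id -> sample name.
    sample_order
        Sample names in chronological order; position (1-based) is the
        time tag ``t_s``.
    """

    cells: list[str]
    sample_of: dict[str, str]
    sample_order: list[str]

    def __post_init__(self) -> None:
        if len(set(self.cells)) != len(self.cells):
            dupes = sorted({c for c in self.cells if self.cells.count(c) > 1})
            raise MetadataError(f"duplicate cell ids: {dupes}")
        if len(set(self.sample_order)) != len(self.sample_order):
            raise MetadataError("sample_order contains duplicates")
        if not self.sample_order:
            raise MetadataError("sample_order is empty")
        known = set(self.sample_order)
        for c in self.cells:
            s = self.sample_of.get(c)
            if s is None:
                raise MetadataError(f"cell {c!r} has no sample assignment")
            if s not in known:
                raise MetadataError(
                    f"sample {s!r} of cell {c!r} not in sample_order {self.sample_order}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_order)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def time_of(self, sample: str) -> int:
        """1-based chronological time tag of *sample*."""
        return self.sample_order.index(sample) + 1

    def cells_of(self, sample: str) -> list[str]:
        return [c for c in self.cells if self.sample_of[c] == sample]

    def counts(self) -> dict[str, int]:
        """Number of cells per sample, ``n_s``."""
        out = {s: 0 for s in self.sample_order}
        for c in self.cells:
            out[self.sample_of[c]] += 1
        return out

    def default_weights(self) -> dict[str, float]:
        """Per-sample likelihood weights ``w_s = (N/S) / n_s``.

        Normalized so every time point contributes equally to the
        weighted likelihood and ``sum_s w_s * n_s = N``.  Samples with
        zero cells get weight 0.
        """
        n = self.counts()
        target = self.n_cells / self.n_samples
        return {s: (target / n[s] if n[s] else 0.0) for s in self.sample_order}


@dataclass
class MutationMatrix:
    """Observed mutation matrix G with its sample partition.

    ``data`` is a cells x variants DataFrame with float entries
    0.0 / 1.0 / NaN (NaN encodes NA).
    """

    data: pd.DataFrame
    metadata: CellMetadata
    # optional per-(cell, variant) depth info carried along for filtering
    total_depth: pd.DataFrame | None = field(default=None, repr=False)
    alt_depth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.metadata.cells):
            raise MetadataError("matrix rows do not match metadata cells")
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise MetadataError("duplicate variant keys in matrix columns")
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise MetadataError("matrix entries must be 0, 1 or NA")

    # -- basic accessors -------------------------------------------------

    @property
    def cells(self) -> list[str]:
        return list(self.data.index)

    @property
    def variants(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_variants(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def sample_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each sample's cells, in matrix order."""
        samples = np.array([self.metadata.sample_of[c] for c in self.cells])
        return {
            s: np.flatnonzero(samples == s) for s in self.metadata.sample_order
        }

    def subset_variants(self, keep: list[str]) -> "MutationMatrix":
        """Return a copy restricted to *keep* (in current column order)."""
        keep_set = set(keep)
        cols = [v for v in self.variants if v in keep_set]
        return MutationMatrix(
            data=self.data[cols].copy(),
            metadata=self.metadata,
            total_depth=None if self.total_depth is None else self.total_depth[cols].copy(),
            alt_depth=None if self.alt_depth is None else self.alt_depth[cols].copy(),
        )

    def with_data(self, data: pd.DataFrame) -> "MutationMatrix":
        cols = list(data.columns)
        return MutationMatrix(
            data=data,
            metadata=self.metadata,
            total_depth=None if self.total_depth is None else self.total_depth[cols].copy(),
            alt_depth=None if self.alt_depth is None else self.alt_depth[cols].copy(),
        )

    def observed_frequencies(self) -> np.ndarray:
        """Fraction of cells observed mutated (entry == 1) per variant."""
        vals = self.values()
        return (vals == 1.0).sum(axis=0) / self.n_cells
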