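"""Filter cascade: per-stage behavior, cascade order, projection properties."""

import numpy as np
import pytest

from longitree.io import CallTable, VariantAnnotation, EXONIC_FUNCTIONS, UNANNOTATED
from longitree.preprocess import (
    FilterConfig,
    FilterConfigError,
    NoVariantsError,
    apply_depth_na,
    binarize_calls,
    filter_by_cell_frequency,
    filter_by_exonic_function,
    filter_by_maf,
    filter_by_median_depths,
    filter_by_missing_fraction,
    run_filter_cascade,
    subset_known_genes,
)
from longitree.simulate import planted_cascade_fixture

from conftest import make_matrix, make_metadata


def calls_from_alt(alt_by_variant: dict[str, list[int]], meta,
                   total: int = 10) -> CallTable:
    calls = CallTable()
    for v, alts in alt_by_variant.items():
        for cell, a in zip(meta.cells, alts):
            calls.add(cell, v, max(total, a), a)
    return calls


def annotation_for(variants, maf=None, func="Nonsynonymous SNV", gene="GENE1"):
    ann = VariantAnnotation()
    for v in variants:
        ann.gene[v] = gene
        ann.exonic_function[v] = func
        if maf is not None:
            ann.maf[v] = maf
    return ann


class TestBinarize:
    def test_threshold_is_inclusive(self):
        meta = make_metadata({"T1": 2})
        calls = calls_from_alt({"v1": [3, 1]}, meta)
        m = binarize_calls(calls, meta, min_alt_reads=2)
        assert m.values().tolist() == [[1.0], [0.0]]

    def test_threshold_one_keeps_any_support(self):
        meta = make_metadata({"T1": 3})
        calls = calls_from_alt({"v1": [1, 2, 0]}, meta)
        m = binarize_calls(calls, meta, min_alt_reads=1)
        assert m.values().tolist() == [[1.0], [1.0], [0.0]]

    def test_unsupported_column_dropped(self):
        meta = make_metadata({"T1": 5})
        calls = calls_from_alt(
            {"v1": [1, 1, 0, 1, 0], "v2": [5, 0, 0, 0, 0]}, meta)
        m = binarize_calls(calls, meta, min_alt_reads=2)
        assert m.variants == ["v2"]

    def test_strict_mode_uses_greater_than(self):
        meta = make_metadata({"T1": 2})
        calls = calls_from_alt({"v1": [2, 3]}, meta)
        m = binarize_calls(calls, meta, min_alt_reads=2, strict=True)
        assert m.values().tolist() == [[0.0], [1.0]]


class TestMafAndAnnotationFilters:
    def test_maf_keep_drop_missing(self):
        m = make_matrix([[1, 1, 1], [1, 1, 1]], {"T1": 2},
                        variants=["v1", "v2", "v3"])
        ann = VariantAnnotation()
        ann.maf = {"v1": 0.005, "v2": 0.02}  # v3 unrecorded
        out = filter_by_maf(m, ann, max_maf=0.01)
        assert out.variants == ["v1", "v3"]

    def test_exonic_selection_and_unknown_class(self):
        m = make_matrix([[1, 1], [1, 1]], {"T1": 2}, variants=["v1", "v2"])
        ann = VariantAnnotation()
        ann.exonic_function = {"v1": "Synonymous SNV", "v2": "Stopgain"}
        allowed = tuple(c for c in EXONIC_FUNCTIONS if c != "Synonymous SNV")
        assert filter_by_exonic_function(m, ann, allowed).variants == ["v2"]
        assert filter_by_exonic_function(
            m, ann, tuple(EXONIC_FUNCTIONS)).variants == ["v1", "v2"]
        with pytest.raises(FilterConfigError, match="nonsense"):
            filter_by_exonic_function(m, ann, ("nonsense",))

    def test_empty_allowed_set_empties_matrix(self):
        m = make_matrix([[1]], {"T1": 1}, variants=["v1"])
        ann = annotation_for(["v1"])
        assert filter_by_exonic_function(m, ann, ()).n_variants == 0

    def test_known_genes_subset_and_absent_warning(self, caplog):
        m = make_matrix([[1, 1]], {"T1": 1}, variants=["v1", "v2"])
        ann = VariantAnnotation()
        ann.gene = {"v1": "BRAF", "v2": "KRAS"}
        assert subset_known_genes(m, ann, ()).variants == ["v1", "v2"]
        assert subset_known_genes(m, ann, ("BRAF",)).variants == ["v1"]
        with caplog.at_level("WARNING"):
            out = subset_known_genes(m, ann, ("ABSENT",))
        assert out.n_variants == 0
        assert any("ABSENT" in r.message for r in caplog.records)


class TestCellFrequency:
    def test_single_carrier_in_fifty_cells_survives_at_default(self):
        vals = np.zeros((100, 1))
        vals[0, 0] = 1.0  # one carrier in T1
        vals[50, 0] = 1.0  # one carrier in T2
        m = make_matrix(vals, {"T1": 50, "T2": 50}, variants=["v1"])
        assert filter_by_cell_frequency(m, 0.01).variants == ["v1"]

    def test_absent_variant_removed(self):
        m = make_matrix([[0], [0]], {"T1": 2}, variants=["v1"])
        assert filter_by_cell_frequency(m, 0.01).n_variants == 0

    def test_threshold_one_requires_full_sample(self):
        m = make_matrix([[1, 1], [1, 0], [0, 1], [0, 1]],
                        {"T1": 2, "T2": 2}, variants=["v1", "v2"])
        # v1 mutated in all of T1; v2 in all of T2 but neither everywhere
        assert filter_by_cell_frequency(m, 1.0).variants == ["v1", "v2"]
        assert filter_by_cell_frequency(m, 1.0, all_samples=True).n_variants == 0


class TestDepthFilters:
    def _depths(self, meta, totals, alts=None, variant="v1"):
        t = CallTable()
        for cell, tot in zip(meta.cells, totals):
            a = 0 if alts is None else alts[meta.cells.index(cell)]
            t.add(cell, variant, tot, min(a, tot))
        return t

    def test_low_depth_becomes_na(self):
        m = make_matrix([[1], [0]], {"T1": 2}, variants=["v1"])
        depths = self._depths(m.metadata, [2, 10])
        out = apply_depth_na(m, depths, min_depth=3)
        assert np.isnan(out.values()[0, 0]) and out.values()[1, 0] == 0.0

    def test_min_depth_zero_is_identity(self):
        m = make_matrix([[1], [0]], {"T1": 2}, variants=["v1"])
        out = apply_depth_na(m, None, min_depth=0)
        assert (out.values() == m.values()).all()

    def test_all_zero_depths_all_na(self):
        m = make_matrix([[1], [0]], {"T1": 2}, variants=["v1"])
        out = apply_depth_na(m, CallTable(), min_depth=3)
        assert np.isnan(out.values()).all()

    def test_missing_fraction_boundary(self):
        m = make_matrix([[1], [np.nan], [np.nan], [0]], {"T1": 4},
                        variants=["v1"])
        assert filter_by_missing_fraction(m, 0.4).n_variants == 0  # 0.5 > 0.4
        assert filter_by_missing_fraction(m, 0.5).variants == ["v1"]  # ties pass
        assert filter_by_missing_fraction(m, 1.0).variants == ["v1"]

    def test_median_depth_rules(self):
        m = make_matrix([[1], [1], [1], [0], [0]], {"T1": 5}, variants=["v1"])
        depths = self._depths(m.metadata, [10, 8, 3, 20, 7], [4, 5, 6, 0, 0])
        # locus median 8 >= 8, support median 5 >= 4
        out = filter_by_median_depths(m, depths, 8, 4)
        assert out.variants == ["v1"]
        assert filter_by_median_depths(m, depths, 9, 4).n_variants == 0
        assert filter_by_median_depths(m, depths, 8, 6).n_variants == 0

    def test_variant_without_mutated_cells_fails_support_test(self):
        m = make_matrix([[np.nan], [0]], {"T1": 2}, variants=["v1"])
        depths = self._depths(m.metadata, [20, 20], [5, 5])
        assert filter_by_median_depths(m, depths, 1, 1).n_variants == 0


class TestCascade:
    def test_planted_fixture_counts(self):
        calls, ann, meta, expected = planted_cascade_fixture()
        matrix, report = run_filter_cascade(calls, ann, meta, FilterConfig())
        assert report.counts() == expected
        assert matrix.variants == ["chr1:101:A:T"]

    def test_counts_non_increasing(self):
        calls, ann, meta, _ = planted_cascade_fixture()
        _, report = run_filter_cascade(calls, ann, meta, FilterConfig())
        counts = [c for _s, c in report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_permissive_thresholds_keep_binarized_input(self):
        calls, ann, meta, _ = planted_cascade_fixture()
        cfg = FilterConfig(min_alt_reads=1, max_maf=0.49, min_cell_freq=1e-6,
                           min_depth=0, max_missing=1.0, min_median_depth=1,
                           min_median_alt_depth=1)
        matrix, report = run_filter_cascade(calls, ann, meta, cfg)
        assert report.counts()["binarize"] == matrix.n_variants == 7

    def test_empty_result_raises(self):
        meta = make_metadata({"T1": 2})
        calls = calls_from_alt({"v1": [5, 5]}, meta, total=2)  # all low depth
        ann = annotation_for(["v1"])
        with pytest.raises(NoVariantsError):
            run_filter_cascade(calls, ann, meta, FilterConfig(max_missing=0.1))

    def test_filters_are_projections(self):
        """Applying a removal filter twice equals applying it once."""
        calls, ann, meta, _ = planted_cascade_fixture()
        m = binarize_calls(calls, meta, 2)
        once = filter_by_maf(m, ann, 0.01)
        twice = filter_by_maf(once, ann, 0.01)
        assert once.variants == twice.variants
        f1 = filter_by_cell_frequency(m, 0.01)
        assert f1.variants == filter_by_cell_frequency(f1, 0.01).variants

    def test_set_semantics_filters_commute(self):
        calls, ann, meta, _ = planted_cascade_fixture()
        m = binarize_calls(calls, meta, 2)
        allowed = tuple(EXONIC_FUNCTIONS) + (UNANNOTATED,)
        a = filter_by_exonic_function(filter_by_maf(m, ann, 0.01), ann, allowed)
        b = filter_by_maf(filter_by_exonic_function(m, ann, allowed), ann, 0.01)
        assert a.variants == b.variants

    def test_config_range_validation(self):
        for bad in (
            {"min_alt_reads": 0},
            {"max_maf": 0.5},
            {"min_cell_freq": 0.0},
            {"max_missing": 1.5},
            {"min_median_depth": 0},
        ):
            with pytest.raises(FilterConfigError):
                FilterConfig(**bad).validate()
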