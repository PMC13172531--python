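"""Paired daughter-cell QC, ERCC normalization and asymmetry calls."""

import numpy as np
import pandas as pd
import pytest

from oe_asym.pair_expression import (
    PairTable,
    ercc_normalize,
    pair_asymmetry_call,
    qc_filter,
    summarize_pairs,
)
from oe_asym.synthetic import gen_pair_counts


@pytest.fixture
def small_table():
    cells = ["p0_a", "p0_b", "p1_a", "p1_b"]
    counts = pd.DataFrame(
        {
            "H3f3a": [30, 10, 12, 10],
            "H3f3b": [8, 9, 11, 10],
            "Trp63": [100, 90, 105, 95],
            "ERCC-00001": [600, 500, 550, 520],
            "ERCC-00002": [400, 500, 450, 480],
        },
        index=cells,
    ).T
    meta = pd.DataFrame(
        {
            "pair_id": ["p0", "p0", "p1", "p1"],
            "genes_detected": [13000, 12500, 12800, 13100],
            "mito_fraction": [0.02, 0.02, 0.03, 0.01],
        },
        index=cells,
    )
    return PairTable(counts=counts, cell_meta=meta)


class TestQCFilter:
    def _meta(self, genes, mito):
        cells = [f"p{i // 2}_{'ab'[i % 2]}" for i in range(len(genes))]
        counts = pd.DataFrame(
            {c: [10, 100] for c in cells}, index=["H3f3a", "ERCC-00001"])
        meta = pd.DataFrame(
            {
                "pair_id": [c.split("_")[0] for c in cells],
                "genes_detected": genes,
                "mito_fraction": mito,
            },
            index=cells,
        )
        return PairTable(counts=counts, cell_meta=meta)

    def test_gene_threshold_is_strict(self):
        """Exactly 10,000 detected genes does not pass 'more than 10,000'."""
        table = self._meta([10_000, 13_000, 12_000, 12_000], [0.02] * 4)
        out, report = qc_filter(table)
        assert "p0" in report.dropped_pairs
        assert out.n_pairs == 1

    def test_mito_threshold_eliminates_above_five_percent(self):
        table = self._meta([13_000] * 4, [0.051, 0.02, 0.05, 0.02])
        out, report = qc_filter(table)
        # 0.051 > 0.05 dropped; 0.05 is kept (not strictly greater)
        assert report.dropped_pairs == ["p0"]
        assert out.n_pairs == 1

    def test_all_cells_meeting_criteria_are_kept(self, rng):
        """A full plate of deeply sequenced cells passes unfiltered."""
        table = self._meta([13_000] * 96, [0.02] * 96)
        out, report = qc_filter(table)
        assert report.n_cells_kept == 96
        assert out.n_pairs == 48

    def test_pairs_never_split(self):
        table = self._meta([13_000, 9_000, 12_000, 12_000], [0.02] * 4)
        out, _ = qc_filter(table)
        sizes = out.cell_meta.groupby("pair_id").size()
        assert (sizes == 2).all()
        assert "p0_a" not in out.counts.columns  # partner of the failing cell

    def test_empty_result_flagged_not_raised(self):
        table = self._meta([9_000, 9_100], [0.02, 0.02])
        _, report = qc_filter(table)
        assert report.empty


class TestErccNormalize:
    def test_pure_depth_difference_removed(self, small_table):
        counts = small_table.counts.copy()
        counts.loc["ERCC-00001"] = [1000, 2000, 1000, 1000]
        counts.loc["ERCC-00002"] = 0
        counts.loc["H3f3a"] = [10, 20, 10, 10]
        table = PairTable(counts=counts, cell_meta=small_table.cell_meta)
        norm = ercc_normalize(table)
        assert norm.normalized.at["H3f3a", "p0_a"] == pytest.approx(
            norm.normalized.at["H3f3a", "p0_b"]
        )

    def test_identical_cells_get_unit_factors(self):
        cells = ["p0_a", "p0_b"]
        counts = pd.DataFrame({c: [50, 300] for c in cells},
                              index=["H3f3a", "ERCC-00001"])
        meta = pd.DataFrame(
            {"pair_id": ["p0", "p0"], "genes_detected": [13000] * 2,
             "mito_fraction": [0.02] * 2},
            index=cells,
        )
        norm = ercc_normalize(PairTable(counts=counts, cell_meta=meta))
        np.testing.assert_allclose(norm.size_factors, 1.0)

    def test_normalization_is_idempotent(self, small_table):
        once = ercc_normalize(small_table)
        renorm = ercc_normalize(
            PairTable(counts=once.normalized, cell_meta=small_table.cell_meta)
        )
        np.testing.assert_allclose(renorm.size_factors, 1.0, atol=1e-9)

    def test_normalized_ercc_totals_equal(self, small_table):
        norm = ercc_normalize(small_table)
        ercc = norm.normalized.loc[["ERCC-00001", "ERCC-00002"]].sum(axis=0)
        assert ercc.max() - ercc.min() <= 1e-9 * ercc.max()

    def test_recovers_generated_capture_efficiencies(self):
        table, truth = gen_pair_counts(n_pairs=24, seed=8)
        norm = ercc_normalize(table)
        cap = pd.Series(truth.params["capture_efficiency"])
        cap = cap / np.exp(np.log(cap).mean())  # same geometric anchor
        rel = (norm.size_factors / cap.loc[norm.size_factors.index] - 1).abs()
        assert rel.max() < 0.02


class TestPairAsymmetryCall:
    def test_clear_asymmetry_called(self, small_table):
        norm = ercc_normalize(small_table)
        calls = {c.pair_id: c for c in pair_asymmetry_call(
            norm.normalized, small_table.cell_meta)}
        assert calls["p0"].label == "asymmetric"  # H3f3a ~30 vs ~10
        assert calls["p1"].label == "symmetric"   # 1.2- and 1.1-fold only

    def test_symmetric_in_cell_order(self, small_table):
        norm = ercc_normalize(small_table)
        flipped_meta = small_table.cell_meta.iloc[::-1]
        a = pair_asymmetry_call(norm.normalized, small_table.cell_meta)
        b = pair_asymmetry_call(norm.normalized, flipped_meta)
        for ca, cb in zip(a, b):
            assert ca.label == cb.label
            assert ca.ratios == pytest.approx(cb.ratios)

    def test_double_zero_gene_excluded(self, small_table):
        counts = small_table.counts.copy()
        counts.loc["H3f3a", ["p1_a", "p1_b"]] = 0
        table = PairTable(counts=counts, cell_meta=small_table.cell_meta)
        norm = ercc_normalize(table)
        calls = {c.pair_id: c for c in pair_asymmetry_call(
            norm.normalized, table.cell_meta)}
        assert np.isnan(calls["p1"].ratios["H3f3a"])
        assert calls["p1"].n_genes_defined == 1

    def test_missing_gene_raises(self, small_table):
        norm = ercc_normalize(small_table)
        with pytest.raises(KeyError):
            pair_asymmetry_call(norm.normalized, small_table.cell_meta,
                                genes=["Nope1"])

    @pytest.mark.parametrize("asym_fraction", [0.0, 0.25, 0.5, 1.0])
    def test_called_fraction_tracks_truth(self, asym_fraction):
        """Across the asymmetric-fraction grid the called fraction matches
        the generating truth within its Wilson interval."""
        table, truth = gen_pair_counts(
            n_pairs=24, asym_fraction=asym_fraction, seed=31)
        filtered, _ = qc_filter(table)
        norm = ercc_normalize(filtered)
        calls = pair_asymmetry_call(norm.normalized, filtered.cell_meta)
        summary = summarize_pairs(calls)
        lo, hi = summary.ci95
        assert lo - 1e-12 <= asym_fraction <= hi + 1e-12


class TestSummarizePairs:
    def _calls(self, n_asym, n_sym):
        from oe_asym.pair_expression import PairCall

        mk = lambda i, lab: PairCall(pair_id=i, ratios={}, label=lab,
                                     rule="any", cutoff=1.5, n_genes_defined=2)
        return [mk(i, "asymmetric") for i in range(n_asym)] + [
            mk(100 + i, "symmetric") for i in range(n_sym)]

    def test_observed_study_fraction(self):
        summary = summarize_pairs(self._calls(15, 33))
        assert summary.fraction_asymmetric == pytest.approx(0.3125)
        assert summary.n_pairs == 48

    @pytest.mark.parametrize("k,n,frac", [(0, 10, 0.0), (10, 10, 1.0)])
    def test_degenerate_fractions(self, k, n, frac):
        summary = summarize_pairs(self._calls(k, n - k))
        assert summary.fraction_asymmetric == frac
        lo, hi = summary.ci95
        assert 0.0 <= lo <= frac <= hi <= 1.0

    def test_fractions_sum_to_one(self):
        s = summarize_pairs(self._calls(3, 5))
        assert s.fraction_asymmetric + s.fraction_symmetric == pytest.approx(1.0)


class TestPairTableValidation:
    def test_rejects_incomplete_pairs(self):
        counts = pd.DataFrame({"c1": [1, 2]}, index=["H3f3a", "ERCC-1"])
        meta = pd.DataFrame(
            {"pair_id": ["p0"], "genes_detected": [13000],
             "mito_fraction": [0.02]}, index=["c1"])
        with pytest.raises(ValueError, match="exactly 2"):
            PairTable(counts=counts, cell_meta=meta)

    def test_rejects_negative_counts(self):
        counts = pd.DataFrame({"c1": [-1, 2], "c2": [1, 2]},
                              index=["H3f3a", "ERCC-1"])
        meta = pd.DataFrame(
            {"pair_id": ["p0", "p0"], "genes_detected": [13000] * 2,
             "mito_fraction": [0.02] * 2}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="nonnegative"):
            PairTable(counts=counts, cell_meta=meta)
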