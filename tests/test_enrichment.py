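"""Signed log-space Fisher statistic, classification, clustering, KW test."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from popgrs.enrichment import (
    DEFAULT_THRESHOLD,
    EnrichmentMatrix,
    build_matrix,
    classify,
    cluster_populations,
    fisher_signed_log10p,
    kruskal_wallis_eaf,
)
from popgrs.errors import ConfigurationError, ValidationError
from popgrs.genotypes import AlleleFrequencyTable


def enumeration_oracle(k1, n1, k2, n2):
    """Two-sided Fisher P by exhaustive integer hypergeometric enumeration.

    Works entirely in exact integer arithmetic (one final division), so
    it is an independent ground truth for the log-space implementation.
    """
    K = k1 + k2
    lo, hi = max(0, K - n2), min(K, n1)
    weights = {x: comb(n1, x) * comb(n2, K - x) for x in range(lo, hi + 1)}
    obs = weights[k1]
    return sum(w for w in weights.values() if w <= obs) / comb(n1 + n2, K)


def freq_table(rows):
    return AlleleFrequencyTable.from_counts(rows)


class TestFisher:
    def test_equal_frequencies_give_p1_and_zero(self):
        res = fisher_signed_log10p(10, 100, 50, 500)
        assert res.p_two_sided == 1.0
        assert res.signed_log10p == 0.0

    def test_hand_table_against_oracle(self):
        res = fisher_signed_log10p(5, 10, 1, 10)
        assert res.p_two_sided == pytest.approx(enumeration_oracle(5, 10, 1, 10), abs=1e-12)
        assert res.signed_log10p > 0  # 0.5 > 0.1: enrichment

    def test_exhaustive_small_margins_match_oracle(self):
        for n1 in range(1, 11):
            for n2 in range(1, 11):
                for k1 in range(n1 + 1):
                    for k2 in range(n2 + 1):
                        p = fisher_signed_log10p(k1, n1, k2, n2).p_two_sided
                        assert abs(p - enumeration_oracle(k1, n1, k2, n2)) <= 1e-12

    def test_random_margins_to_30_match_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(600):
            n1, n2 = rng.integers(1, 31, size=2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            p = fisher_signed_log10p(k1, int(n1), k2, int(n2)).p_two_sided
            assert abs(p - enumeration_oracle(k1, int(n1), k2, int(n2))) <= 1e-12

    def test_agrees_with_scipy_on_large_counts(self):
        from scipy.stats import fisher_exact

        for k1, n1, k2, n2 in [(933, 3444, 1753, 5008), (50, 1000, 100, 1000)]:
            mine = fisher_signed_log10p(k1, n1, k2, n2).p_two_sided
            ref = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1]
            assert mine == pytest.approx(ref, rel=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(
        n1=st.integers(1, 25), n2=st.integers(1, 25),
        f1=st.floats(0, 1), f2=st.floats(0, 1),
    )
    def test_row_swap_symmetry(self, n1, n2, f1, f2):
        k1, k2 = round(f1 * n1), round(f2 * n2)
        a = fisher_signed_log10p(k1, n1, k2, n2)
        b = fisher_signed_log10p(k2, n2, k1, n1)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-12)
        assert a.signed_log10p == pytest.approx(-b.signed_log10p, abs=1e-12)

    def test_p_monotone_away_from_expectation(self):
        # with margins fixed, a more extreme table is never less surprising
        n1, n2, K = 20, 30, 25
        lo, hi = max(0, K - n2), min(K, n1)
        ps = [fisher_signed_log10p(k, n1, K - k, n2).p_two_sided for k in range(lo, hi + 1)]
        mode = int(np.argmax([-p for p in ps]))  # most extreme is smallest p
        expect = n1 * K / (n1 + n2)
        ks = list(range(lo, hi + 1))
        for i in range(1, len(ks)):
            if ks[i] <= expect and ks[i - 1] < ks[i]:
                assert ps[i - 1] <= ps[i] + 1e-12
            if ks[i - 1] >= expect:
                assert ps[i] <= ps[i - 1] + 1e-12

    def test_extreme_table_saturates_not_overflows(self):
        res = fisher_signed_log10p(100, 20000, 19000, 20000)
        assert res.saturated
        assert res.p_two_sided > 0
        assert np.isfinite(res.signed_log10p)
        assert res.signed_log10p < -300  # deeply depleted, beyond float P range

    def test_one_sided_modes_bound_two_sided(self):
        enr = fisher_signed_log10p(8, 10, 2, 10, alternative="enrichment")
        two = fisher_signed_log10p(8, 10, 2, 10)
        assert enr.p_two_sided <= two.p_two_sided

    @pytest.mark.parametrize("bad", [(-1, 10, 1, 10), (5, 10, 11, 10), (2.5, 10, 1, 10)])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValidationError):
            fisher_signed_log10p(*bad)


class TestClassify:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (1.302, "enriched"),
            (DEFAULT_THRESHOLD, "similar"),  # strict inequality at the cut
            (0.0, "similar"),
            (-1.301, "similar"),
            (-1.302, "depleted"),
        ],
    )
    def test_threshold_rule(self, value, expected):
        assert classify(value) == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValidationError):
            classify(1.0, threshold=0)


class TestBuildMatrix:
    def table(self):
        return freq_table(
            [
                ("rs1", "REF", 500, 1000), ("rs2", "REF", 100, 1000),
                ("rs1", "A", 90, 100), ("rs2", "A", 10, 100),
                ("rs1", "B", 50, 100), ("rs2", "B", 0, 0),  # undefined cell
            ]
        )

    def test_shape_and_reference_exclusion(self):
        m = build_matrix(self.table(), ["rs1", "rs2"], ["A", "B", "REF"], "REF")
        assert list(m.values.columns) == ["A", "B"]
        assert list(m.values.index) == ["rs1", "rs2"]
        assert m.classes.loc["rs1", "A"] == "enriched"

    def test_undefined_cell_propagates_as_missing(self):
        m = build_matrix(self.table(), ["rs1", "rs2"], ["A", "B"], "REF")
        assert np.isnan(m.values.loc["rs2", "B"])
        assert any(x["reason"] == "no calls" for x in m.missing)

    def test_classification_partition_sums_to_defined_cells(self):
        m = build_matrix(self.table(), ["rs1", "rs2"], ["A", "B"], "REF")
        counts = m.class_counts()
        total = sum(sum(c.values()) for c in counts.values())
        assert total == len(m.cells) == 3

    def test_missing_reference_is_config_error(self):
        with pytest.raises(ConfigurationError):
            build_matrix(self.table(), ["rs1"], ["A"], "NOPE")

    def test_exclude_focal_subtracts_from_pool(self):
        table = freq_table(
            [("rs1", "POOL", 60, 200), ("rs1", "A", 50, 100), ("rs1", "B", 10, 100)]
        )
        m = build_matrix(table, ["rs1"], ["A", "B"], "POOL", exclude_focal=True)
        direct = fisher_signed_log10p(50, 100, 10, 100).signed_log10p
        assert m.values.loc["rs1", "A"] == pytest.approx(direct)

    def test_single_cell_matrix(self):
        table = freq_table([("rs1", "REF", 10, 100), ("rs1", "A", 10, 100)])
        m = build_matrix(table, ["rs1"], ["A"], "REF")
        assert m.values.shape == (1, 1)
        assert m.classes.loc["rs1", "A"] == "similar"


class TestClustering:
    def matrix_from(self, cols: dict) -> EnrichmentMatrix:
        values = pd.DataFrame(cols)
        return EnrichmentMatrix(values=values, classes=values.copy(), cells=[],
                                reference="REF")

    def test_identical_columns_merge_first_at_zero(self):
        m = self.matrix_from({"X": [1.0, 2.0], "Y": [5.0, -3.0], "Z": [1.0, 2.0]})
        tree = cluster_populations(m, metric="euclidean")
        a, b, height = tree.merges[0][:3]
        assert {tree.labels[a], tree.labels[b]} == {"X", "Z"}
        assert height == 0.0

    def test_manual_average_linkage_merge_order(self):
        # leaves (lexicographic): A=(0,0), B=(1,0), C=(10,0)
        # d(A,B)=1 merges first; then d({A,B},C) = (10+9)/2 = 9.5
        m = self.matrix_from({"A": [0.0, 0.0], "B": [1.0, 0.0], "C": [10.0, 0.0]})
        tree = cluster_populations(m, metric="euclidean", method="average")
        assert tree.merges[0][2] == pytest.approx(1.0)
        assert tree.merges[1][2] == pytest.approx(9.5)
        assert tree.newick == "(C:9.500000,(A:1.000000,B:1.000000):8.500000);"

    def test_deterministic_across_column_permutations(self):
        cols = {"A": [1.0, -2.0, 0.5], "B": [0.9, -1.8, 0.4], "C": [-3.0, 2.0, 1.0]}
        t1 = cluster_populations(self.matrix_from(cols))
        t2 = cluster_populations(self.matrix_from(dict(reversed(cols.items()))))
        assert t1.newick == t2.newick

    def test_missing_cells_imputed_as_zero_and_counted(self):
        m = self.matrix_from({"A": [1.0, np.nan], "B": [1.0, 0.0], "C": [5.0, 2.0]})
        tree = cluster_populations(m, metric="euclidean")
        assert tree.n_imputed == 1
        a, b, _ = tree.merges[0][:3]
        assert {tree.labels[a], tree.labels[b]} == {"A", "B"}

    def test_two_columns_needed(self):
        m = self.matrix_from({"A": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            cluster_populations(m)


class TestKruskalWallis:
    def test_all_identical_values_convention(self):
        table = freq_table(
            [(f"rs{i}", g, 5, 10) for i in range(3) for g in ("A", "B")]
        )
        assert kruskal_wallis_eaf(table, ["A", "B"]) == (0.0, 1.0)

    def test_hand_ranked_three_groups(self):
        # groups occupy ranks 1-3, 4-6, 7-9: rank sums 6, 15, 24
        # H = 12/(9*10) * (6^2+15^2+24^2)/3 - 3*10 = 7.2
        rows = []
        for j, g in enumerate(["A", "B", "C"]):
            for i in range(3):
                k = 10 * (3 * j + i + 1)
                rows.append((f"rs{i}", g, k, 1000))
        table = freq_table(rows)
        h, p = kruskal_wallis_eaf(table, ["A", "B", "C"])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(float(chi2.sf(7.2, df=2)))

    def test_empty_group_is_config_error(self):
        table = freq_table([("rs1", "A", 5, 10)])
        with pytest.raises(ConfigurationError):
            kruskal_wallis_eaf(table, ["A", "B"])
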