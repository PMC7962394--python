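"""Composite genetic risk score, phase filter, prevalence correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popgrs.errors import DegenerateInputError, ValidationError
from popgrs.genotypes import AlleleFrequencyTable, SamplePanel
from popgrs.scores import (
    PopulationScoreSummary,
    PrevalenceRecord,
    composite_risk_score,
    correlate_prevalence,
    high_iop_prevalence,
    phase_concordance_filter,
    population_mean_score,
    score_samples,
)
from popgrs.simulate import PopulationSpec, SyntheticPanelSpec, generate_panel

from conftest import make_matrix


class TestCompositeScore:
    def test_two_copies_everywhere_scores_one(self):
        assert composite_risk_score([2] * 135).score == 1.0

    def test_no_copies_scores_zero(self):
        assert composite_risk_score([0] * 135).score == 0.0

    def test_hand_arithmetic(self):
        sc = composite_risk_score([0, 1, 2, 1])
        assert sc.score == pytest.approx(0.5)
        assert sc.n_snps_used == 4

    def test_missing_dropped_from_both_sides(self):
        sc = composite_risk_score([2, None, 2, np.nan])
        assert sc.score == 1.0
        assert sc.n_snps_used == 2

    def test_all_missing_rejected(self):
        with pytest.raises(DegenerateInputError):
            composite_risk_score([None, np.nan])

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValidationError):
            composite_risk_score([0, 3])

    def test_weighted_extension(self):
        sc = composite_risk_score([2, 0], weights=[1.0, 1.0])
        assert sc.score == pytest.approx(0.5)
        sc = composite_risk_score([2, 0], weights=[3.0, 1.0])
        assert sc.score == pytest.approx(0.75)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=30))
    def test_score_bounded_and_monotone_in_dosage(self, dosages):
        sc = composite_risk_score(dosages)
        assert 0.0 <= sc.score <= 1.0
        bumped = list(dosages)
        for i, d in enumerate(bumped):
            if d < 2:
                bumped[i] = d + 1
                break
        assert composite_risk_score(bumped).score >= sc.score

    def test_random_uniform_dosages_expect_half(self):
        rng = np.random.default_rng(99)
        scores = rng.integers(0, 3, size=(2000, 135)).mean(axis=1) / 2.0
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean() - 0.5) < 3 * se + 1e-12


class TestPopulationMeans:
    def test_group_mean_equals_mean_eaf_without_missingness(self, tiny_panel):
        # two SNPs at realized frequencies 2/8 and 6/8 over 4 samples
        gm = make_matrix([[2, 2], [0, 2], [0, 2], [0, 0]])
        summaries = population_mean_score(gm, tiny_panel, grouping="pooled")
        (summary,) = summaries
        eafs = np.nansum(gm.dosage, axis=0) / (2 * len(gm.samples))
        assert summary.mean_score == pytest.approx(eafs.mean(), abs=1e-12)

    def test_fixed_homozygous_group(self, tiny_panel):
        gm = make_matrix(np.full((4, 3), 2.0))
        (summary,) = population_mean_score(gm, tiny_panel, grouping="pooled")
        assert (summary.mean_score, summary.sd_score) == (1.0, 0.0)

    def test_snp_subset_restricts_score(self, tiny_panel):
        gm = make_matrix([[2, 0], [2, 0], [2, 0], [2, 0]])
        df = score_samples(gm, snp_set=["rs900000"])
        assert set(df["score"]) == {1.0}

    def test_simulated_group_mean_tracks_true_frequency(self):
        spec = SyntheticPanelSpec(
            n_snps=40,
            populations=[PopulationSpec("P1", "S1", 300, 0.05),
                         PopulationSpec("P2", "S1", 300, 0.05)],
            seed=42,
        )
        data = generate_panel(spec)
        summaries = {
            s.group: s for s in population_mean_score(
                data.genotypes, data.panel, grouping="population")
        }
        for label in ("P1", "P2"):
            truth = float(np.mean(data.p_pop[label]))
            s = summaries[label]
            se = s.sd_score / np.sqrt(s.n_samples)
            assert abs(s.mean_score - truth) < 3 * se


class TestPhaseFilter:
    def table(self, group, pairs):
        return AlleleFrequencyTable.from_counts(
            [(rsid, group, int(round(eaf * 1000)), 1000) for rsid, eaf in pairs]
        )

    def test_rule_application(self):
        a = self.table("full", [("rs1", 0.50), ("rs2", 0.50), ("rs3", 0.30)])
        b = self.table("phase2", [("rs1", 0.39), ("rs2", 0.40), ("rs3", 0.30)])
        retained, report = phase_concordance_filter(a, b, "full", "phase2")
        assert retained == ["rs2", "rs3"]  # 0.11 excluded, 0.10 boundary kept
        assert report.iloc[0]["rsid"] == "rs1"

    def test_missing_snp_excluded_with_reason(self):
        a = self.table("full", [("rs1", 0.5)])
        b = self.table("phase2", [("rs2", 0.5)])
        retained, report = phase_concordance_filter(
            a, b, "full", "phase2", candidates=["rs1", "rs2"]
        )
        assert retained == []
        assert set(report["reason"]) == {"missing"}

    def test_raising_cutoff_never_shrinks_retained_set(self):
        rng = np.random.default_rng(11)
        pairs_a = [(f"rs{i}", float(f)) for i, f in enumerate(rng.uniform(0, 1, 30))]
        pairs_b = [(f"rs{i}", float(f)) for i, f in enumerate(rng.uniform(0, 1, 30))]
        a, b = self.table("a", pairs_a), self.table("b", pairs_b)
        previous: set = set()
        for cutoff in (0.05, 0.10, 0.20, 0.50, 1.0):
            retained, _ = phase_concordance_filter(a, b, "a", "b", cutoff=cutoff)
            assert previous <= set(retained)
            previous = set(retained)


class TestPrevalence:
    def test_high_iop_decomposition(self):
        assert high_iop_prevalence(PrevalenceRecord("KOR", 0.040, 0.77)) == pytest.approx(0.0092)
        assert high_iop_prevalence(PrevalenceRecord("X", 0.5, 1.0)) == 0.0
        assert high_iop_prevalence(PrevalenceRecord("X", 0.03, 0.0)) == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            PrevalenceRecord("X", 1.2, 0.5)

    def summaries(self, means):
        return [PopulationScoreSummary(g, 100, m, 0.01) for g, m in means.items()]

    def test_perfectly_linear_pairs(self):
        res = correlate_prevalence(
            self.summaries({"A": 0.1, "B": 0.2, "C": 0.3}),
            [PrevalenceRecord("A", 0.01, 0.5), PrevalenceRecord("B", 0.02, 0.5),
             PrevalenceRecord("C", 0.03, 0.5)],
        )
        assert res.r == pytest.approx(1.0)
        assert res.n == 3

    def test_hand_formula_oracle(self):
        x = np.array([0.1, 0.2, 0.4])
        y = np.array([0.010, 0.015, 0.040])
        manual = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        res = correlate_prevalence(
            self.summaries(dict(zip("ABC", x))),
            [PrevalenceRecord(g, v, 0.0) for g, v in zip("ABC", y)],
        )
        assert res.r == pytest.approx(manual, abs=1e-12)

    def test_groups_without_prevalence_dropped(self):
        res = correlate_prevalence(
            self.summaries({"A": 0.1, "B": 0.2, "C": 0.3, "AMR": 0.25}),
            [PrevalenceRecord("A", 0.01, 0.1), PrevalenceRecord("B", 0.02, 0.1),
             PrevalenceRecord("C", 0.05, 0.1)],
        )
        assert "AMR" in res.dropped

    def test_constant_vector_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            correlate_prevalence(
                self.summaries({"A": 0.2, "B": 0.2, "C": 0.2}),
                [PrevalenceRecord(g, v, 0.1) for g, v in
                 [("A", 0.01), ("B", 0.02), ("C", 0.03)]],
            )

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlate_prevalence(
                self.summaries({"A": 0.1, "B": 0.2}),
                [PrevalenceRecord("A", 0.01, 0.1), PrevalenceRecord("B", 0.02, 0.1)],
            )
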