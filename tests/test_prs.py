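"""Additive PRS scoring, quartile assignment, and case-enrichment tests."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osccohort.prs import (
    assign_quartiles,
    chi_square_2x2,
    harmonize_alleles,
    quartile_risk_test,
    read_base_summary,
    score_individuals,
)


def write_base(tmp_path, rows, header="SNP CHR BP A1 A2 BETA P"):
    path = tmp_path / "base.tsv"
    cols = header.split()
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadBase:
    def test_or_converted_by_natural_log(self, tmp_path):
        path = write_base(
            tmp_path,
            [("rs1", 1, 100, "A", "G", 1.0, 0.5), ("rs2", 1, 200, "C", "T", 2.0, 0.5)],
            header="SNP CHR BP A1 A2 OR P",
        )
        model = read_base_summary(path)
        assert model.loc["rs1", "beta"] == pytest.approx(0.0)
        assert model.loc["rs2", "beta"] == pytest.approx(math.log(2.0))

    def test_p_threshold_one_keeps_everything(self, tmp_path):
        rows = [(f"rs{i}", 1, i, "A", "G", 0.1, (i + 1) / 10) for i in range(10)]
        path = write_base(tmp_path, rows)
        assert len(read_base_summary(path, p_threshold=1.0)) == 10
        assert len(read_base_summary(path, p_threshold=0.5)) == 5

    def test_errors(self, tmp_path):
        path = write_base(tmp_path, [("rs1", 1, 100, "A", "G", 0.1, 0.5)],
                          header="SNP CHR BP A1 A2 WEIGHT P")
        with pytest.raises(ValueError, match="BETA or OR"):
            read_base_summary(path)
        path = write_base(tmp_path, [("rs1", 1, 100, "A", "G", -1.0, 0.5)],
                          header="SNP CHR BP A1 A2 OR P")
        with pytest.raises(ValueError, match="non-positive"):
            read_base_summary(path)
        path = write_base(tmp_path, [("rs1", 1, 100, "A", "G", 0.1, 0.5)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            read_base_summary(path)


def model_frame(betas, a1="A", a2="G"):
    snps = [f"rs{i}" for i in range(len(betas))]
    return pd.DataFrame(
        {"chrom": "1", "pos": range(len(betas)), "a1": a1, "a2": a2,
         "beta": betas, "p": 0.5},
        index=pd.Index(snps, name="SNP"),
    )


class TestScoring:
    def test_hand_computed_two_snp_score(self):
        model = model_frame([0.2, -0.5])
        dosages = pd.DataFrame([[2, 1]], index=["I1"], columns=["rs0", "rs1"])
        score = score_individuals(model, dosages)
        assert score["I1"] == pytest.approx(2 * 0.2 + 1 * -0.5)  # -0.1

    def test_zero_dosages_zero_score(self):
        model = model_frame([0.3, 0.7])
        dosages = pd.DataFrame([[0, 0]], index=["I1"], columns=["rs0", "rs1"])
        assert score_individuals(model, dosages)["I1"] == 0.0

    def test_linearity_in_betas(self):
        rng = np.random.default_rng(8)
        betas = rng.normal(size=12)
        model1, model2 = model_frame(betas), model_frame(2 * betas)
        dosages = pd.DataFrame(
            rng.integers(0, 3, size=(5, 12)),
            index=[f"I{i}" for i in range(5)],
            columns=[f"rs{i}" for i in range(12)],
        )
        s1 = score_individuals(model1, dosages)
        s2 = score_individuals(model2, dosages)
        assert np.allclose(s2.to_numpy(), 2 * s1.to_numpy())

    def test_missing_dosage_imputed_with_cohort_frequency(self):
        model = model_frame([1.0, 1.0])
        dosages = pd.DataFrame(
            {"rs0": [0.0, 2.0, np.nan], "rs1": [1.0, 1.0, 2.0]},
            index=["I1", "I2", "I3"],
        )
        scores = score_individuals(model, dosages)
        # rs0 imputed with the cohort mean dosage (= 2 x allele frequency)
        assert scores["I3"] == pytest.approx(1.0 + 2.0)
        # an individual with no observed dosage at any shared SNP is missing
        all_missing = pd.DataFrame(
            {"rs0": [0.0, np.nan], "rs1": [1.0, np.nan]}, index=["I1", "I4"]
        )
        assert np.isnan(score_individuals(model, all_missing)["I4"])

    def test_scores_match_planted_truth(self, small_bundle):
        model = read_base_summary(small_bundle.prs_base_path)
        dosages = pd.read_csv(small_bundle.prs_dosage_path, sep="\t", index_col=0)
        scores = score_individuals(model, dosages)
        truth = json.loads(small_bundle.truth_path.read_text())
        planted = truth["prs"]["expected_liability"]
        for ind, expected in planted.items():
            assert scores[ind] == pytest.approx(expected, abs=5e-5)

    def test_positive_shift_separates_cases(self, small_bundle):
        model = read_base_summary(small_bundle.prs_base_path)
        dosages = pd.read_csv(small_bundle.prs_dosage_path, sep="\t", index_col=0)
        labels = pd.read_csv(small_bundle.prs_labels_path, sep="\t", index_col=0)
        scores = score_individuals(model, dosages)
        case = labels["status"].eq("case").reindex(scores.index)
        assert scores[case].mean() > scores[~case].mean()


class TestHarmonization:
    def test_swapped_alleles_flip_dosage(self):
        model = model_frame([1.0], a1="A", a2="G")
        target = pd.DataFrame({"a1": ["G"], "a2": ["A"]}, index=["rs0"])
        dosages = pd.DataFrame({"rs0": [2.0]}, index=["I1"])
        score = score_individuals(model, dosages, target_alleles=target)
        assert score["I1"] == pytest.approx(0.0)  # 2 - 2

    def test_complement_strand_folded(self):
        model = model_frame([1.0], a1="A", a2="G")
        target = pd.DataFrame({"a1": ["T"], "a2": ["C"]}, index=["rs0"])
        aligned, flip = harmonize_alleles(model, target)
        assert list(aligned.index) == ["rs0"]
        assert not flip["rs0"]

    def test_palindromic_excluded(self):
        model = model_frame([1.0, 1.0])
        target = pd.DataFrame(
            {"a1": ["A", "A"], "a2": ["T", "G"]}, index=["rs0", "rs1"]
        )
        aligned, _ = harmonize_alleles(model, target)
        assert list(aligned.index) == ["rs1"]


class TestQuartiles:
    def test_even_split_of_eight(self):
        scores = pd.Series(
            [3.0, 1.0, 2.0, 8.0, 5.0, 4.0, 7.0, 6.0],
            index=[f"I{i}" for i in range(8)],
        )
        result = assign_quartiles(scores)
        assert result.sizes() == {"Q1": 2, "Q2": 2, "Q3": 2, "Q4": 2}
        assert set(result.quartile[result.quartile == "Q1"].index) == {"I1", "I2"}
        assert set(result.quartile[result.quartile == "Q4"].index) == {"I3", "I6"}

    def test_remainder_rule_for_225(self):
        scores = pd.Series(np.arange(225, dtype=float),
                           index=[f"I{i:03d}" for i in range(225)])
        low = assign_quartiles(scores)
        assert [low.sizes()[q] for q in ("Q1", "Q2", "Q3", "Q4")] == [57, 56, 56, 56]
        high = assign_quartiles(scores, remainder="high")
        assert [high.sizes()[q] for q in ("Q1", "Q2", "Q3", "Q4")] == [56, 56, 56, 57]

    @settings(max_examples=100, derandomize=True)
    @given(n=st.integers(4, 300))
    def test_partition_sizes_differ_by_at_most_one(self, n):
        scores = pd.Series(np.arange(n, dtype=float) % 17,  # plenty of ties
                           index=[f"I{i:04d}" for i in range(n)])
        result = assign_quartiles(scores)
        sizes = list(result.sizes().values())
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        # Q1 holds the lowest scores
        assert result.scores.iloc[: sizes[0]].max() <= result.scores.iloc[sizes[0]:].min()

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles(pd.Series([1.0, 2.0, 3.0], index=list("abc")))


class TestChiSquare:
    def test_equal_proportions_statistic_zero(self):
        stat, p = chi_square_2x2(50, 5, 50, 5)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_direct_arithmetic_for_printed_tables(self):
        # 0 vs 2 cases in two groups of 56: sum (O-E)^2/E = 2 + 2/55
        stat, p = chi_square_2x2(56, 0, 56, 2)
        assert stat == pytest.approx(1 + 1 + 1 / 55 + 1 / 55)
        assert stat == pytest.approx(2.04, abs=0.005)
        stat3, _ = chi_square_2x2(56, 0, 56, 4)
        assert stat3 == pytest.approx(2 + 2 + 4 / 54 + 4 / 54, abs=1e-9)

    def test_symmetry(self):
        s1, _ = chi_square_2x2(40, 3, 60, 9)
        s2, _ = chi_square_2x2(60, 9, 40, 3)
        s3, _ = chi_square_2x2(40, 37, 60, 51)  # swap case/control labels
        assert s1 == pytest.approx(s2)
        assert s1 == pytest.approx(s3)

    def test_statistic_to_p_consistency(self):
        from scipy.stats import chi2

        assert chi2.sf(17.6, 1) == pytest.approx(2.72e-5, rel=0.01)

    def test_quartile_risk_test_requires_nonempty(self):
        scores = pd.Series(np.arange(8, dtype=float), index=list("abcdefgh"))
        result = assign_quartiles(scores, {k: k in "gh" for k in "abcdefgh"})
        stat, p = quartile_risk_test(result, "Q4")
        assert stat == pytest.approx(4.0)  # [[0,2],[2,0]] on groups of 2
        with pytest.raises(ValueError):
            quartile_risk_test(result, "Q5")
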