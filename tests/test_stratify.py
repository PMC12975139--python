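"""Stage simplification and stratified burden / association statistics."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osccohort.annotate import read_nr_table  # noqa: F401  (fixture sanity)
from osccohort.recurrence import build_matrix
from osccohort.stratify import (
    burden_group_test,
    dunn_posthoc,
    per_gene_association,
    rank_sum_test,
    simplify_stage,
)
from osccohort.variant_io import AnnotatedVariant, SampleCall, VariantKey


def brute_force_ranksum_p(x, y):
    """Independent enumeration oracle: all C(n, n1) allocations of the
    pooled tie-averaged ranks, doubled smaller tail, capped at 1."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    le = ge = 0
    for idx in combinations(range(n), n1):
        w = sum(ranks[i] for i in idx)
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / comb(n, n1))


class TestSimplifyStage:
    @pytest.mark.parametrize(
        "pt, pn, expected",
        [
            ("2", "0", "II"),
            ("1", "0", "I"),
            ("1", "1", "III"),
            ("3", "0", "III"),
            ("3", "1", "III"),
            ("2", "2b", "IV"),
            ("4a", "1", "IV"),
            ("4a", "x", "IV"),
            ("2", "x", "II"),  # Nx treated as N0
        ],
    )
    def test_rule_table(self, pt, pn, expected):
        stage, _rule = simplify_stage(pt, pn)
        assert stage == expected

    def test_invalid_tokens_raise(self):
        with pytest.raises(ValueError):
            simplify_stage("5", "0")
        with pytest.raises(ValueError):
            simplify_stage("2", "9")


class TestRankSum:
    def test_separated_groups_exact_p(self):
        stat, p, method = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert method == "exact"
        assert p == pytest.approx(0.1)  # 2 * (1/20)

    def test_identical_groups_p_one(self):
        _, p, method = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert p == 1.0
        _, p2, _ = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p2 == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            x = rng.integers(0, 6, size=n1).tolist()  # ties likely
            y = rng.integers(0, 6, size=n2).tolist()
            if len(set(x + y)) == 1:
                continue
            _, p, method = rank_sum_test(x, y)
            assert method == "exact"
            assert p == pytest.approx(brute_force_ranksum_p(x, y))

    def test_null_calibration_of_normal_approximation(self):
        # continuous burdens, 12 vs 12 (pooled 24 -> asymptotic path);
        # rejection rate at alpha = 0.05 should sit in the binomial 95% CI
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = rng.normal(size=24)
            _, p, method = rank_sum_test(vals[:12], vals[12:])
            rejections += p < 0.05
        assert method == "normal-approx"
        half_width = 1.96 * (0.05 * 0.95 / n_rep) ** 0.5
        assert abs(rejections / n_rep - 0.05) < half_width + 1e-12


class TestGroupTests:
    def test_two_group_dispatch(self):
        res = burden_group_test({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert res.method.startswith("wilcoxon")
        assert res.p_value == pytest.approx(0.1)

    def test_kruskal_for_three_groups_and_monotone_invariance(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(size=8).tolist() for k in "ABC"}
        res = burden_group_test(groups)
        transformed = {k: [np.exp(v) for v in vals] for k, vals in groups.items()}
        res2 = burden_group_test(transformed)
        assert res.statistic == pytest.approx(res2.statistic)
        assert res.p_value == pytest.approx(res2.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            burden_group_test({"A": [1], "B": []})


class TestDunn:
    def test_identical_constant_groups_all_adjusted_one(self):
        groups = {k: [7.0] * 5 for k in "ABC"}
        df = dunn_posthoc(groups)
        assert (df["p_adjusted"] == 1.0).all()

    def test_z_matches_direct_formula(self):
        groups = {"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0], "C": [7.0, 8.0, 9.0]}
        df = dunn_posthoc(groups)
        # no ties: var = N(N+1)/12 = 9*10/12 = 7.5 ; mean ranks 2, 5, 8
        z_ab = (2 - 5) / np.sqrt(7.5 * (1 / 3 + 1 / 3))
        row = df[(df.group1 == "A") & (df.group2 == "B")].iloc[0]
        assert row["z"] == pytest.approx(z_ab)
        assert row["p_raw"] == pytest.approx(2 * stats.norm.sf(abs(z_ab)))

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(size=6).tolist() for k in "ABCD"}
        df = dunn_posthoc(groups)
        assert (df["p_adjusted"] >= df["p_raw"] - 1e-12).all()
        assert (df["p_adjusted"] <= 1.0).all()


def _matrix_from_pattern(pattern):
    """pattern: dict gene -> set of carrier patient indices (0..n-1)."""
    calls = []
    n = max(max(s) for s in pattern.values() if s) + 1
    for gi, (gene, carriers) in enumerate(sorted(pattern.items())):
        for p in carriers:
            av = AnnotatedVariant(
                key=VariantKey("chr1", 1000 * (gi + 1), "A", "G"),
                gene=gene,
                consequence="intron_variant",
                clnsig_raw="Pathogenic",
                clnsig_labels=frozenset({"pathogenic"}),
            )
            calls.append(SampleCall(f"P{p}T", f"P{p}", "tumor", av, 1))
    # ensure every patient appears
    for p in range(n):
        av = AnnotatedVariant(
            key=VariantKey("chr2", 1 + p, "A", "G"),
            gene="ANCHOR",
            consequence="intron_variant",
            clnsig_raw="Pathogenic",
            clnsig_labels=frozenset({"pathogenic"}),
        )
        calls.append(SampleCall(f"P{p}T", f"P{p}", "tumor", av, 1))
    return build_matrix(calls)


class TestPerGeneAssociation:
    def test_universal_gene_p_one(self):
        matrix = _matrix_from_pattern({"GU": set(range(6))})
        grouping = {f"P{i}": i < 3 for i in range(6)}
        df = per_gene_association(matrix, grouping)
        assert df.loc["GU", "p"] == pytest.approx(1.0)
        assert df.loc["ANCHOR", "p"] == pytest.approx(1.0)

    def test_perfectly_separated_table(self):
        # carriers exactly the 5 patients of group A: [[5,0],[0,5]]
        matrix = _matrix_from_pattern({"GS": set(range(5)), "GU": set(range(10))})
        grouping = {f"P{i}": i < 5 for i in range(10)}
        df = per_gene_association(matrix, grouping)
        assert df.loc["GS", "p"] == pytest.approx(2 / 252)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 7, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            # enumeration: sum point probabilities <= observed
            n, r1, c1 = a + b + c + d, a + b, a + c
            obs = stats.hypergeom.pmf(a, n, r1, c1)
            total = 0.0
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                pk = stats.hypergeom.pmf(k, n, r1, c1)
                if pk <= obs * (1 + 1e-9):
                    total += pk
            assert p_scipy == pytest.approx(min(1.0, total), rel=1e-8)

    def test_bh_step_up_hand_example(self):
        matrix = _matrix_from_pattern({"GU": set(range(6))})
        grouping = {f"P{i}": i < 3 for i in range(6)}
        df = per_gene_association(matrix, grouping)
        # q-values are monotone in p and never below p
        df = df.sort_values("p")
        assert (df["q"].to_numpy() >= df["p"].to_numpy() - 1e-12).all()
        assert (np.diff(df["q"].to_numpy()) >= -1e-12).all()

    def test_non_binary_grouping_rejected(self):
        matrix = _matrix_from_pattern({"GU": set(range(4))})
        with pytest.raises(ValueError):
            per_gene_association(matrix, {f"P{i}": True for i in range(4)})
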