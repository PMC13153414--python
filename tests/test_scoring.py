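"""Single-sample scores and clinical association statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trialsig import (
    GeneSet,
    PlantedSet,
    SyntheticCohortConfig,
    auc_benefit,
    km_logrank_hr,
    label_benefit,
    median_split,
    rank_tests,
    simulate_expression_cohort,
    singscore_up,
    spearman_pfs,
    zscore_mean_score,
)


def auc_by_pair_counting(scores, labels):
    """Concordant-pair fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


def ranksum_p_by_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating every label assignment."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    nx = len(x)
    obs = ranks[:nx].sum()
    stats = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    stats = np.asarray(stats)
    lo = np.mean(stats <= obs)
    hi = np.mean(stats >= obs)
    return min(1.0, 2 * min(lo, hi))


class TestSingscore:
    def test_top_ranks_hit_upper_bound(self, five_gene_single_sample):
        score = singscore_up(five_gene_single_sample, GeneSet.from_genes("s", ["d", "e"]))
        assert score["s1"] == pytest.approx(0.5, abs=1e-12)

    def test_extreme_ranks_centre(self, five_gene_single_sample):
        score = singscore_up(five_gene_single_sample, GeneSet.from_genes("s", ["a", "e"]))
        assert score["s1"] == pytest.approx(0.0, abs=1e-12)

    def test_bottom_ranks_hit_lower_bound(self, five_gene_single_sample):
        score = singscore_up(five_gene_single_sample, GeneSet.from_genes("s", ["a", "b"]))
        assert score["s1"] == pytest.approx(-0.5, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("wxyz"),
        )
        gs = GeneSet.from_genes("s", [f"g{i}" for i in range(5)])
        before = singscore_up(expr, gs)
        expr["x"] = np.exp(expr["x"])  # strictly monotone on one sample
        after = singscore_up(expr, gs)
        pd.testing.assert_series_equal(before, after)

    def test_bounds_for_all_scores(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(50, 8)),
                            index=[f"g{i}" for i in range(50)])
        gs = GeneSet.from_genes("s", [f"g{i}" for i in range(0, 50, 7)])
        sc = singscore_up(expr, gs)
        assert ((sc >= -0.5) & (sc <= 0.5)).all()

    def test_too_few_measured_members(self, five_gene_single_sample):
        with pytest.raises(ValueError, match="missing"):
            singscore_up(five_gene_single_sample, GeneSet.from_genes("s", ["a", "q", "r"]))


class TestZscoreMean:
    def test_two_sample_single_gene(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["x", "y"])
        sc = zscore_mean_score(expr, GeneSet.from_genes("s", ["g"]))
        assert sc["x"] == pytest.approx(-0.7071, abs=1e-4)
        assert sc["y"] == pytest.approx(+0.7071, abs=1e-4)

    def test_scores_centred_across_samples(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(10, 6)),
                            index=[f"g{i}" for i in range(10)])
        sc = zscore_mean_score(expr, GeneSet.from_genes("s", [f"g{i}" for i in range(4)]))
        assert sc.mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_excluded_with_warning(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["var", "flat"]
        )
        with pytest.warns(UserWarning, match="flat"):
            sc = zscore_mean_score(expr, GeneSet.from_genes("s", ["var", "flat"]))
        only = zscore_mean_score(expr, GeneSet.from_genes("s2", ["var"]))
        assert np.allclose(sc.to_numpy(), only.to_numpy())

    def test_all_constant_errors(self):
        expr = pd.DataFrame([[5.0, 5.0]], index=["flat"])
        with pytest.raises(ValueError):
            zscore_mean_score(expr, GeneSet.from_genes("s", ["flat"]))


class TestAuc:
    def test_hand_examples(self):
        assert auc_benefit([1, 2, 3, 4], [0, 0, 1, 1]).statistic == 1.0
        assert auc_benefit([1, 2, 3, 4], [0, 1, 0, 1]).statistic == 0.75

    def test_complete_ties_give_half(self):
        assert auc_benefit([3, 3, 3, 3], [0, 1, 0, 1]).statistic == 0.5

    def test_flip_reports_one_minus_auc(self):
        a = auc_benefit([1, 2, 3, 4], [0, 1, 0, 1])
        b = auc_benefit([1, 2, 3, 4], [0, 1, 0, 1], flip=True)
        assert b.statistic == pytest.approx(1 - a.statistic, abs=1e-12)

    def test_matches_pair_counting_oracle(self):
        """Exhaustive concordant-pair enumeration on random instances, n <= 12."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
            labels = np.zeros(n, bool)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            got = auc_benefit(scores, labels).statistic
            assert got == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_benefit([1, 2, 3], [1, 1, 1])


class TestRankTests:
    def test_extreme_separation_exact_p(self):
        res = rank_tests([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_paired_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = rank_tests([1, 2, 3, 4], [1, 2, 3, 4], paired=True)
        assert res.p_value == 1.0

    def test_paired_unequal_lengths(self):
        with pytest.raises(ValueError):
            rank_tests([1, 2, 3], [1, 2], paired=True)

    def test_matches_enumeration_oracle_small_n(self):
        """Exact two-sided p agrees with full permutation enumeration, n <= 6."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            nx, ny = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            x = rng.normal(size=nx)  # continuous: tie-free
            y = rng.normal(size=ny)
            got = rank_tests(x, y).p_value
            assert got == pytest.approx(ranksum_p_by_enumeration(x, y), abs=1e-9)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_pfs([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert spearman_pfs([1, 2, 3, 4], [40, 30, 20, 10]).statistic == -1.0

    def test_direct_formula(self):
        # sum d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        res = spearman_pfs([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_pfs([1, 1, 1, 1], [1, 2, 3, 4])


def efron_cox_hr(time, event, x):
    """Independent single-covariate Efron partial-likelihood Newton maximizer."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(100):
        u = 0.0
        info = 0.0
        for t in np.unique(time[event]):
            d_idx = np.nonzero(event & (time == t))[0]
            r_idx = np.nonzero(time >= t)[0]
            d = len(d_idx)
            xe = np.exp(beta * x)
            s0_r, s1_r, s2_r = (
                xe[r_idx].sum(),
                (x[r_idx] * xe[r_idx]).sum(),
                (x[r_idx] ** 2 * xe[r_idx]).sum(),
            )
            s0_d, s1_d, s2_d = (
                xe[d_idx].sum(),
                (x[d_idx] * xe[d_idx]).sum(),
                (x[d_idx] ** 2 * xe[d_idx]).sum(),
            )
            u += x[d_idx].sum()
            for j in range(d):
                f = j / d
                s0 = s0_r - f * s0_d
                s1 = s1_r - f * s1_d
                s2 = s2_r - f * s2_d
                u -= s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
        step = u / info
        beta += step
        if abs(step) < 1e-12:
            break
    return np.exp(beta)


class TestSurvival:
    def test_identical_groups_null(self):
        rec = pd.DataFrame(
            {"sample": list("abcdef"), "pfs_months": [1, 2, 3, 1, 2, 3],
             "event": [1, 1, 0, 1, 1, 0]}
        )
        res = km_logrank_hr(rec, ["A", "A", "A", "B", "B", "B"])
        assert res.statistic == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_km_median_uncensored(self):
        rec = pd.DataFrame(
            {"sample": list("abcdeXYZVW"),
             "pfs_months": [1, 2, 3, 4, 5] * 2,
             "event": [1] * 10}
        )
        res = km_logrank_hr(rec, ["A"] * 5 + ["B"] * 5)
        assert res.extra["curves"]["A"]["median"] == 3.0

    def test_hr_direction_and_oracle_agreement(self):
        """Early-event group has elevated hazard; the fitted HR agrees with an
        independent Efron partial-likelihood maximizer to 1e-6."""
        rng = np.random.default_rng(9)
        t = np.concatenate([rng.exponential(2, 20), rng.exponential(6, 20)])
        e = (t < 8).astype(int)
        t = np.minimum(t, 8.0)
        grp = np.array(["early"] * 20 + ["late"] * 20)
        rec = pd.DataFrame({"sample": [f"s{i}" for i in range(40)],
                            "pfs_months": t, "event": e})
        res = km_logrank_hr(rec, grp)
        # x encodes second sorted level ("late"); HR(late vs early) < 1
        assert res.statistic < 1.0
        oracle = efron_cox_hr(t, e.astype(bool), (grp == "late").astype(float))
        assert res.statistic == pytest.approx(oracle, abs=1e-6)

    def test_no_events_rejected(self):
        rec = pd.DataFrame({"sample": list("abcd"), "pfs_months": [1, 2, 3, 4],
                            "event": [0, 0, 0, 0]})
        with pytest.raises(ValueError):
            km_logrank_hr(rec, ["A", "A", "B", "B"])

    def test_planted_hazard_recovered_across_replicates(self):
        """Median-split HR exceeds 1 in >= 90% of 50 replicates at n = 60
        when the hazard increases in the true score."""
        wins = 0
        for rep in range(50):
            cfg = SyntheticCohortConfig(
                n_cb=30, n_ncb=30, n_genes=20,
                planted_sets=(PlantedSet("ncb", tuple(range(10)), 1.0, "NCB"),),
                survival_set="ncb", hazard_theta=0.8, seed=5000 + rep,
            )
            _, clin, _ = simulate_expression_cohort(cfg)
            sc = pd.Series(clin["true_score"].to_numpy() + 1e-9 * np.arange(60),
                           index=clin["sample"])
            groups = median_split(sc)
            res = km_logrank_hr(clin, groups.to_numpy(), reference="low")
            if res.statistic > 1.0:  # high score group has worse outcome
                wins += 1
        assert wins >= 45

    def test_association_p_uniform_under_null(self):
        """Spearman and rank-sum p-values are uniform under the null."""
        from scipy.stats import kstest

        rng = np.random.default_rng(10)
        p_sp, p_rs = [], []
        for _ in range(2000):
            s = rng.normal(size=100)
            t = rng.normal(size=100)
            p_sp.append(spearman_pfs(s, t).p_value)
            p_rs.append(rank_tests(s[:12], s[12:]).p_value)
        assert kstest(p_sp, "uniform").pvalue > 0.01
        assert kstest(p_rs, "uniform").pvalue > 0.01


class TestLabelBenefit:
    @pytest.mark.parametrize(
        "response,pfs,benefit,exceptional",
        [
            ("SD", 4.0, "CB", False),     # boundary inclusive
            ("SD", 3.9, "NCB", False),
            ("PD", 20.0, "NCB", True),    # PD is never CB
            ("SD", 13.6, "CB", True),     # long SD: CB and exceptional
            ("PR", 1.0, "CB", False),     # response dominates
            ("CR", 0.5, "CB", False),
        ],
    )
    def test_rules(self, response, pfs, benefit, exceptional):
        rec = pd.DataFrame(
            {"sample": ["s"], "response": [response], "pfs_months": [pfs]}
        )
        out = label_benefit(rec)
        assert out.loc[0, "benefit"] == benefit
        assert bool(out.loc[0, "exceptional"]) is exceptional

    def test_unknown_response_code(self):
        rec = pd.DataFrame({"sample": ["s"], "response": ["??"], "pfs_months": [1.0]})
        with pytest.raises(ValueError, match=r"\?\?"):
            label_benefit(rec)
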