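import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from bless.core import (
    BlessConfig,
    PValueGroup,
    adjust_group,
    aggregate_groups,
    fit_base_model,
    run_bless,
    sample_features,
    subsample_observations,
    summarize,
)
from bless.io import GenotypeMatrix, SampleTable
from bless.snpwise import fit_marginal
from conftest import bh_bruteforce


def sim_dataset(n=120, p=12, seed=3, signal=None):
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(float)
    lp = np.zeros(n)
    if signal:
        for j, beta in signal.items():
            lp += beta * dos[:, j]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    samples = [f"s{i:03d}" for i in range(n)]
    G = GenotypeMatrix(samples, [f"rs{j:02d}" for j in range(p)], dos)
    S = SampleTable(pd.DataFrame({"y": y}, index=pd.Index(samples)), "y")
    return G, S


class TestSampling:
    def test_subsample_size_is_floor_of_fraction(self):
        rng = np.random.default_rng(0)
        idx = subsample_observations(197, 0.9, rng)
        assert idx.size == 177
        assert np.unique(idx).size == 177

    def test_fraction_one_returns_all_indices(self):
        idx = subsample_observations(10, 1.0, np.random.default_rng(0))
        assert sorted(idx) == list(range(10))

    def test_empty_subsample_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            subsample_observations(3, 0.1, np.random.default_rng(0))

    def test_feature_draw_distinct_and_seed_stable(self):
        ids = [f"rs{j}" for j in range(50)]
        a = sample_features(ids, 7, np.random.default_rng([5, 1]))
        b = sample_features(ids, 7, np.random.default_rng([5, 1]))
        assert a == b
        assert len(set(a)) == 7
        assert sample_features(ids, 50, np.random.default_rng(0)) is not None
        with pytest.raises(ValueError):
            sample_features(ids, 51, np.random.default_rng(0))

    def test_default_feature_count_is_root_p(self):
        assert BlessConfig().resolve_n_features(1000) == 32
        assert BlessConfig(n_features=30).resolve_n_features(1000) == 30


class TestFitBaseModel:
    def test_full_data_equals_single_joint_fit(self):
        G, S = sim_dataset()
        res = fit_base_model(G, S, np.arange(G.n_samples), G.snps)
        X = np.column_stack([np.ones(G.n_samples), G.dosages])
        joint = sm.Logit(S.outcome_vector(G.samples), X).fit(disp=0)
        for j, (snp, p, ok, _) in enumerate(res):
            assert ok
            assert p == pytest.approx(joint.pvalues[1 + j], abs=1e-10)

    def test_constant_snp_in_subsample_flagged_others_reported(self):
        G, S = sim_dataset()
        d = G.dosages.copy()
        d[:60, 0] = 1.0
        G2 = GenotypeMatrix(G.samples, G.snps, d)
        res = fit_base_model(G2, S, np.arange(60), ["rs00", "rs01", "rs02"])
        assert res[0][2] is False and res[0][3] == "monomorphic_in_subsample"
        assert res[1][2] and res[2][2]

    def test_duplicated_snp_column_dropped_as_collinear(self):
        G, S = sim_dataset()
        d = np.column_stack([G.dosages, G.dosages[:, 0]])
        G2 = GenotypeMatrix(G.samples, G.snps + ["rsDUP"], d)
        res = fit_base_model(G2, S, np.arange(G.n_samples), ["rs00", "rsDUP"])
        assert res[0][2] is True
        assert res[1][2] is False and res[1][3] == "collinear_in_subsample"

    def test_single_snp_no_covariates_matches_marginal_fit(self):
        G, S = sim_dataset(signal={0: 0.8})
        res = fit_base_model(G, S, np.arange(G.n_samples), ["rs00"])
        marg = fit_marginal(G, S, "rs00")
        assert res[0][1] == pytest.approx(marg.raw_p, abs=1e-10)


class TestGroupsAndAdjustment:
    def test_aggregation_counts_only_successful_tests(self):
        iters = [
            [("a", 0.1, True, ""), ("b", None, False, "monomorphic_in_subsample")],
            [("a", 0.2, True, ""), ("c", 0.5, True, "")],
            [("b", 0.3, True, "")],
        ]
        groups, never = aggregate_groups(iters, ["a", "b", "c", "d"])
        assert groups["a"].selection_count == 2
        assert groups["b"].pvalues == [0.3]  # the failed test adds no multiplicity
        assert never == ["d"]

    @pytest.mark.parametrize("pvals,expected_min", [
        ([0.001], 0.001),
        ([0.01, 0.02, 0.03], 0.03),
        ([0.04] * 100, 0.04),
    ])
    def test_known_group_adjustments(self, pvals, expected_min):
        _, min_adj = adjust_group(PValueGroup("x", list(pvals),
                                              list(range(len(pvals)))))
        assert min_adj == pytest.approx(expected_min, abs=1e-12)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            adjust_group(PValueGroup("x"))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
           st.floats(0, 1, allow_nan=False))
    def test_group_bh_matches_bruteforce_and_extension_is_monotone(self, p, extra):
        """Within-group BH equals the definitional oracle; appending a
        p-value >= max(group) never lowers the group minimum."""
        g = PValueGroup("x", list(p), list(range(len(p))))
        adjusted, min_adj = adjust_group(g)
        np.testing.assert_allclose(adjusted, bh_bruteforce(p), atol=1e-12)
        worse = max(p) + (1 - max(p)) * extra
        g2 = PValueGroup("x", list(p) + [worse], list(range(len(p) + 1)))
        _, min2 = adjust_group(g2)
        assert min2 >= min_adj - 1e-12


class TestSummarize:
    def make_groups(self):
        return [
            PValueGroup("slow", [0.5] * 4, list(range(4))),
            PValueGroup("hit", [0.0004, 0.2], [0, 1]),
            PValueGroup("tie_b", [0.01], [0]),
            PValueGroup("tie_a", [0.01], [1]),
        ]

    def test_significance_threshold_and_ordering(self):
        feats = summarize(self.make_groups(), alpha=0.05)
        assert [f.snp for f in feats] == ["hit", "tie_a", "tie_b", "slow"]
        assert [f.rank for f in feats] == [1, 2, 3, 4]
        flags = {f.snp: f.significant for f in feats}
        assert flags == {"hit": True, "tie_a": True, "tie_b": True,
                         "slow": False}

    def test_selection_count_breaks_ties_before_snp_id(self):
        # zz: BH of [0.01, 0.01] at m=2 -> min 0.01, tying aa's single 0.01;
        # zz was tested twice, so it ranks first despite the later ID
        groups = [PValueGroup("zz", [0.01, 0.01], [0, 1]),
                  PValueGroup("aa", [0.01], [0])]
        feats = summarize(groups, alpha=0.05)
        assert [f.snp for f in feats] == ["zz", "aa"]
        # zz min adj = min(2*0.02/1, 2*1.0/2) = 0.04 ties aa's 0.04
        groups = [PValueGroup("zz", [0.02, 1.0], [0, 1]),
                  PValueGroup("aa", [0.04], [0])]
        feats = summarize(groups, alpha=0.05)
        assert [f.snp for f in feats] == ["zz", "aa"]

    def test_alpha_zero_keeps_full_ranking_empty_significant_set(self):
        feats = summarize(self.make_groups(), alpha=0.0)
        assert len(feats) == 4
        assert not any(f.significant for f in feats)


class TestRunBless:
    def test_degenerate_config_reproduces_joint_model(self):
        """fraction=1, m=p, 1 iteration: the ensemble is exactly one joint
        logistic fit, and each group of size 1 is BH-invariant."""
        G, S = sim_dataset(n=150, p=8, seed=9)
        cfg = BlessConfig(subsample_fraction=1.0, n_features=8,
                          n_iterations=1, seed=4)
        ranked, log = run_bless(G, S, cfg)
        X = np.column_stack([np.ones(G.n_samples), G.dosages])
        joint = sm.Logit(S.outcome_vector(G.samples), X).fit(disp=0)
        pmap = {s: joint.pvalues[1 + j] for j, s in enumerate(G.snps)}
        assert len(ranked) == 8
        for f in ranked:
            assert f.selection_count == 1
            assert f.min_adjusted_p == pytest.approx(pmap[f.snp], abs=1e-10)
        order = sorted(pmap, key=lambda s: (pmap[s], s))
        assert [f.snp for f in ranked] == order

    def test_seed_determinism_and_thread_invariance(self):
        G, S = sim_dataset(n=100, p=10, seed=2, signal={1: 1.0})
        cfg = dict(subsample_fraction=0.8, n_features=4, n_iterations=40,
                   seed=77)
        r1, _ = run_bless(G, S, BlessConfig(**cfg))
        r2, _ = run_bless(G, S, BlessConfig(**cfg))
        r3, _ = run_bless(G, S, BlessConfig(**cfg, n_jobs=2))
        assert r1 == r2 == r3

    def test_multiplicity_equals_selection_count_every_snp(self):
        G, S = sim_dataset(n=90, p=15, seed=8)
        cfg = BlessConfig(subsample_fraction=0.9, n_features=4,
                          n_iterations=60, seed=5)
        ranked, log = run_bless(G, S, cfg)
        counts = {f.snp: f.selection_count for f in ranked}
        assert sum(counts.values()) + log["n_failed_tests"] == 60 * 4
        assert all(c <= 60 for c in counts.values())
        assert len(ranked) + len(log["never_tested"]) == 15

    def test_monomorphic_outcome_iterations_discarded_not_fatal(self):
        rng = np.random.default_rng(0)
        n = 30
        samples = [f"s{i}" for i in range(n)]
        dos = rng.integers(0, 3, size=(n, 4)).astype(float)
        y = np.zeros(n, dtype=int)
        y[0] = 1  # outcome monomorphic in most 50% subsamples
        G = GenotypeMatrix(samples, [f"rs{j}" for j in range(4)], dos)
        S = SampleTable(pd.DataFrame({"y": y}, index=pd.Index(samples)), "y")
        ranked, log = run_bless(G, S, BlessConfig(
            subsample_fraction=0.5, n_features=2, n_iterations=30, seed=1))
        assert len(log["discarded_iterations"]) > 0

    def test_true_signals_rank_above_null_snps(self):
        """Signal-ranking recovery: mean rank of signal SNPs beats nulls."""
        G, S = sim_dataset(n=197, p=20, seed=13,
                           signal={0: 0.6, 1: 0.6, 2: 0.6})
        ranked, _ = run_bless(G, S, BlessConfig(
            subsample_fraction=0.9, n_features=5, n_iterations=200, seed=6))
        ranks = {f.snp: f.rank for f in ranked}
        true_ranks = [ranks[s] for s in ["rs00", "rs01", "rs02"]]
        null_ranks = [r for s, r in ranks.items()
                      if s not in ("rs00", "rs01", "rs02")]
        assert np.mean(true_ranks) < np.mean(null_ranks)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BlessConfig(subsample_fraction=0.0)
        with pytest.raises(ValueError):
            BlessConfig(n_iterations=0)
        with pytest.raises(ValueError):
            BlessConfig(fdr_method="bonferroni")
        with pytest.raises(ValueError):
            BlessConfig(n_features=10).resolve_n_features(5)
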