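"""Behavioral analyses: psychometrics, nonparametric psi, trade-offs, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import normacc as na
from normacc.behavior import DurationBins, NonparamPsiConfig


class TestPsychometric:
    def test_indifference_point_definition(self):
        p = na.PsychometricParams(phi=1.5, beta_slope=0.8)
        assert p.predict(1.5) == pytest.approx(0.5)

    def test_parameter_recovery(self, rng):
        phi, beta = 1.5, 0.8
        z = rng.uniform(-6, 8, size=2000)
        y = rng.random(2000) < expit((z - phi) / beta)
        fit = na.fit_psychometric(y.astype(int), z)
        assert fit.phi == pytest.approx(phi, abs=0.15)
        assert fit.beta_slope == pytest.approx(beta, abs=0.1)

    def test_bias_tracks_stabilizing_boundary(self):
        # across blocks, the fitted indifference point after strong evidence
        # follows log((1-H)/H) of the observer's hazard
        hz = (0.05, 0.1, 0.3, 0.7)
        trials = na.gen_triangles(
            na.TrianglesConfig(hazard_set=hz, n_trials_per_block=3000, sigma_over_d=0.33, seed=70)
        )
        obs = na.ObserverParams(
            model="normative", subjective_hazard={i: h for i, h in enumerate(hz)},
            gain=1 / 0.33**2, noise=1.0, seed=71,
        )
        data = na.observe(trials, obs)
        st = na.switch_table(data)
        phis, bounds = [], []
        for b, h in enumerate(hz):
            g = st[st["block"] == b]
            fit = na.fit_psychometric(
                g["switch"], g["llr_change"], min_abs_prev_llr=4.0, prev_abs_llr=g["prev_abs_llr"]
            )
            phis.append(fit.phi)
            bounds.append(math.log((1 - h) / h))
        rho = spearmanr(phis, bounds).statistic
        assert rho > 0

    def test_degenerate_responses_rejected(self):
        with pytest.raises(ValueError):
            na.fit_psychometric([1, 1, 1], [0.0, 1.0, 2.0])


class TestNonparametricPsi:
    def test_huge_penalty_flattens_estimate(self, triangles_observed):
        block = triangles_observed[triangles_observed["block"] == 0]
        est = na.estimate_psi_nonparametric(block, NonparamPsiConfig(tikhonov_gamma=1e7), noise=1.0)
        assert est["psi_hat"].std() < 0.05

    def test_default_grid_and_gamma(self):
        cfg = NonparamPsiConfig()
        np.testing.assert_array_equal(cfg.grid, np.arange(-10.0, 10.5, 1.0))
        assert cfg.tikhonov_gamma == pytest.approx(1 / 20)

    def test_recovers_generating_prior_map(self):
        # weak-evidence regime so choices are informative about psi;
        # abundant data beats the node-level wiggle mode
        trials = na.gen_triangles(
            na.TrianglesConfig(hazard_set=(0.1,), n_trials_per_block=20000, sigma_over_d=0.41, seed=72)
        )
        data = na.observe(
            trials,
            na.ObserverParams(model="normative", subjective_hazard=0.1, gain=1 / 0.41**2, noise=1.0, seed=73),
        )
        est = na.estimate_psi_nonparametric(data, noise=1.0, maxiter=1000)
        truth = na.log_prior_odds(est["node"].to_numpy(), 0.1)
        visited = ~est["masked"]
        rms = float(np.sqrt(np.mean((est.loc[visited, "psi_hat"] - truth[visited]) ** 2)))
        assert visited.sum() >= 15
        assert rms < 0.3

    def test_sparse_nodes_masked(self):
        trials = na.gen_triangles(na.TrianglesConfig(hazard_set=(0.5,), n_trials_per_block=60, sigma_over_d=0.24, seed=74))
        data = na.observe(trials, na.ObserverParams(subjective_hazard=0.5, gain=1 / 0.24**2, noise=1.0, seed=75))
        est = na.estimate_psi_nonparametric(data, noise=1.0, maxiter=50)
        assert est["masked"].any()


class TestTradeoffTable:
    def test_counts_conserved(self, triangles_observed):
        tab = na.tradeoff_table(triangles_observed, min_trials=1)
        for (b, ev), g in tab.groupby(["block", "evidence"]):
            data = triangles_observed[triangles_observed["block"] == b]
            llr = data["llr"].abs().to_numpy()
            sel = llr < 2.0 if ev == "weak" else llr > 4.0
            assert g["n"].sum() == sel.sum()

    def test_no_change_points_yields_empty_cp_column(self):
        trials = na.gen_triangles(na.TrianglesConfig(hazard_set=(0.3,), n_trials_per_block=200, seed=76))
        trials["source"] = 1
        trials["choice"] = 1
        tab = na.tradeoff_table(trials, min_trials=1)
        cp = tab[tab["kind"] == "change_point"]
        assert (cp["n"] == 0).all() and cp["accuracy"].isna().all()
        ncp = tab[(tab["kind"] == "non_change_point") & (tab["n"] > 0)]
        assert (ncp["accuracy"] == 1.0).all()

    def test_tradeoff_attenuates_for_strong_evidence(self):
        hz = (0.05, 0.3, 0.7)
        trials = na.gen_triangles(
            na.TrianglesConfig(hazard_set=hz, n_trials_per_block=4000, sigma_over_d=0.41, seed=77)
        )
        data = na.observe(
            trials,
            na.ObserverParams(model="normative", subjective_hazard={i: h for i, h in enumerate(hz)},
                              gain=1 / 0.41**2, noise=1e-9, seed=78),
        )
        tab = na.tradeoff_table(data)
        piv = tab.pivot_table(index="H_true", columns=["evidence", "kind"], values="accuracy")
        weak_cp = piv[("weak", "change_point")]
        weak_ncp = piv[("weak", "non_change_point")]
        assert weak_cp.is_monotonic_increasing
        assert weak_ncp.is_monotonic_decreasing
        strong = piv["strong"]
        assert (strong.max() - strong.min()).max() < (weak_cp.max() - weak_cp.min())


@pytest.fixture(scope="module")
def dots_choices():
    trials_list = []
    for i, lam in enumerate((0.1, 2.0)):
        data = na.gen_dots(na.DotsConfig(lam=lam, n_trials=150, seed=80 + i))
        obs = na.ObserverParams(model="normative", subjective_hazard=lam, gain=0.13, seed=82 + i)
        trials_list.append(na.observe(data, obs))
    return pd.concat(trials_list, ignore_index=True)


class TestAccuracyByDuration:
    def test_bootstrap_mean_matches_plugin(self, dots_choices):
        out = na.accuracy_by_duration(dots_choices, DurationBins(n_bootstrap=300), seed=1)
        big = out[out["n"] >= 20]
        assert np.allclose(big["boot_mean"], big["accuracy"], atol=0.05)

    def test_inclusion_rule(self, dots_choices):
        out = na.accuracy_by_duration(dots_choices, DurationBins(n_bootstrap=10), seed=2)
        eligible = dots_choices[
            (dots_choices["n_switches"] >= 1) & (dots_choices["t_penultimate"] >= 0.3)
            & (dots_choices["t_since_last_switch"] < 3.0)
        ]
        assert out["n"].sum() == len(eligible)

    def test_seeded_bootstrap_reproducible(self, dots_choices):
        a = na.accuracy_by_duration(dots_choices, DurationBins(n_bootstrap=50), seed=3)
        b = na.accuracy_by_duration(dots_choices, DurationBins(n_bootstrap=50), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_bootstrap_se_shrinks_with_sample_size(self):
        data = na.gen_dots(na.DotsConfig(lam=2.0, n_trials=400, seed=84))
        obs = na.ObserverParams(model="normative", subjective_hazard=2.0, gain=0.13, seed=85)
        trials = na.observe(data, obs)
        small = na.accuracy_by_duration(trials.iloc[:100], DurationBins(n_bootstrap=200), seed=4)
        large = na.accuracy_by_duration(trials, DurationBins(n_bootstrap=200), seed=4)
        merged = small.merge(large, on=["lam", "coh_level", "bin_left"], suffixes=("_s", "_l"))
        merged = merged[(merged["n_s"] >= 10) & (merged["n_l"] >= 40)]
        assert (merged["boot_se_l"] < merged["boot_se_s"]).mean() > 0.7

    def test_paired_differences_on_shared_samples(self, dots_choices):
        tab, pairs = na.accuracy_by_duration(
            dots_choices, DurationBins(n_bootstrap=200), seed=5, paired=True
        )
        assert {"mean_diff", "p_a_gt_b", "significant"} <= set(pairs.columns)
        assert pairs["p_a_gt_b"].between(0, 1).all()
        # a tie (identical accuracies in both conditions) is never significant
        ties = pairs[pairs["mean_diff"] == 0]
        assert not ties["significant"].any()

    def test_duration_crossing_between_hazard_conditions(self):
        # low coherence: the low-hazard observer is worse than the
        # high-hazard observer shortly after the final reversal (its belief
        # persists) but better at long viewing durations (longer integration)
        parts = []
        for i, (lam, n) in enumerate(((0.1, 1200), (2.0, 4000))):
            data = na.gen_dots(na.DotsConfig(lam=lam, n_trials=n, p_high=0.0, seed=90 + i))
            obs = na.ObserverParams(model="normative", subjective_hazard=lam, gain=0.13, seed=92 + i)
            parts.append(na.observe(data, obs))
        df = pd.concat(parts, ignore_index=True)
        el = df[(df["n_switches"] >= 1) & (df["t_penultimate"] >= 0.3)]
        el = el.assign(correct=(el["choice"] == el["final_dir"]).astype(float))

        def acc(lam, lo, hi):
            s = el[(el["lam"] == lam) & (el["t_since_last_switch"] >= lo) & (el["t_since_last_switch"] < hi)]
            return s["correct"].mean()

        assert acc(0.1, 0.0, 0.5) < acc(2.0, 0.0, 0.5)
        assert acc(0.1, 1.5, 3.0) > acc(2.0, 1.5, 3.0)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            DurationBins(edges=(0.0, 0.5, 0.2))


class TestNormalizedLeakDiff:
    def test_values(self):
        assert na.normalized_leak_diff(0.3, 0.3) == 0.0
        assert na.normalized_leak_diff(0.3, 0.1) == pytest.approx(0.5)

    def test_positive_leaks_required(self):
        with pytest.raises(ValueError):
            na.normalized_leak_diff(-0.1, 0.2)

    def test_leak_grows_with_coherence_on_normative_data(self):
        # the normative filter leaks faster under stronger evidence, so a
        # leaky fit with coherence-split leaks recovers d_coh > 0
        data = na.gen_dots(na.DotsConfig(lam=2.0, n_trials=80, seed=86))
        obs = na.ObserverParams(model="normative", subjective_hazard=2.0, gain=0.13, seed=87)
        trials = na.observe(data, obs)
        res = na.fit_leaky(
            [(trials, data.frames)],
            na.FitSpec(task="dots", model="leaky", leak_layout="hazard_by_coherence",
                       n_restarts=2, seed=88),
        )
        K = res.params["K"][0]
        assert na.normalized_leak_diff(K["high"], K["low"]) > 0
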