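"""Graded response model: probabilities, EM estimation, EAP scores, margins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from latentmed.grm import (
    GRMItem,
    category_probabilities,
    eap_scores,
    fit_grm,
    gauss_hermite_normal,
    two_way_margins,
)
from latentmed.synthetic import sample_grm_responses

#: moderate 3-item bank used for recovery studies
BANK = {
    "item_a": GRMItem(1.5, (-1.0, 0.0, 1.0), "item_a"),
    "item_b": GRMItem(1.2, (-0.8, 0.9), "item_b"),
    "item_c": GRMItem(0.8, (-1.3, 0.2, 1.4), "item_c"),
}


class TestCategoryProbabilities:
    def test_hand_evaluated_logistic_differences(self):
        # K=4, a=1.5, b=(-1,0,1), theta=0: cumulative expit(1.5), expit(0),
        # expit(-1.5) -> differences computed by hand
        item = GRMItem(1.5, (-1.0, 0.0, 1.0))
        p = category_probabilities(0.0, item)
        assert p == pytest.approx([0.182426, 0.317574, 0.317574, 0.182426], abs=1e-6)

    def test_half_probability_at_first_threshold(self):
        item = GRMItem(1.7, (-0.4, 0.8))
        p = category_probabilities(-0.4, item)
        assert p[1:].sum() == pytest.approx(0.5, abs=1e-12)

    def test_sharp_item_concentrates_between_thresholds(self):
        item = GRMItem(200.0, (0.0, 1.0))
        p = category_probabilities(0.5, item)
        assert p[1] > 1.0 - 1e-10

    @given(
        a=st.floats(min_value=0.2, max_value=4.0),
        b1=st.floats(min_value=-2.5, max_value=2.0),
        gap=st.floats(min_value=0.1, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_normalized_nonnegative_on_quadrature_grid(self, a, b1, gap):
        item = GRMItem(a, (b1, b1 + gap))
        nodes, _ = gauss_hermite_normal(61)
        p = category_probabilities(nodes, item)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GRMItem(1.0, (0.5, -0.5))


class TestSampling:
    @pytest.mark.parametrize("a", [0.001, 1.5])
    def test_marginal_frequencies_match_quadrature_oracle(self, a):
        # oracle: marginal category probability integrated over
        # theta ~ N(0,1) by fine quadrature, independent of the sampler
        item = GRMItem(a, (-0.8, 0.5), "it")
        n = 10000
        rng = np.random.default_rng(7)
        theta = rng.standard_normal(n)
        resp = sample_grm_responses(theta, {"it": item}, rng)["it"]
        nodes, w = gauss_hermite_normal(201)
        marginal = w @ category_probabilities(nodes, item)
        for k in range(3):
            freq = (resp == k).mean()
            mc_se = np.sqrt(marginal[k] * (1 - marginal[k]) / n)
            assert abs(freq - marginal[k]) < 2.5 * mc_se + 1e-9

    def test_seed_determinism(self):
        theta = np.linspace(-2, 2, 50)
        r1 = sample_grm_responses(theta, BANK, 99)
        r2 = sample_grm_responses(theta, BANK, 99)
        pd.testing.assert_frame_equal(r1, r2)


def _simulate_bank(n, seed, bank=None):
    bank = bank or BANK
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n)
    return sample_grm_responses(theta, bank, rng)


@pytest.fixture(scope="module")
def fitted():
    resp = _simulate_bank(2000, 314)
    return resp, fit_grm(resp)


class TestFitGRM:
    def test_parameter_recovery_unbiased(self):
        # simulation oracle: over replicates the mean estimate must sit
        # within 3 MC SEs of the generating values
        ests = {name: {"a": [], "b": []} for name in BANK}
        for seed in range(310, 322):
            model = fit_grm(_simulate_bank(2000, seed))
            for item in model.items:
                ests[item.name]["a"].append(item.discrimination)
                ests[item.name]["b"].append(item.thresholds)
        for name, true in BANK.items():
            a = np.asarray(ests[name]["a"])
            mc_se = a.std(ddof=1) / np.sqrt(len(a))
            assert abs(a.mean() - true.discrimination) < 3 * mc_se + 0.02
            b = np.asarray(ests[name]["b"])
            mc_se_b = b.std(ddof=1, axis=0) / np.sqrt(len(b))
            assert np.all(
                np.abs(b.mean(axis=0) - np.asarray(true.thresholds))
                < 3 * mc_se_b + 0.02
            )

    def test_row_permutation_invariance(self, fitted):
        resp, model = fitted
        shuffled = resp.sample(frac=1.0, random_state=1).reset_index(drop=True)
        model2 = fit_grm(shuffled)
        for it1, it2 in zip(model.items, model2.items):
            assert it1.discrimination == pytest.approx(it2.discrimination, abs=1e-4)
            np.testing.assert_allclose(it1.thresholds, it2.thresholds, atol=1e-4)

    def test_duplication_doubles_loglik(self, fitted):
        resp, model = fitted
        doubled = pd.concat([resp, resp], ignore_index=True)
        model2 = fit_grm(doubled)
        assert model2.log_likelihood == pytest.approx(
            2.0 * model.log_likelihood, rel=1e-5
        )
        for it1, it2 in zip(model.items, model2.items):
            assert it1.discrimination == pytest.approx(it2.discrimination, abs=1e-3)

    def test_order_preserving_relabeling_invariance(self, fitted):
        resp, model = fitted
        relabeled = resp * 10 + 3  # 0,1,2,3 -> 3,13,23,33 keeps the order
        model2 = fit_grm(relabeled)
        assert model2.log_likelihood == pytest.approx(model.log_likelihood, abs=1e-5)
        for it1, it2 in zip(model.items, model2.items):
            np.testing.assert_allclose(it1.thresholds, it2.thresholds, atol=1e-5)

    def test_single_observed_category_instructs_collapse(self):
        resp = pd.DataFrame({"a": [0, 1, 0, 1], "b": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="collapse"):
            fit_grm(resp)

    def test_missing_responses_handled(self):
        resp = _simulate_bank(800, 25).astype(float)
        resp.iloc[::7, 0] = np.nan
        model = fit_grm(resp)
        assert model.converged and np.isfinite(model.log_likelihood)


@pytest.fixture(scope="module")
def model_and_resp():
    resp = _simulate_bank(500, 1234)
    return fit_grm(resp), resp


class TestEAPScores:

    def test_all_lowest_pattern_has_minimum_score(self, model_and_resp):
        model, resp = model_and_resp
        lowest = pd.DataFrame(
            {name: [0] for name in resp.columns}, index=[0]
        )
        augmented = pd.concat([resp, lowest], ignore_index=True)
        scores = eap_scores(model, augmented)
        assert scores.eap.iloc[-1] == pytest.approx(scores.eap.min())

    def test_quadrature_matches_adaptive_integration(self, model_and_resp):
        # oracle: adaptive quadrature of the exact posterior integrals
        model, resp = model_and_resp
        scores = eap_scores(model, resp)
        for i in [0, 13, 101]:
            def like(th):
                L = 1.0
                for item in model.items:
                    k = int(resp.iloc[i][item.name])
                    L *= category_probabilities(th, item)[k]
                return L * norm.pdf(th)

            z0, _ = quad(like, -9, 9, limit=200)
            z1, _ = quad(lambda th: th * like(th), -9, 9, limit=200)
            assert scores.eap.iloc[i] == pytest.approx(z1 / z0, abs=1e-6)

    def test_all_missing_scores_missing_and_standardization(self, model_and_resp):
        model, resp = model_and_resp
        resp2 = resp.astype(float).copy()
        resp2.iloc[3] = np.nan
        scores = eap_scores(model, resp2)
        assert np.isnan(scores.eap.iloc[3])
        z = scores.standardized.dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_score_monotone_in_item_response(self, model_and_resp):
        model, _ = model_and_resp
        names = [it.name for it in model.items]
        base = pd.DataFrame({n: [1] for n in names})
        prev = eap_scores(model, base).eap.iloc[0]
        for k in range(1, model.items[0].n_categories):
            pattern = base.copy()
            pattern[names[0]] = k
            cur = eap_scores(model, pattern).eap.iloc[0]
            assert cur >= prev - 1e-12
            prev = cur


class TestTwoWayMargins:
    def test_expected_counts_normalize_and_null_flag_rate(self):
        resp = _simulate_bank(4000, 77)
        model = fit_grm(resp)
        report = two_way_margins(model, resp)
        for (a, b), grp in report.groupby(["item_a", "item_b"]):
            n_pair = len(resp)
            assert grp["expected"].sum() == pytest.approx(n_pair, rel=1e-6)
            assert grp["observed"].sum() == n_pair
        # data generated from (nearly) the fitted model itself: few flags
        assert report["flagged"].mean() < 0.10

    def test_dependence_beyond_one_trait_is_flagged(self):
        # items a and b share a second trait the model does not know about
        # while c and d depend on the main trait only; with four items the
        # single-factor GRM is overidentified, so the margins must misfit
        # (with three items the discriminations could absorb any violation)
        rng = np.random.default_rng(42)
        n = 4000
        theta = rng.standard_normal(n)
        extra = rng.standard_normal(n)
        scale = 1.0 / np.sqrt(2.0)  # keep marginal trait variance 1
        bank4 = dict(BANK)
        bank4["item_d"] = GRMItem(1.0, (-0.5, 0.7), "item_d")
        resp_null = sample_grm_responses(theta, bank4, rng)
        coupled = scale * (theta + extra)
        resp_dep = pd.DataFrame(
            {
                "item_a": sample_grm_responses(
                    coupled, {"item_a": bank4["item_a"]}, rng
                )["item_a"],
                "item_b": sample_grm_responses(
                    coupled, {"item_b": bank4["item_b"]}, rng
                )["item_b"],
                "item_c": sample_grm_responses(
                    theta, {"item_c": bank4["item_c"]}, rng
                )["item_c"],
                "item_d": sample_grm_responses(
                    theta, {"item_d": bank4["item_d"]}, rng
                )["item_d"],
            }
        )
        m_null = fit_grm(resp_null)
        m_dep = fit_grm(resp_dep)
        rep_null = two_way_margins(m_null, resp_null)
        rep_dep = two_way_margins(m_dep, resp_dep)
        assert rep_dep["flagged"].any()
        assert rep_dep["flagged"].mean() > rep_null["flagged"].mean()
        assert rep_dep["residual"].max() > 2.0 * rep_null["residual"].max()
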