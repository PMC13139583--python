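"""Cue kernels, evidence-vs-choice regression, linear decoding, maps."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from seqaccum.maze import Trial, evidence_before, generate_trials
from seqaccum.tuning import BinnedSession
from seqaccum.encoding import (
    cubic_spline_basis,
    evidence_choice_regression,
    fit_cue_kernels,
    fraction_significant,
    linear_evidence_decoder,
    population_average_map,
    population_difference_trace,
    population_response_by_final_evidence,
    map_cross_sections,
    _ols_partial_f,
)


EDGES = np.arange(-30.0, 305.0, 5.0)
CENTERS = 0.5 * (EDGES[:-1] + EDGES[1:])


def make_binned(rates, trials, choices):
    ev = np.stack([np.asarray(evidence_before(t, EDGES[:-1])) for t in trials])
    return BinnedSession(rates=rates, bin_edges=EDGES, evidence=ev,
                        choices=np.asarray(choices), trials=list(trials))


@pytest.fixture(scope="module")
def trials120():
    return generate_trials(120, rng=np.random.default_rng(31))


def majority_choices(trials, rng, lapse=0.15):
    out = []
    for t in trials:
        d = len(t.right_cues) - len(t.left_cues)
        c = "right" if d > 0 else "left"
        if d == 0:
            c = "left" if rng.random() < 0.5 else "right"
        elif rng.random() < lapse:
            c = "left" if c == "right" else "right"
        out.append(c)
    return out


class TestSplineBasis:
    def test_shape_and_partition(self):
        B = cubic_spline_basis(300, 5, 7)
        assert B.shape == (61, 7)
        assert np.allclose(B.sum(axis=1), 1.0)  # clamped B-splines sum to 1

    def test_df_too_small_rejected(self):
        with pytest.raises(ValueError):
            cubic_spline_basis(300, 5, 3)


class TestOlsOracle:
    def test_vectorized_ols_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(80), rng.normal(size=80),
                             rng.integers(0, 2, 80).astype(float)])
        Y = rng.normal(size=(80, 3))
        beta, p = _ols_partial_f(X, Y)
        for j in range(3):
            ref = sm.OLS(Y[:, j], X).fit()
            assert np.allclose(beta[:, j], ref.params)
            # partial F for one coefficient is the squared t; one-sided
            # upper-tail F p-value equals the two-sided t p-value
            assert np.allclose(p[1:, j], ref.pvalues[1:], atol=1e-10)


class TestCueKernels:
    def _traces_from_kernels(self, trials, KL, KR, intercept=0.7):
        n_bins = CENTERS.size
        traces = np.full((len(trials), n_bins), intercept)
        for k, t in enumerate(trials):
            for cues, K in ((t.left_cues, KL), (t.right_cues, KR)):
                for c in cues:
                    ob = int(np.clip(np.searchsorted(CENTERS, c - 10), 0, n_bins - 1))
                    span = min(K.size, n_bins - ob)
                    traces[k, ob:ob + span] += K[:span]
        return traces

    def test_recovers_generator_kernels_within_15_percent(self, trials120):
        rng = np.random.default_rng(2)
        B = cubic_spline_basis(300, 5, 7)
        KL, KR = B @ rng.normal(0, 1, 7), B @ rng.normal(0, 1, 7)
        traces = self._traces_from_kernels(trials120, KL, KR)
        kf = fit_cue_kernels(traces, trials120, CENTERS)[0]
        assert np.linalg.norm(kf.K_L - KL) / np.linalg.norm(KL) < 0.15
        assert np.linalg.norm(kf.K_R - KR) / np.linalg.norm(KR) < 0.15

    def test_step_kernels_recovered_as_sustained_responses(self, trials120):
        # a perfect integrator responds to each cue with a step; the spline
        # fit should recover sustained kernels of opposite sign
        g = 2.0
        KL = np.full(61, -g)
        KR = np.full(61, +g)
        traces = self._traces_from_kernels(trials120, KL, KR)
        kf = fit_cue_kernels(traces, trials120, CENTERS)[0]
        assert kf.K_R[5:-5].mean() == pytest.approx(g, rel=0.1)
        assert kf.K_L[5:-5].mean() == pytest.approx(-g, rel=0.1)

    def test_zero_trace_shrinks_kernels_to_zero(self, trials120):
        traces = np.zeros((len(trials120), CENTERS.size))
        kf = fit_cue_kernels(traces, trials120, CENTERS)[0]
        assert np.abs(kf.K_L).max() < 1e-8 and np.abs(kf.K_R).max() < 1e-8

    def test_symmetric_generator_gives_symmetric_kernels(self, trials120):
        B = cubic_spline_basis(300, 5, 7)
        K = B @ np.array([0.5, 1.0, 1.2, 1.0, 0.9, 0.8, 0.7])
        traces = self._traces_from_kernels(trials120, K, K)
        kf = fit_cue_kernels(traces, trials120, CENTERS)[0]
        assert np.allclose(kf.K_L, kf.K_R, atol=0.05 * np.abs(K).max())

    def test_split_variants_return_one_fit_per_group(self, trials120):
        traces = np.zeros((len(trials120), CENTERS.size))
        by_pos = fit_cue_kernels(traces, trials120, CENTERS, split="position")
        assert {k.group for k in by_pos} == {"early", "middle", "late"}
        by_ev = fit_cue_kernels(traces, trials120, CENTERS, split="evidence")
        assert {k.group for k in by_ev} == {"low", "medium", "high"}


class TestEvidenceChoiceRegression:
    def _fits_all_active(self, n):
        return pd.DataFrame({
            "neuron": np.arange(n), "mu_p": 135.0, "sigma_p": 200.0,
            "mu_e": 1.0, "significant": True,
        })

    def test_null_neurons_false_positive_rate_near_alpha(self, trials120):
        rng = np.random.default_rng(3)
        n = 400
        rates = rng.normal(3.0, 1.0, (n, len(trials120), CENTERS.size))
        binned = make_binned(rates, trials120, majority_choices(trials120, rng))
        res = evidence_choice_regression(binned, self._fits_all_active(n),
                                         position_bins=[40])
        assert res["sig_evidence"].mean() < 0.04
        assert res["sig_choice"].mean() < 0.04

    def test_pure_choice_neuron(self, trials120):
        rng = np.random.default_rng(4)
        choices = majority_choices(trials120, rng)
        c = (np.asarray(choices) == "right").astype(float)
        rates = np.zeros((1, len(trials120), CENTERS.size))
        rates[0] = 2.0 + 3.0 * c[:, None] + rng.normal(0, 0.2, rates[0].shape)
        binned = make_binned(rates, trials120, choices)
        res = evidence_choice_regression(binned, self._fits_all_active(1),
                                         position_bins=[40, 50])
        assert res["sig_choice"].all()
        assert not res["sig_evidence"].any()

    def test_pure_evidence_neuron(self, trials120):
        rng = np.random.default_rng(5)
        choices = majority_choices(trials120, rng, lapse=0.25)
        binned0 = make_binned(np.zeros((1, len(trials120), CENTERS.size)),
                              trials120, choices)
        rates = np.zeros((1, len(trials120), CENTERS.size))
        rates[0] = 2.0 + 0.8 * binned0.evidence + rng.normal(0, 0.2, rates[0].shape)
        binned = make_binned(rates, trials120, choices)
        res = evidence_choice_regression(binned, self._fits_all_active(1),
                                         position_bins=[40, 50])
        assert res["sig_evidence"].all()
        assert not res["sig_choice"].any()

    def test_active_set_respects_position_window(self, trials120):
        rng = np.random.default_rng(6)
        fits = pd.DataFrame({
            "neuron": [0], "mu_p": [50.0], "sigma_p": [20.0], "mu_e": [1.0],
            "significant": [True],
        })
        rates = rng.normal(2, 0.5, (1, len(trials120), CENTERS.size))
        binned = make_binned(rates, trials120, majority_choices(trials120, rng))
        res = evidence_choice_regression(binned, fits)
        assert res["position"].between(30, 70).all()

    def test_requires_both_choices(self, trials120):
        binned = make_binned(np.ones((1, len(trials120), CENTERS.size)),
                             trials120, ["left"] * len(trials120))
        with pytest.raises(ValueError):
            evidence_choice_regression(binned, self._fits_all_active(1))

    def test_fraction_summary(self, trials120):
        rng = np.random.default_rng(7)
        rates = rng.normal(3.0, 1.0, (20, len(trials120), CENTERS.size))
        binned = make_binned(rates, trials120, majority_choices(trials120, rng))
        res = evidence_choice_regression(binned, self._fits_all_active(20),
                                         position_bins=[30])
        frac = fraction_significant(res)
        assert set(frac.columns) >= {"frac_evidence", "frac_choice"}
        assert ((0 <= frac["frac_evidence"]) & (frac["frac_evidence"] <= 1)).all()


class TestLinearDecoder:
    def _fits(self, n):
        return pd.DataFrame({
            "neuron": np.arange(n), "mu_p": 135.0, "sigma_p": 200.0,
            "mu_e": 1.0, "significant": True,
        })

    def test_linear_population_decodes_and_shuffle_does_not(self, trials120):
        rng = np.random.default_rng(8)
        n = 12
        gains = rng.uniform(0.5, 1.5, n)
        binned0 = make_binned(np.zeros((n, len(trials120), CENTERS.size)),
                              trials120, majority_choices(trials120, rng, 0.0))
        rates = gains[:, None, None] * binned0.evidence[None] + rng.normal(
            0, 0.15, (n, len(trials120), CENTERS.size)
        )
        binned = make_binned(rates, trials120,
                             majority_choices(trials120, rng, 0.0))
        res = linear_evidence_decoder(binned, self._fits(n),
                                      position_bins=[45, 55], rng=rng)
        ok = res.dropna(subset=["correlation"])
        assert (ok["correlation"] > 0.95).all()
        assert (ok["shuffle_correlation"].abs() < 0.35).all()

    def test_sign_only_population_fails_strict_branches(self, trials120):
        # rate = sgn(e): within a strict sign branch there is nothing to
        # decode, ruling out binary sign-of-evidence shortcuts
        rng = np.random.default_rng(9)
        n = 8
        binned0 = make_binned(np.zeros((n, len(trials120), CENTERS.size)),
                              trials120, majority_choices(trials120, rng, 0.0))
        rates = np.sign(binned0.evidence)[None] * np.ones((n, 1, 1)) + rng.normal(
            0, 0.05, (n, len(trials120), CENTERS.size)
        )
        binned = make_binned(rates, trials120,
                             majority_choices(trials120, rng, 0.0))
        res = linear_evidence_decoder(binned, self._fits(n), strict=True,
                                      position_bins=[45, 55], rng=rng)
        ok = res.dropna(subset=["correlation"])
        assert (ok["correlation"].abs() < 0.45).all()

    def test_degenerate_constant_neuron_flagged(self, trials120):
        rng = np.random.default_rng(10)
        rates = np.full((1, len(trials120), CENTERS.size), 2.0)
        binned = make_binned(rates, trials120,
                             majority_choices(trials120, rng, 0.0))
        res = linear_evidence_decoder(binned, self._fits(1),
                                      position_bins=[2], rng=rng)
        # precue bin: evidence is identically zero -> no variance to decode
        assert res["correlation"].isna().all()


class TestPopulationAnalyses:
    def _tuned_session(self, trials, rng, flip=False):
        n = 8
        binned0 = make_binned(np.zeros((n, len(trials), CENTERS.size)),
                              trials, majority_choices(trials, rng, 0.1))
        ev = binned0.evidence
        rates = np.empty((n, len(trials), CENTERS.size))
        mu_es = []
        for u in range(n):
            mu_e = (-1) ** u * rng.uniform(3, 8) * (-1 if flip else 1)
            mu_es.append(mu_e)
            rates[u] = 2 + 2 * np.exp(-(ev - mu_e) ** 2 / 18.0)
        binned = make_binned(rates, trials, binned0.choices)
        fits = pd.DataFrame({
            "neuron": np.arange(n), "mu_p": 150.0, "sigma_p": 200.0,
            "mu_e": mu_es, "sigma_p_": 0, "significant": True,
        })
        return binned, fits

    def test_difference_trace_negates_under_mirror(self, trials120):
        # mirroring the population keeps every rate trace but flips each
        # neuron's evidence preference, so the R-minus-L trace negates
        binned, fits = self._tuned_session(trials120, np.random.default_rng(12))
        mirrored = fits.assign(mu_e=-fits["mu_e"])
        d1 = population_difference_trace(binned, fits)
        d2 = population_difference_trace(binned, mirrored)
        assert np.allclose(np.nan_to_num(d1), -np.nan_to_num(d2))

    def test_identical_populations_give_zero_trace(self, trials120):
        rng = np.random.default_rng(13)
        rates = np.tile(np.linspace(1, 2, CENTERS.size), (2, len(trials120), 1))
        binned = make_binned(rates, trials120, majority_choices(trials120, rng))
        fits = pd.DataFrame({
            "neuron": [0, 1], "mu_p": 150.0, "sigma_p": 200.0,
            "mu_e": [4.0, -4.0], "significant": True,
        })
        assert np.allclose(population_difference_trace(binned, fits), 0.0)

    def test_population_map_reflects_left_preferring(self, trials120):
        rng = np.random.default_rng(14)
        binned, fits = self._tuned_session(trials120, rng)
        pm = population_average_map([(binned, fits)])
        cs = map_cross_sections(pm, [150.0])
        # evidence-tuned neurons remapped to preferred evidence: the map's
        # cross-section rises toward positive preferred evidence
        vals = cs.dropna()
        lo = vals[vals["preferred_evidence"] < -5]["rate"].mean()
        hi = vals[vals["preferred_evidence"] > 5]["rate"].mean()
        assert hi > lo

    def test_band_traces_exist_and_empty_band_flagged(self, trials120):
        rng = np.random.default_rng(15)
        binned, fits = self._tuned_session(trials120, rng)
        enc = evidence_choice_regression(binned, fits, position_bins=[40, 45])
        bands = population_response_by_final_evidence(
            binned, fits, enc,
            bands={"low": (1, 3), "impossible": (40, 50)},
        )
        assert set(bands["band"]) == {"low", "impossible"}
        assert bands[bands["band"] == "impossible"]["difference"].isna().all()
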