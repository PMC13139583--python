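"""Binning, joint position x evidence fits, pseudosession significance,
normalization, 1-D tuning curves, and sequence matrices."""

import numpy as np
import pandas as pd
import pytest

from seqaccum.maze import Trial, evidence_before, generate_trials
from seqaccum.tuning import (
    TuningFit,
    bin_session,
    joint_fit,
    normalize_evidence_params,
    pseudosession_significance,
    sequence_matrix,
    tuning_curve_1d,
    fit_session,
    BinnedSession,
)


@pytest.fixture(scope="module")
def task_grid():
    rng = np.random.default_rng(21)
    trials = generate_trials(120, rng=rng)
    edges = np.arange(-30.0, 305.0, 5.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ev = np.stack([np.asarray(evidence_before(t, edges[:-1])) for t in trials])
    P = np.broadcast_to(centers, ev.shape)
    return trials, centers, ev.astype(float), P


class TestBinSession:
    def test_evidence_boundary_rule(self):
        # a cue at 3 cm counts for the bin starting at 5 cm, not [0, 5)
        t = Trial(right_cues=(3.0,), trial_id=0)
        rates = np.ones((1, 100))
        pos = np.linspace(-30, 299.9, 100)
        binned = bin_session(rates, pos, np.zeros(100, int), [t], ["right"])
        b0 = np.searchsorted(binned.bin_edges, 0.0, "right") - 1
        assert binned.evidence[0, b0] == 0
        assert binned.evidence[0, b0 + 1] == 1

    def test_constant_neuron_all_bins_equal(self):
        t = Trial(trial_id=0)
        pos = np.linspace(-30, 299.9, 660)
        binned = bin_session(np.full((1, 660), 4.0), pos, np.zeros(660, int),
                             [t], ["left"])
        assert np.nanmax(binned.rates) == pytest.approx(4.0)
        assert np.nanmin(binned.rates) == pytest.approx(4.0)

    def test_unvisited_bins_are_missing(self):
        t = Trial(trial_id=0)
        pos = np.linspace(-30, 100, 300)  # never reaches the delay region
        binned = bin_session(np.ones((1, 300)), pos, np.zeros(300, int),
                             [t], ["left"])
        assert np.isnan(binned.rates[0, 0, -1])


class TestJointFit:
    def test_recovers_noiseless_separable_neuron(self, task_grid):
        trials, centers, ev, P = task_grid
        r = 5 * np.exp(-(P - 150) ** 2 / (2 * 30**2)) * np.exp(
            -(ev - 5) ** 2 / (2 * 4**2)
        ) + 0.5
        fit = joint_fit(r.ravel(), P.ravel(), ev.ravel())
        assert fit.mu_p == pytest.approx(150, abs=5)
        assert fit.mu_e == pytest.approx(5, abs=0.5)
        assert fit.sigma_e == pytest.approx(4, abs=1)
        assert fit.eligible

    def test_monotone_neuron_peaks_at_observed_extreme(self, task_grid):
        trials, centers, ev, P = task_grid
        # gentle logistic ramp: best Gaussian peak sits at/beyond the
        # extreme of the evidence range observed near the position peak
        r = (1.0 / (1 + np.exp(-0.2 * ev))) * np.exp(-(P - 150) ** 2 / (2 * 40**2))
        fit = joint_fit(r.ravel(), P.ravel(), ev.ravel())
        near = np.abs(P.ravel() - fit.mu_p) <= 5.0
        e_hi = ev.ravel()[near].max()
        assert fit.mu_e >= 0.8 * e_hi

    def test_constant_neuron_zero_amplitude(self, task_grid):
        trials, centers, ev, P = task_grid
        fit = joint_fit(np.full(P.size, 3.3), P.ravel(), ev.ravel())
        assert fit.amp == 0.0 and fit.mse == 0.0

    def test_respects_printed_bounds(self, task_grid):
        trials, centers, ev, P = task_grid
        rng = np.random.default_rng(5)
        for _ in range(5):
            r = rng.normal(1.0, 0.5, P.shape)
            f = joint_fit(r.ravel(), P.ravel(), ev.ravel())
            assert -50 <= f.mu_p <= 350 and 0 <= f.sigma_p <= 200
            assert 0 <= f.sigma_e <= 30 and 0 <= f.amp <= 10 and 0 <= f.offset <= 1

    def test_recovery_error_shrinks_with_noise(self, task_grid):
        trials, centers, ev, P = task_grid
        rng = np.random.default_rng(6)
        errs = []
        for sd in (1.0, 0.3, 0.0):
            err = []
            for _ in range(4):
                r = 5 * np.exp(-(P - 120) ** 2 / (2 * 35**2)) * np.exp(
                    -(ev + 4) ** 2 / (2 * 3**2)
                ) + 0.5 + rng.normal(0, sd, P.shape)
                f = joint_fit(r.ravel(), P.ravel(), ev.ravel())
                err.append(abs(f.mu_e + 4))
            errs.append(np.mean(err))
        assert errs[2] <= errs[1] <= errs[0] + 0.15


class TestPseudosession:
    def test_zero_pseudosessions_rejected(self):
        with pytest.raises(ValueError):
            pseudosession_significance(1.0, [])

    def test_rank_method_detects_tuned_and_spares_null(self):
        sig, p = pseudosession_significance(0.1, np.linspace(0.5, 1.0, 30))
        assert sig and p == pytest.approx(1 / 31)
        sig2, p2 = pseudosession_significance(0.7, np.linspace(0.5, 1.0, 30))
        assert not sig2

    def test_ttest_variant_directional(self):
        null = np.linspace(0.5, 1.0, 30)
        sig, _ = pseudosession_significance(0.1, null, method="ttest")
        assert sig
        sig2, _ = pseudosession_significance(5.0, null, method="ttest")
        assert not sig2

    def test_strongly_tuned_neuron_significant(self, task_grid):
        trials, centers, ev, P = task_grid
        rng = np.random.default_rng(7)
        r = 5 * np.exp(-(P - 100) ** 2 / (2 * 30**2)) * np.exp(
            -(ev - 4) ** 2 / (2 * 3**2)
        ) + rng.normal(0, 0.2, P.shape)
        choices = ["right" if len(t.right_cues) > len(t.left_cues) else "left"
                   for t in trials]
        edges = np.arange(-30.0, 305.0, 5.0)
        binned = BinnedSession(
            rates=r[None, :, :], bin_edges=edges, evidence=ev.astype(int),
            choices=np.array(choices), trials=list(trials),
        )
        fits = fit_session(binned, n_pseudo=25, rng=np.random.default_rng(8))
        assert bool(fits.loc[0, "significant"])


class TestNormalization:
    @pytest.mark.parametrize(
        "mu_e,expected",
        [(-6.0, -0.5), (8.0, 1.0), (0.0, 0.0)],
    )
    def test_mu_e_normalization(self, mu_e, expected):
        ev = np.r_[np.arange(-12, 0), np.arange(1, 9)]
        mu_n, _ = normalize_evidence_params(mu_e, 5.0, ev)
        assert mu_n == pytest.approx(expected)

    def test_sigma_normalized_by_range(self):
        ev = np.arange(-8, 13)  # range 20
        _, s = normalize_evidence_params(2.0, 5.0, ev)
        assert s == pytest.approx(0.25)

    def test_empty_branch_is_nan(self):
        mu_n, _ = normalize_evidence_params(-3.0, 5.0, np.arange(0, 10))
        assert np.isnan(mu_n)


class TestTuningCurve1D:
    def _binned(self, task_grid, rates):
        trials, centers, ev, P = task_grid
        edges = np.arange(-30.0, 305.0, 5.0)
        choices = ["right" if len(t.right_cues) > len(t.left_cues) else "left"
                   for t in trials]
        return BinnedSession(
            rates=rates[None, :, :], bin_edges=edges, evidence=ev.astype(int),
            choices=np.array(choices), trials=list(trials),
        )

    def test_step_neuron_prefers_logistic(self, task_grid):
        trials, centers, ev, P = task_grid
        r = np.where(ev > 0, 1.0, 0.0) * np.exp(-(P - 150) ** 2 / (2 * 50**2))
        binned = self._binned(task_grid, r)
        fit = TuningFit(mu_p=150, sigma_p=100, mu_e=5, sigma_e=5, amp=1,
                        offset=0, mse=0)
        out = tuning_curve_1d(binned, 0, fit)
        assert out["form"] == "logistic"
        assert abs(out["params"][1]) > 0.4  # steep slope

    def test_gaussian_bump_neuron_prefers_gaussian(self, task_grid):
        trials, centers, ev, P = task_grid
        r = np.exp(-(ev - 2) ** 2 / (2 * 2.0**2)) * np.exp(
            -(P - 150) ** 2 / (2 * 50**2)
        )
        binned = self._binned(task_grid, r)
        fit = TuningFit(mu_p=150, sigma_p=100, mu_e=2, sigma_e=2, amp=1,
                        offset=0, mse=0)
        out = tuning_curve_1d(binned, 0, fit)
        assert out["form"] == "gaussian"
        assert out["params"][1] == pytest.approx(2.0, abs=1.0)


class TestSequenceMatrix:
    def test_single_neuron_matrix(self, task_grid):
        trials, centers, ev, P = task_grid
        r = np.exp(-(P - 100) ** 2 / (2 * 30**2))
        edges = np.arange(-30.0, 305.0, 5.0)
        choices = ["right" if len(t.right_cues) > len(t.left_cues) else "left"
                   for t in trials]
        binned = BinnedSession(
            rates=r[None, :, :], bin_edges=edges, evidence=ev.astype(int),
            choices=np.array(choices), trials=list(trials),
        )
        fits = pd.DataFrame(
            [{"neuron": 0, "mu_p": 100.0, "sigma_p": 30.0, "mu_e": 1.0,
              "significant": True, "preference": "right"}]
        )
        out = sequence_matrix(binned, fits)
        assert out["left_choice"].shape[0] == 1
        peak = max(np.nanmax(out["left_choice"]), np.nanmax(out["right_choice"]))
        assert peak == pytest.approx(1.0)

    def test_chain_session_forms_two_choice_selective_diagonals(self, chain_session):
        binned, fits = chain_session
        out = sequence_matrix(binned, fits)
        n_left = (fits[fits["significant"]]["preference"] == "left").sum()
        left_rows = out["left_choice"][:n_left]   # left-preferring neurons
        right_rows = out["right_choice"][n_left:]
        # each chain is more active on its preferred side
        assert np.nanmean(left_rows) > np.nanmean(out["right_choice"][:n_left])
        assert np.nanmean(right_rows) > np.nanmean(out["left_choice"][n_left:])
        # peak positions advance along the sorted rows (sequence structure)
        peaks = [np.nanargmax(row) for row in left_rows]
        assert np.corrcoef(np.arange(len(peaks)), peaks)[0, 1] > 0.9
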