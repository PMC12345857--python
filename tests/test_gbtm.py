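"""Trajectory mixture model: likelihood oracles, EM behaviour, curves."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm

from adhertraj import gbtm, synthetic
from adhertraj.gbtm import DegenerateFitWarning, IdentifiabilityError


def naive_mixture_loglik(beta, pi, panel):
    """Direct product-and-sum evaluation, no log-sum-exp, no vectorisation."""
    total = 0.0
    for y in panel:
        mix = 0.0
        for b, p_g in zip(beta, pi):
            lik = 1.0
            for t, yt in enumerate(y, start=1):
                p = 1.0 / (1.0 + math.exp(-(sum(bk * t**k for k, bk in enumerate(b)))))
                lik *= p if yt else (1.0 - p)
            mix += p_g * lik
        total += math.log(mix)
    return total


def naive_posterior(beta, pi, panel):
    out = []
    for y in panel:
        liks = []
        for b in beta:
            lik = 1.0
            for t, yt in enumerate(y, start=1):
                p = 1.0 / (1.0 + math.exp(-(sum(bk * t**k for k, bk in enumerate(b)))))
                lik *= p if yt else (1.0 - p)
            liks.append(lik)
        num = [pg * l for pg, l in zip(pi, liks)]
        s = sum(num)
        out.append([v / s for v in num])
    return np.array(out)


class TestLogLikelihood:
    def test_constant_half_probability(self):
        panel = np.random.default_rng(0).integers(0, 2, (7, 12)).astype(float)
        got = gbtm.log_likelihood([[0.0, 0.0, 0.0]], [1.0], panel)
        assert got == pytest.approx(7 * 12 * math.log(0.5), rel=1e-12)

    def test_mixture_of_identical_groups_collapses(self):
        panel = np.random.default_rng(1).integers(0, 2, (9, 12)).astype(float)
        beta = [1.0, -0.2, 0.01]
        one = gbtm.log_likelihood([beta], [1.0], panel)
        two = gbtm.log_likelihood([beta, beta], [0.5, 0.5], panel)
        assert two == pytest.approx(one, rel=1e-12)

    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(2)
        panel = rng.integers(0, 2, (5, 4)).astype(float)
        beta = [[0.5, -0.1], [-1.0, 0.3]]
        pi = [0.3, 0.7]
        got = gbtm.log_likelihood(beta, pi, panel)
        assert got == pytest.approx(naive_mixture_loglik(beta, pi, panel), rel=1e-12)

    def test_short_panel_raises_identifiability_error(self):
        with pytest.raises(IdentifiabilityError):
            gbtm.log_likelihood([[0.0, 0.0, 0.0, 0.0]], [1.0], np.zeros((3, 3)))

    def test_non_binary_panel_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            gbtm.log_likelihood([[0.0]], [1.0], np.full((2, 4), 0.5))


class TestPosterior:
    def _model(self, beta, pi, order):
        beta = np.asarray(beta, dtype=float)
        pi = np.asarray(pi, dtype=float)
        return gbtm.TrajectoryModel(
            n_groups=len(pi), order=order, beta=beta,
            theta=np.log(pi[1:] / pi[0]), pi=pi, loglik=0.0, n_params=1,
            bic=0.0, bic_nagin=0.0, n_subjects=0, converged=True, n_starts_used=0,
        )

    def test_identical_groups_return_prior(self):
        panel = np.random.default_rng(3).integers(0, 2, (6, 8)).astype(float)
        model = self._model([[0.4, 0.0], [0.4, 0.0]], [0.3, 0.7], order=1)
        post = gbtm.posterior(model, panel)
        assert np.allclose(post, [0.3, 0.7])

    def test_perfect_separation_gives_degenerate_posteriors(self):
        panel = np.vstack([np.ones((4, 12)), np.zeros((4, 12))])
        model = self._model([[10.0, 0.0], [-10.0, 0.0]], [0.5, 0.5], order=1)
        post = gbtm.posterior(model, panel)
        assert np.allclose(post[:4, 0], 1.0, atol=1e-8)
        assert np.allclose(post[4:, 1], 1.0, atol=1e-8)

    def test_matches_naive_bayes_rule(self):
        rng = np.random.default_rng(4)
        panel = rng.integers(0, 2, (8, 5)).astype(float)
        beta = [[0.2, 0.1], [-0.5, 0.05], [1.0, -0.3]]
        pi = [0.2, 0.3, 0.5]
        model = self._model(beta, pi, order=1)
        got = gbtm.posterior(model, panel)
        assert np.allclose(got, naive_posterior(beta, pi, panel), atol=1e-12)
        assert np.allclose(got.sum(axis=1), 1.0, atol=1e-10)


class TestFit:
    def test_separable_two_group_panel(self):
        panel = np.vstack([np.ones((50, 12)), np.zeros((50, 12))])
        model = gbtm.fit(panel, n_groups=2, order=2, n_starts=3, seed=0)
        assert np.allclose(np.sort(model.pi), [0.5, 0.5], atol=1e-6)
        t = np.arange(1, 13)
        assert (gbtm.predicted_curve(model, 0, t) > 0.99).all()
        assert (gbtm.predicted_curve(model, 1, t) < 0.01).all()
        assert np.abs(model.beta).max() <= gbtm.BETA_CAP + 1e-9

    def test_single_group_reduces_to_glm(self):
        rng = np.random.default_rng(5)
        panel = (rng.random((60, 12)) < 0.55).astype(float)
        model = gbtm.fit(panel, n_groups=1, order=2, n_starts=1, seed=0)
        X = np.tile(gbtm.time_design(12, 2), (60, 1))
        glm = sm.GLM(panel.ravel(), X, family=sm.families.Binomial()).fit()
        assert np.allclose(model.beta[0], glm.params, atol=1e-6)

    def test_em_loglik_is_monotone(self):
        spec = synthetic.CohortSpec(n_patients=120, seed=31)
        cohort = synthetic.sample_cohort(spec, include_fills=False)
        model = gbtm.fit(
            cohort.monthly_binary.astype(float), 3, order=2, n_starts=3, seed=1,
        )
        diffs = np.diff(model.loglik_history)
        assert (diffs >= -1e-8).all()

    def test_three_group_parameter_recovery(self):
        spec = synthetic.CohortSpec(seed=77)
        cohort = synthetic.sample_cohort(spec, include_fills=False)
        model = gbtm.fit(cohort.monthly_binary.astype(float), 3, 2, n_starts=5, seed=2)
        realized = np.bincount(cohort.true_group, minlength=3) / spec.n_patients
        assert np.abs(model.pi - realized).max() < 0.05
        # group-mean adherence curves close to the generating curves
        t = np.arange(1, 13)
        for g, gs in enumerate(spec.group_specs):
            truth = synthetic.trajectory_probability(gs.beta, t)
            fitted = gbtm.predicted_curve(model, g, t)
            assert np.abs(fitted - truth).max() < 0.1

    def test_nesting_more_groups_never_fit_worse(self):
        spec = synthetic.CohortSpec(n_patients=150, seed=41)
        panel = synthetic.sample_cohort(spec, include_fills=False).monthly_binary.astype(float)
        lls = [
            gbtm.fit(panel, g, 2, n_starts=4, seed=3).loglik for g in (1, 2, 3)
        ]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_same_seed_refit_is_identical_and_subject_order_irrelevant(self):
        spec = synthetic.CohortSpec(n_patients=100, seed=51)
        panel = synthetic.sample_cohort(spec, include_fills=False).monthly_binary.astype(float)
        a = gbtm.fit(panel, 2, 2, n_starts=4, seed=9)
        b = gbtm.fit(panel, 2, 2, n_starts=4, seed=9)
        assert np.array_equal(a.beta, b.beta) and np.array_equal(a.pi, b.pi)
        perm = np.random.default_rng(0).permutation(100)
        c = gbtm.fit(panel[perm], 2, 2, n_starts=4, seed=9)
        assert np.allclose(a.beta, c.beta, atol=1e-4)
        assert np.allclose(a.pi, c.pi, atol=1e-4)
        assert a.loglik == pytest.approx(c.loglik, abs=1e-6)

    def test_canonical_order_is_descending_adherence(self):
        spec = synthetic.CohortSpec(seed=61)
        panel = synthetic.sample_cohort(spec, include_fills=False).monthly_binary.astype(float)
        model = gbtm.fit(panel, 3, 2, n_starts=4, seed=4)
        t = np.arange(1, 13)
        means = [gbtm.predicted_curve(model, g, t).mean() for g in range(3)]
        assert means == sorted(means, reverse=True)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            gbtm.fit(np.ones((2, 12)), n_groups=3)


class TestCurves:
    def test_flat_curve_at_zero_beta(self):
        model = gbtm.fit(np.ones((5, 12)), 1, order=2, n_starts=1, seed=0)
        flat = gbtm.TrajectoryModel(
            n_groups=1, order=2, beta=np.zeros((1, 3)), theta=np.array([]),
            pi=np.array([1.0]), loglik=0, n_params=1, bic=0, bic_nagin=0,
            n_subjects=5, converged=True, n_starts_used=1,
        )
        assert np.allclose(gbtm.predicted_curve(flat, 0, np.arange(1, 13)), 0.5)

    def test_negative_quadratic_is_unimodal(self):
        model = gbtm.TrajectoryModel(
            n_groups=1, order=2, beta=np.array([[0.0, 1.0, -0.1]]),
            theta=np.array([]), pi=np.array([1.0]), loglik=0, n_params=1,
            bic=0, bic_nagin=0, n_subjects=1, converged=True, n_starts_used=1,
        )
        grid = np.linspace(1, 12, 400)
        curve = gbtm.predicted_curve(model, 0, grid)
        peak = curve.argmax()
        assert 0 < peak < len(grid) - 1
        assert (np.diff(curve[: peak + 1]) > 0).all()
        assert (np.diff(curve[peak:]) < 0).all()

    def test_curve_matches_generator_probability_at_integer_times(self):
        beta = np.array([[1.2, -0.3, 0.02]])
        model = gbtm.TrajectoryModel(
            n_groups=1, order=2, beta=beta, theta=np.array([]),
            pi=np.array([1.0]), loglik=0, n_params=1, bic=0, bic_nagin=0,
            n_subjects=1, converged=True, n_starts_used=1,
        )
        t = np.arange(1, 13)
        assert np.allclose(
            gbtm.predicted_curve(model, 0, t),
            synthetic.trajectory_probability(beta[0], t),
        )

    def test_observed_curve_hand_computed_fixture(self):
        panel = np.array(
            [
                [1, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1],  # group 0
                [0, 0, 1, 0], [0, 0, 0, 0], [1, 0, 0, 0],  # group 1
            ],
            dtype=float,
        )
        assignments = np.array([0, 0, 0, 1, 1, 1])
        obs = gbtm.observed_curve(panel, assignments, 2)
        assert np.allclose(obs[0], [1.0, 2 / 3, 2 / 3, 1.0])
        assert np.allclose(obs[1], [1 / 3, 0.0, 1 / 3, 0.0])

    def test_observed_curve_flags_empty_group(self):
        panel = np.ones((3, 4))
        with pytest.warns(DegenerateFitWarning):
            obs = gbtm.observed_curve(panel, np.zeros(3, int), n_groups=2)
        assert np.isnan(obs[1]).all()


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path):
        model = gbtm.fit(
            np.vstack([np.ones((5, 12)), np.zeros((5, 12))]), 2, 2,
            n_starts=2, seed=0,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = gbtm.TrajectoryModel.from_json(path)
        assert np.allclose(back.beta, model.beta)
        assert np.allclose(back.pi, model.pi)
        assert back.bic == pytest.approx(model.bic)
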