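"""Closed-form layer versus independent oracles (urn enumeration, ODE
integration, Monte Carlo) and its internal identities."""

import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import dirichlet as scipy_dirichlet, kstest

import conseed as cs
from conseed import DetectionSpec, SeedingModel
from conseed.analytic import (
    CloneSizeLaw,
    CompositionLaw,
    clone_size_law,
    clone_size_pmf,
    composition_logpdf,
    monoclonality_boundary_influx,
    threshold_polyclonality_probability,
)


def scaled_model(ks):
    return SeedingModel.from_scaled(list(ks), survival_prob=0.05,
                                    net_growth=0.0125)


# ---------------------------------------------------------------------------
# mean clone size


class TestMeanCloneSize:
    def test_zero_time(self, fig2_model):
        assert cs.mean_clone_size(fig2_model, 0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "ki,rho,exp_rt,expected",
        [(0.05, 0.05, 2.0, 1.0), (0.02, 0.05, 101.0, 40.0)],
    )
    def test_against_ode_oracle(self, ki, rho, exp_rt, expected):
        """ybar solves ybar' = r ybar + lambda_i from 0."""
        r = 0.0125
        b = r / rho
        m = SeedingModel.from_scaled([ki], rho, r)
        t_end = np.log(exp_rt) / r
        sol = solve_ivp(
            lambda t, y: r * y + ki * b, (0.0, t_end), [0.0],
            rtol=1e-10, atol=1e-12,
        )
        assert cs.mean_clone_size(m, 0, t_end) == pytest.approx(expected, rel=1e-6)
        assert cs.mean_clone_size(m, 0, t_end) == pytest.approx(
            sol.y[0, -1], rel=1e-6
        )

    def test_monotone_in_time(self, fig2_model):
        t = np.linspace(0, 500, 50)
        y = cs.mean_clone_size(fig2_model, 2, t)
        assert np.all(np.diff(y) > 0)

    def test_negative_time_rejected(self, fig2_model):
        with pytest.raises(ValueError):
            cs.mean_clone_size(fig2_model, 0, -1.0)


class TestCloneSizePmf:
    def test_zero_class_is_q_to_shape(self):
        law = CloneSizeLaw(shape=0.3, q=0.2)
        assert clone_size_pmf(law, 0) == pytest.approx(0.2**0.3, rel=1e-12)

    def test_shape_one_is_geometric(self):
        law = CloneSizeLaw(shape=1.0, q=0.25)
        y = np.arange(50)
        np.testing.assert_allclose(
            clone_size_pmf(law, y), 0.25 * 0.75**y, rtol=1e-12
        )

    def test_normalizes_and_matches_mean(self, fig2_model):
        t = 400.0
        law = clone_size_law(fig2_model, 1, t)
        y = np.arange(0, 200_000)
        p = clone_size_pmf(law, y)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p * y).sum() == pytest.approx(
            cs.mean_clone_size(fig2_model, 1, t), rel=1e-6
        )
        assert law.mean_size == pytest.approx(
            law.shape * (1 - law.q) / law.q, rel=1e-9
        )


# ---------------------------------------------------------------------------
# urn layer


class TestDetectedComposition:
    def test_single_clone_is_certain(self):
        m = scaled_model([0.7])
        assert cs.detected_composition_pmf(m, [5]) == pytest.approx(1.0, rel=1e-12)

    def test_uniform_for_unit_influxes(self):
        m = scaled_model([1.0, 1.0])
        for y1 in range(11):
            assert cs.detected_composition_pmf(m, [y1, 10 - y1]) == pytest.approx(
                1 / 11, rel=1e-12
            )

    def test_small_grid_matches_urn_enumeration(self, urn):
        for ks in [(0.5, 2.0), (1.0, 1.0), (0.5, 1.0, 2.0)]:
            total = 6
            probs = urn.composition_probs(ks, total)
            m = scaled_model(ks)
            for counts, p in probs.items():
                assert cs.detected_composition_pmf(m, list(counts)) == pytest.approx(
                    p, abs=1e-12
                )

    def test_wrong_total_rejected(self):
        m = scaled_model([1.0, 1.0])
        with pytest.raises(ValueError):
            cs.detected_composition_pmf(m, [1.5, 0.5])
        with pytest.raises(ValueError):
            cs.detected_composition_pmf(m, [-1, 3])


class TestCloneNumberAndPolyclonality:
    def test_one_cell_one_clone(self, fig2_model):
        spec = DetectionSpec(1)
        assert cs.mean_num_clones(fig2_model, spec) == pytest.approx(1.0, abs=1e-12)
        assert cs.polyclonality_probability(fig2_model, spec) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_unit_clones_two_cells(self):
        m = scaled_model([1.0, 1.0])
        spec = DetectionSpec(2)
        assert cs.mean_num_clones(m, spec) == pytest.approx(4 / 3, rel=1e-12)
        assert cs.polyclonality_probability(m, spec) == pytest.approx(1 / 3, rel=1e-12)

    def test_saturation_limit(self):
        m = scaled_model([400.0, 400.0])
        spec = DetectionSpec(10**6)
        assert cs.mean_num_clones(m, spec) == pytest.approx(2.0, abs=1e-3)

    def test_single_clone_never_polyclonal(self):
        m = scaled_model([2.0])
        assert cs.polyclonality_probability(m, DetectionSpec(10**8)) == 0.0

    def test_matches_urn_enumeration(self, urn):
        for ks, total in itertools.product(
            [(0.5, 0.5), (1.0, 2.0), (0.5, 1.0, 2.0)], [1, 3, 7]
        ):
            m = scaled_model(ks)
            spec = DetectionSpec(total)
            assert cs.mean_num_clones(m, spec) == pytest.approx(
                urn.mean_clones(ks, total), abs=1e-12
            )
            assert cs.polyclonality_probability(m, spec) == pytest.approx(
                urn.polyclonal_prob(ks, total), abs=1e-12
            )

    def test_monotone_in_detect_size_and_influx(self):
        """P(polyclonal) never decreases with Y, nor when all influxes are
        scaled up together."""
        for k1, k2 in [(0.05, 0.1), (0.5, 1.0), (2.0, 4.0)]:
            probs = [
                cs.polyclonality_probability(scaled_model([k1, k2]), DetectionSpec(y))
                for y in [10, 10**3, 10**5, 10**7, 10**9]
            ]
            assert np.all(np.diff(probs) >= -1e-14)
        # monotone under uniform scaling of all influxes (raising a single
        # clone's influx is NOT monotone: a dominant clone suppresses
        # polyclonality)
        for y in [100, 10**6]:
            probs = [
                cs.polyclonality_probability(
                    scaled_model([c * 1.0, c * 0.3]), DetectionSpec(y)
                )
                for c in [0.01, 0.1, 1.0, 10.0]
            ]
            assert np.all(np.diff(probs) >= -1e-14)

    def test_huge_detect_size_is_finite(self):
        m = scaled_model([0.02, 0.03, 0.05])
        p = cs.polyclonality_probability(m, DetectionSpec(10**9))
        assert 0.0 < p < 1.0


class TestSmallKApproximation:
    def test_vanishing_influx(self):
        assert cs.polyclonality_small_k_approx(1e-12, 3, 10**8) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_close_to_exact_formula(self):
        k, n, y = 0.1, 2, 10**8
        m = scaled_model([k / n] * n)
        exact = cs.polyclonality_probability(m, DetectionSpec(y))
        approx = cs.polyclonality_small_k_approx(k, n, y)
        assert approx == pytest.approx(exact, abs=0.01)

    def test_boundary_influx_splits_even(self):
        y = 10**8
        kappa = monoclonality_boundary_influx(y)
        n = 2
        k = kappa / (1 - 1 / n)
        assert cs.polyclonality_small_k_approx(k, n, y) == pytest.approx(0.5, abs=0.02)

    def test_warns_outside_validity(self):
        with pytest.warns(RuntimeWarning, match="k << N"):
            cs.polyclonality_small_k_approx(5.0, 3, 10**6)


# ---------------------------------------------------------------------------
# composition law and diversity


class TestCompositionLaw:
    def test_uniform_density_for_unit_influxes(self):
        law = CompositionLaw(np.array([1.0, 1.0]))
        for g in [0.1, 0.5, 0.9]:
            assert composition_logpdf(law, [g, 1 - g]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_dirichlet(self):
        law = CompositionLaw(np.array([0.4, 1.3, 2.3]))
        x = np.array([0.2, 0.3, 0.5])
        assert composition_logpdf(law, x) == pytest.approx(
            scipy_dirichlet.logpdf(x, law.influx), rel=1e-12
        )

    def test_marginal_variance_formula(self):
        # var = gbar (1 - gbar) / (1 + k); at gbar = 0.5, k = 1 -> 0.125
        law = CompositionLaw(np.array([0.5, 0.5]))
        assert law.variance[0] == pytest.approx(0.125, rel=1e-12)
        assert law.marginal(0).var() == pytest.approx(0.125, rel=1e-12)

    def test_sampled_variance_matches(self, rng):
        law = CompositionLaw(np.array([0.6, 1.4]))
        draws = law.rvs(100_000, seed=3)
        emp = draws[:, 0].var(ddof=1)
        se = np.sqrt(2.0 / draws.shape[0]) * law.variance[0]  # chi2-scale SE
        assert abs(emp - law.variance[0]) < 3 * se

    def test_boundary_divergence_is_explicit(self):
        law = CompositionLaw(np.array([0.5, 1.5]))
        with pytest.warns(RuntimeWarning, match="diverges"):
            assert composition_logpdf(law, [0.0, 1.0]) == np.inf


class TestDiversity:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([1 / 3, 1 / 3, 1 / 3], 2 / 3)],
    )
    def test_simpson_values(self, freqs, expected):
        assert cs.simpson_diversity(freqs) == pytest.approx(expected, rel=1e-9)

    def test_effective_clone_number(self):
        assert cs.effective_clone_number(0.5) == pytest.approx(2.0)
        assert cs.effective_clone_number(2 / 3) == pytest.approx(3.0)

    @pytest.mark.parametrize("k,expected", [(0.0, 0.0), (1.0, 0.5),
                                            (11.6, 11.6 / 12.6)])
    def test_transfer_ratio(self, k, expected):
        assert cs.diversity_transfer_ratio(k) == pytest.approx(expected, rel=1e-12)

    def test_transfer_ratio_increasing(self):
        ks = [0.1, 0.5, 1, 5, 20]
        vals = [cs.diversity_transfer_ratio(k) for k in ks]
        assert np.all(np.diff(vals) > 0) and all(0 <= v < 1 for v in vals)

    def test_fixation_index(self):
        assert cs.fixation_index(1.0, 1) == 0.0
        assert cs.fixation_index(1.0, 4) == pytest.approx(0.375, rel=1e-12)
        assert cs.fixation_index(1.0, 10**9) == pytest.approx(0.5, rel=1e-6)
        with pytest.raises(ValueError):
            cs.fixation_index(1.0, 0)


# ---------------------------------------------------------------------------
# seeded cells, detection time, self-seeding


class TestExpectedSeededCells:
    def test_unit_influx_value(self):
        # k=1: psi(1) = -euler_gamma, so X = ln(5e6) + 0.5772 = 16.00
        x = cs.expected_seeded_cells(1.0, DetectionSpec(10**8), survival_prob=0.05)
        assert x == pytest.approx(np.log(5e6) + np.euler_gamma, rel=1e-12)
        assert x == pytest.approx(16.00, abs=0.005)

    def test_small_influx_limit_is_one_seed(self):
        # -k psi(k) -> 1 as k -> 0: a detected metastasis always holds at
        # least one surviving seed
        x = cs.expected_seeded_cells(1e-9, DetectionSpec(10**8), survival_prob=0.05)
        assert x == pytest.approx(1.0, abs=1e-6)

    def test_logarithmic_growth_in_detect_size(self):
        k, rho = 0.7, 0.05
        hi = cs.expected_seeded_cells(k, DetectionSpec(10**9), survival_prob=rho)
        lo = cs.expected_seeded_cells(k, DetectionSpec(10**7), survival_prob=rho)
        assert hi - lo == pytest.approx(k * np.log(100), rel=1e-12)

    def test_rejects_undetectable(self):
        with pytest.raises(ValueError, match="rho"):
            cs.expected_seeded_cells(1.0, DetectionSpec(10), survival_prob=0.05)

    def test_detection_time_identity(self, fig2_model):
        # Xbar = rho * lambda * Tbar  <=>  Tbar = [ln(rho Y) - psi(k)] / r
        spec = DetectionSpec(10**8)
        t = cs.mean_detection_time(fig2_model, spec)
        x = cs.expected_seeded_cells(fig2_model, spec)
        lam_tot = fig2_model.seed_rates.sum()
        assert fig2_model.survival_prob * lam_tot * t == pytest.approx(x, rel=1e-12)


class TestSelfSeedingFraction:
    def test_closed_form_values(self):
        assert cs.self_seeding_first_event_fraction(1.0) == pytest.approx(
            np.exp(-np.euler_gamma), rel=1e-12
        )
        assert cs.self_seeding_first_event_fraction(2.0) == pytest.approx(
            np.exp(-np.euler_gamma) / 2, rel=1e-12
        )

    def test_capped_at_mature_size(self):
        assert cs.self_seeding_first_event_fraction(0.1) == 1.0

    def test_matches_thinned_poisson_simulation(self):
        """Geometric-mean first-event size fraction from the event-level
        simulation agrees with exp(-euler_gamma)/k."""
        for k in [1.0, 2.0]:
            fr = cs.simulate_first_seeding_fraction(k, 30_000, seed=77)
            logs = np.log(fr)
            gm = np.exp(logs.mean())
            se_gm = gm * logs.std(ddof=1) / np.sqrt(logs.size)
            assert abs(gm - np.exp(-np.euler_gamma) / k) < 3 * se_gm


class TestThresholdedPolyclonality:
    def test_matches_two_clone_beta(self):
        m = scaled_model([1.0, 2.0])
        spec = DetectionSpec(10**8, 0.05)
        exact = threshold_polyclonality_probability(m, spec)
        draws = CompositionLaw(m.influx).rvs(200_000, seed=5)
        emp = np.mean((draws >= 0.05).sum(axis=1) >= 2)
        assert exact == pytest.approx(emp, abs=0.005)

    def test_threshold_lowers_detected_polyclonality(self):
        m = scaled_model([1.0, 0.05])
        y = 10**8
        p0 = cs.polyclonality_probability(m, DetectionSpec(y))
        p5 = threshold_polyclonality_probability(m, DetectionSpec(y, 0.05))
        assert p5 < p0


def test_predict_table_columns(fig2_model):
    df = cs.predict_table(fig2_model, [10**7, 10**8], n_mets=4,
                          min_cell_fraction=0.05)
    assert list(df["Y"]) == [10**7, 10**8]
    assert {"mean_n_clones", "p_polyclonal", "diversity_transfer", "fst",
            "expected_seeded_cells", "mean_detection_time_days",
            "p_polyclonal_thresholded"} <= set(df.columns)
    assert (df["p_polyclonal"].diff().dropna() >= 0).all()
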