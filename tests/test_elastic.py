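"""Elastic-constant estimators and derived scalar quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnatwist import (BackboneGeometry, ElasticConstants, InverseCovarianceFit,
                      QuadraticPMFFit, backbone_coupling_estimate,
                      backbone_length, effective_twist_stiffness,
                      fit_gaussian_covariance, fit_quadratic_pmf,
                      rise_from_backbone, twist_rigidity,
                      youngs_modulus_surrogate)
from dnatwist.elastic import (IndefiniteStiffnessError, REFERENCE_BACKBONE)
from dnatwist.synthetic import GeneratorSpec, sample_ensemble


class TestInverseCovariance:
    def test_exact_inversion_of_known_covariance(self, rng):
        # per-bp covariance implied by the reference constants:
        # var_omega 9.707 deg^2, var_D 0.006645 nm^2, cov -0.1661 deg nm
        cov = np.array([[9.70742894, -0.16611296],
                        [-0.16611296, 0.00664452]])
        # build data with *exactly* this sample covariance via whitening
        n = 2000
        Z = rng.standard_normal((n, 2))
        Z -= Z.mean(axis=0)
        Z = Z @ np.linalg.inv(np.linalg.cholesky(np.cov(Z, rowvar=False)).T)
        X = Z @ np.linalg.cholesky(cov).T + [34.82, 2.008]
        c = InverseCovarianceFit(n_steps_avg=1).fit(X).constants_
        assert c.k_omega == pytest.approx(0.18, rel=1e-3)
        assert c.k_d == pytest.approx(263.0, rel=1e-3)
        assert c.k_omega_d == pytest.approx(4.5, rel=1e-3)

    def test_diagonal_covariance_gives_zero_coupling(self, rng):
        X = np.column_stack([rng.normal(35, 1, 5000),
                             rng.normal(2, 0.05, 5000)])
        c = InverseCovarianceFit().fit(X).constants_
        assert abs(c.k_omega_d) < 0.05 * c.k_omega * c.k_d

    def test_large_sample_recovery_within_3pct(self, spec):
        ens = sample_ensemble(
            GeneratorSpec(constants=spec.constants, n_frames=100_000,
                          n_steps_avg=19), seed=17)
        c = fit_gaussian_covariance(ens)
        assert c.k_omega == pytest.approx(0.18, rel=0.03)
        assert c.k_d == pytest.approx(263.0, rel=0.03)
        assert c.k_omega_d == pytest.approx(4.5, rel=0.03)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            InverseCovarianceFit().fit(np.array([[34.0, 2.0], [35.0, 2.1]]))

    def test_singular_covariance_rejected(self):
        X = np.tile([34.8, 2.0], (100, 1))
        with pytest.raises(ValueError, match="singular"):
            InverseCovarianceFit().fit(X)


class TestQuadraticPMFFit:
    def test_recovers_generating_constants(self, reference_ensemble):
        est = QuadraticPMFFit(n_steps_avg=19, n_bootstrap=200,
                              random_state=0)
        est.fit(reference_ensemble.as_array())
        c = est.constants_
        # point estimate inside the published-scale uncertainty band; CI
        # calibration itself is checked across replicates below
        assert c.k_omega_d == pytest.approx(4.5, abs=0.8)
        assert c.ci95 is not None
        lo, hi = c.ci95["k_omegaD"]
        assert lo < c.k_omega_d < hi
        assert 0.01 < hi - lo < 1.0
        assert c.k_omega == pytest.approx(0.18, rel=0.08)
        assert c.k_d == pytest.approx(263.0, rel=0.08)
        assert c.omega0 == pytest.approx(34.82, abs=0.02)
        assert c.d0 == pytest.approx(2.008, abs=0.002)

    def test_agrees_with_covariance_route_within_5pct(self, reference_ensemble):
        c_pmf = fit_quadratic_pmf(reference_ensemble, n_bootstrap=0)
        c_cov = fit_gaussian_covariance(reference_ensemble)
        assert c_pmf.k_omega == pytest.approx(c_cov.k_omega, rel=0.05)
        assert c_pmf.k_d == pytest.approx(c_cov.k_d, rel=0.05)
        assert c_pmf.k_omega_d == pytest.approx(c_cov.k_omega_d, rel=0.05)

    def test_uncoupled_data_gives_zero_coupling_in_ci(self, constants):
        uncoupled = ElasticConstants(omega0=34.82, d0=2.008, k_omega=0.18,
                                     k_d=263.0, k_omega_d=0.0)
        ens = sample_ensemble(GeneratorSpec(constants=uncoupled), seed=21)
        est = QuadraticPMFFit(n_steps_avg=19, n_bootstrap=100, random_state=1)
        est.fit(ens.as_array())
        lo, hi = est.constants_.ci95["k_omegaD"]
        assert lo <= 0.0 <= hi

    def test_bootstrap_coverage_over_replicates(self, spec):
        # all three generating constants inside the 95% CI in >= 90% of
        # 50 seeded replicates
        hits = 0
        n_rep = 50
        for s in range(n_rep):
            ens = sample_ensemble(spec, seed=5000 + s)
            est = QuadraticPMFFit(n_steps_avg=19, n_bootstrap=200,
                                  random_state=s)
            est.fit(ens.as_array())
            ci = est.constants_.ci95
            if (ci["k_omega"][0] <= 0.18 <= ci["k_omega"][1]
                    and ci["k_D"][0] <= 263.0 <= ci["k_D"][1]
                    and ci["k_omegaD"][0] <= 4.5 <= ci["k_omegaD"][1]):
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_underdetermined_fit_rejected(self, rng):
        X = np.column_stack([rng.normal(35, 1, 30), rng.normal(2, 0.05, 30)])
        est = QuadraticPMFFit(n_twist_bins=2, n_diam_bins=2, min_count=1,
                              n_bootstrap=0)
        with pytest.raises(ValueError, match="underdetermined"):
            est.fit(X)

    def test_positive_definiteness_preserved_per_bp(self, reference_ensemble):
        c = fit_quadratic_pmf(reference_ensemble, n_bootstrap=0)
        assert c.k_omega > 0 and c.k_d > 0 and c.determinant > 0


class TestDerivedQuantities:
    def test_effective_twist_stiffness_reference_value(self, constants):
        assert effective_twist_stiffness(constants) == pytest.approx(0.103, abs=0.0005)

    def test_effective_stiffness_uncoupled_is_unchanged(self):
        c = ElasticConstants(omega0=34.8, d0=2.0, k_omega=0.18, k_d=263.0,
                             k_omega_d=0.0)
        assert effective_twist_stiffness(c) == 0.18

    def test_effective_stiffness_hand_example(self):
        c = ElasticConstants(omega0=34.8, d0=2.0, k_omega=0.2, k_d=100.0,
                             k_omega_d=3.0)
        assert effective_twist_stiffness(c) == pytest.approx(0.11)

    def test_twist_rigidity_reference(self):
        assert twist_rigidity(0.103, 0.34, 295.0) == pytest.approx(468, rel=0.01)

    def test_twist_rigidity_linear_in_rise(self):
        assert twist_rigidity(0.103, 0.68) == pytest.approx(
            2 * twist_rigidity(0.103, 0.34))

    def test_twist_rigidity_with_geometric_rise(self):
        h = rise_from_backbone(0.694, 0.6077, 2.008)
        assert twist_rigidity(0.103, h, 295.0) == pytest.approx(456, rel=0.01)

    def test_marginal_conditional_identity(self, reference_ensemble, constants):
        # per-bp stiffness from the marginal twist variance equals
        # k_omega - k_omegaD^2/k_D (Gaussian marginal identity)
        var = reference_ensemble.twist.var(ddof=1)
        k_marginal = 1.0 / (var * 19)
        assert k_marginal == pytest.approx(
            effective_twist_stiffness(constants), rel=0.05)

    def test_backbone_coupling_reference(self):
        val = backbone_coupling_estimate(REFERENCE_BACKBONE, 295.15)
        assert val == pytest.approx(2.8, rel=0.02)

    def test_backbone_coupling_linear_in_modulus(self):
        doubled = BackboneGeometry(s0=0.694, h=0.331, stretch_modulus=1930.0,
                                   d0=2.008, omega0_rad=0.6077)
        assert backbone_coupling_estimate(doubled) == pytest.approx(
            2 * backbone_coupling_estimate(REFERENCE_BACKBONE))

    def test_backbone_coupling_force_units_intermediate(self):
        # S_h D0^3 w0^3 / (8 s0^3) = 656 pN per (rad nm)
        g = REFERENCE_BACKBONE
        force = (g.stretch_modulus * g.d0**3 * g.omega0_rad**3
                 / (8 * g.s0**3))
        assert force == pytest.approx(656, rel=0.01)

    def test_backbone_length_closure(self):
        assert backbone_length(0.6077, 2.008, 0.3307) == pytest.approx(0.694, abs=1e-3)
        assert backbone_length(0.0, 2.008, 0.34) == 0.34

    def test_rise_inverts_backbone_length(self):
        assert rise_from_backbone(0.694, 0.6077, 2.008) == pytest.approx(0.331, abs=1e-3)

    @given(omega=st.floats(0.1, 1.0), d=st.floats(1.0, 3.0),
           h=st.floats(0.1, 0.6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_backbone_round_trip_property(self, omega, d, h):
        s = backbone_length(omega, d, h)
        assert rise_from_backbone(s, omega, d) == pytest.approx(h, rel=1e-9)

    def test_negative_radicand_rejected(self):
        with pytest.raises(ValueError, match="rise"):
            rise_from_backbone(0.1, 0.6077, 2.008)

    def test_youngs_modulus_order_of_magnitude(self):
        e = youngs_modulus_surrogate(263.0, 2.008, 0.331)
        assert 3.2e7 < e < 3.2e9

    def test_youngs_modulus_scales_with_stiffness(self):
        assert youngs_modulus_surrogate(526.0, 2.008, 0.331) == pytest.approx(
            2 * youngs_modulus_surrogate(263.0, 2.008, 0.331))

    def test_youngs_modulus_pinned_convention(self):
        # regression pin of this package's lateral-surface convention
        assert youngs_modulus_surrogate(263.0, 2.008, 0.331) == pytest.approx(
            1.031e9, rel=0.001)


class TestElasticConstantsContainer:
    def test_indefinite_matrix_rejected_with_values(self):
        with pytest.raises(IndefiniteStiffnessError) as err:
            ElasticConstants(omega0=34.8, d0=2.0, k_omega=0.18, k_d=263.0,
                             k_omega_d=10.0)
        assert err.value.k_omega_d == 10.0

    def test_json_round_trip_exact(self, tmp_path, constants):
        path = tmp_path / "constants.json"
        constants.to_json(path)
        back = ElasticConstants.from_json(path)
        assert back.k_omega == constants.k_omega
        assert back.k_d == constants.k_d
        assert back.k_omega_d == constants.k_omega_d
        assert back.omega0 == constants.omega0
        assert back.temperature == constants.temperature
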