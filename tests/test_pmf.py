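"""Free-energy landscape construction: normalization, oracles, conditionals."""

import numpy as np
import pytest

from dnatwist import (build_pmf2d, conditional_mean_twist,
                      conditional_pmf_twist, correlation_matrix, write_pmf2d)
from dnatwist.synthetic import (DihedralCouplings, GeneratorSpec,
                                sample_ensemble)


def _gaussian_log_density_surface(pmf, constants, n_steps_avg):
    """Analytic oracle: molecule-level quadratic energy at bin centers."""
    tw, dm = np.meshgrid(pmf.twist_centers, pmf.diameter_centers,
                         indexing="ij")
    d_om, d_di = tw - constants.omega0, dm - constants.d0
    e = n_steps_avg * (0.5 * constants.k_omega * d_om**2
                       + 0.5 * constants.k_d * d_di**2
                       + constants.k_omega_d * d_om * d_di)
    return e


class TestBuild2D:
    def test_counts_conserve_frames(self, reference_ensemble):
        pmf = build_pmf2d(reference_ensemble)
        # default auto range (mean ± 3.5 SD) may clip a handful of frames
        assert pmf.n_frames >= 0.99 * reference_ensemble.n_frames

    def test_min_zero_over_occupied_bins(self, reference_ensemble):
        pmf = build_pmf2d(reference_ensemble)
        assert pmf.values.min() == 0.0
        assert (pmf.values.compressed() >= 0).all()

    def test_unoccupied_bins_masked(self, reference_ensemble):
        pmf = build_pmf2d(reference_ensemble, 30, 30)
        assert pmf.values.mask.any()
        assert (pmf.counts[pmf.values.mask] == 0).all()

    def test_default_bin_widths_near_reference_resolution(self, reference_ensemble):
        # 10x10 bins over mean ± 3.5 SD of 19-step-averaged data give
        # roughly 0.5 deg x 0.01 nm bins
        pmf = build_pmf2d(reference_ensemble)
        assert np.diff(pmf.twist_edges).mean() == pytest.approx(0.5, rel=0.1)
        assert np.diff(pmf.diameter_edges).mean() == pytest.approx(0.013, rel=0.1)

    def test_uniform_samples_give_flat_landscape(self, rng):
        n = 100_000
        X = np.column_stack([rng.uniform(30, 40, n), rng.uniform(1.9, 2.1, n)])
        pmf = build_pmf2d(X, 10, 10, ranges=((30, 40), (1.9, 2.1)))
        spread = pmf.values.compressed().max() - pmf.values.compressed().min()
        assert spread < 0.3

    def test_gaussian_matches_analytic_quadratic(self, reference_ensemble,
                                                 constants):
        pmf = build_pmf2d(reference_ensemble)
        energy = _gaussian_log_density_surface(pmf, constants, 19)

        def resid(min_count):
            ok = (~pmf.values.mask) & (pmf.counts >= min_count)
            r = pmf.values.data[ok] - (energy[ok] - energy[ok].min())
            return r - np.average(r, weights=pmf.counts[ok]), pmf.counts[ok]
        # well-populated bins: Poisson noise < 0.03 kBT, deviation is pure
        # model error (binning smear)
        r, _ = resid(1000)
        assert np.abs(r).max() < 0.2
        # all usable bins: count-weighted RMS absorbs the shot noise
        r, w = resid(100)
        wrms = np.sqrt(np.average(r**2, weights=w))
        assert wrms < 0.15

    def test_all_frames_outside_ranges_error(self, reference_ensemble):
        with pytest.raises(ValueError, match="outside"):
            build_pmf2d(reference_ensemble, ranges=((80, 89), (3.0, 4.0)))

    def test_export_long_format(self, tmp_path, reference_ensemble):
        import pandas as pd
        pmf = build_pmf2d(reference_ensemble)
        out = tmp_path / "pmf.tsv"
        write_pmf2d(out, pmf)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["twist_center", "diameter_center",
                                    "pmf_kBT", "count"]
        assert len(df) == 100
        assert df["count"].sum() == pmf.n_frames


class TestConditional:
    def test_minimum_tracks_window_center_downward(self, reference_ensemble):
        # negative coupling: larger diameters wind the helix less
        minima = []
        for lo in (1.95, 2.00, 2.05):
            prof = conditional_pmf_twist(reference_ensemble, (lo, lo + 0.02))
            minima.append(prof.quadratic_fit()[1])
        assert minima[0] > minima[1] > minima[2]

    def test_window_at_mean_recovers_equilibrium_twist(self, reference_ensemble):
        prof = conditional_pmf_twist(reference_ensemble, (2.003, 2.013))
        _, loc = prof.quadratic_fit()
        assert loc == pytest.approx(34.82, abs=0.05)

    def test_curvature_is_half_molecular_twist_stiffness(self, reference_ensemble):
        prof = conditional_pmf_twist(reference_ensemble, (2.003, 2.013))
        curvature, _ = prof.quadratic_fit()
        assert curvature == pytest.approx(0.5 * 19 * 0.18, rel=0.15)

    def test_empty_window_error_names_window(self, reference_ensemble):
        with pytest.raises(ValueError, match="3.0"):
            conditional_pmf_twist(reference_ensemble, (3.0, 3.1))

    def test_mean_twist_line_slope(self, reference_ensemble, constants):
        df = conditional_mean_twist(reference_ensemble)
        expected = -constants.k_omega_d / constants.k_omega  # -25 deg/nm
        assert df.attrs["slope"] == pytest.approx(expected, abs=5 * df.attrs["slope_se"])
        assert df.attrs["slope"] == pytest.approx(-25.0, rel=0.05)

    def test_uncoupled_generator_gives_flat_line(self, constants):
        from dnatwist.elastic import ElasticConstants
        uncoupled = ElasticConstants(omega0=34.82, d0=2.008, k_omega=0.18,
                                     k_d=263.0, k_omega_d=0.0)
        ens = sample_ensemble(GeneratorSpec(constants=uncoupled), seed=4)
        df = conditional_mean_twist(ens)
        assert abs(df.attrs["slope"]) < 3 * df.attrs["slope_se"] + 0.5


class TestCorrelations:
    def test_dihedral_sign_pattern(self, constants):
        s = GeneratorSpec(constants=constants, n_frames=20_000,
                          dihedral_couplings=DihedralCouplings())
        ens = sample_ensemble(s, seed=6)
        corr = correlation_matrix(ens)
        assert corr.loc["chi", "diameter"] < 0
        assert corr.loc["chi", "twist"] > 0
        assert corr.loc["delta", "diameter"] < 0
        assert corr.loc["delta", "twist"] > 0

    def test_matrix_is_symmetric_unit_diagonal(self, reference_ensemble):
        corr = correlation_matrix(reference_ensemble)
        m = corr.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1.0 + 1e-12).all()

    def test_independent_channels_uncorrelated(self, rng):
        from dnatwist import ConformationEnsemble
        n = 10_000
        ens = ConformationEnsemble(
            twist=rng.normal(35, 1, n).clip(1, 89),
            diameter=rng.normal(2.0, 0.05, n).clip(0.5),
            chi=rng.normal(-100, 5, n))
        corr = correlation_matrix(ens, ["twist", "chi"])
        assert abs(corr.loc["twist", "chi"]) < 0.05

    def test_missing_channel_rejected(self, reference_ensemble):
        with pytest.raises(ValueError, match="chi"):
            correlation_matrix(reference_ensemble, ["twist", "chi"])

    def test_constant_channel_rejected(self):
        from dnatwist import ConformationEnsemble
        ens = ConformationEnsemble(twist=np.array([34.0, 35.0, 36.0]),
                                   diameter=np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(ens)
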