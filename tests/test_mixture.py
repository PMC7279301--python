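"""Two-component mixture model and the coverage estimator."""
import numpy as np
import pytest
from sklearn.base import clone

import xpsprot as xp
from xpsprot.mixture import OBJECTIVES


class TestMixSpectra:
    def test_endpoints_are_identities(self, pcl_spectrum, apoa1_spectrum):
        at0 = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, 0.0)
        at1 = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, 1.0)
        assert at0.intensity == pytest.approx(pcl_spectrum.intensity)
        assert at1.intensity == pytest.approx(apoa1_spectrum.intensity)

    def test_out_of_range_x_rejected(self, pcl_spectrum, apoa1_spectrum):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError, match="outside"):
                xp.mix_spectra(pcl_spectrum, apoa1_spectrum, bad)

    def test_grid_mismatch_rejected(self, pcl_spectrum):
        other = xp.simulate_protein_spectrum(
            xp.pcl_theoretical_profile(), grid=xp.energy_grid(281, 293, 0.05))
        with pytest.raises(ValueError, match="different grids"):
            xp.mix_spectra(pcl_spectrum, other, 0.5)

    def test_unnormalized_input_rejected(self, pcl_spectrum, apoa1_spectrum):
        scaled = xp.Spectrum(pcl_spectrum.energy,
                             2.0 * pcl_spectrum.intensity)
        with pytest.raises(ValueError, match="not max-normalized"):
            xp.mix_spectra(scaled, apoa1_spectrum, 0.5)


def test_self_mixture_is_fixed_point(pcl_spectrum):
    for x in (0.0, 0.25, 0.9, 1.0):
        out = xp.mix_spectra(pcl_spectrum, pcl_spectrum, x)
        assert out.intensity == pytest.approx(pcl_spectrum.intensity)


class TestFitCoverage:
    @pytest.mark.parametrize("x_true", [0.0, 0.09, 0.13, 0.5, 1.0])
    def test_noiseless_self_consistency(self, pcl_spectrum, apoa1_spectrum,
                                        x_true):
        measured = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, x_true)
        res = xp.fit_coverage(pcl_spectrum, apoa1_spectrum, measured)
        assert res.x_hat == pytest.approx(x_true, abs=0.0025)
        assert not res.weakly_identified

    def test_measured_equal_to_substrate_gives_zero(self, pcl_spectrum,
                                                    apoa1_spectrum):
        res = xp.fit_coverage(pcl_spectrum, apoa1_spectrum, pcl_spectrum)
        assert res.x_hat == pytest.approx(0.0, abs=0.0025)

    def test_noisy_recovery_matches_fine_grid_oracle(self, pcl_cooh_spectrum,
                                                     apoa1_spectrum):
        """Poisson noise at 1e4 peak counts: the refined estimate stays
        within 0.01 of truth and within 5e-4 of an exhaustive 1e-4-step
        scan of the same objective."""
        x_true = 0.13
        mixed = xp.mix_spectra(pcl_cooh_spectrum, apoa1_spectrum, x_true)
        rng = np.random.default_rng(42)
        noisy = xp.Spectrum(mixed.energy,
                            rng.poisson(1e4 * mixed.intensity).astype(float))
        res = xp.fit_coverage(pcl_cooh_spectrum, apoa1_spectrum, noisy)
        assert res.x_hat == pytest.approx(x_true, abs=0.01)

        measured = xp.normalize_max(noisy).intensity
        sub = pcl_cooh_spectrum.intensity
        prot = apoa1_spectrum.intensity

        def objective(x):  # independent brute-force re-implementation
            model = (1 - x) * sub + x * prot
            model = model / model.max()
            return np.sqrt(np.mean((model - measured) ** 2))

        xs = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        brute = xs[int(np.argmin([objective(x) for x in xs]))]
        assert res.x_hat == pytest.approx(brute, abs=5e-4)

    def test_invariant_to_measured_scaling(self, pcl_spectrum,
                                           apoa1_spectrum):
        measured = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, 0.11)
        scaled = xp.Spectrum(measured.energy, 3.7e4 * measured.intensity)
        a = xp.fit_coverage(pcl_spectrum, apoa1_spectrum, measured)
        b = xp.fit_coverage(pcl_spectrum, apoa1_spectrum, scaled)
        assert a.x_hat == pytest.approx(b.x_hat, abs=1e-9)

    def test_identical_components_flagged_weakly_identified(
            self, pcl_spectrum):
        res = xp.fit_coverage(pcl_spectrum, pcl_spectrum, pcl_spectrum)
        assert res.weakly_identified

    def test_substrate_distortion_degrades_fit_quality(self, pcl_cooh_spectrum,
                                                       apoa1_spectrum,
                                                       default_grid):
        """A BE-shifted extra component in the measured substrate (more
        286.5 eV carbon than the model expects) raises the attainable
        minimum objective — the convergence becomes 'less evident'."""
        x_true = 0.15
        clean = xp.mix_spectra(pcl_cooh_spectrum, apoa1_spectrum, x_true)
        sigma = 1.1 / (2 * np.sqrt(2 * np.log(2)))
        extra = 0.2 * np.exp(-0.5 * ((default_grid - 286.5) / sigma) ** 2)
        distorted = xp.normalize_max(
            xp.Spectrum(default_grid, clean.intensity + extra))
        res_clean = xp.fit_coverage(pcl_cooh_spectrum, apoa1_spectrum, clean)
        res_dist = xp.fit_coverage(pcl_cooh_spectrum, apoa1_spectrum,
                                   distorted)
        assert res_dist.rmse > res_clean.rmse + 1e-4
        assert res_dist.r_squared < res_clean.r_squared

    def test_objective_curve_covers_full_range_and_min(self, pcl_spectrum,
                                                       apoa1_spectrum):
        measured = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, 0.2)
        res = xp.fit_coverage(pcl_spectrum, apoa1_spectrum, measured)
        xs, objs = res.objective_curve[:, 0], res.objective_curve[:, 1]
        assert xs[0] == 0.0 and xs[-1] == pytest.approx(1.0)
        # refined optimum is at least as good as the best scanned point
        interp = np.interp(res.x_hat, xs, objs)
        assert res.rmse <= objs.min() + 1e-12 or interp >= objs.min()

    def test_no_grid_overlap_rejected(self, pcl_spectrum, apoa1_spectrum):
        off = xp.Spectrum(pcl_spectrum.energy + 50.0, pcl_spectrum.intensity)
        with pytest.raises(ValueError, match="overlap"):
            xp.fit_coverage(pcl_spectrum, apoa1_spectrum, off)

    def test_alternative_objectives(self, pcl_spectrum, apoa1_spectrum):
        measured = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, 0.09)
        for name in OBJECTIVES:
            res = xp.fit_coverage(pcl_spectrum, apoa1_spectrum, measured,
                                  objective=name)
            assert res.x_hat == pytest.approx(0.09, abs=0.0025)


class TestEstimatorProtocol:
    def test_get_params_set_params_clone(self, pcl_spectrum, apoa1_spectrum):
        est = xp.CoverageEstimator(substrate=pcl_spectrum,
                                   protein=apoa1_spectrum, step=0.005)
        params = est.get_params()
        assert params["step"] == 0.005
        est2 = clone(est)
        measured = xp.mix_spectra(pcl_spectrum, apoa1_spectrum, 0.09)
        assert est2.set_params(step=0.0025).fit(measured).x_ == \
            pytest.approx(0.09, abs=0.0025)
        assert est2.predict() == est2.x_

    def test_unfitted_predict_rejected(self, pcl_spectrum, apoa1_spectrum):
        est = xp.CoverageEstimator(substrate=pcl_spectrum,
                                   protein=apoa1_spectrum)
        with pytest.raises(ValueError, match="not fitted"):
            est.predict()


class TestCoverageIncrease:
    def test_adsorption_to_covalent_examples(self):
        assert xp.coverage_increase(0.09, 0.13) == pytest.approx(44.44,
                                                                 abs=0.01)
        assert xp.present_percent(xp.coverage_increase(0.09, 0.13)) == "44%"
        assert xp.coverage_increase(0.08, 0.15) == pytest.approx(87.5)
        assert xp.coverage_increase(0.2, 0.2) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            xp.coverage_increase(0.0, 0.1)
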