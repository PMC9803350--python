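import numpy as np
import pytest
import scipy.signal

from skcam.binding import BindingModel, ComplexSpec
from skcam.fixtures import TABLE2_LOG_KA
from skcam.mals import (
    FitResult,
    MALSDataset,
    aggregate_trials,
    build_crossover_gradient,
    compare_models,
    detection_limit_scan,
    fit_association_constants,
    predict_mw,
)
from skcam.study import cam_species, skp_species, study_binding_model, study_gradient
from skcam.synth import simulate_mals_dataset


class TestGradient:
    def test_pure_peptide_endpoint_is_8_65_uM(self):
        g = build_crossover_gradient(
            0.096, 0.09, skp_species(), cam_species("WT-CaM"), n_steps=3,
            f_min=0.0, f_max=1.0,
        )
        comp = g.compositions()[-1]
        assert comp.cam_total == 0.0
        assert comp.peptide_total == pytest.approx(8.65e-6, rel=1e-3)

    def test_midpoint_is_half_of_each_stock(self):
        g = build_crossover_gradient(
            0.096, 0.09, skp_species(), cam_species("WT-CaM"), n_steps=3,
            f_min=0.0, f_max=1.0,
        )
        mid = g.compositions()[1]
        assert mid.peptide_total == pytest.approx(g.stock_peptide_molar / 2)
        assert mid.cam_total == pytest.approx(g.stock_cam_molar / 2)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            build_crossover_gradient(
                0.096, 0.09, skp_species(), cam_species("WT-CaM"), n_steps=2
            )

    def test_degenerate_stock_rejected(self):
        with pytest.raises(ValueError):
            build_crossover_gradient(
                0.0, 0.09, skp_species(), cam_species("WT-CaM")
            )

    def test_molar_ratio_monotonic(self, standard_gradient):
        ratios = standard_gradient.molar_ratio_cam_to_peptide()
        assert np.all(np.diff(ratios) < 0)  # f increasing => CaM:SKp falling


class TestCurveShapes:
    def test_wt_ca_curve_has_m_shape(self, wt_ca_model, standard_gradient):
        """Two interior maxima flanking a local minimum near equimolar."""
        mw = predict_mw(wt_ca_model, standard_gradient)
        maxima, _ = scipy.signal.find_peaks(mw)
        minima, _ = scipy.signal.find_peaks(-mw)
        assert len(maxima) == 2
        assert len(minima) == 1
        ratios = standard_gradient.molar_ratio_cam_to_peptide()
        lo, hi = sorted(ratios[maxima])
        assert lo < 1.0 < hi  # one peak each side of equimolar
        assert 0.5 < ratios[minima[0]] < 2.0

    def test_single_complex_curve_is_triangular(self, single_complex_model):
        """A 1:1-only model gives one apex, never exceeding the 1/1 mass."""
        g = study_gradient("N-CaM")
        model = BindingModel(
            skp_species(), cam_species("N-CaM"), (ComplexSpec(1, 1, 8.9),)
        )
        mw = predict_mw(model, g)
        maxima, _ = scipy.signal.find_peaks(mw)
        assert len(maxima) == 1
        assert mw.max() <= model.complex_mass(1, 1) + 1e-9


class TestFitting:
    def test_wt_ca_round_trip_with_pc_fixed(self, wt_ca_model, standard_gradient):
        """Noiseless data refit with P-C fixed recovers the generating
        2SKp/1CaM and 1SKp/2CaM constants (started 2 log units low)."""
        data = simulate_mals_dataset(
            wt_ca_model, standard_gradient, noise_cv=0.0, n_replicates=1, seed=0
        )
        fit = fit_association_constants(
            data,
            model_spec=[(1, 1), (2, 1), (1, 2)],
            fixed={(1, 1): 10.4},
            init={(2, 1): 15.0, (1, 2): 14.0},
        )
        assert fit.success
        assert fit.log10_ka[(2, 1)] == pytest.approx(17.0, abs=0.05)
        assert fit.log10_ka[(1, 2)] == pytest.approx(16.0, abs=0.05)

    @pytest.mark.parametrize("construct,condition", sorted(TABLE2_LOG_KA))
    def test_noiseless_round_trip_all_parameter_sets(self, construct, condition):
        """Every fitted-constant set regenerates and refits to within 0.05
        (perturbed starts), unless flagged unconstrained."""
        kas = TABLE2_LOG_KA[(construct, condition)]
        model = study_binding_model(construct, condition)
        g = study_gradient(construct)
        data = simulate_mals_dataset(model, g, noise_cv=0.0, n_replicates=1, seed=0)
        fit = fit_association_constants(
            data, list(kas), init={k: v - 1.0 for k, v in kas.items()}
        )
        for key, true in kas.items():
            if not fit.unconstrained[key]:
                assert fit.log10_ka[key] == pytest.approx(true, abs=0.05), (
                    construct, condition, key,
                )

    def test_noisy_recovery_within_three_sem(self, wt_ca_model, standard_gradient):
        """2% proportional noise, 5 replicates: constrained constants land
        within 3 SEM of the generating values across 5 trials."""
        true = {(1, 1): 10.4, (2, 1): 17.0, (1, 2): 16.0}
        fits = []
        for seed in range(5):
            data = simulate_mals_dataset(
                wt_ca_model, standard_gradient, noise_cv=0.02,
                n_replicates=5, seed=100 + seed,
            )
            fits.append(
                fit_association_constants(
                    data, list(true), init={k: v - 1 for k, v in true.items()}
                )
            )
        summaries = aggregate_trials(fits)
        for key, s in summaries.items():
            assert abs(s.mean - true[key]) <= 3 * s.sem

    def test_empty_complex_set_gives_monomer_line_rss(
        self, wt_ca_model, standard_gradient
    ):
        data = simulate_mals_dataset(
            wt_ca_model, standard_gradient, noise_cv=0.0, n_replicates=1, seed=0
        )
        fit = fit_association_constants(data, model_spec=[])
        empty = BindingModel(wt_ca_model.peptide, wt_ca_model.cam, ())
        line = predict_mw(empty, standard_gradient)
        assert fit.rss == pytest.approx(
            float(np.sum((data.measured_mw[:, 0] - line) ** 2)), rel=1e-9
        )

    def test_fixed_key_must_be_in_spec(self, wt_ca_model, standard_gradient):
        data = simulate_mals_dataset(
            wt_ca_model, standard_gradient, noise_cv=0.0, seed=0
        )
        with pytest.raises(ValueError):
            fit_association_constants(data, [(1, 1)], fixed={(9, 9): 5.0})


@pytest.fixture(scope="module")
def bimolecular_data():
    model = BindingModel(
        skp_species(), cam_species("WT-CaM"), (ComplexSpec(1, 1, 9.0),)
    )
    g = study_gradient("WT-CaM")
    return simulate_mals_dataset(model, g, noise_cv=0.0, n_replicates=1, seed=0)


class TestDetectionLimit:

    def test_strong_bimolecular_constant_flagged_unconstrained(self, bimolecular_data):
        """Data generated at log K_A = 9 leave the constant flat above ~7:
        the profile flags it as outside the detection limit."""
        fit = fit_association_constants(bimolecular_data, [(1, 1)], init={(1, 1): 6.0})
        prof = detection_limit_scan(
            bimolecular_data, fit, (1, 1), np.linspace(5, 12, 15)
        )
        assert prof.unconstrained
        assert fit.unconstrained[(1, 1)]
        # the rise happens below ~7: RSS at 5 is far above threshold
        assert prof.rss[0] > 100 * prof.threshold
        flat_from = prof.grid[prof.rss <= prof.rss.min() + prof.threshold].min()
        assert flat_from <= 8.0

    def test_well_constrained_pcp_profile_rises(self, wt_ca_model, standard_gradient):
        """The 2SKp/1CaM constant of the M-shaped data is sharply localized."""
        data = simulate_mals_dataset(
            wt_ca_model, standard_gradient, noise_cv=0.0, n_replicates=1, seed=0
        )
        fit = fit_association_constants(
            data, [(1, 1), (2, 1), (1, 2)],
            fixed={(1, 1): 10.4}, init={(2, 1): 16.5, (1, 2): 15.5},
        )
        prof = detection_limit_scan(
            data, fit, (2, 1), np.linspace(15.0, 19.0, 9)
        )
        assert not prof.unconstrained
        assert prof.rss[0] > prof.threshold and prof.rss[-1] > prof.threshold

    def test_unknown_parameter_errors(self, bimolecular_data):
        fit = fit_association_constants(bimolecular_data, [(1, 1)], init={(1, 1): 6.0})
        with pytest.raises(ValueError):
            detection_limit_scan(bimolecular_data, fit, (3, 3), [5, 6, 7])


class TestCompareModels:
    def test_pc_only_data_selects_pc_only(self, standard_gradient):
        model = BindingModel(
            skp_species(), cam_species("WT-CaM"), (ComplexSpec(1, 1, 6.5),)
        )
        data = simulate_mals_dataset(model, standard_gradient, 0.0, 1, 0)
        selected, _ = compare_models(data, [[(1, 1)], [(1, 1), (2, 1), (1, 2)]])
        assert selected == [(1, 1)]

    def test_full_model_data_needs_three_complexes(
        self, wt_ca_model, standard_gradient
    ):
        data = simulate_mals_dataset(wt_ca_model, standard_gradient, 0.0, 1, 0)
        selected, rss = compare_models(
            data, [[(1, 1)], [(1, 1), (2, 1)], [(1, 1), (2, 1), (1, 2)]]
        )
        assert selected == [(1, 1), (2, 1), (1, 2)]

    def test_egta_data_shows_no_cpc_signature(self, standard_gradient):
        """Trace-Ca2+ data carry no 1SKp/2CaM signal: adding that complex
        does not improve the fit, so the two-complex model is selected."""
        model = study_binding_model("WT-CaM", "EGTA")
        data = simulate_mals_dataset(model, standard_gradient, 0.0, 1, 0)
        selected, rss = compare_models(
            data, [[(1, 1), (2, 1)], [(1, 1), (2, 1), (1, 2)]]
        )
        assert selected == [(1, 1), (2, 1)]

    def test_tie_goes_to_smaller_set(self, standard_gradient):
        model = BindingModel(
            skp_species(), cam_species("WT-CaM"), (ComplexSpec(1, 1, 6.5),)
        )
        data = simulate_mals_dataset(model, standard_gradient, 0.0, 1, 0)
        selected, _ = compare_models(data, [[(1, 1), (2, 1)], [(1, 1)]])
        assert selected == [(1, 1)]


class TestAggregation:
    @staticmethod
    def _fit(value):
        model = BindingModel(skp_species(), cam_species("WT-CaM"), ())
        return FitResult(
            log10_ka={(2, 1): value}, fixed=frozenset(), success=True, rss=0.0,
            message="", stderr={}, unconstrained={}, model=model,
        )

    def test_mean_se_n_formatting(self):
        summary = aggregate_trials([self._fit(v) for v in (16.8, 17.0, 17.2)])
        assert summary[(2, 1)].formatted() == "17.0 (0.1)3"

    def test_single_fit_has_no_sem(self):
        s = aggregate_trials([self._fit(17.0)])[(2, 1)]
        assert s.sem is None
        assert s.formatted() == "17.0 (n/a)1"

    def test_identical_fits_zero_sem(self):
        s = aggregate_trials([self._fit(12.0)] * 3)[(2, 1)]
        assert s.sem == 0.0


def test_dataset_csv_round_trip(tmp_path, wt_ca_model, standard_gradient):
    data = simulate_mals_dataset(
        wt_ca_model, standard_gradient, noise_cv=0.02, n_replicates=3, seed=5
    )
    path = tmp_path / "mals.csv"
    data.to_csv(path)
    back = MALSDataset.from_csv(
        path, skp_species(), cam_species("WT-CaM"), 0.096, 0.09
    )
    assert np.allclose(back.measured_mw, data.measured_mw)
    assert np.allclose(back.gradient.fractions, data.gradient.fractions)
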