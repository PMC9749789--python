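"""Ground-truth consistency of the synthetic-data generators.

The central contract: re-measuring a noiseless simulation with the
ground-truth masks or closed forms returns exactly the requested
quantity, and the same seed always produces bit-identical output.
"""

import numpy as np
import pytest

from nucleoquant import synthetic as syn
from nucleoquant.constants import K_BOLTZMANN


class TestCondensateImage:
    def test_noiseless_K_recovered_from_truth_masks(self):
        stack, truth = syn.simulate_condensate_image(
            n_nuclei=3, K_true=5.0, noise_sd=0.0, seed=3
        )
        marker = stack.plane(0, "marker")
        foci = truth.masks["nucleolus"]
        nuclei = truth.masks["nucleus"]
        nucleoplasm = (nuclei > 0) & (foci == 0)
        for lab in np.unique(foci[foci > 0]):
            K = marker[foci == lab].mean() / np.median(marker[nucleoplasm])
            assert K == pytest.approx(5.0, rel=1e-6)

    def test_noisy_K_close_to_requested(self):
        stack, truth = syn.simulate_condensate_image(K_true=5.0, noise_sd=0.02, seed=1)
        marker = stack.plane(0, "marker")
        foci = truth.masks["nucleolus"] > 0
        nucleoplasm = (truth.masks["nucleus"] > 0) & ~foci
        K = marker[foci].mean() / np.median(marker[nucleoplasm])
        assert K == pytest.approx(5.0, rel=0.05)

    def test_K_equal_one_means_uniform_nucleus(self):
        stack, truth = syn.simulate_condensate_image(K_true=1.0, noise_sd=0.0, seed=0)
        marker = stack.plane(0, "marker")
        inside = truth.masks["nucleus"] > 0
        assert np.ptp(marker[inside]) == 0.0

    def test_zero_eccentricity_gives_circular_nucleoli(self):
        from skimage.measure import regionprops

        _, truth = syn.simulate_condensate_image(shape_eccentricity=0.0, seed=2)
        for p in regionprops(truth.masks["nucleolus"]):
            assert p.eccentricity < 0.05

    def test_overcrowded_field_raises(self):
        with pytest.raises(RuntimeError, match="overlap"):
            syn.simulate_condensate_image(n_nuclei=40, image_shape=(128, 128), seed=0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_condensate_image(K_true=0.0)
        with pytest.raises(ValueError):
            syn.simulate_condensate_image(shape_eccentricity=1.0)


class TestContourSeries:
    def test_expected_u2_matches_flicker_relation(self):
        # gamma = 1e-6 N/m at 310 K -> u2 = kB*310/1e-6 ~ 4.28e-15 m^2
        target = K_BOLTZMANN * 310.0 / 1e-6
        u2s = []
        for seed in range(50):
            series, truth = syn.simulate_contour_series(1e-6, 310.0, seed=seed)
            assert truth.true_u2 == pytest.approx(target, rel=1e-12)
            dev = series.radii - series.radii.mean()
            u2s.append((dev**2).mean())
        assert np.mean(u2s) == pytest.approx(target, rel=0.1)

    def test_rigid_limit_is_flat(self):
        series, truth = syn.simulate_contour_series(np.inf, 310.0, seed=0)
        assert truth.true_u2 == 0.0
        assert np.ptp(series.radii) == 0.0

    def test_extreme_tension_warns_but_generates(self):
        with pytest.warns(UserWarning, match="numerical resolution"):
            series, _ = syn.simulate_contour_series(1e6, 310.0, R0=2e-6, seed=0)
        assert series.radii.shape == (100, 256)

    def test_mode_content_excludes_breathing_and_translation(self):
        series, _ = syn.simulate_contour_series(1e-6, 310.0, seed=4)
        spec = np.fft.rfft(series.radii - 2e-6, axis=1)
        power = np.abs(spec) ** 2
        assert power[:, 1].max() < 1e-12 * power[:, 2:].max()


class TestDoseResponse:
    def test_zero_concentration_returns_ceiling_exactly(self):
        table, _ = syn.simulate_dose_response(10.0, I0=1.0, Imin=0.1, noise_sd=0.0, seed=0)
        at_zero = table[table.concentration == 0.0].response
        assert (at_zero == 1.0).all()

    def test_midpoint_at_EC50(self):
        table, _ = syn.simulate_dose_response(
            10.0, I0=1.0, Imin=0.1, concentrations=[0, 10.0, 100.0, 1000.0], noise_sd=0.0
        )
        at_ec50 = table[table.concentration == 10.0].response.iloc[0]
        assert at_ec50 == pytest.approx(0.55, rel=1e-12)

    def test_default_grid_is_the_assay_grid(self):
        table, _ = syn.simulate_dose_response(10.0, seed=0)
        assert sorted(table.concentration.unique()) == sorted(syn.MTT_CONCENTRATIONS_UM)
        assert len(syn.MTT_CONCENTRATIONS_UM) == 12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_dose_response(10.0, concentrations=[])
        with pytest.raises(ValueError):
            syn.simulate_dose_response(-1.0)


class TestQpcrTable:
    def test_unit_fold_change_leaves_ct_unchanged(self):
        table, _ = syn.simulate_qpcr_table({"untreated": 1.0, "treated": 1.0}, noise_sd=0.0)
        cts = table.groupby("condition").ct_target.mean()
        assert cts["treated"] == cts["untreated"]

    @pytest.mark.parametrize(
        "fold,delta", [(0.1, np.log2(10)), (2.0, -1.0), (0.5, 1.0)]
    )
    def test_fold_change_shifts_ct_by_minus_log2(self, fold, delta):
        table, _ = syn.simulate_qpcr_table({"untreated": 1.0, "treated": fold}, noise_sd=0.0)
        cts = table.groupby("condition").ct_target.mean()
        assert cts["treated"] - cts["untreated"] == pytest.approx(delta, abs=1e-12)

    def test_reference_condition_required(self):
        with pytest.raises(ValueError, match="reference"):
            syn.simulate_qpcr_table({"treated": 0.5})
        with pytest.raises(ValueError, match="non-positive"):
            syn.simulate_qpcr_table({"untreated": 1.0, "treated": -2.0})


class TestExpressionResistance:
    def test_perfect_correlation_is_degenerate(self):
        table, _ = syn.simulate_expression_resistance(50, rho_true=1.0, seed=0)
        rho = np.corrcoef(table.log2_tpm_NPM1, table.auc)[0, 1]
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_cohort_sizes_supported(self):
        # full cohort and the colorectal subset size
        for n in (371, 23):
            table, _ = syn.simulate_expression_resistance(n, rho_true=0.6, seed=1)
            assert len(table) == n

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_expression_resistance(2, 0.5)
        with pytest.raises(ValueError):
            syn.simulate_expression_resistance(10, 1.5)


@pytest.mark.parametrize(
    "factory",
    [
        lambda s: syn.simulate_condensate_image(seed=s)[0].pixels,
        lambda s: syn.simulate_contour_series(1e-6, seed=s)[0].radii,
        lambda s: syn.simulate_dose_response(10.0, seed=s)[0].response.to_numpy(),
        lambda s: syn.simulate_qpcr_table(
            {"untreated": 1.0, "t": 0.5}, noise_sd=0.3, seed=s
        )[0].ct_target.to_numpy(),
        lambda s: syn.simulate_expression_resistance(30, 0.5, seed=s)[0].auc.to_numpy(),
    ],
    ids=["image", "contour", "dose", "qpcr", "expr"],
)
def test_same_seed_bit_identical(factory):
    a, b = factory(123), factory(123)
    np.testing.assert_array_equal(a, b)
    c = factory(124)
    assert not np.array_equal(a, c)
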