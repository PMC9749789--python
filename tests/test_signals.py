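"""Rim enrichment, per-area signal bookkeeping and time-course fits."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from nucleoquant.segmentation import RegionLabelMap
from nucleoquant.signals import (
    SignalMeasurement,
    fit_association,
    normalize_timecourse,
    nucleolar_signal,
    rim_enrichment,
)
from tests.conftest import make_stack


def scene(n_foci=1, focus_radius=8, marker_value=None, rim_value=None, signal_value=200.0):
    """One nucleus with ``n_foci`` nucleoli; optional rim decoration."""
    shape = (128, 128)
    plane = np.full(shape, 0.0)
    nuc = np.zeros(shape, np.int32)
    foc = np.zeros(shape, np.int32)
    rr, cc = draw_disk((64, 64), 50, shape=shape)
    plane[rr, cc] = 100.0  # nucleoplasm
    nuc[rr, cc] = 1
    centers = [(64, 40), (64, 88), (40, 64), (88, 64)][:n_foci]
    rim_mask = np.zeros(shape, bool)
    for i, ctr in enumerate(centers, start=1):
        rr, cc = draw_disk(ctr, focus_radius, shape=shape)
        plane[rr, cc] = signal_value
        foc[rr, cc] = i
        rr2, cc2 = draw_disk(ctr, focus_radius + 3, shape=shape)
        band = np.zeros(shape, bool)
        band[rr2, cc2] = True
        band &= foc == 0
        rim_mask |= band
    if marker_value is not None:
        plane[:] = marker_value
    if rim_value is not None:
        plane[rim_mask] = rim_value
    stack = make_stack(plane, pixel_size=0.2)
    parents = {i: 1 for i in range(1, n_foci + 1)}
    return stack, RegionLabelMap(nuc, "nucleus"), RegionLabelMap(foc, "nucleolus", parent=parents)


class TestRimEnrichment:
    def test_uniform_marker_gives_unit_enrichment(self):
        stack, nuclei, nucleoli = scene(marker_value=500.0)
        recs = rim_enrichment(stack, 0, nucleoli, nuclei, rim_width=0.6)
        assert recs[0].enrichment == pytest.approx(1.0)

    def test_rim_decorated_nucleolus_recovers_ratio(self):
        # rim five times brighter than the nucleoplasm
        stack, nuclei, nucleoli = scene(rim_value=500.0)
        recs = rim_enrichment(stack, 0, nucleoli, nuclei, rim_width=0.6)
        assert recs[0].enrichment == pytest.approx(5.0, rel=0.1)

    def test_dispersed_marker_gives_near_zero(self):
        stack, nuclei, nucleoli = scene(rim_value=0.0)
        recs = rim_enrichment(stack, 0, nucleoli, nuclei, rim_width=0.6)
        assert recs[0].enrichment < 0.05

    def test_invariant_to_global_rescaling(self):
        stack, nuclei, nucleoli = scene(rim_value=500.0)
        scaled = make_stack(stack.pixels * 3.0, pixel_size=0.2)
        a = rim_enrichment(stack, 0, nucleoli, nuclei)[0].enrichment
        b = rim_enrichment(scaled, 0, nucleoli, nuclei)[0].enrichment
        assert a == pytest.approx(b, rel=1e-12)

    def test_whole_nucleolus_mode(self):
        stack, nuclei, nucleoli = scene(signal_value=300.0)
        recs = rim_enrichment(stack, 0, nucleoli, nuclei, mode="whole")
        assert recs[0].enrichment == pytest.approx(3.0)


class TestNucleolarSignal:
    def test_uniform_signal_returns_that_level(self):
        stack, nuclei, nucleoli = scene(signal_value=200.0)
        m = nucleolar_signal(stack, 0, nucleoli, nuclei)
        assert m.nucleolar_mean == pytest.approx(200.0)
        assert m.nucleoplasmic_mean == pytest.approx(100.0)

    def test_area_halving_keeps_mean_but_halves_total(self):
        # smaller nucleoli at constant per-pixel signal: per-area mean
        # unchanged, total signal tracks the area
        big_stack, big_nuc, big_foc = scene(n_foci=2, focus_radius=10)
        small_stack, small_nuc, small_foc = scene(n_foci=1, focus_radius=10)
        big = nucleolar_signal(big_stack, 0, big_foc, big_nuc)
        small = nucleolar_signal(small_stack, 0, small_foc, small_nuc)
        assert small.nucleolar_mean == pytest.approx(big.nucleolar_mean, rel=1e-9)
        area_ratio = (small_foc.labels > 0).sum() / (big_foc.labels > 0).sum()
        assert small.total_nucleolar_signal == pytest.approx(
            big.total_nucleolar_signal * area_ratio, rel=1e-9
        )

    def test_zero_signal_measures_zero(self):
        stack, nuclei, nucleoli = scene(signal_value=200.0)
        dark = make_stack(np.zeros_like(stack.pixels[0, 0]), pixel_size=0.2)
        m = nucleolar_signal(dark, 0, nucleoli, nuclei)
        assert m.nucleolar_mean == 0.0
        assert m.total_nucleolar_signal == 0.0

    def test_no_nucleoli_flagged(self):
        stack, nuclei, _ = scene()
        empty = RegionLabelMap(np.zeros_like(nuclei.labels), "nucleolus")
        m = nucleolar_signal(stack, 0, empty, nuclei)
        assert m.n_nucleoli == 0
        assert np.isnan(m.nucleolar_mean)


def _series(values, times=None, condition="untreated"):
    times = times if times is not None else list(range(len(values)))
    return [
        SignalMeasurement(condition=condition, time=t, nucleolar_mean=v,
                          nucleoplasmic_mean=v * 0.5, total_nucleolar_signal=v,
                          eccentricity_median=0.3, n_nucleoli=10)
        for t, v in zip(times, values)
    ]


class TestNormalizeTimecourse:
    def test_reference_becomes_one_and_series_scales(self):
        out = normalize_timecourse(_series([2.0, 4.0, 8.0]), "untreated")
        assert [m.nucleolar_mean for m in out] == [1.0, 2.0, 4.0]
        assert [m.nucleoplasmic_mean for m in out] == [1.0, 2.0, 4.0]

    def test_permutation_invariance(self):
        series = _series([2.0, 4.0, 8.0])
        shuffled = [series[2], series[0], series[1]]
        a = {m.time: m.nucleolar_mean for m in normalize_timecourse(series, "untreated")}
        b = {m.time: m.nucleolar_mean for m in normalize_timecourse(shuffled, "untreated")}
        assert a == b

    def test_missing_or_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="no reference"):
            normalize_timecourse(_series([1.0]), "oxaliplatin")
        with pytest.raises(ValueError, match="zero or undefined"):
            normalize_timecourse(_series([0.0, 2.0]), "untreated")


class TestFitAssociation:
    def test_noiseless_one_phase_recovered(self):
        t = np.linspace(0, 6, 10)
        y = 1.0 + (3.0 - 1.0) * (1 - np.exp(-0.7 * t))
        fit = fit_association(t, y, model="one-phase")
        assert fit.y0 == pytest.approx(1.0, rel=1e-4)
        assert fit.plateau == pytest.approx(3.0, rel=1e-4)
        assert fit.k == pytest.approx(0.7, rel=1e-4)
        assert fit.predict(0.0) == pytest.approx(fit.y0)

    def test_linear_fit_on_linear_data_has_zero_rss(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_association(t, 2.0 + 0.5 * t, model="linear")
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.slope == pytest.approx(0.5)

    def test_flat_data_pins_rate_at_zero_boundary(self):
        with pytest.warns(UserWarning, match="k=0 boundary"):
            fit = fit_association([0, 1, 2, 3], [2.0, 2.0, 2.0, 2.0], model="one-phase")
        assert fit.k == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_under_noise(self):
        # 5% noise, 100 Monte-Carlo repeats: y0 and plateau recovered
        # within 10%, the rate within 20% (median absolute error)
        rng_t = np.linspace(0, 8, 12)
        truth = 1.0 + (3.0 - 1.0) * (1 - np.exp(-0.7 * rng_t))
        y0s, plateaus, ks = [], [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = truth * (1 + rng.normal(0, 0.05, truth.shape))
            fit = fit_association(rng_t, y, model="one-phase")
            y0s.append(fit.y0)
            plateaus.append(fit.plateau)
            ks.append(fit.k)
        assert np.median(np.abs(np.array(y0s) - 1.0)) <= 0.1
        assert np.median(np.abs(np.array(plateaus) - 3.0) / 3.0) <= 0.1
        assert np.median(np.abs(np.array(ks) - 0.7) / 0.7) <= 0.2

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_association([0, 1], [1, 2], model="one-phase")
        with pytest.raises(ValueError):
            fit_association([0], [1], model="linear")
        with pytest.raises(ValueError):
            fit_association([0, 1, 2], [1, 2, 3], model="quadratic")
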