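"""Through-focus curve construction and peak/best-focus/DOF extraction."""

import math

import numpy as np
import pytest

from kciq import RunConfig
from kciq.pipeline import run_throughfocus
from kciq.throughfocus import (ThroughFocusCurve, build_curve,
                               default_vergences, median_curve,
                               summarize_curve)
from kciq.zernike import ZernikeCoefficients

CFG = RunConfig(psf_pad_factor=4)


def make_curve(fn):
    v = default_vergences()
    return ThroughFocusCurve(v, fn(v))


def gaussian_ns_curve():
    return make_curve(lambda v: np.log10(np.exp(-v ** 2)))


def test_default_grid_shape():
    v = default_vergences()
    assert len(v) == 17 and v[0] == -4.0 and v[-1] == 4.0
    assert np.allclose(np.diff(v), 0.5)


def test_spline_interpolates_samples():
    curve = gaussian_ns_curve()
    idx = np.searchsorted(curve.fine_vergences, curve.vergences)
    assert np.allclose(curve.fine_log_ns[idx], curve.log_ns, atol=1e-9)


def test_decreasing_grid_rejected():
    with pytest.raises(ValueError, match="increasing"):
        ThroughFocusCurve(np.array([0.0, -1.0]), np.array([0.0, 0.0]))


class TestSummarize:
    def test_gaussian_closed_form_dof(self):
        s = summarize_curve(gaussian_ns_curve())
        assert s.peak_iq == pytest.approx(0.0, abs=1e-9)
        assert s.best_focus == 0.0
        assert s.dof_width == pytest.approx(2 * math.sqrt(math.log(1 / 0.7)),
                                            abs=1e-3)
        assert not s.censored_low and not s.censored_high
        assert s.dof_interval[0] == pytest.approx(-s.dof_interval[1], abs=1e-6)

    def test_monotone_curve_censored(self):
        s = summarize_curve(make_curve(lambda v: -0.1 * v))
        assert s.best_focus == -4.0
        assert s.censored_low and not s.censored_high
        assert s.dof_interval[0] == -4.0

    def test_threshold_monotonicity(self):
        for curve in (gaussian_ns_curve(),
                      make_curve(lambda v: -0.3 * np.abs(v))):
            widths = [summarize_curve(curve, f).dof_width
                      for f in (0.8, 0.7, 0.5)]
            assert widths[0] <= widths[1] <= widths[2]

    def test_plateau_tie_break_prefers_emmetropia(self):
        s = summarize_curve(make_curve(lambda v: np.full_like(v, -1.0)))
        assert s.best_focus == 0.0
        assert s.censored_low and s.censored_high

    def test_nonfinite_rejected(self):
        v = default_vergences()
        y = np.zeros_like(v)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            summarize_curve(ThroughFocusCurve(v, y))

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            summarize_curve(gaussian_ns_curve(), threshold_fraction=1.5)

    def test_logns_scale_option(self):
        curve = make_curve(lambda v: -1.0 - 0.5 * v ** 2)
        lin = summarize_curve(curve, threshold_scale="ns")
        log = summarize_curve(curve, threshold_scale="logns")
        # log-scale floor: peak/0.7 = −1.429, vs NS-scale peak−0.155 = −1.155
        assert log.dof_width == pytest.approx(
            2 * math.sqrt((1 / 0.7 - 1.0) / 0.5 * 1.0), abs=2e-2)
        assert log.dof_width > lin.dof_width
        with pytest.raises(ValueError, match="positive peak"):
            summarize_curve(make_curve(lambda v: 1.0 - v ** 2),
                            threshold_scale="logns")
        with pytest.raises(ValueError, match="unknown"):
            summarize_curve(curve, threshold_scale="bogus")

    def test_secondary_islands_reported(self):
        v = default_vergences()
        y = np.where(np.abs(v) > 3.4, -0.05, -3.0)   # bimodal edges
        y[8] = 0.0                                   # main peak at 0 D
        s = summarize_curve(ThroughFocusCurve(v, y))
        assert s.secondary_intervals
        assert all(hi < s.dof_interval[0] or lo > s.dof_interval[1]
                   for lo, hi in s.secondary_intervals)


@pytest.fixture(scope="module")
def dl_curve():
    return build_curve(ZernikeCoefficients({}, 5.0),
                       samples_across_pupil=256, pad_factor=4)


@pytest.fixture(scope="module")
def coma_curve():
    return run_throughfocus(ZernikeCoefficients({(3, -1): -0.96}, 5.0), CFG)


class TestBuiltCurves:
    def test_dl_curve_peak_at_emmetropia(self, dl_curve):
        s = summarize_curve(dl_curve)
        assert s.best_focus == 0.0
        assert s.peak_iq == pytest.approx(0.0, abs=1e-9)

    def test_dl_curve_symmetric(self, dl_curve):
        assert np.allclose(dl_curve.log_ns, dl_curve.log_ns[::-1], atol=1e-3)

    def test_baseline_defocus_ignored(self, dl_curve):
        # the sweep zeroes second-order terms first, so a baseline refractive
        # error does not change the curve
        with_lo = build_curve(
            ZernikeCoefficients({(2, 0): 1.3, (2, -2): 0.4}, 5.0),
            samples_across_pupil=256, pad_factor=4)
        assert np.allclose(with_lo.log_ns, dl_curve.log_ns, atol=1e-9)

    def test_coma_curve_symmetric_lower_and_flatter(self, dl_curve, coma_curve):
        assert np.allclose(coma_curve.log_ns, coma_curve.log_ns[::-1],
                           atol=1e-3)
        v = coma_curve.vergences
        near = np.abs(v) <= 0.5
        assert np.all(coma_curve.log_ns[near] < dl_curve.log_ns[near])
        # flatter: the drop from the peak out to 1 D is much smaller than
        # for the aberration-free eye
        drop = lambda c: c.log_ns[v == 0.0][0] - c.log_ns[np.abs(v) == 1.0].mean()
        assert drop(coma_curve) < 0.5 * drop(dl_curve)

    def test_coma_widens_dof_and_lowers_peak(self, dl_curve):
        peaks, dofs = [], []
        for mag in (0.0, 0.5, 1.0, 1.5):
            curve = run_throughfocus(
                ZernikeCoefficients({(3, -1): -mag}, 5.0), CFG)
            s = summarize_curve(curve)
            peaks.append(s.peak_iq)
            dofs.append(s.dof_width)
        assert all(b <= a + 1e-6 for a, b in zip(peaks, peaks[1:]))
        assert all(b >= a - 1e-6 for a, b in zip(dofs, dofs[1:]))

    def test_spherical_aberration_shifts_best_focus_antisymmetrically(self):
        pos = summarize_curve(run_throughfocus(
            ZernikeCoefficients({(4, 0): 0.3}, 5.0), CFG))
        neg = summarize_curve(run_throughfocus(
            ZernikeCoefficients({(4, 0): -0.3}, 5.0), CFG))
        assert pos.best_focus > 0.1
        assert neg.best_focus == pytest.approx(-pos.best_focus, abs=0.02)

    def test_interpolation_overshoot_bounded(self, dl_curve, coma_curve):
        for curve in (dl_curve, coma_curve):
            overshoot = curve.fine_log_ns.max() - curve.log_ns.max()
            assert overshoot < 0.05


class TestMedianCurve:
    def test_single_curve_identity(self):
        c = gaussian_ns_curve()
        v, med, q25, q75 = median_curve([c])
        assert np.allclose(med, c.log_ns)
        assert np.allclose(q75 - q25, 0.0)

    def test_pointwise_median(self):
        v = default_vergences()
        curves = [ThroughFocusCurve(v, np.full_like(v, y))
                  for y in (-1.0, -2.0, -6.0)]
        _, med, _, _ = median_curve(curves)
        assert np.allclose(med, -2.0)

    def test_mismatched_grids_rejected(self):
        a = gaussian_ns_curve()
        v = np.linspace(-3, 3, 13)
        b = ThroughFocusCurve(v, np.zeros_like(v))
        with pytest.raises(ValueError, match="mismatch"):
            median_curve([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_curve([])
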