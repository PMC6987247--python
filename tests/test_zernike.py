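"""Zernike basis, wavefront synthesis, defocus conversion and pupil rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import eval_jacobi

from kciq.zernike import (ZernikeCoefficients, average_replicates,
                          defocus_to_coeff, evaluate_basis, horms,
                          rescale_coeffs, term_indices, wavefront_from_coeffs)


def jacobi_basis(n, m, rho, theta):
    """Independent Zernike evaluation via Jacobi polynomials."""
    k = (n - abs(m)) // 2
    radial = ((-1) ** k * rho ** abs(m)
              * eval_jacobi(k, abs(m), 0, 1 - 2 * rho ** 2))
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = 1.0
    return norm * radial * ang


@pytest.mark.parametrize("n,m,rho,theta,expected", [
    (0, 0, 0.37, 1.1, 1.0),                        # piston
    (2, 0, 1.0, 0.0, math.sqrt(3)),                # √3(2ρ²−1) at ρ=1
    (4, 0, 0.5, 0.77, math.sqrt(5) * -0.125),      # √5(6ρ⁴−6ρ²+1) at ρ=0.5
    (1, 1, 0.5, 0.0, 1.0),                         # tilt: 2ρcosθ
    (3, -1, 1.0, math.pi / 2, math.sqrt(8)),       # coma edge, sine meridian
])
def test_basis_closed_forms(n, m, rho, theta, expected):
    assert evaluate_basis(n, m, rho, theta) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("n,m", [(2, 1), (3, 4), (-1, 0), (4, -3)])
def test_invalid_indices_rejected(n, m):
    with pytest.raises(IndexError, match=rf"n={n}, m={m}"):
        evaluate_basis(n, m, 0.5, 0.0)


def test_basis_matches_jacobi_oracle(rng):
    rho = rng.random(200)
    theta = rng.uniform(0, 2 * math.pi, 200)
    for n, m in term_indices(6):
        got = evaluate_basis(n, m, rho, theta)
        want = jacobi_basis(n, m, rho, theta)
        assert np.allclose(got, want, atol=1e-10), (n, m)


def test_orthonormality_by_quadrature():
    # mid-point quadrature over a fine polar grid
    nr, nt = 400, 256
    r = (np.arange(nr) + 0.5) / nr
    t = 2 * math.pi * np.arange(nt) / nt
    rr, tt = np.meshgrid(r, t, indexing="ij")
    w = rr / (nr * nt / (2 * math.pi)) / math.pi  # dA/π
    terms = term_indices(6)
    basis = {k: evaluate_basis(*k, rr, tt) for k in terms}
    for i, a in enumerate(terms):
        self_ip = np.sum(w * basis[a] * basis[a])
        assert self_ip == pytest.approx(1.0, abs=1e-3), a
        for b in terms[i + 1:]:
            assert abs(np.sum(w * basis[a] * basis[b])) < 1e-3, (a, b)


def test_wavefront_zero_and_single_term():
    zero = wavefront_from_coeffs(ZernikeCoefficients({}, 5.0), 128)
    assert np.all(zero.values == 0)
    one = wavefront_from_coeffs(ZernikeCoefficients({(2, 0): 1.0}, 5.0), 256)
    assert one.rms() == pytest.approx(1.0, abs=1e-3)
    coma = wavefront_from_coeffs(ZernikeCoefficients({(3, -1): -0.96}, 5.0), 256)
    assert coma.rms() == pytest.approx(0.96, abs=1e-3)


def test_wavefront_parseval_random_set(rng):
    terms = {k: rng.normal(0, 0.3) for k in term_indices(6, min_order=1)}
    wf = wavefront_from_coeffs(ZernikeCoefficients(terms, 5.0), 256)
    expected = math.sqrt(sum(c * c for c in terms.values()))
    assert wf.rms() == pytest.approx(expected, rel=2e-3)


def test_wavefront_rejects_coarse_grid():
    with pytest.raises(ValueError, match="128"):
        wavefront_from_coeffs(ZernikeCoefficients({}, 5.0), 64)


def test_horms_definition():
    assert horms(ZernikeCoefficients({}, 5.0)) == 0.0
    assert horms(ZernikeCoefficients({(3, -1): 0.3, (4, 0): 0.4}, 5.0)) == \
        pytest.approx(0.5)
    # second-order terms are excluded
    assert horms(ZernikeCoefficients({(3, -1): -0.96, (2, 0): 5.0}, 5.0)) == \
        pytest.approx(0.96)


@pytest.mark.parametrize("vergence,expected", [
    (0.0, 0.0),
    (0.5, 0.451054),
    (4.0, 3.608439),
    (-0.5, -0.451054),
])
def test_defocus_conversion(vergence, expected):
    assert defocus_to_coeff(vergence, 5.0) == pytest.approx(expected, abs=1e-6)


class TestAverageReplicates:
    def test_single_replicate_identity(self):
        c = ZernikeCoefficients({(3, 3): 0.2}, 5.5)
        out = average_replicates([c])
        assert out.terms == c.terms and out.pupil_diameter_mm == 5.5

    def test_termwise_mean(self):
        a = ZernikeCoefficients({(3, 3): 0.2}, 6.0)
        b = ZernikeCoefficients({(3, 3): 0.4}, 6.0)
        assert average_replicates([a, b]).terms[(3, 3)] == pytest.approx(0.3)
        reps = [ZernikeCoefficients({(4, 0): v}, 6.0) for v in (0.1, 0.2, 0.6)]
        assert average_replicates(reps).terms[(4, 0)] == pytest.approx(0.3)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            average_replicates([])

    def test_wavelength_mismatch_rejected(self):
        a = ZernikeCoefficients({}, 6.0, wavelength_um=0.555)
        b = ZernikeCoefficients({}, 6.0, wavelength_um=0.840)
        with pytest.raises(ValueError, match="wavelength"):
            average_replicates([a, b])

    def test_pupil_mismatch_rejected(self):
        a = ZernikeCoefficients({}, 6.0)
        b = ZernikeCoefficients({}, 5.0)
        with pytest.raises(ValueError, match="5%"):
            average_replicates([a, b])


class TestRescale:
    def test_identity_at_same_diameter(self):
        c = ZernikeCoefficients({(3, -1): -0.96}, 6.0)
        out = rescale_coeffs(c, 6.0)
        assert out.terms == c.terms

    def test_pure_defocus_closed_form(self):
        c = ZernikeCoefficients({(2, 0): 1.0}, 6.0)
        out = rescale_coeffs(c, 5.0)
        assert out.terms[(2, 0)] == pytest.approx((5 / 6) ** 2, abs=1e-6)
        assert (0, 0) not in out.terms

    def test_pure_spherical_closed_form(self):
        out = rescale_coeffs(ZernikeCoefficients({(4, 0): 1.0}, 6.0), 5.0)
        s2 = (5 / 6) ** 2
        assert out.terms[(4, 0)] == pytest.approx(s2 * s2, abs=1e-6)
        assert out.terms[(2, 0)] == pytest.approx(
            math.sqrt(15) * s2 * (s2 - 1), abs=1e-6)

    def test_upscaling_rejected(self):
        with pytest.raises(ValueError, match="extrapolat"):
            rescale_coeffs(ZernikeCoefficients({}, 5.0), 6.0)

    def test_restriction_pointwise_oracle(self, rng):
        terms = {k: rng.normal(0, 0.5) for k in term_indices(6, min_order=1)}
        c = ZernikeCoefficients(terms, 6.0)
        out = rescale_coeffs(c, 5.0)
        s = 5.0 / 6.0
        rho = np.linspace(0, 1, 60)
        theta = np.linspace(0, 2 * math.pi, 61)
        rr, tt = np.meshgrid(rho, theta)
        w_orig = sum(v * evaluate_basis(n, m, s * rr, tt)
                     for (n, m), v in c.terms.items())
        w_new = sum(v * evaluate_basis(n, m, rr, tt)
                    for (n, m), v in out.terms.items())
        diff = w_orig - w_new          # may differ by the discarded piston
        assert np.ptp(diff) < 1e-6

    def test_composition(self, rng):
        terms = {k: rng.normal(0, 0.4) for k in term_indices(6, min_order=2)}
        c = ZernikeCoefficients(terms, 6.0)
        two_step = rescale_coeffs(rescale_coeffs(c, 5.5), 5.0)
        one_step = rescale_coeffs(c, 5.0)
        for k in term_indices(6, min_order=1):
            assert two_step.terms.get(k, 0.0) == pytest.approx(
                one_step.terms.get(k, 0.0), abs=1e-8)

    def test_linearity(self, rng):
        a = {k: rng.normal(0, 0.3) for k in term_indices(5, min_order=2)}
        b = {k: rng.normal(0, 0.3) for k in term_indices(5, min_order=2)}
        summed = rescale_coeffs(ZernikeCoefficients(
            {k: a[k] + b[k] for k in a}, 6.0, max_order=5), 5.0)
        parts_a = rescale_coeffs(ZernikeCoefficients(a, 6.0, max_order=5), 5.0)
        parts_b = rescale_coeffs(ZernikeCoefficients(b, 6.0, max_order=5), 5.0)
        for k in term_indices(5, min_order=1):
            assert summed.terms.get(k, 0.0) == pytest.approx(
                parts_a.terms.get(k, 0.0) + parts_b.terms.get(k, 0.0), abs=1e-9)

    @pytest.mark.parametrize("term", [(6, 0), (6, -4), (5, 3)])
    def test_downscaling_shrinks_pure_top_order_horms(self, term):
        c = ZernikeCoefficients({term: 1.0}, 6.0)
        assert horms(rescale_coeffs(c, 5.0)) <= horms(c)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1.0, 1.0), min_size=27, max_size=27),
       st.floats(0.5, 0.99))
def test_rescale_restriction_property(values, s):
    """Rescaled coefficients reproduce the restricted wavefront pointwise."""
    keys = term_indices(6, min_order=1)
    c = ZernikeCoefficients(dict(zip(keys, values)), 6.0)
    out = rescale_coeffs(c, 6.0 * s)
    rho = np.linspace(0, 1, 25)
    theta = np.linspace(0, 2 * math.pi, 23)
    rr, tt = np.meshgrid(rho, theta)
    w_orig = sum(v * evaluate_basis(n, m, s * rr, tt)
                 for (n, m), v in c.terms.items())
    w_new = sum(v * evaluate_basis(n, m, rr, tt)
                for (n, m), v in out.terms.items())
    assert np.ptp(w_orig - w_new) < 1e-6
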