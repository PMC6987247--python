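"""Zernike wavefront representation and manipulation.

Coefficients follow the OSA/ANSI double-index convention: each term is
identified by radial order ``n`` and azimuthal frequency ``m`` (``|m| <= n``,
``n - |m|`` even) and carries unit-variance normalization, so a coefficient in
micrometres equals the RMS wavefront contribution of that term over the pupil.
Negative ``m`` denotes the sine harmonic, positive ``m`` the cosine harmonic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ZernikeCoefficients",
    "WavefrontMap",
    "evaluate_basis",
    "wavefront_from_coeffs",
    "horms",
    "defocus_to_coeff",
    "average_replicates",
    "rescale_coeffs",
    "term_indices",
]


def _validate_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise IndexError(f"invalid Zernike index (n={n}, m={m}): "
                         "require n >= 0, |m| <= n, n - |m| even")


def term_indices(max_order: int, min_order: int = 0) -> list[tuple[int, int]]:
    """All valid (n, m) pairs with ``min_order <= n <= max_order``."""
    out = []
    for n in range(min_order, max_order + 1):
        for m in range(-n, n + 1, 2):
            out.append((n, m))
    return out


@dataclass(frozen=True)
class ZernikeCoefficients:
    """A wavefront described by OSA-indexed Zernike coefficients in µm.

    Absent terms are exactly zero. ``pupil_diameter_mm`` is the pupil over
    which the coefficients are defined; ``wavelength_um`` the design
    wavelength (default 555 nm, peak photopic sensitivity).
    """

    terms: Mapping[tuple[int, int], float]
    pupil_diameter_mm: float
    wavelength_um: float = 0.555
    max_order: int = 6

    def __post_init__(self):
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil_diameter_mm must be positive")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        clean = {}
        for (n, m), c in dict(self.terms).items():
            _validate_nm(int(n), int(m))
            clean[(int(n), int(m))] = float(c)
        object.__setattr__(self, "terms", clean)

    def get(self, n: int, m: int) -> float:
        _validate_nm(n, m)
        return self.terms.get((n, m), 0.0)

    def with_terms(self, updates: Mapping[tuple[int, int], float]) -> "ZernikeCoefficients":
        """Return a copy with the given terms overwritten."""
        new = dict(self.terms)
        new.update({k: float(v) for k, v in updates.items()})
        return replace(self, terms=new)

    def drop_terms(self, keys: Iterable[tuple[int, int]]) -> "ZernikeCoefficients":
        new = {k: v for k, v in self.terms.items() if k not in set(keys)}
        return replace(self, terms=new)


@dataclass(frozen=True)
class WavefrontMap:
    """Sampled optical path difference (µm) over a square grid spanning the pupil."""

    values: np.ndarray
    mask: np.ndarray
    pupil_diameter_mm: float

    def rms(self) -> float:
        """RMS of the wavefront over the pupil mask."""
        return float(np.sqrt(np.mean(self.values[self.mask] ** 2)))


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    k_max = (n - m_abs) // 2
    out = np.zeros_like(rho, dtype=float)
    for k in range(k_max + 1):
        coef = ((-1) ** k * math.factorial(n - k)
                / (math.factorial(k)
                   * math.factorial((n + m_abs) // 2 - k)
                   * math.factorial((n - m_abs) // 2 - k)))
        out += coef * rho ** (n - 2 * k)
    return out


def evaluate_basis(n: int, m: int, rho, theta):
    """Evaluate the unit-variance (OSA-normalized) Zernike polynomial Z(n, m).

    ``rho`` is the normalized pupil radius in [0, 1], ``theta`` the azimuth in
    radians. Accepts scalars or arrays (broadcast).
    """
    _validate_nm(n, m)
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2 * (n + 1))
    radial = _radial_poly(n, abs(m), rho)
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(np.broadcast_arrays(rho, theta)[1])
    out = norm * radial * ang
    return out if out.shape else float(out)


def _unit_grid(samples: int):
    # sample centers offset by half a pixel so the grid is symmetric about 0
    x = (np.arange(samples) - samples / 2 + 0.5) * (2.0 / samples)
    xx, yy = np.meshgrid(x, x)
    rho = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    return rho, theta


def wavefront_from_coeffs(coeffs: ZernikeCoefficients,
                          samples_across_pupil: int = 256) -> WavefrontMap:
    """Reconstruct the sampled wavefront W(ρ, θ) = Σ c(n,m) Z(n,m)."""
    if samples_across_pupil < 128:
        raise ValueError("samples_across_pupil must be >= 128")
    rho, theta = _unit_grid(samples_across_pupil)
    mask = rho <= 1.0
    values = np.zeros_like(rho)
    for (n, m), c in coeffs.terms.items():
        if c != 0.0:
            values += c * evaluate_basis(n, m, rho, theta)
    values = np.where(mask, values, 0.0)
    return WavefrontMap(values=values, mask=mask,
                        pupil_diameter_mm=coeffs.pupil_diameter_mm)


def horms(coeffs: ZernikeCoefficients) -> float:
    """Higher-order RMS: sqrt of the sum of squared coefficients with n >= 3 (µm)."""
    return float(np.sqrt(sum(c * c for (n, _m), c in coeffs.terms.items() if n >= 3)))


def defocus_to_coeff(vergence_d: float, pupil_diameter_mm: float) -> float:
    """Defocus Zernike coefficient ΔZ(2,0) in µm equivalent to a spherical vergence.

    ΔZ(2,0) = V · r² / (4√3) with r the pupil radius in mm and V in diopters.
    Positive vergence is labeled induced myopia on the through-focus axis.
    """
    if pupil_diameter_mm <= 0:
        raise ValueError("pupil_diameter_mm must be positive")
    r = pupil_diameter_mm / 2.0
    return vergence_d * r * r / (4.0 * math.sqrt(3.0))


def average_replicates(replicates: list[ZernikeCoefficients]) -> ZernikeCoefficients:
    """Term-wise arithmetic mean of repeated measurements of one eye.

    Replicates must share the wavelength exactly and agree on pupil diameter
    within 5%; the output carries the mean pupil diameter.
    """
    if not replicates:
        raise ValueError("average_replicates requires at least one replicate")
    wl = replicates[0].wavelength_um
    if any(r.wavelength_um != wl for r in replicates):
        raise ValueError("replicates measured at different wavelengths")
    diam = np.array([r.pupil_diameter_mm for r in replicates])
    if diam.max() > 1.05 * diam.min():
        raise ValueError(
            f"replicate pupil diameters differ by more than 5%: {sorted(diam)}")
    keys = set()
    for r in replicates:
        keys.update(r.terms)
    mean_terms = {k: float(np.mean([r.terms.get(k, 0.0) for r in replicates]))
                  for k in keys}
    return ZernikeCoefficients(
        terms=mean_terms,
        pupil_diameter_mm=float(diam.mean()),
        wavelength_um=wl,
        max_order=max(r.max_order for r in replicates),
    )


def _quadrature_nodes(max_order: int):
    """Gauss-Legendre × uniform-azimuth nodes exact for polynomials of the basis order.

    Nodes in ρ² make the radial quadrature exact for radial polynomials up to
    degree 2·max_order; the azimuthal trapezoid is exact for harmonics up to
    the node count.
    """
    n_r = max(2 * max_order + 2, 24)
    n_t = max(4 * max_order + 4, 64)
    u, w = np.polynomial.legendre.leggauss(n_r)  # on [-1, 1]
    rho2 = 0.5 * (u + 1.0)
    rho = np.sqrt(rho2)
    w_r = 0.5 * w  # ∫ f(ρ²) dρ² over [0,1]; area element 2ρdρ = dρ²
    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    return rho, w_r, theta


def rescale_coeffs(coeffs: ZernikeCoefficients,
                   target_diameter_mm: float) -> ZernikeCoefficients:
    """Re-express a coefficient set over a smaller concentric pupil.

    The wavefront is evaluated on the restricted pupil (radius ratio
    s = target/source) and re-projected onto the same Zernike order set; the
    projection is exact because the restriction is itself a polynomial of the
    same degree. The piston change induced by restriction is discarded.
    Upscaling would extrapolate beyond the measured pupil and is rejected.
    """
    if target_diameter_mm <= 0:
        raise ValueError("target_diameter_mm must be positive")
    if target_diameter_mm > coeffs.pupil_diameter_mm * (1 + 1e-12):
        raise ValueError(
            f"cannot rescale {coeffs.pupil_diameter_mm} mm coefficients up to "
            f"{target_diameter_mm} mm: extrapolation beyond the measured pupil")
    s = target_diameter_mm / coeffs.pupil_diameter_mm
    if abs(s - 1.0) < 1e-12:
        return replace(coeffs, pupil_diameter_mm=float(target_diameter_mm))

    rho, w_r, theta = _quadrature_nodes(coeffs.max_order)
    rr, tt = np.meshgrid(rho, theta, indexing="ij")
    # original wavefront sampled at the restricted radius s·ρ'
    w_restricted = np.zeros_like(rr)
    for (n, m), c in coeffs.terms.items():
        if c != 0.0:
            w_restricted += c * evaluate_basis(n, m, s * rr, tt)
    # Project onto the orthonormal basis: c'_j = (1/π)∫∫ W Z_j ρ dρ dθ, which
    # with the dρ² Gauss weights (Σw_r = 1) and the azimuthal mean reduces to
    # mean_θ[Σ_r w_r · W · Z_j]. Exact: the restricted wavefront is a
    # polynomial within the quadrature degree.
    n_t = theta.size
    new_terms = {
        k: float(np.sum(w_r[:, None] * w_restricted
                        * evaluate_basis(k[0], k[1], rr, tt)) / n_t)
        for k in term_indices(coeffs.max_order)
    }
    new_terms.pop((0, 0), None)  # piston change from restriction is irrelevant
    new_terms = {k: v for k, v in new_terms.items() if abs(v) > 1e-14}
    return ZernikeCoefficients(
        terms=new_terms,
        pupil_diameter_mm=float(target_diameter_mm),
        wavelength_um=coeffs.wavelength_um,
        max_order=coeffs.max_order,
    )
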