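"""Through-focus logNS curves and their summary parameters.

A through-focus curve sweeps spherical vergence from 4 D of hyperopia to 4 D
of induced myopia in 0.5 D steps by substituting the equivalent defocus
coefficient Z(2,0) while leaving higher-order terms untouched, emulating a
spectacle lens that manipulates only the lower-order refraction. Positive
vergence denotes induced myopia. Three parameters summarize each curve: the
peak IQ (maximum logNS), the best focus (vergence at the peak) and the depth
of focus (contiguous vergence interval where NS stays above a fraction —
70% by default — of its peak value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import optics
from .zernike import ZernikeCoefficients, defocus_to_coeff

__all__ = [
    "ThroughFocusCurve",
    "IQSummary",
    "build_curve",
    "summarize_curve",
    "median_curve",
    "default_vergences",
]


def default_vergences(v_min: float = -4.0, v_max: float = 4.0,
                      step: float = 0.5) -> np.ndarray:
    n = int(round((v_max - v_min) / step))
    return np.round(np.linspace(v_min, v_max, n + 1), 6)


@dataclass(frozen=True)
class ThroughFocusCurve:
    """Sampled logNS vs vergence plus a cubic-spline fine-grid representation."""

    vergences: np.ndarray
    log_ns: np.ndarray
    fine_vergences: np.ndarray = field(repr=False, default=None)
    fine_log_ns: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        v = np.asarray(self.vergences, dtype=float)
        y = np.asarray(self.log_ns, dtype=float)
        if v.ndim != 1 or v.shape != y.shape:
            raise ValueError("vergences and log_ns must be matching 1-D arrays")
        if np.any(np.diff(v) <= 0):
            raise ValueError("vergence grid must be strictly increasing")
        object.__setattr__(self, "vergences", v)
        object.__setattr__(self, "log_ns", y)
        if self.fine_vergences is None:
            spline = CubicSpline(v, y)
            fine_v = np.round(np.arange(round(v[0] * 100), round(v[-1] * 100) + 1)
                              / 100.0, 6)
            object.__setattr__(self, "fine_vergences", fine_v)
            object.__setattr__(self, "fine_log_ns", spline(fine_v))


@dataclass(frozen=True)
class IQSummary:
    """Peak IQ, best focus and 70%-threshold depth of focus of one curve."""

    peak_iq: float
    best_focus: float
    dof_width: float
    dof_interval: tuple[float, float]
    censored_low: bool
    censored_high: bool
    secondary_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        lo, hi = self.dof_interval
        if not (lo - 1e-9 <= self.best_focus <= hi + 1e-9):
            raise ValueError("dof_interval must contain best_focus")
        if self.dof_width < -1e-9 or self.dof_width > 8.0 + 1e-9:
            raise ValueError("dof_width must lie in [0, 8] D")


def build_curve(coeffs: ZernikeCoefficients,
                vergences: np.ndarray | None = None,
                samples_across_pupil: int = 256,
                pad_factor: int = 8,
                sigma_arcmin: float = 1.0) -> ThroughFocusCurve:
    """Sweep the defocus term and evaluate logNS at each vergence.

    The baseline defocus Z(2,0) and both astigmatism terms Z(2,±2) are zeroed
    first (full sphero-cylindrical correction); each vergence V then sets
    Z(2,0) to its dioptric equivalent over the coefficient pupil.
    """
    if vergences is None:
        vergences = default_vergences()
    base = coeffs.with_terms({(2, 0): 0.0, (2, -2): 0.0, (2, 2): 0.0})
    values = np.empty(len(vergences))
    for i, v in enumerate(vergences):
        c20 = defocus_to_coeff(float(v), coeffs.pupil_diameter_mm)
        values[i] = optics.log_ns(base.with_terms({(2, 0): c20}),
                                  samples_across_pupil, pad_factor, sigma_arcmin)
    return ThroughFocusCurve(vergences=np.asarray(vergences, float),
                             log_ns=values)


def _contiguous_interval(v: np.ndarray, above: np.ndarray, i_peak: int):
    lo = i_peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < len(v) - 1 and above[hi + 1]:
        hi += 1
    return lo, hi


def summarize_curve(curve: ThroughFocusCurve,
                    threshold_fraction: float = 0.70,
                    threshold_scale: str = "ns") -> IQSummary:
    """Extract peak IQ, best focus and depth of focus from the fine curve.

    The DOF threshold is applied on the linear NS scale by default
    (NS >= f·NS_peak, i.e. logNS >= peak + log10(f)); ``threshold_scale='logns'``
    instead thresholds logNS directly at f·peak, which is only meaningful for
    negative peaks. If the fine maximum is a plateau (within 1e-6), the
    plateau point closest to 0 D is reported as best focus. Disjoint
    super-threshold islands away from the best focus are reported separately
    and excluded from the DOF width.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    v = curve.fine_vergences
    y = curve.fine_log_ns
    if not np.all(np.isfinite(y)):
        raise ValueError("through-focus curve contains non-finite values")
    peak = float(y.max())
    plateau = np.flatnonzero(y >= peak - 1e-6)
    i_peak = plateau[np.argmin(np.abs(v[plateau]))]
    best_focus = float(v[i_peak])

    if threshold_scale == "ns":
        thr = peak + np.log10(threshold_fraction)
    elif threshold_scale == "logns":
        # "above f of peak" read on the log scale: multiplying a negative
        # peak by f < 1 would put the floor above the peak, so divide instead
        if peak > 0:
            raise ValueError("logNS-scale threshold undefined for positive peak")
        thr = peak / threshold_fraction
    else:
        raise ValueError(f"unknown threshold_scale {threshold_scale!r}")

    above = y >= thr
    lo, hi = _contiguous_interval(v, above, i_peak)
    # refine the crossing positions below the fine-grid spacing
    v_lo = float(v[lo])
    if lo > 0 and y[lo] != y[lo - 1]:
        v_lo = float(v[lo] - (v[lo] - v[lo - 1]) * (y[lo] - thr) / (y[lo] - y[lo - 1]))
    v_hi = float(v[hi])
    if hi < len(v) - 1 and y[hi] != y[hi + 1]:
        v_hi = float(v[hi] + (v[hi + 1] - v[hi]) * (y[hi] - thr) / (y[hi] - y[hi + 1]))
    interval = (v_lo, v_hi)
    # disjoint super-threshold islands (possible for flat multimodal curves)
    padded = np.concatenate(([False], above, [False])).astype(int)
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1) - 1
    secondary = [(float(v[s]), float(v[e]))
                 for s, e in zip(starts, ends) if not (s <= i_peak <= e)]

    return IQSummary(
        peak_iq=peak,
        best_focus=best_focus,
        dof_width=float(interval[1] - interval[0]),
        dof_interval=interval,
        censored_low=bool(lo == 0),
        censored_high=bool(hi == len(v) - 1),
        secondary_intervals=tuple(secondary),
    )


def median_curve(curves: list[ThroughFocusCurve]):
    """Vergence-wise median and 25th/75th percentile curves of a group.

    Returns ``(vergences, median, q25, q75)`` arrays.
    """
    if not curves:
        raise ValueError("median_curve requires at least one curve")
    v0 = curves[0].vergences
    for c in curves[1:]:
        if c.vergences.shape != v0.shape or not np.allclose(c.vergences, v0):
            raise ValueError("curves have mismatched vergence grids")
    stack = np.vstack([c.log_ns for c in curves])
    return (v0.copy(),
            np.median(stack, axis=0),
            np.percentile(stack, 25, axis=0),
            np.percentile(stack, 75, axis=0))
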