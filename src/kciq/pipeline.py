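"""End-to-end orchestration: simulate cohorts, sweep focus, summarize.

Ties the generator, wavefront handling, PSF metric and curve summaries
together behind :class:`~kciq.config.RunConfig`. Pupils larger than the
analysis diameter are rescaled down first; smaller pupils are rejected
(coefficients cannot be extrapolated outward). Eyes whose wavefront slope
exceeds the pupil grid's Nyquist limit at the extremes of the vergence sweep
are automatically re-evaluated point-wise on a finer grid (doubling the
sample count up to ``psf_max_samples``).
"""

from __future__ import annotations

import logging

import numpy as np

from . import cohort, optics, throughfocus
from .cohort import EyeRecord
from .config import RunConfig
from .throughfocus import IQSummary, ThroughFocusCurve
from .zernike import defocus_to_coeff, rescale_coeffs

__all__ = ["simulate_study", "analyze_record", "run_throughfocus", "study_seeds"]

log = logging.getLogger("kciq")

_PRESET_ORDER = ("control", "KCE_unaided", "KCE_RGP", "VAE_unaided", "VAE_RGP")


def study_seeds(master_seed: int) -> dict[str, int]:
    """One independent child seed per cohort preset, derived from the master."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_PRESET_ORDER))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_PRESET_ORDER, children)}


def simulate_study(config: RunConfig) -> list[EyeRecord]:
    """Generate every cohort preset at the study sizes (12 KCE, 9 VAE, 20 controls).

    Controls contribute only the right eye to the returned records unless
    ``include_control_left_eye`` is set; the generator itself always draws
    both eyes so interocular statistics remain well defined upstream.
    """
    import dataclasses

    specs = cohort.default_specs()
    seeds = study_seeds(config.seed)
    records: list[EyeRecord] = []
    for name in _PRESET_ORDER:
        spec = specs[name]
        overrides = config.cohort_overrides.get(name, {})
        if overrides:
            spec = dataclasses.replace(spec, **overrides)
        recs = cohort.generate_cohort(spec, seed=seeds[name])
        if name == "control" and not config.include_control_left_eye:
            recs = [r for r in recs if r.eye == "OD"]
        records.extend(recs)
        log.info("simulated %s: %d eye records", name, len(recs))
    return records


def _adaptive_log_ns(coeffs, vergence, config: RunConfig) -> float:
    c20 = defocus_to_coeff(vergence, coeffs.pupil_diameter_mm)
    swept = coeffs.with_terms({(2, 0): c20})
    samples = config.psf_samples_across_pupil
    while True:
        try:
            return optics.log_ns(swept, samples, config.psf_pad_factor,
                                 config.metric_sigma_arcmin)
        except optics.SamplingError:
            if samples * 2 > config.psf_max_samples:
                raise
            samples *= 2
            log.debug("escalating pupil sampling to %d at V=%+.1f D",
                      samples, vergence)


def run_throughfocus(coeffs, config: RunConfig) -> ThroughFocusCurve:
    """Through-focus curve under a config, with automatic sampling escalation."""
    vergences = throughfocus.default_vergences(
        config.vergence_min_d, config.vergence_max_d, config.vergence_step_d)
    base = coeffs.with_terms({(2, 0): 0.0, (2, -2): 0.0, (2, 2): 0.0})
    values = np.array([_adaptive_log_ns(base, float(v), config)
                       for v in vergences])
    return ThroughFocusCurve(vergences=vergences, log_ns=values)


def analyze_record(record: EyeRecord,
                   config: RunConfig) -> tuple[ThroughFocusCurve, IQSummary]:
    """Rescale to the analysis pupil, sweep focus, and summarize one eye."""
    coeffs = record.coeffs
    if coeffs.pupil_diameter_mm < config.pupil_diameter_mm - 1e-9:
        raise ValueError(
            f"{record.subject_id}/{record.eye}: measured pupil "
            f"{coeffs.pupil_diameter_mm} mm is smaller than the "
            f"{config.pupil_diameter_mm} mm analysis pupil (cannot upscale)")
    if coeffs.pupil_diameter_mm > config.pupil_diameter_mm + 1e-9:
        coeffs = rescale_coeffs(coeffs, config.pupil_diameter_mm)
    curve = run_throughfocus(coeffs, config)
    summary = throughfocus.summarize_curve(
        curve, config.threshold_fraction, config.threshold_scale)
    return curve, summary
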