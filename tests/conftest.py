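"""Shared fixtures, including a session-scoped full synthetic study run."""

from __future__ import annotations

import numpy as np
import pytest

from kciq import RunConfig, ZernikeCoefficients
from kciq.io import summaries_to_frame
from kciq.pipeline import analyze_record, simulate_study

# Published per-eye median (q25, q75) HORMS in µm, used as recovery bands.
HORMS_TABLE = {
    ("control", "unaided"): {"OD": (0.35, 0.27, 0.42), "OS": (0.36, 0.24, 0.46)},
    ("KCE", "unaided"): {"OD": (1.96, 1.50, 2.44), "OS": (1.57, 1.38, 2.25)},
    ("KCE", "RGP"): {"OD": (0.62, 0.49, 0.83), "OS": (0.60, 0.48, 0.63)},
    ("VAE", "unaided"): {"ectatic": (1.76, 1.36, 2.35),
                         "fellow": (0.52, 0.47, 0.63)},
    ("VAE", "RGP"): {"ectatic": (0.78, 0.61, 0.94)},
}

# Interocular-average HORMS median (q25, q75), µm.
IOA_TABLE = {
    "control": (0.37, 0.24, 0.46),
    "KCE_unaided": (1.69, 1.46, 2.08),
    "KCE_RGP": (0.62, 0.52, 0.80),
}

KCE_MEDIAN_SET = {(3, -3): 0.64, (3, -1): -0.96, (3, 1): -0.67,
                  (3, 3): 0.13, (4, 0): -0.40}


@pytest.fixture(scope="session")
def study_config() -> RunConfig:
    # analysis sampling for the synthetic study: 256 pupil samples, 4x padding
    # (grid-convergence-checked against the 8x default)
    return RunConfig(seed=1, psf_pad_factor=4)


@pytest.fixture(scope="session")
def study(study_config):
    """Full synthetic study: 95 eye-conditions swept through focus.

    Returns ``(table, curves)`` where curves maps (cohort, condition) to the
    list of through-focus curves of that group.
    """
    records = simulate_study(study_config)
    entries = []
    curves: dict[tuple[str, str], list] = {}
    for rec in records:
        curve, summary = analyze_record(rec, study_config)
        entries.append((rec, summary))
        curves.setdefault((rec.cohort, rec.condition), []).append(curve)
    return summaries_to_frame(entries), curves


@pytest.fixture()
def dl_coeffs() -> ZernikeCoefficients:
    return ZernikeCoefficients({}, 5.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
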