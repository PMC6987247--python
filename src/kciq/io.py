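"""Readers and writers for the coefficient, curve and summary file schemas.

Coefficient files are plain CSV (UTF-8, comma, '.' decimal, header required)
with identifying columns ``subject_id, eye, cohort, condition,
pupil_diameter_mm, wavelength_um`` followed by one column per Zernike term
named ``z{n}_{m}`` (e.g. ``z3_-1``) holding the coefficient in µm. A JSON
mirror of the same schema is supported. Through-focus curves are exported as
one ``vergence_D, log_ns`` CSV per eye-condition, and curve summaries as a
single CSV with one row per eye-condition.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EyeRecord
from .throughfocus import IQSummary, ThroughFocusCurve
from .zernike import ZernikeCoefficients, horms

__all__ = [
    "term_column", "parse_term_column",
    "records_to_frame", "frame_to_records",
    "read_coeffs", "write_coeffs_csv", "write_coeffs_json",
    "write_curve_csv", "read_curve_csv",
    "summaries_to_frame", "write_psf_text", "read_psf_text",
]

ID_COLUMNS = ("subject_id", "eye", "cohort", "condition",
              "pupil_diameter_mm", "wavelength_um")
_TERM_RE = re.compile(r"^z(\d+)_(-?\d+)$")


def term_column(n: int, m: int) -> str:
    return f"z{n}_{m}"


def parse_term_column(name: str) -> tuple[int, int] | None:
    m = _TERM_RE.match(name)
    return (int(m.group(1)), int(m.group(2))) if m else None


def records_to_frame(records: list[EyeRecord]) -> pd.DataFrame:
    terms = sorted({t for r in records for t in r.coeffs.terms})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "eye": r.eye, "cohort": r.cohort,
            "condition": r.condition,
            "pupil_diameter_mm": r.coeffs.pupil_diameter_mm,
            "wavelength_um": r.coeffs.wavelength_um,
        }
        for t in terms:
            row[term_column(*t)] = r.coeffs.terms.get(t, 0.0)
        rows.append(row)
    cols = list(ID_COLUMNS) + [term_column(*t) for t in terms]
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(frame: pd.DataFrame, source: str = "<frame>") -> list[EyeRecord]:
    missing = [c for c in ID_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    term_cols = {c: parse_term_column(c) for c in frame.columns}
    term_cols = {c: t for c, t in term_cols.items() if t is not None}
    records = []
    for i, row in frame.iterrows():
        try:
            terms = {t: float(row[c]) for c, t in term_cols.items()
                     if pd.notna(row[c]) and float(row[c]) != 0.0}
            coeffs = ZernikeCoefficients(
                terms=terms,
                pupil_diameter_mm=float(row["pupil_diameter_mm"]),
                wavelength_um=float(row["wavelength_um"]),
            )
        except (ValueError, TypeError, IndexError) as exc:
            raise ValueError(f"{source}: line {i + 2}: {exc}") from exc
        records.append(EyeRecord(
            subject_id=str(row["subject_id"]), eye=str(row["eye"]),
            cohort=str(row["cohort"]), condition=str(row["condition"]),
            coeffs=coeffs))
    return records


def write_coeffs_csv(records: list[EyeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_coeffs_json(records: list[EyeRecord], path) -> None:
    frame = records_to_frame(records)
    Path(path).write_text(json.dumps(frame.to_dict("records"), indent=1))


def read_coeffs(path) -> list[EyeRecord]:
    """Read a coefficient file in the CSV schema or its JSON mirror."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path)
    return frame_to_records(frame, source=str(path))


def write_curve_csv(curve: ThroughFocusCurve, path) -> None:
    pd.DataFrame({"vergence_D": curve.vergences,
                  "log_ns": curve.log_ns}).to_csv(path, index=False)


def read_curve_csv(path) -> ThroughFocusCurve:
    df = pd.read_csv(path)
    return ThroughFocusCurve(vergences=df["vergence_D"].to_numpy(),
                             log_ns=df["log_ns"].to_numpy())


def summaries_to_frame(entries: list[tuple[EyeRecord, IQSummary]]) -> pd.DataFrame:
    rows = []
    for rec, s in entries:
        rows.append({
            "subject_id": rec.subject_id, "eye": rec.eye,
            "cohort": rec.cohort, "condition": rec.condition,
            "horms_um": horms(rec.coeffs),
            "peak_iq": s.peak_iq, "best_focus_D": s.best_focus,
            "dof_D": s.dof_width,
            "dof_lower_D": s.dof_interval[0], "dof_upper_D": s.dof_interval[1],
            "censored_low": s.censored_low, "censored_high": s.censored_high,
        })
    return pd.DataFrame(rows)


def write_psf_text(psf, path) -> None:
    """Portable float-grid export with an angular-calibration header."""
    header = (f"arcmin_per_pixel={psf.arcmin_per_pixel!r} "
              f"center_index={psf.center_index[0]},{psf.center_index[1]}")
    np.savetxt(path, psf.intensity, header=header)


def read_psf_text(path):
    from .optics import PSFGrid
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(kv.split("=") for kv in header.split())
    cy, cx = (int(v) for v in fields["center_index"].split(","))
    return PSFGrid(intensity=np.loadtxt(path),
                   arcmin_per_pixel=float(fields["arcmin_per_pixel"]),
                   center_index=(cy, cx))
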