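"""Reading and writing the pipeline's delimited-text record formats.

One CSV per record type; times in hours, activities in MBq, concentrations
in MBq/g, doses in Gy.  Synthetic cohorts are written in exactly the
schemas accepted for real data, so a generated cohort can be re-read and
must produce identical downstream results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .quantification import (
    BMCompartmentSeries,
    RoiRecord,
    SpectRecord,
    SphereMeasurement,
)
from .synthetic import SyntheticPatient

PHANTOM_COLUMNS = ["diameter_mm", "true_concentration", "measured_concentration"]
PLANAR_COLUMNS = [
    "patient_id", "t_h", "tumour_roi_activity_mbq", "background_roi_activity_mbq",
    "tumour_roi_size", "background_roi_size",
]
SPECT_COLUMNS = ["patient_id", "c_spect_24h_mbq_per_g", "equivalent_diameter_mm"]
KIDNEY_COLUMNS = ["patient_id", "t_h", "concentration_mbq_per_g"]
BM_COLUMNS = [
    "patient_id", "t_h", "a_low_mbq", "a_high_mbq",
    "m_low_g", "cf", "s_bm_from_low", "s_bm_from_high",
]


def write_phantom_csv(measurements: Sequence[SphereMeasurement], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "diameter_mm": m.diameter_mm,
                "true_concentration": m.true_concentration,
                "measured_concentration": m.measured_concentration,
            }
            for m in measurements
        ],
        columns=PHANTOM_COLUMNS,
    ).to_csv(path, index=False)


def read_phantom_csv(path: Path) -> list[SphereMeasurement]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SphereMeasurement(
            diameter_mm=row.diameter_mm,
            true_concentration=row.true_concentration,
            measured_concentration=row.measured_concentration,
        )
        for row in df.itertuples()
    ]


def write_cohort_csvs(
    cohort: Iterable[SyntheticPatient], outdir: Path
) -> dict[str, Path]:
    """Write planar / SPECT / kidney / bone-marrow CSVs for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planar_rows, spect_rows, kidney_rows, bm_rows = [], [], [], []
    for p in cohort:
        for r in p.planar_series:
            planar_rows.append(
                [p.patient_id, r.t_h, r.tumour_roi_activity,
                 r.background_roi_activity, r.tumour_roi_size,
                 r.background_roi_size]
            )
        spect_rows.append(
            [p.patient_id, p.spect_24h.c_spect_24h,
             p.spect_24h.equivalent_diameter_mm]
        )
        for t, c in p.kidney_series:
            kidney_rows.append([p.patient_id, t, c])
        bm = p.bm_series
        for t, a_low, a_high in bm.samples:
            bm_rows.append(
                [p.patient_id, t, a_low, a_high, bm.m_low_g, bm.cf,
                 bm.s_bm_from_low, bm.s_bm_from_high]
            )
    paths = {
        "planar": outdir / "planar.csv",
        "spect": outdir / "spect.csv",
        "kidney": outdir / "kidney.csv",
        "bone_marrow": outdir / "bone_marrow.csv",
    }
    pd.DataFrame(planar_rows, columns=PLANAR_COLUMNS).to_csv(
        paths["planar"], index=False
    )
    pd.DataFrame(spect_rows, columns=SPECT_COLUMNS).to_csv(
        paths["spect"], index=False
    )
    pd.DataFrame(kidney_rows, columns=KIDNEY_COLUMNS).to_csv(
        paths["kidney"], index=False
    )
    pd.DataFrame(bm_rows, columns=BM_COLUMNS).to_csv(
        paths["bone_marrow"], index=False
    )
    return paths


def read_cohort_csvs(indir: Path) -> dict[str, "PatientRecords"]:
    """Read measurement CSVs back into per-patient record bundles."""
    indir = Path(indir)
    planar = pd.read_csv(indir / "planar.csv", float_precision="round_trip")
    spect = pd.read_csv(indir / "spect.csv", float_precision="round_trip")
    kidney = pd.read_csv(indir / "kidney.csv", float_precision="round_trip")
    bm = pd.read_csv(indir / "bone_marrow.csv", float_precision="round_trip")
    patients: dict[str, PatientRecords] = {}
    for pid, sub in spect.groupby("patient_id", sort=True):
        row = sub.iloc[0]
        psub = planar[planar.patient_id == pid].sort_values("t_h")
        ksub = kidney[kidney.patient_id == pid].sort_values("t_h")
        bsub = bm[bm.patient_id == pid].sort_values("t_h")
        patients[str(pid)] = PatientRecords(
            patient_id=str(pid),
            planar_series=tuple(
                RoiRecord(
                    t_h=r.t_h,
                    tumour_roi_activity=r.tumour_roi_activity_mbq,
                    background_roi_activity=r.background_roi_activity_mbq,
                    tumour_roi_size=r.tumour_roi_size,
                    background_roi_size=r.background_roi_size,
                )
                for r in psub.itertuples()
            ),
            spect_24h=SpectRecord(
                c_spect_24h=row.c_spect_24h_mbq_per_g,
                equivalent_diameter_mm=row.equivalent_diameter_mm,
            ),
            kidney_series=tuple(
                (r.t_h, r.concentration_mbq_per_g) for r in ksub.itertuples()
            ),
            bm_series=BMCompartmentSeries(
                samples=tuple(
                    (r.t_h, r.a_low_mbq, r.a_high_mbq) for r in bsub.itertuples()
                ),
                m_low_g=float(bsub.iloc[0].m_low_g),
                cf=float(bsub.iloc[0].cf),
                s_bm_from_low=float(bsub.iloc[0].s_bm_from_low),
                s_bm_from_high=float(bsub.iloc[0].s_bm_from_high),
            ),
        )
    return patients


@dataclass(frozen=True)
class PatientRecords:
    """Measurement records for one patient, synthetic or real."""

    patient_id: str
    planar_series: tuple[RoiRecord, ...]
    spect_24h: SpectRecord
    kidney_series: tuple[tuple[float, float], ...]
    bm_series: BMCompartmentSeries


def records_from_patient(p: SyntheticPatient) -> PatientRecords:
    """View a synthetic patient as its measurement records only."""
    return PatientRecords(
        patient_id=p.patient_id,
        planar_series=p.planar_series,
        spect_24h=p.spect_24h,
        kidney_series=p.kidney_series,
        bm_series=p.bm_series,
    )


def write_json(obj, path: Path) -> None:
    """Deterministic JSON (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
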