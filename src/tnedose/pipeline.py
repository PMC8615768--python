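"""End-to-end pipeline: data -> quantification -> fits -> doses -> TNED.

``run_pipeline`` drives the whole chain from a single validated config:
generate (or read) measurement records, calibrate the recovery coefficient,
quantify tissue dose-rate series, fit biexponential curves, integrate the
standard interval set, compute TND/TNED scenarios and the window scan, and
summarise the cohort.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .constants import LU177
from .dose_rate import (
    BiexpFit,
    DoseRateSeries,
    TISSUE_SHAPES,
    concentration_to_dose_rate,
    fit_biexponential,
)
from .enhancement import RBEWindow, cohort_summary, tned, window_scan
from .errors import ConfigurationError
from .intervals import STANDARD_INTERVALS, TimeInterval, standard_dose_table
from .io import (
    PatientRecords,
    read_cohort_csvs,
    read_phantom_csv,
    records_from_patient,
    write_cohort_csvs,
    write_json,
    write_phantom_csv,
)
from .quantification import (
    RCModel,
    bm_dose_rate_series,
    fit_recovery_curve,
    tumour_concentration_series,
)
from .synthetic import CohortConfig, generate_cohort, generate_phantom

logger = logging.getLogger("tnedose")


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["synthetic", "from-files"] = "synthetic"
    n_patients: int = Field(default=17, ge=1)
    seed: int = 0
    input_dir: str | None = None  # required in from-files mode
    output_dir: str = "tnedose-out"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    pve_mode: Literal["divide", "multiply"] = "divide"
    rbe_tumour: float = 2.0
    rbe_normal_grid: tuple[float, ...] = (1.0, 1.5, 2.0)
    window_start_h: float = 24.0
    window_stop_h: float = 672.0
    scan_start_grid: tuple[float, ...] = (0.0, 6.0, 24.0)
    scan_stop_grid: tuple[float, ...] = (672.0, math.inf)


def quantify_patient(
    records: PatientRecords,
    rc: RCModel,
    pve_mode: Literal["divide", "multiply"] = "divide",
) -> dict[str, DoseRateSeries]:
    """Measurement records -> per-tissue dose-rate series (Gy/h)."""
    conc = tumour_concentration_series(
        records.spect_24h, records.planar_series, rc, pve_mode=pve_mode
    )
    tum = DoseRateSeries(
        tissue="tumour",
        t_h=tuple(t for t, _ in conc),
        rate_gy_per_h=tuple(
            float(concentration_to_dose_rate(c)) for _, c in conc
        ),
    )
    kid = DoseRateSeries(
        tissue="kidney",
        t_h=tuple(t for t, _ in records.kidney_series),
        rate_gy_per_h=tuple(
            float(concentration_to_dose_rate(c)) for _, c in records.kidney_series
        ),
    )
    return {
        "tumour": tum,
        "bone_marrow": bm_dose_rate_series(records.bm_series),
        "kidney": kid,
    }


def fit_patient(
    series: dict[str, DoseRateSeries]
) -> dict[str, BiexpFit]:
    """Fit each tissue with its default curve shape."""
    return {
        tissue: fit_biexponential(s, shape=TISSUE_SHAPES.get(tissue, "free"))
        for tissue, s in series.items()
    }


def _fit_record(pid: str, tissue: str, fit: BiexpFit) -> dict:
    return {
        "patient_id": pid, "tissue": tissue, "C1": fit.C1, "C2": fit.C2,
        "a": fit.a, "b": fit.b, "r": fit.r, "shape": fit.shape,
        "residual_rel": fit.residual_rel,
    }


def validate_inputs(indir: Path) -> list[dict]:
    """Schema and sanity checks on an input directory of measurement CSVs.

    Returns machine-readable findings; an empty list means the inputs are
    well formed (times in hours and monotone per patient, activities and
    concentrations non-negative, required files and columns present).
    """
    from .io import BM_COLUMNS, KIDNEY_COLUMNS, PLANAR_COLUMNS, SPECT_COLUMNS

    indir = Path(indir)
    findings: list[dict] = []
    expected = {
        "planar.csv": PLANAR_COLUMNS,
        "spect.csv": SPECT_COLUMNS,
        "kidney.csv": KIDNEY_COLUMNS,
        "bone_marrow.csv": BM_COLUMNS,
    }
    frames: dict[str, pd.DataFrame] = {}
    for fname, cols in expected.items():
        path = indir / fname
        if not path.exists():
            findings.append({"type": "missing-file", "file": fname})
            continue
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            findings.append(
                {"type": "missing-columns", "file": fname, "columns": missing}
            )
            continue
        frames[fname] = df
    for fname, df in frames.items():
        num = df.select_dtypes("number")
        for col in num.columns:
            bad = df.index[num[col] < 0].tolist()
            for row in bad:
                findings.append(
                    {"type": "negative-value", "file": fname, "row": int(row),
                     "column": col}
                )
        if "t_h" in df.columns and "patient_id" in df.columns:
            for pid, sub in df.groupby("patient_id"):
                t = sub["t_h"].to_numpy()
                if np.any(np.diff(t) <= 0):
                    findings.append(
                        {"type": "time-order", "file": fname,
                         "patient_id": str(pid)}
                    )
    return findings


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write all outputs; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for p in written:  # no partial output set on failure
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    # --- stage 1: obtain measurement records -------------------------------
    if config.mode == "synthetic":
        cc = config.cohort
        phantom = generate_phantom(
            cc.sphere_diameters_mm, cc.rc_truth(), cc.noise_cv,
            seed=config.seed + 1, true_concentration=cc.phantom_true_concentration,
        )
        cohort = generate_cohort(config.n_patients, cc, seed=config.seed)
        inputs_dir = outdir / "inputs"
        paths = write_cohort_csvs(cohort, inputs_dir)
        write_phantom_csv(phantom, inputs_dir / "phantom.csv")
        written += [*paths.values(), inputs_dir / "phantom.csv"]
        patients = {
            p.patient_id: records_from_patient(p) for p in cohort
        }
        logger.info("generated %d synthetic patients", len(patients))
    else:
        if not config.input_dir:
            raise ConfigurationError("from-files mode requires input_dir")
        indir = Path(config.input_dir)
        findings = validate_inputs(indir)
        fatal = [f for f in findings if f["type"] != "negative-value"]
        if fatal:
            raise ConfigurationError(f"input validation failed: {fatal}")
        phantom = read_phantom_csv(indir / "phantom.csv")
        patients = read_cohort_csvs(indir)
        logger.info("read %d patients from %s", len(patients), indir)

    # --- stage 2: recovery calibration + quantification ---------------------
    rc = fit_recovery_curve(phantom)
    logger.info("recovery curve: a=%.3f mm, b=%.3f", rc.a, rc.b)
    all_series = {
        pid: quantify_patient(rec, rc, pve_mode=config.pve_mode)
        for pid, rec in sorted(patients.items())
    }

    # --- stage 3: biexponential fits ----------------------------------------
    fits = {pid: fit_patient(series) for pid, series in all_series.items()}
    fit_rows = [
        _fit_record(pid, tissue, f)
        for pid, tf in fits.items()
        for tissue, f in tf.items()
    ]
    fits_json = outdir / "fits.json"
    write_json(fit_rows, fits_json)
    written.append(fits_json)
    pd.DataFrame(fit_rows).to_csv(outdir / "fits.csv", index=False)
    written.append(outdir / "fits.csv")

    # --- stage 4: interval dose tables --------------------------------------
    tables = pd.concat(
        [standard_dose_table(tf, pid) for pid, tf in fits.items()],
        ignore_index=True,
    )
    tables.to_csv(outdir / "dose_table.csv", index=False)
    written.append(outdir / "dose_table.csv")

    # --- stage 5: enhancement ------------------------------------------------
    window = TimeInterval(config.window_start_h, config.window_stop_h)
    tned_rows = []
    for pid, tf in fits.items():
        for tissue in ("bone_marrow", "kidney"):
            for rbe_nt in config.rbe_normal_grid:
                res = tned(
                    tf["tumour"], tf[tissue],
                    RBEWindow(window, config.rbe_tumour, rbe_nt),
                    patient_id=pid, normal_tissue=tissue,
                )
                tned_rows.append(
                    {
                        "patient_id": pid, "normal_tissue": tissue,
                        "rbe_tumour": config.rbe_tumour, "rbe_normal": rbe_nt,
                        "tnd": res.tnd, "ed_tumour": res.ed_tumour,
                        "ed_normal": res.ed_normal, "tned": res.tned,
                        "relative_to_tnd_pct": res.relative_to_tnd,
                    }
                )
    tned_df = pd.DataFrame(tned_rows)
    tned_df.to_csv(outdir / "tned.csv", index=False)
    written.append(outdir / "tned.csv")

    summary = cohort_summary(
        tned_df,
        value_columns=("tnd", "tned", "relative_to_tnd_pct"),
        group_columns=("normal_tissue", "rbe_normal"),
    )
    summary.to_csv(outdir / "tned_summary.csv", index=False)
    written.append(outdir / "tned_summary.csv")

    scans = pd.concat(
        [
            window_scan(
                tf["tumour"],
                {t: tf[t] for t in ("bone_marrow", "kidney")},
                start_grid=config.scan_start_grid,
                stop_grid=config.scan_stop_grid,
                rbe_pairs=tuple(
                    (config.rbe_tumour, r) for r in config.rbe_normal_grid
                ),
                patient_id=pid,
            )
            for pid, tf in fits.items()
        ],
        ignore_index=True,
    )
    scan_records = scans.replace({math.inf: "inf"}).to_dict(orient="records")
    write_json(scan_records, outdir / "window_scan.json")
    written.append(outdir / "window_scan.json")

    # --- manifest -------------------------------------------------------------
    cfg_json = config.model_dump_json()
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_patients": len(patients),
        "tnedose_version": __version__,
        "recovery_model": {"a_mm": rc.a, "b": rc.b},
        "outputs": sorted(str(p.relative_to(outdir)) for p in written),
    }
    manifest = json.loads(
        json.dumps(manifest).replace("Infinity", '"inf"')
    )
    write_json(manifest, outdir / "manifest.json")
    return manifest
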