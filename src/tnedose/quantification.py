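"""Raw measurement records -> tissue concentration / dose-rate series.

Covers the four quantification steps upstream of curve fitting:

* recovery-coefficient (RC) calibration from phantom sphere measurements,
  RC(d) = 1 / (1 + (a/d)^b), correcting partial-volume underestimation;
* planar ROI background subtraction with ROI-size adjustment;
* hybrid planar/SPECT tumour quantification: the SPECT concentration at
  24 h anchors the absolute scale, the planar net-activity curve supplies
  the kinetic shape;
* the two-compartment bone-marrow dose-rate model combining a
  concentration-based self-dose term (calibration factor CF) with S-value
  cross-dose terms from the low- and high-uptake areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import LU177, PhysicalConstants
from .dose_rate import DoseRateSeries
from .errors import FittingError, QuantificationError


@dataclass(frozen=True)
class RCModel:
    """Sigmoid recovery coefficient RC(d) = 1 / (1 + (a/d)^b).

    ``a`` (mm) is the diameter at which half the activity is recovered;
    ``b`` controls the steepness.  RC is strictly increasing in d with
    RC(a) = 1/2 and RC -> 1 as d -> inf.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("RC parameters a and b must be positive")

    def __call__(self, d: float | np.ndarray) -> float | np.ndarray:
        return recovery_coefficient(self, d)


def recovery_coefficient(
    model: RCModel, d: float | np.ndarray
) -> float | np.ndarray:
    """Recovered fraction of the true concentration for diameter d (mm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("sphere diameter must be positive")
    out = 1.0 / (1.0 + (model.a / d) ** model.b)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SphereMeasurement:
    """One phantom sphere: known vs measured activity concentration."""

    diameter_mm: float
    true_concentration: float      # MBq/mL
    measured_concentration: float  # MBq/mL

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.true_concentration <= 0 or self.measured_concentration <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def ratio(self) -> float:
        return self.measured_concentration / self.true_concentration


def fit_recovery_curve(measurements: Sequence[SphereMeasurement]) -> RCModel:
    """Least-squares sigmoid fit of measured/true ratios vs sphere diameter."""
    if len({m.diameter_mm for m in measurements}) < 2:
        raise FittingError("recovery fit needs >= 2 distinct sphere diameters")
    d = np.array([m.diameter_mm for m in measurements], dtype=float)
    rc = np.array([m.ratio for m in measurements], dtype=float)
    if np.ptp(rc) < 1e-12:
        raise FittingError(
            "all recovery ratios are identical; the sigmoid scale parameter "
            "is unidentifiable"
        )

    def model(dd: np.ndarray, a: float, b: float) -> np.ndarray:
        return 1.0 / (1.0 + (a / dd) ** b)

    # start a at the diameter closest to 50% recovery
    a0 = float(d[np.argmin(np.abs(rc - 0.5))])
    try:
        popt, _ = curve_fit(
            model, d, rc, p0=(a0, 2.0),
            bounds=((1e-6, 1e-6), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FittingError(f"recovery-curve fit failed: {exc}") from exc
    return RCModel(a=float(popt[0]), b=float(popt[1]))


@dataclass(frozen=True)
class RoiRecord:
    """Planar tumour + background ROI activities at one time point."""

    t_h: float
    tumour_roi_activity: float      # MBq (counts-proportional)
    background_roi_activity: float  # MBq
    tumour_roi_size: float          # pixels or area
    background_roi_size: float      # pixels or area

    def __post_init__(self) -> None:
        if self.tumour_roi_size <= 0 or self.background_roi_size <= 0:
            raise ValueError("ROI sizes must be positive")
        if self.tumour_roi_activity < 0 or self.background_roi_activity < 0:
            raise ValueError("ROI activities must be non-negative")


def background_correct(record: RoiRecord) -> float:
    """Net tumour activity: background subtracted, scaled to the ROI size.

    net = A_tumour - A_background * (size_tumour / size_background),
    clamped at zero (with a warning) when noise pushes it negative.
    """
    net = record.tumour_roi_activity - record.background_roi_activity * (
        record.tumour_roi_size / record.background_roi_size
    )
    if net < 0:
        warnings.warn(
            f"net tumour activity negative ({net:.4g} MBq) at "
            f"t={record.t_h} h; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return net


@dataclass(frozen=True)
class SpectRecord:
    """SPECT VOI concentration at 24 h and the tumour-equivalent diameter."""

    c_spect_24h: float           # MBq/g, measured (partial-volume affected)
    equivalent_diameter_mm: float

    def __post_init__(self) -> None:
        if self.c_spect_24h <= 0 or self.equivalent_diameter_mm <= 0:
            raise ValueError("SPECT concentration and diameter must be positive")


def tumour_concentration_series(
    spect: SpectRecord,
    planar: Sequence[RoiRecord],
    rc: RCModel,
    pve_mode: Literal["divide", "multiply"] = "divide",
    t24_tol: float = 1e-6,
) -> list[tuple[float, float]]:
    """Hybrid planar/SPECT tumour concentration series (t in h, C in MBq/g).

    C(t) = C_corrected(24 h) * A_net(t) / A_net(24 h), where the measured
    SPECT concentration is partial-volume corrected by the recovery
    coefficient.  A measured small-object concentration underestimates the
    true one by the factor RC < 1, so the correction divides by RC(d)
    (default).  ``pve_mode="multiply"`` applies the multiplication form
    instead, for compatibility with pipelines that fold the RC into the
    calibration differently.
    """
    rcd = recovery_coefficient(rc, spect.equivalent_diameter_mm)
    c24 = spect.c_spect_24h / rcd if pve_mode == "divide" else spect.c_spect_24h * rcd
    ref = [r for r in planar if abs(r.t_h - 24.0) <= t24_tol]
    if not ref:
        raise QuantificationError("planar series lacks a 24 h record")
    a24 = background_correct(ref[0])
    if a24 <= 0:
        raise QuantificationError("net tumour activity at 24 h is zero")
    return [
        (r.t_h, c24 * background_correct(r) / a24)
        for r in sorted(planar, key=lambda r: r.t_h)
    ]


@dataclass(frozen=True)
class BMCompartmentSeries:
    """Two-compartment bone-marrow activity series with model constants.

    ``samples`` holds (t in h, A_low in MBq, A_high in MBq) for the low-
    and high-uptake planar areas.  ``m_low`` is the mass of the low-uptake
    area; ``cf`` the self-dose calibration factor (3.2 by default); the two
    S-values give bone-marrow dose per unit activity in each source region.
    """

    samples: tuple[tuple[float, float, float], ...]
    m_low_g: float
    cf: float = 3.2
    s_bm_from_low: float = 0.0   # Gy/(MBq*h)
    s_bm_from_high: float = 0.0  # Gy/(MBq*h)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("bone-marrow series must be non-empty")
        if self.m_low_g <= 0 or self.cf <= 0:
            raise ValueError("m_low and CF must be positive")
        if self.s_bm_from_low < 0 or self.s_bm_from_high < 0:
            raise ValueError("S-values must be non-negative")
        for t, a_low, a_high in self.samples:
            if a_low < 0 or a_high < 0:
                raise ValueError(f"negative activity at t={t} h")


def bm_dose_rate_series(
    bm: BMCompartmentSeries, constants: PhysicalConstants = LU177
) -> DoseRateSeries:
    """Bone-marrow dose rate from the two-compartment model.

    D'(t) = A_low(t)/m_low * phi_e * E_e * CF * k
          + A_low(t) * S_bm<-low + A_high(t) * S_bm<-high
    """
    self_coeff = constants.gy_per_h_per_mbq_per_g * bm.cf / bm.m_low_g
    t = [s[0] for s in bm.samples]
    rate = [
        a_low * self_coeff + a_low * bm.s_bm_from_low + a_high * bm.s_bm_from_high
        for _, a_low, a_high in bm.samples
    ]
    return DoseRateSeries(tissue="bone_marrow", t_h=tuple(t), rate_gy_per_h=tuple(rate))
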