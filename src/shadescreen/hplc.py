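"""HPLC peak-table quantitation: calibration curves, peak identification and
back-calculation to mg/g dry weight.

Each analyte is quantified against an external standard curve (ordinary
least squares of detector area on standard concentration).  Peaks are
identified by matching sample retention times to reference retention times
of the standards, then back-calculated:

    concentration (ug/mL) = (area - intercept) / slope
    mg/g dry weight       = concentration * extract_volume_mL / sample_mass_mg

The mass/volume defaults (100 mg tissue extracted in 5 mL 80:20 MeOH/H2O)
follow the extraction protocol the pipeline models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import ANALYTES

__all__ = [
    "CalibrationCurve",
    "PeakRecord",
    "fit_standard_curve",
    "identify_peaks",
    "quantify",
    "quantify_peak_table",
]

logger = logging.getLogger(__name__)

#: Extraction defaults: ~100 mg dry tissue in 5 mL extraction solvent.
DEFAULT_SAMPLE_MASS_MG = 100.0
DEFAULT_EXTRACT_VOLUME_ML = 5.0
#: Retention-time matching tolerance (minutes); the gradient runs 0-70 min.
DEFAULT_RT_TOLERANCE_MIN = 0.2
GRADIENT_WINDOW_MIN = (0.0, 70.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear external-standard calibration for one analyte.

    slope is detector area per (ug/mL); rt_reference is the standard's
    retention time in minutes, used for peak identification.
    """

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    rt_reference: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: calibration slope must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"{self.analyte}: r_squared outside [0, 1]")


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak."""

    sample_id: str
    retention_time: float
    area: float
    analyte: str | None = field(default=None)

    def __post_init__(self) -> None:
        lo, hi = GRADIENT_WINDOW_MIN
        if not lo <= self.retention_time <= hi:
            raise ValueError(
                f"retention time {self.retention_time} min outside gradient window {lo}-{hi}"
            )
        if self.area < 0:
            raise ValueError("peak area must be >= 0")


def fit_standard_curve(
    standard_levels: list[tuple[float, float]],
    analyte: str = "",
    rt_reference: float | None = None,
) -> CalibrationCurve:
    """Fit an ordinary-least-squares line area = slope*conc + intercept.

    ``standard_levels`` is a list of (concentration ug/mL, area) pairs with
    at least two distinct concentrations.
    """
    if len(standard_levels) < 2:
        raise ValueError("need at least 2 standard levels")
    conc = np.asarray([c for c, _ in standard_levels], dtype=float)
    area = np.asarray([a for _, a in standard_levels], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("degenerate design: all standard concentrations identical")
    res = stats.linregress(conc, area)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rt_reference=rt_reference,
    )


def identify_peaks(
    peaks: list[PeakRecord],
    curves: list[CalibrationCurve],
    rt_tolerance: float = DEFAULT_RT_TOLERANCE_MIN,
) -> list[PeakRecord]:
    """Assign each peak to the analyte whose reference retention time is
    nearest, within ``rt_tolerance`` minutes; otherwise leave it unassigned.

    If two references fall within tolerance of one peak the nearest wins; an
    exact tie goes to the analyte earlier in the canonical analyte ordering.
    Both situations are logged as warnings.
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be > 0")
    refs = [(c.analyte, c.rt_reference) for c in curves if c.rt_reference is not None]
    if not refs:
        raise ValueError("no calibration curve carries a reference retention time")
    order = {a: i for i, a in enumerate(ANALYTES)}
    assigned: list[PeakRecord] = []
    for pk in peaks:
        in_tol = [
            (abs(pk.retention_time - rt), order.get(a, len(order)), a)
            for a, rt in refs
            if abs(pk.retention_time - rt) <= rt_tolerance
        ]
        if not in_tol:
            assigned.append(PeakRecord(pk.sample_id, pk.retention_time, pk.area, None))
            continue
        in_tol.sort()
        if len(in_tol) > 1:
            logger.warning(
                "peak at %.3f min (%s) matches %d references within %.3g min; "
                "assigning nearest (%s)",
                pk.retention_time, pk.sample_id, len(in_tol), rt_tolerance, in_tol[0][2],
            )
        assigned.append(
            PeakRecord(pk.sample_id, pk.retention_time, pk.area, in_tol[0][2])
        )
    return assigned


def quantify(
    peak: PeakRecord,
    curve: CalibrationCurve,
    sample_mass_mg: float = DEFAULT_SAMPLE_MASS_MG,
    extract_volume_mL: float = DEFAULT_EXTRACT_VOLUME_ML,
) -> float:
    """Back-calculate a peak to mg analyte per g dry weight.

    Negative back-calculated concentrations (area below the intercept) clamp
    to zero with a logged warning.
    """
    if sample_mass_mg <= 0 or extract_volume_mL <= 0:
        raise ValueError("sample mass and extract volume must be > 0")
    conc_ug_ml = (peak.area - curve.intercept) / curve.slope
    if conc_ug_ml < 0:
        logger.warning(
            "peak %s/%s back-calculated below zero (%.4g ug/mL); clamping to 0",
            peak.sample_id, curve.analyte, conc_ug_ml,
        )
        conc_ug_ml = 0.0
    # ug/mL * mL / mg = ug/mg = mg/g
    return conc_ug_ml * extract_volume_mL / sample_mass_mg


def quantify_peak_table(
    peaks: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    rt_tolerance: float = DEFAULT_RT_TOLERANCE_MIN,
    sample_mass_mg: float = DEFAULT_SAMPLE_MASS_MG,
    extract_volume_mL: float = DEFAULT_EXTRACT_VOLUME_ML,
) -> pd.DataFrame:
    """Identify and quantify a whole peak table into a concentration table.

    ``peaks`` needs columns ``sample_id``, ``retention_time``, ``area``.
    Returns one row per sample with the twelve analyte columns in mg/g;
    analytes with no assigned peak in a sample are reported as 0.  Output is
    sorted by sample_id, so it is invariant to the peak-row order.
    """
    required = {"sample_id", "retention_time", "area"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peak table must have columns {sorted(required)}")
    records = [
        PeakRecord(str(r.sample_id), float(r.retention_time), float(r.area))
        for r in peaks.itertuples(index=False)
    ]
    assigned = identify_peaks(records, list(curves.values()), rt_tolerance)
    samples = sorted({p.sample_id for p in assigned})
    out = pd.DataFrame(0.0, index=samples, columns=list(ANALYTES))
    for pk in assigned:
        if pk.analyte is None:
            continue
        out.loc[pk.sample_id, pk.analyte] = quantify(
            pk, curves[pk.analyte], sample_mass_mg, extract_volume_mL
        )
    out.index.name = "sample_id"
    return out.reset_index()
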