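"""Peak extraction, calibration fitting and detection-limit analysis.

The pipeline mirrors standard voltammetric sensor practice: a faradaic peak
current is read off each voltammogram after subtracting a straight baseline
interpolated through the flanks of the peak window; the sensitivity is the
slope of the ordinary-least-squares calibration line of |peak current|
against concentration; the limit of detection is 3*sd(blank signal)/slope;
and the per-area sensitivity divides the slope by the 12.56 mm^2
working-electrode area.  The two-drug analysis regresses per-family
sensitivities on the modulator concentration and t-tests the activation
slope against zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .voltammetry import CalibrationSeries, DrugIsoformPreset, Voltammogram

#: Extraction window half-width (mV) around the monitored peak potential and
#: the width of the flanking baseline margins.  The window must stay clear of
#: the neighbouring cathodic region 120 mV away.
DEFAULT_WINDOW_HALF_MV = 50.0
DEFAULT_BASELINE_MARGIN_MV = 25.0


@dataclass(frozen=True)
class PeakMeasurement:
    """Baseline-subtracted signed peak current at its potential."""

    peak_potential: float
    peak_current: float
    window: tuple[float, float]
    segment: str


@dataclass(frozen=True)
class CalibrationResult:
    """Sensitivity, detection limit and diagnostics of one series."""

    slope: float  # nA/uM
    slope_per_area: float  # nA/(uM*mm^2)
    intercept: float  # nA
    r_squared: float
    lod: float  # uM
    linear_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class PairInteractionResult:
    """Sensitivity of one electrode as a function of a second drug."""

    modulator_concs: tuple[float, ...]
    sensitivities: tuple[float, ...]
    activation_slope: float  # (nA/uM) per uM of modulator
    p_value: float
    monotone_increase: bool
    overlap: bool | None  # None when too few families for the t-test


def extract_peak_current(
    v: Voltammogram,
    window: tuple[float, float],
    segment: str = "reverse",
    baseline_margin: float = DEFAULT_BASELINE_MARGIN_MV,
    at_potential: float | None = None,
) -> PeakMeasurement:
    """Baseline-subtracted peak current inside a potential window.

    A straight baseline is least-squares fitted through the samples in the
    two flanking margins of the window on the chosen sweep branch; the peak
    current is the extremal signed deviation from that baseline inside the
    window (with ``at_potential`` given, the deviation at the sample nearest
    that potential instead - used for blank signals, where there is no peak
    to search for).
    """
    lo, hi = window
    if not lo < hi:
        raise InvalidParameterError("window must have lo < hi")
    pot, cur = v.branch(segment)
    if pot.size == 0:
        raise InsufficientDataError(f"no samples on segment {segment!r}")
    in_win = (pot >= lo) & (pot <= hi)
    left = (pot >= lo - baseline_margin) & (pot < lo)
    right = (pot > hi) & (pot <= hi + baseline_margin)
    if not in_win.any():
        raise InsufficientDataError("window contains no samples")
    if left.sum() < 2 or right.sum() < 2:
        raise InsufficientDataError("baseline margins contain too few samples")
    flank = left | right
    coef = np.polyfit(pot[flank], cur[flank], 1)
    dev = cur[in_win] - np.polyval(coef, pot[in_win])
    if at_potential is None:
        i = int(np.argmax(np.abs(dev)))
    else:
        i = int(np.argmin(np.abs(pot[in_win] - at_potential)))
    return PeakMeasurement(float(pot[in_win][i]), float(dev[i]), (lo, hi), segment)


def fit_calibration(
    concentrations: Sequence[float], peak_currents: Sequence[float]
) -> tuple[float, float, float]:
    """OLS calibration line of |peak current| on concentration.

    Returns (slope, intercept, r_squared); the slope is the sensitivity in
    nA/uM.  Cathodic and anodic peaks share the absolute-value convention.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.abs(np.asarray(peak_currents, dtype=float))
    if x.size != y.size:
        raise InvalidParameterError("concentrations and currents must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise InsufficientDataError("need at least 2 distinct concentrations")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def detection_limit(blank_currents: Sequence[float], slope: float) -> float:
    """3-sigma detection limit: 3*sd(blank signals)/slope, in uM."""
    if slope <= 0:
        raise InvalidParameterError("slope must be positive")
    b = np.asarray(blank_currents, dtype=float)
    if b.size < 3:
        raise InsufficientDataError("need at least 3 blank replicates")
    return 3.0 * float(b.std(ddof=1)) / slope


def sensitivity_per_area(slope: float, electrode_area: float = 12.56) -> float:
    """Normalise a whole-electrode sensitivity to nA/(uM*mm^2)."""
    if electrode_area <= 0:
        raise InvalidParameterError("electrode area must be positive")
    return slope / electrode_area


def _series_currents(
    series: CalibrationSeries,
    window: tuple[float, float] | None = None,
    baseline_margin: float = DEFAULT_BASELINE_MARGIN_MV,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(concentrations, currents, blank currents) extracted from one series."""
    preset = series.preset
    if window is None:
        window = (
            preset.monitored_peak_mv - DEFAULT_WINDOW_HALF_MV,
            preset.monitored_peak_mv + DEFAULT_WINDOW_HALF_MV,
        )
    concs, currents, blanks = [], [], []
    for conc, vg in series.records:
        if conc == 0.0:
            m = extract_peak_current(
                vg, window, preset.peak_segment, baseline_margin,
                at_potential=preset.monitored_peak_mv,
            )
            blanks.append(m.peak_current)
        else:
            m = extract_peak_current(vg, window, preset.peak_segment, baseline_margin)
            concs.append(conc)
            currents.append(m.peak_current)
    return np.asarray(concs), np.asarray(currents), np.asarray(blanks)


def analyze_series(
    series: CalibrationSeries,
    window: tuple[float, float] | None = None,
    restrict_to_range: bool = True,
) -> CalibrationResult:
    """Extract -> fit -> LOD for one concentration series."""
    preset = series.preset
    concs, currents, blanks = _series_currents(series, window)
    lo, hi = preset.pharmacological_range
    if restrict_to_range:
        keep = (concs >= lo * (1 - 1e-9)) & (concs <= hi * (1 + 1e-9))
        concs, currents = concs[keep], currents[keep]
    slope, intercept, r2 = fit_calibration(concs, currents)
    if blanks.size < 3:
        raise InsufficientDataError("LOD requires at least 3 blank replicates")
    lod = detection_limit(blanks, slope)
    return CalibrationResult(
        slope=slope,
        slope_per_area=sensitivity_per_area(slope, preset.electrode_area_mm2),
        intercept=intercept,
        r_squared=r2,
        lod=lod,
        linear_range=(lo, hi),
        n_points=int(concs.size),
    )


def analyze_panel(
    panel: Sequence[CalibrationSeries],
) -> dict[tuple[str, str, str], CalibrationResult]:
    """Run the full pipeline over a panel of series.

    Keys are (drug, isoform, matrix); use :func:`panel_to_frame` for a table
    mirroring the per-drug performance summary (per-area sensitivity + LOD,
    PBS and serum columns).
    """
    out: dict[tuple[str, str, str], CalibrationResult] = {}
    for series in panel:
        key = (series.preset.drug, series.preset.isoform, series.matrix)
        out[key] = analyze_series(series)
    return out


def panel_to_frame(results: dict[tuple[str, str, str], CalibrationResult]) -> pd.DataFrame:
    rows = [
        {
            "drug": drug,
            "isoform": isoform,
            "matrix": matrix,
            "sensitivity_nA_per_uM": r.slope,
            "sensitivity_per_area_nA_per_uM_mm2": r.slope_per_area,
            "lod_uM": r.lod,
            "r_squared": r.r_squared,
            "n_points": r.n_points,
        }
        for (drug, isoform, matrix), r in results.items()
    ]
    return pd.DataFrame(rows)


def fit_activation(
    modulator_concs: Sequence[float], sensitivities: Sequence[float]
) -> tuple[float, float]:
    """Regress sensitivity on modulator concentration.

    Returns (activation_slope, p_value of the two-sided t-test of the slope
    against zero; nan with fewer than 3 families).
    """
    x = np.asarray(modulator_concs, dtype=float)
    y = np.asarray(sensitivities, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("need at least 2 (modulator, sensitivity) pairs")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def analyze_drug_pair(
    families: Sequence[tuple[float, CalibrationSeries]],
    alpha: float = 0.05,
) -> PairInteractionResult:
    """Hetero-activation analysis of a family of calibration curves.

    Each family is one full calibration series acquired at a fixed modulator
    concentration.  ``monotone_increase`` flags a strictly increasing
    sensitivity sequence; ``overlap`` flags an activation slope statistically
    indistinguishable from zero (two-sided t-test at ``alpha``), i.e. the
    curves coincide and the modulator does not interact.
    """
    if len(families) < 2:
        raise InsufficientDataError("need at least 2 modulator concentrations")
    mods, sens = [], []
    for m, series in sorted(families, key=lambda f: f[0]):
        concs, currents, _ = _series_currents(series)
        slope, _, _ = fit_calibration(concs, currents)
        mods.append(float(m))
        sens.append(slope)
    activation_slope, p = fit_activation(mods, sens)
    monotone = bool(np.all(np.diff(sens) > 0))
    overlap = None if np.isnan(p) else bool(p >= alpha)
    return PairInteractionResult(
        modulator_concs=tuple(mods),
        sensitivities=tuple(sens),
        activation_slope=activation_slope,
        p_value=p,
        monotone_increase=monotone,
        overlap=overlap,
    )
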