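"""Synthetic cyclic-voltammogram generation for the calibration pipeline.

Emulates the potentiostat protocol used with P450/CNT screen-printed
electrodes: a triangular potential sweep from -600 mV to +300 mV and back at
20 mV/s.  The current trace is composed of

* a capacitive (non-faradaic) background proportional to the scan rate, with
  opposite sign on the forward and reverse branch (the CV hysteresis
  envelope),
* a linear resistive baseline,
* Gaussian faradaic peaks at the potentials seen on these electrodes -
  cathodic reductions near -330 and -450 mV, the oxygen-moiety peak of the
  nanotubes near -200 mV, and for the bare-CNT etoposide electrode anodic
  oxidations at +220/+450 mV with reductions at +150/+350 mV,
* i.i.d. Gaussian sample noise.

Peak amplitudes of the monitored peak scale linearly with drug concentration
through the per-area sensitivities measured for each drug/isoform pair,
times the 12.56 mm^2 working-electrode area.  Hetero-activation by a second
drug is modelled as a linear modulation of the sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError, ValidationError

SWEEP_MIN_MV = -600.0
SWEEP_MAX_MV = 300.0
DEFAULT_SCAN_RATE = 20.0  # mV/s
ELECTRODE_AREA_MM2 = 12.56
DEFAULT_PEAK_WIDTH_MV = 15.0


@dataclass
class Voltammogram:
    """One triangular-sweep record: potential (mV), current (nA), segment."""

    potential: np.ndarray
    current: np.ndarray
    segment: np.ndarray  # "forward" / "reverse" per sample
    scan_rate: float = DEFAULT_SCAN_RATE

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (len(self.potential) == len(self.current) == len(self.segment)):
            raise ValidationError("potential, current and segment must have equal length")
        if self.potential.size and (
            self.potential.min() < SWEEP_MIN_MV - 1e-9 or self.potential.max() > SWEEP_MAX_MV + 1e-9
        ):
            raise ValidationError("potentials outside the sweep range [-600, +300] mV")
        for name, sign in (("forward", 1.0), ("reverse", -1.0)):
            v = self.potential[self.segment == name]
            if v.size > 1 and np.any(sign * np.diff(v) <= 0):
                raise ValidationError(f"{name} segment is not monotone")

    def branch(self, segment: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == segment
        return self.potential[m], self.current[m]


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian faradaic peak (centre/sigma in mV, signed amplitude in nA)."""

    center: float
    width: float
    amplitude: float
    segment: str = "reverse"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("peak width must be positive")
        if self.segment not in ("forward", "reverse"):
            raise InvalidParameterError("segment must be 'forward' or 'reverse'")


@dataclass(frozen=True)
class CVNoiseModel:
    """Background and noise parameters of the synthetic trace.

    The true capacitive and noise magnitudes of the electrodes are only shown
    graphically in the source measurements, so these defaults are free
    parameters chosen to give a realistic-looking envelope.
    """

    capacitance_scale: float = 10.0  # nA per (mV/s)
    baseline_slope: float = 0.1  # nA/mV
    noise_sd: float = 5.0  # nA
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DrugIsoformPreset:
    """Measured response of one drug/isoform electrode.

    Per-area sensitivities in nA/(uM*mm^2) in buffer (PBS) and in human serum
    (serum sensitivity is always the lower of the two: plasma-protein binding
    reduces the free drug at the electrode); pharmacological range in uM.
    """

    drug: str
    isoform: str
    pharmacological_range: tuple[float, float]
    sensitivity_pbs: float
    sensitivity_serum: float
    monitored_peak_mv: float
    peak_segment: str
    peak_sign: int  # -1 cathodic, +1 anodic
    electrode_area_mm2: float = ELECTRODE_AREA_MM2
    peak_width_mv: float = DEFAULT_PEAK_WIDTH_MV

    def __post_init__(self) -> None:
        lo, hi = self.pharmacological_range
        if not lo < hi:
            raise InvalidParameterError("pharmacological range must have lower < upper")
        if self.sensitivity_pbs <= 0 or self.sensitivity_serum <= 0:
            raise InvalidParameterError("sensitivities must be positive")
        if self.sensitivity_serum > self.sensitivity_pbs:
            raise InvalidParameterError("serum sensitivity must not exceed PBS sensitivity")

    def sensitivity_per_area(self, matrix: str) -> float:
        if matrix == "pbs":
            return self.sensitivity_pbs
        if matrix == "serum":
            return self.sensitivity_serum
        raise InvalidParameterError(f"unknown matrix {matrix!r}; use 'pbs' or 'serum'")

    def slope_nA_per_uM(self, matrix: str) -> float:
        """Whole-electrode sensitivity (calibration slope), nA/uM."""
        return self.sensitivity_per_area(matrix) * self.electrode_area_mm2


#: Measured presets: per-area sensitivities (PBS | serum) and pharmacological
#: ranges for each drug/isoform electrode; the etoposide electrode is bare
#: CNT and is monitored on its +220 mV oxidation peak, the CYP electrodes on
#: the -330 mV reduction peak.
PRESETS: dict[str, DrugIsoformPreset] = {
    "cyclophosphamide_2b6": DrugIsoformPreset(
        "cyclophosphamide", "2B6", (2.68, 76.6), 1.0, 0.3, -330.0, "reverse", -1
    ),
    "cyclophosphamide_3a4": DrugIsoformPreset(
        "cyclophosphamide", "3A4", (2.68, 76.6), 0.6, 0.3, -330.0, "reverse", -1
    ),
    "ifosfamide_2b6": DrugIsoformPreset(
        "ifosfamide", "2B6", (10.0, 160.0), 1.2, 0.1, -330.0, "reverse", -1
    ),
    "ifosfamide_3a4": DrugIsoformPreset(
        "ifosfamide", "3A4", (10.0, 160.0), 1.6, 0.4, -330.0, "reverse", -1
    ),
    "ftorafur_1a2": DrugIsoformPreset(
        "ftorafur", "1A2", (1.0, 10.0), 8.8, 3.9, -330.0, "reverse", -1
    ),
    "etoposide_cnt": DrugIsoformPreset(
        "etoposide", "CNT", (33.98, 101.94), 73.7, 9.1, 220.0, "forward", +1
    ),
}

#: Modulator grids used in the two-drug experiments: etoposide held fixed
#: while the CYP substrate is titrated, and ifosfamide held fixed while
#: etoposide is titrated.
ETOPOSIDE_MODULATOR_GRID_UM = (0.0, 25.0, 50.0, 75.0, 100.0)
IFOSFAMIDE_MODULATOR_GRID_UM = (0.0, 40.0, 80.0, 120.0, 160.0)


def generate_voltammogram(
    peaks: Sequence[PeakSpec],
    noise: CVNoiseModel = CVNoiseModel(),
    step: float = 1.0,
    scan_rate: float = DEFAULT_SCAN_RATE,
    rng: np.random.Generator | None = None,
) -> Voltammogram:
    """Compose one triangular-sweep voltammogram from peaks + background.

    Forward branch sweeps -600 -> +300 mV, reverse +300 -> -600 mV; the
    capacitive background is +/-capacitance_scale*scan_rate by branch.
    Deterministic for a fixed ``noise.seed`` (or supplied ``rng``).
    """
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    for p in peaks:
        if not SWEEP_MIN_MV <= p.center <= SWEEP_MAX_MV:
            raise InvalidParameterError(f"peak center {p.center} mV outside the sweep range")
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    v_fwd = np.arange(SWEEP_MIN_MV, SWEEP_MAX_MV + step / 2, step)
    v_rev = v_fwd[::-1]

    def branch_current(v: np.ndarray, segment: str, cap_sign: float) -> np.ndarray:
        cur = cap_sign * noise.capacitance_scale * scan_rate + noise.baseline_slope * v
        for p in peaks:
            if p.segment == segment:
                cur = cur + p.amplitude * np.exp(-0.5 * ((v - p.center) / p.width) ** 2)
        if noise.noise_sd > 0:
            cur = cur + rng.normal(0.0, noise.noise_sd, v.size)
        return cur

    i_fwd = branch_current(v_fwd, "forward", +1.0)
    i_rev = branch_current(v_rev, "reverse", -1.0)
    return Voltammogram(
        potential=np.concatenate([v_fwd, v_rev]),
        current=np.concatenate([i_fwd, i_rev]),
        segment=np.array(["forward"] * v_fwd.size + ["reverse"] * v_rev.size),
        scan_rate=scan_rate,
    )


def effective_sensitivity(base: float, modulator_conc: float, gamma: float) -> float:
    """Hetero-activation: sensitivity under a co-present modulator drug.

    Linear modulation base*(1 + gamma*modulator_conc); gamma = 0 is the
    no-interaction case (overlapping calibration curves), gamma > 0 the
    activation seen when etoposide boosts CYP-mediated turnover of a second
    substrate.
    """
    if base <= 0:
        raise InvalidParameterError("base sensitivity must be positive")
    if modulator_conc < 0:
        raise InvalidParameterError("modulator concentration must be >= 0")
    out = base * (1.0 + gamma * modulator_conc)
    if out <= 0:
        raise InvalidParameterError("modulated sensitivity must stay positive")
    return out


def _electrode_peaks(preset: DrugIsoformPreset, peak_current: float) -> list[PeakSpec]:
    """Cathodic (CYP electrode) peak structure at a given monitored current.

    Besides the monitored -330 mV reduction, the second cathodic region at
    -450 mV (amplitude tied to the monitored one) and the constant -200 mV
    oxygen-moiety peak of the nanotubes are included.
    """
    w = preset.peak_width_mv
    return [
        PeakSpec(preset.monitored_peak_mv, w, peak_current, "reverse"),
        PeakSpec(-450.0, w, 0.8 * peak_current, "reverse"),
        PeakSpec(-200.0, 20.0, -60.0, "reverse"),
    ]


def _cnt_peaks(preset: DrugIsoformPreset, peak_current: float) -> list[PeakSpec]:
    """Anodic (bare-CNT / etoposide) peak structure inside the sweep window.

    The +220 mV oxidation is monitored; its +150 mV reduction counterpart and
    the oxygen-moiety peak appear on the reverse branch.  (The +450/+350 mV
    pair reported for this electrode lies outside the -600..+300 mV sweep and
    is therefore not part of the synthetic trace.)
    """
    w = preset.peak_width_mv
    return [
        PeakSpec(220.0, w, peak_current, "forward"),
        PeakSpec(150.0, w, -0.4 * peak_current, "reverse"),
        PeakSpec(-200.0, 20.0, -60.0, "reverse"),
    ]


@dataclass
class CalibrationSeries:
    """One concentration series of voltammograms for a single electrode."""

    preset_id: str
    preset: DrugIsoformPreset
    matrix: str
    records: list[tuple[float, Voltammogram]]
    seed: int | None = None
    modulator_conc: float = 0.0
    gamma: float = 0.0
    noise: CVNoiseModel = field(default_factory=CVNoiseModel)


def generate_calibration_series(
    preset: DrugIsoformPreset | str,
    concentrations: Sequence[float] | None = None,
    n_replicates: int = 3,
    matrix: str = "pbs",
    noise: CVNoiseModel = CVNoiseModel(),
    seed: int = 0,
    n_blanks: int = 3,
    gamma: float = 0.0,
    modulator_conc: float = 0.0,
    blank_amplitude: float = 0.0,
    step: float = 1.0,
) -> CalibrationSeries:
    """Synthesise a full calibration series for one drug/isoform electrode.

    The monitored-peak amplitude of each voltammogram is
    ``sign * (sensitivity_per_area * area * concentration + blank)``, with the
    PBS or serum per-area sensitivity selected by ``matrix`` and optionally
    modulated by a second drug (``gamma``, ``modulator_conc``).  Blank
    (zero-concentration) replicates are included for detection-limit
    estimation.  Each voltammogram uses an independent substream derived from
    ``seed``.
    """
    preset_id = preset if isinstance(preset, str) else "custom"
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise InvalidParameterError(
                f"unknown preset {preset!r}; valid: {', '.join(sorted(PRESETS))}"
            )
        preset = PRESETS[preset_id]
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    slope = effective_sensitivity(preset.slope_nA_per_uM(matrix), modulator_conc, gamma)
    if concentrations is None:
        lo, hi = preset.pharmacological_range
        concentrations = np.linspace(lo, hi, 5)

    master = np.random.default_rng(seed)
    records: list[tuple[float, Voltammogram]] = []
    all_concs = [0.0] * n_blanks + [float(c) for c in concentrations for _ in range(n_replicates)]
    for conc in all_concs:
        if conc < 0:
            raise InvalidParameterError("concentrations must be >= 0")
        peak_current = preset.peak_sign * (slope * conc + blank_amplitude)
        peaks = (
            _cnt_peaks(preset, peak_current)
            if preset.peak_sign > 0
            else _electrode_peaks(preset, peak_current)
        )
        sub = np.random.default_rng(master.integers(2**31))
        vg = generate_voltammogram(peaks, replace(noise, seed=None), step=step, rng=sub)
        records.append((conc, vg))
    return CalibrationSeries(
        preset_id=preset_id,
        preset=preset,
        matrix=matrix,
        records=records,
        seed=seed,
        modulator_conc=modulator_conc,
        gamma=gamma,
        noise=noise,
    )


def generate_pair_families(
    preset: DrugIsoformPreset | str,
    modulator_concs: Sequence[float] = ETOPOSIDE_MODULATOR_GRID_UM,
    gamma: float = 0.005,
    matrix: str = "pbs",
    noise: CVNoiseModel = CVNoiseModel(),
    seed: int = 0,
    n_replicates: int = 2,
    n_blanks: int = 0,
    concentrations: Sequence[float] | None = None,
) -> list[tuple[float, CalibrationSeries]]:
    """One calibration series per fixed modulator concentration.

    Emulates the two-drug experiment: the primary drug is titrated over its
    pharmacological range while the modulator is held at each grid value.
    """
    if len(modulator_concs) < 2:
        raise InvalidParameterError("need at least two modulator concentrations")
    out = []
    for k, m in enumerate(modulator_concs):
        series = generate_calibration_series(
            preset,
            concentrations=concentrations,
            n_replicates=n_replicates,
            matrix=matrix,
            noise=noise,
            seed=seed + 1000 * k,
            n_blanks=n_blanks,
            gamma=gamma,
            modulator_conc=float(m),
        )
        out.append((float(m), series))
    return out
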