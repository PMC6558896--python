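"""Event segmentation, exposure/dose summaries, and cross-species dose.

The human chain couples a time-averaged number size distribution to the
simplified ICRP regional deposition curves at a light-exercise minute
ventilation of 25 L·min⁻¹: per-bin deposited dose rate
= concᵢ × ventilation × DFᵣ(dᵢ), summed over bins and regions.

Dose-rate semantics: DR_N and DR_m are **total deposited** (HA + TB + AL)
number/mass per minute, so that particles_per_event = DR_N × t holds by
construction; the raw inhaled rates (no deposition weighting) are exposed
separately as :func:`inhaled_dose_rates`.  Regional percentages are each
region's share of total deposited, normalized to 100.

The mouse route deliberately bypasses the human curves: the species-specific
alveolar deposition of the exposure distribution is folded into a single
scalar alveolar mass fraction (default 0.096), applied to inhaled mass at a
resting ventilation of 1.8 L·h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import deposition
from .size_distribution import (MassSizeDistribution, NumberSizeDistribution,
                                apply_respirable, effective_density,
                                number_to_mass)

__all__ = [
    "BreathingPattern",
    "HUMAN_LIGHT_EXERCISE",
    "MOUSE",
    "EventWindow",
    "LabeledSeries",
    "ExposureSummary",
    "segment",
    "summarize_exposure",
    "inhaled_dose_rates",
    "mouse_alveolar_dose",
    "workday_equivalents",
    "WorkdayEquivalence",
    "MOUSE_ALVEOLAR_MASS_FRACTION",
]

#: Scalar alveolar deposition fraction (by mass) for the mouse at the
#: exposure size distribution; used instead of species deposition curves.
MOUSE_ALVEOLAR_MASS_FRACTION = 0.096


@dataclass(frozen=True)
class BreathingPattern:
    """Species-level ventilation coupling air concentration to intake."""

    species: str
    minute_ventilation_l: float  # L·min⁻¹

    def __post_init__(self):
        if self.minute_ventilation_l <= 0:
            raise ValueError("ventilation must be positive")


#: 70 kg adult during light exercise.
HUMAN_LIGHT_EXERCISE = BreathingPattern("human_light_exercise", 25.0)
#: Resting mouse, 1.8 L·h⁻¹.
MOUSE = BreathingPattern("mouse", 1.8 / 60.0)


@dataclass(frozen=True)
class EventWindow:
    """A labeled half-open time slice [start, end), seconds."""

    label: str
    start: float
    end: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0


@dataclass
class LabeledSeries:
    """Snapshots falling in one event window."""

    window: EventWindow
    snapshots: list[NumberSizeDistribution]

    @property
    def label(self) -> str:
        return self.window.label


@dataclass(frozen=True)
class ExposureSummary:
    """One exposure/dose table row for an event window.

    Units: t min; n cm⁻³; m, m_pm4 μg·m⁻³; dr_n particles·min⁻¹;
    dr_m μg·min⁻¹; regional shares in % of total deposited;
    particles_per_event count; mass_per_event μg.
    """

    label: str
    t_min: float
    n_cm3: float
    m_ug_m3: float
    m_pm4_ug_m3: float
    dr_n_per_min: float
    ha_n_pct: float
    tb_n_pct: float
    al_n_pct: float
    dr_m_ug_min: float
    ha_m_pct: float
    tb_m_pct: float
    al_m_pct: float
    particles_per_event: float
    mass_per_event_ug: float

    COLUMNS = ("label", "t_min", "n_cm3", "m_ug_m3", "m_pm4_ug_m3",
               "dr_n_per_min", "ha_n_pct", "tb_n_pct", "al_n_pct",
               "dr_m_ug_min", "ha_m_pct", "tb_m_pct", "al_m_pct",
               "particles_per_event", "mass_per_event_ug")

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


def segment(series: Sequence[NumberSizeDistribution],
            windows: Sequence[EventWindow]) -> list[LabeledSeries]:
    """Assign snapshots to labeled windows (half-open [start, end)).

    Every window must lie within the series time span and catch at least one
    snapshot.
    """
    if not series:
        raise ValueError("empty series")
    times = np.array([s.timestamp for s in series], dtype=float)
    if np.any(np.isnan(times)):
        raise ValueError("all snapshots need timestamps for segmentation")
    t_lo, t_hi = times.min(), times.max()
    out = []
    for w in windows:
        # a half-open window may end one step beyond the last stamp, but it
        # must begin inside the sampled span
        if w.start < t_lo or w.start > t_hi:
            raise ValueError(
                f"window {w.label!r} [{w.start}, {w.end}) outside series "
                f"span [{t_lo}, {t_hi}]")
        mask = (times >= w.start) & (times < w.end)
        if not mask.any():
            raise ValueError(f"window {w.label!r} contains no snapshots")
        out.append(LabeledSeries(w, [series[i] for i in np.flatnonzero(mask)]))
    return out


def _mean_distribution(sub: LabeledSeries) -> NumberSizeDistribution:
    """Arithmetic time-average per bin (trapezoidal for non-uniform stamps)."""
    grid = sub.snapshots[0].grid
    conc = np.stack([s.conc for s in sub.snapshots])
    if len(sub.snapshots) == 1:
        mean = conc[0]
    else:
        t = np.array([s.timestamp for s in sub.snapshots], dtype=float)
        if np.allclose(np.diff(t), np.diff(t)[0]):
            mean = conc.mean(axis=0)
        else:
            mean = np.trapezoid(conc, t, axis=0) / (t[-1] - t[0])
    return NumberSizeDistribution(grid, mean)


def summarize_exposure(sub: LabeledSeries,
                       breathing: BreathingPattern = HUMAN_LIGHT_EXERCISE,
                       density: Callable | float = effective_density,
                       ) -> ExposureSummary:
    """Exposure/dose summary row for one labeled window.

    n and m are time-averages of total number and mass concentration;
    m_pm4 applies the respirable convention.  Deposited dose rates use the
    simplified ICRP curves at the pattern's minute ventilation.
    """
    if not sub.snapshots:
        raise ValueError("empty sub-series")
    mean_dist = _mean_distribution(sub)
    mass_dist = number_to_mass(mean_dist, density=density)
    m_pm4 = apply_respirable(mass_dist).total()

    d_um = mean_dist.grid.midpoints * 1e6
    df = deposition.regional_deposition(d_um)

    vent_cm3_min = breathing.minute_ventilation_l * 1000.0  # L→cm³
    # deposited number per minute, per region
    dep_n = [float(np.sum(mean_dist.conc * vent_cm3_min * r))
             for r in (df.head_airways, df.tracheobronchial, df.alveolar)]
    # deposited mass per minute, per region (μg·m⁻³ → μg·cm⁻³ is 1e-6)
    dep_m = [float(np.sum(mass_dist.mass_conc * 1e-6 * vent_cm3_min * r))
             for r in (df.head_airways, df.tracheobronchial, df.alveolar)]

    dr_n, dr_m = sum(dep_n), sum(dep_m)
    sh_n = [100.0 * x / dr_n if dr_n > 0 else 0.0 for x in dep_n]
    sh_m = [100.0 * x / dr_m if dr_m > 0 else 0.0 for x in dep_m]

    t_min = sub.window.duration_min
    return ExposureSummary(
        label=sub.label, t_min=t_min,
        n_cm3=mean_dist.total(), m_ug_m3=mass_dist.total(),
        m_pm4_ug_m3=m_pm4,
        dr_n_per_min=dr_n, ha_n_pct=sh_n[0], tb_n_pct=sh_n[1], al_n_pct=sh_n[2],
        dr_m_ug_min=dr_m, ha_m_pct=sh_m[0], tb_m_pct=sh_m[1], al_m_pct=sh_m[2],
        particles_per_event=dr_n * t_min, mass_per_event_ug=dr_m * t_min)


def inhaled_dose_rates(sub: LabeledSeries,
                       breathing: BreathingPattern = HUMAN_LIGHT_EXERCISE,
                       density: Callable | float = effective_density,
                       ) -> tuple[float, float]:
    """Raw inhaled (not deposition-weighted) number and mass per minute.

    Returns (particles·min⁻¹, μg·min⁻¹).
    """
    mean_dist = _mean_distribution(sub)
    mass_dist = number_to_mass(mean_dist, density=density)
    vent_cm3_min = breathing.minute_ventilation_l * 1000.0
    return (mean_dist.total() * vent_cm3_min,
            mass_dist.total() * 1e-6 * vent_cm3_min)


def mouse_alveolar_dose(concentration_ug_m3: float, duration_h: float,
                        breathing: BreathingPattern = MOUSE,
                        alveolar_mass_fraction: float = MOUSE_ALVEOLAR_MASS_FRACTION,
                        ) -> float:
    """Alveolar-deposited mass (μg) for a mouse breathing `concentration`.

    concentration × duration × ventilation × alveolar fraction, with
    μg·m⁻³ × L converted through 1 m³ = 1000 L.  The canonical workday
    check: 1000 μg·m⁻³ × 8 h × 1.8 L·h⁻¹ × 0.096 = 1.38 μg.
    """
    if concentration_ug_m3 < 0:
        raise ValueError("concentration must be >= 0")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if not 0 < alveolar_mass_fraction <= 1:
        raise ValueError("alveolar fraction must be in (0, 1]")
    vent_l_per_h = breathing.minute_ventilation_l * 60.0
    inhaled_m3 = vent_l_per_h * duration_h / 1000.0
    return concentration_ug_m3 * inhaled_m3 * alveolar_mass_fraction


@dataclass(frozen=True)
class WorkdayEquivalence:
    workdays: int
    ratio: float


def workday_equivalents(instilled_dose_ug: float,
                        per_workday_dose_ug: float) -> WorkdayEquivalence:
    """How many 8-h workdays of exposure an instilled bolus corresponds to.

    Nearest-integer rounding of the raw ratio; the raw ratio is returned
    alongside.
    """
    if instilled_dose_ug <= 0 or per_workday_dose_ug <= 0:
        raise ValueError("doses must be positive")
    ratio = instilled_dose_ug / per_workday_dose_ug
    return WorkdayEquivalence(workdays=int(round(ratio)), ratio=ratio)
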