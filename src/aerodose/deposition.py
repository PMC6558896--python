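"""Simplified ICRP respiratory-tract deposition curves and the LDSA metric.

Closed-form fits (Hinds' textbook form of the ICRP reference-worker model,
light-exercise adult, no nose/mouth switch) give, as a function of particle
diameter d in μm:

* inhalable fraction IF(d),
* head-airways (extra-thoracic) deposition DF_HA(d),
* tracheobronchial deposition DF_TB(d),
* alveolar deposition DF_AL(d).

The fits are valid for 0.001 μm ≤ d ≤ 100 μm; outside this range the module
raises rather than extrapolates.  All constants live in one auditable table
(:data:`ICRP_CONSTANTS`) so the provenance of every coefficient is explicit.

LDSA (lung-deposited surface area) weights the geometric surface of each
size bin by its alveolar deposition fraction — the exposure metric reported
by diffusion-charger monitors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .size_distribution import NumberSizeDistribution

__all__ = [
    "DepositionFractions",
    "inhalable_fraction",
    "regional_deposition",
    "ldsa_concentration",
    "deposition_curve",
    "DIAMETER_RANGE_UM",
]

DIAMETER_RANGE_UM = (1e-3, 1e2)

#: Coefficients of the simplified deposition fits (d in μm, ln = natural log).
#:
#: IF   = 1 − 0.5·(1 − 1/(b·d^p + 1))
#: HA   = IF·( 1/(1+exp(a1 + b1·ln d)) + 1/(1+exp(a2 − b2·ln d)) )
#: TB   = (c/d)·( exp(−k1·(ln d + m1)²) + A·exp(−k2·(ln d − m2)²) )
#: AL   = (c/d)·( exp(−k1·(ln d + m1)²) + A·exp(−k2·(ln d − m2)²) )
ICRP_CONSTANTS = {
    "IF": {"b": 7.6e-4, "p": 2.8},
    "HA": {"a1": 6.84, "b1": 1.183, "a2": 0.924, "b2": 1.885},
    "TB": {"c": 0.00352, "k1": 0.234, "m1": 3.40, "A": 63.9,
           "k2": 0.819, "m2": 1.61},
    "AL": {"c": 0.0155, "k1": 0.416, "m1": 2.84, "A": 19.11,
           "k2": 0.482, "m2": 1.362},
}


@dataclass(frozen=True)
class DepositionFractions:
    """Per-diameter deposition fractions; arrays when evaluated on a grid."""

    d_um: np.ndarray
    inhalable: np.ndarray
    head_airways: np.ndarray
    tracheobronchial: np.ndarray
    alveolar: np.ndarray

    @property
    def total(self) -> np.ndarray:
        """Total deposited fraction HA + TB + AL."""
        return self.head_airways + self.tracheobronchial + self.alveolar


def _validate(d_um) -> np.ndarray:
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    lo, hi = DIAMETER_RANGE_UM
    if np.any((d < lo) | (d > hi)):
        bad = d[(d < lo) | (d > hi)]
        raise ValueError(
            f"diameter {np.atleast_1d(bad)[0]:.4g} μm outside the validated "
            f"model range [{lo:g}, {hi:g}] μm")
    return d


def inhalable_fraction(d_um):
    """Fraction of ambient particles entering the respiratory tract.

    Tends to 1 for fine particles and asymptotes to 0.5 for very coarse
    ones; monotone non-increasing.
    """
    d = _validate(d_um)
    c = ICRP_CONSTANTS["IF"]
    out = 1.0 - 0.5 * (1.0 - 1.0 / (c["b"] * d ** c["p"] + 1.0))
    return float(out) if out.ndim == 0 else out


def regional_deposition(d_um) -> DepositionFractions:
    """Regional deposition fractions at diameter(s) d (μm).

    Alveolar deposition peaks for ultrafines around 0.01–0.05 μm (diffusion),
    head-airways deposition dominates above ~1 μm (impaction/sedimentation).
    """
    d = _validate(d_um)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    ln_d = np.log(d)

    inh = np.atleast_1d(inhalable_fraction(d))

    h = ICRP_CONSTANTS["HA"]
    ha = inh * (1.0 / (1.0 + np.exp(h["a1"] + h["b1"] * ln_d))
                + 1.0 / (1.0 + np.exp(h["a2"] - h["b2"] * ln_d)))

    t = ICRP_CONSTANTS["TB"]
    tb = (t["c"] / d) * (np.exp(-t["k1"] * (ln_d + t["m1"]) ** 2)
                         + t["A"] * np.exp(-t["k2"] * (ln_d - t["m2"]) ** 2))

    a = ICRP_CONSTANTS["AL"]
    al = (a["c"] / d) * (np.exp(-a["k1"] * (ln_d + a["m1"]) ** 2)
                         + a["A"] * np.exp(-a["k2"] * (ln_d - a["m2"]) ** 2))

    if scalar:
        d, inh, ha, tb, al = (x[0] for x in (d, inh, ha, tb, al))
    return DepositionFractions(d_um=d, inhalable=inh, head_airways=ha,
                               tracheobronchial=tb, alveolar=al)


def ldsa_concentration(dist: NumberSizeDistribution,
                       band_m: tuple[float, float] | None = None) -> float:
    """Lung-deposited (alveolar) surface-area concentration, cm²·m⁻³.

    Σᵢ concᵢ · π dᵢ² · DF_AL(dᵢ), with dᵢ the bin midpoints.  Pass
    ``band_m=(20e-9, 400e-9)`` to restrict to the ~20–400 nm band a
    diffusion-charger monitor responds to; the default uses the full grid.
    Unit chain: conc [cm⁻³] × area [μm²] is μm²·cm⁻³; 1 μm²·cm⁻³ =
    10⁻² cm²·m⁻³.
    """
    d_m = dist.grid.midpoints
    mask = np.ones_like(d_m, dtype=bool)
    if band_m is not None:
        mask = (d_m >= band_m[0]) & (d_m <= band_m[1])
    if not mask.any():
        return 0.0
    al = regional_deposition(d_m[mask] * 1e6).alveolar
    area_um2 = np.pi * (d_m[mask] * 1e6) ** 2
    ldsa_um2_cm3 = float(np.sum(dist.conc[mask] * area_um2 * al))
    return ldsa_um2_cm3 * 1e-2


def deposition_curve(d_um) -> pd.DataFrame:
    """Tabulate the deposition curves on a diameter grid (μm), for export.

    Columns: d_um, IF, HA, TB, AL, total.
    """
    df = regional_deposition(np.asarray(d_um, dtype=float))
    return pd.DataFrame({
        "d_um": np.atleast_1d(df.d_um),
        "IF": np.atleast_1d(df.inhalable),
        "HA": np.atleast_1d(df.head_airways),
        "TB": np.atleast_1d(df.tracheobronchial),
        "AL": np.atleast_1d(df.alveolar),
        "total": np.atleast_1d(df.total),
    })
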