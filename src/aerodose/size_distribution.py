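"""Core size-distribution algebra.

Diameter-binned number concentrations are the atom of the exposure pipeline:
everything downstream (mass conversion, respirable filtering, lung deposition,
dose rates) is a per-bin weighting of a :class:`NumberSizeDistribution`.

Conventions
-----------
* Diameters are stored in **metres** in all in-memory containers and data
  files; display units (nm, μm) are a reporting concern.
* Per-bin number concentration is in particles·cm⁻³; the spectral-density
  dialect dN/dlog₁₀Dp is available via :attr:`NumberSizeDistribution.density`
  and :meth:`NumberSizeDistribution.from_density` (per-bin = density × Δlog₁₀Dp).
* Mass concentrations are in μg·m⁻³.

The number→mass conversion uses a mass-mobility effective-density law for
fractal soot aggregates, ρ_eff(d_p) = A·d_p^(Dm−3) with d_p in metres,
A = 11.92 kg·m⁻³ and mass-mobility exponent Dm = 2.76 as measured for
turbofan-engine nonvolatile exhaust particles.  At 10 nm this gives
≈ 992 kg·m⁻³, decaying to ≈ 330 kg·m⁻³ at 1 μm, the expected behaviour for
aggregated combustion soot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SizeGrid",
    "NumberSizeDistribution",
    "MassSizeDistribution",
    "GeometricSummary",
    "effective_density",
    "number_to_mass",
    "respirable_penetration",
    "apply_respirable",
    "geometric_summary",
    "total_number",
    "total_mass",
    "series_to_csv",
    "series_from_csv",
]

# Unit chain for number→mass: conc [cm⁻³] × volume [m³] × ρ [kg·m⁻³] is in
# kg·cm⁻³·m⁻³·m³ ... made coherent as:  cm⁻³ → m⁻³ costs 1e6, kg → μg costs
# 1e9, so (cm⁻³ · m³ · kg·m⁻³) → μg·m⁻³ is a factor 1e15.
UG_M3_PER_KG_CM3 = 1.0e15

#: Effective-density law coefficient [kg·m⁻³ at d_p = 1 m] and mass-mobility
#: exponent for turbofan nonvolatile exhaust soot.
EFFECTIVE_DENSITY_COEFF = 11.92
MASS_MOBILITY_EXPONENT = 2.76

#: Respirable-convention (EN 481 / ACGIH, simplified cumulative-lognormal
#: form): median cut 4.25 μm, GSD 1.5.
RESPIRABLE_MEDIAN_UM = 4.25
RESPIRABLE_GSD = 1.5


class SizeGrid:
    """A strictly increasing set of diameter bin edges, in metres.

    Bin midpoints are geometric means of adjacent edges, matching how
    impactor/SMPS channels are conventionally labeled.
    """

    __slots__ = ("edges",)

    def __init__(self, edges: Sequence[float]):
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least two edges")
        if np.any(edges <= 0):
            raise ValueError("diameter edges must be positive")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("diameter edges must be strictly increasing")
        self.edges = edges

    @classmethod
    def default(cls, n_channels: int = 14, d_min: float = 6e-9,
                d_max: float = 10e-6) -> "SizeGrid":
        """Log-spaced grid spanning ~6 nm–10 μm, the span covered by a
        cascade-impactor + diffusion-charger instrument pair (14 channels
        mirrors the nominal ELPI stage layout)."""
        return cls(np.geomspace(d_min, d_max, n_channels + 1))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def dlog10(self) -> np.ndarray:
        """Per-bin width in log₁₀-diameter space."""
        return np.diff(np.log10(self.edges))

    def refine(self, factor: int = 2) -> "SizeGrid":
        """Subdivide each bin into `factor` log-equal sub-bins."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        log_e = np.log10(self.edges)
        parts = [np.linspace(log_e[i], log_e[i + 1], factor + 1)[:-1]
                 for i in range(self.n_bins)]
        new = np.concatenate(parts + [log_e[-1:]])
        return SizeGrid(10.0 ** new)

    def __eq__(self, other) -> bool:
        return isinstance(other, SizeGrid) and np.array_equal(self.edges, other.edges)

    def __hash__(self):
        return hash(self.edges.tobytes())

    def __repr__(self) -> str:
        return (f"SizeGrid({self.n_bins} bins, "
                f"{self.edges[0]:.3g}–{self.edges[-1]:.3g} m)")


@dataclass
class NumberSizeDistribution:
    """One diameter-binned number-concentration snapshot.

    `conc` is per-bin concentration in particles·cm⁻³ (not spectral density).
    """

    grid: SizeGrid
    conc: np.ndarray
    timestamp: float | None = None
    diameter_kind: str = "aerodynamic"  # or "mobility"; provenance only

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (self.grid.n_bins,):
            raise ValueError(
                f"conc has {self.conc.size} bins, grid has {self.grid.n_bins}")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.diameter_kind not in ("aerodynamic", "mobility"):
            raise ValueError(f"unknown diameter_kind {self.diameter_kind!r}")

    @property
    def density(self) -> np.ndarray:
        """Spectral density dN/dlog₁₀Dp, particles·cm⁻³ per log₁₀ decade."""
        return self.conc / self.grid.dlog10

    @classmethod
    def from_density(cls, grid: SizeGrid, density: Sequence[float],
                     **kw) -> "NumberSizeDistribution":
        density = np.asarray(density, dtype=float)
        return cls(grid, density * grid.dlog10, **kw)

    def total(self) -> float:
        return float(self.conc.sum())


@dataclass
class MassSizeDistribution:
    """Diameter-binned mass concentration, μg·m⁻³ per bin."""

    grid: SizeGrid
    mass_conc: np.ndarray
    timestamp: float | None = None
    respirable_filtered: bool = False

    def __post_init__(self):
        self.mass_conc = np.asarray(self.mass_conc, dtype=float)
        if self.mass_conc.shape != (self.grid.n_bins,):
            raise ValueError("mass_conc length does not match grid")
        if np.any(self.mass_conc < 0):
            raise ValueError("mass concentrations must be non-negative")

    def total(self) -> float:
        return float(self.mass_conc.sum())


@dataclass(frozen=True)
class GeometricSummary:
    """Geometric mean / geometric standard deviation of a positive series."""

    geometric_mean: float
    geometric_std: float
    n_obs: int
    n_floored: int = 0


def effective_density(d_p, *, coefficient: float = EFFECTIVE_DENSITY_COEFF,
                      mass_mobility_exponent: float = MASS_MOBILITY_EXPONENT):
    """Size-dependent effective density ρ_eff = A·d_p^(Dm−3), kg·m⁻³.

    Parameters
    ----------
    d_p : float or array
        Particle diameter in **metres** (must be > 0).
    coefficient : float
        A, kg·m⁻³ evaluated at d_p = 1 m.  Default is the turbofan
        nonvolatile-soot value 11.92.
    mass_mobility_exponent : float
        Dm; 3 recovers a size-independent density equal to `coefficient`,
        fractal soot aggregates have Dm < 3 so density falls with size.
    """
    d_p = np.asarray(d_p, dtype=float)
    if np.any(d_p <= 0):
        raise ValueError("diameter must be positive")
    out = coefficient * d_p ** (mass_mobility_exponent - 3.0)
    return float(out) if out.ndim == 0 else out


def number_to_mass(dist: NumberSizeDistribution,
                   density: Callable[[np.ndarray], np.ndarray] | float = effective_density,
                   ) -> MassSizeDistribution:
    """Convert a number distribution to a mass distribution, μg·m⁻³ per bin.

    Per bin i (midpoint diameter d_i, metres):

        mass_i = conc_i · (π/6)·d_i³ · ρ(d_i) · 10¹⁵

    where the 10¹⁵ converts kg·cm⁻³-of-air to μg·m⁻³-of-air (10⁶ for
    cm⁻³→m⁻³, 10⁹ for kg→μg).  `density` may be a callable d[m] → kg·m⁻³
    (default: the soot effective-density law) or a constant in kg·m⁻³.
    """
    d = dist.grid.midpoints
    rho = density(d) if callable(density) else float(density) * np.ones_like(d)
    mass = dist.conc * (np.pi / 6.0) * d ** 3 * rho * UG_M3_PER_KG_CM3
    return MassSizeDistribution(dist.grid, mass, timestamp=dist.timestamp)


def respirable_penetration(d_um):
    """Respirable-convention penetration efficiency for diameter d (μm).

    Simplified cumulative-lognormal form: 1 − Φ(ln(d/4.25)/ln 1.5); equals
    0.5 at the 4.25 μm median and → 1 for fine particles.  Monotone
    non-increasing in d.
    """
    d_um = np.asarray(d_um, dtype=float)
    if np.any(d_um <= 0):
        raise ValueError("diameter must be positive")
    z = np.log(d_um / RESPIRABLE_MEDIAN_UM) / np.log(RESPIRABLE_GSD)
    out = norm.sf(z)
    return float(out) if out.ndim == 0 else out


def apply_respirable(dist: MassSizeDistribution) -> MassSizeDistribution:
    """Weight each mass bin by the respirable penetration at its midpoint.

    Produces the respirable (PM4-convention) mass distribution.  Applying the
    filter twice is an error — the flag records that the convention has
    already been folded in.
    """
    if dist.respirable_filtered:
        raise ValueError("distribution is already respirable-filtered")
    pen = respirable_penetration(dist.grid.midpoints * 1e6)
    return MassSizeDistribution(dist.grid, dist.mass_conc * pen,
                                timestamp=dist.timestamp,
                                respirable_filtered=True)


def geometric_summary(series: Iterable[float],
                      detection_floor: float | None = None) -> GeometricSummary:
    """GM/GSD of a positive-valued series.

    GM = exp(mean ln x); GSD = exp(sd ln x) with the sample (n−1)
    denominator (GSD = 1 for n = 1 or constant series).  Values at or below
    `detection_floor` are floored to it before the log transform; by default
    the floor is the smallest positive observation, so zero readings from an
    instrument's off-scale-low channel do not blow up the log.  The number of
    floored values is reported.
    """
    x = np.asarray(list(series), dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    positive = x[x > 0]
    if detection_floor is None:
        if positive.size == 0:
            raise ValueError("no positive values in series")
        detection_floor = float(positive.min())
    if detection_floor <= 0:
        raise ValueError("detection floor must be positive")
    n_floored = int(np.sum(x < detection_floor))
    x = np.maximum(x, detection_floor)
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    gsd = 1.0 if x.size < 2 else float(np.exp(logs.std(ddof=1)))
    return GeometricSummary(gm, gsd, n_obs=int(x.size), n_floored=n_floored)


def total_number(dist: NumberSizeDistribution) -> float:
    """Grid-integrated number concentration, particles·cm⁻³."""
    return dist.total()


def total_mass(dist: MassSizeDistribution) -> float:
    """Grid-integrated mass concentration, μg·m⁻³."""
    return dist.total()


# ---------------------------------------------------------------------------
# long-format CSV round-trip (shared dialect with the synthetic generator)

def series_to_csv(series: Sequence[NumberSizeDistribution], path) -> None:
    """Write snapshots as long-format CSV: one row per (timestamp, channel).

    Columns: timestamp_s, channel_lo_m, channel_hi_m, conc_per_cm3, saturated.
    Truth series are never saturated; the column exists so device records and
    truth share one dialect.
    """
    if not series:
        raise ValueError("empty series")
    rows = []
    for snap in series:
        lo, hi = snap.grid.edges[:-1], snap.grid.edges[1:]
        t = np.nan if snap.timestamp is None else snap.timestamp
        for j in range(snap.grid.n_bins):
            rows.append((t, lo[j], hi[j], snap.conc[j], 0))
    pd.DataFrame(rows, columns=["timestamp_s", "channel_lo_m", "channel_hi_m",
                                "conc_per_cm3", "saturated"]).to_csv(path, index=False)


def series_from_csv(path) -> list[NumberSizeDistribution]:
    """Inverse of :func:`series_to_csv` (lossless for shared grids)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for t, grp in df.groupby("timestamp_s", sort=True, dropna=False):
        grp = grp.sort_values("channel_lo_m")
        edges = np.append(grp["channel_lo_m"].to_numpy(),
                          grp["channel_hi_m"].to_numpy()[-1])
        ts = None if pd.isna(t) else float(t)
        out.append(NumberSizeDistribution(SizeGrid(edges),
                                          grp["conc_per_cm3"].to_numpy(),
                                          timestamp=ts))
    return out
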