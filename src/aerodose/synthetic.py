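"""Event-structured synthetic aerosol time series and instrument emulation.

Raw field records from airfield campaigns are rarely deposited; this module
generates aerosol truth with the statistical structure the downstream
analysis assumes — multimodal lognormal size distributions, an event
timeline (background, engine-running peaks, fuel-truck shoulder), and
instrument-like artifacts (channel rebinning, multiplicative counting noise,
hard saturation at the device's upper detection limit).

Randomness contract: every operation takes an explicit integer seed and is
bit-reproducible.  Child streams are derived from a root seed with
``numpy.random.SeedSequence(root, spawn_key=(stream,))``; the pipeline uses
stream 0 for truth generation, 1 for the channelized instrument, 2 for
scalar instruments, 3 for scalar fixture series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .size_distribution import NumberSizeDistribution, SizeGrid

__all__ = [
    "LognormalMode",
    "ScenarioEvent",
    "EventScenario",
    "InstrumentSpec",
    "DeviceRecord",
    "generate_timeseries",
    "simulate_instrument",
    "generate_scalar_series",
    "child_rng",
    "discmini_spec",
    "elpi_spec",
    "airfield_cycle_scenario",
    "commercial_airport_scenario",
]

EVENT_LABELS = ("background", "PL", "PA", "FT", "custom")


def child_rng(root_seed: int, stream: int) -> np.random.Generator:
    """Deterministic child generator for operation `stream` of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(root_seed), spawn_key=(int(stream),)))


@dataclass(frozen=True)
class LognormalMode:
    """One lognormal mode: total N (cm⁻³), GMD (m), GSD (≥ 1).

    GSD = 1 is the monodisperse degenerate case: all of N lands in the bin
    containing the GMD.
    """

    number_concentration: float  # particles·cm⁻³
    gmd: float                   # geometric mean diameter, m
    gsd: float                   # geometric standard deviation

    def __post_init__(self):
        if self.number_concentration < 0:
            raise ValueError("mode N must be >= 0")
        if self.gmd <= 0:
            raise ValueError("GMD must be positive")
        if self.gsd < 1:
            raise ValueError("GSD must be >= 1")

    def bin_concentrations(self, grid: SizeGrid) -> np.ndarray:
        """Per-bin concentration (cm⁻³) of the mode on `grid`.

        Exact bin integral via lognormal CDF differences, so the grid total
        equals N up to truncation outside the grid span.
        """
        if self.gsd == 1.0:  # monodisperse: a delta at the GMD
            conc = np.zeros(grid.n_bins)
            if grid.edges[0] <= self.gmd < grid.edges[-1]:
                idx = int(np.searchsorted(grid.edges, self.gmd, side="right") - 1)
                conc[idx] = self.number_concentration
            return conc
        z = np.log(grid.edges / self.gmd) / np.log(self.gsd)
        cdf = norm.cdf(z)
        return self.number_concentration * np.diff(cdf)


@dataclass(frozen=True)
class ScenarioEvent:
    """A labeled time window emitting a set of lognormal modes.

    Profiles: ``step`` (constant amplitude 1 within the window) or
    ``rise-decay`` (instant rise at `start`, exponential decay with time
    constant `decay_s`) — the latter reproduces the peak-then-shoulder shape
    of engine-start events.
    """

    label: str
    start: float
    end: float
    modes: tuple[LognormalMode, ...]
    profile: str = "step"
    decay_s: float = 60.0

    def __post_init__(self):
        if self.label not in EVENT_LABELS:
            raise ValueError(f"label must be one of {EVENT_LABELS}")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        if self.profile not in ("step", "rise-decay"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.decay_s <= 0:
            raise ValueError("decay constant must be positive")
        object.__setattr__(self, "modes", tuple(self.modes))

    def amplitude(self, t) -> np.ndarray:
        """Temporal scaling of the event's modes at time(s) t."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.start) & (t < self.end)
        if self.profile == "step":
            return inside.astype(float)
        return np.where(inside, np.exp(-(t - self.start) / self.decay_s), 0.0)


@dataclass
class EventScenario:
    """Ordered event timeline on one measurement track.

    Background events form their own track and may underlie anything;
    non-background event windows must be pairwise non-overlapping.
    """

    events: list[ScenarioEvent]
    grid: SizeGrid = field(default_factory=SizeGrid.default)
    noise_sigma: float = 0.0  # multiplicative lognormal ln-space sigma on truth

    def __post_init__(self):
        if not self.events:
            raise ValueError("scenario has no events")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        fg = sorted((e for e in self.events if e.label != "background"),
                    key=lambda e: e.start)
        for a, b in zip(fg, fg[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"event windows overlap: {a.label} [{a.start},{a.end}) and "
                    f"{b.label} [{b.start},{b.end})")

    @property
    def span(self) -> tuple[float, float]:
        return (min(e.start for e in self.events),
                max(e.end for e in self.events))

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "grid": {"edges_m": [float(x) for x in self.grid.edges]},
            "noise_sigma": float(self.noise_sigma),
            "events": [
                {
                    "label": e.label, "start_s": e.start, "end_s": e.end,
                    "profile": e.profile, "decay_s": e.decay_s,
                    "modes": [{"n_per_cm3": m.number_concentration,
                               "gmd_m": m.gmd, "gsd": m.gsd}
                              for m in e.modes],
                }
                for e in self.events
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EventScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        grid = SizeGrid(doc["grid"]["edges_m"])
        events = [
            ScenarioEvent(
                label=e["label"], start=float(e["start_s"]),
                end=float(e["end_s"]), profile=e.get("profile", "step"),
                decay_s=float(e.get("decay_s", 60.0)),
                modes=tuple(LognormalMode(float(m["n_per_cm3"]),
                                          float(m["gmd_m"]), float(m["gsd"]))
                            for m in e["modes"]),
            )
            for e in doc["events"]
        ]
        return cls(events=events, grid=grid,
                   noise_sigma=float(doc.get("noise_sigma", 0.0)))


@dataclass(frozen=True)
class InstrumentSpec:
    """How a device distorts truth: channels, saturation, noise, cadence.

    `channel_edges` is None for scalar devices (they report the grid-
    integrated total).  `noise_sigma` is the ln-space sigma of per-reading
    multiplicative lognormal noise (noise GSD = exp(sigma)).  Any reading
    above `saturation` is clipped there and flagged.
    """

    name: str
    saturation: float               # particles·cm⁻³
    channel_edges: tuple[float, ...] | None = None
    time_resolution: float = 1.0    # s
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.saturation <= 0:
            raise ValueError("saturation must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.time_resolution <= 0:
            raise ValueError("time resolution must be positive")
        if self.channel_edges is not None:
            e = np.asarray(self.channel_edges, dtype=float)
            if e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("channel edges must be strictly increasing")
            object.__setattr__(self, "channel_edges", tuple(float(x) for x in e))


@dataclass
class DeviceRecord:
    """What an instrument reported: clipped, noisy, possibly rebinned truth."""

    name: str
    times: np.ndarray
    values: np.ndarray               # (n_t, n_ch) or (n_t,) for scalar devices
    saturated: np.ndarray            # same shape, bool
    channel_edges: np.ndarray | None
    clipped_fraction: float

    @property
    def is_scalar(self) -> bool:
        return self.channel_edges is None

    def totals(self) -> np.ndarray:
        return self.values if self.is_scalar else self.values.sum(axis=1)

    def to_csv(self, path) -> None:
        """Long-format CSV; scalar devices omit the channel columns."""
        if self.is_scalar:
            df = pd.DataFrame({"timestamp_s": self.times,
                               "conc_per_cm3": self.values,
                               "saturated": self.saturated.astype(int)})
        else:
            nt, nch = self.values.shape
            lo = np.tile(self.channel_edges[:-1], nt)
            hi = np.tile(self.channel_edges[1:], nt)
            df = pd.DataFrame({
                "timestamp_s": np.repeat(self.times, nch),
                "channel_lo_m": lo, "channel_hi_m": hi,
                "conc_per_cm3": self.values.ravel(),
                "saturated": self.saturated.ravel().astype(int)})
        df.to_csv(path, index=False)


def _truth_bins(scenario: EventScenario, t: float) -> np.ndarray:
    conc = np.zeros(scenario.grid.n_bins)
    for ev in scenario.events:
        amp = float(ev.amplitude(t))
        if amp > 0:
            for m in ev.modes:
                conc += amp * m.bin_concentrations(scenario.grid)
    return conc


def generate_timeseries(scenario: EventScenario, step: float,
                        seed: int) -> list[NumberSizeDistribution]:
    """Generate one truth snapshot per `step` seconds across the scenario span.

    Within an event window the underlying truth is the sum of the active
    events' modes on the grid, scaled by each event's temporal profile.  If
    the scenario carries `noise_sigma` > 0, multiplicative lognormal noise is
    applied per bin per step; deterministic given `seed`.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rng = np.random.default_rng(seed)
    t0, t1 = scenario.span
    times = np.arange(t0, t1, step)
    out = []
    for t in times:
        conc = _truth_bins(scenario, float(t))
        if scenario.noise_sigma > 0:
            conc = conc * rng.lognormal(0.0, scenario.noise_sigma, conc.size)
        out.append(NumberSizeDistribution(scenario.grid, conc, timestamp=float(t)))
    return out


def _rebin(conc: np.ndarray, src: SizeGrid, dst_edges: np.ndarray) -> np.ndarray:
    """Redistribute per-bin concentrations onto destination channels by
    log-diameter overlap (uniform density in log d within each source bin).
    Exact when destination edges nest within source edges."""
    s_lo, s_hi = np.log(src.edges[:-1]), np.log(src.edges[1:])
    d_lo, d_hi = np.log(dst_edges[:-1]), np.log(dst_edges[1:])
    out = np.zeros(d_lo.size)
    for j in range(d_lo.size):
        ov = np.clip(np.minimum(d_hi[j], s_hi) - np.maximum(d_lo[j], s_lo),
                     0.0, None)
        out[j] = np.sum(conc * ov / (s_hi - s_lo))
    return out


def simulate_instrument(truth: Sequence[NumberSizeDistribution],
                        spec: InstrumentSpec, seed: int) -> DeviceRecord:
    """Pass a truth series through an instrument model.

    Channelized devices rebin truth onto their channels; scalar devices
    report the grid-integrated total.  Multiplicative lognormal noise (ln-
    sigma `spec.noise_sigma`) is applied, then values above `spec.saturation`
    are clipped there and flagged; the clipped fraction of readings is
    reported on the record.
    """
    if not truth:
        raise ValueError("empty truth series")
    grid = truth[0].grid
    times = np.array([s.timestamp if s.timestamp is not None else i
                      for i, s in enumerate(truth)], dtype=float)
    rng = np.random.default_rng(seed)

    if spec.channel_edges is None:
        vals = np.array([s.total() for s in truth])
    else:
        edges = np.asarray(spec.channel_edges)
        if edges[0] < grid.edges[0] * (1 - 1e-12) or \
           edges[-1] > grid.edges[-1] * (1 + 1e-12):
            raise ValueError("instrument channels extend outside the truth grid")
        vals = np.stack([_rebin(s.conc, grid, edges) for s in truth])

    if spec.noise_sigma > 0:
        vals = vals * rng.lognormal(0.0, spec.noise_sigma, vals.shape)

    saturated = vals > spec.saturation
    vals = np.minimum(vals, spec.saturation)
    clipped = float(saturated.mean())
    ch = None if spec.channel_edges is None else np.asarray(spec.channel_edges)
    return DeviceRecord(name=spec.name, times=times, values=vals,
                        saturated=saturated, channel_edges=ch,
                        clipped_fraction=clipped)


def generate_scalar_series(gm: float, gsd: float, n: int,
                           seed: int) -> np.ndarray:
    """I.i.d. lognormal draws with geometric mean `gm` and geometric SD `gsd`.

    GSD = 1 degenerates to a constant series of `gm`.
    """
    if gm <= 0:
        raise ValueError("geometric mean must be positive")
    if gsd < 1:
        raise ValueError("GSD must be >= 1")
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=np.log(gm), sigma=np.log(gsd), size=n)


# ---------------------------------------------------------------------------
# presets (order-of-magnitude, illustrative)

def discmini_spec(noise_sigma: float = 0.0) -> InstrumentSpec:
    """Diffusion-charger-like scalar monitor: saturates at 10⁶ cm⁻³."""
    return InstrumentSpec(name="discmini", saturation=1e6,
                          channel_edges=None, time_resolution=1.0,
                          noise_sigma=noise_sigma)


def elpi_spec(grid: SizeGrid | None = None,
              noise_sigma: float = 0.0) -> InstrumentSpec:
    """Cascade-impactor-like channelized device: saturates at 10⁸ cm⁻³."""
    grid = grid or SizeGrid.default()
    return InstrumentSpec(name="elpi", saturation=1e8,
                          channel_edges=tuple(float(x) for x in grid.edges),
                          time_resolution=1.0, noise_sigma=noise_sigma)


def _soot_modes(peak_n: float) -> tuple[LognormalMode, ...]:
    # bimodal engine plume: nucleation-mode soot ~10 nm plus ~150 nm soot mode
    return (LognormalMode(0.95 * peak_n, 10e-9, 1.7),
            LognormalMode(0.05 * peak_n, 150e-9, 1.6))


def airfield_cycle_scenario(n_cycles: int = 2, cycle_s: float = 1800.0,
                            background_n: float = 2e4,
                            peak_n: float = 5e7,
                            noise_sigma: float = 0.0) -> EventScenario:
    """Jet-shelter workflow: repeated plane-leaving / plane-arriving +
    fuel-truck cycles over a steady background.

    Peak concentrations are illustrative order-of-magnitude values (engine
    events drive channelized readings toward 10⁷–10⁸ cm⁻³, far above a
    ~10⁴ cm⁻³ background); no deposited record constrains them further.
    """
    total = n_cycles * cycle_s
    events = [ScenarioEvent("background", 0.0, total,
                            (LognormalMode(background_n, 20e-9, 2.0),))]
    for k in range(n_cycles):
        t0 = k * cycle_s
        events.append(ScenarioEvent("PL", t0 + 120, t0 + 420,
                                    _soot_modes(peak_n),
                                    profile="rise-decay", decay_s=120.0))
        events.append(ScenarioEvent("PA", t0 + 900, t0 + 1200,
                                    _soot_modes(peak_n),
                                    profile="rise-decay", decay_s=120.0))
        events.append(ScenarioEvent("FT", t0 + 1200, t0 + 1500,
                                    _soot_modes(0.1 * peak_n),
                                    profile="rise-decay", decay_s=180.0))
    return EventScenario(events=events, noise_sigma=noise_sigma)


def commercial_airport_scenario(duration_s: float = 3600.0,
                                noise_sigma: float = 0.0) -> EventScenario:
    """Apron background: bimodal (<20 nm and ~140 nm) at a ~2×10⁴ cm⁻³ level."""
    modes = (LognormalMode(1.5e4, 15e-9, 1.8),
             LognormalMode(0.7e4, 140e-9, 1.7))
    return EventScenario(
        events=[ScenarioEvent("background", 0.0, duration_s, modes)],
        noise_sigma=noise_sigma)
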