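"""End-to-end run configuration and output bundle.

A run turns one scenario (generated or loaded) into a deterministic bundle:

* ``series.csv`` — the truth size-distribution time series (long format)
* ``device_<name>.csv`` — instrument-like records
* ``exposure_summary.csv`` — one exposure/dose row per event window
* ``deposition_curve.csv`` — IF/HA/TB/AL on a log grid
* ``dose_report.json`` — human deposited-dose rates, mouse workday dose,
  workday equivalents for the instilled bolus doses
* ``composition.json`` — ΣPAH aggregates and the >3× enrichment report
* ``trend.csv`` — linear-trend R² per endpoint/particle series
* ``manifest.json`` — package version, seed, config hash

Child seeds for each stochastic stage derive from the root seed via
``SeedSequence(root, spawn_key=(stream,))`` (streams documented in
:mod:`aerodose.synthetic`), so one root seed pins the whole bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import composition as comp
from . import dose_response as dr
from .deposition import deposition_curve
from .dosimetry import (HUMAN_LIGHT_EXERCISE, MOUSE, EventWindow,
                        mouse_alveolar_dose, segment, summarize_exposure,
                        workday_equivalents)
from .synthetic import (EventScenario, airfield_cycle_scenario, child_rng,
                        discmini_spec, elpi_spec, generate_timeseries,
                        simulate_instrument)
from .size_distribution import series_to_csv

__all__ = ["RunConfig", "run_pipeline"]

#: Reference shift-scenario air concentration (μg·m⁻³) and instilled bolus
#: doses (μg) used in the cross-species workday-equivalence report.
WORKDAY_CONCENTRATION_UG_M3 = 1000.0
WORKDAY_HOURS = 8.0
INSTILLED_DOSES_UG = (6.0, 18.0, 54.0)


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    out_dir: Path
    seed: int = 0
    scenario_path: Path | None = None     # YAML; None → built-in preset
    step_s: float = 5.0
    windows: list[EventWindow] = field(default_factory=list)  # [] → preset
    instrument_noise_sigma: float = 0.05
    density_model: str = "effective_power_law"   # or "constant:<rho>"
    mouse_concentration_ug_m3: float = WORKDAY_CONCENTRATION_UG_M3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        windows = [EventWindow(w["label"], float(w["start_s"]), float(w["end_s"]))
                   for w in doc.get("windows", [])]
        return cls(out_dir=Path(doc["out_dir"]),
                   seed=int(doc.get("seed", 0)),
                   scenario_path=Path(doc["scenario"]) if doc.get("scenario") else None,
                   step_s=float(doc.get("step_s", 5.0)),
                   windows=windows,
                   instrument_noise_sigma=float(doc.get("instrument_noise_sigma", 0.05)),
                   density_model=str(doc.get("density_model", "effective_power_law")),
                   mouse_concentration_ug_m3=float(
                       doc.get("mouse_concentration_ug_m3",
                               WORKDAY_CONCENTRATION_UG_M3)))

    def density(self):
        from .size_distribution import effective_density
        if self.density_model == "effective_power_law":
            return effective_density
        if self.density_model.startswith("constant:"):
            return float(self.density_model.split(":", 1)[1])
        raise ValueError(f"unknown density model {self.density_model!r}")


def _default_windows(cycle_s: float = 1800.0) -> list[EventWindow]:
    # one-cycle averaging windows over the preset timeline
    return [EventWindow("PL", 120.0, 420.0),
            EventWindow("PA+FT", 900.0, 1500.0),
            EventWindow("tPM4", 0.0, cycle_s)]


def _config_hash(cfg: RunConfig) -> str:
    doc = dataclasses.asdict(cfg)
    doc["out_dir"] = str(doc["out_dir"])
    doc["scenario_path"] = str(doc["scenario_path"]) if cfg.scenario_path else None
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and write the bundle; returns the manifest."""
    if cfg.scenario_path is not None:
        if not Path(cfg.scenario_path).exists():
            raise FileNotFoundError(f"scenario file not found: {cfg.scenario_path}")
        scenario = EventScenario.from_yaml(cfg.scenario_path)
    else:
        scenario = airfield_cycle_scenario()

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    density = cfg.density()
    seeds = {name: child_rng(cfg.seed, k).integers(0, 2 ** 31 - 1)
             for k, name in enumerate(["truth", "elpi", "discmini", "scalar"])}

    # 1. truth series + instrument records
    series = generate_timeseries(scenario, step=cfg.step_s, seed=int(seeds["truth"]))
    series_to_csv(series, out / "series.csv")
    elpi = simulate_instrument(series, elpi_spec(scenario.grid,
                                                cfg.instrument_noise_sigma),
                               seed=int(seeds["elpi"]))
    disc = simulate_instrument(series, discmini_spec(cfg.instrument_noise_sigma),
                               seed=int(seeds["discmini"]))
    elpi.to_csv(out / "device_elpi.csv")
    disc.to_csv(out / "device_discmini.csv")

    # 2. exposure/dose summary per window
    windows = cfg.windows or _default_windows()
    rows = [summarize_exposure(sub, HUMAN_LIGHT_EXERCISE, density).as_row()
            for sub in segment(series, windows)]
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "exposure_summary.csv", index=False)

    # 3. deposition curves
    deposition_curve(np.geomspace(1e-3, 1e2, 200)).to_csv(
        out / "deposition_curve.csv", index=False)

    # 4. cross-species dose report
    per_workday = mouse_alveolar_dose(cfg.mouse_concentration_ug_m3,
                                      WORKDAY_HOURS, MOUSE)
    equivalence = {
        f"{d:g}ug": dataclasses.asdict(workday_equivalents(d, per_workday))
        for d in INSTILLED_DOSES_UG}
    dose_report = {
        "human": {"minute_ventilation_l": HUMAN_LIGHT_EXERCISE.minute_ventilation_l,
                  "windows": {r["label"]: {"dr_n_per_min": r["dr_n_per_min"],
                                           "dr_m_ug_min": r["dr_m_ug_min"]}
                              for r in rows}},
        "mouse": {"concentration_ug_m3": cfg.mouse_concentration_ug_m3,
                  "workday_hours": WORKDAY_HOURS,
                  "ventilation_l_per_h": MOUSE.minute_ventilation_l * 60.0,
                  "alveolar_mass_fraction": 0.096,
                  "alveolar_dose_ug_per_workday": round(per_workday, 2)},
        "workday_equivalents": equivalence,
    }
    (out / "dose_report.json").write_text(json.dumps(dose_report, indent=2))

    # 5. composition aggregates
    pah = {col: dataclasses.asdict(comp.sum_pah(comp.load_pah_table(col)))
           for col in ("CAP", "JEP")}
    metals = comp.compare_profiles(comp.load_metals_table("CAP"),
                                   comp.load_metals_table("JEP"))
    enriched = metals[metals["exceeds"]]["analyte"].tolist()
    (out / "composition.json").write_text(json.dumps(
        {"sum_pah_mg_per_g": pah, "cap_over_jep_gt3x": enriched}, indent=2))

    # 6. dose-response trend statistics
    trend_rows = []
    for particle in ("JEP", "CAP", "NIST2975"):
        for endpoint in ("neutrophils", "total_cells"):
            res = dr.linear_trend(dr.load_bal_groups(endpoint, particle))
            trend_rows.append({"particle": particle, "endpoint": endpoint,
                               "between_r2": res.between_r2,
                               "total_r2": res.total_r2})
    pd.DataFrame(trend_rows).to_csv(out / "trend.csv", index=False)

    manifest = {
        "package": "aerodose", "version": __version__,
        "seed": cfg.seed, "config_sha256": _config_hash(cfg),
        "child_seeds": {k: int(v) for k, v in seeds.items()},
        "n_snapshots": len(series),
        "clipped_fraction": {"elpi": elpi.clipped_fraction,
                             "discmini": disc.clipped_fraction},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
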