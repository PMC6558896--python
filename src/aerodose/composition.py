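"""Analyte composition tables (PAH, metals) with not-detected semantics.

CSV dialect: columns ``analyte, value, uncertainty, unit``.  The literal
token ``ND`` in the value column means not detected; a slash value ``x/y``
is a pair of replicate measurements, retained individually and reported as
the mean of the detected replicates (a detected/ND pair is flagged).

The ΣPAH aggregate treats not-detected analytes as zero — the convention
used when comparing airport particulate to diesel reference materials.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["CompositionTable", "sum_pah", "compare_profiles",
           "load_pah_table", "load_metals_table"]


@dataclass(frozen=True)
class AnalyteEntry:
    analyte: str
    value: float | None           # mean of detected replicates; None if ND
    replicates: tuple[float | None, ...]  # raw replicates, None per ND
    uncertainty: float | None
    unit: str

    @property
    def detected(self) -> bool:
        return self.value is not None

    @property
    def mixed_detection(self) -> bool:
        """True when replicates disagree on detection (e.g. '5/ND')."""
        flags = [r is not None for r in self.replicates]
        return any(flags) and not all(flags)


def _parse_value(raw) -> tuple[float | None, tuple[float | None, ...]]:
    """Parse 'ND', '12.3' or replicate notation '12.3/ND' etc."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None, (None,)
    s = str(raw).strip()
    reps: list[float | None] = []
    for part in s.split("/"):
        part = part.strip()
        if part.upper() in ("ND", "-", "−", ""):
            reps.append(None)
        else:
            v = float(part)
            if v < 0:
                raise ValueError(f"negative analyte value {v}")
            reps.append(v)
    detected = [r for r in reps if r is not None]
    mean = float(np.mean(detected)) if detected else None
    return mean, tuple(reps)


class CompositionTable:
    """Analyte → concentration mapping with detection flags."""

    def __init__(self, entries: list[AnalyteEntry], name: str = ""):
        names = [e.analyte for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")
        self.entries = list(entries)
        self.name = name

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, analyte: str) -> AnalyteEntry:
        for e in self.entries:
            if e.analyte == analyte:
                return e
        raise KeyError(analyte)

    @property
    def analytes(self) -> list[str]:
        return [e.analyte for e in self.entries]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "value",
                   name: str = "") -> "CompositionTable":
        entries = []
        for _, row in df.iterrows():
            mean, reps = _parse_value(row[value_col])
            unc = row.get("uncertainty")
            unc = None if unc is None or pd.isna(unc) else float(unc)
            entries.append(AnalyteEntry(analyte=str(row["analyte"]).strip(),
                                        value=mean, replicates=reps,
                                        uncertainty=unc,
                                        unit=str(row.get("unit", ""))))
        return cls(entries, name=name)

    @classmethod
    def from_csv(cls, path, value_col: str = "value",
                 name: str = "") -> "CompositionTable":
        return cls.from_frame(pd.read_csv(path, dtype={value_col: str}),
                              value_col=value_col, name=name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            raw = "/".join("ND" if r is None else f"{r:g}" for r in e.replicates)
            rows.append({"analyte": e.analyte, "value": raw,
                         "uncertainty": e.uncertainty, "unit": e.unit})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PahSum:
    total: float
    n_detected: int
    n_not_detected: int
    unit: str


def sum_pah(table: CompositionTable) -> PahSum:
    """ΣPAH with not-detected = 0; reports how many analytes were ND."""
    if len(table) == 0:
        raise ValueError("empty composition table")
    detected = [e.value for e in table.entries if e.detected]
    unit = table.entries[0].unit
    return PahSum(total=float(sum(detected)), n_detected=len(detected),
                  n_not_detected=len(table) - len(detected), unit=unit)


def compare_profiles(a: CompositionTable, b: CompositionTable,
                     ratio_threshold: float = 3.0) -> pd.DataFrame:
    """Per-analyte ratio a/b for analytes detected in both tables.

    Rows where either side is ND carry a NaN ratio and a ``flag`` noting
    which side was undetected.  ``exceeds`` marks ratios above
    `ratio_threshold` (default 3×, the conventional report filter for a
    markedly enriched analyte).
    """
    common = [x for x in a.analytes if x in set(b.analytes)]
    rows = []
    for analyte in common:
        ea, eb = a[analyte], b[analyte]
        if ea.detected and eb.detected and eb.value > 0:
            ratio = ea.value / eb.value
            flag = ""
        else:
            ratio = np.nan
            sides = []
            if not ea.detected:
                sides.append("a")
            if not eb.detected:
                sides.append("b")
            flag = "ND:" + ",".join(sides) if sides else "zero-denominator"
        rows.append({"analyte": analyte, "value_a": ea.value,
                     "value_b": eb.value, "ratio": ratio, "flag": flag,
                     "exceeds": bool(ratio > ratio_threshold)
                     if not np.isnan(ratio) else False})
    return pd.DataFrame(rows)


def _load_packaged(fname: str) -> pd.DataFrame:
    with resources.files("aerodose.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, dtype=str)


def load_pah_table(column: str = "CAP") -> CompositionTable:
    """Packaged 16-PAH table (mg·g⁻¹) for the airport particle samples and
    diesel reference materials; columns: CAP, JEP, NIST1650B, NIST2975."""
    df = _load_packaged("pah_content.csv")
    if column not in df.columns:
        raise KeyError(f"no column {column!r} in PAH table")
    sub = pd.DataFrame({"analyte": df["analyte"], "value": df[column],
                        "uncertainty": df.get(f"{column}_sd"),
                        "unit": "mg/g"})
    return CompositionTable.from_frame(sub, name=column)


def load_metals_table(column: str = "CAP") -> CompositionTable:
    """Packaged elemental (metals) table, μg·g⁻¹; columns: JEP, CAP,
    NIST2975, CB.  Replicate pairs are kept in slash notation."""
    df = _load_packaged("metal_content.csv")
    if column not in df.columns:
        raise KeyError(f"no column {column!r} in metals table")
    sub = pd.DataFrame({"analyte": df["analyte"], "value": df[column],
                        "unit": "ug/g"})
    return CompositionTable.from_frame(sub, name=column)
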