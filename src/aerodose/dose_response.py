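"""Group summaries and the test-for-linear-trend (alerting R²).

For a one-way layout of dose groups with means ȳᵢ, sizes nᵢ and centered
dose scores cᵢ = doseᵢ − Σnᵢdoseᵢ/Σnᵢ, the linear-trend contrast is

    L = Σ nᵢ cᵢ ȳᵢ,     SS_linear = L² / Σ nᵢ cᵢ²,

which for equal n reduces to the textbook n·(Σcᵢȳᵢ)²/Σcᵢ² form.  Two R²
normalizations are reported side by side:

* ``between_r2`` = SS_linear / SS_between — the fraction of between-group-
  mean variance explained by the linear trend ("alerting R²" in the
  between-means sense; equals the R² of an OLS fit of group means on dose
  for equal n);
* ``total_r2`` = SS_linear / (SS_between + SS_within) — the total-variance
  variant, available only when within-group spread (SEMs or raw values) is
  supplied, with SS_within = Σ (nᵢ−1)·(semᵢ·√nᵢ)².

Dose scores default to the actual instilled masses, not ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DoseGroup", "DoseGroupSet", "GroupSummary", "TrendResult",
           "group_summary", "linear_trend", "load_bal_groups"]


@dataclass(frozen=True)
class DoseGroup:
    """One dose group: raw per-animal values, or (mean, sem, n) summary."""

    dose: float
    values: tuple[float, ...] | None = None
    mean: float | None = None
    sem: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.values is not None:
            object.__setattr__(self, "values", tuple(float(v) for v in self.values))
            if len(self.values) < 2:
                raise ValueError("raw-value groups need n >= 2")
            object.__setattr__(self, "n", len(self.values))
            object.__setattr__(self, "mean", float(np.mean(self.values)))
            object.__setattr__(
                self, "sem",
                float(np.std(self.values, ddof=1) / np.sqrt(len(self.values))))
        else:
            if self.mean is None or self.n is None:
                raise ValueError("summary groups need mean and n")
            if self.n < 1:
                raise ValueError("group size must be >= 1")


class DoseGroupSet:
    """Ordered dose groups with distinct doses."""

    def __init__(self, groups: Sequence[DoseGroup]):
        groups = sorted(groups, key=lambda g: g.dose)
        doses = [g.dose for g in groups]
        if len(set(doses)) != len(doses):
            raise ValueError("doses must be distinct")
        self.groups = list(groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups])

    @property
    def means(self) -> np.ndarray:
        return np.array([g.mean for g in self.groups])

    @property
    def sems(self) -> np.ndarray | None:
        sems = [g.sem for g in self.groups]
        if any(s is None for s in sems):
            return None
        return np.array(sems)

    @property
    def ns(self) -> np.ndarray:
        return np.array([g.n for g in self.groups])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseGroupSet":
        """Build from long form (dose_ug, value) or summary form
        (dose_ug, mean, sem, n)."""
        if "value" in df.columns:
            groups = [DoseGroup(dose=float(d), values=tuple(g["value"]))
                      for d, g in df.groupby("dose_ug")]
        else:
            groups = [DoseGroup(dose=float(r["dose_ug"]), mean=float(r["mean"]),
                                sem=float(r["sem"]), n=int(r["n"]))
                      for _, r in df.iterrows()]
        return cls(groups)


@dataclass(frozen=True)
class GroupSummary:
    dose: float
    mean: float
    sem: float
    n: int


def group_summary(groups: DoseGroupSet) -> list[GroupSummary]:
    """Per-group mean and SEM (= sd/√n, sample sd) from raw values."""
    out = []
    for g in groups.groups:
        if g.values is None:
            raise ValueError("group_summary needs raw per-animal values")
        out.append(GroupSummary(dose=g.dose, mean=g.mean, sem=g.sem, n=g.n))
    return out


@dataclass(frozen=True)
class TrendResult:
    contrast: float          # L = Σ nᵢ cᵢ ȳᵢ
    ss_linear: float
    ss_between: float
    ss_within: float | None
    between_r2: float
    total_r2: float | None
    degenerate: bool         # all group means equal → SS_between = 0


def linear_trend(groups: DoseGroupSet,
                 scores: Sequence[float] | None = None) -> TrendResult:
    """Linear-trend contrast across ≥ 3 dose groups.

    `scores` defaults to the doses themselves.  Unequal group sizes use
    nᵢ-weighted centering, reducing exactly to the classic equal-n contrast.
    Both R² normalizations are bounded in [0, 1]; the degenerate all-equal-
    means case reports 0 with a flag rather than 0/0.
    """
    if len(groups) < 3:
        raise ValueError("linear trend needs at least 3 dose groups")
    scores = groups.doses if scores is None else np.asarray(scores, dtype=float)
    if scores.size != len(groups):
        raise ValueError("one score per group required")
    if len(set(scores.tolist())) != scores.size:
        raise ValueError("scores must be distinct")

    n = groups.ns.astype(float)
    means = groups.means
    w_total = n.sum()
    c = scores - float(np.sum(n * scores) / w_total)
    grand = float(np.sum(n * means) / w_total)

    contrast = float(np.sum(n * c * means))
    ss_linear = contrast ** 2 / float(np.sum(n * c ** 2))
    ss_between = float(np.sum(n * (means - grand) ** 2))

    sems = groups.sems
    ss_within = None
    if sems is not None:
        ss_within = float(np.sum((n - 1) * (sems * np.sqrt(n)) ** 2))

    if ss_between <= 0:
        return TrendResult(contrast=contrast, ss_linear=ss_linear,
                           ss_between=ss_between, ss_within=ss_within,
                           between_r2=0.0,
                           total_r2=0.0 if ss_within is not None else None,
                           degenerate=True)

    between_r2 = ss_linear / ss_between
    total_r2 = None
    if ss_within is not None:
        total_r2 = ss_linear / (ss_between + ss_within)
    return TrendResult(contrast=contrast, ss_linear=ss_linear,
                       ss_between=ss_between, ss_within=ss_within,
                       between_r2=between_r2, total_r2=total_r2,
                       degenerate=False)


def load_bal_groups(endpoint: str = "neutrophils", particle: str = "JEP",
                    day: int = 1) -> DoseGroupSet:
    """Packaged broncho-alveolar-lavage cell counts (Mean ± SEM, ×10³ cells)
    for instilled airport and reference particles, as dose-group summaries."""
    from importlib import resources

    with resources.files("aerodose.data").joinpath("bal_cells.csv").open() as fh:
        df = pd.read_csv(fh)
    sub = df[(df["endpoint"] == endpoint) & (df["particle"] == particle)
             & (df["day"] == day)]
    if sub.empty:
        raise KeyError(f"no packaged groups for {endpoint}/{particle}/day {day}")
    return DoseGroupSet.from_frame(sub)
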