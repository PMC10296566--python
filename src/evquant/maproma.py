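"""MAProMa differential indexes and DEP calling.

For a protein with aPSM values X and Y in two compared conditions:

* DAve (Differential Average) = (X - Y) / (X + Y) / 0.5 = 2(X - Y)/(X + Y),
  a bounded fold-change-like index in [-2, 2];
* DCI (Differential Confidence Index) = (X + Y)(X - Y)/2, an
  abundance-weighted difference.

A protein is a DEP when |DAve| >= 0.2 and |DCI| >= 2 (both thresholds
configurable; use ``dci_threshold=0`` to reproduce DAve-only calling).
A fold change f between the two conditions implies DAve = 2(f-1)/(f+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ConditionDesign, CountMatrix

DAVE_THRESHOLD = 0.2
DCI_THRESHOLD = 2.0


def dave(x, y):
    """2(X - Y)/(X + Y); 0 where X = Y = 0. Accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("aPSM values must be non-negative")
    total = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 2.0 * (x - y) / np.where(total > 0, total, 1.0), 0.0)
    return out.item() if out.ndim == 0 else out


def dci(x, y):
    """(X + Y)(X - Y)/2. Accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("aPSM values must be non-negative")
    out = (x + y) * (x - y) / 2.0
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class ComparisonSpec:
    name: str
    x_condition: str
    y_condition: str
    dave_threshold: float = DAVE_THRESHOLD
    dci_threshold: float = DCI_THRESHOLD

    def __post_init__(self) -> None:
        if self.x_condition == self.y_condition:
            raise ValueError("x and y conditions must differ")
        if self.dave_threshold < 0 or self.dci_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class DepCall:
    protein: str
    x_apsm: float
    y_apsm: float
    dave: float
    dci: float
    is_dep: bool
    direction: str  # "up_in_X" | "up_in_Y" | "none"


def compare(matrix: CountMatrix, spec: ComparisonSpec) -> list[DepCall]:
    """One DepCall per protein present (aPSM > 0) in either condition.

    is_dep requires both |DAve| >= dave_threshold and |DCI| >= dci_threshold;
    direction follows the sign of DAve (positive = up in the X term).
    """
    if matrix.column_kind != "condition":
        raise ValueError("compare expects a condition-level aPSM matrix")
    for c in (spec.x_condition, spec.y_condition):
        if c not in matrix.data.columns:
            raise ValueError(f"condition column {c!r} missing from matrix")
    x = matrix.data[spec.x_condition].to_numpy(dtype=float)
    y = matrix.data[spec.y_condition].to_numpy(dtype=float)
    present = (x + y) > 0
    d_ave = dave(x, y)
    d_ci = dci(x, y)
    is_dep = (np.abs(d_ave) >= spec.dave_threshold) & (
        np.abs(d_ci) >= spec.dci_threshold
    )
    calls = []
    for i in np.flatnonzero(present):
        if d_ave[i] > 0:
            direction = "up_in_X"
        elif d_ave[i] < 0:
            direction = "up_in_Y"
        else:
            direction = "none"
        calls.append(
            DepCall(
                matrix.proteins[i],
                float(x[i]),
                float(y[i]),
                float(d_ave[i]),
                float(d_ci[i]),
                bool(is_dep[i]),
                direction,
            )
        )
    return calls


def calls_to_frame(calls: list[DepCall]) -> pd.DataFrame:
    frame = pd.DataFrame([c.__dict__ for c in calls])
    if not frame.empty:
        # DAve reported to 2 decimals as in the figure labels; full precision
        # is retained in the DepCall objects
        frame["dave"] = frame["dave"].round(2)
    return frame


def common_trend(
    comparisons: list[list[DepCall]], min_support: int | None = None
) -> dict[str, set[str]]:
    """Proteins that are DEPs with the same direction in >= min_support
    comparisons (default: in all of them — the "always up/down" sets)."""
    if len(comparisons) < 2:
        raise ValueError("need at least 2 comparisons")
    if min_support is None:
        min_support = len(comparisons)
    support: dict[tuple[str, str], int] = {}
    for calls in comparisons:
        for call in calls:
            if call.is_dep and call.direction != "none":
                key = (call.protein, call.direction)
                support[key] = support.get(key, 0) + 1
    out: dict[str, set[str]] = {"up_in_X": set(), "up_in_Y": set()}
    for (protein, direction), n in support.items():
        if n >= min_support:
            out[direction].add(protein)
    return out


def comparison_family(
    design: ConditionDesign,
    dave_threshold: float = DAVE_THRESHOLD,
    dci_threshold: float = DCI_THRESHOLD,
) -> list[ComparisonSpec]:
    """The study's pairwise comparison families.

    * BPA family: BPA+ vs BPA- at every matched (dose, harvest) cell
      (6 specs for the default design); X = BPA+.
    * Dose family: within BPA+, highest dose vs each lower dose at every
      harvest time (0 vs 11.3 Gy and 1.9 vs 11.3 Gy at 6 h and 24 h -> 4
      specs); X = the highest dose.
    """
    table = design.condition_table()
    if table.empty:
        raise ValueError("empty design")
    specs: list[ComparisonSpec] = []
    cells = {(r.bpa, r.dose_gy, r.harvest_h): r.condition
             for r in table.itertuples(index=False)}
    unmatched = []
    for (bpa, dose, harvest), cond in sorted(cells.items()):
        if bpa != "plus":
            continue
        partner = cells.get(("minus", dose, harvest))
        if partner is None:
            unmatched.append(cond)
            continue
        specs.append(
            ComparisonSpec(
                f"{cond}_vs_{partner}", cond, partner, dave_threshold, dci_threshold
            )
        )
    for (bpa, dose, harvest), cond in sorted(cells.items()):
        if bpa == "minus" and ("plus", dose, harvest) not in cells:
            unmatched.append(cond)
    plus_cells = sorted({(d, h) for (b, d, h) in cells if b == "plus"})
    doses = sorted({d for d, _ in plus_cells})
    if len(doses) > 1:
        top = doses[-1]
        for harvest in sorted({h for _, h in plus_cells}):
            hi = cells.get(("plus", top, harvest))
            if hi is None:
                continue
            for low in doses[:-1]:
                lo = cells.get(("plus", low, harvest))
                if lo is None:
                    unmatched.append(f"plus/{low}Gy/{harvest}h")
                    continue
                specs.append(
                    ComparisonSpec(
                        f"{hi}_vs_{lo}", hi, lo, dave_threshold, dci_threshold
                    )
                )
    if unmatched:
        warnings.warn(f"unmatched design cell(s) skipped: {sorted(set(unmatched))}")
    return specs


def write_comparison(calls: list[DepCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
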