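"""Run normalization, condition-level aPSM averaging and repeatability.

aPSM (average peptide spectrum matches) is the mean spectral count of a
protein over all runs of one experimental condition; it is the relative
abundance proxy that every downstream comparison consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConditionDesign, CountMatrix


@dataclass
class RepeatabilitySummary:
    pair_kind: str  # "technical" | "biological"
    r2_values: list[float]
    pair_labels: list[str]

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_values))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2_values, ddof=1)) if len(self.r2_values) > 1 else 0.0


def normalize_runs(matrix: CountMatrix) -> CountMatrix:
    """Scale each run so its total equals the mean of the raw run totals.

    Total-count normalization: within-run proportions are preserved and the
    operation is idempotent.
    """
    if matrix.column_kind != "run":
        raise ValueError("normalize_runs expects a run-level matrix")
    totals = matrix.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero run column(s): {list(zero.index)}")
    target = totals.mean()
    scaled = matrix.data * (target / totals)
    return CountMatrix(scaled, "run", matrix.species)


def average_condition(
    matrix: CountMatrix, design: ConditionDesign, nested: bool = False
) -> CountMatrix:
    """Average run counts to condition-level aPSM profiles.

    Default: plain mean over all runs of the condition, so the aPSM is the
    average spectral evidence across every replicate run.
    ``nested=True`` averages technical replicates first, then
    biological replicates (equal-weighted), which differs only for unbalanced
    designs.
    """
    if matrix.column_kind != "run":
        raise ValueError("average_condition expects a run-level matrix")
    cond = design.condition_of()
    cols = {}
    for label in design.condition_labels:
        runs = design.runs_of(label)
        missing = [r for r in runs if r not in matrix.data.columns]
        if missing:
            raise ValueError(f"run(s) {missing} of condition {label!r} not in matrix")
        sub = matrix.data[runs]
        if nested:
            meta = design.frame.set_index("run_id").loc[runs]
            per_bio = sub.T.groupby(meta["biorep"]).mean().T
            cols[label] = per_bio.mean(axis=1)
        else:
            cols[label] = sub.mean(axis=1)
    out = pd.DataFrame(cols)
    return CountMatrix(out, "condition", matrix.species)


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation (symmetric in its arguments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def repeatability_r2(
    matrix: CountMatrix, design: ConditionDesign, pair_kind: str
) -> RepeatabilitySummary:
    """Pairwise replicate agreement as OLS R^2 of count profiles.

    technical: the two technical runs of each (condition, biorep);
    biological: biorep pairs within each condition, technical runs averaged
    first. R^2 is the squared Pearson correlation over the union of proteins
    (zeros filled), hence symmetric in the pair.
    """
    if pair_kind not in ("technical", "biological"):
        raise ValueError("pair_kind must be 'technical' or 'biological'")
    cond = design.condition_of()
    meta = design.frame.copy()
    meta["condition"] = cond.values
    r2s: list[float] = []
    labels: list[str] = []
    if pair_kind == "technical":
        for (c, b), grp in meta.groupby(["condition", "biorep"]):
            runs = list(grp["run_id"])
            if len(runs) < 2:
                continue
            for i in range(len(runs)):
                for j in range(i + 1, len(runs)):
                    r2s.append(
                        _pearson_r2(
                            matrix.data[runs[i]].values, matrix.data[runs[j]].values
                        )
                    )
                    labels.append(f"{runs[i]} vs {runs[j]}")
    else:
        for c, grp in meta.groupby("condition"):
            per_bio = {
                b: matrix.data[list(g["run_id"])].mean(axis=1)
                for b, g in grp.groupby("biorep")
            }
            bios = sorted(per_bio)
            if len(bios) < 2:
                continue
            for i in range(len(bios)):
                for j in range(i + 1, len(bios)):
                    r2s.append(
                        _pearson_r2(per_bio[bios[i]].values, per_bio[bios[j]].values)
                    )
                    labels.append(f"{c} b{bios[i]} vs b{bios[j]}")
    if not r2s:
        raise ValueError(f"no replicate pairs of kind {pair_kind!r} in design")
    return RepeatabilitySummary(pair_kind, r2s, labels)


def frequency_filter(matrix: CountMatrix, min_conditions: int = 2) -> list[str]:
    """Proteins with aPSM > 0 in at least ``min_conditions`` conditions."""
    if matrix.column_kind != "condition":
        raise ValueError("frequency_filter expects a condition-level aPSM matrix")
    present = (matrix.data > 0).sum(axis=1)
    return list(matrix.data.index[present >= min_conditions])


def overlap_percent(query: set[str] | list[str], reference: set[str] | list[str]) -> float:
    """|query intersect reference| / |query| as a percentage."""
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    return 100.0 * len(query & set(reference)) / len(query)
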