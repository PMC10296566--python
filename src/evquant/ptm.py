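"""Residue-level modification-rate statistics.

For a residue (Met or Tyr), the modification rate is the number of PSMs
flagged as modified divided by the number of PSMs whose peptide contains the
residue — a spectra-level occupancy, not a distinct-peptide fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
import scipy.stats as st

from .io import ConditionDesign, PsmRecord, _as_frame

RESIDUE_LETTER = {"Met": "M", "Tyr": "Y"}
MOD_COLUMN = {"Met": "met_oxidized", "Tyr": "tyr_nitrosylated"}


@dataclass(frozen=True)
class PtmRate:
    scope: str  # condition label or "pooled"
    residue: str  # "Met" | "Tyr"
    modified_psms: int
    containing_psms: int

    def __post_init__(self) -> None:
        if self.residue not in RESIDUE_LETTER:
            raise ValueError(f"unknown residue {self.residue!r}")
        if self.modified_psms > self.containing_psms:
            raise ValueError("modified_psms exceeds containing_psms")

    @property
    def rate(self) -> float:
        if self.containing_psms == 0:
            return 0.0
        return self.modified_psms / self.containing_psms


def ptm_rate(
    records: pd.DataFrame | Iterable[PsmRecord],
    residue: str,
    scope: str = "pooled",
    design: ConditionDesign | None = None,
) -> PtmRate:
    """Modification rate of one residue over a scope.

    ``scope`` is ``"pooled"`` (all records) or a condition label, in which
    case ``design`` must be given to map runs to conditions.
    """
    frame = _as_frame(records)
    if scope != "pooled":
        if design is None:
            raise ValueError("design required for a condition scope")
        cond = design.condition_of()
        frame = frame[frame["run_id"].map(cond) == scope]
    letter = RESIDUE_LETTER[residue]
    containing = frame["peptide"].str.contains(letter, regex=False)
    modified = frame.loc[containing, MOD_COLUMN[residue]]
    return PtmRate(scope, residue, int(modified.sum()), int(containing.sum()))


def rates_by_condition(
    records: pd.DataFrame | Iterable[PsmRecord],
    design: ConditionDesign,
    residue: str,
) -> dict[str, PtmRate]:
    return {
        label: ptm_rate(records, residue, label, design)
        for label in design.condition_labels
    }


def contribution_ratio(rate_a: PtmRate, rate_b: PtmRate) -> float | None:
    """Ratio of modified-PSM counts (absolute contribution of a vs b).

    Returns None (undefined) when the denominator count is zero.
    """
    if rate_a.scope != rate_b.scope:
        raise ValueError("rates computed on different scopes")
    if rate_b.modified_psms == 0:
        return None
    return rate_a.modified_psms / rate_b.modified_psms


def compare_rates(rate_a: PtmRate, rate_b: PtmRate, method: str = "ztest") -> float:
    """Two-sided comparison of two modification rates.

    ``ztest``: two-proportion z-test with continuity correction (via the
    equivalent corrected chi-square on the 2x2 table); ``exact``: Fisher's
    exact test for small counts.
    """
    if rate_a.containing_psms == 0 or rate_b.containing_psms == 0:
        raise ValueError("cannot compare rates with zero containing PSMs")
    table = [
        [rate_a.modified_psms, rate_a.containing_psms - rate_a.modified_psms],
        [rate_b.modified_psms, rate_b.containing_psms - rate_b.modified_psms],
    ]
    if method == "exact":
        return float(st.fisher_exact(table)[1])
    if method != "ztest":
        raise ValueError(f"unknown method {method!r}")
    if rate_a.rate == rate_b.rate:
        return 1.0
    col_tot = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in col_tot:  # all modified or none modified on both sides
        return float(st.fisher_exact(table)[1])
    return float(st.chi2_contingency(table, correction=True)[1])


def ptm_report(
    records: pd.DataFrame | Iterable[PsmRecord],
    design: ConditionDesign,
    contrasts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Tidy per-(scope, residue) rate table with optional contrast p-values."""
    frame = _as_frame(records)
    rows = []
    for residue in ("Met", "Tyr"):
        pooled = ptm_rate(frame, residue)
        rows.append(
            dict(
                scope="pooled",
                residue=residue,
                modified_psms=pooled.modified_psms,
                containing_psms=pooled.containing_psms,
                rate=pooled.rate,
            )
        )
        per_cond = rates_by_condition(frame, design, residue)
        for label, r in per_cond.items():
            rows.append(
                dict(
                    scope=label,
                    residue=residue,
                    modified_psms=r.modified_psms,
                    containing_psms=r.containing_psms,
                    rate=r.rate,
                )
            )
        if contrasts:
            for a, b in contrasts:
                p = compare_rates(per_cond[a], per_cond[b])
                rows.append(
                    dict(
                        scope=f"{a} vs {b}",
                        residue=residue,
                        modified_psms=pd.NA,
                        containing_psms=pd.NA,
                        rate=pd.NA,
                        p_value=p,
                    )
                )
    out = pd.DataFrame(rows)
    if "p_value" not in out.columns:
        out["p_value"] = pd.NA
    return out
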