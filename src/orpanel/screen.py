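"""Dual-luciferase screening cascade.

The cascade mirrors high-throughput OR deorphanization practice: a primary
screen ranks receptor-odorant pairs by the fold change of Renilla-normalized
reporter activity over no-odor controls and selects candidates (top-k or a
fold threshold); a secondary screen retests candidates in triplicate at
three doses against triplicate no-odor controls with an uncorrected
two-sided t-test per dose; a pair is confirmed when any dose is significant
*and* the odor mean exceeds the control mean (suppression never counts as a
hit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError, ParameterError
from .stats import welch_t_test

__all__ = [
    "reporter_activity", "primary_rank", "secondary_confirm", "screen_summary",
    "run_screen", "SecondaryResult",
]


def reporter_activity(firefly: float, renilla: float) -> float:
    """Firefly / Renilla ratio: transfection-efficiency-controlled activity."""
    if renilla <= 0:
        raise DataError("renilla luminescence must be positive")
    return firefly / renilla


def _activities(records: pd.DataFrame) -> pd.Series:
    if np.any(records["renilla"] <= 0):
        raise DataError("renilla luminescence must be positive")
    return records["firefly"] / records["renilla"]


def primary_rank(
    records: pd.DataFrame,
    select_rule: str = "fold:2.0",
) -> pd.DataFrame:
    """Rank receptor-odorant pairs by fold change over the no-odor control.

    ``records`` uses the screen dialect (or_id, odorant_id,
    concentration_molar with NaN for no-odor controls, replicate, firefly,
    renilla).  ``select_rule`` is ``"top:K"`` or ``"fold:X"``.  Output is
    sorted descending by fold change with ties broken by or_id; pairs with a
    zero control mean are flagged unrankable and never selected.
    """
    df = records.copy()
    df["activity"] = _activities(df)
    is_control = df["concentration_molar"].isna()
    rows = []
    for (or_id, odorant), grp in df.groupby(["or_id", "odorant_id"], sort=True):
        odor = grp.loc[~is_control.loc[grp.index], "activity"]
        ctrl = grp.loc[is_control.loc[grp.index], "activity"]
        if odor.empty or ctrl.empty:
            raise InsufficientDataError(f"pair ({or_id}, {odorant}): need odor and control wells")
        ctrl_mean = ctrl.mean()
        rankable = ctrl_mean > 0
        rows.append({
            "or_id": or_id, "odorant_id": odorant,
            "odor_mean": odor.mean(), "control_mean": ctrl_mean,
            "fold": odor.mean() / ctrl_mean if rankable else np.nan,
            "rankable": rankable,
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(["rankable", "fold", "or_id"],
                          ascending=[False, False, True],
                          kind="stable").reset_index(drop=True)
    kind, _, arg = select_rule.partition(":")
    if kind == "top":
        k = int(arg)
        out["candidate"] = out["rankable"] & (np.arange(len(out)) < k)
    elif kind == "fold":
        out["candidate"] = out["rankable"] & (out["fold"] >= float(arg))
    else:
        raise ParameterError(f"select_rule must be 'top:K' or 'fold:X', got {select_rule!r}")
    return out


@dataclass(frozen=True)
class SecondaryResult:
    or_id: str
    odorant_id: str
    p_by_dose: dict[float, float]
    direction_by_dose: dict[float, bool]  # odor mean > control mean
    confirmed: bool


def secondary_confirm(
    dose_records: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> SecondaryResult:
    """Confirm one candidate pair from triplicate dose data.

    One two-sided t-test (Welch by default, uncorrected) per dose against
    the no-odor wells; confirmation requires some dose with p < alpha and an
    odor mean above the control mean.
    """
    df = dose_records.copy()
    df["activity"] = _activities(df)
    pairs = set(zip(df["or_id"], df["odorant_id"]))
    if len(pairs) != 1:
        raise ParameterError("secondary_confirm expects records for exactly one pair")
    or_id, odorant = pairs.pop()
    ctrl = df.loc[df["concentration_molar"].isna(), "activity"].to_numpy()
    doses = sorted(df.loc[df["concentration_molar"].notna(), "concentration_molar"].unique())
    if ctrl.size < 2:
        raise InsufficientDataError("need >= 2 no-odor control replicates")
    p_by_dose: dict[float, float] = {}
    direction: dict[float, bool] = {}
    for dose in doses:
        odor = df.loc[df["concentration_molar"] == dose, "activity"].to_numpy()
        if odor.size < 2:
            raise InsufficientDataError(f"dose {dose:g}: need >= 2 replicates")
        _, p = welch_t_test(odor, ctrl, equal_var=equal_var)
        p_by_dose[float(dose)] = p
        direction[float(dose)] = bool(odor.mean() > ctrl.mean())
    confirmed = any(p_by_dose[d] < alpha and direction[d] for d in p_by_dose)
    return SecondaryResult(or_id=or_id, odorant_id=odorant,
                           p_by_dose=p_by_dose, direction_by_dose=direction,
                           confirmed=confirmed)


def screen_summary(results: list[SecondaryResult]) -> dict:
    """Per-odorant confirmed counts, total confirmed pairs, distinct ORs."""
    confirmed = [r for r in results if r.confirmed]
    per_odorant: dict[str, int] = {}
    for r in confirmed:
        per_odorant[r.odorant_id] = per_odorant.get(r.odorant_id, 0) + 1
    return {
        "per_odorant": per_odorant,
        "confirmed_pairs": len(confirmed),
        "unique_ors": len({r.or_id for r in confirmed}),
    }


def run_screen(
    primary_records: pd.DataFrame,
    secondary_records: pd.DataFrame,
    select_rule: str = "fold:2.0",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[SecondaryResult], dict]:
    """Full cascade: rank, select, confirm candidates only, summarize."""
    ranked = primary_rank(primary_records, select_rule)
    candidates = set(zip(ranked.loc[ranked["candidate"], "or_id"],
                         ranked.loc[ranked["candidate"], "odorant_id"]))
    results = []
    for (or_id, odorant), grp in secondary_records.groupby(["or_id", "odorant_id"], sort=True):
        if (or_id, odorant) in candidates:
            results.append(secondary_confirm(grp, alpha=alpha))
    return ranked, results, screen_summary(results)
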