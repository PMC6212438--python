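"""Trace normalization and response quantification.

Normalization follows the kinetic assay convention: each well's raw trace is
first divided by its own cycle-1 value (removing static per-well gain), then
by the per-cycle mean of the initially-normalized vector-control wells of
the same run and condition (removing shared drift and any odor-independent
luminescence change).  A scalar response per well is then either

* ``auc_raw``       — the sum of normalized values over all cycles,
* ``auc_baseline``  — the sum of (normalized value - 1); a null well scores 0,
* ``peak``          — the maximum normalized value minus 1.

``auc_baseline`` is the default because it sends the vector-control row of a
response matrix to ~0, which is how heat maps of panel activation are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Condition, LuminescenceTrace, PlateRun, check_shared_cycles
from .errors import DataError, InsufficientDataError, ParameterError, StructureError

__all__ = [
    "NormalizedTrace",
    "ResponseMatrix",
    "normalize_trace",
    "normalize_run",
    "auc",
    "peak",
    "quantify",
    "build_response_matrix",
    "auc_peak_concordance",
    "MODES",
]

MODES = ("auc_raw", "auc_baseline", "peak")


@dataclass
class NormalizedTrace:
    """A dimensionless trace; cycle 1 equals 1 exactly by construction."""

    well_id: str
    or_id: str
    condition: Condition
    replicate: int
    values: np.ndarray
    cycle_interval_s: float

    @property
    def n_cycles(self) -> int:
        return int(self.values.size)


def normalize_trace(
    trace: LuminescenceTrace,
    control_traces: Sequence[LuminescenceTrace],
) -> NormalizedTrace:
    """Initial-value then vector-control normalization of one trace."""
    if not control_traces:
        raise StructureError(f"well {trace.well_id}: no control traces supplied")
    n = check_shared_cycles([trace, *control_traces])
    if trace.values[0] <= 0:
        raise DataError(f"well {trace.well_id}: non-positive cycle-1 value")
    self_norm = trace.values / trace.values[0]
    control = np.mean([c.values / c.values[0] for c in control_traces], axis=0)
    if np.any(control <= 0):
        raise DataError("control mean is non-positive at some cycle")
    values = self_norm / control
    assert values.shape == (n,)
    return NormalizedTrace(
        well_id=trace.well_id, or_id=trace.or_id, condition=trace.condition,
        replicate=trace.replicate, values=values,
        cycle_interval_s=trace.cycle_interval_s,
    )


def normalize_run(run: PlateRun) -> list[NormalizedTrace]:
    """Normalize every trace of a run against the run's own vector-control wells.

    Controls are matched by condition; the control wells themselves are kept
    (normalized against the control set they belong to, hence ~1 throughout).
    """
    out = []
    for cond in run.conditions:
        controls = run.control_traces(cond)
        for trace in run.traces_for(cond):
            out.append(normalize_trace(trace, controls))
    return out


def auc(ntrace: NormalizedTrace, mode: str = "auc_baseline") -> float:
    """Summed normalized luminescence (the assay's scalar response).

    The sum runs over all cycles with no time weighting; in baseline mode
    each cycle contributes (value - 1) so a flat null trace scores exactly 0.
    """
    if mode == "auc_raw":
        return float(np.sum(ntrace.values))
    if mode == "auc_baseline":
        return float(np.sum(ntrace.values - 1.0))
    raise ParameterError(f"auc mode must be auc_raw or auc_baseline, got {mode!r}")


def peak(ntrace: NormalizedTrace, mode: str = "peak") -> float:
    """Maximum normalized value; reported baseline-subtracted (max - 1)."""
    if mode == "peak_raw":
        return float(np.max(ntrace.values))
    if mode == "peak":
        return float(np.max(ntrace.values) - 1.0)
    raise ParameterError(f"peak mode must be peak or peak_raw, got {mode!r}")


def quantify(ntrace: NormalizedTrace, mode: str) -> float:
    if mode in ("auc_raw", "auc_baseline"):
        return auc(ntrace, mode)
    if mode in ("peak", "peak_raw"):
        return peak(ntrace, mode)
    raise ParameterError(f"unknown quantification mode {mode!r}")


@dataclass
class ResponseMatrix:
    """Replicate-resolved OR x condition response table.

    ``tidy`` has one row per well with columns or_id, odorant_id, phase,
    concentration, condition (the serialized key), replicate, run_id, day,
    value.  ``or_ids`` preserves panel order (vector control included).
    """

    tidy: pd.DataFrame
    mode: str
    or_ids: list[str]
    control_id: str | None = None
    metadata: dict = field(default_factory=dict)

    REQUIRED = ("or_id", "odorant_id", "phase", "concentration",
                "condition", "replicate", "run_id", "day", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.tidy.columns]
        if missing:
            raise StructureError(f"tidy response table missing columns {missing}")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}")

    @property
    def condition_keys(self) -> list[str]:
        seen: dict[str, None] = {}
        for k in self.tidy["condition"]:
            seen.setdefault(k, None)
        return list(seen)

    def cell_stats(self) -> pd.DataFrame:
        """Per OR x condition: replicate mean, s.e.m. (sd/sqrt(n), n-1 sd), n."""
        g = self.tidy.groupby(["or_id", "condition"], sort=False)["value"]
        stats = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        stats["sem"] = stats["sd"] / np.sqrt(stats["n"])
        return stats.reset_index()

    def means_wide(self) -> pd.DataFrame:
        """OR x condition matrix of replicate means, panel row order preserved."""
        wide = self.tidy.pivot_table(
            index="or_id", columns="condition", values="value", aggfunc="mean",
        )
        return wide.reindex(index=self.or_ids, columns=self.condition_keys)

    def replicate_values(self, or_id: str, condition_key: str) -> np.ndarray:
        sel = self.tidy[(self.tidy["or_id"] == or_id) & (self.tidy["condition"] == condition_key)]
        return sel["value"].to_numpy()

    def restrict(self, *, phase: str | None = None, concentration: float | None = None,
                 odorants: Iterable[str] | None = None) -> "ResponseMatrix":
        t = self.tidy
        if phase is not None:
            t = t[t["phase"] == phase]
        if concentration is not None:
            t = t[np.isclose(t["concentration"].astype(float), concentration)]
        if odorants is not None:
            t = t[t["odorant_id"].isin(list(odorants))]
        return ResponseMatrix(t.reset_index(drop=True), self.mode, list(self.or_ids),
                              self.control_id, dict(self.metadata))


def build_response_matrix(
    plate_runs: Sequence[PlateRun] | PlateRun,
    mode: str = "auc_baseline",
) -> ResponseMatrix:
    """Normalize runs and assemble the central OR x condition response matrix."""
    if isinstance(plate_runs, PlateRun):
        plate_runs = [plate_runs]
    if not plate_runs:
        raise StructureError("no plate runs given")
    panel = plate_runs[0].or_ids
    control = plate_runs[0].control_id
    rows = []
    for run in plate_runs:
        if run.or_ids != panel:
            raise StructureError(f"run {run.run_id}: panel differs from first run")
        for nt in normalize_run(run):
            rows.append({
                "or_id": nt.or_id,
                "odorant_id": nt.condition.odorant_id,
                "phase": nt.condition.phase,
                "concentration": nt.condition.concentration,
                "condition": nt.condition.key,
                "replicate": nt.replicate,
                "run_id": run.run_id,
                "day": run.day,
                "value": quantify(nt, mode),
            })
    return ResponseMatrix(pd.DataFrame(rows), mode=mode, or_ids=list(panel), control_id=control)


def auc_peak_concordance(m_auc: ResponseMatrix, m_peak: ResponseMatrix) -> float:
    """Squared Pearson correlation between paired AUC and peak cell means."""
    a = m_auc.means_wide()
    b = m_peak.means_wide()
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise StructureError("matrices do not share rows/columns")
    x = a.to_numpy().ravel()
    y = b.to_numpy().ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InsufficientDataError("need at least 3 paired cells")
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    return float(r * r)
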