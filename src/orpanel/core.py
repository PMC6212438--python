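"""Core containers shared by the simulator and the analysis stages.

A *condition* is one stimulation setting: an odorant delivered either in the
liquid phase (concentration in mol/L) or in the vapor phase (a vol/vol
dilution in mineral oil, in (0, 1]).  A *trace* is the kinetic luminescence
readout of one well (one receptor, one condition, one replicate), and a
*plate run* bundles all traces recorded in one session (one "day").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import DataError, ParameterError, StructureError

PHASES = ("liquid", "vapor")


def format_concentration(value: float) -> str:
    """Serialize a concentration.

    Vapor dilutions used in practice are exact powers of ten; those are
    written as decade strings ("1e-2") so they survive round trips as exact
    dictionary keys.  Anything else uses ``repr`` which round-trips floats.
    """
    if value > 0:
        exponent = math.log10(value)
        nearest = round(exponent)
        if math.isclose(exponent, nearest, abs_tol=1e-12):
            return f"1e{nearest:d}"
    return repr(float(value))


@dataclass(frozen=True, order=True)
class Condition:
    """One stimulation condition: odorant, delivery phase and concentration."""

    odorant_id: str
    phase: str
    concentration: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ParameterError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not self.concentration > 0:
            raise ParameterError("concentration must be positive")
        if self.phase == "vapor" and self.concentration > 1:
            raise ParameterError("vapor dilution must lie in (0, 1]")

    @property
    def key(self) -> str:
        return f"{self.odorant_id}|{self.phase}|{format_concentration(self.concentration)}"


@dataclass
class LuminescenceTrace:
    """Raw kinetic readout of one well.

    ``values[i]`` is the luminescence at cycle ``i + 1`` (cycles are
    1-based); the time of cycle ``i`` is ``(i - 1) * cycle_interval_s``.
    """

    well_id: str
    or_id: str
    condition: Condition
    replicate: int
    values: np.ndarray
    cycle_interval_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise StructureError(f"well {self.well_id}: need >= 2 cycles")
        if not np.all(self.values > 0):
            raise DataError(f"well {self.well_id}: non-positive luminescence value")
        if not self.cycle_interval_s > 0:
            raise ParameterError("cycle_interval_s must be positive")

    @property
    def n_cycles(self) -> int:
        return int(self.values.size)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_interval_s


@dataclass
class PlateRun:
    """All traces measured in one kinetic session, plus provenance metadata."""

    run_id: str
    day: str
    traces: list[LuminescenceTrace]
    control_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise StructureError(f"run {self.run_id}: no traces")
        n = {t.n_cycles for t in self.traces}
        if len(n) != 1:
            raise StructureError(f"run {self.run_id}: mixed cycle counts {sorted(n)}")

    @property
    def n_cycles(self) -> int:
        return self.traces[0].n_cycles

    @property
    def conditions(self) -> list[Condition]:
        seen: dict[Condition, None] = {}
        for t in self.traces:
            seen.setdefault(t.condition, None)
        return list(seen)

    @property
    def or_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.or_id, None)
        return list(seen)

    def traces_for(self, condition: Condition, or_id: str | None = None) -> list[LuminescenceTrace]:
        out = [t for t in self.traces if t.condition == condition]
        if or_id is not None:
            out = [t for t in out if t.or_id == or_id]
        return out

    def control_traces(self, condition: Condition) -> list[LuminescenceTrace]:
        out = self.traces_for(condition, self.control_id)
        if not out:
            raise StructureError(
                f"run {self.run_id}: no vector-control ({self.control_id}) wells for {condition.key}"
            )
        return out


def check_shared_cycles(traces: Iterable[LuminescenceTrace]) -> int:
    """Return the common cycle count of *traces*, or raise StructureError."""
    counts = {t.n_cycles for t in traces}
    if len(counts) != 1:
        raise StructureError(f"traces disagree on cycle count: {sorted(counts)}")
    return counts.pop()
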