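"""Generative model for odorant-receptor panel plate runs.

The simulator emulates a live-cell cAMP reporter (GloSensor-style) assay in
which each well of a 96-well plate expresses one odorant receptor (OR) and
luminescence is read kinetically while an odorant is presented either
dissolved in the medium (liquid phase) or as an equilibrated vapor that must
partition into the medium.

The generative chain per well is:

    dilution --(linear partition)--> dissolved concentration
    concentration --(Hill occupancy)--> receptor occupancy
    occupancy x efficacy --(saturating sum over mixture)--> effective drive E
    value(t) = gain * baseline * drift^cycle
               * [1 + E * (1 - exp(-k * max(0, t - onset)))] * noise

with multiplicative log-normal noise at three scales: a static per-well gain
(a transfection-efficiency surrogate), a per-run gain (day effect) and a
per-read measurement jitter.  The per-well gain and day gain cancel exactly
under the initial-value + vector-control normalization applied downstream;
the per-read jitter is what limits replicate reproducibility.

Randomness is keyed: every well draws from a stream seeded by
``(root seed, condition index, receptor index, replicate)``, so adding wells
or conditions never perturbs the values of existing wells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Condition, LuminescenceTrace, PlateRun
from .errors import ConfigError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "PanelDesign",
    "AffinityEntry",
    "AffinityModel",
    "KineticParams",
    "NoiseParams",
    "LigandMix",
    "Ces1dModel",
    "ToxicityModel",
    "occupancy",
    "vapor_to_dissolved",
    "apply_ces1d",
    "simulate_trace",
    "simulate_plate_run",
    "simulate_screen",
    "default_panel_or_ids",
    "acetophenone_analog_affinities",
    "analog_panel_design",
    "ANALOG_ODORANTS",
    "VECTOR_CONTROL",
]

VECTOR_CONTROL = "pCI"

# 31-receptor panel (vector control pCI completes the 32-unit readout).
_PANEL_ORS = (
    "Olfr90", "Olfr109", "Olfr145", "Olfr167", "Olfr169", "Olfr211",
    "Olfr476", "Olfr491", "Olfr502", "Olfr549", "Olfr556", "Olfr876",
    "Olfr889", "Olfr978", "Olfr979", "Olfr982", "Olfr992", "Olfr1062",
    "Olfr1079", "Olfr1093", "Olfr1104", "Olfr1364", "Olfr1370", "Olfr1377",
    "Olfr1411", "Olfr1484", "Olfr1512", "Olfr2", "Olfr73", "Olfr124",
    "Olfr160",
)

# Acetophenone and six structural analogs used for the discrimination panel.
ANALOG_ODORANTS = ("AC", "MAC", "PP", "BA", "HAC", "MS", "ME")


def default_panel_or_ids() -> list[str]:
    """The default 32-unit panel: 31 ORs plus the vector control."""
    return list(_PANEL_ORS) + [VECTOR_CONTROL]


@dataclass(frozen=True)
class PanelDesign:
    """Layout of a kinetic experiment: who is transfected where, and when reads happen."""

    or_ids: tuple[str, ...]
    control_id: str
    odorant_ids: tuple[str, ...]
    conditions: tuple[Condition, ...]
    replicates: int = 3
    n_cycles: int = 20
    cycle_interval_s: float = 90.0

    def __post_init__(self) -> None:
        if self.or_ids.count(self.control_id) != 1:
            raise ConfigError(
                f"panel must contain exactly one vector-control label {self.control_id!r}"
            )
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if self.n_cycles < 2:
            raise ConfigError("n_cycles must be >= 2")
        for cond in self.conditions:
            if cond.odorant_id not in self.odorant_ids:
                raise ConfigError(f"condition odorant {cond.odorant_id!r} not in odorant_ids")

    @property
    def n_wells(self) -> int:
        return len(self.or_ids) * len(self.conditions) * self.replicates


@dataclass(frozen=True)
class AffinityEntry:
    ec50: float          # mol/L
    efficacy: float      # maximal fold-increase over baseline, >= 0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise ParameterError("ec50 must be > 0")
        if self.efficacy < 0:
            raise ParameterError("efficacy must be >= 0")
        if not self.hill > 0:
            raise ParameterError("hill must be > 0")


@dataclass
class AffinityModel:
    """Per (receptor, odorant) generative dose-response parameters.

    A missing key means the receptor does not respond to that odorant.  The
    vector control must have no entries at all.
    """

    entries: dict[tuple[str, str], AffinityEntry] = field(default_factory=dict)

    def entry(self, or_id: str, odorant_id: str) -> AffinityEntry | None:
        return self.entries.get((or_id, odorant_id))

    def effective_efficacy(self, or_id: str, mix: "LigandMix") -> float:
        """Saturating combination of drives over a ligand mixture.

        The sum of efficacy x occupancy over components is capped at the
        largest single efficacy among the components present, so mixtures
        never exceed the strongest single-ligand response.
        """
        total = 0.0
        cap = 0.0
        for odorant_id, conc in mix.components.items():
            if conc <= 0:
                continue
            e = self.entry(or_id, odorant_id)
            if e is None or e.efficacy == 0:
                continue
            total += e.efficacy * occupancy(conc, e.ec50, e.hill)
            cap = max(cap, e.efficacy)
        return min(total, cap)


@dataclass(frozen=True)
class KineticParams:
    """Shape of the odor-evoked luminescence rise.

    ``rise_rate`` is the first-order rate constant k (1/s) of the saturating
    exponential; with the default k = 1/300 s^-1 the response reaches ~95% of
    plateau by 900 s, matching a rise that is visible within the first
    reading cycle and plateaus over a 30-min run.  ``control_drift`` is a
    per-cycle multiplicative drift applied to every well (reagent decay or
    warm-up); it cancels under vector-control normalization.
    """

    baseline_lum: float = 1000.0
    rise_rate: float = 1.0 / 300.0
    onset_delay_s: float = 0.0
    control_drift: float = 1.005

    def __post_init__(self) -> None:
        if not self.baseline_lum > 0:
            raise ParameterError("baseline_lum must be > 0")
        if not self.rise_rate > 0:
            raise ParameterError("rise_rate must be > 0")
        if self.onset_delay_s < 0:
            raise ParameterError("onset_delay_s must be >= 0")
        if not 0.9 < self.control_drift < 1.1:
            raise ParameterError("control_drift must lie in (0.9, 1.1)")


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative log-normal noise scales (coefficients of variation)."""

    well_scale_cv: float = 0.10
    additive_cv: float = 0.03
    day_effect_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("well_scale_cv", "additive_cv", "day_effect_cv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseParams":
        return cls(0.0, 0.0, 0.0)


@dataclass
class LigandMix:
    """Dissolved odorant concentrations (mol/L) reaching the receptors."""

    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.components.items():
            if v < 0:
                raise ParameterError(f"negative concentration for {k!r}")

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))


@dataclass(frozen=True)
class Ces1dModel:
    """Carboxyl-esterase conversion: each substrate ester maps to one product."""

    conversions: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        substrates = [s for s, _, _ in self.conversions]
        if len(substrates) != len(set(substrates)):
            raise ParameterError("each substrate may have only one product")
        for s, p, f in self.conversions:
            if not 0 <= f <= 1:
                raise ParameterError(f"conversion fraction for {s}->{p} must be in [0,1]")


@dataclass(frozen=True)
class ToxicityModel:
    """Scalar response attenuation at near-undiluted vapor exposure.

    Above ``threshold`` (vol/vol) the effective drive is multiplied by the
    odorant's viability floor; at or below threshold there is no attenuation.
    Defaults model a harsh (eugenol-like, floor 0.25) versus mild
    (methyl-benzoate-like, floor 0.8) contrast via ``floors``.
    """

    threshold: float = 0.1
    floors: dict[str, float] = field(default_factory=dict)
    default_floor: float = 1.0

    def __post_init__(self) -> None:
        for odorant, f in list(self.floors.items()) + [("default", self.default_floor)]:
            if not 0 <= f <= 1:
                raise ParameterError(f"viability floor for {odorant!r} must be in [0,1]")

    def scale(self, condition: Condition) -> float:
        if condition.phase == "vapor" and condition.concentration > self.threshold:
            return self.floors.get(condition.odorant_id, self.default_floor)
        return 1.0


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def occupancy(concentration: float, ec50: float, hill: float) -> float:
    """Hill occupancy c^n / (c^n + EC50^n), computed overflow-safely."""
    if not ec50 > 0:
        raise ParameterError("ec50 must be > 0")
    if not hill > 0:
        raise ParameterError("hill must be > 0")
    if concentration < 0:
        raise ParameterError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    # 1 / (1 + (EC50/c)^n) avoids overflow for extreme ratios
    log_ratio = hill * (math.log(ec50) - math.log(concentration))
    if log_ratio > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(log_ratio))


def vapor_to_dissolved(dilution: float, partition_coeff: float) -> float:
    """Map a vapor vol/vol dilution to a dissolved concentration (mol/L).

    A deliberately simple linear transfer: dissolved = coeff * dilution.
    """
    if not 0 < dilution <= 1:
        raise ParameterError("vapor dilution must lie in (0, 1]")
    return partition_coeff * dilution


def apply_ces1d(mix: LigandMix, model: Ces1dModel) -> LigandMix:
    """Apply esterase substrate->product conversion; conserves total molarity."""
    out = dict(mix.components)
    for substrate, product, fraction in model.conversions:
        if substrate not in out:
            logger.warning("Ces1d substrate %r not present in mix; skipped", substrate)
            continue
        moved = out[substrate] * fraction
        out[substrate] -= moved
        out[product] = out.get(product, 0.0) + moved
    return LigandMix(out)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_trace(
    or_id: str,
    mix: LigandMix,
    affinity: AffinityModel,
    kinetics: KineticParams,
    toxicity_scale: float,
    rng: np.random.Generator,
    *,
    n_cycles: int,
    cycle_interval_s: float,
    additive_cv: float = 0.0,
    gain: float = 1.0,
) -> np.ndarray:
    """Simulate one well's raw luminescence values over ``n_cycles`` reads."""
    t = np.arange(n_cycles) * cycle_interval_s
    e_eff = toxicity_scale * affinity.effective_efficacy(or_id, mix)
    shape = 1.0 + e_eff * (1.0 - np.exp(-kinetics.rise_rate * np.maximum(0.0, t - kinetics.onset_delay_s)))
    drift = kinetics.control_drift ** np.arange(n_cycles)
    noise = _lognormal_factor(rng, additive_cv, size=n_cycles)
    return gain * kinetics.baseline_lum * drift * shape * noise


def _well_rng(seed: int, condition_index: int, or_index: int, replicate: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=(seed, condition_index, or_index, replicate)))
    )


def simulate_plate_run(
    design: PanelDesign,
    affinity: AffinityModel,
    kinetics: KineticParams = KineticParams(),
    noise: NoiseParams = NoiseParams(),
    ces1d: Ces1dModel | None = None,
    toxicity: ToxicityModel | None = None,
    *,
    seed: int,
    run_id: str = "run",
    day: str = "D1",
    partition_coeff: float | dict[str, float] = 1e-2,
) -> PlateRun:
    """Simulate a full kinetic session: one trace per OR x condition x replicate.

    Pure function of its inputs: the same arguments always yield a
    bit-identical :class:`PlateRun`.
    """
    for (or_id, _), e in affinity.entries.items():
        if or_id == design.control_id and e.efficacy > 0:
            raise ConfigError("vector control must have zero efficacy for all odorants")

    day_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=(seed, 0xDA1))))
    day_gain = float(_lognormal_factor(day_rng, noise.day_effect_cv))

    toxicity = toxicity or ToxicityModel()
    traces: list[LuminescenceTrace] = []
    for ci, cond in enumerate(design.conditions):
        if cond.phase == "vapor":
            coeff = partition_coeff if isinstance(partition_coeff, float) else partition_coeff.get(cond.odorant_id, 1e-2)
            dissolved = vapor_to_dissolved(cond.concentration, coeff)
        else:
            dissolved = cond.concentration
        mix = LigandMix({cond.odorant_id: dissolved})
        if ces1d is not None:
            mix = apply_ces1d(mix, ces1d)
        tox = toxicity.scale(cond)
        for oi, or_id in enumerate(design.or_ids):
            for rep in range(1, design.replicates + 1):
                rng = _well_rng(seed, ci, oi, rep)
                well_gain = day_gain * float(_lognormal_factor(rng, noise.well_scale_cv))
                values = simulate_trace(
                    or_id, mix, affinity, kinetics, tox, rng,
                    n_cycles=design.n_cycles,
                    cycle_interval_s=design.cycle_interval_s,
                    additive_cv=noise.additive_cv,
                    gain=well_gain,
                )
                linear = ci * len(design.or_ids) * design.replicates \
                    + oi * design.replicates + (rep - 1)
                row, col = divmod(linear % 96, 12)
                well = f"P{ci + 1:02d}-{chr(ord('A') + row)}{col + 1:02d}"
                traces.append(LuminescenceTrace(
                    well_id=well, or_id=or_id, condition=cond,
                    replicate=rep, values=values,
                    cycle_interval_s=design.cycle_interval_s,
                ))
    return PlateRun(
        run_id=run_id, day=day, traces=traces, control_id=design.control_id,
        metadata={
            "seed": seed,
            "kinetics": kinetics,
            "noise": noise,
            "toxicity": toxicity,
            "ces1d": ces1d,
            "partition_coeff": partition_coeff,
        },
    )


# ---------------------------------------------------------------------------
# Default study presets
# ---------------------------------------------------------------------------

def acetophenone_analog_affinities(seed: int = 1207) -> AffinityModel:
    """Default affinity table: 31 ORs x 7 structural analogs.

    Efficacy vectors are built as a weighted blend of a shared receptor
    tuning profile and an analog-specific profile.  The shared component
    models structural similarity between analogs, so that panel response
    profiles of two different analogs correlate at squared-Pearson values
    spanning roughly 0.1-0.85, while repeated runs of the same analog
    correlate above 0.9 at default noise.  EC50s are log-uniform over
    3e-6 to 3e-4 mol/L, bracketing the ~1e-4 mol/L dissolved concentration
    produced by a 1e-2 vapor dilution at the default partition coefficient.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n_or = len(_PANEL_ORS)
    shared = np.abs(rng.normal(size=n_or))
    # per-analog blend weight: high = structurally close to the panel centroid
    weights = rng.uniform(0.35, 0.95, size=len(ANALOG_ODORANTS))
    # potency and cooperativity are mostly receptor-intrinsic, with a small
    # per-analog perturbation (half a log unit of EC50 jitter)
    or_log_ec50 = rng.uniform(math.log10(3e-6), math.log10(3e-4), size=n_or)
    or_hill = rng.uniform(0.8, 1.5, size=n_or)
    entries: dict[tuple[str, str], AffinityEntry] = {}
    for ai, odorant in enumerate(ANALOG_ODORANTS):
        specific = np.abs(rng.normal(size=n_or))
        profile = weights[ai] * shared + (1 - weights[ai]) * specific
        efficacy = 8.0 * profile / profile.max()
        efficacy[efficacy < 1.0] = 0.0  # sparse code: weak drives are non-responders
        log_ec50 = or_log_ec50 + rng.uniform(-0.25, 0.25, size=n_or)
        for oi, or_id in enumerate(_PANEL_ORS):
            if efficacy[oi] > 0:
                entries[(or_id, odorant)] = AffinityEntry(
                    ec50=10.0 ** log_ec50[oi], efficacy=float(efficacy[oi]),
                    hill=float(or_hill[oi]),
                )
    return AffinityModel(entries)


def analog_panel_design(
    odorants: tuple[str, ...] = ANALOG_ODORANTS,
    dilutions: tuple[float, ...] = (1e-2,),
    *,
    replicates: int = 3,
    n_cycles: int = 20,
    cycle_interval_s: float = 90.0,
) -> PanelDesign:
    """Vapor-phase design over the default 32-unit panel."""
    conditions = tuple(
        Condition(od, "vapor", d) for od in odorants for d in dilutions
    )
    return PanelDesign(
        or_ids=tuple(default_panel_or_ids()),
        control_id=VECTOR_CONTROL,
        odorant_ids=tuple(odorants),
        conditions=conditions,
        replicates=replicates,
        n_cycles=n_cycles,
        cycle_interval_s=cycle_interval_s,
    )


# ---------------------------------------------------------------------------
# Dual-luciferase screen generator
# ---------------------------------------------------------------------------

def simulate_screen(
    or_ids: list[str],
    odorant_ids: list[str],
    responders: dict[tuple[str, str], float],
    *,
    seed: int,
    replicates: int = 3,
    concentrations: tuple[float, ...] = (1e-6, 1e-5, 1e-4),
    noise_cv: float = 0.1,
    baseline_activity: float = 1.0,
):
    """Simulate dual-reporter (firefly/Renilla) screen measurements.

    ``responders`` maps (or_id, odorant_id) to the fold-increase of
    firefly/Renilla activity at the top concentration; lower doses scale by
    concentration / max(concentration).  Returns a pandas DataFrame in the
    screen CSV dialect (or_id, odorant_id, concentration_molar, replicate,
    firefly, renilla); control wells carry an empty concentration.
    """
    import pandas as pd

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=(seed, 0x5C12EE))))
    top = max(concentrations)
    rows = []
    for or_id in or_ids:
        for odorant in odorant_ids:
            fold = responders.get((or_id, odorant), 0.0)
            for conc in (None,) + tuple(concentrations):
                for rep in range(1, replicates + 1):
                    renilla = 100.0 * _lognormal_factor(rng, noise_cv)
                    drive = 0.0 if conc is None else fold * conc / top
                    activity = baseline_activity * (1.0 + drive) * _lognormal_factor(rng, noise_cv)
                    rows.append({
                        "or_id": or_id,
                        "odorant_id": odorant,
                        "concentration_molar": np.nan if conc is None else conc,
                        "replicate": rep,
                        "firefly": activity * renilla,
                        "renilla": renilla,
                    })
    return pd.DataFrame(rows)
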