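"""File formats, clustering and heat-map reporting, configuration, pipeline.

The plate CSV dialect has one row per well per cycle with columns
``run_id, day, well_id, or_id, odorant_id, phase, concentration, replicate,
cycle, time_s, luminescence``.  Floats are written with ``repr`` (shortest
round-tripping form) and vapor decade dilutions as exact strings like
``1e-2``, so write(read(x)) is byte-identical on canonical files.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import logging
from configparser import ConfigParser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import discrim, stats, synth, traceproc
from .core import Condition, LuminescenceTrace, PlateRun, format_concentration
from .errors import ConfigError, DataError, StructureError
from .traceproc import ResponseMatrix

logger = logging.getLogger(__name__)

PLATE_COLUMNS = [
    "run_id", "day", "well_id", "or_id", "odorant_id", "phase",
    "concentration", "replicate", "cycle", "time_s", "luminescence",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def write_plate_csv(run: PlateRun, path) -> None:
    """Serialize a run, wells in run order, cycles ascending within a well."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for t in run.traces:
            conc = format_concentration(t.condition.concentration)
            for i, v in enumerate(t.values):
                writer.writerow([
                    run.run_id, run.day, t.well_id, t.or_id,
                    t.condition.odorant_id, t.condition.phase, conc,
                    t.replicate, i + 1, _fmt(i * t.cycle_interval_s), _fmt(v),
                ])


def read_plate_csv(path, control_id: str = synth.VECTOR_CONTROL) -> PlateRun:
    """Parse and validate the plate dialect back into a PlateRun."""
    df = pd.read_csv(path, dtype={"concentration": str}, float_precision="round_trip")
    if df.empty:
        raise StructureError(f"{path}: empty plate file")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: missing columns {missing}")
    if (df["luminescence"] <= 0).any():
        row = df.index[df["luminescence"] <= 0][0] + 2
        raise DataError(f"{path}: non-positive luminescence at row {row}")
    run_ids = df["run_id"].unique()
    if len(run_ids) != 1:
        raise StructureError(f"{path}: expected one run_id, found {list(run_ids)}")
    n_cycles = int(df["cycle"].max())
    traces: list[LuminescenceTrace] = []
    for well_id, grp in df.groupby("well_id", sort=False):
        cycles = grp["cycle"].to_numpy()
        if len(cycles) != len(set(cycles)):
            dup = int(pd.Series(cycles).loc[pd.Series(cycles).duplicated()].iloc[0])
            raise StructureError(f"{path}: duplicate cycle {dup} for well {well_id}")
        expected = set(range(1, n_cycles + 1))
        got = set(int(c) for c in cycles)
        if got != expected:
            missing_c = sorted(expected - got)
            raise StructureError(
                f"{path}: well {well_id} missing cycle(s) {missing_c}")
        grp = grp.sort_values("cycle")
        interval = float(grp["time_s"].iloc[1] - grp["time_s"].iloc[0]) if n_cycles > 1 else 90.0
        first = grp.iloc[0]
        traces.append(LuminescenceTrace(
            well_id=str(well_id), or_id=str(first["or_id"]),
            condition=Condition(str(first["odorant_id"]), str(first["phase"]),
                                float(first["concentration"])),
            replicate=int(first["replicate"]),
            values=grp["luminescence"].to_numpy(dtype=float),
            cycle_interval_s=interval,
        ))
    first = df.iloc[0]
    return PlateRun(run_id=str(first["run_id"]), day=str(first["day"]),
                    traces=traces, control_id=control_id)


def write_response_matrix_csv(matrix: ResponseMatrix, tidy_path, wide_path=None) -> None:
    matrix.tidy.to_csv(tidy_path, index=False)
    if wide_path is not None:
        matrix.means_wide().to_csv(wide_path)


def read_response_matrix_csv(tidy_path, mode: str, control_id: str | None = None) -> ResponseMatrix:
    tidy = pd.read_csv(tidy_path)
    or_ids = list(dict.fromkeys(tidy["or_id"]))
    return ResponseMatrix(tidy, mode=mode, or_ids=or_ids, control_id=control_id)


# ---------------------------------------------------------------------------
# Clustering and heat map
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    row_order: list[str]
    linkage: np.ndarray
    method: str = "average"
    metric: str = "euclidean"


def hierarchical_cluster(matrix: ResponseMatrix) -> ClusterResult:
    """Average-linkage agglomeration of receptor response profiles.

    Rows are pre-sorted lexicographically by receptor label before linkage
    so that equal-distance merges resolve the same way on every run; for a
    constant matrix the resulting order is simply alphabetical.
    """
    wide = matrix.means_wide().fillna(0.0)
    if wide.shape[0] < 2:
        raise StructureError("need >= 2 rows to cluster")
    wide = wide.loc[sorted(wide.index)]
    z = hierarchy.linkage(pdist(wide.to_numpy(), metric="euclidean"), method="average")
    order = [wide.index[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(row_order=list(order), linkage=z)


def heatmap_export(matrix: ResponseMatrix, row_order: list[str] | None, path) -> dict:
    """Write a color-coded response image plus the ordered CSV next to it.

    Returns metadata including the color-scale bounds actually used; an
    all-constant matrix falls back to a [0, 1] scale.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = matrix.means_wide()
    if row_order is not None:
        wide = wide.loc[row_order]
    data = wide.to_numpy(dtype=float)
    vmin, vmax = float(np.nanmin(data)), float(np.nanmax(data))
    if vmin == vmax:
        vmin, vmax = 0.0, 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * wide.shape[1] + 2),
                                    max(4, 0.22 * wide.shape[0] + 1)))
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=vmin, vmax=vmax)
    ax.set_yticks(range(wide.shape[0]), labels=wide.index, fontsize=6)
    ax.set_xticks(range(wide.shape[1]), labels=wide.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label=matrix.mode)
    fig.tight_layout()
    path = Path(path)
    try:
        fig.savefig(path, dpi=150)
    except OSError as exc:
        raise OSError(f"failed writing heat map to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    sidecar = path.with_suffix(".csv")
    wide.to_csv(sidecar)
    return {"path": str(path), "sidecar": str(sidecar),
            "vmin": vmin, "vmax": vmax, "shape": list(wide.shape)}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Round-trippable pipeline configuration (INI-style key/value sections)."""

    odorants: tuple[str, ...] = synth.ANALOG_ODORANTS
    dilutions: tuple[float, ...] = (1e-2,)
    replicates: int = 3
    n_cycles: int = 20
    cycle_interval_s: float = 90.0
    affinity_seed: int = 1207
    noise: synth.NoiseParams = field(default_factory=synth.NoiseParams)
    kinetics: synth.KineticParams = field(default_factory=synth.KineticParams)
    auc_mode: str = "auc_baseline"
    alpha: float = 0.05
    classifier: str = "random_forest"
    seed: int = 1

    def to_ini(self) -> str:
        cp = ConfigParser()
        cp["panel"] = {
            "odorants": ",".join(self.odorants),
            "dilutions": ",".join(format_concentration(d) for d in self.dilutions),
            "replicates": str(self.replicates),
            "n_cycles": str(self.n_cycles),
            "cycle_interval_s": repr(self.cycle_interval_s),
        }
        cp["generator"] = {
            "affinity_seed": str(self.affinity_seed),
            "well_scale_cv": repr(self.noise.well_scale_cv),
            "additive_cv": repr(self.noise.additive_cv),
            "day_effect_cv": repr(self.noise.day_effect_cv),
            "baseline_lum": repr(self.kinetics.baseline_lum),
            "rise_rate": repr(self.kinetics.rise_rate),
            "onset_delay_s": repr(self.kinetics.onset_delay_s),
            "control_drift": repr(self.kinetics.control_drift),
        }
        cp["analysis"] = {
            "auc_mode": self.auc_mode,
            "alpha": repr(self.alpha),
            "classifier": self.classifier,
            "seed": str(self.seed),
        }
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "RunConfig":
        cp = ConfigParser()
        cp.read_string(text)
        panel, gen, ana = cp["panel"], cp["generator"], cp["analysis"]
        return cls(
            odorants=tuple(panel["odorants"].split(",")),
            dilutions=tuple(float(x) for x in panel["dilutions"].split(",")),
            replicates=panel.getint("replicates"),
            n_cycles=panel.getint("n_cycles"),
            cycle_interval_s=panel.getfloat("cycle_interval_s"),
            affinity_seed=gen.getint("affinity_seed"),
            noise=synth.NoiseParams(gen.getfloat("well_scale_cv"),
                                    gen.getfloat("additive_cv"),
                                    gen.getfloat("day_effect_cv")),
            kinetics=synth.KineticParams(gen.getfloat("baseline_lum"),
                                         gen.getfloat("rise_rate"),
                                         gen.getfloat("onset_delay_s"),
                                         gen.getfloat("control_drift")),
            auc_mode=ana["auc_mode"],
            alpha=ana.getfloat("alpha"),
            classifier=ana["classifier"],
            seed=ana.getint("seed"),
        )

    def hash(self) -> str:
        return hashlib.sha256(self.to_ini().encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(self.to_ini())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_ini(Path(path).read_text())


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def simulate_from_config(config: RunConfig, *, seed: int, day: str, run_id: str) -> PlateRun:
    design = synth.analog_panel_design(
        odorants=config.odorants, dilutions=config.dilutions,
        replicates=config.replicates, n_cycles=config.n_cycles,
        cycle_interval_s=config.cycle_interval_s,
    )
    affinity = synth.acetophenone_analog_affinities(config.affinity_seed)
    return synth.simulate_plate_run(
        design, affinity, config.kinetics, config.noise,
        seed=seed, run_id=run_id, day=day,
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate two sessions, quantify, analyze, discriminate, and report.

    Every artifact is stamped with the config hash; any stage failure aborts
    with the stage name in the raised error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = config.hash()
    manifest: dict = {"config_hash": stamp, "seed": config.seed, "stages": {}}
    if config.replicates < 2:
        raise ConfigError("pipeline stage 'simulate': replicates must be >= 2 for statistics")

    stage = "simulate"
    try:
        run1 = simulate_from_config(config, seed=config.seed, day="D1", run_id="run1")
        run2 = simulate_from_config(config, seed=config.seed + 1, day="D2", run_id="run2")
        write_plate_csv(run1, outdir / "plate_day1.csv")
        write_plate_csv(run2, outdir / "plate_day2.csv")
        config.save(outdir / "config.ini")
        manifest["stages"][stage] = {"runs": ["plate_day1.csv", "plate_day2.csv"]}

        stage = "quantify"
        m1 = traceproc.build_response_matrix(run1, mode=config.auc_mode)
        m2 = traceproc.build_response_matrix(run2, mode=config.auc_mode)
        write_response_matrix_csv(m1, outdir / "responses_day1.csv",
                                  outdir / "responses_day1_wide.csv")
        write_response_matrix_csv(m2, outdir / "responses_day2.csv",
                                  outdir / "responses_day2_wide.csv")
        manifest["stages"][stage] = {"mode": config.auc_mode}

        stage = "stats"
        counts = stats.differential_activation_counts(m1, alpha=config.alpha)
        counts.to_csv(outdir / "differential_counts.csv")
        same_day_r2 = {}
        w1, w2 = m1.means_wide(), m2.means_wide()
        for key in w1.columns:
            reg = stats.regression_r2(w1[key].to_numpy(), w2[key].to_numpy())
            same_day_r2[key] = reg.r_squared
        (outdir / "cross_day_r2.json").write_text(json.dumps(same_day_r2, indent=2))
        manifest["stages"][stage] = {"cross_day_r2": same_day_r2}

        stage = "discriminate"
        report = discrim.cross_day_report(m1, m2, method=config.classifier, seed=config.seed)
        report.confusion.to_csv(outdir / "confusion.csv")
        report.predictions.to_csv(outdir / "predictions.csv", index=False)
        manifest["stages"][stage] = {"method": report.method,
                                     "accuracy_pct": report.accuracy_pct}

        stage = "report"
        cluster = hierarchical_cluster(m1)
        heat = heatmap_export(m1, cluster.row_order, outdir / "heatmap.png")
        manifest["stages"][stage] = {"row_order": cluster.row_order, "heatmap": heat}
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete (config %s): accuracy %.1f%%",
                stamp, manifest["stages"]["discriminate"]["accuracy_pct"])
    return manifest
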