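"""End-to-end orchestration: simulate/read -> preprocess -> measures ->
cluster -> fit -> timecourse -> report.

One :class:`PipelineConfig` (usually loaded from YAML) drives a full run.
Outputs are plain CSV tables plus a machine-readable ``manifest.json``
(package/library versions, seed, config hash, and per-stage trial counts)
sufficient to re-run the analysis bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_K,
    DEFAULT_X_THRESHOLD,
    cluster_trajectories,
    label_partial_error_clusters,
    pe_rates,
)
from .conditions import COMPONENT_NAMES
from .errors import ConfigError, DataError
from .inference import components_frame, estimate_components
from .io import read_trials, write_trials
from .layout import ScreenLayout, default_layout
from .measures import measures_table, profiles_table
from .preprocess import filter_trials, remap_and_align, space_normalize, time_normalize
from .simulate import SimulationConfig, simulate_dataset
from .timecourse import fit_timecourse
from .trial import RawTrial

log = logging.getLogger("stroop_trace")

_FLOAT_FMT = "%.10g"
GLOBAL_MEASURES = ("it", "rt", "md", "pe")
TIMECOURSE_MEASURES = ("deviation", "x_coordinate")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    layout: ScreenLayout = field(default_factory=default_layout)
    simulation: SimulationConfig | None = None
    metadata_path: str | None = None
    samples_path: str | None = None
    k: int = DEFAULT_K
    x_threshold: float = DEFAULT_X_THRESHOLD
    linkage: str = "ward"
    ci_global: float = 0.99
    ci_step: float = 0.95
    min_run: int = 10
    movement_threshold_px: float = 0.0
    timecourse_components: tuple[str, ...] = COMPONENT_NAMES
    timecourse_measures: tuple[str, ...] = TIMECOURSE_MEASURES
    timecourse_slope: str = "auto"
    run_timecourse: bool = True

    def validate(self) -> "PipelineConfig":
        for name in ("ci_global", "ci_step"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}: must be in (0, 1)")
        if self.min_run < 1:
            raise ConfigError("min_run: must be >= 1")
        if self.simulation is None and not (self.metadata_path and self.samples_path):
            raise ConfigError(
                "metadata_path/samples_path: required when no simulation block is given"
            )
        unknown = set(self.timecourse_components) - set(COMPONENT_NAMES)
        if unknown:
            raise ConfigError(f"timecourse_components: unknown {sorted(unknown)}")
        unknown = set(self.timecourse_measures) - set(TIMECOURSE_MEASURES)
        if unknown:
            raise ConfigError(f"timecourse_measures: unknown {sorted(unknown)}")
        if self.simulation is not None:
            self.simulation.validate()
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        if "layout" in d:
            kwargs["layout"] = ScreenLayout.from_dict(d.pop("layout"))
        if "simulation" in d:
            sim = dict(d.pop("simulation"))
            sim.setdefault("seed", kwargs.get("seed", 0))
            kwargs["simulation"] = SimulationConfig.from_dict(sim)
        data = d.pop("data", None)
        if data:
            kwargs["metadata_path"] = data.get("metadata")
            kwargs["samples_path"] = data.get("samples")
        clustering = d.pop("clustering", {})
        for src, dst in (("k", "k"), ("x_threshold", "x_threshold"), ("linkage", "linkage")):
            if src in clustering:
                kwargs[dst] = clustering[src]
        inference = d.pop("inference", {})
        for src in ("ci_global", "ci_step", "min_run", "movement_threshold_px"):
            if src in inference:
                kwargs[src] = inference[src]
        tc = d.pop("timecourse", {})
        if "components" in tc:
            kwargs["timecourse_components"] = tuple(tc["components"])
        if "measures" in tc:
            kwargs["timecourse_measures"] = tuple(tc["measures"])
        if "slope" in tc:
            kwargs["timecourse_slope"] = tc["slope"]
        if "enabled" in tc:
            kwargs["run_timecourse"] = bool(tc["enabled"])
        if d:
            raise ConfigError(f"unknown pipeline config sections: {sorted(d)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "layout": self.layout.to_dict(),
            "simulation": None
            if self.simulation is None
            else {k: v for k, v in self.simulation.__dict__.items()},
            "metadata_path": self.metadata_path,
            "samples_path": self.samples_path,
            "k": self.k,
            "x_threshold": self.x_threshold,
            "linkage": self.linkage,
            "ci_global": self.ci_global,
            "ci_step": self.ci_step,
            "min_run": self.min_run,
            "movement_threshold_px": self.movement_threshold_px,
            "timecourse_components": list(self.timecourse_components),
            "timecourse_measures": list(self.timecourse_measures),
            "timecourse_slope": self.timecourse_slope,
            "run_timecourse": self.run_timecourse,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def load_trials(config: PipelineConfig) -> list[RawTrial]:
    """Simulate trials, or read them from the configured CSV pair."""
    if config.simulation is not None:
        sim = config.simulation.with_seed(config.seed)
        return simulate_dataset(sim, config.layout)
    return read_trials(config.metadata_path, config.samples_path)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing the report tables into ``out_dir``.

    Returns a summary dict (also written as ``manifest.json``). Any stage
    failure aborts with the stage named; earlier outputs are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "stroop-trace",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage = "load"
    try:
        trials = load_trials(config)
        manifest["stages"]["load"] = {"n_trials": len(trials)}
        log.info("loaded %d trials", len(trials))

        stage = "filter"
        kept, report = filter_trials(trials)
        _write(report.to_frame(), out / "exclusions.csv")
        if report.per_participant is not None:
            _write(report.per_participant, out / "exclusions_per_participant.csv")
        manifest["stages"]["filter"] = {
            "n_kept": report.n_kept,
            "n_omission": report.n_omission,
            "n_error": report.n_error,
            "n_rt_outlier": report.n_rt_outlier,
        }
        log.info("kept %d/%d trials", report.n_kept, report.n_total)

        stage = "measures"
        meas = measures_table(kept, config.layout, config.movement_threshold_px)
        _write(meas, out / "measures.csv")
        prof = profiles_table(kept, config.layout)
        _write(prof, out / "profiles.csv")
        manifest["stages"]["measures"] = {"n_trials": len(meas)}

        stage = "cluster"
        snorm = {
            t.key: space_normalize(remap_and_align(t, config.layout)) for t in kept
        }
        model = cluster_trajectories(snorm, k=config.k, linkage_method=config.linkage)
        label_partial_error_clusters(model, config.x_threshold)
        _write(model.assignment_frame(), out / "cluster_assignments.csv")
        _write(model.mean_paths_frame(), out / "cluster_means.csv")
        rates = pe_rates(model, kept)
        _write(rates, out / "pe_rates.csv")
        manifest["stages"]["cluster"] = {
            "k": config.k,
            "partial_error_clusters": sorted(model.partial_error_cluster_ids),
        }

        stage = "fit"
        fit_summaries = {}
        for measure in GLOBAL_MEASURES:
            data = rates if measure == "pe" else meas
            analysis = estimate_components(data, measure, ci_level=config.ci_global)
            mm = analysis.marginal.table.copy()
            mm.insert(0, "measure", measure)
            _write(mm, out / f"marginal_means_{measure}.csv")
            comp = components_frame(analysis.components)
            comp.insert(0, "measure", measure)
            _write(comp, out / f"components_{measure}.csv")
            fit_summaries[measure] = {
                "random_structure": analysis.model.structure.describe(),
                "converged": analysis.model.converged,
                "singular": analysis.model.singular,
            }
        manifest["stages"]["fit"] = fit_summaries

        if config.run_timecourse:
            stage = "timecourse"
            tc_rows, int_rows = [], []
            for measure in config.timecourse_measures:
                for component in config.timecourse_components:
                    res = fit_timecourse(
                        prof,
                        measure,
                        component,
                        ci_level=config.ci_step,
                        min_run=config.min_run,
                        slope=config.timecourse_slope,
                    )
                    t = res.table.copy()
                    t.insert(0, "component", component)
                    t.insert(0, "measure", measure)
                    tc_rows.append(t)
                    for a, b in res.intervals:
                        int_rows.append(
                            {
                                "measure": measure,
                                "component": component,
                                "start_step": a,
                                "end_step": b,
                            }
                        )
            _write(pd.concat(tc_rows, ignore_index=True), out / "timecourse.csv")
            _write(
                pd.DataFrame(
                    int_rows, columns=["measure", "component", "start_step", "end_step"]
                ),
                out / "timecourse_intervals.csv",
            )
            manifest["stages"]["timecourse"] = {"n_intervals": len(int_rows)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def simulate_to_csv(config: PipelineConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate a synthetic dataset and write the two-file CSV format."""
    if config.simulation is None:
        raise ConfigError("simulation: config block required to simulate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = simulate_dataset(config.simulation.with_seed(config.seed), config.layout)
    meta, samples = out / "metadata.csv", out / "samples.csv"
    write_trials(trials, meta, samples)
    return meta, samples


def normalized_tables(
    trials: list[RawTrial], layout: ScreenLayout
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format time- and space-normalized trajectory tables."""
    t_rows, s_rows = [], []
    for t in trials:
        aligned = remap_and_align(t, layout)
        tn = time_normalize(aligned)
        sn = space_normalize(aligned)
        t_rows.append(
            pd.DataFrame(
                {
                    "participant_id": t.participant_id,
                    "trial_index": t.trial_index,
                    "step": np.arange(1, len(tn) + 1),
                    "x": tn.x,
                    "y": tn.y,
                }
            )
        )
        s_rows.append(
            pd.DataFrame(
                {
                    "participant_id": t.participant_id,
                    "trial_index": t.trial_index,
                    "point": np.arange(1, len(sn) + 1),
                    "x": sn.x,
                    "y": sn.y,
                }
            )
        )
    if not t_rows:
        raise DataError("no correct trials to normalize")
    return pd.concat(t_rows, ignore_index=True), pd.concat(s_rows, ignore_index=True)
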