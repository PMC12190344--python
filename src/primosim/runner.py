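"""Reproducible scenario execution for both simulators.

A run is fully specified by a :class:`RunConfig`; the same config and seed
produce bit-identical CSV outputs.  Every emitted file is referenced from
the run's ``summary.json``, and the resolved configuration is echoed
verbatim into ``metadata.json`` so a run can be reconstructed from its
output directory alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import ABMParams, AgentBreed, init_abm, step_abm
from .cpm import (
    SCENARIOS,
    SceneSpec,
    apply_scenario,
    build_primordium_scene,
    monte_carlo_step,
)
from .metrics import RosetteReport, abm_cluster_count, detect_rosettes_cpm
from . import render

log = logging.getLogger("primosim")

#: Agent-model scenario presets: parameter overrides on ABMParams defaults.
ABM_SCENARIOS: dict[str, dict] = {
    "abm_no_migration": {"speed_wnt": 0.0, "speed_fgf": 0.0},
    "abm_fast_leader": {"speed_wnt": 0.018, "speed_fgf": 0.016},
    "abm_slow_leader": {"speed_wnt": 0.016, "speed_fgf": 0.018},
    "abm_shrinking_wnt": {
        "speed_wnt": 0.018,
        "speed_fgf": 0.016,
        "shrinkage_enabled": True,
    },
}

#: Threshold of the "settled" criterion: rosette count unchanged this long.
SETTLE_WINDOW = 200


@dataclass
class RunConfig:
    model: str = "abm"  # "abm" | "cpm"
    scenario: str = "abm_fast_leader"
    seed: int = 1
    n_steps: int = 2000
    out_dir: str = "runs/out"
    snapshot_interval: int = 100
    report_interval: int = 20
    abm: dict = field(default_factory=dict)  # ABMParams field overrides
    cpm: dict = field(default_factory=dict)  # SceneSpec overrides (+ "scene" preset)
    metrics: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.model not in ("abm", "cpm"):
            raise ValueError(f"unknown model {self.model!r}; choose 'abm' or 'cpm'")
        valid = ABM_SCENARIOS if self.model == "abm" else SCENARIOS
        if self.scenario not in valid:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: {sorted(valid)}"
            )
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_abm_params(config: RunConfig) -> ABMParams:
    overrides = dict(ABM_SCENARIOS[config.scenario])
    overrides.update(config.abm)
    return ABMParams().with_overrides(**overrides)


def make_scene_spec(config: RunConfig) -> SceneSpec:
    from .cpm import EngineParams

    overrides = dict(config.cpm)
    preset = overrides.pop("scene", "desk")
    if isinstance(overrides.get("engine"), dict):
        overrides["engine"] = EngineParams(**overrides["engine"])
    if preset == "desk":
        return SceneSpec.desk(**overrides)
    if preset == "full":
        return SceneSpec(**overrides)
    raise ValueError(f"unknown scene preset {preset!r}")


def settling_time(series: list[RosetteReport], window: int = SETTLE_WINDOW):
    """Time at which the rosette count last changed, if the count then stayed
    constant for at least ``window`` time units; None if never settled."""
    if not series:
        return None
    last_change = series[0].time
    for prev, cur in zip(series, series[1:]):
        if cur.n_rosettes != prev.n_rosettes:
            last_change = cur.time
    if series[-1].time - last_change >= window:
        return last_change
    return None


def _write_rosette_series(series: list[RosetteReport], path: Path) -> None:
    rows = [
        {
            "time": r.time,
            "n_rosettes": r.n_rosettes,
            "sizes": ";".join(map(str, r.sizes)),
            "centroids_x": ";".join(f"{c[0]:.3f}" for c in r.centroids),
            "primordium_length": round(r.primordium_length, 6),
            "leading_edge_x": round(r.leading_edge_x, 6),
            "trailing_edge_x": round(r.trailing_edge_x, 6),
        }
        for r in series
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def run(config: RunConfig) -> dict:
    """Execute one scenario; returns the summary dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    files: list[str] = []

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t_wall = time.time()
    try:
        log.info("run start: %s", config.to_dict())
        (out / "metadata.json").write_text(json.dumps(config.to_dict(), indent=2))
        files.append("metadata.json")
        if config.model == "abm":
            series, ts = _run_abm(config, rng, out, files)
        else:
            series, ts = _run_cpm(config, rng, out, files)
        ts.to_csv(out / "timeseries.csv", index=False)
        files.append("timeseries.csv")
        _write_rosette_series(series, out / "rosettes.csv")
        files.append("rosettes.csv")
        summary = {
            "model": config.model,
            "scenario": config.scenario,
            "seed": config.seed,
            "n_steps": config.n_steps,
            "terminal_n_rosettes": series[-1].n_rosettes if series else None,
            "terminal_sizes": series[-1].sizes if series else [],
            "terminal_length": series[-1].primordium_length if series else None,
            "settling_time": settling_time(series),
            "wall_seconds": round(time.time() - t_wall, 2),
            "files": sorted(set(files + ["summary.json", "run.log"])),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("run done in %.1fs", time.time() - t_wall)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_abm(config: RunConfig, rng, out: Path, files: list[str]):
    params = make_abm_params(config)
    state = init_abm(params)
    series: list[RosetteReport] = []
    rows = []

    def record():
        rep = abm_cluster_count(state, params)
        series.append(rep)
        counts = state.breed_counts()
        rows.append(
            {
                "step": state.step_index,
                "n_agents": state.n_agents,
                "n_wnter": counts[AgentBreed.WNTER],
                "n_fgfer": counts[AgentBreed.FGFER],
                "n_depositer": counts[AgentBreed.DEPOSITER],
                "n_links": state.n_links,
                "primordium_length": round(rep.primordium_length, 6),
                "n_clusters": rep.n_rosettes,
            }
        )

    def snapshot():
        tag = f"{state.step_index:06d}"
        state.to_frame().to_csv(out / f"agents_{tag}.csv", index=False)
        files.append(f"agents_{tag}.csv")
        for mode in ("breed", "density"):
            render.render_abm(state, params, str(out / f"abm_{mode}_{tag}.png"), mode)
            files.append(f"abm_{mode}_{tag}.png")

    record()
    snapshot()
    for step in range(1, config.n_steps + 1):
        state = step_abm(state, params, rng)
        if step % config.report_interval == 0 or step == config.n_steps:
            record()
        if config.snapshot_interval and step % config.snapshot_interval == 0:
            snapshot()
        if step % 1000 == 0:
            log.info("step %d/%d", step, config.n_steps)
    return series, pd.DataFrame(rows)


def _run_cpm(config: RunConfig, rng, out: Path, files: list[str]):
    spec = make_scene_spec(config)
    state = build_primordium_scene(spec)
    scenario = SCENARIOS[config.scenario]
    min_members = config.metrics.get("min_apical_members", 3)
    series: list[RosetteReport] = []
    rows = []

    def record(accepted=0):
        rep = detect_rosettes_cpm(state, min_apical_members=min_members)
        series.append(rep)
        rows.append(
            {
                "step": state.mcs,
                "n_rosettes": rep.n_rosettes,
                "primordium_length": round(rep.primordium_length, 6),
                "leading_edge_x": round(rep.leading_edge_x, 6),
                "trailing_edge_x": round(rep.trailing_edge_x, 6),
                "n_active_links": len(state.active_links()),
                "accepted_copies": accepted,
            }
        )

    def snapshot():
        tag = f"{state.mcs:06d}"
        np.savetxt(out / f"lattice_{tag}.txt", state.lattice, fmt="%d")
        files.append(f"lattice_{tag}.txt")
        cells = pd.DataFrame(
            {
                "cell_id": state.cell_ids(),
                "type": [state.type_name_of(c) for c in state.cell_ids()],
                "composite_id": [state.cell_composite[c] for c in state.cell_ids()],
                "volume": [state.volume_of(c) for c in state.cell_ids()],
                "surface": [state.surface_of(c) for c in state.cell_ids()],
                "com_x": [round(state.center_of_mass(c)[0], 3) for c in state.cell_ids()],
                "com_y": [round(state.center_of_mass(c)[1], 3) for c in state.cell_ids()],
            }
        )
        cells.to_csv(out / f"cells_{tag}.csv", index=False)
        files.append(f"cells_{tag}.csv")
        render.render_cpm(state, str(out / f"cpm_{tag}.png"))
        files.append(f"cpm_{tag}.png")

    record()
    snapshot()
    for t in range(1, config.n_steps + 1):
        apply_scenario(state, scenario, t)
        accepted = monte_carlo_step(state, rng)
        if t % config.report_interval == 0 or t == config.n_steps:
            record(accepted)
        if config.snapshot_interval and t % config.snapshot_interval == 0:
            snapshot()
        if t % 1000 == 0:
            log.info("mcs %d/%d", t, config.n_steps)
    return series, pd.DataFrame(rows)


def sweep(
    base: RunConfig, grid: dict[str, list], seeds: list[int], out_dir: str
) -> pd.DataFrame:
    """Run the cross-product of a parameter grid over seeds.

    Grid keys use dotted paths into the config (e.g. ``abm.speed_wnt`` or
    ``cpm.force_wnt``).  Writes one summary CSV with per-seed terminal
    rosette counts and their mean/sd per grid cell.
    """
    if not seeds:
        raise ValueError("seed list must be non-empty")
    import itertools

    keys = sorted(grid)
    rows = []
    outp = Path(out_dir)
    outp.mkdir(parents=True, exist_ok=True)
    for values in itertools.product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, values))
        per_seed = []
        for seed in seeds:
            cfg = RunConfig(**{**base.to_dict(), "seed": seed})
            for key, val in cell.items():
                section, _, name = key.partition(".")
                if name:
                    getattr(cfg, section)[name] = val
                else:
                    setattr(cfg, section, val)
            tag = "_".join(f"{k.split('.')[-1]}={v}" for k, v in cell.items())
            cfg.out_dir = str(outp / f"{tag}_seed{seed}")
            cfg.snapshot_interval = 0
            per_seed.append(run(cfg)["terminal_n_rosettes"])
        rows.append(
            {
                **cell,
                "seeds": ";".join(map(str, seeds)),
                "terminal_counts": ";".join(map(str, per_seed)),
                "mean": float(np.mean(per_seed)),
                "sd": float(np.std(per_seed, ddof=1)) if len(per_seed) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outp / "sweep_summary.csv", index=False)
    return table
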