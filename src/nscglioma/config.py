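"""Structured configuration for the command-line interface.

A config file is YAML with one section per module, e.g.::

    mutation:
      u: 1.0e-7
      n_min: 5
      S: 100.0
    population:
      N0: 1.0e5
      k: 0.035
    schedule:
      mode: linear
      r_young: 251
      r_aged: 318
      t_start: 0
      t_end: 85
    grid:
      dt: 0.001
      t_max: 100

Command-line flags override config values; the effective (merged) config
is dumped alongside every output so a run can be replayed exactly.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .params import DivisionSchedule, MutationParams, PopulationParams, SimulationGrid

__all__ = ["load_config", "merge_config", "dump_config", "build_params", "effective_config"]

SECTIONS = ("mutation", "population", "schedule", "grid", "fit", "bootstrap", "synthetic")


def load_config(path) -> dict:
    """Load a YAML config file into a nested dict (missing sections empty)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r} must be a mapping of sections")
    unknown = set(raw) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {s: dict(raw.get(s) or {}) for s in SECTIONS}


def merge_config(base: dict, overrides: dict) -> dict:
    """Overlay non-None override values onto a loaded config."""
    out = {s: dict(base.get(s, {})) for s in SECTIONS}
    for section, values in overrides.items():
        for key, value in values.items():
            if value is not None:
                out.setdefault(section, {})[key] = value
    return out


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def build_params(config: dict):
    """Materialise (MutationParams, PopulationParams, DivisionSchedule,
    SimulationGrid) from a merged config, with clear errors for the two
    parameters that have no defaults."""
    mut_cfg = dict(config.get("mutation", {}))
    if mut_cfg.get("u") is None:
        raise ValueError(
            "mutation.u is required and has no default: supply the per-gene "
            "per-division mutation probability from a published estimate "
            "(the Frank 2010 somatic mutation-frequency estimate)"
        )
    pop_cfg = dict(config.get("population", {}))
    if pop_cfg.get("N0") is None:
        raise ValueError("population.N0 (NSC count at birth) is required and has no default")
    if pop_cfg.get("k") is None:
        raise ValueError("population.k is required for a forward run (or use calibrate)")
    mut = MutationParams(
        u=float(mut_cfg["u"]),
        n_min=int(mut_cfg.get("n_min", 5)),
        S=float(mut_cfg.get("S", 100.0)),
        n_onco=int(mut_cfg.get("n_onco", 29)),
        G=int(mut_cfg.get("G", 18440)),
        ordering_model=str(mut_cfg.get("ordering_model", "factorial")),
    )
    pop = PopulationParams(N0=float(pop_cfg["N0"]), k=float(pop_cfg["k"]))
    sch_cfg = dict(config.get("schedule", {}))
    schedule = DivisionSchedule(
        mode=str(sch_cfg.get("mode", "linear")),
        r_young=float(sch_cfg.get("r_young", 251.0)),
        r_aged=float(sch_cfg.get("r_aged", 318.0)),
        t_start=float(sch_cfg.get("t_start", 0.0)),
        t_end=float(sch_cfg.get("t_end", 85.0)),
    )
    grid_cfg = dict(config.get("grid", {}))
    grid = SimulationGrid(
        dt=float(grid_cfg.get("dt", 0.001)),
        t_max=float(grid_cfg.get("t_max", 100.0)),
    )
    return mut, pop, schedule, grid


def effective_config(mut, pop, schedule, grid, extra: dict | None = None) -> dict:
    """Nested-dict snapshot of the parameters actually used in a run."""
    cfg = {
        "mutation": asdict(mut),
        "population": asdict(pop),
        "schedule": asdict(schedule),
        "grid": asdict(grid),
    }
    if extra:
        cfg.update(extra)
    return cfg
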