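"""YAML run configuration: boxes, grids, radius schedules, thresholds.

A config file mirrors the CLI flags so that a full profiling run is
reproducible from one declarative document, e.g.::

    box:
      center: [0, 0, 0]
      dims: [15, 15, 60]
      counts: [4, 4, 12]
    prune: {min_clash: 2.0, max_shell: 8.0}
    radii: {start: 3.0, stop: 10.0, step: 0.5, convention: inclusive}
    tol: 0.5
    threshold: 0.5
    cutoff: 4.0
    tag_table: {HIS: 3}      # optional per-residue overrides

Unknown top-level keys are rejected to catch typos early.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .similarity_profiler import RadiusSchedule, radius_schedule
from .structure_io import DEFAULT_TAG_TABLE

_KNOWN_KEYS = {"box", "prune", "radii", "tol", "threshold", "cutoff",
               "tag_table", "denominator", "epsilon", "merge_eps",
               "sort_axis"}

DEFAULTS = {
    "prune": {"min_clash": 2.0, "max_shell": 8.0},
    "radii": {"start": 3.0, "stop": 10.0, "step": 0.5,
              "convention": "inclusive"},
    "tol": 0.5,
    "threshold": 0.5,
    "cutoff": 4.0,
    "denominator": "max",
    "epsilon": 1.5,
    "merge_eps": 1.5,
    "sort_axis": None,
    "tag_table": None,
}


def load_config(path: str | Path | None) -> dict:
    """Load and validate a YAML config, layered over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULTS.items()}
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    if "tag_table" in cfg and cfg.get("tag_table"):
        table = dict(DEFAULT_TAG_TABLE)
        table.update({str(k).upper(): int(v)
                      for k, v in cfg["tag_table"].items()})
        cfg["tag_table"] = table
    else:
        cfg["tag_table"] = None
    return cfg


def schedule_from_config(cfg: dict) -> RadiusSchedule:
    r = cfg["radii"]
    return radius_schedule(r["start"], r["stop"], r["step"], r["convention"])


def parse_schedule(text: str) -> RadiusSchedule:
    """Parse a CLI schedule spec 'start:stop:step:convention',
    e.g. '3:10:0.5:inclusive' or '3:10:0.1:halfopen'."""
    parts = text.split(":")
    if len(parts) != 4:
        raise ValueError("schedule must be start:stop:step:convention")
    convention = {"halfopen": "half-open"}.get(parts[3], parts[3])
    return radius_schedule(float(parts[0]), float(parts[1]), float(parts[2]),
                           convention)
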