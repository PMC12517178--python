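"""YAML/JSON run configuration with strict (unknown-key rejecting) parsing."""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .entropy import PEParams
from .errors import SchemaError
from .pipeline import RunConfig
from .preprocess import PreprocessConfig
from .recording import GROUPS, STATES
from .spectral import MultitaperParams

_SECTIONS = ("seed", "simulate", "preprocess", "spectral", "entropy", "stats")


@dataclass(frozen=True)
class SimConfig:
    """What the simulator generates for a cohort run."""

    n_per_group: int = 5
    groups: tuple[str, ...] = GROUPS
    states: tuple[str, ...] = ("baseline", "steady_state")
    duration_s: float = 60.0
    fs: float = 2000.0

    def __post_init__(self) -> None:
        unknown = set(self.states) - set(STATES)
        if unknown:
            raise SchemaError(f"unknown state(s) {sorted(unknown)}")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise SchemaError(f"unknown group(s) {sorted(unknown)}")


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    kwargs = dict(section)
    for key in ("states", "groups"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[int, SimConfig, RunConfig]:
    """Parse a run configuration file into (seed, SimConfig, RunConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise SchemaError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    sim = _build(SimConfig, raw.get("simulate", {}), "simulate")
    stats_section = dict(raw.get("stats", {}))
    entropy_section = dict(raw.get("entropy", {}))
    pe_band = entropy_section.pop("band", None)
    run_kwargs = {
        "preprocess": _build(PreprocessConfig, raw.get("preprocess", {}),
                             "preprocess"),
        "multitaper": _build(MultitaperParams, raw.get("spectral", {}), "spectral"),
        "pe": _build(PEParams, entropy_section, "entropy"),
    }
    if pe_band is not None:
        run_kwargs["pe_band"] = tuple(pe_band)
    allowed_stats = {"alpha", "lmm_region"}
    unknown = set(stats_section) - allowed_stats
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} in section 'stats'")
    run_kwargs.update(stats_section)
    return seed, sim, RunConfig(**run_kwargs)
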