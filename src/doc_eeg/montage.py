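"""10-20 montage conventions: the 19-channel set, region groupings, channel
aliases and the neighbour table used for interpolation.

Region groupings follow the clinical convention for this montage: frontal
(F3, Fz, F4), central (C3, Cz, C4), parietal (P3, Pz, P4), occipital (O1, O2)
and temporal (T3, T4), plus a prefrontal pair (FP1, FP2) because anesthesia
effects are strongest there. Alias and adjacency tables ship as JSON data so
they can be audited and extended without touching code.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .errors import ParameterError

#: The 19 scalp electrodes of the legacy 10-20 system, in conventional order.
CHANNELS_19 = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

_CANONICAL_CASE = {c.upper(): c for c in CHANNELS_19}

DEFAULT_REGIONS = {
    "prefrontal": ("FP1", "FP2"),
    "frontal": ("F3", "Fz", "F4"),
    "central": ("C3", "Cz", "C4"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("O1", "O2"),
    "temporal": ("T3", "T4"),
}


def _load_data(name: str) -> dict:
    with resources.files("doc_eeg.data").joinpath(name).open() as fh:
        return json.load(fh)


def alias_table() -> dict[str, str]:
    """Mapping from modern 10-10 style names (T7...) to legacy names (T3...)."""
    return dict(_load_data("channel_aliases.json")["aliases"])


def neighbor_table() -> dict[str, list[str]]:
    """Nearest-neighbour electrodes on the 19-channel layout."""
    return {k: list(v) for k, v in _load_data("adjacency_10_20.json")["neighbors"].items()}


def normalize_label(label: str) -> str | None:
    """Map a raw channel label onto the 19-label set, or None if unmappable.

    Case-insensitive; applies the modern->legacy alias table (e.g. T7 -> T3).
    Idempotent: normalizing an already-canonical label returns it unchanged.
    """
    up = label.strip().upper()
    aliases = {k.upper(): v for k, v in alias_table().items()}
    up = aliases.get(up, up)
    return _CANONICAL_CASE.get(up)


@dataclass(frozen=True)
class Montage:
    """Grouping of 10-20 channels into named scalp regions."""

    region_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_REGIONS.items()}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for region, chans in self.region_map.items():
            for ch in chans:
                if ch not in CHANNELS_19:
                    raise ParameterError(f"region {region!r}: unknown channel {ch!r}")
                if ch in seen:
                    raise ParameterError(f"channel {ch!r} assigned to two regions")
                seen.add(ch)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_map)

    def channels_of(self, region: str) -> tuple[str, ...]:
        try:
            return tuple(self.region_map[region])
        except KeyError:
            raise ParameterError(f"unknown region {region!r}") from None
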