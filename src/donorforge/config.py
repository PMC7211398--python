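"""Flat YAML configuration for thresholds, layouts and fixture specs."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .enzymes import DEFAULT_ENZYMES, RestrictionEnzyme
from .fixtures import FixtureSpec
from .linkers import LinkerLayout, default_layout
from .seq_metrics import FilterThresholds

__all__ = ["load_thresholds", "load_layout", "load_fixture_spec"]


def _read_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    return data


def load_thresholds(path) -> FilterThresholds:
    """Thresholds from a flat key/value YAML file; omitted keys keep defaults."""
    return FilterThresholds.from_dict(_read_yaml(path))


def _resolve_enzyme(entry, table: dict[str, RestrictionEnzyme]) -> RestrictionEnzyme:
    if isinstance(entry, str):
        if entry not in table:
            raise KeyError(f"unknown enzyme {entry!r}")
        return table[entry]
    return RestrictionEnzyme(
        entry["name"], entry["site"], int(entry["cut_top"]), int(entry["cut_bottom"])
    )


def load_layout(path, enzymes: dict[str, RestrictionEnzyme] | None = None) -> LinkerLayout:
    """Layout from YAML: enzymes_a/enzymes_b (names or full definitions),
    gaps_a/gaps_b, optional linker_len.  An empty file gives the default."""
    data = _read_yaml(path)
    if not data:
        return default_layout()
    table = enzymes or DEFAULT_ENZYMES
    return LinkerLayout(
        enzymes_a=tuple(_resolve_enzyme(e, table) for e in data["enzymes_a"]),
        enzymes_b=tuple(_resolve_enzyme(e, table) for e in data["enzymes_b"]),
        gaps_a=tuple(data["gaps_a"]),
        gaps_b=tuple(data["gaps_b"]),
        linker_len=int(data.get("linker_len", 30)),
    )


def load_fixture_spec(path) -> FixtureSpec:
    data = _read_yaml(path)
    known = {f.name for f in fields(FixtureSpec)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown fixture spec keys: {sorted(unknown)}")
    if "plant_sequences" in data:
        data["plant_sequences"] = [(str(s), int(c)) for s, c in data["plant_sequences"]]
    return FixtureSpec(**data)
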