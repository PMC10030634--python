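"""Published coefficient presets, packaged as JSON data files.

Each preset carries a full :class:`~beeheat.budget.CoefficientSet`
(value per coefficient, entered exactly as printed in the source
tables), the reported fit statistics, per-coefficient t and P>|t|
values, a units note and a caveat flagging transcription ambiguities in
the flattened source tables.
"""
from __future__ import annotations

import json
from importlib import resources

from ..budget import CoefficientSet

_PACKAGE = __name__


def available_presets() -> tuple[str, ...]:
    """Names of the shipped presets."""
    files = resources.files(_PACKAGE)
    return tuple(
        sorted(p.name[: -len(".json")] for p in files.iterdir() if p.name.endswith(".json"))
    )


def load_preset_raw(name: str) -> dict:
    """The preset file as a plain dict (coefficients, statistics, notes)."""
    files = resources.files(_PACKAGE)
    path = files / f"{name}.json"
    if not path.is_file():
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(available_presets())}"
        )
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_preset(name: str) -> CoefficientSet:
    """A shipped preset as a validated :class:`CoefficientSet`."""
    raw = load_preset_raw(name)
    return CoefficientSet(
        variant=raw["variant"],
        values=raw["coefficients"],
        name=raw["name"],
        note=raw.get("caveat"),
    )
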