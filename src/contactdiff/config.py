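"""Run configuration: defaults, profiles and a flat key=value file format.

Two named profiles encode the two parameterisations used throughout:
``analysis1`` (5 A all-atom contacts, amino-acid-level enrichment) and
``analysis2`` (6 A all-atom contacts, pair-level enrichment plus
betweenness filtering).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from .seqalign import AlignParams
from .target_selection import SelectionCriteria

__all__ = ["RunConfig", "load_config", "save_config", "PROFILES"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    cutoff: float = 5.0
    atom_scheme: str = "all_atom"
    min_separation: int = 2
    mode: str = "aa"  # enrichment/classification level: aa or pair
    denominator: str = "sharing"
    align: AlignParams = AlignParams()
    selection: SelectionCriteria = SelectionCriteria()
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


PROFILES = {
    "analysis1": RunConfig(cutoff=5.0, mode="aa"),
    "analysis2": RunConfig(cutoff=6.0, mode="pair"),
}

# flat key -> (section, field) routing for the config file
_TOP = {f.name for f in dataclasses.fields(RunConfig)} - {"align", "selection"}
_ALIGN = {f.name for f in dataclasses.fields(AlignParams)}
_SEL = {f.name for f in dataclasses.fields(SelectionCriteria)}


def _coerce(value: str, current):
    if isinstance(current, bool):
        return value.strip().lower() in ("1", "true", "yes", "on")
    if isinstance(current, int):
        return int(value)
    if isinstance(current, float):
        return float(value)
    if current is None:
        return None if value.strip().lower() in ("", "none") else int(value)
    return value.strip()


def load_config(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Flat ``key = value`` file; '#' comments.  Keys of the alignment and
    selection sub-configs are addressed by their own field names
    (e.g. ``gap_open``, ``min_conservation_count``)."""
    cfg = base or RunConfig()
    top, align, sel = {}, {}, {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ValueError(f"config line without '=': {ln!r}")
        key, value = (part.strip() for part in ln.split("=", 1))
        if key == "profile":
            cfg = PROFILES[value]
        elif key in _TOP:
            top[key] = value
        elif key in _ALIGN:
            align[key] = value
        elif key in _SEL:
            sel[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    align_obj = dataclasses.replace(
        cfg.align,
        **{k: _coerce(v, getattr(cfg.align, k)) for k, v in align.items()},
    )
    sel_obj = dataclasses.replace(
        cfg.selection,
        **{k: _coerce(v, getattr(cfg.selection, k)) for k, v in sel.items()},
    )
    return dataclasses.replace(
        cfg,
        align=align_obj,
        selection=sel_obj,
        **{k: _coerce(v, getattr(cfg, k)) for k, v in top.items()},
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = []
    for k in sorted(_TOP):
        lines.append(f"{k} = {getattr(cfg, k)}")
    for k in sorted(_ALIGN):
        lines.append(f"{k} = {getattr(cfg.align, k)}")
    for k in sorted(_SEL):
        lines.append(f"{k} = {getattr(cfg.selection, k)}")
    Path(path).write_text("\n".join(lines) + "\n")
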