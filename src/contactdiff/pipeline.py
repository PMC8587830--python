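"""Convenience wiring: contact maps + position maps for a dataset.

Thin glue shared by the classification routines, the CLI and the
analysis scripts; no science of its own.
"""

from __future__ import annotations

from typing import Sequence

from .contact_map import ContactMap, build_contact_map
from .seqalign import AlignParams, PositionMap, align_pair, identity_map
from .structure_io import StructureModel

__all__ = ["prepare"]

Prepared = list[tuple[StructureModel, ContactMap, PositionMap]]


def prepare(
    ref: StructureModel,
    models: Sequence[StructureModel],
    cutoff: float = 5.0,
    scheme: str = "all_atom",
    min_separation: int = 2,
    align_params: AlignParams | None = None,
) -> Prepared:
    """(model, contact map, position map vs ``ref``) for every model."""
    ref_seq = ref.sequence
    out: Prepared = []
    for m in models:
        cm = build_contact_map(m, cutoff, scheme, min_separation)
        if m.id == ref.id:
            pm = identity_map(ref.id, m.id, len(ref))
        else:
            pm = align_pair(ref_seq, m.sequence, align_params, ref_id=ref.id, tgt_id=m.id)
        out.append((m, cm, pm))
    return out
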