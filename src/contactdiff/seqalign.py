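"""Mapping residue positions between a reference and target protein.

Contacts of different proteins can only be compared after their residue
numberings have been reconciled.  A :class:`PositionMap` is a partial,
strictly order-preserving, one-to-one map from reference linear indices
to target linear indices.  It can come from the built-in pairwise
aligner (global, affine gaps, BLOSUM62) or from a user-supplied FASTA
multiple alignment, e.g. one produced by ClustalW or a structural
aligner — the recommended route when reproducing published analyses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .contact_map import ContactMap

__all__ = [
    "AlignParams",
    "PositionMap",
    "AlignmentError",
    "align_pair",
    "load_alignment",
    "map_contact",
    "identity_map",
]

GAP_CHARS = {"-", "."}


class AlignmentError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AlignParams:
    """EMBOSS-needle-style defaults."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclasses.dataclass(frozen=True)
class PositionMap:
    ref_id: str
    tgt_id: str
    pairs: tuple[tuple[int, int], ...]  # sorted (ref_index, tgt_index)

    def __post_init__(self) -> None:
        prev_r, prev_t = 0, 0
        for r, t in self.pairs:
            if r <= prev_r or t <= prev_t:
                raise ValueError("PositionMap must be strictly increasing in both coordinates")
            prev_r, prev_t = r, t

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def get(self, ref_index: int) -> int | None:
        return self.as_dict().get(ref_index)

    def __len__(self) -> int:
        return len(self.pairs)


def identity_map(ref_id: str, tgt_id: str, length: int) -> PositionMap:
    return PositionMap(ref_id, tgt_id, tuple((i, i) for i in range(1, length + 1)))


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load(params.matrix)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


def align_pair(
    ref_seq: str,
    tgt_seq: str,
    params: AlignParams | None = None,
    ref_id: str = "ref",
    tgt_id: str = "tgt",
) -> PositionMap:
    """Global affine-gap alignment; aligned (non-gap) columns become pairs.

    Deterministic: the aligner's first optimal alignment is used.
    Residues unknown to the substitution matrix are scored as 'X'.
    """
    if not ref_seq or not tgt_seq:
        raise AlignmentError("sequences must be non-empty")
    params = params or AlignParams()
    aligner = _make_aligner(params)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    ref_clean = "".join(c if c in alphabet else "X" for c in ref_seq.upper())
    tgt_clean = "".join(c if c in alphabet else "X" for c in tgt_seq.upper())
    aln = aligner.align(ref_clean, tgt_clean)[0]
    pairs: list[tuple[int, int]] = []
    for (rs, re), (ts, te) in zip(*aln.aligned):
        pairs.extend((r + 1, t + 1) for r, t in zip(range(rs, re), range(ts, te)))
    return PositionMap(ref_id=ref_id, tgt_id=tgt_id, pairs=tuple(sorted(pairs)))


def load_alignment(fasta_msa: str | Path, ref_id: str, tgt_id: str) -> PositionMap:
    """Position map from two rows of an aligned FASTA file."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_msa), "fasta")}
    for rid in (ref_id, tgt_id):
        if rid not in records:
            raise AlignmentError(f"id {rid!r} not found in {fasta_msa}")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment in {fasta_msa}: lengths {sorted(lengths)}")
    ref_row, tgt_row = records[ref_id], records[tgt_id]
    pairs: list[tuple[int, int]] = []
    r = t = 0
    for cr, ct in zip(ref_row, tgt_row):
        ref_gap = cr in GAP_CHARS
        tgt_gap = ct in GAP_CHARS
        if not ref_gap:
            r += 1
        if not tgt_gap:
            t += 1
        if not ref_gap and not tgt_gap:
            pairs.append((r, t))
    return PositionMap(ref_id=ref_id, tgt_id=tgt_id, pairs=tuple(pairs))


def map_contact(
    c: tuple[int, int], pm: PositionMap, tgt_map: ContactMap
) -> str:
    """Classify a reference contact against a target: shared / absent / unalignable."""
    d = pm.as_dict()
    mi, mj = d.get(c[0]), d.get(c[1])
    if mi is None or mj is None:
        return "unalignable"
    pair = (mi, mj) if mi < mj else (mj, mi)
    return "shared" if pair in tgt_map.contacts else "absent"
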