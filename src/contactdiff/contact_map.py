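"""Residue-residue contact maps at a distance cutoff.

A contact map is the set of residue pairs (i, j), i < j in linear
indices, whose minimum interatomic distance does not exceed a cutoff.
Two atom schemes are supported: ``all_atom`` (every atom of the residue,
the scheme used for the 5 A and 6 A analyses) and ``ca`` (alpha-carbons
only).  Sequence-local pairs can be excluded with ``min_separation``:
pairs with j - i < min_separation are never contacts.  The cutoff is
inclusive (distance <= cutoff counts).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, StructureModel

__all__ = [
    "ContactMap",
    "MissingAtomError",
    "residue_min_distance",
    "build_contact_map",
    "distance_to_site",
    "write_contact_map",
    "read_contact_map",
]

ATOM_SCHEMES = ("all_atom", "ca")


class MissingAtomError(ValueError):
    """A residue lacks the atom required by the chosen scheme."""


@dataclasses.dataclass(frozen=True)
class ContactMap:
    structure_id: str
    cutoff: float
    atom_scheme: str
    min_separation: int
    contacts: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not i < j:
                raise ValueError(f"contact ({i},{j}) must have i < j")
            if j - i < self.min_separation:
                raise ValueError(
                    f"contact ({i},{j}) violates min_separation={self.min_separation}"
                )

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(sorted(pair)) in self.contacts

    def __len__(self) -> int:
        return len(self.contacts)


def _scheme_coords(r: Residue, scheme: str) -> np.ndarray:
    if scheme == "all_atom":
        if not r.atoms:
            raise MissingAtomError(f"residue {r.name3} {r.author_number} has no atoms")
        return r.atom_coords()
    if scheme == "ca":
        ca = r.get_atom("CA")
        if ca is None:
            raise MissingAtomError(f"residue {r.name3} {r.author_number} has no CA atom")
        return ca.coord[None, :]
    raise ValueError(f"unknown atom scheme {scheme!r}")


def residue_min_distance(a: Residue, b: Residue, scheme: str = "all_atom") -> float:
    """Minimum Euclidean distance between two residues under a scheme."""
    ca, cb = _scheme_coords(a, scheme), _scheme_coords(b, scheme)
    d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def build_contact_map(
    s: StructureModel,
    cutoff: float = 5.0,
    scheme: str = "all_atom",
    min_separation: int = 2,
) -> ContactMap:
    """All residue pairs within ``cutoff`` (inclusive) under ``scheme``.

    Uses a KD-tree over atom coordinates; equivalent to the exhaustive
    all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords, owner = [], []
    for idx, r in enumerate(s.polymer, start=1):
        c = _scheme_coords(r, scheme)
        coords.append(c)
        owner.extend([idx] * len(c))
    pts = np.concatenate(coords, axis=0)
    owner_arr = np.asarray(owner)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts: set[tuple[int, int]] = set()
    if len(pairs):
        ri = owner_arr[pairs[:, 0]]
        rj = owner_arr[pairs[:, 1]]
        lo = np.minimum(ri, rj)
        hi = np.maximum(ri, rj)
        # self-pairs (atoms of one residue) are never contacts, any min_separation
        keep = (hi > lo) & ((hi - lo) >= min_separation)
        contacts = set(zip(lo[keep].tolist(), hi[keep].tolist()))
    return ContactMap(
        structure_id=s.id,
        cutoff=float(cutoff),
        atom_scheme=scheme,
        min_separation=int(min_separation),
        contacts=frozenset(contacts),
    )


def distance_to_site(
    s: StructureModel,
    position: int,
    site: Sequence[int | Residue],
) -> float:
    """Minimum all-atom distance from a residue to a set of site members.

    ``site`` members are linear indices (e.g. catalytic residues) and/or
    hetero-group :class:`Residue` objects (e.g. a bound ligand).  A
    position that is itself part of the site has distance 0.
    """
    if len(site) == 0:
        raise ValueError("site must be non-empty")
    res = s.residue(position)
    best = np.inf
    for member in site:
        if isinstance(member, int):
            if member == position:
                return 0.0
            other = s.residue(member)
        else:
            other = member
        d = residue_min_distance(res, other, scheme="all_atom")
        best = min(best, d)
    return float(best)


def write_contact_map(cm: ContactMap, path: str | Path) -> None:
    """Text format: '#' headers then one tab-separated i<TAB>j pair per line."""
    lines = [
        f"#id\t{cm.structure_id}",
        f"#cutoff\t{cm.cutoff!r}",
        f"#scheme\t{cm.atom_scheme}",
        f"#min_separation\t{cm.min_separation}",
    ]
    for i, j in sorted(cm.contacts):
        lines.append(f"{i}\t{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_map(path: str | Path) -> ContactMap:
    meta: dict[str, str] = {}
    contacts: set[tuple[int, int]] = set()
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("\t")
            meta[key] = val
            continue
        i, j = ln.split("\t")
        contacts.add((int(i), int(j)))
    return ContactMap(
        structure_id=meta["id"],
        cutoff=float(meta["cutoff"]),
        atom_scheme=meta["scheme"],
        min_separation=int(meta["min_separation"]),
        contacts=frozenset(contacts),
    )
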