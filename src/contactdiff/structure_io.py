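"""Reading protein structures and dataset manifests into a uniform model.

Structures arrive as PDB or mmCIF files.  Each is reduced to a single
polymer chain (the enzymes analysed here are treated as monomers), whose
standard amino-acid residues are numbered contiguously 1..L ("linear
index").  Non-water hetero groups (bound ligands such as the transition
state analogue acarbose) are retained separately so that residue-to-ligand
distances can be measured later.

Parsing is delegated to :mod:`gemmi`; this module only normalises the
result (chain selection, altloc resolution, water removal, one-letter
codes) into plain dataclasses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ManifestEntry",
    "DatasetManifest",
    "StructureFormatError",
    "EmptySelectionError",
    "ManifestError",
    "AA3TO1",
    "STANDARD_AA1",
    "read_structure",
    "extract_sequence",
    "read_manifest",
]

STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: 3-letter -> 1-letter codes: the 20 standard residues plus common
#: modified residues with an unambiguous standard parent.  Amino-acid
#: residues outside this table become 'X' (kept for geometry, excluded
#: from frequency counting).
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues with a standard parent
    "MSE": "M", "FME": "M", "SEP": "S", "TPO": "T", "PTR": "Y",
    "CSO": "C", "CSD": "C", "OCS": "C", "HYP": "P", "MLY": "K",
    "KCX": "K", "PCA": "E", "CME": "C", "SEC": "C", "PYL": "K",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureFormatError(ValueError):
    """The file could not be parsed as PDB or mmCIF."""


class EmptySelectionError(ValueError):
    """The selected chain contains no standard amino-acid residues."""


class ManifestError(ValueError):
    """The dataset manifest is malformed."""


@dataclasses.dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not np.all(np.isfinite(self.coord)) or self.coord.shape != (3,):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")


@dataclasses.dataclass
class Residue:
    chain_id: str
    author_number: int
    icode: str
    name3: str
    aa1: str
    atoms: list[Atom]

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclasses.dataclass
class StructureModel:
    """One selected chain of a structure, linear-indexed from 1."""

    id: str
    polymer: list[Residue]
    hetero_groups: list[Residue] = dataclasses.field(default_factory=list)
    group_label: str = "unknown"  # H, T or unknown

    def __len__(self) -> int:
        return len(self.polymer)

    def residue(self, linear_index: int) -> Residue:
        """1-based access into the polymer."""
        if not 1 <= linear_index <= len(self.polymer):
            raise IndexError(f"linear index {linear_index} outside 1..{len(self.polymer)}")
        return self.polymer[linear_index - 1]

    @property
    def sequence(self) -> str:
        return "".join(r.aa1 for r in self.polymer)


@dataclasses.dataclass(frozen=True)
class ManifestEntry:
    id: str
    path: str
    group: str
    chain: str = "auto"


@dataclasses.dataclass
class DatasetManifest:
    entries: list[ManifestEntry]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]


def _is_amino_acid(name3: str) -> bool:
    if name3 in AA3TO1:
        return True
    info = gemmi.find_tabulated_residue(name3)
    return info is not None and info.is_amino_acid()


def _one_letter(name3: str) -> str:
    return AA3TO1.get(name3, "X")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per atom name: highest occupancy, ties first in file."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def _convert_residue(chain_id: str, res: gemmi.Residue, hetero: bool) -> Residue:
    atoms = [
        Atom(
            name=at.name,
            element=at.element.name,
            coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
            is_hetero=hetero,
            altloc=at.altloc if at.altloc != "\0" else "",
            occupancy=float(at.occ),
        )
        for at in res
    ]
    atoms = _resolve_altlocs(atoms)
    name3 = res.name
    return Residue(
        chain_id=chain_id,
        author_number=res.seqid.num,
        icode=res.seqid.icode.strip() if res.seqid.icode else "",
        name3=name3,
        aa1=_one_letter(name3) if _is_amino_acid(name3) else "X",
        atoms=atoms,
    )


def read_structure(path: str | Path, chain: str = "auto") -> StructureModel:
    """Read a PDB/mmCIF file into a :class:`StructureModel`.

    ``chain="auto"`` selects the chain with the most amino-acid residues
    (ties broken by chain id).  Only the first model of multi-model files
    is used.  Waters are dropped; all other hetero groups are kept in
    ``hetero_groups`` regardless of chain.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureFormatError(f"{path}: cannot parse as PDB/mmCIF: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: file contains no models")
    model = st[0]

    aa_count: dict[str, int] = {}
    for ch in model:
        aa_count[ch.name] = sum(1 for r in ch if _is_amino_acid(r.name))
    if chain == "auto":
        candidates = sorted(aa_count, key=lambda c: (-aa_count[c], c))
        if not candidates or aa_count[candidates[0]] == 0:
            raise EmptySelectionError(f"{path}: no chain with amino-acid residues")
        chain_id = candidates[0]
    else:
        if chain not in aa_count:
            raise EmptySelectionError(f"{path}: chain {chain!r} not present")
        chain_id = chain

    polymer: list[Residue] = []
    hetero_groups: list[Residue] = []
    for ch in model:
        for res in ch:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            if _is_amino_acid(res.name):
                if ch.name == chain_id:
                    polymer.append(_convert_residue(ch.name, res, hetero=False))
            else:
                hetero_groups.append(_convert_residue(ch.name, res, hetero=True))

    if not polymer:
        raise EmptySelectionError(f"{path}: chain {chain_id!r} has no amino-acid residues")
    return StructureModel(id=path.stem, polymer=polymer, hetero_groups=hetero_groups)


def extract_sequence(s: StructureModel) -> str:
    """One-letter sequence in linear-index order."""
    if not s.polymer:
        raise EmptySelectionError(f"{s.id}: empty polymer")
    return s.sequence


_VALID_GROUPS = {"H", "T", "unknown"}


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a 4-column TSV manifest (id, path, group, chain); '#' comments."""
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ManifestError(f"{path}: empty manifest")
    header = [c.strip() for c in lines[0].split("\t")]
    required = ["id", "path", "group", "chain"]
    if header[: len(required)] != required:
        raise ManifestError(f"{path}: header must be {required}, got {header}")
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        cols = [c.strip() for c in ln.split("\t")]
        if len(cols) < 4:
            raise ManifestError(f"{path}: row has {len(cols)} columns, need 4: {ln!r}")
        eid, epath, group, ch = cols[:4]
        if eid in seen:
            raise ManifestError(f"{path}: duplicate id {eid!r}")
        if group not in _VALID_GROUPS:
            raise ManifestError(f"{path}: unknown group {group!r} (allowed: H, T, unknown)")
        seen.add(eid)
        entries.append(ManifestEntry(id=eid, path=epath, group=group, chain=ch or "auto"))
    return DatasetManifest(entries=entries)


def load_dataset(
    manifest: DatasetManifest, base_dir: str | Path | None = None
) -> list[StructureModel]:
    """Read every manifest entry, attaching ids and group labels."""
    base = Path(base_dir) if base_dir is not None else None
    models = []
    for e in manifest.entries:
        p = Path(e.path)
        if base is not None and not p.is_absolute():
            p = base / p
        m = read_structure(p, chain=e.chain)
        m.id = e.id
        m.group_label = e.group
        models.append(m)
    return models
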