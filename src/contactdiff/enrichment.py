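"""Amino-acid and pair enrichment factors over shared contacts.

For every contact of the reference protein, the dataset is scanned for
proteins in which the mapped residue pair is also a contact ("shared").
Among the group of sharing proteins with a given functional label, the
frequency of each amino acid occupying a contact endpoint (f_aa) and of
each ordered amino-acid pair (f_pair) is computed.  The enrichment
factor is the transferase-minus-hydrolase frequency difference:

    delta    = f_aa(T)   - f_aa(H)      (per endpoint, per amino acid)
    delta_p  = f_pair(T) - f_pair(H)    (per contact, per amino-acid pair)

Both lie in [-1, 1]; positive values mark amino acids (or pairs) more
typical of transglycosidases, negative values of hydrolases.

Frequencies are by default conditional on the contact being shared: the
denominator is the number of group members sharing the contact, which
normalises each endpoint's frequency vector to sum 1.  A total-group-
size denominator is available via ``denominator="group_size"`` (changes
delta magnitudes; documented in the methods note).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence

import pandas as pd

from .contact_map import ContactMap
from .seqalign import PositionMap, identity_map
from .structure_io import StructureModel

__all__ = [
    "Observation",
    "SharedContactTable",
    "EnrichmentEntry",
    "PairEnrichmentEntry",
    "EnrichmentTables",
    "UndefinedFrequencyError",
    "build_shared_table",
    "aa_frequencies",
    "enrichment_factor",
    "pair_enrichment_factor",
    "full_enrichment_table",
]

Contact = tuple[int, int]
Denominator = Literal["sharing", "group_size"]


class UndefinedFrequencyError(ValueError):
    """No member of a required group shares the contact."""


@dataclasses.dataclass(frozen=True)
class Observation:
    status: str  # shared / absent / unalignable
    aa_i: str | None = None  # recorded only when shared; ordered by reference endpoint
    aa_j: str | None = None


@dataclasses.dataclass
class SharedContactTable:
    """Per reference contact, per dataset member: status and occupying amino acids."""

    ref_id: str
    contacts: tuple[Contact, ...]
    member_ids: tuple[str, ...]
    groups: dict[str, str]  # member id -> H / T
    cells: dict[tuple[str, Contact], Observation]

    def observation(self, member_id: str, contact: Contact) -> Observation:
        return self.cells[(member_id, contact)]

    def sharing_members(self, contact: Contact, group: str | None = None) -> list[str]:
        out = []
        for m in self.member_ids:
            if group is not None and self.groups[m] != group:
                continue
            if self.cells[(m, contact)].status == "shared":
                out.append(m)
        return out

    def group_size(self, group: str) -> int:
        return sum(1 for m in self.member_ids if self.groups[m] == group)

    def with_swapped_labels(self) -> "SharedContactTable":
        """Exchange H and T labels of every member (antisymmetry checks)."""
        flip = {"H": "T", "T": "H"}
        return dataclasses.replace(
            self, groups={m: flip.get(g, g) for m, g in self.groups.items()}
        )


def build_shared_table(
    ref: StructureModel,
    ref_cm: ContactMap,
    dataset: Sequence[tuple[StructureModel, ContactMap, PositionMap]],
    include_reference: bool = True,
) -> SharedContactTable:
    """One row per reference contact, one column per dataset member.

    The reference itself is included as a member of its own functional
    group (with the identity position map) unless already present in
    ``dataset`` or ``include_reference`` is false.
    """
    members: list[tuple[StructureModel, ContactMap, PositionMap]] = list(dataset)
    ids = {m.id for m, _, _ in members}
    if include_reference and ref.id not in ids:
        members.insert(0, (ref, ref_cm, identity_map(ref.id, ref.id, len(ref))))

    contacts = tuple(sorted(ref_cm.contacts))
    cells: dict[tuple[str, Contact], Observation] = {}
    groups: dict[str, str] = {}
    for model, cm, pm in members:
        groups[model.id] = model.group_label
        lookup = pm.as_dict()
        for c in contacts:
            mi, mj = lookup.get(c[0]), lookup.get(c[1])
            if mi is None or mj is None:
                cells[(model.id, c)] = Observation("unalignable")
                continue
            pair = (mi, mj) if mi < mj else (mj, mi)
            if pair in cm.contacts:
                cells[(model.id, c)] = Observation(
                    "shared",
                    aa_i=model.residue(mi).aa1,
                    aa_j=model.residue(mj).aa1,
                )
            else:
                cells[(model.id, c)] = Observation("absent")
    return SharedContactTable(
        ref_id=ref.id,
        contacts=contacts,
        member_ids=tuple(m.id for m, _, _ in members),
        groups=groups,
        cells=cells,
    )


@dataclasses.dataclass(frozen=True)
class EnrichmentEntry:
    contact: Contact
    endpoint: int  # one of the contact's positions (reference indices)
    aa: str
    n_T: int
    n_H: int
    faa_T: float
    faa_H: float
    delta: float


@dataclasses.dataclass(frozen=True)
class PairEnrichmentEntry:
    contact: Contact
    aa_pair: tuple[str, str]  # ordered by reference endpoint (i before j)
    n_T: int
    n_H: int
    faap_T: float
    faap_H: float
    delta_pair: float


def _endpoint_aa(obs: Observation, contact: Contact, endpoint: int) -> str | None:
    if endpoint == contact[0]:
        return obs.aa_i
    if endpoint == contact[1]:
        return obs.aa_j
    raise ValueError(f"endpoint {endpoint} is not part of contact {contact}")


def _tally(
    t: SharedContactTable,
    contact: Contact,
    group: str,
    key,  # Observation -> hashable or None (None = excluded from counting)
    denominator: Denominator,
) -> tuple[dict, int]:
    counts: dict = {}
    n_countable = 0
    for m in t.sharing_members(contact, group):
        k = key(t.observation(m, contact))
        if k is None:  # 'X' occupancy: contact counts as shared, aa not counted
            continue
        counts[k] = counts.get(k, 0) + 1
        n_countable += 1
    denom = t.group_size(group) if denominator == "group_size" else n_countable
    return counts, denom


def aa_frequencies(
    t: SharedContactTable,
    contact: Contact,
    endpoint: int,
    group: str,
    denominator: Denominator = "sharing",
) -> dict[str, float]:
    """Frequency of each amino acid at one endpoint among sharing group members."""
    if not t.sharing_members(contact, group):
        raise UndefinedFrequencyError(
            f"no {group}-group member shares contact {contact}"
        )

    def key(obs: Observation):
        aa = _endpoint_aa(obs, contact, endpoint)
        return None if aa == "X" else aa

    counts, denom = _tally(t, contact, group, key, denominator)
    if denom == 0:
        raise UndefinedFrequencyError(
            f"contact {contact} endpoint {endpoint}: all {group}-group occupants are 'X'"
        )
    return {aa: n / denom for aa, n in counts.items()}


def enrichment_factor(
    t: SharedContactTable,
    contact: Contact,
    endpoint: int,
    aa: str,
    denominator: Denominator = "sharing",
) -> EnrichmentEntry:
    """delta = f_aa(T) - f_aa(H); unobserved amino acids have frequency 0."""
    fT = aa_frequencies(t, contact, endpoint, "T", denominator)
    fH = aa_frequencies(t, contact, endpoint, "H", denominator)

    def count(group: str) -> int:
        return sum(
            1
            for m in t.sharing_members(contact, group)
            if _endpoint_aa(t.observation(m, contact), contact, endpoint) == aa
        )

    faa_T, faa_H = fT.get(aa, 0.0), fH.get(aa, 0.0)
    return EnrichmentEntry(
        contact=contact,
        endpoint=endpoint,
        aa=aa,
        n_T=count("T"),
        n_H=count("H"),
        faa_T=faa_T,
        faa_H=faa_H,
        delta=faa_T - faa_H,
    )


def pair_frequencies(
    t: SharedContactTable,
    contact: Contact,
    group: str,
    denominator: Denominator = "sharing",
    ordered: bool = True,
) -> dict[tuple[str, str], float]:
    if not t.sharing_members(contact, group):
        raise UndefinedFrequencyError(
            f"no {group}-group member shares contact {contact}"
        )

    def key(obs: Observation):
        if obs.aa_i == "X" or obs.aa_j == "X":
            return None
        pair = (obs.aa_i, obs.aa_j)
        return pair if ordered else tuple(sorted(pair))

    counts, denom = _tally(t, contact, group, key, denominator)
    if denom == 0:
        raise UndefinedFrequencyError(
            f"contact {contact}: all {group}-group pairs involve 'X'"
        )
    return {p: n / denom for p, n in counts.items()}


def pair_enrichment_factor(
    t: SharedContactTable,
    contact: Contact,
    aa_pair: tuple[str, str],
    denominator: Denominator = "sharing",
    ordered: bool = True,
) -> PairEnrichmentEntry:
    """delta_p = f_pair(T) - f_pair(H) for one ordered amino-acid pair."""
    fT = pair_frequencies(t, contact, "T", denominator, ordered)
    fH = pair_frequencies(t, contact, "H", denominator, ordered)
    probe = tuple(aa_pair) if ordered else tuple(sorted(aa_pair))

    def count(group: str) -> int:
        n = 0
        for m in t.sharing_members(contact, group):
            obs = t.observation(m, contact)
            pair = (obs.aa_i, obs.aa_j) if ordered else tuple(sorted((obs.aa_i, obs.aa_j)))
            if pair == probe:
                n += 1
        return n

    faap_T, faap_H = fT.get(probe, 0.0), fH.get(probe, 0.0)
    return PairEnrichmentEntry(
        contact=contact,
        aa_pair=tuple(aa_pair),
        n_T=count("T"),
        n_H=count("H"),
        faap_T=faap_T,
        faap_H=faap_H,
        delta_pair=faap_T - faap_H,
    )


@dataclasses.dataclass
class EnrichmentTables:
    """Full per-contact enrichment results with fast lookups."""

    ref_id: str
    aa_entries: list[EnrichmentEntry]
    pair_entries: list[PairEnrichmentEntry]
    skipped: list[tuple[Contact, str]]

    def __post_init__(self) -> None:
        self.aa_delta: dict[tuple[Contact, int, str], float] = {
            (e.contact, e.endpoint, e.aa): e.delta for e in self.aa_entries
        }
        self.pair_delta: dict[tuple[Contact, tuple[str, str]], float] = {
            (e.contact, e.aa_pair): e.delta_pair for e in self.pair_entries
        }
        self.skipped_contacts: set[Contact] = {c for c, _ in self.skipped}

    def get_aa_delta(self, contact: Contact, endpoint: int, aa: str) -> float | None:
        """None when the contact was skipped or the amino acid never observed."""
        if contact in self.skipped_contacts:
            return None
        return self.aa_delta.get((contact, endpoint, aa))

    def get_pair_delta(self, contact: Contact, aa_pair: tuple[str, str]) -> float | None:
        if contact in self.skipped_contacts:
            return None
        return self.pair_delta.get((contact, tuple(aa_pair)))

    def aa_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_contact_i": e.contact[0],
                    "ref_contact_j": e.contact[1],
                    "endpoint": e.endpoint,
                    "aa": e.aa,
                    "n_T": e.n_T,
                    "n_H": e.n_H,
                    "faa_T": e.faa_T,
                    "faa_H": e.faa_H,
                    "delta": e.delta,
                }
                for e in self.aa_entries
            ]
        )

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_contact_i": e.contact[0],
                    "ref_contact_j": e.contact[1],
                    "aa_i": e.aa_pair[0],
                    "aa_j": e.aa_pair[1],
                    "n_T": e.n_T,
                    "n_H": e.n_H,
                    "faap_T": e.faap_T,
                    "faap_H": e.faap_H,
                    "delta_pair": e.delta_pair,
                }
                for e in self.pair_entries
            ]
        )

    def skipped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"ref_contact_i": c[0], "ref_contact_j": c[1], "reason": r}
                for c, r in self.skipped
            ]
        )


def full_enrichment_table(
    t: SharedContactTable,
    denominator: Denominator = "sharing",
    ordered_pairs: bool = True,
) -> EnrichmentTables:
    """Enrichment entries for every (contact, endpoint, observed aa) and pair.

    Contacts not shared by at least one member of each group are skipped
    with a reason rather than silently dropped.
    """
    aa_entries: list[EnrichmentEntry] = []
    pair_entries: list[PairEnrichmentEntry] = []
    skipped: list[tuple[Contact, str]] = []
    for c in t.contacts:
        missing = [g for g in ("T", "H") if not t.sharing_members(c, g)]
        if missing:
            skipped.append((c, f"no sharing member in group(s) {','.join(missing)}"))
            continue
        try:
            for endpoint in c:
                observed = set(aa_frequencies(t, c, endpoint, "T", denominator)) | set(
                    aa_frequencies(t, c, endpoint, "H", denominator)
                )
                for aa in sorted(observed):
                    aa_entries.append(
                        enrichment_factor(t, c, endpoint, aa, denominator)
                    )
            observed_pairs = set(
                pair_frequencies(t, c, "T", denominator, ordered_pairs)
            ) | set(pair_frequencies(t, c, "H", denominator, ordered_pairs))
            for pair in sorted(observed_pairs):
                pair_entries.append(
                    pair_enrichment_factor(t, c, pair, denominator, ordered_pairs)
                )
        except UndefinedFrequencyError as exc:
            skipped.append((c, str(exc)))
    return EnrichmentTables(
        ref_id=t.ref_id, aa_entries=aa_entries, pair_entries=pair_entries, skipped=skipped
    )
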