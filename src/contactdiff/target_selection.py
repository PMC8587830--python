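"""Selecting mutation sites expected to shift reaction specificity.

A position of the query enzyme is a candidate for switching specificity
toward transglycosylation (direction ``toT``) when

  1. it takes part in a well-conserved contact (shared by at least
     ``min_conservation_count`` of the dataset enzymes),
  2. the amino acid currently occupying it is not transferase-enriched
     (enrichment factor <= ``wild_delta_max``, default 0), and
  3. some alternative amino acid at that contact endpoint is clearly
     transferase-enriched (enrichment factor >= ``candidate_delta_min``,
     default 0.2).

Direction ``toH`` mirrors every sign.  Pair-level selection instead
requires the contact's observed amino-acid pair enrichment to sit in
the extreme tails of the global pair-enrichment distribution and both
endpoints to rank in the top betweenness-centrality fraction of the
contact network.  Positions in contact with the bound transition-state
analogue are demoted in the ranking, not removed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

from .contact_map import distance_to_site
from .contact_network import BetweennessResult, top_percentile
from .conservation import ConservationProfile
from .enrichment import EnrichmentTables
from .structure_io import Residue, StructureModel

__all__ = [
    "SelectionCriteria",
    "MutationCandidate",
    "SelectionResult",
    "select_aa_level",
    "select_pair_level",
    "explain_candidate",
]

Contact = tuple[int, int]


@dataclasses.dataclass(frozen=True)
class SelectionCriteria:
    direction: Literal["toT", "toH"] = "toT"
    min_conservation_count: int = 10
    dataset_size: int = 14
    wild_delta_max: float = 0.0  # alternative reading: -0.2
    candidate_delta_min: float = 0.2
    pair_extreme_fraction: float = 0.01
    betweenness_fraction: float = 0.10  # 0.20 under the looser reading
    prefer_non_ligand_contact: bool = True
    ligand_contact_cutoff: float = 5.0
    max_candidates: int | None = None

    def __post_init__(self) -> None:
        for name in ("pair_extreme_fraction", "betweenness_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_conservation_count > self.dataset_size:
            raise ValueError("min_conservation_count cannot exceed dataset_size")

    @property
    def sign(self) -> int:
        """+1 for toT (seek positive enrichment), -1 for toH."""
        return 1 if self.direction == "toT" else -1


@dataclasses.dataclass
class MutationCandidate:
    position: int
    author_number: int
    wild_aa: str
    proposed_aa: str
    wild_delta: float
    proposed_delta: float
    conservation_count: int
    betweenness_percentile: float | None
    distance_to_site: float | None
    ligand_contact: bool
    contacts_involved: list[Contact]
    passes: dict[str, bool]
    rank_score: float  # signed enrichment gain; higher is better

    @property
    def mutation(self) -> str:
        return f"{self.wild_aa}{self.author_number}{self.proposed_aa}"


@dataclasses.dataclass
class SelectionResult:
    candidates: list[MutationCandidate]
    rejected: list[tuple[int, str]]  # (position, reason)


def _site_info(
    query: StructureModel,
    position: int,
    site: Sequence | None,
    criteria: SelectionCriteria,
) -> tuple[float | None, bool]:
    if not site:
        return None, False
    d = distance_to_site(query, position, site)
    return d, d <= criteria.ligand_contact_cutoff


def _rank(cands: list[MutationCandidate], criteria: SelectionCriteria) -> list[MutationCandidate]:
    def key(c: MutationCandidate):
        demoted = c.ligand_contact and criteria.prefer_non_ligand_contact
        dist = c.distance_to_site if c.distance_to_site is not None else -1.0
        return (demoted, -c.rank_score, -c.conservation_count, -dist)

    ranked = sorted(cands, key=key)
    if criteria.max_candidates is not None:
        ranked = ranked[: criteria.max_candidates]
    return ranked


def select_aa_level(
    query: StructureModel,
    tables: EnrichmentTables,
    conservation: ConservationProfile,
    criteria: SelectionCriteria,
    site: Sequence | None = None,
) -> SelectionResult:
    """Amino-acid-level candidates; the query anchors the contact frame.

    ``tables`` and ``conservation`` must have been computed with the
    query as reference, so contact indices are query linear indices.
    ``site`` (optional) lists active-site members — hetero groups and/or
    catalytic residue positions — for distance reporting and ligand
    demotion.
    """
    s = criteria.sign
    by_position: dict[int, list[Contact]] = {}
    for c in conservation.n_sharing:
        by_position.setdefault(c[0], []).append(c)
        by_position.setdefault(c[1], []).append(c)

    candidates: list[MutationCandidate] = []
    rejected: list[tuple[int, str]] = []
    for pos in sorted(by_position):
        wild_aa = query.residue(pos).aa1
        if wild_aa == "X":
            continue
        cons_ok = [
            c for c in by_position[pos]
            if conservation.n_sharing[c] >= criteria.min_conservation_count
        ]
        if not cons_ok:
            rejected.append((pos, "conservation"))
            continue
        best: MutationCandidate | None = None
        saw_wild_ok = False
        for c in cons_ok:
            wd = tables.get_aa_delta(c, pos, wild_aa)
            wd = 0.0 if wd is None else wd
            if s * wd > criteria.wild_delta_max:
                continue
            saw_wild_ok = True
            for (cc, ep, aa), delta in tables.aa_delta.items():
                if cc != c or ep != pos or aa == wild_aa:
                    continue
                if s * delta < criteria.candidate_delta_min:
                    continue
                gain = s * (delta - wd)
                if best is None or gain > best.rank_score:
                    dist, lig = _site_info(query, pos, site, criteria)
                    best = MutationCandidate(
                        position=pos,
                        author_number=query.residue(pos).author_number,
                        wild_aa=wild_aa,
                        proposed_aa=aa,
                        wild_delta=wd,
                        proposed_delta=delta,
                        conservation_count=conservation.n_sharing[c],
                        betweenness_percentile=None,
                        distance_to_site=dist,
                        ligand_contact=lig,
                        contacts_involved=sorted(cons_ok),
                        passes={
                            "conservation": True,
                            "wild_delta": True,
                            "candidate_delta": True,
                        },
                        rank_score=gain,
                    )
        if best is not None:
            candidates.append(best)
        else:
            rejected.append((pos, "candidate_delta" if saw_wild_ok else "wild_delta"))
    return SelectionResult(candidates=_rank(candidates, criteria), rejected=rejected)


def _pair_extreme_cuts(values: list[float], fraction: float) -> tuple[float, float]:
    """(low cut, high cut): values <= low or >= high are in the extreme tails."""
    if not values:
        raise ValueError("no pair-enrichment values")
    k = max(1, math.ceil(fraction * len(values)))
    ordered = sorted(values)
    return ordered[k - 1], ordered[-k]


def select_pair_level(
    query: StructureModel,
    tables: EnrichmentTables,
    conservation: ConservationProfile,
    bet: BetweennessResult,
    criteria: SelectionCriteria,
    site: Sequence | None = None,
) -> SelectionResult:
    """Pair-level candidates filtered by conservation, pair-enrichment extremes
    and betweenness centrality of both endpoints."""
    s = criteria.sign
    all_deltas = [e.delta_pair for e in tables.pair_entries]
    lo_cut, hi_cut = _pair_extreme_cuts(all_deltas, criteria.pair_extreme_fraction)
    central = top_percentile(bet, criteria.betweenness_fraction)

    candidates: list[MutationCandidate] = []
    rejected: list[tuple[int, str]] = []
    for c in sorted(conservation.n_sharing):
        if conservation.n_sharing[c] < criteria.min_conservation_count:
            rejected.append((c[0], "conservation"))
            continue
        if not (c[0] in central and c[1] in central):
            rejected.append((c[0], "betweenness"))
            continue
        wild_pair = (query.residue(c[0]).aa1, query.residue(c[1]).aa1)
        wd = tables.get_pair_delta(c, wild_pair)
        wd = 0.0 if wd is None else wd
        if not (wd <= lo_cut or wd >= hi_cut):
            rejected.append((c[0], "pair_extreme"))
            continue
        # best target-group-enriched pair at this contact
        best_pair, best_delta = None, None
        for (cc, pair), delta in tables.pair_delta.items():
            if cc != c:
                continue
            if best_delta is None or s * delta > s * best_delta:
                best_pair, best_delta = pair, delta
        if best_pair is None or s * best_delta <= s * wd:
            rejected.append((c[0], "no_enriched_pair"))
            continue
        for ep, proposed in zip(c, best_pair):
            wild_aa = query.residue(ep).aa1
            if proposed == wild_aa:
                continue
            dist, lig = _site_info(query, ep, site, criteria)
            candidates.append(
                MutationCandidate(
                    position=ep,
                    author_number=query.residue(ep).author_number,
                    wild_aa=wild_aa,
                    proposed_aa=proposed,
                    wild_delta=wd,
                    proposed_delta=best_delta,
                    conservation_count=conservation.n_sharing[c],
                    betweenness_percentile=bet.percentile[ep],
                    distance_to_site=dist,
                    ligand_contact=lig,
                    contacts_involved=[c],
                    passes={
                        "conservation": True,
                        "betweenness": True,
                        "pair_extreme": True,
                    },
                    rank_score=s * (best_delta - wd),
                )
            )
    return SelectionResult(candidates=_rank(candidates, criteria), rejected=rejected)


def explain_candidate(c: MutationCandidate, criteria: SelectionCriteria) -> str:
    """Human-readable evidence report for one proposed substitution."""
    lines = [
        f"Candidate {c.mutation} (linear index {c.position})",
        f"  direction            : {criteria.direction}",
        f"  wild residue         : {c.wild_aa}  (enrichment {c.wild_delta:+.3f}, "
        f"threshold <= {criteria.wild_delta_max:+.2f} toward target group)",
        f"  proposed residue     : {c.proposed_aa}  (enrichment {c.proposed_delta:+.3f}, "
        f"threshold >= {criteria.candidate_delta_min:+.2f})",
        f"  enrichment gain      : {c.rank_score:+.3f}",
        f"  conservation count   : {c.conservation_count} / {criteria.dataset_size} "
        f"(threshold >= {criteria.min_conservation_count})",
    ]
    if c.betweenness_percentile is not None:
        lines.append(
            f"  betweenness          : percentile {c.betweenness_percentile:.1f} "
            f"(top {criteria.betweenness_fraction:.0%} required)"
        )
    if c.distance_to_site is not None:
        lines.append(f"  distance to site     : {c.distance_to_site:.1f} A")
    if c.ligand_contact:
        lines.append(
            "  NOTE: residue contacts the bound ligand; demoted in ranking"
            if criteria.prefer_non_ligand_contact
            else "  residue contacts the bound ligand"
        )
    lines.append(
        "  criteria passed      : "
        + ", ".join(f"{k}={'yes' if v else 'NO'}" for k, v in c.passes.items())
    )
    lines.append(
        "  contacts involved    : "
        + "; ".join(f"({i},{j})" for i, j in c.contacts_involved)
    )
    return "\n".join(lines)
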