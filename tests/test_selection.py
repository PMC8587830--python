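"""Mutation-site selection: criteria, ranking, monotonicity, mirroring."""

import dataclasses

import numpy as np
import pytest

from contactdiff.classify import qualify_residue
from contactdiff.conservation import ConservationProfile, conservation_profile
from contactdiff.contact_map import build_contact_map
from contactdiff.contact_network import betweenness, build_graph
from contactdiff.enrichment import (
    EnrichmentEntry,
    EnrichmentTables,
    build_shared_table,
    full_enrichment_table,
)
from contactdiff.pipeline import prepare
from contactdiff.synthetic import PlantedSite, SyntheticSpec, default_planted_sites, generate
from contactdiff.target_selection import (
    SelectionCriteria,
    explain_candidate,
    select_aa_level,
    select_pair_level,
)

from conftest import make_model


def _entry(contact, endpoint, aa, delta):
    pos = max(delta, 0.0)
    return EnrichmentEntry(contact, endpoint, aa, n_T=0, n_H=0,
                           faa_T=pos, faa_H=pos - delta, delta=delta)


def _toy_setup(cons_count=14, wild_delta=0.0, alt_delta=0.45):
    """One contact (1, 4), wild Lys with configurable deltas for Pro alternative."""
    query = make_model("q", [[0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0]],
                       sequence="KAAK")
    tables = EnrichmentTables(
        ref_id="q",
        aa_entries=[
            _entry((1, 4), 1, "K", wild_delta),
            _entry((1, 4), 1, "P", alt_delta),
            _entry((1, 4), 4, "K", 0.0),
        ],
        pair_entries=[],
        skipped=[],
    )
    profile = ConservationProfile("q", 14, {(1, 4): cons_count}, {})
    return query, tables, profile


def test_zero_wild_delta_with_strong_alternative_selected():
    """A neutral wild residue with a 0.45-enriched alternative qualifies."""
    query, tables, profile = _toy_setup()
    res = select_aa_level(query, tables, profile, SelectionCriteria(direction="toT"))
    assert [c.mutation for c in res.candidates][0] == "K1P"
    top = res.candidates[0]
    assert top.wild_delta == 0.0
    assert top.proposed_delta == pytest.approx(0.45)
    assert qualify_residue(top.proposed_delta) == "T"


def test_low_conservation_rejected_with_reason():
    query, tables, profile = _toy_setup(cons_count=9)
    res = select_aa_level(query, tables, profile, SelectionCriteria(direction="toT"))
    assert not res.candidates
    assert (1, "conservation") in res.rejected


def test_transferase_enriched_wild_residue_rejected():
    query, tables, profile = _toy_setup(wild_delta=0.3)
    res = select_aa_level(query, tables, profile, SelectionCriteria(direction="toT"))
    assert all(c.position != 1 for c in res.candidates)
    assert (1, "wild_delta") in res.rejected


def _aa_level_inputs(spec, query_group="H"):
    ds = generate(spec)
    query = [m for m in ds.labeled_models if m.group_label == query_group][0]
    prep = prepare(query, ds.labeled_models)
    qcm = build_contact_map(query)
    table = build_shared_table(query, qcm, prep)
    tables = full_enrichment_table(table)
    profile = conservation_profile(query, qcm,
                                   [p for p in prep if p[0].id != query.id])
    return ds, query, tables, profile


THREE_SITES = (
    PlantedSite((1, 4), 1, "W", "E", 1.0),
    PlantedSite((5, 8), 5, "F", "K", 1.0),
    PlantedSite((9, 12), 9, "L", "D", 1.0),
)


def test_exactly_planted_positions_selected():
    spec = SyntheticSpec(seed=13, planted_sites=THREE_SITES,
                         contact_dropout=0.0, background_mutation_prob=0.0)
    ds, query, tables, profile = _aa_level_inputs(spec)
    res = select_aa_level(query, tables, profile, SelectionCriteria(direction="toT"))
    assert sorted(c.position for c in res.candidates) == [1, 5, 9]
    assert sorted(c.position for c in res.candidates) == ds.ground_truth[
        "qualifying_positions"
    ]
    assert {c.proposed_aa for c in res.candidates} == {"W", "F", "L"}


def test_tightening_thresholds_never_enlarges_candidate_set():
    spec = SyntheticSpec(seed=17)
    _, query, tables, profile = _aa_level_inputs(spec)
    rng = np.random.default_rng(99)
    base = SelectionCriteria(direction="toT")
    for _ in range(15):
        loose = dataclasses.replace(
            base,
            min_conservation_count=int(rng.integers(1, 12)),
            wild_delta_max=float(rng.uniform(-0.2, 0.4)),
            candidate_delta_min=float(rng.uniform(0.05, 0.8)),
        )
        tight = dataclasses.replace(
            loose,
            min_conservation_count=min(loose.min_conservation_count
                                       + int(rng.integers(0, 3)), 14),
            wild_delta_max=loose.wild_delta_max - float(rng.uniform(0, 0.3)),
            candidate_delta_min=loose.candidate_delta_min + float(rng.uniform(0, 0.3)),
        )
        loose_set = {c.position for c in
                     select_aa_level(query, tables, profile, loose).candidates}
        tight_set = {c.position for c in
                     select_aa_level(query, tables, profile, tight).candidates}
        assert tight_set <= loose_set


def test_direction_mirror_under_label_swap():
    spec = SyntheticSpec(seed=21, contact_dropout=0.0, background_mutation_prob=0.0)
    ds, query, tables, profile = _aa_level_inputs(spec)
    toT = select_aa_level(query, tables, profile, SelectionCriteria(direction="toT"))
    flip = {"H": "T", "T": "H"}
    for m in ds.labeled_models:
        m.group_label = flip[m.group_label]
    try:
        _, _, tables_sw, profile_sw = (None, None, None, None)
        prep = prepare(query, ds.labeled_models)
        qcm = build_contact_map(query)
        table_sw = build_shared_table(query, qcm, prep)
        tables_sw = full_enrichment_table(table_sw)
        profile_sw = conservation_profile(
            query, qcm, [p for p in prep if p[0].id != query.id])
        toH = select_aa_level(query, tables_sw, profile_sw,
                              SelectionCriteria(direction="toH"))
    finally:
        for m in ds.labeled_models:
            m.group_label = flip[m.group_label]
    assert [(c.position, c.proposed_aa) for c in toT.candidates] == [
        (c.position, c.proposed_aa) for c in toH.candidates
    ]


CENTRAL_SITES = tuple(default_planted_sites(1.0)) + (
    PlantedSite((29, 32), 29, "Y", "R", 1.0),
    PlantedSite((29, 32), 32, "Y", "R", 1.0),
)


def _pair_level_inputs():
    spec = SyntheticSpec(seed=9, planted_sites=CENTRAL_SITES,
                         contact_dropout=0.0, background_mutation_prob=0.0)
    ds, query, tables, profile = _aa_level_inputs(spec)
    g = build_graph(build_contact_map(query, 5.0, "all_atom", 0), query)
    return ds, query, tables, profile, betweenness(g)


def test_engineered_central_pair_ranked_first():
    ds, query, tables, profile, bet = _pair_level_inputs()
    crit = SelectionCriteria(direction="toT", pair_extreme_fraction=0.05)
    res = select_pair_level(query, tables, profile, bet, crit,
                            site=list(query.hetero_groups))
    assert res.candidates, "expected the planted central pair to qualify"
    assert {c.position for c in res.candidates} == {29, 32}
    assert all(c.proposed_aa == "Y" for c in res.candidates)
    assert all(c.betweenness_percentile >= 90.0 for c in res.candidates)


def test_low_betweenness_contacts_rejected():
    ds, query, tables, profile, bet = _pair_level_inputs()
    crit = SelectionCriteria(direction="toT", pair_extreme_fraction=0.05)
    res = select_pair_level(query, tables, profile, bet, crit)
    # the peripheral planted contact (1, 4) is enrichment-extreme but not central
    assert (1, "betweenness") in res.rejected


def test_explain_candidate_echoes_evidence():
    query, tables, profile = _toy_setup()
    crit = SelectionCriteria(direction="toT")
    res = select_aa_level(query, tables, profile, crit)
    text = explain_candidate(res.candidates[0], crit)
    assert "K1P" in text
    assert "+0.450" in text
    assert "14 / 14" in text


def test_ligand_contacting_candidates_demoted_not_removed():
    ds, query, tables, profile, bet = _pair_level_inputs()
    crit = SelectionCriteria(direction="toT", pair_extreme_fraction=0.05)
    res = select_pair_level(query, tables, profile, bet, crit,
                            site=list(query.hetero_groups))
    assert all(c.ligand_contact for c in res.candidates)  # demoted but present
    text = explain_candidate(res.candidates[0], crit)
    assert "demoted" in text


def test_criteria_validation():
    with pytest.raises(ValueError):
        SelectionCriteria(betweenness_fraction=0.0)
    with pytest.raises(ValueError):
        SelectionCriteria(min_conservation_count=20, dataset_size=14)
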