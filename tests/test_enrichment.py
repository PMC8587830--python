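"""Enrichment factors: arithmetic, normalisation, antisymmetry, planted signal."""

import numpy as np
import pytest

from contactdiff.contact_map import build_contact_map
from contactdiff.enrichment import (
    Observation,
    SharedContactTable,
    UndefinedFrequencyError,
    aa_frequencies,
    build_shared_table,
    enrichment_factor,
    full_enrichment_table,
    pair_enrichment_factor,
)
from contactdiff.pipeline import prepare
from contactdiff.seqalign import map_contact


def tiny_table(columns):
    """SharedContactTable over one contact (1, 4) from explicit columns.

    ``columns``: list of (member_id, group, status, aa_i, aa_j).
    """
    cells = {}
    groups = {}
    for mid, group, status, aa_i, aa_j in columns:
        groups[mid] = group
        obs = (
            Observation("shared", aa_i, aa_j)
            if status == "shared"
            else Observation(status)
        )
        cells[(mid, (1, 4))] = obs
    return SharedContactTable(
        ref_id=columns[0][0],
        contacts=((1, 4),),
        member_ids=tuple(c[0] for c in columns),
        groups=groups,
        cells=cells,
    )


def test_frequencies_over_sharing_members():
    t = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("t2", "T", "shared", "A", "G"),
        ("h1", "H", "shared", "A", "G"),
        ("h2", "H", "shared", "G", "G"),
    ])
    assert aa_frequencies(t, (1, 4), 1, "T") == {"A": 1.0}
    assert aa_frequencies(t, (1, 4), 1, "H") == {"A": 0.5, "G": 0.5}


def test_enrichment_factor_arithmetic():
    t = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("t2", "T", "shared", "A", "G"),
        ("h1", "H", "shared", "A", "G"),
        ("h2", "H", "shared", "G", "G"),
    ])
    e = enrichment_factor(t, (1, 4), 1, "A")
    assert e.delta == pytest.approx(1.0 - 0.5)
    assert (e.n_T, e.n_H) == (2, 1)
    # amino acid absent from both groups
    assert enrichment_factor(t, (1, 4), 1, "W").delta == 0.0


def test_pair_enrichment_extremes():
    t = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("t2", "T", "shared", "A", "G"),
        ("h1", "H", "shared", "C", "V"),
        ("h2", "H", "shared", "C", "V"),
    ])
    assert pair_enrichment_factor(t, (1, 4), ("A", "G")).delta_pair == 1.0
    # pair equally frequent in both groups
    t2 = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("h1", "H", "shared", "A", "G"),
    ])
    assert pair_enrichment_factor(t2, (1, 4), ("A", "G")).delta_pair == 0.0


def test_undefined_when_no_group_member_shares():
    t = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("h1", "H", "absent", None, None),
    ])
    with pytest.raises(UndefinedFrequencyError):
        aa_frequencies(t, (1, 4), 1, "H")
    tables = full_enrichment_table(t)
    assert tables.skipped and tables.skipped[0][0] == (1, 4)
    assert not tables.aa_entries


def test_x_occupancy_excluded_but_contact_not_invalidated():
    t = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("t2", "T", "shared", "X", "G"),
        ("h1", "H", "shared", "A", "G"),
    ])
    assert aa_frequencies(t, (1, 4), 1, "T") == {"A": 1.0}
    assert aa_frequencies(t, (1, 4), 4, "T") == {"G": 1.0}


def test_entry_count_for_two_observed_aa_per_endpoint():
    t = tiny_table([
        ("t1", "T", "shared", "A", "V"),
        ("h1", "H", "shared", "G", "L"),
    ])
    tables = full_enrichment_table(t)
    assert len(tables.aa_entries) == 4
    assert len(tables.pair_entries) == 2


def test_shared_table_statuses_match_per_contact_recheck(default_dataset):
    models = default_dataset.labeled_models[:6]
    ref = models[0]
    prep = prepare(ref, models)
    ref_cm = build_contact_map(ref)
    table = build_shared_table(ref, ref_cm, prep)
    for model, cm, pm in prep:
        for c in table.contacts:
            assert table.observation(model.id, c).status == map_contact(c, pm, cm)


def test_identical_target_shares_everything(default_dataset):
    ref = default_dataset.models[0]
    ref_cm = build_contact_map(ref)
    table = build_shared_table(ref, ref_cm, [])  # reference only
    for c in table.contacts:
        obs = table.observation(ref.id, c)
        assert obs.status == "shared"
        assert obs.aa_i == ref.residue(c[0]).aa1
        assert obs.aa_j == ref.residue(c[1]).aa1


def _full_tables(dataset):
    models = dataset.labeled_models
    ref = models[0]
    prep = prepare(ref, models)
    ref_cm = build_contact_map(ref)
    table = build_shared_table(ref, ref_cm, prep)
    return table, full_enrichment_table(table)


def test_frequency_normalisation_and_bounds(default_dataset):
    table, tables = _full_tables(default_dataset)
    frame = tables.aa_frame()
    assert ((frame["delta"] >= -1) & (frame["delta"] <= 1)).all()
    sums = frame.groupby(["ref_contact_i", "ref_contact_j", "endpoint"])[
        ["faa_T", "faa_H", "delta"]
    ].sum()
    assert np.allclose(sums["faa_T"], 1.0, atol=1e-12)
    assert np.allclose(sums["faa_H"], 1.0, atol=1e-12)
    assert np.allclose(sums["delta"], 0.0, atol=1e-12)


def test_label_swap_negates_all_deltas(default_dataset):
    table, tables = _full_tables(default_dataset)
    swapped = full_enrichment_table(table.with_swapped_labels())
    assert set(swapped.aa_delta) == set(tables.aa_delta)
    for key, delta in tables.aa_delta.items():
        assert swapped.aa_delta[key] == pytest.approx(-delta, abs=1e-15)
    for key, delta in tables.pair_delta.items():
        assert swapped.pair_delta[key] == pytest.approx(-delta, abs=1e-15)


def test_planted_signal_one_gives_unit_delta(default_dataset):
    _, tables = _full_tables(default_dataset)
    gt = default_dataset.ground_truth
    for key, deltas in gt["expected_delta"].items():
        contact_str, ep = key.split(":")
        i, j = map(int, contact_str.split(","))
        for aa, expected in deltas.items():
            assert tables.get_aa_delta((i, j), int(ep), aa) == pytest.approx(expected)


def test_frequencies_match_ground_truth_tallies(default_dataset):
    """Hand-count planted amino acids from the generator's bookkeeping."""
    table, _ = _full_tables(default_dataset)
    gt = default_dataset.ground_truth["proteins"]
    contact, endpoint = (1, 4), 1
    for group in ("T", "H"):
        expected = {}
        n = 0
        for mid, info in gt.items():
            if info["group"] != group:
                continue
            aa = info["planted_aa"][str(endpoint)]
            expected[aa] = expected.get(aa, 0) + 1
            n += 1
        freqs = aa_frequencies(table, contact, endpoint, group)
        assert freqs == {aa: c / n for aa, c in expected.items()}


def test_group_size_denominator_scales_frequencies():
    t = tiny_table([
        ("t1", "T", "shared", "A", "G"),
        ("t2", "T", "absent", None, None),
        ("h1", "H", "shared", "A", "G"),
    ])
    assert aa_frequencies(t, (1, 4), 1, "T")["A"] == 1.0
    assert aa_frequencies(t, (1, 4), 1, "T", denominator="group_size")["A"] == 0.5
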