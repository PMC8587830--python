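"""Shared fixtures: toy structures built by hand and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from contactdiff import SyntheticSpec, generate
from contactdiff.structure_io import Atom, Residue, StructureModel


def make_residue(name3, aa1, coords, chain="A", number=1, names=None):
    """Residue from a list of 3-vectors (fabricated geometry)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    names = names or [f"C{i}" for i in range(len(coords))]
    atoms = [Atom(name=n, element="C", coord=c) for n, c in zip(names, coords)]
    return Residue(chain_id=chain, author_number=number, icode="",
                   name3=name3, aa1=aa1, atoms=atoms)


def make_model(model_id, coords_per_residue, sequence=None, group="unknown"):
    """Structure whose residue i sits at the i-th coordinate block.

    Each block may be a single 3-vector (one CA atom) or an (n, 3) array.
    """
    seq = sequence or "A" * len(coords_per_residue)
    polymer = []
    for i, block in enumerate(coords_per_residue, start=1):
        block = np.atleast_2d(np.asarray(block, dtype=float))
        names = ["CA"] + [f"C{k}" for k in range(1, len(block))]
        polymer.append(make_residue("ALA", seq[i - 1], block, number=i, names=names))
    return StructureModel(id=model_id, polymer=polymer, group_label=group)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 4 T / 10 H, signal 1.0, 10% dropout."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def outgroup_dataset():
    return generate(SyntheticSpec(seed=2, unrelated_scaffold=True))


@pytest.fixture(scope="session")
def clean_dataset():
    """No dropout, no background mutations: fully deterministic signal."""
    return generate(SyntheticSpec(seed=5, contact_dropout=0.0,
                                  background_mutation_prob=0.0))
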