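"""Qualifying contacts and classifying enzymes from contact composition.

Each amino acid occupying a shared contact endpoint is qualified by the
sign of its enrichment factor: transglycosidic (T) when delta > 0,
hydrolytic (H) when delta < 0.  A contact is T only when both endpoints
are T, H only when both are H; otherwise it is mixed (opposite signs)
or unclassified (an endpoint with delta = 0 or never observed in
training).  Counting a protein's T and H contacts, normalised by its
number of shared contacts, places it in a 2D (H-fraction, T-fraction)
space where hydrolases and transglycosidases separate; prediction is by
nearest group centroid (a simple threshold rule on the T-fraction is
available as an alternative).
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .contact_map import ContactMap, build_contact_map
from .enrichment import (
    EnrichmentTables,
    SharedContactTable,
    build_shared_table,
    full_enrichment_table,
)
from .pipeline import prepare as _prepare
from .seqalign import AlignParams
from .structure_io import StructureModel

__all__ = [
    "ClassificationRecord",
    "DegenerateRecordError",
    "qualify_residue",
    "qualify_contact",
    "count_contacts",
    "fit_centroids",
    "classify_enzyme",
    "classify_dataset",
    "leave_one_out",
    "evaluate_holdout",
    "accuracy",
]

Mode = Literal["aa", "pair"]


class DegenerateRecordError(ValueError):
    """The protein shares no contact with the reference."""


def qualify_residue(delta: float) -> str:
    """T if delta > 0, H if delta < 0, unclassified at exactly 0."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    if delta > 0:
        return "T"
    if delta < 0:
        return "H"
    return "unclassified"


def qualify_contact(q_i: str, q_j: str) -> str:
    """T iff both T; H iff both H; unclassified dominates; else mixed."""
    if "unclassified" in (q_i, q_j):
        return "unclassified"
    if q_i == q_j:
        return q_i
    return "mixed"


@dataclasses.dataclass
class ClassificationRecord:
    protein_id: str
    n_T: int
    n_H: int
    n_other: int  # mixed + unclassified
    n_not_shared: int
    truth: str = "unknown"
    predicted: str | None = None

    @property
    def n_shared(self) -> int:
        return self.n_T + self.n_H + self.n_other

    def normalized(self) -> tuple[float, float]:
        """(H-fraction, T-fraction) of the protein's shared contacts."""
        if self.n_shared == 0:
            raise DegenerateRecordError(f"{self.protein_id} shares no contacts")
        return (self.n_H / self.n_shared, self.n_T / self.n_shared)


def count_contacts(
    protein_id: str,
    observations: SharedContactTable,
    tables: EnrichmentTables,
    mode: Mode = "aa",
) -> ClassificationRecord:
    """Tally T / H / other contacts of one protein against the reference frame.

    ``observations`` provides the protein's per-contact status and
    occupying amino acids; ``tables`` provides enrichment fitted on a
    (possibly different) labeled training set.  In pair mode a contact
    is qualified by the sign of the pair enrichment of its observed
    amino-acid pair.
    """
    n_T = n_H = n_other = n_not_shared = 0
    for c in observations.contacts:
        obs = observations.observation(protein_id, c)
        if obs.status != "shared":
            n_not_shared += 1
            continue
        if mode == "aa":
            di = tables.get_aa_delta(c, c[0], obs.aa_i)
            dj = tables.get_aa_delta(c, c[1], obs.aa_j)
            q = qualify_contact(
                qualify_residue(di if di is not None else 0.0),
                qualify_residue(dj if dj is not None else 0.0),
            )
        else:
            dp = tables.get_pair_delta(c, (obs.aa_i, obs.aa_j))
            q = qualify_residue(dp if dp is not None else 0.0)
        if q == "T":
            n_T += 1
        elif q == "H":
            n_H += 1
        else:
            n_other += 1
    rec = ClassificationRecord(
        protein_id=protein_id,
        n_T=n_T,
        n_H=n_H,
        n_other=n_other,
        n_not_shared=n_not_shared,
        truth=observations.groups.get(protein_id, "unknown"),
    )
    if rec.n_shared == 0:
        raise DegenerateRecordError(f"{protein_id} shares no contacts with {observations.ref_id}")
    return rec


def fit_centroids(records: Sequence[ClassificationRecord]) -> dict[str, tuple[float, float]]:
    """Per-group mean of normalised (H-fraction, T-fraction)."""
    pts: dict[str, list[tuple[float, float]]] = {}
    for r in records:
        if r.truth in ("H", "T"):
            pts.setdefault(r.truth, []).append(r.normalized())
    if set(pts) != {"H", "T"}:
        raise ValueError("training records must include both H and T proteins")
    return {g: tuple(np.mean(v, axis=0)) for g, v in pts.items()}


def classify_enzyme(
    record: ClassificationRecord,
    centroids: dict[str, tuple[float, float]],
    rule: Literal["centroid", "threshold"] = "centroid",
    t_threshold: float = 0.5,
) -> str:
    """Predict H or T; centroid ties resolve to H (the majority class)."""
    h_frac, t_frac = record.normalized()
    if rule == "threshold":
        denom = record.n_T + record.n_H
        if denom == 0:
            return "H"
        return "T" if record.n_T / denom > t_threshold else "H"
    dH = (h_frac - centroids["H"][0]) ** 2 + (t_frac - centroids["H"][1]) ** 2
    dT = (h_frac - centroids["T"][0]) ** 2 + (t_frac - centroids["T"][1]) ** 2
    return "T" if dT < dH else "H"


def classify_dataset(
    ref: StructureModel,
    models: Sequence[StructureModel],
    cutoff: float = 5.0,
    scheme: str = "all_atom",
    min_separation: int = 2,
    mode: Mode = "aa",
    align_params: AlignParams | None = None,
    rule: Literal["centroid", "threshold"] = "centroid",
) -> pd.DataFrame:
    """Fit enrichment + centroids on the full labeled dataset and classify it."""
    prepared = _prepare(ref, models, cutoff, scheme, min_separation, align_params)
    ref_cm = build_contact_map(ref, cutoff, scheme, min_separation)
    table = build_shared_table(ref, ref_cm, prepared)
    tables = full_enrichment_table(table)
    records = [count_contacts(m.id, table, tables, mode) for m in models]
    centroids = fit_centroids(records)
    for r in records:
        r.predicted = classify_enzyme(r, centroids, rule=rule)
    return _records_frame(records)


def _records_frame(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.protein_id,
                "n_T": r.n_T,
                "n_H": r.n_H,
                "n_other": r.n_other,
                "n_not_shared": r.n_not_shared,
                "predicted": r.predicted,
                "truth": r.truth,
            }
            for r in records
        ]
    )


def leave_one_out(
    ref: StructureModel,
    models: Sequence[StructureModel],
    cutoff: float = 5.0,
    scheme: str = "all_atom",
    min_separation: int = 2,
    mode: Mode = "aa",
    align_params: AlignParams | None = None,
    rule: Literal["centroid", "threshold"] = "centroid",
) -> pd.DataFrame:
    """Leave-one-out evaluation: enrichment and centroids refitted per fold.

    The reference always provides the contact frame; when the reference
    itself is held out it is excluded from the frequency counts of that
    fold but still defines the contacts.
    """
    prepared = _prepare(ref, models, cutoff, scheme, min_separation, align_params)
    ref_cm = build_contact_map(ref, cutoff, scheme, min_separation)
    full = build_shared_table(ref, ref_cm, prepared)
    records: list[ClassificationRecord] = []
    for held in models:
        fold_members = [p for p in prepared if p[0].id != held.id]
        fold_table = build_shared_table(
            ref, ref_cm, fold_members, include_reference=(held.id != ref.id)
        )
        tables = full_enrichment_table(fold_table)
        train_records = [
            count_contacts(m.id, full, tables, mode)
            for m, _, _ in fold_members
        ]
        centroids = fit_centroids(train_records)
        rec = count_contacts(held.id, full, tables, mode)
        rec.predicted = classify_enzyme(rec, centroids, rule=rule)
        records.append(rec)
    return _records_frame(records)


def evaluate_holdout(
    ref: StructureModel,
    train: Sequence[StructureModel],
    test: Sequence[StructureModel],
    cutoff: float = 5.0,
    scheme: str = "all_atom",
    min_separation: int = 2,
    mode: Mode = "aa",
    align_params: AlignParams | None = None,
    rule: Literal["centroid", "threshold"] = "centroid",
) -> pd.DataFrame:
    """Fit on train, predict test; train/test ids must be disjoint.

    The reference (which anchors the contact frame) must belong to the
    training set.
    """
    overlap = {m.id for m in train} & {m.id for m in test}
    if overlap:
        raise ValueError(f"train/test ids overlap: {sorted(overlap)}")
    if ref.id not in {m.id for m in train}:
        raise ValueError("reference must be part of the training set")
    ref_cm = build_contact_map(ref, cutoff, scheme, min_separation)
    train_prep = _prepare(ref, train, cutoff, scheme, min_separation, align_params)
    test_prep = _prepare(ref, test, cutoff, scheme, min_separation, align_params)
    train_table = build_shared_table(ref, ref_cm, train_prep)
    tables = full_enrichment_table(train_table)
    train_records = [count_contacts(m.id, train_table, tables, mode) for m in train]
    centroids = fit_centroids(train_records)
    test_table = build_shared_table(ref, ref_cm, test_prep, include_reference=False)
    test_records = []
    for m in test:
        rec = count_contacts(m.id, test_table, tables, mode)
        rec.predicted = classify_enzyme(rec, centroids, rule=rule)
        test_records.append(rec)
    return _records_frame(test_records)


def accuracy(frame: pd.DataFrame) -> float:
    """Fraction of rows whose prediction matches an H/T truth label."""
    labeled = frame[frame["truth"].isin(["H", "T"])]
    if labeled.empty:
        raise ValueError("no labeled rows")
    return float((labeled["predicted"] == labeled["truth"]).mean())
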