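"""Contact conservation profiles and the contact-similarity coefficient.

The conservation score of a reference contact is the fraction of
dataset proteins (reference included) in which the aligned residue pair
is also a contact.  Plotting one protein's conservation scores against
another's, over the contacts they share, yields a squared Pearson
correlation r^2 — the contact-similarity coefficient.  Within a family
this coefficient is high; proteins from unrelated folds show markedly
lower values, which makes the all-against-all similarity matrix usable
for flagging family outliers.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contact_map import ContactMap, build_contact_map
from .seqalign import AlignParams, PositionMap, align_pair, identity_map
from .structure_io import StructureModel

__all__ = [
    "ConservationProfile",
    "SimilarityResult",
    "conservation_profile",
    "similarity_coefficient",
    "similarity_matrix",
]

Contact = tuple[int, int]


@dataclasses.dataclass
class ConservationProfile:
    ref_id: str
    n_dataset: int  # N, reference included
    n_sharing: dict[Contact, int]
    status: dict[Contact, dict[str, int]]  # per contact: counts of shared/absent/unalignable

    def score(self, contact: Contact) -> float:
        return self.n_sharing[contact] / self.n_dataset

    def scores(self) -> dict[Contact, float]:
        return {c: n / self.n_dataset for c, n in self.n_sharing.items()}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"i": c[0], "j": c[1], "n_sharing": n, "score": n / self.n_dataset}
                for c, n in sorted(self.n_sharing.items())
            ]
        )


def conservation_profile(
    ref: StructureModel,
    ref_cm: ContactMap,
    dataset: Sequence[tuple[StructureModel, ContactMap, PositionMap]],
) -> ConservationProfile:
    """Count, per reference contact, how many dataset members share it.

    The reference counts itself (every score is at least 1/N), so
    profiles are comparable across choices of reference.  ``dataset``
    must not contain the reference; N = len(dataset) + 1.
    """
    n_sharing = {c: 1 for c in ref_cm.contacts}  # the reference shares its own contacts
    status = {c: {"shared": 1, "absent": 0, "unalignable": 0} for c in ref_cm.contacts}
    for model, cm, pm in dataset:
        if model.id == ref.id:
            raise ValueError("dataset must exclude the reference itself")
        lookup = pm.as_dict()
        for c in ref_cm.contacts:
            mi, mj = lookup.get(c[0]), lookup.get(c[1])
            if mi is None or mj is None:
                status[c]["unalignable"] += 1
            elif (min(mi, mj), max(mi, mj)) in cm.contacts:
                status[c]["shared"] += 1
                n_sharing[c] += 1
            else:
                status[c]["absent"] += 1
    return ConservationProfile(
        ref_id=ref.id,
        n_dataset=len(dataset) + 1,
        n_sharing=n_sharing,
        status=status,
    )


@dataclasses.dataclass(frozen=True)
class SimilarityResult:
    n_points: int
    r: float | None
    r_squared: float | None

    @property
    def defined(self) -> bool:
        return self.r_squared is not None


def similarity_coefficient(
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    cm_b: ContactMap,
    pm_ab: PositionMap,
) -> SimilarityResult:
    """Pearson correlation of conservation scores over contacts shared by A and B.

    Points are the contacts of A whose mapped pair is a contact of B
    (intersection; unalignable or absent contacts are dropped, never
    imputed).  Undefined with fewer than 3 points or zero variance.
    """
    lookup = pm_ab.as_dict()
    xs, ys = [], []
    for c, score_a in profile_a.scores().items():
        mi, mj = lookup.get(c[0]), lookup.get(c[1])
        if mi is None or mj is None:
            continue
        pair = (min(mi, mj), max(mi, mj))
        if pair in cm_b.contacts and pair in profile_b.n_sharing:
            xs.append(score_a)
            ys.append(profile_b.score(pair))
    n = len(xs)
    if n < 3:
        return SimilarityResult(n_points=n, r=None, r_squared=None)
    x, y = np.asarray(xs), np.asarray(ys)
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        # identical constant vectors: perfectly similar profiles
        return SimilarityResult(n_points=n, r=1.0, r_squared=1.0)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return SimilarityResult(n_points=n, r=None, r_squared=None)
    r = float(stats.pearsonr(x, y).statistic)
    return SimilarityResult(n_points=n, r=r, r_squared=r * r)


def similarity_matrix(
    models: Sequence[StructureModel],
    cutoff: float = 5.0,
    scheme: str = "all_atom",
    min_separation: int = 2,
    align_params: AlignParams | None = None,
) -> pd.DataFrame:
    """All-against-all contact-similarity coefficients (r^2); diagonal 1.

    Every protein serves once as the reference for its own conservation
    profile over the whole dataset; profiles are then correlated for
    each ordered pair.  Undefined pairs are NaN.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 proteins")
    cms = {m.id: build_contact_map(m, cutoff, scheme, min_separation) for m in models}
    pms: dict[tuple[str, str], PositionMap] = {}
    for a in models:
        for b in models:
            if a.id == b.id:
                pms[(a.id, b.id)] = identity_map(a.id, b.id, len(a))
            else:
                pms[(a.id, b.id)] = align_pair(
                    a.sequence, b.sequence, align_params, ref_id=a.id, tgt_id=b.id
                )
    profiles = {
        a.id: conservation_profile(
            a, cms[a.id], [(b, cms[b.id], pms[(a.id, b.id)]) for b in models if b.id != a.id]
        )
        for a in models
    }
    ids = [m.id for m in models]
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a in models:
        for b in models:
            if a.id == b.id:
                mat.loc[a.id, b.id] = 1.0
                continue
            res = similarity_coefficient(
                profiles[a.id], profiles[b.id], cms[b.id], pms[(a.id, b.id)]
            )
            if res.defined:
                mat.loc[a.id, b.id] = res.r_squared
    # report the symmetrised coefficient: A->B and B->A use the same point set
    # up to alignment asymmetries; average removes any residual asymmetry
    sym = (mat + mat.T) / 2.0
    return sym
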