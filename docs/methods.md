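# Methods

## Model and assumptions

`contactdiff` treats an enzyme as a single polymer chain with a set of
residue–residue contacts, and a family of enzymes as a labelled sample
from two functional groups (hydrolases H, transglycosidases T). The core
statistic is a per-contact frequency difference: for a contact endpoint
of a reference protein, the frequency of each amino acid among the
group members *sharing* that contact is computed separately for T and H,
and their difference Δf = f_T − f_H is the enrichment factor. Pair-level
enrichment does the same for the ordered amino-acid pair occupying the
contact.

Assumptions baked into this model:

- **Monomer, one chain.** Multi-chain files are reduced to one selected
  chain ("auto" = the chain with most amino-acid residues, ties by chain
  id). Quaternary contacts are invisible by design.
- **Contacts are binary and geometric.** A pair is a contact iff its
  minimum interatomic distance is ≤ the cutoff (inclusive). No weights,
  no probabilistic contacts.
- **Groups are exchangeable samples.** No phylogenetic down-weighting of
  redundant sequences and no pseudocounts; with small groups the
  frequencies are coarse (multiples of 1/n) and Δ values are similarly
  quantised. Both corrections are listed as future work.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| contact cutoff | 5.0 (enrichment), 6.0 (pair/network) | Å | the two standard parameterisations (`analysis1` / `analysis2` profiles) |
| atom scheme | all_atom | — | all atoms of polymer residues, hydrogens included when present |
| min_separation | 2 | residues | excludes i,i+1 pairs, which are contacts in every protein and carry no group signal; 0 restores strict map-viewer behaviour |
| gap open / extend | 10 / 0.5, BLOSUM62 | score | EMBOSS-needle-style global alignment defaults |
| min_conservation_count | 10 (of 14) | proteins | a candidate site must sit in a contact shared by ≥ 10 dataset enzymes |
| wild_delta_max | 0.0 | Δ | wild residue must not already be enriched toward the target group (−0.2 available as the stricter reading) |
| candidate_delta_min | 0.2 | Δ | proposed residue must be clearly enriched |
| pair_extreme_fraction | 0.01 | — | pair-level candidates must sit in the extreme tails of the global pair-Δ distribution |
| betweenness_fraction | 0.10 | — | both endpoints must rank in the top betweenness decile (0.20 is the documented looser alternative) |

## Decisions where the design was genuinely open

- **Frequency denominator.** Frequencies are conditional on the contact
  being shared (denominator = sharing group members), which makes each
  endpoint's frequency vector sum to 1 and hence Σ_aa Δ = 0 per endpoint.
  The alternative (total group size) is available via
  `denominator="group_size"`; it shrinks Δ magnitudes for poorly shared
  contacts and breaks the sum-to-zero property.
- **The reference counts itself** both in enrichment (member of its own
  group) and in conservation (a contact unique to the reference scores
  1/N, never 0), keeping profiles comparable across references.
- **Betweenness.** "Paths" are shortest paths (the standard definition);
  pairs are unordered, endpoints excluded, values unnormalised. The
  implementation is Brandes' accumulation algorithm, with correctness
  anchored in tests to an exhaustive shortest-path enumeration oracle
  (and cross-checked against networkx, which is otherwise used only as a
  graph container).
- **Classification rule.** The groups separate in the normalised
  (H-fraction, T-fraction) plane; prediction is nearest group centroid
  (Euclidean), ties to H, the majority class in the motivating datasets.
  A plain threshold on the T-fraction is available (`rule="threshold"`).
  An amino acid never observed in training has Δ = 0 and its contact is
  left unclassified — never extrapolated.
- **Similarity over the intersection.** The similarity coefficient
  correlates conservation scores over contacts present in both proteins;
  absent/unalignable contacts are dropped, not imputed. Fewer than 3
  common points, or zero variance on one axis only, is reported as
  undefined (NaN in the matrix). When ranking proteins by mean
  off-diagonal similarity (outlier detection), undefined is treated as 0:
  a pair that shares too few contacts to correlate is maximally
  dissimilar for this purpose.
- **Selection ranking** (enrichment gain, then conservation, then
  distance from the active site, ligand-contacting positions demoted) is
  this package's own convention; the criteria define a pass/fail set but
  no ordering on their own.
- **Conservation threshold reading.** "Above 10 of 14" is implemented as
  count ≥ 10 (inclusive); the knob is exposed for the strict reading.
- **Pair extremes** are taken over the global distribution of pair-Δ
  values, not per contact.

## Numerical choices

- Cutoffs are inclusive (distance ≤ cutoff). Contact maps via a KD-tree
  over atom coordinates, verified against the O(L²) scan in tests.
- Alignment ties are resolved deterministically by taking the aligner's
  first optimal alignment; supplying a curated FASTA alignment
  (`load_alignment`) overrides the built-in aligner and is the
  recommended route for reproducing published analyses.
- Altloc duplicates resolve to the highest occupancy (ties: first in
  file); first model only for multi-model files; waters dropped; hetero
  groups kept from all chains since ligands often sit in their own chain.
- Modified residues with a standard parent (MSE→M etc.) keep their
  parent code; others become 'X' — retained for contact geometry,
  excluded from frequency counting.
- Degenerate inputs fail loudly: empty chains, contacts shared by no
  member of a group (skip-listed with a reason), proteins sharing zero
  contacts, similarity with < 3 points.

## The synthetic generator

The generator emulates the *statistical* structure the method assumes,
not protein physics:

- A 60-residue scaffold along a gently curved arc (CA spacing 3.8 Å,
  radius 100 Å) with one pseudo side-chain atom per residue. Fifteen
  designed contacts (i, i+3) on disjoint residue quartets are switched
  on by raising the two side-chain pseudo-atoms toward each other; the
  realised 5 Å map of every emitted protein is verified against the
  intended set at generation time.
- Default conditions mirror the motivating study: 4 T vs 10 H proteins,
  full-strength signal (p = 1.0) planted at both endpoints of 5
  contacts, 10% per-protein dropout of non-planted contacts, a shared
  consensus sequence mutated at 10% per position.
- Planted sites: a group-G protein carries the group's amino acid with
  probability p, otherwise a uniform draw from all 20. Closed form:
  E[f_T(aa_T)] = p + (1−p)/20, E[f_H(aa_T)] = (1−p)/20, so E[Δ(aa_T)] = p
  exactly (and −p for aa_H). This is what `expected_enrichment` returns
  and what the replicate tests converge to.
- The optional outgroup ("OUT01") uses a different scaffold curve with a
  shifted contact topology and a random sequence, standing in for
  family-outlier structures: its contacts barely map onto the family's,
  so its similarity coefficients are undefined-or-low and it ranks last.
- Amino-acid identity lives in the residue name, not the geometry, so
  sequence signal and contact geometry vary independently.

What passing tests on this generator do **not** show: robustness to real
structural noise (loop flexibility, missing density, alternate
conformations), to imperfect alignments between genuinely divergent
folds, or to phylogenetic correlation within groups. Real datasets mix
all three; the generator isolates the counting, normalisation and
selection logic from them.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so a
full pass stays in the minutes range on one CPU: 14-protein datasets on
60-residue scaffolds, 50 seeded datasets for normalisation checks,
100–200 replicates for stochastic convergence, 200–500 random graphs
(≤ 8 nodes) for the betweenness oracle, 20–25 random threshold grids for
selection monotonicity.

## Known limitations

- Two functional groups only; no multi-class extension.
- No combinatorial multi-site optimisation and no stability (ΔΔG)
  screening of proposed substitutions.
- Frequencies from small groups are coarse; Δ thresholds (0.2, 1%) are
  conventions, not significance levels — no multiple-testing control is
  attempted.
- External aligners (structural alignment, curated MSAs) are consumed,
  never re-implemented; the built-in pairwise aligner is a fallback, and
  results can differ between the two routes for divergent sequences.
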