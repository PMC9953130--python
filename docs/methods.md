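# Methods

## Scope and model

`pharmscreen` implements the hit-identification stage of a structure-based
pharmacophore workflow: contact analysis of inhibitor-bound complexes,
hypothesis generation and merging, hybrid-model construction on key
active-site residues, library screening by rigid feature mapping, and
decoy-set validation. Docking, molecular dynamics, binding free-energy
estimation and ADMET prediction are deliberately out of scope; the ADMET
stage of the screening funnel is a pluggable predicate that defaults to
pass-all, and conformers are inputs (multi-record SDF), not generated.

## Contact detection

Hydrogen bonds are evaluated on a dual criterion with defaults
`D···A ≤ 3.5 Å`, `H···A ≤ 2.9 Å`, `∠D–H···A ≥ 120°`. Because PDB inputs
usually lack hydrogens, the donor H is idealized at 1.01 Å along the
reversed bisector of the donor's covalent bonds; explicit H atoms, when
present, are used as-is, and a donor with no resolvable H direction falls
back to the heavy-atom distance criterion alone. The reported distance is
H···A whenever an H was placed, else D···A. Protein donor/acceptor typing
follows standard residue chemistry (backbone N donates, backbone O accepts,
ambivalent hydroxyls appear on both sides); ligand N/O atoms are treated as
donor-capable unless fully substituted, and N/O/S as acceptor-capable.
Carbon hydrogen bonds (C–H donors at a relaxed 3.8 Å cutoff) can be
detected on request but never count toward the key-residue hit criterion,
which mirrors how such contacts are reported separately from conventional
hydrogen bonds.

Hydrophobic contacts pair apolar ligand atoms (C/S/halogen with no bonded
N/O) or all-carbon ring centroids with apolar protein side-chain atoms
within 4.5 Å; contacts with one aromatic partner are labeled `pi_alkyl`,
with two `pi_pi`. Residues within 4.0 Å that carry no classified contact
are listed as van der Waals neighbors. All cutoffs are arguments, not
constants, since the reference assignments they emulate come from software
whose exact thresholds are not published. Contacts are ordered by
(residue number, distance) so reports are reproducible byte for byte.

## Pharmacophore generation, merging, hybrid

One deterministic hypothesis is generated per complex, directly from its
interaction report: ligand atoms accepting an H-bond become HBA features
projected toward the protein donor, donating atoms become HBD features,
hydrophobic ligand units (rings/chains) with at least one contact become
HYP features at their centroid, and formally charged atoms become PI/NI.
The commercial tool this emulates samples ten hypotheses per structure and
has an undisclosed ranking; a single deterministic hypothesis per complex
is used here because the merged endpoint is what the pipeline consumes and
determinism is what makes the artifact testable.

Tolerance radii default to 1.6 Å for centers and 2.2 Å for projected
points (common defaults for this model class; the reference software does
not document its radii) and are overridable everywhere.

Merging applies complete-linkage clustering per feature kind with a 1.5 Å
radius: each cluster collapses to the unweighted mean center, the maximum
member tolerance, and the deterministically sorted union of residue
annotations and sources. Kinds never merge across. The hybrid construction
then keeps at most one HBA/HBD feature per (kind, key residue) pair —
ties broken by smallest tolerance, then input order — plus the `keep_hyp`
hydrophobes supported by the most source structures. With the two
single-structure reference compositions (8 features: 3 HBD/2 HBA/2 HYP/1 PI;
7 features: 4 HYP/2 HBD/1 HBA) and key residues {T205, A208, D270}, this
yields the published five-feature hybrid: three H-bond anchors plus two
hydrophobes.

Models serialize to a small JSON schema (`id`, `frame`, `provenance`,
`features[{kind, center, tolerance, projected, residue, source}]`) with a
lossless round-trip.

## Mapping and fit score

Mapping a conformer onto a model searches kind-compatible injective
assignments of model features to perceived ligand feature points,
pruned by pairwise distance consistency
(`|d_model(i,j) − d_ligand(i,j)| ≤ tol_i + tol_j`), refines every surviving
assignment by Kabsch least-squares superposition, and accepts when each
matched displacement fits its tolerance sphere, allowing up to `max_omit`
unmatched features. The fit score is `Σ_f w_f (1 − (d_f / tol_f)²)` —
1 per feature at a perfect hit, 0 at the boundary. The commercial FitValue
formula is unpublished, so only ranking *within* this package is claimed.
The pruned search is property-tested against exhaustive enumeration of all
correspondences on small cases. Ties are resolved by (higher fit, fewer
omissions, lexicographically smallest correspondence). Projected points are
only scored when `require_projected` is set, because ligand H positions are
frequently absent.

Ligand feature perception: HBD at N/O with ≥ 1 explicit-or-implicit H; HBA
at N/O excluding amide and aniline-type nitrogens and nitro oxygens; HYP at
centroids of all-carbon rings and apolar chains of ≥ 3 contiguous carbons;
PI at formally positive atoms and aliphatic amines; NI at formally negative
atoms. The same rules drive the Lipinski donor/acceptor counts so the
filter and the mapper never disagree about chemistry.

## Validation statistics

`compute_stats` validates the count invariants (including
`Ht − Ha ≤ D − A`, without which the GH penalty term leaves [0, 1]) and
evaluates GH and EF at full precision; report formatting rounds to two
decimals. Degenerate screens (`Ht = 0`, `A = 0`, `D = A`) return 0 for the
affected quantities with a warning rather than raising, since empty
retrievals are legitimate outcomes of strict models.

## Synthetic data

`make_toy_complex` plants pseudo-residues (3–4 atoms) on well-separated
directions (cube corners, then face centers — pairwise ≥ 54.7°, so planted
sites can never cross-contaminate at the default cutoffs) around a
star-shaped ligand: protein-donor sites put a backbone N at D···A = 2.9 Å
from a ligand O with ideal angle, ligand-donor sites invert the roles, and
hydrophobic sites put a side-chain carbon at 4.0 Å from a lone apolar
ligand carbon. Every planned role therefore yields exactly one contact
under the default criteria, which is what the detector recovery tests and
the rigid-invariance properties assert.

`make_labeled_library` emulates the decoy-set *structure* of a kinase
validation set — 20 actives below 100 nM and 120 inactives above 1000 nM by
default — not any real compound collection. Actives realize every model
feature within `tolerance × margin_in` (default 0.4; this bound keeps even
the worst-case least-squares redistribution of per-feature error inside the
tolerance spheres for models up to ~6 features). Decoys displace one
feature group by at least `tolerance + margin_out` (default 1 Å); because a
single planted violation is not in general sufficient to defeat every
alternative same-kind correspondence after rigid refitting, the generator
verifies each decoy against the mapper and enlarges the displacement until
it provably fails in every conformer. Tests re-confirm decoy rejection with
the independent brute-force oracle. Additional conformers are rigid copies,
so labels are conformer-invariant by construction. Pseudo-molecules use
minimal chemically plausible topologies (hub-and-spoke with hexagonal
hydrophobes) and are valid SDF V2000; they are geometric probes, not
chemistry models, so perception subtleties of real molecules (tautomers,
charge states, fused rings) are *not* exercised by them — the perception
rules are instead tested on real SMILES-derived molecules.

All generators take one explicit seed and use a single `numpy` generator
per call; identical inputs give bit-identical outputs.

## Problem sizes and limitations

The default test and pipeline runs use the 140-compound synthetic library,
models of ≤ 7 features and pockets of ≤ 14 sites; oracle-equivalence suites
run on ~100 random ≤ 6-feature models. These sizes were chosen so the full
suite completes in well under a minute while still exercising every branch
of the search. Known limitations: no excluded-volume or shape constraints;
no water-mediated bridges, salt-bridge or halogen-bond taxonomies; mmCIF
and protonation-state assignment are out of scope; screening of
multi-million-compound vendor databases is untested at that scale; and the
AlogP fallback (Wildman–Crippen) is not bit-compatible with the proprietary
descriptor, which is why precomputed values in SDF properties take
precedence.
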