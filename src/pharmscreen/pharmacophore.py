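"""Receptor–ligand pharmacophore generation, merging, and the hybrid model.

A hypothesis is derived deterministically from a complex's interaction
report: ligand atoms accepting a hydrogen bond become HBA features with a
projected point toward the protein donor, donating atoms become HBD features
projected toward the protein acceptor, apolar rings/chains with hydrophobic
contacts become HYP features at their centroid, and charged groups become
PI/NI features. Features carry the complementary protein residue as an
annotation, which is what the hybrid construction keys on.

Default tolerance radii are 1.6 Å for feature centers and 2.2 Å for
projected points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .structio import (ProteinLigandComplex, RigidTransform, SchemaError,
                       superpose_points)
from .interactions import InteractionReport

__all__ = [
    "PharmacophoreFeature", "PharmacophoreModel", "generate_model",
    "merge_models", "align_frames", "build_hybrid",
    "CENTER_TOLERANCE", "PROJECTED_TOLERANCE",
]

CENTER_TOLERANCE = 1.6
PROJECTED_TOLERANCE = 2.2

FEATURE_KINDS = ("HBA", "HBD", "HYP", "PI", "NI", "RA")
_ANNOTATION_SEP = "|"


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One typed feature: a center with a tolerance sphere.

    HBA/HBD features may carry a projected point (direction toward the
    complementary protein atom); other kinds never do.
    """

    kind: str
    center: tuple[float, float, float]
    tolerance: float = CENTER_TOLERANCE
    projected_point: tuple[float, float, float] | None = None
    projected_tolerance: float = PROJECTED_TOLERANCE
    residue_annotation: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.projected_point is not None and self.kind not in ("HBA", "HBD"):
            raise ValueError(f"{self.kind} features cannot carry a projected point")
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))
        if self.projected_point is not None:
            object.__setattr__(self, "projected_point",
                               tuple(float(x) for x in self.projected_point))

    @property
    def center_array(self) -> np.ndarray:
        return np.array(self.center)

    def residues(self) -> tuple[str, ...]:
        if not self.residue_annotation:
            return ()
        return tuple(self.residue_annotation.split(_ANNOTATION_SEP))

    def sources(self) -> tuple[str, ...]:
        if not self.source:
            return ()
        return tuple(self.source.split(_ANNOTATION_SEP))

    def transformed(self, rt: RigidTransform) -> "PharmacophoreFeature":
        proj = None if self.projected_point is None else \
            tuple(rt.apply(np.array(self.projected_point)))
        return replace(self, center=tuple(rt.apply(self.center_array)),
                       projected_point=proj)


@dataclass
class PharmacophoreModel:
    """A set of features expressed in one reference complex's frame."""

    id: str
    features: list[PharmacophoreFeature] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    frame: str | None = None

    def transformed(self, rt: RigidTransform) -> "PharmacophoreModel":
        return PharmacophoreModel(self.id,
                                  [f.transformed(rt) for f in self.features],
                                  list(self.provenance), self.frame)

    def kind_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.kind] = counts.get(f.kind, 0) + 1
        return counts

    # -- JSON schema ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "frame": self.frame,
            "provenance": list(self.provenance),
            "features": [
                {
                    "kind": f.kind,
                    "center": list(f.center),
                    "tolerance": f.tolerance,
                    "projected": None if f.projected_point is None else
                        {"point": list(f.projected_point),
                         "tolerance": f.projected_tolerance},
                    "residue": f.residue_annotation,
                    "source": f.source,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PharmacophoreModel":
        for key in ("id", "frame", "provenance", "features"):
            if key not in doc:
                raise SchemaError(f"model JSON missing field {key!r}")
        feats = []
        for i, fd in enumerate(doc["features"]):
            for key in ("kind", "center", "tolerance", "projected",
                        "residue", "source"):
                if key not in fd:
                    raise SchemaError(
                        f"feature {i}: missing field {key!r}")
            proj = fd["projected"]
            try:
                feats.append(PharmacophoreFeature(
                    kind=fd["kind"],
                    center=tuple(fd["center"]),
                    tolerance=float(fd["tolerance"]),
                    projected_point=None if proj is None
                        else tuple(proj["point"]),
                    projected_tolerance=PROJECTED_TOLERANCE if proj is None
                        else float(proj["tolerance"]),
                    residue_annotation=fd["residue"],
                    source=fd["source"],
                ))
            except (TypeError, ValueError, KeyError) as exc:
                raise SchemaError(f"feature {i}: {exc}") from None
        return cls(id=doc["id"], features=feats,
                   provenance=list(doc["provenance"]), frame=doc["frame"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, PharmacophoreModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_model(cx: ProteinLigandComplex,
                   report: InteractionReport,
                   center_tolerance: float = CENTER_TOLERANCE,
                   projected_tolerance: float = PROJECTED_TOLERANCE
                   ) -> PharmacophoreModel:
    """Derive one deterministic pharmacophore hypothesis from a complex.

    The hypothesis places complementary features on the ligand side of every
    classified contact in ``report`` and annotates each with its protein
    partner residue.
    """
    lig = cx.ligand_coords()
    prot_by_key = {(a.residue_code, a.name): a for a in cx.protein_atoms}
    features: list[PharmacophoreFeature] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()

    for c in report.hbonds:
        if c.kind != "hbond":
            continue
        kind = "HBA" if c.donor_side == "protein" else "HBD"
        key = (kind, c.ligand_atom_indices)
        if key in seen or not c.ligand_atom_indices:
            continue
        seen.add(key)
        center = lig[c.ligand_atom_indices[0]]
        partner = prot_by_key.get((c.protein_residue, c.protein_atom))
        proj = tuple(partner.coords) if partner is not None else None
        features.append(PharmacophoreFeature(
            kind, tuple(center), center_tolerance, proj,
            projected_tolerance, c.protein_residue, cx.id))

    # hydrophobic units: one HYP per ligand ring/chain with >=1 contact
    unit_contacts: dict[tuple[int, ...], list] = {}
    for c in report.pi + report.hydrophobic:
        unit_contacts.setdefault(c.ligand_atom_indices, []).append(c)
    for unit, contacts in sorted(unit_contacts.items()):
        if not unit:
            continue
        centroid = lig[list(unit)].mean(axis=0)
        res = sorted({c.protein_residue for c in contacts},
                     key=lambda r: min(cc.distance for cc in contacts
                                       if cc.protein_residue == r))
        features.append(PharmacophoreFeature(
            "HYP", tuple(centroid), center_tolerance, None,
            projected_tolerance, _ANNOTATION_SEP.join(res), cx.id))

    # ionizable groups from ligand formal charges
    for i, a in enumerate(cx.ligand_atoms):
        if a.formal_charge > 0:
            features.append(PharmacophoreFeature(
                "PI", tuple(lig[i]), center_tolerance, None,
                projected_tolerance, None, cx.id))
        elif a.formal_charge < 0:
            features.append(PharmacophoreFeature(
                "NI", tuple(lig[i]), center_tolerance, None,
                projected_tolerance, None, cx.id))

    return PharmacophoreModel(id=f"{cx.id}-hypothesis", features=features,
                              provenance=[cx.id], frame=cx.id)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_models(models: list[PharmacophoreModel],
                 cluster_radius: float = 1.5,
                 merged_id: str = "merged") -> PharmacophoreModel:
    """Merge same-kind features lying within ``cluster_radius``.

    Complete-linkage clustering per feature kind; each cluster is replaced by
    one feature at the unweighted mean center with tolerance = max of the
    members and deterministically joined annotations. Features of different
    kinds never merge.
    """
    if not models:
        raise ValueError("need at least one model to merge")
    all_feats = [f for m in models for f in m.features]
    provenance = sorted({p for m in models for p in m.provenance})
    frame = models[0].frame

    merged: list[PharmacophoreFeature] = []
    for kind in FEATURE_KINDS:
        group = [f for f in all_feats if f.kind == kind]
        if not group:
            continue
        merged.extend(_cluster_group(group, cluster_radius))
    merged.sort(key=lambda f: (FEATURE_KINDS.index(f.kind), f.center))
    return PharmacophoreModel(merged_id, merged, provenance, frame)


def _cluster_group(group: list[PharmacophoreFeature],
                   radius: float) -> list[PharmacophoreFeature]:
    if len(group) == 1:
        return list(group)
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    centers = np.array([f.center for f in group])
    labels = fcluster(linkage(pdist(centers), method="complete"),
                      t=radius, criterion="distance")
    out = []
    for lab in sorted(set(labels)):
        members = [f for f, l in zip(group, labels) if l == lab]
        if len(members) == 1:
            out.append(members[0])
            continue
        center = tuple(np.mean([m.center for m in members], axis=0))
        tolerance = max(m.tolerance for m in members)
        annotations = sorted({r for m in members for r in m.residues()})
        sources = sorted({s for m in members for s in m.sources()})
        projs = [np.array(m.projected_point) for m in members
                 if m.projected_point is not None]
        proj = tuple(np.mean(projs, axis=0)) if projs else None
        proj_tol = max((m.projected_tolerance for m in members
                        if m.projected_point is not None),
                       default=PROJECTED_TOLERANCE)
        out.append(PharmacophoreFeature(
            members[0].kind, center, tolerance, proj, proj_tol,
            _ANNOTATION_SEP.join(annotations) or None,
            _ANNOTATION_SEP.join(sources) or None))
    return out


# ---------------------------------------------------------------------------
# frame alignment
# ---------------------------------------------------------------------------

def align_frames(ref: ProteinLigandComplex, mobile: ProteinLigandComplex,
                 site_residues: list[str] | None = None
                 ) -> tuple[RigidTransform, float]:
    """Transform mapping ``mobile`` onto ``ref`` via binding-site backbone.

    Backbone atoms (N, CA, C) of residues matched by residue number are
    superposed by least squares. ``site_residues`` restricts the match to
    the given residue codes (e.g. ``["T205", "A208"]``); by default all
    shared residue numbers are used. At least 3 matched residues required.
    """
    wanted: set[int] | None = None
    if site_residues is not None:
        wanted = {int("".join(ch for ch in r if ch.isdigit()))
                  for r in site_residues}

    def backbone(cx: ProteinLigandComplex) -> dict[tuple[int, str], np.ndarray]:
        out = {}
        for a in cx.protein_atoms:
            if a.name in ("N", "CA", "C") and a.residue_number is not None:
                if wanted is None or a.residue_number in wanted:
                    out[(a.residue_number, a.name)] = a.coords
        return out

    ref_bb = backbone(ref)
    mob_bb = backbone(mobile)
    shared = sorted(set(ref_bb) & set(mob_bb))
    matched_residues = {num for num, _ in shared}
    if len(matched_residues) < 3:
        raise ValueError(
            f"need >=3 shared site residues with backbone atoms, "
            f"got {len(matched_residues)}")
    P = np.array([ref_bb[k] for k in shared])
    Q = np.array([mob_bb[k] for k in shared])
    return superpose_points(P, Q)


# ---------------------------------------------------------------------------
# hybrid construction
# ---------------------------------------------------------------------------

def build_hybrid(model: PharmacophoreModel, keep_residues: set[str],
                 keep_hyp: int = 2,
                 hybrid_id: str = "hybrid") -> PharmacophoreModel:
    """Retain key-residue H-bond features plus the best-supported HYPs.

    Keeps (a) HBA/HBD features annotated with a residue in ``keep_residues``,
    at most one per (kind, residue) pair (ties: smallest tolerance, then
    input order), and (b) the ``keep_hyp`` HYP features supported by the most
    source structures (ties: smallest tolerance, then input order). All other
    features, including ionizable ones, are dropped.
    """
    chosen: dict[tuple[str, str], PharmacophoreFeature] = {}
    order: dict[int, int] = {id(f): i for i, f in enumerate(model.features)}
    for f in model.features:
        if f.kind not in ("HBA", "HBD"):
            continue
        for res in f.residues():
            if res not in keep_residues:
                continue
            key = (f.kind, res)
            prev = chosen.get(key)
            if prev is None or (f.tolerance, order[id(f)]) < \
                    (prev.tolerance, order[id(prev)]):
                chosen[key] = f

    hyps = [f for f in model.features if f.kind == "HYP"]
    hyps.sort(key=lambda f: (-len(f.sources()), f.tolerance, order[id(f)]))
    kept_hyps = hyps[:keep_hyp]

    unmet = set(keep_residues) - {res for _, res in chosen}
    if unmet:
        warnings.warn(f"no annotated H-bond feature for residues: "
                      f"{sorted(unmet)}")

    kept = [f for f in model.features
            if f in set(chosen.values()) or f in kept_hyps]
    return PharmacophoreModel(hybrid_id, kept, list(model.provenance),
                              model.frame)
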