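"""Protein–ligand contact detection, interaction reports, key-residue filter.

Hydrogen bonds are detected from heavy-atom geometry with idealized donor-H
placement: when explicit hydrogens are absent, the D–H vector is taken along
the reversed bisector of the donor's covalent bonds. A contact is accepted
when D···A <= max_da_dist AND, whenever an H position (explicit or idealized)
is available, H···A <= max_ha_dist and the D–H···A angle >= min_dha_angle.

Hydrophobic contacts pair apolar ligand atoms/rings with apolar protein
side-chain atoms; ring-involved contacts are classified pi_alkyl (one aromatic
partner) or pi_pi (both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import AtomRecord, ProteinLigandComplex, HALOGENS

__all__ = [
    "HBondCriteria", "Contact", "InteractionReport", "KeyResidueSet",
    "detect_hbonds", "detect_hydrophobic", "build_report",
    "key_contact_filter", "hbond_target_matrix",
]

# protein H-bond chemistry: backbone N donates, backbone O accepts; side
# chains per standard residue chemistry (ambivalent hydroxyls appear in both)
PROTEIN_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("LYS", "NZ"), ("TRP", "NE1"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
PROTEIN_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("MET", "SD"), ("HIS", "ND1"), ("HIS", "NE2"),
}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

#: aromatic side-chain ring atoms, for pi contact classification
AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

_DH_LENGTH = 1.01  # idealized donor-H bond length, Å
_COVALENT_CUTOFF = 1.8  # heavy-atom covalent neighbor search, Å


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds for hydrogen bonds."""

    max_da_dist: float = 3.5
    max_ha_dist: float = 2.9
    min_dha_angle: float = 120.0

    def __post_init__(self) -> None:
        if min(self.max_da_dist, self.max_ha_dist, self.min_dha_angle) <= 0:
            raise ValueError("all criteria must be positive")
        if self.max_ha_dist > self.max_da_dist:
            raise ValueError("max_ha_dist must not exceed max_da_dist")


@dataclass(frozen=True)
class Contact:
    """One classified protein–ligand interaction."""

    kind: str  # hbond | carbon_hbond | vdw | pi_alkyl | pi_pi | hydrophobic
    protein_residue: str  # e.g. "A208"
    protein_atom: str
    ligand_atom: str
    distance: float
    angle: float | None = None
    donor_side: str | None = None  # "protein" | "ligand" (hbond kinds only)
    residue_number: int = 0
    ligand_atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.kind == "hbond" and not (self.protein_atom and self.ligand_atom):
            raise ValueError("hbond contacts need both atom names")


@dataclass
class InteractionReport:
    """Per-complex interaction summary (one report row per contact class)."""

    complex_id: str
    hbonds: list[Contact] = field(default_factory=list)
    pi: list[Contact] = field(default_factory=list)
    hydrophobic: list[Contact] = field(default_factory=list)
    vdw_residues: list[str] = field(default_factory=list)

    @property
    def pi_residues(self) -> list[str]:
        return sorted({c.protein_residue for c in self.pi},
                      key=lambda r: _residue_sort_key(r))

    def to_frame(self) -> pd.DataFrame:
        """Tabular report with the interaction-table column names."""
        rows = []
        for c in self.hbonds + self.pi + self.hydrophobic:
            rows.append({
                "Name": self.complex_id,
                "Interaction": c.kind,
                "Amino Acid": c.protein_residue,
                "Amino Acid Atom": c.protein_atom,
                "Ligand Atom": c.ligand_atom,
                "Distance": round(c.distance, 2),
            })
        for r in self.vdw_residues:
            rows.append({"Name": self.complex_id, "Interaction": "vdw",
                         "Amino Acid": r, "Amino Acid Atom": "",
                         "Ligand Atom": "", "Distance": float("nan")})
        return pd.DataFrame(rows)


def _residue_sort_key(code: str) -> tuple[int, str]:
    digits = "".join(ch for ch in code if ch.isdigit())
    return (int(digits) if digits else 0, code)


@dataclass(frozen=True)
class KeyResidueSet:
    """Key active-site residues and the minimum H-bonded count for a hit.

    Defaults target the kinase gatekeeper (T205), hinge (A208) and DFG motif
    aspartate (D270): a compound passes when it hydrogen-bonds at least
    ``min_hbonds`` distinct members.
    """

    residues: frozenset[str] = frozenset({"T205", "A208", "D270"})
    min_hbonds: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(self.residues))
        if self.min_hbonds > len(self.residues):
            raise ValueError("min_hbonds cannot exceed the number of residues")


# ---------------------------------------------------------------------------
# donor / acceptor typing
# ---------------------------------------------------------------------------

def _protein_is_donor(a: AtomRecord) -> bool:
    if a.name == "N" and a.residue_name.upper() != "PRO":
        return True
    return (a.residue_name.upper(), a.name) in PROTEIN_SIDECHAIN_DONORS


def _protein_is_acceptor(a: AtomRecord) -> bool:
    if a.name in ("O", "OXT"):
        return True
    return (a.residue_name.upper(), a.name) in PROTEIN_SIDECHAIN_ACCEPTORS


def _ligand_neighbor_indices(cx: ProteinLigandComplex, idx: int) -> list[int]:
    out = [j for i, j, _ in cx.ligand_bonds if i == idx]
    out += [i for i, j, _ in cx.ligand_bonds if j == idx]
    return sorted(set(out))


def _ligand_donor_capable(cx: ProteinLigandComplex, idx: int) -> bool:
    """N/O (donor candidates); explicit H settles it, else assume capable."""
    a = cx.ligand_atoms[idx]
    if a.element not in ("N", "O"):
        return False
    nbrs = _ligand_neighbor_indices(cx, idx)
    h_nbrs = [j for j in nbrs if cx.ligand_atoms[j].element == "H"]
    if h_nbrs:
        return True
    heavy = [j for j in nbrs if cx.ligand_atoms[j].element != "H"]
    # a fully substituted N/O (>=3 / >=2 heavy neighbors) cannot donate
    max_heavy = 2 if a.element == "N" else 1
    return len(heavy) <= max_heavy


def _ligand_acceptor_capable(cx: ProteinLigandComplex, idx: int) -> bool:
    return cx.ligand_atoms[idx].element in ("N", "O", "S")


def _idealized_h_direction(donor: np.ndarray,
                           heavy_neighbors: list[np.ndarray]) -> np.ndarray | None:
    """Unit D->H direction along the reversed bisector of covalent bonds."""
    if not heavy_neighbors:
        return None
    acc = np.zeros(3)
    for nb in heavy_neighbors:
        v = donor - nb
        norm = np.linalg.norm(v)
        if norm > 1e-9:
            acc += v / norm
    n = np.linalg.norm(acc)
    return acc / n if n > 1e-9 else None


def _protein_heavy_neighbors(cx: ProteinLigandComplex,
                             donor: AtomRecord) -> list[np.ndarray]:
    out = []
    for a in cx.protein_atoms:
        if a is donor or a.element == "H":
            continue
        if np.linalg.norm(a.coords - donor.coords) <= _COVALENT_CUTOFF:
            out.append(a.coords)
    return out


def _protein_explicit_hs(cx: ProteinLigandComplex,
                         donor: AtomRecord) -> list[np.ndarray]:
    out = []
    for a in cx.protein_atoms:
        if a.element == "H" and \
                np.linalg.norm(a.coords - donor.coords) <= 1.3:
            out.append(a.coords)
    return out


def _hbond_geometry(donor: np.ndarray, acceptor: np.ndarray,
                    h_positions: list[np.ndarray],
                    h_direction: np.ndarray | None,
                    crit: HBondCriteria) -> tuple[bool, float, float | None]:
    """Evaluate the dual distance/angle criterion.

    Returns (accepted, reported_distance, angle). The reported distance is
    H···A when an H is placed, else heavy-atom D···A.
    """
    da = float(np.linalg.norm(acceptor - donor))
    if da > crit.max_da_dist:
        return False, da, None
    if not h_positions and h_direction is not None:
        h_positions = [donor + _DH_LENGTH * h_direction]
    if not h_positions:
        return True, da, None  # no H information: distance criterion only
    best = None
    for h in h_positions:
        ha = float(np.linalg.norm(acceptor - h))
        v1 = donor - h
        v2 = acceptor - h
        cosang = float(v1 @ v2 /
                       (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12))
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if ha <= crit.max_ha_dist and angle >= crit.min_dha_angle:
            if best is None or ha < best[0]:
                best = (ha, angle)
    if best is None:
        return False, da, None
    return True, best[0], best[1]


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_hbonds(cx: ProteinLigandComplex,
                  crit: HBondCriteria | None = None,
                  include_carbon: bool = False) -> list[Contact]:
    """Detect hydrogen bonds in both directions (protein↔ligand).

    Each (protein atom, ligand atom) pair yields at most one contact; when
    both directions satisfy the criteria, the protein-donor reading is kept.
    Results are sorted by (residue number, distance). With
    ``include_carbon=True``, C–H donors are additionally paired with
    acceptors at a relaxed heavy-atom cutoff of 3.8 Å and labeled
    ``carbon_hbond`` (excluded from key-residue counting downstream).
    """
    crit = crit or HBondCriteria()
    lig_coords = cx.ligand_coords()
    contacts: dict[tuple[str, int, str], Contact] = {}

    lig_heavy = [i for i, a in enumerate(cx.ligand_atoms) if a.element != "H"]
    lig_h_of = {i: [j for j in _ligand_neighbor_indices(cx, i)
                    if cx.ligand_atoms[j].element == "H"] for i in lig_heavy}

    def lig_h_positions(idx: int) -> tuple[list[np.ndarray], np.ndarray | None]:
        hs = [lig_coords[j] for j in lig_h_of[idx]]
        if hs:
            return hs, None
        heavy = [lig_coords[j] for j in _ligand_neighbor_indices(cx, idx)
                 if cx.ligand_atoms[j].element != "H"]
        return [], _idealized_h_direction(lig_coords[idx], heavy)

    for p in cx.protein_atoms:
        if p.element == "H":
            continue
        p_donor = _protein_is_donor(p)
        p_acceptor = _protein_is_acceptor(p)
        if not (p_donor or p_acceptor):
            continue
        for li in lig_heavy:
            la = cx.ligand_atoms[li]
            d_heavy = float(np.linalg.norm(p.coords - la.coords))
            if d_heavy > crit.max_da_dist:
                continue
            key = (p.residue_code, li, p.name)
            accepted = None
            # protein donor -> ligand acceptor
            if p_donor and _ligand_acceptor_capable(cx, li):
                hs = _protein_explicit_hs(cx, p)
                hdir = None if hs else _idealized_h_direction(
                    p.coords, _protein_heavy_neighbors(cx, p))
                ok, dist, ang = _hbond_geometry(p.coords, la.coords, hs,
                                                hdir, crit)
                if ok:
                    accepted = Contact("hbond", p.residue_code, p.name,
                                       la.name, dist, ang, "protein",
                                       p.residue_number or 0, (li,))
            # ligand donor -> protein acceptor
            if accepted is None and p_acceptor and _ligand_donor_capable(cx, li):
                hs, hdir = lig_h_positions(li)
                ok, dist, ang = _hbond_geometry(la.coords, p.coords, hs,
                                                hdir, crit)
                if ok:
                    accepted = Contact("hbond", p.residue_code, p.name,
                                       la.name, dist, ang, "ligand",
                                       p.residue_number or 0, (li,))
            if accepted is not None and key not in contacts:
                contacts[key] = accepted

    out = list(contacts.values())
    if include_carbon:
        out.extend(_detect_carbon_hbonds(cx, lig_heavy, lig_coords))
    out.sort(key=lambda c: (c.residue_number, c.distance, c.protein_atom,
                            c.ligand_atom))
    return out


def _detect_carbon_hbonds(cx: ProteinLigandComplex, lig_heavy, lig_coords,
                          cutoff: float = 3.8) -> list[Contact]:
    out = []
    for p in cx.protein_atoms:
        if not _protein_is_acceptor(p):
            continue
        for li in lig_heavy:
            la = cx.ligand_atoms[li]
            if la.element != "C":
                continue
            d = float(np.linalg.norm(p.coords - la.coords))
            if 0 < d <= cutoff:
                out.append(Contact("carbon_hbond", p.residue_code, p.name,
                                   la.name, d, None, "ligand",
                                   p.residue_number or 0, (li,)))
    return out


def _ligand_apolar_atoms(cx: ProteinLigandComplex) -> list[int]:
    """C/S/halogen ligand atoms with no covalently attached polar atom."""
    out = []
    for i, a in enumerate(cx.ligand_atoms):
        if a.element not in ({"C", "S"} | HALOGENS):
            continue
        nbr_elems = {cx.ligand_atoms[j].element
                     for j in _ligand_neighbor_indices(cx, i)}
        if nbr_elems & {"N", "O"}:
            continue
        out.append(i)
    return out


def _ligand_rings(cx: ProteinLigandComplex) -> list[tuple[int, ...]]:
    """All-carbon rings in the ligand bond graph (cycle basis)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(cx.ligand_atoms)))
    g.add_edges_from((i, j) for i, j, _ in cx.ligand_bonds)
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if 4 <= len(cycle) <= 8 and all(
                cx.ligand_atoms[i].element == "C" for i in cycle):
            rings.append(tuple(sorted(cycle)))
    return rings


def _protein_apolar_atoms(cx: ProteinLigandComplex) -> list[AtomRecord]:
    return [a for a in cx.protein_atoms
            if a.element in ("C", "S") and a.name not in BACKBONE_NAMES]


def _is_aromatic_protein_atom(a: AtomRecord) -> bool:
    return a.name in AROMATIC_RING_ATOMS.get(a.residue_name.upper(), ())


def detect_hydrophobic(cx: ProteinLigandComplex,
                       cutoff: float = 4.5) -> list[Contact]:
    """Detect hydrophobic / pi_alkyl / pi_pi contacts.

    Apolar ligand rings are represented by their centroid; one contact is
    kept per (ligand unit, protein residue) pair, at the minimum distance.
    """
    lig_coords = cx.ligand_coords()
    rings = _ligand_rings(cx)
    ring_members = {i for ring in rings for i in ring}
    apolar = [i for i in _ligand_apolar_atoms(cx) if i not in ring_members]
    prot = _protein_apolar_atoms(cx)

    best: dict[tuple[str, str], Contact] = {}

    def consider(unit_label: str, unit_indices: tuple[int, ...],
                 pos: np.ndarray, lig_is_ring: bool) -> None:
        for p in prot:
            d = float(np.linalg.norm(p.coords - pos))
            if d > cutoff or d <= 0:
                continue
            prot_ring = _is_aromatic_protein_atom(p)
            if lig_is_ring and prot_ring:
                kind = "pi_pi"
            elif lig_is_ring or prot_ring:
                kind = "pi_alkyl"
            else:
                kind = "hydrophobic"
            key = (unit_label, p.residue_code)
            c = Contact(kind, p.residue_code, p.name, unit_label, d, None,
                        None, p.residue_number or 0, unit_indices)
            if key not in best or d < best[key].distance:
                best[key] = c

    for ring in rings:
        centroid = lig_coords[list(ring)].mean(axis=0)
        label = cx.ligand_atoms[ring[0]].name + "-ring"
        consider(label, ring, centroid, True)
    for i in apolar:
        consider(cx.ligand_atoms[i].name, (i,), lig_coords[i], False)

    out = sorted(best.values(),
                 key=lambda c: (c.residue_number, c.distance, c.ligand_atom))
    return out


def build_report(cx: ProteinLigandComplex,
                 crit: HBondCriteria | None = None,
                 hydrophobic_cutoff: float = 4.5,
                 vdw_cutoff: float = 4.0,
                 include_carbon: bool = False) -> InteractionReport:
    """Build the full per-complex interaction report.

    Hydrogen bonds and hydrophobic-class contacts come from the detectors;
    any remaining residue with a heavy atom within ``vdw_cutoff`` of the
    ligand is listed as a van der Waals residue.
    """
    hb = detect_hbonds(cx, crit, include_carbon=include_carbon)
    hydro = detect_hydrophobic(cx, hydrophobic_cutoff)
    pi = [c for c in hydro if c.kind in ("pi_alkyl", "pi_pi")]
    plain = [c for c in hydro if c.kind == "hydrophobic"]

    classified = {c.protein_residue for c in hb} \
        | {c.protein_residue for c in hydro}
    lig = cx.ligand_coords()
    vdw = {}
    for a in cx.protein_atoms:
        if a.element == "H" or a.residue_code in classified:
            continue
        dmin = float(np.min(np.linalg.norm(lig - a.coords, axis=1)))
        if dmin <= vdw_cutoff:
            prev = vdw.get(a.residue_code)
            if prev is None or dmin < prev[1]:
                vdw[a.residue_code] = (a.residue_number or 0, dmin)
    vdw_residues = sorted(vdw, key=lambda r: (vdw[r][0], r))
    return InteractionReport(cx.id, hb, pi, plain, vdw_residues)


def key_contact_filter(report: InteractionReport,
                       keys: KeyResidueSet | None = None) -> bool:
    """True iff >= min_hbonds distinct key residues carry a conventional hbond."""
    keys = keys or KeyResidueSet()
    bonded = {c.protein_residue for c in report.hbonds if c.kind == "hbond"}
    return len(bonded & keys.residues) >= keys.min_hbonds


def hbond_target_matrix(complexes: list[ProteinLigandComplex],
                        residues: list[str],
                        crit: HBondCriteria | None = None) -> pd.DataFrame:
    """Residue × complex boolean H-bond matrix (interaction fingerprint).

    Cell (residue, complex) is True iff the complex has at least one
    conventional hydrogen bond to that residue.
    """
    if not complexes:
        raise ValueError("need at least one complex")
    data = {}
    for cx in complexes:
        bonded = {c.protein_residue for c in detect_hbonds(cx, crit)}
        data[cx.id] = [r in bonded for r in residues]
    return pd.DataFrame(data, index=residues)
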