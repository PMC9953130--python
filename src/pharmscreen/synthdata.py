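"""Synthetic fixtures: toy binding pockets and labeled conformer libraries.

The pocket generator plants pseudo-residues (3–4 atoms each) around a
star-shaped ligand so that every planned hydrogen-bond role yields exactly
one geometry satisfying the default criteria and every hydrophobic role
exactly one contact within the cutoff. The library generator emulates the
statistical structure of a kinase decoy set — by default 20 actives
(pseudo-IC50 < 100 nM) and 120 inactives (> 1000 nM) — by realizing each
model feature within a controlled fraction of its tolerance for actives and
planting a geometric violation for decoys.

All generators are pure functions of (spec, seed): one explicit seeded
random generator per call, never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structio import Atom, AtomRecord, ONE_TO_THREE, ProteinLigandComplex, \
    SmallMolecule
from .pharmacophore import PharmacophoreModel
from .screening import MappingParams, map_conformer
from .validation import DecoyLabels

__all__ = [
    "PocketSpec", "LibrarySpec", "GroundTruth",
    "make_toy_complex", "make_labeled_library", "perturb_conformer",
]

ROLES = ("hbond_donor", "hbond_acceptor", "hydrophobic")

# site geometry (Å along the site direction): margins inside the default
# detection criteria so small coordinate noise does not flip detections
_LIG_R = 3.5        # ligand interaction atom radius
_DON_R = 6.4        # protein donor/acceptor heavy atom (D···A = 2.9)
_HYD_R = 7.5        # protein apolar atom for hydrophobic roles (d = 4.0)

#: well-separated unit directions: cube corners then face centers (14 sites)
_DIRECTIONS = [np.array(v) / np.linalg.norm(v) for v in (
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1),
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)]


@dataclass(frozen=True)
class PocketSpec:
    """Plan for a toy binding pocket."""

    residue_plan: tuple[tuple[str, str], ...]
    noise_sigma: float = 0.0
    seed: int = 0
    #: optional explicit site slots in the shared direction table, so pockets
    #: built for different "structures" live in one common frame
    site_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_plan", tuple(
            (str(c), str(r)) for c, r in self.residue_plan))
        codes = [c for c, _ in self.residue_plan]
        if len(set(codes)) != len(codes):
            raise ValueError("residue codes must be unique")
        for _, role in self.residue_plan:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.site_indices is not None:
            object.__setattr__(self, "site_indices",
                               tuple(int(i) for i in self.site_indices))
            if len(self.site_indices) != len(self.residue_plan):
                raise ValueError("site_indices must match the residue plan")
            if len(set(self.site_indices)) != len(self.site_indices):
                raise ValueError("site indices must be unique")


@dataclass(frozen=True)
class LibrarySpec:
    """Plan for a labeled multi-conformer library.

    Actives realize every model feature within tolerance * margin_in in at
    least one conformer; decoys violate at least one feature by at least
    margin_out Å beyond its tolerance in every conformer.
    """

    n_active: int = 20
    n_decoy: int = 120
    margin_in: float = 0.4
    margin_out: float = 1.0
    conformers: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.margin_in < 1):
            raise ValueError("margin_in must be in (0, 1)")
        if self.margin_out <= 0:
            raise ValueError("margin_out must be positive")
        if self.n_active < 0 or self.n_decoy < 0 or self.conformers < 1:
            raise ValueError("counts must be non-negative, conformers >= 1")


@dataclass
class GroundTruth:
    """Generator-side record of a molecule's intended behavior."""

    name: str
    label: str
    ic50_nM: float
    violated_feature: int | None = None
    displacements: dict[int, float] = field(default_factory=dict)


def _parse_code(code: str) -> tuple[str, int]:
    one = code[0].upper()
    number = int(code[1:])
    return ONE_TO_THREE.get(one, "GLY"), number


# ---------------------------------------------------------------------------
# toy pockets
# ---------------------------------------------------------------------------

def make_toy_complex(spec: PocketSpec) -> ProteinLigandComplex:
    """Build a pocket whose contacts exactly realize the residue plan."""
    k = len(spec.residue_plan)
    if k == 0:
        raise ValueError("residue plan is empty")
    slots = spec.site_indices if spec.site_indices is not None \
        else tuple(range(k))
    if max(slots, default=0) >= len(_DIRECTIONS) or k > len(_DIRECTIONS):
        raise ValueError(
            f"infeasible plan: sites would overlap "
            f"(at most {len(_DIRECTIONS)} slots supported)")
    rng = np.random.default_rng(spec.seed)

    ligand_atoms: list[AtomRecord] = []
    ligand_bonds: list[tuple[int, int, int]] = []
    protein_atoms: list[AtomRecord] = []

    hub = AtomRecord("C", "C1", "LIG", 900, "A", np.zeros(3), is_hetero=True)
    ligand_atoms.append(hub)

    def add_prot(element: str, name: str, resname: str, resnum: int,
                 pos: np.ndarray) -> None:
        protein_atoms.append(AtomRecord(element, name, resname, resnum,
                                        "A", pos))

    for site, (code, role) in enumerate(spec.residue_plan):
        u = _DIRECTIONS[slots[site]]
        resname, resnum = _parse_code(code)
        lig_pos = _LIG_R * u
        lat = _lateral(u)  # unit vector orthogonal to the site direction
        if role == "hbond_donor":
            # protein backbone N donates to a ligand acceptor oxygen
            lig = AtomRecord("O", f"O{site + 2}", "LIG", 900, "A", lig_pos,
                             is_hetero=True)
            add_prot("N", "N", resname, resnum, _DON_R * u)
            add_prot("C", "CA", resname, resnum, (_DON_R + 1.5) * u)
            add_prot("C", "C", resname, resnum,
                     (_DON_R + 2.3) * u + 1.0 * lat)
        elif role == "hbond_acceptor":
            # ligand donor nitrogen (H idealized away from the hub) donates
            # to a protein backbone carbonyl oxygen
            lig = AtomRecord("N", f"N{site + 2}", "LIG", 900, "A", lig_pos,
                             is_hetero=True)
            add_prot("O", "O", resname, resnum, _DON_R * u)
            add_prot("C", "C", resname, resnum, (_DON_R + 1.2) * u)
            add_prot("C", "CA", resname, resnum,
                     (_DON_R + 2.4) * u + 1.0 * lat)
        else:  # hydrophobic: lone apolar ligand carbon near a side-chain C
            lig = AtomRecord("C", f"C{site + 2}", "LIG", 900, "A", lig_pos,
                             is_hetero=True)
            add_prot("C", "CD1", resname, resnum, _HYD_R * u)
            add_prot("C", "CB", resname, resnum,
                     (_HYD_R + 1.3) * u + 0.8 * lat)
            add_prot("C", "CA", resname, resnum, (_HYD_R + 2.5) * u)
        ligand_atoms.append(lig)
        ligand_bonds.append((0, len(ligand_atoms) - 1, 1))

    cx = ProteinLigandComplex(
        id=f"toy-{spec.seed}", protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms, ligand_bonds=ligand_bonds,
        ligand_id="LIG")
    if spec.noise_sigma > 0:
        for a in cx.protein_atoms + cx.ligand_atoms:
            a.coords = a.coords + rng.normal(0.0, spec.noise_sigma, 3)
    return cx


def _lateral(u: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(u @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, probe)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# labeled libraries
# ---------------------------------------------------------------------------

_HEX_RADIUS = 1.4  # planted six-carbon ring radius, Å


def make_labeled_library(model: PharmacophoreModel, spec: LibrarySpec
                         ) -> tuple[list[SmallMolecule], DecoyLabels,
                                    list[GroundTruth]]:
    """Generate a labeled decoy-set library around a pharmacophore model.

    Each active realizes every model feature within tolerance * margin_in;
    each decoy carries one feature displaced beyond tolerance + margin_out
    (enlarged if necessary until the mapper provably rejects it in every
    conformer). Pseudo-IC50s are drawn below/above the 100/1000 nM label
    thresholds. Deterministic under the given seed.
    """
    if not model.features:
        raise ValueError("model has no features")
    rng = np.random.default_rng(spec.seed)
    molecules: list[SmallMolecule] = []
    truths: list[GroundTruth] = []
    labels: dict[str, str] = {}

    for i in range(spec.n_active):
        name = f"active_{i:03d}"
        disp = {fi: float(rng.uniform(0.0, f.tolerance * spec.margin_in))
                for fi, f in enumerate(model.features)}
        mol = _build_molecule(model, disp, {}, name, rng, spec.conformers)
        ic50 = float(10.0 ** rng.uniform(0.0, 1.95))  # < 100 nM
        mol.properties["ic50_nM"] = f"{ic50:.3f}"
        molecules.append(mol)
        labels[name] = "active"
        truths.append(GroundTruth(name, "active", ic50, None, disp))

    for i in range(spec.n_decoy):
        name = f"decoy_{i:03d}"
        violated = int(rng.integers(0, len(model.features)))
        disp = {fi: float(rng.uniform(0.0, f.tolerance * spec.margin_in))
                for fi, f in enumerate(model.features)}
        mol, delta = _build_rejected_decoy(model, disp, violated, name, rng,
                                           spec)
        ic50 = float(10.0 ** rng.uniform(3.05, 5.0))  # > 1000 nM
        mol.properties["ic50_nM"] = f"{ic50:.3f}"
        molecules.append(mol)
        labels[name] = "inactive"
        gt_disp = dict(disp)
        gt_disp[violated] = delta
        truths.append(GroundTruth(name, "inactive", ic50, violated, gt_disp))

    return molecules, DecoyLabels(labels), truths


def _build_rejected_decoy(model, disp, violated, name, rng, spec
                          ) -> tuple[SmallMolecule, float]:
    """Plant the violation, enlarging it until mapping provably fails."""
    feat = model.features[violated]
    delta = feat.tolerance + spec.margin_out
    direction = _unit(rng.normal(size=3))
    params = MappingParams(max_omit=0)
    for _attempt in range(12):
        mol = _build_molecule(model, disp, {violated: delta * direction},
                              name, rng, spec.conformers)
        if all(map_conformer(mol, ci, model, params) is None
               for ci in range(len(mol.conformers))):
            return mol, delta
        delta *= 1.6
    raise RuntimeError(f"could not construct unmappable decoy {name!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _build_molecule(model: PharmacophoreModel, disp: dict[int, float],
                    offsets: dict[int, np.ndarray], name: str,
                    rng: np.random.Generator,
                    n_conformers: int) -> SmallMolecule:
    """Star molecule realizing each feature at center + displacement."""
    atoms: list[Atom] = [Atom("C", 0, 0)]  # hub
    bonds: list[tuple[int, int, int]] = []
    centers = np.array([f.center for f in model.features])
    coords: list[np.ndarray] = [centers.mean(axis=0)]

    for fi, feat in enumerate(model.features):
        target = np.array(feat.center) + disp[fi] * _unit(rng.normal(size=3))
        if fi in offsets:
            target = np.array(feat.center) + offsets[fi]
        anchor = len(atoms)
        if feat.kind == "HBA":
            atoms.append(Atom("O", 0, 0))
            coords.append(target)
        elif feat.kind == "HBD":
            atoms.append(Atom("O", 0, 1))
            coords.append(target)
        elif feat.kind == "PI":
            atoms.append(Atom("N", 1, 2))
            coords.append(target)
        elif feat.kind == "NI":
            atoms.append(Atom("O", -1, 0))
            coords.append(target)
        else:  # HYP (and RA): planted all-carbon hexagon, centroid on target
            e1 = _lateral(_unit(rng.normal(size=3)))
            e2 = np.cross(_unit(rng.normal(size=3)), e1)
            e2 = _unit(e2) if np.linalg.norm(e2) > 1e-9 else _lateral(e1)
            first = len(atoms)
            for j in range(6):
                ang = j * math.pi / 3.0
                atoms.append(Atom("C", 0, 0))
                coords.append(target + _HEX_RADIUS
                              * (math.cos(ang) * e1 + math.sin(ang) * e2))
                if j > 0:
                    bonds.append((first + j - 1, first + j, 1))
            bonds.append((first + 5, first, 1))
        bonds.append((0, anchor, 1))

    base = np.array(coords)
    conformers = []
    for _ in range(n_conformers):
        rt = _random_rigid(rng)
        conformers.append(base @ rt[0].T + rt[1])
    return SmallMolecule(name, atoms, bonds, conformers,
                         {"AlogP": "2.00"})


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
    t = rng.uniform(-10.0, 10.0, 3)
    return R, t


def perturb_conformer(mol: SmallMolecule, sigma: float, seed: int,
                      conformer_index: int = 0) -> SmallMolecule:
    """Copy of ``mol`` with seeded Gaussian noise on one conformer."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    conformers = [c.copy() for c in mol.conformers]
    if sigma > 0:
        conformers[conformer_index] = conformers[conformer_index] \
            + rng.normal(0.0, sigma, conformers[conformer_index].shape)
    props = dict(mol.properties)
    props["perturb_seed"] = str(seed)
    return SmallMolecule(mol.name, list(mol.atoms), list(mol.bonds),
                         conformers, props)
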