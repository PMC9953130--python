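"""File formats, shared geometric data model, and rigid superposition.

Reads protein–ligand complexes from PDB (via gemmi) and multi-conformer
small-molecule libraries from SDF V2000 (via RDKit), computes the Lipinski
descriptor set, and provides the Kabsch least-squares rigid superposition
used everywhere a frame change or feature mapping is needed. Pharmacophore
models round-trip through a small JSON schema.

All coordinates are Ångström throughout the package; no unit conversion
happens anywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord", "ProteinLigandComplex", "Atom", "SmallMolecule",
    "DescriptorSet", "RigidTransform", "read_complex", "read_library",
    "write_library", "compute_descriptors", "superpose_points",
    "read_model", "write_model", "molecule_from_smiles",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: elements treated as halogens for apolarity decisions
HALOGENS = {"F", "CL", "BR", "I"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class SelectorError(ValueError):
    """Raised when a ligand selector matches zero or several residues."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AtomRecord:
    """One atom of a protein–ligand complex (PDB-style record)."""

    element: str
    name: str
    residue_name: str
    residue_number: int | None
    chain: str
    coords: np.ndarray
    is_hetero: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        self.element = self.element.upper()

    @property
    def residue_code(self) -> str:
        """Compact one-letter+number residue code, e.g. ``A208``."""
        one = THREE_TO_ONE.get(self.residue_name.upper(), "X")
        return f"{one}{self.residue_number}"


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ProteinLigandComplex:
    """A receptor plus one extracted ligand, in one coordinate frame."""

    id: str
    protein_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    ligand_bonds: list[tuple[int, int, int]] = field(default_factory=list)
    ligand_id: str = "LIG"

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("complex must contain at least one ligand atom")
        n = len(self.ligand_atoms)
        for i, j, _order in self.ligand_bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"ligand bond ({i},{j}) out of range")

    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms])

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms])

    def transformed(self, rt: "RigidTransform") -> "ProteinLigandComplex":
        """Return a copy with ``rt`` applied jointly to protein and ligand."""
        def move(atoms: list[AtomRecord]) -> list[AtomRecord]:
            return [
                AtomRecord(a.element, a.name, a.residue_name, a.residue_number,
                           a.chain, rt.apply(a.coords), a.is_hetero, a.formal_charge)
                for a in atoms
            ]
        return ProteinLigandComplex(
            self.id, move(self.protein_atoms), move(self.ligand_atoms),
            list(self.ligand_bonds), self.ligand_id)


@dataclass(frozen=True)
class Atom:
    """One atom of a small molecule: element, formal charge and H count."""

    element: str
    formal_charge: int = 0
    n_h: int = 0  # explicit-plus-implicit hydrogens attached


@dataclass
class SmallMolecule:
    """A library molecule with one or more 3D conformers.

    Bond orders are integers (1/2/3; 4 marks aromatic bonds read from SDF).
    ``properties`` carries SDF tag data (may include precomputed MW/AlogP/...).
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]
    conformers: list[np.ndarray]
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"molecule {self.name!r} must have >=1 conformer")
        n = len(self.atoms)
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for c in self.conformers:
            if c.shape != (n, 3):
                raise ValueError(
                    f"molecule {self.name!r}: conformer shape {c.shape} "
                    f"does not match {n} atoms")

    def neighbors(self, i: int) -> list[int]:
        out = [j for a, j, _ in self.bonds if a == i]
        out += [a for a, j, _ in self.bonds if j == i]
        return sorted(out)

    def bond_order(self, i: int, j: int) -> int:
        for a, b, order in self.bonds:
            if {a, b} == {i, j}:
                return order
        return 0


@dataclass(frozen=True)
class DescriptorSet:
    """Lipinski rule-of-five descriptor quartet."""

    mw: float
    n_hbd: int
    n_hba: int
    alogp: float

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        if self.n_hbd < 0 or self.n_hba < 0:
            raise ValueError("donor/acceptor counts must be non-negative")


@dataclass
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_complex(path: str | Path, ligand_selector: str,
                 chain: str | None = None) -> ProteinLigandComplex:
    """Read a PDB file and extract a single protein chain plus one ligand.

    ``ligand_selector`` is the HET residue code (e.g. ``"DBQ"``). If the code
    occurs in more than one chain, ``chain`` must disambiguate. Waters and all
    hetero residues other than the selected ligand are dropped; protein atoms
    come from the ligand's chain only.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from None
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: no models in structure")
    model = st[0]

    candidates = []  # (chain_name, residue)
    for ch in model:
        for res in ch:
            if res.name.upper() == ligand_selector.upper():
                candidates.append((ch.name, res))
    if chain is not None:
        candidates = [(c, r) for c, r in candidates if c == chain]
    if not candidates:
        raise SelectorError(
            f"no residue {ligand_selector!r} found"
            + (f" in chain {chain!r}" if chain else "")
            + f"; hetero residues present: {sorted(_het_names(model))}")
    if len(candidates) > 1:
        places = [f"{c}/{r.seqid.num}" for c, r in candidates]
        raise SelectorError(
            f"ligand selector {ligand_selector!r} is ambiguous: {places}; "
            f"pass a chain to disambiguate")
    lig_chain, lig_res = candidates[0]

    protein_atoms: list[AtomRecord] = []
    ligand_atoms: list[AtomRecord] = []
    for ch in model:
        if ch.name != lig_chain:
            continue
        for res in ch:
            if res.name.upper() in WATER_NAMES:
                continue
            het = res.het_flag == "H"
            if het and res is not lig_res:
                continue
            for at in res:
                rec = AtomRecord(
                    element=at.element.name,
                    name=at.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain=ch.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_hetero=het,
                    formal_charge=int(at.charge),
                )
                (ligand_atoms if res is lig_res else protein_atoms).append(rec)

    return ProteinLigandComplex(
        id=Path(path).stem,
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        ligand_bonds=_infer_bonds(ligand_atoms),
        ligand_id=lig_res.name,
    )


def _het_names(model) -> set[str]:
    names = set()
    for ch in model:
        for res in ch:
            if res.het_flag == "H" and res.name not in WATER_NAMES:
                names.add(res.name)
    return names


#: covalent radii (Å) for bond inference among heavy atoms; generous defaults
_COV_RADII = {"C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02, "P": 1.06, "H": 0.37,
              "F": 0.71, "CL": 0.99, "BR": 1.14, "I": 1.33}


def _infer_bonds(atoms: list[AtomRecord]) -> list[tuple[int, int, int]]:
    """Distance-based single-bond inference for ligands read from PDB."""
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = _COV_RADII.get(atoms[i].element, 0.8)
            rj = _COV_RADII.get(atoms[j].element, 0.8)
            d = float(np.linalg.norm(atoms[i].coords - atoms[j].coords))
            if d <= (ri + rj) * 1.25:
                bonds.append((i, j, 1))
    return bonds


# ---------------------------------------------------------------------------
# SDF reading / writing
# ---------------------------------------------------------------------------

_RDKIT_ORDER = {1: 1, 2: 2, 3: 3}


def read_library(path: str | Path, merge_conformers: bool = True,
                 strict: bool = False) -> list[SmallMolecule]:
    """Read a multi-record SDF into SmallMolecule objects.

    Consecutive records sharing a name are merged as conformers of one
    molecule (disable with ``merge_conformers=False``). SDF properties of the
    first record of each molecule are preserved. Under ``strict=True``,
    records whose coordinates are entirely planar in z (2D depictions) are
    skipped with a warning.
    """
    from rdkit import Chem

    if Path(path).stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out: list[SmallMolecule] = []
    for rd in supplier:
        if rd is None:
            continue
        try:
            Chem.SanitizeMol(rd)
        except Exception:
            pass  # pseudo-molecules need not satisfy valence rules
        if rd.GetNumConformers() == 0:
            continue
        coords = rd.GetConformer().GetPositions()
        if strict and np.allclose(coords[:, 2], 0.0):
            warnings.warn(f"skipping 2D record {rd.GetProp('_Name') or '?'}")
            continue
        mol = _from_rdkit(rd)
        if merge_conformers and out and out[-1].name == mol.name \
                and len(out[-1].atoms) == len(mol.atoms):
            out[-1].conformers.extend(mol.conformers)
        else:
            out.append(mol)
    return out


def _from_rdkit(rd) -> SmallMolecule:
    from rdkit import Chem

    atoms = [
        Atom(a.GetSymbol().upper(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in rd.GetAtoms()
    ]
    bonds = []
    for b in rd.GetBonds():
        if b.GetBondType() == Chem.BondType.AROMATIC:
            order = 4
        else:
            order = _RDKIT_ORDER.get(int(b.GetBondTypeAsDouble()), 1)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    conformers = [rd.GetConformer(i).GetPositions().copy()
                  for i in range(rd.GetNumConformers())]
    name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
    props = {k: rd.GetProp(k) for k in rd.GetPropNames()}
    return SmallMolecule(name or "unnamed", atoms, bonds, conformers, props)


def to_rdkit(mol: SmallMolecule, conformer_index: int | None = None):
    """Build an RDKit Mol (explicit H counts pinned, no sanitization magic)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element.capitalize())
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.n_h)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
          3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, bt.get(order, Chem.BondType.SINGLE))
    m = rw.GetMol()
    m.SetProp("_Name", mol.name)
    indices = range(len(mol.conformers)) if conformer_index is None \
        else [conformer_index]
    for ci in indices:
        conf = Chem.Conformer(len(mol.atoms))
        for ai, xyz in enumerate(mol.conformers[ci]):
            conf.SetAtomPosition(ai, Point3D(*map(float, xyz)))
        m.AddConformer(conf, assignId=True)
    try:
        Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION)
    except Exception:
        pass
    return m


def write_library(path: str | Path, molecules: Iterable[SmallMolecule]) -> None:
    """Write molecules to SDF V2000, one record per conformer."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            rd = to_rdkit(mol)
            for k, v in mol.properties.items():
                rd.SetProp(k, str(v))
            for ci in range(rd.GetNumConformers()):
                writer.write(rd, confId=ci)
    finally:
        writer.close()


def molecule_from_smiles(smiles: str, name: str = "",
                         embed: bool = True, seed: int = 7) -> SmallMolecule:
    """Convenience constructor used in tests and examples."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise FormatError(f"invalid SMILES: {smiles!r}")
    if embed:
        rd3 = Chem.AddHs(rd)
        AllChem.EmbedMolecule(rd3, randomSeed=seed)
        rd3 = Chem.RemoveHs(rd3)
        rd = rd3
    mol = _from_rdkit(rd)
    if not rd.GetNumConformers():
        mol = SmallMolecule(name or smiles, mol.atoms, mol.bonds,
                            [np.zeros((len(mol.atoms), 3))], mol.properties)
    if name:
        mol.name = name
    elif not mol.name or mol.name == "unnamed":
        mol.name = smiles
    return mol


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

_ALOGP_KEYS = ("AlogP", "ALogP", "ALOGP", "alogp", "LogP", "logP", "CLOGP")


def compute_descriptors(mol: SmallMolecule) -> DescriptorSet:
    """Compute the Lipinski descriptor quartet for one molecule.

    MW sums standard atomic weights over all atoms including attached
    hydrogens; donor/acceptor counts use the same perception rules the
    screening module applies to feature points; AlogP is taken from the SDF
    properties when present, otherwise computed with the Wildman–Crippen
    atomic-contribution method.
    """
    from rdkit.Chem import GetPeriodicTable

    pt = GetPeriodicTable()
    mw = 0.0
    for a in mol.atoms:
        try:
            mw += pt.GetAtomicWeight(a.element.capitalize())
        except Exception:
            raise ValueError(f"unknown element {a.element!r} in {mol.name!r}")
        mw += a.n_h * pt.GetAtomicWeight("H")

    from .screening import count_donors_acceptors  # shared perception rules
    n_hbd, n_hba = count_donors_acceptors(mol)

    alogp = None
    for key in _ALOGP_KEYS:
        if key in mol.properties:
            alogp = float(mol.properties[key])
            break
    if alogp is None:
        from rdkit.Chem import Crippen
        try:
            alogp = float(Crippen.MolLogP(to_rdkit(mol, conformer_index=0)))
        except Exception:
            alogp = 0.0
    return DescriptorSet(mw=mw, n_hbd=n_hbd, n_hba=n_hba, alogp=alogp)


# ---------------------------------------------------------------------------
# rigid superposition (Kabsch)
# ---------------------------------------------------------------------------

def superpose_points(P: np.ndarray, Q: np.ndarray,
                     weights: Sequence[float] | None = None
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of Q onto P.

    Returns the proper rigid transform minimizing the (weighted) RMSD of
    ``R @ Q + t`` against ``P``, plus the residual RMSD after the transform.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.ndim == 1:
        P = P.reshape(1, 3)
    if Q.ndim == 1:
        Q = Q.reshape(1, 3)
    if P.shape != Q.shape or P.shape[1] != 3:
        raise ValueError("P and Q must be matching n x 3 arrays")
    n = P.shape[0]
    if n == 0:
        raise ValueError("cannot superpose empty point sets")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mu_p = w @ P
    mu_q = w @ Q
    Pc = P - mu_p
    Qc = Q - mu_q
    H = (Qc * w[:, None]).T @ Pc
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_p - R @ mu_q
    rt = RigidTransform(R, t)
    diff = rt.apply(Q) - P
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return rt, rmsd


# ---------------------------------------------------------------------------
# model JSON round-trip
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Raised when a model JSON document violates the schema."""


def write_model(path: str | Path, model) -> None:
    """Serialize a PharmacophoreModel to the package's JSON schema."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_model(path: str | Path):
    """Read a PharmacophoreModel from JSON, validating the schema."""
    from .pharmacophore import PharmacophoreModel

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from None
    return PharmacophoreModel.from_dict(doc)
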