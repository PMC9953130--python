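"""Shared fixtures: toy pockets, pipeline models, and independent oracles."""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest

import pharmscreen as ps
from pharmscreen.screening import perceive_features
from pharmscreen.structio import superpose_points


# ---------------------------------------------------------------------------
# PDB text fixture helper (hand-formatted records, independent of the writer)
# ---------------------------------------------------------------------------

def pdb_line(serial: int, name: str, resname: str, chain: str, resnum: int,
             xyz, element: str, hetero: bool = False) -> str:
    record = "HETATM" if hetero else "ATOM  "
    x, y, z = xyz
    return (f"{record}{serial:>5} {name:<4}{resname:>4} {chain}{resnum:>4}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {element:>2}")


@pytest.fixture
def simple_pdb_text() -> str:
    """Three protein residues, a 5-atom ligand, and one water."""
    lines = [
        pdb_line(1, "N", "THR", "A", 205, (0, 0, 0), "N"),
        pdb_line(2, "CA", "THR", "A", 205, (1.5, 0, 0), "C"),
        pdb_line(3, "C", "THR", "A", 205, (2.2, 1.2, 0), "C"),
        pdb_line(4, "N", "ALA", "A", 208, (4, 0, 0), "N"),
        pdb_line(5, "CA", "ALA", "A", 208, (5.5, 0, 0), "C"),
        pdb_line(6, "N", "ASP", "A", 270, (8, 0, 0), "N"),
        pdb_line(7, "CA", "ASP", "A", 270, (9.5, 0, 0), "C"),
        pdb_line(8, "C1", "LIG", "A", 900, (0, 5, 0), "C", hetero=True),
        pdb_line(9, "C2", "LIG", "A", 900, (1.4, 5, 0), "C", hetero=True),
        pdb_line(10, "O1", "LIG", "A", 900, (2.1, 6.1, 0), "O", hetero=True),
        pdb_line(11, "N1", "LIG", "A", 900, (2.1, 3.9, 0), "N", hetero=True),
        pdb_line(12, "C3", "LIG", "A", 900, (3.5, 5, 0), "C", hetero=True),
        pdb_line(13, "O", "HOH", "A", 901, (6, 6, 6), "O", hetero=True),
        "END",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline fixtures (two toy pockets sharing a frame -> hybrid model)
# ---------------------------------------------------------------------------

PLAN_A = (("A208", "hbond_donor"), ("D270", "hbond_donor"),
          ("K158", "hbond_acceptor"), ("L132", "hydrophobic"))
PLAN_B = (("A208", "hbond_donor"), ("T205", "hbond_acceptor"),
          ("M203", "hydrophobic"), ("L259", "hydrophobic"))
KEY_RESIDUES = {"T205", "A208", "D270"}


@pytest.fixture(scope="session")
def pocket_pair() -> list[ps.ProteinLigandComplex]:
    ca = ps.make_toy_complex(ps.PocketSpec(PLAN_A, seed=42,
                                           site_indices=(0, 1, 2, 3)))
    ca.id = "toy-A"
    cb = ps.make_toy_complex(ps.PocketSpec(PLAN_B, seed=42,
                                           site_indices=(0, 4, 5, 6)))
    cb.id = "toy-B"
    return [ca, cb]


@pytest.fixture(scope="session")
def hybrid_model(pocket_pair) -> ps.PharmacophoreModel:
    models = [ps.generate_model(cx, ps.build_report(cx))
              for cx in pocket_pair]
    merged = ps.merge_models(models)
    return ps.build_hybrid(merged, KEY_RESIDUES, keep_hyp=2)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_map(mol, conformer_index, model, max_omit=0):
    """Exhaustive enumeration of all kind-compatible correspondences.

    No distance pruning, no backtracking: every injective assignment of
    ligand points to every feature subset is refined by superposition and
    tested against the tolerances. Returns (fit, n_omitted) of the best
    accepted correspondence, or None.
    """
    points = perceive_features(mol, conformer_index)
    n = len(model.features)
    best = None
    for n_omit in range(0, min(max_omit, n - 1) + 1):
        for subset in combinations(range(n), n - n_omit):
            for perm in permutations(range(len(points)), len(subset)):
                if any(points[p].kind != model.features[f].kind
                       for f, p in zip(subset, perm)):
                    continue
                P = np.array([model.features[f].center for f in subset])
                Q = np.array([points[p].centroid for p in perm])
                rt, _ = superpose_points(P, Q)
                moved = rt.apply(Q)
                ds = [float(np.linalg.norm(m - np.array(
                    model.features[f].center)))
                    for f, m in zip(subset, moved)]
                if any(d > model.features[f].tolerance
                       for f, d in zip(subset, ds)):
                    continue
                fit = sum(1.0 - (d / model.features[f].tolerance) ** 2
                          for f, d in zip(subset, ds))
                if best is None or fit > best[0]:
                    best = (fit, n_omit)
    return best


def brute_force_hbond_pairs(cx, max_da=3.5):
    """All-pairs heavy-atom donor/acceptor candidates within the cutoff.

    Distance-only necessary condition: protein N/O/S vs ligand N/O/S within
    ``max_da``. Every detected hydrogen bond must be among these pairs.
    """
    pairs = set()
    for p in cx.protein_atoms:
        if p.element not in ("N", "O", "S"):
            continue
        for li, la in enumerate(cx.ligand_atoms):
            if la.element not in ("N", "O", "S"):
                continue
            if np.linalg.norm(p.coords - la.coords) <= max_da:
                pairs.add((p.residue_code, p.name, la.name))
    return pairs


def random_rigid_transform(rng) -> ps.RigidTransform:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return ps.RigidTransform(R, t)
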