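"""Drug-likeness filtering and pharmacophore mapping of conformer libraries.

Mapping searches kind-compatible correspondences between model features and
ligand feature points, prunes candidates by inter-point distance consistency,
refines each surviving correspondence by rigid least-squares superposition,
and accepts when every matched feature's displacement fits inside its
tolerance sphere (allowing up to ``max_omit`` unmatched features). The fit
score is sum_f w_f * (1 - (d_f / tol_f)^2): each feature contributes 1 at a
perfect hit, 0 at the tolerance boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np

from .structio import (DescriptorSet, HALOGENS, RigidTransform, SmallMolecule,
                       compute_descriptors, superpose_points)
from .pharmacophore import PharmacophoreModel

__all__ = [
    "FeaturePoint", "MappingParams", "MappingResult", "FunnelStats",
    "rof_filter", "perceive_features", "count_donors_acceptors",
    "fit_score", "map_conformer", "screen_library",
]


@dataclass(frozen=True)
class FeaturePoint:
    """Ligand-side counterpart of a pharmacophore feature."""

    kind: str
    atom_indices: tuple[int, ...]
    centroid: tuple[float, float, float]

    @property
    def centroid_array(self) -> np.ndarray:
        return np.array(self.centroid)


@dataclass(frozen=True)
class MappingParams:
    """Strictness knobs for conformer→model mapping."""

    max_omit: int = 0
    require_projected: bool = False

    def __post_init__(self) -> None:
        if self.max_omit < 0:
            raise ValueError("max_omit must be >= 0")


@dataclass
class MappingResult:
    """An accepted feature↔point correspondence with its rigid transform."""

    correspondence: dict[int, FeaturePoint]  # model feature index -> point
    transform: RigidTransform
    displacements: dict[int, float]  # model feature index -> Å
    fit: float
    n_omitted: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.correspondence)


@dataclass(frozen=True)
class FunnelStats:
    """Compound counts through the screening funnel stages."""

    n_input: int
    n_druglike: int
    n_mapped: int
    n_selected: int

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_druglike >= self.n_mapped
                >= self.n_selected >= 0):
            raise ValueError("funnel counts must be monotonically decreasing")


# ---------------------------------------------------------------------------
# rule-of-five
# ---------------------------------------------------------------------------

def rof_filter(d: DescriptorSet) -> bool:
    """Lipinski rule of five; all thresholds inclusive."""
    return (d.n_hbd <= 5 and d.n_hba <= 10
            and d.mw <= 500.0 and d.alogp <= 5.0)


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def _adjacency(mol: SmallMolecule) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for i, j, _ in mol.bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _rings(mol: SmallMolecule) -> list[tuple[int, ...]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    out = []
    for cycle in nx.minimum_cycle_basis(g):
        if 3 <= len(cycle) <= 8:
            out.append(tuple(sorted(cycle)))
    return sorted(out)


def _is_donor(mol: SmallMolecule, i: int, adj) -> bool:
    a = mol.atoms[i]
    if a.element not in ("N", "O"):
        return False
    if a.n_h > 0:
        return True
    return any(mol.atoms[j].element == "H" for j in adj[i])


def _is_acceptor(mol: SmallMolecule, i: int, adj,
                 ring_members: set[int]) -> bool:
    a = mol.atoms[i]
    if a.element not in ("N", "O"):
        return False
    if a.formal_charge > 0:
        return False
    heavy = [j for j in adj[i] if mol.atoms[j].element != "H"]
    if a.element == "N":
        # amide N: bonded to a carbonyl carbon
        for j in heavy:
            if mol.atoms[j].element == "C" and any(
                    mol.atoms[k].element == "O" and mol.bond_order(j, k) == 2
                    for k in adj[j]):
                return False
        # aniline-like N: attached to an aromatic/all-carbon ring atom
        for j in heavy:
            if j in ring_members and mol.atoms[j].element == "C":
                return False
    else:
        # nitro O: bonded to an N carrying two oxygens
        for j in heavy:
            if mol.atoms[j].element == "N":
                n_ox = sum(1 for k in adj[j] if mol.atoms[k].element == "O")
                if n_ox >= 2:
                    return False
    return True


def _is_apolar_carbon(mol: SmallMolecule, i: int, adj) -> bool:
    a = mol.atoms[i]
    if a.element not in ({"C", "S"} | HALOGENS):
        return False
    return not any(mol.atoms[j].element in ("N", "O") for j in adj[i])


def count_donors_acceptors(mol: SmallMolecule) -> tuple[int, int]:
    """Donor/acceptor atom counts under the perception rules used for mapping."""
    adj = _adjacency(mol)
    ring_members = {i for ring in _rings(mol) for i in ring
                    if all(mol.atoms[k].element == "C" for k in ring)}
    n_hbd = sum(1 for i in range(len(mol.atoms)) if _is_donor(mol, i, adj))
    n_hba = sum(1 for i in range(len(mol.atoms))
                if _is_acceptor(mol, i, adj, ring_members))
    return n_hbd, n_hba


def perceive_features(mol: SmallMolecule,
                      conformer_index: int = 0) -> list[FeaturePoint]:
    """Enumerate a conformer's pharmacophore feature points.

    HBD at N/O bearing >=1 H; HBA at N/O acceptors (amide/aniline N and
    nitro O excluded); HYP at centroids of all-carbon rings and of apolar
    chains of >=3 contiguous carbons; PI at positively charged atoms and
    aliphatic amine N; NI at negatively charged atoms. Deterministic order.
    """
    coords = mol.conformers[conformer_index]
    adj = _adjacency(mol)
    rings = _rings(mol)
    apolar_rings = [r for r in rings
                    if all(mol.atoms[i].element == "C" for i in r)]
    ring_members = {i for r in rings for i in r}
    apolar_ring_members = {i for r in apolar_rings for i in r}

    points: list[FeaturePoint] = []
    for i in range(len(mol.atoms)):
        if mol.atoms[i].element == "H":
            continue
        if _is_donor(mol, i, adj):
            points.append(FeaturePoint("HBD", (i,), tuple(coords[i])))
        if _is_acceptor(mol, i, adj, apolar_ring_members):
            points.append(FeaturePoint("HBA", (i,), tuple(coords[i])))

    for ring in apolar_rings:
        centroid = coords[list(ring)].mean(axis=0)
        points.append(FeaturePoint("HYP", ring, tuple(centroid)))

    # apolar chains: connected components of non-ring apolar carbons
    chain_atoms = [i for i in range(len(mol.atoms))
                   if i not in ring_members and _is_apolar_carbon(mol, i, adj)]
    chain_set = set(chain_atoms)
    seen: set[int] = set()
    for start in chain_atoms:
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            comp.append(cur)
            stack.extend(j for j in adj[cur] if j in chain_set)
        if len(comp) >= 3:
            comp = tuple(sorted(comp))
            centroid = coords[list(comp)].mean(axis=0)
            points.append(FeaturePoint("HYP", comp, tuple(centroid)))

    for i, a in enumerate(mol.atoms):
        if a.element == "H":
            continue
        if a.formal_charge > 0 or _is_aliphatic_amine(mol, i, adj, ring_members):
            points.append(FeaturePoint("PI", (i,), tuple(coords[i])))
        elif a.formal_charge < 0:
            points.append(FeaturePoint("NI", (i,), tuple(coords[i])))

    points.sort(key=lambda p: (p.kind, p.atom_indices))
    return points


def _is_aliphatic_amine(mol: SmallMolecule, i: int, adj,
                        ring_members: set[int]) -> bool:
    a = mol.atoms[i]
    if a.element != "N" or a.formal_charge != 0 or i in ring_members:
        return False
    heavy = [j for j in adj[i] if mol.atoms[j].element != "H"]
    if not heavy or any(mol.atoms[j].element != "C" for j in heavy):
        return False
    # exclude amide/aryl-bound N and any N on a multiply-bonded carbon
    for j in heavy:
        if j in ring_members:
            return False
        if any(order > 1 for x, y, order in mol.bonds if j in (x, y)):
            return False
    return True


# ---------------------------------------------------------------------------
# fit score and mapping
# ---------------------------------------------------------------------------

def fit_score(displacements: Sequence[float], tolerances: Sequence[float],
              weights: Sequence[float] | None = None) -> float:
    """sum_f w_f * (1 - (d_f / tol_f)^2); requires every d <= tol."""
    if len(displacements) != len(tolerances):
        raise ValueError("displacements and tolerances must match in length")
    w = [1.0] * len(displacements) if weights is None else list(weights)
    if len(w) != len(displacements):
        raise ValueError("weights length mismatch")
    score = 0.0
    for d, tol, wf in zip(displacements, tolerances, w):
        if d > tol:
            raise ValueError(f"displacement {d:.3f} exceeds tolerance {tol:.3f}")
        score += wf * (1.0 - (d / tol) ** 2)
    return score


def _evaluate_assignment(model: PharmacophoreModel,
                         feature_indices: Sequence[int],
                         points: Sequence[FeaturePoint],
                         mol: SmallMolecule, conformer_index: int,
                         params: MappingParams) -> MappingResult | None:
    """Superpose matched points onto feature centers and test tolerances."""
    P = np.array([model.features[fi].center for fi in feature_indices])
    Q = np.array([p.centroid for p in points])
    rt, _ = superpose_points(P, Q)
    moved = rt.apply(Q)
    displacements = {}
    for fi, pos in zip(feature_indices, moved):
        d = float(np.linalg.norm(pos - np.array(model.features[fi].center)))
        if d > model.features[fi].tolerance:
            return None
        displacements[fi] = d
    if params.require_projected and not _projected_ok(
            model, feature_indices, points, mol, conformer_index, rt):
        return None
    fit = fit_score([displacements[fi] for fi in feature_indices],
                    [model.features[fi].tolerance for fi in feature_indices])
    return MappingResult(
        correspondence=dict(zip(feature_indices, points)),
        transform=rt,
        displacements=displacements,
        fit=fit,
        n_omitted=len(model.features) - len(feature_indices),
    )


def _projected_ok(model, feature_indices, points, mol, conformer_index,
                  rt) -> bool:
    """Check projected points against explicit ligand H positions."""
    coords = mol.conformers[conformer_index]
    adj = _adjacency(mol)
    for fi, p in zip(feature_indices, points):
        feat = model.features[fi]
        if feat.projected_point is None:
            continue
        anchor = p.atom_indices[0]
        h_pos = [coords[j] for j in adj[anchor]
                 if mol.atoms[j].element == "H"]
        if not h_pos:
            return False
        target = np.array(feat.projected_point)
        if all(np.linalg.norm(rt.apply(np.array(h)) - target)
               > feat.projected_tolerance for h in h_pos):
            return False
    return True


def map_conformer(mol: SmallMolecule, conformer_index: int,
                  model: PharmacophoreModel,
                  params: MappingParams | None = None
                  ) -> MappingResult | None:
    """Best mapping of one conformer onto the model, or None.

    Backtracking over kind-compatible injective assignments, pruned by the
    pairwise test |d_model(i,j) - d_ligand(i,j)| <= tol_i + tol_j; every
    surviving complete assignment is refined by rigid superposition. The best
    accepted result maximizes fit (ties: fewest omissions, then
    lexicographically smallest correspondence).
    """
    if not model.features:
        raise ValueError("model has no features")
    params = params or MappingParams()
    points = perceive_features(mol, conformer_index)
    n_feat = len(model.features)
    max_omit = min(params.max_omit, n_feat - 1)

    pts_by_kind: dict[str, list[int]] = {}
    for idx, p in enumerate(points):
        pts_by_kind.setdefault(p.kind, []).append(idx)

    centers = np.array([f.center for f in model.features])
    pt_coords = np.array([p.centroid for p in points]) if points else \
        np.zeros((0, 3))

    best: tuple[float, int, tuple[int, ...]] | None = None
    best_result: MappingResult | None = None

    for n_omit in range(0, max_omit + 1):
        for subset in combinations(range(n_feat), n_feat - n_omit):
            for assignment in _assignments(subset, model, points,
                                           pts_by_kind, centers, pt_coords):
                result = _evaluate_assignment(
                    model, subset, [points[i] for i in assignment],
                    mol, conformer_index, params)
                if result is None:
                    continue
                key = (-result.fit, result.n_omitted, assignment)
                if best is None or key < best:
                    best = key
                    best_result = result
    return best_result


def _assignments(subset: Sequence[int], model: PharmacophoreModel,
                 points: Sequence[FeaturePoint],
                 pts_by_kind: dict[str, list[int]],
                 centers: np.ndarray, pt_coords: np.ndarray
                 ) -> Iterable[tuple[int, ...]]:
    """Yield injective kind-compatible point assignments, distance-pruned."""
    chosen: list[int] = []
    used: set[int] = set()

    def recurse(pos: int):
        if pos == len(subset):
            yield tuple(chosen)
            return
        fi = subset[pos]
        feat = model.features[fi]
        for pi in pts_by_kind.get(feat.kind, ()):
            if pi in used:
                continue
            ok = True
            for prev_pos in range(pos):
                fj = subset[prev_pos]
                pj = chosen[prev_pos]
                dm = np.linalg.norm(centers[fi] - centers[fj])
                dl = np.linalg.norm(pt_coords[pi] - pt_coords[pj])
                if abs(dm - dl) > feat.tolerance + \
                        model.features[fj].tolerance:
                    ok = False
                    break
            if not ok:
                continue
            chosen.append(pi)
            used.add(pi)
            yield from recurse(pos + 1)
            chosen.pop()
            used.remove(pi)

    yield from recurse(0)


# ---------------------------------------------------------------------------
# library screening
# ---------------------------------------------------------------------------

def screen_library(library: Sequence[SmallMolecule],
                   model: PharmacophoreModel,
                   params: MappingParams | None = None,
                   apply_rof: bool = True,
                   admet_predicate: Callable[[SmallMolecule], bool] | None = None,
                   max_hits: int | None = None
                   ) -> tuple[list[tuple[SmallMolecule, MappingResult]], FunnelStats]:
    """Screen a library: drug-likeness filter, then conformer mapping.

    For each drug-like molecule, every conformer is mapped and the best fit
    kept. ``admet_predicate`` is a pluggable selection stage (default:
    pass-all); ``max_hits`` optionally truncates the ranked hit list. Hits
    are ordered by (fit desc, name).
    """
    params = params or MappingParams()
    n_input = len(library)
    druglike = []
    for mol in library:
        if not apply_rof or rof_filter(compute_descriptors(mol)):
            druglike.append(mol)

    mapped: list[tuple[SmallMolecule, MappingResult]] = []
    for mol in druglike:
        best: MappingResult | None = None
        for ci in range(len(mol.conformers)):
            res = map_conformer(mol, ci, model, params)
            if res is not None and (best is None or res.fit > best.fit):
                best = res
        if best is not None:
            mapped.append((mol, best))
    mapped.sort(key=lambda pair: (-pair[1].fit, pair[0].name))

    selected = mapped
    if admet_predicate is not None:
        selected = [(m, r) for m, r in selected if admet_predicate(m)]
    if max_hits is not None:
        selected = selected[:max_hits]

    stats = FunnelStats(n_input, len(druglike), len(mapped), len(selected))
    return selected, stats
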