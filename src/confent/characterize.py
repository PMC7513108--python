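"""Structure comparison and descriptors for conformational ensembles.

Least-squares (Kabsch) superposition RMSD, average-linkage (UPGMA)
deduplication of decoy sets at a hard distance threshold, Cα contact
maps, radius of gyration, Shrake–Rupley solvent-accessible surface
area, and a simplified three-state secondary-structure assignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .structures import StructureModel

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "kabsch_rmsd",
    "pairwise_rmsd",
    "upgma_dedup",
    "contact_map",
    "radius_of_gyration",
    "sasa_shrake_rupley",
    "secondary_structure",
    "ATOM_RADII",
]

# Van der Waals radii (Å) for the elements of standard amino acids.
ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass
class DistanceMatrix:
    """Symmetric conformation-by-conformation distance matrix (Å).

    The triangle inequality is *not* assumed: RMSDs obtained after
    independent pairwise superpositions may violate it.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in row)
                         + "\n")


@dataclass
class ClusterResult:
    """Partition of conformation names with one representative each."""

    clusters: list[list[str]]
    representatives: list[str]
    threshold: float
    seed: int

    def __post_init__(self) -> None:
        flat = [x for c in self.clusters for x in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters must partition the inputs")
        for rep, cluster in zip(self.representatives, self.clusters):
            if rep not in cluster:
                raise ValueError(f"representative {rep!r} not in its cluster")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"clusters": self.clusters,
                       "representatives": self.representatives,
                       "threshold": self.threshold,
                       "seed": self.seed}, fh, indent=1)


# ---------------------------------------------------------------------------
# Superposition RMSD
# ---------------------------------------------------------------------------

def _selected_coords(model: StructureModel, selection: str) -> np.ndarray:
    if selection == "CA":
        return model.ca_coords()
    if selection == "backbone":
        names = {"N", "CA", "C"}
    elif selection == "all-shared":
        names = None
    else:
        raise ValueError(f"unknown atom selection {selection!r}")
    rows = [xyz for an, xyz in zip(model.atom_names, model.coords)
            if names is None or an in names]
    return np.array(rows)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation R and translation aligning P onto Q.

    Returns ``(R, t, rmsd)`` minimising ``|P @ R.T + t - Q|``; the
    reflection branch of the SVD is corrected so ``det(R) = +1``.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("point sets must match and contain >= 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def kabsch_rmsd(A: StructureModel, B: StructureModel,
                selection: Literal["CA", "backbone", "all-shared"] = "CA",
                ) -> float:
    """Minimal RMSD (Å) between two conformations over rigid motions."""
    P = _selected_coords(A, selection)
    Q = _selected_coords(B, selection)
    if P.shape != Q.shape:
        raise ValueError(
            f"selection {selection!r} yields {len(P)} vs {len(Q)} atoms")
    return kabsch_superpose(P, Q)[2]


def pairwise_rmsd(models: Sequence[StructureModel],
                  selection: str = "CA") -> DistanceMatrix:
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kabsch_rmsd(models[i], models[j], selection)
    return DistanceMatrix([m.name for m in models], D)


# ---------------------------------------------------------------------------
# UPGMA deduplication
# ---------------------------------------------------------------------------

def upgma_dedup(D: DistanceMatrix, threshold: float = 5.0,
                seed: int = 0) -> ClusterResult:
    """Collapse groups of mutually similar conformations.

    Average-linkage agglomeration proceeds while the smallest linkage is
    strictly below ``threshold`` (Å); each resulting cluster is reduced
    to one representative drawn uniformly with ``seed``.  Deterministic
    given ``(D, seed)``.
    """
    n = len(D.labels)
    if n == 1:
        return ClusterResult([list(D.labels)], list(D.labels),
                             threshold, seed)
    Z = linkage(squareform(D.values, checks=False), method="average")
    # strict "< threshold" cut of the merge tree
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, height, _) in enumerate(Z):
        node = n + k
        if height < threshold:
            parent[find(int(a))] = node
            parent[find(int(b))] = node
            parent[node] = node
    groups: dict[int, list[str]] = {}
    for i, lab in enumerate(D.labels):
        groups.setdefault(find(i), []).append(lab)
    clusters = sorted(groups.values(), key=lambda c: c[0])
    rng = np.random.default_rng(seed)
    reps = [c[int(rng.integers(len(c)))] for c in clusters]
    return ClusterResult(clusters, reps, threshold, seed)


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def contact_map(S: StructureModel) -> np.ndarray:
    """Symmetric Nres × Nres matrix of Cα–Cα distances (Å)."""
    ca = S.ca_coords()
    diff = ca[:, None, :] - ca[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def radius_of_gyration(S: StructureModel) -> float:
    """Unweighted radius of gyration (Å) over all atoms."""
    x = S.coords - S.coords.mean(axis=0)
    return float(np.sqrt((x ** 2).sum(axis=-1).mean()))


def _sphere_points(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa_shrake_rupley(S: StructureModel, probe_radius: float = 1.4,
                       n_points: int = 960,
                       default_radius: float | None = None):
    """Solvent-accessible surface area by probe-sphere point sampling.

    Each atom is inflated by the probe radius and covered with
    ``n_points`` test points; points inside any neighbouring inflated
    sphere are buried.  Returns ``(total Å², per-residue dict)`` where
    per-residue values sum to the total.

    Unknown elements raise unless ``default_radius`` is given.
    """
    radii = np.empty(S.n_atoms)
    for i, el in enumerate(S.elements):
        r = ATOM_RADII.get(el.upper(), default_radius)
        if r is None:
            raise ValueError(f"no radius for element {S.elements[i]!r} "
                             f"(pass default_radius to override)")
        radii[i] = r
    inflated = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(S.coords)
    per_atom = np.zeros(S.n_atoms)
    max_r = inflated.max()
    for i in range(S.n_atoms):
        pts = S.coords[i] + inflated[i] * unit
        neighbours = [j for j in tree.query_ball_point(
            S.coords[i], inflated[i] + max_r) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - S.coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > inflated[j] ** 2
        per_atom[i] = (4.0 * np.pi * inflated[i] ** 2
                       * exposed.sum() / n_points)
    per_residue: dict[tuple[str, int], float] = {}
    for (c, r), a in zip(zip(S.chain_ids, S.res_ids), per_atom):
        key = (c, int(r))
        per_residue[key] = per_residue.get(key, 0.0) + float(a)
    return float(per_atom.sum()), per_residue


# ---------------------------------------------------------------------------
# Simplified secondary structure
# ---------------------------------------------------------------------------

_HB_CUTOFF = -0.5          # kcal/mol
_HB_Q1Q2F = 0.084 * 332.0  # electrostatic H-bond energy prefactor


def _backbone_hbonds(S: StructureModel) -> set[tuple[int, int]]:
    """(donor residue position, acceptor residue position) pairs.

    Energy follows the classic electrostatic form
    ``E = 0.084·332·(1/rON + 1/rCH − 1/rOH − 1/rCN)`` with the amide H
    placed 1 Å from N along the preceding carbonyl C→O direction.
    """
    residues = S.residues()
    coords = {}
    for i, (c, r, rn) in enumerate(residues):
        coords[i] = {a: S.atom(c, r, a) for a in ("N", "CA", "C", "O")}
        coords[i]["resname"] = rn
        coords[i]["chain"] = c
    # amide H positions
    H = {}
    for i in range(1, len(residues)):
        if coords[i]["chain"] != coords[i - 1]["chain"]:
            continue
        if coords[i]["resname"] == "PRO":
            continue
        n = coords[i]["N"]
        c_prev, o_prev = coords[i - 1]["C"], coords[i - 1]["O"]
        if n is None or c_prev is None or o_prev is None:
            continue
        d = c_prev - o_prev
        H[i] = n + d / np.linalg.norm(d)
    bonds: set[tuple[int, int]] = set()
    for i, h in H.items():  # donor NH of residue i
        n = coords[i]["N"]
        for j in range(len(residues)):  # acceptor CO of residue j
            if abs(i - j) < 2:
                continue
            c, o = coords[j]["C"], coords[j]["O"]
            if c is None or o is None:
                continue
            r_on = np.linalg.norm(o - n)
            if r_on > 5.2:  # beyond any plausible H-bond
                continue
            e = _HB_Q1Q2F * (1 / r_on + 1 / np.linalg.norm(c - h)
                             - 1 / np.linalg.norm(o - h)
                             - 1 / np.linalg.norm(c - n))
            if e < _HB_CUTOFF:
                bonds.add((i, j))
    return bonds


def secondary_structure(S: StructureModel) -> list[str]:
    """Per-residue H/E/C labels from backbone hydrogen bonding.

    An i→i+4 H-bond pattern on two consecutive starts marks a helical
    turn (H); mutual or offset long-range H-bond bridges mark extended
    ladders (E); everything else is coil (C).  Residues missing a
    backbone O are labelled C with a warning.
    """
    residues = S.residues()
    n = len(residues)
    labels = ["C"] * n
    for i, (c, r, rn) in enumerate(residues):
        if not S.has_atom(c, r, "O") and i < n - 1:
            warnings.warn(f"residue {rn} {c}{r} missing O; labelled C")
    if n < 5:
        return labels
    bonds = _backbone_hbonds(S)
    turn = [(i + 4, i) in bonds for i in range(n)]
    for i in range(n - 1):
        if turn[i] and (i + 1 < n and turn[i + 1]):
            for k in range(i + 1, min(i + 5, n)):
                labels[k] = "H"
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 3 or labels[i] == "H" or labels[j] == "H":
                continue
            anti = (i, j) in bonds and (j, i) in bonds
            para = (i, j - 1) in bonds and (j + 1, i) in bonds
            if anti or para:
                if labels[i] != "H":
                    labels[i] = "E"
                if labels[j] != "H":
                    labels[j] = "E"
    return labels
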