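"""Protein structures and their internal (torsion) coordinates.

A :class:`StructureModel` is a flat, array-backed view of one conformation:
atom records plus an ``(N, 3)`` coordinate block in Å.  Multi-model PDB
files become lists of models sharing labels, which is the substrate for
:func:`compute_torsions` — the conversion from Cartesian coordinates to a
:class:`TorsionEnsemble` of φ/ψ/χ angles in radians.

Conventions
-----------
* Residue indexing is 1-based, PDB style.
* Torsions follow the IUPAC sign convention; values live in ``[-π, π)``.
* ω (the peptide bond torsion) is treated as rigid and never emitted.
* φ is undefined for the first residue of a chain and ψ for the last;
  those labels are simply omitted.
* Hydrogens and HETATM records are ignored on input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "StructureModel",
    "TorsionEnsemble",
    "PDBParseError",
    "DihedralGeometryError",
    "read_pdb",
    "write_pdb",
    "dihedral",
    "compute_torsions",
    "CHI_ATOMS",
    "THREE_TO_ONE",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be turned into a StructureModel."""


class DihedralGeometryError(ValueError):
    """Raised for degenerate four-point geometries (coincident/collinear)."""


THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Side-chain torsion definitions: atom name quadruples per residue type.
# chi_k exists only for the types listed; e.g. Ala/Gly carry no chi at all.
CHI_ATOMS: Mapping[str, Sequence[Sequence[str]]] = {
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}

_BACKBONE = ("N", "CA", "C")


@dataclass
class StructureModel:
    """One protein conformation as parallel per-atom arrays.

    Parameters
    ----------
    atom_names, elements, res_names, chain_ids : per-atom string labels
    res_ids : per-atom 1-based residue indices (strictly increasing
        within a chain)
    coords : ``(N, 3)`` float array, Å
    model_id : integer model number (1 for single-model files)
    name : free-form conformation name used in reports
    """

    atom_names: list[str]
    elements: list[str]
    res_ids: np.ndarray
    res_names: list[str]
    chain_ids: list[str]
    coords: np.ndarray
    model_id: int = 1
    name: str = "model"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom label/coordinate length mismatch")
        self._index = {
            (c, int(r), a): i
            for i, (c, r, a) in enumerate(
                zip(self.chain_ids, self.res_ids, self.atom_names))
        }
        # residue indices must be non-decreasing within a chain
        per_chain: dict[str, int] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            prev = per_chain.get(c)
            if prev is not None and r < prev:
                raise ValueError(
                    f"residue indices not increasing in chain {c!r}: "
                    f"{r} after {prev}")
            per_chain[c] = r

    # -- residue-level views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_id, res_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        for c, r, rn in zip(self.chain_ids, self.res_ids, self.res_names):
            seen.setdefault((c, int(r)), rn)
        return [(c, r, rn) for (c, r), rn in seen.items()]

    @property
    def n_residues(self) -> int:
        return len(self.residues())

    @property
    def sequence(self) -> str:
        return "".join(
            THREE_TO_ONE.get(rn, "X") for _, _, rn in self.residues())

    def atom(self, chain: str, res_id: int, name: str) -> np.ndarray | None:
        """Coordinates of one atom, or None if absent."""
        i = self._index.get((chain, int(res_id), name))
        return None if i is None else self.coords[i]

    def has_atom(self, chain: str, res_id: int, name: str) -> bool:
        return (chain, int(res_id), name) in self._index

    def incomplete_residues(self) -> list[tuple[str, int]]:
        """Residues missing any of the N/CA/C backbone atoms."""
        out = []
        for c, r, _ in self.residues():
            if not all(self.has_atom(c, r, a) for a in _BACKBONE):
                out.append((c, r))
        return out

    def ca_coords(self) -> np.ndarray:
        """(Nres, 3) Cα coordinates; raises if a residue lacks CA."""
        rows = []
        for c, r, rn in self.residues():
            ca = self.atom(c, r, "CA")
            if ca is None:
                raise ValueError(f"residue {rn} {c}{r} has no CA atom")
            rows.append(ca)
        return np.array(rows)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    name: str | None = None) -> "StructureModel":
        """Copy with coords -> coords @ R.T + t (rigid motion)."""
        return StructureModel(
            list(self.atom_names), list(self.elements), self.res_ids.copy(),
            list(self.res_names), list(self.chain_ids),
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
            model_id=self.model_id, name=name or self.name)


@dataclass
class TorsionEnsemble:
    """Frames × labelled torsion variables, radians in [-π, π).

    ``labels`` are ``(residue index, torsion name)`` pairs with names in
    ``{"phi", "psi", "chi1".."chi4"}``; ``samples`` has shape ``(F, T)``.
    """

    labels: list[tuple[int, str]]
    samples: np.ndarray
    sequence: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.samples.shape[1] != len(self.labels):
            raise ValueError("label/sample column mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("torsion labels must be unique")
        if self.samples.size and (
                self.samples.min() < -math.pi
                or self.samples.max() >= math.pi):
            raise ValueError("torsion samples must lie in [-pi, pi)")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.samples.shape[1]

    def column(self, residue: int, name: str) -> np.ndarray:
        return self.samples[:, self.labels.index((residue, name))]

    def residue_labels(self, residue: int) -> list[tuple[int, str]]:
        return [lab for lab in self.labels if lab[0] == residue]

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(f"{r}:{n}" for r, n in self.labels)
        np.savetxt(path, self.samples, delimiter="\t", header=header,
                   comments="", fmt="%.8f")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 sequence: str = "") -> "TorsionEnsemble":
        with open(path) as fh:
            header = fh.readline().split()
        labels = []
        for tok in header:
            r, n = tok.split(":")
            labels.append((int(r), n))
        samples = np.loadtxt(path, skiprows=1, ndmin=2)
        return cls(labels, samples, sequence)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _model_to_structure(model, model_id: int, name: str) -> StructureModel:
    atom_names, elements, res_ids, res_names, chain_ids, xyz = \
        [], [], [], [], [], []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _ = residue.id
            if hetflag.strip():
                continue  # HETATM / water
            for atom in residue:
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                atom_names.append(atom.get_name())
                elements.append(atom.element or atom.get_name()[0])
                res_ids.append(resseq)
                res_names.append(residue.get_resname())
                chain_ids.append(chain.id)
                xyz.append(atom.get_coord())
    if not atom_names:
        raise PDBParseError(f"{name}: no ATOM records found")
    return StructureModel(atom_names, elements, np.array(res_ids),
                          res_names, chain_ids, np.array(xyz, dtype=float),
                          model_id=model_id, name=name)


def read_pdb(path: str | Path,
             model_policy: Literal["first", "all"] = "first",
             name: str | None = None):
    """Read a PDB file into StructureModel(s).

    ``model_policy="first"`` returns a single :class:`StructureModel`;
    ``"all"`` returns a list with one model per MODEL block.  Alternate
    locations resolve to the highest-occupancy copy (ties to the first,
    Biopython's default).  Hydrogens and HETATM records are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    base = name or path.stem
    models = list(structure)
    if not models:
        raise PDBParseError(f"{path}: empty structure")
    if model_policy == "first":
        return _model_to_structure(models[0], 1, base)
    out = []
    for i, m in enumerate(models, start=1):
        label = base if len(models) == 1 else f"{base}_m{i}"
        out.append(_model_to_structure(m, i, label))
    return out


def write_pdb(models: StructureModel | Sequence[StructureModel],
              path: str | Path,
              bfactors: Mapping[int, float] | None = None) -> None:
    """Write model(s) as a (multi-model) PDB file.

    ``bfactors`` maps residue index -> scalar placed in the B-factor
    column of every atom of that residue — used to color per-residue
    quantities (e.g. entropy differences) in molecular viewers.
    """
    if isinstance(models, StructureModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for k, m in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            serial = 1
            for an, el, ri, rn, ci, xyz in zip(
                    m.atom_names, m.elements, m.res_ids, m.res_names,
                    m.chain_ids, m.coords):
                b = 0.0 if bfactors is None else float(bfactors.get(int(ri), 0.0))
                pad = an if len(an) == 4 else f" {an:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {pad:<4s} {rn:<3s} {ci:1s}"
                    f"{int(ri):4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}"
                    f"{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
                    f"          {el:>2s}\n")
                serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Torsion geometry
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, IUPAC convention, in [-π, π).

    Zero for an eclipsed (syn) arrangement, ±π for anti; the sign flips
    under mirror reflection and is unchanged when the four points are
    given in reverse order.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if (np.linalg.norm(b0) < 1e-10 or nb1 < 1e-10
            or np.linalg.norm(b2) < 1e-10):
        raise DihedralGeometryError("coincident consecutive points")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise DihedralGeometryError("collinear consecutive points")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.atan2(y, x)
    if ang >= math.pi:  # map +π to -π so the range is [-π, π)
        ang -= 2.0 * math.pi
    return ang


def _torsion_atom_quads(model: StructureModel, warn_missing: bool = True):
    """Yield ((res_id, torsion_name), four atom keys) for every defined
    torsion of the model.  Chain-end φ/ψ and chi angles with missing
    atoms are omitted."""
    residues = model.residues()
    by_chain: dict[str, list[tuple[int, str]]] = {}
    for c, r, rn in residues:
        by_chain.setdefault(c, []).append((r, rn))
    quads = []
    for chain, rs in by_chain.items():
        for i, (rid, rname) in enumerate(rs):
            prev_rid = rs[i - 1][0] if i > 0 else None
            next_rid = rs[i + 1][0] if i + 1 < len(rs) else None
            if prev_rid is not None:
                quads.append(((rid, "phi"),
                              [(chain, prev_rid, "C"), (chain, rid, "N"),
                               (chain, rid, "CA"), (chain, rid, "C")]))
            if next_rid is not None:
                quads.append(((rid, "psi"),
                              [(chain, rid, "N"), (chain, rid, "CA"),
                               (chain, rid, "C"), (chain, next_rid, "N")]))
            for k, names in enumerate(CHI_ATOMS.get(rname, ()), start=1):
                atom_keys = [(chain, rid, a) for a in names]
                if all(model.has_atom(*key) for key in atom_keys):
                    quads.append(((rid, f"chi{k}"), atom_keys))
                elif warn_missing:
                    warnings.warn(
                        f"{model.name}: chi{k} of {rname} {chain}{rid} "
                        f"omitted (missing side-chain atoms)")
    # drop torsions whose backbone atoms are missing (incomplete residues)
    out = []
    for label, keys in quads:
        if all(model.has_atom(*key) for key in keys):
            out.append((label, keys))
    return out


def compute_torsions(models: StructureModel | Sequence[StructureModel],
                     ) -> TorsionEnsemble:
    """Torsion-angle ensemble of one or more conformations of a chain.

    All models must share sequence and atom naming; the torsion set of
    the first model defines the columns.  φ of the first and ψ of the
    last residue of each chain are omitted, as are χ angles with missing
    side-chain atoms.
    """
    if isinstance(models, StructureModel):
        models = [models]
    if not models:
        raise ValueError("no models given")
    ref = models[0]
    quads = _torsion_atom_quads(ref)
    if not quads:
        raise ValueError("no torsion angles definable for this structure")
    labels = [lab for lab, _ in quads]
    rows = []
    for m in models:
        if m.sequence != ref.sequence:
            raise ValueError(
                f"model {m.name}: sequence differs from {ref.name}")
        m_quads = dict(_torsion_atom_quads(m, warn_missing=False))
        for lab in labels:
            if lab not in m_quads:
                raise ValueError(
                    f"model {m.name}: torsion {lab} missing "
                    f"(first mismatching label)")
        row = [dihedral(*(m.atom(*key) for key in m_quads[lab]))
               for lab in labels]
        rows.append(row)
    return TorsionEnsemble(labels, np.array(rows), sequence=ref.sequence)
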