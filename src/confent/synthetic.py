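"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here without any
download: ideal-geometry peptide chains built from torsion targets,
torsion-angle ensembles with *analytic* total entropy (the oracle for
the histogram estimators), decoy sets with planted near-duplicates for
clustering, and energy tables with planted enthalpy/entropy gaps that
reproduce the entropic-stabilization ranking reversal.

Couplings between torsions use a Gaussian copula because its mutual
information has the closed form −½·ln(1−ρ²) for any pair of marginals,
giving exact ground truth without simulation.  All generators are pure
functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0, i1
from scipy.stats import norm

from .structures import StructureModel, TorsionEnsemble, dihedral
from .thermo import EnergyTable

__all__ = [
    "SyntheticEnsembleSpec",
    "SyntheticTableSpec",
    "build_chain",
    "sample_torsion_ensemble",
    "make_decoy_set",
    "make_energy_table",
    "von_mises_entropy",
    "copula_mutual_information",
]

_TWO_PI = 2.0 * math.pi

# Ideal backbone geometry (Å, degrees): Engh–Huber-style averages.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.526
ANGLE_N_CA_C = math.radians(111.2)
ANGLE_CA_C_N = math.radians(116.2)
ANGLE_C_N_CA = math.radians(121.7)
ANGLE_CA_C_O = math.radians(120.5)
OMEGA = math.pi  # rigid trans peptide bond


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Next atom D with |C−D|=bond, ∠(B,C,D)=angle, dihedral(A,B,C,D)=torsion."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear frame atoms: cannot place next atom")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(angle),
                        bond * math.sin(angle) * math.cos(torsion),
                        bond * math.sin(angle) * math.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Chain construction from torsion targets
# ---------------------------------------------------------------------------

def build_chain(sequence: str,
                torsions: Mapping[int, Mapping[str, float]],
                chain_id: str = "A",
                name: str = "chain") -> StructureModel:
    """Build an ideal-geometry backbone (N, CA, C, O, CB) from φ/ψ targets.

    ``torsions`` maps 1-based residue index to ``{"phi": ..., "psi": ...}``
    in radians; φ of the first and ψ of the last residue are ignored if
    given.  Bond lengths/angles are fixed ideal values and ω is held at
    180°, so :func:`~confent.structures.compute_torsions` recovers the
    targets exactly (round-trip ≤ 1e-6 rad).
    """
    sequence = sequence.upper()
    nres = len(sequence)
    if nres < 1:
        raise ValueError("empty sequence")
    for i in range(2, nres + 1):
        if "phi" not in torsions.get(i, {}):
            raise ValueError(f"missing phi target for residue {i}")
    for i in range(1, nres):
        if "psi" not in torsions.get(i, {}):
            raise ValueError(f"missing psi target for residue {i}")

    one_to_three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    C = [CA[0] + BOND_CA_C * np.array([math.cos(math.pi - ANGLE_N_CA_C),
                                       math.sin(math.pi - ANGLE_N_CA_C),
                                       0.0])]
    for i in range(1, nres):
        psi = torsions[i]["psi"]
        n_next = _place(N[i - 1], CA[i - 1], C[i - 1],
                        BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place(CA[i - 1], C[i - 1], n_next,
                         BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        phi = torsions[i + 1]["phi"]
        c_next = _place(C[i - 1], n_next, ca_next,
                        BOND_CA_C, ANGLE_N_CA_C, phi)
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)

    atom_names, elements, res_ids, res_names, chain_ids, xyz = \
        [], [], [], [], [], []

    def add(nm, el, ri, coord):
        atom_names.append(nm)
        elements.append(el)
        res_ids.append(ri)
        res_names.append(one_to_three.get(sequence[ri - 1], "ALA"))
        chain_ids.append(chain_id)
        xyz.append(coord)

    for i in range(nres):
        rid = i + 1
        add("N", "N", rid, N[i])
        add("CA", "C", rid, CA[i])
        add("C", "C", rid, C[i])
        # carbonyl O anti to the next N (or pseudo-ψ=π for the C-terminus)
        psi = torsions.get(rid, {}).get("psi", math.pi) \
            if i < nres - 1 else torsions.get(rid, {}).get("psi", 0.0)
        o = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                   _wrap(psi + math.pi))
        add("O", "O", rid, o)
        if sequence[i] != "G":
            u1 = N[i] - CA[i]
            u1 /= np.linalg.norm(u1)
            u2 = C[i] - CA[i]
            u2 /= np.linalg.norm(u2)
            bisec = u1 + u2
            bisec /= np.linalg.norm(bisec)
            perp = np.cross(u1, u2)
            perp /= np.linalg.norm(perp)
            cb = CA[i] + BOND_CA_CB * (-0.57735 * bisec + 0.81650 * perp)
            add("CB", "C", rid, cb)

    return StructureModel(atom_names, elements, np.array(res_ids),
                          res_names, chain_ids, np.array(xyz), name=name)


def _wrap(x):
    return (np.asarray(x) + math.pi) % _TWO_PI - math.pi


# ---------------------------------------------------------------------------
# Torsion ensembles with analytic entropy
# ---------------------------------------------------------------------------

def von_mises_entropy(kappa: float) -> float:
    """Differential entropy of the von Mises(μ, κ) circular density, nats."""
    if kappa == 0:
        return math.log(_TWO_PI)
    return math.log(_TWO_PI * i0(kappa)) - kappa * i1(kappa) / i0(kappa)


def copula_mutual_information(rho: float) -> float:
    """MI of a Gaussian-copula pair, −½ ln(1−ρ²) nats (marginal-free)."""
    return -0.5 * math.log1p(-rho * rho)


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Recipe for a torsion ensemble with exact analytic total entropy.

    ``marginals`` is one entry per torsion: ``("uniform",)`` or
    ``("von_mises", mu, kappa)``.  ``coupled_pairs`` holds
    ``(i, j, rho)`` column-index pairs coupled through a Gaussian
    copula; pairs must be disjoint so the analytic total
    Σ H_marginal − Σ MI is exact.  ``labels`` defaults to one χ1 per
    pseudo-residue (no covalent adjacency between columns unless the
    caller says so).
    """

    marginals: tuple
    frames: int
    seed: int
    coupled_pairs: tuple = ()
    labels: tuple = ()

    def __post_init__(self):
        used: set[int] = set()
        for i, j, rho in self.coupled_pairs:
            if not -1.0 < rho < 1.0:
                raise ValueError(f"copula rho must be in (-1, 1), got {rho}")
            if i in used or j in used or i == j:
                raise ValueError("coupled pairs must be disjoint")
            used.update((i, j))

    @property
    def n_torsions(self) -> int:
        return len(self.marginals)


def _marginal_entropy_analytic(marg) -> float:
    if marg[0] == "uniform":
        return math.log(_TWO_PI)
    if marg[0] == "von_mises":
        return von_mises_entropy(marg[2])
    raise ValueError(f"unknown marginal {marg[0]!r}")


def _quantile(marg, u: np.ndarray) -> np.ndarray:
    """Push uniform(0,1) variates through the marginal's inverse CDF."""
    if marg[0] == "uniform":
        return -math.pi + _TWO_PI * u
    _, mu, kappa = marg
    grid = np.linspace(-math.pi, math.pi, 8193)
    pdf = np.exp(kappa * np.cos(grid)) / (_TWO_PI * i0(kappa))
    cdf = np.concatenate([[0.0], np.cumsum(
        (pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    x = np.interp(u, cdf, grid)
    return _wrap(x + mu)


def sample_torsion_ensemble(spec: SyntheticEnsembleSpec):
    """Draw the ensemble and return ``(TorsionEnsemble, analytic_total_kB)``.

    Dependence is injected in Gaussian space (correlate the normals,
    then map through Φ and the marginal quantile function), so each
    coupled pair carries exactly −½ ln(1−ρ²) nats of MI regardless of
    its marginals.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.n_torsions
    z = rng.standard_normal((spec.frames, t))
    for i, j, rho in spec.coupled_pairs:
        z[:, j] = rho * z[:, i] + math.sqrt(1.0 - rho * rho) * z[:, j]
    u = norm.cdf(z)
    cols = [_quantile(m, u[:, k]) for k, m in enumerate(spec.marginals)]
    samples = _wrap(np.column_stack(cols))
    labels = list(spec.labels) or [(k + 1, "chi1") for k in range(t)]
    analytic = sum(_marginal_entropy_analytic(m) for m in spec.marginals)
    analytic -= sum(copula_mutual_information(rho)
                    for _, _, rho in spec.coupled_pairs)
    return TorsionEnsemble(labels, samples), float(analytic)


# ---------------------------------------------------------------------------
# Decoy sets
# ---------------------------------------------------------------------------

def make_decoy_set(sequence: str, n_decoys: int,
                   perturbation_scale: float = 1.0, seed: int = 0,
                   duplicates: Mapping[int, int] | None = None,
                   duplicate_scale: float = 0.005,
                   ) -> list[StructureModel]:
    """Decoy conformations of one sequence for clustering exercises.

    Each decoy gets independent random φ/ψ targets (uniform on the
    circle, scaled deviations from an extended reference by
    ``perturbation_scale``); entries of ``duplicates`` (decoy index →
    source index) instead copy the source's targets with tiny
    ``duplicate_scale`` jitter, planting near-duplicate groups whose
    mutual RMSD falls far below a 5 Å clustering threshold.
    """
    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    rng = np.random.default_rng(seed)
    duplicates = dict(duplicates or {})
    nres = len(sequence)
    targets: list[dict] = []
    for k in range(n_decoys):
        if k in duplicates:
            src = targets[duplicates[k]]
            t = {r: {nm: _wrap(v + duplicate_scale * rng.standard_normal())
                     for nm, v in d.items()}
                 for r, d in src.items()}
        else:
            t = {}
            for r in range(1, nres + 1):
                t[r] = {
                    "phi": float(_wrap(math.pi + perturbation_scale
                                       * rng.uniform(-math.pi, math.pi))),
                    "psi": float(_wrap(math.pi + perturbation_scale
                                       * rng.uniform(-math.pi, math.pi))),
                }
        targets.append(t)
    return [build_chain(sequence, t, name=f"decoy_{k:03d}")
            for k, t in enumerate(targets)]


# ---------------------------------------------------------------------------
# Energy tables with planted gaps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for an energy table with a designated free-energy winner.

    Gap sequences give each rival's offset (kcal/mol) from the winner in
    Eintra, Gsolv and −TSconf; Gaussian noise of ``noise_sd`` is added
    to every entry.  With zero noise the winner has the lowest
    Ghat = Eintra + Gsolv + (−TSconf) iff every rival's three gaps sum
    positive — the planted entropic-stabilization scenario makes a
    rival win on enthalpy alone while the winner keeps the lowest total.
    """

    n_conformations: int
    delta_Eintra: tuple
    delta_Gsolv: tuple
    delta_minusTS: tuple
    noise_sd: float = 0.0
    seed: int = 0
    winner: str = "WIN"

    def __post_init__(self):
        n = self.n_conformations - 1
        for gaps in (self.delta_Eintra, self.delta_Gsolv,
                     self.delta_minusTS):
            if len(gaps) != n:
                raise ValueError("need one gap per non-winner conformation")
            if not all(math.isfinite(g) for g in gaps):
                raise ValueError("gaps must be finite")


def make_energy_table(spec: SyntheticTableSpec) -> EnergyTable:
    rng = np.random.default_rng(spec.seed)
    names = [spec.winner] + [f"RIV{k + 1}" for k in
                             range(spec.n_conformations - 1)]
    rows = [(0.0, 0.0, 0.0)]
    rows += list(zip(spec.delta_Eintra, spec.delta_Gsolv,
                     spec.delta_minusTS))
    arr = np.array(rows, dtype=float)
    if spec.noise_sd > 0:
        arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
    df = pd.DataFrame(arr, index=pd.Index(names, name="name"),
                      columns=["Eintra", "Gsolv", "minusTSconf"])
    return EnergyTable(df, notes=f"synthetic planted table seed={spec.seed}")
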