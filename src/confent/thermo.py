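"""Free-energy cost functions and Boltzmann ranking of conformations.

The free energy of a protein conformation in solvent decomposes, up to
a conformation-independent constant, into intramolecular enthalpy,
solvation free-energy, and the configurational-entropy term:

    G ≈ Eintra + Gsolv − T·Sconf + const.

Three cost functions of increasing completeness rank a set of competing
conformations: ``Eintra`` alone, ``G0 = Eintra + Gsolv``, and the full
``Ghat = Eintra + Gsolv − T·Sconf``.  Equilibrium populations follow
from Boltzmann weights w(k) = exp(−βX(k)) / Σ exp(−βX(i)); because the
weights are invariant under adding a constant to every cost, energy
tables may ship with each column shifted so its minimum is zero.

The per-conformation energies are *inputs* (kcal/mol); this module
never computes enthalpies or solvation terms itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import KB_KCAL_PER_MOL_K

__all__ = [
    "COST_FUNCTIONS",
    "EnergyTable",
    "WeightVector",
    "MinimalSubset",
    "load_reference_energy_table",
    "evaluate_cost",
    "boltzmann_weights",
    "minimal_subset",
    "rank_report",
    "report_to_files",
    "entropy_gap_in_kBT",
    "exhaustive_minimal_subset",
]

#: Cost-function name -> energy columns summed.
COST_FUNCTIONS: Mapping[str, tuple[str, ...]] = {
    "Eintra": ("Eintra",),
    "G0": ("Eintra", "Gsolv"),
    "Ghat": ("Eintra", "Gsolv", "minusTSconf"),
}

_COLUMNS = ("Eintra", "Gsolv", "minusTSconf")


@dataclass
class EnergyTable:
    """Per-conformation energy terms in kcal/mol.

    ``minusTSconf`` stores −T·Sconf (so that Ghat is a plain row sum);
    it may be absent only while evaluating cost functions that do not
    need it.
    """

    frame: pd.DataFrame
    temperature: float = 300.0
    notes: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ("Eintra", "Gsolv") if c not in self.frame]
        if missing:
            raise ValueError(f"energy table missing columns: {missing}")
        cols = [c for c in _COLUMNS if c in self.frame]
        if not np.all(np.isfinite(self.frame[cols].to_numpy(float))):
            raise ValueError("energy values must be finite")

    @property
    def names(self) -> list[str]:
        return list(self.frame.index)

    @classmethod
    def from_csv(cls, path: str | Path, temperature: float = 300.0,
                 notes: str = "") -> "EnergyTable":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep, index_col="name")
        return cls(df, temperature, notes)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="name")


def load_reference_energy_table() -> EnergyTable:
    """The published six-conformation energy table for the Cas4 nuclease
    SSO0001: its crystallographic native state (NAT, one protomer of the
    toroidal decamer, PDB 4IC1 chain D) and five CASP10 decoy models
    (DEC1–DEC5).  Columns are shifted so each minimum is zero, which
    leaves every Boltzmann weight unchanged."""
    with resources.files("confent").joinpath(
            "data/sso0001_energies.csv").open() as fh:
        df = pd.read_csv(fh, index_col="name")
    return EnergyTable(df, temperature=300.0,
                       notes="published SSO0001 NAT + CASP10 decoy table")


# ---------------------------------------------------------------------------
# Cost evaluation and weights
# ---------------------------------------------------------------------------

def evaluate_cost(table: EnergyTable, cost: str) -> pd.Series:
    """Cost-function values per conformation, shifted so min = 0."""
    try:
        cols = COST_FUNCTIONS[cost]
    except KeyError:
        raise ValueError(
            f"unknown cost function {cost!r}; "
            f"choose from {sorted(COST_FUNCTIONS)}") from None
    missing = [c for c in cols if c not in table.frame]
    if missing:
        raise ValueError(f"cost {cost!r} needs missing columns: {missing}")
    vals = table.frame[list(cols)].sum(axis=1).astype(float)
    return vals - vals.min()


@dataclass
class WeightVector:
    """Normalized Boltzmann weights over one conformation set."""

    weights: pd.Series
    cost: str
    beta: float  # (kB T)^-1, mol/kcal

    def __post_init__(self) -> None:
        s = float(self.weights.sum())
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights sum to {s}, not 1")

    def __getitem__(self, name: str) -> float:
        return float(self.weights[name])


def boltzmann_weights(costs: pd.Series | Mapping[str, float],
                      temperature: float = 300.0,
                      cost_name: str = "") -> WeightVector:
    """Equilibrium weights w(k) = exp(−β c_k) / Σ exp(−β c_i).

    The minimum cost is subtracted before exponentiation (pure numerics;
    the weights are exactly shift-invariant).
    """
    costs = pd.Series(costs, dtype=float)
    if costs.empty:
        raise ValueError("no conformations to weight")
    if not np.all(np.isfinite(costs)):
        raise ValueError("costs must be finite")
    beta = 1.0 / (KB_KCAL_PER_MOL_K * temperature)
    e = np.exp(-beta * (costs - costs.min()))
    return WeightVector(e / e.sum(), cost_name, beta)


# ---------------------------------------------------------------------------
# Minimal contributing subset
# ---------------------------------------------------------------------------

@dataclass
class MinimalSubset:
    """Smallest conformation subsets carrying all but ε of the weight."""

    per_cost: dict[str, list[str]]
    joint: list[str]
    epsilon: float = 1e-7

    def covers(self, weights: WeightVector,
               members: Sequence[str] | None = None) -> bool:
        members = self.joint if members is None else members
        return float(weights.weights[list(members)].sum()) > 1 - self.epsilon


def minimal_subset(table: EnergyTable,
                   costs: Sequence[str] = ("Eintra", "G0", "Ghat"),
                   epsilon: float = 1e-7,
                   temperature: float | None = None) -> MinimalSubset:
    """Conformations that together carry weight > 1 − ε under each cost.

    Per cost function the subset is the shortest prefix of conformations
    sorted by descending weight (ties broken by name) — optimal for a
    single cost.  The joint set is the union of the per-cost prefixes.
    """
    T = table.temperature if temperature is None else temperature
    per_cost: dict[str, list[str]] = {}
    joint: list[str] = []
    for x in costs:
        w = boltzmann_weights(evaluate_cost(table, x), T, x)
        order = sorted(w.weights.items(), key=lambda kv: (-kv[1], kv[0]))
        acc, members = 0.0, []
        for name, wk in order:
            members.append(name)
            acc += wk
            if acc > 1 - epsilon:
                break
        per_cost[x] = members
        joint.extend(m for m in members if m not in joint)
    return MinimalSubset(per_cost, sorted(joint), epsilon)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _ranks(values: pd.Series) -> pd.Series:
    # competition ranking: ties share the lower rank
    return values.rank(method="min").astype(int)


def rank_report(table: EnergyTable,
                temperature: float | None = None) -> pd.DataFrame:
    """Shifted energies and bracketed ranks for every term and cost.

    Columns: Eintra, Gsolv, minusTSconf, G0, Ghat (each shifted to a
    zero minimum) plus ``rank_*`` integer columns.
    """
    df = pd.DataFrame(index=table.frame.index)
    for col in _COLUMNS:
        if col in table.frame:
            df[col] = table.frame[col] - table.frame[col].min()
    for cost in ("G0", "Ghat"):
        try:
            df[cost] = evaluate_cost(table, cost)
        except ValueError:
            continue
    for col in list(df.columns):
        df[f"rank_{col}"] = _ranks(df[col])
    return df


def report_to_files(table: EnergyTable, out_dir: str | Path,
                    temperature: float | None = None,
                    epsilon: float = 1e-7) -> dict:
    """Write the full ranking report: TSV table + JSON weights/subsets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    T = table.temperature if temperature is None else temperature
    report = rank_report(table, T)
    report.to_csv(out_dir / "rank_report.tsv", sep="\t",
                  index_label="name", float_format="%.4f")
    payload: dict = {"temperature_K": T, "epsilon": epsilon, "weights": {},
                     "gaps": {}}
    available = [x for x in COST_FUNCTIONS
                 if all(c in table.frame for c in COST_FUNCTIONS[x])]
    for x in available:
        c = evaluate_cost(table, x)
        w = boltzmann_weights(c, T, x)
        payload["weights"][x] = {k: float(v) for k, v in w.weights.items()}
        gap = float(c.nsmallest(2).iloc[-1]) if len(c) > 1 else 0.0
        payload["gaps"][x] = {"kcal_per_mol": gap,
                              "kBT": entropy_gap_in_kBT(gap, T)}
    sub = minimal_subset(table, available, epsilon, T)
    payload["minimal_subset"] = {"per_cost": sub.per_cost,
                                 "joint": sub.joint}
    with open(out_dir / "weights.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload


def entropy_gap_in_kBT(gap_kcal_per_mol: float,
                       temperature: float = 300.0) -> float:
    """Express an energy gap as a multiple of kB·T (1 kcal/mol ≈ 1.67
    kBT at 300 K)."""
    return gap_kcal_per_mol / (KB_KCAL_PER_MOL_K * temperature)


def exhaustive_minimal_subset(table: EnergyTable, cost: str,
                              epsilon: float = 1e-7,
                              temperature: float | None = None) -> list[str]:
    """Brute-force smallest covering subset for one cost function.

    Enumerates all 2^N subsets — a cross-check for small conformation
    sets, not for production use.
    """
    T = table.temperature if temperature is None else temperature
    w = boltzmann_weights(evaluate_cost(table, cost), T, cost)
    names = list(w.weights.index)
    for size in range(1, len(names) + 1):
        best = None
        for combo in combinations(sorted(names), size):
            if float(w.weights[list(combo)].sum()) > 1 - epsilon:
                if best is None:
                    best = list(combo)
        if best is not None:
            return best
    return sorted(names)
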