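# confent

Configurational-entropy decomposition and Boltzmann ranking of protein
conformational ensembles.

## The problem

Cost-function-based protein software (structure prediction scoring,
design, decoy ranking) usually approximates the free energy of a
conformation by its intramolecular enthalpy `Eintra` plus solvation
free-energy `Gsolv`, and neglects configurational entropy `Sconf`
because it is expensive to sample.  For many proteins this is harmless;
for some it selects the wrong native state.  The Cas4 nuclease SSO0001
of *Sulfolobus solfataricus* is a striking case: its open, loosely
packed native fold (one protomer of a toroidal decamer) has *higher*
enthalpy than several compact decoy models, and only the entropic term
`−T·Sconf` puts it at the bottom of the free-energy landscape:

    G ≈ Eintra + Gsolv − T·Sconf + const.

`confent` implements the analysis machinery for this kind of study:

* **Entropy estimation** (`confent.entropy`): per-residue partial
  entropies from torsion-angle ensembles,
  `S_i = Σ H(torsion) − Σ I(adjacent torsion pairs)`, with
  `Sconf + C = Σ S_i` (MIST-style decomposition; the constant `C`
  cancels in all comparisons).  Circular histogram estimators with
  Miller–Madow bias correction.
* **Thermodynamic ranking** (`confent.thermo`): cost functions
  `Eintra`, `G0 = Eintra + Gsolv`, `Ghat = Eintra + Gsolv − T·Sconf`;
  Boltzmann weights `w(k) = exp(−β X(k)) / Σ_i exp(−β X(i))`; minimal
  subsets of conformations carrying weight `> 1 − ε`; Table-style rank
  reports.  The published SSO0001 energy table ships as a fixture.
* **Structure handling** (`confent.structures`): PDB reading (single- and
  multi-model), φ/ψ/χ torsion extraction, B-factor-annotated PDB output
  for per-residue coloring.
* **Characterization** (`confent.characterize`): Kabsch RMSD, UPGMA
  deduplication of decoy sets at a 5 Å threshold, Cα contact maps,
  radius of gyration, Shrake–Rupley SASA, simplified H/E/C secondary
  structure.
* **Synthetic ground truth** (`confent.synthetic`): ideal-geometry
  chains built from torsion targets, torsion ensembles with *analytic*
  entropy (uniform / von Mises marginals, Gaussian-copula couplings),
  decoy sets with planted duplicates, and energy tables with planted
  enthalpy/entropy gaps.

A `confent` command-line tool exposes the workflow as subcommands
(`dedup`, `rank`, `entropy`, `diff`, `characterize`, `simulate`).

## Worked example

Rank the bundled SSO0001 table (native state NAT plus decoys DEC1–DEC5,
energies in kcal/mol at 300 K):

```python
from confent import (load_reference_energy_table, evaluate_cost,
                     boltzmann_weights, entropy_gap_in_kBT)

table = load_reference_energy_table()
for cost in ("Eintra", "G0", "Ghat"):
    w = boltzmann_weights(evaluate_cost(table, cost))
    top = sorted(w.weights.items(), key=lambda kv: -kv[1])[:3]
    print(cost, " ".join(f"{n}={v:.3f}" for n, v in top))
```

prints

```
Eintra DEC1=0.675 DEC2=0.176 DEC3=0.149
G0 DEC3=0.586 NAT=0.299 DEC5=0.109
Ghat NAT=1.000 DEC5=0.000 DEC3=0.000
```

Enthalpy alone predicts a mixture of three compact decoys and gives the
native state a weight of ~10⁻⁵; adding solvation (`G0`) makes NAT a
30% minority species; only the full cost function including
`−T·Sconf` identifies NAT as the dominant state (weight > 0.99999,
separated from the runner-up by 7.6 kcal/mol ≈ 12.7 kBT).

Entropy estimation against analytic ground truth:

```python
from confent import (SyntheticEnsembleSpec, sample_torsion_ensemble,
                     partial_entropies)

spec = SyntheticEnsembleSpec(
    marginals=(("von_mises", 0.0, 2.0), ("uniform",)),
    frames=100_000, seed=1, coupled_pairs=((0, 1, 0.5),),
    labels=((1, "chi1"), (1, "chi2")))
ensemble, analytic = sample_torsion_ensemble(spec)
profile = partial_entropies(ensemble)
print(f"estimated total = {profile.total:.4f} kB (analytic {analytic:.4f} kB)")
```

prints

```
estimated total = 2.9629 kB (analytic 2.9604 kB)
```

— a von Mises torsion (κ=2) plus a uniform torsion coupled at ρ=0.5
carry `1.2663 + 1.8379 − 0.1438 ≈ 2.96 kB` of entropy, recovered by the
histogram estimator to a few thousandths of a kB at 10⁵ frames.

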