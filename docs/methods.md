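# Methods

## Free-energy model

A conformation `k` of a protein in solvent is scored by

    G(k) ≈ Eintra(k) + Gsolv(k) − T·Sconf(k) + const,

where `Eintra` is the average intramolecular enthalpy, `Gsolv` the
average solvation free-energy, and `Sconf` the configurational entropy
of the protein's internal degrees of freedom (not solvent entropy).
The constant is conformation-independent and never enters a
comparison.  `Eintra` and `Gsolv` are consumed as inputs (kcal/mol,
e.g. from an empirical force-field tool); computing them is explicitly
out of scope.  Equilibrium populations over a conformation set `M`
follow the Boltzmann distribution

    w_X(k) = exp(−β X(k)) / Σ_{i∈M} exp(−β X(i)),   β = 1/(kB·T),

for a cost function `X ∈ {Eintra, G0 = Eintra+Gsolv,
Ghat = Eintra+Gsolv−T·Sconf}`.  We use kB = 0.0019872 kcal/(mol·K) and
default T = 300 K everywhere; the rounded kBT ≈ 0.6 kcal/mol appears
only in prose.  Weights are computed with the minimum cost subtracted
before exponentiation; this is exact (shift invariance), which is also
why shipping energy tables with each column shifted to a zero minimum
is harmless.

**Minimal contributing subset.** For pruning large decoy sets, the
smallest subset `U ⊂ M` with `Σ_{k∈U} w_X(k) > 1 − ε` (default
ε = 10⁻⁷) is taken per cost function as the shortest prefix of
conformations sorted by descending weight — optimal for a single cost
function; ties broken by name for determinism.  The joint subset is the
union of the per-cost prefixes.  A union of prefix-optimal sets over a
shared ground set cannot be beaten by a smaller joint set satisfying
all three coverage constraints separately, and an exhaustive 2^N
enumeration is kept in the test suite as an oracle for small N.

## Entropy decomposition

The configurational entropy of a torsion-angle ensemble is decomposed
into per-residue partial entropies

    S_i = Σ_t H(θ_t)  −  Σ_{(t,u)} I(θ_t, θ_u),

where `t` runs over the torsions belonging to residue `i` (φ, ψ,
χ1–χ4) and `(t,u)` over the *covalently adjacent* torsion pairs
charged to residue `i`.  Then `Sconf + C = Σ_i S_i` with `C` a
sequence-dependent constant; `C` is never estimated, and every reported
quantity is a difference in which it cancels.  This is an
approximation in the spirit of the maximum-information-spanning-tree
(MIST) bound: marginals minus pairwise mutual informations.

Conventions (stand-ins where the field has no single canon; all are
explicit package contracts):

* Adjacent pairs: (φᵢ,ψᵢ), (φᵢ,χ1ᵢ), (ψᵢ,χ1ᵢ), (χkᵢ,χk+1ᵢ), and the
  backbone link (ψᵢ, φᵢ₊₁).
* Ownership: intra-residue pairs are charged to their residue; the
  cross-residue backbone pair to residue i+1.  Ownership is an
  arbitrary but fixed bookkeeping needed to make Σ S_i well defined;
  totals are ownership-independent.
* *All* adjacent pairs are subtracted, not a maximum-information
  spanning tree; with loops in the adjacency graph (φ–ψ–χ1 triangle)
  this can over-subtract relative to a strict MIST bound.  Documented
  limitation.
* ω is treated as rigid and never emitted; φ of the first and ψ of the
  last residue of a chain are simply omitted (chain-end convention).
* χ angles follow the standard side-chain atom quadruples; residues
  with missing side-chain atoms lose the affected χ with a warning.

## Estimators

Marginal differential entropies use 30 equal circular bins on [−π, π)
(≈12° resolution): `Ĥ = −Σ p̂ ln p̂ + ln(2π/30)`.  Mutual information
uses the 30×30 product grid: `Î = Ĥ(x) + Ĥ(y) − Ĥ(x,y)` (the bin-width
reference terms cancel).  30 bins balances discretization bias against
counting noise in the 10³–10⁵-frame regime this package targets; the
bin count is a config parameter.  Miller–Madow bias correction
(`+(K−1)/2F` per entropy, `K` = occupied bins) is on by default;
corrected MI below zero is clipped to 0, which preserves the invariant
that the decomposed total never exceeds the sum of marginals.  Units
are kB (nats) throughout; `entropy_to_free_energy` converts to
−TS kcal/mol.

Expected accuracy (asserted in the tests): at 10⁵ frames, marginal
entropies of uniform and von Mises (κ ≤ 8) torsions are recovered
within 0.05 kB and Gaussian-copula MI within 0.02 kB.  The dominant
residual at high κ is the O(w²) discretization bias (~0.014 kB at
κ = 8), well inside those bands.

## Structure handling and descriptors

* PDB parsing via Biopython; altloc resolved to highest occupancy,
  hydrogens and HETATM ignored.  Torsions use the IUPAC sign
  convention (anti = ±180°), values in [−π, π).
* Kabsch superposition by SVD with the reflection branch corrected to a
  proper rotation; RMSD selection defaults to Cα (the usual convention
  for decoy-model comparison).
* Deduplication: UPGMA (scipy average linkage) with a *strict* cut —
  merges happen only while the linkage is below the threshold (default
  5 Å); one representative per cluster drawn uniformly with the given
  seed.
* Shrake–Rupley SASA with golden-spiral point sampling (960 points
  default, 92 for speed), probe 1.4 Å, built-in radius table
  C 1.70 / N 1.55 / O 1.52 / S 1.80 Å.
* Secondary structure is a deliberately simplified three-state
  assignment for reports only: amide H placed along the preceding C=O
  direction, the classic electrostatic H-bond energy
  `0.084·332·(1/rON + 1/rCH − 1/rOH − 1/rCN)` kcal/mol with a
  −0.5 cutoff, i→i+4 patterns → H, mutual/offset long-range bridges
  → E, else C.  It is not a DSSP replacement.
* The "unfolded model" drop in the dedup pipeline uses an Rg heuristic
  (`Rg > c·Nres^0.38`, c configurable, default 3.0 Å) — a documented
  stand-in, since compactness scaling is the only structure-only signal
  available.

## Synthetic data: what it emulates and what it does not

The generators replace inputs that would otherwise require downloads
or molecular-dynamics sampling:

* `build_chain` constructs backbones (N, CA, C, O, CB) with ideal
  bond geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å; ω = 180°) from
  φ/ψ targets; `compute_torsions` recovers the targets to < 10⁻⁶ rad,
  making chain construction and torsion extraction mutually testable.
* `sample_torsion_ensemble` draws torsion ensembles with uniform or
  von Mises marginals and Gaussian-copula couplings.  The copula was
  chosen because its MI has the closed form −½·ln(1−ρ²) for *any*
  marginals, so every generated ensemble carries an exact analytic
  total entropy — the oracle for the estimators.  Coupled pairs must be
  disjoint to keep that total exact.
* `make_decoy_set` perturbs φ/ψ targets to produce mutually distinct
  conformations, with optional near-duplicate groups (jitter ~0.005
  rad) planted well below a 5 Å clustering threshold.
* `make_energy_table` plants per-conformation enthalpy/solvation/
  entropy gaps around a designated winner, reproducing the ranking
  reversal: the winner loses under `G0` but wins under `Ghat` exactly
  when its planted entropic advantage exceeds the rival's `G0` lead.

What the synthetic data does **not** emulate: real side-chain packing,
correlated backbone motion beyond pairwise copulas, force-field
energies, solvent structure, or the statistics of real decoy sets.
Passing tests therefore demonstrate correctness of the estimators and
bookkeeping under known ground truth, not accuracy of entropy
estimates on real MD ensembles.

## Numerical and design choices

* Degenerate dihedrals (coincident/collinear points) raise instead of
  returning an arbitrary angle.
* Entropy of a frozen ensemble (all frames identical) evaluates to the
  single-bin floor `ln(2π/30)` per torsion — finite by construction of
  the histogram estimator, not a statement about true (−∞) point-mass
  differential entropy.
* Rank reports use competition ranking (ties share the lower rank).
* UPGMA determinism: scipy's merge order is deterministic for a fixed
  input ordering; representatives are seeded.
* Problem sizes in tests and examples (10⁵ frames, ≤ 40-residue
  chains, six-conformation tables) are desk-scale choices that keep
  the full suite in a few seconds while leaving estimator errors an
  order of magnitude below the asserted tolerances.

## Known limitations

* The adjacency/ownership conventions above are package conventions,
  not a reproduction of any published exact definition.
* The per-residue decomposition ignores MI between non-adjacent
  torsions entirely; long-range correlated motions are invisible.
* Secondary-structure assignment is approximate near chain ends and
  for irregular strands.
* Energy-table inputs are trusted as given; no force-field validation
  is performed.
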