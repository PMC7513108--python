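"""Entropy estimators, adjacency bookkeeping, and unit conversions."""

import math

import numpy as np
import pytest

from confent.entropy import (build_adjacency, entropy_difference,
                             entropy_to_free_energy, marginal_entropy,
                             mutual_information, partial_entropies,
                             PartialEntropyProfile)
from confent.structures import TorsionEnsemble
from confent.synthetic import (SyntheticEnsembleSpec, copula_mutual_information,
                               sample_torsion_ensemble, von_mises_entropy)

LN_2PI = math.log(2 * math.pi)


def _ensemble(labels, samples):
    return TorsionEnsemble(labels, np.asarray(samples))


class TestAdjacency:
    def test_two_residue_backbone_pair_owned_downstream(self):
        ens = _ensemble([(1, "psi"), (2, "phi")], np.zeros((2, 2)))
        adj = build_adjacency(ens)
        pair = tuple(sorted([(1, "psi"), (2, "phi")]))
        assert set(adj.pairs) == {pair}
        assert adj.owner[pair] == 2

    def test_single_torsion_no_pairs(self):
        ens = _ensemble([(1, "chi1")], np.zeros((2, 1)))
        assert not build_adjacency(ens).pairs

    def test_lysine_side_chain_ladder(self):
        labels = [(2, "phi"), (2, "psi"), (2, "chi1"), (2, "chi2"),
                  (2, "chi3"), (2, "chi4")]
        adj = build_adjacency(_ensemble(labels, np.zeros((2, 6))))
        owned = adj.owned_by(2)
        expected = {
            tuple(sorted([(2, "phi"), (2, "psi")])),
            tuple(sorted([(2, "phi"), (2, "chi1")])),
            tuple(sorted([(2, "psi"), (2, "chi1")])),
            tuple(sorted([(2, "chi1"), (2, "chi2")])),
            tuple(sorted([(2, "chi2"), (2, "chi3")])),
            tuple(sorted([(2, "chi3"), (2, "chi4")])),
        }
        assert set(owned) == expected


class TestMarginalEntropy:
    def test_uniform_matches_closed_form(self, rng):
        x = rng.uniform(-math.pi, math.pi, 100_000)
        assert marginal_entropy(x) == pytest.approx(LN_2PI, abs=0.01)

    def test_von_mises_matches_analytic(self, rng):
        x = rng.vonmises(0.0, 2.0, 100_000)
        x = (x + math.pi) % (2 * math.pi) - math.pi
        assert von_mises_entropy(2.0) == pytest.approx(1.2664, abs=1e-4)
        assert marginal_entropy(x) == pytest.approx(von_mises_entropy(2.0),
                                                    abs=0.02)

    def test_von_mises_analytic_against_quadrature(self):
        from scipy.integrate import quad
        from scipy.special import i0
        for kappa in (0.5, 2.0, 8.0):
            def neg_plogp(t):
                p = math.exp(kappa * math.cos(t)) / (2 * math.pi * i0(kappa))
                return -p * math.log(p)
            num, _ = quad(neg_plogp, -math.pi, math.pi)
            assert von_mises_entropy(kappa) == pytest.approx(num, abs=1e-9)

    def test_point_mass_hits_single_bin_floor(self):
        x = np.full(500, 0.123)
        assert marginal_entropy(x, bins=30) == pytest.approx(
            math.log(2 * math.pi / 30), abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            marginal_entropy(np.array([]))


class TestMutualInformation:
    def test_independent_near_zero(self, rng):
        x = rng.uniform(-math.pi, math.pi, 100_000)
        y = rng.uniform(-math.pi, math.pi, 100_000)
        assert mutual_information(x, y) <= 0.01

    def test_copy_is_maximal(self, rng):
        x = rng.uniform(-math.pi, math.pi, 50_000)
        mi = mutual_information(x, x)
        discrete_h = marginal_entropy(x) - math.log(2 * math.pi / 30)
        assert mi == pytest.approx(discrete_h, abs=0.01)

    def test_gaussian_copula_closed_form(self):
        spec = SyntheticEnsembleSpec(
            marginals=(("von_mises", 0.0, 2.0), ("von_mises", 0.0, 2.0)),
            frames=100_000, seed=11, coupled_pairs=((0, 1, 0.5),))
        ens, _ = sample_torsion_ensemble(spec)
        target = copula_mutual_information(0.5)
        assert target == pytest.approx(-0.5 * math.log(1 - 0.25), abs=1e-12)
        assert mutual_information(ens.samples[:, 0], ens.samples[:, 1]) \
            == pytest.approx(target, abs=0.02)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(5), np.zeros(6))

    def test_never_negative(self, rng):
        for _ in range(5):
            x = rng.uniform(-math.pi, math.pi, 200)
            y = rng.uniform(-math.pi, math.pi, 200)
            assert mutual_information(x, y) >= 0.0


class TestPartialEntropies:
    def test_independent_uniform_profile(self, rng):
        f = 50_000
        labels = [(1, "psi"), (2, "phi"), (2, "psi"), (3, "phi")]
        samples = rng.uniform(-math.pi, math.pi, (f, 4))
        prof = partial_entropies(_ensemble(labels, samples))
        # per residue: torsion count × ln 2π minus ~zero MI
        counts = {1: 1, 2: 2, 3: 1}
        for r, si in zip(prof.residues, prof.si):
            assert si == pytest.approx(counts[r] * LN_2PI, abs=0.05)
        assert prof.total == pytest.approx(4 * LN_2PI, abs=0.1)
        assert prof.total == pytest.approx(prof.si.sum(), abs=1e-12)

    def test_rigid_ensemble_hits_floor(self):
        labels = [(1, "psi"), (2, "phi")]
        samples = np.tile([0.5, -1.0], (10, 1))
        prof = partial_entropies(_ensemble(labels, samples))
        floor = math.log(2 * math.pi / 30)
        # MI of two point masses is 0; each residue sits at the one-bin floor
        np.testing.assert_allclose(prof.si, [floor, floor], atol=1e-9)

    def test_coupled_pair_lowers_owner_entropy(self):
        rho = 0.8
        marginals = tuple(("uniform",) for _ in range(6))
        labels = ((1, "chi1"), (2, "chi1"), (3, "chi1"), (5, "chi1"),
                  (5, "chi2"), (6, "chi1"))
        spec = SyntheticEnsembleSpec(marginals=marginals, frames=100_000,
                                     seed=5, coupled_pairs=((3, 4, rho),),
                                     labels=labels)
        ens, analytic = sample_torsion_ensemble(spec)
        prof = partial_entropies(ens)
        s5 = prof.si[prof.residues.index(5)]
        expected = 2 * LN_2PI - copula_mutual_information(rho)
        assert copula_mutual_information(rho) == pytest.approx(0.5108, abs=1e-4)
        assert s5 == pytest.approx(expected, abs=0.05)
        assert prof.total == pytest.approx(analytic, abs=0.1)

    def test_frame_permutation_invariance(self, rng):
        labels = [(1, "psi"), (2, "phi")]
        samples = rng.uniform(-math.pi, math.pi, (500, 2))
        p1 = partial_entropies(_ensemble(labels, samples))
        p2 = partial_entropies(_ensemble(labels,
                                         samples[rng.permutation(500)]))
        np.testing.assert_allclose(p1.si, p2.si, atol=1e-12)

    def test_total_bounded_by_sum_of_marginals(self, rng):
        spec = SyntheticEnsembleSpec(
            marginals=tuple(("von_mises", 0.0, 1.0) for _ in range(4)),
            frames=2000, seed=9, coupled_pairs=((0, 1, 0.6), (2, 3, 0.4)),
            labels=((1, "chi1"), (1, "chi2"), (2, "chi1"), (2, "chi2")))
        ens, _ = sample_torsion_ensemble(spec)
        prof = partial_entropies(ens)
        indep = sum(marginal_entropy(ens.samples[:, k]) for k in range(4))
        assert prof.total <= indep + 1e-12

    def test_estimates_converge_with_frames(self):
        errors = []
        for frames in (1000, 10_000, 100_000):
            spec = SyntheticEnsembleSpec(
                marginals=(("von_mises", 0.5, 2.0), ("uniform",)),
                frames=frames, seed=2, coupled_pairs=((0, 1, 0.5),),
                labels=((1, "chi1"), (1, "chi2")))
            ens, analytic = sample_torsion_ensemble(spec)
            prof = partial_entropies(ens)
            errors.append(abs(prof.total - analytic))
        assert errors[-1] <= errors[0] + 0.01
        assert errors[-1] < 0.05

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            partial_entropies(_ensemble([(1, "psi")], np.zeros((1, 1))))


class TestEntropyDifference:
    def _profile(self, si, seq="AAAA"):
        return PartialEntropyProfile(list(range(1, len(si) + 1)),
                                     np.asarray(si, float), seq)

    def test_identical_profiles_zero(self):
        a = self._profile([1.0, 2.0, 3.0, 4.0])
        d = entropy_difference(a, a)
        assert np.all(d.delta_si == 0) and d.total == 0

    def test_total_is_difference_of_totals(self, rng):
        a = self._profile(rng.standard_normal(4))
        b = self._profile(rng.standard_normal(4))
        d = entropy_difference(a, b)
        assert d.total == pytest.approx(a.total - b.total, abs=1e-12)

    def test_segment_fraction_printed_values(self):
        # a 6.4 kB segment of a 14.6 kB total difference carries 44%
        si = np.zeros(100)
        si[52:72] = 6.4 / 20  # residues 53..72
        si[:52] = (14.6 - 6.4) / 52
        d = entropy_difference(self._profile(si, "A" * 100),
                               self._profile(np.zeros(100), "A" * 100))
        assert d.segment_sum(53, 72) == pytest.approx(6.4, abs=1e-9)
        assert 100 * d.segment_fraction(53, 72) == pytest.approx(44.0,
                                                                 abs=1.0)

    def test_full_segment_is_total(self):
        a = self._profile([0.5, 1.0, -0.25, 2.0])
        d = entropy_difference(a, self._profile([0, 0, 0, 0]))
        assert d.segment_fraction(1, 4) == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            entropy_difference(self._profile([1.0]),
                               self._profile([1.0, 2.0], "AA"))


class TestConversions:
    def test_zero(self):
        assert entropy_to_free_energy(0.0) == 0.0

    def test_one_kb_at_300K(self):
        assert entropy_to_free_energy(1.0, 300.0) == pytest.approx(
            -0.59616, abs=1e-9)

    def test_published_entropy_difference_in_kcal(self):
        # 14.6 kB at 300 K <-> -8.70 kcal/mol
        assert entropy_to_free_energy(14.6, 300.0) == pytest.approx(
            -8.70, abs=0.05)
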