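"""Partition-function occupancy simulator: oracles, invariants, competition.

The enumeration-based simulator is checked against hand-derived closed-form
partition functions for small promoters, against independence factorization
at unit cooperativity, and against the qualitative competition behaviour of
weak- vs strong-dimerizing receptor archetypes.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srbind as sb
from srbind.errors import InvalidParameterError, PromoterSizeError
from srbind.occupancy_sim import state_probabilities, state_weight


def make_species(name="s", k_dim=16e-9, k_half=1e-6, k_pal=10e-9, k_c=1.0):
    return sb.ReceptorSpecies(name=name, k_dim=k_dim, k_half=k_half,
                              k_pal=k_pal, k_c=k_c)


# ---------------------------------------------------------------------------
# closed-form oracles (hand-derived partition functions)


def closed_form_one_site(site, species_list, totals):
    """Z for a single site: 1 + sum_s c_s, P_s = c_s / Z."""
    cs = []
    for sp, t in zip(species_list, totals):
        x, m2 = sp.solution_concentrations(t)
        cs.append(x / sp.k_half if site == "half" else m2 / sp.k_pal)
    z = 1.0 + sum(cs)
    return [c / z for c in cs]


def closed_form_two_sites(sites, species_list, totals):
    """P(full homotypic) for two sites: c1_s c2_s k_c,s / Z with
    Z = (1 + sum c1)(1 + sum c2) + sum c1_s c2_s (k_c,s - 1)."""
    c1, c2 = [], []
    for sp, t in zip(species_list, totals):
        x, m2 = sp.solution_concentrations(t)
        c1.append(x / sp.k_half if sites[0] == "half" else m2 / sp.k_pal)
        c2.append(x / sp.k_half if sites[1] == "half" else m2 / sp.k_pal)
    z = (1 + sum(c1)) * (1 + sum(c2)) + sum(
        a * b * (sp.k_c - 1.0) for a, b, sp in zip(c1, c2, species_list)
    )
    return [a * b * sp.k_c / z for a, b, sp in zip(c1, c2, species_list)]


def closed_form_three_sites(sites, species_list, totals):
    """P(full homotypic) for a linear three-site promoter.

    Full homotypic weight: c1 c2 c3 k_c^2 (two adjacent pairs); Z summed
    over all 4^3-style states by brute products here, independently of the
    package's enumeration order.
    """
    concs = []
    for sp, t in zip(species_list, totals):
        x, m2 = sp.solution_concentrations(t)
        concs.append(
            [x / sp.k_half if s == "half" else m2 / sp.k_pal for s in sites]
        )
    n = len(species_list)
    z = 0.0
    full = [0.0] * n
    for o1 in range(-1, n):
        for o2 in range(-1, n):
            for o3 in range(-1, n):
                w = 1.0
                for pos, occ in enumerate((o1, o2, o3)):
                    if occ >= 0:
                        w *= concs[occ][pos]
                if o1 >= 0 and o1 == o2:
                    w *= species_list[o1].k_c
                if o2 >= 0 and o2 == o3:
                    w *= species_list[o2].k_c
                z += w
                if o1 == o2 == o3 and o1 >= 0:
                    full[o1] += w
    return [f / z for f in full]


ARCHS_1 = [("half",), ("palindrome",)]
ARCHS_2 = [("half", "half"), ("half", "palindrome"),
           ("palindrome", "half"), ("palindrome", "palindrome")]
ARCHS_3 = [("half", "half", "half"), ("half", "palindrome", "half"),
           ("palindrome", "palindrome", "palindrome"),
           ("palindrome", "half", "palindrome")]


class TestEnumeration:
    def test_single_palindrome_two_states(self):
        arch = sb.PromoterArchitecture(["palindrome"])
        states = sb.enumerate_microstates(arch, [make_species()])
        assert set(states) == {(0,), (None,)}

    def test_state_count_two_sites_three_species(self):
        arch = sb.PromoterArchitecture(["half", "palindrome"])
        species = [make_species(name=f"s{i}") for i in range(3)]
        assert len(sb.enumerate_microstates(arch, species)) == 16

    def test_double_half_site_weight_includes_cooperativity(self):
        # both half-sites occupied by one species: (x/k_half)^2 * k_c
        sp = make_species(k_c=25.0)
        arch = sb.PromoterArchitecture(["half", "half"])
        x, m2 = sp.solution_concentrations(1e-7)
        w = state_weight((0, 0), arch, [sp], [x], [m2])
        assert w == pytest.approx((x / sp.k_half) ** 2 * 25.0, rel=1e-12)

    def test_heterotypic_pair_gets_no_cooperativity(self):
        sp1, sp2 = make_species("a", k_c=100.0), make_species("b", k_c=100.0)
        arch = sb.PromoterArchitecture(["half", "half"])
        xs = [sp.solution_concentrations(1e-7) for sp in (sp1, sp2)]
        x, m2 = zip(*xs)
        w = state_weight((0, 1), arch, [sp1, sp2], x, m2)
        assert w == pytest.approx((x[0] / sp1.k_half) * (x[1] / sp2.k_half),
                                  rel=1e-12)

    def test_size_bound(self):
        with pytest.raises(PromoterSizeError):
            sb.PromoterArchitecture(["half"] * 13)


class TestClosedFormOracles:
    SPECIES_SETS = [
        [make_species("a", k_dim=16e-9, k_c=1.0)],
        [make_species("a", k_dim=16e-9, k_c=1.0),
         make_species("b", k_dim=1e-6, k_c=50.0)],
        [make_species("a", k_dim=10e-6, k_half=2e-6, k_c=200.0),
         make_species("b", k_dim=1e-6, k_pal=5e-9, k_c=50.0),
         make_species("c", k_dim=16e-9, k_c=1.0)],
    ]

    @pytest.mark.parametrize("arch_sites", ARCHS_1)
    @pytest.mark.parametrize("iset", range(3))
    def test_one_site(self, arch_sites, iset):
        species = self.SPECIES_SETS[iset]
        totals = [1e-7 * (i + 1) for i in range(len(species))]
        arch = sb.PromoterArchitecture(arch_sites)
        got = sb.prob_fully_ligated(arch, species, totals)
        want = closed_form_one_site(arch_sites[0], species, totals)
        for sp, w in zip(species, want):
            assert got[sp.name] == pytest.approx(w, abs=1e-10)

    @pytest.mark.parametrize("arch_sites", ARCHS_2)
    @pytest.mark.parametrize("iset", range(3))
    def test_two_sites(self, arch_sites, iset):
        species = self.SPECIES_SETS[iset]
        totals = [2e-7] * len(species)
        arch = sb.PromoterArchitecture(arch_sites)
        got = sb.prob_fully_ligated(arch, species, totals)
        want = closed_form_two_sites(arch_sites, species, totals)
        for sp, w in zip(species, want):
            assert got[sp.name] == pytest.approx(w, abs=1e-10)

    @pytest.mark.parametrize("arch_sites", ARCHS_3)
    @pytest.mark.parametrize("iset", range(3))
    def test_three_sites(self, arch_sites, iset):
        species = self.SPECIES_SETS[iset]
        totals = [5e-8 * (i + 1) for i in range(len(species))]
        arch = sb.PromoterArchitecture(arch_sites)
        got = sb.prob_fully_ligated(arch, species, totals)
        want = closed_form_three_sites(arch_sites, species, totals)
        for sp, w in zip(species, want):
            assert got[sp.name] == pytest.approx(w, abs=1e-10)

    def test_single_species_palindrome_reference_point(self):
        # green-like receptor, 100 nM total: x = 24.57 nM, [M2] = 37.7 nM,
        # P(bound) = 37.7 / (10 + 37.7) = 0.790
        sp = make_species(k_dim=16e-9, k_pal=10e-9)
        arch = sb.PromoterArchitecture(["palindrome"])
        got = sb.prob_fully_ligated(arch, [sp], [100e-9])
        assert got[sp.name] == pytest.approx(0.790, abs=0.001)


class TestInvariants:
    @given(
        log_total=st.floats(min_value=-10, max_value=-4),
        n_sites=st.integers(min_value=1, max_value=3),
        kc=st.floats(min_value=0.1, max_value=500.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_normalization(self, log_total, n_sites, kc):
        species = [make_species("a", k_c=kc), make_species("b", k_dim=1e-6)]
        arch = sb.PromoterArchitecture(
            ["half", "palindrome", "half"][:n_sites]
        )
        probs = state_probabilities(arch, species, [10.0**log_total] * 2)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-10)
        assert all(0.0 <= p <= 1.0 for p in probs.values())

    def test_unit_cooperativity_factorizes(self):
        # with k_c = 1 joint occupancy is the product of site occupancies
        sp = make_species(k_c=1.0)
        arch2 = sb.PromoterArchitecture(["half", "half"])
        arch1 = sb.PromoterArchitecture(["half"])
        p_joint = sb.prob_fully_ligated(arch2, [sp], [1e-7])[sp.name]
        p_single = sb.prob_fully_ligated(arch1, [sp], [1e-7])[sp.name]
        assert p_joint == pytest.approx(p_single**2, abs=1e-10)

    def test_identical_species_split_equally(self):
        a = make_species("a", k_dim=1e-6, k_c=50.0)
        b = make_species("b", k_dim=1e-6, k_c=50.0)
        arch = sb.PromoterArchitecture(["palindrome", "palindrome"])
        got = sb.prob_fully_ligated(arch, [a, b], [1e-7, 1e-7])
        assert got["a"] == pytest.approx(got["b"], rel=1e-12)

    def test_species_permutation_invariance(self, fig10_species):
        arch = sb.PromoterArchitecture(["half", "palindrome"])
        totals = [1e-7, 2e-7, 3e-7]
        got = sb.prob_fully_ligated(arch, fig10_species, totals)
        perm = [2, 0, 1]
        got_perm = sb.prob_fully_ligated(
            arch,
            [fig10_species[i] for i in perm],
            [totals[i] for i in perm],
        )
        for name in got:
            assert got[name] == pytest.approx(got_perm[name], rel=1e-12)

    def test_monotone_in_own_concentration(self, fig10_species):
        arch = sb.PromoterArchitecture(["half", "half"])
        others = [1e-7, 1e-7]
        probs = [
            sb.prob_fully_ligated(arch, fig10_species, [t] + others)["red"]
            for t in np.logspace(-9, -4, 30)
        ]
        assert np.all(np.diff(probs) >= -1e-12)

    def test_non_dimerizing_species_cannot_occupy_palindrome(self):
        sp = sb.ReceptorSpecies(name="m", k_dim=None, k_half=1e-6, k_pal=10e-9)
        arch = sb.PromoterArchitecture(["palindrome"])
        assert sb.prob_fully_ligated(arch, [sp], [1e-5])["m"] == 0.0

    def test_zero_totals_zero_occupancy(self, fig10_species):
        arch = sb.PromoterArchitecture(["half", "palindrome"])
        got = sb.prob_fully_ligated(arch, fig10_species, [0.0] * 3)
        assert all(p == 0.0 for p in got.values())

    def test_saturation_limit(self):
        sp = make_species()
        arch = sb.PromoterArchitecture(["palindrome"])
        p = sb.prob_fully_ligated(arch, [sp], [1e-2])[sp.name]
        assert p > 0.999


class TestCompetitionSweeps:
    GRID = np.logspace(-10, -2, 80)

    def test_single_point_grid_matches_prob_fully_ligated(self, fig10_species):
        arch = sb.PromoterArchitecture(["half"])
        prof = sb.occupancy_sweep(arch, fig10_species, [1e-7])
        direct = sb.prob_fully_ligated(arch, fig10_species, [1e-7] * 3)
        for name, p in direct.items():
            assert prof.fully_ligated[name][0] == pytest.approx(p, rel=1e-12)

    def test_half_site_favors_weak_dimerizer(self, fig10_species):
        # weak dimerization keeps the monomer pool high: red >= blue >= green
        arch = sb.PromoterArchitecture(["half"])
        prof = sb.occupancy_sweep(arch, fig10_species, self.GRID)
        f = prof.fully_ligated
        assert np.all(f["red"] >= f["blue"] - 1e-12)
        assert np.all(f["blue"] >= f["green"] - 1e-12)

    def test_palindrome_favors_strong_dimerizer(self, fig10_species):
        arch = sb.PromoterArchitecture(["palindrome"])
        prof = sb.occupancy_sweep(arch, fig10_species, self.GRID)
        f = prof.fully_ligated
        assert np.all(f["green"] >= f["blue"] - 1e-12)
        assert np.all(f["blue"] >= f["red"] - 1e-12)

    def test_two_palindromes_give_blue_a_winning_interval(self, fig10_species):
        # moderate dimerization + moderate cooperativity wins on multi-palindrome
        arch = sb.PromoterArchitecture(["palindrome", "palindrome"])
        prof = sb.occupancy_sweep(arch, fig10_species, self.GRID)
        f = prof.fully_ligated
        blue_max = (f["blue"] > f["red"]) & (f["blue"] > f["green"])
        assert blue_max.any()

    def test_two_half_sites_give_red_the_maximum(self, fig10_species):
        arch = sb.PromoterArchitecture(["half", "half"])
        prof = sb.occupancy_sweep(arch, fig10_species, self.GRID)
        f = prof.fully_ligated
        red_max_somewhere = (f["red"] > f["blue"]) & (f["red"] > f["green"])
        assert red_max_somewhere.any()
        assert f["red"].max() == max(v.max() for v in f.values())

    def test_profile_classes_sum_to_one(self, fig10_species):
        arch = sb.PromoterArchitecture(["half", "palindrome"])
        prof = sb.occupancy_sweep(arch, fig10_species, self.GRID)
        total = prof.mixed_full + prof.partial_or_empty
        for v in prof.fully_ligated.values():
            total = total + v
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_empty_grid_rejected(self, fig10_species):
        with pytest.raises(InvalidParameterError):
            sb.occupancy_sweep(
                sb.PromoterArchitecture(["half"]), fig10_species, []
            )
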