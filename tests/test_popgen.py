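import itertools
import math
from collections import Counter

import numpy as np
import pytest

from kmlst.popgen import (
    codon_sites,
    dn_ds,
    index_of_association,
    locus_heterozygosity,
    pair_incompatibility,
    pairwise_codon_differences,
    parsimony_informative_columns,
    phi_statistic,
    phi_test,
)
from kmlst.profiles import DstCatalog, StrainProfile
from kmlst.simulate import simulate_population, SimulationConfig


def _catalog(rows, loci=("L1", "L2", "L3", "L4", "L5")):
    return DstCatalog.from_profiles(
        [StrainProfile(f"s{i}", tuple(r)) for i, r in enumerate(rows)],
        loci=loci[: len(rows[0])],
    )


def ia_oracle(rows, ddof=0):
    """Independent brute-force I_A: explicit pair enumeration, no numpy."""
    n, l = len(rows), len(rows[0])
    ks = [sum(a != b for a, b in zip(rows[i], rows[j]))
          for i, j in itertools.combinations(range(n), 2)]
    mean_k = sum(ks) / len(ks)
    v_d = sum((k - mean_k) ** 2 for k in ks) / (len(ks) - ddof)
    v_e = 0.0
    for j in range(l):
        counts = Counter(r[j] for r in rows)
        h = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))
        v_e += h * (1 - h)
    i_a = v_d / v_e - 1
    return {"mean_k": mean_k, "v_d": v_d, "v_e": v_e,
            "i_a": i_a, "i_sa": i_a / (l - 1)}


class TestHeterozygosity:
    def test_monomorphic_locus(self):
        cat = _catalog([(1, 1), (1, 2), (1, 3)], loci=("A", "B"))
        assert locus_heterozygosity(cat, "A") == 0.0

    def test_two_strains_two_genotypes(self):
        cat = _catalog([(1, 1), (2, 1)], loci=("A", "B"))
        assert locus_heterozygosity(cat, "A") == pytest.approx(1.0)

    def test_four_strains_balanced(self):
        cat = _catalog([(1,), (1,), (2,), (2,)], loci=("A",))
        assert locus_heterozygosity(cat, "A") == pytest.approx(2 / 3)


class TestIndexOfAssociation:
    def test_two_fully_linked_haplotypes(self):
        rows = [(1, 1, 1, 1, 1), (1, 1, 1, 1, 1),
                (2, 2, 2, 2, 2), (2, 2, 2, 2, 2)]
        r = index_of_association(_catalog(rows))
        assert r.mean_k == pytest.approx(10 / 3)
        assert r.v_d == pytest.approx(50 / 9)
        assert r.v_e == pytest.approx(10 / 9)
        assert r.i_a == pytest.approx(4.0)
        assert r.i_sa == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [tuple(rng.integers(1, 4, size=4)) for _ in range(8)]
        if len({tuple(r) for r in rows}) == 1:
            pytest.skip("degenerate draw")
        cat = _catalog(rows, loci=("A", "B", "C", "D"))
        r = index_of_association(cat)
        want = ia_oracle(rows)
        assert r.mean_k == pytest.approx(want["mean_k"])
        assert r.v_d == pytest.approx(want["v_d"])
        assert r.v_e == pytest.approx(want["v_e"])
        assert r.i_sa == pytest.approx(want["i_sa"])

    def test_partially_monomorphic_two_locus_case(self):
        # locus 1 monomorphic, locus 2 polymorphic with one shared genotype
        rows = [(1, 1), (1, 2), (1, 3), (1, 3)]
        r = index_of_association(_catalog(rows, loci=("A", "B")))
        want = ia_oracle(rows)
        assert r.i_a == pytest.approx(want["i_a"])
        assert r.i_sa == pytest.approx(want["i_sa"])

    def test_fully_polymorphic_locus_makes_expected_variance_zero(self):
        # unbiased h = 1 when every strain is unique at every locus,
        # so V_e degenerates to zero and the statistic is undefined
        rows = [(1, 1), (2, 2), (3, 3), (4, 4)]
        with pytest.raises(ValueError, match="monomorphic|zero"):
            index_of_association(_catalog(rows, loci=("A", "B")))

    def test_sample_variance_option(self):
        rows = [(1, 1, 1), (2, 2, 2), (1, 2, 1), (2, 1, 2)]
        cat = _catalog(rows, loci=("A", "B", "C"))
        pop = index_of_association(cat).v_d
        samp = index_of_association(cat, variance="sample").v_d
        assert samp == pytest.approx(pop * 6 / 5)

    def test_relabeling_invariance(self):
        rows = [(1, 1, 1), (2, 2, 2), (1, 2, 1), (2, 1, 2), (1, 1, 2)]
        relabeled = [(r[0] * 7, 5 - r[1], r[2] + 10) for r in rows]
        a = index_of_association(_catalog(rows, loci=("A", "B", "C")))
        b = index_of_association(_catalog(relabeled, loci=("A", "B", "C")))
        assert a.i_sa == pytest.approx(b.i_sa)

    def test_panmictic_population_near_zero(self):
        cfg = SimulationConfig(seed=11, n_strains=100, n_loci=5,
                               fragment_lengths=60, alleles_per_locus=10,
                               polymorphic_sites_per_locus=10,
                               recombination_mode="panmictic")
        pop = simulate_population(cfg)
        r = index_of_association(pop.profiles)
        assert abs(r.i_sa) < 0.05

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError):
            index_of_association(_catalog([(1,), (2,), (3,)], loci=("A",)))

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            index_of_association(_catalog([(1, 1), (1, 1), (1, 1)],
                                          loci=("A", "B")))

    def test_permutation_p_reproducible_and_significant_for_linked(self):
        rows = [(1, 1, 1, 1, 1)] * 5 + [(2, 2, 2, 2, 2)] * 5
        cat = _catalog(rows)
        r1 = index_of_association(cat, n_permutations=199, seed=3)
        r2 = index_of_association(cat, n_permutations=199, seed=3)
        assert r1.p_value == r2.p_value
        assert r1.p_value < 0.05


class TestPhiMachinery:
    def test_informative_columns_ignore_ambiguity(self):
        seqs = ["AR", "AR", "TA", "TA"]
        cols = parsimony_informative_columns(seqs)
        # column 1: A,A,T,T informative; column 2: R,R treated missing,
        # leaving A,A -> single state, not informative
        assert [c for c, _ in cols] == [0]

    def test_compatible_pair_scores_zero(self):
        # 3 observed gametes: E=3, V=4, C=1
        a = ["A", "A", "C", "C"]
        b = ["G", "T", "T", "T"]
        assert pair_incompatibility(a, b) == 0

    def test_all_four_gametes_score_one(self):
        a = ["A", "A", "C", "C"]
        b = ["G", "T", "G", "T"]
        assert pair_incompatibility(a, b) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_binary_pair_equals_four_gamete_test(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.choice(["A", "G"], size=12))
        b = list(rng.choice(["C", "T"], size=12))
        gametes = len(set(zip(a, b)))
        expected = 1 if gametes == 4 else 0
        assert pair_incompatibility(a, b) == expected

    def test_phi_one_when_every_pair_shows_four_gametes(self):
        seqs = ["AT", "AA", "TA", "TT", "AT", "AA", "TA", "TT"]
        r = phi_statistic(seqs)
        assert r.phi == pytest.approx(1.0)
        assert r.n_informative == 2

    def test_window_limits_pairs(self):
        # two informative sites 150 apart: no qualifying pair at w=100
        left = ["A", "A", "C", "C"]
        seqs = ["".join([left[i]] + ["G"] * 149 + [left[i]]) for i in range(4)]
        assert phi_statistic(seqs, w=100).computable is False
        assert phi_statistic(seqs, w=200).computable is True

    def test_too_few_informative_sites(self):
        r = phi_statistic(["ACGT", "ACGT", "ACGT", "ACGT"])
        assert not r.computable

    def test_phi_test_reproducible(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(8)]
        a = phi_test(seqs, n_permutations=99, seed=42)
        b = phi_test(seqs, n_permutations=99, seed=42)
        assert a.p_value == b.p_value


class TestDnDs:
    def test_identical_sequences(self):
        r = dn_ds(["TTTGGG", "TTTGGG"], n_bootstrap=0)
        assert r.dn == 0 and r.ds == 0 and r.ratio is None

    def test_single_synonymous_change_gives_ratio_zero(self):
        r = dn_ds(["TTTGGG", "TTCGGG"], n_bootstrap=0)
        assert r.dn == 0
        assert r.ds > 0
        assert r.ratio == 0.0

    def test_single_nonsynonymous_change_gives_infinite_ratio(self):
        r = dn_ds(["AAAGGG", "GAAGGG"], n_bootstrap=0)
        assert r.ds == 0 and r.dn > 0
        assert math.isinf(r.ratio)

    def test_two_pathway_codon_pair_matches_hand_enumeration(self):
        # TTT -> GTA: path via GTT gives (syn 1, nonsyn 1); path via TTA
        # gives (0, 2); average (0.5, 1.5)
        assert pairwise_codon_differences("TTT", "GTA") == (0.5, 1.5)

    def test_pathways_through_stops_are_excluded(self):
        # TGT -> TAA: via TAT (Tyr) then TAA... both orders hit a stop at
        # the end codon itself; intermediate stop exclusion applies to TGA
        sd, nd = pairwise_codon_differences("TGT", "AGA")
        # paths TGT->AGT(Ser)->AGA(Arg): 0 syn 2 nonsyn;
        # TGT->TGA(stop, blocked) -> excluded; average = (0, 2)
        assert (sd, nd) == (0.0, 2.0)

    def test_codon_site_counts(self):
        # GGG: third position fully synonymous, others not
        s, n = codon_sites("GGG")
        assert s == pytest.approx(1.0)
        assert n == pytest.approx(2.0)

    def test_symmetry_and_codon_order_invariance(self):
        a = "TTTGGGAAACCC"
        b = "TTCGGAAAGCCA"
        r1 = dn_ds([a, b], n_bootstrap=0)
        r2 = dn_ds([b, a], n_bootstrap=0)
        assert (r1.dn, r1.ds) == (r2.dn, r2.ds)
        perm = [3, 0, 2, 1]
        ap = "".join(a[3 * i:3 * i + 3] for i in perm)
        bp = "".join(b[3 * i:3 * i + 3] for i in perm)
        r3 = dn_ds([ap, bp], n_bootstrap=0)
        assert r3.dn == pytest.approx(r1.dn)
        assert r3.ds == pytest.approx(r1.ds)

    def test_frame_violation(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            dn_ds(["TTTG", "TTTG"], n_bootstrap=0)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            dn_ds(["TAAGGG", "TAAGGG"], n_bootstrap=0)

    def test_ambiguous_codons_skipped_by_default(self):
        r_skip = dn_ds(["TTTGGR", "TTCGGG"], n_bootstrap=0)
        r_clean = dn_ds(["TTT", "TTC"], n_bootstrap=0)
        assert r_skip.ds == pytest.approx(r_clean.ds)

    def test_bootstrap_se_reproducible(self):
        a = "TTTGGGAAACCCGATTAC"
        b = "TTCGGAAAGCCAGACTAC"
        r1 = dn_ds([a, b], n_bootstrap=50, seed=7)
        r2 = dn_ds([a, b], n_bootstrap=50, seed=7)
        assert r1.se == r2.se
        assert r1.se >= 0
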