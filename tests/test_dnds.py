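"""Modified Nei–Gojobori counting, JC correction, Z- and t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genedecay.code import STANDARD_CODE
from genedecay.dnds import (
    DnDsConfig,
    PairwiseDnDs,
    count_differences,
    count_sites,
    group_t_test,
    jukes_cantor,
    pairwise_dnds,
    z_test,
)
from genedecay.errors import GenedecayError, SaturationError
from oracles import naive_pathway_counts, naive_site_counts

SENSE = list(STANDARD_CODE.sense_codons)


class TestSiteCounting:
    def test_phenylalanine_unweighted(self):
        s, n = count_sites("TTT", DnDsConfig(R=1.0))
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_phenylalanine_transition_weighted(self):
        s, n = count_sites("TTT", DnDsConfig(R=2.0))
        assert (s, n) == (pytest.approx(0.5), pytest.approx(2.5))

    @pytest.mark.parametrize("R", [0.5, 1.0, 2.0, 5.0])
    def test_fourfold_third_position_contributes_one_site(self, R):
        # all three third-position changes of GGG are synonymous and both
        # other positions are fully nonsynonymous, so the synonymous site
        # count is exactly 1 regardless of R
        s, n = count_sites("GGG", DnDsConfig(R=R))
        assert s == pytest.approx(1.0, abs=1e-12)
        assert n == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("R", [0.5, 1.0, 2.0, 3.7])
    def test_sites_sum_to_three_for_every_sense_codon(self, R):
        cfg = DnDsConfig(R=R)
        for codon in SENSE:
            s, n = count_sites(codon, cfg)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(GenedecayError):
            count_sites("TAA")

    @given(st.sampled_from(SENSE), st.floats(0.2, 8.0))
    @settings(deadline=None, max_examples=120, derandomize=True)
    def test_matches_independent_enumeration(self, codon, R):
        got = count_sites(codon, DnDsConfig(R=R))
        exp = naive_site_counts(codon, R)
        assert got == (pytest.approx(exp[0]), pytest.approx(exp[1]))


class TestDifferenceCounting:
    def test_single_synonymous_step(self):
        assert count_differences("TTT", "TTC") == (1.0, 0.0)

    def test_two_pathway_average(self):
        # TTT->GTA via GTT (nonsyn, then syn) or via TTA (nonsyn, nonsyn)
        assert count_differences("TTT", "GTA") == (pytest.approx(0.5), pytest.approx(1.5))

    def test_identical_codons_zero(self):
        assert count_differences("AAA", "AAA") == (0.0, 0.0)

    def test_stop_blocked_pair_returns_sentinel(self):
        # find a pair whose every pathway crosses a stop, via the oracle
        blocked = [
            (a, b)
            for a in SENSE
            for b in SENSE
            if a != b and naive_pathway_counts(a, b) is None
        ]
        if blocked:
            a, b = blocked[0]
            assert count_differences(a, b) is None

    @given(st.sampled_from(SENSE), st.sampled_from(SENSE))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_factorial_enumeration(self, ca, cb):
        got = count_differences(ca, cb)
        exp = naive_pathway_counts(ca, cb)
        if exp is None:
            assert got is None
        else:
            assert got == (pytest.approx(exp[0]), pytest.approx(exp[1]))
            k = sum(1 for i in range(3) if ca[i] != cb[i])
            assert got[0] + got[1] == pytest.approx(k)


class TestPairwise:
    def test_identical_sequences(self):
        seq = "ATGGCCAAATTTGGGCCC"
        res = pairwise_dnds(seq, seq)
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.omega is None  # dS = 0: undefined

    def test_jc_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)

    def test_counts_match_per_codon_accumulation(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            codons_a = rng.choice(SENSE, size=10)
            codons_b = []
            for c in codons_a:
                # perturb ~40% of codons at one position, keeping divergence
                # below JC saturation
                if rng.random() < 0.4:
                    pos = int(rng.integers(0, 3))
                    alt = str(rng.choice([b for b in "ACGT" if b != c[pos]]))
                    mut = c[:pos] + alt + c[pos + 1 :]
                    codons_b.append(mut if mut in SENSE else c)
                else:
                    codons_b.append(c)
            sa, sb = "".join(codons_a), "".join(codons_b)
            res = pairwise_dnds(sa, sb, DnDsConfig(R=2.0))
            # naive accumulation oracle
            S_acc = Sd = Nd = 0.0
            kept = 0
            for ca, cb in zip(codons_a, codons_b):
                d = naive_pathway_counts(ca, cb)
                if d is None:
                    continue
                S_acc += (naive_site_counts(ca, 2.0)[0] + naive_site_counts(cb, 2.0)[0]) / 2
                Sd += d[0]
                Nd += d[1]
                kept += 1
            assert res.S == pytest.approx(S_acc)
            assert res.N == pytest.approx(3 * kept - S_acc)
            assert (res.Sd, res.Nd) == (pytest.approx(Sd), pytest.approx(Nd))

    def test_symmetric_in_sequences(self):
        a = "ATGGCCAAATTTGGGCCCGAGAAAATGGCCAAATTTGGGCCC"
        b = "ATGGCTAAGTTTGGGCCAGAAAAAATGGCCAAATTTGGGCCC"
        ra, rb = pairwise_dnds(a, b), pairwise_dnds(b, a)
        assert (ra.dN, ra.dS) == (pytest.approx(rb.dN), pytest.approx(rb.dS))

    def test_pairwise_deletion_of_gap_and_stop_codons(self):
        a = "ATG---TAAGGG"
        b = "ATGCCCAAAGGG"
        res = pairwise_dnds(a, b)
        assert res.n_codons == 2  # gap codon and stop codon dropped


class TestZTest:
    def test_equal_rates_give_zero(self):
        res = PairwiseDnDs(N=100, S=50, Nd=5, Sd=5, dN=0.05, dS=0.05,
                           varN=1e-4, varS=1e-4, n_codons=50)
        t = z_test(res)
        assert t.Z == 0.0 and t.p_two_sided == pytest.approx(1.0)

    def test_strong_purifying_selection(self):
        res = PairwiseDnDs(N=100, S=50, Nd=2, Sd=5, dN=0.02, dS=0.10,
                           varN=2e-4, varS=2e-4, n_codons=50)
        t = z_test(res)
        assert t.Z == pytest.approx(-4.0)
        assert t.p_two_sided == pytest.approx(2 * stats.norm.sf(4.0), rel=1e-6)
        assert t.p_two_sided == pytest.approx(6.33e-5, rel=1e-2)
        assert t.p_purifying < 1e-4

    def test_sign_antisymmetry(self):
        res = PairwiseDnDs(N=100, S=50, Nd=2, Sd=5, dN=0.02, dS=0.10,
                           varN=2e-4, varS=2e-4, n_codons=50)
        flipped = PairwiseDnDs(N=100, S=50, Nd=5, Sd=2, dN=0.10, dS=0.02,
                               varN=2e-4, varS=2e-4, n_codons=50)
        assert z_test(res).Z == pytest.approx(-z_test(flipped).Z)


class TestGroupComparison:
    def test_all_equal_to_reference(self):
        res = group_t_test([0.48, 0.48, 0.48], 0.48)
        assert res.t == 0.0 and res.p_two_tailed == pytest.approx(1.0)
        assert res.degenerate

    def test_textbook_one_sample_t(self):
        ratios = [0.5, 0.45, 0.49]
        res = group_t_test(ratios, 0.48)
        mean = sum(ratios) / 3
        sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / 2)
        t_exp = (mean - 0.48) / (sd / math.sqrt(3))
        assert res.t == pytest.approx(t_exp)
        assert res.df == 2
        assert res.p_two_tailed == pytest.approx(2 * stats.t.sf(abs(t_exp), 2))

    def test_reflection_invariance(self):
        ratios = [0.52, 0.40, 0.55, 0.47]
        reflected = [2 * 0.48 - r for r in ratios]
        assert group_t_test(ratios, 0.48).p_two_tailed == pytest.approx(
            group_t_test(reflected, 0.48).p_two_tailed
        )

    def test_sd_uses_n_minus_one(self):
        res = group_t_test([0.4, 0.6], 0.5)
        assert res.sd == pytest.approx(np.std([0.4, 0.6], ddof=1))


class TestSimulatedCalibration:
    """Distance behavior on simulated two-taxon data."""

    def _simulate_pair(self, omega, n_codons, t, seed):
        from genedecay.core import SpeciesTree
        from genedecay.simulate import SimulationConfig, simulate

        tree = SpeciesTree.from_newick(f"(A:{t / 2},B:{t / 2});")
        cfg = SimulationConfig(
            tree=tree, n_codons=n_codons, kappa=2.0, omega_by_branch=omega,
            seed=seed, reference_id="A",
        )
        aln, _ = simulate(cfg)
        return aln.sequence("A"), aln.sequence("B")

    def test_neutral_omega_near_one_on_average(self):
        omegas = []
        for r in range(50):
            a, b = self._simulate_pair(1.0, 400, 0.8, 3000 + r)
            res = pairwise_dnds(a, b)
            if res.omega is not None:
                omegas.append(res.omega)
        mean = float(np.mean(omegas))
        se = float(np.std(omegas, ddof=1) / math.sqrt(len(omegas)))
        assert abs(mean - 1.0) < 3 * se

    def test_purifying_detected_with_high_power(self):
        rejections = 0
        n = 40
        for r in range(n):
            # tree length 0.3 yields pairwise dS around 0.3 at omega = 0.1
            a, b = self._simulate_pair(0.1, 500, 0.3, 4000 + r)
            res = pairwise_dnds(a, b)
            if z_test(res).p_purifying < 0.05:
                rejections += 1
        assert rejections / n >= 0.8
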