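"""Pruning likelihood, branch-model fitting, likelihood-ratio tests."""

import numpy as np
import pytest

from genedecay.core import SpeciesTree
from genedecay.errors import GenedecayError
from genedecay.gy94 import default_space, sanitize_for_model, uniform_frequencies
from genedecay.likelihood import (
    SCHEMES,
    BranchModelFit,
    CodonModelParams,
    FitOptions,
    PruningEngine,
    chi2_tail,
    fit_branch_model,
    lrt,
)
from oracles import exhaustive_loglik, naive_gy94_q

SPACE = default_space()
PI = uniform_frequencies(SPACE)


def _engine(matrix, taxa, newick, scheme="one_ratio", freqs=None):
    tree = SpeciesTree.from_newick(newick)
    return (
        PruningEngine(matrix, taxa, tree, SCHEMES[scheme], freqs=freqs),
        tree,
    )


class TestPruning:
    def test_zero_branch_limit_recovers_stationary_logprob(self):
        seq = [SPACE.index[c] for c in ("ATG", "GCC", "AAA")]
        matrix = np.array([seq, seq])
        eng, _ = _engine(matrix, ["A", "B"], "(A:1e-9,B:1e-9);", freqs=PI)
        lnl = eng.log_likelihood(2.0, np.array([0.5]), eng.default_branch_lengths())
        expected = sum(np.log(PI[s]) for s in seq)
        assert lnl == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("kappa,omega", [(2.0, 0.5), (4.0, 0.1), (1.0, 1.0)])
    def test_matches_exhaustive_summation(self, kappa, omega, micro_sim):
        aln, _, cfg = micro_sim
        matrix, taxa, _ = sanitize_for_model(aln, min_codons=1)
        eng = PruningEngine(
            matrix, taxa, cfg.tree, SCHEMES["one_ratio"], freqs=PI
        )
        lnl = eng.log_likelihood(kappa, np.array([omega]), eng.default_branch_lengths())
        row = {t: r for r, t in enumerate(taxa)}
        sites = [
            {t: int(matrix[row[t], s]) for t in taxa} for s in range(matrix.shape[1])
        ]
        lnl_bf = exhaustive_loglik(
            cfg.tree.tree, sites, naive_gy94_q(kappa, omega, PI), PI
        )
        assert lnl == pytest.approx(lnl_bf, abs=1e-8)

    def test_missing_taxon_contributes_all_ones(self, micro_sim):
        aln, _, cfg = micro_sim
        matrix, taxa, _ = sanitize_for_model(aln, min_codons=1)
        # drop taxon C from the data but keep it on the tree
        keep = [i for i, t in enumerate(taxa) if t != "C"]
        eng = PruningEngine(
            matrix[keep], [taxa[i] for i in keep], cfg.tree,
            SCHEMES["one_ratio"], freqs=PI,
        )
        lnl = eng.log_likelihood(2.0, np.array([0.5]), eng.default_branch_lengths())
        row = {t: r for r, t in enumerate(taxa)}
        sites = [
            {t: (int(matrix[row[t], s]) if t != "C" else -1) for t in taxa}
            for s in range(matrix.shape[1])
        ]
        lnl_bf = exhaustive_loglik(
            cfg.tree.tree, sites, naive_gy94_q(2.0, 0.5, PI), PI
        )
        assert lnl == pytest.approx(lnl_bf, abs=1e-8)

    def test_reroot_invariance_under_reversibility(self, micro_sim):
        """Moving the root along a branch leaves lnL unchanged (pulley
        principle), checked numerically on the micro fixture."""
        aln, _, cfg = micro_sim
        matrix, taxa, _ = sanitize_for_model(aln, min_codons=1)

        def lnl_for(newick):
            eng, _ = _engine(matrix, taxa, newick, freqs=PI)
            return eng.log_likelihood(
                2.0, np.array([0.5]), eng.default_branch_lengths()
            )

        # micro tree is (A:0.10,(B:0.15,C:0.20):0.05); slide the root
        assert lnl_for("(A:0.10,(B:0.15,C:0.20):0.05);") == pytest.approx(
            lnl_for("(A:0.02,(B:0.15,C:0.20):0.13);"), abs=1e-8
        )


class TestFitting:
    def test_nested_fit_never_beats_alternative(self, stem_loss_sim):
        aln, _, cfg = stem_loss_sim
        matrix, taxa, _ = sanitize_for_model(aln)
        opts = FitOptions(fix_branch_lengths=True, restarts=0)
        f1 = fit_branch_model(matrix, taxa, cfg.tree, "one_ratio", opts)
        f2 = fit_branch_model(matrix, taxa, cfg.tree, "stem_two_ratio", opts)
        assert f2.lnL >= f1.lnL - 1e-6
        assert f2.n_free_params == f1.n_free_params + 1

    def test_refit_from_optimum_is_stable(self, stem_loss_sim):
        aln, _, cfg = stem_loss_sim
        matrix, taxa, _ = sanitize_for_model(aln)
        opts = FitOptions(fix_branch_lengths=True, restarts=0)
        fit = fit_branch_model(matrix, taxa, cfg.tree, "one_ratio", opts)
        opts2 = FitOptions(
            fix_branch_lengths=True, restarts=0,
            init_kappa=fit.params.kappa,
            init_omega=fit.params.omega_by_class["background"],
        )
        refit = fit_branch_model(matrix, taxa, cfg.tree, "one_ratio", opts2)
        assert refit.lnL == pytest.approx(fit.lnL, abs=1e-4)

    def test_deterministic_given_seed(self, stem_loss_sim):
        aln, _, cfg = stem_loss_sim
        matrix, taxa, _ = sanitize_for_model(aln)
        opts = FitOptions(fix_branch_lengths=True, restarts=1, seed=3)
        a = fit_branch_model(matrix, taxa, cfg.tree, "one_ratio", opts)
        b = fit_branch_model(matrix, taxa, cfg.tree, "one_ratio", opts)
        assert a.lnL == b.lnL
        assert a.params.kappa == b.params.kappa

    def test_joint_branch_length_estimation_runs(self, micro_sim):
        aln, _, cfg = micro_sim
        matrix, taxa, _ = sanitize_for_model(aln, min_codons=1)
        fit = fit_branch_model(
            matrix, taxa, cfg.tree, "one_ratio",
            FitOptions(fix_branch_lengths=False, restarts=0),
        )
        assert np.isfinite(fit.lnL)
        assert len(fit.params.branch_lengths) == 4
        assert fit.n_free_params == 1 + 1 + 4


class TestLRT:
    def _fit(self, lnl, k):
        params = CodonModelParams(
            kappa=2.0, omega_by_class={"background": 0.1},
            codon_freqs=PI, branch_lengths={},
        )
        return BranchModelFit(params=params, lnL=lnl, n_free_params=k, scheme="x")

    def test_equal_likelihoods(self):
        res = lrt(self._fit(-100.0, 2), self._fit(-100.0, 3))
        assert res.stat == 0.0 and res.p == pytest.approx(1.0)

    def test_chi_square_tail_values(self):
        assert chi2_tail(3.841, 1) == pytest.approx(0.050, abs=5e-4)
        assert chi2_tail(5.32, 1) == pytest.approx(0.021, abs=5e-4)

    def test_lrt_p_from_fits(self):
        res = lrt(self._fit(-100.0, 2), self._fit(-97.34, 3))
        assert res.stat == pytest.approx(5.32)
        assert res.df == 1
        assert res.p == pytest.approx(0.021, abs=5e-4)

    def test_non_nested_df_rejected(self):
        with pytest.raises(GenedecayError):
            lrt(self._fit(-100.0, 3), self._fit(-99.0, 3))
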