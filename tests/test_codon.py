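import numpy as np
import pytest

from chromoevol.codon import (CodonProcess, SiteClassCodonModel,
                              SiteClassModel, clade_site_df, equal_freqs,
                              m0_rescale_tree, model_loglik,
                              n_free_site_params, rate_matrix, site_loglik,
                              transition_probs)
from chromoevol.io import CodonAlignment
from chromoevol.trees import LabeledTree

from conftest import make_alignment
from oracles import (brute_force_site_loglik_3taxon,
                     brute_force_site_loglik_4taxon,
                     sample_column_3taxon, sample_column_4taxon)


def random_freqs(rng):
    return rng.dirichlet(np.ones(61))


class TestRateMatrix:
    def test_uniform_neutral_symmetry(self):
        q = rate_matrix(CodonProcess(1.0, 1.0, equal_freqs()))
        off = q[~np.eye(61, dtype=bool)]
        vals = np.unique(np.round(off[off > 0], 12))
        assert len(vals) == 1  # all single-step rates equal

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        q = rate_matrix(CodonProcess(float(rng.uniform(0.5, 5)),
                                     float(rng.uniform(0.05, 5)),
                                     random_freqs(rng)))
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_detailed_balance(self, seed):
        rng = np.random.default_rng(100 + seed)
        f = random_freqs(rng)
        q = rate_matrix(CodonProcess(2.0, float(rng.uniform(0.05, 5)), f))
        flux = f[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unit_expected_rate(self):
        f = equal_freqs()
        q = rate_matrix(CodonProcess(2.0, 0.3, f))
        assert -(f * np.diag(q)).sum() == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CodonProcess(0.0, 1.0, equal_freqs())
        with pytest.raises(ValueError):
            CodonProcess(1.0, 1.0, np.ones(61))


class TestTransitionProbs:
    def setup_method(self):
        self.f = equal_freqs()
        self.q = rate_matrix(CodonProcess(2.0, 0.5, self.f))

    def test_zero_time_identity(self):
        assert np.allclose(transition_probs(self.q, 0.0, self.f),
                           np.eye(61), atol=1e-12)

    def test_ergodic_limit(self):
        p = transition_probs(self.q, 500.0, self.f)
        assert np.allclose(p, np.tile(self.f, (61, 1)), atol=1e-6)

    def test_chapman_kolmogorov(self):
        pa = transition_probs(self.q, 0.3, self.f)
        pb = transition_probs(self.q, 0.7, self.f)
        pab = transition_probs(self.q, 1.0, self.f)
        assert np.allclose(pa @ pb, pab, atol=1e-9)

    def test_rows_stochastic(self):
        p = transition_probs(self.q, 0.42, self.f)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()


class TestSiteLoglik:
    def test_single_leaf_is_log_freq(self):
        f = equal_freqs()
        tree = LabeledTree.from_newick("(a:0.0);")
        proc = CodonProcess(2.0, 0.5, f)
        for c in (0, 17, 60):
            ll = site_loglik(np.array([c]), tree, ["a"], lambda lab: proc)
            assert ll == pytest.approx(np.log(f[c]), abs=1e-10)

    def test_two_leaves_zero_length(self):
        f = equal_freqs()
        tree = LabeledTree.from_newick("(a:0.0,b:0.0);")
        proc = CodonProcess(2.0, 0.5, f)
        same = site_loglik(np.array([5, 5]), tree, ["a", "b"],
                           lambda lab: proc)
        assert same == pytest.approx(np.log(f[5]), abs=1e-8)
        diff = site_loglik(np.array([5, 6]), tree, ["a", "b"],
                           lambda lab: proc)
        assert diff < -30  # impossible event guarded as large negative

    @pytest.mark.parametrize("seed", range(6))
    def test_three_taxon_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        f = random_freqs(rng)
        kappa = float(rng.uniform(1, 4))
        omega = float(rng.uniform(0.05, 3))
        lengths = rng.uniform(0.05, 1.0, size=3)
        tree = LabeledTree.from_newick(
            "(a:%.17g,b:%.17g,c:%.17g);" % tuple(lengths))
        proc = CodonProcess(kappa, omega, f)
        col = sample_column_3taxon(lengths, kappa, omega, f, rng)
        ll = site_loglik(col, tree, ["a", "b", "c"], lambda lab: proc)
        oracle = brute_force_site_loglik_3taxon(col, lengths, kappa,
                                                omega, f)
        assert ll == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_four_taxon_brute_force(self, seed):
        rng = np.random.default_rng(50 + seed)
        f = random_freqs(rng)
        kappa, omega = float(rng.uniform(1, 4)), float(rng.uniform(0.1, 2))
        ta, tb, tc, td, txy = rng.uniform(0.05, 0.8, size=5)
        tree = LabeledTree.from_newick(
            "((a:%.17g,b:%.17g):0.0,(c:%.17g,d:%.17g):%.17g);"
            % (ta, tb, tc, td, txy))
        proc = CodonProcess(kappa, omega, f)
        col = sample_column_4taxon((ta, tb, tc, td, txy), kappa, omega,
                                   f, rng)
        ll = site_loglik(col, tree, list("abcd"), lambda lab: proc)
        oracle = brute_force_site_loglik_4taxon(
            col, (ta, tb, tc, td, txy), kappa, omega, f)
        assert ll == pytest.approx(oracle, abs=1e-10)


class TestModelLoglik:
    def test_single_class_reduces_to_sum(self, study_tree):
        aln, _, model = make_alignment("M0", n_sites=40, seed=1)
        proc = CodonProcess(model.kappa, model.omega, model.freqs)
        total = sum(
            site_loglik(aln.codons[:, j], study_tree, aln.taxa,
                        lambda lab: proc)
            for j in range(aln.ncols_kept))
        assert model_loglik(aln, study_tree, model) == pytest.approx(
            total, abs=1e-8)

    def test_duplicated_columns_double_loglik(self, study_tree):
        aln, _, model = make_alignment("modelA", n_sites=30, seed=2)
        doubled = CodonAlignment(
            list(aln.taxa), np.hstack([aln.codons, aln.codons]),
            ncols_original=60)
        assert model_loglik(doubled, study_tree, model) == pytest.approx(
            2 * model_loglik(aln, study_tree, model), abs=1e-8)

    def test_modelA_omega2_one_equals_null(self, study_tree):
        aln, _, _ = make_alignment("modelA", n_sites=30, seed=3)
        kw = dict(kappa=2.0, p0=0.5, p1=0.3, omega0=0.1,
                  foreground=frozenset({"FG"}))
        alt = SiteClassModel(model_id="modelA", omega2=1.0, **kw)
        null = SiteClassModel(model_id="modelA_null", **kw)
        assert model_loglik(aln, study_tree, alt) == pytest.approx(
            model_loglik(aln, study_tree, null), abs=1e-10)

    def test_invariant_under_taxon_reordering(self, study_tree):
        aln, _, model = make_alignment("M1a", n_sites=30, seed=4)
        perm = np.arange(aln.ntaxa)[::-1]
        shuffled = CodonAlignment(
            [aln.taxa[i] for i in perm], aln.codons[perm],
            ncols_original=aln.ncols_original)
        assert model_loglik(shuffled, study_tree, model) == pytest.approx(
            model_loglik(aln, study_tree, model), abs=1e-8)

    def test_invariant_under_rerooting(self):
        # the same unrooted 3-taxon tree written with two different root
        # placements along unlabeled branches gives the same likelihood
        aln, _, model = make_alignment(
            "M0", n_sites=40, seed=5,
            tree=LabeledTree.from_newick("((a:0.2,b:0.3):0.1,c:0.4);"))
        t1 = LabeledTree.from_newick("((a:0.2,b:0.3):0.1,c:0.4);")
        t2 = LabeledTree.from_newick("(c:0.4,(a:0.2,b:0.3):0.1);")
        ll1 = model_loglik(aln, t1, model)
        assert ll1 == pytest.approx(model_loglik(aln, t2, model),
                                    abs=1e-8)


class TestDegreesOfFreedom:
    def test_clade_model_df_three(self):
        assert clade_site_df(2) == 3
        assert (n_free_site_params("cladeC_ext", 2)
                - n_free_site_params("M1a")) == 3

    def test_more_branch_types_add_df(self):
        assert clade_site_df(3) == 4
        assert n_free_site_params("modelA") - \
            n_free_site_params("modelA_null") == 1


class TestFitting:
    def test_m0_parameter_recovery(self):
        # simulated omega = 0.2, kappa = 2: estimates near truth
        omegas = []
        for seed in range(3):
            aln, _, _ = make_alignment("M0", n_sites=400, seed=30 + seed,
                                       omega=0.2)
            from chromoevol.simulate import default_labeled_tree
            res = SiteClassCodonModel(aln, default_labeled_tree(),
                                      "M0").fit(seed=seed, n_starts=1)
            assert res.converged
            omegas.append(res.params["omega"])
        assert 0.15 <= float(np.median(omegas)) <= 0.25

    def test_identical_sequences_flagged(self):
        from chromoevol.simulate import default_labeled_tree
        tree = default_labeled_tree()
        aln = CodonAlignment([f"t{i}" for i in range(1, 9)],
                             np.tile(np.arange(40) % 61, (8, 1)),
                             ncols_original=40)
        res = SiteClassCodonModel(aln, tree, "M0").fit(seed=0, n_starts=1)
        assert "scale" in res.boundary

    def test_nesting_of_fitted_logliks(self, study_tree):
        aln, _, _ = make_alignment("modelA", n_sites=200, seed=40)
        m0_tree, _ = m0_rescale_tree(aln, study_tree, seed=0)
        fits = {}
        for mid in ("M1a", "modelA_null", "modelA"):
            fits[mid] = SiteClassCodonModel(
                aln, m0_tree, mid, foreground="FG").fit(seed=1, n_starts=1)
        assert fits["modelA"].loglik >= fits["modelA_null"].loglik - 1e-6
        # M1a is the modelA_null omega distribution restricted to two
        # classes; the four-class null can only do better
        assert fits["modelA_null"].loglik >= fits["M1a"].loglik - 1e-4

    def test_null_data_pushes_omega2_to_boundary(self, study_tree):
        hits = 0
        for seed in range(3):
            aln, _, _ = make_alignment("modelA_null", n_sites=300,
                                       seed=60 + seed, omega2=1.0)
            m0_tree, _ = m0_rescale_tree(aln, study_tree, seed=seed)
            res = SiteClassCodonModel(aln, m0_tree, "modelA",
                                      foreground="FG").fit(seed=seed,
                                                           n_starts=1)
            if res.boundary.get("omega2") or res.params["omega2"] < 1.3:
                hits += 1
        assert hits >= 2

    def test_summary_mentions_key_parameters(self, study_tree):
        aln, _, _ = make_alignment("M0", n_sites=60, seed=70)
        res = SiteClassCodonModel(aln, study_tree, "M0").fit(seed=0,
                                                             n_starts=1)
        text = res.summary()
        assert "log-likelihood" in text and "omega" in text
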