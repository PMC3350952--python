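import numpy as np
import pytest

from chromoevol.selection import (BranchScanReport, branch_site_test,
                                  chi2_pvalue, clade_site_test,
                                  hochberg_adjust, holm_adjust,
                                  hommel_adjust, mean_pairwise_ds,
                                  mixture_chi2_pvalue, scan_branches,
                                  site_posteriors)
from chromoevol.simulate import default_labeled_tree

from conftest import make_alignment
from oracles import closure_simes_adjust

# published branch-site statistics for the chromodomain tree (inputs for
# the multiple-testing layer; order T, R, G, TR, GTR)
BRANCH_STATS = {"T": 1.634722, "R": 1.11799, "G": 4.766098,
                "TR": 3.720944, "GTR": 5.652052}
BRANCH_PVALS = {"T": 0.1005255, "R": 0.145176, "G": 0.014513,
                "TR": 0.026867, "GTR": 0.0087175}


class TestNullDistributions:
    @pytest.mark.parametrize("branch", list(BRANCH_STATS))
    def test_mixture_pvalues_reproduce_published(self, branch):
        p = mixture_chi2_pvalue(BRANCH_STATS[branch])
        expect = BRANCH_PVALS[branch]
        assert p == pytest.approx(expect, rel=1e-4)

    def test_mixture_boundary_conventions(self):
        assert mixture_chi2_pvalue(0.0) == 1.0
        assert mixture_chi2_pvalue(-1.0) == 1.0

    def test_chi2_quantile(self):
        assert chi2_pvalue(3.841459, 1) == pytest.approx(0.05, abs=1e-6)
        assert chi2_pvalue(0.0, 3) == 1.0

    def test_monotone_in_statistic(self):
        stats = np.linspace(0.1, 20, 50)
        ps = [mixture_chi2_pvalue(s) for s in stats]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_mixture_is_half_chi2(self):
        # quadrature identity: P(mix >= s) = 0.5 * P(chi2_1 >= s)
        from scipy.integrate import quad
        from scipy.stats import chi2 as chi2_dist
        s = 2.345
        tail, _ = quad(lambda x: 0.5 * chi2_dist.pdf(x, 1), s, np.inf)
        assert mixture_chi2_pvalue(s) == pytest.approx(tail, abs=1e-10)


class TestHommel:
    def test_single_pvalue_unchanged(self):
        assert hommel_adjust([0.03]) == pytest.approx([0.03])

    def test_against_closure_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(0, 1, size=5)
            assert np.allclose(hommel_adjust(p), closure_simes_adjust(p),
                               atol=1e-12)

    def test_published_vector_against_oracle(self):
        p = [BRANCH_PVALS[b] for b in ("T", "R", "G", "TR", "GTR")]
        assert np.allclose(hommel_adjust(p), closure_simes_adjust(p))

    def test_two_tests_equal_hochberg(self):
        grid = np.linspace(0.01, 0.99, 15)
        for a in grid:
            for b in grid:
                assert np.allclose(hommel_adjust([a, b]),
                                   hochberg_adjust([a, b]), atol=1e-12)

    def test_no_less_powerful_than_holm(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            p = rng.uniform(0, 1, size=7)
            assert np.all(hommel_adjust(p) <= holm_adjust(p) + 1e-12)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, size=6)
        adj = hommel_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            hommel_adjust([0.1, 1.2])
        with pytest.raises(ValueError):
            hommel_adjust([])

    def test_fwer_controlled_under_global_null(self):
        # 500 global-null replicates of 5 uniform p-values
        rng = np.random.default_rng(8)
        false_hommel = false_holm = 0
        for _ in range(500):
            p = rng.uniform(0, 1, size=5)
            false_hommel += np.any(hommel_adjust(p) < 0.05)
            false_holm += np.any(holm_adjust(p) < 0.05)
        assert false_hommel / 500 <= 0.08
        assert false_holm / 500 <= 0.08


class TestScanReports:
    def test_published_pvalues_reject_g_tr_gtr(self):
        names = list(BRANCH_PVALS)
        report = BranchScanReport.from_pvalues(
            names, [BRANCH_PVALS[n] for n in names], alpha=0.1)
        assert set(report.rejected) == {"G", "TR", "GTR"}
        adj = dict(zip(names, report.p_adjusted))
        assert adj["GTR"] < 0.05
        assert adj["TR"] < 0.1 and adj["G"] < 0.1

    def test_single_branch_adjustment_identity(self):
        report = BranchScanReport.from_pvalues(["T"], [0.031], alpha=0.05)
        assert report.p_adjusted[0] == pytest.approx(0.031)

    def test_rejections_monotone_in_alpha(self):
        names = list(BRANCH_PVALS)
        p = [BRANCH_PVALS[n] for n in names]
        prev: set = set()
        for alpha in (0.01, 0.05, 0.1, 0.2, 0.5):
            rej = set(BranchScanReport.from_pvalues(names, p,
                                                    alpha).rejected)
            assert prev <= rej
            prev = rej

    def test_report_table_columns(self):
        names = list(BRANCH_PVALS)
        report = BranchScanReport.from_pvalues(
            names, [BRANCH_PVALS[n] for n in names], alpha=0.1)
        table = report.to_table()
        assert list(table["foreground_branch"]) == names
        assert {"2dlnL", "p_raw", "p_hommel", "rejected"} <= \
            set(table.columns)


class TestBranchSiteTest:
    def test_positive_data_detected(self, study_tree):
        aln, _, _ = make_alignment("modelA", n_sites=400, seed=1,
                                   omega2=6.0)
        res = branch_site_test(aln, study_tree, "FG", seed=0, n_starts=1)
        assert res.stat >= 0
        assert res.null_family == "mixture_half_chi2_0_1"
        assert res.p_raw < 0.05
        assert res.mean_pairwise_ds is not None

    def test_null_family_fallback_chi2(self, study_tree):
        aln, _, _ = make_alignment("modelA_null", n_sites=150, seed=2)
        res = branch_site_test(aln, study_tree, "FG", seed=0, n_starts=1,
                               null_family="chi2")
        assert res.null_family == "chi2" and res.df == 1
        assert res.p_raw >= mixture_chi2_pvalue(res.stat) - 1e-12

    def test_clade_site_test_df_and_nesting(self, study_tree):
        aln, _, _ = make_alignment("modelA", n_sites=200, seed=3)
        res = clade_site_test(aln, study_tree, seed=0, n_starts=1)
        assert res.df == 3
        assert res.alt_fit.loglik >= res.null_fit.loglik - 1e-6

    def test_scan_invariant_to_branch_order(self, study_tree):
        aln, _, _ = make_alignment("modelA", n_sites=150, seed=4)
        r1 = scan_branches(aln, study_tree, ["FG", "background"],
                           alpha=0.1, seed=0, n_starts=1)
        r2 = scan_branches(aln, study_tree, ["background", "FG"],
                           alpha=0.1, seed=0, n_starts=1)
        assert dict(zip(r1.branch_names, r1.p_raw)) == pytest.approx(
            dict(zip(r2.branch_names, r2.p_raw)))
        assert set(r1.rejected) == set(r2.rejected)


class TestSitePosteriors:
    def test_zero_positive_mass_zero_posteriors(self, study_tree):
        from chromoevol.codon import SiteClassCodonModel, SiteClassModel
        from chromoevol.codon import FitResult
        aln, _, _ = make_alignment("modelA", n_sites=50, seed=5)
        model = SiteClassModel(model_id="modelA", kappa=2.0, p0=0.7,
                               p1=0.3 - 1e-12, omega0=0.1, omega2=2.0,
                               foreground=frozenset({"FG"}))
        fit = FitResult(model_id="modelA", model=model, loglik=0.0,
                        params={}, converged=True, n_restarts=1,
                        boundary={}, tree=study_tree, alignment=aln)
        post = site_posteriors(fit)
        assert np.all(post.probs <= 1e-9)

    def test_flag_nesting_and_truth_separation(self, study_tree):
        from chromoevol.codon import SiteClassCodonModel, m0_rescale_tree
        aln, truth, _ = make_alignment("modelA", n_sites=400, seed=6,
                                       omega2=6.0)
        m0_tree, _ = m0_rescale_tree(aln, study_tree, seed=0)
        fit = SiteClassCodonModel(aln, m0_tree, "modelA",
                                  foreground="FG").fit(seed=0, n_starts=1)
        post = site_posteriors(fit)
        assert set(post.flagged_95) <= set(post.flagged_90)
        is_pos = np.isin(truth.site_classes, ("2a", "2b"))
        # AUC of the posterior against the simulated class labels
        order = np.argsort(post.probs)
        ranks = np.empty(len(order))
        ranks[order] = np.arange(1, len(order) + 1)
        n1, n0 = is_pos.sum(), (~is_pos).sum()
        auc = (ranks[is_pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc > 0.8

    def test_grid_eb_close_to_neb_on_strong_signal(self, study_tree):
        from chromoevol.codon import SiteClassCodonModel, m0_rescale_tree
        aln, _, _ = make_alignment("modelA", n_sites=150, seed=7,
                                   omega2=6.0)
        m0_tree, _ = m0_rescale_tree(aln, study_tree, seed=0)
        fit = SiteClassCodonModel(aln, m0_tree, "modelA",
                                  foreground="FG").fit(seed=0, n_starts=1)
        neb = site_posteriors(fit, method="NEB")
        grid = site_posteriors(fit, method="grid_EB", grid_sizes=(3, 3, 4))
        assert grid.method == "grid_EB"
        assert np.corrcoef(neb.probs, grid.probs)[0, 1] > 0.8


class TestSaturationGuard:
    def test_low_divergence_alignment_not_flagged(self):
        aln, _, _ = make_alignment("M0", n_sites=150, seed=8, omega=0.2)
        assert mean_pairwise_ds(aln) < 3.0
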