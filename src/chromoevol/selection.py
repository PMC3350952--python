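"""Likelihood-ratio tests for positive selection with FWER control.

The branch-site test compares branch-site model A (omega2 >= 1 free on a
chosen foreground branch type) against the same model with omega2 fixed
at 1; because the null pins omega2 at a boundary, the test statistic
2*delta-lnL is referred to the 1/2 chi2_0 + 1/2 chi2_1 mixture. The
clade-site test compares the extended clade model C with the nearly
neutral M1a model on a chi2 with df equal to the free-parameter
difference (3 for a single foreground type). Scanning several candidate
branches treats each as foreground in turn and controls the family-wise
error rate with the Hommel step-up procedure. Sites in the positively
selected classes are flagged from their empirical-Bayes posterior
probabilities (naive EB at the MLEs by default; a grid-averaged variant
approximates Bayes empirical Bayes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .codon import (FitResult, SiteClassCodonModel, SiteClassModel,
                    class_site_logliks, clade_site_df, m0_rescale_tree,
                    n_free_site_params)
from .genetics import standard_code
from .io import CodonAlignment
from .trees import BACKGROUND, LabeledTree

logger = logging.getLogger(__name__)

STAT_TOL = 1e-6
SATURATION_DS = 3.0


# ---------------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------------

def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if not np.isfinite(stat):
        raise ValueError("statistic must be finite")
    if stat <= 0:
        return 1.0
    return float(chi2.sf(stat, df))


def mixture_chi2_pvalue(stat: float) -> float:
    """Upper tail of the 1/2 chi2_0 + 1/2 chi2_1 boundary mixture."""
    if not np.isfinite(stat):
        raise ValueError("statistic must be finite")
    if stat <= 0:
        return 1.0
    return float(0.5 * chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Hommel FWER adjustment
# ---------------------------------------------------------------------------

def hommel_adjust(p_values) -> np.ndarray:
    """Hommel (1988) adjusted p-values (closed stepwise form).

    Equivalent to the closure principle with Simes local tests; uniformly
    no less powerful than Hochberg among these FWER procedures.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 1:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, n + 1)
    q = np.full(n, min(n * ps / i))
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)              # 1..n-m+1 (0-based)
        i2 = np.arange(n - m + 1, n)           # n-m+2..n
        q1 = np.min(m * ps[i2] / np.arange(2, m + 1))
        q[i1] = np.minimum(m * ps[i1], q1)
        q[i2] = q[n - m]
        pa = np.maximum(pa, q)
    pa = np.maximum(pa, ps)
    out = np.empty(n)
    out[order] = np.minimum(pa, 1.0)
    return out


def simes_pvalue(p_subset) -> float:
    """Simes combination p-value of one intersection hypothesis."""
    ps = np.sort(np.asarray(p_subset, dtype=float))
    k = np.arange(1, ps.size + 1)
    return float(np.min(ps.size * ps / k))


def holm_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate((n - np.arange(n)) * p[order])
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def hochberg_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    stepdown = (n - np.arange(n)) * p[order]
    adj = np.minimum.accumulate(stepdown[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# LRT machinery
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    null_fit: FitResult | None
    alt_fit: FitResult | None
    stat: float
    null_family: str               # "chi2" or "mixture_half_chi2_0_1"
    p_raw: float
    df: int | None = None
    p_adjusted: float | None = None
    mean_pairwise_ds: float | None = None

    def summary(self) -> str:
        lines = [f"LRT ({self.null_family}"
                 + (f", df={self.df}" if self.df else "") + ")",
                 f"  2*delta-lnL   {self.stat:.6f}",
                 f"  p (raw)       {self.p_raw:.6g}"]
        if self.p_adjusted is not None:
            lines.append(f"  p (adjusted)  {self.p_adjusted:.6g}")
        if self.alt_fit is not None:
            lines.append("alternative model:")
            lines.append(self.alt_fit.summary())
        if self.null_fit is not None:
            lines.append("null model:")
            lines.append(self.null_fit.summary())
        return "\n".join(lines)


def _lrt_stat(null_loglik: float, alt_loglik: float) -> float:
    stat = 2.0 * (alt_loglik - null_loglik)
    if stat < 0:
        if stat < -STAT_TOL:
            warnings.warn(f"negative LRT statistic {stat:.3g} clamped to 0 "
                          "(optimizer noise)")
        stat = 0.0
    return stat


def branch_site_test(alignment: CodonAlignment, tree: LabeledTree,
                     foreground_type: str, seed: int = 0,
                     n_starts: int = 3, m0_tree: LabeledTree | None = None,
                     null_family: str = "mixture") -> LRTResult:
    """Branch-site test of positive selection on one foreground type.

    Branch lengths are fixed from an M0 stage (rescaling of the input
    tree's lengths) shared by the alternative and null fits.
    """
    if m0_tree is None:
        m0_tree, _ = m0_rescale_tree(alignment, tree, seed=seed)
    alt = SiteClassCodonModel(alignment, m0_tree, "modelA",
                              foreground=foreground_type).fit(
        seed=seed, n_starts=n_starts)
    null = SiteClassCodonModel(alignment, m0_tree, "modelA_null",
                               foreground=foreground_type).fit(
        seed=seed + 1, n_starts=n_starts)
    stat = _lrt_stat(null.loglik, alt.loglik)
    if null_family == "mixture":
        p = mixture_chi2_pvalue(stat)
        family = "mixture_half_chi2_0_1"
        df = None
    else:
        p = chi2_pvalue(stat, 1)
        family = "chi2"
        df = 1
    return LRTResult(null, alt, stat, family, p, df=df,
                     mean_pairwise_ds=_guarded_ds(alignment))


def clade_site_test(alignment: CodonAlignment, tree: LabeledTree,
                    branch_types=None, seed: int = 0,
                    n_starts: int = 3,
                    m0_tree: LabeledTree | None = None) -> LRTResult:
    """Clade-site test: extended clade model C vs the nearly neutral M1a."""
    if m0_tree is None:
        m0_tree, _ = m0_rescale_tree(alignment, tree, seed=seed)
    alt_model = SiteClassCodonModel(alignment, m0_tree, "cladeC_ext")
    if branch_types is not None:
        declared = set(branch_types) | {BACKGROUND}
        if set(alt_model.branch_types) - declared:
            raise ValueError("tree carries branch types outside the "
                             "declared set")
    null = SiteClassCodonModel(alignment, m0_tree, "M1a").fit(
        seed=seed, n_starts=n_starts)
    alt = alt_model.fit(seed=seed + 1, n_starts=n_starts)
    n_types = len(alt_model.branch_types)
    df = (n_free_site_params("cladeC_ext", n_types)
          - n_free_site_params("M1a"))
    stat = _lrt_stat(null.loglik, alt.loglik)
    return LRTResult(null, alt, stat, "chi2", chi2_pvalue(stat, df), df=df,
                     mean_pairwise_ds=_guarded_ds(alignment))


@dataclass
class BranchScanReport:
    """One branch-site test per candidate branch, Hommel-corrected."""

    branch_names: list
    results: dict                  # name -> LRTResult
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    alpha: float
    rejected: list = field(default_factory=list)

    @classmethod
    def from_pvalues(cls, names, p_raw, alpha: float = 0.05):
        """Assemble a report from precomputed raw p-values (e.g. published
        statistics); applies the Hommel adjustment and rejection rule."""
        names = list(names)
        p_raw = np.asarray(p_raw, dtype=float)
        adj = hommel_adjust(p_raw)
        results = {
            n: LRTResult(None, None, float("nan"),
                         "mixture_half_chi2_0_1", float(p),
                         p_adjusted=float(a))
            for n, p, a in zip(names, p_raw, adj)}
        rejected = [n for n, a in zip(names, adj) if a < alpha]
        return cls(names, results, p_raw, adj, alpha, rejected)

    def to_table(self):
        import pandas as pd
        rows = []
        for name in self.branch_names:
            r = self.results[name]
            row = {"foreground_branch": name, "2dlnL": r.stat,
                   "p_raw": r.p_raw, "p_hommel": r.p_adjusted,
                   "rejected": name in self.rejected}
            if r.alt_fit is not None:
                row.update({k: v for k, v in r.alt_fit.params.items()
                            if k in ("p0", "p1", "omega0", "omega2")})
                if r.alt_fit.boundary.get("omega2"):
                    row["omega2_note"] = r.alt_fit.boundary["omega2"]
            rows.append(row)
        return pd.DataFrame(rows)


def scan_branches(alignment: CodonAlignment, tree: LabeledTree,
                  branch_names, alpha: float = 0.05, seed: int = 0,
                  n_starts: int = 3) -> BranchScanReport:
    """Treat each named branch type as foreground in turn; Hommel-adjust."""
    branch_names = list(branch_names)
    m0_tree, _ = m0_rescale_tree(alignment, tree, seed=seed)
    results = {}
    for k, name in enumerate(sorted(branch_names)):
        results[name] = branch_site_test(
            alignment, tree, name, seed=seed + 1000 * (1 + k),
            n_starts=n_starts, m0_tree=m0_tree)
    p_raw = np.array([results[n].p_raw for n in branch_names])
    adj = hommel_adjust(p_raw)
    for n, a in zip(branch_names, adj):
        results[n].p_adjusted = float(a)
    rejected = [n for n, a in zip(branch_names, adj) if a < alpha]
    return BranchScanReport(branch_names, results, p_raw, adj, alpha,
                            rejected)


# ---------------------------------------------------------------------------
# site identification
# ---------------------------------------------------------------------------

@dataclass
class SitePosteriors:
    probs: np.ndarray
    method: str                    # "NEB" or "grid_EB"
    flagged_90: np.ndarray = field(init=False)
    flagged_95: np.ndarray = field(init=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any((self.probs < -1e-9) | (self.probs > 1 + 1e-9)):
            raise ValueError("posteriors must lie in [0, 1]")
        self.flagged_90 = np.where(self.probs >= 0.90)[0]
        self.flagged_95 = np.where(self.probs >= 0.95)[0]


_POSITIVE_CLASSES = ("2a", "2b")


def site_posteriors(alt_fit: FitResult, method: str = "NEB",
                    grid_sizes=(4, 4, 6)) -> SitePosteriors:
    """Posterior probability per site of the positively selected classes.

    ``NEB`` evaluates Bayes' rule at the MLEs. ``grid_EB`` additionally
    averages the posterior over a uniform-prior grid on (p0, p1, omega2),
    weighting each grid point by its marginal data likelihood - a
    light-weight approximation to Bayes empirical Bayes that acknowledges
    uncertainty in the mixture parameters.
    """
    if alt_fit.model_id not in ("modelA", "modelA_null"):
        raise ValueError("site identification applies to model A fits")
    if method == "NEB":
        ids, post = alt_fit.class_posteriors()
        probs = sum(post[ids.index(c)] for c in _POSITIVE_CLASSES
                    if ids.index(c) >= 0)
        return SitePosteriors(probs, "NEB")
    if method != "grid_EB":
        raise ValueError(f"unknown method {method!r}")
    n0, n1, n2 = grid_sizes
    p0_grid = np.linspace(0.15, 0.9, n0)
    p1f_grid = np.linspace(0.1, 0.9, n1)    # p1 as a fraction of 1 - p0
    w2_grid = np.geomspace(1.0, 16.0, n2)
    logliks, posts = [], []
    base = alt_fit.model
    for p0 in p0_grid:
        for p1f in p1f_grid:
            p1 = (1.0 - p0) * p1f
            for w2 in w2_grid:
                model = SiteClassModel(
                    model_id="modelA", kappa=base.kappa, freqs=base.freqs,
                    p0=float(p0), p1=float(p1), omega0=base.omega0,
                    omega2=float(w2), foreground=base.foreground)
                ids, w, mat = class_site_logliks(
                    alt_fit.alignment, alt_fit.tree, model)
                logw = np.log(np.maximum(w, 1e-300))[:, None]
                joint = mat + logw
                tot = logsumexp(joint, axis=0)
                logliks.append(tot.sum())
                pos = np.exp(logsumexp(
                    joint[[ids.index(c) for c in _POSITIVE_CLASSES]],
                    axis=0) - tot)
                posts.append(pos)
    logliks = np.array(logliks)
    weights = np.exp(logliks - logsumexp(logliks))
    probs = np.tensordot(weights, np.array(posts), axes=1)
    return SitePosteriors(probs, "grid_EB")


# ---------------------------------------------------------------------------
# saturation guard
# ---------------------------------------------------------------------------

def _ng86_tables():
    """Per-codon synonymous site counts and pairwise (syn, nonsyn)
    difference counts with equal-path averaging (NG86)."""
    code = standard_code()
    n = code.n_sense
    syn_sites = np.zeros(n)
    for i, codon in enumerate(code.sense_codons):
        for pos in range(3):
            paths = syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if code.is_stop(alt):
                    continue
                paths += 1
                if code.aa(alt) == code.aa(codon):
                    syn += 1
            if paths:
                syn_sites[i] += syn / paths
    return syn_sites


_SYN_SITES = None


def _pair_path_counts(ci, cj, code):
    diffs = [k for k in range(3) if ci[k] != cj[k]]
    if not diffs:
        return 0.0, 0.0
    sd = nd = used = 0
    for order in permutations(diffs):
        cur = ci
        s = ns = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cj[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.aa(cur) == code.aa(nxt):
                s += 1
            else:
                ns += 1
            cur = nxt
        if ok:
            sd += s
            nd += ns
            used += 1
    if used == 0:
        return 0.0, float(len(diffs))
    return sd / used, nd / used


def mean_pairwise_ds(alignment: CodonAlignment) -> float:
    """Mean pairwise synonymous distance (NG86 counting, JC correction)."""
    global _SYN_SITES
    code = alignment.code
    if _SYN_SITES is None:
        _SYN_SITES = _ng86_tables()
    codons = alignment.codons
    n = alignment.ntaxa
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            S = float(_SYN_SITES[codons[i]].sum()
                      + _SYN_SITES[codons[j]].sum()) / 2.0
            sd = 0.0
            for a, b in zip(codons[i], codons[j]):
                if a != b:
                    s, _ns = _pair_path_counts(code.codon(int(a)),
                                               code.codon(int(b)), code)
                    sd += s
            if S <= 0:
                continue
            ps = sd / S
            if ps >= 0.75:
                vals.append(np.inf)
            else:
                vals.append(-0.75 * np.log(1.0 - 4.0 * ps / 3.0))
    return float(np.mean(vals)) if vals else 0.0


def _guarded_ds(alignment: CodonAlignment) -> float:
    ds = mean_pairwise_ds(alignment)
    if ds > SATURATION_DS:
        warnings.warn(
            f"mean pairwise synonymous distance {ds:.2f} exceeds "
            f"{SATURATION_DS}: synonymous substitutions may be saturated "
            "and positive-selection inference unreliable")
    return ds
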