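"""Codon substitution models and maximum-likelihood fitting.

The engine implements a GY94-style codon process (transition/transversion
ratio kappa, selection parameter omega = dN/dS, stationary codon
frequencies) and Felsenstein-pruning log-likelihoods for site-class
mixture models in which omega may differ between branch types:

* ``M0``        - one omega for all sites and branches;
* ``M1a``       - nearly neutral: p0 sites with omega0 in (0,1), the rest
                  neutral (omega = 1);
* ``modelA``    - branch-site model A: classes 0 (omega0), 1 (neutral),
                  2a (omega0 -> omega2 on foreground branches) and
                  2b (1 -> omega2 on foreground), omega2 >= 1;
* ``modelA_null`` - model A with omega2 fixed at 1 (the LRT null);
* ``cladeC_ext``  - clade model C extended to arbitrarily many branch
                  types: class 2 has one free omega per branch type,
                  including the background.

Fitting follows a statsmodels-like shape: :class:`SiteClassCodonModel`
holds the data (codon alignment + labeled tree) and ``.fit()`` returns a
:class:`FitResult` with the estimates, convergence/boundary diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .genetics import is_transition, standard_code
from .io import CodonAlignment
from .trees import BACKGROUND, LabeledTree, Node

logger = logging.getLogger(__name__)

OMEGA_LO = 1e-4
OMEGA_HI = 999.0
KAPPA_LO, KAPPA_HI = 0.01, 100.0

MODEL_IDS = ("M0", "M1a", "modelA", "modelA_null", "cladeC_ext")


# ---------------------------------------------------------------------------
# codon process and rate matrix
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _pair_structure(code_name: str = "standard"):
    """Index arrays over sense-codon pairs differing at one nucleotide."""
    code = standard_code()
    n = code.n_sense
    ii, jj, ts, syn = [], [], [], []
    for i in range(n):
        ci = code.sense_codons[i]
        for j in range(i + 1, n):
            cj = code.sense_codons[j]
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(*diffs[0]))
            syn.append(code.aa(ci) == code.aa(cj))
    return (np.array(ii), np.array(jj), np.array(ts, dtype=bool),
            np.array(syn, dtype=bool))


@dataclass(frozen=True)
class CodonProcess:
    """Parameter bundle of one GY94 codon process."""

    kappa: float
    omega: float
    freqs: np.ndarray  # 61 stationary codon frequencies

    def __post_init__(self):
        if self.kappa <= 0 or self.omega <= 0:
            raise ValueError("kappa and omega must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (61,) or abs(f.sum() - 1.0) > 1e-8 or (f <= 0).any():
            raise ValueError("freqs must be 61 positive values summing to 1")
        object.__setattr__(self, "freqs", f)


def _raw_q(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    """Unscaled generator; q_ij = {1,kappa} x {1,omega} x pi_j."""
    ii, jj, ts, syn = _pair_structure()
    mult = np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    q = np.zeros((61, 61))
    q[ii, jj] = mult * freqs[jj]
    q[jj, ii] = mult * freqs[ii]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def expected_rate(kappa: float, omega: float, freqs: np.ndarray) -> float:
    """Expected substitutions per unit time of the unscaled generator."""
    q = _raw_q(kappa, omega, freqs)
    return float(-(freqs * np.diag(q)).sum())


def rate_matrix(process: CodonProcess) -> np.ndarray:
    """Generator scaled to one expected substitution per unit time."""
    q = _raw_q(process.kappa, process.omega, process.freqs)
    return q / expected_rate(process.kappa, process.omega, process.freqs)


class _EigQ:
    """Spectral form of a reversible generator; P(t) in two matmuls."""

    __slots__ = ("lam", "A", "B", "rate")

    def __init__(self, kappa, omega, freqs):
        q = _raw_q(kappa, omega, freqs)
        self.rate = float(-(freqs * np.diag(q)).sum())
        sq = np.sqrt(freqs)
        sym = q * (sq[:, None] / sq[None, :])
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        self.lam = lam
        self.A = u / sq[:, None]
        self.B = (u * sq[:, None]).T

    def pmat(self, t: float) -> np.ndarray:
        p = (self.A * np.exp(self.lam * t)) @ self.B
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def transition_probs(q: np.ndarray, t: float,
                     freqs: np.ndarray | None = None) -> np.ndarray:
    """Stochastic matrix exp(Q t) for a reversible codon generator."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if freqs is None:
        # stationary distribution from the null left eigenvector
        from scipy.linalg import expm
        return expm(q * t)
    sq = np.sqrt(freqs)
    sym = q * (sq[:, None] / sq[None, :])
    lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
    p = ((u / sq[:, None]) * np.exp(lam * t)) @ (u * sq[:, None]).T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def equal_freqs() -> np.ndarray:
    return np.full(61, 1.0 / 61.0)


def f3x4_freqs(alignment: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies."""
    code = alignment.code
    counts = np.full((3, 4), 1.0)  # +1 pseudocount per cell
    idx = {b: k for k, b in enumerate("ACGT")}
    for row in alignment.codons:
        for c in row:
            codon = code.codon(int(c))
            for pos in range(3):
                counts[pos, idx[codon[pos]]] += 1
    nt = counts / counts.sum(axis=1, keepdims=True)
    f = np.array([nt[0, idx[c[0]]] * nt[1, idx[c[1]]] * nt[2, idx[c[2]]]
                  for c in code.sense_codons])
    return f / f.sum()


# ---------------------------------------------------------------------------
# site-class models
# ---------------------------------------------------------------------------

@dataclass
class SiteClassModel:
    """Parameters of one site-class mixture (see module docstring)."""

    model_id: str
    kappa: float = 2.0
    freqs: np.ndarray = field(default_factory=equal_freqs)
    omega: float = 0.5           # M0
    p0: float = 0.5
    p1: float = 0.3              # modelA / cladeC_ext only
    omega0: float = 0.1
    omega2: float = 2.0          # modelA; fixed to 1 in modelA_null
    omega_map: dict = field(default_factory=dict)  # cladeC_ext: type->omega
    foreground: frozenset = frozenset()            # modelA foreground types

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        for name, val in (("kappa", self.kappa), ("omega", self.omega),
                          ("omega0", self.omega0), ("omega2", self.omega2)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for t, w in self.omega_map.items():
            if w <= 0:
                raise ValueError(f"omega for branch type {t!r} must be "
                                 f"positive")
        if self.model_id == "modelA_null":
            self.omega2 = 1.0
        if self.model_id in ("modelA", "modelA_null") and self.omega2 < 1.0:
            raise ValueError("model A requires omega2 >= 1")
        ws = self.class_weights()
        if any(w < -1e-12 for w in ws.values()) or abs(sum(ws.values()) - 1) > 1e-8:
            raise ValueError("class proportions must be nonnegative and "
                             "sum to 1")

    def class_weights(self) -> dict:
        if self.model_id == "M0":
            return {"0": 1.0}
        if self.model_id == "M1a":
            return {"0": self.p0, "1": 1.0 - self.p0}
        if self.model_id in ("modelA", "modelA_null"):
            p2 = 1.0 - self.p0 - self.p1
            tot = self.p0 + self.p1
            return {"0": self.p0, "1": self.p1,
                    "2a": p2 * self.p0 / tot, "2b": p2 * self.p1 / tot}
        # cladeC_ext
        return {"0": self.p0, "1": self.p1, "2": 1.0 - self.p0 - self.p1}

    def omega_for(self, cls: str, branch_label: str) -> float:
        fg = branch_label in self.foreground
        if self.model_id == "M0":
            return self.omega
        if cls == "0":
            return self.omega0
        if cls == "1":
            return 1.0
        if self.model_id in ("modelA", "modelA_null"):
            if fg:
                return self.omega2
            return self.omega0 if cls == "2a" else 1.0
        if branch_label not in self.omega_map:
            raise ValueError(f"no class-2 omega declared for branch type "
                             f"{branch_label!r}")
        return self.omega_map[branch_label]

    def background_rate(self) -> float:
        """Mixture-average substitution rate on background branches.

        Used as the common scaling factor so branch lengths are expected
        substitutions per codon site under the background mixture.
        """
        r = 0.0
        for cls, w in self.class_weights().items():
            if w <= 0:
                continue
            r += w * expected_rate(self.kappa,
                                   self.omega_for(cls, BACKGROUND),
                                   self.freqs)
        return r


def n_free_site_params(model_id: str, n_branch_types: int = 2) -> int:
    """Free parameters of the omega distribution (kappa/freqs/lengths are
    shared between nested models and cancel in LRT degrees of freedom)."""
    if model_id == "M0":
        return 1
    if model_id == "M1a":
        return 2                      # p0, omega0
    if model_id == "modelA":
        return 4                      # p0, p1, omega0, omega2
    if model_id == "modelA_null":
        return 3
    if model_id == "cladeC_ext":
        return 3 + n_branch_types     # p0, p1, omega0, one omega per type
    raise ValueError(model_id)


def clade_site_df(n_branch_types: int = 2) -> int:
    """LRT degrees of freedom: extended clade model C vs M1a."""
    return (n_free_site_params("cladeC_ext", n_branch_types)
            - n_free_site_params("M1a"))


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder-compiled tree: arrays the pruning loop iterates over."""

    def __init__(self, tree: LabeledTree, taxa: Sequence[str]):
        self.nodes = tree.postorder()
        self.index = {id(n): k for k, n in enumerate(self.nodes)}
        self.root = len(self.nodes) - 1
        rowmap = {t: r for r, t in enumerate(taxa)}
        self.leaf_row = np.full(len(self.nodes), -1, dtype=int)
        self.lengths = np.zeros(len(self.nodes))
        self.labels = []
        self.children: list[list[int]] = []
        for k, n in enumerate(self.nodes):
            if n.is_leaf:
                if n.name not in rowmap:
                    raise ValueError(f"leaf {n.name!r} missing from alignment")
                self.leaf_row[k] = rowmap[n.name]
            self.lengths[k] = n.length
            self.labels.append(n.label)
            self.children.append([self.index[id(c)] for c in n.children])
        if sorted(self.leaf_row[self.leaf_row >= 0]) != list(range(len(taxa))):
            raise ValueError("tree leaves and alignment taxa differ")


def _prune_class(codons: np.ndarray, tindex: _TreeIndex,
                 pmats: list, freqs: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood for one site class (pmats indexed by node)."""
    nsites = codons.shape[1]
    partial = [None] * len(tindex.nodes)
    logscale = np.zeros(nsites)
    for k, kids in enumerate(tindex.children):
        if not kids:
            continue
        acc = None
        for c in kids:
            if tindex.leaf_row[c] >= 0:
                term = pmats[c].T[codons[tindex.leaf_row[c]]]
            else:
                term = partial[c] @ pmats[c].T
                partial[c] = None
            acc = term if acc is None else acc * term
        m = acc.max(axis=1)
        m[m == 0] = 1e-300
        logscale += np.log(m)
        partial[k] = acc / m[:, None]
    return np.log(np.maximum(partial[tindex.root] @ freqs, 1e-300)) + logscale


def site_loglik(column: np.ndarray, tree: LabeledTree, taxa: Sequence[str],
                process_for_branch) -> float:
    """Log-probability of a single codon column under per-branch processes.

    ``process_for_branch`` maps a branch label to a :class:`CodonProcess`
    (each scaled to unit expected rate). Root is weighted by the stationary
    frequencies of the root-adjacent process.
    """
    tindex = _TreeIndex(tree, taxa)
    pmats: list = [None] * len(tindex.nodes)
    freqs = None
    for k, node in enumerate(tindex.nodes):
        if k == tindex.root:
            continue
        proc = process_for_branch(tindex.labels[k])
        eig = _EigQ(proc.kappa, proc.omega, proc.freqs)
        pmats[k] = eig.pmat(tindex.lengths[k] / eig.rate)
        freqs = proc.freqs
    col = np.asarray(column, dtype=np.int16).reshape(-1, 1)
    return float(_prune_class(col, tindex, pmats, freqs)[0])


def class_site_logliks(alignment: CodonAlignment, tree: LabeledTree,
                       model: SiteClassModel,
                       tindex: _TreeIndex | None = None) -> tuple:
    """(class ids, weights, per-class per-site loglik matrix)."""
    tindex = tindex or _TreeIndex(tree, alignment.taxa)
    scale = model.background_rate()
    eig_cache: dict = {}
    pmat_cache: dict = {}
    weights = model.class_weights()
    cls_ids = list(weights)
    mat = np.zeros((len(cls_ids), alignment.ncols_kept))
    for ci, cls in enumerate(cls_ids):
        pmats: list = [None] * len(tindex.nodes)
        for k in range(len(tindex.nodes)):
            if k == tindex.root:
                continue
            w = model.omega_for(cls, tindex.labels[k])
            key = (w, tindex.lengths[k])
            if key not in pmat_cache:
                if w not in eig_cache:
                    eig_cache[w] = _EigQ(model.kappa, w, model.freqs)
                pmat_cache[key] = eig_cache[w].pmat(
                    tindex.lengths[k] / scale)
            pmats[k] = pmat_cache[key]
        mat[ci] = _prune_class(alignment.codons, tindex, pmats, model.freqs)
    return cls_ids, np.array([weights[c] for c in cls_ids]), mat


def model_loglik(alignment: CodonAlignment, tree: LabeledTree,
                 model: SiteClassModel) -> float:
    """Total log-likelihood: sum over sites of the class mixture."""
    _ids, w, mat = class_site_logliks(alignment, tree, model)
    keep = w > 0
    return float(logsumexp(mat[keep], b=w[keep, None], axis=0).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """ML estimates of one site-class model fit."""

    model_id: str
    model: SiteClassModel
    loglik: float
    params: dict
    converged: bool
    n_restarts: int
    boundary: dict
    scale: float | None = None
    tree: LabeledTree | None = None
    alignment: CodonAlignment | None = None

    def summary(self) -> str:
        lines = [f"Site-class codon model fit: {self.model_id}",
                 f"  log-likelihood  {self.loglik:.6f}",
                 f"  converged       {self.converged} "
                 f"({self.n_restarts} start(s))"]
        for k, v in self.params.items():
            note = ""
            if self.boundary.get(k):
                note = f"   [{self.boundary[k]}]"
            lines.append(f"  {k:<12s}{v:.5f}{note}")
        if self.scale is not None:
            lines.append(f"  tree scale   {self.scale:.5f}")
        return "\n".join(lines)

    def class_posteriors(self) -> tuple:
        """(class ids, per-site posterior matrix) at the MLEs (NEB)."""
        ids, w, mat = class_site_logliks(self.alignment, self.tree,
                                         self.model)
        logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
        joint = mat + logw[:, None]
        post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True))
        return ids, post


class SiteClassCodonModel:
    """Codon-model likelihood bound to one alignment and labeled tree.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : LabeledTree
        Branch lengths are interpreted as expected substitutions per codon
        site; branch labels define foreground types.
    model_id : one of M0, M1a, modelA, modelA_null, cladeC_ext
    freq_mode : "equal" or "f3x4"
    foreground : branch type treated as foreground (modelA); defaults to
        every non-background label on the tree.
    """

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree,
                 model_id: str = "M0", freq_mode: str = "equal",
                 foreground: str | None = None):
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {model_id!r}")
        self.alignment = alignment
        self.tree = tree
        self.model_id = model_id
        self.freqs = (equal_freqs() if freq_mode == "equal"
                      else f3x4_freqs(alignment))
        self.tindex = _TreeIndex(tree, alignment.taxa)
        labels = set(self.tindex.labels) - {BACKGROUND}
        if foreground is not None:
            self.foreground = frozenset([foreground])
        else:
            self.foreground = frozenset(labels)
        self.branch_types = sorted(labels | {BACKGROUND})
        if model_id in ("modelA", "modelA_null") and not self.foreground:
            raise ValueError("model A needs at least one labeled "
                             "foreground branch")

    # -- parameter packing -------------------------------------------
    def _pack(self, branch_mode: str):
        names, init, lo, hi = [], [], [], []

        def add(name, x0, a, b):
            names.append(name)
            init.append(x0)
            lo.append(a)
            hi.append(b)

        add("log_kappa", np.log(2.0), np.log(KAPPA_LO), np.log(KAPPA_HI))
        mid = self.model_id
        if mid == "M0":
            add("log_omega", np.log(0.3), np.log(OMEGA_LO), np.log(OMEGA_HI))
        elif mid == "M1a":
            add("logit_p0", 1.0, -8.0, 8.0)
            add("log_omega0", np.log(0.2), np.log(OMEGA_LO), -1e-8)
        elif mid in ("modelA", "modelA_null"):
            add("logit_p0", 0.5, -8.0, 8.0)
            add("logit_p1", 0.5, -8.0, 8.0)
            add("log_omega0", np.log(0.2), np.log(OMEGA_LO), -1e-8)
            if mid == "modelA":
                add("log_omega2", np.log(2.5), 0.0, np.log(OMEGA_HI))
        else:  # cladeC_ext
            add("logit_p0", 0.5, -8.0, 8.0)
            add("logit_p1", 0.5, -8.0, 8.0)
            add("log_omega0", np.log(0.2), np.log(OMEGA_LO), -1e-8)
            for t in self.branch_types:
                add(f"log_omega2_{t}", 0.0, np.log(OMEGA_LO),
                    np.log(OMEGA_HI))
        if branch_mode == "scale":
            add("log_scale", 0.0, -5.0, 5.0)
        elif branch_mode == "all":
            for k in range(len(self.tindex.nodes) - 1):
                add(f"log_t{k}", np.log(0.1), np.log(1e-6), np.log(20.0))
        return names, np.array(init), list(zip(lo, hi))

    def _decode(self, names, theta):
        v = dict(zip(names, theta))
        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        kw = dict(model_id=self.model_id, kappa=float(np.exp(v["log_kappa"])),
                  freqs=self.freqs, foreground=self.foreground)
        mid = self.model_id
        if mid == "M0":
            kw["omega"] = float(np.exp(v["log_omega"]))
        elif mid == "M1a":
            kw["p0"] = float(sig(v["logit_p0"]))
            kw["omega0"] = float(np.exp(v["log_omega0"]))
        elif mid in ("modelA", "modelA_null"):
            p0 = sig(v["logit_p0"])
            kw["p0"] = float(p0)
            kw["p1"] = float((1.0 - p0) * sig(v["logit_p1"]))
            kw["omega0"] = float(np.exp(v["log_omega0"]))
            if mid == "modelA":
                kw["omega2"] = float(np.exp(v["log_omega2"]))
        else:
            p0 = sig(v["logit_p0"])
            kw["p0"] = float(p0)
            kw["p1"] = float((1.0 - p0) * sig(v["logit_p1"]))
            kw["omega0"] = float(np.exp(v["log_omega0"]))
            kw["omega_map"] = {t: float(np.exp(v[f"log_omega2_{t}"]))
                               for t in self.branch_types}
        model = SiteClassModel(**kw)
        scale = float(np.exp(v["log_scale"])) if "log_scale" in v else None
        lengths = None
        if any(n.startswith("log_t") for n in names):
            lengths = np.array([np.exp(v[f"log_t{k}"])
                                for k in range(len(self.tindex.nodes) - 1)])
        return model, scale, lengths

    def _loglik(self, model, scale=None, lengths=None) -> float:
        tindex = self.tindex
        saved = tindex.lengths
        try:
            if lengths is not None:
                tindex.lengths = np.append(lengths, 0.0)
            elif scale is not None:
                tindex.lengths = saved * scale
            _ids, w, mat = class_site_logliks(
                self.alignment, self.tree, model, tindex=tindex)
            keep = w > 0
            return float(logsumexp(mat[keep], b=w[keep, None], axis=0).sum())
        finally:
            tindex.lengths = saved

    def fit(self, seed: int = 0, n_starts: int = 3,
            branch_mode: str | None = None, maxiter: int = 500) -> FitResult:
        """Bounded multi-start L-BFGS-B maximization.

        ``branch_mode``: "fixed" (use the tree's lengths as given; default
        for site-class models), "scale" (one free rescaling factor; default
        for M0 on a tree with lengths) or "all" (free per-branch lengths;
        default for M0 on a tree without lengths).
        """
        if branch_mode is None:
            if self.model_id == "M0":
                branch_mode = ("scale" if self.tree.total_length() > 0
                               else "all")
            else:
                branch_mode = "fixed"
        names, x0, bounds = self._pack(branch_mode)
        rng = np.random.default_rng(seed)

        def nll(theta):
            model, scale, lengths = self._decode(names, theta)
            return -self._loglik(model, scale, lengths)

        best = None
        any_ok = False
        for s in range(max(1, n_starts)):
            start = x0.copy()
            if s > 0:
                start = np.clip(start + rng.normal(0, 0.5, len(start)),
                                [b[0] for b in bounds],
                                [b[1] for b in bounds])
            res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-11})
            any_ok = any_ok or res.success
            if best is None or res.fun < best.fun:
                best = res
        model, scale, lengths = self._decode(names, best.x)
        loglik = -best.fun

        params = {"kappa": model.kappa}
        boundary = {}
        if scale is not None and scale <= np.exp(-5.0) * 1.01:
            boundary["scale"] = ("at lower bound: no substitutions "
                                 "observed, omega unidentifiable")
        if self.model_id == "M0":
            params["omega"] = model.omega
        else:
            params.update(p0=model.p0, omega0=model.omega0)
            if self.model_id != "M1a":
                params["p1"] = model.p1
            if self.model_id == "modelA":
                params["omega2"] = model.omega2
                if model.omega2 >= 0.95 * OMEGA_HI:
                    boundary["omega2"] = "unbounded (at upper bound)"
                elif model.omega2 <= 1.0 + 1e-3:
                    boundary["omega2"] = "at lower bound 1"
            if self.model_id == "cladeC_ext":
                for t, w in model.omega_map.items():
                    params[f"omega2_{t}"] = w
                    if w >= 0.95 * OMEGA_HI:
                        boundary[f"omega2_{t}"] = "unbounded (at upper bound)"
        tree = self.tree
        if lengths is not None:
            tree = self.tree.copy()
            for k, node in enumerate(tree.postorder()):
                if k < len(lengths):
                    node.length = float(lengths[k])
        elif scale is not None:
            tree = self.tree.scale(scale)
        return FitResult(model_id=self.model_id, model=model, loglik=loglik,
                         params=params, converged=bool(any_ok),
                         n_restarts=max(1, n_starts), boundary=boundary,
                         scale=scale, tree=tree, alignment=self.alignment)


def fit(alignment: CodonAlignment, tree: LabeledTree, model_id: str,
        options: dict | None = None) -> FitResult:
    """Functional wrapper around :class:`SiteClassCodonModel`."""
    options = dict(options or {})
    ctor = {k: options.pop(k) for k in ("freq_mode", "foreground")
            if k in options}
    return SiteClassCodonModel(alignment, tree, model_id, **ctor).fit(
        **options)


def m0_rescale_tree(alignment: CodonAlignment, tree: LabeledTree,
                    freq_mode: str = "equal", seed: int = 0,
                    n_starts: int = 1) -> tuple:
    """M0 branch-length stage: returns (tree with M0 lengths, M0 fit).

    When the input tree carries lengths, a single rescaling factor is
    estimated under M0; a tree without lengths gets free per-branch
    estimates. Site-class fits then hold these lengths fixed.
    """
    mod = SiteClassCodonModel(alignment, tree, "M0", freq_mode=freq_mode)
    res = mod.fit(seed=seed, n_starts=n_starts)
    return res.tree, res
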