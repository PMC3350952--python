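"""Independent oracles used by the test suite.

These deliberately avoid the package's eigendecomposition/pruning code:
transition matrices come from scipy's generic matrix exponential and the
site likelihood is computed by explicit summation over all internal-node
state assignments.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from chromoevol.codon import _raw_q
from chromoevol.selection import simes_pvalue


def brute_force_pmat(kappa, omega, freqs, t):
    q = _raw_q(kappa, omega, freqs)
    rate = float(-(freqs * np.diag(q)).sum())
    return expm(q * (t / rate))


def brute_force_site_loglik_3taxon(col, lengths, kappa, omega, freqs):
    """Explicit 61-state sum for a 3-leaf star tree rooted at the hub."""
    pa, pb, pc = (brute_force_pmat(kappa, omega, freqs, t)
                  for t in lengths)
    total = 0.0
    for r in range(61):
        total += (freqs[r] * pa[r, col[0]] * pb[r, col[1]]
                  * pc[r, col[2]])
    return float(np.log(total))


def brute_force_site_loglik_4taxon(col, lengths, kappa, omega, freqs):
    """Explicit 61^2-state enumeration for ((a,b)x,(c,d)y) rooted between
    the two cherry nodes x and y (root placed at x; edge tx+ty joins y)."""
    ta, tb, tc, td, txy = lengths
    pa = brute_force_pmat(kappa, omega, freqs, ta)
    pb = brute_force_pmat(kappa, omega, freqs, tb)
    pc = brute_force_pmat(kappa, omega, freqs, tc)
    pd = brute_force_pmat(kappa, omega, freqs, td)
    pxy = brute_force_pmat(kappa, omega, freqs, txy)
    total = 0.0
    for x in range(61):
        lx = freqs[x] * pa[x, col[0]] * pb[x, col[1]]
        if lx == 0.0:
            continue
        sy = 0.0
        for y in range(61):
            sy += pxy[x, y] * pc[y, col[2]] * pd[y, col[3]]
        total += lx * sy
    return float(np.log(total))


def sample_column_3taxon(lengths, kappa, omega, freqs, rng):
    """Draw one codon column from the 3-leaf star process (root from the
    stationary law, leaves via the branch transition matrices)."""
    mats = [brute_force_pmat(kappa, omega, freqs, t) for t in lengths]
    root = rng.choice(61, p=freqs)
    return np.array([rng.choice(61, p=m[root] / m[root].sum())
                     for m in mats])


def sample_column_4taxon(lengths, kappa, omega, freqs, rng):
    ta, tb, tc, td, txy = lengths
    pa, pb, pc, pd, pxy = (brute_force_pmat(kappa, omega, freqs, t)
                           for t in (ta, tb, tc, td, txy))
    x = rng.choice(61, p=freqs)
    y = rng.choice(61, p=pxy[x] / pxy[x].sum())
    pick = lambda m, s: rng.choice(61, p=m[s] / m[s].sum())
    return np.array([pick(pa, x), pick(pb, x), pick(pc, y), pick(pd, y)])


def closure_simes_adjust(p_values):
    """Closed-testing adjusted p-values with Simes local tests.

    The adjusted p for hypothesis i is the maximum Simes p-value over all
    2^n - 1 intersection hypotheses containing i (the definition Hommel's
    stepwise algorithm shortcuts).
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    adj = np.zeros(n)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            local = simes_pvalue(p[list(subset)])
            for i in subset:
                adj[i] = max(adj[i], local)
    return np.minimum(adj, 1.0)
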