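"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (direct
convolution sums, exhaustive grids, exact permutation enumeration) without
going through the package's optimized code paths.
"""

import itertools

import numpy as np


def direct_convolved_decay(alpha1, tau1, tau2, c, photons, irf_hist, dt):
    """Expected decay curve by explicit double-sum convolution."""
    n = len(irf_hist)
    irf_n = np.asarray(irf_hist, dtype=float)
    irf_n = irf_n / irf_n.sum()
    t = (np.arange(n) + 0.5) * dt
    d = alpha1 * np.exp(-t / tau1) + (1 - alpha1) * np.exp(-t / tau2)
    conv = np.zeros(n)
    for k in range(n):
        for j in range(k + 1):
            conv[k] += irf_n[j] * d[k - j]
    total = conv.sum()
    if photons == 0 or total <= 0:
        return np.full(n, float(c))
    return photons * conv / total + c


def grid_search_biexp(y, irf, w_sqrt, a1_range, t1_range, t2_range,
                      da1=0.01, dtau=0.02):
    """Exhaustive grid minimization of the profiled weighted-SSE objective.

    Amplitude and background are solved per grid point by weighted linear
    least squares (background clipped at zero).  Returns
    (best objective, (alpha1, tau1, tau2)).
    """
    n = irf.n_bins
    t = (np.arange(n) + 0.5) * irf.dt
    irfn = irf.normalized
    t1s = np.arange(t1_range[0], t1_range[1] + dtau / 2, dtau)
    t2s = np.arange(t2_range[0], t2_range[1] + dtau / 2, dtau)
    a1s = np.arange(a1_range[0], a1_range[1] + da1 / 2, da1)
    c1 = np.stack([np.convolve(irfn, np.exp(-t / tau))[:n] for tau in t1s])
    c2 = np.stack([np.convolve(irfn, np.exp(-t / tau))[:n] for tau in t2s])
    y = np.asarray(y, dtype=float)
    w = w_sqrt ** 2
    wy = w * y
    g22 = w.sum()
    b2 = wy.sum()
    best = (np.inf, None)
    for i, tau1 in enumerate(t1s):
        for a1 in a1s:
            S = a1 * c1[i][None, :] + (1 - a1) * c2      # (n_t2, bins)
            g11 = (S * S * w).sum(1)
            g12 = (S * w).sum(1)
            b1 = (S * wy).sum(1)
            det = g11 * g22 - g12 * g12
            A = (b1 * g22 - b2 * g12) / det
            C = (b2 * g11 - b1 * g12) / det
            neg = C < 0
            A[neg] = b1[neg] / g11[neg]
            C[neg] = 0.0
            np.maximum(A, 0.0, out=A)
            r = (A[:, None] * S + C[:, None] - y) * w_sqrt
            obj = np.einsum("ij,ij->i", r, r)
            j = int(np.argmin(obj))
            if obj[j] < best[0]:
                best = (float(obj[j]), (float(a1), float(tau1), float(t2s[j])))
    return best


def exact_ranksum_pvalue(x, y):
    """Two-sided rank-sum p-value by complete enumeration of group assignments.

    Valid for tie-free data with small n (C(n+m, n) assignments).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    n = x.size
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    m = y.size
    total = 0
    extreme = 0
    mean_u = n * m / 2
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            extreme += 1
    return extreme / total
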