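"""Independent brute-force oracles used to validate the library implementations.

Everything here is written as plainly as possible — nested loops, explicit
sums, scipy distributions — and deliberately shares no code with the package.
"""

import numpy as np
from scipy.stats import hypergeom


def minima_brute_force(cr):
    """Exhaustive scan of the local-minimum double inequality."""
    cr = np.asarray(cr, float)
    n = len(cr)
    locs = []
    for i in range(n):
        if i - 3 < 0 or i + 3 >= n:
            continue
        left = sum(cr[j] for j in range(i, i + 3)) - sum(cr[j] for j in range(i - 3, i))
        right = sum(cr[j] for j in range(i + 1, i + 4)) - sum(cr[j] for j in range(i - 2, i + 1))
        if left < 0 and right >= 0:
            locs.append(i)
    out = []
    for t, i in enumerate(locs):
        lo = locs[t - 1] if t > 0 else 0
        hi = locs[t + 1] if t + 1 < len(locs) else n - 1
        out.append((i, max(cr[lo:hi + 1]) - cr[i]))
    return out


def mi_brute_force(t, k):
    """Double-sum mutual information in nats, looped over cluster pairs."""
    t, k = np.asarray(t), np.asarray(k)
    n = len(t)
    total = 0.0
    for a in np.unique(t):
        for b in np.unique(k):
            nij = np.sum((t == a) & (k == b))
            if nij == 0:
                continue
            pij = nij / n
            pi = np.sum(t == a) / n
            pj = np.sum(k == b) / n
            total += pij * np.log(pij / (pi * pj))
    return total


def entropy_brute_force(x):
    x = np.asarray(x)
    n = len(x)
    return -sum((np.sum(x == v) / n) * np.log(np.sum(x == v) / n)
                for v in np.unique(x))


def emi_brute_force(t, k):
    """Expected MI under the hypergeometric permutation model."""
    t, k = np.asarray(t), np.asarray(k)
    n = len(t)
    a_sizes = [np.sum(t == v) for v in np.unique(t)]
    b_sizes = [np.sum(k == v) for v in np.unique(k)]
    emi = 0.0
    for a in a_sizes:
        for b in b_sizes:
            lo = max(1, a + b - n)
            hi = min(a, b)
            for nij in range(lo, hi + 1):
                p = hypergeom.pmf(nij, n, a, b)
                if p > 0:
                    emi += p * (nij / n) * np.log(n * nij / (a * b))
    return emi


def ami_brute_force(t, k):
    mi = mi_brute_force(t, k)
    emi = emi_brute_force(t, k)
    h = max(entropy_brute_force(t), entropy_brute_force(k))
    denom = h - emi
    if abs(denom) < 1e-15:
        return 1.0
    return (mi - emi) / denom


def ws_brute_force(t_domains, k_domains):
    """Weighted similarity via explicit bin sets."""
    t_sets = [set(range(a, b)) for a, b in t_domains]
    k_sets = [set(range(a, b)) for a, b in k_domains]
    num = den = 0.0
    for kj in k_sets:
        s = max((len(ti & kj) / np.sqrt(len(ti) * len(kj)) for ti in t_sets),
                default=0.0)
        num += s * len(kj)
        den += len(kj)
    return num / den


def se_brute_force(boundary_bins, F):
    """Structure entropy evaluated term by term from the segment edges."""
    F = np.asarray(F, float)
    N = F.shape[0]
    edges = sorted(set([0, N] + [int(b) for b in boundary_bins if 0 < b < N]))
    num = sum(F[i, j] for i in range(N) for j in range(N) if i != j)
    total = 0.0
    for s in range(len(edges) - 1):
        lo, hi = edges[s], edges[s + 1]
        vol = sum(F[a, b] for a in range(lo, hi) for b in range(N) if b != a)
        intra = sum(F[a, b] for a in range(lo, hi) for b in range(lo, hi) if b != a)
        cut = vol - intra
        if vol > 0:
            total += (cut / num) * np.log(vol / num)
        for j in range(lo, hi):
            deg = sum(F[j, b] for b in range(N) if b != j)
            if deg > 0 and vol > 0:
                total += (deg / num) * np.log(deg / vol)
    return -total / np.log(N)


def bp_brute_force(bounds_t, bounds_k, n_bins):
    """Symmetrized mean nearest-boundary distance over the boundary sets."""
    bt, bk = list(bounds_t), list(bounds_k)
    d1 = np.mean([min(abs(b - c) for c in bk) for b in bt])
    d2 = np.mean([min(abs(b - c) for c in bt) for b in bk])
    return (d1 + d2) / (2 * n_bins)


def random_partition(n, rng, max_clusters=6):
    """Random contiguous-ish label vector over n bins."""
    n_cuts = rng.integers(1, max_clusters)
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_cuts, replace=False))
    labels = np.zeros(n, dtype=int)
    for c in cuts:
        labels[c:] += 1
    return labels
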