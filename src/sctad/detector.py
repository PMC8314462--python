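"""NMF consensus-clustering detector of TAD-like domain boundaries.

The detector slides half-overlapping windows (default 8 Mb) along the
chromosome.  Inside each window the contact submatrix is factorized by
non-negative matrix factorization (NMF) repeatedly with different random
initializations; each run assigns every bin to the component on which it
loads most.  The fraction of runs in which two bins co-cluster forms the
consensus map C.  A per-bin *cluster rate* CR (mean of C over a small square
at the diagonal) dips where the local neighborhood is split inconsistently —
i.e. at domain boundaries.  Local minima of CR become boundary candidates;
the strongest ``n - 1`` plus all candidates above a strength cutoff are
called, and the component number ``n`` itself is selected by a silhouette
score computed on the dissimilarity ``D = 1 - C``.  Only the middle half of
each window is reported, so every bin is called by the window that sees it
with the most context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
import warnings

from .hic_io import ContactMatrix, DomainSet

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorParams",
    "Window",
    "ConsensusMap",
    "make_windows",
    "nmf_cluster_once",
    "consensus_map",
    "cluster_rate_profile",
    "find_local_minima",
    "select_boundaries",
    "silhouette_for_partition",
    "detect_window",
    "detect_chromosome",
]


@dataclass
class DetectorParams:
    """Tunable detector parameters (defaults follow the recommended setting
    for mammalian chromosomes at 40-kb bins)."""

    window_bp: int = 8_000_000          # sliding-window length L
    min_contacts: int = 100             # windows below this are no-call
    k: int = 10                         # NMF repetitions per candidate n
    n_range: tuple[int, ...] = (8, 9, 10, 11, 12, 13)
    strength_cutoff: float = 0.3        # CR-strength threshold for extra calls
    cr_width: int = 11                  # side of the CR averaging square
    cr_anchor: str = "corner"           # 'corner' (literal) or 'centered'
    seed_base: int = 0                  # NMF seeds are seed_base .. seed_base+k-1
    nmf_max_iter: int = 200
    nmf_tol: float = 1e-4


@dataclass
class Window:
    """One sliding window over a chromosome, in bin coordinates."""

    start: int                 # first bin
    end: int                   # past-the-end bin
    report_start: int          # report interval [report_start, report_end)
    report_end: int
    no_call: bool = False      # too few intra-window contacts

    @property
    def n_bins(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusMap:
    """Co-clustering frequencies over k NMF runs plus derived profiles."""

    C: np.ndarray              # bin x bin co-clustering frequency in [0, 1]
    k: int

    @property
    def D(self) -> np.ndarray:
        """Dissimilarity 1 - C."""
        return 1.0 - self.C


def make_windows(m: ContactMatrix, window_bp: int = 8_000_000,
                 min_contacts: int = 100) -> list[Window]:
    """Tile the chromosome with windows of length L overlapping by L/2.

    Report intervals are the middle halves ``[start + L/4, start + 3L/4)``;
    the first is extended back to bin 0 and the last forward to the
    chromosome end, so together they cover every bin exactly once.  Windows
    whose intra-window contact total is below ``min_contacts`` are flagged
    no-call.  A chromosome shorter than L yields a single whole-chromosome
    window.
    """
    if window_bp % (2 * m.binsize):
        raise ValueError("window length must be a multiple of 2*binsize")
    n = m.n_bins
    L = window_bp // m.binsize
    half, quarter = L // 2, L // 4
    if n <= L:
        n_win = 1
    else:
        n_win = int(np.ceil((n - half) / half))
    windows = []
    for w in range(n_win):
        s = w * half
        e = min(s + L, n)
        rs = 0 if w == 0 else s + quarter
        re = n if w == n_win - 1 else s + 3 * quarter
        sub = m.counts[s:e, s:e]
        total = np.triu(sub).sum()
        windows.append(Window(s, e, rs, min(re, n), no_call=total < min_contacts))
    return windows


def nmf_cluster_once(sub: np.ndarray, n_components: int, seed: int,
                     max_iter: int = 200, tol: float = 1e-4,
                     max_retries: int = 3) -> np.ndarray:
    """One NMF run: label each bin by the argmax row of its coefficient column.

    The submatrix is factorized as ``W @ H`` with random initialization from
    ``seed``; bin ``j``'s label is the row index of the maximum of column
    ``j`` of the coefficient matrix ``H`` (ties go to the lowest row).  A
    failed factorization is retried with an offset seed.
    """
    sub = np.asarray(sub, dtype=float)
    if (sub < 0).any():
        raise ValueError("contact submatrix must be non-negative")
    if n_components >= sub.shape[0]:
        raise ValueError("n_components must be smaller than the window size")
    for attempt in range(max_retries):
        try:
            model = NMF(n_components=n_components, init="random",
                        random_state=seed + attempt * 1_000_003,
                        max_iter=max_iter, tol=tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit_transform(sub)
            H = model.components_
            return np.argmax(H, axis=0)
        except Exception:
            if attempt == max_retries - 1:
                raise
            logger.warning("NMF failed with seed %d, retrying", seed)
    raise RuntimeError("unreachable")


def consensus_map(sub: np.ndarray, n_components: int, k: int = 10,
                  seed_base: int = 0, max_iter: int = 200,
                  tol: float = 1e-4) -> ConsensusMap:
    """Co-clustering frequency over k NMF runs with seeds seed_base..+k-1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = sub.shape[0]
    C = np.zeros((n, n))
    for r in range(k):
        labels = nmf_cluster_once(sub, n_components, seed_base + r,
                                  max_iter=max_iter, tol=tol)
        C += (labels[:, None] == labels[None, :])
    C /= k
    return ConsensusMap(C=C, k=k)


def cluster_rate_profile(cm: ConsensusMap, w: int = 11,
                         anchor: str = "corner") -> np.ndarray:
    """Per-bin cluster rate: mean of C over a w-bin diagonal square.

    ``anchor='corner'`` places the square's top-left corner at ``(i, i)``
    (extending downstream); ``anchor='centered'`` centers it on ``(i, i)``.
    The square is truncated at the window edges.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    C, n = cm.C, cm.C.shape[0]
    cr = np.empty(n)
    for i in range(n):
        if anchor == "corner":
            lo, hi = i, min(i + w, n)
        elif anchor == "centered":
            lo, hi = max(i - w // 2, 0), min(i + w // 2 + 1, n)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        cr[i] = C[lo:hi, lo:hi].mean()
    return cr


def find_local_minima(cr: np.ndarray) -> list[tuple[int, float]]:
    """Local minima of the cluster-rate profile, with their strengths.

    A bin ``i`` is a local minimum when the sum of CR over ``[i, i+2]`` minus
    the sum over ``[i-3, i-1]`` is negative while the same difference shifted
    one bin right is non-negative (a discrete sign change of a smoothed
    derivative).  The strength of minimum ``i_t`` is the maximum CR between
    the neighbouring minima (sentinels: first and last bin) minus CR at
    ``i_t``.
    """
    cr = np.asarray(cr, dtype=float)
    n = len(cr)
    if n < 7:
        return []
    locs = []
    for i in range(3, n - 3):
        left = cr[i:i + 3].sum() - cr[i - 3:i].sum()
        right = cr[i + 1:i + 4].sum() - cr[i - 2:i + 1].sum()
        if left < 0 <= right:
            locs.append(i)
    out = []
    for t, i in enumerate(locs):
        prev_i = locs[t - 1] if t > 0 else 0
        next_i = locs[t + 1] if t + 1 < len(locs) else n - 1
        strength = cr[prev_i:next_i + 1].max() - cr[i]
        out.append((i, float(strength)))
    return out


def select_boundaries(minima: list[tuple[int, float]], n_components: int,
                      strength_cutoff: float = 0.3) -> list[tuple[int, float]]:
    """Union of the n-1 strongest minima and all minima above the cutoff.

    If fewer than ``n_components - 1`` minima exist, all are returned.
    Result sorted by bin.
    """
    if not minima:
        return []
    by_strength = sorted(minima, key=lambda t: -t[1])
    chosen = set(b for b, _ in by_strength[:max(n_components - 1, 0)])
    chosen |= {b for b, s in minima if s > strength_cutoff}
    return sorted((b, s) for b, s in minima if b in chosen)


def silhouette_for_partition(cm: ConsensusMap, boundaries) -> float:
    """Silhouette of a boundary partition on the dissimilarity D = 1 - C.

    Boundaries split the window into clusters ``[i_k, i_{k+1})`` (with
    sentinels at the window edges).  Each bin contributes
    ``(mean_between - mean_within) / max(mean_between, mean_within)``, where
    the within mean runs over its own cluster (including the zero self
    dissimilarity) and the between mean over all other bins; bins of a
    single-cluster partition contribute 0.  The sum is divided by the window
    length.
    """
    D = cm.D
    n = D.shape[0]
    cuts = sorted({int(b) for b in boundaries if 0 < b < n})
    edges = [0] + cuts + [n]
    total = 0.0
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        inside = D[lo:hi, lo:hi]
        within = inside.mean(axis=1)               # includes D[a,a] = 0
        if lo == 0 and hi == n:
            continue                               # single cluster: terms are 0
        outside = np.concatenate([D[lo:hi, :lo], D[lo:hi, hi:]], axis=1)
        between = outside.mean(axis=1)
        denom = np.maximum(between, within)
        terms = np.where(denom > 0, (between - within) / np.where(denom > 0, denom, 1.0), 0.0)
        total += terms.sum()
    return float(total / n)


def _boundary_offset(w: int, anchor: str) -> int:
    # On an ideal two-block consensus map the local-minimum test selects the
    # bin (w+1)//2 upstream of the block junction when the CR square is
    # anchored at its corner (1 upstream when centered); shift calls so the
    # boundary bin is the first bin of the downstream domain.
    return (w + 1) // 2 if anchor == "corner" else 1


def detect_window(sub: np.ndarray, params: DetectorParams | None = None
                  ) -> tuple[list[int], dict]:
    """Run the full per-window pipeline; return boundary bins and diagnostics.

    For each candidate component number ``n`` the consensus map, cluster-rate
    profile, minima and boundary selection are computed; the ``n`` with the
    highest silhouette wins (ties to the smaller ``n``).  Returned boundary
    bins are window-local, corrected by the CR-anchor offset so each marks
    the first bin of its downstream domain.  Diagnostics include per-``n``
    silhouettes and the selected ``n``.
    """
    p = params or DetectorParams()
    n_bins = sub.shape[0]
    best = None
    sil_by_n = {}
    for n in p.n_range:
        if n >= n_bins:
            continue
        cm = consensus_map(sub, n, k=p.k, seed_base=p.seed_base,
                           max_iter=p.nmf_max_iter, tol=p.nmf_tol)
        cr = cluster_rate_profile(cm, w=p.cr_width, anchor=p.cr_anchor)
        minima = find_local_minima(cr)
        calls = select_boundaries(minima, n, p.strength_cutoff)
        off = _boundary_offset(p.cr_width, p.cr_anchor)
        bounds = sorted({b + off for b, _ in calls if 0 < b + off < n_bins})
        sil = silhouette_for_partition(cm, bounds)
        sil_by_n[n] = sil
        if best is None or sil > best[0] + 1e-12:
            best = (sil, n, bounds)
    if best is None:
        return [], {"selected_n": None, "silhouette": sil_by_n}
    logger.info("window: selected n=%d (silhouette=%.4f)", best[1], best[0])
    return best[2], {"selected_n": best[1], "silhouette": sil_by_n}


def detect_chromosome(m: ContactMatrix, params: DetectorParams | None = None
                      ) -> tuple[DomainSet, list[dict]]:
    """Detect TAD-like domains on a whole chromosome.

    Windows are processed independently; each contributes only boundaries
    falling inside its report interval (the middle half, extended to the
    chromosome edges for the terminal windows).  Report intervals of no-call
    windows become gaps.  Returns the stitched DomainSet and per-window
    diagnostics.
    """
    p = params or DetectorParams()
    windows = make_windows(m, p.window_bp, p.min_contacts)
    boundaries: list[int] = []
    covered: list[tuple[int, int]] = []
    diags = []
    for w in windows:
        if w.no_call:
            diags.append({"window": (w.start, w.end), "no_call": True})
            continue
        sub = m.counts[w.start:w.end, w.start:w.end]
        local, d = detect_window(sub, p)
        d["window"] = (w.start, w.end)
        d["no_call"] = False
        diags.append(d)
        covered.append((w.report_start, w.report_end))
        for b in local:
            ab = w.start + b
            if w.report_start <= ab < w.report_end:
                boundaries.append(ab)
    if not covered:
        warnings.warn("all windows no-call; empty domain set")
        return DomainSet(m.chrom, m.binsize, m.n_bins, []), diags
    # merge covered report intervals into contiguous segments and cut them
    covered.sort()
    merged = [list(covered[0])]
    for a, b in covered[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    bset = sorted(set(boundaries))
    domains = []
    for a, b in merged:
        cuts = [a] + [x for x in bset if a < x < b] + [b]
        domains += [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    return DomainSet(m.chrom, m.binsize, m.n_bins, domains), diags
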