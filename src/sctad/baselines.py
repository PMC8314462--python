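"""Simple reference boundary callers used for comparison.

Only a naive insulation-score caller is provided: the insulation profile is
the total contact count in a square sliding along the diagonal, and
boundaries are local minima whose normalized depth (delta of the log2
insulation relative to the flanking maxima) exceeds a threshold.  It is the
classic sliding-square heuristic, deliberately minimal, and serves as a
stability yardstick for the consensus detector under extreme downsampling.
"""

from __future__ import annotations

import numpy as np

from .hic_io import ContactMatrix, DomainSet, domain_set_from_boundaries

__all__ = ["insulation_profile", "insulation_boundaries", "detect_insulation"]


def insulation_profile(m: ContactMatrix, window_bins: int = 10) -> np.ndarray:
    """Total contacts in a (window x window) square crossing the diagonal at
    each bin; NaN where the square leaves the matrix."""
    n = m.n_bins
    w = window_bins
    prof = np.full(n, np.nan)
    for i in range(w, n - w):
        prof[i] = m.counts[i - w:i, i:i + w].sum()
    return prof


def insulation_boundaries(profile: np.ndarray, delta: float = 0.1) -> np.ndarray:
    """Local minima of the log2 insulation profile with relative depth > delta."""
    with np.errstate(divide="ignore"):
        lp = np.log2(profile + 1.0)
    n = lp.size
    out = []
    for i in range(1, n - 1):
        if not np.isfinite(lp[i - 1:i + 2]).all():
            continue
        if lp[i] <= lp[i - 1] and lp[i] < lp[i + 1]:
            left = np.nanmax(lp[max(i - 10, 0):i + 1])
            right = np.nanmax(lp[i:min(i + 11, n)])
            depth = min(left, right) - lp[i]
            if depth > delta:
                out.append(i)
    return np.array(out, dtype=int)


def detect_insulation(m: ContactMatrix, window_bins: int = 10,
                      delta: float = 0.1) -> DomainSet:
    """Insulation-minimum domain call over the whole chromosome."""
    prof = insulation_profile(m, window_bins)
    bounds = insulation_boundaries(prof, delta)
    return domain_set_from_boundaries(bounds, m.n_bins, m.chrom, m.binsize)
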