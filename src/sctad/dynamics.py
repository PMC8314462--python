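"""Boundary dynamics across a population of single cells.

Given per-cell TAD-like domain sets and an ensemble (bulk) domain set, these
analyses ask how domain boundaries vary between cells: which ensemble
boundaries are over- or under-used (binomial popularity model), which
single-cell boundaries are absent from the ensemble (scSBs, classed by the
number of carrying cells), whether a cell merged, split or shifted ensemble
domains, which ensemble boundaries are nested (high cross-boundary contact)
or unnested, which boundaries are specific to a cell condition, whether the
domain structure alone classifies cells (WS similarity -> Spearman -> PCA),
and whether a per-bin signal (e.g. DNA methylation) is more correlated
within domains than across boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hic_io import ContactMatrix, DomainSet
from .metrics import ws

__all__ = [
    "BoundaryCatalog",
    "build_catalog",
    "classify_variation",
    "boundary_popularity",
    "classify_scsb",
    "nested_unnested",
    "condition_specific_boundaries",
    "cell_classification",
    "inter_intra_correlation",
    "compartment_domain_boundaries",
]


@dataclass
class BoundaryCatalog:
    """Boundary usage across cells on one chromosome."""

    n_bins: int
    n_cells: int
    per_cell: list[np.ndarray]            # boundary bins per cell
    ensemble: np.ndarray | None = None    # ensemble boundary bins
    occurrence: np.ndarray = field(init=False)  # per-bin cell counts

    def __post_init__(self) -> None:
        occ = np.zeros(self.n_bins, dtype=int)
        for b in self.per_cell:
            occ[np.unique(np.asarray(b, dtype=int))] += 1
        self.occurrence = occ


def build_catalog(cell_domains: list[DomainSet],
                  ensemble: DomainSet | None = None) -> BoundaryCatalog:
    """Collect per-cell boundary bins into a catalog."""
    if not cell_domains:
        raise ValueError("no cells")
    n_bins = cell_domains[0].n_bins
    per_cell = [d.internal_boundaries for d in cell_domains]
    ens = ensemble.internal_boundaries if ensemble is not None else None
    return BoundaryCatalog(n_bins, len(cell_domains), per_cell, ens)


def classify_variation(ensemble: DomainSet, cell: DomainSet,
                       flank_bp: int = 100_000) -> list[str]:
    """Classify each cell domain against the ensemble TADs.

    Ensemble boundary regions are the bins within ``flank_bp`` of an
    ensemble boundary bin.  A cell domain is *matched* when both its ends
    fall in boundary regions and it contains no further ensemble boundary;
    *merged* when both ends align but one or more ensemble boundaries lie
    strictly inside; *split* when exactly one end aligns and the other falls
    inside an ensemble domain; *shifted* when neither end aligns and the two
    ends fall into two different ensemble domains; anything else is *other*.
    """
    if not ensemble.domains or not cell.domains:
        raise ValueError("empty domain set")
    flank = flank_bp // ensemble.binsize
    # alignment targets: every ensemble domain edge, plus the chromosome
    # ends (implicit edges); "inside" checks use internal boundaries only
    edges = np.array(sorted({0, ensemble.n_bins,
                             *[a for a, _ in ensemble.domains],
                             *[b for _, b in ensemble.domains]}))
    ebounds = ensemble.internal_boundaries

    def aligned(b: int) -> bool:
        return bool(np.abs(edges - b).min() <= flank)

    def host_domain(b: int) -> int:
        for i, (a, e) in enumerate(ensemble.domains):
            if a <= b < e:
                return i
        return -1

    out = []
    for a, b in cell.domains:
        start_ok, end_ok = aligned(a), aligned(b)
        inside = [x for x in ebounds if a + flank < x < b - flank]
        if start_ok and end_ok:
            out.append("merged" if inside else "matched")
        elif start_ok != end_ok:
            out.append("split")
        else:
            ha, hb = host_domain(a), host_domain(max(b - 1, a))
            out.append("shifted" if ha != hb and ha >= 0 and hb >= 0 else "other")
    return out


def boundary_popularity(catalog: BoundaryCatalog, hi: int = 12, lo: int = 6,
                        n_draws: int = 10_000, seed: int = 0,
                        p_null: float | None = None) -> dict:
    """Over/under-represented ensemble boundaries under a binomial null.

    Each ensemble boundary's cell count is compared with B(n_cells, p̂),
    p̂ being the mean occurrence frequency (or an explicit ``p_null``).
    Boundaries seen in more than ``hi`` cells are *popular*, in fewer than
    ``lo`` *unpopular* (the defaults mirror thresholds appropriate for ~150
    cells at p̂ ≈ 0.06).  The deviation p-value is the Monte-Carlo
    probability that the binomial null produces at least as many tail
    boundaries (popular + unpopular).
    """
    if catalog.ensemble is None:
        raise ValueError("catalog lacks an ensemble boundary set")
    if catalog.n_cells < 2:
        raise ValueError("need at least two cells")
    counts = catalog.occurrence[catalog.ensemble]
    n_b = counts.size
    p_hat = counts.mean() / catalog.n_cells if p_null is None else p_null
    popular = catalog.ensemble[counts > hi]
    unpopular = catalog.ensemble[counts < lo]
    obs_tail = popular.size + unpopular.size
    rng = np.random.default_rng(seed)
    sims = rng.binomial(catalog.n_cells, p_hat, size=(n_draws, n_b))
    sim_tail = ((sims > hi).sum(axis=1) + (sims < lo).sum(axis=1))
    p = (1 + (sim_tail >= obs_tail).sum()) / (n_draws + 1)
    return {"popular": popular, "unpopular": unpopular, "p_value": float(p),
            "p_hat": float(p_hat), "counts": counts}


def classify_scsb(catalog: BoundaryCatalog, n_perm: int = 100,
                  mappable=None, seed: int = 0) -> dict:
    """Class counts of single-cell-specific boundaries (scSBs).

    An scSB is a cell boundary bin absent from the ensemble set (same-bin
    identity).  Bins are classed by the number of carrying cells: scSB-1,
    scSB-2, scSB-m (>2); mappable bins never used as a boundary in any cell
    are *absent*.  A permutation control repositions each cell's boundaries
    uniformly over mappable bins (preserving per-cell counts) and records
    the class counts of each permutation.
    """
    if catalog.ensemble is None:
        raise ValueError("catalog lacks an ensemble boundary set")
    if mappable is None:
        mappable = np.ones(catalog.n_bins, dtype=bool)
    pool = np.flatnonzero(np.asarray(mappable, dtype=bool))
    ens = set(catalog.ensemble.tolist())

    def classes(per_cell) -> dict:
        occ = np.zeros(catalog.n_bins, dtype=int)
        for b in per_cell:
            occ[np.unique(np.asarray(b, dtype=int))] += 1
        sc = np.array([i for i in np.flatnonzero(occ) if i not in ens])
        c = occ[sc] if sc.size else np.array([], dtype=int)
        used = np.zeros(catalog.n_bins, dtype=bool)
        if sc.size:
            used[sc] = True
        used[list(ens)] = True
        absent = int((~used[pool]).sum())
        return {"scSB-1": int((c == 1).sum()), "scSB-2": int((c == 2).sum()),
                "scSB-m": int((c > 2).sum()), "absent": absent}

    observed = classes(catalog.per_cell)
    rng = np.random.default_rng(seed)
    control = {k: [] for k in observed}
    for _ in range(n_perm):
        perm = [rng.choice(pool, size=len(np.unique(np.asarray(b, dtype=int))),
                           replace=False) for b in catalog.per_cell]
        for k, v in classes(perm).items():
            control[k].append(v)
    return {"observed": observed,
            "control": {k: np.array(v) for k, v in control.items()}}


def nested_unnested(ensemble: DomainSet, f: ContactMatrix,
                    n_top: int = 20, n_drop: int = 20,
                    flank_bp: int = 400_000) -> tuple[np.ndarray, np.ndarray]:
    """Split ensemble boundaries into nested and unnested by cross contacts.

    Each boundary is scored by the number of contacts between its upstream
    and downstream ``flank_bp`` regions.  The ``n_drop`` lowest-scoring
    boundaries are removed first (typically unmappable artifacts); of the
    rest, the ``n_top`` highest are *nested* and the ``n_top`` lowest
    *unnested*.
    """
    if flank_bp % f.binsize:
        raise ValueError("flank must be a whole number of bins")
    w = flank_bp // f.binsize
    bounds = ensemble.internal_boundaries
    if bounds.size < 2 * n_top + n_drop:
        raise ValueError("not enough boundaries for the requested selection")
    cross = np.array([
        f.counts[max(b - w, 0):b, b:min(b + w, f.n_bins)].sum() for b in bounds
    ])
    order = np.argsort(cross, kind="stable")
    keep = order[n_drop:]
    nested = bounds[keep[-n_top:]]
    unnested = bounds[keep[:n_top]]
    return np.sort(nested), np.sort(unnested)


def condition_specific_boundaries(catalog_a: BoundaryCatalog,
                                  catalog_b: BoundaryCatalog,
                                  n_select: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Bins most biased toward condition A and toward condition B.

    Per-bin bias is the difference in the proportion of cells using the bin
    as a boundary (freq_A - freq_B); the top ``n_select`` bins are
    A-specific and the bottom ``n_select`` B-specific.
    """
    if catalog_a.n_bins != catalog_b.n_bins:
        raise ValueError("catalogs must share binning")
    bias = (catalog_a.occurrence / catalog_a.n_cells
            - catalog_b.occurrence / catalog_b.n_cells)
    if np.allclose(bias, bias[0]):
        warnings.warn("bias is constant; no condition-specific boundaries")
        return np.array([], dtype=int), np.array([], dtype=int)
    if 2 * n_select > catalog_a.n_bins:
        raise ValueError("selections would overlap on this genome")
    order = np.argsort(bias, kind="stable")
    a_spec = np.sort(order[-n_select:])
    b_spec = np.sort(order[:n_select])
    return a_spec, b_spec


def _pc1(mat: np.ndarray) -> np.ndarray:
    """First principal-component scores of the rows, sign-fixed."""
    X = mat - mat.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    nz = np.flatnonzero(v)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return X @ v


def _spearman_matrix(M: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation; constant rows correlate 0."""
    n = M.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 1, M)
    sd = ranks.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn("constant similarity rows; Spearman set to 0")
    Z = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((Z ** 2).sum(axis=1))
    denom[denom == 0] = 1.0
    C = (Z @ Z.T) / np.outer(denom, denom)
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def cell_classification(cells: list[dict[str, DomainSet]],
                        labels=None) -> dict:
    """Classify cells by their TAD-like domain structure alone.

    Per chromosome, the asymmetric WS similarity between every cell pair
    forms M; its row-wise Spearman correlation C is summarized by the first
    principal component, whose per-cell sign ``S`` (+1/0/-1; 0 when the
    chromosome is missing for a cell) votes in the agreement matrix
    ``T_ij = sum_k S_ik S_jk / sum_k |S_ik S_jk|`` (0 when no chromosome
    informs the pair).  The classification index is PC1 of T.  When binary
    ``labels`` are given, the ROC AUC of the index is reported as
    ``max(auc, 1 - auc)`` (the index sign is arbitrary).
    """
    n = len(cells)
    if n < 2:
        raise ValueError("need at least two cells")
    chroms = sorted({c for cell in cells for c in cell})
    S = np.zeros((n, len(chroms)))
    for ci, chrom in enumerate(chroms):
        have = [i for i in range(n) if chrom in cells[i]]
        if len(have) < 2:
            continue
        m = len(have)
        M = np.zeros((m, m))
        for a in range(m):
            for b in range(m):
                M[a, b] = 1.0 if a == b else ws(cells[have[a]][chrom],
                                                cells[have[b]][chrom])
        C = _spearman_matrix(M)
        v = _pc1(C)
        S[have, ci] = np.sign(v)
    T = np.zeros((n, n))
    undefined = 0
    for i in range(n):
        for j in range(n):
            prod = S[i] * S[j]
            denom = np.abs(prod).sum()
            if denom > 0:
                T[i, j] = prod.sum() / denom
            elif i != j:
                undefined += 1
    if undefined:
        warnings.warn(f"{undefined} cell pairs share no informative chromosome")
    index = _pc1(T)
    out = {"index": index, "T": T, "S": S}
    if labels is not None:
        from sklearn.metrics import roc_auc_score
        y = np.asarray(labels)
        auc = roc_auc_score(y, index)
        out["auc"] = float(max(auc, 1.0 - auc))
    return out


def inter_intra_correlation(cell_domains: list[DomainSet],
                            signal: np.ndarray, sep_bins: int = 6,
                            min_obs: int = 3) -> dict:
    """Compare signal correlation within domains vs. across boundaries.

    ``signal`` is a (cells x bins) array (NaN = missing).  For every bin
    pair at separation ``sep_bins`` (default 240 kb at 40-kb bins) and each
    class — *intra* when the pair lies in one domain of a cell, *inter* when
    a boundary separates it — the Pearson correlation is computed across the
    cells assigning that class (requiring ``min_obs`` complete
    observations), then averaged over pairs within each class.  The classes
    are compared by Fisher's z-test with the number of contributing pairs as
    the effective sample sizes.
    """
    signal = np.asarray(signal, dtype=float)
    n_cells, n_bins = signal.shape
    if len(cell_domains) != n_cells:
        raise ValueError("one domain set per cell required")
    # per cell, map each bin to its domain id (-1 in gaps)
    dom_id = np.full((n_cells, n_bins), -1, dtype=int)
    for c, d in enumerate(cell_domains):
        for k, (a, b) in enumerate(d.domains):
            dom_id[c, a:b] = k
    r_intra, r_inter = [], []
    for a in range(n_bins - sep_bins):
        b = a + sep_bins
        x, y = signal[:, a], signal[:, b]
        ok = np.isfinite(x) & np.isfinite(y)
        same = (dom_id[:, a] == dom_id[:, b]) & (dom_id[:, a] >= 0)
        for cls, sel in (("intra", ok & same), ("inter", ok & ~same)):
            if sel.sum() < min_obs:
                continue
            xs, ys = x[sel], y[sel]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            (r_intra if cls == "intra" else r_inter).append(r)
    if not r_intra or not r_inter:
        raise ValueError("one of the correlation groups is empty")
    ri, re = float(np.mean(r_intra)), float(np.mean(r_inter))
    n1, n2 = len(r_intra), len(r_inter)
    eps = 1e-12
    z = (np.arctanh(np.clip(ri, -1 + eps, 1 - eps))
         - np.arctanh(np.clip(re, -1 + eps, 1 - eps)))
    if min(n1, n2) > 3:
        z /= np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = float("nan")
    return {"r_intra": ri, "r_inter": re, "n_intra": n1, "n_inter": n2,
            "z": float(z), "p_value": p}


def compartment_domain_boundaries(ensemble: DomainSet,
                                  score: np.ndarray) -> np.ndarray:
    """Boundaries whose flanking bins carry opposite-signed compartment scores.

    ``score`` is a per-bin track (NaN = missing); a boundary bin ``b`` is
    selected when ``score[b-1]`` and ``score[b]`` have strictly opposite
    signs.  Boundaries with a missing flank are skipped with a warning.
    """
    score = np.asarray(score, dtype=float)
    if score.size != ensemble.n_bins:
        raise ValueError("score track must cover all bins")
    out, skipped = [], 0
    for b in ensemble.internal_boundaries:
        if b == 0:
            continue
        left, right = score[b - 1], score[b]
        if not (np.isfinite(left) and np.isfinite(right)):
            skipped += 1
            continue
        if left * right < 0:
            out.append(int(b))
    if skipped:
        warnings.warn(f"{skipped} boundaries skipped for missing scores")
    return np.array(out, dtype=int)
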