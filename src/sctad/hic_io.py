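"""Contact-matrix and domain-interval I/O, normalization and resampling.

A :class:`ContactMatrix` holds the symmetric bin-by-bin contact counts of a
single chromosome at a fixed bin size.  A :class:`DomainSet` holds an ordered,
non-overlapping set of half-open bin intervals (TAD-like domains); bins not
covered by any domain form *gaps* (intermediate windows).  All coordinates are
0-based half-open, both internally and in BED output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMatrix",
    "DomainSet",
    "read_contact_matrix",
    "read_domains_bed",
    "write_domains_bed",
    "ice_normalize",
    "downsample_contacts",
    "rebin_matrix",
    "sparsity",
]


@dataclass
class ContactMatrix:
    """Symmetric non-negative contact counts for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    binsize : int
        Bases per bin.
    counts : ndarray of shape (n_bins, n_bins)
        Symmetric, non-negative contact counts (floats allowed after
        normalization).
    mappable : ndarray of bool, optional
        Per-bin mappability flag.  By default a bin is mappable when its
        marginal (row sum) is positive.
    """

    chrom: str
    binsize: int
    counts: np.ndarray
    mappable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("negative contact counts")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.mappable is None:
            self.mappable = self.counts.sum(axis=0) > 0
        else:
            self.mappable = np.asarray(self.mappable, dtype=bool)
            if self.mappable.shape != (self.n_bins,):
                raise ValueError("mappable mask has wrong length")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        """Total number of contacts (upper triangle including diagonal)."""
        return float(np.triu(self.counts).sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.binsize, self.counts.copy(),
                             self.mappable.copy())


@dataclass
class DomainSet:
    """Ordered, disjoint half-open bin intervals on one chromosome.

    ``domains`` is a list of ``(start_bin, end_bin)`` pairs; every boundary
    bin is the start of a domain.  Bins of ``[0, n_bins)`` not covered by a
    domain are gaps ("intermediate windows").
    """

    chrom: str
    binsize: int
    n_bins: int
    domains: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        doms = sorted((int(a), int(b)) for a, b in self.domains)
        prev_end = 0
        for a, b in doms:
            if b <= a:
                raise ValueError(f"empty or inverted domain ({a}, {b})")
            if a < prev_end:
                raise ValueError("domains overlap")
            if b > self.n_bins:
                raise ValueError("domain extends past chromosome end")
            prev_end = b
        self.domains = doms

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Complement intervals of the domains within ``[0, n_bins)``."""
        out, pos = [], 0
        for a, b in self.domains:
            if a > pos:
                out.append((pos, a))
            pos = b
        if pos < self.n_bins:
            out.append((pos, self.n_bins))
        return out

    @property
    def boundaries(self) -> np.ndarray:
        """Start bins of all domains, sorted."""
        return np.array([a for a, _ in self.domains], dtype=int)

    @property
    def internal_boundaries(self) -> np.ndarray:
        """Domain starts that are preceded immediately by another domain."""
        ends = {b for _, b in self.domains}
        return np.array([a for a, _ in self.domains if a in ends], dtype=int)

    def __len__(self) -> int:
        return len(self.domains)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainSet):
            return NotImplemented
        return (self.chrom == other.chrom and self.binsize == other.binsize
                and self.n_bins == other.n_bins
                and self.domains == other.domains)


def read_contact_matrix(path, format: str = "triplet", chrom: str = "chr1",
                        binsize: int = 40_000, n_bins: int | None = None,
                        coords: str = "auto") -> ContactMatrix:
    """Read a contact matrix from triplet text, dense text or a .cool file.

    Triplet rows are ``i j count`` where ``i``/``j`` are either 0-based bin
    indices or base-pair positions (``coords='auto'`` treats values as
    positions when every one is a multiple of ``binsize`` and at least one
    exceeds the largest plausible bin index).  Duplicate ``(i, j)`` rows are
    summed.  Dense files are whitespace-separated square matrices.  For
    ``.cool`` input the standard cooler HDF5 layout is read with h5py.
    """
    if format == "dense":
        mat = np.loadtxt(path, dtype=float, ndmin=2)
        if (mat < 0).any():
            raise ValueError("negative counts in dense matrix")
        mat = np.maximum(mat, mat.T) if not np.allclose(mat, mat.T) else mat
        return ContactMatrix(chrom, binsize, mat)
    if format == "cool":
        return _read_cool(path, chrom, binsize)
    if format != "triplet":
        raise ValueError(f"unknown format {format!r}")

    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.size == 0:
        if n_bins is None:
            raise ValueError("empty triplet file and no n_bins given")
        return ContactMatrix(chrom, binsize, np.zeros((n_bins, n_bins)))
    if data.shape[1] != 3:
        raise ValueError("triplet rows must have 3 columns")
    ii, jj, cc = data[:, 0], data[:, 1], data[:, 2]
    if (cc < 0).any():
        raise ValueError("negative counts")
    as_pos = coords == "pos"
    if coords == "auto":
        vals = np.concatenate([ii, jj])
        as_pos = bool(np.all(vals % binsize == 0) and vals.max() >= binsize
                      and n_bins is not None and vals.max() >= n_bins)
        if n_bins is None:
            as_pos = bool(np.all(vals % binsize == 0) and vals.max() > 10_000)
    if as_pos:
        ii, jj = ii // binsize, jj // binsize
    ii = ii.astype(int)
    jj = jj.astype(int)
    n = int(max(ii.max(), jj.max())) + 1 if n_bins is None else n_bins
    if ii.max() >= n or jj.max() >= n:
        raise ValueError("bin index beyond declared n_bins")
    mat = np.zeros((n, n))
    np.add.at(mat, (ii, jj), cc)
    low = ii != jj
    np.add.at(mat, (jj[low], ii[low]), cc[low])
    return ContactMatrix(chrom, binsize, mat)


def _read_cool(path, chrom: str, binsize: int) -> ContactMatrix:
    """Minimal reader for the single-resolution cooler HDF5 schema."""
    import h5py

    with h5py.File(path, "r") as f:
        if int(f.attrs.get("bin-size", binsize)) != binsize:
            raise ValueError("cool file binsize does not match request")
        names = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in f["chroms/name"][:]]
        if chrom not in names:
            raise ValueError(f"chromosome {chrom!r} not in cool file")
        cid = names.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        sel = np.flatnonzero(bin_chrom == cid)
        offset, n = int(sel[0]), len(sel)
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:].astype(float)
    keep = (b1 >= offset) & (b1 < offset + n) & (b2 >= offset) & (b2 < offset + n)
    ii, jj, cc = b1[keep] - offset, b2[keep] - offset, cnt[keep]
    mat = np.zeros((n, n))
    np.add.at(mat, (ii, jj), cc)
    low = ii != jj
    np.add.at(mat, (jj[low], ii[low]), cc[low])
    return ContactMatrix(chrom, binsize, mat)


def write_cool(m: ContactMatrix, path) -> None:
    """Write a minimal single-resolution cooler file (upper-triangle pixels)."""
    import h5py

    iu, ju = np.triu_indices(m.n_bins)
    nz = m.counts[iu, ju] != 0
    iu, ju = iu[nz], ju[nz]
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = m.binsize
        f.create_dataset("chroms/name", data=np.array([m.chrom], dtype="S32"))
        f.create_dataset("chroms/length",
                         data=np.array([m.n_bins * m.binsize], dtype=np.int64))
        f.create_dataset("bins/chrom", data=np.zeros(m.n_bins, dtype=np.int32))
        starts = np.arange(m.n_bins, dtype=np.int64) * m.binsize
        f.create_dataset("bins/start", data=starts)
        f.create_dataset("bins/end", data=starts + m.binsize)
        f.create_dataset("pixels/bin1_id", data=iu.astype(np.int64))
        f.create_dataset("pixels/bin2_id", data=ju.astype(np.int64))
        f.create_dataset("pixels/count", data=m.counts[iu, ju])


def write_triplet(m: ContactMatrix, path) -> None:
    """Write the upper triangle (including diagonal) as ``i j count`` rows."""
    iu, ju = np.triu_indices(m.n_bins)
    nz = m.counts[iu, ju] != 0
    cols = np.column_stack([iu[nz], ju[nz], m.counts[iu[nz], ju[nz]]])
    np.savetxt(path, cols, fmt="%d %d %g")


def ice_normalize(m: ContactMatrix, max_iter: int = 200,
                  tol: float = 1e-5) -> ContactMatrix:
    """Iterative correction (ICE): equalize marginals of mappable bins.

    Repeatedly divides the matrix by the outer product of its scaled
    marginals until the bias update changes by less than ``tol`` in relative
    terms.  Unmappable bins are zeroed.  The output is rescaled so the total
    mass over mappable bins equals the input's.
    """
    if m.counts.sum() == 0:
        raise ValueError("empty matrix")
    mask = m.mappable.copy()
    W = m.counts.copy()
    W[~mask, :] = 0.0
    W[:, ~mask] = 0.0
    target = W.sum()
    for _ in range(max_iter):
        s = W.sum(axis=0)
        s_m = s[mask]
        b = np.ones_like(s)
        b[mask] = s_m / s_m.mean()
        W = W / np.outer(b, b)
        W[~mask, :] = 0.0
        W[:, ~mask] = 0.0
        if np.abs(b[mask] - 1.0).max() < tol:
            break
    W *= target / W.sum()
    return ContactMatrix(m.chrom, m.binsize, W, mask)


def downsample_contacts(m: ContactMatrix, rate: float,
                        seed: int | np.random.Generator = 0) -> ContactMatrix:
    """Binomially thin raw integer counts, keeping each read with prob. ``rate``.

    Operates on the upper triangle and mirrors, so the result stays
    symmetric.  Only raw (integer) matrices may be thinned; normalize after
    downsampling, not before.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    if not np.allclose(m.counts, np.round(m.counts)):
        raise ValueError("downsampling requires raw integer counts")
    if rate == 1.0:
        return m.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.triu_indices(m.n_bins)
    kept = rng.binomial(np.round(m.counts[iu, ju]).astype(np.int64), rate)
    out = np.zeros_like(m.counts)
    out[iu, ju] = kept
    out[ju, iu] = kept
    return ContactMatrix(m.chrom, m.binsize, out)


def rebin_matrix(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum ``factor`` x ``factor`` blocks of counts; binsize grows accordingly.

    A trailing partial block (when ``n_bins`` is not divisible by ``factor``)
    is kept as a short final bin so that total counts are conserved.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return m.copy()
    n = m.n_bins
    n_out = -(-n // factor)
    pad = n_out * factor - n
    c = np.pad(m.counts, ((0, pad), (0, pad)))
    out = c.reshape(n_out, factor, n_out, factor).sum(axis=(1, 3))
    return ContactMatrix(m.chrom, m.binsize * factor, out)


def sparsity(m: ContactMatrix, include_diagonal: bool = True) -> float:
    """Fraction of zero entries among mappable-bin pairs.

    Counts the upper triangle of the mappable submatrix; the diagonal is
    included by default (configurable, as conventions differ).
    """
    mask = m.mappable
    if not mask.any():
        raise ValueError("no mappable bins")
    sub = m.counts[np.ix_(mask, mask)]
    k = 0 if include_diagonal else 1
    iu, ju = np.triu_indices(sub.shape[0], k=k)
    vals = sub[iu, ju]
    return float((vals == 0).sum() / vals.size)


def write_domains_bed(d: DomainSet, path) -> None:
    """Write one BED row per domain (0-based half-open genomic coordinates)."""
    with open(path, "w") as fh:
        fh.write(f"# domains for {d.chrom} binsize={d.binsize} n_bins={d.n_bins}\n")
        for a, b in d.domains:
            fh.write(f"{d.chrom}\t{a * d.binsize}\t{b * d.binsize}\n")


def read_domains_bed(path, binsize: int | None = None,
                     n_bins: int | None = None) -> DomainSet:
    """Read a domain BED file written by :func:`write_domains_bed`.

    ``binsize``/``n_bins`` default to values recorded in the header comment;
    coordinates that are not multiples of ``binsize`` are floored to bins
    with a warning.
    """
    chrom, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(("#", "track", "browser")):
                if "binsize=" in line:
                    for tok in line.split():
                        if tok.startswith("binsize=") and binsize is None:
                            binsize = int(tok.split("=")[1])
                        if tok.startswith("n_bins=") and n_bins is None:
                            n_bins = int(tok.split("=")[1])
                continue
            parts = line.split()
            chrom = chrom or parts[0]
            rows.append((int(parts[1]), int(parts[2])))
    if binsize is None:
        raise ValueError("binsize not given and not recorded in file")
    doms = []
    for s, e in rows:
        if s % binsize or e % binsize:
            warnings.warn("interval not aligned to binsize; flooring to bins")
        doms.append((s // binsize, -(-e // binsize)))
    if n_bins is None:
        n_bins = max((b for _, b in doms), default=0)
    return DomainSet(chrom or "chr1", binsize, n_bins, doms)


def domain_set_from_boundaries(boundaries, n_bins: int, chrom: str = "chr1",
                               binsize: int = 40_000) -> DomainSet:
    """Build a gap-free DomainSet from internal boundary bins.

    Boundary bins are starts of their downstream domain; bin 0 implicitly
    starts the first domain.
    """
    cuts = sorted({int(b) for b in boundaries if 0 < b < n_bins})
    edges = [0] + cuts + [n_bins]
    doms = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return DomainSet(chrom, binsize, n_bins, doms)
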