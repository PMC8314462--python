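"""Simulation of reference and single-cell Hi-C from 3D chromatin models.

Contacts are sampled from an ordered chain of particles (one per fine bin,
default 10 kb).  The reference (bulk-like) map weights every locus pair by
the inverse of its Euclidean distance and draws Poisson counts; the
single-cell map keeps only pairs closer than a threshold ``D``, weights them
by ``D - distance``, and distributes a fixed small read budget over those
pairs.  Default budgets emulate deep ensemble Hi-C (0.35 M reads per 5 Mb)
and single-cell Hi-C (1,000 reads per 5 Mb).

Because restraint-based 3D modelling from real Hi-C is out of scope, a
synthetic block-polymer generator provides structures whose blocks are
ground-truth domains: block centers follow a coarse random walk while
particles within a block fluctuate around their center, so blocks form
spatial globules whose separation is controlled by the inter/intra scale
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .hic_io import ContactMatrix, DomainSet, rebin_matrix

__all__ = [
    "Structure3D",
    "SimParams",
    "generate_synthetic_structure",
    "distance_quantile_threshold",
    "simulate_reference_hic",
    "simulate_single_cell_hic",
    "simulate_cell_population",
    "PopulationSim",
]


@dataclass
class Structure3D:
    """Ordered particle coordinates, one particle per fine genomic bin."""

    coords: np.ndarray          # (n_particles, 3)
    fine_binsize: int = 10_000
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


@dataclass
class SimParams:
    """Simulation parameters; read budgets are per the modeled region."""

    D: float | None = None            # single-cell contact threshold (model units)
    D_quantile: float = 0.2           # used when D is None
    reads_reference: int = 350_000    # ~0.35 M per 5 Mb
    reads_cell: int = 1_000           # ~1,000 per 5 Mb
    fine_binsize: int = 10_000
    out_binsize: int = 40_000
    cell_mode: str = "multinomial"    # or 'binomial' (independent per pair)
    seed: int = 0


def load_structure_xyz(path, fine_binsize: int = 10_000,
                       chrom: str = "chr1") -> Structure3D:
    """Read a plain-text particle table (``index x y z`` or ``x y z``)."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 4:
        order = np.argsort(data[:, 0])
        data = data[order, 1:]
    elif data.shape[1] != 3:
        raise ValueError("xyz table must have 3 or 4 columns")
    return Structure3D(data, fine_binsize, chrom)


def write_structure_xyz(s: Structure3D, path) -> None:
    idx = np.arange(s.n_particles)[:, None]
    np.savetxt(path, np.hstack([idx, s.coords]), fmt="%d %.6f %.6f %.6f")


def generate_synthetic_structure(n_particles: int, block_lengths,
                                 intra_scale: float = 1.0,
                                 inter_scale: float = 5.0,
                                 seed: int | np.random.Generator = 0,
                                 rho: float = 0.8) -> Structure3D:
    """Synthetic block polymer: globular blocks along a coarse random walk.

    Block centers take 3D Gaussian steps of scale ``2 * inter_scale``;
    within a block, particles follow a mean-reverting (AR(1), coefficient
    ``rho``) walk around the center with innovation scale ``intra_scale``,
    which keeps each block a compact globule.  With
    ``inter_scale == intra_scale`` the globules overlap and no block
    structure survives; ratios of ~5 give well-separated domains.
    """
    block_lengths = [int(b) for b in block_lengths]
    if sum(block_lengths) != n_particles:
        raise ValueError("block lengths must sum to n_particles")
    if min(block_lengths) < 1:
        raise ValueError("blocks must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.empty((n_particles, 3))
    center = np.zeros(3)
    pos = 0
    x = np.zeros(3)
    for b, length in enumerate(block_lengths):
        if b > 0:
            center = center + rng.normal(0.0, 2.0 * inter_scale, 3)
        x = center + rng.normal(0.0, intra_scale, 3)
        for t in range(length):
            coords[pos] = x
            x = center + rho * (x - center) + rng.normal(0.0, intra_scale, 3)
            pos += 1
    return Structure3D(coords)


def truth_domains(block_lengths, fine_binsize: int = 10_000,
                  out_binsize: int = 40_000, chrom: str = "chr1") -> DomainSet:
    """Ground-truth DomainSet of a block structure at the output binsize."""
    factor = out_binsize // fine_binsize
    n_fine = sum(int(b) for b in block_lengths)
    n_out = -(-n_fine // factor)
    edges_fine = np.cumsum([0] + [int(b) for b in block_lengths])
    # block edges rounded to the nearest coarse-bin edge, deduplicated
    edges = sorted({min(int(round(e / factor)), n_out) for e in edges_fine})
    if edges[0] != 0:
        edges = [0] + edges
    if edges[-1] != n_out:
        edges.append(n_out)
    doms = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return DomainSet(chrom, out_binsize, n_out, doms)


def distance_quantile_threshold(s: Structure3D, q: float) -> float:
    """q-quantile of all pairwise Euclidean distances between particles."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(pdist(s.coords), q))


def _pair_weights_reference(s: Structure3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = pdist(s.coords)
    if (d == 0).any():
        raise ValueError("coincident particles")
    iu, ju = np.triu_indices(s.n_particles, k=1)
    w = 1.0 / d
    return iu, ju, w / w.sum()


def simulate_reference_hic(s: Structure3D, p: SimParams) -> ContactMatrix:
    """Reference (bulk-like) Hi-C: weights 1/d, Poisson counts at fine bins.

    Expected counts are the normalized inverse-distance weights times
    ``reads_reference``; self pairs are excluded.
    """
    rng = np.random.default_rng(p.seed)
    iu, ju, w = _pair_weights_reference(s)
    lam = w * p.reads_reference
    counts = rng.poisson(lam)
    mat = np.zeros((s.n_particles, s.n_particles))
    mat[iu, ju] = counts
    mat[ju, iu] = counts
    return ContactMatrix(s.chrom, p.fine_binsize, mat)


def _pair_weights_cell(s: Structure3D, D: float):
    d = pdist(s.coords)
    if (d == 0).any():
        raise ValueError("coincident particles")
    iu, ju = np.triu_indices(s.n_particles, k=1)
    w = np.maximum(D - d, 0.0)
    if w.sum() == 0:
        raise ValueError("no contacts at this threshold")
    return iu, ju, w / w.sum()


def simulate_single_cell_hic(s: Structure3D, p: SimParams,
                             D: float | None = None) -> ContactMatrix:
    """Single-cell Hi-C: weights max(D - d, 0), a fixed small read budget.

    In the default multinomial mode the ``reads_cell`` budget is partitioned
    over contacting pairs (each pair marginally binomial), so totals are
    exact; ``cell_mode='binomial'`` draws an independent binomial per pair
    instead.  Pairs farther apart than ``D`` receive no reads.
    """
    rng = np.random.default_rng(p.seed)
    D = D if D is not None else (p.D if p.D is not None
                                 else distance_quantile_threshold(s, p.D_quantile))
    iu, ju, w = _pair_weights_cell(s, D)
    if p.cell_mode == "multinomial":
        counts = rng.multinomial(p.reads_cell, w)
    elif p.cell_mode == "binomial":
        counts = rng.binomial(p.reads_cell, w)
    else:
        raise ValueError(f"unknown cell_mode {p.cell_mode!r}")
    mat = np.zeros((s.n_particles, s.n_particles))
    mat[iu, ju] = counts
    mat[ju, iu] = counts
    return ContactMatrix(s.chrom, p.fine_binsize, mat)


def expected_single_cell_matrix(s: Structure3D, p: SimParams,
                                D: float | None = None) -> ContactMatrix:
    """Noise-free expectation of the single-cell map (no read sampling).

    Returns the normalized ``max(D - d, 0)`` weights times the read budget
    as a float matrix at fine bins — the infinite-sampling limit of
    :func:`simulate_single_cell_hic`.
    """
    D = D if D is not None else (p.D if p.D is not None
                                 else distance_quantile_threshold(s, p.D_quantile))
    iu, ju, w = _pair_weights_cell(s, D)
    mat = np.zeros((s.n_particles, s.n_particles))
    mat[iu, ju] = w * p.reads_cell
    mat[ju, iu] = mat[iu, ju]
    return ContactMatrix(s.chrom, p.fine_binsize, mat)


@dataclass
class PopulationSim:
    """A simulated cell population with its reference map and ground truth."""

    cells: list[ContactMatrix]
    reference: ContactMatrix
    truth: DomainSet
    structures: list[Structure3D] = field(default_factory=list)


def simulate_cell_population(block_lengths, p: SimParams, n_cells: int,
                             intra_scale: float = 1.0,
                             inter_scale: float = 5.0,
                             structures=None,
                             truth: DomainSet | None = None) -> PopulationSim:
    """Simulate a cell population sharing one domain layout.

    Each cell gets its own synthetic structure (same block layout, fresh
    conformation) unless explicit ``structures`` are given; single-cell and
    reference maps are rebinned from fine to ``out_binsize``.  The reference
    map is sampled from the first structure.  The generating block layout is
    attached as ground truth.
    """
    root = np.random.SeedSequence(p.seed)
    n_fine = sum(int(b) for b in block_lengths) if block_lengths is not None else None
    if structures is None:
        if block_lengths is None:
            raise ValueError("need block_lengths or structures")
        child = root.spawn(n_cells)
        structures = [
            generate_synthetic_structure(n_fine, block_lengths, intra_scale,
                                         inter_scale,
                                         seed=np.random.default_rng(c))
            for c in child
        ]
    if truth is None:
        if block_lengths is None:
            raise ValueError("need block_lengths or an explicit truth DomainSet")
        truth = truth_domains(block_lengths, p.fine_binsize, p.out_binsize)
    factor = p.out_binsize // p.fine_binsize
    cell_seeds = np.random.default_rng(root.spawn(1)[0]).integers(0, 2**31 - 1,
                                                                  n_cells + 1)
    cells = []
    for i, s in enumerate(structures[:n_cells]):
        pc = SimParams(**{**p.__dict__, "seed": int(cell_seeds[i])})
        cells.append(rebin_matrix(simulate_single_cell_hic(s, pc), factor))
    pr = SimParams(**{**p.__dict__, "seed": int(cell_seeds[-1])})
    reference = rebin_matrix(simulate_reference_hic(structures[0], pr), factor)
    return PopulationSim(cells=cells, reference=reference, truth=truth,
                         structures=list(structures[:n_cells]))
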