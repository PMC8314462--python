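"""Run configuration and the end-to-end synthetic benchmark.

:class:`RunConfig` bundles every tunable of the simulator, detector and
metrics with defaults matching the recommended mammalian settings (8-Mb
windows, 40-kb bins, k = 10 NMF repetitions, component range 8-13, strength
cutoff 0.3, CR width 11, 100-contact window threshold).  All randomness
flows from a single master seed through named substreams.  The benchmark
simulates a cell population, detects domains per cell, scores them against
the planted truth and the reference call, and classifies two planted
populations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import dynamics, metrics
from .detector import DetectorParams, detect_chromosome
from .hic_io import DomainSet
from .simulator import SimParams, simulate_cell_population

__all__ = ["RunConfig", "run_benchmark", "substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a master seed."""
    digest = int.from_bytes(name.encode(), "big") % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


@dataclass
class RunConfig:
    """Defaults for a full synthetic benchmark run."""

    # detector
    window_bp: int = 8_000_000
    binsize: int = 40_000
    k: int = 10
    n_range: tuple[int, ...] = (8, 9, 10, 11, 12, 13)
    strength_cutoff: float = 0.3
    cr_width: int = 11
    min_contacts: int = 100
    # simulator (budgets are per simulated region)
    region_bp: int = 5_000_000
    reads_cell: int = 1_000
    reads_reference: int = 350_000
    fine_binsize: int = 10_000
    D_quantile: float = 0.2
    inter_intra_ratio: float = 5.0
    n_cells: int = 20
    n_blocks: int = 10
    # metrics
    n_perm: int = 10_000
    seed: int = 0

    def detector_params(self) -> DetectorParams:
        return DetectorParams(window_bp=self.window_bp,
                              min_contacts=self.min_contacts, k=self.k,
                              n_range=tuple(self.n_range),
                              strength_cutoff=self.strength_cutoff,
                              cr_width=self.cr_width)

    def sim_params(self, seed: int) -> SimParams:
        return SimParams(D_quantile=self.D_quantile,
                         reads_reference=self.reads_reference,
                         reads_cell=self.reads_cell,
                         fine_binsize=self.fine_binsize,
                         out_binsize=self.binsize, seed=seed)

    def block_lengths(self, rng: np.random.Generator | None = None) -> list[int]:
        """Planted domain lengths in fine bins: equal blocks unless jittered."""
        n_fine = self.region_bp // self.fine_binsize
        base = [n_fine // self.n_blocks] * self.n_blocks
        base[-1] += n_fine - sum(base)
        if rng is not None:
            # jitter block edges by up to ~20% while keeping every block >= 4 fine bins
            for i in range(self.n_blocks - 1):
                shift = int(rng.integers(-base[i] // 5, base[i] // 5 + 1))
                if base[i] + shift >= 4 and base[i + 1] - shift >= 4:
                    base[i] += shift
                    base[i + 1] -= shift
        return base

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a key=value config file (unknown keys rejected)."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                f = known[key]
                if f.name == "n_range":
                    kwargs[key] = tuple(int(x) for x in val.replace(",", " ").split())
                elif f.type in ("int", int):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


def _shuffled_domains(d: DomainSet, rng: np.random.Generator) -> DomainSet:
    """Random partition with the same number of internal boundaries."""
    n_b = len(d.internal_boundaries)
    cuts = rng.choice(np.arange(1, d.n_bins), size=min(n_b, d.n_bins - 1),
                      replace=False)
    from .hic_io import domain_set_from_boundaries
    return domain_set_from_boundaries(cuts, d.n_bins, d.chrom, d.binsize)


def run_benchmark(config: RunConfig | None = None) -> dict:
    """End-to-end synthetic benchmark; returns a nested result dict.

    Stages: simulate a population -> detect per cell -> similarity to the
    planted truth and to the reference call (AMI/WS/VI/BP) -> quality
    indices (SE, modularity) on the reference map -> classification AUC on
    two planted populations with distinct layouts.
    """
    cfg = config or RunConfig()
    p = cfg.detector_params()
    rng = substream(cfg.seed, "benchmark")

    pop = simulate_cell_population(cfg.block_lengths(), cfg.sim_params(cfg.seed),
                                   cfg.n_cells,
                                   inter_scale=cfg.inter_intra_ratio)
    truth = pop.truth
    ref_call, _ = detect_chromosome(pop.reference, p)

    rows = []
    cell_calls = []
    for i, cell in enumerate(pop.cells):
        call, _ = detect_chromosome(cell, p)
        cell_calls.append(call)
        lt = metrics.partition_labels(truth)
        lc = metrics.partition_labels(call)
        shuf = _shuffled_domains(call, rng)
        row = {
            "cell": i,
            "ami_truth": metrics.ami(lt, lc),
            "ami_shuffled": metrics.ami(lt, metrics.partition_labels(shuf)),
            "vi_truth": metrics.vi(lt, lc),
            "bp_truth": metrics.bp_score(truth, call),
        }
        row["ws_truth"] = metrics.ws(truth, call) if call.domains else np.nan
        if ref_call.domains and call.domains:
            row["ws_ref"] = metrics.ws(ref_call, call)
            row["ami_ref"] = metrics.ami(metrics.partition_labels(ref_call), lc)
        rows.append(row)

    se_truth = metrics.structure_entropy(truth, pop.reference)
    se_ref = metrics.structure_entropy(ref_call, pop.reference)
    mod_truth = metrics.modularity(truth, pop.reference)

    # two-population classification: second layout with a shifted block grid
    alt = RunConfig(**{**asdict(cfg), "n_blocks": max(cfg.n_blocks - 3, 2),
                       "seed": cfg.seed + 1})
    pop_b = simulate_cell_population(alt.block_lengths(), alt.sim_params(alt.seed),
                                     cfg.n_cells,
                                     inter_scale=cfg.inter_intra_ratio)
    calls_b = [detect_chromosome(c, p)[0] for c in pop_b.cells]
    cells_cls = ([{truth.chrom: c} for c in cell_calls]
                 + [{truth.chrom: c} for c in calls_b])
    labels = [0] * len(cell_calls) + [1] * len(calls_b)
    cls = dynamics.cell_classification(cells_cls, labels)

    frac_beat = float(np.mean([r["ami_truth"] > r["ami_shuffled"] for r in rows]))
    return {
        "config": asdict(cfg),
        "per_cell": rows,
        "median_ami_truth": float(np.median([r["ami_truth"] for r in rows])),
        "median_ws_truth": float(np.nanmedian([r["ws_truth"] for r in rows])),
        "median_vi_truth": float(np.median([r["vi_truth"] for r in rows])),
        "median_bp_truth": float(np.median([r["bp_truth"] for r in rows])),
        "frac_cells_beating_shuffled": frac_beat,
        "structure_entropy_truth": se_truth,
        "structure_entropy_reference_call": se_ref,
        "modularity_truth": mod_truth,
        "classification_auc": cls["auc"],
    }
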