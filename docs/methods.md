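# Methods

## Problem setting

A Hi-C contact matrix records, for one chromosome at a fixed bin size, how
often every pair of genomic bins was ligated. In bulk data, topologically
associating domains (TADs) are blocks of enriched contact along the
diagonal. A single cell contributes at most a couple of ligations per
locus, so a 5-Mb region yields on the order of 10³ contacts and the matrix
is >90% zeros at 40-kb bins. Callers that score local coverage
(insulation squares, directionality statistics) degrade badly at this
depth; the detector here instead asks which low-rank block structure best
explains the whole window, which is much more robust to thinning.

## Detector

**Windows.** The chromosome is tiled with windows of length L (default
8 Mb) at stride L/2. Each window reports only its middle half
[L/4, 3L/4), extended to the chromosome edges for the first and last
window, so every bin is reported exactly once by the window that sees it
with the most flanking context. Windows with fewer than `min_contacts`
(default 100) intra-window contacts are no-calls; their report intervals
become gaps in the output partition. Trailing windows shorter than L are
kept and their report interval extended, rather than zero-padding the
matrix.

**Consensus clustering.** In each window, NMF (scikit-learn, Frobenius
objective, coordinate-descent solver, `init="random"`, tol 1e-4, ≤200
iterations) is run k = 10 times with seeds 0…k−1 (offset by a
user-settable `seed_base`). A run labels bin j by the argmax row of column
j of the coefficient matrix H, ties to the lowest row index. The consensus
map C is the fraction of runs co-clustering each bin pair; the cluster
rate CR_i is the mean of C over a `cr_width` = 11-bin diagonal square,
truncated at window edges.

**Anchoring and boundary offset.** The CR square is anchored with its
top-left corner at (i, i) by default, i.e. it summarizes the *downstream*
11-bin neighborhood. On an ideal two-block consensus map one can show the
local-minimum test (below) then fires (w+1)//2 = 6 bins upstream of the
true block junction: the dip of CR is centered where the square straddles
the junction evenly. Raw minima are therefore shifted by (w+1)//2 bins
when converted to boundary calls, so that a call is the first bin of its
downstream domain. A `centered` anchor (square centered on (i, i), offset
1) is available for sensitivity checks; on clean block matrices the two
produce identical calls.

**Minima and strength.** Bin i is a candidate boundary when

    sum(CR[i..i+2]) − sum(CR[i−3..i−1]) < 0 ≤ sum(CR[i+1..i+3]) − sum(CR[i−2..i])

— a sign change of a 3-bin-smoothed discrete derivative. Its strength is
the maximum CR between the two neighbouring minima (sentinels: first/last
window bin) minus CR at the minimum. Calls are the union of the n−1
strongest minima and all minima with strength > 0.3. The 0.3 cutoff,
k = 10, w = 11, n-range 8–13 and the 8-Mb/40-kb geometry are the
recommended mammalian-chromosome settings and are all exposed.

**Model selection.** For each candidate n, the silhouette of the called
partition on the dissimilarity D = 1 − C is the per-bin sum of
(mean_between − mean_within)/max(mean_between, mean_within), divided by
the window length (the within-mean runs over the bin's own cluster
including its zero self-dissimilarity; single-cluster partitions score 0).
The n with the largest silhouette wins; ties go to the smaller n. Note a
structural property of this score: whenever the consensus is perfectly
pure within the called clusters, every bin's term is exactly 1 and the
score saturates at 1.0 regardless of n. On strictly binary block matrices
several n can therefore tie; any distance decay or sampling noise breaks
the degeneracy. This is why test fixtures use noiseless *expected* Hi-C
(power-law decay P(s) ∝ 1/(1+s) with 5-fold within-block enrichment)
rather than 0/1 matrices.

**Determinism.** With fixed (k, n_range, seed_base) the output is
bit-reproducible on one platform; across platforms it is stable up to NMF
solver tolerance.

## Simulator

Real single-cell structures come from restraint-based 3D modelling, which
is outside this package's scope; a synthetic block polymer stands in.
Block centers take 3D Gaussian steps of scale 2·`inter_scale`; within a
block, particles follow a mean-reverting AR(1) walk (coefficient 0.8)
around the center with innovation scale `intra_scale`, giving compact
globules whose separation is controlled by the inter/intra ratio. At a
ratio of 1 the globules overlap and detection is at chance; at the default
ratio 5 domains are well separated. One particle represents one 10-kb fine
bin.

Reference (bulk-like) maps weight every pair by 1/d (Euclidean) and draw
Poisson counts with total budget 0.35 M reads per 5 Mb. Single-cell maps
keep only pairs with d < D — D defaults to the 0.2 quantile of all
pairwise distances, mirroring the tightest of the 20/40/60% quantile
settings used in practice — weight them by D − d, and distribute exactly
1,000 reads per 5 Mb by multinomial partitioning (each pair marginally
binomial; an independent-per-pair binomial mode exists for strict
literalism, at the cost of a varying total). Self-pairs are excluded from
both schemes; coincident particles are rejected. Fine-bin maps are summed
4×4 into 40-kb bins for detection.

What the simulator does *not* emulate: genomic distance-dependent
mappability, translocations/CNVs, trans contacts, restriction-fragment
granularity, and duplicate reads. Passing recovery tests on it shows the
detector handles extreme sparsity and block structure, not every artifact
of experimental scHi-C.

## Metrics

MI/AMI/VI operate on per-bin label vectors; each contiguous inter-domain
gap is its own cluster by default (configurable to a single gap cluster).
All logs are natural — the choice cancels in AMI. AMI uses max-entropy
normalization, (MI − E[MI])/(max(H_T, H_K) − E[MI]), with the
hypergeometric expectation; the implementation delegates to scikit-learn
and is validated against a direct brute-force evaluation of E[MI] to
1e-10. WS excludes gaps and is deliberately asymmetric (reference first):
each evaluated domain scores its best overlap/√(size product), weighted by
its size. BP is a boundary-level dissimilarity, reconstructed from its
use in TAD-caller benchmarking as the symmetrized mean nearest-boundary
distance normalized by chromosome length (0 iff identical boundary sets);
its brute-force re-evaluation in the tests is its contract.

Structure entropy is the two-level graph entropy of the partition on the
contact network: per segment, −(cut/Num)·log(vol/Num) plus per bin
−(deg/Num)·log(deg/vol), normalized by log N; lower is better. The
leading minus is part of the canonical definition — without it the true
block partition of a strong block matrix would score *worse* than a
shifted one, inverting the index's meaning. Modularity removes the
diagonal, log1p-transforms the counts, splits the chromosome into 6-Mb
windows (dropping windows under 100 raw contacts) and averages the
standard within-domain modularity across retained windows.

MNPPB (mean number of peaks per bin) profiles peak counts at offsets
−10…10 bins from each boundary; peaks are assigned to bins by midpoint.
Confidence bands are percentile 95% intervals over 1,000 bootstrap
resamples of the boundary set. The enrichment permutation test scores the
total peak count within ±1 bin of any boundary against uniform
repositioning of the boundary set over mappable bins (default 10,000
permutations, +1-smoothed p-value).

## Dynamics

Boundary identity across cells is same-bin by default. Variation classes
compare each cell domain's two ends against ensemble domain edges with a
±100-kb tolerance: matched (both ends align, no internal ensemble
boundary), merged (both align, ≥1 ensemble boundary strictly inside),
split (exactly one end aligns), shifted (neither aligns and the ends sit
in different ensemble domains), other. Chromosome ends count as aligned
edges. Boundary popularity fits B(n_cells, p̂) with p̂ the mean occurrence
frequency (or an explicit rate); the over/under thresholds (defaults
12/6, appropriate for ~150 cells at p̂ ≈ 0.06) are parameters, and the
deviation p-value is Monte-Carlo on the tail-boundary count. scSB classes
count carrying cells (1, 2, >2) for cell boundaries absent from the
ensemble, with permutation controls preserving per-cell boundary counts.

Cell classification: per chromosome, the WS matrix between cells →
row-wise Spearman correlation (constant rows → 0 with a warning) → first
principal component → per-cell sign; signs vote across chromosomes in the
ratio matrix T, and PC1 of T is the classification index. The PC sign is
fixed by making the first nonzero loading positive; since the index sign
remains arbitrary for unordered labels, AUC is reported as
max(auc, 1 − auc). The inter/intra signal correlation computes, for each
bin pair at a fixed separation (default 240 kb) and each class the pair
takes in a given cell (intra-domain vs boundary-separated), a Pearson
correlation across cells (≥3 complete observations), averages the
correlations per class, and compares the two with Fisher's z using the
number of contributing pairs as effective sample sizes — the variance unit
is a documented approximation.

## Problem sizes in tests

The test suite and the acceptance script run entirely on synthetic data at
sizes chosen for a single CPU: 200-bin windows for planted recovery, 5-Mb
regions (125 bins at 40 kb) with 50 cells for stochastic recovery, 12–16
cells per classification replicate, a 24-Mb (600-bin) chromosome for the
thinning-stability comparison, and 100-replicate null calibrations with
400–2,000 permutation draws. These mirror, at desk scale, the design of
the full-genome experiments the method targets.

## Known limitations

- The silhouette saturation described above makes the selected n
  non-identifiable on exactly binary consensus maps (not a practical
  regime, but visible in constructed tests).
- BP is a reconstruction, not a literal transcription of a published
  formula.
- ICE here balances a single chromosome; genome-wide joint balancing is a
  non-goal.
- The simulator's fixed per-cell read budget ignores the heavy-tailed
  depth variation of real scHi-C libraries.
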