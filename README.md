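# sctad

TAD-like domain detection and boundary-dynamics analysis for **ultra-sparse
(single-cell) Hi-C** contact matrices.

Topologically associating domains (TADs) appear as blocks on a bulk Hi-C
map, but a single cell yields only ~10³ contacts per 5 Mb — far too sparse
for insulation-score or HMM-style callers. `sctad` implements a detector
that exploits the low-rank structure of the contact matrix instead of its
local coverage: repeated **non-negative matrix factorization (NMF) consensus
clustering** inside 8-Mb sliding windows. It ships with a polymer-model
Hi-C simulator that provides ground-truth domains, the standard
partition-similarity metrics, structural quality indices, and analyses of
boundary dynamics across cell populations.

## The method

For each half-overlapping window of length *L* (default 8 Mb at 40-kb bins)
the contact submatrix is factorized *k* = 10 times
(`NMF(n_components=n, init="random", random_state=r)`, *r* = 0…*k*−1); each
run labels bin *j* by the argmax row of column *j* of the coefficient
matrix. The **consensus map** is

> C<sub>ij</sub> = (number of runs co-clustering bins *i* and *j*) / *k*,

and the per-bin **cluster rate** CR<sub>i</sub> is the mean of C over an
11-bin diagonal square at bin *i*. Candidate boundaries are local minima of
CR (a sign change of the smoothed discrete derivative
Σ<sub>j=i…i+2</sub>CR<sub>j</sub> − Σ<sub>j=i−3…i−1</sub>CR<sub>j</sub>);
each minimum's **strength** is the flanking CR maximum minus CR at the
minimum. The called set is the union of the *n*−1 strongest minima and all
minima with strength > 0.3. The component number *n* itself (range 8–13)
is selected by a silhouette score on the dissimilarity D = 1 − C, and each
window reports only its middle half, so a chromosome is stitched from
windows with full context.

The simulator samples reference Hi-C with pair weights 1/d (Poisson counts,
budget 0.35 M reads per 5 Mb) and single-cell Hi-C with weights
max(D − d, 0) over pairs closer than a distance threshold D (fixed budget
of 1,000 reads per 5 Mb), from synthetic block polymers whose blocks are
the ground-truth domains.

Similarity metrics: AMI (max-normalized), weighted similarity WS,
variation of information VI, and a boundary-distance score BP. Quality
indices: two-level structure entropy (lower = better) and per-6-Mb network
modularity (higher = better). Dynamics: matched/merged/split/shifted
classification, binomial boundary popularity, single-cell-specific boundary
(scSB) classes with permutation controls, nested/unnested boundaries,
condition-specific boundaries, WS-based unsupervised cell classification,
and inter- vs intra-domain signal correlation (Fisher z-test).

## Worked example

```bash
# simulate 20 single cells of a 5-Mb region with 10 planted domains
sctad simulate --region 5000000 --blocks 10 --cells 20 --seed 1 --out-dir sim/

# detect TAD-like domains in one cell (~1,000 contacts)
sctad detect --matrix sim/cell_000.txt --out cell0.bed

# compare the call with the planted truth
sctad compare --ref sim/truth.bed --query cell0.bed
```

which prints (numbers from this exact command sequence):

```
wrote reference, truth and 20 cells to sim
INFO sctad.detector: window: selected n=10 (silhouette=0.8790)
10 domains -> cell0.bed
{
  "ami": 0.9556208604956191,
  "ws": 0.9763332705545186,
  "vi": 0.16783584045378674,
  "bp": 0.0024
}
```

An AMI of 0.96 against the planted truth from a single simulated cell —
a 125 × 40-kb-bin matrix with only ~1,000 contacts, >90% of entries zero —
is the operating point the detector is built for: a shuffled boundary set
of the same size scores ≈ 0.3. `sctad benchmark --seed 0 --out report.json`
runs the full simulate → detect → score → classify loop in one command.

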