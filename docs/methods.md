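# Methods

## The forward model and what inversion requires

A delta-normalized matrix stores, for every nonzero count `C` of cell `i`,

```
N = log_b(C · L / T_i + p)
```

where `T_i` is the cell's library size (total counts), `L` the target sum,
`p` the pseudo-count, and `b` the log base.  Zeros are stored implicitly;
with `p = 1` (the log1p convention) their image is exactly 0, so the
sparsity pattern is unchanged by normalization.  For `p ∉ {0, 1}` the image
of zero, `log_b(p)`, cannot be represented sparsely; we assume — as observed
in deposited matrices — that only nonzero images are stored, and the matrix
is annotated accordingly (`meta['zeros_untransformed']`).  `p = 0` means the
pseudo-count was never added, and implicit zeros are untouched.

Inverting the model means recovering three things: the matrix-wide `(b, p)`,
and one scale factor `s_i = T_i / L` per cell.  `L` itself is not needed for
inversion (it cancels inside `s_i`); it is inferred afterwards as the mode
of the rounded detransformed cell sums and reported.

## The count-rank ladder

Under the negative-binomial (Gamma–Poisson) model of UMI counts, zero is the
most probable value, then 1, 2, … in decreasing order.  Within one cell,
ranking the *distinct nonzero* values by their frequency therefore recovers
the integers 1, 2, 3, … for the top ranks, with a probability that decreases
as the rank grows.  Monotone transforms preserve the ranking, so the two
most frequent stored values of a cell identify the images of counts 1 and 2.
This is the entire source of information the inversion uses — no metadata,
no reference profile.

Ties in frequency are broken toward the smaller value (under the count model
smaller values are a priori more frequent).  Cells with fewer than two
distinct nonzero values cannot anchor the ladder; they are flagged
unsolvable, carried through to the output unchanged, and counted in the
denominator of the success rate.

## Stage 1 — detransformation

**Detection.**  Raw counts are overdispersed (`var = μ + φμ²` per gene),
log data are strongly range-compressed.  The classifier computes per-gene
mean and variance over the gene's *stored (nonzero)* entries and calls the
matrix untransformed when more than half of the sampled genes (default
sample: 1000 genes) have variance above mean.  Two deliberate choices:

* moments use nonzero entries only — with zeros included, any gene whose
  nonzero image is large (base 2, large `L`) has a dropout-driven variance
  far above its mean on *any* scale, which says nothing about the transform;
* the sample prefers genes with stored mean ≥ 2, where zero-truncation is
  negligible on the count side and expression is informative on the log
  side; matrices containing negative values are called transformed outright
  (counts and scaled counts are nonnegative).

The verdict only *orders* the subsequent attempts; every candidate transform
must still validate against the data (below), so a borderline verdict cannot
send a recoverable matrix down a dead end.

**Empirical search.**  Standard workflows use `b ∈ {2, e, 10}` and
`p ∈ {1, 0, 0.1, 0.01}` (1 first — log1p dominates in practice).  Each
candidate is validated on a subset of 100 solvable cells, sampled without
replacement with a fixed, exposed seed: detransform the subset, unscale each
cell by the closed-form factor from its top two values, and compute the MAE
to the nearest integers.  A candidate passes when at least half the subset
cells fall below the 0.05 cutoff (a quorum rather than unanimity, so that
precision-degraded matrices, where a minority of deep cells exceed the
cutoff, still select the right transform); among passing candidates the
smallest median MAE wins, because a pseudo-count wrong by a small offset
(`p = 0` against true `p = 0.1`) can sneak under the cutoff on shallow cells
while the true candidate sits at machine precision.  The trial unscale also
requires the top value to recover to a count ≥ 1 — a degenerate scale that
collapses every value below 0.5 would otherwise trivialize the MAE.

**Optimized fit.**  If no empirical candidate validates, `(b, p)` are fitted
by minimizing the top-pair identity residual

```
Σ_i (p − 2·b^{N1_i} + b^{N2_i})²
```

with bounded L-BFGS-B (`b ∈ (1.000001, 100]`, `p ∈ [0, 10]`; tolerances
tightened to `ftol = 1e-18`).  The optimizer is multi-started from the
empirical bases plus the best points of a profiled base grid (for fixed `b`
the optimal `p` is the mean of `2·b^{N1} − b^{N2}`, clipped to its bounds).
One pitfall is built into this objective: as `b → 1` every `b^N → 1` and
`p = 1` fits *any* data, so a boundary plateau of near-zero objective always
exists.  Candidate minima are therefore tried in order of objective and the
first that passes the same trial-unscale validation is accepted; the
objective alone never accepts a fit.  The per-cell solved pseudo-counts'
variance is reported (`p_variance`) as a consistency diagnostic rather than
gated on a guessed threshold.  A fit is accepted only with mean squared
residual ≤ 1e-5 per cell.

**Validation of the detransformed matrix.**  After `x = b^N − p` is applied
(64-bit arithmetic throughout, regardless of storage precision), three
acceptance paths are tried in order: (1) *sum check* — all cells should sum
to (nearly) the same target sum: at least 90% of cells within 0.5 of the
mean; (2) *probe MSE* — gene filtering breaks the sums, so up to 20 probe
cells are trial-unscaled and the median per-value squared error against
nearest integers must be ≤ 1e-5; (3) *probe MAE* — lossy storage inflates
the MSE while the data remain recoverable, so a median probe MAE below the
0.05 cutoff also passes.  Failing all three aborts the run.

## Stage 2 — unscaling

Per solvable cell, two estimators of `s_i` over the merged frequency table:

* **closed form** (default — fast and robust): `s = (c₂−c₁)/(x₂−x₁)` from
  the top two values; any residual pseudo-count cancels in the difference;
* **regression**: least squares of `c_i/s + p − x_i` over the top (at most)
  five rank-value pairs, ranks mapped positionally to counts 1..5.  The
  objective is quadratic in `u = 1/s`, so the bounded minimizer is computed
  exactly as `u = Σc_i(x_i−p)/Σc_i²`; `u ≤ 0` flags the cell unsolvable.
  With the pseudo-count already removed by detransformation the same
  formulas apply with `p = 0`; the two conventions differ by a constant
  absorbed into the fit.

**Refinement.**  The anchor estimate uses 2 (or 5) values; its noise is the
dominant error on precision-degraded data (at 5-decimal storage, a deep cell
with counts near 500 carries a few-times-1e-5 relative scale error, i.e. a
recovery error approaching 1e-2).  Each cell's factor therefore gets one
integer-anchored least-squares polish: with `y = x·s` rounded onto integers,
`s ← Σ x·round(y) / Σ x²` re-fits the factor against those integers using
every stored entry of the cell.  On exact data this is a fixed point (round
trips stay bit-identical); it cannot rescue non-delta data, whose MAE stays
far above the cutoff.  It can be disabled (`refine_scales=False`).

**Success.**  Cell values are multiplied by `s_i`; the per-cell MAE
`mean |y − round(y)|` over stored entries decides success (cutoff 0.05), a
successful cell must additionally keep at least one nonzero recovered count,
and the final integerization rounds half away from zero, dropping entries
that round to ≤ 0.  The matrix-level MAE must beat the cutoff or the run
fails.  Unsolvable and failed cells are kept in the output with their
scaled values and `success = false`.

## Near-duplicate merging

Lossy storage can split one true normalized value into several nearby stored
values, demoting its frequency rank and breaking the ladder.  Before any
fitting, each cell's table is merged: values that round together at `d`
decimals are pooled (frequencies summed, representative = frequency-weighted
mean), with `d` lowered from 8 toward 3 (half precision carries ~3–4
significant decimals) until the top two values are *separated* — their gap
exceeds one part in 10³ of their magnitude, with `10^-d` as an absolute
floor near zero.  The criterion is relative because storage noise is
relative, while a genuine count ladder is spaced by several percent at
least.  Well-separated tables pass through unchanged.

## Evaluation metrics

* **rounding error** = `round(y) − y` per denormalized entry;
* **recovery error** = `x − z`, where `z` renormalizes the recovered counts
  (defaults: `L = 1e4`, natural base, `p = 1`; overridable).  Shape
  mismatches are structural errors; pattern mismatches (rounding legitimately
  drops sub-0.5 entries of degraded data) are counted and the errors taken
  over the union of stored positions;
* **success rate** = `Nsuccess / Ntotal`, unsolvable and failed cells in the
  denominator.  The matrix verdict is `success` when the rate is 1,
  `partial` when the matrix MAE beats the cutoff but some cells failed.

Summaries report max, mean and the 50/95/99% quantiles of absolute errors.

## The synthetic generator

All tests and the acceptance script run on synthetic data from
`denorm.simulate`:

| parameter | default | meaning |
|---|---|---|
| `mean_depth` | 2500 | median library size (counts per cell) |
| `dispersion` (φ) | 0.3 | NB overdispersion, `var = μ + φμ²`; 0 = Poisson |
| `depth_sigma` | 0.4 | log-normal spread of per-cell depth (≈3–5× range) |
| `mean_sigma` | 1.6 | log-normal spread of gene means (long tail) |

Gene means are log-normal and normalized to sum to `mean_depth`, so a
handful of genes dominate and most entries are small — the regime in which
the count-rank ladder is informative.  Depth factors are log-normal with
median 1, making per-cell scale inference non-trivial.  One global φ is
used (the inversion never uses φ).

What the generator does **not** emulate: ambient RNA, doublets, batch
structure, UMI collisions, per-gene dispersion, and the gene-length biases
of full-length protocols.  Passing tests therefore demonstrate correctness
of the *inversion* under the delta model and its common degradations
(reduced decimal precision, half/single float storage, gene filtering,
per-sample parameter differences), not robustness to every artifact of real
data.  Degraded inputs are produced by `degrade_precision` (round to `d ≥ 1`
decimals, or cast through IEEE 754 binary16/binary32) and `filter_genes`
(top-variance or random).  Negative controls come from `corrupt_non_delta`:
TPM-like per-gene length scaling (destroys the within-cell value ladder) and
residual-like per-gene z-scoring (negative, mean-centered); both must fail.

## Numerical and design choices

* All arithmetic in float64 regardless of storage dtype, isolating inference
  error from storage error.
* Rounding is nearest-integer, ties away from zero.
* Orientation fixed cells×genes; transposed files are read with an explicit
  flag, never guessed.
* Per-sample mode (`denormalize_by_group`) fits everything per group and
  reassembles rows in input order; a failing group is reported (its cells
  returned as empty rows) while the others proceed; `share_base=True` forces
  the first successful group's `(b, p)` on the rest.  Note that *different
  target sums alone do not require per-sample mode*: with a shared `(b, p)`,
  the per-cell factors absorb differing `L` and a single pass is exact.
  Grouping is needed when the transform itself (base, pseudo-count, or
  presence of a log) differs between samples.
* The scikit-learn estimators treat `(b, p)` as the learned state
  (`fit`) and the per-cell factors as per-sample statistics re-estimated in
  `transform`, mirroring how `Normalizer` treats row norms.
* Benchmark harness (`run_benchmark`) reports errors over successfully
  recovered cells and the success rate separately, so partial recoveries
  are visible rather than averaged in.

## Problem sizes

The test suite and the acceptance script use 500×2000 matrices (the full
parameter-grid round trip, precision and rounding-error measurements; five
seeds for the rounding bound) and 2000×2000 for the count-rank prevalence
figure; benchmark sweeps in the unit tests run at 150×800.  These sizes give
sub-percent sampling noise on every reported quantity while keeping the
whole suite under a minute.

## Known limitations

* Only delta-method normalization is invertible here; TPM/FPKM, Pearson
  residuals, and model-based normalizations are detected and rejected, not
  reversed.
* Cells whose top two frequency ranks are not counts 1 and 2 (very shallow
  cells, heavily filtered gene sets) get a wrong scale factor; they are
  flagged failed rather than silently emitted, and heavy gene filtering
  (≲ 300 genes kept) measurably reduces the success rate.
* A scaled-but-unlogged matrix downscaled far below typical library sizes
  compresses toward the Poisson boundary and can be mis-detected by the
  moment heuristic; the validation-driven routing recovers it, but the
  reported detection verdict may read "transformed".
* The inferred target sum is the mode of detransformed cell sums; after
  gene filtering it reflects the filtered matrix, not the original library.
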