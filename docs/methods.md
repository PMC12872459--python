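# Methods

This note records the modelling choices, defaults and numerical conventions
behind `cortexcf`, and what the synthetic test bed does and does not show
about real data.

## Surface geometry and the spectral basis

The Laplace–Beltrami operator is discretized as the cotangent stiffness
matrix with a lumped (barycentric) mass matrix — the standard linear-FEM
choice.  Negative cotangent weights on obtuse triangles are kept (no
clamping) to preserve the standard operator.  Eigenpairs come from the
mass-whitened symmetric problem: dense `eigh` up to ~2200 vertices,
shift-invert Lanczos beyond.  Eigenfunctions are mass-orthonormal
(ΦᵀMΦ = I to 1e-8) and sign-fixed so the largest-magnitude entry of each
mode is positive, making bases bit-reproducible.

The constant mode is excluded from connective-field design matrices by
default (`drop_constant=True`): its model time course is the source's
spatial-mean series, i.e. exactly the non-topographic null regressor, so
keeping it would blur the model/null distinction.  Constant-inclusive bases
are used wherever a *field profile itself* must be representable — the
basis-adequacy rule and the full-versus-restricted source comparison — and
the flag is exposed everywhere.

Geodesic distances are shortest paths on the mesh edge graph (Dijkstra,
Euclidean edge weights).  This upper-bounds exact polyhedral geodesics by a
few percent; all uses here (extents, chunks, coordinates) are ordinal or
threshold-based.  Simulator grid meshes alternate quad-diagonal orientation
to keep the edge-graph metric nearly isotropic.

## Basis adequacy

`adequacy_k` sizes a basis as the smallest K for which a geodesic Gaussian
field of the working width (default σ = 4 mm), centred at *every* vertex,
is reconstructed by the first K eigenfunctions with minimum R² ≥ 0.98.
R² here is the uncentered energy fraction 1 − SS_res/Σw²: a constant-mode
basis thus reconstructs a constant field perfectly, which is the behaviour
a truncated expansion should have at the wide-field limit.  (At the
operating point the centred and uncentered conventions differ by ~1e-3.)
On a 10 cm², 1 mm-resolution patch the rule is satisfied comfortably by 70
modes (`scripts/acceptance.py` recomputes this).

## Preprocessing

High-pass filtering is the residual of a third-order Savitzky–Golay smooth
over a 210 s window (211 samples at 1 Hz), applied per vertex and strictly
per run; polynomial drifts up to cubic are removed exactly.  Percent signal
change is 100·(x − mean)/mean per vertex per run, with near-zero-mean
vertices flagged and zeroed.  The train/test split removes the final 103 s
of each run into a concatenated test set (four 900 s runs → 412 s test).
Filter-then-PSC order is the default and configurable.

## Banded ridge and the product measure

Penalties are searched on a per-band log grid (default 1e-2…1e6, 20
points) over the full Cartesian product of bands, scored by mean
held-out-run R² per target; ties prefer the more regularized combination,
and final coefficients are refit on all training runs.  Each candidate is a
Cholesky solve of the penalized normal equations from precomputed per-fold
Gram matrices, so many targets are fit simultaneously.  Closed-form
single-band ridge and the band-rescaling identity (scale band columns by
1/√λᵢ, solve at λ = 1) serve as independent oracles in the tests.

The product measure R̃²ᵢ = Σ ŷᵢ(2y − ŷ)/Σ y² is additive by algebra
(Σᵢ ŷᵢ = ŷ), holds to 1e-10 on every fit, and can be negative for a band
whose sub-prediction opposes the data.  Topographic connectivity scores
subtract, per band, the test R² of a single-regressor null model built
from that source's spatial-mean time course and fit with the identical CV
protocol.

Connective fields are reconstructed as Φb* in the standardized-regressor
space in which the model was fit (the profile is an importance map).  For
comparisons against generative ground truth in signal units, passing the
design divides coefficients by their column training s.d. first, undoing
the z-scoring.

Map projection rectifies weights (clips at zero) before the weighted
average by default: the normalizing denominator Σw is ill-defined under
sign cancellation.  Raw-weight mode is available; peak ties break toward
the lowest vertex index; extents never cross hemisphere labels.

## Restricted-source comparison

`restricted_model_compare` fits per-subfield source models with the
identical protocol and reports ΔR² = full − best restricted on the test
set.  Both sides use constant-inclusive bases: a restricted basis stripped
of its constant mode cannot represent its own field mean while the full
basis still can, which biases ΔR² upward systematically.  In the test
suite, "restricted wins or ties" for field-confined targets is
operationalized with a |ΔR²| ≤ 0.01 tie tolerance — the CV-noise scale of
the test-set R² at the simulated sizes — alongside a mean-ΔR² ≤ 0 check.

## Permutation machinery

*Surrogates.* A surrogate flips each eigenfunction coefficient's sign
independently with probability ½ (one sign vector per surrogate, applied
to all targets), exactly preserving amplitude spectra and hence spatial
autocorrelation.  Ensembles are reproducible from (seed, n).

*Empirical p values* are reported in the raw-proportion convention, with
the protected (count+1)/(n+1) value alongside; minima and significance
calls use the protected value so p ∈ (0, 1].

*Split-half*: R² (squared Pearson) of one half's map predicting the other,
ranked within each half's surrogate ensemble; the two directional p values
are summed (range [0, 2]).  *Searchlight*: geodesic chunks (default radius
8 mm) centred at every vertex; the null pools chunk-wise surrogate
correlations; per-vertex maps keep the minimum p over covering chunks;
chunks with sub-threshold target range (e.g. < 1 DVA) or < 3 vertices are
excluded.  Note that chunk p values within one map are mutually dependent
(shared map, overlapping chunks), so null-uniformity is a statement across
independent draws, and that is how the tests assess it.

*TFCE* uses H = 2, E = 0.5 and 100 integration steps on the vertex
adjacency graph, positive and negative tails separately; the null flips
participant signs and keeps the maximum |TFCE| (default 2000 permutations,
α = 0.01 two-tailed).  *Co-localization*: N^vs counts participants above
threshold in both modalities per vertex; surrogate maps regenerate one
modality from sign-randomized whole-surface eigenfunction regressions,
re-binarized at each participant's original density; the cluster threshold
k_min is a user input (no standard binomial formula reproduces a published
reference value, so none is imposed).  *Bootstrap coverage* resamples
participants with replacement (default 10 000); note that re-testing a
null sample under resampling inflates the nominal α somewhat — coverage
under pure noise sits above 2.5% but far below any real effect.

## Body-part selectivity model

Selectivity regressors are X_part = presence × (number of the *other* 16
parts absent); counting all 17 would force X = 0 identically.  Keypoints
flagged present but outside the image crop box are recoded absent before
averaging over entities.  The ridge fit uses leave-one-run-out CV on the
training runs with held-out test runs.  The default preferred-position
readout is the rectified rank-weighted mean (bounded by the axis; a plain
dot product conflates response amplitude with position and is retained as
`mode="dot"`).  Left/right instances keep separate regressors but share an
ordinal rank (ankle 1 … nose 9), configurable.

## Synthetic test bed: scope and limits

The simulator produces spatially smooth source activity (truncated geodesic
Gaussian kernel, default correlation length 5 mm, unit-l2 kernel rows),
targets as gain-weighted CF sums plus white Gaussian noise at a chosen SNR
(s.d. signal / s.d. noise), and ground-truth records for scoring.  Default
study conditions for recovery checks: 4 runs × 250 samples at 1 Hz, SNR 1,
σ = 6 mm, 50 targets; desk-scale test splits hold out 50 s per run (the
fixed 103 s tail is the real-protocol default and applies to long runs).
The restricted-source checks shorten the correlation length to 3 mm so
cross-boundary predictability does not mask the field structure at
σ = 4 mm.

Not emulated: hemodynamic convolution, physiological/motion noise,
inter-subject variability, partial-voluming near source borders, and
magnitude scales of real BOLD.  Passing recovery tests therefore shows the
estimator is correct and well-conditioned under the stated generative
model, not that real-data effect sizes will match.

## Reproducibility

All randomness flows through seeded `numpy` Generators; every artifact the
pipeline writes carries the config hash, seed and stage; reruns with the
same config are numerically identical.
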