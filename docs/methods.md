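# Methods

## The geometry

Functional connectomes are Pearson-correlation matrices F = DDᵀ of demeaned,
normalized regional time series. When no thresholding is applied and the
time dimension exceeds the region count, they are full-rank and hence
symmetric positive definite (SPD). The SPD matrices form an open convex cone
inside the symmetric matrices; `spdmap` equips it with the affine-invariant
Riemannian metric, whose geodesic distance is

    d²(A, B) = Tr log²(A^{-1/2} B A^{-1/2}) = Σᵢ log² σᵢ,

with σᵢ the generalized eigenvalues of the pencil (B, A). The distance is
invariant under congruence A ↦ XAXᵀ for any invertible X and under joint
inversion, and diverges as either argument approaches a singular matrix —
matrices that are not valid full-rank correlation matrices are infinitely
far away. All matrix functions (powers, log, exp) are computed through the
symmetric eigendecomposition; eigenvector signs are fixed (largest-magnitude
component positive) so downstream rotation fits are reproducible.

Positivity checks use a scale-free floor, 1e-10 × trace/M, so that badly
conditioned correlation matrices of any overall scale are treated uniformly.
Borderline matrices can be either rejected or repaired (eigenvalue clipping
to the floor, with the clipped mass reported) via an explicit `repair` flag;
nothing is regularized silently.

### Fréchet means

The reference "zeroth-order" predictor is the mean of the training
functionals. Under the Euclidean metric it is the arithmetic mean; under the
affine-invariant metric the Fréchet (Karcher) mean is computed by the
fixed-point iteration

    F̄ ← F̄^{1/2} exp( (1/K) Σₖ log(F̄^{-1/2} Fₖ F̄^{-1/2}) ) F̄^{1/2},

initialized at the arithmetic mean (always SPD for SPD inputs, and
empirically a fast starting point), and stopped when the Frobenius norm of
the averaged tangent term — the Riemannian gradient up to scale — falls
below `tol` (default 1e-8, at most 200 iterations; non-convergence raises,
carrying the last gradient norm). The averaged tangent term is explicitly
symmetrized each iteration: near convergence its entries are ~1e-8 and
matmul round-off would otherwise trip the relative symmetry check.

## Preprocessing

Structural connectomes are symmetrized by summing transposed entries, the
diagonal is zeroed, and the matrix is normalized by its total off-diagonal
sum (both triangles — the choice only rescales S globally). No pruning of
weak connections is performed by default. The normalized Laplacian
L = I − D^{-1/2} S D^{-1/2} uses degrees computed from the normalized S.
Functional matrices built from time series keep negative correlations; a
T ≤ M table triggers a rank-deficiency warning and the repair-or-reject
path.

## Mapping families and fitting

The five eigenmode families (see README table) are all evaluated in the
eigenbasis of their input, so polynomials of order P = 6 are computed as
g(λ) on eigenvalues rather than by repeated matrix multiplication —
identical by the spectral theorem and numerically stabler. The heat kernel's
rate and time constants multiply each other and are merged into a single
parameter θ. The constant term C is constrained symmetric, so the
`spectral_rotation_constant` family has M(M+1)/2 constant parameters; the
conventional tabulation as M² is available under `convention="table"`.

The cohort loss L(f) = (1/K) Σₖ d²(f(Sₖ), Fₖ) is minimized by blockwise
coordinate descent with three blocks:

* **weights** (θ, (a, α, b), or a₀…a_P): scipy L-BFGS-B with central
  (3-point) finite differences;
* **rotation** R ∈ SO(M): parameterized as R ← R·exp(K(x)) with K(x)
  skew-symmetric, optimized over x with forward (2-point) differences —
  cheaper for the (M²−M)/2 coordinates, and the retraction keeps R exactly
  orthogonal (re-orthonormalized by SVD after each accepted step);
* **constant** C: optimized over the M(M+1)/2 upper-triangle coordinates.

A block update is accepted only if it does not increase the loss, making
the per-outer-iteration loss trajectory non-increasing by construction.
Predictions that leave the SPD cone during the search are eigenvalue-clipped
to the floor and the loss is augmented by `spd_penalty` (default 1e3) times
the clipped mass — the objective stays finite and continuous, which matters
because the polynomial/spectral families start at coefficients (0, 1, 0, …),
i.e. the prediction f(S) = S, which has zero trace and is never SPD; the
first weight step escapes the penalized region immediately in practice.
Three outer iterations (the default) suffice for loss changes below 1% on
the bundled synthetic worlds. Everything in the fit is deterministic given
its inputs.

Analytic manifold gradients are deliberately out of scope: the parameter
counts are modest and finite differences on the batched, eigendecomposition-
based loss are fast enough at desk scale.

### Nearest-neighbors mean

The Riemannian nearest-structural-neighbors mean predicts a new subject's F
as the Fréchet mean of the functional matrices of the P training subjects
with the closest structural connectomes. Structural proximity defaults to
the Frobenius distance: structural matrices have zero diagonal, so they are
not SPD and the geodesic distance does not apply to them without
modification; a callable metric can be supplied instead.

## Evaluation

`loocv_evaluate` scores each requested predictor by leave-one-out
cross-validation: fit (or average) on K−1 subjects, predict the left-out
functional matrix from its structural matrix, record the squared Riemannian
distance; MSD is the mean over subjects. The Riemannian mean reference is
always included. Failing folds are recorded and skipped rather than
aborting. Cohort-level analyses — pairwise distance matrices under both
metrics with mean ± SD/range summaries, nearest-neighbor maps and their
cross-metric agreement, and the z-scored structural-vs-functional distance
R² (squared Pearson correlation of the upper-triangle distance vectors) —
are exposed alongside. No significance testing between model MSDs is
performed; per-fold distances are exported so users can test externally.

## The synthetic world

The generator draws a connected weighted template graph (Erdős–Rényi
support at density 0.3 plus a random spanning tree; lognormal(0, 1) edge
weights, emulating heavy-tailed streamline-weight distributions), jitters
each subject's edge weights by lognormal factors of scale `subject_jitter`
(default 0.1), and normalizes. Functional matrices are the ground-truth
mapping's prediction perturbed in the tangent space:
F = F₀^{1/2} exp(E) F₀^{1/2}, with E symmetric, entries iid N(0, σ²)
(default σ = 0.05) on and above the diagonal, mirrored. Tangent-space noise
keeps every functional matrix exactly SPD, which elementwise noise would
not, and obeys the closed form E[d²(F, F₀)] = σ²M² used as a Monte-Carlo
calibration test. Default size is M = 15 regions, K = 20 subjects.

What a green test on this world does *not* establish: real functional
matrices are correlation-normalized (unit diagonal — an optional post-hoc
rescaling exists but breaks exact parameter recovery), real structural
variability is not a single lognormal jitter around one template, and real
structure–function coupling is far weaker and confounded by acquisition
noise. The generator validates the estimation machinery, not the
neuroscience.

Ground-truth defaults: θ* = 0.5 (heat kernel), (a, α, b)* = (1.2, 0.8, 0.1)
(affine diffusion); for polynomial/spectral truths g(λ) = 0.5 + 2λ + 4λ²,
chosen strictly positive over the small, zero-centered spectrum of a
normalized structural matrix so the base predictions are SPD, with a Haar
rotation and a small random SPD constant where the family carries them.

## Numerical choices and limitations

* Relative symmetry tolerance 1e-10·max|A|; SPD floor 1e-10·trace/M.
* Riemannian distances in fitting are computed batched (stacked eigh over
  subjects) with per-subject whitening by F_k^{-1/2} precomputed once.
* Nearest-neighbor ties resolve to the lowest subject index; eigenvector
  sign ties to the first largest-magnitude component.
* LOOCV of the rotation/constant families is quadratic-ish in cohort size;
  the bundled tests use reduced optimizer budgets (2 outer iterations,
  capped manifold steps) and small cohorts to stay within minutes on one
  CPU. Margins between a well-specified mapping and the Riemannian mean are
  small (a few percent of MSD) whenever tangent noise dominates structural
  dispersion — matching the small real-data margins this line of work
  reports — so benchmark conclusions are majority-over-seeds, not per-seed.
* The implementation targets dense matrices at M ≲ a few hundred; no
  sparse or low-rank acceleration, and no SPD metrics other than the
  affine-invariant one.
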