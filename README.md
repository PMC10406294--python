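# spdmap

Structure–function brain connectome mapping under the affine-invariant
Riemannian geometry of symmetric positive definite (SPD) matrices.

## The problem

A subject's brain can be described by two networks over the same set of M
cortical regions: a **structural connectome** S (white-matter connection
weights, e.g. from diffusion-MRI tractography) and a **functional
connectome** F (Pearson correlations between regional resting-state fMRI
signals). *Structure–function mapping* asks for a single function f, shared
across a cohort of K subjects, that predicts F from S by minimizing

    L(f) = (1/K) Σₖ d²(f(Sₖ), Fₖ).

Full-rank correlation matrices are SPD, and the natural geometry of the SPD
cone is not Euclidean. `spdmap` measures d with the affine-invariant
geodesic distance

    d(A, B) = ‖log(A^{-1/2} B A^{-1/2})‖_F ,

fits the classical eigenmode mapping families under that loss, and
benchmarks them against the geometry's own zeroth-order reference — the
Fréchet (Karcher) mean of the training functionals — by leave-one-out
cross-validation (LOOCV), scored as the mean squared Riemannian test
distance (MSD).

All eigenmode mappings share the form f(S) = Σₙ g(λₙ) h(uₙ) + C with
(λₙ, uₙ) the eigenpairs of S or of its normalized Laplacian
L = I − D^{-1/2} S D^{-1/2}. Five families are implemented:

| family                       | f                                   | input | DOF                  |
|------------------------------|-------------------------------------|-------|----------------------|
| `heat_kernel`                | exp(−θL)                            | L     | 1                    |
| `diffusion_affine`           | a·exp(−αL) + b·I                    | L     | 3                    |
| `polynomial`                 | Σₘ aₘ Sᵐ, m ≤ P                     | S     | P+1                  |
| `spectral_rotation`          | R·U·g(Λ)·Uᵀ·Rᵀ                      | S     | P+1 + (M²−M)/2       |
| `spectral_rotation_constant` | same + C                            | S     | + M(M+1)/2           |

Fitting is blockwise coordinate descent on the Riemannian loss: quasi-Newton
for the eigenvalue weights, a skew-symmetric/matrix-exponential retraction on
the rotation group SO(M) for R, and quasi-Newton over the symmetric matrices
for C. A Riemannian nearest-structural-neighbors mean (Fréchet mean of the P
functionals whose structural matrices are closest) completes the model set.

A bundled synthetic-cohort generator produces paired (Sₖ, Fₖ) with a known
ground-truth mapping and SPD-preserving tangent-space noise, so the entire
pipeline is testable without any imaging data.

## Worked example

```python
import spdmap as sm

spec = sm.SyntheticSpec(seed=1)           # M=15 regions, K=20 subjects,
cohort, truth = sm.generate_cohort(spec)  # heat-kernel truth theta*=0.5

model = sm.StructureFunctionModel(cohort, "heat_kernel")
res = model.fit()
print(res.summary())

report = sm.loocv_evaluate(["heat_kernel", "euclidean_mean"], cohort)
print(report.summary())
```

prints (abridged):

```
Structure-Function Mapping Results
==============================================
family:            heat_kernel
regions (M):       15
subjects (K):      20
degrees of freedom:     1
weights:           [0.49842]
final loss (MSD):  0.567309
converged:         True
==============================================
Leave-one-out evaluation (squared Riemannian test distance)
----------------------------------------------------------
heat_kernel                    MSD = 0.567927
riemannian_mean                MSD = 0.606629
euclidean_mean                 MSD = 0.611838
```

The fitted diffusivity θ̂ = 0.498 recovers the generating θ* = 0.5 from
noisy data, and the structure-aware mapping attains a lower held-out MSD
than either mean reference: knowing a subject's structural connectome
improves the prediction of their functional connectome, once distances are
measured in the geometry the functional matrices actually live in.

The same pipeline is available from the shell:

```bash
spdmap simulate --M 15 --K 20 --seed 1 --out cohort/
spdmap fit --cohort cohort/manifest.yaml --family heat_kernel --out params.yaml
spdmap evaluate --cohort cohort/manifest.yaml --models heat_kernel,euclidean_mean --out report/
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch on a seeded
synthetic cohort — generation, pairwise-distance analyses (both metrics,
nearest-neighbor agreement, the z-scored structure-vs-function distance R²),
mapping fits, and the LOOCV benchmark against the Riemannian mean — and
writes its JSON summary to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/spdmap/geometry.py` — SPD distances, matrix functions, Fréchet means
- `src/spdmap/io.py` — connectome I/O, normalization, Laplacian, cohorts
- `src/spdmap/mappings.py` — the eigenmode mapping families
- `src/spdmap/fitting.py` — Riemannian loss and coordinate descent
- `src/spdmap/model.py` — Model/Results interface
- `src/spdmap/evaluation.py` — distances, regression, LOOCV benchmarking
- `src/spdmap/synthetic.py` — synthetic cohort generator
- `docs/methods.md` — the methods note
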