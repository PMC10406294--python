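"""Synthetic paired structural/functional cohorts with known ground truth.

Stands in for a real cohort (e.g. 100 young-adult subjects with 200-region
parcellations) so that every fitting and evaluation routine can be tested
without any download.  The generative story:

1. A group-template weighted graph is drawn: Erdos-Renyi support at the
   requested density, augmented with a random spanning tree so the graph is
   always connected, with lognormal edge weights (streamline-weight
   distributions are heavy-tailed and strictly positive).
2. Each subject multiplies the template's edge weights by independent
   lognormal jitter of scale ``subject_jitter``, then the matrix goes
   through the standard symmetrize/zero-diagonal/unit-off-diagonal-sum
   normalization.  Jitter 0 gives identical subjects.
3. Each subject's functional matrix is the ground-truth mapping applied to
   their structural matrix, perturbed *in the tangent space* at the base
   prediction:  F = F0^{1/2} exp(E) F0^{1/2} with E random symmetric whose
   independent entries (diagonal and upper triangle, mirrored) are
   N(0, noise_sigma^2).  This keeps every functional matrix exactly SPD --
   elementwise noise would not -- and gives the closed form
   E[d^2(F, F0)] = E||E||_F^2 = noise_sigma^2 * M^2.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import geometry, mappings
from .exceptions import NotSPDError
from .io import Cohort, save_cohort, symmetrize_normalize

__all__ = [
    "SyntheticSpec",
    "default_true_params",
    "generate_structural",
    "generate_functional",
    "generate_cohort",
]


@dataclass
class SyntheticSpec:
    """Stated world of the synthetic cohort.

    Defaults: 15 regions and 20 subjects (large enough for a nontrivial
    rotation manifold, small enough for seconds-scale fits), 30% graph
    density (typical of unthresholded but sparse structural supports at
    this scale), heat-kernel ground truth with theta = 0.5, tangent noise
    sigma = 0.05 and between-subject structural jitter 0.1.
    """

    M_regions: int = 15
    K_subjects: int = 20
    graph_density: float = 0.3
    true_family: str = "heat_kernel"
    true_params: mappings.MappingParams | None = None
    noise_sigma: float = 0.05
    subject_jitter: float = 0.1
    seed: int = 0
    order: int = 2
    as_correlation: bool = False  # post-hoc rescale to unit diagonal; breaks
    #                               exactness of parameter-recovery tests

    def __post_init__(self):
        if not 0.0 < self.graph_density <= 1.0:
            raise ValueError("graph_density must be in (0, 1]")
        if self.noise_sigma < 0 or self.subject_jitter < 0:
            raise ValueError("noise_sigma and subject_jitter must be >= 0")
        if self.true_family not in mappings.FAMILIES:
            raise ValueError(f"unknown family {self.true_family!r}")


def default_true_params(family: str, M: int, order: int = 2,
                        rng=None) -> mappings.MappingParams:
    """Ground-truth parameters guaranteed to produce SPD base predictions.

    heat_kernel: theta = 0.5.  diffusion_affine: (a, alpha, b) =
    (1.2, 0.8, 0.1); both act on the Laplacian whose spectrum is [0, 2], so
    positivity is automatic.  Polynomial/spectral families act on the
    normalized structural matrix, whose eigenvalues are small and centered
    at zero; g(lambda) = 0.5 + 2 lambda + 4 lambda^2 (padded with zeros to
    the requested order) stays strictly positive over that range while
    still expressing the structure.  Spectral families get a random
    rotation (Haar, from ``rng``) and the constant family a small random
    SPD constant.
    """
    if family == "heat_kernel":
        return mappings.MappingParams(family, [0.5])
    if family == "diffusion_affine":
        return mappings.MappingParams(family, [1.2, 0.8, 0.1])
    w = np.zeros(order + 1)
    base = np.array([0.5, 2.0, 4.0])
    w[: min(3, order + 1)] = base[: min(3, order + 1)]
    kw = {}
    if family in mappings.ROTATION_FAMILIES:
        if rng is None:
            rng = np.random.default_rng(0)
        kw["rotation"] = mappings.random_rotation(M, rng)
    if family in mappings.CONSTANT_FAMILIES:
        if rng is None:
            rng = np.random.default_rng(0)
        W = rng.normal(size=(M, 2 * M))
        kw["constant"] = 0.1 * (W @ W.T) / (2 * M)
    return mappings.MappingParams(family, w, order=order, **kw)


def _template_graph(spec: SyntheticSpec, rng) -> np.ndarray:
    """Connected weighted template: ER support + random spanning tree,
    lognormal weights, upper triangle only (symmetrized downstream)."""
    M = spec.M_regions
    support = np.triu(rng.random((M, M)) < spec.graph_density, k=1)
    # spanning tree over a random node ordering guarantees connectivity
    perm = rng.permutation(M)
    for i in range(1, M):
        a, b = perm[i], perm[rng.integers(0, i)]
        support[min(a, b), max(a, b)] = True
    weights = np.zeros((M, M))
    weights[support] = rng.lognormal(mean=0.0, sigma=1.0, size=int(support.sum()))
    return weights


def generate_structural(spec: SyntheticSpec, rng=None) -> list[np.ndarray]:
    """K structural connectomes: jittered copies of one template graph."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    template = _template_graph(spec, rng)
    edges = template > 0
    out = []
    for _ in range(spec.K_subjects):
        raw = template.copy()
        raw[edges] *= rng.lognormal(mean=0.0, sigma=spec.subject_jitter,
                                    size=int(edges.sum()))
        out.append(symmetrize_normalize(raw))
    return out


def _symmetric_noise(M: int, sigma: float, rng) -> np.ndarray:
    E = np.zeros((M, M))
    iu = np.triu_indices(M)
    E[iu] = rng.normal(0.0, sigma, size=len(iu[0]))
    return E + E.T - np.diag(np.diag(E))


def generate_functional(S, spec: SyntheticSpec, rng=None,
                        true_params: mappings.MappingParams | None = None) -> np.ndarray:
    """Ground-truth prediction for S plus tangent-space noise (exactly SPD)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    if true_params is None:
        true_params = spec.true_params or default_true_params(
            spec.true_family, spec.M_regions, order=spec.order,
            rng=np.random.default_rng(spec.seed))
    X = mappings.mapping_input(S, true_params.family)
    F0 = mappings.apply_mapping(true_params, X)
    F0, clipped = geometry.assert_spd(F0, repair=True)
    if clipped > 1e-6 * max(np.trace(F0), 1.0):
        raise NotSPDError(
            f"ground-truth prediction far from SPD (clipped mass {clipped:.3e}); "
            "choose ground-truth weights positive over the input spectrum"
        )
    if spec.noise_sigma == 0.0:
        F = F0.copy()
    else:
        E = _symmetric_noise(F0.shape[0], spec.noise_sigma, rng)
        H = geometry.spd_power(F0, 0.5)
        F = H @ geometry.sym_exp(E) @ H
        F = 0.5 * (F + F.T)
    if spec.as_correlation:
        d = 1.0 / np.sqrt(np.diag(F))
        F = F * np.outer(d, d)
        np.fill_diagonal(F, 1.0)
    return F


def generate_cohort(spec: SyntheticSpec, out_dir=None):
    """Full synthetic cohort plus its generating ground truth.

    Returns ``(Cohort, MappingParams)``; with ``out_dir`` the cohort is also
    written to disk (manifest + CSV matrices, round-trippable through
    ``load_cohort``, plus the ground-truth parameter file).
    """
    rng = np.random.default_rng(spec.seed)
    true_params = spec.true_params or default_true_params(
        spec.true_family, spec.M_regions, order=spec.order, rng=rng)
    structurals = generate_structural(spec, rng)
    functionals = [
        generate_functional(S, spec, rng=rng, true_params=true_params)
        for S in structurals
    ]
    subjects = [f"sub-{i:03d}" for i in range(spec.K_subjects)]
    cohort = Cohort(subjects, structurals, functionals)
    if out_dir is not None:
        save_cohort(cohort, out_dir)
        mappings.save_params(true_params,
                             os.path.join(out_dir, "ground_truth_params.yaml"))
    return cohort, true_params
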