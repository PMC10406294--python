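"""Model/Results interface over the fitting machinery.

``StructureFunctionModel`` is built from a cohort and a mapping family;
``fit()`` returns a ``StructureFunctionResults`` carrying the estimated
mapping parameters, the loss trajectory, diagnostics and a ``summary()``
table, with ``predict()`` for new structural matrices.  Two reference
predictors that ignore (or only rank by) structure complete the benchmark
set: the Frechet mean of the training functionals (Euclidean or
Riemannian), and the Riemannian nearest-structural-neighbors mean.
"""

from __future__ import annotations

import numpy as np

from . import fitting, geometry, mappings
from .io import Cohort, load_cohort

__all__ = [
    "StructureFunctionModel",
    "StructureFunctionResults",
    "FrechetMeanModel",
    "FrechetMeanResults",
    "NearestNeighborsMeanModel",
]


class StructureFunctionModel:
    """One eigenmode mapping family, to be fitted across a cohort.

    Parameters
    ----------
    cohort : Cohort
        Paired structural/functional connectomes over a common region set.
    family : str
        One of ``mappings.FAMILIES``.
    order : int
        Polynomial order P for the polynomial/spectral families (default 6).
    """

    def __init__(self, cohort: Cohort, family: str, order: int = 6):
        if family not in mappings.FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.cohort = cohort
        self.family = family
        self.order = order

    @classmethod
    def from_manifest(cls, manifest_path, family: str, order: int = 6):
        return cls(load_cohort(manifest_path), family, order=order)

    def loss(self, params: mappings.MappingParams,
             spd_penalty: float = 1e3) -> float:
        """Cohort Riemannian loss of arbitrary parameters (for diagnostics)."""
        return fitting.riemannian_loss(params, self.cohort, spd_penalty=spd_penalty)

    def fit(self, config: fitting.FitConfig | None = None,
            init: mappings.MappingParams | None = None) -> "StructureFunctionResults":
        result = fitting.fit(self.family, self.cohort, config=config,
                             order=self.order, init=init)
        return StructureFunctionResults(self, result)


class StructureFunctionResults:
    """Fitted mapping: estimates, trajectory, diagnostics, predictions."""

    def __init__(self, model: StructureFunctionModel, result: fitting.FitResult):
        self.model = model
        self.params = result.params
        self.loss_trajectory = result.loss_trajectory
        self.converged = result.converged
        self.diagnostics = result.diagnostics

    @property
    def final_loss(self) -> float:
        return float(self.loss_trajectory[-1])

    def predict(self, S_new, repair: bool = True) -> np.ndarray:
        """Predicted functional matrix for a new structural connectome.

        The raw mapping output is not guaranteed SPD; with ``repair`` (the
        default) eigenvalues are clipped up to the positivity floor so the
        prediction is a valid functional matrix.
        """
        X = mappings.mapping_input(S_new, self.params.family)
        F = mappings.apply_mapping(self.params, X)
        F, _ = geometry.assert_spd(F, repair=repair)
        return F

    def degrees_of_freedom(self, convention: str = "symmetric") -> int:
        return mappings.degrees_of_freedom(self.params, self.model.cohort.M,
                                           convention=convention)

    def summary(self) -> str:
        traj = ", ".join(f"{v:.6g}" for v in self.loss_trajectory)
        lines = [
            "Structure-Function Mapping Results",
            "=" * 46,
            f"family:            {self.params.family}",
            f"input:             {self.params.input_kind}",
            f"regions (M):       {self.model.cohort.M}",
            f"subjects (K):      {self.model.cohort.K}",
            f"order (P):         {self.params.order}",
            f"degrees of freedom:{self.degrees_of_freedom():>6d}",
            f"weights:           {np.array2string(self.params.weights, precision=5)}",
            f"loss trajectory:   [{traj}]",
            f"final loss (MSD):  {self.final_loss:.6g}",
            f"converged:         {self.converged}",
            "=" * 46,
        ]
        return "\n".join(lines)


class FrechetMeanModel:
    """Zeroth-order reference: the mean of the training functionals.

    ``metric="riemannian"`` gives the Frechet (Karcher) mean under the
    affine-invariant distance; ``metric="euclidean"`` the arithmetic mean.
    Either ignores the structural matrix entirely.
    """

    def __init__(self, cohort: Cohort, metric: str = "riemannian",
                 tol: float = 1e-8, max_iter: int = 200):
        if metric not in ("riemannian", "euclidean"):
            raise ValueError(f"unknown metric {metric!r}")
        self.cohort = cohort
        self.metric = metric
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> "FrechetMeanResults":
        if self.metric == "riemannian":
            mean = geometry.frechet_mean_riemannian(
                self.cohort.functionals, tol=self.tol, max_iter=self.max_iter)
        else:
            mean = geometry.frechet_mean_euclidean(self.cohort.functionals)
        return FrechetMeanResults(self, mean)


class FrechetMeanResults:
    def __init__(self, model, mean: np.ndarray):
        self.model = model
        self.mean_ = mean

    def predict(self, S_new=None) -> np.ndarray:
        return self.mean_

    def summary(self) -> str:
        return (f"Frechet mean reference ({self.model.metric} metric), "
                f"K={self.model.cohort.K}, M={self.model.cohort.M}")


class NearestNeighborsMeanModel:
    """Riemannian nearest-structural-neighbors mean predictor.

    For a new subject, returns the Frechet mean of the functional matrices
    of the ``n_neighbors`` training subjects whose structural connectomes
    are closest (Frobenius distance by default).
    """

    def __init__(self, cohort: Cohort, n_neighbors: int = 50,
                 structural_metric="euclidean"):
        if not 1 <= n_neighbors <= cohort.K:
            raise ValueError(f"n_neighbors={n_neighbors} out of range [1, {cohort.K}]")
        self.cohort = cohort
        self.n_neighbors = n_neighbors
        self.structural_metric = structural_metric

    def fit(self) -> "NearestNeighborsMeanModel":
        return self  # lazy: all work happens per query

    def predict(self, S_new) -> np.ndarray:
        return fitting.nn_mean_predict(S_new, self.cohort, self.n_neighbors,
                                       structural_metric=self.structural_metric)

    def summary(self) -> str:
        return (f"Riemannian nearest-neighbors mean, P={self.n_neighbors}, "
                f"K={self.cohort.K}, M={self.cohort.M}")
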