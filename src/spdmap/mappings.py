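"""The unified eigenmode mapping family and its five concrete members.

Every eigenmode-based structure-function mapping can be written as

    f(S) = sum_n g(lambda_n) h(u_n) + C

where (lambda_n, u_n) are the eigenpairs of the structural matrix S (or of
its normalized Laplacian L), g re-weights the eigenvalues, h transforms the
eigenvector outer products (possibly through a shared rotation R, i.e.
h(u_n) = R u_n u_n^T R^T), and C is a constant symmetric matrix.  The five
members implemented here:

=========================  =========================================  ==========
family                     f                                          input
=========================  =========================================  ==========
heat_kernel                exp(-theta L)                              Laplacian
diffusion_affine           a exp(-alpha L) + b I                      Laplacian
polynomial                 sum_{m<=P} a_m S^m                         S
spectral_rotation          R U g(Lambda) U^T R^T, g poly of order P   S
spectral_rotation_constant same + C                                   S
=========================  =========================================  ==========

The heat kernel's beta and t multiply each other and are unidentifiable
separately, so they are merged into theta = beta * t (one degree of
freedom).  All families are evaluated through the eigendecomposition, so
they share the common form above exactly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace

import numpy as np
import yaml

from . import geometry
from .exceptions import DimensionError
from .io import normalized_laplacian

__all__ = [
    "FAMILIES",
    "LAPLACIAN_FAMILIES",
    "ROTATION_FAMILIES",
    "CONSTANT_FAMILIES",
    "MappingParams",
    "mapping_input",
    "apply_mapping",
    "degrees_of_freedom",
    "initial_params",
    "rotation_from_skew",
    "random_rotation",
    "save_params",
    "load_params",
]

FAMILIES = (
    "heat_kernel",
    "diffusion_affine",
    "polynomial",
    "spectral_rotation",
    "spectral_rotation_constant",
)
LAPLACIAN_FAMILIES = frozenset({"heat_kernel", "diffusion_affine"})
ROTATION_FAMILIES = frozenset({"spectral_rotation", "spectral_rotation_constant"})
CONSTANT_FAMILIES = frozenset({"spectral_rotation_constant"})
POLYNOMIAL_FAMILIES = frozenset(
    {"polynomial", "spectral_rotation", "spectral_rotation_constant"}
)


@dataclass
class MappingParams:
    """Parameters of one eigenmode mapping.

    ``weights`` holds theta for heat_kernel, (a, alpha, b) for
    diffusion_affine, and the polynomial coefficients a_0..a_P (ascending)
    for the three polynomial-based families.  ``rotation`` (orthogonal,
    det +1) and ``constant`` (symmetric) are present only for the families
    that carry them.
    """

    family: str
    weights: np.ndarray
    order: int | None = None
    rotation: np.ndarray | None = None
    constant: np.ndarray | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown mapping family {self.family!r}; "
                             f"choose from {FAMILIES}")
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.family == "heat_kernel" and self.weights.size != 1:
            raise ValueError("heat_kernel takes a single weight theta")
        if self.family == "diffusion_affine" and self.weights.size != 3:
            raise ValueError("diffusion_affine takes weights (a, alpha, b)")
        if self.family in POLYNOMIAL_FAMILIES:
            if self.order is None:
                self.order = self.weights.size - 1
            if self.weights.size != self.order + 1:
                raise ValueError(
                    f"{self.family}: got {self.weights.size} coefficients for "
                    f"order P={self.order} (need P+1)"
                )
        if self.family in ROTATION_FAMILIES:
            if self.rotation is None:
                raise ValueError(f"{self.family} requires a rotation matrix")
            R = np.asarray(self.rotation, dtype=float)
            err = np.max(np.abs(R.T @ R - np.eye(R.shape[0])))
            if err > 1e-8:
                raise ValueError(f"rotation is not orthogonal: max |R^T R - I| = {err:.3e}")
            if np.linalg.det(R) <= 0:
                raise ValueError("rotation must have determinant +1")
            self.rotation = R
        elif self.rotation is not None:
            raise ValueError(f"{self.family} does not carry a rotation")
        if self.family in CONSTANT_FAMILIES:
            if self.constant is None:
                raise ValueError(f"{self.family} requires a symmetric constant")
            self.constant = geometry.check_symmetric(self.constant, "constant C")
        elif self.constant is not None:
            raise ValueError(f"{self.family} does not carry a constant")

    @property
    def input_kind(self) -> str:
        return "laplacian" if self.family in LAPLACIAN_FAMILIES else "structural"

    def copy(self) -> "MappingParams":
        return replace(
            self,
            weights=self.weights.copy(),
            rotation=None if self.rotation is None else self.rotation.copy(),
            constant=None if self.constant is None else self.constant.copy(),
        )


def mapping_input(S, family: str) -> np.ndarray:
    """Family-appropriate input: the normalized Laplacian for the diffusion
    families, the structural matrix itself for the polynomial/spectral ones."""
    if family in LAPLACIAN_FAMILIES:
        return normalized_laplacian(S)
    if family not in FAMILIES:
        raise ValueError(f"unknown mapping family {family!r}")
    return np.asarray(S, dtype=float)


def eigenvalue_weights(params: MappingParams, lam: np.ndarray) -> np.ndarray:
    """g(lambda) for the family, evaluated elementwise on eigenvalues."""
    w = params.weights
    if params.family == "heat_kernel":
        return np.exp(-w[0] * lam)
    if params.family == "diffusion_affine":
        a, alpha, b = w
        return a * np.exp(-alpha * lam) + b
    return np.polynomial.polynomial.polyval(lam, w)


def apply_mapping(params: MappingParams, X, basis=None) -> np.ndarray:
    """Predicted functional matrix from the family-appropriate input ``X``.

    ``basis`` may carry a precomputed ``(eigenvalues, eigenvectors)`` of X.
    Output is symmetric; SPD is *not* guaranteed (the caller decides whether
    to repair or penalize).
    """
    X = np.asarray(X, dtype=float)
    if params.rotation is not None and params.rotation.shape[0] != X.shape[0]:
        raise DimensionError(
            f"rotation side {params.rotation.shape[0]} does not match input side {X.shape[0]}"
        )
    lam, U = geometry.sym_eig(X) if basis is None else basis
    g = eigenvalue_weights(params, lam)
    F = (U * g) @ U.T
    if params.rotation is not None:
        R = params.rotation
        F = R @ F @ R.T
    if params.constant is not None:
        F = F + params.constant
    return 0.5 * (F + F.T)


def degrees_of_freedom(params: MappingParams, n_regions: int | None = None,
                       convention: str = "symmetric") -> int:
    """Number of free parameters of the mapping.

    With P the polynomial order and M the region count: 1 (heat_kernel);
    3 (diffusion_affine); P+1 (polynomial); P+1 + (M^2-M)/2
    (spectral_rotation); and for spectral_rotation_constant additionally the
    constant's dimension -- M(M+1)/2 under ``convention="symmetric"`` (the
    constant is constrained symmetric) or M^2 under ``convention="table"``
    (the count as conventionally tabulated).
    """
    if n_regions is None:
        for A in (params.rotation, params.constant):
            if A is not None:
                n_regions = A.shape[0]
                break
    if params.family == "heat_kernel":
        return 1
    if params.family == "diffusion_affine":
        return 3
    dof = params.order + 1
    if params.family in ROTATION_FAMILIES:
        if n_regions is None:
            raise ValueError("n_regions required for rotation families")
        dof += (n_regions**2 - n_regions) // 2
    if params.family in CONSTANT_FAMILIES:
        if convention == "table":
            dof += n_regions**2
        elif convention == "symmetric":
            dof += n_regions * (n_regions + 1) // 2
        else:
            raise ValueError(f"unknown convention {convention!r}")
    return dof


def initial_params(family: str, n_regions: int, order: int = 6) -> MappingParams:
    """Optimizer starting point: near-identity, nested warm start.

    heat_kernel theta=1; diffusion_affine (a, alpha, b) = (1, 1, 0);
    polynomial coefficients (0, 1, 0, ...); rotation at identity and
    constant at zero, which reduces the spectral families to the plain
    polynomial family at the start.
    """
    if family == "heat_kernel":
        return MappingParams(family, [1.0])
    if family == "diffusion_affine":
        return MappingParams(family, [1.0, 1.0, 0.0])
    w = np.zeros(order + 1)
    if order >= 1:
        w[1] = 1.0
    else:
        w[0] = 1.0
    kw = {}
    if family in ROTATION_FAMILIES:
        kw["rotation"] = np.eye(n_regions)
    if family in CONSTANT_FAMILIES:
        kw["constant"] = np.zeros((n_regions, n_regions))
    return MappingParams(family, w, order=order, **kw)


def rotation_from_skew(x, n: int) -> np.ndarray:
    """Rotation ``exp(K)`` from the n(n-1)/2 upper-triangle entries of a
    skew-symmetric matrix K (the Lie-algebra parameterization of SO(n))."""
    import scipy.linalg

    K = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    K[iu] = x
    K -= K.T
    return scipy.linalg.expm(K)


def random_rotation(n: int, rng) -> np.ndarray:
    """Haar-ish random rotation (QR of a Gaussian matrix, det fixed to +1)."""
    Q, R = np.linalg.qr(rng.normal(size=(n, n)))
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _matrix_to_text(A: np.ndarray) -> str:
    buf = _io.StringIO()
    np.savetxt(buf, A, delimiter=",", fmt="%.17g")
    return buf.getvalue()


def _matrix_from_text(text: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(_io.StringIO(text), delimiter=","))


def save_params(params: MappingParams, path) -> None:
    """Serialize fitted parameters to one YAML file (matrices embedded as
    delimited grids)."""
    doc = {
        "family": params.family,
        "order": params.order,
        "weights": [float(w) for w in params.weights],
    }
    if params.rotation is not None:
        doc["rotation"] = _matrix_to_text(params.rotation)
    if params.constant is not None:
        doc["constant"] = _matrix_to_text(params.constant)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> MappingParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return MappingParams(
        family=doc["family"],
        weights=np.asarray(doc["weights"], dtype=float),
        order=doc.get("order"),
        rotation=_matrix_from_text(doc["rotation"]) if "rotation" in doc else None,
        constant=_matrix_from_text(doc["constant"]) if "constant" in doc else None,
    )
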