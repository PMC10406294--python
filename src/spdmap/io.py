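"""Connectome I/O and preprocessing.

Structural connectomes arrive as square nonnegative weighted adjacency
matrices (e.g. summed streamline weights between cortical parcels).  They
are symmetrized by summing the (i, j) and (j, i) entries, the diagonal is
zeroed, and the matrix is normalized to unit off-diagonal sum, which makes
cohorts comparable across acquisition scale.  No pruning of weak
connections is applied by default.

Functional connectomes are Pearson-correlation matrices of parcel time
series, with negative entries preserved so the matrices stay full-rank SPD.

Matrices are stored as plain delimited text (CSV/TSV), optionally with a
single header row and label column; cohorts are described by a small YAML
manifest listing per-subject file paths.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .exceptions import (
    CohortError,
    DegenerateGraphError,
    DimensionError,
    NotSPDError,
    ZeroVarianceError,
)

__all__ = [
    "load_matrix",
    "save_matrix",
    "symmetrize_normalize",
    "normalized_laplacian",
    "pearson_functional",
    "Cohort",
    "load_cohort",
    "save_cohort",
]


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def load_matrix(path, require_symmetric: bool = True,
                return_labels: bool = False):
    """Load a square numeric matrix from delimited text.

    A single header row plus label column is detected automatically (the
    top-left cell of a labelled file is non-numeric or empty).  Ragged rows,
    non-numeric cells and non-square grids raise :class:`DimensionError`.
    """
    sep = _delimiter_for(path)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise DimensionError(f"{path}: ragged or malformed grid: {exc}") from exc
    labels = None
    first = df.iloc[0, 0]
    if pd.isna(first) or not _is_number(first):
        labels = [str(x) for x in df.iloc[0, 1:]]
        df = df.iloc[1:, 1:]
    try:
        A = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DimensionError(f"{path}: non-numeric cell in matrix: {exc}") from exc
    if np.isnan(A).any():
        raise DimensionError(f"{path}: missing or non-numeric cells in matrix")
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"{path}: matrix is not square, shape {A.shape}")
    if require_symmetric:
        A = geometry.check_symmetric(A, os.path.basename(str(path)))
    if return_labels:
        return A, labels
    return A


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def save_matrix(A, path, labels=None) -> None:
    """Save a matrix as delimited text at full double precision.

    Round trip through :func:`load_matrix` reproduces values to 1e-12.
    """
    A = np.asarray(A, dtype=float)
    sep = _delimiter_for(path)
    if labels is not None:
        df = pd.DataFrame(A, index=labels, columns=labels)
        df.to_csv(path, sep=sep, float_format="%.17g")
    else:
        np.savetxt(path, A, delimiter=sep, fmt="%.17g")


def symmetrize_normalize(raw) -> np.ndarray:
    """Symmetrize and normalize a raw structural connectome.

    ``W = raw + raw.T`` (summing the (i, j) and (j, i) entries), the diagonal
    is set to zero, and the result is divided by its total off-diagonal sum
    so that ``sum_{i != j} W_ij = 1``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise DimensionError(f"structural matrix must be square, got {raw.shape}")
    if (raw < 0).any():
        raise ValueError("structural connectome entries must be nonnegative")
    W = raw + raw.T
    np.fill_diagonal(W, 0.0)
    total = float(W.sum())
    if total <= 0.0:
        raise DegenerateGraphError("structural connectome has no off-diagonal mass")
    return W / total


def normalized_laplacian(S) -> np.ndarray:
    """Symmetric normalized graph Laplacian ``L = I - D^{-1/2} S D^{-1/2}``.

    ``D`` is the diagonal degree matrix of row sums of the (normalized)
    structural matrix.  The spectrum lies in [0, 2]; a connected graph has a
    single ~0 eigenvalue with eigenvector ``D^{1/2} 1``.
    """
    S = geometry.check_symmetric(S, "structural matrix")
    deg = S.sum(axis=1)
    zero = np.flatnonzero(deg <= 0)
    if zero.size:
        raise DegenerateGraphError(
            f"zero-degree (isolated) node(s) at index {zero.tolist()}: "
            "normalized Laplacian undefined"
        )
    dinv = 1.0 / np.sqrt(deg)
    L = -S * np.outer(dinv, dinv)
    np.fill_diagonal(L, 1.0)
    return 0.5 * (L + L.T)


def pearson_functional(timeseries, repair: bool = False) -> np.ndarray:
    """Pearson-correlation functional connectome from parcel time series.

    ``timeseries`` is M x T (one row per brain region).  Negative
    correlations are preserved.  For T <= M the matrix is rank-deficient and
    a warning is issued; positive definiteness is then enforced or rejected
    according to ``repair``.
    """
    X = np.asarray(timeseries, dtype=float)
    if X.ndim != 2:
        raise DimensionError("time series table must be 2-D (regions x time)")
    M, T = X.shape
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ZeroVarianceError(
            f"constant time series (zero variance) in row(s) {bad.tolist()}"
        )
    if T <= M:
        warnings.warn(
            f"T={T} <= M={M}: correlation matrix is rank-deficient, not SPD",
            stacklevel=2,
        )
    F = np.corrcoef(X)
    F = 0.5 * (F + F.T)
    np.fill_diagonal(F, 1.0)
    F, _ = geometry.assert_spd(F, repair=repair)
    np.fill_diagonal(F, 1.0)
    return F


@dataclass
class Cohort:
    """Ordered collection of paired structural/functional connectomes."""

    subjects: list[str]
    structurals: list[np.ndarray]
    functionals: list[np.ndarray]
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.subjects) == len(self.structurals) == len(self.functionals)):
            raise CohortError("subjects, structurals and functionals differ in length")
        if len(self.subjects) == 0:
            raise CohortError("empty cohort")
        if len(set(self.subjects)) != len(self.subjects):
            raise CohortError("duplicate subject identifiers")
        sides = {A.shape[0] for A in self.structurals} | {
            A.shape[0] for A in self.functionals
        }
        if len(sides) != 1:
            raise CohortError(f"matrices do not share a common region count: {sorted(sides)}")

    @property
    def M(self) -> int:
        return self.structurals[0].shape[0]

    @property
    def K(self) -> int:
        return len(self.subjects)

    def __len__(self) -> int:
        return self.K

    def drop(self, index: int) -> "Cohort":
        """Cohort without subject ``index`` (for leave-one-out folds)."""
        keep = [i for i in range(self.K) if i != index]
        return Cohort(
            [self.subjects[i] for i in keep],
            [self.structurals[i] for i in keep],
            [self.functionals[i] for i in keep],
        )


def load_cohort(manifest_path) -> Cohort:
    """Load a cohort from a YAML manifest.

    The manifest lists subjects with per-subject ``structural`` and
    ``functional`` file paths (relative to the manifest).  With
    ``structural_raw: true`` the structural matrices are passed through
    :func:`symmetrize_normalize` on load; functional matrices are validated
    SPD (repaired if ``functional_repair: true``).
    """
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or not manifest.get("subjects"):
        raise CohortError(f"{manifest_path}: empty or subject-less manifest")
    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    raw = bool(manifest.get("structural_raw", False))
    repair = bool(manifest.get("functional_repair", False))
    subjects, structurals, functionals = [], [], []
    for entry in manifest["subjects"]:
        sid = str(entry["id"])
        spath = os.path.join(base, entry["structural"])
        fpath = os.path.join(base, entry["functional"])
        for p in (spath, fpath):
            if not os.path.exists(p):
                raise CohortError(f"subject {sid}: missing file {p}")
        S = load_matrix(spath, require_symmetric=not raw)
        if raw:
            S = symmetrize_normalize(S)
        F = load_matrix(fpath)
        try:
            F, _ = geometry.assert_spd(F, repair=repair)
        except NotSPDError as exc:
            raise NotSPDError(f"subject {sid}: functional matrix not SPD: {exc}") from exc
        subjects.append(sid)
        structurals.append(S)
        functionals.append(F)
    return Cohort(subjects, structurals, functionals)


def save_cohort(cohort: Cohort, directory, manifest_name: str = "manifest.yaml") -> str:
    """Write a cohort as per-subject CSV matrices plus a YAML manifest.

    Returns the manifest path; the result round-trips through
    :func:`load_cohort` to 1e-12.
    """
    os.makedirs(directory, exist_ok=True)
    entries = []
    for sid, S, F in zip(cohort.subjects, cohort.structurals, cohort.functionals):
        sname, fname = f"{sid}_structural.csv", f"{sid}_functional.csv"
        save_matrix(S, os.path.join(directory, sname))
        save_matrix(F, os.path.join(directory, fname))
        entries.append({"id": sid, "structural": sname, "functional": fname})
    manifest_path = os.path.join(directory, manifest_name)
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"subjects": entries, "structural_raw": False}, fh,
                       sort_keys=False)
    return manifest_path
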