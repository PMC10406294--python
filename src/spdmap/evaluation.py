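"""Cohort-level analyses and leave-one-out model benchmarking.

Implements the distance-based cohort analyses -- pairwise subject distances
under both metrics, nearest-neighbor maps and their agreement, and the
z-scored structure-function distance regression -- plus the leave-one-out
cross-validation harness that scores mapping families against the Frechet
mean reference by squared Riemannian test distance (MSD).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fitting, geometry, mappings
from .exceptions import DimensionError
from .io import Cohort
from .model import FrechetMeanModel, NearestNeighborsMeanModel, StructureFunctionModel

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "nearest_neighbors",
    "nn_agreement",
    "distance_regression",
    "EvaluationReport",
    "loocv_evaluate",
    "parse_model_spec",
]


@dataclass
class DistanceMatrix:
    """K x K symmetric pairwise-distance matrix with provenance tags."""

    values: np.ndarray
    metric_tag: str = "riemannian"
    domain_tag: str = "functional"
    subjects: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def summary(self) -> dict:
        """Off-diagonal distance statistics (mean, sample SD, range)."""
        iu = np.triu_indices(self.K, k=1)
        d = self.values[iu]
        return {
            "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
            "min": float(d.min()),
            "max": float(d.max()),
        }


def pairwise_distances(matrices, metric: str = "riemannian",
                       domain: str = "functional",
                       subjects=None) -> DistanceMatrix:
    """All pairwise distances within a list of matrices."""
    matrices = [np.asarray(A, dtype=float) for A in matrices]
    K = len(matrices)
    if K < 2:
        raise ValueError("need at least two matrices")
    if metric == "riemannian":
        dist = geometry.riemannian_distance
    elif metric == "euclidean":
        dist = geometry.euclidean_distance
    else:
        raise ValueError(f"unknown metric {metric!r}")
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            D[i, j] = D[j, i] = dist(matrices[i], matrices[j])
    return DistanceMatrix(D, metric_tag=metric, domain_tag=domain,
                          subjects=subjects)


def nearest_neighbors(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Index of each subject's nearest neighbor (off-diagonal row argmin,
    ties to the lowest index)."""
    V = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    K = V.shape[0]
    if K < 2:
        raise ValueError("need at least two subjects")
    masked = V + np.diag(np.full(K, np.inf))
    return np.argmin(masked, axis=1)


def nn_agreement(nn_a, nn_b) -> int:
    """Number of subjects with the same nearest neighbor in both maps."""
    nn_a, nn_b = np.asarray(nn_a), np.asarray(nn_b)
    if nn_a.shape != nn_b.shape:
        raise DimensionError("neighbor vectors differ in length")
    return int(np.sum(nn_a == nn_b))


def distance_regression(D_struct, D_func) -> float:
    """R^2 between z-scored structural and functional pairwise distances.

    Takes the K(K-1)/2 upper-triangle pairs of each distance matrix,
    z-scores both vectors (sample SD) and returns the squared Pearson
    correlation.  Quantifies how much structurally similar subjects are
    also functionally similar.
    """
    Vs = D_struct.values if isinstance(D_struct, DistanceMatrix) else np.asarray(D_struct, float)
    Vf = D_func.values if isinstance(D_func, DistanceMatrix) else np.asarray(D_func, float)
    if Vs.shape != Vf.shape:
        raise DimensionError("distance matrices differ in shape")
    K = Vs.shape[0]
    if K < 3:
        raise ValueError("need K >= 3 subjects for a distance regression")
    iu = np.triu_indices(K, k=1)
    x, y = Vs[iu], Vf[iu]
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance distance vector: R^2 undefined")
    zx, zy = (x - x.mean()) / sx, (y - y.mean()) / sy
    r = float(np.mean(zx * zy) * len(zx) / (len(zx) - 1))
    return min(r * r, 1.0)


@dataclass
class EvaluationReport:
    """Per-model LOOCV squared test distances and their means."""

    subjects: list
    per_model: dict = field(default_factory=dict)
    # optional cohort-level analyses
    nn_agreement: int | None = None
    r_squared: dict = field(default_factory=dict)

    def add_model(self, name: str, distances, failures=None):
        distances = np.asarray(distances, dtype=float)
        ok = ~np.isnan(distances)
        self.per_model[name] = {
            "squared_distances": distances,
            "msd": float(distances[ok].mean()) if ok.any() else float("nan"),
            "failed_folds": list(failures or []),
        }

    def msd(self, name: str) -> float:
        return self.per_model[name]["msd"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {name: rec["squared_distances"] for name, rec in self.per_model.items()},
            index=self.subjects,
        )
        df.index.name = "subject"
        return df

    def summary(self) -> str:
        lines = ["Leave-one-out evaluation (squared Riemannian test distance)",
                 "-" * 58]
        for name, rec in sorted(self.per_model.items(), key=lambda kv: kv[1]["msd"]):
            flag = f"  [{len(rec['failed_folds'])} failed folds]" if rec["failed_folds"] else ""
            lines.append(f"{name:<30s} MSD = {rec['msd']:.6g}{flag}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.to_frame().to_csv(os.path.join(directory, "per_subject_distances.csv"))
        with open(os.path.join(directory, "report.txt"), "w") as fh:
            fh.write(self.summary() + "\n")


def parse_model_spec(spec: str):
    """Parse "family[:order]", "riemannian_mean", "euclidean_mean" or
    "nn_mean:P" into a (kind, options) pair."""
    name, _, arg = spec.partition(":")
    if name in ("riemannian_mean", "euclidean_mean"):
        return name, {}
    if name == "nn_mean":
        if not arg:
            raise ValueError("nn_mean requires :P, e.g. nn_mean:50")
        return name, {"P": int(arg)}
    if name in mappings.FAMILIES:
        return name, {"order": int(arg)} if arg else {}
    raise ValueError(f"unknown model spec {spec!r}")


def _fold_prediction(kind: str, opts: dict, train: Cohort, S_test,
                     config: fitting.FitConfig, order: int):
    if kind == "riemannian_mean":
        return FrechetMeanModel(train, metric="riemannian").fit().predict()
    if kind == "euclidean_mean":
        return FrechetMeanModel(train, metric="euclidean").fit().predict()
    if kind == "nn_mean":
        return NearestNeighborsMeanModel(train, n_neighbors=opts["P"]).predict(S_test)
    model = StructureFunctionModel(train, kind, order=opts.get("order", order))
    return model.fit(config=config).predict(S_test, repair=True)


def loocv_evaluate(model_specs, cohort: Cohort,
                   config: fitting.FitConfig | None = None,
                   order: int = 6,
                   include_reference: bool = True) -> EvaluationReport:
    """Leave-one-out cross-validation of a set of predictors.

    For each subject k: the model is fitted (or the mean computed) on the
    remaining K-1 subjects, the left-out functional matrix is predicted
    from S_k, and the squared Riemannian distance to the observed F_k is
    recorded.  MSD is the average over subjects.  The Riemannian mean
    reference is always evaluated unless ``include_reference=False``.
    A failing fit marks that fold failed (NaN) rather than aborting.
    """
    if config is None:
        config = fitting.FitConfig()
    if cohort.K < 2:
        raise ValueError("LOOCV needs at least two subjects")
    specs = [parse_model_spec(s) if isinstance(s, str) else s for s in model_specs]
    names = [s if isinstance(s, str) else s[0] for s in model_specs]
    if include_reference and "riemannian_mean" not in names:
        specs.append(("riemannian_mean", {}))
        names.append("riemannian_mean")

    report = EvaluationReport(subjects=list(cohort.subjects))
    for name, (kind, opts) in zip(names, specs):
        d2 = np.full(cohort.K, np.nan)
        failures = []
        for k in range(cohort.K):
            train = cohort.drop(k)
            try:
                pred = _fold_prediction(kind, opts, train,
                                        cohort.structurals[k], config, order)
                pred, _ = geometry.assert_spd(pred, repair=True)
                d2[k] = geometry.riemannian_distance(pred, cohort.functionals[k]) ** 2
            except Exception as exc:  # record the fold, keep going
                failures.append((cohort.subjects[k], repr(exc)))
        report.add_model(name, d2, failures)
    return report
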