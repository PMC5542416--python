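"""Representational similarity analysis in RDM space.

Model RDMs are either binary factor models (1 where two conditions differ
in a factor's level, 0 otherwise) or feature-derived matrices
(1 - Spearman correlation between per-condition feature vectors). Brain
RDMs are the time-resolved pairwise decoding matrices. All comparisons use
the strictly lower triangle (the matrices are symmetric with an undefined
diagonal) and Spearman rank correlation with average ranks on ties; the
partial-correlation variant residualizes on ranks before correlating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GroupTimeCourse, RDMSeries
from .design import FACTORS, LEVELS, Design

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Per-condition feature vectors for one model layer."""

    features: np.ndarray  # conditions x dimensions
    condition_ids: np.ndarray
    layer: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.condition_ids = np.asarray(self.condition_ids)
        if self.features.ndim != 2 or len(self.features) != len(self.condition_ids):
            raise ValueError("features must be conditions x dimensions")


@dataclass
class ModelRDM:
    """A condition x condition dissimilarity matrix from a model.

    ``semantics`` records the value convention: ``"one_minus_spearman"``
    (values in [0, 2]) or ``"binary"`` ({0, 1} level disagreement).
    """

    dissimilarity: np.ndarray
    condition_ids: np.ndarray
    source: str = ""
    semantics: str = "one_minus_spearman"

    def __post_init__(self) -> None:
        d = np.asarray(self.dissimilarity, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity must be square")
        off = ~np.eye(len(d), dtype=bool)
        if not np.allclose(d[off], d.T[off], equal_nan=True):
            raise ValueError("dissimilarity must be symmetric")
        if self.semantics == "binary" and not np.isin(d[off], (0.0, 1.0)).all():
            raise ValueError("binary model RDM must contain only 0/1 off-diagonal")
        self.dissimilarity = d
        self.condition_ids = np.asarray(self.condition_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n_conditions, k=-1)
        return self.dissimilarity[i, j]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.dissimilarity, index=self.condition_ids, columns=self.condition_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, source: str = "", semantics: str = "one_minus_spearman") -> "ModelRDM":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(), frame.columns.to_numpy(dtype=int), source, semantics)


def factor_model_rdm(design: Design, factor: str) -> ModelRDM:
    """Binary explicit model: 1 where two conditions differ in the factor."""
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    levels = design.levels(factor).to_numpy()
    diff = (levels[:, None] != levels[None, :]).astype(float)
    return ModelRDM(diff, design.condition_ids.to_numpy(), source=factor, semantics="binary")


def feature_rdm(features: FeatureSet) -> ModelRDM:
    """1 - Spearman correlation between every pair of feature vectors."""
    f = features.features
    if len(f) < 2 or f.shape[1] < 2:
        raise ValueError("need >= 2 conditions and feature dimension >= 2")
    constant = np.flatnonzero(f.std(axis=1) == 0)
    if len(constant):
        cid = features.condition_ids[constant[0]]
        raise ValueError(f"constant feature vector for condition {cid}: Spearman undefined")
    ranks = np.apply_along_axis(stats.rankdata, 1, f)
    rho = np.corrcoef(ranks)
    rdm = 1.0 - rho
    np.fill_diagonal(rdm, 0.0)
    rdm = (rdm + rdm.T) / 2  # exact symmetry against float noise
    return ModelRDM(rdm, features.condition_ids, source=features.layer)


def _level_cell_masks(design: Design, factor: str):
    levels = design.levels(factor).to_numpy()
    i, j = np.tril_indices(design.n_conditions, k=-1)
    between = levels[i] != levels[j]
    return i, j, between


def clustering_timecourse(rdms, design: Design, factor: str) -> GroupTimeCourse:
    """Representational clustering: mean between-level minus mean
    within-level decoding accuracy, per time point.

    Positive values indicate that the factor's levels form separable
    clusters in representational space; units are percent decoding-accuracy
    difference and the null reference is 0.
    """
    if len(LEVELS.get(factor, ())) != 2:
        raise ValueError(f"factor {factor!r} is not a binary design factor")
    rdms_list = [rdms] if isinstance(rdms, RDMSeries) else list(rdms)
    i, j, between = _level_cell_masks(design, factor)
    courses = []
    for r in rdms_list:
        tri = r.accuracies[:, i, j]
        values = tri[:, between].mean(axis=1) - tri[:, ~between].mean(axis=1)
        courses.append(
            GroupTimeCourse(
                values=values[None, :],
                times=r.times,
                subject_ids=np.array([r.subject_id]),
                label=f"{factor} clustering (between - within)",
                chance=0.0,
            )
        )
    return GroupTimeCourse.stack(courses)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def rsa_timecourse(rdms, model) -> GroupTimeCourse:
    """Spearman correlation between brain and model RDMs over time.

    ``model`` may be a single :class:`ModelRDM` or a list of per-layer
    RDMs; for multi-layer models the per-layer correlations are averaged
    (arithmetic mean) into the reported time course.
    """
    rdms_list = [rdms] if isinstance(rdms, RDMSeries) else list(rdms)
    layers = [model] if isinstance(model, ModelRDM) else list(model)
    tris = []
    for layer in layers:
        tri = layer.lower_triangle()
        if np.all(tri == tri[0]):
            raise ValueError(f"model RDM {layer.source!r} is constant; correlation undefined")
        tris.append(tri)
    courses = []
    for r in rdms_list:
        brain = r.lower_triangle()
        values = np.mean(
            [[_spearman(brain[t], tri) for t in range(len(r.times))] for tri in tris],
            axis=0,
        )
        courses.append(
            GroupTimeCourse(
                values=np.asarray(values)[None, :],
                times=r.times,
                subject_ids=np.array([r.subject_id]),
                label=f"RSA: {layers[0].source}",
                chance=0.0,
            )
        )
    return GroupTimeCourse.stack(courses)


def partial_spearman(x: np.ndarray, y: np.ndarray, nuisance=()) -> float:
    """Spearman correlation of x and y after partialling out nuisance vectors.

    All vectors are rank-transformed (average ranks on ties); the ranks of
    x and y are residualized on the nuisance ranks (plus an intercept) by
    least squares, and the Pearson correlation of the residuals is
    returned. With no nuisance this reduces to plain Spearman. Collinear
    nuisance columns are handled by the least-squares pseudoinverse and
    logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nuis = [np.asarray(z, dtype=float) for z in nuisance]
    n = len(x)
    if any(len(v) != n for v in [y, *nuis]):
        raise ValueError("all vectors must have the same length")
    if n <= len(nuis) + 2:
        raise ValueError(f"need more than {len(nuis) + 2} observations, got {n}")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if not nuis:
        return float(np.corrcoef(rx, ry)[0, 1])
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(z) for z in nuis])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        logger.info("collinear nuisance set: rank %d of %d columns", rank, Z.shape[1])
    coef_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    res_x, res_y = rx - Z @ coef_x, ry - Z @ coef_y
    nx, ny = np.linalg.norm(res_x), np.linalg.norm(res_y)
    # a vector fully explained by the nuisance set leaves rounding-level
    # residuals; its partial correlation is 0 by convention
    tiny = 1e-10 * np.linalg.norm(rx)
    if nx <= tiny or ny <= tiny:
        return 0.0
    return float(res_x @ res_y / (nx * ny))


def partial_rsa_timecourse(rdms, target: ModelRDM, nuisance_models) -> GroupTimeCourse:
    """RSA time course for the target model after partialling out all
    layer RDMs of a nuisance model (e.g. the explicit size model after
    removing everything a feature hierarchy explains)."""
    rdms_list = [rdms] if isinstance(rdms, RDMSeries) else list(rdms)
    nuis_tris = [m.lower_triangle() for m in nuisance_models]
    target_tri = target.lower_triangle()
    courses = []
    for r in rdms_list:
        brain = r.lower_triangle()
        values = np.array(
            [partial_spearman(brain[t], target_tri, nuis_tris) for t in range(len(r.times))]
        )
        courses.append(
            GroupTimeCourse(
                values=values[None, :],
                times=r.times,
                subject_ids=np.array([r.subject_id]),
                label=f"partial RSA: {target.source}",
                chance=0.0,
            )
        )
    return GroupTimeCourse.stack(courses)
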