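"""Unsupervised trajectory model selection.

Pipeline: (i) two-stage sigma-unit energy filtering, (ii) PCA (SVD) of the
standardized 10-feature matrix with elbow-based component-count selection
followed by k-means with WCSS-elbow cluster-count selection, (iii)
representative-cluster choice by lowest mean local/total/Go energies and
cohort thresholding on high CC and low energies.

Seven components participate in the filter: E_repulsive, E_local,
E_stacking, E_pairing, B_stage in stage 1, then CC_AFM (lower bound) and
E_total (upper bound) in stage 2.  All z-scores use the population
standard deviation.

No single set of sigma cutoffs or cohort quantiles is canonical across
instruments and trajectories, so all of them are configuration keys, with
permissive defaults (stage-1 upper bounds +3 sigma; stage-2 CC >= -1 sigma
and E_total <= +1 sigma; cohort CC quantile 0.90, energy quantiles 0.25).

``CohortSelector`` wraps the pipeline as a scikit-learn-style estimator
(``fit`` on a list of energy records, fitted attributes with trailing
underscores) so it composes with sklearn tooling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SKPCA

from .io_formats import ENERGY_FIELDS, EnergyRecord

__all__ = [
    "FilterConfig",
    "CohortConfig",
    "PCAResult",
    "ClusterResult",
    "UMLResult",
    "standardize",
    "energy_filter",
    "pca",
    "cluster",
    "select_representative_cluster",
    "select_cohort",
    "run_uml",
    "CohortSelector",
]

logger = logging.getLogger(__name__)

STAGE1_COMPONENTS = ("e_repulsive", "e_local", "e_stacking", "e_pairing", "b_stage")


@dataclass
class FilterConfig:
    """Sigma-unit cutoffs for the two filtering stages.

    Stage 1 keeps frames whose z-score on each listed energy component is
    at or below the cutoff (one-sided upper bound).  Stage 2 keeps frames
    with CC z-score >= ``cc_afm`` and E_total z-score <= ``e_total``.
    """

    stage1_cutoffs: dict[str, float] = field(
        default_factory=lambda: {c: 3.0 for c in STAGE1_COMPONENTS})
    stage2_cutoffs: dict[str, float] = field(
        default_factory=lambda: {"cc_afm": -1.0, "e_total": 1.0})

    def __post_init__(self):
        if set(self.stage1_cutoffs) != set(STAGE1_COMPONENTS):
            raise ValueError(
                f"stage1_cutoffs must have exactly the keys {STAGE1_COMPONENTS}")
        if set(self.stage2_cutoffs) != {"cc_afm", "e_total"}:
            raise ValueError("stage2_cutoffs must have keys cc_afm and e_total")


@dataclass
class CohortConfig:
    """Quantile thresholds for the final cohort within the representative
    cluster: CC above its ``cc_quantile_min`` quantile and each listed
    energy below its ``energy_quantile_max`` quantile."""

    cc_quantile_min: float = 0.90
    energy_quantile_max: dict[str, float] = field(
        default_factory=lambda: {"e_total": 0.25, "e_local": 0.25, "e_go": 0.25})

    def __post_init__(self):
        qs = [self.cc_quantile_min, *self.energy_quantile_max.values()]
        if not all(0.0 < q < 1.0 for q in qs):
            raise ValueError("quantiles must lie in (0, 1)")


@dataclass
class PCAResult:
    loadings: np.ndarray            # (n_components, n_features), orthonormal rows
    scores: np.ndarray              # (n_frames, n_components)
    eigenvalues: np.ndarray         # population covariance eigenvalues, desc
    explained_variance_ratio: np.ndarray
    n_components_selected: int


@dataclass
class ClusterResult:
    labels: np.ndarray
    k_selected: int
    wcss_curve: np.ndarray          # WCSS for k = 1..k_max
    centers: np.ndarray


@dataclass
class UMLResult:
    stage1_indices: np.ndarray      # indices into the input record list
    stage2_indices: np.ndarray
    pca: PCAResult
    clusters: ClusterResult
    representative_cluster: int
    cluster_indices: np.ndarray
    cohort_indices: np.ndarray
    provenance: dict


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-scores with the population standard deviation (mean 0, sigma 1)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 values")
    sigma = v.std(ddof=0)
    if sigma == 0:
        raise ValueError("zero variance: cannot standardize")
    return (v - v.mean()) / sigma


def _records_matrix(records: Sequence[EnergyRecord]) -> np.ndarray:
    return np.array([r.as_array() for r in records], dtype=float)


def energy_filter(records: Sequence[EnergyRecord],
                  cfg: FilterConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage sigma filtering; returns (stage1_indices, stage2_indices).

    Z-scores for stage 2 are recomputed on the stage-1 survivors.  An empty
    survivor set raises, advising cutoff relaxation.
    """
    cfg = cfg or FilterConfig()
    if len(records) < 10:
        raise ValueError("need at least 10 frames to filter")
    m = _records_matrix(records)
    cols = {f: i for i, f in enumerate(ENERGY_FIELDS)}

    keep = np.ones(len(records), dtype=bool)
    for comp, cut in cfg.stage1_cutoffs.items():
        try:
            z = standardize(m[:, cols[comp]])
        except ValueError:
            continue                      # constant component filters nothing
        keep &= z <= cut
    stage1 = np.flatnonzero(keep)
    if len(stage1) == 0:
        raise ValueError("stage-1 filter removed every frame; relax the cutoffs")

    sub = m[stage1]
    keep2 = np.ones(len(stage1), dtype=bool)
    try:
        keep2 &= standardize(sub[:, cols["cc_afm"]]) >= cfg.stage2_cutoffs["cc_afm"]
    except ValueError:
        pass
    try:
        keep2 &= standardize(sub[:, cols["e_total"]]) <= cfg.stage2_cutoffs["e_total"]
    except ValueError:
        pass
    stage2 = stage1[keep2]
    if len(stage2) == 0:
        raise ValueError("stage-2 filter removed every frame; relax the cutoffs")
    return stage1, stage2


def pca(matrix: np.ndarray, gain_threshold: float = 0.05,
        floor: int = 3) -> PCAResult:
    """PCA of a standardized frames-by-features matrix via SVD.

    Eigenvalues follow the population-covariance convention.  The selected
    component count is the smallest n whose next component's marginal
    explained-variance share drops below ``gain_threshold`` (floor 3,
    matching the 3-D component plots used to visualize trajectories).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more frames than features")
    p = _SKPCA(n_components=X.shape[1], svd_solver="full")
    scores = p.fit_transform(X)
    eigen = p.explained_variance_ * (X.shape[0] - 1) / X.shape[0]
    evr = p.explained_variance_ratio_
    below = np.flatnonzero(evr < gain_threshold)
    n_sel = int(below[0]) if len(below) else X.shape[1]
    n_sel = max(floor, n_sel)
    return PCAResult(
        loadings=p.components_,
        scores=scores,
        eigenvalues=eigen,
        explained_variance_ratio=evr,
        n_components_selected=min(n_sel, X.shape[1]),
    )


def cluster(scores: np.ndarray, k_max: int = 8, seed: int = 0,
            elbow_fraction: float = 0.10) -> ClusterResult:
    """k-means over PCA scores with WCSS-elbow selection of k.

    k-means++ seeding with 10 restarts at every k.  The selected k is the
    smallest k whose *next* WCSS drop falls below ``elbow_fraction`` of the
    initial drop.  When even the best split removes less than half of the
    total WCSS there is no cluster structure to speak of and k = 1 is
    selected (a single Gaussian blob loses only ~35-40%).
    """
    X = np.asarray(scores, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if X.shape[0] < k_max:
        raise ValueError("need at least k_max frames")
    wcss = np.empty(k_max)
    fits = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X)
        wcss[k - 1] = km.inertia_
        fits.append(km)
    drops = wcss[:-1] - wcss[1:]                  # drop going to k+1
    if len(drops) == 0 or drops[0] <= 0.5 * wcss[0]:
        k_sel = 1
    else:
        k_sel = k_max
        for k in range(2, k_max):
            if drops[k - 1] < elbow_fraction * drops[0]:
                k_sel = k
                break
    km = fits[k_sel - 1]
    return ClusterResult(labels=km.labels_.copy(), k_selected=k_sel,
                         wcss_curve=wcss, centers=km.cluster_centers_.copy())


def select_representative_cluster(clusters: ClusterResult,
                                  records: Sequence[EnergyRecord]) -> int:
    """Cluster minimizing the summed standardized means of E_local, E_total
    and E_go; ties resolve to the lowest cluster id."""
    if len(records) != len(clusters.labels):
        raise ValueError("records and labels must be parallel")
    m = _records_matrix(records)
    cols = {f: i for i, f in enumerate(ENERGY_FIELDS)}
    score = np.zeros(clusters.k_selected)
    for comp in ("e_local", "e_total", "e_go"):
        v = m[:, cols[comp]]
        try:
            z = standardize(v)
        except ValueError:
            continue
        for c in range(clusters.k_selected):
            sel = clusters.labels == c
            score[c] += z[sel].mean() if np.any(sel) else np.inf
    winners = np.flatnonzero(score == score.min())
    if len(winners) > 1:
        logger.info("representative-cluster tie between %s; taking lowest id",
                    winners.tolist())
    return int(winners[0])


def select_cohort(records: Sequence[EnergyRecord],
                  cfg: CohortConfig | None = None) -> np.ndarray:
    """Cohort of frames with CC above and energies below their quantile
    thresholds; empty intersections relax the quantiles stepwise by 0.05
    (with a warning) until non-empty, falling back to the full cluster."""
    cfg = cfg or CohortConfig()
    if len(records) == 0:
        raise ValueError("empty cluster")
    m = _records_matrix(records)
    cols = {f: i for i, f in enumerate(ENERGY_FIELDS)}
    cc = m[:, cols["cc_afm"]]
    cc_q = cfg.cc_quantile_min
    e_q = dict(cfg.energy_quantile_max)
    for relax_round in range(40):
        keep = cc >= np.quantile(cc, cc_q)
        for comp, q in e_q.items():
            v = m[:, cols[comp]]
            keep &= v <= np.quantile(v, q)
        if np.any(keep):
            if relax_round:
                warnings.warn(
                    f"cohort thresholds relaxed {relax_round} step(s) "
                    f"to obtain a non-empty cohort", stacklevel=2)
            return np.flatnonzero(keep)
        cc_q = max(cc_q - 0.05, 0.0)
        e_q = {c: min(q + 0.05, 1.0) for c, q in e_q.items()}
    return np.arange(len(records))


def run_uml(records: Sequence[EnergyRecord],
            filter_cfg: FilterConfig | None = None,
            cohort_cfg: CohortConfig | None = None,
            seed: int = 0,
            k_max: int = 8,
            pca_gain_threshold: float = 0.05) -> UMLResult:
    """Full unsupervised pipeline: filter -> PCA -> k-means -> cluster ->
    cohort.  Deterministic given the seed; all returned index arrays refer
    to positions in the input record list."""
    if len(records) < 100:
        raise ValueError("need at least 100 frames")
    stage1, stage2 = energy_filter(records, filter_cfg)
    survivors = [records[i] for i in stage2]
    m = _records_matrix(survivors)
    ms = np.empty_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        s = col.std(ddof=0)
        ms[:, j] = (col - col.mean()) / s if s > 0 else 0.0
    p = pca(ms, gain_threshold=pca_gain_threshold)
    cl = cluster(p.scores[:, : p.n_components_selected], k_max=k_max, seed=seed)
    rep = select_representative_cluster(cl, survivors)
    in_rep = np.flatnonzero(cl.labels == rep)
    cluster_abs = stage2[in_rep]
    cohort_rel = select_cohort([survivors[i] for i in in_rep], cohort_cfg)
    cohort_abs = cluster_abs[cohort_rel]
    prov = {
        "n_input": len(records),
        "n_stage1": int(len(stage1)),
        "n_stage2": int(len(stage2)),
        "n_components": int(p.n_components_selected),
        "k_selected": int(cl.k_selected),
        "representative_cluster": int(rep),
        "n_cluster": int(len(cluster_abs)),
        "n_cohort": int(len(cohort_abs)),
        "seed": int(seed),
    }
    return UMLResult(stage1_indices=stage1, stage2_indices=stage2, pca=p,
                     clusters=cl, representative_cluster=rep,
                     cluster_indices=cluster_abs, cohort_indices=cohort_abs,
                     provenance=prov)


class CohortSelector(BaseEstimator):
    """Scikit-learn-style wrapper around :func:`run_uml`.

    ``fit`` takes a sequence of :class:`EnergyRecord`; fitted attributes
    expose the cohort (``cohort_indices_``), the intermediate stages and
    provenance counts.
    """

    def __init__(self, filter_cfg: FilterConfig | None = None,
                 cohort_cfg: CohortConfig | None = None,
                 k_max: int = 8, pca_gain_threshold: float = 0.05,
                 random_state: int = 0):
        self.filter_cfg = filter_cfg
        self.cohort_cfg = cohort_cfg
        self.k_max = k_max
        self.pca_gain_threshold = pca_gain_threshold
        self.random_state = random_state

    def fit(self, X: Sequence[EnergyRecord], y=None):
        res = run_uml(X, self.filter_cfg, self.cohort_cfg,
                      seed=self.random_state, k_max=self.k_max,
                      pca_gain_threshold=self.pca_gain_threshold)
        self.result_ = res
        self.cohort_indices_ = res.cohort_indices
        self.cluster_indices_ = res.cluster_indices
        self.pca_ = res.pca
        self.clusters_ = res.clusters
        self.provenance_ = res.provenance
        return self

    def transform(self, X: Sequence[EnergyRecord]) -> list[EnergyRecord]:
        """Return the cohort records selected during fit."""
        if not hasattr(self, "cohort_indices_"):
            raise RuntimeError("CohortSelector is not fitted")
        return [X[i] for i in self.cohort_indices_]

    def fit_transform(self, X: Sequence[EnergyRecord], y=None):
        return self.fit(X).transform(X)
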