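"""Collinearity reduction of dosimetric variables.

Pearson correlations among all dosimetric variables are clustered
hierarchically on the distance 1 - |r|; cutting the dendrogram at
1 - threshold (default threshold 0.75) yields groups of mutually redundant
variables, and the member best correlated with the endpoint represents each
group in the multivariate stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DataError, ParameterError, UndefinedStatisticError

DEFAULT_THRESHOLD = 0.75


@dataclass(frozen=True)
class ClusterAssignment:
    feature: str
    cluster_id: int
    representative: bool
    rs_with_endpoint: float


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the feature columns."""
    if features.shape[1] < 2:
        raise ParameterError("need at least 2 feature columns")
    if len(features) < 3:
        raise ParameterError("need at least 3 patients")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [features.columns[i] for i in constant]
        raise UndefinedStatisticError(f"constant feature column(s): {names}")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=features.columns, columns=features.columns)


def cluster_features(
    corr: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "average",
    use_abs: bool = True,
) -> dict[str, int]:
    """Agglomerative clustering of features at the correlation threshold.

    Distance is ``1 - |r|`` (or ``1 - r`` when ``use_abs`` is off); the
    dendrogram is cut at height ``1 - threshold``.  Returns feature ->
    cluster id (ids are contiguous, ordered by first appearance).
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    names = list(corr.index)
    if list(corr.columns) != names:
        raise ParameterError("correlation matrix must be square with matching labels")
    if len(names) == 1:
        return {names[0]: 1}
    r = corr.to_numpy(dtype=float)
    dist = 1.0 - (np.abs(r) if use_abs else r)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, lab in zip(names, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[name] = remap[lab]
    return out


def select_representatives(
    clusters: Mapping[str, int],
    rs_with_endpoint: Mapping[str, float],
) -> list[ClusterAssignment]:
    """Pick, per cluster, the member best correlated with the endpoint.

    Ties on |rs| are broken by the alphabetically first feature name so the
    result is deterministic and order-independent.
    """
    missing = [f for f in clusters if f not in rs_with_endpoint]
    if missing:
        raise DataError(f"no univariate result for feature(s): {missing}")
    by_cluster: dict[int, list[str]] = {}
    for feat, cid in clusters.items():
        by_cluster.setdefault(cid, []).append(feat)
    assignments: list[ClusterAssignment] = []
    for cid in sorted(by_cluster):
        members = sorted(by_cluster[cid])
        rep = min(members, key=lambda f: (-abs(rs_with_endpoint[f]), f))
        for feat in members:
            assignments.append(
                ClusterAssignment(
                    feature=feat,
                    cluster_id=cid,
                    representative=feat == rep,
                    rs_with_endpoint=float(rs_with_endpoint[feat]),
                )
            )
    return assignments


def reduced_features(assignments: Sequence[ClusterAssignment]) -> list[str]:
    """The cluster representatives, one per cluster."""
    return [a.feature for a in assignments if a.representative]


def decorrelate(
    features: pd.DataFrame,
    rs_with_endpoint: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "average",
    use_abs: bool = True,
) -> tuple[list[ClusterAssignment], list[str]]:
    """Convenience wrapper: correlation matrix -> clusters -> representatives."""
    corr = pearson_matrix(features)
    clusters = cluster_features(corr, threshold=threshold, method=method, use_abs=use_abs)
    assignments = select_representatives(clusters, rs_with_endpoint)
    return assignments, reduced_features(assignments)


def assignments_frame(assignments: Sequence[ClusterAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in assignments])
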