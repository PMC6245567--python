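"""Agglomerative clustering of provider profiles and dominance analysis.

Providers are clustered on their composition profiles with Ward's minimum-
variance criterion (Euclidean distances); centroid linkage is available
behind a flag.  The cluster-specialty dominance analysis asks, for each
cluster, which specialty is most frequent and what fraction of the cluster
it accounts for — on real data 91% of 605 clusters had one specialty at
>= 30%, i.e. unsupervised prescribing-pattern clusters largely recover the
specialty taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._regions import resolve_region
from .containers import ProfileMatrix
from .errors import ValidationError


@dataclass
class ClusterAssignment:
    """A flat cut of an agglomerative merge tree."""

    labels: pd.Series  # npi -> cluster id (1..k)
    linkage_matrix: np.ndarray  # scipy linkage encoding of the merge tree
    n_clusters: int
    criterion: str
    metric: str


def ward_cluster(
    profile: ProfileMatrix,
    n_clusters: int | None = None,
    height: float | None = None,
    method: str = "ward",
) -> ClusterAssignment:
    """Agglomerative clustering of profile rows, cut at a count or height.

    Parameters
    ----------
    n_clusters
        Number of flat clusters to cut the tree into.  Mutually exclusive
        with ``height``.
    height
        Cophenetic-distance threshold for the cut instead of a count.
    method
        ``'ward'`` (default) or ``'centroid'``.
    """
    if (n_clusters is None) == (height is None):
        raise ValidationError("specify exactly one of n_clusters or height")
    if method not in ("ward", "centroid"):
        raise ValidationError("method must be 'ward' or 'centroid'")
    n = profile.shape[0]
    if n_clusters is not None and not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters={n_clusters} outside [1, {n}]")
    Z = linkage(profile.values, method=method, metric="euclidean")
    if n_clusters is not None:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        flat = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(flat, index=profile.providers, name="cluster_id")
    return ClusterAssignment(
        labels=labels,
        linkage_matrix=Z,
        n_clusters=int(labels.nunique()),
        criterion=method,
        metric="euclidean",
    )


@dataclass
class DominanceReport:
    """Per-cluster dominant-specialty table and its summary."""

    per_cluster: pd.DataFrame
    summary_fraction: float  # share of clusters with dominance >= threshold
    threshold: float
    second_specialty_tally: pd.Series


def cluster_dominance(
    assignment: ClusterAssignment,
    annotations: pd.DataFrame,
    threshold: float = 0.30,
) -> DominanceReport:
    """Dominant specialty per cluster and the fraction of clusters dominated.

    Dominance fraction = (count of most frequent specialty) / cluster size.
    Ties are broken lexicographically and flagged.  The summary is the share
    of clusters whose dominance fraction is >= ``threshold``; the
    second-specialty tally counts runner-up specialties across clusters with
    >= 2 specialties.
    """
    spec = annotations["specialty"].reindex(assignment.labels.index)
    if spec.isna().any():
        raise ValidationError("all providers must carry a specialty annotation")
    rows = []
    seconds = []
    for cid, members in spec.groupby(assignment.labels):
        counts = members.value_counts().sort_index()  # lexicographic tie-break
        counts = counts.sort_values(ascending=False, kind="stable")
        assert len(members) > 0
        dominant = counts.index[0]
        frac = counts.iloc[0] / len(members)
        tie = len(counts) > 1 and counts.iloc[1] == counts.iloc[0]
        second = counts.index[1] if len(counts) > 1 else None
        if second is not None:
            seconds.append(second)
        rows.append(
            {
                "cluster_id": cid,
                "size": len(members),
                "dominant_specialty": dominant,
                "dominant_fraction": float(frac),
                "second_specialty": second,
                "tie": tie,
            }
        )
    per_cluster = pd.DataFrame(rows).set_index("cluster_id")
    summary = float((per_cluster["dominant_fraction"] >= threshold).mean())
    tally = pd.Series(seconds, dtype=object).value_counts()
    return DominanceReport(
        per_cluster=per_cluster,
        summary_fraction=summary,
        threshold=threshold,
        second_specialty_tally=tally,
    )


def cluster_region_cross(
    assignment: ClusterAssignment,
    annotations: pd.DataFrame,
    region_level: str = "federal_region",
) -> pd.DataFrame:
    """Cluster x region composition table (rows sum to 1).

    ``region_level`` is one of ``'federal_region'``, ``'census_region'`` or
    ``'state'``.  States that resolve to no region are reported in an
    ``'unresolved'`` column rather than dropped.
    """
    states = annotations["state"].reindex(assignment.labels.index)
    regions = states.map(lambda s: resolve_region(s, region_level) or "unresolved")
    table = pd.crosstab(assignment.labels, regions)
    return table.div(table.sum(axis=1), axis=0)
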