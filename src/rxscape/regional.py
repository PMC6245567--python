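"""Regional prescribing-profile comparison.

Providers are aggregated into regions (CBSAs or states); each region's
feature vector is its total claims per drug divided by the region's Part D
enrollee count, restricted to drugs with enough national volume (on the real
2013 release: 532 drugs with over 100,000 claims across the 52 largest
CBSAs).  Regions are compared through the correlation distance
``d_ij = 1 - r_ij`` (Pearson r between region rows), embedded with classical
multidimensional scaling, and judged against a permutation null built by
shuffling provider-region memberships while preserving per-region provider
counts: if regional prescribing differences were mere sampling noise, the
real configuration's dispersion would fall inside the permuted cloud.

Also provides pairwise region fold-difference comparisons (which drugs
differ more than, say, 5-fold per enrollee between two cities) and the
Mantel-style correlation between a prescribing-pattern distance matrix and
a disease-prevalence distance matrix across states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes

from .containers import ClaimsMatrix, DistanceMatrix, RegionProfileMatrix
from .errors import ValidationError


def region_profiles(
    matrix: ClaimsMatrix,
    annotations: pd.DataFrame,
    enrollees: pd.Series,
    region_col: str = "cbsa",
    min_national_claims: int = 0,
) -> RegionProfileMatrix:
    """Region x drug claims-per-enrollee matrix.

    Features are restricted to drugs whose national (post-censoring) total
    is strictly greater than ``min_national_claims``; each region row is the
    sum of its providers' claims divided by the region's enrollee count.
    Providers with no region label and regions without positive enrollee
    counts are excluded (the latter with a warning).
    """
    national = matrix.column_totals()
    keep = national > min_national_claims
    if not keep.any():
        raise ValidationError(
            f"no feature exceeds min_national_claims={min_national_claims}"
        )
    labels = annotations[region_col].reindex(matrix.providers)
    has_region = labels.notna().to_numpy()
    sub = matrix.counts[has_region][:, keep]
    lab = labels[has_region].to_numpy()

    regions = pd.Index(sorted(pd.unique(lab)), name="region")
    onehot = np.zeros((len(regions), sub.shape[0]))
    onehot[regions.get_indexer(lab), np.arange(sub.shape[0])] = 1.0
    sums = onehot @ sub.toarray()

    enr = enrollees.reindex(regions)
    ok = enr.notna() & (enr > 0)
    if not ok.all():
        warnings.warn(
            f"regions without positive enrollee counts excluded: "
            f"{list(regions[~ok])}",
            UserWarning,
        )
    regions, sums, enr = regions[ok.to_numpy()], sums[ok.to_numpy()], enr[ok]
    values = sums / enr.to_numpy()[:, None]
    return RegionProfileMatrix(
        values=values,
        regions=regions,
        features=matrix.drugs[keep],
        enrollees=enr,
        provenance={"min_national_claims": min_national_claims,
                    "region_col": region_col},
    )


def correlation_distance(profiles: RegionProfileMatrix) -> DistanceMatrix:
    """Pairwise d_ij = 1 - Pearson r between region feature rows.

    Values lie in [0, 2]: 0 for identical profiles, 2 for perfect
    anticorrelation.  A zero-variance region row makes r undefined and is
    an error naming the region.
    """
    X = profiles.values
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(profiles.regions[sd == 0])
        raise ValidationError(f"zero-variance region row(s), r undefined: {bad}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(values=d, labels=profiles.regions, metric="1-pearson")


def classical_mds(D: DistanceMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, eigendecomposes the Gram
    matrix, and returns the top-k coordinates together with all eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are truncated with a
    warning; if fewer than ``k`` positive eigenvalues exist the trailing
    coordinates are zero-padded with a warning.
    """
    d = D.values
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-9 * max(1.0, abs(eigval[0]))).any():
        warnings.warn(
            "distance matrix is non-Euclidean; negative eigenvalues truncated",
            UserWarning,
        )
    pos = eigval > 1e-12
    n_pos = int(pos.sum())
    use = min(k, n_pos)
    if use < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; coordinates zero-padded to k={k}",
            UserWarning,
        )
    coords = np.zeros((n, k))
    coords[:, :use] = eigvec[:, :use] * np.sqrt(eigval[:use])
    return coords, eigval


def _dispersion(coords: np.ndarray) -> float:
    """Mean distance of region points from their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.linalg.norm(c, axis=1).mean())


def _align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Center and rotate/reflect ``coords`` onto ``reference`` (no scaling)."""
    a = coords - coords.mean(axis=0)
    b = reference - reference.mean(axis=0)
    R, _ = orthogonal_procrustes(a, b)
    return a @ R


@dataclass
class PermutationNullResult:
    """Real MDS configuration and its label-permutation null."""

    regions: pd.Index
    real_coords: np.ndarray  # (n_regions, 2)
    permuted_coords: np.ndarray  # (n_perm, n_regions, 2), Procrustes-aligned
    real_dispersion: float
    permuted_dispersions: np.ndarray  # (n_perm,)


def permutation_null(
    matrix: ClaimsMatrix,
    annotations: pd.DataFrame,
    enrollees: pd.Series,
    n_perm: int = 100,
    seed: int | None = None,
    region_col: str = "cbsa",
    min_national_claims: int = 0,
) -> PermutationNullResult:
    """Permutation null for the regional MDS configuration.

    For each permutation the provider-region labels are shuffled (preserving
    per-region provider counts exactly), the region-profiles ->
    correlation-distance -> classical-MDS pipeline is recomputed, and the
    permuted configuration is Procrustes-aligned to the real one.  The
    dispersion summary (mean distance from the configuration centroid) of
    the real data can then be compared against the null distribution.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def run(ann: pd.DataFrame):
        prof = region_profiles(matrix, ann, enrollees, region_col,
                               min_national_claims)
        coords, _ = classical_mds(correlation_distance(prof), k=2)
        return prof.regions, coords

    regions, real = run(annotations)
    permuted = np.empty((n_perm, len(regions), 2))
    disps = np.empty(n_perm)
    labels = annotations[region_col].to_numpy()
    for p in range(n_perm):
        shuffled = annotations.copy()
        shuffled[region_col] = rng.permutation(labels)
        reg_p, coords_p = run(shuffled)
        if not reg_p.equals(regions):  # a region could lose all providers
            coords_p = pd.DataFrame(coords_p, index=reg_p).reindex(
                regions, fill_value=0.0
            ).to_numpy()
        permuted[p] = _align(coords_p, real)
        disps[p] = _dispersion(coords_p)
    return PermutationNullResult(
        regions=regions,
        real_coords=real - real.mean(axis=0),
        permuted_coords=permuted,
        real_dispersion=_dispersion(real),
        permuted_dispersions=disps,
    )


def pairwise_region_compare(
    profiles: RegionProfileMatrix,
    region_a: str,
    region_b: str,
    fold: float = 5.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-feature claims-per-enrollee rates for two regions, fold-flagged.

    Features whose rate ratio max/min exceeds ``fold`` are flagged.
    Features with a zero rate in either region are excluded by default
    (they cannot be placed on a log-log panel); passing ``pseudocount``
    adds it to every rate instead and keeps them.
    """
    for r in (region_a, region_b):
        if r not in profiles.regions:
            raise ValidationError(f"region {r!r} not in profile matrix")
    ia = profiles.regions.get_loc(region_a)
    ib = profiles.regions.get_loc(region_b)
    ra = profiles.values[ia].copy()
    rb = profiles.values[ib].copy()
    features = profiles.features
    if pseudocount is not None:
        ra, rb = ra + pseudocount, rb + pseudocount
    keep = (ra > 0) & (rb > 0)
    ra, rb, features = ra[keep], rb[keep], features[keep]
    ratio = np.maximum(ra, rb) / np.minimum(ra, rb)
    return pd.DataFrame(
        {"rate_a": ra, "rate_b": rb, "fold_ratio": ratio, "flagged": ratio > fold},
        index=features,
    )


def state_distance_correlation(
    prescribing: pd.DataFrame,
    prevalence: pd.DataFrame,
) -> tuple[DistanceMatrix, DistanceMatrix, float]:
    """Mantel-style R^2 between prescribing and disease-prevalence distances.

    Both inputs are state x feature tables (e.g. mean drug-class composition
    per state, and mean percent prevalence of chronic conditions per state)
    over the same states with no missing entries.  Euclidean distances are
    computed within each domain and R^2 is the squared Pearson correlation
    between the two matrices' upper-triangle entries.
    """
    if not prescribing.index.equals(prevalence.index):
        prevalence = prevalence.reindex(prescribing.index)
    if prescribing.isna().any().any() or prevalence.isna().any().any():
        raise ValidationError("state vectors must be complete (no missing entries)")
    if len(prescribing) < 3:
        raise ValidationError("need >= 3 states for a distance correlation")

    def dmat(df: pd.DataFrame, metric_name: str) -> DistanceMatrix:
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(
            values=squareform(pdist(df.to_numpy(), metric="euclidean")),
            labels=df.index,
            metric=metric_name,
        )

    d_rx = dmat(prescribing, "euclidean-prescribing")
    d_dz = dmat(prevalence, "euclidean-prevalence")
    a, b = d_rx.condensed(), d_dz.condensed()
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero variance in a distance matrix; R^2 undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return d_rx, d_dz, r**2


def compare_region_fractions(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples of fractions.

    Uses the exact null distribution when the combined sample size is <= 20
    and tie-free, and the tie-corrected normal approximation otherwise.
    Returns (U statistic for sample_a, two-sided p-value).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
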