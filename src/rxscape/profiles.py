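"""Per-provider feature vectors and univariate prescribing statistics.

A provider's feature vector is their row of claim counts over drugs (or drug
classes after many-to-one aggregation).  Dividing by the provider's total
expresses the pattern as a composition, the input to embedding and
clustering.  This module also computes the descriptive statistics used to
characterize a national claims release: prescribing diversity and volume
distributions, Gini concentration indexes with bootstrap confidence
intervals, high-volume/standard-volume cohort splits, and state-level
provider-vs-enrollee share regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClaimsMatrix, ProfileMatrix
from .errors import MappingError, ValidationError


def build_profiles(
    matrix: ClaimsMatrix,
    feature_level: str = "drugs",
    class_map: pd.Series | None = None,
    normalize: bool = True,
) -> ProfileMatrix:
    """Build the provider x feature matrix at drug or class level.

    Class aggregation sums member-drug counts per provider *before* any
    normalization, so class-level totals equal drug-level totals exactly.
    Normalization divides each row by the provider's total claims (zero-total
    rows are left at zero).

    Raises
    ------
    MappingError
        If ``feature_level='classes'`` and any matrix column lacks a class.
    """
    if feature_level not in ("drugs", "classes"):
        raise ValidationError(f"feature_level must be 'drugs' or 'classes', got {feature_level!r}")
    dense = matrix.to_dense().astype(float)
    totals = dense.sum(axis=1)
    if feature_level == "classes":
        if class_map is None:
            raise MappingError("class_map is required at feature_level='classes'")
        mapped = class_map.reindex(matrix.drugs)
        if mapped.isna().any():
            offenders = list(matrix.drugs[mapped.isna()][:10])
            raise MappingError(f"drugs without a class mapping: {offenders}")
        frame = pd.DataFrame(dense, index=matrix.providers, columns=matrix.drugs)
        agg = frame.T.groupby(mapped.to_numpy()).sum().T
        values = agg.to_numpy()
        features = pd.Index(agg.columns, name="drug_class")
    else:
        values = dense
        features = matrix.drugs
    if normalize:
        nz = totals > 0
        values = values.copy()
        values[nz] = values[nz] / totals[nz, None]
    return ProfileMatrix(
        values=values,
        providers=matrix.providers,
        features=features,
        normalized=normalize,
        totals=totals,
        provenance={
            "censor_threshold": matrix.censor_threshold,
            "feature_level": feature_level,
        },
    )


def filter_min_claims(profile: ProfileMatrix, min_claims: int) -> ProfileMatrix:
    """Retain providers whose raw total claims are >= ``min_claims``."""
    keep = profile.totals >= min_claims
    prov = dict(profile.provenance, min_claims=min_claims)
    return ProfileMatrix(
        values=profile.values[keep],
        providers=profile.providers[keep],
        features=profile.features,
        normalized=profile.normalized,
        totals=profile.totals[keep],
        provenance=prov,
    )


def diversity_volume(matrix: ClaimsMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-provider and per-feature diversity/volume statistics.

    Returns
    -------
    provider_stats
        ``unique_drugs`` (count of surviving nonzero cells per row) and
        ``total_claims`` per provider.
    feature_stats
        ``prescriber_fraction`` (share of providers with a surviving cell
        for the drug, in [0, 1]) and ``total_claims`` per drug.
    """
    nnz_row = np.asarray((matrix.counts != 0).sum(axis=1)).ravel()
    nnz_col = np.asarray((matrix.counts != 0).sum(axis=0)).ravel()
    provider_stats = pd.DataFrame(
        {"unique_drugs": nnz_row, "total_claims": matrix.row_totals()},
        index=matrix.providers,
    )
    feature_stats = pd.DataFrame(
        {
            "prescriber_fraction": nnz_col / max(matrix.n_providers, 1),
            "total_claims": matrix.column_totals(),
        },
        index=matrix.drugs,
    )
    return provider_stats, feature_stats


def threshold_summary(
    values, threshold: float, feature_total: int | None = None
) -> tuple[int, float]:
    """Count and percent of features meeting ``value >= threshold``.

    ``feature_total`` defaults to ``len(values)``; the percent is reported
    rounded to one decimal, matching how such summaries are printed
    (e.g. 165 of 2892 drugs prescribed by >= 5% of providers -> 5.7%).
    """
    values = np.asarray(values)
    if feature_total is None:
        feature_total = len(values)
    if feature_total == 0:
        raise ValidationError("feature_total is 0; percent undefined")
    count = int((values >= threshold).sum())
    return count, round(100.0 * count / feature_total, 1)


@dataclass
class SkewnessReport:
    """Gini concentration index with a percentile-bootstrap CI."""

    gini: float
    ci_low: float
    ci_high: float
    n: int
    mean: float
    bootstrap_reps: int


def _gini_point(values: np.ndarray) -> float:
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    mu = x.mean()
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * n * mu))


def gini(
    values,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> SkewnessReport:
    """Gini index G = sum_i (2i - n - 1) x_i / (n^2 mu), x sorted ascending.

    G = 0 when all values are equal; G -> 1 as the distribution concentrates
    on a single observation.  Equivalent to half the mean absolute pairwise
    difference divided by the mean.  The CI is a percentile bootstrap over
    observations.

    Raises
    ------
    ValidationError
        If the input is empty or sums to zero (mu = 0, G undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or (x < 0).any():
        raise ValidationError("gini requires a non-empty, non-negative sample")
    if x.sum() == 0:
        raise ValidationError("all values are zero; mean is 0 and G is undefined")
    point = _gini_point(x)
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        samp = x[rng.integers(0, len(x), size=len(x))]
        reps[b] = _gini_point(samp) if samp.sum() > 0 else 0.0
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    # percentile CI can miss the point estimate in tiny skewed samples; widen
    lo, hi = min(lo, point), max(hi, point)
    return SkewnessReport(
        gini=point, ci_low=float(lo), ci_high=float(hi),
        n=len(x), mean=float(x.mean()), bootstrap_reps=bootstrap_reps,
    )


@dataclass
class CohortSplit:
    """High-volume / standard-volume provider partition and composition test."""

    hv: pd.Index
    sv: pd.Index
    composition: pd.DataFrame  # specialty x {HV, SV} proportions
    chi2: float | None
    p_value: float | None
    threshold: int


def split_cohorts(
    matrix: ClaimsMatrix,
    annotations: pd.DataFrame,
    hv_threshold: int = 25000,
) -> CohortSplit:
    """Partition providers at a claims threshold and compare specialty mix.

    Providers with total claims >= ``hv_threshold`` form the high-volume
    (HV) cohort.  The specialty composition of the two cohorts is compared
    with a chi-square test on the specialty contingency table; if either
    cohort is empty the comparison is skipped with a warning.
    """
    totals = pd.Series(matrix.row_totals(), index=matrix.providers)
    hv = totals.index[totals >= hv_threshold]
    sv = totals.index[totals < hv_threshold]
    spec = annotations["specialty"].reindex(totals.index)
    table = pd.DataFrame(
        {
            "HV": spec.loc[hv].value_counts(),
            "SV": spec.loc[sv].value_counts(),
        }
    ).fillna(0)
    chi2 = p = None
    if len(hv) == 0 or len(sv) == 0:
        warnings.warn("one cohort is empty; composition test skipped", UserWarning)
        comp = table
    else:
        counts = table.to_numpy()
        keep = counts.sum(axis=1) > 0
        if keep.sum() >= 2:
            chi2, p, _, _ = stats.chi2_contingency(counts[keep])
            chi2, p = float(chi2), float(p)
        comp = table / table.sum(axis=0)
    return CohortSplit(hv=hv, sv=sv, composition=comp, chi2=chi2, p_value=p,
                       threshold=hv_threshold)


@dataclass
class StateShareFit:
    """State provider-share vs enrollee-share scatter and its OLS fit."""

    shares: pd.DataFrame  # state x {provider_share, enrollee_share}, percent
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool


def state_shares(
    annotations: pd.DataFrame,
    enrollee_table: pd.DataFrame,
    subset: pd.Index | None = None,
) -> StateShareFit:
    """Percent share of providers vs Part D enrollees by state, with OLS fit.

    ``enrollee_table`` needs columns ``state`` and ``enrollees``.  Shares
    each sum to 100%.  With a single state the fit is degenerate and flagged.
    """
    ann = annotations if subset is None else annotations.loc[subset]
    enr = enrollee_table.set_index("state")["enrollees"].astype(float)
    if enr.sum() <= 0:
        raise ValidationError("enrollee counts are zero everywhere")
    prov_counts = ann["state"].value_counts()
    states = enr.index
    prov_share = 100.0 * prov_counts.reindex(states, fill_value=0) / max(len(ann), 1)
    enr_share = 100.0 * enr / enr.sum()
    shares = pd.DataFrame(
        {"provider_share": prov_share, "enrollee_share": enr_share}
    )
    if len(states) < 2 or np.isclose(enr_share.var(), 0):
        return StateShareFit(shares, float("nan"), float("nan"), float("nan"), True)
    fit = stats.linregress(shares["enrollee_share"], shares["provider_share"])
    return StateShareFit(
        shares, float(fit.slope), float(fit.intercept), float(fit.rvalue**2), False
    )
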