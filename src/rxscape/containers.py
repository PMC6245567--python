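"""Core in-memory containers.

The central object is :class:`ClaimsMatrix`: a sparse, non-negative integer
provider-by-drug matrix of prescription claim counts, together with its
provider (NPI) and drug indexes and the privacy-censoring threshold that has
been applied to it.  Drugs are keyed by the (brand name, generic name) pair,
which is unique in Part D-style public use files; a bare brand name is not.

Provider annotations travel as a plain :class:`pandas.DataFrame` indexed by
NPI with columns ``specialty``, ``state``, ``county_fips``, ``cbsa`` and
``total_claims``; a drug-class map is a :class:`pandas.Series` indexed by the
drug key.  Helper validators enforce the invariants the pipeline relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import IntegrityError, ValidationError

#: Columns every provider-annotation frame must carry.
ANNOTATION_COLUMNS = ("specialty", "state", "county_fips", "cbsa", "total_claims")


def make_drug_index(drug_names, generic_names) -> pd.MultiIndex:
    """Build the canonical (drug_name, generic_name) drug index."""
    return pd.MultiIndex.from_arrays(
        [pd.Index(drug_names, dtype=object), pd.Index(generic_names, dtype=object)],
        names=["drug_name", "generic_name"],
    )


@dataclass
class ClaimsMatrix:
    """Sparse provider x drug claim-count matrix with censoring metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, shape ``(n_providers, n_drugs)``.
    providers
        NPI strings, one per row; unique.
    drugs
        ``MultiIndex`` of (drug_name, generic_name) pairs, one per column;
        unique.
    censor_threshold
        The censoring threshold already applied: every stored nonzero is
        guaranteed to be ``>= censor_threshold``.  0 means uncensored.
    """

    counts: sp.csr_matrix
    providers: pd.Index
    drugs: pd.MultiIndex
    censor_threshold: int = 0

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        self.providers = pd.Index(self.providers, name="npi")
        if self.counts.shape != (len(self.providers), len(self.drugs)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.providers)} providers x {len(self.drugs)} drugs"
            )
        if self.providers.has_duplicates:
            raise IntegrityError("duplicate NPIs in provider index")
        if self.drugs.has_duplicates:
            raise IntegrityError("duplicate (drug_name, generic_name) keys")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("claim counts must be non-negative")
        if self.censor_threshold < 0:
            raise ValidationError("censor_threshold must be >= 0")
        if self.counts.nnz and self.counts.data.min() < self.censor_threshold:
            raise IntegrityError(
                "stored nonzero below the declared censor_threshold"
            )

    @property
    def n_providers(self) -> int:
        return len(self.providers)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_totals(self) -> np.ndarray:
        """Total (post-censoring) claims per provider."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def column_totals(self) -> np.ndarray:
        """Total (post-censoring) claims per drug."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.providers, columns=self.drugs)

    def equals(self, other: "ClaimsMatrix") -> bool:
        return (
            self.providers.equals(other.providers)
            and self.drugs.equals(other.drugs)
            and (self.counts != other.counts).nnz == 0
        )


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check a provider-annotation frame and return it with a clean index.

    Raises
    ------
    IntegrityError
        If NPIs are duplicated.
    SchemaError via KeyError
        If a required column is absent.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"annotation table missing columns: {missing}")
    if annotations.index.has_duplicates:
        raise IntegrityError("duplicate NPIs in annotation table")
    out = annotations.copy()
    out.index = pd.Index(out.index.astype(str), name="npi")
    return out


@dataclass
class ProfileMatrix:
    """Provider x feature matrix of raw counts or compositions.

    ``features`` are either drug keys or drug-class labels.  When
    ``normalized`` is True every nonzero row sums to 1 (a composition);
    ``totals`` always carries the raw pre-normalization provider totals so
    volume filters remain possible after closure.
    """

    values: np.ndarray
    providers: pd.Index
    features: pd.Index
    normalized: bool
    totals: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.providers = pd.Index(self.providers, name="npi")
        if self.values.shape != (len(self.providers), len(self.features)):
            raise ValidationError("values shape does not match indexes")
        if self.normalized:
            sums = self.values.sum(axis=1)
            nz = sums > 0
            if nz.any() and not np.allclose(sums[nz], 1.0, atol=1e-9):
                raise ValidationError("composition rows must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.providers, columns=self.features)


@dataclass
class RegionProfileMatrix:
    """Region x feature matrix of claims per enrollee."""

    values: np.ndarray
    regions: pd.Index
    features: pd.Index
    enrollees: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.regions = pd.Index(self.regions, name="region")
        if self.values.shape != (len(self.regions), len(self.features)):
            raise ValidationError("values shape does not match indexes")
        if (self.values < 0).any():
            raise ValidationError("claims-per-enrollee values must be >= 0")
        enr = self.enrollees.reindex(self.regions)
        if enr.isna().any() or (enr <= 0).any():
            raise ValidationError("every included region needs enrollees > 0")
        self.enrollees = enr.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.features)


@dataclass
class DistanceMatrix:
    """Symmetric region-by-region distance matrix."""

    values: np.ndarray
    labels: pd.Index
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        self.labels = pd.Index(self.labels)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]
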