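"""Reading and writing PUF-shaped claims tables.

CMS-style prescriber public use files ship as three delimited tables:

1. a provider table keyed by NPI with annotations (specialty, state, ...),
2. a drug table keyed by the unique (brand, generic) name pair,
3. a long-format link table of (npi, drug_name, generic_name,
   total_claim_count) rows — a bipartite provider/drug graph weighted by
   claim counts.

This module reads the three tables into a :class:`ClaimsMatrix`, applies the
privacy censoring rule (cells below a threshold are zeroed — in the released
2013 file cells under 11 claims are suppressed), trims empty rows/columns,
and links providers to metropolitan regions (CBSAs) through a county-FIPS
crosswalk.  All identifiers (NPI, FIPS, CBSA) are handled as zero-padded
text, never integers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ClaimsMatrix, make_drug_index, validate_annotations
from .errors import IntegrityError, SchemaError, ValidationError

PROVIDER_COLUMNS = ("npi", "specialty_description", "nppes_provider_state")
DRUG_COLUMNS = ("drug_name", "generic_name")
LINK_COLUMNS = ("npi", "drug_name", "generic_name", "total_claim_count")

_FIPS_RE = re.compile(r"^\d{5}$")


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing required column(s): {missing}")


def read_puf(
    provider_file,
    drug_file,
    link_file,
    *,
    delimiter: str = ",",
    keep_empty: bool = True,
    censor_threshold: int = 0,
) -> tuple[ClaimsMatrix, pd.DataFrame]:
    """Read the three PUF tables into a claims matrix and annotations.

    Parameters
    ----------
    provider_file, drug_file, link_file
        Paths to the provider, drug and long-format link tables.
    keep_empty
        If True (default) providers and drugs listed in their tables but
        absent from the link table are retained as all-zero rows/columns;
        if False the matrix covers only linked providers and drugs.
    censor_threshold
        Threshold already applied to the link table counts (recorded as
        metadata; no re-censoring is performed here).

    Returns
    -------
    (ClaimsMatrix, annotations DataFrame indexed by NPI)

    Raises
    ------
    SchemaError
        If a required column is missing.
    IntegrityError
        If the link table contains a duplicate (npi, drug) row.
    """
    prov = pd.read_csv(provider_file, sep=delimiter, dtype=str)
    drug = pd.read_csv(drug_file, sep=delimiter, dtype=str)
    link = pd.read_csv(
        link_file,
        sep=delimiter,
        dtype={"npi": str, "drug_name": str, "generic_name": str},
    )
    _require_columns(prov, PROVIDER_COLUMNS, "provider")
    _require_columns(drug, DRUG_COLUMNS, "drug")
    _require_columns(link, LINK_COLUMNS, "link")

    key_cols = ["npi", "drug_name", "generic_name"]
    if len(link) and link.duplicated(key_cols).any():
        dups = link.loc[link.duplicated(key_cols), key_cols].head()
        raise IntegrityError(f"duplicate (npi, drug) rows in link table, e.g.\n{dups}")

    if keep_empty:
        providers = pd.Index(prov["npi"], name="npi")
        drugs = make_drug_index(drug["drug_name"], drug["generic_name"])
    else:
        providers = pd.Index(pd.unique(link["npi"]), name="npi")
        drugs = make_drug_index(
            *zip(*pd.unique(list(zip(link["drug_name"], link["generic_name"]))))
        ) if len(link) else make_drug_index([], [])
    if providers.has_duplicates:
        raise IntegrityError("duplicate NPIs in provider table")
    if drugs.has_duplicates:
        raise IntegrityError("duplicate (drug_name, generic_name) rows in drug table")

    rows = providers.get_indexer(link["npi"])
    cols = drugs.get_indexer(list(zip(link["drug_name"], link["generic_name"])))
    if len(link) and ((rows < 0).any() or (cols < 0).any()):
        raise IntegrityError(
            "link table references providers/drugs absent from their tables"
        )
    counts = sp.coo_matrix(
        (link["total_claim_count"].to_numpy(dtype=np.int64), (rows, cols)),
        shape=(len(providers), len(drugs)),
    ).tocsr()
    matrix = ClaimsMatrix(counts, providers, drugs, censor_threshold=censor_threshold)

    ann = pd.DataFrame(
        {
            "specialty": prov["specialty_description"].to_numpy(),
            "state": prov["nppes_provider_state"].to_numpy(),
            "county_fips": prov.get("county_fips", pd.Series([""] * len(prov))).to_numpy(),
            "cbsa": prov.get("cbsa", pd.Series([None] * len(prov))).to_numpy(),
        },
        index=pd.Index(prov["npi"], name="npi"),
    )
    ann["total_claims"] = pd.Series(
        matrix.row_totals(), index=matrix.providers
    ).reindex(ann.index, fill_value=0)
    return matrix, validate_annotations(ann)


def write_puf_tables(
    matrix: ClaimsMatrix,
    annotations: pd.DataFrame,
    path,
    *,
    delimiter: str = ",",
) -> dict[str, Path]:
    """Write a claims matrix and annotations as the three PUF-shaped tables.

    Emits ``providers.csv``, ``drugs.csv`` and ``links.csv`` under ``path``;
    the link table holds one row per nonzero (post-censoring) cell.  The
    output round-trips through :func:`read_puf` with zero loss.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not matrix.providers.equals(pd.Index(annotations.index, name="npi")):
        raise ValidationError("matrix and annotations must share the provider index")

    prov_out = pd.DataFrame(
        {
            "npi": matrix.providers,
            "specialty_description": annotations["specialty"].to_numpy(),
            "nppes_provider_state": annotations["state"].to_numpy(),
            "county_fips": annotations["county_fips"].to_numpy(),
            "cbsa": annotations["cbsa"].to_numpy(),
            "total_claim_count": matrix.row_totals(),
        }
    )
    drug_out = matrix.drugs.to_frame(index=False)

    coo = matrix.counts.tocoo()
    link_out = pd.DataFrame(
        {
            "npi": matrix.providers[coo.row],
            "drug_name": matrix.drugs.get_level_values("drug_name")[coo.col],
            "generic_name": matrix.drugs.get_level_values("generic_name")[coo.col],
            "total_claim_count": coo.data.astype(np.int64),
        }
    )

    paths = {
        "provider": path / "providers.csv",
        "drug": path / "drugs.csv",
        "link": path / "links.csv",
    }
    prov_out.to_csv(paths["provider"], sep=delimiter, index=False)
    drug_out.to_csv(paths["drug"], sep=delimiter, index=False)
    link_out.to_csv(paths["link"], sep=delimiter, index=False)
    return paths


def apply_censoring(matrix: ClaimsMatrix, threshold: int = 11) -> ClaimsMatrix:
    """Zero every cell strictly below ``threshold`` (the CMS privacy rule).

    Cells equal to the threshold survive: a provider with exactly 11 claims
    for a drug appears in the released 2013 file.  Idempotent, and censoring
    at t1 then t2 >= t1 equals censoring at t2 alone.
    """
    if threshold < 0:
        raise ValidationError("censor threshold must be >= 0")
    counts = matrix.counts.copy()
    counts.data = np.where(counts.data < threshold, 0, counts.data)
    counts.eliminate_zeros()
    return ClaimsMatrix(
        counts,
        matrix.providers,
        matrix.drugs,
        censor_threshold=max(threshold, matrix.censor_threshold),
    )


def drop_empty(matrix: ClaimsMatrix) -> tuple[ClaimsMatrix, dict]:
    """Remove all-zero rows and columns.

    After censoring, providers with no surviving cell carry no information
    (in the 2013 file only 808,020 of 1,049,381 providers survive).  Returns
    the trimmed matrix and a report with the number of providers/drugs
    removed and retained.
    """
    row_nnz = np.asarray((matrix.counts != 0).sum(axis=1)).ravel()
    col_nnz = np.asarray((matrix.counts != 0).sum(axis=0)).ravel()
    keep_rows = row_nnz > 0
    keep_cols = col_nnz > 0
    report = {
        "providers_removed": int((~keep_rows).sum()),
        "drugs_removed": int((~keep_cols).sum()),
        "providers_retained": int(keep_rows.sum()),
        "drugs_retained": int(keep_cols.sum()),
    }
    if not keep_rows.any():
        warnings.warn("matrix is entirely zero after censoring", UserWarning)
    trimmed = ClaimsMatrix(
        matrix.counts[keep_rows][:, keep_cols],
        matrix.providers[keep_rows],
        matrix.drugs[keep_cols],
        censor_threshold=matrix.censor_threshold,
    )
    return trimmed, report


def attach_geography(
    annotations: pd.DataFrame,
    fips_cbsa_crosswalk: pd.DataFrame,
    enrollee_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Attach CBSA labels via a county-FIPS crosswalk and load enrollee counts.

    Parameters
    ----------
    fips_cbsa_crosswalk
        Columns ``county_fips`` (5-digit text) and ``cbsa``.
    enrollee_table
        Columns ``region`` and ``enrollees`` (Part D enrollee counts).

    Providers in counties absent from the crosswalk get ``cbsa = None``
    (tolerated: many rural counties fall outside any metropolitan CBSA).

    Raises
    ------
    ValidationError
        If a FIPS code is not 5-digit text, or a county maps to more than
        one CBSA.
    """
    xwalk = fips_cbsa_crosswalk.copy()
    xwalk["county_fips"] = xwalk["county_fips"].astype(str)
    bad = [f for f in xwalk["county_fips"] if not _FIPS_RE.match(f)]
    bad += [
        f
        for f in annotations["county_fips"].astype(str)
        if f not in ("", "nan", "None") and not _FIPS_RE.match(f)
    ]
    if bad:
        raise ValidationError(f"malformed FIPS code(s), expected 5 digits: {sorted(set(bad))[:5]}")
    if xwalk["county_fips"].duplicated().any():
        raise ValidationError("crosswalk maps a county to more than one CBSA")

    lookup = xwalk.set_index("county_fips")["cbsa"]
    out = annotations.copy()
    out["cbsa"] = out["county_fips"].astype(str).map(lookup)
    out["cbsa"] = out["cbsa"].where(out["cbsa"].notna(), None)

    enrollees = (
        enrollee_table.set_index("region")["enrollees"].astype(float).rename("enrollees")
    )
    return out, enrollees
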