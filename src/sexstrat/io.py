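"""Readers, writers and validators for the pipeline's tabular artifacts.

Counts are held as a pandas DataFrame with gene identifiers on the index and
sample identifiers on the columns (integer dtype, non-negative).  Sample
metadata is a DataFrame with columns ``sample_id``, ``study``, ``condition``
(``PS`` or ``Control``) and ``sex`` (``male``, ``female`` or ``unknown``);
unknown sex is always encoded explicitly, never as a missing cell.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CONDITIONS = ("PS", "Control")
SEXES = ("male", "female", "unknown")
#: Four-group design labels, in the fixed order used for design matrices.
GROUPS = ("PS_male", "PS_female", "Control_male", "Control_female")

METADATA_COLUMNS = ("sample_id", "study", "condition", "sex")


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its structural contract."""


class MetadataError(ValueError):
    """Raised when sample metadata is malformed or mismatched."""


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-by-sample count matrix and return it with int64 values.

    Raises :class:`CountMatrixError` on duplicate identifiers, missing,
    negative, non-finite or non-integer entries.
    """
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise CountMatrixError(f"duplicate gene identifiers: {dups[:10]}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise CountMatrixError(f"duplicate sample identifiers: {dups[:10]}")
    values = counts.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        bad = counts.index[counts.isna().any(axis=1) | counts.apply(
            lambda c: pd.to_numeric(c, errors="coerce").isna()).any(axis=1)]
        raise CountMatrixError(f"non-numeric entries in rows: {bad[:10].tolist()}")
    if np.isnan(values.astype(float)).any():
        bad = counts.index[counts.isna().any(axis=1)].tolist()
        raise CountMatrixError(f"missing values in rows: {bad[:10]} (ragged input?)")
    fvals = values.astype(float)
    if (fvals < 0).any():
        bad = counts.index[(fvals < 0).any(axis=1)].tolist()
        raise CountMatrixError(f"negative counts in rows: {bad[:10]}")
    if not np.allclose(fvals, np.round(fvals)):
        bad = counts.index[(~np.isclose(fvals, np.round(fvals))).any(axis=1)].tolist()
        raise CountMatrixError(f"non-integer counts in rows: {bad[:10]}")
    out = counts.astype(np.int64)
    out.index = out.index.astype(str).rename(None)
    out.columns = out.columns.astype(str).rename(None)
    return out


def read_counts(path: str | os.PathLike, format: str = "tsv") -> pd.DataFrame:
    """Read a gene-by-sample count matrix from TSV or MatrixMarket.

    TSV: tab-separated with a header row, gene identifiers in the first
    column.  MTX: ``path`` is the ``.mtx`` file; row (gene) and column
    (sample) identifiers are read from sibling ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` files, one identifier per line.
    """
    path = os.fspath(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        except pd.errors.ParserError as exc:
            raise CountMatrixError(f"cannot parse {path}: {exc}") from exc
        return validate_counts(df)
    if format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_id_list(stem + ".genes.txt")
        samples = _read_id_list(stem + ".samples.txt")
        if mat.shape != (len(genes), len(samples)):
            raise CountMatrixError(
                f"{path}: matrix is {mat.shape} but index files give "
                f"({len(genes)}, {len(samples)})")
        return validate_counts(pd.DataFrame(mat, index=genes, columns=samples))
    raise ValueError(f"unknown count format {format!r}; use 'tsv' or 'mtx'")


def _read_id_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_counts(counts: pd.DataFrame, path: str | os.PathLike,
                 format: str = "tsv") -> None:
    """Write counts in a form :func:`read_counts` accepts (round-trip safe)."""
    path = os.fspath(path)
    counts = validate_counts(counts)
    if format == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        scipy.io.mmwrite(path if path.endswith(".mtx") else stem + ".mtx",
                         scipy.sparse.coo_matrix(counts.to_numpy()))
        for suffix, ids in ((".genes.txt", counts.index),
                            (".samples.txt", counts.columns)):
            with open(stem + suffix, "w") as fh:
                fh.write("\n".join(ids) + "\n")
    else:
        raise ValueError(f"unknown count format {format!r}; use 'tsv' or 'mtx'")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table; returns a normalized copy."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    meta = meta.loc[:, list(METADATA_COLUMNS) +
                    [c for c in meta.columns if c not in METADATA_COLUMNS]].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample ids in metadata: {dups[:10]}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise MetadataError(f"invalid condition values: {sorted(bad_cond)}")
    if meta["sex"].isna().any():
        raise MetadataError("sex must be 'male', 'female' or 'unknown', not missing")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise MetadataError(f"invalid sex values: {sorted(bad_sex)}")
    return meta.reset_index(drop=True)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | os.PathLike) -> pd.Series:
    """Read a two-column TSV (gene_id, gene_length in bases)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, gene_length")
    lengths = pd.Series(df.iloc[:, 1].to_numpy(float),
                        index=df.iloc[:, 0].astype(str))
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad[:10]}")
    return lengths


def validate_pairing(counts: pd.DataFrame,
                     meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check counts/metadata agree on samples; reorder metadata to counts order.

    Raises :class:`MetadataError` listing any missing or extra sample ids.
    """
    counts = validate_counts(counts)
    meta = validate_metadata(meta)
    c_ids = list(counts.columns)
    m_ids = set(meta["sample_id"])
    missing = [s for s in c_ids if s not in m_ids]
    extra = sorted(m_ids - set(c_ids))
    if missing or extra:
        raise MetadataError(
            f"counts/metadata sample mismatch: missing from metadata "
            f"{missing[:10]}, extra in metadata {extra[:10]}")
    meta = meta.set_index("sample_id").loc[c_ids]
    meta.index.name = "sample_id"
    return counts, meta.reset_index()


def group_labels(meta: pd.DataFrame) -> pd.Series:
    """Derive four-group labels (e.g. ``PS_male``); sex must be known."""
    unknown = meta.loc[meta["sex"] == "unknown", "sample_id"].tolist()
    if unknown:
        raise MetadataError(
            f"group undefined for samples with unknown sex: {unknown[:10]}")
    return pd.Series(meta["condition"].str.cat(meta["sex"], sep="_").to_numpy(),
                     index=meta["sample_id"].to_numpy(), name="group")


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label)
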