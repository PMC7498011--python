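"""Shared in-memory containers and TSV readers/writers.

The central object is :class:`ExpressionMatrix`: a genes x samples matrix of
continuous expression values together with per-sample metadata (disease label
and case/control status). All pipeline stages consume and produce this
container, so file formats are parsed exactly once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_tsv",
    "read_sample_sheet",
    "read_probe_map",
    "read_gene_list",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Must be numeric, with unique index and columns and no
        missing values.
    sample_meta
        Optional DataFrame indexed by sample id with columns ``disease``
        (group label) and ``status`` (``"case"`` or ``"control"``). When
        provided, its index must cover every sample column.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError("missing values are not supported; clean the input first")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from sample sheet: {sorted(missing)[:5]}")
            # keep metadata aligned to column order
            self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    # -- basic accessors ---------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        meta = None if self.sample_meta is None else self.sample_meta.loc[sample_ids]
        return ExpressionMatrix(self.values[sample_ids], meta)

    def diseases(self) -> list[str]:
        if self.sample_meta is None:
            return []
        return list(pd.unique(self.sample_meta["disease"]))

    # -- IO ----------------------------------------------------------------

    def write_tsv(self, path: str | Path, sample_sheet: str | Path | None = None) -> None:
        """Write the matrix (and optionally the sample sheet) as TSV.

        The matrix file has the gene id as first column (header ``gene_id``)
        and one column per sample. The sample sheet has columns
        ``sample_id``, ``disease``, ``status``.
        """
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")
        if sample_sheet is not None:
            if self.sample_meta is None:
                raise ValueError("no sample metadata to write")
            meta = self.sample_meta.copy()
            meta.index.name = "sample_id"
            meta.to_csv(sample_sheet, sep="\t")


def read_expression_tsv(path: str | Path, sample_sheet: str | Path | None = None) -> ExpressionMatrix:
    """Read a TSV expression table (first column = gene id, header = samples).

    Lines starting with ``!`` or ``#`` are skipped, which also accepts the
    comment preamble of a GEO series-matrix file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, skiprows=_comment_rows(path))
    df.index = df.index.astype(str)
    meta = read_sample_sheet(sample_sheet) if sample_sheet is not None else None
    return ExpressionMatrix(df, meta)


def _comment_rows(path: str | Path):
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith(("!", "#")):
                rows.append(i)
    return rows or None


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, disease, status."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"disease", "status"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}, got {list(meta.columns)}")
    return meta


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe -> gene TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map must have two columns: probe, gene")
    first = df.columns[0]
    if not first.lower().startswith(("probe", "id")):
        # headerless file: the first row was data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
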