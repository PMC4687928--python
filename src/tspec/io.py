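"""Reading, writing and replicate-averaging of FPKM expression tables.

The on-disk convention follows the public multi-tissue FPKM downloads this
package targets: UTF-8 tab-separated values, ``.`` decimal separator, no
quoting.  The expression matrix is genes x samples with a header row of
sample identifiers and a first column headed ``gene_id``; the sample map is
a two-column TSV ``sample_id<TAB>tissue``.  Missing measurements are not
representable — producers must write explicit zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, MetadataError

logger = logging.getLogger(__name__)

#: Column order of the classification table written by
#: :func:`write_classification_table`.
CLASSIFICATION_COLUMNS = (
    "gene_id",
    "category",
    "subcategory",
    "group_tissues",
    "target_fpkm",
    "ts_score",
)


@dataclass
class ExpressionMatrix:
    """Replicate-level FPKM values (genes x samples) plus a sample→tissue map.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
        All entries must be finite and non-negative.
    sample_tissue
        Mapping from each sample identifier in ``values.columns`` to the
        tissue it was taken from.
    """

    values: pd.DataFrame
    sample_tissue: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("FPKM values must be numeric")
        if arr.size and (~np.isfinite(arr)).any():
            raise ValueError("FPKM values must be finite (no NaN/inf)")
        if arr.size and (arr < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = [s for s in v.columns if s not in self.sample_tissue]
        if missing:
            raise MetadataError(f"samples without tissue assignment: {missing}")
        # keep only mappings for samples actually present
        self.sample_tissue = {s: self.sample_tissue[s] for s in v.columns}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue names, lexicographically sorted."""
        return sorted(set(self.sample_tissue.values()))


@dataclass
class TissueExpression:
    """Per-tissue mean FPKM per gene (replicates averaged on the FPKM scale)."""

    mean_fpkm: pd.DataFrame  # genes x tissues
    n_samples: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_fpkm.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.mean_fpkm.columns)


def read_fpkm_matrix(matrix_path, sample_map_path) -> ExpressionMatrix:
    """Read an FPKM matrix TSV and its sample→tissue map.

    Samples present in the matrix but absent from the map raise
    :class:`~tspec.errors.MetadataError`; map entries for samples not in the
    matrix are ignored with a logged warning.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            raise ValueError(
                f"non-numeric FPKM value in sample column {col!r}"
            )
    smap = pd.read_csv(
        sample_map_path, sep="\t", header=None, names=["sample_id", "tissue"],
        dtype=str, comment="#",
    )
    # tolerate a header line in the sample map
    if len(smap) and smap.iloc[0, 0] in ("sample_id", "sample"):
        smap = smap.iloc[1:]
    if smap["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample map")
    sample_tissue = dict(zip(smap["sample_id"], smap["tissue"]))
    extra = set(sample_tissue) - set(values.columns)
    if extra:
        logger.warning(
            "sample map entries absent from the matrix ignored: %s",
            sorted(extra),
        )
    return ExpressionMatrix(values=values, sample_tissue=sample_tissue)


def write_fpkm_matrix(m: ExpressionMatrix, matrix_path, sample_map_path) -> None:
    """Write the matrix and map in the format :func:`read_fpkm_matrix` reads."""
    m.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    with open(sample_map_path, "w", encoding="utf-8") as fh:
        for s in m.sample_ids:
            fh.write(f"{s}\t{m.sample_tissue[s]}\n")


def average_by_tissue(m: ExpressionMatrix) -> TissueExpression:
    """Average replicate samples into one mean-FPKM profile per tissue.

    The arithmetic mean is taken on the FPKM scale (not log scale), matching
    how detection and fold-change rules are defined downstream.  Output
    tissue order is lexicographic; gene order is preserved.
    """
    by_tissue = m.values.T.groupby(pd.Series(m.sample_tissue)).mean().T
    by_tissue = by_tissue[sorted(by_tissue.columns)]
    counts: dict[str, int] = {}
    for t in m.sample_tissue.values():
        counts[t] = counts.get(t, 0) + 1
    return TissueExpression(mean_fpkm=by_tissue, n_samples=counts)


def write_classification_table(rows, path) -> None:
    """Write per-gene classification records as a TSV.

    Columns: gene_id, category, subcategory, group_tissues (semicolon-joined,
    empty when the gene has no enriched group), target_fpkm, ts_score.  The
    table round-trips losslessly through :func:`read_classification_table`.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("classification table must contain at least one row")
    records = []
    for r in rows:
        records.append(
            {
                "gene_id": r.gene_id,
                "category": r.category.value,
                "subcategory": r.subcategory,
                "group_tissues": ";".join(sorted(r.group_tissues)),
                "target_fpkm": repr(float(r.target_fpkm)),
                "ts_score": repr(float(r.ts_score)),
            }
        )
    df = pd.DataFrame.from_records(records, columns=list(CLASSIFICATION_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_classification_table(path):
    """Read a TSV written by :func:`write_classification_table`."""
    from .specificity import Category, GeneClassification

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CLASSIFICATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"classification table missing columns: {sorted(missing)}")
    out = []
    for rec in df.itertuples(index=False):
        group = frozenset(t for t in rec.group_tissues.split(";") if t)
        out.append(
            GeneClassification(
                gene_id=rec.gene_id,
                category=Category(rec.category),
                group_tissues=group,
                target_fpkm=float(rec.target_fpkm),
                ts_score=float(rec.ts_score),
            )
        )
    return out


def check_aligned(te: TissueExpression, rows) -> None:
    """Raise ConsistencyError unless ``rows`` matches ``te.gene_ids`` in order."""
    if [r.gene_id for r in rows] != te.gene_ids:
        raise ConsistencyError(
            "classification rows are not aligned with the expression table"
        )
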