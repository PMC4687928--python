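"""Summary statistics over a classified multi-tissue expression table.

Covers the descriptive layer of the analysis: how the target tissue's
transcript pool (summed FPKM) splits across specificity categories, how
similar samples and tissues are to each other (Spearman rank correlation of
log-scaled FPKM), which tissue combinations share group-enriched genes, and
a ranked table of the most target-elevated genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .io import ExpressionMatrix, TissueExpression, check_aligned
from .specificity import Category, GeneClassification

logger = logging.getLogger(__name__)


def pool_fractions(
    te: TissueExpression,
    rows: list[GeneClassification],
    target: str,
) -> dict[str, float]:
    """Fraction of the target tissue's summed FPKM carried by each category.

    ``fraction(c) = sum of target FPKM over genes in c / sum over all genes``.
    Fractions sum to 1 whenever the total is positive; a zero-total input
    yields all-zero fractions with a logged warning.
    """
    check_aligned(te, rows)
    if target not in te.tissues:
        raise KeyError(f"target tissue {target!r} not in expression table")
    fpkm = te.mean_fpkm[target].to_numpy(dtype=float)
    total = float(fpkm.sum())
    out = {c.value: 0.0 for c in Category}
    if total <= 0:
        logger.warning("total target FPKM is zero; pool fractions all zero")
        return out
    for r, v in zip(rows, fpkm):
        out[r.category.value] += float(v)
    return {c: v / total for c, v in out.items()}


def spearman_matrix(
    data: Union[ExpressionMatrix, TissueExpression],
    level: str = "sample",
) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between columns.

    ``level="sample"`` correlates raw replicate columns of an
    :class:`ExpressionMatrix`; ``level="tissue"`` correlates tissue-averaged
    profiles (a :class:`TissueExpression`, or the matrix averaged first).
    Values are log2(FPKM + 1)-transformed before ranking — rank-equivalent
    to raw FPKM, kept for parity with how the scatter diagnostics are drawn.
    Ties receive average ranks.  A constant column has no defined rank
    correlation; its entries are returned as NaN with a warning.
    """
    if level not in ("sample", "tissue"):
        raise ValueError("level must be 'sample' or 'tissue'")
    if isinstance(data, ExpressionMatrix):
        if level == "tissue":
            from .io import average_by_tissue

            df = average_by_tissue(data).mean_fpkm
        else:
            df = data.values
    else:
        if level == "sample":
            raise ValueError("sample-level correlation needs an ExpressionMatrix")
        df = data.mean_fpkm
    if df.shape[1] < 2:
        raise ValueError("need at least two columns to correlate")
    logged = np.log2(df.astype(float) + 1.0)
    constant = [c for c in logged.columns if logged[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant columns have undefined rank correlation: {constant}",
            RuntimeWarning,
            stacklevel=2,
        )
    corr = logged.corr(method="spearman")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    np.fill_diagonal(corr.values, [np.nan if c in constant else 1.0 for c in corr.columns])
    return corr


def build_network(rows: Iterable[GeneClassification]) -> nx.Graph:
    """Bipartite tissue-sharing network of group-enriched genes.

    One ``kind="group"`` node per distinct enriched tissue set, carrying
    ``count`` (number of genes sharing exactly that set) and ``size``
    (square root of the count, the conventional node-area scaling); one
    ``kind="tissue"`` node per tissue appearing in at least one group, with
    edges from each group node to its member tissues.  No group-enriched
    genes yields an empty (but valid) graph.
    """
    tallies: dict[frozenset[str], int] = {}
    for r in rows:
        if r.category is Category.GROUP_ENRICHED:
            if not r.group_tissues:
                raise ConsistencyError(
                    f"group_enriched gene {r.gene_id!r} has an empty tissue set"
                )
            tallies[r.group_tissues] = tallies.get(r.group_tissues, 0) + 1
    g = nx.Graph()
    for tissues, count in sorted(tallies.items(), key=lambda kv: sorted(kv[0])):
        node = "group:" + ";".join(sorted(tissues))
        g.add_node(node, kind="group", count=count, size=math.sqrt(count))
        for t in sorted(tissues):
            if t not in g:
                g.add_node(t, kind="tissue")
            g.add_edge(node, t)
    return g


def write_network(g: nx.Graph, path) -> None:
    """Export the tissue-sharing network as GraphML."""
    nx.write_graphml(g, path)


def top_elevated_report(
    te: TissueExpression,
    rows: list[GeneClassification],
    target: str,
    n: int = 20,
) -> pd.DataFrame:
    """The ``n`` most target-elevated genes ranked by TS score.

    Only elevated genes (enriched, group-enriched, enhanced) appear, sorted
    by TS score descending with ties broken by gene id.  Target FPKM is
    rounded to an integer and the TS score to one decimal, the conventional
    display precision; ordering uses the unrounded scores.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    check_aligned(te, rows)
    elevated = [r for r in rows if r.category.is_elevated]
    elevated.sort(key=lambda r: (-r.ts_score, r.gene_id))
    records = []
    for r in elevated[:n]:
        records.append(
            {
                "gene_id": r.gene_id,
                "category": r.category.value,
                "group_tissues": ";".join(sorted(r.group_tissues)),
                "target_fpkm": int(round(r.target_fpkm)),
                "ts_score": round(r.ts_score, 1),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["gene_id", "category", "group_tissues", "target_fpkm", "ts_score"],
    )
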