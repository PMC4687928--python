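"""Semi-quantitative immunohistochemistry (IHC) scoring and concordance.

Manual IHC annotation of tissue-microarray cores scores each antibody
staining on two 0–3 scales: the fraction of positive cells (binned
0 = 0–1%, 1 = 2–25%, 2 = 26–75%, 3 = >75%) and the staining intensity
(0 negative, 1 weak, 2 moderate, 3 strong).  For the urinary bladder the
protein's localisation is additionally recorded against a fixed compartment
vocabulary: the whole urothelium, the superficial umbrella cells, the
intermediate/basal layers, some other pattern, or not analyzed (no antibody
available).  This module encodes that scheme and summarises how the
protein-level annotations line up with the transcript-level specificity
classification of the elevated genes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .errors import ConsistencyError, FormatError
from .specificity import GeneClassification

#: Percent-positive boundaries of the four fraction bins (upper edges).
FRACTION_BIN_EDGES = (1.0, 25.0, 75.0, 100.0)


class Compartment(str, enum.Enum):
    WHOLE_UROTHELIUM = "whole_urothelium"
    UMBRELLA = "umbrella"
    INTERMEDIATE_BASAL = "intermediate_basal"
    OTHER = "other"
    NOT_ANALYZED = "not_analyzed"


@dataclass(frozen=True)
class IHCAnnotation:
    """One antibody staining record for one gene."""

    gene_id: str
    antibody_id: str
    compartment: Compartment
    fraction_bin: Optional[int] = None
    intensity: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        if self.compartment is Compartment.NOT_ANALYZED:
            if self.fraction_bin is not None or self.intensity is not None:
                raise ValueError("not_analyzed records carry no scores")
        else:
            for name in ("fraction_bin", "intensity"):
                v = getattr(self, name)
                if v is None or v not in (0, 1, 2, 3):
                    raise ValueError(f"{name} must be an integer in 0..3, got {v!r}")


def fraction_to_bin(percent_positive: float) -> int:
    """Bin a percent-positive-cells value onto the 0–3 scale.

    The published anchors (0–1%, 2–25%, 26–75%, >75%) are integer examples;
    the bins are implemented as half-open intervals [0,1], (1,25], (25,75],
    (75,100] so the map is total and monotone on [0, 100].
    """
    p = float(percent_positive)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent positive must be in [0, 100], got {p}")
    for b, edge in enumerate(FRACTION_BIN_EDGES):
        if p <= edge:
            return b
    raise AssertionError("unreachable")  # pragma: no cover


def read_annotations(path) -> list[IHCAnnotation]:
    """Read an annotation TSV (gene_id, antibody_id, compartment, fraction_bin, intensity).

    Empty score cells are allowed (and required) for not_analyzed rows.
    Extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "antibody_id", "compartment", "fraction_bin", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            IHCAnnotation(
                gene_id=rec.gene_id,
                antibody_id=rec.antibody_id,
                compartment=Compartment(rec.compartment),
                fraction_bin=int(rec.fraction_bin) if rec.fraction_bin != "" else None,
                intensity=int(rec.intensity) if rec.intensity != "" else None,
            )
        )
    return out


def write_annotations(annotations: Iterable[IHCAnnotation], path) -> None:
    records = [
        {
            "gene_id": a.gene_id,
            "antibody_id": a.antibody_id,
            "compartment": a.compartment.value,
            "fraction_bin": "" if a.fraction_bin is None else a.fraction_bin,
            "intensity": "" if a.intensity is None else a.intensity,
        }
        for a in annotations
    ]
    pd.DataFrame.from_records(
        records,
        columns=["gene_id", "antibody_id", "compartment", "fraction_bin", "intensity"],
    ).to_csv(path, sep="\t", index=False)


def consensus_compartment(
    annotations: Iterable[IHCAnnotation],
    consensus: str = "error",
) -> dict[str, Compartment]:
    """Collapse possibly multiple antibody records per gene to one compartment.

    ``consensus="error"`` (default) raises on conflicting informative
    compartments for a gene; ``consensus="max"`` keeps the compartment of
    the strongest staining (highest (fraction_bin, intensity), compartment
    name as the final tie-break).  ``not_analyzed`` records never override
    an informative one.
    """
    if consensus not in ("error", "max"):
        raise ValueError("consensus must be 'error' or 'max'")
    per_gene: dict[str, list[IHCAnnotation]] = {}
    for a in annotations:
        per_gene.setdefault(a.gene_id, []).append(a)
    out: dict[str, Compartment] = {}
    for gene, recs in per_gene.items():
        informative = [r for r in recs if r.compartment is not Compartment.NOT_ANALYZED]
        if not informative:
            out[gene] = Compartment.NOT_ANALYZED
            continue
        compartments = {r.compartment for r in informative}
        if len(compartments) > 1:
            if consensus == "error":
                raise ConsistencyError(
                    f"conflicting compartments for gene {gene!r}: "
                    f"{sorted(c.value for c in compartments)}"
                )
            best = max(
                informative,
                key=lambda r: (r.fraction_bin, r.intensity, r.compartment.value),
            )
            out[gene] = best.compartment
        else:
            out[gene] = informative[0].compartment
    return out


def compartment_counts(
    annotations: Iterable[IHCAnnotation],
    elevated_genes: set[str],
    consensus: str = "error",
) -> dict[str, int]:
    """Number of elevated genes per consensus compartment.

    Only genes in ``elevated_genes`` are counted; elevated genes with no
    annotation at all count as not_analyzed.  Values sum to
    ``len(elevated_genes)``.
    """
    by_gene = consensus_compartment(annotations, consensus=consensus)
    out = {c.value: 0 for c in Compartment}
    for gene in elevated_genes:
        out[by_gene.get(gene, Compartment.NOT_ANALYZED).value] += 1
    return out


class ConcordanceReport(NamedTuple):
    table: pd.DataFrame
    analyzed: int
    not_analyzed: int


def concordance_report(
    rows: Iterable[GeneClassification],
    annotations: Iterable[IHCAnnotation],
    consensus: str = "error",
) -> ConcordanceReport:
    """Transcript–protein concordance table for the elevated genes.

    One row per elevated gene (transcript category, TS score, consensus
    compartment, analyzed flag) plus summary counts of how many elevated
    genes have protein-level data at all.
    """
    by_gene = consensus_compartment(annotations, consensus=consensus)
    records = []
    for r in rows:
        if not r.category.is_elevated:
            continue
        comp = by_gene.get(r.gene_id, Compartment.NOT_ANALYZED)
        records.append(
            {
                "gene_id": r.gene_id,
                "category": r.category.value,
                "ts_score": r.ts_score,
                "compartment": comp.value,
                "analyzed": comp is not Compartment.NOT_ANALYZED,
            }
        )
    table = pd.DataFrame.from_records(
        records, columns=["gene_id", "category", "ts_score", "compartment", "analyzed"]
    )
    analyzed = int(table["analyzed"].sum()) if len(table) else 0
    return ConcordanceReport(table, analyzed, len(table) - analyzed)


def load_bladder_elevated_fixture():
    """Packaged urinary-bladder elevated-gene IHC fixture.

    Returns ``(annotations, categories)`` where ``categories`` maps each of
    the 90 bladder-elevated gene ids to its transcript specificity category.
    The 27 compartment-localised genes (20 whole urothelium, 4 umbrella,
    3 intermediate/basal) and their categories are transcribed from the
    published urothelial profiling; the remaining analyzed (45, compartment
    ``other``) and not-analyzed (18) gene identities are mostly not public,
    so placeholder ids — and all antibody ids and staining scores — are
    synthetic stand-ins that preserve the published counts.
    """
    ref = resources.files("tspec.data").joinpath("bladder_elevated_ihc_synthetic.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        annotations = read_annotations(path)
    categories = dict(zip(df["gene_id"], df["category"]))
    return annotations, categories
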