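"""Seven-category tissue-specificity classification of FPKM profiles.

Every protein-coding gene is placed, relative to a chosen target tissue,
into exactly one of seven categories based on its per-tissue mean FPKM:

1. ``not_detected_any``      — below the detection cutoff in every tissue;
2. ``not_detected_target``   — below the cutoff in the target tissue;
3. ``tissue_enriched``       — target at least ``fold_factor`` (default 5x)
   above the maximum of all other tissues;
4. ``group_enriched``        — a group of 2–7 tissues containing the target
   whose mean is at least ``fold_factor`` above every tissue outside it;
5. ``tissue_enhanced``       — target at least ``fold_factor`` above the
   mean FPKM across tissues;
6. ``expressed_in_all``      — detected in every tissue;
7. ``mixed``                 — detected in some tissues, none of the above.

Detection is ``FPKM >= detection_cutoff`` (default 1 FPKM, roughly one mRNA
copy per average cell).  Fold comparisons are non-strict (``>=``) so a gene
exactly at the fold boundary counts as elevated.  The categories overlap by
definition, so the order above is a fixed precedence: specificity outranks
ubiquity, and the partition property (each gene in exactly one class)
follows from it.

The tissue-specificity (TS) score of a gene is its target-tissue FPKM
divided by the maximum FPKM over all other tissues, with the denominator
floored at ``ts_floor`` so genes absent everywhere else keep a finite score.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import TissueExpression

ELEVATED = ("tissue_enriched", "group_enriched", "tissue_enhanced")


class Category(str, enum.Enum):
    NOT_DETECTED_ANY = "not_detected_any"
    NOT_DETECTED_TARGET = "not_detected_target"
    TISSUE_ENRICHED = "tissue_enriched"
    GROUP_ENRICHED = "group_enriched"
    TISSUE_ENHANCED = "tissue_enhanced"
    EXPRESSED_IN_ALL = "expressed_in_all"
    MIXED = "mixed"

    @property
    def is_elevated(self) -> bool:
        return self.value in ELEVATED


class EnhancedBaseline(str, enum.Enum):
    """Denominator of the enhanced rule: mean over all tissues (default,
    matching the classification's stated definition) or over the non-target
    tissues only (the variant some summary tables describe)."""

    ALL_TISSUES = "all_tissues"
    OTHER_TISSUES = "other_tissues"


@dataclass(frozen=True)
class ClassificationParams:
    """Tunable constants of the classification.

    detection_cutoff : FPKM level at/above which a gene counts as expressed
        in a tissue (default 1.0 FPKM).
    fold_factor : fold-change required by the enriched/group/enhanced rules
        (default 5.0).
    group_min, group_max : allowed size range of an enriched group,
        target included (defaults 2 and 7).
    ts_floor : lower bound applied to the TS-score denominator (default
        0.1 FPKM) so the score stays finite for genes silent elsewhere.
    enhanced_baseline : which mean the enhanced rule compares against.
    """

    detection_cutoff: float = 1.0
    fold_factor: float = 5.0
    group_min: int = 2
    group_max: int = 7
    ts_floor: float = 0.1
    enhanced_baseline: EnhancedBaseline = EnhancedBaseline.ALL_TISSUES

    def __post_init__(self):
        if not self.detection_cutoff > 0:
            raise ConfigError("detection_cutoff must be > 0")
        if not self.fold_factor > 1:
            raise ConfigError("fold_factor must be > 1")
        if not 2 <= self.group_min <= self.group_max:
            raise ConfigError("need 2 <= group_min <= group_max")
        if not self.ts_floor > 0:
            raise ConfigError("ts_floor must be > 0")
        object.__setattr__(
            self, "enhanced_baseline", EnhancedBaseline(self.enhanced_baseline)
        )

    def validate_for(self, n_tissues: int) -> None:
        if not self.group_max < n_tissues:
            raise ConfigError(
                f"group_max={self.group_max} must be smaller than the "
                f"number of tissues ({n_tissues})"
            )


@dataclass(frozen=True)
class GeneClassification:
    """Per-gene classification record."""

    gene_id: str
    category: Category
    target_fpkm: float
    ts_score: float
    group_tissues: frozenset[str] = field(default_factory=frozenset)

    @property
    def subcategory(self) -> str:
        """Elevated subcategory label; empty for non-elevated genes."""
        return self.category.value if self.category.is_elevated else ""


def _as_series(profile) -> pd.Series:
    if isinstance(profile, pd.Series):
        return profile.astype(float)
    return pd.Series(profile, dtype=float)


def ts_score(profile, target: str, params: ClassificationParams = ClassificationParams()) -> float:
    """Target FPKM divided by the (floored) maximum FPKM of other tissues."""
    s = _as_series(profile)
    if target not in s.index:
        raise KeyError(f"target tissue {target!r} not in profile")
    others = s.drop(target)
    if others.empty:
        raise ValueError("profile needs at least 2 tissues")
    denom = max(float(others.max()), params.ts_floor)
    return float(s[target]) / denom


def find_enriched_group(
    profile,
    target: str,
    params: ClassificationParams = ClassificationParams(),
) -> Optional[frozenset[str]]:
    """Smallest qualifying enriched group containing the target, or ``None``.

    A group G qualifies when ``group_min <= |G| <= group_max``, the target
    belongs to G, and ``mean(G) >= fold_factor * max(tissues outside G)``.
    Only one candidate per size is examined, smallest size first: the
    target plus the ``size - 1`` highest-FPKM other tissues (ties broken
    lexicographically by tissue name).  For each size this candidate
    simultaneously maximises the group mean and minimises the out-of-group
    maximum over all target-containing groups of that size, so a qualifying
    group of some size exists iff the candidate of that size qualifies —
    the search is exactly equivalent to exhaustive subset enumeration.
    """
    s = _as_series(profile)
    if target not in s.index:
        raise KeyError(f"target tissue {target!r} not in profile")
    others = sorted((t for t in s.index if t != target), key=lambda t: (-s[t], t))
    values = np.concatenate(([s[target]], s[others].to_numpy()))
    prefix_sum = np.cumsum(values)
    for size in range(params.group_min, min(params.group_max, len(s) - 1) + 1):
        mean_in = prefix_sum[size - 1] / size
        max_out = float(s[others[size - 1]])  # largest tissue left outside
        if mean_in >= params.fold_factor * max_out:
            return frozenset([target] + others[: size - 1])
    return None


def classify_gene(
    profile,
    target: str,
    params: ClassificationParams = ClassificationParams(),
    gene_id: str = "",
) -> GeneClassification:
    """Assign one category to a per-tissue FPKM profile (see module docs)."""
    s = _as_series(profile)
    if target not in s.index:
        raise KeyError(f"target tissue {target!r} not in profile")
    cutoff = params.detection_cutoff
    fold = params.fold_factor
    tval = float(s[target])
    others = s.drop(target)
    score = ts_score(s, target, params)

    def rec(cat: Category, group: frozenset[str] = frozenset()) -> GeneClassification:
        return GeneClassification(
            gene_id=gene_id, category=cat, target_fpkm=tval,
            ts_score=score, group_tissues=group,
        )

    if (s < cutoff).all():
        return rec(Category.NOT_DETECTED_ANY)
    if tval < cutoff:
        return rec(Category.NOT_DETECTED_TARGET)
    if tval >= fold * float(others.max()):
        return rec(Category.TISSUE_ENRICHED)
    group = find_enriched_group(s, target, params)
    if group is not None:
        return rec(Category.GROUP_ENRICHED, group)
    if params.enhanced_baseline is EnhancedBaseline.ALL_TISSUES:
        baseline = float(s.mean())
    else:
        baseline = float(others.mean())
    if tval >= fold * baseline:
        return rec(Category.TISSUE_ENHANCED)
    if (s >= cutoff).all():
        return rec(Category.EXPRESSED_IN_ALL)
    return rec(Category.MIXED)


def classify_all(
    te: TissueExpression,
    target: str,
    params: ClassificationParams = ClassificationParams(),
) -> list[GeneClassification]:
    """Classify every gene of a tissue-expression table, preserving order."""
    if target not in te.tissues:
        raise KeyError(f"target tissue {target!r} not in expression table")
    params.validate_for(len(te.tissues))
    return [
        classify_gene(te.mean_fpkm.loc[g], target, params, gene_id=g)
        for g in te.gene_ids
    ]


def category_counts(rows: Iterable[GeneClassification]) -> dict[str, int]:
    """Tally genes per category; includes the elevated total.

    Returns a mapping with one entry per category value plus
    ``"elevated_total"`` (enriched + group-enriched + enhanced) and
    ``"total"``.
    """
    counter = Counter(r.category.value for r in rows)
    out = {c.value: counter.get(c.value, 0) for c in Category}
    out["elevated_total"] = sum(out[c] for c in ELEVATED)
    out["total"] = sum(counter.values())
    return out


def category_percentages(counts: Mapping[str, int], total: Optional[int] = None) -> dict[str, float]:
    """Percentage of genes per category, rounded as conventionally printed.

    Percentages at or above 1% are rounded to whole numbers; smaller ones
    keep one decimal so rare classes do not round to zero.  ``counts`` may
    carry ``detected`` / ``elevated_total`` style aggregate keys — every
    numeric entry except ``total`` is converted.
    """
    if total is None:
        total = counts["total"]
    if total <= 0:
        raise ValueError("total must be positive")
    out = {}
    for key, n in counts.items():
        if key == "total":
            continue
        pct = 100.0 * n / total
        out[key] = round(pct, 1) if pct < 1 else float(round(pct))
    return out
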