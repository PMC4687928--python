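"""Synthetic multi-tissue FPKM matrices with planted specificity truth.

The generator emulates the study design the classifier targets: ~32 tissues
with a small number of replicates each, FPKM-scale abundances with a
right-skewed (log-normal) baseline, and genes planted to satisfy exactly
one of the seven specificity categories with a configurable multiplicative
safety margin (strictly above 1) over the category thresholds.  Replicate noise is
multiplicative log-normal, so zeros stay zero and the positive, skewed
character of FPKM data is preserved.

Construction per category (tissue means; ``c`` = detection cutoff, ``f`` =
fold factor, ``m`` = margin >= 1):

* ``tissue_enriched`` — non-target tissues draw baseline values; the target
  is set to ``m*f*max(others, c)``.
* ``group_enriched`` — a random group of ``group_min..group_max`` tissues
  containing the target is set uniformly to ``m*f*max(outsiders, c)``;
  equal member levels keep the target below 5-fold over its partners, so
  precedence cannot promote the gene to tissue-enriched.
* ``tissue_enhanced`` — the hardest class to plant: the gene must clear the
  fold rule against the overall mean while failing both the enriched and
  every group rule.  A ladder of ``group_max`` companion tissues is placed
  under the target at levels ``x_j * target`` chosen so each prefix group
  fails its dominance test by factor ``m`` while the companions stay light
  enough that the target still clears ``m*f*mean(all)`` (solved in closed
  form; infeasible parameter combinations raise a config error).
* ``expressed_in_all`` — every tissue uniform in ``[m*c, 2*m*c]``; ratios
  are bounded by 2, far below the fold factor.
* ``mixed`` — a random subset of tissues (including the target, larger
  than any allowed group and at least ``ceil(m*n/f)``) detected at a common
  level ``2*m*c``, the rest near zero; the detected count keeps the target
  below the enhanced rule and a detected tissue outside every group.
* ``not_detected_target`` — target below ``c/(2m)``, a random non-empty
  subset of others detected.
* ``not_detected_any`` — every tissue below ``c/(2m)``.

With ``noise_sigma = 0`` classification recovers the planted truth exactly
for any valid configuration; with the default noise the margin dominates
the replicate scatter and recovery stays near-perfect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .io import ExpressionMatrix, average_by_tissue
from .specificity import Category, ClassificationParams, GeneClassification

DEFAULT_GENES_PER_CATEGORY = {c.value: 100 for c in Category}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic matrix.

    Defaults mirror the multi-tissue design the classifier was built for:
    32 tissues, two replicates each, 100 genes planted per category, a 2x
    margin over every category threshold and 10% (log-normal sigma 0.1)
    replicate noise.  The baseline log-normal (natural-log mean 1.0,
    sd 1.0, median ~2.7 FPKM) represents ordinarily detected genes.
    """

    n_tissues: int = 32
    replicates_per_tissue: int = 2
    genes_per_category: dict = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CATEGORY)
    )
    margin: float = 2.0
    noise_sigma: float = 0.1
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    seed: int = 0
    target_tissue: str = "urinary_bladder"
    params: ClassificationParams = field(default_factory=ClassificationParams)

    def __post_init__(self):
        if self.n_tissues < 9:
            raise ConfigError("need n_tissues >= 9 so groups of 7 leave outsiders")
        if self.replicates_per_tissue < 1:
            raise ConfigError("need at least one replicate per tissue")
        if self.margin <= 1:
            raise ConfigError(
                "margin must be > 1: planted genes on the fail side of a "
                "rule (e.g. enhanced-but-not-enriched) would sit exactly on "
                "the non-strict thresholds at margin 1"
            )
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        unknown = set(self.genes_per_category) - {c.value for c in Category}
        if unknown:
            raise ConfigError(f"unknown categories: {sorted(unknown)}")
        # fail fast on constructions that cannot work at these settings
        if self.genes_per_category.get(Category.TISSUE_ENHANCED.value, 0) > 0:
            _enhanced_ladder(self.params, self.margin, self.n_tissues)
        if self.genes_per_category.get(Category.MIXED.value, 0) > 0:
            if _mixed_min_detected(self.params, self.margin, self.n_tissues) > self.n_tissues - 1:
                raise ConfigError(
                    "infeasible config: planted mixed genes need a detected "
                    "subset larger than any enriched group yet smaller than "
                    "all tissues; add tissues or lower the margin"
                )

    @property
    def tissues(self) -> list[str]:
        others = [f"tissue_{i:02d}" for i in range(2, self.n_tissues + 1)]
        return [self.target_tissue] + others


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted category (and group tissue set) per generated gene."""

    category: dict[str, Category]
    group_tissues: dict[str, frozenset[str]]


def _enhanced_ladder(params: ClassificationParams, margin: float, n_tissues: int):
    """Companion levels (fractions of the target) for planted enhanced genes.

    ``x_1 = m/f`` makes the enriched rule fail by factor ``m``; each further
    rung makes the size-(j+1) prefix group fail its dominance test by the
    same factor.  Returns (ladder, S) where S = 1 + sum(ladder).  Raises
    ConfigError when ``m*f*S >= n_tissues`` (the companions alone would push
    the overall mean too high for the enhanced rule to ever hold).
    """
    f = params.fold_factor
    r = f / margin
    if r <= 1:
        raise ConfigError("margin must be smaller than fold_factor")
    ladder = [1.0 / r]
    for j in range(2, params.group_max + 1):
        ladder.append((1.0 + sum(ladder)) / (j * r))
    s = 1.0 + sum(ladder)
    if margin * f * s >= n_tissues:
        raise ConfigError(
            "infeasible config: planted tissue_enhanced genes need "
            f"margin*fold_factor*{s:.2f} < n_tissues "
            f"({margin * f * s:.1f} >= {n_tissues}); lower the margin or "
            "fold factor, or add tissues"
        )
    return ladder, s


def _mixed_min_detected(params: ClassificationParams, margin: float, n: int) -> int:
    """Smallest detected-tissue count for a planted mixed gene.

    Large enough that (a) the target at the common detected level fails the
    enhanced rule by factor ``margin`` and (b) every allowed group leaves a
    detected tissue outside, so no group rule can fire.
    """
    return max(math.ceil(margin * n / params.fold_factor), params.group_max + 1, 2)


def generate(config: GeneratorConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Build a replicate-level FPKM matrix with planted category truth.

    Deterministic given ``config`` (including its seed): the same
    configuration always yields a byte-identical matrix.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    c = p.detection_cutoff
    f = p.fold_factor
    m = config.margin
    tissues = config.tissues
    n = config.n_tissues
    target_idx = 0
    low = c / (2.0 * m)  # "safely undetected" ceiling

    def baseline(size) -> np.ndarray:
        return rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size)

    profiles: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth_cat: dict[str, Category] = {}
    truth_group: dict[str, frozenset[str]] = {}
    counter = 0

    def plant(category: Category, prof: np.ndarray, group=frozenset()):
        nonlocal counter
        counter += 1
        gid = f"g{counter:05d}"
        gene_ids.append(gid)
        profiles.append(prof)
        truth_cat[gid] = category
        truth_group[gid] = frozenset(group)

    order = [c_.value for c_ in Category]
    for cat_name in order:
        cat = Category(cat_name)
        n_genes = int(config.genes_per_category.get(cat_name, 0))
        for _ in range(n_genes):
            prof = np.zeros(n)
            if cat is Category.NOT_DETECTED_ANY:
                prof = rng.uniform(0.0, low, n)
            elif cat is Category.NOT_DETECTED_TARGET:
                prof = rng.uniform(0.0, low, n)
                n_det = int(rng.integers(1, n))
                detected = rng.choice(np.arange(1, n), size=n_det, replace=False)
                prof[detected] = rng.uniform(m * c, 2 * m * c, n_det)
            elif cat is Category.TISSUE_ENRICHED:
                prof = np.concatenate(([0.0], baseline(n - 1)))
                prof[target_idx] = m * f * max(prof[1:].max(), c)
            elif cat is Category.GROUP_ENRICHED:
                size = int(rng.integers(p.group_min, p.group_max + 1))
                members = [target_idx] + list(
                    rng.choice(np.arange(1, n), size=size - 1, replace=False)
                )
                prof = np.concatenate(([0.0], baseline(n - 1)))
                outsiders = np.setdiff1d(np.arange(n), members)
                level = m * f * max(prof[outsiders].max(), c)
                prof[members] = level
                truth_set = frozenset(tissues[i] for i in members)
            elif cat is Category.TISSUE_ENHANCED:
                ladder, s = _enhanced_ladder(p, m, n)
                n_rest = n - 1 - len(ladder)
                rest = baseline(n_rest)
                # target solves T = m*f*(T*S + sum(rest))/n exactly, then
                # gets a further 2x headroom; scale up if below detection
                t_val = 2.0 * m * f * rest.sum() / (n - m * f * s)
                t_val = max(t_val, m * f * c)
                companions = np.array(ladder) * t_val
                values = np.concatenate(([t_val], companions, rest))
                # companions occupy random non-target slots
                perm = rng.permutation(np.arange(1, n))
                prof = np.empty(n)
                prof[target_idx] = t_val
                prof[perm] = values[1:]
            elif cat is Category.EXPRESSED_IN_ALL:
                # upper level bounded so max/mean stays below fold/margin
                upper = min(2.0, 0.5 * (1.0 + f / m))
                prof = rng.uniform(m * c, upper * m * c, n)
            elif cat is Category.MIXED:
                d_min = _mixed_min_detected(p, m, n)
                n_det = int(rng.integers(d_min, n))  # detected incl. target
                prof = rng.uniform(0.0, low, n)
                detected = [target_idx] + list(
                    rng.choice(np.arange(1, n), size=n_det - 1, replace=False)
                )
                prof[detected] = 2 * m * c
            if cat is Category.GROUP_ENRICHED:
                plant(cat, prof, truth_set)
            else:
                plant(cat, prof)

    means = np.vstack(profiles) if profiles else np.zeros((0, n))
    reps = config.replicates_per_tissue
    sample_ids = []
    sample_tissue = {}
    cols = []
    for j, t in enumerate(tissues):
        for r_i in range(1, reps + 1):
            sid = f"{t}_rep{r_i}"
            sample_ids.append(sid)
            sample_tissue[sid] = t
            if config.noise_sigma > 0:
                noise = np.exp(rng.normal(0.0, config.noise_sigma, means.shape[0]))
            else:
                noise = np.ones(means.shape[0])
            cols.append(means[:, j] * noise)
    values = pd.DataFrame(
        np.column_stack(cols) if cols else np.zeros((0, 0)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    matrix = ExpressionMatrix(values=values, sample_tissue=sample_tissue)
    return matrix, SyntheticTruth(category=truth_cat, group_tissues=truth_group)


def recovery_score(truth: SyntheticTruth, rows: list[GeneClassification]) -> float:
    """Fraction of genes whose assigned category matches the planted one.

    Group-enriched genes additionally require the recovered tissue set to
    equal the planted set.  Raises on a gene-id mismatch.
    """
    assigned = {r.gene_id: r for r in rows}
    if set(assigned) != set(truth.category):
        raise ConsistencyError("truth and classification cover different genes")
    if not truth.category:
        return 1.0
    hits = 0
    for gid, cat in truth.category.items():
        r = assigned[gid]
        if r.category is not cat:
            continue
        if cat is Category.GROUP_ENRICHED and r.group_tissues != truth.group_tissues[gid]:
            continue
        hits += 1
    return hits / len(truth.category)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the planted truth as TSV (gene_id, category, group_tissues)."""
    records = [
        {
            "gene_id": g,
            "category": truth.category[g].value,
            "group_tissues": ";".join(sorted(truth.group_tissues[g])),
        }
        for g in truth.category
    ]
    pd.DataFrame.from_records(
        records, columns=["gene_id", "category", "group_tissues"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cat = {r.gene_id: Category(r.category) for r in df.itertuples(index=False)}
    grp = {
        r.gene_id: frozenset(t for t in r.group_tissues.split(";") if t)
        for r in df.itertuples(index=False)
    }
    return SyntheticTruth(category=cat, group_tissues=grp)


def classify_synthetic(config: GeneratorConfig):
    """Convenience: generate, average replicates, classify; returns
    (matrix, truth, rows, recovery fraction)."""
    from .specificity import classify_all

    matrix, truth = generate(config)
    te = average_by_tissue(matrix)
    rows = classify_all(te, config.target_tissue, config.params)
    return matrix, truth, rows, recovery_score(truth, rows)
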