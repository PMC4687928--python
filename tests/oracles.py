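"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: plain loops,
exhaustive enumeration and textbook formulas, so agreement with the
implementation is meaningful.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exhaustive_group_qualifies(profile: dict, target: str, fold: float,
                               group_min: int, group_max: int):
    """All qualifying enriched groups by exhaustive subset enumeration.

    Returns the list of qualifying tissue sets (any size in
    ``group_min..group_max`` containing the target whose mean is at least
    ``fold`` times every outside tissue).
    """
    tissues = list(profile)
    others = [t for t in tissues if t != target]
    qualifying = []
    for size in range(group_min, min(group_max, len(tissues) - 1) + 1):
        for combo in combinations(others, size - 1):
            group = set(combo) | {target}
            outside = [profile[t] for t in tissues if t not in group]
            mean_in = sum(profile[t] for t in group) / size
            if mean_in >= fold * max(outside):
                qualifying.append(frozenset(group))
    return qualifying


def group_qualifies_in(group: frozenset, profile: dict, fold: float) -> bool:
    """Check one candidate group against the dominance rule directly."""
    outside = [v for t, v in profile.items() if t not in group]
    mean_in = sum(profile[t] for t in group) / len(group)
    return mean_in >= fold * max(outside)


def spearman_rank_then_pearson(x: np.ndarray) -> np.ndarray:
    """Spearman correlation as average ranks followed by Pearson."""
    ranks = np.column_stack([rankdata(x[:, j], method="average")
                             for j in range(x.shape[1])])
    return np.corrcoef(ranks, rowvar=False)


def mean_by_tissue_loops(values, sample_ids, sample_tissue):
    """Per-tissue arithmetic means with explicit loops (no pandas)."""
    tissues = sorted(set(sample_tissue.values()))
    out = np.zeros((values.shape[0], len(tissues)))
    for ti, tissue in enumerate(tissues):
        cols = [j for j, s in enumerate(sample_ids) if sample_tissue[s] == tissue]
        for gi in range(values.shape[0]):
            out[gi, ti] = sum(values[gi, j] for j in cols) / len(cols)
    return tissues, out
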