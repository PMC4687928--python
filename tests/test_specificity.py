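import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tspec import (
    Category,
    ClassificationParams,
    ConfigError,
    EnhancedBaseline,
    GeneClassification,
    TissueExpression,
    category_counts,
    category_percentages,
    classify_all,
    classify_gene,
    find_enriched_group,
    ts_score,
)
from conftest import FPKM_GRID, random_profile
from oracles import exhaustive_group_qualifies, group_qualifies_in


def profile(target_value, others, target="bladder"):
    names = [target] + [f"t{i:02d}" for i in range(1, len(others) + 1)]
    return pd.Series([target_value] + list(others), index=names)


class TestTsScore:
    def test_reconstructed_uroplakin_ratio(self, params):
        # bladder 54 FPKM against a ceiling of 1.4 elsewhere gives the
        # published-precision specificity ratio 38.6
        p = profile(54.0, [1.4] * 31)
        assert ts_score(p, "bladder", params) == pytest.approx(38.6, abs=0.05)

    def test_zero_numerator(self, params):
        assert ts_score(profile(0.0, [5.0, 2.0]), "bladder", params) == 0.0

    def test_denominator_floor(self, params):
        # all other tissues silent: denominator floored at 0.1 FPKM
        assert ts_score(profile(10.0, [0.0] * 8), "bladder", params) == 100.0

    def test_missing_target_is_key_error(self, params):
        with pytest.raises(KeyError):
            ts_score(profile(1.0, [1.0]), "liver", params)


class TestClassifyGene:
    def test_all_zero_profile_not_detected(self, params):
        r = classify_gene(profile(0.0, [0.0] * 31), "bladder", params)
        assert r.category is Category.NOT_DETECTED_ANY

    def test_undetected_target_with_detected_others(self, params):
        r = classify_gene(profile(0.5, [8.0] + [0.0] * 30), "bladder", params)
        assert r.category is Category.NOT_DETECTED_TARGET

    def test_enriched_when_fivefold_over_every_other_tissue(self, params):
        r = classify_gene(profile(54.0, [1.4] * 31), "bladder", params)
        assert r.category is Category.TISSUE_ENRICHED
        assert r.ts_score >= params.fold_factor

    def test_group_when_partner_blocks_enrichment(self, params):
        # target 20 with one tissue at 18: fails 5-fold alone, but the pair
        # mean 19 dominates the 0.5 background 5-fold
        p = profile(20.0, [18.0] + [0.5] * 30)
        r = classify_gene(p, "bladder", params)
        assert r.category is Category.GROUP_ENRICHED
        assert r.group_tissues == frozenset({"bladder", "t01"})
        assert group_qualifies_in(r.group_tissues, p.to_dict(), params.fold_factor)

    def test_enhanced_against_overall_mean(self, params):
        # ladder of mid-level tissues blocks enriched and every group rule
        others = [10.0, 7.0, 6.0, 5.0, 4.5, 4.2, 4.0] + [1.2] * 24
        r = classify_gene(profile(25.0, others), "bladder", params)
        assert r.category is Category.TISSUE_ENHANCED

    def test_enhanced_baseline_switch_changes_denominator(self):
        # others-mean 2.0, others-max 3.0: target 10.5 clears 5x the
        # others-mean but not 5x the all-tissues mean (~2.27)
        others = [3.0] * 15 + [1.0625] * 16
        p = profile(10.5, others)
        all_mean = ClassificationParams()
        other_mean = ClassificationParams(enhanced_baseline=EnhancedBaseline.OTHER_TISSUES)
        assert classify_gene(p, "bladder", all_mean).category is Category.EXPRESSED_IN_ALL
        assert classify_gene(p, "bladder", other_mean).category is Category.TISSUE_ENHANCED

    def test_expressed_in_all(self, params):
        r = classify_gene(profile(2.0, [1.5] * 31), "bladder", params)
        assert r.category is Category.EXPRESSED_IN_ALL

    def test_mixed(self, params):
        r = classify_gene(profile(2.0, [2.0] * 20 + [0.0] * 11), "bladder", params)
        assert r.category is Category.MIXED

    def test_exact_fold_boundary_counts_as_elevated(self, params):
        r = classify_gene(profile(5.0, [1.0] * 31), "bladder", params)
        assert r.category is Category.TISSUE_ENRICHED

    def test_detection_boundary_is_detected(self, params):
        r = classify_gene(profile(1.0, [0.0] * 31), "bladder", params)
        assert r.category is not Category.NOT_DETECTED_TARGET


class TestFindEnrichedGroup:
    def test_returns_smallest_qualifying_prefix(self, params):
        p = profile(26.0, [24.0] + [1.0] * 30)
        assert find_enriched_group(p, "bladder", params) == \
            frozenset({"bladder", "t01"})

    def test_precedence_lives_in_classify_not_here(self, params):
        # a solo-enriched target still yields a size-2 group when called
        # directly, because the pair dominates outsiders too
        p = profile(100.0, [1.0] * 31)
        assert find_enriched_group(p, "bladder", params) == \
            frozenset({"bladder", "t01"})

    def test_none_when_nothing_dominates(self, params):
        assert find_enriched_group(profile(2.0, [2.0] * 31), "bladder", params) is None

    def test_tied_target_not_pushed_out_of_prefix(self, params):
        # target ties a lexicographically-earlier tissue; the qualifying
        # 7-group must still be found
        p = pd.Series([1.0, 1.0] + [100.0] * 6 + [0.0, 0.0],
                      index=["z_bladder", "a_t"] + [f"big{i}" for i in range(6)]
                      + ["low1", "low2"])
        got = find_enriched_group(p, "z_bladder", params)
        assert got is not None and "z_bladder" in got
        assert group_qualifies_in(got, p.to_dict(), params.fold_factor)

    def test_agrees_with_exhaustive_enumeration(self, rng, params):
        """Prefix search and brute-force subset enumeration must agree on
        whether any qualifying group exists (2000 random grid profiles)."""
        for _ in range(2000):
            n = int(rng.integers(8, 11))
            p = random_profile(rng, n)
            if p["bladder"] < params.detection_cutoff:
                continue
            got = find_enriched_group(p, "bladder", params)
            brute = exhaustive_group_qualifies(
                p.to_dict(), "bladder", params.fold_factor,
                params.group_min, params.group_max)
            assert (got is not None) == bool(brute)
            if got is not None:
                assert group_qualifies_in(got, p.to_dict(), params.fold_factor)


class TestInvariantsAndProperties:
    def test_partition_exactly_one_category(self, rng, params):
        counts = {c: 0 for c in Category}
        for _ in range(1500):
            p = random_profile(rng, int(rng.integers(9, 13)))
            r = classify_gene(p, "bladder", params)
            counts[r.category] += 1
        assert sum(counts.values()) == 1500

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_target_fpkm(self, seed):
        """Raising only the target FPKM never demotes an elevated gene."""
        params = ClassificationParams()
        rng = np.random.default_rng(seed)
        p = random_profile(rng, 10)
        r = classify_gene(p, "bladder", params)
        if r.category.is_elevated:
            boosted = p.copy()
            boosted["bladder"] *= 1.0 + rng.uniform(0, 10)
            assert classify_gene(boosted, "bladder", params).category.is_elevated

    @given(st.integers(min_value=0, max_value=40).map(lambda k: 2.0**k))
    @settings(max_examples=41, deadline=None, derandomize=True)
    def test_scale_invariance_of_fold_decisions(self, scale):
        """Scaling all FPKM by c >= 1 (detection unchanged) keeps categories.

        Power-of-two scales keep the float arithmetic exact, so genes lying
        exactly on a fold boundary stay on it.
        """
        params = ClassificationParams()
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = random_profile(rng, 10, grid=FPKM_GRID[FPKM_GRID >= 1.0])
            before = classify_gene(p, "bladder", params)
            after = classify_gene(p * scale, "bladder", params)
            assert after.category is before.category
            assert after.group_tissues == before.group_tissues

    def test_ts_score_consistency_with_enriched_call(self, rng, params):
        """Away from the denominator floor, tissue_enriched <=> detected
        target with TS score >= fold factor ... unless a smaller group
        cannot exist (it can't: enriched is checked first)."""
        for _ in range(800):
            p = random_profile(rng, 10)
            if p.drop("bladder").max() <= params.ts_floor:
                continue  # floor active
            r = classify_gene(p, "bladder", params)
            enriched = (r.category is Category.TISSUE_ENRICHED)
            should = (p["bladder"] >= params.detection_cutoff
                      and r.ts_score >= params.fold_factor)
            assert enriched == should


class TestClassifyAll:
    def build_te(self, profiles):
        df = pd.DataFrame(profiles).T
        return TissueExpression(mean_fpkm=df)

    def test_one_gene_per_category(self, params):
        profiles = {
            "nd_any": profile(0.0, [0.0] * 31),
            "nd_target": profile(0.0, [10.0] + [0.0] * 30),
            "enriched": profile(100.0, [1.0] * 31),
            "grouped": profile(20.0, [18.0] + [0.5] * 30),
            "enhanced": profile(25.0, [10.0, 7.0, 6.0, 5.0, 4.5, 4.2, 4.0] + [1.2] * 24),
            "everywhere": profile(2.0, [1.5] * 31),
            "mixed": profile(2.0, [2.0] * 20 + [0.0] * 11),
        }
        te = self.build_te(profiles)
        rows = classify_all(te, "bladder", params)
        got = {r.gene_id: r.category for r in rows}
        assert got == {
            "nd_any": Category.NOT_DETECTED_ANY,
            "nd_target": Category.NOT_DETECTED_TARGET,
            "enriched": Category.TISSUE_ENRICHED,
            "grouped": Category.GROUP_ENRICHED,
            "enhanced": Category.TISSUE_ENHANCED,
            "everywhere": Category.EXPRESSED_IN_ALL,
            "mixed": Category.MIXED,
        }
        assert [r.gene_id for r in rows] == list(profiles)

    def test_empty_gene_list(self, params):
        te = TissueExpression(mean_fpkm=pd.DataFrame(
            columns=[f"t{i}" for i in range(10)], dtype=float))
        assert classify_all(te, "t0", params) == []

    def test_group_max_must_leave_outsiders(self):
        te = self.build_te({"g": profile(1.0, [1.0] * 6)})
        with pytest.raises(ConfigError):
            classify_all(te, "bladder", ClassificationParams(group_max=7))


def make_rows(cat_counts):
    rows = []
    i = 0
    for cat, n in cat_counts.items():
        for _ in range(n):
            group = (frozenset({"bladder", "esophagus"})
                     if cat is Category.GROUP_ENRICHED else frozenset())
            rows.append(GeneClassification(
                gene_id=f"g{i:05d}", category=cat, target_fpkm=1.0,
                ts_score=1.0, group_tissues=group))
            i += 1
    return rows


class TestCategoryCounts:
    def test_elevated_subcategories_sum(self):
        rows = make_rows({Category.TISSUE_ENRICHED: 1,
                          Category.GROUP_ENRICHED: 23,
                          Category.TISSUE_ENHANCED: 66})
        counts = category_counts(rows)
        assert counts["elevated_total"] == 90
        assert counts["total"] == 90

    def test_no_elevated_genes(self):
        counts = category_counts(make_rows({Category.NOT_DETECTED_ANY: 5}))
        assert counts["elevated_total"] == 0

    def test_matches_loop_tally(self, rng):
        cats = list(Category)
        rows = make_rows({c: int(rng.integers(0, 40)) for c in cats})
        counts = category_counts(rows)
        for c in cats:
            assert counts[c.value] == sum(1 for r in rows if r.category is c)
        assert counts["total"] == len(rows)


class TestCategoryPercentages:
    def test_rounding_matches_reporting_convention(self):
        counts = {
            "detected": 13914,
            "expressed_in_all": 8874,
            "mixed": 4954,
            "elevated_total": 90,
            "not_detected_target": 4594,
            "not_detected_any": 1832,
        }
        pct = category_percentages(counts, total=20344)
        assert pct == {
            "detected": 68.0,
            "expressed_in_all": 44.0,
            "mixed": 24.0,
            "elevated_total": 0.4,
            "not_detected_target": 23.0,
            "not_detected_any": 9.0,
        }

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            category_percentages({"mixed": 0}, total=0)
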