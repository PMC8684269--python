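"""Engineered features: srf filter, ICD roll-up, CCMU, windows, assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edlos.config import SrfParams
from edlos.features import (
    FeatureBuilder,
    FeatureSetError,
    activity_index,
    build_feature_matrix,
    concept_incidence,
    derive_stay_features,
    encode_ccmu,
    filter_relevant_concepts,
    label_long_stay,
    recent_visit_flag,
    rollup_icd10,
    srf_score,
)

from .oracles import brute_force_rollup


class TestLongStayLabel:
    @pytest.mark.parametrize("los,expected", [(7.0, 1), (6.9, 0), (2.1, 0), (30.0, 1)])
    def test_seven_day_threshold(self, los, expected):
        assert label_long_stay(los) == expected

    def test_nonpositive_los_rejected(self):
        with pytest.raises(ValueError):
            label_long_stay(0.0)

    def test_configurable_six_day_reading(self):
        assert label_long_stay(6.5, SrfParams(long_stay_threshold_days=6.0)) == 1


class TestSrf:
    def test_reference_value(self):
        assert round(srf_score(55, 45), 3) == 1.688

    def test_empty_counts_floor(self):
        assert srf_score(0, 0) == 1.0

    def test_strong_imbalance(self):
        assert srf_score(100, 1) == pytest.approx(math.log2(102))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            srf_score(-1, 3)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(0, 10_000), c=st.integers(0, 10_000))
    def test_symmetric_and_at_least_one(self, a, c):
        assert srf_score(a, c) == srf_score(c, a)
        assert srf_score(a, c) >= 1.0

    @settings(derandomize=True, max_examples=100)
    @given(a=st.integers(0, 1000), c=st.integers(0, 1000), bump=st.integers(1, 50))
    def test_nondecreasing_in_dominant_count(self, a, c, bump):
        hi = max(a, c)
        assert srf_score(hi + bump, min(a, c)) >= srf_score(hi, min(a, c))


class TestRelevanceFilter:
    def test_boundary_concept_is_non_relevant(self):
        # (55, 45) sits exactly at the 45% prevalence cutoff
        assert filter_relevant_concepts({"x": (55, 45)}) == set()

    def test_imbalanced_concept_kept(self):
        assert filter_relevant_concepts({"x": (90, 10)}) == {"x"}

    def test_balanced_concept_dropped(self):
        assert filter_relevant_concepts({"x": (50, 50)}) == set()

    def test_empty_incidence(self):
        assert filter_relevant_concepts({}) == set()

    def test_incidence_counts(self):
        concepts = {"s1": {"a", "b"}, "s2": {"a"}, "s3": {"b"}}
        labels = {"s1": 1, "s2": 0, "s3": 1}
        assert concept_incidence(concepts, labels) == {"a": (1, 1), "b": (2, 0)}


class TestIcdRollup:
    def test_worked_example_chain(self):
        mapping = rollup_icd10({"M6289": 3, "M628": 1, "M62": 0})
        assert mapping == {"M6289": "M62", "M628": "M62", "M62": "M62"}

    def test_frequent_code_unchanged(self):
        assert rollup_icd10({"J189": 212}) == {"J189": "J189"}

    def test_three_char_code_never_shortened(self):
        assert rollup_icd10({"A00": 1}) == {"A00": "A00"}

    def test_short_code_rejected(self):
        with pytest.raises(ValueError):
            rollup_icd10({"A0": 3})

    def test_child_counts_rescue_parent(self):
        # M6289 rolls into M628, whose pooled count then reaches 5
        mapping = rollup_icd10({"M6289": 4, "M628": 1})
        assert mapping == {"M6289": "M628", "M628": "M628"}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(23)
        letters = "ABCJKMRS"
        for _ in range(30):
            n_codes = int(rng.integers(2, 25))
            codes = set()
            while len(codes) < n_codes:
                code = rng.choice(list(letters)) + "".join(
                    str(d) for d in rng.integers(0, 10, size=int(rng.integers(2, 5)))
                )
                codes.add(code)
            counts = {c: int(rng.integers(0, 9)) for c in codes}
            mapping = rollup_icd10(counts)
            assert mapping == brute_force_rollup(counts)
            # postcondition sweep: pooled >= 5 or 3 characters
            pooled = {}
            for orig, cur in mapping.items():
                pooled[cur] = pooled.get(cur, 0) + counts[orig]
            assert all(n >= 5 or len(c) == 3 for c, n in pooled.items())


class TestCcmu:
    @pytest.mark.parametrize(
        "raw,expected", [("D", 6), ("P", 0), ("1", 1), ("3", 3), ("5", 5)]
    )
    def test_letter_and_digit_mapping(self, raw, expected):
        assert encode_ccmu(raw) == expected

    def test_illegal_symbol_rejected(self):
        with pytest.raises(ValueError):
            encode_ccmu("Q")


class TestRecentVisitFlag:
    ENTRY = pd.Timestamp("2019-03-10 08:00")

    def test_prior_visit_inside_window(self):
        assert recent_visit_flag(self.ENTRY, [self.ENTRY - pd.Timedelta(days=3)]) == 1

    def test_no_prior_visits(self):
        assert recent_visit_flag(self.ENTRY, []) == 0

    def test_prior_visit_outside_window(self):
        assert recent_visit_flag(self.ENTRY, [self.ENTRY - pd.Timedelta(days=8)]) == 0

    def test_window_is_half_open(self):
        assert recent_visit_flag(self.ENTRY, [self.ENTRY - pd.Timedelta(days=7)]) == 1

    def test_future_prior_rejected(self):
        with pytest.raises(ValueError):
            recent_visit_flag(self.ENTRY, [self.ENTRY + pd.Timedelta(hours=1)])


class TestActivityIndex:
    KS = np.arange(0, 100)  # d1 = 9.9, d9 = 89.1

    def test_below_first_decile_is_zero(self):
        assert activity_index([0], self.KS)[0] == 0.0

    def test_above_ninth_decile_is_one(self):
        assert activity_index([99], self.KS)[0] == 1.0

    def test_midpoint_interpolates_to_half(self):
        d1, d9 = np.quantile(self.KS, [0.1, 0.9])
        assert activity_index([(d1 + d9) / 2], self.KS)[0] == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        vals = activity_index(np.arange(-5, 110), self.KS)
        assert np.all(np.diff(vals) >= 0)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_degenerate_distribution_yields_half(self):
        assert np.all(activity_index([3, 5], np.full(20, 4)) == 0.5)


class TestDerivedStayColumns:
    def test_recent_visit_rate_matches_generator_target(self, stays_df, gen_config):
        rate = stays_df["recent_visit"].mean()
        assert abs(rate - gen_config.second_visit_rate) < 0.05

    def test_activity_index_spans_unit_interval(self, stays_df):
        assert stays_df["activity_index"].between(0, 1).all()


class TestFeatureAssembly:
    def test_common_set_has_no_diagnosis_or_concept_columns(self, stays_df, concepts_by_stay):
        m = build_feature_matrix(stays_df, concepts_by_stay, "common")
        assert not any(
            c.startswith(("icd10=", "gemsa=", "concept=")) or c == "ccmu"
            for c in m.column_names
        )

    def test_structured_icd_block_one_hot_per_row(self, stays_df, concepts_by_stay):
        m = build_feature_matrix(stays_df, concepts_by_stay, "structured")
        icd_cols = [i for i, c in enumerate(m.column_names) if c.startswith("icd10=")]
        assert icd_cols
        assert np.all(m.values[:, icd_cols].sum(axis=1) == 1)

    def test_unstructured_block_is_multi_hot(self, stays_df, concepts_by_stay):
        m = build_feature_matrix(stays_df, concepts_by_stay, "unstructured")
        cols = {c: i for i, c in enumerate(m.column_names)}
        concept_cols = [i for c, i in cols.items() if c.startswith("concept=")]
        assert concept_cols
        relevant = {c.split("=", 1)[1] for c in cols if c.startswith("concept=")}
        row = {sid: r for sid, r in zip(m.stay_ids, m.values)}
        for sid in m.stay_ids[:50]:
            expected = concepts_by_stay.get(sid, set()) & relevant
            hot = {
                c.split("=", 1)[1]
                for c, i in cols.items()
                if c.startswith("concept=") and row[sid][i] == 1
            }
            assert hot == expected

    def test_common_columns_identical_across_sets(self, stays_df, concepts_by_stay):
        mats = {
            fs: build_feature_matrix(stays_df, concepts_by_stay, fs)
            for fs in ("common", "structured", "unstructured")
        }
        common_cols = mats["common"].column_names
        for fs in ("structured", "unstructured"):
            idx = [mats[fs].column_names.index(c) for c in common_cols]
            assert np.array_equal(mats[fs].values[:, idx], mats["common"].values)

    def test_unseen_categories_encode_to_zero(self, stays_df, concepts_by_stay):
        builder = FeatureBuilder("structured").fit(stays_df)
        novel = stays_df.head(1).copy()
        novel.loc[:, "ward"] = "lunar medicine"
        novel.loc[:, "gemsa"] = 1
        m = builder.transform(novel)
        ward_cols = [i for i, c in enumerate(m.column_names) if c.startswith("ward=")]
        assert m.values[0, ward_cols].sum() == 0

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(FeatureSetError):
            FeatureBuilder("everything")

    def test_matrix_does_not_depend_on_test_labels(self, stays_df, concepts_by_stay):
        """Leakage check: shuffling held-out labels cannot change the matrix."""
        train = stays_df.iloc[:300].reset_index(drop=True)
        test = stays_df.iloc[300:].reset_index(drop=True)
        builder = FeatureBuilder("unstructured").fit(
            train, concepts_by_stay, train["long_stay"].to_numpy()
        )
        m1 = builder.transform(test, concepts_by_stay)
        shuffled = test.copy()
        shuffled["long_stay"] = np.random.default_rng(0).permutation(
            shuffled["long_stay"].to_numpy()
        )
        m2 = builder.transform(shuffled, concepts_by_stay)
        assert np.array_equal(m1.values, m2.values)
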