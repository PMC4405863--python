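import warnings

import pytest

from sbmlfeatures import (
    ExtractionConfig,
    FeatureSet,
    FixtureSpec,
    InputError,
    extract,
    method1_static,
    method2_topdown,
    method3_bottomup,
    method4_scored,
    score_T,
)
from sbmlfeatures.feature_extraction import short_id

from helpers import (
    chain_taxonomy,
    corpus_index,
    index_from_counts,
    perfect_binary,
    small_tree,
)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"method": 5}, {"method": 0}, {"max_features": 0}, {"min_df": -1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InputError):
            ExtractionConfig(**kwargs)


class TestMethod1:
    def test_perfect_binary_tree_budget_four(self):
        t = perfect_binary(3)  # 15 concepts
        fs = method1_static(t, ExtractionConfig(method=1, max_features=4))
        assert fs.ids == ["T:0004", "T:0005", "T:0006", "T:0007"]
        assert all(f.depth == 2 for f in fs.features)

    def test_budget_one_keeps_root(self):
        t = perfect_binary(3)
        fs = method1_static(t, ExtractionConfig(method=1, max_features=1))
        assert fs.ids == ["T:0001"]

    def test_chain_descends_fully(self):
        t = chain_taxonomy("T:r", "T:a", "T:b")
        fs = method1_static(t, ExtractionConfig(method=1, max_features=2))
        assert fs.ids == ["T:b"]

    def test_corpus_independent(self):
        t = perfect_binary(3)
        assert method1_static(t).ids == method1_static(t).ids


class TestMethod2:
    def test_features_follow_annotations_into_one_subtree(self):
        t = perfect_binary(3)
        # annotations only in the left root branch (T:0002 subtree)
        idx = index_from_counts(t, {"T:0008": 3, "T:0009": 2, "T:0005": 1})
        fs = method2_topdown(t, idx, ExtractionConfig(method=2, max_features=8))
        left = t.descendants("T:0002") | {"T:0002"}
        assert set(fs.ids) <= left
        assert all(f.ef > 0 for f in fs.features)

    def test_single_annotated_concept(self):
        t = perfect_binary(3)
        idx = index_from_counts(t, {"T:0013": 4})
        for budget in (1, 5, 15):
            fs = method2_topdown(
                t, idx, ExtractionConfig(method=2, max_features=budget))
            assert fs.ids == ["T:0013"]

    def test_uniform_leaf_annotations_reach_leaves(self):
        t = perfect_binary(2)  # leaves T:0004..T:0007
        idx = index_from_counts(
            t, {"T:0004": 1, "T:0005": 1, "T:0006": 1, "T:0007": 1})
        fs = method2_topdown(t, idx, ExtractionConfig(method=2, max_features=4))
        assert fs.ids == ["T:0004", "T:0005", "T:0006", "T:0007"]

    def test_annotated_internal_concept_is_retained_as_feature(self):
        t = chain_taxonomy("T:r", "T:x", "T:y")
        idx = index_from_counts(t, {"T:x": 2, "T:y": 1})
        fs = method2_topdown(t, idx, ExtractionConfig(method=2, max_features=5))
        assert fs.ids == ["T:x", "T:y"]

    def test_empty_index_warns_and_returns_empty(self):
        t = small_tree()
        idx = index_from_counts(t, {})
        with pytest.warns(UserWarning, match="empty"):
            fs = method2_topdown(t, idx)
        assert len(fs) == 0


class TestMethod3:
    def test_no_merging_needed_is_identity(self):
        t = perfect_binary(3)
        idx = index_from_counts(t, {"T:0009": 2, "T:0013": 1})
        fs = method3_bottomup(t, idx, ExtractionConfig(method=3, max_features=5))
        assert fs.ids == ["T:0009", "T:0013"]

    def test_two_siblings_merge_into_parent(self):
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 2, "T:b": 1})
        fs = method3_bottomup(t, idx, ExtractionConfig(method=3, max_features=1))
        assert fs.ids == ["T:p"]


class TestScore:
    def test_root_scores_zero(self):
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 5})
        assert score_T(t, idx, "T:r") == 0.0

    def test_leaf_score_is_ic_times_ef(self):
        t = small_tree()  # N=4, ic(T:a) = -log2(1/4) = 2
        idx = index_from_counts(t, {"T:a": 5})
        assert score_T(t, idx, "T:a") == pytest.approx(10.0)

    def test_unannotated_concept_scores_zero(self):
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 5})
        assert score_T(t, idx, "T:b") == 0.0


class TestMethod4:
    def test_representatives_balance_support_and_specificity(self):
        # score table: a=2*5=10, b=2*1=2, p=log2(4/3)^-..*6~2.49, r=0
        t = small_tree()
        idx = index_from_counts(t, {"T:a": 5, "T:b": 1})
        fs = method4_scored(t, idx, ExtractionConfig(method=4, max_features=15))
        assert fs.ids == ["T:a", "T:p"]

    def test_single_deep_concept_represents_itself(self):
        t = chain_taxonomy("T:r", "T:a", "T:b", "T:c")
        idx = index_from_counts(t, {"T:c": 3})
        fs = method4_scored(t, idx)
        assert fs.ids == ["T:c"]

    def test_empty_index_gives_empty_set(self):
        t = small_tree()
        fs = method4_scored(t, index_from_counts(t, {}))
        assert len(fs) == 0


class TestSharedProperties:
    @pytest.mark.parametrize("method", [1, 2, 3, 4])
    @pytest.mark.parametrize("budget", [1, 5, 15])
    def test_budget_respected_and_deterministic(
            self, study_taxonomy, method, budget):
        t = study_taxonomy
        idx = corpus_index(t, FixtureSpec(seed=21))
        cfg = ExtractionConfig(method=method, max_features=budget)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs1 = extract(t, idx, cfg)
            fs2 = extract(t, idx, cfg)
        assert len(fs1) <= budget
        assert fs1.ids == fs2.ids
        if method != 1:
            assert all(f.ef > 0 for f in fs1.features)

    @pytest.mark.parametrize("method", [2, 3, 4])
    def test_every_annotated_concept_is_covered(self, study_taxonomy, method):
        """Each directly annotated concept descends from (or is) a feature."""
        t = study_taxonomy
        idx = corpus_index(t, FixtureSpec(seed=33))
        fs = extract(t, idx, ExtractionConfig(method=method, max_features=15))
        feature_ids = set(fs.ids)
        for cid in idx.annotated_concepts():
            assert t.ancestors(cid) & feature_ids, cid

    def test_topdown_equals_bottomup_without_ties(self, study_taxonomy):
        t = study_taxonomy
        for seed in range(20):
            idx = corpus_index(t, FixtureSpec(seed=400 + seed))
            f2 = method2_topdown(t, idx, ExtractionConfig(method=2, max_features=15))
            f3 = method3_bottomup(t, idx, ExtractionConfig(method=3, max_features=15))
            if not (f2.tied or f3.tied):
                assert f2.ids == f3.ids


class TestSerialization:
    def test_short_ids_match_table_convention(self):
        assert short_id("SBO:0000064") == "064"
        assert short_id("GO:0051234") == "51234"

    def test_feature_set_json_roundtrip(self, study_taxonomy):
        t = study_taxonomy
        idx = corpus_index(t, FixtureSpec(seed=2))
        fs = method4_scored(t, idx)
        back = FeatureSet.from_dict(fs.to_dict())
        assert back.ids == fs.ids
        assert back.average_depth == fs.average_depth
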