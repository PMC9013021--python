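import json

import numpy as np
import pytest

from riskpattern.discovery import DiscoveryConfig, discover_pattern
from riskpattern.errors import EditError
from riskpattern.knowledge import PatternEdit, apply_in_mode, apply_post_mode
from riskpattern.pattern import Condition, Pattern, deserialize, serialize

from conftest import make_table


@pytest.fixture
def train():
    rng = np.random.default_rng(42)
    n = 500
    age = rng.normal(64, 11, n)
    contrast = rng.normal(135, 70, n)
    urgent = rng.choice(["Yes", "No"], n, p=[0.15, 0.85])
    risk = 0.02 + 0.25 * ((age > 70) & (contrast > 150)) + 0.15 * (urgent == "Yes")
    label = rng.random(n) < risk
    return make_table(
        {"age": age.tolist(), "contrast_volume": contrast.tolist(),
         "urgent_pci": urgent.tolist()},
        label.astype(int).tolist(),
        target_name="AKI",
    )


@pytest.fixture
def pre_pattern(train):
    return discover_pattern(train, DiscoveryConfig(), timestamp=None)


class TestInMode:
    def test_comparator_flip_preserves_variable_set(self, pre_pattern, train):
        assert "age" in pre_pattern.variables()
        edits = [PatternEdit("set_comparator", "age", ">")]
        updated, metrics = apply_in_mode(pre_pattern, edits, train, timestamp=None)
        assert set(updated.variables()) == set(pre_pattern.variables())
        assert updated.condition_for("age").comparator == ">"
        assert updated.condition_for("age").value == pre_pattern.condition_for(
            "age").value
        assert updated.mode_tag == "in"
        assert 1 <= updated.min_matches <= updated.m
        assert metrics.f_score >= 0.0

    def test_untouched_conditions_identical(self, pre_pattern, train):
        edits = [PatternEdit("set_comparator", "age", ">")]
        updated, _ = apply_in_mode(pre_pattern, edits, train, timestamp=None)
        for c in pre_pattern.conditions:
            if c.variable != "age":
                assert updated.condition_for(c.variable) == c

    def test_empty_edit_list_is_noop_with_history(self, pre_pattern, train):
        updated, _ = apply_in_mode(pre_pattern, [], train, timestamp=None)
        assert updated.conditions == pre_pattern.conditions
        assert updated.min_matches == pre_pattern.min_matches
        assert len(updated.history) == len(pre_pattern.history) + 1

    def test_categorical_value_on_numeric_variable_rejected(self, pre_pattern, train):
        edits = [PatternEdit("add_variable", "contrast_volume",
                             {"comparator": "==", "value": "high"})]
        if "contrast_volume" in pre_pattern.variables():
            edits = [PatternEdit("set_value", "contrast_volume", "high")]
        with pytest.raises(EditError):
            apply_in_mode(pre_pattern, edits, train, timestamp=None)

    def test_set_min_matches_rejected_in_mode(self, pre_pattern, train):
        with pytest.raises(EditError, match="post-mode"):
            apply_in_mode(
                pre_pattern, [PatternEdit("set_min_matches", payload=1)],
                train, timestamp=None,
            )

    def test_unknown_variable_rejected(self, pre_pattern, train):
        with pytest.raises(EditError, match="unknown"):
            apply_in_mode(
                pre_pattern, [PatternEdit("set_value", "bogus", 1.0)],
                train, timestamp=None,
            )

    def test_add_variable_pulls_cutoff_from_train(self, pre_pattern, train):
        missing = [v for v in ("age", "contrast_volume", "urgent_pci")
                   if v not in pre_pattern.variables()]
        if not missing:
            pytest.skip("discovery already used every variable")
        var = missing[0]
        updated, _ = apply_in_mode(
            pre_pattern, [PatternEdit("add_variable", var)], train, timestamp=None
        )
        assert var in updated.variables()


class TestPostMode:
    def test_value_overrides_keep_threshold(self, pre_pattern):
        edits = [PatternEdit("set_value", "age", 70.0),
                 PatternEdit("set_comparator", "age", ">")]
        updated = apply_post_mode(pre_pattern, edits, timestamp=None)
        assert updated.condition_for("age") == Condition("age", ">", 70.0)
        assert updated.min_matches == pre_pattern.min_matches
        assert updated.mode_tag == "post"

    def test_runs_without_any_cohort(self):
        # pure function of (pattern, edits): no data in scope at all
        pat = Pattern("AKI", "Yes",
                      [Condition("age", ">", 58.5),
                       Condition("contrast_volume", ">", 79.5)], 1)
        updated = apply_post_mode(
            pat,
            [PatternEdit("set_value", "age", 70.0),
             PatternEdit("set_value", "contrast_volume", 100.0)],
            timestamp=None,
        )
        assert updated.condition_for("age").value == 70.0
        assert updated.condition_for("contrast_volume").value == 100.0
        assert updated.min_matches == pat.min_matches

    def test_threshold_above_m_rejected(self, pre_pattern):
        with pytest.raises(EditError):
            apply_post_mode(
                pre_pattern,
                [PatternEdit("set_min_matches", payload=pre_pattern.m + 1)],
                timestamp=None,
            )

    def test_set_min_matches_applied_verbatim(self, pre_pattern):
        updated = apply_post_mode(
            pre_pattern, [PatternEdit("set_min_matches", payload=pre_pattern.m)],
            timestamp=None,
        )
        assert updated.min_matches == updated.m

    def test_serialization_roundtrip_with_history(self, pre_pattern):
        updated = apply_post_mode(
            pre_pattern, [PatternEdit("set_value", "age", 70.0)], timestamp=None
        )
        back = deserialize(json.loads(json.dumps(serialize(updated))))
        assert back == updated
        assert [h.mode for h in back.history] == ["pre", "post"]


class TestHistoryReplay:
    def test_history_grows_one_entry_per_apply(self, pre_pattern, train):
        p1, _ = apply_in_mode(
            pre_pattern, [PatternEdit("set_comparator", "age", ">")], train,
            timestamp=None,
        )
        p2 = apply_post_mode(
            p1, [PatternEdit("set_value", "age", 70.0)], timestamp=None
        )
        assert [h.mode for h in p2.history] == ["pre", "in", "post"]

    def test_replaying_history_reconstructs_final_pattern(self, pre_pattern, train):
        p1, _ = apply_in_mode(
            pre_pattern, [PatternEdit("set_comparator", "age", ">")], train,
            timestamp=None,
        )
        final = apply_post_mode(
            p1, [PatternEdit("set_value", "age", 70.0),
                 PatternEdit("set_min_matches", payload=p1.min_matches)],
            timestamp=None,
        )
        # replay: start from the discovery output and re-apply each
        # recorded edit list in its recorded mode
        replayed = pre_pattern
        for entry in final.history[1:]:
            edits = [PatternEdit.from_dict(e) for e in entry.edits]
            if entry.mode == "in":
                replayed, _ = apply_in_mode(replayed, edits, train, timestamp=None)
            else:
                replayed = apply_post_mode(replayed, edits, timestamp=None)
        assert replayed.conditions == final.conditions
        assert replayed.min_matches == final.min_matches
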