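"""Weight learning: class-anchored averages, error, updates, training loop."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdemap import (
    CDECorpus,
    CDEMapper,
    DegenerateInputError,
    SimilarityWeights,
    TrainingConfig,
    ValidationError,
    ConfigurationError,
    SyntheticConfig,
    generate_corpus,
    other_class_avg,
    train,
    training_error,
    update_weights,
    within_class_avg,
)
from cdemap.model import TrainingState

from conftest import make_record

W1 = SimilarityWeights((1, 0, 0, 0, 0, 0))  # overall similarity == s1 (long name)
THR = 0.9


def ln_record(pid, long_name, cls="C"):
    """Record whose only populated attribute is the long name."""
    return make_record(pid, long_name=long_name, mapped_class=cls)


# With weights W1 and threshold 0.9, the overall similarity of two records
# is the fraction of greedily matched long-name tokens — exact fractions
# can be read off the shared-token counts.


def test_within_class_avg_hand_case():
    anchor = ln_record("a", "p q r s t")
    b = ln_record("b", "p q r s x")  # 4/5 tokens match -> 0.8
    c = ln_record("c", "p q r x y")  # 3/5 -> 0.6
    assert within_class_avg(anchor, [anchor, b, c], W1, THR) == pytest.approx(0.7)


def test_within_class_avg_excludes_anchor():
    anchor = ln_record("a", "p q r s t")
    b = ln_record("b", "p q x y z")  # 2/5 -> 0.4
    # the anchor's self-similarity of 1.0 must not enter the average
    assert within_class_avg(anchor, [anchor, b], W1, THR) == pytest.approx(0.4)


def test_within_class_avg_identical_pair_is_one():
    a = ln_record("a", "p q")
    b = ln_record("b", "p q")
    assert within_class_avg(a, [a, b], W1, THR) == 1.0


def test_within_class_avg_singleton_errors():
    a = ln_record("a", "p q")
    with pytest.raises(DegenerateInputError):
        within_class_avg(a, [a], W1, THR)


def test_other_class_avg_hand_cases():
    anchor = ln_record("a", "p q r s t", cls="A")
    outs = [
        ln_record("o1", "p x y z w", cls="B"),   # 1/5 -> 0.2
        ln_record("o2", "p q x y z", cls="B"),   # 2/5 -> 0.4
        ln_record("o3", "p q r x y", cls="C"),   # 3/5 -> 0.6
    ]
    corpus = CDECorpus([anchor] + outs)
    assert other_class_avg(anchor, corpus, "A", W1, THR) == pytest.approx(0.4)
    # single outside record
    corpus2 = CDECorpus([anchor, outs[0]])
    assert other_class_avg(anchor, corpus2, "A", W1, THR) == pytest.approx(0.2)


def test_other_class_avg_ignores_own_class_members():
    anchor = ln_record("a", "p q r s t", cls="A")
    peer = ln_record("p", "p q r s t", cls="A")
    out = ln_record("o", "p q x y z", cls="B")
    c1 = CDECorpus([anchor, peer, out])
    c2 = CDECorpus([anchor, replace(peer, long_name="totally different words"), out])
    assert other_class_avg(anchor, c1, "A", W1, THR) == other_class_avg(
        anchor, c2, "A", W1, THR
    )


def test_other_class_avg_no_outside_records_errors():
    anchor = ln_record("a", "p q", cls="A")
    peer = ln_record("b", "p q", cls="A")
    with pytest.raises(DegenerateInputError):
        other_class_avg(anchor, CDECorpus([anchor, peer]), "A", W1, THR)


# ---------------------------------------------------------------------------
# error and update rule


@pytest.mark.parametrize(
    "s_avg, s_other, expected",
    [(0.7, 0.5, 0.0), (0.4, 0.6, 0.02), (0.3, 0.3, 0.0), (0.0, 1.0, 0.5)],
)
def test_training_error_cases(s_avg, s_other, expected):
    assert training_error(s_avg, s_other) == pytest.approx(expected)


def test_training_state_invariants():
    state = TrainingState(SimilarityWeights.uniform(), s_avg=0.4,
                          s_avg_other_cls=0.6, iteration=3)
    assert state.s_max == 0.6
    assert state.error == pytest.approx(0.02)
    dominant = TrainingState(SimilarityWeights.uniform(), s_avg=0.7,
                             s_avg_other_cls=0.5, iteration=0)
    assert dominant.error == 0.0


def test_update_no_op_when_own_class_dominates():
    w = SimilarityWeights((0.3, 0.2, 0.1, 0.1, 0.1, 0.2))
    assert update_weights(w, 0.7, 0.5, [1, 1, 1, 1, 1, 1], eta=0.05) == w


def test_update_hand_computation():
    w = update_weights(
        SimilarityWeights.uniform(), 0.4, 0.6, [1, 0, 0, 0, 0, 0], eta=0.05
    )
    # raw step: w1 -> 1/6 + 0.05*0.2*1 = 0.1766..; total 1.01; renormalise
    assert w.values[0] == pytest.approx((1 / 6 + 0.01) / 1.01)
    for v in w.values[1:]:
        assert v == pytest.approx((1 / 6) / 1.01)
    assert w.values[0] == pytest.approx(0.17492, abs=1e-5)
    assert w.values[1] == pytest.approx(0.16502, abs=1e-5)


def test_update_uniform_mean_attr_preserves_relative_weights():
    w0 = SimilarityWeights((0.4, 0.2, 0.1, 0.1, 0.1, 0.1))
    w1 = update_weights(w0, 0.3, 0.8, [0.5] * 6, eta=0.05)
    # adding the same amount everywhere then renormalising keeps order
    assert np.argmax(w1.as_array()) == 0
    ratios = w1.as_array() / w0.as_array()
    assert ratios.std() < ratios.mean()  # no component singled out


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(0.01, 1), min_size=6, max_size=6),
    st.floats(0, 1),
    st.floats(0, 1),
    st.lists(st.floats(0, 1), min_size=6, max_size=6),
)
def test_update_preserves_simplex(raw, s_avg, s_other, mean_attr):
    arr = np.array(raw) / np.sum(raw)
    w = SimilarityWeights.from_array(arr)
    out = update_weights(w, s_avg, s_other, mean_attr, eta=0.05)
    assert abs(sum(out.values) - 1.0) <= 1e-9
    assert all(v >= 0 for v in out.values)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 1), min_size=6, max_size=6))
def test_update_directionality(mean_attr):
    # when an update fires, the largest mean-attribute component gains
    # relative weight and the smallest loses
    w0 = SimilarityWeights.uniform()
    w1 = update_weights(w0, 0.2, 0.8, mean_attr, eta=0.05)
    hi, lo = int(np.argmax(mean_attr)), int(np.argmin(mean_attr))
    if mean_attr[hi] > mean_attr[lo]:
        assert w1.values[hi] > w0.values[hi] - 1e-12
        assert w1.values[lo] < w0.values[lo] + 1e-12


# ---------------------------------------------------------------------------
# the training loop


def test_train_zero_error_fixed_point(tiny_labeled_corpus):
    results = train(tiny_labeled_corpus, TrainingConfig(min_class_size=2))
    assert results.weights == SimilarityWeights.uniform()
    assert all(e == 0.0 for e in results.training_log)
    assert results.converged


def test_train_rejects_unmapped_records(tiny_labeled_corpus):
    records = list(tiny_labeled_corpus.records) + [make_record("stray")]
    with pytest.raises(ValidationError):
        train(CDECorpus(records), TrainingConfig(min_class_size=2))


def test_train_rejects_single_class():
    records = [make_record(f"r{i}", long_name="x", mapped_class="A") for i in range(4)]
    with pytest.raises(DegenerateInputError):
        train(CDECorpus(records), TrainingConfig(min_class_size=2))


def test_train_rejects_singleton_class(tiny_labeled_corpus):
    records = list(tiny_labeled_corpus.records) + [
        make_record("solo", long_name="z", mapped_class="Solo")
    ]
    with pytest.raises(ValidationError):
        train(CDECorpus(records), TrainingConfig(min_class_size=2))


def test_training_config_validation():
    with pytest.raises(ConfigurationError):
        TrainingConfig(eta=0)
    with pytest.raises(ConfigurationError):
        TrainingConfig(max_iterations=0)
    with pytest.raises(ConfigurationError):
        TrainingConfig(anchor_mode="middle")


def test_class_order_ascending_by_size_ties_lexicographic():
    records = []
    for cls, n in [("Bigger", 4), ("Tie2", 2), ("Tie1", 2)]:
        for i in range(n):
            records.append(make_record(f"{cls}{i}", long_name=cls.lower(), mapped_class=cls))
    mapper = CDEMapper(CDECorpus(records), TrainingConfig(min_class_size=2))
    assert mapper.class_order == ("Tie1", "Tie2", "Bigger")


def test_train_weights_on_simplex_and_deterministic():
    corpus = generate_corpus(
        SyntheticConfig(n_classes=5, members_per_class=6, overlap_fraction=0.6,
                        typo_rate=0.2, seed=9)
    )
    cfg = TrainingConfig(min_class_size=2, seed=9)
    r1 = train(corpus, cfg)
    r2 = train(corpus, cfg)
    assert r1.weights == r2.weights  # bit-identical
    assert abs(sum(r1.weights.values) - 1.0) <= 1e-9
    assert all(v >= 0 for v in r1.weights.values)
    assert all(np.isfinite(e) and e >= 0 for e in r1.training_log)
    assert r1.n_iterations <= cfg.max_iterations


def test_train_anchor_mode_first_runs_and_differs_in_cost():
    corpus = generate_corpus(
        SyntheticConfig(n_classes=4, members_per_class=6, overlap_fraction=0.7,
                        typo_rate=0.2, seed=3)
    )
    r_first = train(corpus, TrainingConfig(min_class_size=2, anchor_mode="first"))
    assert abs(sum(r_first.weights.values) - 1.0) <= 1e-9


def test_parameter_recovery_property_attribute():
    # only attribute 3 (property) uses class vocabulary; training must
    # concentrate weight there
    corpus = generate_corpus(
        SyntheticConfig(n_classes=6, members_per_class=10, vocab_size_per_class=8,
                        overlap_fraction=0.5, typo_rate=0.1,
                        informative_attribute=3, seed=4)
    )
    results = train(corpus, TrainingConfig(min_class_size=2, seed=4))
    w = np.array(results.weights.values)
    assert w[2] > max(np.delete(w, 2))


def test_from_dataframe_constructor(tiny_labeled_corpus, tmp_path):
    import pandas as pd
    from cdemap import write_corpus

    path = tmp_path / "c.csv"
    write_corpus(tiny_labeled_corpus, path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapper = CDEMapper.from_dataframe(df, TrainingConfig(min_class_size=2))
    assert mapper.corpus == tiny_labeled_corpus


def test_results_persistence_round_trip(tiny_labeled_corpus, tmp_path):
    results = train(tiny_labeled_corpus, TrainingConfig(min_class_size=2))
    path = tmp_path / "model.json"
    results.save(path)
    back = type(results).load(path)
    assert back.weights == results.weights
    assert back.threshold == results.threshold
    assert back.config == results.config
    assert back.training_log == results.training_log
    assert set(back.class_members) == set(results.class_members)
    for cls in results.class_members:
        assert back.class_members[cls] == results.class_members[cls]


def test_load_rejects_off_simplex_weights(tiny_labeled_corpus, tmp_path):
    import json

    results = train(tiny_labeled_corpus, TrainingConfig(min_class_size=2))
    path = tmp_path / "model.json"
    results.save(path)
    doc = json.loads(path.read_text())
    doc["weights"]["w1"] = 0.9
    path.write_text(json.dumps(doc))
    with pytest.raises(ConfigurationError):
        type(results).load(path)


def test_summary_mentions_weights_and_iterations(tiny_labeled_corpus):
    results = train(tiny_labeled_corpus, TrainingConfig(min_class_size=2))
    text = results.summary()
    assert "Question Text" in text
    assert "iterations run" in text
    assert f"{results.weights.values[5]:.9f}" in text
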