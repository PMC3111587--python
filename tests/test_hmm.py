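"""HMM training, smoothing and path scoring."""

import json
import math
import io

import pytest

from tokenlattice import (
    BOS,
    CorpusFormatError,
    HmmModel,
    TagSet,
    emission_logprob,
    load_model,
    parse_slash_corpus,
    save_model,
    score_path,
    train,
    transition_logprob,
)
from tokenlattice.hmm import format_slash_corpus, tag_logprob

TINY = [[("a", "DT"), ("dog", "NN")]]
TWO_TAGS = TagSet(tags=frozenset({"DT", "NN"}))


def test_single_event_mle():
    model = train(TINY, order=1, alpha=0.0, tagset=TWO_TAGS)
    assert math.isclose(transition_logprob(model, "DT", "NN"), 0.0)
    assert math.isclose(emission_logprob(model, "dog", "NN"), 0.0)
    assert math.isclose(transition_logprob(model, BOS, "DT"), 0.0)


def test_laplace_emission_hand_computed():
    # vocab {a, dog} plus the unknown bucket => vocab_size 3;
    # P(dog|NN) = (count+alpha)/(count(NN)+alpha*vocab_size) = (1+1)/(1+3)
    model = train(TINY, order=1, alpha=1.0, tagset=TWO_TAGS)
    assert model.vocab_size == 3
    expected = (1 + 1) / (1 + 1 * 3)
    assert math.isclose(emission_logprob(model, "dog", "NN"), math.log(expected))
    # all unseen tokens share one smoothed value given the tag
    u1 = emission_logprob(model, "zzz", "NN")
    u2 = emission_logprob(model, "qqq", "NN")
    assert math.isclose(u1, u2)
    assert u1 < emission_logprob(model, "dog", "NN")


def test_unseen_pair_is_impossible_without_smoothing():
    model = train(TINY, order=1, alpha=0.0, tagset=TWO_TAGS)
    assert emission_logprob(model, "zzz", "NN") == float("-inf")
    assert emission_logprob(model, "dog", "DT") == float("-inf")


def test_corpus_concatenation_leaves_mle_unchanged():
    base = [[("a", "DT"), ("dog", "NN")], [("the", "DT"), ("cat", "NN")]]
    m1 = train(base, order=1, alpha=0.0, tagset=TWO_TAGS)
    m2 = train(base * 3, order=1, alpha=0.0, tagset=TWO_TAGS)
    for prev, tag in [(BOS, "DT"), ("DT", "NN")]:
        assert math.isclose(
            transition_logprob(m1, prev, tag), transition_logprob(m2, prev, tag)
        )
    for tok, tag in [("dog", "NN"), ("the", "DT")]:
        assert math.isclose(
            emission_logprob(m1, tok, tag), emission_logprob(m2, tok, tag)
        )


@pytest.mark.parametrize("alpha", [0.1, 1.0])
@pytest.mark.parametrize("kind", ["emission", "transition", "prior"])
def test_conditional_distributions_normalize(fixture_model, alpha, kind):
    """Each smoothed conditional distribution sums to 1 (within 1e-9)."""
    corpus = [[("a", "DT"), ("dog", "NN")], [("dog", "NN"), ("runs", "VB")]]
    model = train(corpus, order=1, alpha=alpha,
                  tagset=TagSet(tags=frozenset({"DT", "NN", "VB"})))
    if kind == "emission":
        # sum over seen types plus the unknown bucket
        for tag in model.tag_counts:
            total = sum(
                math.exp(emission_logprob(model, tok, tag)) for tok in model.vocab
            ) + math.exp(emission_logprob(model, "<unseen>", tag))
            assert math.isclose(total, 1.0, abs_tol=1e-9)
    elif kind == "transition":
        for prev in [BOS, *model.tagset.tags]:
            total = sum(
                math.exp(transition_logprob(model, prev, tag))
                for tag in model.tagset.tags
            )
            assert math.isclose(total, 1.0, abs_tol=1e-9)
    else:
        total = sum(math.exp(tag_logprob(model, tag)) for tag in model.tagset.tags)
        assert math.isclose(total, 1.0, abs_tol=1e-9)


def test_monotone_data_never_decreases_seen_emission():
    base = [[("a", "DT"), ("dog", "NN"), ("cat", "NN")]]
    more = base + [[("dog", "NN")]]
    m1 = train(base, order=1, alpha=0.0, tagset=TWO_TAGS)
    m2 = train(more, order=1, alpha=0.0, tagset=TWO_TAGS)
    assert emission_logprob(m2, "dog", "NN") >= emission_logprob(m1, "dog", "NN")


def test_score_path_decomposition():
    """Order-1 score equals the sum of its printed components."""
    corpus = [[("a", "DT"), ("dog", "NN"), ("runs", "VB")]]
    model = train(corpus, order=1, alpha=0.1,
                  tagset=TagSet(tags=frozenset({"DT", "NN", "VB"})))
    path = [("a", "DT"), ("dog", "NN"), ("runs", "VB")]
    expected = (
        transition_logprob(model, BOS, "DT") + emission_logprob(model, "a", "DT")
        + transition_logprob(model, "DT", "NN") + emission_logprob(model, "dog", "NN")
        + transition_logprob(model, "NN", "VB") + emission_logprob(model, "runs", "VB")
    )
    assert math.isclose(score_path(model, path), expected)


def test_order0_score_is_permutation_invariant():
    corpus = [[("a", "DT"), ("dog", "NN"), ("runs", "VB")]]
    model = train(corpus, order=0, alpha=0.1,
                  tagset=TagSet(tags=frozenset({"DT", "NN", "VB"})))
    path = [("a", "DT"), ("dog", "NN"), ("runs", "VB")]
    reversed_path = list(reversed(path))
    assert math.isclose(score_path(model, path), score_path(model, reversed_path))
    # the order-1 score is not
    m1 = train(corpus, order=1, alpha=0.1,
               tagset=TagSet(tags=frozenset({"DT", "NN", "VB"})))
    assert not math.isclose(score_path(m1, path), score_path(m1, reversed_path))


def test_train_rejects_bad_input():
    with pytest.raises(ValueError):
        train([], order=1)
    with pytest.raises(ValueError):
        train([[]], order=1)
    with pytest.raises(ValueError):
        train([[("", "NN")]], order=1)
    with pytest.raises(ValueError):
        train(TINY, order=2)
    with pytest.raises(ValueError):
        train(TINY, alpha=-1.0)


def test_slash_corpus_round_trip_and_errors():
    text = "The/DT patient/NN 's/POS\nPrimidone/NNP 1/2/CD\n"
    corpus = parse_slash_corpus(text.splitlines())
    assert corpus[0][2] == ("'s", "POS")
    assert corpus[1][1] == ("1/2", "CD")  # last slash separates the tag
    assert format_slash_corpus(corpus) == text
    with pytest.raises(CorpusFormatError, match="line 2"):
        parse_slash_corpus(["ok/DT", "token-without-slash"])


def test_model_json_round_trip(fixture_model):
    buf = io.StringIO()
    save_model(fixture_model, buf)
    buf.seek(0)
    clone = load_model(buf)
    assert clone.order == fixture_model.order
    assert clone.alpha == fixture_model.alpha
    assert clone.vocab == fixture_model.vocab
    assert clone.tag_counts == fixture_model.tag_counts
    assert clone.transition_counts == fixture_model.transition_counts
    assert score_path(clone, [("The", "DT"), ("patient", "NN")]) == pytest.approx(
        score_path(fixture_model, [("The", "DT"), ("patient", "NN")])
    )
    buf2 = io.StringIO(json.dumps({"format_version": 99}))
    with pytest.raises(ValueError, match="version"):
        load_model(buf2)
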