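"""Adapted Viterbi decoding vs the brute-force oracle."""

import math

import numpy as np
import pytest

from tokenlattice import (
    NoCompletePathError,
    TagSet,
    build_lattice,
    brute_force_decode,
    enumerate_token_sequences,
    tokenize,
    train,
    viterbi_decode,
)
from tokenlattice.decoder import AllPathsImpossibleError, CombinationBoundExceeded
from tokenlattice.hmm import score_path

from conftest import build_segment_lattice, random_model, random_segment_lattice


def test_single_path_lattice_scores_like_score_path(transducers, fixture_model):
    lat = build_lattice("dental", transducers)
    result = viterbi_decode(lat, fixture_model)
    assert result.tokens == ("dental",)
    assert result.logprob == pytest.approx(
        score_path(fixture_model, list(result.items))
    )


def test_decoder_equals_oracle_on_random_lattices(subtests=None):
    """Score and sequence agree with exhaustive enumeration (seeded)."""
    rng = np.random.default_rng(20260929)
    for _ in range(60):
        lat = random_segment_lattice(rng, max_segments=4)
        model = random_model(rng)
        v = viterbi_decode(lat, model)
        b = brute_force_decode(lat, model, max_combinations=500_000)
        assert v.items == b.items
        assert v.logprob == pytest.approx(b.logprob)


def test_optimality_certificate(transducers, fixture_model):
    """The returned score bounds every sequence's best tagging."""
    lat = build_lattice("Primidone 50mg tablet", transducers)
    best = viterbi_decode(lat, fixture_model)
    oracle = brute_force_decode(lat, fixture_model, max_combinations=10_000_000)
    assert best.logprob == pytest.approx(oracle.logprob)
    assert best.items == oracle.items


def test_tie_breaking_consistency():
    """On equal-scoring paths both decoders pick the same one."""
    # two one-token readings with identical counts => identical scores
    lat = build_segment_lattice([[("aa",), ("bb",)]])
    corpus = [[("aa", "T1")], [("bb", "T1")]]
    model = train(corpus, order=1, alpha=0.0, tagset=TagSet(tags=frozenset({"T1"})))
    v = viterbi_decode(lat, model)
    b = brute_force_decode(lat, model)
    assert v.items == b.items == (("aa", "T1"),)  # lexicographic winner


def test_tag_ties_break_lexicographically():
    """A token equally probable under two tags gets the smaller tag."""
    lat = build_segment_lattice([[("aa",)]])
    corpus = [[("aa", "T2")], [("aa", "T1")]]
    model = train(corpus, order=1, alpha=0.0,
                  tagset=TagSet(tags=frozenset({"T1", "T2"})))
    v = viterbi_decode(lat, model)
    b = brute_force_decode(lat, model)
    assert v.items == b.items == (("aa", "T1"),)


def test_epsilon_edges_contribute_no_score(transducers, fixture_model):
    one = viterbi_decode(build_lattice("dental", transducers), fixture_model)
    spaced = viterbi_decode(build_lattice("   dental  ", transducers), fixture_model)
    assert spaced.tokens == one.tokens
    assert spaced.logprob == pytest.approx(one.logprob)


def test_empty_unit_decodes_to_empty_sequence(transducers, fixture_model):
    assert tokenize("", transducers, fixture_model).items == ()
    assert tokenize("", transducers, fixture_model).logprob == 0.0


def test_all_paths_impossible_without_smoothing():
    lat = build_segment_lattice([[("aa",)]])
    model = train([[("zz", "T1")]], order=1, alpha=0.0,
                  tagset=TagSet(tags=frozenset({"T1"})))
    with pytest.raises(AllPathsImpossibleError):
        viterbi_decode(lat, model)
    with pytest.raises(AllPathsImpossibleError):
        brute_force_decode(lat, model)


def test_no_complete_path_signalled(fixture_model):
    lat = build_segment_lattice([[("aa",)]])
    lat.graph.remove_edges_from(list(lat.graph.edges(keys=True)))
    with pytest.raises(NoCompletePathError):
        viterbi_decode(lat, fixture_model)


def test_combination_bound_enforced(transducers, fixture_model):
    lat = build_lattice("The patient's 10mg tablet.", transducers)
    with pytest.raises(CombinationBoundExceeded):
        brute_force_decode(lat, fixture_model, max_combinations=10)


def test_normalized_mode_agrees_with_normalized_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        lat = random_segment_lattice(rng, max_segments=3)
        model = random_model(rng)
        v = viterbi_decode(lat, model, normalize=True)
        b = brute_force_decode(lat, model, normalize=True,
                               max_combinations=500_000)
        assert v.items == b.items


@pytest.mark.parametrize(
    "text, expected",
    [
        ("Entire upper dental arch (body structure)",
         ("Entire", "upper", "dental", "arch", "(", "body", "structure", ")")),
        ("Primidone 50mg tablet", ("Primidone", "50", "mg", "tablet")),
    ],
)
def test_tokenize_composes_lattice_and_decoder(transducers, fixture_model,
                                               text, expected):
    assert tokenize(text, transducers, fixture_model).tokens == expected


def test_decoding_throughput_on_generated_units(transducers):
    """A batch of generated units decodes well under the complexity budget."""
    import time
    from tokenlattice import FixtureSpec, generate_eval_set, generate_tagged_corpus

    spec = FixtureSpec(seed=5, n_units=100)
    units, _ = generate_eval_set(spec)
    corpus, _ = generate_tagged_corpus(
        FixtureSpec(seed=5, n_units=100, n_train_sentences=300))
    model = train(corpus, order=1, alpha=0.1)
    t0 = time.time()
    for u in units:
        tokenize(u, transducers, model)
    assert time.time() - t0 < 60.0
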