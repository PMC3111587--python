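"""Shared fixtures and random-structure helpers for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from tokenlattice import TextUnit, TokenLattice, TagSet, train, paper_training_corpus
from tokenlattice.transducers import default_transducers


@pytest.fixture(scope="session")
def transducers():
    return default_transducers()


@pytest.fixture(scope="session")
def fixture_model():
    """Order-1 model trained on the hand-tagged worked-example corpus."""
    return train(paper_training_corpus(), order=1, alpha=0.1)


def build_segment_lattice(readings_per_segment):
    """Construct a lattice directly from per-segment candidate readings.

    ``readings_per_segment`` is a list of segments; each segment is a list
    of readings and each reading is a tuple of tokens.  The unit text is
    the first reading of each segment joined by single spaces; edges mirror
    the constructor's conventions (epsilon edges for the separating spaces,
    auxiliary-vertex chains for multi-token readings).
    """
    surfaces = ["".join(r[0]) for r in readings_per_segment]
    text = " ".join(surfaces)
    graph = nx.MultiDiGraph()
    next_aux = [len(text) + 1]
    pos = 0
    for idx, (surface, readings) in enumerate(zip(surfaces, readings_per_segment)):
        start, end = pos, pos + len(surface)
        for reading in {tuple(r) for r in readings}:
            if len(reading) == 1:
                graph.add_edge(start, end, key=reading[0])
                continue
            prev = start
            for tok in reading[:-1]:
                aux = next_aux[0]
                next_aux[0] += 1
                graph.add_edge(prev, aux, key=tok)
                prev = aux
            graph.add_edge(prev, end, key=reading[-1])
        pos = end
        if idx < len(readings_per_segment) - 1:
            from tokenlattice.lattice import EPSILON

            graph.add_edge(pos, pos + 1, key=EPSILON)
            pos += 1
    graph.add_node(0)
    graph.add_node(len(text))
    return TokenLattice(unit=TextUnit(text=text), graph=graph)


_WORDS = ("aa", "bb", "cc", "dd", "ee", "ff", "gg")


def random_segment_lattice(rng: np.random.Generator, max_segments=6):
    """A random small lattice: <= ``max_segments`` segments, <= 3 readings
    of 1-2 tokens each."""
    k = int(rng.integers(1, max_segments + 1))
    segments = []
    for _ in range(k):
        n_read = int(rng.integers(1, 4))
        readings = []
        for _ in range(n_read):
            n_tok = int(rng.integers(1, 3))
            readings.append(tuple(
                _WORDS[int(rng.integers(len(_WORDS)))] for _ in range(n_tok)
            ))
        segments.append(readings)
    return build_segment_lattice(segments)


def random_model(rng: np.random.Generator, order=None, alpha=None):
    """A small random HMM over the helper vocabulary and two tags."""
    tags = ("T1", "T2")
    corpus = []
    for _ in range(int(rng.integers(3, 8))):
        sentence = [
            (_WORDS[int(rng.integers(len(_WORDS)))], tags[int(rng.integers(2))])
            for _ in range(int(rng.integers(1, 6)))
        ]
        corpus.append(sentence)
    if order is None:
        order = int(rng.integers(0, 2))
    if alpha is None:
        alpha = float(rng.choice([0.1, 0.5, 1.0]))
    return train(corpus, order=order, alpha=alpha,
                 tagset=TagSet(tags=frozenset(tags)))
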