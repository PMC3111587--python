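"""Best-path selection over a token lattice: adapted Viterbi and an oracle.

The adapted Viterbi decoder runs dynamic programming over states
``(vertex, last tag)`` in topological order of the lattice DAG, so it finds
the tagged token sequence maximizing the HMM path score over *all* complete
paths and all tag assignments -- the argmax that defines a good tokenizer.
Epsilon (whitespace) edges advance the vertex without contributing score.

Paths of different lengths are compared by raw joint log-probability by
default; a per-token-normalized mode is available behind a flag (it augments
the DP state with the emitted-token count, since a length-normalized
objective is not prefix-decomposable otherwise).

Ties are broken deterministically: fewer tokens first, then lexicographic on
token strings, then lexicographic on tags.  ``brute_force_decode``
exhaustively enumerates (path, tagging) combinations with the same
tie-breaking and serves as the independent testing oracle.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import networkx as nx

from .hmm import (
    BOS,
    HmmModel,
    emission_logprob,
    score_path,
    tag_logprob,
    transition_logprob,
)
from .lattice import (
    EPSILON,
    Context,
    NoCompletePathError,
    TaggedTokenSequence,
    TextUnit,
    TokenLattice,
    build_lattice,
    enumerate_token_sequences,
)
from .transducers import Transducer

__all__ = [
    "AllPathsImpossibleError",
    "CombinationBoundExceeded",
    "viterbi_decode",
    "brute_force_decode",
    "tokenize",
]


class AllPathsImpossibleError(ValueError):
    """Every complete path scores -inf under the model (alpha == 0)."""


class CombinationBoundExceeded(ValueError):
    """The brute-force oracle's (path, tagging) combination bound was hit."""


# A DP entry: score, then the deterministic tie key (token count, tokens,
# tags), then the prefix items needed to reconstruct the result.
_Entry = tuple[float, tuple[int, tuple[str, ...], tuple[str, ...]], tuple[tuple[str, str], ...]]


def _better(a: _Entry, b: Optional[_Entry]) -> bool:
    """True when entry ``a`` beats ``b``: higher score, then smaller tie key."""
    if b is None:
        return True
    if a[0] != b[0]:
        return a[0] > b[0]
    return a[1] < b[1]


def _emit_tags(model: HmmModel) -> tuple[str, ...]:
    return tuple(sorted(model.tagset.tags))


def viterbi_decode(
    lattice: TokenLattice,
    model: HmmModel,
    normalize: bool = False,
) -> TaggedTokenSequence:
    """Select the maximum-probability tagged token sequence from a lattice.

    Returns a complete path's tagged token sequence maximizing the HMM path
    score over all complete paths and all tag assignments.  With
    ``normalize=True`` the objective is score divided by token count
    (empty-token-sequence paths keep raw score 0).  Raises
    :class:`NoCompletePathError` on an uncovered lattice and
    :class:`AllPathsImpossibleError` when every path is impossible.
    """
    graph = lattice.graph
    start, end = lattice.start, lattice.end
    if start == end:
        return TaggedTokenSequence(items=(), logprob=0.0)
    if start not in graph or end not in graph:
        raise NoCompletePathError("no complete path in lattice")

    tags = _emit_tags(model)
    # per-vertex DP table: (last tag or BOS[, token count]) -> best entry;
    # the token count joins the state only in normalized mode, where path
    # length takes part in the objective
    table: dict[int, dict[tuple, _Entry]] = {
        start: {(BOS, 0) if normalize else (BOS,): (0.0, (0, (), ()), ())}
    }

    for u in nx.topological_sort(graph):
        at_u = table.get(u)
        if not at_u:
            continue
        out_edges = list(graph.out_edges(u, keys=True))
        for key, entry in at_u.items():
            prev_tag = key[0]
            count = key[1] if normalize else 0
            score, _, items = entry
            for _, v, label in out_edges:
                dest = table.setdefault(v, {})
                if label is EPSILON:
                    k2 = (prev_tag, count) if normalize else (prev_tag,)
                    if _better(entry, dest.get(k2)):
                        dest[k2] = entry
                    continue
                for tag in tags:
                    if model.order == 1:
                        step = transition_logprob(model, prev_tag, tag)
                    else:
                        step = tag_logprob(model, tag)
                    step += emission_logprob(model, label, tag)
                    items2 = items + ((label, tag),)
                    cand: _Entry = (
                        score + step,
                        (len(items2), _toks(items2), _tgs(items2)),
                        items2,
                    )
                    k2 = (tag, count + 1) if normalize else (tag,)
                    if _better(cand, dest.get(k2)):
                        dest[k2] = cand

    finals = list(table.get(end, {}).values())
    if not finals:
        raise NoCompletePathError("no complete path in lattice")

    best: Optional[_Entry] = None
    best_obj = float("-inf")
    for e in finals:
        obj = e[0] / len(e[2]) if (normalize and e[2]) else e[0]
        if best is None or obj > best_obj or (obj == best_obj and e[1] < best[1]):
            best, best_obj = e, obj
    assert best is not None
    if best_obj == float("-inf"):
        raise AllPathsImpossibleError("all paths impossible under the model")
    return TaggedTokenSequence(items=best[2], logprob=best[0])


def _toks(items: tuple[tuple[str, str], ...]) -> tuple[str, ...]:
    return tuple(t for t, _ in items)


def _tgs(items: tuple[tuple[str, str], ...]) -> tuple[str, ...]:
    return tuple(g for _, g in items)


def brute_force_decode(
    lattice: TokenLattice,
    model: HmmModel,
    normalize: bool = False,
    max_combinations: int = 1_000_000,
) -> TaggedTokenSequence:
    """Exhaustive oracle: enumerate all complete paths and tag assignments.

    Independent of the Viterbi recursion -- it scores each candidate with
    :func:`tokenlattice.hmm.score_path` -- but applies the same tie-breaking.
    Raises :class:`CombinationBoundExceeded` when the number of (path,
    tagging) combinations exceeds ``max_combinations``.
    """
    sequences = sorted(enumerate_token_sequences(lattice))
    n_tags = len(model.tagset)
    total = sum(n_tags ** len(seq) for seq in sequences)
    if total > max_combinations:
        raise CombinationBoundExceeded(
            f"{total} (path, tagging) combinations exceed bound {max_combinations}"
        )

    tags = _emit_tags(model)
    best: Optional[_Entry] = None
    best_obj = float("-inf")
    for seq in sequences:
        if not seq:
            cand: _Entry = (0.0, (0, (), ()), ())
            obj = 0.0
            if best is None or obj > best_obj or (obj == best_obj and cand[1] < best[1]):
                best, best_obj = cand, obj
            continue
        for assignment in itertools.product(tags, repeat=len(seq)):
            items = tuple(zip(seq, assignment))
            score = score_path(model, items)
            obj = score / len(items) if normalize else score
            cand = (score, (len(items), seq, assignment), items)
            if best is None or obj > best_obj or (obj == best_obj and cand[1] < best[1]):
                best, best_obj = cand, obj
    if best is None:
        raise NoCompletePathError("no complete path in lattice")
    if best_obj == float("-inf"):
        raise AllPathsImpossibleError("all paths impossible under the model")
    return TaggedTokenSequence(items=best[2], logprob=best[0])


def tokenize(
    unit: TextUnit | str,
    transducers: Sequence[Transducer],
    model: HmmModel,
    context: Context = (),
    normalize: bool = False,
) -> TaggedTokenSequence:
    """Tokenize one text unit: build its lattice, then decode the best path.

    The returned tagged token sequence's ``tokens`` are the tokenizer
    output; component errors (uncovered text, impossible paths) propagate.
    """
    lattice = build_lattice(unit, transducers, context)
    return viterbi_decode(lattice, model, normalize=normalize)
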