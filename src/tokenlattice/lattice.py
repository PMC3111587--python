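"""Token lattice construction over a text unit.

A token lattice is a bounded DAG whose vertices are positions between
characters of one text unit (plus auxiliary vertices for multi-token
readings) and whose edges carry candidate tokens.  Every complete path from
the start vertex to the end vertex is a candidate tokenization; whitespace is
consumed by unlabelled (epsilon) edges that are elided when a path is read
off as a token sequence.

The constructor applies every transducer at every character position
(position-exhaustive), then prunes edges that lie on no complete path; the
pruning preserves the set of complete paths.  Coordinates are 0-based,
half-open: a transducer application at position ``i`` consuming ``l``
characters spans ``[i, i+l)`` and its edge path runs from vertex ``i`` to
vertex ``i+l``.

Interior vertices of a multi-token reading are shared position vertices when
the emitted tokens tile the consumed surface exactly (``"patient" + "'s" ==
"patient's"``); otherwise ("C1-4" -> "C1 to 4", where "to" replaces "-")
fresh auxiliary vertices are used.  Sharing makes edge-level deduplication
collapse readings that different transducers produce identically (the
quantity split "50"+"mg" coincides with the numeric-then-alphabetic chain),
so no two complete paths yield the same token sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import networkx as nx

from .transducers import Transducer

__all__ = [
    "EPSILON",
    "TextUnit",
    "Context",
    "TokenLattice",
    "TaggedTokenSequence",
    "UncoveredTextError",
    "NoCompletePathError",
    "build_lattice",
    "enumerate_token_sequences",
    "lattice_to_dot",
]

class _EpsilonType:
    """Singleton label of a token-less (whitespace) edge."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "EPSILON"


#: Edge label of a token-less (whitespace) edge.
EPSILON = _EpsilonType()

#: A tokenization context: a tuple of tokenizer-instance information,
#: empty by default.  It is passed through unchanged to every transducer.
Context = tuple


class UncoveredTextError(ValueError):
    """No complete start-to-end path covers the unit's text."""


class NoCompletePathError(ValueError):
    """A lattice operation required a complete path and found none."""


@dataclass(frozen=True)
class TextUnit:
    """One unit of raw text (a line: sentence or concept description)."""

    text: str
    unit_id: str = "u0"

    def __len__(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class TaggedTokenSequence:
    """An ordered sequence of (token, POS tag) pairs with a log-probability.

    This is the tokenizer's output type.  Tokens are non-empty; the score is
    a natural-log joint probability (0.0 for the empty sequence).
    """

    items: tuple[tuple[str, str], ...]
    logprob: float = 0.0

    def __post_init__(self) -> None:
        if any(not tok for tok, _ in self.items):
            raise ValueError("empty token in tagged sequence")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(tok for tok, _ in self.items)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(tag for _, tag in self.items)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class TokenLattice:
    """Bounded lattice of candidate segmentations over one text unit.

    Position vertices are the integers ``0..len(text)``; auxiliary vertices
    (interiors of non-tiling multi-token readings) are integers above
    ``len(text)``.  Edges are ``(u, label, v)`` with ``label`` a token string
    or :data:`EPSILON`; no two edges share ``(u, label, v)``.
    """

    unit: TextUnit
    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    @property
    def start(self) -> int:
        return 0

    @property
    def end(self) -> int:
        return len(self.unit.text)

    def edges(self) -> Iterator[tuple[int, Optional[str], int]]:
        """Iterate over ``(from_vertex, label, to_vertex)`` triples."""
        for u, v, label in self.graph.edges(keys=True):
            yield u, label, v

    @property
    def position_vertices(self) -> list[int]:
        return [v for v in self.graph.nodes if v <= self.end]

    @property
    def auxiliary_vertices(self) -> list[int]:
        return [v for v in self.graph.nodes if v > self.end]


def _add_application(
    graph: nx.MultiDiGraph,
    i: int,
    consumed: int,
    tokens: Sequence[str],
    text: str,
    next_aux: list[int],
) -> None:
    """Insert the edge path for one transducer application at position i."""
    j = i + consumed
    if not tokens:
        graph.add_edge(i, j, key=EPSILON)
        return
    if len(tokens) == 1:
        graph.add_edge(i, j, key=tokens[0])
        return
    if "".join(tokens) == text[i:j]:
        # tokens tile the surface: interior nodes are real positions, so
        # identical readings from different transducers share edges
        pos = i
        for tok in tokens:
            graph.add_edge(pos, pos + len(tok), key=tok)
            pos += len(tok)
        return
    # non-tiling output (a token was rewritten): fresh interior vertices
    prev = i
    for tok in tokens[:-1]:
        aux = next_aux[0]
        next_aux[0] += 1
        graph.add_edge(prev, aux, key=tok)
        prev = aux
    graph.add_edge(prev, j, key=tokens[-1])


def build_lattice(
    unit: TextUnit | str,
    transducers: Sequence[Transducer],
    context: Context = (),
) -> TokenLattice:
    """Build the token lattice for one text unit.

    Applies every transducer at every character position reachable from the
    start, inserts the resulting edge paths (deduplicated), and prunes edges
    that lie on no complete path.  Raises :class:`UncoveredTextError` when no
    complete start-to-end path exists (e.g. an empty transducer set on
    non-empty text).
    """
    if isinstance(unit, str):
        unit = TextUnit(unit)
    text = unit.text
    n = len(text)
    graph = nx.MultiDiGraph()
    graph.add_node(0)
    next_aux = [n + 1]
    seen_multi: set[tuple[int, tuple[str, ...], int]] = set()

    for i in range(n):
        suffix = text[i:]
        for t in transducers:
            for res in t.transduce_all(context, suffix):
                if not res.applicable:
                    continue
                if res.consumed > len(suffix):
                    raise ValueError(
                        f"transducer {t.name!r} consumed {res.consumed} of a "
                        f"{len(suffix)}-character suffix"
                    )
                if len(res.tokens) > 1 and "".join(res.tokens) != text[i : i + res.consumed]:
                    key = (i, res.tokens, i + res.consumed)
                    if key in seen_multi:
                        continue
                    seen_multi.add(key)
                _add_application(graph, i, res.consumed, res.tokens, text, next_aux)

    graph.add_node(n)
    # prune to edges on complete paths (pure optimization: the complete-path
    # set is unchanged)
    forward = {0} | nx.descendants(graph, 0)
    if n not in forward:
        raise UncoveredTextError(
            f"uncovered position: no complete path over unit {unit.unit_id!r}"
        )
    backward = {n} | nx.ancestors(graph, n)
    keep = forward & backward
    pruned = graph.subgraph(keep).copy()
    return TokenLattice(unit=unit, graph=pruned)


def enumerate_token_sequences(lattice: TokenLattice) -> set[tuple[str, ...]]:
    """All distinct token sequences read off complete paths.

    Epsilon edges are elided.  Raises :class:`NoCompletePathError` on a
    lattice without a complete path.  The empty unit yields ``{()}``.
    """
    end = lattice.end
    graph = lattice.graph
    if lattice.start == end:
        return {()}
    if end not in graph or lattice.start not in graph:
        raise NoCompletePathError("no complete path in lattice")

    memo: dict[int, frozenset[tuple[str, ...]]] = {}

    def suffixes(v: int) -> frozenset[tuple[str, ...]]:
        if v == end:
            return frozenset({()})
        if v in memo:
            return memo[v]
        acc: set[tuple[str, ...]] = set()
        for _, w, label in graph.out_edges(v, keys=True):
            for tail in suffixes(w):
                acc.add(tail if label is EPSILON else (label,) + tail)
        memo[v] = frozenset(acc)
        return memo[v]

    result = set(suffixes(lattice.start))
    if not result:
        raise NoCompletePathError("no complete path in lattice")
    return result


def lattice_to_dot(lattice: TokenLattice) -> str:
    """Render the lattice in DOT graph-description format for inspection."""
    lines = ["digraph tokenlattice {", "  rankdir=LR;"]
    end = lattice.end
    for v in sorted(lattice.graph.nodes):
        shape = "circle" if v <= end else "point"
        peripheries = 2 if v in (0, end) else 1
        lines.append(
            f'  v{v} [label="{v if v <= end else ""}", shape={shape}, '
            f"peripheries={peripheries}];"
        )
    for u, label, v in sorted(
        lattice.edges(), key=lambda e: (e[0], e[2], e[1] or "")
    ):
        txt = "ε" if label is EPSILON else label.replace("\\", "\\\\").replace('"', '\\"')
        style = ", style=dashed" if label is EPSILON else ""
        lines.append(f'  v{u} -> v{v} [label="{txt}"{style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
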