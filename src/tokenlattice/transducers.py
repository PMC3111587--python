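"""Token transducers for biomedical English.

A token transducer inspects the *start* of a text suffix and either consumes a
span of characters, emitting a (possibly transformed) sequence of candidate
tokens, or declares itself not applicable.  Formally a transducer is a
deterministic function ``(context, suffix) -> (consumed, tokens)`` where
``consumed == 0`` with an empty token tuple means "not applicable" and a
positive ``consumed`` with an empty token tuple means the span carries no
token at all (whitespace).

The default set covers the token classes observed in SNOMED CT style concept
descriptions: plain alphabetic words (with internal hyphens), numerals
(integers, decimals, comma-grouped, simple fractions, roman numerals),
possessive clitics, standalone punctuation, chemical substances / serotypes /
functional names, and the closed-class expansions used by the gold protocol
("C1-4" -> "C1 to 4", "organ/system" -> "organ and system", "ml/g" ->
"ml per g", "a + b" -> "a and b", "50mg" -> "50 mg").

Every applicable transducer contributes its reading to the token lattice;
ambiguity between readings is *not* resolved here but by the decoder's POS
likelihood.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

__all__ = [
    "TransduceResult",
    "Transducer",
    "NOT_APPLICABLE",
    "transduce_whitespace",
    "transduce_word_run",
    "transduce_alphabetic",
    "transduce_numeric",
    "transduce_possessive",
    "transduce_independent",
    "transduce_expansion",
    "transduce_expansion_all",
    "transduce_substance",
    "default_transducers",
    "transducers_from_names",
    "load_closed_class_words",
    "TRANSDUCER_FUNCTIONS",
]


class TransduceResult(NamedTuple):
    """Outcome of applying a transducer to a text suffix.

    ``consumed`` is the number of characters used from the start of the
    suffix; ``tokens`` is the emitted token sequence.  ``(0, ())`` is the
    distinguished "not applicable" value.  A positive ``consumed`` with an
    empty ``tokens`` is legal and means the span is consumed silently
    (whitespace).
    """

    consumed: int
    tokens: tuple[str, ...]

    @property
    def applicable(self) -> bool:
        return self.consumed > 0


NOT_APPLICABLE = TransduceResult(0, ())

TransduceFn = Callable[[tuple, str], TransduceResult]

# ---------------------------------------------------------------------------
# Patterns
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")
_WORD = re.compile(r"\S+")
# letters with optional internal hyphens ("non-commissioned" is one token)
_ALPHA = re.compile(r"[A-Za-z]+(?:-[A-Za-z]+)*")
_POSSESSIVE = re.compile(r"([A-Za-z]+(?:-[A-Za-z]+)*)(['’]s)(?![A-Za-z0-9])")
_CLITIC_AHEAD = re.compile(r"['’]s(?![A-Za-z0-9])")

# numeric alternatives; the longest match wins so "1.2" is never read as "1"
_NUMERIC_PATTERNS = (
    re.compile(r"\d{1,3}(?:,\d{3})+"),          # 10,000
    re.compile(r"\d+\.\d+"),                    # 1.2
    re.compile(r"\d+/\d+(?![\d.])"),            # 1/2
    re.compile(r"[IVXLCDM]+(?![A-Za-z0-9])"),   # III
    re.compile(r"\d+"),                         # 1500
)

# one standalone punctuation symbol; the apostrophe is deliberately absent
# (owned by the possessive transducer) as are "/" ":" "+" (owned by the
# expansion and substance transducers).
_INDEPENDENT = frozenset("()[]{}<>,.?!;\"-")

# expansion patterns
_QUANTITY = re.compile(r"(\d+(?:\.\d+)?)([A-Za-z]+)(?![A-Za-z0-9])")
_RANGE = re.compile(r"([A-Za-z]+\d+)-(\d+)(?![A-Za-z0-9])")
_SLASH = re.compile(r"([A-Za-z]+)/([A-Za-z]+)(?![A-Za-z0-9])")
_PLUS = re.compile(
    r"([A-Za-z0-9]+(?:-[A-Za-z0-9]+)*)\s*\+\s*([A-Za-z0-9]+(?:-[A-Za-z0-9]+)*)"
    r"(?![A-Za-z0-9])"
)

# substances / serotypes / functional names: alphanumeric parts joined by
# hyphen, colon or comma, containing at least one digit
_SUBSTANCE = re.compile(r"[A-Za-z0-9]+(?:[-:,][A-Za-z0-9]+)+(?![A-Za-z0-9])")
# the exact range shape ("C1-4") belongs to the range expansion, not here
_RANGE_SHAPE = re.compile(r"[A-Za-z]+\d+-\d+\Z")

# a slash joins two *unit* symbols when both sides are short lowercase runs
_UNIT_SIDE = re.compile(r"[a-z]{1,3}\Z")


# ---------------------------------------------------------------------------
# Transducer functions
# ---------------------------------------------------------------------------

def transduce_whitespace(context: tuple, suffix: str) -> TransduceResult:
    """Consume a maximal run of whitespace, emitting no token."""
    m = _WS.match(suffix)
    if not m:
        return NOT_APPLICABLE
    return TransduceResult(m.end(), ())


def transduce_word_run(context: tuple, suffix: str) -> TransduceResult:
    """Consume a maximal run of non-whitespace as a single unsplit token.

    This is the "keep whole" reading ("patient's", "10mg", "tablet.") that
    competes in the lattice against the finer-grained readings below.
    """
    m = _WORD.match(suffix)
    if not m:
        return NOT_APPLICABLE
    return TransduceResult(m.end(), (m.group(),))


def transduce_alphabetic(context: tuple, suffix: str) -> TransduceResult:
    """Consume a maximal alphabetic run (internal hyphens allowed).

    Not applicable when the run is immediately followed by a possessive
    clitic boundary -- that span belongs to :func:`transduce_possessive`.
    """
    m = _ALPHA.match(suffix)
    if not m:
        return NOT_APPLICABLE
    if _CLITIC_AHEAD.match(suffix, m.end()):
        return NOT_APPLICABLE
    return TransduceResult(m.end(), (m.group(),))


def transduce_numeric(context: tuple, suffix: str) -> TransduceResult:
    """Consume one numeric token: integer, decimal, comma-grouped,
    simple fraction or roman numeral.  Decimals are never split."""
    best = 0
    for pat in _NUMERIC_PATTERNS:
        m = pat.match(suffix)
        if m and m.end() > best:
            best = m.end()
    if best == 0:
        return NOT_APPLICABLE
    return TransduceResult(best, (suffix[:best],))


def transduce_possessive(context: tuple, suffix: str) -> TransduceResult:
    """Split a possessive clitic: "Sjogren's" -> ("Sjogren", "'s")."""
    m = _POSSESSIVE.match(suffix)
    if not m:
        return NOT_APPLICABLE
    return TransduceResult(m.end(), (m.group(1), m.group(2)))


def transduce_independent(context: tuple, suffix: str) -> TransduceResult:
    """Consume exactly one standalone punctuation symbol."""
    if suffix and suffix[0] in _INDEPENDENT:
        return TransduceResult(1, (suffix[0],))
    return NOT_APPLICABLE


def _expansion_matches(suffix: str) -> list[TransduceResult]:
    results: list[TransduceResult] = []
    m = _QUANTITY.match(suffix)
    if m:
        results.append(TransduceResult(m.end(), (m.group(1), m.group(2))))
    m = _RANGE.match(suffix)
    if m:
        results.append(TransduceResult(m.end(), (m.group(1), "to", m.group(2))))
    m = _SLASH.match(suffix)
    if m:
        a, b = m.group(1), m.group(2)
        unitish = bool(_UNIT_SIDE.match(a)) and bool(_UNIT_SIDE.match(b))
        if unitish:
            # "ml/g" -> "ml per g"; the "and" reading also enters the lattice
            results.append(TransduceResult(m.end(), (a, "per", b)))
        results.append(TransduceResult(m.end(), (a, "and", b)))
    m = _PLUS.match(suffix)
    if m:
        results.append(TransduceResult(m.end(), (m.group(1), "and", m.group(2))))
    return results


def transduce_expansion(context: tuple, suffix: str) -> TransduceResult:
    """Expand abbreviated closed-class constructs into their regular form.

    Handles quantity-unit fusion ("50mg" -> "50 mg"), ranges
    ("C1-4" -> "C1 to 4"), slash lists ("organ/system" -> "organ and system",
    "ml/g" -> "ml per g") and plus lists ("a + b" -> "a and b").  Returns the
    primary reading; :func:`transduce_expansion_all` yields every applicable
    one (a slash over unit symbols contributes both "per" and "and").
    """
    results = _expansion_matches(suffix)
    return results[0] if results else NOT_APPLICABLE


def transduce_expansion_all(context: tuple, suffix: str) -> tuple[TransduceResult, ...]:
    return tuple(_expansion_matches(suffix))


def transduce_substance(context: tuple, suffix: str) -> TransduceResult:
    """Keep chemical substances, serotypes and functional names unsplit.

    Matches alphanumeric parts joined by hyphen/colon/comma that contain a
    digit ("Precorrin-3B", "O128:NM", "47:k:1,5,7", "H-987"), pre-empting
    splits that would yield unlikely POS sequences.  The pure range shape
    ("C1-4") is excluded; the range expansion owns it.
    """
    m = _SUBSTANCE.match(suffix)
    if not m:
        return NOT_APPLICABLE
    span = m.group()
    if not any(c.isdigit() for c in span):
        return NOT_APPLICABLE
    if _RANGE_SHAPE.match(span):
        return NOT_APPLICABLE
    return TransduceResult(m.end(), (span,))


# ---------------------------------------------------------------------------
# Transducer objects and the default set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transducer:
    """A named token transducer.

    ``transduce`` follows the formal contract (one result); ``transduce_all``
    exposes every applicable reading so genuinely ambiguous constructs (the
    slash's "and"/"per") each contribute a lattice path.  An optional
    ``transform_table`` maps emitted surface tokens to replacement forms
    (e.g. ``{"mg": "milligrams"}``).
    """

    name: str
    fn: TransduceFn
    all_fn: Optional[Callable[[tuple, str], tuple[TransduceResult, ...]]] = None
    transform_table: Optional[Mapping[str, str]] = None

    def _apply_transform(self, result: TransduceResult) -> TransduceResult:
        if not self.transform_table or not result.applicable:
            return result
        tokens = tuple(self.transform_table.get(t, t) for t in result.tokens)
        return TransduceResult(result.consumed, tokens)

    def transduce(self, context: tuple, suffix: str) -> TransduceResult:
        return self._apply_transform(self.fn(context, suffix))

    def transduce_all(self, context: tuple, suffix: str) -> tuple[TransduceResult, ...]:
        if self.all_fn is not None:
            results = self.all_fn(context, suffix)
        else:
            r = self.fn(context, suffix)
            results = (r,) if r.applicable else ()
        return tuple(self._apply_transform(r) for r in results)

    def with_transform(self, table: Mapping[str, str]) -> "Transducer":
        return replace(self, transform_table=dict(table))


TRANSDUCER_FUNCTIONS: dict[str, TransduceFn] = {
    "whitespace": transduce_whitespace,
    "word_run": transduce_word_run,
    "alphabetic": transduce_alphabetic,
    "numeric": transduce_numeric,
    "possessive": transduce_possessive,
    "independent": transduce_independent,
    "expansion": transduce_expansion,
    "substance": transduce_substance,
}


def _make(name: str, table: Optional[Mapping[str, str]] = None) -> Transducer:
    all_fn = transduce_expansion_all if name == "expansion" else None
    t = Transducer(name=name, fn=TRANSDUCER_FUNCTIONS[name], all_fn=all_fn)
    return t.with_transform(table) if table else t


def default_transducers() -> tuple[Transducer, ...]:
    """The default biomedical-English transducer set."""
    return tuple(_make(name) for name in TRANSDUCER_FUNCTIONS)


def transducers_from_names(
    names: Sequence[str],
    transform_tables: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> tuple[Transducer, ...]:
    """Build a transducer set from class names (for config files).

    Raises ``KeyError`` on an unknown class name.
    """
    tables = transform_tables or {}
    return tuple(_make(n, tables.get(n)) for n in names)


def load_closed_class_words() -> frozenset[str]:
    """The packaged closed-class word inventory (one word per line).

    These are the grammatical words whose abbreviated forms ("-" for "to",
    "/" for "and"/"per", "+" for "and") the gold protocol expands.
    """
    text = (
        resources.files("tokenlattice")
        .joinpath("data/closed_class_words.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(w for w in text.split() if w)
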