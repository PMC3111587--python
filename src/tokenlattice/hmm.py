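"""POS-tag hidden Markov language model.

Supervised training by counting from a tagged corpus, with additive
(Lidstone) smoothing and a single unknown-token bucket.  Two model orders
are supported:

* order 1 -- first-order HMM: a path scores
  ``sum_i [log P(tag_i | tag_{i-1}) + log P(token_i | tag_i)]`` with the
  first tag conditioned on the distinguished begin-of-sequence symbol;
* order 0 -- no transition probabilities: a path scores
  ``sum_i [log P(tag_i) + log P(token_i | tag_i)]`` (the joint of a unigram
  tag prior and the emission).

All scoring is in natural-log space.  With ``alpha == 0`` unseen events
score ``-inf``.  The smoothed emission denominator uses ``vocab_size ==
len(vocab) + 1``: one extra slot is the unknown-token bucket, into which
every out-of-vocabulary token falls.

The slash corpus format ("token/TAG" whitespace-separated, one sentence per
line, Penn-Treebank style) is parsed here; models persist to JSON.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

__all__ = [
    "BOS",
    "PENN_TAGS",
    "TagSet",
    "HmmModel",
    "CorpusFormatError",
    "train",
    "emission_logprob",
    "transition_logprob",
    "tag_logprob",
    "score_path",
    "parse_slash_corpus",
    "format_slash_corpus",
    "save_model",
    "load_model",
]

#: Distinguished begin-of-sequence symbol; never emitted, never a tag.
BOS = "<s>"

#: Penn Treebank POS tag inventory (word classes plus punctuation tags).
PENN_TAGS: tuple[str, ...] = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNS", "NNP", "NNPS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
    "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP",
    "VBZ", "WDT", "WP", "WP$", "WRB",
    "$", "#", "``", "''", "(", ")", ",", ".", ":",
)

MODEL_FORMAT_VERSION = 1

TaggedSentence = Sequence[tuple[str, str]]


class CorpusFormatError(ValueError):
    """A slash-format corpus line could not be parsed."""


@dataclass(frozen=True)
class TagSet:
    """A finite POS tag inventory plus the begin-of-sequence symbol."""

    tags: frozenset[str] = frozenset(PENN_TAGS)
    bos: str = BOS

    def __post_init__(self) -> None:
        if not self.tags:
            raise ValueError("empty tag set")
        if self.bos in self.tags:
            raise ValueError("BOS symbol must not be an emitting tag")

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def __len__(self) -> int:
        return len(self.tags)


@dataclass
class HmmModel:
    """Counts-based POS-tag language model of order 0 or 1."""

    tagset: TagSet
    order: int
    alpha: float
    emission_counts: dict[str, Counter]          # tag -> token -> count
    transition_counts: dict[str, Counter]        # prev tag (incl BOS) -> tag -> count
    tag_counts: Counter                          # tag -> emitted-token count
    transition_totals: Counter                   # prev tag -> outgoing transition count
    vocab: frozenset[str]
    total_tokens: int

    @property
    def vocab_size(self) -> int:
        """Distinct trained tokens plus one unknown-token bucket."""
        return len(self.vocab) + 1

    @property
    def n_tags(self) -> int:
        return len(self.tagset)


def train(
    corpus: Iterable[TaggedSentence],
    order: int = 1,
    alpha: float = 0.1,
    tagset: TagSet | None = None,
) -> HmmModel:
    """Train an HMM from a tagged corpus by counting.

    Tags outside the provided tag set are added to it.  Transition counts
    include the begin-of-sequence event for each sentence.  Raises
    ``ValueError`` on an empty corpus, an empty sentence, an empty token or
    an invalid order/alpha.
    """
    if order not in (0, 1):
        raise ValueError(f"order must be 0 or 1, got {order!r}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha!r}")

    emission: dict[str, Counter] = {}
    transition: dict[str, Counter] = {}
    tag_counts: Counter = Counter()
    trans_totals: Counter = Counter()
    vocab: set[str] = set()
    seen_tags: set[str] = set()
    total = 0
    n_sentences = 0

    for sentence in corpus:
        if not sentence:
            raise ValueError("malformed corpus: empty sentence")
        n_sentences += 1
        prev = BOS
        for pair in sentence:
            try:
                token, tag = pair
            except (TypeError, ValueError):
                raise ValueError(f"malformed corpus entry: {pair!r}") from None
            if not token:
                raise ValueError("malformed corpus: empty token")
            if not tag or tag == BOS:
                raise ValueError(f"malformed corpus: invalid tag {tag!r}")
            emission.setdefault(tag, Counter())[token] += 1
            tag_counts[tag] += 1
            transition.setdefault(prev, Counter())[tag] += 1
            trans_totals[prev] += 1
            vocab.add(token)
            seen_tags.add(tag)
            total += 1
            prev = tag

    if n_sentences == 0:
        raise ValueError("empty corpus")

    base = tagset or TagSet()
    tags = frozenset(base.tags | seen_tags)
    return HmmModel(
        tagset=TagSet(tags=tags, bos=base.bos),
        order=order,
        alpha=alpha,
        emission_counts=emission,
        transition_counts=transition,
        tag_counts=tag_counts,
        transition_totals=trans_totals,
        vocab=frozenset(vocab),
        total_tokens=total,
    )


def _log_ratio(count: int, total: int, alpha: float, bins: int) -> float:
    num = count + alpha
    if num == 0:
        return float("-inf")
    return math.log(num) - math.log(total + alpha * bins)


def emission_logprob(model: HmmModel, token: str, tag: str) -> float:
    """``log P(token | tag)`` with additive smoothing.

    Out-of-vocabulary tokens fall into the single unknown bucket; with
    ``alpha == 0`` an unseen (tag, token) pair scores ``-inf``.
    """
    if tag not in model.tagset:
        raise ValueError(f"tag {tag!r} not in tag set")
    count = 0
    if token in model.vocab:
        counter = model.emission_counts.get(tag)
        count = counter[token] if counter else 0
    return _log_ratio(count, model.tag_counts[tag], model.alpha, model.vocab_size)


def transition_logprob(model: HmmModel, prev: str, tag: str) -> float:
    """``log P(tag | prev)``; ``prev`` may be the BOS symbol."""
    if tag not in model.tagset:
        raise ValueError(f"tag {tag!r} not in tag set")
    if prev != BOS and prev not in model.tagset:
        raise ValueError(f"tag {prev!r} not in tag set")
    counter = model.transition_counts.get(prev)
    count = counter[tag] if counter else 0
    return _log_ratio(count, model.transition_totals[prev], model.alpha, model.n_tags)


def tag_logprob(model: HmmModel, tag: str) -> float:
    """Unigram tag prior ``log P(tag)`` (used by the order-0 score)."""
    if tag not in model.tagset:
        raise ValueError(f"tag {tag!r} not in tag set")
    return _log_ratio(model.tag_counts[tag], model.total_tokens, model.alpha, model.n_tags)


def score_path(model: HmmModel, path: Sequence[tuple[str, str]]) -> float:
    """Joint log-probability of a tagged token sequence under the model.

    Order 1 chains tag transitions from BOS; order 0 replaces transitions by
    the unigram tag prior.  Raises ``ValueError`` on an empty path.
    """
    items = list(path)
    if not items:
        raise ValueError("empty path")
    score = 0.0
    prev = BOS
    for token, tag in items:
        if model.order == 1:
            score += transition_logprob(model, prev, tag)
        else:
            score += tag_logprob(model, tag)
        score += emission_logprob(model, token, tag)
        prev = tag
    return score


# ---------------------------------------------------------------------------
# Slash corpus format
# ---------------------------------------------------------------------------

def parse_slash_corpus(lines: Iterable[str]) -> list[list[tuple[str, str]]]:
    """Parse "token/TAG" whitespace-separated lines, one sentence per line.

    The *last* slash separates token from tag, so tokens may themselves
    contain slashes ("1/2/CD").  Blank lines are skipped.  Raises
    :class:`CorpusFormatError` naming the offending line number.
    """
    sentences: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        sentence: list[tuple[str, str]] = []
        for item in line.split():
            token, sep, tag = item.rpartition("/")
            if not sep or not token or not tag:
                raise CorpusFormatError(
                    f"line {lineno}: expected token/TAG, got {item!r}"
                )
            sentence.append((token, tag))
        sentences.append(sentence)
    return sentences


def format_slash_corpus(corpus: Iterable[TaggedSentence]) -> str:
    """Render sentences back to slash format, one per line."""
    return "\n".join(
        " ".join(f"{tok}/{tag}" for tok, tag in sentence) for sentence in corpus
    ) + "\n"


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def save_model(model: HmmModel, fp: IO[str]) -> None:
    """Serialize a model to JSON (versioned, human-diffable)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "order": model.order,
        "alpha": model.alpha,
        "tags": sorted(model.tagset.tags),
        "bos": model.tagset.bos,
        "emission_counts": {t: dict(c) for t, c in model.emission_counts.items()},
        "transition_counts": {t: dict(c) for t, c in model.transition_counts.items()},
        "tag_counts": dict(model.tag_counts),
        "transition_totals": dict(model.transition_totals),
        "vocab": sorted(model.vocab),
        "total_tokens": model.total_tokens,
    }
    json.dump(payload, fp, indent=1, sort_keys=True)


def load_model(fp: IO[str]) -> HmmModel:
    payload = json.load(fp)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version!r}")
    return HmmModel(
        tagset=TagSet(tags=frozenset(payload["tags"]), bos=payload["bos"]),
        order=int(payload["order"]),
        alpha=float(payload["alpha"]),
        emission_counts={t: Counter(c) for t, c in payload["emission_counts"].items()},
        transition_counts={t: Counter(c) for t, c in payload["transition_counts"].items()},
        tag_counts=Counter(payload["tag_counts"]),
        transition_totals=Counter(payload["transition_totals"]),
        vocab=frozenset(payload["vocab"]),
        total_tokens=int(payload["total_tokens"]),
    )
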