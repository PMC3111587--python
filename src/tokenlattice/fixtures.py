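"""Synthetic fixtures: worked examples, ground-truth HMMs and corpora.

The original evaluation data for this kind of tokenizer (SNOMED CT concept
descriptions, a Penn Treebank sample, the MedPost corpus) is licensed, so
this module makes the whole pipeline testable without it:

* :func:`paper_examples` -- seven worked concept descriptions with their
  gold segmentations, exercising every default token class;
* :func:`paper_training_corpus` -- a small hand-tagged corpus covering the
  worked examples' vocabulary, for training the fixture decoding model;
* :func:`clinical_hmm_params` / :func:`general_hmm_params` -- known
  first-order HMMs over a clinical (concept-description-like) and a generic
  newswire-like tag/vocabulary distribution; :func:`sample_tagged_corpus`
  draws slash-format training corpora from them;
* :func:`generate_eval_set` -- a seeded evaluation set of SNOMED-style
  units (drug doses "50mg", possessives, trailing periods, ranges "C1-4",
  slash and plus lists, parenthesized semantic tags) with gold
  tokenizations built alongside the text, at a configurable ambiguity rate.

Every generated unit's gold sequence is reachable in the default lattice by
construction, and an ambiguous unit is exactly one whose gold sequence
differs from its whitespace segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .lattice import TextUnit

__all__ = [
    "HmmParams",
    "FixtureSpec",
    "paper_examples",
    "paper_training_corpus",
    "clinical_hmm_params",
    "general_hmm_params",
    "toy_hmm_params",
    "sample_tagged_corpus",
    "generate_eval_set",
    "generate_tagged_corpus",
    "is_ambiguous_unit",
]

TaggedSentence = list[tuple[str, str]]


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

_PAPER_EXAMPLES: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "Entire upper dental arch (body structure)",
        ("Entire", "upper", "dental", "arch", "(", "body", "structure", ")"),
    ),
    (
        "Royal Navy - non-commissioned personnel (occupation)",
        ("Royal", "Navy", "-", "non-commissioned", "personnel", "(", "occupation", ")"),
    ),
    (
        "Primidone 50mg tablet",
        ("Primidone", "50", "mg", "tablet"),
    ),
    (
        "Primary Sjogren's syndrome with organ/system involvement (disorder)",
        ("Primary", "Sjogren", "'s", "syndrome", "with", "organ", "and", "system",
         "involvement", "(", "disorder", ")"),
    ),
    (
        "Posterior cervical spinal cord injury, without spinal injury, C1-4",
        ("Posterior", "cervical", "spinal", "cord", "injury", ",", "without",
         "spinal", "injury", ",", "C1", "to", "4"),
    ),
    (
        "Precorrin-3B C17-methyltransferase",
        ("Precorrin-3B", "C17-methyltransferase"),
    ),
    (
        "Salmonella III arizonae 47:k:1,5,7",
        ("Salmonella", "III", "arizonae", "47:k:1,5,7"),
    ),
)


def paper_examples() -> list[tuple[str, tuple[str, ...]]]:
    """The worked concept descriptions with their gold segmentations.

    The practice examples of the annotation instructions are the same five
    descriptions as items 1, 2, 3, 5 and 6 and are deduplicated away.
    """
    return [(text, gold) for text, gold in _PAPER_EXAMPLES]


_FIXTURE_CORPUS_TEXT = """\
The/DT patient/NN 's/POS 10/CD mg/NN tablet/NN ./.
Entire/JJ upper/JJ dental/JJ arch/NN (/( body/NN structure/NN )/)
Royal/NNP Navy/NNP -/: non-commissioned/JJ personnel/NNS (/( occupation/NN )/)
Primidone/NNP 50/CD mg/NN tablet/NN
Primary/JJ Sjogren/NNP 's/POS syndrome/NN with/IN organ/NN and/CC system/NN involvement/NN (/( disorder/NN )/)
Posterior/JJ cervical/JJ spinal/JJ cord/NN injury/NN ,/, without/IN spinal/JJ injury/NN ,/, C1/NN to/TO 4/CD
Precorrin-3B/NN C17-methyltransferase/NN
Salmonella/NNP III/CD arizonae/NN 47:k:1,5,7/NN
The/DT patient/NN 's/POS tablet/NN ./.
A/DT dental/JJ tablet/NN ./.
body/NN and/CC structure/NN involvement/NN
organ/NN and/CC system/NN disorder/NN
spinal/JJ cord/NN injury/NN C1/NN to/TO 4/CD
dental/JJ injury/NN ,/, C1/NN to/TO 4/CD
"""


def paper_training_corpus(copies: int = 50) -> list[TaggedSentence]:
    """Hand-tagged sentences covering the worked examples' vocabulary.

    The sentences are replicated ``copies`` times: count ratios are
    unchanged, but the replication keeps the smoothed unknown-token bucket
    small relative to seen events, which a realistically sized corpus would
    also do.
    """
    from .hmm import parse_slash_corpus

    sentences = parse_slash_corpus(_FIXTURE_CORPUS_TEXT.splitlines())
    return sentences * copies


# ---------------------------------------------------------------------------
# Ground-truth HMMs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HmmParams:
    """A fully specified first-order HMM: the sampling ground truth.

    ``bos`` is the start distribution over tags, ``transitions`` maps each
    tag to its next-tag distribution, ``emissions`` maps each tag to its
    token distribution.  All rows must sum to 1.
    """

    tags: tuple[str, ...]
    bos: Mapping[str, float]
    transitions: Mapping[str, Mapping[str, float]]
    emissions: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        rows: list[Mapping[str, float]] = [self.bos, *self.transitions.values()]
        for row in rows:
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError("transition row does not sum to 1")
            if any(t not in self.tags for t in row):
                raise ValueError("transition row names an unknown tag")
        for tag in self.tags:
            emis = self.emissions[tag]
            if abs(sum(emis.values()) - 1.0) > 1e-9:
                raise ValueError(f"emission row for {tag!r} does not sum to 1")


def _uniform(words: Sequence[str]) -> dict[str, float]:
    p = 1.0 / len(words)
    return {w: p for w in words}


# clinical vocabulary; template instantiation draws from these same lists
_JJ = ("Entire", "upper", "Chronic", "Severe", "Acute", "Primary", "Posterior",
       "Partial", "Benign", "Malignant", "lower", "cervical", "spinal", "recurrent")
_NN_PLAIN = ("arch", "tablet", "syndrome", "disease", "injury", "structure",
             "disorder", "finding", "procedure", "colon", "dose", "solution",
             "fracture", "cord", "involvement", "lesion", "body", "organ",
             "system", "capsule", "caffeine", "codeine")
_NN_UNITS = ("mg", "ml", "g", "kg", "mcg")
_NN_FUNCTIONAL = ("C1", "C2", "C3", "C4")
_NN_SUBSTANCES = ("O128:NM", "H-987")
_NN = _NN_PLAIN + _NN_UNITS + _NN_FUNCTIONAL + _NN_SUBSTANCES
_NNS = ("symptoms", "signs", "organs", "systems", "findings", "disorders",
        "lesions", "injuries", "fractures")
_NNP = ("Primidone", "Paracetamol", "Warfarin", "Aspirin", "Metformin",
        "Crohn", "Sjogren", "Hodgkin", "Addison", "Salmonella")
_CD_INT = ("1", "2", "3", "4", "5", "6", "7", "8", "9", "10", "25", "50",
           "100", "250", "500")
_CD = _CD_INT + ("0.5", "1.2", "2.4", "10,000")
_SEMANTIC_TAGS = ("disorder", "finding", "procedure", "body", "structure",
                  "occupation")
_EPONYMS = ("Crohn", "Sjogren", "Hodgkin", "Addison")


def clinical_hmm_params() -> HmmParams:
    """Known first-order HMM over concept-description-like text.

    Its transition structure encodes the regularities the decoder exploits:
    plural nouns precede coordinations (NNS -> CC) but not prepositions,
    unit nouns follow numbers (CD -> NN) and precede "per" (NN -> IN),
    parenthesized semantic tags are ( NN ) spans.
    """
    tags = ("JJ", "NN", "NNS", "NNP", "CD", "POS", "IN", "CC", "TO",
            "(", ")", ",", ".")
    bos = {"JJ": 0.3, "NNP": 0.3, "NN": 0.2, "CD": 0.1, "NNS": 0.1}
    transitions = {
        "JJ": {"NN": 0.5, "JJ": 0.15, "NNS": 0.25, "NNP": 0.1},
        "NN": {"NN": 0.2, "IN": 0.12, "POS": 0.05, "(": 0.1, ")": 0.1,
               ".": 0.1, ",": 0.08, "CD": 0.07, "TO": 0.03, "CC": 0.03,
               "JJ": 0.05, "NNS": 0.07},
        "NNS": {"CC": 0.3, ".": 0.15, ",": 0.1, "NN": 0.15, "(": 0.1,
                ")": 0.1, "NNS": 0.1},
        "NNP": {"CD": 0.25, "NN": 0.3, "POS": 0.2, "CC": 0.15, "NNP": 0.1},
        "CD": {"NN": 0.55, "TO": 0.1, "CD": 0.1, ",": 0.1, "NNS": 0.1,
               ".": 0.05},
        "POS": {"NN": 0.5, "JJ": 0.3, "NNS": 0.2},
        "IN": {"NN": 0.55, "JJ": 0.2, "NNP": 0.15, "CD": 0.1},
        "CC": {"NNS": 0.35, "NN": 0.3, "NNP": 0.35},
        "TO": {"CD": 0.9, "NN": 0.1},
        "(": {"NN": 0.85, "NNS": 0.15},
        ")": {".": 0.3, "NN": 0.2, ",": 0.2, "CD": 0.1, "JJ": 0.1, "NNS": 0.1},
        ",": {"IN": 0.3, "JJ": 0.25, "NN": 0.25, "NNP": 0.1, "CD": 0.1},
        ".": {"NN": 0.3, "NNP": 0.4, "JJ": 0.3},
    }
    emissions = {
        "JJ": _uniform(_JJ),
        "NN": _uniform(_NN),
        "NNS": _uniform(_NNS),
        "NNP": _uniform(_NNP),
        "CD": _uniform(_CD),
        "POS": {"'s": 1.0},
        "IN": {"of": 0.3, "with": 0.25, "without": 0.2, "in": 0.1, "per": 0.15},
        "CC": {"and": 0.7, "or": 0.3},
        "TO": {"to": 1.0},
        "(": {"(": 1.0},
        ")": {")": 1.0},
        ",": {",": 1.0},
        ".": {".": 1.0},
    }
    return HmmParams(tags=tags, bos=bos, transitions=transitions,
                     emissions=emissions)


def general_hmm_params() -> HmmParams:
    """Known first-order HMM over generic newswire-like text.

    Out-of-domain relative to the evaluation units: no parentheses, no unit
    or drug vocabulary, ordinary sentence structure.  Training on this alone
    emulates the out-of-domain condition.
    """
    tags = ("DT", "JJ", "NN", "NNS", "NNP", "VBD", "VB", "IN", "CD",
            "POS", "CC", "TO", ",", ".")
    bos = {"DT": 0.45, "NNP": 0.3, "CD": 0.1, "JJ": 0.15}
    transitions = {
        "DT": {"NN": 0.5, "JJ": 0.35, "NNS": 0.15},
        "JJ": {"NN": 0.6, "NNS": 0.3, "JJ": 0.1},
        "NN": {"VBD": 0.3, "IN": 0.25, ".": 0.15, ",": 0.1, "POS": 0.05,
               "NN": 0.15},
        "NNS": {"VBD": 0.4, ".": 0.2, ",": 0.15, "CC": 0.15, "NN": 0.1},
        "NNP": {"VBD": 0.35, "POS": 0.25, "NNP": 0.2, ",": 0.1, ".": 0.1},
        "VBD": {"DT": 0.4, "CD": 0.2, "IN": 0.2, "TO": 0.1, "NNS": 0.1},
        "VB": {"DT": 0.6, "NNS": 0.2, "CD": 0.2},
        "IN": {"DT": 0.5, "NNP": 0.25, "CD": 0.15, "NN": 0.1},
        "CD": {"NN": 0.4, "NNS": 0.3, ".": 0.15, ",": 0.15},
        "POS": {"NN": 0.6, "JJ": 0.3, "NNS": 0.1},
        "CC": {"DT": 0.3, "NNP": 0.3, "NNS": 0.2, "VBD": 0.2},
        "TO": {"VB": 1.0},
        ",": {"DT": 0.3, "VBD": 0.2, "NNP": 0.2, "JJ": 0.15, "CC": 0.15},
        ".": {"DT": 0.5, "NNP": 0.5},
    }
    emissions = {
        "DT": {"the": 0.6, "a": 0.3, "this": 0.1},
        "JJ": _uniform(("new", "last", "big", "financial", "strong", "early")),
        "NN": _uniform(("company", "market", "report", "year", "price",
                        "plan", "meeting", "record", "statement", "quarter")),
        "NNS": _uniform(("shares", "results", "sales", "profits", "reports",
                         "analysts")),
        "NNP": _uniform(("Smith", "London", "Johnson", "Acme", "Barker")),
        "VBD": _uniform(("said", "reported", "rose", "fell", "announced")),
        "VB": _uniform(("buy", "sell", "pay", "report")),
        "IN": {"of": 0.3, "in": 0.25, "with": 0.15, "on": 0.1, "at": 0.1,
               "per": 0.05, "without": 0.05},
        "CD": _uniform(("1", "2", "5", "10", "20", "50", "100", "1987", "2.5")),
        "POS": {"'s": 1.0},
        "CC": {"and": 0.6, "or": 0.2, "but": 0.2},
        "TO": {"to": 1.0},
        ",": {",": 1.0},
        ".": {".": 1.0},
    }
    return HmmParams(tags=tags, bos=bos, transitions=transitions,
                     emissions=emissions)


def toy_hmm_params() -> HmmParams:
    """A small 3-tag HMM with well-separated rows, for recovery tests."""
    tags = ("A", "B", "C")
    return HmmParams(
        tags=tags,
        bos={"A": 0.5, "B": 0.3, "C": 0.2},
        transitions={
            "A": {"A": 0.1, "B": 0.6, "C": 0.3},
            "B": {"A": 0.4, "B": 0.2, "C": 0.4},
            "C": {"A": 0.3, "B": 0.5, "C": 0.2},
        },
        emissions={
            "A": {"x": 0.7, "y": 0.3},
            "B": {"y": 0.6, "z": 0.4},
            "C": {"z": 0.5, "w": 0.3, "x": 0.2},
        },
    )


def _draw(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def sample_tagged_corpus(
    params: HmmParams,
    n_sentences: int,
    sentence_len: int = 12,
    seed: int | np.random.Generator = 0,
) -> list[TaggedSentence]:
    """Sample fixed-length tagged sentences from a known HMM."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corpus: list[TaggedSentence] = []
    for _ in range(n_sentences):
        sentence: TaggedSentence = []
        tag = _draw(rng, params.bos)
        for _ in range(sentence_len):
            token = _draw(rng, params.emissions[tag])
            sentence.append((token, tag))
            tag = _draw(rng, params.transitions[tag])
        corpus.append(sentence)
    return corpus


# ---------------------------------------------------------------------------
# Evaluation-set generation
# ---------------------------------------------------------------------------

_AMBIGUOUS_TEMPLATES = ("paren", "dose", "possessive", "slash_and",
                        "slash_per", "range", "period", "plus")
_PLAIN_TEMPLATES = ("jj_nn", "jj_jj_nn", "drug_nn", "jj_nns", "nn_of_nn")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic evaluation world.

    ``ambiguity_rate`` is the proportion of units containing at least one
    ambiguous token boundary (default 0.455, the ambient rate of the kind of
    concept-description data this emulates); the achieved count is
    ``floor(rate * n_units + 0.5)`` (half-up), exact by construction.
    ``in_domain_fraction`` sets the clinical share of the training-corpus
    mixture (1.0 = in-domain only, 0.0 = out-of-domain only).
    """

    seed: int
    n_units: int = 500
    ambiguity_rate: float = 0.455
    in_domain_fraction: float = 1.0
    n_train_sentences: int = 1200
    train_sentence_len: int = 12
    ambiguous_templates: tuple[str, ...] = _AMBIGUOUS_TEMPLATES
    plain_templates: tuple[str, ...] = _PLAIN_TEMPLATES

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError(f"invalid ambiguity rate {self.ambiguity_rate!r}")
        if not 0.0 <= self.in_domain_fraction <= 1.0:
            raise ValueError("in_domain_fraction must be in [0, 1]")
        unknown = set(self.ambiguous_templates) - set(_AMBIGUOUS_TEMPLATES)
        unknown |= set(self.plain_templates) - set(_PLAIN_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _instantiate_ambiguous(name: str, rng: np.random.Generator
                           ) -> tuple[str, tuple[str, ...]]:
    if name == "paren":
        jj, nn = _pick(rng, _JJ), _pick(rng, _NN_PLAIN)
        sem = _pick(rng, _SEMANTIC_TAGS)
        return f"{jj} {nn} ({sem})", (jj, nn, "(", sem, ")")
    if name == "dose":
        drug = _pick(rng, _NNP)
        num = _pick(rng, _CD_INT + ("0.5", "1.2", "2.4"))
        unit = _pick(rng, _NN_UNITS)
        nn = _pick(rng, ("tablet", "solution", "dose", "capsule"))
        return f"{drug} {num}{unit} {nn}", (drug, num, unit, nn)
    if name == "possessive":
        epo = _pick(rng, _EPONYMS)
        nn = _pick(rng, ("syndrome", "disease", "disorder"))
        return f"{epo}'s {nn}", (epo, "'s", nn)
    if name == "slash_and":
        jj = _pick(rng, _JJ)
        a, b = _pick(rng, _NNS), _pick(rng, _NNS)
        return f"{jj} {a}/{b}", (jj, a, "and", b)
    if name == "slash_per":
        num = _pick(rng, _CD_INT)
        a = _pick(rng, _NN_UNITS)
        b = _pick(rng, tuple(u for u in _NN_UNITS if u != a))
        nn = _pick(rng, ("dose", "solution"))
        return f"{num} {a}/{b} {nn}", (num, a, "per", b, nn)
    if name == "range":
        jj, nn = _pick(rng, _JJ), _pick(rng, ("injury", "fracture", "lesion"))
        c = _pick(rng, _NN_FUNCTIONAL)
        d = _pick(rng, ("4", "5", "6", "7", "8", "9"))
        return f"{jj} {nn} {c}-{d}", (jj, nn, c, "to", d)
    if name == "period":
        jj, nn = _pick(rng, _JJ), _pick(rng, _NN_PLAIN)
        return f"{jj} {nn}.", (jj, nn, ".")
    if name == "plus":
        d1 = _pick(rng, _NNP[:5])
        d2 = _pick(rng, tuple(d for d in _NNP[:5] if d != d1))
        nn = _pick(rng, ("tablet", "solution"))
        return f"{d1} + {d2} {nn}", (d1, "and", d2, nn)
    raise ValueError(f"unknown template {name!r}")


def _instantiate_plain(name: str, rng: np.random.Generator
                       ) -> tuple[str, tuple[str, ...]]:
    if name == "jj_nn":
        toks = (_pick(rng, _JJ), _pick(rng, _NN_PLAIN))
    elif name == "jj_jj_nn":
        toks = (_pick(rng, _JJ), _pick(rng, _JJ), _pick(rng, _NN_PLAIN))
    elif name == "drug_nn":
        toks = (_pick(rng, _NNP[:5]), _pick(rng, ("tablet", "solution", "capsule")))
    elif name == "jj_nns":
        toks = (_pick(rng, _JJ), _pick(rng, _NNS))
    elif name == "nn_of_nn":
        toks = (_pick(rng, _NN_PLAIN), "of", _pick(rng, _NN_PLAIN))
    else:
        raise ValueError(f"unknown template {name!r}")
    return " ".join(toks), toks


def is_ambiguous_unit(text: str, gold: Sequence[str]) -> bool:
    """A unit is ambiguous iff its gold differs from whitespace splitting."""
    return tuple(text.split()) != tuple(gold)


def generate_eval_set(spec: FixtureSpec
                      ) -> tuple[list[TextUnit], dict[str, tuple[str, ...]]]:
    """Generate a seeded evaluation set with gold tokenizations.

    Exactly ``floor(rate * n + 0.5)`` units contain an ambiguous boundary;
    the rest are tokenizable by whitespace alone.  Same spec (same seed)
    yields byte-identical output.  Every gold sequence is reachable in the
    default lattice by construction.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_units
    n_amb = int(spec.ambiguity_rate * n + 0.5)
    flags = np.zeros(n, dtype=bool)
    flags[:n_amb] = True
    rng.shuffle(flags)

    units: list[TextUnit] = []
    gold: dict[str, tuple[str, ...]] = {}
    for i, ambiguous in enumerate(flags):
        if ambiguous:
            name = _pick(rng, spec.ambiguous_templates)
            text, tokens = _instantiate_ambiguous(name, rng)
        else:
            name = _pick(rng, spec.plain_templates)
            text, tokens = _instantiate_plain(name, rng)
        uid = f"u{i:04d}"
        units.append(TextUnit(text=text, unit_id=uid))
        gold[uid] = tokens
    return units, gold


def generate_tagged_corpus(
    spec: FixtureSpec,
) -> tuple[list[TaggedSentence], dict[str, HmmParams]]:
    """Sample a slash-format training corpus per the spec's domain mixture.

    Returns the sentences together with the ground-truth HMM parameters of
    each mixture component actually used (keys ``"clinical"`` and/or
    ``"general"``), for parameter-recovery tests.
    """
    n_in = int(spec.in_domain_fraction * spec.n_train_sentences + 0.5)
    n_out = spec.n_train_sentences - n_in
    sentences: list[TaggedSentence] = []
    params: dict[str, HmmParams] = {}
    if n_in:
        params["clinical"] = clinical_hmm_params()
        sentences += sample_tagged_corpus(
            params["clinical"], n_in, spec.train_sentence_len,
            np.random.default_rng([spec.seed, 2]),
        )
    if n_out:
        params["general"] = general_hmm_params()
        sentences += sample_tagged_corpus(
            params["general"], n_out, spec.train_sentence_len,
            np.random.default_rng([spec.seed, 3]),
        )
    return sentences, params
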