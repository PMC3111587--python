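# Methods

## Model and procedure

A tokenizer is formalized as `T = (Σ, L_m, Γ)`: an alphabet, a language
model with a finite POS tag set `E(L_m)` and contexts `C(L_m)`, and a
tokenization function `Γ : C × S′ → T_t` mapping a context and a string to
a tagged token sequence. A *good* tokenizer returns
`argmax_{t_t} P(t_t | c, s, L_m)`. The implementation factors this argmax
into three parts.

**Token transducers.** Each transducer `τ(c, s′) → (l, (t₀…t_m))` inspects
the start of a suffix and either consumes `l > 0` characters, emitting a
candidate token sequence, or returns the not-applicable value `(0, ∅)`.
Transducers are deterministic pattern rules; all applicable readings enter
the lattice, so rule precedence never matters. The slash is genuinely
ambiguous between coordination and rate (`organ/system` = "organ and
system", `ml/g` = "ml per g"); the expansion transducer contributes *both*
readings when both are plausible (short lowercase sides look like units)
and the decoder resolves the choice by POS likelihood.

**Lattice construction.** For one text unit the constructor applies every
transducer at every character position and inserts each result as an edge
path from position vertex `v_i` to `v_{i+l}`. Whitespace is consumed by an
unlabelled ε-edge. Edges are deduplicated on `(from, label, to)`; edges on
no complete `v_0 → v_n` path are pruned afterwards, which preserves the
complete-path set. Coordinates are 0-based, half-open.

Interior vertices of multi-token readings: when the emitted tokens tile
the consumed surface exactly (`patient + 's = patient's`, `50 + mg =
50mg`), interior nodes are the real position vertices, so a reading that
two transducers produce independently (the quantity split, and the numeric
run followed by the alphabetic run) collapses into one edge path — no two
complete paths carry the same token sequence. When a token was rewritten
(`C1-4 → C1 to 4`; `to` replaces `-`), fresh auxiliary vertices keep the
reading isolated so alternatives cannot cross-talk. For this sharing to be
safe the apostrophe is not an independent punctuation symbol: the
possessive transducer owns it, otherwise the interior vertex of
`patient + 's` would open a spurious `patient ' s` path (and the worked
eight-reading example would not count eight).

**Decoding.** The adapted Viterbi decoder runs dynamic programming over
states `(vertex, last tag)` in topological order of the DAG; ε-edges
advance the vertex without scoring. It is exact for the argmax above:
scores are raw joint log-probabilities, so paths of different lengths
compete by probability alone (the literal argmax; no length
normalization). A per-token-normalized mode exists behind a flag; it
augments the DP state with the emitted-token count, since a normalized
objective is otherwise not prefix-decomposable. Ties break
deterministically: fewer tokens, then lexicographic tokens, then
lexicographic tags. A brute-force oracle (exhaustive path × tagging
enumeration scored independently via `score_path`) backs the decoder in
the test suite; the two are never collapsed onto one code path.

**Language model.** Supervised counting from a slash-format tagged corpus.
Order 1 scores `Σ_i log P(tag_i | tag_{i−1}) + log P(token_i | tag_i)`
with the first transition conditioned on a begin-of-sequence symbol; order
0 replaces the transition by the unigram tag prior (the joint
`P(tag, token)` — "no transitional probabilities" forbids only the
transitions; a pure-emission variant would make all order-0 comparisons
degenerate across tags with equal emission support). There is no
end-of-sequence factor. All scoring is in natural logs.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `order` | 1 | HMM order: 0 = tag prior + emissions, 1 = adds one-step tag transitions |
| `alpha` | 0.1 | additive (Lidstone) smoothing constant for emissions, transitions and the tag prior; 0 = MLE, unseen events impossible |
| `vocab_size` | trained types + 1 | emission denominator bins; the +1 is a single unknown-token bucket into which every out-of-vocabulary token falls |
| `normalize` | off | per-token-normalized decoding objective |
| `ambiguity_rate` | 0.455 | fixture generator: fraction of units with ≥ 1 ambiguous boundary (the ambient rate in the concept-description data this emulates) |
| `in_domain_fraction` | 1.0 | fixture generator: clinical share of the training-corpus mixture |

The smoothing scheme is this package's choice; nothing forces additive
smoothing or a single unknown bucket, and both are deliberately simple.
Consistent with that simplicity, rare numeric forms unseen in training
(e.g. novel decimals) score as unknowns and can be mis-segmented — a
feature-based unknown model would be the natural extension.

## Synthetic data: what it emulates, and what it does not

The fixture generator emulates SNOMED CT style concept descriptions with
the documented ambiguity sources: digit–unit fusion (`50mg`), possessive
clitics, terminal periods, ranges (`C1-4`), slash and plus lists, and
parenthesized semantic tags (`(disorder)`). Gold sequences are built
alongside the text, so gold reachability in the default lattice is a hard
generator guarantee. Exactly `floor(rate · n + 0.5)` units are ambiguous
(half-up rule); an ambiguous unit is precisely one whose gold differs from
its whitespace segmentation.

Training corpora are sampled from fully specified first-order HMMs whose
parameters are returned for recovery tests. The *clinical* HMM encodes the
regularities the decoder exploits: plural nouns precede coordinations
(NNS → CC, never → IN), unit nouns follow numbers and precede "per"
(CD → NN → IN), parenthesized tags are `( NN )` spans. The *general* HMM is
newswire-like: no parentheses, no unit or drug vocabulary. Mixing them
emulates out-of-domain vs domain-augmented training.

The synthetic world is far more regular than real clinical text: tiny
vocabularies, template-bound syntax, no misspellings, no abbreviation
periods, no genuinely out-of-grammar descriptions. Passing tests therefore
demonstrate the *mechanisms* — that the lattice holds gold readings, that
POS context resolves boundary ambiguity, that domain-matched training data
helps — not any particular accuracy on real descriptions. Accuracies
measured on this world (high 80s for the order-1 decoder, mid 50s for
out-of-domain training, which collapses to whitespace-level performance)
reproduce the direction and rough shape of those mechanisms only.

The hand-tagged fixture corpus behind the worked examples consists of the
examples' gold segmentations plus four extra pattern sentences
(coordination and range constructs in second contexts), replicated 50×
(≈ 3.6k tokens). The replication leaves count ratios unchanged but scales
counts so the smoothed unknown bucket is small relative to seen events, as
it would be under a realistically sized corpus; at toy scale the unknown
bucket is so cheap that unsplit unknown tokens would beat three-token
expansions regardless of fit.

## Numerical and design choices

- **Problem sizes.** The qualitative order/domain comparisons run on a
  seeded 500-unit evaluation set with 1200 training sentences of 12 tokens;
  parameter recovery uses 10,000 sampled tokens of a 3-tag HMM. Decoder ×
  oracle equivalence is checked on 200 random lattices of ≤ 4 segments
  (≤ 3 readings of 1–2 tokens each) under 2-tag random models, sizes at
  which exhaustive enumeration is itself cheap to trust.
- **Degenerate inputs.** The empty unit yields a single-vertex lattice and
  the empty tagged sequence with log-probability 0; whitespace-only units
  decode the same way through ε-edges. An empty transducer set on
  non-empty text raises an uncovered-position error; with `alpha = 0`, a
  lattice whose every path contains an unseen event raises an
  all-paths-impossible error rather than returning an arbitrary path.
- **Hyphen policy.** A hyphen between alphabetic runs stays in-token
  (`non-commissioned`); an alphanumeric head before a pure-number tail is
  a range (`C1-4`); a pure-letter head keeps the token whole as a
  functional name (`H-987`); a free-standing hyphen is an independent
  token.
- **Emission of expansions.** Default output keeps surface forms
  (`50mg → 50 mg`, not `milligrams`); per-transducer transform tables can
  rewrite emitted tokens when normalized forms are wanted.
- **Tag inventory.** Penn Treebank tags by default; training extends the
  inventory with any additional tags observed in the corpus.
- **Numerals.** Among the numeric sub-patterns (comma-grouped, decimal,
  fraction, roman, integer) the longest match wins, so `1.2` is never read
  as `1`. Pure-digit fractions (`1/2`) belong to the numeric class, not to
  the slash expansion.

## Known limitations

- The unknown-token model is a single bucket: all out-of-vocabulary tokens
  are equally likely given a tag. Decimals, novel substances and typos are
  indistinguishable to it.
- Transducers are position-exhaustive pattern rules; there is no learned
  transducer (e.g. a named-entity recognizer), although the contract
  admits one.
- The context tuple is threaded through but the default transducers ignore
  it; context-sensitive transduction is unexercised.
- No sentence segmentation: every input line is one unit.
- `k`-best decoding and lattice rescoring with external models are out of
  scope.
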