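# tokenlattice

Lattice-based tokenization of biomedical and clinical text.

Tokenizing clinical phrases is harder than it looks: in a SNOMED CT style
concept description such as `The patient's 10mg tablet.`, the apostrophe,
the letter `m` and the final period all *ambiguously* act as token
boundaries (`10mg` vs `10 mg`, `tablet.` vs `tablet .`). Rule lists resolve
such ambiguity by fiat and generalize poorly. This package takes a
different route: keep every plausible reading, and let a part-of-speech
language model choose.

The tokenizer is assembled from three components:

1. **Token transducers** — small deterministic functions
   `τ(c, s) → (l, (t₀…t_m))` that, at a text position, consume `l`
   characters and emit a (possibly transformed) candidate token sequence.
   The default set covers alphabetic words, numerals (decimals, comma
   groups, fractions, roman numerals), possessive clitics (`Sjogren's →
   Sjogren 's`), standalone punctuation, chemical substances / serotypes /
   functional names (`Precorrin-3B`, `O128:NM`, `H-987` stay whole) and
   closed-class expansions (`C1-4 → C1 to 4`, `organ/system → organ and
   system`, `ml/g → ml per g`, `50mg → 50 mg`).
2. **The lattice constructor** — applies every transducer at every
   character position and assembles the results into a bounded DAG
   `G = (V, E)` whose vertices are character positions and whose labelled
   edges carry candidate tokens; every complete path is a candidate
   tokenization. Whitespace becomes unlabelled ε-edges.
3. **An adapted Viterbi decoder** — dynamic programming over lattice
   states `(vertex, tag)` under a POS-tag hidden Markov model, returning

   `Γ(c, s) = argmax_{t_t} P(t_t | c, s, L_m)`,

   the most likely *tagged* token sequence over all complete paths and all
   tag assignments. The HMM (order 0 = emissions with a unigram tag prior;
   order 1 = with one-step tag transitions) is trained by counting from a
   `token/TAG` slash-format corpus with additive smoothing and a single
   unknown-token bucket.

Evaluation utilities implement exact-match tokenization accuracy with the
normal-approximation binomial confidence interval, and inter-segmentor
agreement via Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` with a coin-toss
chance term `p_e = 0.5`. A fixtures module generates seeded synthetic
concept descriptions (with a configurable ambiguous-boundary rate), gold
tokenizations, and training corpora sampled from known ground-truth HMMs,
so the full pipeline is testable without licensed corpora.

## Worked example

```python
from tokenlattice import build_lattice, enumerate_token_sequences
from tokenlattice import train, tokenize, paper_training_corpus
from tokenlattice.transducers import default_transducers

td = default_transducers()
lat = build_lattice("The patient's 10mg tablet.", td)
print(len(enumerate_token_sequences(lat)))

model = train(paper_training_corpus(), order=1, alpha=0.1)
result = tokenize("The patient's 10mg tablet.", td, model)
print(result.tokens)
print([tag for _, tag in result.items])
print(round(result.logprob, 2))
```

prints

```
8
('The', 'patient', "'s", '10', 'mg', 'tablet', '.')
['DT', 'NN', 'POS', 'CD', 'NN', 'NN', '.']
-19.55
```

The lattice holds the eight readings produced by the three ambiguous
boundaries (2 × 2 × 2, times the unambiguous `The`); the decoder picks the
fully split reading because `patient 's`, `10 mg` and `tablet .` form the
most probable tagged sequence under the model — e.g. `'s` is a possessive
clitic (`POS`) that follows nouns, and a number (`CD`) before a unit noun
is far more likely than the unknown token `10mg`. Its natural-log joint
probability is −19.55.

The same pipeline is available from the shell:

```sh
tokenlattice fixtures --seed 42 --n-units 500 --outdir world/
tokenlattice train world/corpus.txt -o model.json --order 1 --alpha 0.1
tokenlattice tokenize world/units.tsv -m model.json --with-ids -o pred.tsv
tokenlattice evaluate pred.tsv world/gold.tsv
tokenlattice lattice "Primidone 50mg tablet" --dot lattice.dot
```

`evaluate` prints accuracy as a percentage with its 95% confidence
interval, plus percent agreement and kappa against the gold.

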