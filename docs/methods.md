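# Methods

This note documents the models and procedures implemented in `mdrel`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic corpus does and does not establish.

## Entity tagging

Tokenization is whitespace plus punctuation splitting with punctuation kept
as separate tokens; the synthetic tree fixtures use the same tokenization,
which keeps token/leaf alignment exact. Lexicon matching is longest-match,
leftmost-first and case-insensitive, with one exception: single-token
all-uppercase entries (acronyms such as `MRSA`) match case-sensitively, to
avoid false hits on common lowercase words. When a microbe match and a
disease match overlap, the microbe lexicon wins by default — strain names
are the more specific vocabulary — and the order is a parameter of
`tag_entities`. Tagging is idempotent because tagged tokens carry the
`BAC00`/`DIS00` prefix and never re-match a lexicon entry.

## Relation detector

**Architecture.** Six layers: input, embedding, entity-based attention,
four bottom many-to-one bi-LSTMs (Seq1, Seq2, Seq3, SDP), a top bi-LSTM
over six steps, and a linear softmax head. Defaults follow the reference
geometry: word 200 / POS 10 / dependency-tag 10 / position 20 dims, hidden
100 (so each bi-LSTM emits a 200-vector), 60 time steps per phrase and 12
for the SDP, Adam at learning rate 0.001, 30 epochs, input/output dropout
0.7/0.5.

Decisions taken where the architecture description leaves room:

- **Position features** (20 dims): two concatenated 10-bin one-hots, the
  relative distance to each entity clipped to [−4, +5], one bin per value.
- **Top-layer order**: [Seq1, E1, Seq2, E2, Seq3, SDP] — sentence order,
  SDP last.
- **Entity embedding**: mean of the word vectors of the canonical-name
  components; when the word dimension differs from 2·hidden (only in
  reduced geometries) a trainable linear projection aligns them.
- **Attention combination**: the averaged weights multiply the word-vector
  block of each token's features before the bottom LSTMs, rescaled by the
  sentence length so weighted vectors keep unit-order magnitude (a raw
  softmax weight scales as 1/length and would shrink long sentences).
  The averaged weights already sum to 1 and are not renormalized.
- **Many-to-one readout**: concatenation of the last forward and last
  backward hidden state at each sequence's true length. Masking freezes
  the recurrent state beyond the true length, so extra padding provably
  never changes the output (tested). Empty segments contribute zero
  vectors.
- **Truncation**: segments longer than the budget are cut at the end
  farthest from the nearest entity (Seq1 keeps its right end, Seq3 its
  left end, Seq2 and the SDP keep both ends); entity-adjacent context
  matters most.
- **Dropout semantics**: the configured values are keep-probabilities by
  default (`dropout_semantics="drop"` flips the interpretation), applied
  as inverted dropout at training time only; inference is deterministic.
- **POS/dependency embeddings** are trained jointly from seeded random
  initialisation. Word vectors are loaded from word2vec text format or
  drawn deterministically per token from a seeded hash; they are not
  fine-tuned.
- Ties at probability 0.5 predict the negative class. Loss is unweighted
  cross-entropy.

**Implementation.** The network and Adam run on a small in-package
reverse-mode autodiff core (`mdrel.autodiff`) over numpy arrays — 2-D
tensors, matmul, slicing, concat, embedding gather, fused softmax
cross-entropy. Training is batched with per-sample length masks; the
backward direction consumes sequences reversed within their true length at
the array level. All randomness flows through `numpy.random.Generator`
seeded from the config, so training is bit-reproducible.

**Desk-scale geometry.** `DetectorConfig.desk_scale()` — word 50, hidden
32, 8/6 time steps, 6 epochs, batch 64, learning rate 0.003 — is the same
architecture at a size that makes tenfold cross-validation on ~1000 pairs
take about a minute on one CPU. The tests and the acceptance script use
it; the full-size defaults remain available and are exercised for the
tensor-geometry checks.

**Evaluation.** Pair-level precision/recall/F over candidate pairs;
sentence-level metrics aggregate by "any positive pair" on both gold and
prediction sides, since a sentence asserts an association iff at least one
of its pairs does.

## TPE engine

The pattern grammar is `{LABEL_RE item*}` for internal nodes,
`<POS_RE WORD_RE>` for leaves, `*` for exactly one arbitrary subtree, `**`
for a gap of zero or more consecutive siblings, and a `k#` prefix marking
capture k ∈ {1,2,3}. Regexes use full-match semantics. Matching anchors
the pattern at every node and aligns child sequences left-to-right with
backtracking over gaps; all distinct captured triples are reported and
verified against an exhaustive alignment-enumeration oracle on random
trees. Matching is monotone in the pattern library by construction.

The two shipped patterns were canonicalised from typeset originals that
carry spacing and bracket artifacts; the verbatim forms are preserved as
comments in `mdrel/data/patterns.tsv`. Where the original notation was
ambiguous about whether `*` spans one subtree or many, this implementation
fixes `*` = one subtree and `**` = gap, and the canonical patterns use
`**` wherever a single-subtree reading cannot embed in a conventional
constituency tree. Relation words are stemmed at extraction time.

## Stemming

Relation words are reduced by an inflectional stemmer that strips only
-s/-es/-ed/-ing (with the standard AT→ATE / BL→BLE / IZ→IZE and
doubled-consonant repairs), applied per underscore-separated component of
chunked words. Full derivational stemming is deliberately not used: it
maps "causes"→"caus" and "associated"→"associ", destroying the surface
readability the output triplets need, whereas the inflectional steps give
"cause" and "associate" and are idempotent.

## Dependency-based extraction

Fixed rule pipeline per sentence: chunk → distance filter → preposition
rule → LCA rule → inheritance.

- **Chunking.** For each `word —nmod:of/with→ entity` edge the governing
  word merges with its amod/compound modifiers (innermost governors
  first), e.g. "common cause of DIS00sepsis" → node `common_cause`; an
  entity attached to its parent by a compound edge merges with the parent,
  the parent word retained as the chunk's relation candidate. Merges are
  group contractions of connected subgraphs, so acyclicity and
  single-headedness are preserved by construction and the merged nodes
  partition the original tokens (both tested).
- **Distance filter.** Pairs farther than 4 edges apart (default,
  `--max-dep-distance`) are dropped; conj, conj:and, conj:or, compound and
  appos edges are free. The boundary value is retained.
- **Preposition rule** (PREP_SIMPLE): a direct entity–entity edge whose
  nmod/obl subtype is one of by, in, from, on, with, of, due_to, between
  emits that connector; "induced" is additionally recognised as an amod on
  either entity.
- **LCA rule.** The LCA of the pair on the chunked tree carries the
  relation: a child attached by acl, acl:relcl, amod, xcomp, ccomp, appos,
  nmod:as, conj:and, conj:or, advcl or dep if one exists, else the LCA's
  own word (both under rule id LCA_CHILD). Qualifying children are ranked
  by that label-list order, ties broken by token position — an acl
  participle ("implicated") outranks an incidental amod ("emerging") on
  the same head, which plain leftmost selection would wrongly prefer. The
  edge-label list is treated as exact and is configurable. When an entity
  is itself the LCA the connecting edge's label is emitted
  (LCA_SELF_EDGE) — a deliberate, low-precision fallback whose
  reliability the ensemble learns; when the entity chunk already carries a
  combined word, that word is emitted instead (NO_LCA_CHUNK).
- **Inheritance** (INHERIT): same-class entity chunks connected
  (transitively, either direction) by conj/appos/compound edges form
  components; a relation held by any member propagates to all. Disabling
  inheritance removes exactly the pure-INHERIT triplets.

Both the preposition and the LCA rule may fire for one pair; both triplets
are emitted and the ensemble arbitrates. DBE outputs surface relation
words; stemming is applied once, centrally, at the ensemble merge, which
keeps worked examples legible ("implicated") while merging consistently.

## Ensemble

Pattern reliabilities are estimated from labelled extractions with
add-α smoothing (α = 1 by default; an unseen-word bucket of size |V|+1
avoids zero likelihoods): Pr(p) = (n_correct+α)/(n_extractions+2α), and
Pr(r|p), Pr(r|¬p) as smoothed frequencies among correct/incorrect
extractions. Correctness is exact match of (microbe, disease, stemmed
relation) against gold — no partial credit. DBE rule ids act as patterns
alongside TPE pattern ids. A pattern queried with no recorded extractions
falls back to the pure-smoothing prior 0.5 with a logged warning.

The posterior is the two-hypothesis Bayes formula; the triplet confidence
is the maximum posterior over contributing patterns from both extractors;
merged triplets below the threshold (default 0.5, the value at which the
extraction F peaks) are dropped. Monotonicity in the prior and the unit
interval of the posterior are property-tested.

Extraction quality is reported as macro-averaged precision/recall/F over
the relation-word classes present in gold; classes with no predictions
score zero precision. Cross-validation splits at sentence level so all
pairs of a sentence share a fold, deterministically under the seed.

## Association network

Aggregation counts extractions per (microbe, disease) and keeps the bag of
stemmed relation words. Filtering is fixed-order: excluded disease terms
first (default {"infection"} — a generic co-mention magnet), then records
whose count falls strictly below the mean count of the remaining records.
The mean is always computed from the data at hand; no corpus-specific
constant is hard-coded. Disease pairs need ≥ 2 shared microbes for a
Jaccard edge (the single-common-bacterium exclusion read as a pair-wise
intersection condition; the alternative per-disease reading is available
as `min_microbes_per_disease`), and the network keeps edges at similarity
≥ 0.6 with node size = microbe count. MeSH categories enter only as a
user-supplied two-column lookup table.

## Synthetic corpus

The generator emulates a hand-annotated corpus of co-mention sentences at
the scale used throughout (920 sentences ≈ 1000 candidate pairs, 60%
positive) with seven positive construction families — active verb,
passive participle, comma appositive, copular of-chunk, coordinated
diseases, due-to connector, entity compound — and two negative co-mention
families, each with exact template-generated trees. The generator shares
no code with the extractors; planted relation words are declared, not
computed. The noise knob rewrites the relation verb of a fraction of
positive sentences (default for end-to-end runs: 0.1) to an
out-of-inventory synonym while keeping the planted gold word, so extractor
recall and detector difficulty are non-degenerate.

What passing tests on this corpus show: the architecture trains and
separates structurally distinct positives from negatives; the extractors
recover exactly the planted words on the families they cover; the ensemble
strictly dominates either extractor because their template coverage is
complementary (TPE misses chunked and connector families, DBE mis-handles
the appositive via its entity-as-LCA fallback and fires spuriously on
negatives, which the confidence threshold then suppresses). What they do
not show: robustness to real parser errors, paraphrase variety,
cross-sentence coreference, or lexical ambiguity of real abstracts — the
templates are syntactically faithful but lexically narrow, and detector
scores near 1.0 on this corpus should be read as a correctness check, not
a performance claim.

## Numerical and degenerate-input choices

- All stochastic components (generator, initialisation, shuffling,
  dropout, fold assignment, OOV vectors) draw from PCG64 generators seeded
  from explicit config values; identical seeds give byte-identical
  corpora and bit-identical training runs.
- Attention softmax subtracts the max score; sigmoid inputs are clipped at
  ±50; cross-entropy clips probabilities at 1e-12.
- LSTM forget-gate biases initialise to 1, other weights Glorot-uniform.
- A sentence with zero microbe or zero disease mentions yields zero
  candidate pairs (not an error); a single-class training set is an error.
- Duplicate triplets merge provenance in first-seen order and keep the
  first surface form.

## Known limitations

- The dictionary tagger does no abbreviation resolution or ontology
  normalization; unseen surface forms are simply missed.
- Only basic (single-head) dependency trees are supported; enhanced graphs
  with multiple heads are out of scope.
- The shipped TPE library holds the two curated patterns; realistic recall
  on free text requires users to extend the pattern file.
- The LCA rule emits a raw edge label when an entity dominates its partner
  — informative to the ensemble, rarely a fluent relation word.
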