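# mdrel — microbe–disease association extraction from the literature

`mdrel` extracts microbe–disease associations from biomedical text. It is
aimed at researchers who want to mine sentences such as

> *"Pseudomonas aeruginosa is a pathogen that frequently causes acute lung
> injury."*

into structured relation triplets — (microbe, disease, relation word), here
`(Pseudomonas_aeruginosa, acute_lung_injury, cause)` — and aggregate them
corpus-wide into association tables and a disease-similarity network.

## The pipeline

1. **Entity tagging** (`mdrel.ner`) — dictionary NER with longest-match,
   case-insensitive lookup against microbe and disease lexicons. Matched
   mentions are collapsed to single tagged tokens
   (`BAC00Pseudomonas_aeruginosa`, `DIS00acute_lung_injury`) so that one
   entity is always one token for every later stage.

2. **Relation detection** (`mdrel.detector`) — a hierarchical bidirectional
   LSTM decides, per candidate pair (one microbe × one disease mention in a
   sentence), whether an association is asserted. The two entities split the
   sentence into three phrases Seq1/Seq2/Seq3; together with the shortest
   dependency path (SDP) these feed four many-to-one bi-LSTMs. Each token is
   represented by word, POS, dependency-tag and relative-position features
   (200+10+10+20 dims), reweighted by entity-based attention

   θᵢᵏ = softmaxᵢ(wᵢ·eₖ),  θᵢ = (θᵢ¹+θᵢ²)/2,  k ∈ {1,2}.

   The 4×200 bottom output, interleaved with the two entity embeddings as
   [Seq1, E1, Seq2, E2, Seq3, SDP], forms the 6×200 input of a top bi-LSTM
   whose 200-vector output feeds a softmax over {no relation, relation}.

3. **Relation-word extraction** — two complementary parse-tree methods:
   * **TPE** (`mdrel.tpe`): tree pattern expressions — a query language over
     constituency parses with label/word regexes, subtree wildcards (`*`),
     sibling gaps (`**`) and capture groups `1#`(microbe) `2#`(disease)
     `3#`(relation). Two curated patterns ship in `mdrel/data/patterns.tsv`
     (appositive-with-commas, passive past-participle); the file format is
     user-extensible.
   * **DBE** (`mdrel.dbe`): dependency-tree rules — chunking of
     `word (of|with) entity` and entity compounds (`common cause of sepsis`
     → node `common_cause`), a pair-distance filter (≤ 4, coordination /
     apposition / compound edges free), a simple preposition-connector rule,
     relation words from the lowest common ancestor (LCA) or a descriptive
     child (acl, amod, xcomp, …), and inheritance across coordinated
     same-class entities.

4. **Ensemble** (`mdrel.ensemble`) — each triplet is scored with a Bayes
   confidence: for pattern pᵢ and relation word rⱼ,

   Pr(pᵢ|rⱼ) = Pr(rⱼ|pᵢ)Pr(pᵢ) / (Pr(rⱼ|pᵢ)Pr(pᵢ) + Pr(rⱼ|¬pᵢ)Pr(¬pᵢ)),
   conf(rⱼ) = maxᵢ Pr(pᵢ|rⱼ),

   with Pr(pᵢ) the pattern's empirical precision (add-α smoothed). Triplets
   below a confidence threshold (default 0.5) are dropped; the union of the
   two extractors under this score outperforms either alone.

5. **Association network** (`mdrel.network`) — triplets are aggregated per
   (microbe, disease) with counts; generic diseases (default `infection`)
   and below-mean-frequency records are filtered; diseases sharing ≥ 2
   microbes get a Jaccard similarity |A∩B|/|A∪B|, and pairs at ≥ 0.6 form
   the disease–disease network.

A seeded synthetic corpus generator (`mdrel.synthetic`) emits sentences with
gold constituency/dependency trees, pair labels and planted relation words
across the syntactic families above, so the whole pipeline is testable
without external parsers or downloads.

## Worked example

```bash
mdrel fixtures --out corpus --seed 5            # synthetic gold corpus
mdrel tag --text corpus/sentences.tsv \
          --microbes corpus/microbes.tsv --diseases corpus/diseases.tsv \
          --out tagged.jsonl
mdrel extract tpe --sentences tagged.jsonl --trees corpus --out tpe.tsv
mdrel extract dbe --sentences tagged.jsonl --trees corpus --out dbe.tsv
# fit pattern statistics on labelled data, then merge:
mdrel ensemble --tpe tpe.tsv --dbe dbe.tsv --stats stats.json \
               --threshold 0.5 --out merged.tsv
mdrel eval --pred merged.tsv --gold corpus/gold_triplets.tsv --mode macro
```

prints, for the 200-sentence seed-5 corpus:

```
tagged 200 sentences -> tagged.jsonl
TPE extracted 44 triplets -> tpe.tsv
DBE extracted 227 triplets -> dbe.tsv
kept 134 triplets at threshold 0.5 -> merged.tsv
macro precision=1.0000 recall=1.0000 f=1.0000
```

The DBE stream is noisy on purpose (it also fires on co-mention sentences
with no asserted relation); the confidence threshold removes those
extractions — 271 raw triplets shrink to 134 kept ones — while keeping every
planted gold triplet, hence the perfect macro scores on this noise-free
corpus. The detector is trained and evaluated the same way:

```bash
mdrel detect train --config dcfg.yaml --data corpus/gold_pairs.tsv \
                   --sentences tagged.jsonl --trees corpus --model model.npz --seed 3
mdrel detect eval  --data corpus/gold_pairs.tsv --sentences tagged.jsonl \
                   --trees corpus --model model.npz --level sentence
# -> sentence precision=1.0000 recall=1.0000 f=1.0000
```

In library code the same example is three calls:
`generate(GeneratorConfig(...))` → `LabelledCorpus.from_bundle(...)` →
`detector_tenfold_cv(...)` / `extraction_tenfold_cv(...)` (see
`mdrel.pipeline`).

## Scope notes

- No parser is bundled: trees come from gold fixtures or an external-parser
  adapter (`mdrel.trees.AdapterParseProvider`).
- Disease NER uses the same dictionary mechanism as microbe NER (no
  statistical NER model is included).
- Word vectors are file-loadable (word2vec text format) or deterministic
  seeded draws; no pretraining corpus is required.
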