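# farmaner

Recognition of chemical, drug and protein mentions in Spanish clinical
text, and normalization of each mention to a unique SNOMED-CT-style
concept code.

Clinical case reports mention pharmacological substances in endlessly
varied forms — acronyms (*GGT*), brand names (*Adriamicina*), reordered
multi-word terms (*D dímero* vs *dímero D*) — while a terminology such as
SNOMED-CT stores one canonical description per concept.  `farmaner`
implements the two stages needed to bridge that gap:

1. **Mention recognition.**  A BiLSTM-CRF sequence labeler over stacked
   word embeddings.  Each sentence is embedded token-by-token as
   `X = (x_1, …, x_n)`, where every `x_i` is the concatenation of the
   vectors produced by an ordered set of providers (static word vectors,
   corpus-trained medical vectors, pooled character-contextual vectors).
   A forward and a backward LSTM read `X`, a tanh layer projects the
   concatenated states to per-tag confidence scores, and a linear-chain
   CRF with learned transition scores decodes the best BIO tag path by
   Viterbi.  Training maximizes the CRF log-likelihood
   `score(y | X) − log Σ_y' exp score(y' | X)` by mini-batch SGD.
2. **Concept indexing.**  A hybrid matcher assigns each mention a code:
   first a supervised lookup in a surface→code map harvested from coded
   training mentions; then exact matching of the normalized mention, its
   dictionary synonyms, and their token permutations against catalog
   descriptions; finally fuzzy ranking of suggestion candidates by
   Levenshtein distance to the normalized mention.  All resources and
   queries share one normalization (lowercase, accents stripped,
   punctuation and Spanish stopwords removed).

Both stages are scored by strict-span micro-averaged precision/recall/F1
(a prediction counts only when document, start, end and entity type all
match a gold mention), plus per-document code-set comparison for indexing
and McNemar's paired test for system comparison.

The tagger, including the CRF forward/backward and Viterbi dynamic
programs and the LSTM backpropagation, is implemented directly in numpy;
exactness is verified against brute-force path enumeration in the test
suite.

## Worked example

```python
import farmaner as f

resources = f.make_fixture_resources()      # toy dictionary + catalog
code_map = f.TrainingCodeMap({})            # no supervised training codes

for surface in ["GGT", "Adriamicina", "beta-HCG", "antiRNA"]:
    r = f.index_mention(surface, code_map, resources.dictionary,
                        resources.catalog)
    print(f"{surface:12s} -> {r.code}  stage={r.stage:16s} "
          f"d={r.distance}  ({r.matched_description})")
```

prints

```
GGT          -> 60153001  stage=exact-synonym    d=0  (gamma glutamiltransferasa)
Adriamicina  -> 372817009  stage=exact-synonym    d=0  (doxorrubicina)
beta-HCG     -> 412126005  stage=fuzzy            d=26  (gonadotrofina corionica humana)
antiRNA      -> 47646004  stage=fuzzy            d=2  (antiarina)
```

*GGT* is not itself a catalog description, but its synonym group contains
*gamma-glutamiltransferasa*, which is — an exact match at distance 0.
*Adriamicina* reaches *doxorrubicina* the same way.  *beta-HCG* has no
synonym entry, so the fuzzy stage ranks suggestion candidates by edit
distance and selects the shorter of the two chorionic-gonadotropin
descriptions.  *antiRNA* lands on *antiarina* at distance 2 — a known
failure mode of edit-distance ranking on short acronyms, reproduced here
deliberately.

The command-line interface wires the same pieces into a workflow:

```bash
farmaner synth --seed 5 --out corpus/          # synthetic corpus + resources
farmaner train --train-dir corpus/train --dev-dir corpus/dev -o model.npz
farmaner tag --model model.npz -i corpus/test --out tagged/
farmaner index --synonyms corpus/synonyms.tsv --catalog corpus/catalog.tsv \
               --ann-dir tagged/ --out indexed/
farmaner eval-ner --gold corpus/test --system tagged/
```

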