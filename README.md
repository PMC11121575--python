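# comine

Literature-based comorbidity mining for an index disease, from MeSH-indexed
PubMed records.

Clinicians and bioinformaticians who want comorbid-disease candidates for a
disease of interest usually turn to electronic health records, which are hard
to access. `comine` implements the alternative: mine the co-indexing of
disease terms in the MeSH fields of a comorbidity-focused literature corpus,
rank the co-occurring diseases, test which co-occurrences are statistically
significant, and intersect disease gene sets to find genes shared across
three or more of the diseases ("multimorbidity signatures").

## The statistics

Given a corpus of articles retrieved with a query of the form
*index disease* [MeSH] AND *Comorbidity* [MeSH]:

- **Sort ratio.** Each co-occurring disease C is ranked by
  `P_eachPair / P_all`, where `P_eachPair` is the number of articles whose
  MeSH index contains both the index disease and C, and `P_all` the number of
  articles containing the index disease together with at least one
  co-occurring disease.
- **Exact Fisher test.** For each C, four counts are tabulated: articles with
  both diseases (a), with C but not the index disease (b), with the index
  disease but not C (c), and the total size of the comorbidity corpus (N).
  A one-sided (enrichment) Fisher exact test is computed on the resulting
  2×2 table. P-values in this setting reach magnitudes of 1e-238 and below,
  so the hypergeometric tail is accumulated entirely in log space from
  log-gamma terms — no underflow down to the smallest printable tails.
  Three selectable table conventions (`margins`, `remainder`, `direct`)
  cover the published assembly of the four counts and the exact
  single-partition table; see `docs/methods.md`.
- **Multimorbidity signatures.** Given GMT gene sets for the index disease
  and its comorbid diseases, every gene is assigned the exact set of
  diseases whose gene sets contain it; genes shared by the index disease and
  two or more others form disjoint signature rows.

A synthetic-data module generates MEDLINE corpora with planted
index-conditional co-occurrence lift and GMT collections with planted shared
cores, so the whole pipeline is testable without any downloads.

## Worked example

```python
from comine import (ComorbidityModel, CorpusSpec, PlantedDisease,
                    simulate_corpus, build_lexicon, MeshDescriptor)

spec = CorpusSpec(
    n_articles=10_000,
    index_prevalence=0.4,
    planted=(
        PlantedDisease("Dementia", 0.12, 0.02),                  # 6x lift
        PlantedDisease("Diabetes Mellitus, Type 2", 0.06, 0.02), # 3x lift
    ),
    background=(("Hypertension", 0.03), ("Osteoporosis", 0.03)), # no lift
    seed=7,
)
corpus = simulate_corpus(spec)
names = ["Alzheimer Disease", "Dementia", "Diabetes Mellitus, Type 2",
         "Hypertension", "Osteoporosis"]
lexicon = build_lexicon(
    [MeshDescriptor(n, frozenset({"Nervous System Diseases"})) for n in names])

res = ComorbidityModel(corpus, lexicon, "Alzheimer Disease").fit()
print(res.summary())
```

```
Comorbidity mining results
==============================================================
Index disease:        Alzheimer Disease
Articles in corpus:   10000
Pairing articles:     865 (index + >=1 co-disease)
Co-occurring diseases:     4
Significant (p < 5e-08): 2
Fisher test:          greater, convention=remainder
--------------------------------------------------------------
Top 4 by sort ratio:
  Dementia                           455 /   865  ratio=0.5260  p=2.55e-96 *
  Diabetes Mellitus, Type 2          227 /   865  ratio=0.2624  p=4.01e-23 *
  Hypertension                       130 /   865  ratio=0.1503  p=4.61e-01
  Osteoporosis                       126 /   865  ratio=0.1457  p=9.79e-02
--------------------------------------------------------------
* significant at the configured threshold
```

The two diseases planted with co-occurrence lift rank first by sort ratio
(455 and 227 of the 865 pairing articles) and are flagged significant at the
5e-8 threshold; the two background diseases, sampled independently of the
index disease, are not. `res.cooccurrence` and `res.comorbidity` hold the
same numbers as pandas DataFrames.

The same pipeline is scriptable from the shell:

```bash
comine simulate corpus --config corpus.yaml --out corpus.medline
comine mine --lexicon descriptors.tsv --corpus corpus.medline \
            --index-disease "Alzheimer Disease" --out run/
comine genesets --gmt disease_sets.gmt --index-disease AD --out run/
comine fet --counts four_counts.tsv --convention margins
```

`mine` writes `cooccurrence.tsv` (ranked sort ratios), `comorbidity.tsv`
(four counts, p-values, significance) and a `manifest.json` with input
checksums; `genesets` writes `multimorbidity.tsv` and `pairwise.tsv`.

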