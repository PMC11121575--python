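# Methods

## Problem and model

`comine` infers comorbidity candidates for an index disease from literature
co-indexing. The unit of observation is one MeSH-indexed article from a
comorbidity-focused corpus (every article carries the "Comorbidity" MeSH
descriptor). Disease mentions are detected only in the MeSH index, by exact
match against a lexicon of disease descriptors; titles and abstracts are
never mined. This trades recall for precision: MeSH indexing is curated, so
an exact descriptor match is a high-confidence disease assignment, while
free-text mining would need disambiguation machinery out of scope here.

Two statistics are computed per co-occurring disease C:

1. **Sort ratio** `P_eachPair / P_all`: the fraction of "pairing" articles
   (index disease plus at least one other lexicon disease) that mention C.
   It is a ranking statistic, not a test: it orders co-diseases by how
   dominant they are among the index disease's literature co-mentions.
2. **Exact Fisher p-value** on a 2×2 table derived from four counts: a =
   articles with both diseases, b = with C but not the index disease, c =
   with the index disease but not C, N = total corpus size. The one-sided
   "greater" alternative asks whether the two diseases are co-indexed more
   often than independence at the table's margins would predict.

## Contingency conventions and their calibration

The four counts over-determine a 2×2 table, and published analyses of this
design are not explicit about the assembly. Three conventions are
implemented:

- `margins` *(default for pre-tabulated counts)*: b and c are treated as
  the two hypergeometric margins over a population of size N, i.e. cells
  `(a, b−a, c−a, N−b−c+a)`. Exact computation against the five reference
  rows of the analysis this package reproduces shows this convention
  matches **all five** published p-values to within 0.5% relative
  (1.30e-238, 0.68, 0.59, 6.28e-30, 1.88e-34); it is therefore the
  calibrated replication convention. Note that when b and c are defined
  *exclusively* (articles with C but **not** the index disease), this
  assembly subtracts the overlap twice; it is the exact test only when the
  marginal counts are inclusive.
- `remainder` *(default for corpus-derived analysis, `ComorbidityModel.fit`)*:
  cells `(a, b, c, N−a−b−c)`. For exclusive counts this is the exact
  single-partition table (both / C-only / index-only / neither) and is the
  statistically correct Fisher test; it coincides with `margins` applied to
  inclusive margins. The Type-I calibration test of the package uses it.
- `direct`: cells `(a, b, c, N)` with the corpus total dropped in as the
  d-cell. It approximates `remainder` when the index disease is rare in the
  corpus, but inflates the table total — and is anticonservative — when the
  index disease is common. Kept selectable for sensitivity analysis.

On the reference rows, `direct` reproduces only the two non-significant
p-values (0.667 vs 0.68; 0.584 vs 0.59) and misses the extreme tails by
~50 orders of magnitude, which is what motivated the calibration above.

Significance is the strict inequality `p < alpha` with `alpha = 5e-8` by
default — a genome-wide-style fixed threshold, used deliberately without
multiple-testing correction to mirror the replicated analysis. A
Benjamini–Hochberg option (`correction="bh"`, via
`scipy.stats.false_discovery_control`) is available but off by default.

## Numerical implementation

The hypergeometric tail is computed entirely in log space: log point
probabilities from log-gamma binomial terms, accumulated with log-sum-exp.
Tails are returned as both log-p (`fisher_exact_log_pvalue`) and p; p-values
below float underflow (~1e-308) come back as 0.0 while the log form stays
finite. A tail spanning the entire support is returned as exactly 1. The
two-sided rule sums every table whose point probability is at most the
observed one, with relative slack 1e-7 to absorb float noise in the
comparison; the enumeration oracle (`fisher_bruteforce_oracle`, exact
rational arithmetic via `fractions.Fraction`, limited to N ≤ 200) applies
the same rule, and the test suite checks agreement to 1e-10 relative on 500
random tables.

Ties in the sort-ratio ranking and in p-value ordering are broken
alphabetically; ratios are stored at full precision and rounded to four
decimals only in reports, p-values printed with three significant digits.

## Lexicon and parsing choices

- Normalization lowercases, strips the major-topic marker `*`, cuts
  qualifiers at the first `/`, collapses whitespace and maps Unicode
  apostrophes to ASCII. Matching is exact on the normalized string: entry
  terms/synonyms are not expanded, because MeSH indexing uses descriptor
  names verbatim.
- A descriptor is excluded only when *all* of its categories are excluded
  (default exclusion: "Animal Diseases"); a disease cross-listed under a
  human category survives.
- MEDLINE parsing is delegated to `Bio.Medline`; continuation lines join
  with a single space. Records without a PMID are skipped with a warning;
  duplicate PMIDs are an error, because article counts drive every
  statistic. Raw lexicon sizes and corpus tallies are recorded as
  provenance metadata, never asserted: they depend on the MeSH release and
  the query access date.

## Synthetic data: what it emulates and what it does not

`simulate_corpus` emulates a comorbidity query result: every article gets
the "Comorbidity" tag; the index disease appears with a configurable
prevalence; each planted co-disease appears with probability
`p_given_index` or `p_given_not_index` depending on the article's index
status; background diseases are independent of the index. Diseases are
conditionally independent given index status — adequate because the mining
statistics only consume pairwise margins. Not emulated: realistic MeSH
vocabulary sizes, qualifier usage, citation structure, or any higher-order
disease dependence; passing tests therefore demonstrate correct counting
and calibrated testing under the stated sampling model, not robustness to
real-world indexing noise. PMIDs are sequential integers offset to 9e8 to
stay clear of real PMIDs.

`simulate_genesets` plants gene "cores" shared by exactly a declared subset
of diseases plus disjoint private genes, making the expected multimorbidity
table known by construction.

All randomness flows through one `numpy.random.Generator` from a single
integer seed; equal seeds give byte-identical corpora.

## Validation problem sizes

The recovery study uses 20 replicates of 20,000-article corpora with one
planted co-disease (15% given the index disease, 1% otherwise; index
prevalence 0.5) among 20 background diseases at 1%, requiring the planted
disease to rank first and fall below 5e-8 in at least 95% of replicates.
Type-I calibration uses 200 replicates with zero lift and requires the
rejection rate at 0.05 to lie in [0.01, 0.10] — at or below nominal, since
the exact test is conservative on discrete tables. These sizes give stable
empirical rates while keeping the default suite fast.

## Known limitations

- Co-occurrence in a curated index is evidence of co-reporting, not of
  clinical comorbidity; the significance test inherits every bias of
  literature attention.
- Exact matching misses diseases indexed under narrower descriptors
  (no tree-walking or synonym expansion).
- The gene-set stage consumes whatever GMT sets it is given; no gene-alias
  harmonization or cross-species homology mapping is attempted.
- Pairwise gene-set counts and multimorbidity rows depend entirely on the
  curation tier of the input sets; nothing is tested against live gene-set
  services.
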