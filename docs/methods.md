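# Methods

## Text normalization and lexicon matching

Responses are normalized before matching: lowercase; any character that is
not a Unicode letter (punctuation, digits, hyphens, underscores) acts as a
token separator and is discarded. Umlauts and ß are letters and survive.
There is deliberately **no** spell correction, stemming or lemmatization:
the wordlist is the unit of scoring, so inflected forms must be enumerated
in it explicitly. This keeps matching transparent and reproducible — a
clinician can always point at the wordlist row that produced a score.

Matching is a left-to-right scan with longest-match-first, non-overlapping
consumption: at each token position the longest wordlist entry starting
there (up to the longest phrase in the list) is taken and its tokens are
consumed. Consequences worth knowing:

- every token contributes to at most one match, so `allsum` cannot
  double-count a token that belongs to both a phrase and a single entry;
- a phrase entry always beats its own prefix ("sehr traurig" wins over
  "traurig" when both are present at that position);
- every *occurrence* of an entry produces a separate match — repetition is
  visible to the 334 rule's identity test;
- matching is deterministic: identical (tokens, wordlist) pairs give
  identical results.

Phrase conflicts between *different* entries (e.g. overlapping phrases) are
resolved purely by scan order, which is the standard dictionary-matcher
behaviour and the simplest rule that is exactly reproducible.

"Identical" throughout the 334 family compares normalized wordlist *entry
ids* (the normalized surface), never raw tokens: the wordlist is the scoring
unit, and two different inflections listed as separate entries are therefore
different emotions as far as 334/3345plus are concerned.

## Scoring rules and their edge cases

Methods that do not distinguish self from other (`highest4`, `allsum`,
`334`) still match the two sections *separately* and pool the matches,
rather than matching the concatenated token stream. The two are equivalent
except when a phrase would span the self/other boundary — a match that ought
not to exist — so pooling is the safer construction.

- A purely cognitive response ("I would think he was wrong") matches
  nothing and scores 0 under every level method; no special level-0 handling
  exists or is needed.
- Missing or blank items score 0 and stay in the 20-item protocol sum, so
  the protocol scale never silently shrinks.
- `3345plus` compares the **sets** of value-3 entry ids across sections
  (duplicates ignored): "sad and angry" vs "angry and sad" is identical,
  "sad and angry" vs "sad and ashamed" is not.
- The `time` method never removes a respondent from scoring; the one-hour
  flag (`> 60` minutes, on the assumption that such respondents paused
  mid-entry) only excludes them from time-adjusted correlations.

## Statistics layer

- **Cronbach's α**: k/(k−1) · (1 − Σ s²ᵢ / s²_total) with sample (n−1)
  variances. The 95% CI is Feldt's classical F interval
  (df₁ = n−1, df₂ = (n−1)(k−1)) — the closed-form choice when no CI method
  is otherwise mandated; it agrees with `pingouin.cronbach_alpha`. Zero
  total variance raises an explicit undefined-statistic error rather than
  returning NaN.
- **Pearson r**: via `scipy.stats.pearsonr`; two-sided p from t with n−2
  df; CI by Fisher z (degenerate |r| = 1 collapses the CI to a point; n = 3
  has no Fisher CI).
- **Partial correlation**: residual method via `pingouin.partial_corr`
  (identical to the recursive partial-correlation formula); p from t with
  n−2−q df; the Fisher-z CI uses the covariate-adjusted standard error
  1/√(n−q−3). Word count and vocabulary are controlled *jointly* (one
  two-covariate partial correlation); rank-deficient covariate designs are
  rejected up front.
- **Group comparison**: Welch's unequal-variance t with Welch–Satterthwaite
  df — the safer default over pooled-variance Student's t, and consistent
  with non-integer error df under unequal group sizes.
- **Mean difference** between a method and a reference scoring is the mean
  *absolute* per-protocol difference — a magnitude, so methods that err in
  opposite directions on different respondents cannot cancel to a
  misleading zero.
- Missing covariate data are handled by listwise deletion per statistic,
  with the effective n reported in every cell. Binary covariates (gender,
  children) are coded 0/1 with the coding recorded in the report, since any
  sign convention is otherwise ambiguous.

## Synthetic data: what it emulates and what it does not

The original scored wordlist (1,093 German entries) and respondent data are
not redistributable, so `leascore.simulate` generates structural stand-ins.
The generator's contract is that **every score is known analytically**:

- Wordlist surfaces are pronounceable pseudo-German built from a fixed
  syllable alphabet; filler (never-matching) tokens come from a *disjoint*
  letter alphabet, so no filler can collide with a lexicon surface. At
  least one filler token separates consecutive inserted entries, so phrase
  matches cannot bridge them. Both guarantees together make the expected
  score of every constructed item exact, not approximate.
- Each respondent follows one profile applied to all 20 items — filler-only
  (level0), a single value-1/2/3 entry in self (level1–3), two distinct
  value-3 entries in self (level4), two distinct value-3 entries in *each*
  section with differing sets (level5_distinct) or identical sets
  (level5_identical). The expected item scores per profile follow directly
  from the scoring rules (e.g. level5_identical: 3345 = 5 but
  3345plus = 4 on every item).
- `level5_distinct` needs at least three value-3 entries in the wordlist
  (the other section reuses one self entry plus one fresh entry so the sets
  differ); the generator validates this and fails loudly.
- Auxiliary covariates emulate a healthy community sample: age ~ N(32,
  12.5²) clipped to 18–65, gender female with probability 130/208,
  education ordinal 1–4, children with probability 44/208, completion time
  uniform on 15–55 min with a 5% chance of a 65–90-min outlier so the
  one-hour exclusion is exercised. A graded covariate (`pat_like`,
  emulating a facial-affect perception total) is drawn as
  20 + 1.5·level + N(0, 3²) by default — slope and noise chosen to give a
  clearly positive but imperfect association, the regime the validity
  analyses assume.
- The default filler rate is 10 non-lexicon tokens per item, giving item
  lengths in the realistic range for written LEAS answers while keeping
  generation fast.

What passing tests on this fixture show: the pipeline implements the
scoring rules exactly, end to end through file I/O and the CLI, and the
statistics layer behaves correctly on data with known structure. What they
do **not** show: anything about real German responses — lexical coverage of
a real wordlist, rater-vs-machine disagreement on idioms, negation
("nicht traurig" scores as *traurig*), or spelling noise. Those are
properties of a wordlist and a sample, not of this engine.

## Numerical and design choices

- Digits are treated as token separators like punctuation ("abc123def" →
  two tokens), the simplest reproducible rule for stray numerals.
- Score tables are plain pandas DataFrames with `respondent_id` as index
  and `<method>_item01..20` / `<method>_protocol` columns — flat,
  spreadsheet-friendly, lossless through CSV.
- All randomness is confined to the generator and requires an explicit
  seed; two runs with the same recipe produce byte-identical files.
- Problem sizes in the test suite (50–70 synthetic respondents for
  end-to-end checks, 10,000 random items for the stress invariants, 1,000
  protocols in the acceptance stress suite) are chosen so the whole suite
  runs in well under a minute while every profile and every rule branch is
  exercised many times over.

## Known limitations

- No negation, intensifier or context handling: the hand-scoring manual's
  context-sensitive re-scoring rules are out of scope by design.
- Correlations involving 0/1-coded binaries are point-biserial by
  construction; no biserial correction is applied.
- The α CI assumes the Feldt model (essentially parallel items); bootstrap
  or IRT-based reliability is not implemented.
- The 10-item LEAS short form is not supported; the protocol is fixed at
  20 items.
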