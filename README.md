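# leascore

Automated scoring and psychometric analysis for the **Levels of Emotional
Awareness Scale (LEAS)**.

The LEAS presents 20 hypothetical, emotion-evoking scenarios and asks the
respondent to write, in free text, how they themselves ("self") and the other
person in the scenario ("other") would feel. Trained raters assign each item
to one of five awareness levels — bodily sensations (1), action tendencies or
non-specific valence (2), single explicit emotions (3), blends of emotions
(4), and blends of blends across self and other (5) — a process that is slow
and cognitively demanding. `leascore` automates it: responses are matched
against a scored emotion wordlist (words and phrases with values 1–3) and
item scores are derived from the matched values. It is aimed at clinical and
research groups who administer the LEAS digitally and want protocol scores,
reliability statistics, and agreement-with-hand-scoring analyses without
manual rating.

## Scoring methods

Texts are lowercased, stripped of punctuation and digits (umlauts and ß are
preserved — the design targets German-language wordlists, but any language
works), and scanned left-to-right with longest-match-first, non-overlapping
lexicon lookup. With the matched values $v_1, v_2, \dots$ of an item:

| method | rule | item max | protocol max |
|---|---|---|---|
| `highest4` | sum of the four largest matched values | 12 | 240 |
| `allsum` | sum of all matched values | — | — |
| `334` | two non-identical value-3 entries → 4; only identical value-3 entries → 3; otherwise max matched value | 4 | 80 |
| `3345` | 334 per section; 5 if self **and** other both reach 4, else the max of the two | 5 | 100 |
| `3345plus` | as 3345, but the 5 requires the value-3 entry *sets* of self and other to differ | 5 | 100 |

`wordcount`, `vocabulary` (total and distinct tokens per item) and `time`
(minutes to completion, with respondents over one hour excluded from
time-based correlations) complete the registry. A protocol score is the sum
over the 20 items; the 3345-family lives on the conventional 0–100 scale.

The psychometrics layer computes Cronbach's α over each method's 20 item
scores (95% CI by Feldt's F interval), Pearson correlations with Fisher-z
CIs, partial correlations (controlling word count + vocabulary jointly, or
completion time), Welch's t for group comparisons, and the mean absolute
per-protocol difference against a reference scoring.

## Worked example

```python
from leascore import WordList, ItemResponse, match_item, score_item

wl = WordList.from_pairs([
    ("traurig", 3), ("wütend", 3), ("enttäuscht", 3), ("beschämt", 3),
    ("weinen", 2), ("schlecht", 2), ("kopfschmerzen", 1),
])
item = ItemResponse(
    index=1,
    self_text="Ich wäre traurig und wütend, vielleicht würde ich weinen.",
    other_text="Mein Chef wäre enttäuscht und beschämt.",
)
for method in ("highest4", "allsum", "334", "3345", "3345plus"):
    print(f"{method:>9}: {score_item(item, wl, method)}")
```

prints

```
 highest4: 12
   allsum: 14
      334: 4
     3345: 5
 3345plus: 5
```

The self section matches *traurig* (3), *wütend* (3) and *weinen* (2); the
other section matches *enttäuscht* (3) and *beschämt* (3). The four highest
values are 3+3+3+3 = 12; all values sum to 14; the item holds non-identical
value-3 entries (334 → 4) in both sections (3345 → 5), and the two sections'
entry sets differ, so 3345plus keeps the 5. Had the boss also been "traurig
und wütend", 3345plus would fall back to 4.

The same pipeline runs from the shell:

```bash
leascore simulate --n 50 --seed 7 --out survey.csv --wordlist-out wl.csv
leascore score --input survey.csv --wordlist wl.csv \
    --methods 3345plus,334,wordcount,vocabulary,time --out scores.csv
leascore analyze --scores scores.csv --out report.json
```

`simulate` generates a synthetic survey with analytically known scores (see
`leascore.simulate`); `analyze` writes a JSON report with internal
consistency, covariate-adjusted correlations and group tests, plus agreement
statistics when `--reference` supplies hand scores.

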