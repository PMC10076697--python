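"""Seeded synthetic wordlists and surveys with known ground-truth scores.

The original German emotion lexicon and respondent data are not
redistributable, so this module generates structurally equivalent stand-ins:
pronounceable pseudo-German wordlist entries with values 1-3, and respondents
whose 20 items are *constructed* to sit at a chosen awareness level, so the
exact score of every item under every method is known analytically.

Two disjoint letter alphabets keep the construction exact: lexicon surfaces
use only consonants ``b d f g t w z`` with vowels ``a e ä ö ü``; filler
(never-matching) tokens use only ``k l m n p s`` with ``i o u``.  No filler
token can therefore collide with a lexicon surface, and at least one filler
token always separates two inserted lexicon entries, so phrase matches cannot
bridge them.

Respondent profiles (each applied to all 20 items):

===================  ======================================================
profile              construction per item
===================  ======================================================
``level0``           filler only (a purely cognitive response)
``level1``           one value-1 entry in the self section
``level2``           one value-2 entry in the self section
``level3``           one value-3 entry in the self section
``level4``           two distinct value-3 entries in the self section
``level5_distinct``  two distinct value-3 entries in each section, the two
                     sections' entry sets differing
``level5_identical`` the same two value-3 entries in both sections
===================  ======================================================

A graded covariate (``pat_like``, emulating a facial-affect perception
total) is drawn with a configurable positive dependence on the profile
level, so covariate-based analyses have a known signal to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .lexicon import WordList, WordListEntry
from .scoring import ItemResponse, N_ITEMS
from .survey import Respondent, Survey

__all__ = [
    "PROFILES",
    "PROFILE_LEVEL",
    "GeneratorSpec",
    "generate_wordlist",
    "make_filler_pool",
    "generate_respondent",
    "generate_survey",
]

_LEX_CONSONANTS = ["b", "d", "f", "g", "t", "w", "z", "br", "tr"]
_LEX_VOWELS = ["a", "e", "ä", "ö", "ü"]
_FILLER_CONSONANTS = ["k", "l", "m", "n", "p", "s"]
_FILLER_VOWELS = ["i", "o", "u"]

PROFILES = (
    "level0",
    "level1",
    "level2",
    "level3",
    "level4",
    "level5_distinct",
    "level5_identical",
)

#: numeric awareness level of each profile (drives the graded covariate)
PROFILE_LEVEL = {
    "level0": 0,
    "level1": 1,
    "level2": 2,
    "level3": 3,
    "level4": 4,
    "level5_distinct": 5,
    "level5_identical": 5,
}

#: analytically expected item scores per profile, for every level method
_EXPECTED_ITEM = {
    "level0": {"highest4": 0, "allsum": 0, "334": 0, "3345": 0, "3345plus": 0},
    "level1": {"highest4": 1, "allsum": 1, "334": 1, "3345": 1, "3345plus": 1},
    "level2": {"highest4": 2, "allsum": 2, "334": 2, "3345": 2, "3345plus": 2},
    "level3": {"highest4": 3, "allsum": 3, "334": 3, "3345": 3, "3345plus": 3},
    "level4": {"highest4": 6, "allsum": 6, "334": 4, "3345": 4, "3345plus": 4},
    "level5_distinct": {"highest4": 12, "allsum": 12, "334": 4, "3345": 5, "3345plus": 5},
    "level5_identical": {"highest4": 12, "allsum": 12, "334": 4, "3345": 5, "3345plus": 4},
}


def _word(rng: np.random.Generator, consonants: list[str], vowels: list[str]) -> str:
    n_syll = int(rng.integers(2, 4))
    return "".join(
        str(rng.choice(consonants)) + str(rng.choice(vowels)) for _ in range(n_syll)
    )


def _unique_words(rng, consonants, vowels, n: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        w = _word(rng, consonants, vowels)
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def generate_wordlist(
    n1: int, n2: int, n3: int, phrase_fraction: float = 0.0, seed: int = 0
) -> WordList:
    """Generate a scored wordlist with ``n1``/``n2``/``n3`` entries per value.

    ``phrase_fraction`` of the entries are 2-3-token phrases; the rest are
    single tokens.  Surfaces are unique after normalization and drawn from
    the lexicon alphabet only.  Deterministic in ``seed``.
    """
    if min(n1, n2, n3) < 0:
        raise UsageError("entry counts must be non-negative")
    if n3 < 2:
        raise UsageError("need at least two value-3 entries (n3 >= 2)")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    entries: list[WordListEntry] = []
    for value, count in ((1, n1), (2, n2), (3, n3)):
        n_phrases = int(round(phrase_fraction * count))
        for j in range(count):
            if j < n_phrases:
                length = int(rng.integers(2, 4))
                tokens = tuple(
                    _unique_words(rng, _LEX_CONSONANTS, _LEX_VOWELS, length, taken)
                )
            else:
                tokens = tuple(
                    _unique_words(rng, _LEX_CONSONANTS, _LEX_VOWELS, 1, taken)
                )
            entries.append(WordListEntry(tokens, value))
    return WordList(entries)


def make_filler_pool(size: int = 60, seed: int = 0) -> list[str]:
    """A pool of never-matching filler tokens (disjoint alphabet)."""
    rng = np.random.default_rng(seed)
    return _unique_words(rng, _FILLER_CONSONANTS, _FILLER_VOWELS, size, set())


def _by_value(wl: WordList) -> dict[int, list[WordListEntry]]:
    pools: dict[int, list[WordListEntry]] = {1: [], 2: [], 3: []}
    for e in wl:
        pools[e.value].append(e)
    return pools


def _section_tokens(
    entries: Sequence[WordListEntry],
    rng: np.random.Generator,
    filler_pool: Sequence[str],
    lam: float,
) -> list[str]:
    """Interleave entry token sequences with filler tokens.

    Filler counts per gap are Poisson(lam / gaps); interior gaps are forced
    to at least one filler token so adjacent entries can never be re-read as
    a longer phrase.
    """
    n_gaps = len(entries) + 1
    tokens: list[str] = []
    for g in range(n_gaps):
        k = int(rng.poisson(lam / n_gaps)) if lam > 0 else 0
        if 0 < g < n_gaps - 1:
            k = max(k, 1)
        tokens.extend(str(rng.choice(filler_pool)) for _ in range(k))
        if g < len(entries):
            tokens.extend(entries[g].tokens)
    return tokens


def _profile_entries(
    profile: str, pools: dict[int, list[WordListEntry]], rng: np.random.Generator
) -> tuple[list[WordListEntry], list[WordListEntry]]:
    """Pick the lexicon entries for the self and other sections of one item."""
    def pick(value: int, k: int, exclude: set[str] = frozenset()) -> list[WordListEntry]:
        pool = [e for e in pools[value] if e.id not in exclude]
        if len(pool) < k:
            raise UsageError(
                f"profile {profile!r} needs {k} value-{value} entries"
                + (f" outside {sorted(exclude)}" if exclude else "")
                + f"; wordlist has {len(pool)}"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[int(i)] for i in idx]

    if profile == "level0":
        return [], []
    if profile == "level1":
        return pick(1, 1), []
    if profile == "level2":
        return pick(2, 1), []
    if profile == "level3":
        return pick(3, 1), []
    if profile == "level4":
        return pick(3, 2), []
    if profile == "level5_identical":
        pair = pick(3, 2)
        return pair, list(pair)
    if profile == "level5_distinct":
        self_pair = pick(3, 2)
        # other must reach a 334 score of 4 with a *different* entry set;
        # one fresh entry suffices (needs n3 >= 3)
        fresh = pick(3, 1, exclude={e.id for e in self_pair})
        other_pair = [self_pair[int(rng.integers(0, 2))], fresh[0]]
        return self_pair, other_pair
    raise UsageError(f"unknown profile {profile!r}; valid: {', '.join(PROFILES)}")


def generate_respondent(
    profile: str,
    wl: WordList,
    seed_or_rng,
    respondent_id: str = "r000",
    filler_pool: Sequence[str] | None = None,
    filler_rate: float = 10.0,
) -> tuple[Respondent, dict]:
    """Build one respondent at a fixed profile plus their expected scores.

    Returns the respondent and a flat dict of expected item and protocol
    scores for all seven methods, derived from the construction itself.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if profile not in PROFILES:
        raise UsageError(f"unknown profile {profile!r}; valid: {', '.join(PROFILES)}")
    if filler_pool is None:
        filler_pool = make_filler_pool(seed=0)
    pools = _by_value(wl)
    lam = filler_rate / 2.0  # per section
    items: dict[int, ItemResponse] = {}
    expected: dict[str, int] = {}
    protocol = {m: 0 for m in _EXPECTED_ITEM["level0"]}
    wc_total = voc_total = 0
    for i in range(1, N_ITEMS + 1):
        self_entries, other_entries = _profile_entries(profile, pools, rng)
        self_tokens = _section_tokens(self_entries, rng, filler_pool, lam)
        other_tokens = _section_tokens(other_entries, rng, filler_pool, lam)
        items[i] = ItemResponse(
            index=i,
            self_text=" ".join(self_tokens),
            other_text=" ".join(other_tokens),
        )
        for m, v in _EXPECTED_ITEM[profile].items():
            expected[f"{m}_item{i:02d}"] = v
            protocol[m] += v
        wc = len(self_tokens) + len(other_tokens)
        voc = len(set(self_tokens) | set(other_tokens))
        expected[f"wordcount_item{i:02d}"] = wc
        expected[f"vocabulary_item{i:02d}"] = voc
        wc_total += wc
        voc_total += voc
    for m, v in protocol.items():
        expected[f"{m}_protocol"] = v
    expected["wordcount_protocol"] = wc_total
    expected["vocabulary_protocol"] = voc_total
    return Respondent(respondent_id, items, {}), expected


@dataclass
class GeneratorSpec:
    """Reproducible recipe for a synthetic survey.

    ``profiles`` fixes each respondent's profile explicitly; when omitted,
    profiles are drawn uniformly from all seven.  ``filler_rate`` is the
    expected number of non-lexicon tokens per item.  ``covariate_slope`` and
    ``covariate_sd`` shape the graded ``pat_like`` covariate
    (``20 + slope * level + N(0, sd)``).  The seed is mandatory.
    """

    n_respondents: int
    seed: int
    profiles: list[str] | None = None
    filler_rate: float = 10.0
    covariate_slope: float = 1.5
    covariate_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise UsageError("n_respondents must be positive")
        if self.profiles is not None:
            if len(self.profiles) != self.n_respondents:
                raise UsageError("profiles list must match n_respondents")
            bad = sorted(set(self.profiles) - set(PROFILES))
            if bad:
                raise UsageError(f"unknown profile(s): {', '.join(bad)}")

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "seed": self.seed,
            "profiles": self.profiles,
            "filler_rate": self.filler_rate,
            "covariate_slope": self.covariate_slope,
            "covariate_sd": self.covariate_sd,
        }


def generate_survey(
    spec: GeneratorSpec, wl: WordList
) -> tuple[Survey, pd.DataFrame, pd.DataFrame]:
    """Generate a full survey plus its ground truth.

    Returns ``(survey, expected_scores, truth)``: the survey (with auxiliary
    covariates), the analytically expected score table (same layout as
    ``score_survey`` over all seven methods), and a truth frame with each
    respondent's profile, numeric level and noiseless covariate mean.

    Auxiliary covariates emulate a healthy community sample: age ~ N(32,
    12.5) clipped to 18-65, gender female with probability 130/208,
    education ordinal 1-4, children yes with probability 44/208, completion
    time uniform on 15-55 minutes with a 5% chance of a 65-90-minute outlier
    (exercising the one-hour exclusion), and the graded ``pat_like``
    covariate.
    """
    rng = np.random.default_rng(spec.seed)
    filler_pool = make_filler_pool(seed=spec.seed)
    if spec.profiles is None:
        profiles = [str(p) for p in rng.choice(PROFILES, size=spec.n_respondents)]
    else:
        profiles = list(spec.profiles)
    respondents: list[Respondent] = []
    expected_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i, profile in enumerate(profiles):
        rid = f"r{i:03d}"
        resp, expected = generate_respondent(
            profile, wl, rng, rid, filler_pool, spec.filler_rate
        )
        level = PROFILE_LEVEL[profile]
        age = int(np.clip(round(rng.normal(32.0, 12.5)), 18, 65))
        gender = "female" if rng.random() < 130 / 208 else "male"
        education = int(rng.integers(1, 5))
        children = "yes" if rng.random() < 44 / 208 else "no"
        if rng.random() < 0.05:
            time_minutes = round(float(rng.uniform(65.0, 90.0)), 1)
        else:
            time_minutes = round(float(rng.uniform(15.0, 55.0)), 1)
        cov_mean = 20.0 + spec.covariate_slope * level
        pat_like = round(float(cov_mean + rng.normal(0.0, spec.covariate_sd)), 3)
        resp.auxiliary.update(
            {
                "age": age,
                "gender": gender,
                "education": education,
                "children": children,
                "time_minutes": time_minutes,
                "pat_like": pat_like,
            }
        )
        respondents.append(resp)
        expected_rows.append(expected)
        truth_rows.append(
            {"profile": profile, "level": level, "covariate_mean": cov_mean}
        )
    index = pd.Index([r.respondent_id for r in respondents], name="respondent_id")
    expected_table = pd.DataFrame(expected_rows, index=index)
    truth = pd.DataFrame(truth_rows, index=index)
    return Survey(respondents), expected_table, truth
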