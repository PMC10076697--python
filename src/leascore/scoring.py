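"""Item- and protocol-level LEAS scoring methods.

An item is one scenario's response, split into a "self" section (how the
respondent would feel) and an "other" section (how the counterpart would
feel).  A protocol is a respondent's full set of 20 items; protocol scores are
sums over the 20 item scores.

Five lexicon-based methods are implemented:

``highest4``
    Sum of the four highest match values in the item (self and other pooled).
    Item maximum 12, protocol maximum 240.
``allsum``
    Sum of all match values in the item (self and other pooled).  Unbounded.
``334``
    If the item contains two non-identical value-3 entries the item scores 4;
    if all value-3 entries are identical it scores 3; with no value-3 entry it
    scores the maximum matched value (0 if nothing matched).  Item maximum 4,
    protocol maximum 80.
``3345``
    Self and other are scored separately with the 334 rule; the item scores 5
    when both sections reach 4, otherwise the maximum of the two.  Item
    maximum 5, protocol maximum 100 — the conventional 0-100 LEAS protocol
    scale.
``3345plus``
    As 3345, but a 5 additionally requires the value-3 entry sets of the two
    sections to differ; identical sets fall back to 4.

Two auxiliary text metrics (``wordcount``, ``vocabulary``) and the ``time``
method (minutes to completion, with an exclusion flag above one hour) complete
the method registry.  "Identical" always compares normalized wordlist entry
ids, never raw tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError
from .lexicon import MatchResult, WordList, match_wordlist, normalize_text

__all__ = [
    "LEVEL_METHODS",
    "TEXT_METHODS",
    "ALL_METHODS",
    "ItemResponse",
    "ItemMatches",
    "TimeScore",
    "match_item",
    "score_highest4",
    "score_allsum",
    "score_334",
    "score_3345",
    "score_3345plus",
    "score_wordcount",
    "score_vocabulary",
    "score_item",
    "score_protocol",
    "ITEM_MAX",
    "PROTOCOL_MAX",
    "TIME_EXCLUSION_MINUTES",
]

#: methods whose values live on the emotional-awareness level scale
LEVEL_METHODS = ("highest4", "allsum", "334", "3345", "3345plus")
#: linguistic side metrics
TEXT_METHODS = ("wordcount", "vocabulary")
ALL_METHODS = LEVEL_METHODS + TEXT_METHODS + ("time",)

#: printed per-item score ceilings (allsum is unbounded)
ITEM_MAX = {"highest4": 12, "334": 4, "3345": 5, "3345plus": 5}
#: printed per-protocol score ceilings
PROTOCOL_MAX = {"highest4": 240, "334": 80, "3345": 100, "3345plus": 100}

N_ITEMS = 20
TIME_EXCLUSION_MINUTES = 60.0


@dataclass(frozen=True)
class ItemResponse:
    """One LEAS item: the raw self and other texts plus the item index 1..20."""

    index: int
    self_text: str = ""
    other_text: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_ITEMS:
            raise UsageError(f"item index {self.index} outside 1..{N_ITEMS}")


@dataclass
class ItemMatches:
    """Lexicon matches of one item, per section.

    The two sections are matched independently and pooled where a method does
    not distinguish self from other; this keeps phrase matches from spanning
    the section boundary.
    """

    self_matches: MatchResult = field(default_factory=MatchResult)
    other_matches: MatchResult = field(default_factory=MatchResult)

    @property
    def combined(self) -> MatchResult:
        return self.self_matches + self.other_matches


def match_item(item: ItemResponse, wl: WordList) -> ItemMatches:
    """Normalize and match both sections of an item against the wordlist."""
    return ItemMatches(
        self_matches=match_wordlist(normalize_text(item.self_text), wl),
        other_matches=match_wordlist(normalize_text(item.other_text), wl),
    )


def score_highest4(m: MatchResult) -> int:
    """Sum of the four largest match values (all of them when fewer)."""
    return sum(sorted(m.values, reverse=True)[:4])


def score_allsum(m: MatchResult) -> int:
    """Sum of all match values."""
    return sum(m.values)


def score_334(m: MatchResult) -> int:
    """The 334 rule on one pool of matches."""
    threes = m.ids_with_value(3)
    if threes:
        return 4 if len(set(threes)) >= 2 else 3
    return max(m.values, default=0)


def score_3345(self_m: MatchResult, other_m: MatchResult) -> int:
    """334 per section; 5 when both sections reach 4, else their maximum."""
    s, o = score_334(self_m), score_334(other_m)
    return 5 if (s == 4 and o == 4) else max(s, o)


def score_3345plus(self_m: MatchResult, other_m: MatchResult) -> int:
    """3345 with a distinctness constraint on the 5.

    When both sections reach a 334 score of 4, the 5 is awarded only if the
    sets of value-3 entry ids found in self and other differ; equal sets give
    a 4.  Duplicated hits within a section are ignored (set comparison).
    """
    s, o = score_334(self_m), score_334(other_m)
    if s == 4 and o == 4:
        if set(self_m.ids_with_value(3)) != set(other_m.ids_with_value(3)):
            return 5
        return 4
    return max(s, o)


def score_wordcount(item: ItemResponse) -> int:
    """Number of normalized tokens across both sections."""
    return len(normalize_text(item.self_text)) + len(normalize_text(item.other_text))


def score_vocabulary(item: ItemResponse) -> int:
    """Number of distinct normalized tokens across both sections."""
    return len(set(normalize_text(item.self_text)) | set(normalize_text(item.other_text)))


def score_item(item: ItemResponse, wl: WordList, method: str) -> int:
    """Score one item with one method.

    The text metrics need no wordlist matching; the level methods match each
    section once and apply their rule.
    """
    if method == "wordcount":
        return score_wordcount(item)
    if method == "vocabulary":
        return score_vocabulary(item)
    if method not in LEVEL_METHODS:
        raise UsageError(
            f"unknown item-level method {method!r}; valid: "
            f"{', '.join(LEVEL_METHODS + TEXT_METHODS)}"
        )
    im = match_item(item, wl)
    if method == "highest4":
        return score_highest4(im.combined)
    if method == "allsum":
        return score_allsum(im.combined)
    if method == "334":
        return score_334(im.combined)
    if method == "3345":
        return score_3345(im.self_matches, im.other_matches)
    return score_3345plus(im.self_matches, im.other_matches)


@dataclass(frozen=True)
class TimeScore:
    """Completion time in minutes plus the one-hour exclusion flag.

    Exclusion only removes the respondent from time-based correlations; it
    never removes them from scoring.
    """

    minutes: float
    excluded: bool


def score_protocol(respondent, wl: WordList | None, method: str):
    """Protocol-level score: the sum over the respondent's 20 items.

    Missing items count as empty texts (score 0), keeping the 20-item scale
    fixed.  ``method='time'`` instead returns a :class:`TimeScore` built from
    the respondent's ``time_minutes`` auxiliary field.
    """
    if method == "time":
        minutes = respondent.auxiliary.get("time_minutes")
        if minutes is None:
            raise UsageError(
                f"respondent {respondent.respondent_id!r} has no time_minutes"
            )
        minutes = float(minutes)
        return TimeScore(minutes, minutes > TIME_EXCLUSION_MINUTES)
    if method not in LEVEL_METHODS + TEXT_METHODS:
        raise UsageError(
            f"unknown method {method!r}; valid: {', '.join(ALL_METHODS)}"
        )
    total = 0
    for idx in range(1, N_ITEMS + 1):
        item = respondent.items.get(idx, ItemResponse(index=idx))
        total += score_item(item, wl, method)
    return total
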