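"""Text normalization, scored wordlists and lexicon matching.

The scoring substrate of the LEAS automation is a wordlist: emotion words and
phrases, each carrying an integer awareness value (1 = bodily sensation,
2 = action tendency / non-specific valenced emotion, 3 = single specific
emotion).  Free-text responses are reduced to lowercase letter-only tokens and
scanned left to right; at each position the longest wordlist entry that matches
is consumed, so every token contributes to at most one match and repeated
occurrences of an entry yield repeated matches.

No spell correction, stemming or lemmatization is applied: inflected forms
must be enumerated in the wordlist itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "VALID_VALUES",
    "WordListEntry",
    "WordList",
    "Match",
    "MatchResult",
    "normalize_text",
    "load_wordlist",
    "match_wordlist",
]

VALID_VALUES = frozenset({1, 2, 3})

# Unicode letters only: punctuation, digits, underscores and hyphens all act
# as token separators.  German letters (umlauts, eszett) are letters and are
# therefore preserved.
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def normalize_text(raw: str) -> list[str]:
    """Normalize a raw response into a token sequence.

    Lowercases, strips punctuation and digits (both act as separators),
    preserves umlauts and eszett, splits on whitespace.  No spell correction
    and no stemming.

    >>> normalize_text("Wütend – und traurig.")
    ['wütend', 'und', 'traurig']
    """
    if not raw:
        return []
    return _TOKEN_RE.findall(raw.lower())


@dataclass(frozen=True)
class WordListEntry:
    """One scored lexicon entry: a normalized token sequence plus its value.

    The entry id is the normalized surface itself (tokens joined by single
    spaces), which makes ids stable across loads.
    """

    tokens: tuple[str, ...]
    value: int

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError("wordlist entry has an empty surface")
        if self.value not in VALID_VALUES:
            raise ValidationError(
                f"wordlist value {self.value!r} for {' '.join(self.tokens)!r} "
                f"is outside {sorted(VALID_VALUES)}"
            )

    @property
    def id(self) -> str:
        return " ".join(self.tokens)


class WordList:
    """A scored lexicon of unique normalized single- and multi-token entries."""

    def __init__(self, entries: Iterable[WordListEntry]):
        self._by_tokens: dict[tuple[str, ...], WordListEntry] = {}
        for e in entries:
            if e.tokens in self._by_tokens:
                raise ValidationError(f"duplicate wordlist entry {e.id!r}")
            self._by_tokens[e.tokens] = e
        if not self._by_tokens:
            raise ValidationError("wordlist is empty")
        self.max_phrase_len = max(len(t) for t in self._by_tokens)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "WordList":
        """Build from (surface, value) pairs; surfaces are normalized first."""
        entries = []
        for surface, value in pairs:
            tokens = tuple(normalize_text(surface))
            entries.append(WordListEntry(tokens, int(value)))
        return cls(entries)

    def __len__(self) -> int:
        return len(self._by_tokens)

    def __iter__(self):
        return iter(self._by_tokens.values())

    def __contains__(self, tokens: tuple[str, ...]) -> bool:
        return tokens in self._by_tokens

    def get(self, tokens: tuple[str, ...]) -> WordListEntry | None:
        return self._by_tokens.get(tokens)

    @property
    def entries(self) -> list[WordListEntry]:
        return list(self._by_tokens.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"entry": [e.id for e in self], "value": [e.value for e in self]}
        )


@dataclass(frozen=True)
class Match:
    """One lexicon hit: entry id, its value, and the half-open token span."""

    entry_id: str
    value: int
    span: tuple[int, int]


@dataclass
class MatchResult:
    """Ordered, non-overlapping lexicon matches found in one token sequence."""

    matches: list[Match] = field(default_factory=list)

    @property
    def values(self) -> list[int]:
        return [m.value for m in self.matches]

    def ids_with_value(self, value: int) -> list[str]:
        return [m.entry_id for m in self.matches if m.value == value]

    def __len__(self) -> int:
        return len(self.matches)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        # Pooling matches from separately matched sections; spans keep their
        # section-local indices and are only meaningful per section.
        return MatchResult(self.matches + other.matches)


def load_wordlist(path: str | Path) -> WordList:
    """Load a scored wordlist from a CSV or XLSX file.

    The file must have columns ``entry`` and ``value``; phrase entries carry
    internal spaces.  Surfaces are normalized before deduplication, so
    entries that collapse to the same normal form are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, encoding="utf-8")
    missing = {"entry", "value"} - set(df.columns)
    if missing:
        raise FormatError(
            f"wordlist file {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    entries = []
    seen: dict[tuple[str, ...], int] = {}
    for row_no, (surface, value) in enumerate(
        zip(df["entry"], df["value"]), start=2
    ):  # row 1 is the header
        tokens = tuple(normalize_text(str(surface)))
        if not tokens:
            raise ValidationError(f"row {row_no}: entry normalizes to nothing")
        try:
            ival = int(value)
        except (TypeError, ValueError):
            raise ValidationError(f"row {row_no}: value {value!r} is not an integer")
        if ival not in VALID_VALUES:
            raise ValidationError(
                f"row {row_no}: value {ival} outside {sorted(VALID_VALUES)}"
            )
        if tokens in seen:
            raise ValidationError(
                f"row {row_no}: duplicate entry {' '.join(tokens)!r} "
                f"(first seen at row {seen[tokens]})"
            )
        seen[tokens] = row_no
        entries.append(WordListEntry(tokens, ival))
    return WordList(entries)


def save_wordlist(wl: WordList, path: str | Path) -> None:
    """Write a wordlist back to CSV (header ``entry,value``)."""
    wl.to_frame().to_csv(path, index=False, encoding="utf-8")


def match_wordlist(tokens: Sequence[str], wl: WordList) -> MatchResult:
    """Scan normalized tokens for wordlist entries.

    Left-to-right, longest match first, no overlaps: at each position the
    longest entry (up to the wordlist's longest phrase) starting there is
    taken and its tokens consumed.  Deterministic for fixed inputs.
    """
    matches: list[Match] = []
    n = len(tokens)
    i = 0
    while i < n:
        hit = None
        for length in range(min(wl.max_phrase_len, n - i), 0, -1):
            entry = wl.get(tuple(tokens[i : i + length]))
            if entry is not None:
                hit = (entry, length)
                break
        if hit is None:
            i += 1
        else:
            entry, length = hit
            matches.append(Match(entry.id, entry.value, (i, i + length)))
            i += length
    return MatchResult(matches)
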