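"""Antimicrobial name lexicon and clinical-note term matching.

Pre-incisional antimicrobial prophylaxis is frequently documented only in
free-text procedure or anesthesia notes, so part of the detection algorithm
is a case-insensitive, whole-word search of note text for antimicrobial
names.  The lexicon holds one entry per agent (keyed by generic name)
together with brand names and common misspelling variants, plus per-agent
attributes driving the refinement filters:

* ``oral_only`` — agent available only in oral formulation; these are
  rarely the pre-incisional agent and mostly generate false positives from
  post-procedure course recommendations.
* ``rarely_prophylactic`` — agent seldom used for surgical prophylaxis
  (e.g. fluoroquinolones prescribed for unrelated infections).
* ``text_search_excluded`` — agent dropped from note searches only, the
  canonical case being penicillin, which appears overwhelmingly in allergy
  documentation rather than as the administered drug.

Matching is deliberately simple: no stemming, fuzzy matching, negation or
section detection.  Misspellings are covered only by explicit alias
variants.  An allergy mention of a retained agent will match — the
algorithm's answer to the allergy false-positive problem is solely the
removal of penicillin from the note lexicon.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from .errors import LexiconError

if TYPE_CHECKING:  # pragma: no cover
    from .detector import AlgorithmVariant

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "TermMatch",
    "TermMatcher",
    "normalize_term",
    "load_lexicon",
    "default_lexicon",
    "build_matcher",
    "match_text",
    "PROPHYLAXIS_TERM",
]

#: Pseudo-agent optionally added to the note matcher; matches the bare word
#: "prophylaxis" and contributes nonspecific evidence only.
PROPHYLAXIS_TERM = "prophylaxis"

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lowercase, strip, and collapse internal whitespace."""
    return _WS.sub(" ", term.strip().lower())


@dataclass(frozen=True)
class LexiconEntry:
    """One antimicrobial agent with its surface-form aliases."""

    canonical_name: str
    aliases: frozenset[str] = frozenset()
    oral_only: bool = False
    rarely_prophylactic: bool = False
    text_search_excluded: bool = False

    def __post_init__(self) -> None:
        canon = normalize_term(self.canonical_name)
        if not canon:
            raise LexiconError("canonical_name must be non-empty")
        alias_set = {normalize_term(a) for a in self.aliases}
        alias_set.discard("")
        alias_set.add(canon)  # canonical name is always its own alias
        object.__setattr__(self, "canonical_name", canon)
        object.__setattr__(self, "aliases", frozenset(alias_set))


@dataclass
class Lexicon:
    """A validated collection of :class:`LexiconEntry`.

    Alias lookup is total over the union of all alias sets and maps each
    alias to exactly one canonical name; collisions are rejected at
    construction time.
    """

    entries: list[LexiconEntry]
    version: str = "unversioned"
    _alias_map: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise LexiconError("lexicon has no entries")
        alias_map: dict[str, str] = {}
        seen: set[str] = set()
        for entry in self.entries:
            if entry.canonical_name in seen:
                raise LexiconError(
                    f"duplicate canonical name {entry.canonical_name!r}"
                )
            seen.add(entry.canonical_name)
            for alias in entry.aliases:
                other = alias_map.get(alias)
                if other is not None and other != entry.canonical_name:
                    raise LexiconError(
                        f"alias {alias!r} maps to both {other!r} and "
                        f"{entry.canonical_name!r}"
                    )
                alias_map[alias] = entry.canonical_name
        self._alias_map = alias_map

    @property
    def aliases(self) -> frozenset[str]:
        return frozenset(self._alias_map)

    def resolve(self, term: str) -> str:
        """Map a surface form to its canonical agent name (KeyError if unknown)."""
        return self._alias_map[normalize_term(term)]

    def get(self, term: str) -> str | None:
        return self._alias_map.get(normalize_term(term))

    def entry(self, canonical_name: str) -> LexiconEntry:
        for e in self.entries:
            if e.canonical_name == normalize_term(canonical_name):
                return e
        raise KeyError(canonical_name)

    def structured_alias_map(self, variant: "AlgorithmVariant") -> dict[str, str]:
        """Alias → canonical map for *fielded* drug names (orders/administrations).

        Applies the variant's agent filters (oral-only exclusion,
        common-prophylaxis restriction) but not ``text_search_excluded``,
        which governs note searches only.
        """
        out: dict[str, str] = {}
        for e in self.entries:
            if variant.exclude_oral_only and e.oral_only:
                continue
            if variant.restrict_common_prophylaxis and e.rarely_prophylactic:
                continue
            for a in e.aliases:
                out[a] = e.canonical_name
        return out


@dataclass(frozen=True)
class TermMatch:
    """A single lexicon hit in a piece of text — the evidence trail unit."""

    canonical_name: str
    surface_form: str
    start_offset: int
    source_id: str = ""


class TermMatcher:
    """Compiled whole-word, case-insensitive matcher over an alias map.

    Word boundaries are alphanumeric: an alias never matches inside a longer
    alphanumeric run (``cefazolin`` does not fire on ``xcefazolinx``).  At a
    given offset the longest alias wins; matches are non-overlapping and
    reported left to right.
    """

    def __init__(self, alias_map: Mapping[str, str]):
        if not alias_map:
            raise LexiconError("matcher has no terms")
        self.alias_map = {normalize_term(k): v for k, v in alias_map.items()}
        ordered = sorted(self.alias_map, key=lambda a: (-len(a), a))
        alternation = "|".join(re.escape(a) for a in ordered)
        self._rx = re.compile(
            rf"(?<![a-z0-9])(?:{alternation})(?![a-z0-9])", re.IGNORECASE
        )

    def find(self, text: str, source_id: str = "") -> list[TermMatch]:
        matches = []
        for m in self._rx.finditer(text):
            surface = m.group(0)
            matches.append(
                TermMatch(
                    canonical_name=self.alias_map[normalize_term(surface)],
                    surface_form=surface,
                    start_offset=m.start(),
                    source_id=source_id,
                )
            )
        return matches

    def __len__(self) -> int:
        return len(self.alias_map)


def build_matcher(lexicon: Lexicon, variant: "AlgorithmVariant") -> TermMatcher:
    """Compile the note-text matcher for an algorithm variant.

    Entries flagged ``text_search_excluded`` are always dropped; oral-only
    and rarely-prophylactic entries are dropped according to the variant;
    the bare "prophylaxis" pseudo-term is added when the variant asks for it.
    """
    alias_map: dict[str, str] = {}
    for e in lexicon.entries:
        if e.text_search_excluded:
            continue
        if variant.exclude_oral_only and e.oral_only:
            continue
        if variant.restrict_common_prophylaxis and e.rarely_prophylactic:
            continue
        for a in e.aliases:
            alias_map[a] = e.canonical_name
    if variant.include_prophylaxis_term:
        alias_map[PROPHYLAXIS_TERM] = PROPHYLAXIS_TERM
    if not alias_map:
        raise LexiconError("variant filters removed every agent from the matcher")
    return TermMatcher(alias_map)


def match_text(text: str, matcher: TermMatcher, source_id: str = "") -> list[TermMatch]:
    """All non-overlapping lexicon hits in *text*, ordered by offset."""
    return matcher.find(text, source_id=source_id)


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise LexiconError(f"{context}: cannot parse boolean {value!r}")


_TABULAR_COLUMNS = (
    "alias",
    "canonical_name",
    "oral_only",
    "rarely_prophylactic",
    "text_search_excluded",
)


def _load_tabular(path: Path) -> list[LexiconEntry]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _TABULAR_COLUMNS if c not in header]
        if missing:
            raise LexiconError(f"{path}: missing columns {missing}")
        grouped: dict[str, dict] = {}
        for i, row in enumerate(reader, start=2):
            canon = normalize_term(row["canonical_name"])
            if not canon:
                raise LexiconError(f"{path}:{i}: empty canonical_name")
            flags = {
                k: _parse_bool(row[k], f"{path}:{i}")
                for k in ("oral_only", "rarely_prophylactic", "text_search_excluded")
            }
            rec = grouped.setdefault(canon, {"aliases": set(), "flags": flags})
            if rec["flags"] != flags:
                raise LexiconError(
                    f"{path}:{i}: conflicting attribute flags for agent {canon!r}"
                )
            rec["aliases"].add(normalize_term(row["alias"]))
    return [
        LexiconEntry(canonical_name=canon, aliases=frozenset(rec["aliases"]), **rec["flags"])
        for canon, rec in grouped.items()
    ]


def _load_structured(path: Path) -> list[LexiconEntry]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("entries", [])
    entries = []
    for obj in data:
        entries.append(
            LexiconEntry(
                canonical_name=obj["canonical_name"],
                aliases=frozenset(obj.get("aliases", [])),
                oral_only=bool(obj.get("oral_only", False)),
                rarely_prophylactic=bool(obj.get("rarely_prophylactic", False)),
                text_search_excluded=bool(obj.get("text_search_excluded", False)),
            )
        )
    return entries


def load_lexicon(path: str | Path, format: str | None = None) -> Lexicon:
    """Read a lexicon file.

    ``format`` is ``"tabular"`` (CSV, one row per alias) or
    ``"structured-text"`` (JSON, one object per agent with an alias array);
    when omitted it is inferred from the extension (.csv/.tsv vs .json).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "structured-text" if path.suffix.lower() == ".json" else "tabular"
    if format == "tabular":
        entries = _load_tabular(path)
    elif format == "structured-text":
        entries = _load_structured(path)
    else:
        raise LexiconError(f"unknown lexicon format {format!r}")
    return Lexicon(entries=entries, version=path.name)


def default_lexicon() -> Lexicon:
    """The packaged guideline-derived default lexicon.

    Covers the agents recommended for cardiac device prophylaxis
    (first-generation cephalosporins, vancomycin for beta-lactam-allergic
    patients, etc.) plus common brand names and misspelling variants, and a
    handful of agents kept only so the refinement filters have something to
    filter (oral-only cephalexin, rarely-prophylactic fluoroquinolones,
    allergy-prone penicillin).  Fully user-overridable via
    :func:`load_lexicon`.
    """
    with resources.as_file(
        resources.files("prophyflag").joinpath("data/default_lexicon.csv")
    ) as p:
        lex = load_lexicon(p, format="tabular")
    lex.version = "default-1"
    return lex
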