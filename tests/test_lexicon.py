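"""Lexicon loading, matcher compilation and whole-word text matching."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

import prophyflag as pf
from prophyflag.detector import AlgorithmVariant
from prophyflag.errors import LexiconError
from prophyflag.lexicon import (
    PROPHYLAXIS_TERM,
    TermMatcher,
    build_matcher,
    match_text,
    normalize_term,
)

TEXT_VARIANT = AlgorithmVariant(use_text=True)


def write_tabular(path, rows):
    header = "alias,canonical_name,oral_only,rarely_prophylactic,text_search_excluded\n"
    path.write_text(header + "".join(",".join(r) + "\n" for r in rows), encoding="utf-8")


class TestLoadLexicon:
    def test_tabular_round_trip(self, tmp_path):
        p = tmp_path / "lex.csv"
        write_tabular(
            p,
            [
                ("cefazolin", "cefazolin", "false", "false", "false"),
                ("ancef", "cefazolin", "false", "false", "false"),
                ("cefazolen", "cefazolin", "false", "false", "false"),
            ],
        )
        lex = pf.load_lexicon(p)
        assert len(lex.entries) == 1
        assert lex.entries[0].oral_only is False
        assert {lex.resolve(a) for a in ("ancef", "Cefazolen", "CEFAZOLIN")} == {"cefazolin"}

    def test_structured_text_format(self, tmp_path):
        p = tmp_path / "lex.json"
        p.write_text(
            json.dumps(
                [
                    {"canonical_name": "cefazolin", "aliases": ["Ancef"]},
                    {"canonical_name": "penicillin", "text_search_excluded": True},
                ]
            )
        )
        lex = pf.load_lexicon(p)
        assert lex.resolve("ancef") == "cefazolin"
        assert lex.entry("penicillin").text_search_excluded

    def test_alias_collision_names_both_agents(self, tmp_path):
        p = tmp_path / "lex.csv"
        write_tabular(
            p,
            [
                ("cefazolin", "cefazolin", "false", "false", "false"),
                ("cefazolin", "vancomycin", "false", "false", "false"),
            ],
        )
        with pytest.raises(LexiconError, match="cefazolin.*vancomycin|vancomycin.*cefazolin"):
            pf.load_lexicon(p)

    def test_empty_entry_set_rejected(self, tmp_path):
        p = tmp_path / "lex.csv"
        write_tabular(p, [])
        with pytest.raises(LexiconError):
            pf.load_lexicon(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pf.load_lexicon(tmp_path / "nope.csv")

    def test_shipped_default_every_alias_resolves_uniquely(self, lexicon):
        # brute-force exhaustive lookup over the union of all alias sets
        owners = {}
        for entry in lexicon.entries:
            for alias in entry.aliases:
                owners.setdefault(alias, set()).add(entry.canonical_name)
        assert all(len(v) == 1 for v in owners.values())
        for alias in owners:
            assert lexicon.resolve(alias) == next(iter(owners[alias]))


class TestBuildMatcher:
    def test_text_search_excluded_always_dropped(self, lexicon):
        matcher = build_matcher(lexicon, TEXT_VARIANT)
        assert "penicillin" not in matcher.alias_map
        assert "cefazolin" in matcher.alias_map

    def test_filters_match_set_comprehension_oracle(self, lexicon):
        for variant in (
            TEXT_VARIANT,
            AlgorithmVariant(use_text=True, exclude_oral_only=True),
            AlgorithmVariant(use_text=True, restrict_common_prophylaxis=True),
            pf.FINAL_VARIANT,
        ):
            matcher = build_matcher(lexicon, variant)
            expected = {
                a
                for e in lexicon.entries
                if not e.text_search_excluded
                and not (variant.exclude_oral_only and e.oral_only)
                and not (variant.restrict_common_prophylaxis and e.rarely_prophylactic)
                for a in e.aliases
            }
            assert set(matcher.alias_map) == expected

    def test_filters_exhausting_entries_is_an_error(self):
        lex = pf.Lexicon([pf.LexiconEntry("cephalexin", frozenset(["keflex"]), oral_only=True)])
        with pytest.raises(LexiconError):
            build_matcher(lex, AlgorithmVariant(use_text=True, exclude_oral_only=True))

    def test_prophylaxis_pseudo_term(self, lexicon):
        variant = AlgorithmVariant(use_text=True, include_prophylaxis_term=True)
        matcher = build_matcher(lexicon, variant)
        hits = match_text("antimicrobial prophylaxis administered", matcher)
        assert [h.canonical_name for h in hits] == [PROPHYLAXIS_TERM]


def brute_force_scan(text, alias_map):
    """Independent longest-match scan used as the matching oracle."""
    low = text.lower()
    hits, i = [], 0
    while i < len(low):
        best = None
        for alias in alias_map:
            j = i + len(alias)
            if low[i:j] != alias:
                continue
            if i > 0 and low[i - 1].isalnum():
                continue
            if j < len(low) and low[j].isalnum():
                continue
            if best is None or len(alias) > len(best):
                best = alias
        if best is not None:
            hits.append((i, best))
            i += len(best)
        else:
            i += 1
    return hits


class TestMatchText:
    def test_empty_text(self, lexicon):
        matcher = build_matcher(lexicon, TEXT_VARIANT)
        assert match_text("", matcher) == []

    def test_single_hit_with_offset(self, lexicon):
        matcher = build_matcher(lexicon, TEXT_VARIANT)
        hits = match_text("Cefazolin 1 g IV administered prior to incision", matcher)
        assert len(hits) == 1
        assert hits[0].canonical_name == "cefazolin"
        assert hits[0].start_offset == 0
        assert hits[0].surface_form == "Cefazolin"

    def test_penicillin_allergy_not_matched_by_default(self, lexicon):
        matcher = build_matcher(lexicon, TEXT_VARIANT)
        assert match_text("penicillin allergy noted", matcher) == []

    def test_whole_word_boundaries(self, lexicon):
        matcher = build_matcher(lexicon, TEXT_VARIANT)
        assert match_text("xcefazolinx and cefazolin2", matcher) == []
        assert len(match_text("(cefazolin)", matcher)) == 1

    def test_longest_alias_wins_at_an_offset(self):
        matcher = TermMatcher({"vanco": "vancomycin", "vancomycin": "vancomycin"})
        hits = matcher.find("vancomycin 1 g")
        assert len(hits) == 1
        assert hits[0].surface_form == "vancomycin"

    @pytest.mark.parametrize(
        "text",
        [
            "Cefazolin 1g IV, then Ancef again; vanco held.",
            "no antimicrobials given",
            "pt allergic to PCN, received CEFUROXIME (Zinacef).",
            "gentamicin-flush used; cleocin po",
        ],
    )
    def test_matches_agree_with_brute_force_scan(self, lexicon, text):
        matcher = build_matcher(lexicon, TEXT_VARIANT)
        got = [(h.start_offset, normalize_term(h.surface_form)) for h in matcher.find(text)]
        assert got == brute_force_scan(text, set(matcher.alias_map))

    @given(
        st.lists(
            st.sampled_from(
                ["cefazolin", "ancef", "vanco", "patient", "allergy", "iv", "keflex", "x2"]
            ),
            max_size=12,
        )
    )
    def test_every_match_revalidates_and_shrinking_is_antimonotone(self, words):
        text = " ".join(words)
        lex = pf.default_lexicon()
        matcher = build_matcher(lex, TEXT_VARIANT)
        hits = matcher.find(text)
        for h in hits:
            segment = text[h.start_offset : h.start_offset + len(h.surface_form)]
            assert normalize_term(segment) in matcher.alias_map
            assert matcher.alias_map[normalize_term(segment)] == h.canonical_name
        # idempotence / determinism
        assert matcher.find(text) == hits
        # removing entries never adds matches
        smaller = pf.Lexicon([e for e in lex.entries if e.canonical_name != "cefazolin"])
        sub_matcher = build_matcher(smaller, TEXT_VARIANT)
        sub_offsets = {(h.start_offset, h.surface_form) for h in sub_matcher.find(text)}
        full_offsets = {(h.start_offset, h.surface_form) for h in hits}
        assert sub_offsets <= full_offsets
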