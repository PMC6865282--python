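import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opichatter.lexicon import (
    Keyword,
    Lexicon,
    expand_lexicon,
    expand_variants,
    filter_noise,
    match_post,
    read_lexicon,
    write_lexicon,
)


def damerau_levenshtein(a: str, b: str) -> int:
    """Independent DP oracle (optimal string alignment)."""
    d = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        d[i][0] = i
    for j in range(len(b) + 1):
        d[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[len(a)][len(b)]


class TestExpandVariants:
    def test_contains_surface_and_first_char(self):
        variants = expand_variants("percocet", 10)
        assert "percocet" in variants
        assert all(v.startswith("p") for v in variants)

    @pytest.mark.parametrize("k", [0, 1, 5, 50])
    def test_identity_always_included(self, k):
        assert "oxycodone" in expand_variants("oxycodone", k)

    def test_zero_budget(self):
        assert expand_variants("oxy", 0) == {"oxy"}

    def test_budget_caps_size(self):
        assert len(expand_variants("fentanyl", 4)) <= 5

    def test_short_surface_rejected(self):
        with pytest.raises(ValueError):
            expand_variants("ox", 5)

    def test_edit_distance_at_most_one(self):
        for surface in ["percocet", "oxycontin", "heroin", "tramadol"]:
            for v in expand_variants(surface, 100):
                assert damerau_levenshtein(surface, v) <= 1, (surface, v)

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=3, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_variant_properties_random_words(self, word):
        variants = expand_variants(word, 20)
        assert word in variants
        for v in variants:
            assert v[0] == word[0]
            assert damerau_levenshtein(word, v) <= 1


class TestMatchPost:
    def test_direct_hit_case_insensitive(self, small_lexicon):
        assert match_post("Took Percocet again", small_lexicon) == {"percocet"}

    def test_variant_maps_to_canonical_surface(self, small_lexicon):
        # oracle: exhaustive lookup in the variant table
        table = {v: k.surface for k in small_lexicon.keywords for v in k.all_forms}
        assert table["percoset"] == "percocet"
        assert match_post("percoset helps", small_lexicon) == {"percocet"}

    def test_no_match(self, small_lexicon):
        assert match_post("nice weather", small_lexicon) == set()

    def test_whole_token_not_substring(self, small_lexicon):
        assert match_post("playing guitar tonight", small_lexicon) == set()
        assert match_post("sticky tar on the road", small_lexicon) == {"tar"}

    def test_returned_names_are_surfaces(self, small_lexicon):
        surfaces = {k.surface for k in small_lexicon.keywords}
        got = match_post("percoset and herroin and dopee", small_lexicon)
        assert got <= surfaces
        assert got == {"percocet", "heroin", "dope"}

    def test_phrase_matched_contiguously(self):
        lex = Lexicon(keywords=[Keyword("china white", "illicit", False, set())])
        assert match_post("got some china white today", lex) == {"china white"}
        assert match_post("china bought white paint", lex) == set()

    def test_empty_text_rejected(self, small_lexicon):
        with pytest.raises(ValueError):
            match_post("", small_lexicon)


class TestFilterNoise:
    def test_reference_noise_example(self, small_lexicon, posts_factory):
        posts = [
            posts_factory(0, "that song is dope"),
            posts_factory(1, "took oxycodone for pain"),
        ]
        kept, removed = filter_noise(posts, small_lexicon)
        assert [p.text for p in kept] == ["took oxycodone for pain"]
        assert removed == 1

    def test_token_scan_count(self, small_lexicon, posts_factory):
        texts = ["tar pit", "hot tar", "guitar solo", "tar again", "tar here",
                 "clean road", "fresh snow", "blue sky", "green grass", "red sun"]
        posts = [posts_factory(i, t) for i, t in enumerate(texts)]
        # brute-force token scan oracle
        expected_removed = sum("tar" in t.split() for t in texts)
        kept, removed = filter_noise(posts, small_lexicon)
        assert removed == expected_removed == 4
        assert len(kept) == 6

    def test_identity_when_clean(self, small_lexicon, posts_factory):
        posts = [posts_factory(i, "sunny day") for i in range(3)]
        kept, removed = filter_noise(posts, small_lexicon)
        assert kept == posts
        assert removed == 0

    def test_idempotent(self, small_lexicon, posts_factory):
        posts = [posts_factory(i, t) for i, t in enumerate(
            ["dope beats", "oxycodone refill", "tar roof", "quiet night"])]
        kept1, _ = filter_noise(posts, small_lexicon)
        kept2, removed2 = filter_noise(kept1, small_lexicon)
        assert kept2 == kept1
        assert removed2 == 0

    def test_order_preserved(self, small_lexicon, posts_factory):
        posts = [posts_factory(i, f"post number {i}") for i in range(5)]
        kept, _ = filter_noise(posts, small_lexicon)
        assert [p.id for p in kept] == [p.id for p in posts]

    def test_no_noise_keywords_is_misconfiguration(self, posts_factory):
        lex = Lexicon(keywords=[Keyword("percocet", "prescription", False, set())])
        with pytest.raises(ValueError, match="noise"):
            filter_noise([posts_factory(0, "hello")], lex)


class TestLexiconType:
    def test_duplicate_surfaces_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Lexicon(keywords=[Keyword("percocet"), Keyword("percocet")])

    def test_counts(self, small_lexicon):
        assert small_lexicon.n_expressions == 5
        # surfaces (5) + extra variants (percoset, perkocet, herroin, dopee)
        assert small_lexicon.n_terms == 9
        assert small_lexicon.n_terms >= small_lexicon.n_expressions

    def test_surface_always_in_variants(self, small_lexicon):
        for kw in small_lexicon.keywords:
            assert kw.surface in kw.variants

    def test_tsv_round_trip(self, small_lexicon, tmp_path):
        path = tmp_path / "lex.tsv"
        write_lexicon(small_lexicon, path)
        back = read_lexicon(path)
        assert back.n_expressions == small_lexicon.n_expressions
        assert {k.surface: k.all_forms for k in back.keywords} == {
            k.surface: k.all_forms for k in small_lexicon.keywords
        }
        assert [k.is_noise for k in back.keywords] == [
            k.is_noise for k in small_lexicon.keywords
        ]

    def test_tsv_comments_ignored(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text("# comment\npercocet\tprescription\t0\tpercoset\n")
        lex = read_lexicon(path)
        assert lex.n_expressions == 1

    def test_expand_lexicon_adds_variants(self, small_lexicon):
        bigger = expand_lexicon(small_lexicon, 5)
        assert bigger.n_terms > small_lexicon.n_terms
        assert bigger.n_expressions == small_lexicon.n_expressions
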