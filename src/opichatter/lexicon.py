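"""Opioid keyword lexicon: spelling-variant expansion, post matching, noise filtering.

Keywords carry a drug-class tag (prescription/illicit) and a noise flag;
noise-flagged terms (and their spelling variants) are used to discard posts
that are overwhelmingly off-topic (slang senses such as "that song is dope").
Matching is whole-token and case-insensitive; multi-word phrases match as
contiguous token sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Keyword",
    "Lexicon",
    "expand_variants",
    "match_post",
    "filter_noise",
    "read_lexicon",
    "write_lexicon",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")
_VOWELS = set("aeiou")


def tokenize(text: str) -> list[str]:
    """Lowercase whole-token split shared by matching and filtering."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Keyword:
    """A lexicon entry: canonical surface plus its matchable spelling variants."""

    surface: str
    drug_class: str = "prescription"  # or "illicit"
    is_noise: bool = False
    variants: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.surface = self.surface.strip().lower()
        if not self.surface:
            raise ValueError("keyword surface must be nonempty")
        if self.drug_class not in ("prescription", "illicit"):
            raise ValueError(f"unknown drug_class {self.drug_class!r}")
        self.variants = {v.strip().lower() for v in self.variants if v.strip()}
        self.variants.add(self.surface)

    @property
    def all_forms(self) -> set[str]:
        return self.variants


@dataclass
class Lexicon:
    keywords: list[Keyword] = field(default_factory=list)

    def __post_init__(self) -> None:
        surfaces = [k.surface for k in self.keywords]
        if len(surfaces) != len(set(surfaces)):
            dupes = sorted({s for s in surfaces if surfaces.count(s) > 1})
            raise ValueError(f"duplicate keyword surfaces: {dupes}")

    @property
    def n_expressions(self) -> int:
        """Distinct canonical surfaces."""
        return len(self.keywords)

    @property
    def n_terms(self) -> int:
        """Surfaces plus spelling variants (every matchable form)."""
        return sum(len(k.all_forms) for k in self.keywords)

    def noise_keywords(self) -> list[Keyword]:
        return [k for k in self.keywords if k.is_noise]

    def signal_keywords(self) -> list[Keyword]:
        return [k for k in self.keywords if not k.is_noise]


def _consonant_skeleton(word: str) -> str:
    out = []
    for ch in word:
        if ch in _VOWELS:
            continue
        if out and out[-1] == ch:
            continue
        out.append(ch)
    return "".join(out)


def _candidate_edits(surface: str) -> set[str]:
    """Single deletions, adjacent transpositions, double-letter collapses and
    expansions — all Damerau-Levenshtein distance 1 from the surface."""
    cands: set[str] = set()
    n = len(surface)
    for i in range(1, n):  # never delete the first character
        cands.add(surface[:i] + surface[i + 1 :])
    for i in range(1, n - 1):  # transpose, keeping the first character fixed
        if surface[i] != surface[i + 1]:
            cands.add(surface[:i] + surface[i + 1] + surface[i] + surface[i + 2 :])
    for i in range(n):  # double a letter (misspellings like "herroin")
        cands.add(surface[: i + 1] + surface[i] + surface[i + 1 :])
    cands.discard(surface)
    return {c for c in cands if len(c) >= 2 and c[0] == surface[0]}


def expand_variants(surface: str, max_variants: int) -> set[str]:
    """Return ``surface`` plus up to ``max_variants`` candidate misspellings.

    Each variant is within Damerau-Levenshtein distance 1 of the surface and
    shares its first character.  Candidates preserving the consonant skeleton
    (the phonetically closest ones) are preferred.

    Parameters
    ----------
    surface : str
        Lowercase keyword, at least 3 characters.
    max_variants : int
        Budget of variants beyond the surface itself (>= 0).
    """
    surface = surface.strip().lower()
    if len(surface) < 3:
        raise ValueError(
            f"surface {surface!r} too short for variant generation (min 3 chars)"
        )
    if max_variants < 0:
        raise ValueError("max_variants must be >= 0")
    skeleton = _consonant_skeleton(surface)
    ranked = sorted(
        _candidate_edits(surface),
        key=lambda c: (_consonant_skeleton(c) != skeleton, c),
    )
    return {surface, *ranked[:max_variants]}


def _phrase_in_tokens(phrase_tokens: Sequence[str], tokens: Sequence[str]) -> bool:
    k = len(phrase_tokens)
    if k == 0 or k > len(tokens):
        return False
    if k == 1:
        return phrase_tokens[0] in tokens
    return any(
        tokens[i : i + k] == list(phrase_tokens) for i in range(len(tokens) - k + 1)
    )


def match_post(text: str, lexicon: Lexicon) -> set[str]:
    """Canonical surfaces of every lexicon keyword whose surface or any
    variant occurs in ``text`` as a whole token (phrases: contiguous tokens)."""
    if not text:
        raise ValueError("text must be nonempty")
    tokens = tokenize(text)
    token_set = set(tokens)
    matched: set[str] = set()
    for kw in lexicon.keywords:
        for form in kw.all_forms:
            if " " in form:
                if _phrase_in_tokens(tokenize(form), tokens):
                    matched.add(kw.surface)
                    break
            elif form in token_set:
                matched.add(kw.surface)
                break
    return matched


def filter_noise(posts: Sequence, lexicon: Lexicon) -> tuple[list, int]:
    """Drop every post matching a noise-flagged keyword (or its variants).

    Returns ``(kept, removed_count)``; ``kept`` preserves input order.
    Raises ``ValueError`` if the lexicon flags no noise keywords, which would
    silently turn the filter into a no-op.
    """
    noise = lexicon.noise_keywords()
    if not noise:
        raise ValueError("lexicon has no noise-flagged keywords; nothing to filter")
    noise_lex = Lexicon(keywords=noise)
    kept = [p for p in posts if not match_post(p.text, noise_lex)]
    return kept, len(posts) - len(kept)


# ---------------------------------------------------------------------------
# TSV I/O: surface<TAB>drug_class<TAB>is_noise<TAB>comma-joined-variants

def read_lexicon(path: str | Path) -> Lexicon:
    keywords = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        surface, drug_class, noise_flag = parts[0], parts[1], parts[2]
        if noise_flag.lower() not in ("0", "1", "true", "false"):
            raise ValueError(f"{path}:{lineno}: bad is_noise flag {noise_flag!r}")
        variants = set()
        if len(parts) >= 4 and parts[3].strip():
            variants = {v.strip() for v in parts[3].split(",") if v.strip()}
        keywords.append(
            Keyword(
                surface=surface,
                drug_class=drug_class.strip().lower(),
                is_noise=noise_flag.lower() in ("1", "true"),
                variants=variants,
            )
        )
    return Lexicon(keywords=keywords)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    lines = ["# surface\tdrug_class\tis_noise\tvariants"]
    for kw in lexicon.keywords:
        extra = sorted(kw.variants - {kw.surface})
        lines.append(
            f"{kw.surface}\t{kw.drug_class}\t{int(kw.is_noise)}\t{','.join(extra)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def expand_lexicon(lexicon: Lexicon, max_variants: int) -> Lexicon:
    """New lexicon with every keyword's variant set expanded in place."""
    expanded = []
    for kw in lexicon.keywords:
        variants = set(kw.variants)
        if len(kw.surface) >= 3 and " " not in kw.surface:
            variants |= expand_variants(kw.surface, max_variants)
        expanded.append(
            Keyword(kw.surface, kw.drug_class, kw.is_noise, variants)
        )
    return Lexicon(keywords=expanded)
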