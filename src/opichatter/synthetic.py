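"""Synthetic corpus and reference-metric generator with known ground truth.

Produces labeled, geolocated, timestamped short posts whose class signal,
drug-name misspellings, regional skew and metric correlation are all
controlled by :class:`GeneratorConfig`, so every downstream stage can be
tested against generator parameters without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus import ClassDistribution, ClassLabel, LABELS, Post
from .lexicon import Keyword, Lexicon, expand_variants

__all__ = ["GeneratorConfig", "gen_corpus", "gen_reference_metrics", "default_lexicon"]

# Default drug-name vocabulary for classes A and I (prescription + illicit).
DRUG_TERMS = (
    "percocet", "oxycontin", "oxycodone", "vicodin", "hydrocodone",
    "fentanyl", "tramadol", "methadone", "suboxone", "heroin",
)

NOISE_TERMS = ("dope", "tar", "skunk", "smack")

# Shared background vocabulary (class-neutral chatter).
_BACKGROUND = tuple(
    f"bg{i:03d}" for i in range(200)
) + ("today", "feeling", "work", "home", "friend", "night", "love", "life")

# Class-discriminative content tokens.
_CLASS_TOKENS = {
    ClassLabel.A: ("popped", "crushed", "snorted", "high", "buzz", "craving",
                   "score", "refill", "pills", "blasted") + DRUG_TERMS,
    ClassLabel.I: ("article", "news", "study", "report", "epidemic", "crisis",
                   "awareness", "overdose", "deaths", "health") + DRUG_TERMS,
    ClassLabel.U: ("game", "movie", "music", "team", "weather", "school",
                   "dinner", "party", "traffic", "weekend"),
    # non-English simulated as a distinct token alphabet
    ClassLabel.E: ("zolo", "miraq", "vexun", "talpo", "quorem", "fyran",
                   "welbi", "ostrik", "plumel", "gravix"),
}


def default_lexicon(max_variants: int = 3) -> Lexicon:
    """A small opioid lexicon matching the generator's drug vocabulary,
    with the four canonical noise terms flagged."""
    kws = [
        Keyword(t, "illicit" if t == "heroin" else "prescription", False,
                expand_variants(t, max_variants))
        for t in DRUG_TERMS
    ]
    kws += [
        Keyword(t, "illicit", True, expand_variants(t, max_variants))
        for t in NOISE_TERMS
    ]
    return Lexicon(keywords=kws)


@dataclass
class GeneratorConfig:
    n_posts: int = 1000
    # defaults follow the reference corpus counts 1748/2001/4830/427 of 9006
    prevalences: ClassDistribution = field(
        default_factory=lambda: ClassDistribution(
            {
                ClassLabel.A: 1748 / 9006,
                ClassLabel.I: 2001 / 9006,
                ClassLabel.U: 4830 / 9006,
                ClassLabel.E: 427 / 9006,
            }
        )
    )
    separability: float = 0.9  # weight on class profile vs shared background
    misspell_rate: float = 0.0  # chance a drug-name token is perturbed
    noise_term_rate: float = 0.0  # chance a class-U post carries a noise term
    regions: tuple[tuple[str, int], ...] = tuple(
        (f"R{i:02d}", int(20_000 * (i + 1) ** 1.5)) for i in range(10)
    )
    region_skew: float = 0.0  # posts drawn ~ population^(1 + skew)
    region_abuse_spread: float = 0.0  # relative spread of per-region abuse odds
    months: tuple[str, str] = ("2012-01", "2014-12")
    target_rho: float = 0.5
    noise_sd: float = 1.0
    min_tokens: int = 5
    max_tokens: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0, 1]")
        if abs(self.target_rho) > 1.0:
            raise ValueError("|target_rho| must be <= 1")
        if self.n_posts < 1:
            raise ValueError("n_posts must be positive")
        if not self.regions:
            raise ValueError("region list must be nonempty")
        if not 0.0 <= self.misspell_rate <= 1.0:
            raise ValueError("misspell_rate must be in [0, 1]")


def _misspell(token: str, rng: np.random.Generator) -> str:
    """Perturb a drug name with the same edit family used by the lexicon's
    variant generator (so expanded lexicons can re-match it)."""
    variants = sorted(expand_variants(token, 10) - {token})
    if not variants:
        return token
    return variants[rng.integers(0, len(variants))]


def _month_range(months: tuple[str, str]) -> tuple[datetime, datetime]:
    start = datetime.strptime(months[0], "%Y-%m").replace(tzinfo=timezone.utc)
    end_month = datetime.strptime(months[1], "%Y-%m")
    if end_month.month == 12:
        end = end_month.replace(year=end_month.year + 1, month=1)
    else:
        end = end_month.replace(month=end_month.month + 1)
    return start, end.replace(tzinfo=timezone.utc)


def gen_corpus(config: GeneratorConfig) -> list[Post]:
    """Generate a labeled synthetic corpus; byte-identical for a fixed config
    and seed."""
    rng = np.random.default_rng(config.seed)
    labels_order = list(LABELS)
    base_p = np.asarray([config.prevalences[lab] for lab in labels_order])

    region_ids = [r for r, _pop in config.regions]
    pops = np.asarray([p for _r, p in config.regions], dtype=float)
    region_w = pops ** (1.0 + config.region_skew)
    region_w /= region_w.sum()

    # optional per-region tilt of the abuse prevalence (mass moved from U)
    a_idx = labels_order.index(ClassLabel.A)
    u_idx = labels_order.index(ClassLabel.U)
    tilt = np.ones(len(region_ids))
    if config.region_abuse_spread > 0:
        tilt = np.clip(
            rng.normal(1.0, config.region_abuse_spread, size=len(region_ids)),
            0.2,
            1.8,
        )
    region_p = np.tile(base_p, (len(region_ids), 1))
    region_p[:, a_idx] = base_p[a_idx] * tilt
    region_p[:, u_idx] += base_p[a_idx] - region_p[:, a_idx]
    region_p /= region_p.sum(axis=1, keepdims=True)

    start, end = _month_range(config.months)
    span = (end - start).total_seconds()

    posts: list[Post] = []
    for i in range(config.n_posts):
        ridx = int(rng.choice(len(region_ids), p=region_w))
        label = labels_order[int(rng.choice(len(labels_order), p=region_p[ridx]))]
        n_tok = int(rng.integers(config.min_tokens, config.max_tokens + 1))
        class_tokens = _CLASS_TOKENS[label]
        tokens = []
        has_drug = False
        for _ in range(n_tok):
            if rng.random() < config.separability:
                tok = class_tokens[rng.integers(0, len(class_tokens))]
            else:
                tok = _BACKGROUND[rng.integers(0, len(_BACKGROUND))]
            if tok in DRUG_TERMS:
                has_drug = True
                if rng.random() < config.misspell_rate:
                    tok = _misspell(tok, rng)
            tokens.append(tok)
        if label == ClassLabel.U and rng.random() < config.noise_term_rate:
            tokens[rng.integers(0, len(tokens))] = NOISE_TERMS[
                rng.integers(0, len(NOISE_TERMS))
            ]
        # class A/I posts mention a drug name (as retrieved posts do), but the
        # guarantee is gated on separability so that separability=0 keeps the
        # text distribution label-independent
        if (
            label in (ClassLabel.A, ClassLabel.I)
            and not has_drug
            and rng.random() < config.separability
        ):
            tok = DRUG_TERMS[rng.integers(0, len(DRUG_TERMS))]
            if rng.random() < config.misspell_rate:
                tok = _misspell(tok, rng)
            tokens[rng.integers(0, len(tokens))] = tok
        ts = start + timedelta(seconds=float(rng.random() * span))
        posts.append(
            Post(
                id=f"synth{i:07d}",
                text=" ".join(tokens),
                timestamp=ts,
                region_id=region_ids[ridx],
                gold_label=label,
            )
        )
    return posts


def true_region_abuse_rates(posts: Sequence[Post]) -> dict[str, float]:
    """Realized per-region share of gold class-A posts."""
    totals: dict[str, int] = {}
    abuse: dict[str, int] = {}
    for p in posts:
        totals[p.region_id] = totals.get(p.region_id, 0) + 1
        if p.gold_label == ClassLabel.A:
            abuse[p.region_id] = abuse.get(p.region_id, 0) + 1
    return {r: abuse.get(r, 0) / n for r, n in sorted(totals.items())}


def gen_reference_metrics(
    true_rates: Mapping[str, float],
    target_rho: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Reference metric per region with sample Pearson correlation
    ``target_rho`` against the true rates.

    The metric is ``rho * z(rates) + sqrt(1 - rho^2) * e`` where ``e`` is
    standardized noise residualized against the rates, so the *sample*
    correlation equals the target exactly; ``noise_sd`` only rescales the
    output.  Deterministic given the seed.
    """
    if abs(target_rho) > 1.0:
        raise ValueError("|target_rho| must be <= 1")
    regions = sorted(true_rates)
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    x = np.asarray([true_rates[r] for r in regions], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("true rates have zero variance")
    z = (x - x.mean()) / x.std()
    rng = np.random.default_rng(seed)
    if abs(target_rho) == 1.0:
        m = np.sign(target_rho) * z
    else:
        e = rng.normal(size=len(regions))
        e = e - e.mean() - z * (e @ z) / (z @ z)  # orthogonal to the signal
        if np.allclose(e, 0):
            raise ValueError("degenerate noise draw; change the seed")
        e /= e.std()
        m = target_rho * z + np.sqrt(1.0 - target_rho**2) * e
    m = m * max(noise_sd, 1e-12)
    return {r: float(v) for r, v in zip(regions, m)}
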