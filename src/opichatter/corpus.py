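"""Post data model, JSONL/CSV I/O, corpus splitting and class distributions.

The label scheme is a fixed 4-class set: A (self-reported abuse/misuse),
I (information sharing), U (unrelated), E (non-English).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ClassLabel",
    "LABELS",
    "Post",
    "ClassDistribution",
    "CorpusFormatError",
    "read_posts",
    "write_posts",
    "split_corpus",
    "class_distribution",
]


class ClassLabel(str, Enum):
    A = "A"  # self-reported abuse or misuse
    I = "I"  # information sharing
    U = "U"  # unrelated
    E = "E"  # non-English

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LABELS: tuple[ClassLabel, ...] = (
    ClassLabel.A,
    ClassLabel.I,
    ClassLabel.U,
    ClassLabel.E,
)


def parse_label(value: str) -> ClassLabel:
    try:
        return ClassLabel(value)
    except ValueError:
        raise ValueError(
            f"unknown class label {value!r}; expected one of A, I, U, E"
        ) from None


@dataclass
class Post:
    id: str
    text: str
    timestamp: datetime
    region_id: str = ""
    gold_label: Optional[ClassLabel] = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"post {self.id!r}: text must be nonempty")
        if isinstance(self.timestamp, str):
            self.timestamp = datetime.fromisoformat(self.timestamp)
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)
        else:
            self.timestamp = self.timestamp.astimezone(timezone.utc)
        if isinstance(self.gold_label, str):
            self.gold_label = parse_label(self.gold_label)


@dataclass
class ClassDistribution:
    """Per-class prevalence, summing to 1."""

    proportions: dict[ClassLabel, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for lab in LABELS:
            self.proportions.setdefault(lab, 0.0)

    def __getitem__(self, label: ClassLabel) -> float:
        return self.proportions[label]

    def percentages(self, ndigits: int = 1) -> dict[ClassLabel, float]:
        """Prevalences as percentages rounded to ``ndigits`` decimals."""
        return {lab: round(100.0 * p, ndigits) for lab, p in self.proportions.items()}


class CorpusFormatError(ValueError):
    """Raised when rows fail validation; carries per-row messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        summary = f"{len(errors)} malformed row(s)"
        super().__init__(summary + ": " + "; ".join(errors[:5]))


_FIELDS = ("id", "text", "timestamp", "region_id", "label")


def _post_from_record(record: dict, lineno: int) -> Post:
    missing = [k for k in ("id", "text", "timestamp") if not record.get(k)]
    if missing:
        raise ValueError(f"line {lineno}: missing required field(s) {missing}")
    label = record.get("label") or None
    return Post(
        id=str(record["id"]),
        text=record["text"],
        timestamp=record["timestamp"],
        region_id=str(record.get("region_id") or ""),
        gold_label=parse_label(label) if label else None,
    )


def read_posts(path: str | Path, format: str = "jsonl") -> list[Post]:
    """Read posts from JSONL or CSV; malformed rows are collected and reported
    with their line numbers in a single :class:`CorpusFormatError`."""
    path = Path(path)
    posts: list[Post] = []
    errors: list[str] = []
    if format == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    posts.append(_post_from_record(json.loads(line), lineno))
                except (ValueError, KeyError) as exc:
                    errors.append(f"line {lineno}: {exc}")
    elif format == "csv":
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    posts.append(_post_from_record(row, lineno))
                except (ValueError, KeyError) as exc:
                    errors.append(f"line {lineno}: {exc}")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
    if errors:
        raise CorpusFormatError(errors)
    seen: set[str] = set()
    for p in posts:
        if p.id in seen:
            raise CorpusFormatError([f"duplicate post id {p.id!r}"])
        seen.add(p.id)
    return posts


def _post_record(post: Post) -> dict:
    return {
        "id": post.id,
        "text": post.text,
        "timestamp": post.timestamp.isoformat(),
        "region_id": post.region_id,
        "label": post.gold_label.value if post.gold_label else "",
    }


def write_posts(posts: Iterable[Post], path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    if format == "jsonl":
        with open(path, "w") as fh:
            for p in posts:
                fh.write(json.dumps(_post_record(p)) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for p in posts:
                writer.writerow(_post_record(p))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")


def _split_sizes(n: int, ratios: Sequence[float]) -> tuple[int, int, int]:
    # floor on train and validation, remainder to test: 9006 -> 6304/900/1802
    n_train = int(math.floor(n * ratios[0] + 1e-9))
    n_val = int(math.floor(n * ratios[1] + 1e-9))
    return n_train, n_val, n - n_train - n_val


def split_corpus(
    posts: Sequence[Post],
    ratios: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
    stratify: bool = False,
) -> tuple[list[Post], list[Post], list[Post]]:
    """Randomly partition posts into train/validation/test.

    Sizes are ``floor(n*r_train)``, ``floor(n*r_val)`` and the remainder.
    ``stratify=False`` is the default: the natural class distribution is
    allowed to vary between partitions.  Deterministic for a fixed seed.
    """
    if not posts:
        raise ValueError("cannot split an empty corpus")
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive proportions")
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"ratios sum to {sum(ratios)}, expected 1")
    rng = np.random.default_rng(seed)
    if not stratify:
        order = rng.permutation(len(posts))
        n_train, n_val, _ = _split_sizes(len(posts), ratios)
        shuffled = [posts[i] for i in order]
        return (
            shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :],
        )
    if any(p.gold_label is None for p in posts):
        raise ValueError("stratified splitting requires every post to be labeled")
    train: list[Post] = []
    val: list[Post] = []
    test: list[Post] = []
    for label in LABELS:
        group = [p for p in posts if p.gold_label == label]
        if not group:
            continue
        order = rng.permutation(len(group))
        n_train, n_val, _ = _split_sizes(len(group), ratios)
        shuffled = [group[i] for i in order]
        train += shuffled[:n_train]
        val += shuffled[n_train : n_train + n_val]
        test += shuffled[n_train + n_val :]
    return train, val, test


def class_distribution(posts: Sequence[Post]) -> ClassDistribution:
    """Empirical prevalence of each class in a fully labeled corpus."""
    if not posts:
        raise ValueError("empty corpus has no class distribution")
    unlabeled = [p.id for p in posts if p.gold_label is None]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} unlabeled post(s), e.g. {unlabeled[:3]}"
        )
    n = len(posts)
    return ClassDistribution(
        {lab: sum(p.gold_label == lab for p in posts) / n for lab in LABELS}
    )


def labels_of(posts: Sequence[Post]) -> list[ClassLabel]:
    return [p.gold_label for p in posts]
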