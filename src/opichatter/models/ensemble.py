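"""Ensemble voting rules.

Two rules are provided:

* ``majority_vote`` — the most frequent label wins; a tie for the mode is
  resolved by the vote of the best-performing individual classifier.
* ``biased_vote`` — if a priority label (by default A or I, the content-rich
  minority classes) is predicted by at least ``min_votes`` classifiers, it is
  assigned; otherwise the majority rule applies.  When both priority labels
  qualify, the one with more votes wins; an exact tie between them goes to
  the best classifier's vote if that vote is itself a priority label, and
  otherwise to the first priority label in A<I<U<E order (abuse is the
  surveillance-critical class).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from ..corpus import ClassLabel, LABELS

__all__ = ["VotePanel", "majority_vote", "biased_vote"]

_ORDER = {lab: i for i, lab in enumerate(LABELS)}


def _coerce(label) -> ClassLabel:
    return label if isinstance(label, ClassLabel) else ClassLabel(str(label))


@dataclass
class VotePanel:
    """Predicted labels for one post, ordered by a fixed classifier roster."""

    votes: list[ClassLabel]
    best_index: int = 0

    def __post_init__(self) -> None:
        if not self.votes:
            raise ValueError("empty vote panel")
        self.votes = [_coerce(v) for v in self.votes]
        if not (0 <= self.best_index < len(self.votes)):
            raise ValueError(
                f"best_index {self.best_index} out of range for {len(self.votes)} votes"
            )


def majority_vote(panel: VotePanel) -> ClassLabel:
    """Modal label; ties for the mode resolved by the best classifier's vote."""
    counts = Counter(panel.votes)
    top = max(counts.values())
    modes = [lab for lab, c in counts.items() if c == top]
    if len(modes) == 1:
        return modes[0]
    return panel.votes[panel.best_index]


def biased_vote(
    panel: VotePanel,
    priority: frozenset = frozenset({ClassLabel.A, ClassLabel.I}),
    min_votes: int = 2,
) -> ClassLabel:
    """Minority-favouring rule: a priority label with >= ``min_votes`` votes
    wins; otherwise fall through to :func:`majority_vote`."""
    if len(panel.votes) < min_votes:
        raise ValueError(
            f"panel of {len(panel.votes)} votes smaller than min_votes={min_votes}"
        )
    priority = {_coerce(p) for p in priority}
    counts = Counter(panel.votes)
    qualified = {p: counts[p] for p in priority if counts[p] >= min_votes}
    if not qualified:
        return majority_vote(panel)
    if len(qualified) == 1:
        return next(iter(qualified))
    top = max(qualified.values())
    leaders = sorted(
        (p for p, c in qualified.items() if c == top), key=_ORDER.__getitem__
    )
    if len(leaders) == 1:
        return leaders[0]
    best = panel.votes[panel.best_index]
    if best in leaders:
        return best
    return leaders[0]
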