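"""Class-imbalance resampling: random undersampling of the majority class,
random oversampling and SMOTE for the minority content classes.

The paper-faithful semantics are label-specific: undersampling reduces the
majority class U to the size of the largest other class; oversampling and
SMOTE raise the content classes A and I to the size of class U.  Original
rows are never modified — undersampling selects a subset, oversampling and
SMOTE append rows.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ..corpus import ClassLabel

__all__ = ["resample"]

STRATEGIES = ("random_under", "random_over", "smote")


def _as_labels(labels: Sequence) -> np.ndarray:
    return np.asarray([str(l) for l in labels], dtype=object)


def _vstack(parts):
    if any(sp.issparse(p) for p in parts):
        return sp.vstack([sp.csr_matrix(p) for p in parts], format="csr")
    return np.vstack(parts)


def resample(
    features,
    labels: Sequence,
    strategy: str,
    seed: int = 0,
    smote_k: int = 5,
    majority_label: str = "U",
    minority_labels: tuple[str, ...] = ("A", "I"),
):
    """Return resampled ``(features, labels)``.

    Parameters
    ----------
    features : array or sparse matrix, shape (n, d)
    labels : sequence of class labels aligned with rows
    strategy : {'random_under', 'random_over', 'smote'}
    smote_k : neighbours considered when interpolating synthetic points
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    y = _as_labels(labels)
    n = y.shape[0]
    if sp.issparse(features):
        features = sp.csr_matrix(features)
    else:
        features = np.asarray(features)
    if features.shape[0] != n:
        raise ValueError(f"{features.shape[0]} feature rows vs {n} labels")
    rng = np.random.default_rng(seed)

    if strategy == "random_under":
        sizes = {lab: int(np.sum(y == lab)) for lab in np.unique(y)}
        others = {lab: s for lab, s in sizes.items() if lab != majority_label}
        if majority_label not in sizes or not others:
            return features, y
        target = max(others.values())
        maj_idx = np.flatnonzero(y == majority_label)
        if maj_idx.size <= target:
            return features, y
        keep_maj = rng.choice(maj_idx, size=target, replace=False)
        keep = np.sort(np.concatenate([np.flatnonzero(y != majority_label), keep_maj]))
        return features[keep], y[keep]

    target = int(np.sum(y == majority_label))
    extra_feats, extra_labels = [], []
    for lab in minority_labels:
        idx = np.flatnonzero(y == lab)
        n_extra = target - idx.size
        if idx.size == 0 or n_extra <= 0:
            continue
        if strategy == "random_over":
            picks = rng.choice(idx, size=n_extra, replace=True)
            extra_feats.append(features[picks])
        else:  # smote
            if idx.size <= smote_k:
                raise ValueError(
                    f"SMOTE needs class {lab!r} to have more than "
                    f"{smote_k} members (has {idx.size})"
                )
            block = features[idx]
            nn = NearestNeighbors(n_neighbors=smote_k + 1).fit(block)
            neigh = nn.kneighbors(block, return_distance=False)[:, 1:]
            base = rng.integers(0, idx.size, size=n_extra)
            chosen = neigh[base, rng.integers(0, smote_k, size=n_extra)]
            lam = rng.random(n_extra)
            a = block[base]
            b = block[chosen]
            if sp.issparse(a):
                lam_d = sp.diags(lam)
                synth = a + lam_d @ (b - a)
            else:
                synth = a + lam[:, None] * (b - a)
            extra_feats.append(synth)
        extra_labels.append(np.full(n_extra, lab, dtype=object))
    if not extra_feats:
        return features, y
    return (
        _vstack([features] + extra_feats),
        np.concatenate([y] + extra_labels),
    )
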