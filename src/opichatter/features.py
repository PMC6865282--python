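"""Text preprocessing and featurization.

Traditional classifiers consume a sparse concatenation of word n-gram counts,
bag-of-word-cluster counts and abuse-term presence/count features, extracted
from lowercased, Porter-stemmed tokens.  The neural classifier consumes
fixed-length token-id sequences over unstemmed tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._porter import porter_stem

__all__ = [
    "preprocess",
    "FeatureSpace",
    "load_cluster_map",
    "train_cluster_map",
    "load_embedding_table",
    "train_embedding_table",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")

PAD_ID = 0
UNK_ID = 1


def preprocess(text: str, stem: bool = True) -> list[str]:
    """Lowercase, tokenize on non-alphanumerics, optionally Porter-stem.

    Traditional classifiers use ``stem=True``; the neural classifier keeps raw
    token forms (``stem=False``).  All-punctuation input yields ``[]``.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    if stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def _ngrams(tokens: Sequence[str], min_n: int, max_n: int) -> Iterable[str]:
    for n in range(min_n, max_n + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i : i + n])


@dataclass
class FeatureSpace:
    """Fitted mapping from token lists to feature vectors.

    The vocabulary is frozen at fit time on training data only: unseen
    n-grams never create new columns.
    """

    ngram_range: tuple[int, int] = (1, 3)
    cluster_map: dict[str, int] = field(default_factory=dict)
    abuse_terms: set[str] = field(default_factory=set)
    embedding_table: Optional[dict[str, np.ndarray]] = None
    max_features: Optional[int] = None

    vocabulary: Optional[dict[str, int]] = None
    _cluster_ids: Optional[dict[int, int]] = None
    _embed_vocab: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        lo, hi = self.ngram_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad ngram_range {self.ngram_range}")
        if self.embedding_table:
            dims = {len(v) for v in self.embedding_table.values()}
            if len(dims) > 1:
                raise ValueError(f"embedding vectors of mixed dimension: {dims}")

    # -- fitting ------------------------------------------------------------

    def fit(self, token_lists: Sequence[Sequence[str]]) -> "FeatureSpace":
        counts: dict[str, int] = {}
        for tokens in token_lists:
            for g in _ngrams(tokens, *self.ngram_range):
                counts[g] = counts.get(g, 0) + 1
        grams = sorted(counts)
        if self.max_features is not None and len(grams) > self.max_features:
            grams = sorted(
                sorted(counts, key=lambda g: (-counts[g], g))[: self.max_features]
            )
        self.vocabulary = {g: i for i, g in enumerate(grams)}
        self._cluster_ids = {
            cid: j for j, cid in enumerate(sorted(set(self.cluster_map.values())))
        }
        if self.embedding_table is not None:
            self._embed_vocab = {
                tok: i + 2 for i, tok in enumerate(sorted(self.embedding_table))
            }
        else:
            seen = sorted({t for tokens in token_lists for t in tokens})
            self._embed_vocab = {tok: i + 2 for i, tok in enumerate(seen)}
        return self

    @property
    def is_fitted(self) -> bool:
        return self.vocabulary is not None

    @property
    def n_features(self) -> int:
        self._check_fitted()
        return len(self.vocabulary) + len(self._cluster_ids) + 2

    def _check_fitted(self) -> None:
        if not self.is_fitted:
            raise RuntimeError("FeatureSpace not fitted; call fit() on training data")

    # -- extraction ---------------------------------------------------------

    def extract(self, tokens: Sequence[str]) -> sp.csr_matrix:
        """Sparse row: [n-gram counts | cluster-id counts | abuse presence | abuse count]."""
        self._check_fitted()
        return self.transform([tokens])

    def transform(self, token_lists: Sequence[Sequence[str]]) -> sp.csr_matrix:
        self._check_fitted()
        n_vocab = len(self.vocabulary)
        n_clust = len(self._cluster_ids)
        data, rows, cols = [], [], []
        for r, tokens in enumerate(token_lists):
            row_counts: dict[int, int] = {}
            for g in _ngrams(tokens, *self.ngram_range):
                j = self.vocabulary.get(g)
                if j is not None:
                    row_counts[j] = row_counts.get(j, 0) + 1
            for t in tokens:
                cid = self.cluster_map.get(t)
                if cid is not None:
                    j = n_vocab + self._cluster_ids[cid]
                    row_counts[j] = row_counts.get(j, 0) + 1
            n_abuse = sum(t in self.abuse_terms for t in tokens)
            if n_abuse:
                row_counts[n_vocab + n_clust] = 1
                row_counts[n_vocab + n_clust + 1] = n_abuse
            for j, v in row_counts.items():
                rows.append(r)
                cols.append(j)
                data.append(v)
        return sp.csr_matrix(
            (data, (rows, cols)),
            shape=(len(token_lists), n_vocab + n_clust + 2),
            dtype=np.float64,
        )

    # -- id sequences for the neural classifier ------------------------------

    def to_id_sequence(self, tokens: Sequence[str], max_len: int) -> np.ndarray:
        """Map tokens to embedding-row ids, pad/truncate to ``max_len``.

        Id 0 is reserved for padding and id 1 for unknown tokens.
        """
        if max_len < 1:
            raise ValueError("max_len must be >= 1")
        self._check_fitted()
        ids = [self._embed_vocab.get(t, UNK_ID) for t in tokens[:max_len]]
        ids += [PAD_ID] * (max_len - len(ids))
        return np.asarray(ids, dtype=np.int64)

    @property
    def embed_vocab_size(self) -> int:
        self._check_fitted()
        return len(self._embed_vocab) + 2

    def embedding_matrix(self, dim: int, rng: np.random.Generator) -> np.ndarray:
        """Initial embedding weights: loaded rows where available, else small
        random values; row 0 (pad) is zero."""
        self._check_fitted()
        mat = rng.normal(0.0, 0.1, size=(self.embed_vocab_size, dim))
        mat[PAD_ID] = 0.0
        if self.embedding_table is not None:
            for tok, vec in self.embedding_table.items():
                if len(vec) != dim:
                    raise ValueError(
                        f"embedding table dimension {len(vec)} != requested {dim}"
                    )
                mat[self._embed_vocab[tok]] = vec
        return mat


# ---------------------------------------------------------------------------
# cluster map and embedding table I/O / fallback trainers

def load_cluster_map(path: str | Path) -> dict[str, int]:
    """TSV of token<TAB>cluster_id."""
    out: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            tok, cid = line.split("\t")
            out[tok] = int(cid)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected token<TAB>cluster_id")
    return out


def train_cluster_map(
    token_lists: Sequence[Sequence[str]],
    n_clusters: int = 50,
    min_count: int = 5,
    seed: int = 0,
) -> dict[str, int]:
    """Derive a hard token clustering from co-occurrence when no cluster file
    is supplied.  Tokens below ``min_count`` are left unclustered."""
    from sklearn.cluster import KMeans

    counts: dict[str, int] = {}
    for tokens in token_lists:
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if len(vocab) <= n_clusters:
        return {t: i for i, t in enumerate(vocab)}
    index = {t: i for i, t in enumerate(vocab)}
    # token x token windowed co-occurrence
    rows, cols = [], []
    for tokens in token_lists:
        idx = [index[t] for t in tokens if t in index]
        for i in range(len(idx)):
            for j in range(max(0, i - 2), min(len(idx), i + 3)):
                if i != j:
                    rows.append(idx[i])
                    cols.append(idx[j])
    cooc = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(vocab), len(vocab))
    )
    # row-normalized context profiles
    norm = np.asarray(cooc.sum(axis=1)).ravel()
    norm[norm == 0] = 1.0
    profiles = sp.diags(1.0 / norm) @ cooc
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=3)
    assignment = km.fit_predict(profiles.toarray())
    return {t: int(assignment[i]) for t, i in index.items()}


def load_embedding_table(path: str | Path) -> dict[str, np.ndarray]:
    """TSV of token<TAB>v1<TAB>...<TAB>vd."""
    table: dict[str, np.ndarray] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected token plus >=1 float")
        table[parts[0]] = np.asarray([float(x) for x in parts[1:]])
    dims = {len(v) for v in table.values()}
    if len(dims) > 1:
        raise ValueError(f"{path}: mixed embedding dimensions {dims}")
    return table


def train_embedding_table(
    token_lists: Sequence[Sequence[str]],
    dim: int = 50,
    min_count: int = 2,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Small corpus-trained embeddings via truncated SVD of the PPMI
    co-occurrence matrix — a stand-in for externally trained vectors."""
    counts: dict[str, int] = {}
    for tokens in token_lists:
        for t in tokens:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    index = {t: i for i, t in enumerate(vocab)}
    rows, cols = [], []
    for tokens in token_lists:
        idx = [index[t] for t in tokens if t in index]
        for i in range(len(idx)):
            for j in range(max(0, i - 2), min(len(idx), i + 3)):
                if i != j:
                    rows.append(idx[i])
                    cols.append(idx[j])
    if not rows:
        raise ValueError("corpus too small to train embeddings")
    cooc = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(vocab), len(vocab))
    ).toarray()
    total = cooc.sum()
    row_m = cooc.sum(axis=1, keepdims=True)
    col_m = cooc.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((cooc * total) / (row_m @ col_m))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    k = min(dim, len(vocab) - 1)
    if k < 1:
        raise ValueError("vocabulary too small for requested dimension")
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    vecs = u[:, :k] * np.sqrt(s[:k])
    if k < dim:  # pad so downstream dimension contracts hold
        vecs = np.hstack([vecs, np.zeros((len(vocab), dim - k))])
    return {t: vecs[i] for t, i in index.items()}


def write_embedding_table(table: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tok in sorted(table):
            vals = "\t".join(f"{x:.6g}" for x in table[tok])
            fh.write(f"{tok}\t{vals}\n")
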