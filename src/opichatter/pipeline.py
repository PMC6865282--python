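"""End-to-end orchestration: filter -> split -> train -> ensemble-predict ->
evaluate -> geo-correlate, with seeded, reproducible stages.

One global seed fans out to per-stage seeds via a stable hash so any stage
can be rerun in isolation with identical results.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .corpus import ClassLabel, Post, class_distribution, read_posts, split_corpus, write_posts
from .evaluate import confusion, metric_report, micro_f1
from .features import FeatureSpace, preprocess
from .geotemporal import (
    attach_metrics,
    correlate,
    monthly_series,
    read_reference_metrics,
    region_rates,
    threshold_filter,
)
from .lexicon import filter_noise, read_lexicon
from .models import ClassifierSpec, TrainedModel, VotePanel, biased_vote, majority_vote, train

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "TextClassifier", "EnsembleClassifier", "run_pipeline", "stage_seed"]

DEFAULT_ROSTER = ("cnn", "random_forest", "svm", "naive_bayes")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256 of '<seed>:<stage>' mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class TextClassifier:
    """Preprocessing + feature space + one classifier, fitted together.

    Traditional families use Porter-stemmed tokens and sparse n-gram/cluster/
    abuse-term features; the CNN uses raw tokens mapped to id sequences.
    """

    def __init__(
        self,
        spec: ClassifierSpec,
        ngram_range: tuple[int, int] = (1, 3),
        max_features: Optional[int] = 20000,
        max_len: int = 30,
        cluster_map: Optional[dict] = None,
        abuse_terms: Optional[set] = None,
        embedding_table: Optional[dict] = None,
    ):
        self.spec = spec
        self.max_len = max_len
        self.space = FeatureSpace(
            ngram_range=ngram_range,
            cluster_map=cluster_map or {},
            abuse_terms=abuse_terms or set(),
            embedding_table=embedding_table,
            max_features=max_features,
        )
        self.model: Optional[TrainedModel] = None

    @property
    def _stem(self) -> bool:
        return self.spec.family != "cnn"

    def _featurize(self, posts: Sequence[Post]):
        tokens = [preprocess(p.text, stem=self._stem) for p in posts]
        if self.spec.family == "cnn":
            return np.stack([self.space.to_id_sequence(t, self.max_len) for t in tokens])
        return self.space.transform(tokens)

    def fit(
        self, train_posts: Sequence[Post], val_posts: Sequence[Post] = ()
    ) -> "TextClassifier":
        tokens = [preprocess(p.text, stem=self._stem) for p in train_posts]
        self.space.fit(tokens)
        labels = [p.gold_label for p in train_posts]
        if self.spec.family == "cnn":
            hp = dict(self.spec.hyperparameters)
            hp.setdefault("vocab_size", self.space.embed_vocab_size)
            spec = replace(self.spec, hyperparameters=hp)
            X = np.stack([self.space.to_id_sequence(t, self.max_len) for t in tokens])
            val_X = self._featurize(val_posts) if len(val_posts) else None
            val_y = [p.gold_label for p in val_posts] if len(val_posts) else None
            self.model = train(spec, X, labels, val_X, val_y)
        else:
            X = self.space.transform(tokens)
            self.model = train(self.spec, X, labels)
        return self

    def predict(self, posts: Sequence[Post]) -> list[ClassLabel]:
        if self.model is None:
            raise RuntimeError("classifier not fitted")
        return self.model.predict(self._featurize(posts))

    def validation_micro_f1(self, val_posts: Sequence[Post]) -> float:
        pred = self.predict(val_posts)
        return micro_f1(confusion([p.gold_label for p in val_posts], pred))


class EnsembleClassifier:
    """Fixed-roster voting ensemble over fitted :class:`TextClassifier`s."""

    def __init__(
        self,
        members: Sequence[TextClassifier],
        rule: str = "majority",
        best_index: int = 0,
    ):
        if len(members) < 2:
            raise ValueError("ensemble needs at least 2 members")
        if rule not in ("majority", "biased"):
            raise ValueError(f"unknown ensemble rule {rule!r}")
        self.members = list(members)
        self.rule = rule
        self.best_index = best_index

    def predict(self, posts: Sequence[Post]) -> list[ClassLabel]:
        votes = [m.predict(posts) for m in self.members]
        out = []
        vote_fn = majority_vote if self.rule == "majority" else biased_vote
        for i in range(len(posts)):
            panel = VotePanel([v[i] for v in votes], best_index=self.best_index)
            out.append(vote_fn(panel))
        return out


@dataclass
class RunConfig:
    corpus_path: str
    lexicon_path: str
    metrics_path: Optional[str] = None
    out_dir: str = "run_out"
    seed: int = 0
    ratios: tuple[float, float, float] = (0.70, 0.10, 0.20)
    stratify: bool = False
    roster: tuple[str, ...] = DEFAULT_ROSTER
    ensemble_rule: str = "majority"
    resampling: str = "none"
    n_resamples: int = 1000
    rate_mode: str = "per_post"
    min_deaths: tuple[int, ...] = (0, 50, 100)
    max_features: Optional[int] = 20000
    cnn_epochs: int = 12
    stages: tuple[str, ...] = ("filter", "split", "train", "evaluate", "geo")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg


def _fit_roster(
    config: RunConfig, train_posts, val_posts, abuse_terms
) -> tuple[list[TextClassifier], int]:
    members = []
    for family in config.roster:
        hp = {"n_epochs": config.cnn_epochs} if family == "cnn" else {}
        spec = ClassifierSpec(
            family,
            hyperparameters=hp,
            resampling=config.resampling,
            seed=stage_seed(config.seed, f"train:{family}"),
        )
        clf = TextClassifier(
            spec, max_features=config.max_features, abuse_terms=abuse_terms
        )
        log.info("training %s", family)
        clf.fit(train_posts, val_posts)
        members.append(clf)
    scores = [m.validation_micro_f1(val_posts) for m in members]
    best_index = int(np.argmax(scores))
    log.info("validation micro-F1: %s -> best %s",
             dict(zip(config.roster, [round(s, 3) for s in scores])),
             config.roster[best_index])
    return members, best_index


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured stages; returns artifact name -> path.

    Reruns with the same config and seed reproduce all numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    try:
        lexicon = read_lexicon(config.lexicon_path)
        posts = read_posts(config.corpus_path, "jsonl")

        kept, removed = filter_noise(posts, lexicon)
        write_posts(kept, out / "filtered.jsonl")
        artifacts["filtered"] = str(out / "filtered.jsonl")
        log.info("noise filter removed %d of %d posts", removed, len(posts))

        train_p, val_p, test_p = split_corpus(
            kept, config.ratios, seed=stage_seed(config.seed, "split"),
            stratify=config.stratify,
        )
        for name, part in (("train", train_p), ("val", val_p), ("test", test_p)):
            write_posts(part, out / f"{name}.jsonl")
            artifacts[name] = str(out / f"{name}.jsonl")

        abuse_terms = {k.surface for k in lexicon.signal_keywords()}
        members, best_index = _fit_roster(config, train_p, val_p, abuse_terms)
        ensemble = EnsembleClassifier(members, config.ensemble_rule, best_index)

        # Table-1-style report on the held-out test set
        y_true = [p.gold_label for p in test_p]
        rows = []
        for family, member in zip(config.roster, members):
            rep = metric_report(
                y_true, member.predict(test_p), config.n_resamples,
                seed=stage_seed(config.seed, f"bootstrap:{family}"),
            )
            rows.append(rep.as_row(family))
        y_ens = ensemble.predict(test_p)
        rep = metric_report(
            y_true, y_ens, config.n_resamples, seed=stage_seed(config.seed, "bootstrap:ens"),
        )
        rows.append(rep.as_row(f"ensemble_{config.ensemble_rule}"))
        report_path = out / "report.csv"
        with open(report_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
        artifacts["report"] = str(report_path)

        # label the full corpus with the ensemble for geotemporal analysis
        predicted = [
            replace_label(p, lab) for p, lab in zip(kept, ensemble.predict(kept))
        ]
        series = monthly_series(predicted)
        series.table.to_csv(out / "monthly.csv")
        artifacts["monthly"] = str(out / "monthly.csv")

        rates = region_rates(predicted, mode=config.rate_mode)
        rates.table.to_csv(out / "rates.csv")
        artifacts["rates"] = str(out / "rates.csv")

        if config.metrics_path:
            metrics = read_reference_metrics(config.metrics_path)
            merged = attach_metrics(rates, metrics)
            corr_rows = []
            for md in config.min_deaths:
                sub = merged
                if md > 0:
                    if "death_count" not in merged.table.columns:
                        continue
                    sub = threshold_filter(merged, md)
                valid = sub.table.dropna(subset=["abuse_rate", "reference_metric"])
                res = correlate(valid["abuse_rate"], valid["reference_metric"])
                corr_rows.append(res.as_row(f"reference_metric(min_deaths={md})"))
            corr_path = out / "correlations.csv"
            with open(corr_path, "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(corr_rows[0]))
                writer.writeheader()
                writer.writerows(corr_rows)
            artifacts["correlations"] = str(corr_path)

        run_log = {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {
                s: stage_seed(config.seed, s) for s in ("split", "train", "evaluate")
            },
            "n_posts": len(posts),
            "n_removed": removed,
            "split_sizes": [len(train_p), len(val_p), len(test_p)],
            "roster": list(config.roster),
            "best_index": best_index,
            "artifacts": artifacts,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        artifacts["run_log"] = str(out / "run_log.json")
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial artifacts retained\n")
        raise
    return artifacts


def replace_label(post: Post, label: ClassLabel) -> Post:
    return Post(
        id=post.id,
        text=post.text,
        timestamp=post.timestamp,
        region_id=post.region_id,
        gold_label=label,
    )
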