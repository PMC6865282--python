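# opichatter

Building blocks for monitoring opioid-related social-media chatter with
supervised learning:

- **lexicon** — opioid keyword lists with generated spelling variants
  (Damerau–Levenshtein distance 1, first character fixed), whole-token post
  matching, and exclusion of posts carrying noise terms (*dope*, *tar*,
  *skunk*, *smack* by default).
- **corpus** — post data model (4 classes: A abuse/misuse, I information,
  U unrelated, E non-English), JSONL/CSV I/O, unstratified 70/10/20
  train/validation/test splitting (floor on train and validation, remainder
  to test), class distributions.
- **features** — lowercasing, tokenization and an in-package Porter stemmer;
  sparse word n-gram counts plus engineered features (bag of word-cluster
  ids, abuse-term presence and count); token-id sequences for the neural
  model; loadable or corpus-trained cluster maps and embeddings.
- **models** — six classifier families (naive Bayes, decision tree, k-NN,
  random forest, linear SVM, and a small numpy text CNN with parallel
  filter widths 3/4/5); random undersampling of class U, random
  oversampling and SMOTE for classes A and I; majority voting with
  best-classifier tie-break and a minority-favouring biased voting rule.
- **evaluate** — confusion matrices, per-class precision/recall,
  microaveraged F1 (= accuracy), percentile bootstrap 95% CIs
  (1000 resamples), Cohen kappa, and the prevalence-random baseline
  (sum of squared prevalences).
- **geotemporal** — monthly frequency/proportion series, per-region
  abuse-post rates (per-post or per-100k-capita), Pearson/Spearman
  correlation against reference metrics, death-count thresholding.
- **synthetic** — seeded generator for labeled, geolocated, timestamped
  corpora with controllable class separability, misspelling rate, regional
  skew, and reference metrics at an exact target correlation.

## CLI

Every stage is independently invocable under a single entry point:

```bash
opichatter synth corpus --n-posts 5000 --seed 1 --out posts.jsonl
opichatter synth metrics --corpus posts.jsonl --rho 0.5 --seed 1 --out metrics.csv
opichatter lexicon expand --in lexicon.tsv --max-variants 5 --out expanded.tsv
opichatter corpus filter --lexicon expanded.tsv --in posts.jsonl --out kept.jsonl --report
opichatter corpus split --in kept.jsonl --ratios 0.7,0.1,0.2 --seed 1 --out-dir splits/
opichatter model train --spec spec.yaml --train splits/train.jsonl --val splits/val.jsonl --out nb.bin
opichatter model predict --models nb.bin,svm.bin --ensemble majority --in splits/test.jsonl --out pred.jsonl
opichatter evaluate run --truth splits/test.jsonl --pred pred.jsonl --bootstrap 1000 --seed 1
opichatter geo rates --in pred.jsonl --out rates.csv
opichatter geo correlate --rates rates.csv --metrics metrics.csv --min-deaths 50
```

or chained end to end from one YAML config and one global seed (per-stage
seeds are derived by a stable hash):

```bash
opichatter run --config run.yaml --seed 1 --out run_out/
```

The run directory contains the filtered corpus, split manifests, a
per-system report CSV (per-class precision/recall, micro-F1 with bootstrap
CI), monthly series, region rates, a correlation summary CSV, and a JSON
run log with all seeds.

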