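#!/usr/bin/env python
"""Fit and evaluate the score-prediction regression.

Normal-equation multivariate linear regression on the top-k selected
features, k = 1..4, each evaluated over 10 random 70:30 splits
(42 train / 18 test rows from the 60-row matrix); then the best model
predicts 30 random test-size subsamples and the predictions are
aggregated by true group.  Writes results/model_report.json and the
per-iteration CSV.
"""

import json
from pathlib import Path

import pandas as pd

import eegscore as es

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def main() -> None:
    fm = pd.read_csv(ROOT / "results" / "features.csv")
    sel = es.correlation_select(fm, alpha=0.05)
    K = min(4, len(sel.kept))
    cv = es.evaluate_cv(fm, sel.kept, K=K, n_iter=10, seed=SEED)
    cv.iterations.to_csv(ROOT / "results" / "cv_iterations.csv", index=False)
    print(f"split: {cv.train_size} train / {cv.test_size} test rows, "
          f"{cv.n_iter} iterations per k")
    for k, acc in cv.accuracies.items():
        print(f"  k={k} ({', '.join(sel.kept[:k])}): accuracy {acc:.2f}")
    best = cv.best_k()

    summary = es.group_prediction_summary(fm, sel.kept, k=best, n_subsamples=30, seed=SEED)
    print(f"\nbest model k={best}; 30 random subsamples of {summary.test_size} rows:")
    print(summary.per_group.round(2).to_string())

    report = {
        "accuracies": {str(k): v for k, v in cv.accuracies.items()},
        "best_k": best,
        "selected_features": sel.kept,
        "group_prediction": summary.per_group.to_dict(),
    }
    (ROOT / "results" / "model_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )


if __name__ == "__main__":
    main()
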