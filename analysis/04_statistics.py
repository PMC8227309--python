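#!/usr/bin/env python
"""Statistical layer over the feature matrix.

Runs the 600-entry two-sample t-test grid (video vs text, per
repetition/channel/descriptor), the 200 Pearson correlation tests
against the score with p < 0.05 selection and inverse-ratio pruning,
and the Friedman factor tests (group, difficulty) on score, exam time
and the selected features.  Writes three CSVs to results/.
"""

from pathlib import Path

import pandas as pd

import eegscore as es

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fm = pd.read_csv(ROOT / "results" / "features.csv")
    results = ROOT / "results"

    grid = es.group_ttest_grid(fm, alpha=0.05)
    grid.to_csv(results / "ttest_grid.csv", index=False)
    sig = grid[grid.direction != "V=T"]
    print(f"t-test grid: {len(grid)} tests, {len(sig)} significant at p<0.05")
    print(sig.groupby("descriptor").size().sort_values(ascending=False).head(8).to_string())

    sel = es.correlation_select(fm, alpha=0.05)
    table = sel.significant.copy()
    table["status"] = ["pruned" if f in sel.redundant else "kept" for f in table.feature]
    table.to_csv(results / "selection.csv", index=False)
    print(f"\ncorrelation selection: {sel.n_tests} tests, "
          f"{len(sel.significant)} significant, kept {len(sel.kept)} after pruning "
          f"{len(sel.redundant)} inverse ratios")
    print(table.head(6).to_string(index=False))

    responses = ["score", "exam_time_s"] + sel.kept[:6]
    factors = es.friedman_factor_tests(fm, responses)
    factors.to_csv(results / "factor_tests.csv", index=False)
    print(f"\nFriedman factor tests ({len(factors)} responses):")
    print(factors[["response", "p_group", "p_difficulty"]].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
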