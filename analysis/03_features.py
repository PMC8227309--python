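#!/usr/bin/env python
"""Extract the 200-column spectral feature matrix from the cleaned EEG.

Per (participant, repetition) row: 40 eyes-open-normalized band powers
(8 channels x 5 bands, averaged over the 150-s learning task) and 160
raw band-power ratios (8 channels x 20 ordered band pairs).  Writes
results/features.csv.
"""

from pathlib import Path

import eegscore as es
from eegscore import io as eio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    recs = [
        eio.read_recording_edf(p)
        for p in sorted((ROOT / "scratch" / "cohort_eeg_clean").glob("*.edf"))
    ]
    scores = eio.read_scores_csv(ROOT / "results" / "scores.csv")
    fm = es.build_feature_matrix(recs, scores)
    out = ROOT / "results" / "features.csv"
    fm.to_csv(out, index=False)
    n_feat = fm.shape[1] - 5
    n_norm = sum("/" not in c for c in fm.columns) - 5
    print(f"feature matrix: {fm.shape[0]} rows x {n_feat} features "
          f"({n_norm} normalized band powers + {n_feat - n_norm} power ratios) -> {out}")


if __name__ == "__main__":
    main()
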