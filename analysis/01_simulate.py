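#!/usr/bin/env python
"""Generate the default synthetic cohort (10 text + 10 video participants,
three learning-task repetitions each) with injected movement-like
transients, and write the raw EEG plus the score table.

EEG waveforms are bulky and reproducible from the seed, so they go to
scratch/ (EDF, one file per participant); the score table and a cohort
overview land in results/.
"""

from pathlib import Path

import eegscore as es
from eegscore import io as eio
from eegscore.config import PipelineConfig
from eegscore.pipeline import simulate_stage

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = PipelineConfig(seed=SEED, artifact_rate=2.0, artifact_amplitude=30.0)
    recordings, scores = simulate_stage(cfg)

    eeg_dir = ROOT / "scratch" / "cohort_eeg"
    for rec in recordings:
        eio.write_recording_edf(rec, eeg_dir / f"{rec.participant_id}.edf")

    results = ROOT / "results"
    eio.write_scores_csv(scores, results / "scores.csv")
    cfg.save(results / "cohort_config.yaml")

    dur = recordings[0].duration_s
    print(f"generated {len(recordings)} recordings ({dur:.0f} s each at "
          f"{recordings[0].fs:.0f} Hz) -> {eeg_dir}")
    print(f"wrote {len(scores)} score records -> {results/'scores.csv'}")
    by_group = {}
    for s in scores:
        by_group.setdefault(s.group, []).append(s.score)
    for g, vals in sorted(by_group.items()):
        print(f"  mean score {g}: {sum(vals)/len(vals):.2f} (n={len(vals)})")


if __name__ == "__main__":
    main()
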