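"""Score and exam-time summaries per group/repetition and improvement metrics.

Improvements compare the video (V) and text/reading (T) groups at each
repetition r:

    SI_r = SV_r - ST_r                  (score improvement, points)
    TI_r = (1 - TV_r / TT_r) * 100      (time improvement, %)

The signed-difference SI is the primary definition; a relative form
``(1 - ST/SV) * 100`` is reported alongside under ``relative_SI``
because published summary tables sometimes print the ratio form --
both are always emitted, neither silently substituted for the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import ScoreRecord


def score_improvement(sv: float, st: float) -> float:
    """Signed score difference SV - ST (video minus text)."""
    for v in (sv, st):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"score {v} outside [0, 100]")
    return sv - st


def relative_score_improvement(sv: float, st: float) -> float:
    """Ratio-form improvement (1 - ST/SV) * 100; requires SV > 0."""
    if sv <= 0:
        raise ValueError("video score must be positive for the relative form")
    return (1.0 - st / sv) * 100.0


def time_improvement(tv: float, tt: float) -> float:
    """Time improvement (1 - TV/TT) * 100; positive when video is faster."""
    if tt <= 0:
        raise ValueError("text exam time must be positive")
    return (1.0 - tv / tt) * 100.0


@dataclass
class PerformanceSummary:
    """Group/repetition means and per-repetition improvement metrics."""

    means: pd.DataFrame  # index (group), columns MultiIndex (repetition, score/exam_time_s)
    improvements: pd.DataFrame  # index repetition, columns SI, relative_SI, TI (+ rounded)

    def table(self) -> pd.DataFrame:
        """Rendered summary in the conventional layout: one row per group,
        R1..R3 score/time columns, plus an integer-percent improvement row."""
        reps = sorted(self.improvements.index)
        cols = []
        for r in reps:
            cols += [f"R{r} Score", f"R{r} ET (s)"]
        rows = {}
        for group in ("video", "text"):
            rows[group.capitalize()] = [
                round(float(self.means.loc[group, (r, field)]), 2)
                for r in reps
                for field in ("score", "exam_time_s")
            ]
        improvement = []
        for r in reps:
            improvement += [
                f"{int(round(self.improvements.loc[r, 'relative_SI']))}%",
                f"{int(round(self.improvements.loc[r, 'TI']))}%",
            ]
        rows["Improvement"] = improvement
        return pd.DataFrame(rows, index=cols).T


def summarize(records: list[ScoreRecord]) -> PerformanceSummary:
    """Per-(group, repetition) mean score and exam time, with improvements."""
    if not records:
        raise ValueError("no score records")
    df = pd.DataFrame(
        {
            "group": [r.group for r in records],
            "repetition": [r.repetition for r in records],
            "score": [r.score for r in records],
            "exam_time_s": [r.exam_time_s for r in records],
        }
    )
    reps = sorted(df["repetition"].unique())
    for r in reps:
        present = set(df.loc[df["repetition"] == r, "group"])
        if present != {"text", "video"}:
            raise ValueError(f"repetition {r}: both groups required, found {sorted(present)}")

    means = df.groupby(["group", "repetition"])[["score", "exam_time_s"]].mean()
    means = means.unstack("repetition").swaplevel(axis=1).sort_index(axis=1)

    improvements = {}
    for r in reps:
        sv = float(means.loc["video", (r, "score")])
        st = float(means.loc["text", (r, "score")])
        tv = float(means.loc["video", (r, "exam_time_s")])
        tt = float(means.loc["text", (r, "exam_time_s")])
        improvements[r] = {
            "SI": score_improvement(sv, st),
            "relative_SI": relative_score_improvement(sv, st),
            "TI": time_improvement(tv, tt),
        }
    imp = pd.DataFrame(improvements).T
    imp.index.name = "repetition"
    return PerformanceSummary(means=means, improvements=imp)
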