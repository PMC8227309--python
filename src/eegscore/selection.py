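"""Group statistics and correlation-based feature selection.

Three pieces:

* a 600-entry two-sample t-test grid (8 channels x (5 bands + 20
  ratios) x 3 repetitions) comparing video vs text feature values;
* Pearson-correlation feature selection against the test score over all
  rows (both groups, all repetitions pooled), keeping raw p < alpha and
  pruning a ratio when its channel-matched inverse is already selected
  with a smaller p;
* Friedman factor tests on a replicated two-way layout (columns =
  group, rows = difficulty/repetition, replicates = participants).

No multiple-testing correction is applied by default: the selection
deliberately interprets raw p-values, with an optional Benjamini-
Hochberg adjustment for users who want it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BAND_NAMES, RATIOS
from .recording import CHANNELS

logger = logging.getLogger(__name__)

#: The 25 per-channel feature descriptors of the grid: 5 bands + 20 ratios.
DESCRIPTORS: tuple[str, ...] = tuple(BAND_NAMES) + tuple(r.name for r in RATIOS)


def group_ttest_grid(
    fm: pd.DataFrame, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sample t-tests (video vs text) per repetition, channel and descriptor.

    Returns a 600-row frame with columns repetition, channel, descriptor,
    feature, t, p and direction ("V>T"/"V<T" when p < alpha, else "V=T").
    Student's pooled-variance test by default; ``equal_var=False`` gives
    Welch's variant.
    """
    rows = []
    for rep in sorted(fm["repetition"].unique()):
        sub = fm[fm["repetition"] == rep]
        video = sub[sub["group"] == "video"]
        text = sub[sub["group"] == "text"]
        if len(video) == 0 or len(text) == 0:
            raise ValueError(f"repetition {rep}: both groups required "
                             f"(video n={len(video)}, text n={len(text)})")
        for ch in CHANNELS:
            for desc in DESCRIPTORS:
                feature = f"{ch}_{desc}"
                v = video[feature].to_numpy(dtype=float)
                t = text[feature].to_numpy(dtype=float)
                stat, p = stats.ttest_ind(v, t, equal_var=equal_var)
                if p < alpha:
                    direction = "V>T" if v.mean() > t.mean() else "V<T"
                else:
                    direction = "V=T"
                rows.append(
                    {
                        "repetition": int(rep),
                        "channel": ch,
                        "descriptor": desc,
                        "feature": feature,
                        "t": float(stat),
                        "p": float(p),
                        "direction": direction,
                    }
                )
    return pd.DataFrame(rows)


def _is_ratio(desc: str) -> bool:
    return "/" in desc


def _inverse_name(feature: str) -> str | None:
    """C3_theta/alpha -> C3_alpha/theta; None for plain band features."""
    ch, _, desc = feature.partition("_")
    if not _is_ratio(desc):
        return None
    num, den = desc.split("/")
    return f"{ch}_{den}/{num}"


@dataclass
class SelectionResult:
    """Correlation-ranked feature list with inverse-redundancy pruning.

    ``entries`` holds one row per tested feature (r, p); ``significant``
    the p < alpha subset sorted ascending by p; ``kept`` the ordered
    names surviving pruning; ``redundant`` the pruned inverse ratios.
    """

    entries: pd.DataFrame
    significant: pd.DataFrame
    kept: list[str]
    redundant: list[str]
    alpha: float
    n_tests: int
    skipped: list[str] = field(default_factory=list)


def pearson_correlations(fm: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Pearson r and two-sided p of every feature against the score column."""
    y = fm["score"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("scores are constant; correlation undefined")
    if len(y) < 3:
        raise ValueError("need at least 3 rows for correlation tests")
    rows = []
    for name in features:
        x = fm[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append({"feature": name, "r": np.nan, "p": np.nan, "constant": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"feature": name, "r": float(r), "p": float(p), "constant": False})
    return pd.DataFrame(rows)


def correlation_select(
    fm: pd.DataFrame, alpha: float = 0.05, bh_correct: bool = False
) -> SelectionResult:
    """Select score-correlated features and prune redundant inverse ratios.

    All rows (both groups, all repetitions) are pooled; features with
    p < alpha are kept, sorted ascending by p (ties broken by name), and
    when both A/B and B/A survive for a channel only the smaller-p one
    is retained.  ``bh_correct=True`` applies Benjamini-Hochberg to the
    p-values before thresholding (off by default: raw p-values are the
    method's stated behaviour and are not corrected for 200 tests).
    """
    meta = {"participant_id", "group", "repetition", "score", "exam_time_s"}
    features = [c for c in fm.columns if c not in meta]
    entries = pearson_correlations(fm, features)
    skipped = entries.loc[entries["constant"], "feature"].tolist()
    for name in skipped:
        logger.warning("feature %s is constant; skipped from correlation tests", name)
    tested = entries[~entries["constant"]].copy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        tested["p"] = multipletests(tested["p"].to_numpy(), method="fdr_bh")[1]
    sig = tested[tested["p"] < alpha].sort_values(["p", "feature"]).reset_index(drop=True)

    kept: list[str] = []
    redundant: list[str] = []
    for name in sig["feature"]:
        inv = _inverse_name(name)
        if inv is not None and inv in kept:
            redundant.append(name)
        else:
            kept.append(name)
    if redundant:
        logger.info("pruned %d redundant inverse ratios: %s", len(redundant), redundant)
    return SelectionResult(
        entries=entries.drop(columns="constant"),
        significant=sig.drop(columns="constant"),
        kept=kept,
        redundant=redundant,
        alpha=alpha,
        n_tests=len(tested),
        skipped=skipped,
    )


def friedman_replicated(data: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test on a replicated two-way ranked layout.

    ``data`` has shape (blocks, treatments, replicates): within each
    block all treatments x replicates observations are ranked together;
    treatment rank sums are compared by the chi-square approximation
    with treatments-1 degrees of freedom, with the standard tie
    correction.  Reduces to the classical Friedman statistic when
    replicates == 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (blocks, treatments, replicates)")
    r, c, m = data.shape
    if c < 2:
        raise ValueError("need at least 2 treatments")
    n_cell = c * m
    rank_sums = np.zeros(c)
    tie_term = 0.0
    for block in data:
        flat = block.reshape(-1)
        ranks = stats.rankdata(flat).reshape(c, m)
        rank_sums += ranks.sum(axis=1)
        _, counts = np.unique(flat, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    expected = r * m * (n_cell + 1) / 2.0
    chi2 = 12.0 / (r * m**2 * c * (n_cell + 1)) * float(np.sum((rank_sums - expected) ** 2))
    correction = 1.0 - tie_term / (r * (n_cell**3 - n_cell))
    if correction <= 0:
        return 0.0, 1.0  # all values tied in every block
    chi2 /= correction
    p = float(stats.chi2.sf(chi2, df=c - 1))
    return float(chi2), p


def friedman_factor_tests(
    fm: pd.DataFrame, responses: list[str]
) -> pd.DataFrame:
    """Friedman p-values for the group and difficulty factors per response.

    The layout places groups in columns and difficulties (repetitions)
    in row blocks with participants as replicates; the difficulty
    factor is tested by exchanging the roles of rows and columns.
    Requires balanced cells (same participant count per group).
    """
    groups = sorted(fm["group"].unique())
    reps = sorted(fm["repetition"].unique())
    counts = fm.groupby(["group", "repetition"]).size()
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced cells:\n{counts}")
    m = int(counts.iloc[0])

    rows = []
    for resp in responses:
        # cube[group, repetition, participant]
        cube = np.empty((len(groups), len(reps), m))
        for gi, g in enumerate(groups):
            for ri, rep in enumerate(reps):
                cell = fm[(fm["group"] == g) & (fm["repetition"] == rep)]
                cube[gi, ri] = cell.sort_values("participant_id")[resp].to_numpy(dtype=float)
        # group factor: blocks = difficulty, treatments = group
        chi_g, p_group = friedman_replicated(cube.transpose(1, 0, 2))
        # difficulty factor: blocks = group, treatments = difficulty
        chi_d, p_difficulty = friedman_replicated(cube)
        rows.append(
            {
                "response": resp,
                "chi2_group": chi_g,
                "p_group": p_group,
                "chi2_difficulty": chi_d,
                "p_difficulty": p_difficulty,
            }
        )
    return pd.DataFrame(rows)
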