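"""Group t-test grid, correlation selection and Friedman factor tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eegscore as es
from eegscore.selection import DESCRIPTORS, friedman_replicated


def tiny_fm(features: dict[str, np.ndarray], score: np.ndarray) -> pd.DataFrame:
    n = len(score)
    base = {
        "participant_id": [f"P{i}" for i in range(n)],
        "group": ["text"] * (n // 2) + ["video"] * (n - n // 2),
        "repetition": [1] * n,
        "score": score,
        "exam_time_s": np.full(n, 60.0),
    }
    base.update(features)
    return pd.DataFrame(base)


class TestGroupTtestGrid:
    def test_grid_has_600_entries(self, full_fm):
        grid = es.group_ttest_grid(full_fm)
        assert len(grid) == 600
        assert len(DESCRIPTORS) == 25
        assert set(grid["repetition"]) == {1, 2, 3}
        assert grid.groupby(["repetition", "channel"]).size().eq(25).all()

    def test_identical_groups_yield_no_significance(self, full_fm):
        text = full_fm[full_fm.group == "text"].copy()
        clone = text.copy()
        clone["group"] = "video"
        clone["participant_id"] = clone["participant_id"] + "v"
        grid = es.group_ttest_grid(pd.concat([text, clone], ignore_index=True))
        assert (grid["direction"] == "V=T").all()

    def test_missing_group_rejected(self, full_fm):
        only_text = full_fm[full_fm.group == "text"]
        with pytest.raises(ValueError, match="both groups"):
            es.group_ttest_grid(only_text)

    def test_localized_alpha_effect_detected(self):
        """A 50% video alpha raise confined to O1/O2 during the learning
        task shows up as V>T on those channels' alpha entries."""
        amps = es.synthetic.default_band_amplitudes()
        topo = np.array(es.synthetic.DEFAULT_TOPOGRAPHY["alpha"])
        base = amps["video"]["LT"]["alpha"]
        vec = base * topo
        vec[[6, 7]] *= 1.5  # O2, O1
        amps["video"]["LT"]["alpha"] = vec
        amps["text"]["LT"]["alpha"] = amps["text"]["LT"]["alpha"] * topo
        spec = es.CohortSpec(seed=21, band_amplitudes=amps)
        recs = es.generate_cohort_recordings(spec)
        fm0 = es.build_feature_matrix(recs)
        scores = es.generate_scores(spec, fm0)
        fm = es.spectral.attach_scores(fm0, scores)
        grid = es.group_ttest_grid(fm)
        hits = grid[(grid.channel.isin(["O1", "O2"])) & (grid.descriptor == "alpha")]
        assert len(hits) == 6
        assert (hits["direction"] == "V>T").sum() >= 5


class TestCorrelationSelect:
    def test_score_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        score = rng.uniform(50, 100, 30)
        fm = tiny_fm(
            {"C3_alpha": score.copy(), "C4_beta": rng.normal(size=30)}, score
        )
        sel = es.correlation_select(fm)
        assert sel.significant.iloc[0]["feature"] == "C3_alpha"
        assert sel.significant.iloc[0]["r"] == pytest.approx(1.0)
        assert sel.significant.iloc[0]["p"] < 1e-30

    def test_inverse_ratio_pruned_keeps_smaller_p(self):
        rng = np.random.default_rng(1)
        score = rng.uniform(50, 100, 40)
        x = score + rng.normal(0, 3, 40)
        fm = tiny_fm({"C3_alpha/theta": x, "C3_theta/alpha": 1.0 / x}, score)
        sel = es.correlation_select(fm)
        assert set(sel.significant["feature"]) == {"C3_alpha/theta", "C3_theta/alpha"}
        assert len(sel.kept) == 1
        assert sel.redundant == [sel.significant.iloc[1]["feature"]]
        assert sel.kept[0] == sel.significant.iloc[0]["feature"]

    def test_bookkeeping_counts_200_tests(self, full_fm):
        sel = es.correlation_select(full_fm)
        assert sel.n_tests == 200
        assert len(sel.entries) == 200
        assert (sel.significant["p"] < 0.05).all()
        assert sel.significant["p"].is_monotonic_increasing

    def test_constant_feature_skipped(self):
        rng = np.random.default_rng(2)
        score = rng.uniform(0, 100, 20)
        fm = tiny_fm({"C3_alpha": np.full(20, 3.3), "C4_alpha": score + rng.normal(size=20)}, score)
        sel = es.correlation_select(fm)
        assert sel.skipped == ["C3_alpha"]
        assert sel.n_tests == 1

    def test_pearson_matches_covariance_formula(self):
        """r from the selection stage equals the explicit covariance-based
        formula to near machine precision."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fm = tiny_fm({"C3_alpha": x}, y * 10 + 50)
            r = es.correlation_select(fm, alpha=1.1).entries.iloc[0]["r"]
            yv = y * 10 + 50
            oracle = np.sum((x - x.mean()) * (yv - yv.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((yv - yv.mean()) ** 2)
            )
            assert r == pytest.approx(oracle, abs=1e-12)

    def test_affine_rescaling_invariance(self, full_fm):
        rescaled = full_fm.copy()
        rescaled["C3_alpha/theta"] = 3.7 * rescaled["C3_alpha/theta"] + 11.0
        a = es.correlation_select(full_fm)
        b = es.correlation_select(rescaled)
        assert list(a.significant["feature"]) == list(b.significant["feature"])
        ra = a.entries.set_index("feature").loc["C3_alpha/theta", "r"]
        rb = b.entries.set_index("feature").loc["C3_alpha/theta", "r"]
        assert rb == pytest.approx(ra, abs=1e-12)


class TestFriedman:
    def test_matches_scipy_without_replicates(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(12, 4))  # 12 blocks, 4 treatments
        chi2, p = friedman_replicated(data[:, :, None])
        ref_chi2, ref_p = stats.friedmanchisquare(*[data[:, j] for j in range(4)])
        assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)

    def test_null_data_rarely_significant(self):
        """Pure noise in a 3x2x10 layout: both factors stay above 0.05
        in at least 90% of seeded replicates."""
        ok_group = ok_diff = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            cube = rng.normal(size=(2, 3, 10))  # group x difficulty x replicate
            _, p_group = friedman_replicated(cube.transpose(1, 0, 2))
            _, p_diff = friedman_replicated(cube)
            ok_group += p_group > 0.05
            ok_diff += p_diff > 0.05
        assert ok_group >= 90
        assert ok_diff >= 90

    def test_group_effect_detected(self):
        """An additive group shift of 3 noise SDs is caught by the group
        factor while the difficulty factor stays null."""
        hit_group = null_diff = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            cube = rng.normal(size=(2, 3, 10))
            cube[1] += 3.0
            _, p_group = friedman_replicated(cube.transpose(1, 0, 2))
            _, p_diff = friedman_replicated(cube)
            hit_group += p_group < 0.05
            null_diff += p_diff > 0.05
        assert hit_group >= 90
        assert null_diff >= 90

    def test_eight_responses_tested(self, full_fm):
        sel = es.correlation_select(full_fm)
        responses = ["score", "exam_time_s"] + sel.kept[:6]
        result = es.friedman_factor_tests(full_fm, responses)
        assert len(result) == 8
        assert result["p_group"].between(0, 1).all()
        assert result["p_difficulty"].between(0, 1).all()

    def test_unbalanced_cells_rejected(self, full_fm):
        unbalanced = full_fm.drop(index=full_fm.index[:1])
        with pytest.raises(ValueError, match="unbalanced"):
            es.friedman_factor_tests(unbalanced, ["score"])
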