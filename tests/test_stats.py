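"""Group statistics: contrasts, onsets, peaks, chi-squared, mixed-model LRTs."""

import numpy as np
import pandas as pd
import pytest

from lamsurf.stats import (
    PeakCall,
    classify_peak,
    condition_contrast,
    detect_response_onset,
    lme_interaction_lrt,
    superficial_ratio_chisq,
)


def profile_table(values, conditions=("motion", "dynamic"), n_sub=4, depths=None, noise=0.0, rng=None):
    """Build a long-format profile table from a {condition: profile} dict."""
    depths = depths if depths is not None else np.linspace(0, 1, len(next(iter(values.values()))))
    rows = []
    for s in range(n_sub):
        for cond in conditions:
            prof = np.asarray(values[cond], dtype=float)
            if noise and rng is not None:
                prof = prof + rng.normal(0, noise, prof.shape)
            for d, v in zip(depths, prof):
                rows.append({"subject": f"s{s}", "condition": cond, "depth_fraction": d, "psc": v})
    return pd.DataFrame(rows)


class TestConditionContrast:
    def test_identical_conditions_give_zero(self, rng):
        prof = rng.normal(size=6)
        table = profile_table({"motion": prof, "dynamic": prof})
        out = condition_contrast(table, "motion", "dynamic")
        assert np.allclose(out["mean"], 0.0)

    def test_phantom_truth_contrast_recovers_increment(self, small_phantom):
        truth_m = small_phantom.truth[("motion", "sustained")]
        truth_d = small_phantom.truth[("dynamic", "sustained")]
        interior = (small_phantom.columns["band"] == "interior").to_numpy()
        table = profile_table(
            {
                "motion": truth_m[interior].mean(axis=0),
                "dynamic": truth_d[interior].mean(axis=0),
            },
            depths=small_phantom.depth_fractions,
        )
        out = condition_contrast(table, "motion", "dynamic")
        expected = (truth_m - truth_d)[interior].mean(axis=0)
        assert np.allclose(out["mean"].to_numpy(), expected)

    def test_sem_matches_direct_formula(self, rng):
        table = profile_table(
            {"motion": np.zeros(3), "dynamic": np.zeros(3)},
            n_sub=6,
            noise=0.5,
            rng=rng,
        )
        out = condition_contrast(table, "motion", "dynamic")
        per = out.attrs["per_subject"]
        for _, row in out.iterrows():
            d = per.loc[per["depth_fraction"] == row["depth_fraction"], "delta_psc"]
            assert row["sem"] == pytest.approx(d.std(ddof=1) / np.sqrt(len(d)))

    def test_unbalanced_subjects_raise(self):
        table = profile_table({"motion": np.zeros(3), "dynamic": np.zeros(3)})
        table = table[~((table.subject == "s0") & (table.condition == "dynamic"))]
        with pytest.raises(ValueError, match="unbalanced"):
            condition_contrast(table, "motion", "dynamic")


class TestOnsetDetection:
    def test_all_zero_gives_none(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert detect_response_onset(np.zeros((5, 10))) is None

    def test_strong_step_detected_at_onset_volume(self, rng):
        n_sub, n_t, k = 8, 15, 6
        y = rng.normal(0, 0.1, (n_sub, n_t))
        y[:, k:] += 1.0  # 10x the subject SD
        assert detect_response_onset(y) == k

    def test_one_volume_offset_between_two_rois(self, rng):
        """An edge ROI stepping one volume before a centre ROI yields onsets
        that differ by exactly one volume."""
        n_sub, n_t = 9, 16
        base = rng.normal(0, 0.08, (2, n_sub, n_t))
        edge, centre = base[0].copy(), base[1].copy()
        edge[:, 5:] += 1.0       # positive transient at the edge
        centre[:, 6:] -= 1.0     # delayed negative sustained response
        onset_edge = detect_response_onset(edge)
        onset_centre = detect_response_onset(centre)
        assert onset_centre - onset_edge == 1

    def test_detection_is_sign_agnostic(self, rng):
        y = rng.normal(0, 0.05, (8, 10))
        y[:, 4:] -= 1.0
        assert detect_response_onset(y) == 4

    def test_monotone_in_alpha(self, rng):
        y = rng.normal(0, 0.4, (6, 12))
        y[:, 5:] += 1.0
        strict = detect_response_onset(y, alpha=0.01)
        loose = detect_response_onset(y, alpha=0.10)
        if strict is not None:
            assert loose is not None and loose <= strict

    def test_fewer_than_two_subjects_raise(self):
        with pytest.raises(ValueError, match="subjects"):
            detect_response_onset(np.zeros((1, 5)))


class TestPeakClassification:
    depths = np.linspace(0, 1, 11)

    def test_peak_at_quarter_depth_is_superficial(self):
        prof = -((self.depths - 0.25) ** 2)
        call = classify_peak(prof, self.depths)
        assert call.superficial
        assert call.peak_depth_fraction in (0.2, 0.3)

    def test_peak_at_half_depth_is_not_superficial(self):
        prof = -((self.depths - 0.5) ** 2)
        call = classify_peak(prof, self.depths)
        assert not call.superficial
        assert call.peak_depth_fraction == pytest.approx(0.5)

    def test_monotone_increase_towards_pial_peaks_at_zero(self):
        call = classify_peak(1.0 - self.depths, self.depths)
        assert call.peak_depth_fraction == 0.0 and call.superficial

    def test_all_equal_profile_is_degenerate_and_superficial_by_tie_rule(self):
        call = classify_peak(np.ones(11), self.depths)
        assert call.degenerate
        assert call.peak_depth_fraction == 0.0
        deep = classify_peak(np.ones(11), self.depths, tie_rule="deep")
        assert deep.peak_depth_fraction == 1.0

    def test_boundary_third_counts_as_superficial(self):
        call = classify_peak(np.array([0.0, 1.0, 0.0]), np.array([0.0, 1 / 3, 1.0]))
        assert call.superficial


class TestChiSquared:
    def test_identical_proportions_give_zero(self):
        stat, df, p = superficial_ratio_chisq({"V1": (4, 4), "V2": (6, 6)})
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        obs = np.array([[7.0, 1.0], [5.0, 11.0]])
        stat, df, p = superficial_ratio_chisq({"V1": (7, 1), "V2+V3": (5, 11)})
        # direct enumeration of expected counts
        row, col, tot = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True), obs.sum()
        expected = row @ col / tot
        assert stat == pytest.approx(((obs - expected) ** 2 / expected).sum())
        assert df == 1

    def test_df_for_three_groups(self):
        _, df, _ = superficial_ratio_chisq({"V1": (5, 4), "V2": (2, 7), "V3": (3, 6)})
        assert df == 2

    def test_invariant_to_group_label_swap(self):
        a = superficial_ratio_chisq({"V1": (7, 2), "V2": (3, 6)})
        b = superficial_ratio_chisq({"V2": (3, 6), "V1": (7, 2)})
        assert a[0] == pytest.approx(b[0])

    def test_accepts_peak_call_lists(self):
        calls = {
            "V1": [PeakCall(0.1, True), PeakCall(0.2, True), PeakCall(0.6, False)],
            "V2": [PeakCall(0.5, False), PeakCall(0.6, False), PeakCall(0.1, True)],
        }
        stat, df, p = superficial_ratio_chisq(calls)
        expected = superficial_ratio_chisq({"V1": (2, 1), "V2": (1, 2)})
        assert stat == pytest.approx(expected[0])

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError, match="expected"):
            superficial_ratio_chisq({"V1": (0, 0), "V2": (0, 0)})


def simulate_lmm(rng, interaction=0.0, n_sub=9, n_area=3, n_cond=3, n_depth=5, sd=0.2):
    rows = []
    area_eff = rng.normal(0, 0.3, n_area)
    cond_eff = rng.normal(0, 0.3, n_cond)
    inter = interaction * rng.standard_normal((n_area, n_cond))
    depths = np.linspace(0, 1, n_depth)
    for s in range(n_sub):
        b0, b1 = rng.normal(0, 0.15, 2)
        for a in range(n_area):
            for c in range(n_cond):
                for d in depths:
                    y = area_eff[a] + cond_eff[c] + 0.4 * d + inter[a, c] + b0 + b1 * d
                    rows.append(
                        {
                            "subject": f"s{s}",
                            "area": f"A{a}",
                            "condition": f"C{c}",
                            "depth_fraction": d,
                            "psc": y + rng.normal(0, sd),
                        }
                    )
    return pd.DataFrame(rows)


FULL_TERMS = [
    "area",
    "condition",
    "depth_fraction",
    "area:condition",
    "area:depth_fraction",
    "condition:depth_fraction",
]
NULL_TERMS = [t for t in FULL_TERMS if t != "area:condition"]


class TestMixedModelLRT:
    def test_full_equals_null_gives_zero_statistic(self, rng):
        df = simulate_lmm(rng)
        res = lme_interaction_lrt(df, FULL_TERMS, FULL_TERMS)
        assert res.statistic == 0.0 and res.df == 0

    def test_non_nested_terms_raise(self, rng):
        df = simulate_lmm(rng)
        with pytest.raises(ValueError, match="nested"):
            lme_interaction_lrt(df, NULL_TERMS, FULL_TERMS)

    def test_strong_interaction_detected(self, rng):
        # programmed condition x area interaction at 5x the residual SD
        df = simulate_lmm(rng, interaction=1.0, sd=0.2)
        res = lme_interaction_lrt(df, FULL_TERMS, NULL_TERMS)
        assert res.df == 4
        assert res.statistic >= 0.0
        assert res.p_value < 0.001

    def test_null_data_usually_accepted(self, rng):
        # one replicate under the null: p should not be extreme
        df = simulate_lmm(rng, interaction=0.0)
        res = lme_interaction_lrt(df, FULL_TERMS, NULL_TERMS)
        assert res.p_value > 0.001
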