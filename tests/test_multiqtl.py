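"""Multi-QTL models, penalized LOD, support intervals, effects, per-cue tests."""

import numpy as np
import pandas as pd
import pytest

from prefqtl.core import GenotypeProbabilities
from prefqtl.multiqtl import (
    compare_groups,
    effect_size,
    fit_multiqtl,
    penalized_lod,
    per_cue_effects,
    support_interval,
)
from prefqtl.scan import ScanResult, scan_glmm


def _scan_from_profile(pos, lod, chrom="c1"):
    table = pd.DataFrame({"chrom": chrom, "pos_cm": pos, "lod": lod, "converged": True})
    return ScanResult(table, n_used=100, model="glmm")


class TestPenalizedLod:
    def test_three_qtl_model_identity(self):
        assert penalized_lod(14.90, 3, 2.99) == pytest.approx(5.93)

    def test_empty_model_scores_zero(self):
        assert penalized_lod(0.0, 0, 2.99) == 0.0

    def test_identity_holds_for_fitted_model(self, small_cross):
        model = fit_multiqtl(
            small_cross["probs"], small_cross["pheno"],
            [("chr2", 20.0), ("chr1", 10.0)], threshold=2.0,
        )
        assert model.plod == pytest.approx(model.lod - 2.0 * 2, abs=1e-12)

    def test_duplicate_loci_rejected(self, small_cross):
        with pytest.raises(ValueError, match="duplicate"):
            fit_multiqtl(
                small_cross["probs"], small_cross["pheno"],
                [("chr2", 20.0), ("chr2", 20.0)], threshold=2.0,
            )


class TestFitMultiqtl:
    def test_drop_tests_detect_real_qtl(self, small_cross):
        model = fit_multiqtl(
            small_cross["probs"], small_cross["pheno"],
            [("chr2", 20.0), ("chr3", 20.0)], threshold=2.99,
        )
        tests = model.drop_tests.set_index("chrom")
        assert tests.loc["chr2", "p"] < 0.001
        assert tests.loc["chr2", "two_delta_lnl"] > tests.loc["chr3", "two_delta_lnl"]
        # dropping the real QTL costs pLOD; dropping the null one recovers ~T
        assert tests.loc["chr2", "delta_plod"] < 0
        assert tests.loc["chr3", "delta_plod"] == pytest.approx(
            2.99 - tests.loc["chr3", "two_delta_lnl"] / (2 * np.log(10)), abs=1e-6
        )

    def test_additive_data_drops_interactions(self, small_cross):
        model = fit_multiqtl(
            small_cross["probs"], small_cross["pheno"],
            [("chr2", 20.0), ("chr1", 20.0), ("chr3", 30.0)], threshold=2.99,
        )
        assert model.interactions == []
        assert len(model.drop_tests) == 3


class TestSupportInterval:
    def test_single_point_spike_is_zero_width(self):
        scan = _scan_from_profile([0, 5, 10, 15], [0.1, 6.0, 0.2, 0.1])
        assert support_interval(scan, "c1") == (5.0, 5.0)

    def test_drop_rule_and_clipping(self):
        scan = _scan_from_profile([0, 2, 4, 6, 8], [5.0, 6.0, 5.2, 4.4, 3.0])
        # peak 6.0 at 2; LOD >= 4.5 holds from 0 through 4
        assert support_interval(scan, "c1") == (0.0, 4.0)

    def test_width_non_increasing_in_drop(self):
        scan = _scan_from_profile(np.arange(11), 5 - 0.5 * np.abs(np.arange(11) - 5))
        widths = []
        for drop in (0.5, 1.0, 1.5, 2.0):
            lo, hi = support_interval(scan, "c1", drop=drop)
            widths.append(hi - lo)
        assert all(a <= b for a, b in zip(widths, widths[1:]))

    def test_flat_profile_returns_whole_chromosome(self):
        scan = _scan_from_profile([0, 5, 10], [1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="flat"):
            assert support_interval(scan, "c1") == (0.0, 10.0)

    def test_tie_breaks_to_lowest_cm(self):
        scan = _scan_from_profile([0, 5, 10], [4.0, 2.0, 4.0])
        lo, hi = support_interval(scan, "c1", drop=1.5)
        assert (lo, hi) == (0.0, 0.0)


def _probs_two_class(calls, chrom="c1", pos=0.0):
    grid = pd.DataFrame({"chrom": [chrom], "pos_cm": [pos], "is_marker": [True]})
    ids = np.array([f"i{k}" for k in range(len(calls))])
    return GenotypeProbabilities(ids, grid, np.asarray(calls, float)[:, None])


class TestEffectSize:
    def _pheno(self, ids, y, n):
        return pd.DataFrame(
            {
                "id": ids,
                "minutes_mel": y,
                "minutes_cyd": np.asarray(n) - np.asarray(y),
                "n_trials": 5,
            }
        )

    def test_equal_class_means_give_zero_percent(self):
        probs = _probs_two_class([0, 0, 1, 1])
        est = effect_size(
            probs, self._pheno(probs.ids, [5, 5, 5, 5], [10, 10, 10, 10]),
            ("c1", 0.0), (0.1, 0.9),
        )
        assert est.percent_of_parental_difference == pytest.approx(0.0)

    def test_full_gap_is_hundred_percent(self):
        probs = _probs_two_class([0, 0, 1, 1])
        est = effect_size(
            probs, self._pheno(probs.ids, [1, 1, 9, 9], [10, 10, 10, 10]),
            ("c1", 0.0), (0.1, 0.9),
        )
        assert est.percent_of_parental_difference == pytest.approx(100.0)

    def test_minutes_weighted_class_means(self):
        probs = _probs_two_class([0, 0, 1, 1])
        est = effect_size(
            probs, self._pheno(probs.ids, [0, 4, 9, 1], [10, 30, 10, 2]),
            ("c1", 0.0), (0.0, 1.0),
        )
        assert est.mean_hom == pytest.approx(4 / 40)
        assert est.mean_het == pytest.approx(10 / 12)
        assert est.mean_het_unweighted == pytest.approx((0.9 + 0.5) / 2)

    def test_rescaling_minutes_leaves_percent_unchanged(self):
        probs = _probs_two_class([0, 1, 0, 1, 1, 0])
        y = np.array([2, 8, 3, 7, 9, 1])
        n = np.array([10, 12, 8, 9, 14, 6])
        a = effect_size(probs, self._pheno(probs.ids, y, n), ("c1", 0.0), (0.05, 0.95))
        b = effect_size(
            probs, self._pheno(probs.ids, 3 * y, 3 * n), ("c1", 0.0), (0.05, 0.95)
        )
        assert a.percent_of_parental_difference == pytest.approx(
            b.percent_of_parental_difference
        )

    def test_ambiguous_calls_excluded(self):
        probs = _probs_two_class([0.0, 0.5, 1.0, 1.0])
        est = effect_size(
            probs, self._pheno(probs.ids, [1, 5, 8, 9], [10, 10, 10, 10]),
            ("c1", 0.0), (0.1, 0.9),
        )
        assert est.n_ambiguous == 1
        assert est.n_hom == 1 and est.n_het == 2

    def test_zero_parental_gap_rejected(self):
        probs = _probs_two_class([0, 1])
        with pytest.raises(ValueError, match="parental"):
            effect_size(
                probs, self._pheno(probs.ids, [1, 2], [5, 5]), ("c1", 0.0), (0.5, 0.5)
            )

    def test_ci_brackets_class_mean(self, small_cross):
        est = effect_size(
            small_cross["probs"], small_cross["pheno"], ("chr2", 20.0), (0.05, 0.95)
        )
        assert est.ci_hom[0] < est.mean_hom < est.ci_hom[1]
        assert est.ci_het[0] < est.mean_het < est.ci_het[1]
        assert 10 < est.percent_of_parental_difference < 80


class TestCompareGroups:
    def _pheno(self, y, n):
        return pd.DataFrame(
            {
                "id": [f"g{k}" for k in range(len(y))],
                "minutes_mel": y,
                "minutes_cyd": np.asarray(n) - np.asarray(y),
                "n_trials": 5,
            }
        )

    def test_identical_groups_near_zero(self):
        ph = self._pheno([3, 6, 2, 8], [10, 10, 10, 10])
        res = compare_groups(ph, ph.assign(id=ph["id"] + "_copy"))
        assert res["two_delta_lnl"] == pytest.approx(0.0, abs=1e-6)
        assert res["p"] > 0.9

    def test_separated_groups_significant(self, rng):
        n = np.full(30, 12)
        a = self._pheno(rng.binomial(12, 0.15, 30), n)
        b = self._pheno(rng.binomial(12, 0.75, 30), n)
        res = compare_groups(a, b)
        assert res["p"] < 1e-6

    def test_power_with_logit_gap_two(self, rng):
        # simulated 30 vs 30 males with a logit-scale gap of 2.0
        from scipy.special import expit

        hits = 0
        reps = 25
        for _ in range(reps):
            n = rng.poisson(8, 60) + 1
            eta = np.r_[np.full(30, -1.0), np.full(30, 1.0)]
            y = rng.binomial(n, expit(eta + rng.normal(0, 0.5, 60)))
            a = self._pheno(y[:30], n[:30])
            b = self._pheno(y[30:], n[30:])
            if compare_groups(a, b)["p"] < 0.05:
                hits += 1
        assert hits >= 0.8 * reps

    def test_zero_courtship_group_rejected(self):
        ph = self._pheno([2, 3], [5, 5])
        empty = self._pheno([0, 0], [0, 0])
        with pytest.raises(ValueError, match="zero total"):
            compare_groups(ph, empty)


class TestPerCueEffects:
    def _table(self, rng, effect=0.0):
        n = 80
        calls = pd.DataFrame(
            rng.integers(0, 2, (n, 3)).astype(float),
            index=[f"m{k}" for k in range(n)],
            columns=["q1", "q2", "q3"],
        )
        trials = rng.poisson(4, n) + 1
        mel = rng.poisson(2 * trials * np.exp(effect * calls["q1"].to_numpy()))
        cyd = rng.poisson(2 * trials)
        pheno = pd.DataFrame(
            {
                "id": calls.index,
                "minutes_mel": mel,
                "minutes_cyd": cyd,
                "n_trials": trials,
            }
        )
        return calls, pheno

    def test_constant_response_gives_zero_f(self):
        calls = pd.DataFrame(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]],
            index=list("abcd"), columns=["q1", "q2", "q3"], dtype=float,
        )
        pheno = pd.DataFrame(
            {
                "id": list("abcd"),
                "minutes_mel": [4, 4, 4, 4],
                "minutes_cyd": [4, 4, 4, 4],
                "n_trials": [4, 4, 4, 4],
            }
        )
        res = per_cue_effects(calls, pheno)
        for sp in ("cydno", "melpomene"):
            assert np.allclose(res[sp]["tests"]["F"], 0.0, atol=1e-20)

    def test_matches_one_way_anova_on_balanced_table(self):
        # 8 males, one segregating locus, two constant loci are dropped from
        # the design: marginal F equals the textbook one-way ANOVA F
        ids = [f"m{k}" for k in range(8)]
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        calls = pd.DataFrame({"q1": g}, index=ids)
        mel = np.array([1, 2, 2, 3, 7, 8, 9, 8])
        pheno = pd.DataFrame(
            {
                "id": ids,
                "minutes_mel": mel,
                "minutes_cyd": 4,
                "n_trials": 4,
            }
        )
        res = per_cue_effects(calls, pheno, n_tests=6)
        resp = np.sqrt(mel / 4)
        grand = resp.mean()
        ss_between = 4 * ((resp[:4].mean() - grand) ** 2 + (resp[4:].mean() - grand) ** 2)
        ss_within = ((resp[:4] - resp[:4].mean()) ** 2).sum() + (
            (resp[4:] - resp[4:].mean()) ** 2
        ).sum()
        f_oracle = ss_between / (ss_within / 6)
        got = res["melpomene"]["tests"].set_index("locus").loc["q1"]
        assert got["F"] == pytest.approx(f_oracle, rel=1e-9)
        assert got["p_bonferroni"] == pytest.approx(min(1, 6 * got["p_raw"]), rel=1e-12)

    def test_detects_planted_single_species_effect(self, rng):
        calls, pheno = self._table(rng, effect=1.0)
        res = per_cue_effects(calls, pheno)
        mel = res["melpomene"]["tests"].set_index("locus")
        cyd = res["cydno"]["tests"].set_index("locus")
        assert mel.loc["q1", "p_bonferroni"] < 0.01
        assert cyd.loc["q1", "p_raw"] > 0.01
        assert np.isfinite(res["melpomene"]["levene"]["stat"])

    def test_zero_trial_males_excluded_with_warning(self, rng):
        calls, pheno = self._table(rng)
        pheno.loc[0, "n_trials"] = 0
        with pytest.warns(UserWarning, match="zero trials"):
            per_cue_effects(calls, pheno)
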