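"""Synthetic-data generators: segregation, error model, phenotypes, frequencies."""

import numpy as np
import pandas as pd
import pytest

from prefqtl.admixture import windowed_fd
from prefqtl.ld import recomb_fraction
from prefqtl.simulate import (
    CountSpec,
    QtlSpec,
    SimulationConfig,
    simulate_backcross,
    simulate_four_population_frequencies,
    simulate_preference_phenotypes,
    solve_logit_for_mean,
)


def _two_marker_config(n, gap_cm, **kw):
    return SimulationConfig(
        n_individuals=n,
        chromosomes=(("c1", gap_cm),),
        marker_spacing=gap_cm if gap_cm > 0 else 1.0,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        **kw,
    )


class TestBackcross:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_individuals=30, seed=42)
        a = simulate_backcross(cfg)
        b = simulate_backcross(cfg)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_different_seed_differs(self):
        a = simulate_backcross(SimulationConfig(n_individuals=30, seed=1))
        b = simulate_backcross(SimulationConfig(n_individuals=30, seed=2))
        assert not a[2].equals(b[2])

    def test_zero_length_chromosome_has_identical_markers(self):
        _, obs, truth = simulate_backcross(_two_marker_config(200, 0.0, seed=3))
        assert truth.shape[1] == 2
        assert (truth.iloc[:, 0] == truth.iloc[:, 1]).all()
        assert (obs == truth).all().all()

    def test_recombinant_fraction_matches_haldane_10cm(self):
        # 10,000 meioses across two markers 10 cM apart
        n = 10_000
        _, _, truth = simulate_backcross(_two_marker_config(n, 10.0, seed=4))
        r_hat = (truth.iloc[:, 0] != truth.iloc[:, 1]).mean()
        r = recomb_fraction(10.0)  # 0.0906
        se = np.sqrt(r * (1 - r) / n)
        assert abs(r_hat - r) < 3 * se

    def test_marginal_het_frequency_near_half(self):
        cfg = SimulationConfig(
            n_individuals=4000,
            chromosomes=(("c1", 30.0),),
            marker_spacing=10.0,
            genotyping_error_rate=0.0,
            missing_rate=0.0,
            seed=5,
        )
        _, _, truth = simulate_backcross(cfg)
        het = truth.to_numpy().mean(axis=0)
        assert np.all(np.abs(het - 0.5) < 3 * np.sqrt(0.25 / 4000))

    def test_double_recombinants_match_no_interference(self):
        # adjacent 10 cM intervals: P(double recombinant) = r^2 under Haldane
        n = 100_000
        cfg = SimulationConfig(
            n_individuals=n,
            chromosomes=(("c1", 20.0),),
            marker_spacing=10.0,
            genotyping_error_rate=0.0,
            missing_rate=0.0,
            seed=6,
        )
        _, _, truth = simulate_backcross(cfg)
        g = truth.to_numpy()
        double = ((g[:, 0] != g[:, 1]) & (g[:, 1] != g[:, 2])).mean()
        r2 = recomb_fraction(10.0) ** 2
        se = np.sqrt(r2 * (1 - r2) / n)
        assert abs(double - r2) < 4 * se

    def test_error_and_missing_rates_realized(self):
        cfg = SimulationConfig(
            n_individuals=2000,
            chromosomes=(("c1", 50.0),),
            marker_spacing=5.0,
            genotyping_error_rate=0.05,
            missing_rate=0.1,
            seed=7,
        )
        _, obs, truth = simulate_backcross(cfg)
        o, t = obs.to_numpy(), truth.to_numpy()
        miss = np.isnan(o).mean()
        flip = (o[~np.isnan(o)] != t[~np.isnan(o)]).mean()
        assert abs(miss - 0.1) < 0.01
        assert abs(flip - 0.05) < 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=0)
        with pytest.raises(ValueError):
            SimulationConfig(chromosomes=())
        with pytest.raises(ValueError):
            SimulationConfig(genotyping_error_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(parental_means=(0.9, 0.1))


class TestPreferencePhenotypes:
    def test_zero_effect_zero_overdispersion_recovers_baseline(self):
        cfg = _two_marker_config(5000, 10.0, seed=8)
        lmap, _, truth = simulate_backcross(cfg)
        ph = simulate_preference_phenotypes(
            truth, lmap, [], parental_means=(0.2, 0.9), overdispersion_sd=0.0, seed=9
        )
        pooled = ph["minutes_mel"].sum() / (ph["minutes_mel"] + ph["minutes_cyd"]).sum()
        assert pooled == pytest.approx(0.2, abs=0.01)

    def test_full_effect_spans_parental_gap(self):
        # one QTL at 100% effect moves the het class mean by the whole gap
        cfg = _two_marker_config(6000, 10.0, seed=10)
        lmap, _, truth = simulate_backcross(cfg)
        spec = QtlSpec("c1", 0.0, 100.0)
        ph = simulate_preference_phenotypes(
            truth, lmap, [spec], parental_means=(0.1, 0.9),
            overdispersion_sd=0.0,
            trials_spec=CountSpec("fixed", value=5),
            minutes_per_trial_spec=CountSpec("fixed", value=10),
            seed=11,
        )
        het = truth.iloc[:, 0].to_numpy() == 1
        prop = ph["minutes_mel"] / (ph["minutes_mel"] + ph["minutes_cyd"])
        assert prop[het].mean() - prop[~het].mean() == pytest.approx(0.8, abs=0.02)

    def test_marginal_effect_calibration_under_overdispersion(self):
        # planted 30% effect stays a 30% marginal contrast despite logit noise
        cfg = _two_marker_config(40_000, 10.0, seed=12)
        lmap, _, truth = simulate_backcross(cfg)
        spec = QtlSpec("c1", 0.0, 30.0)
        ph = simulate_preference_phenotypes(
            truth, lmap, [spec], parental_means=(0.05, 0.95),
            overdispersion_sd=1.0, seed=13,
        )
        het = truth.iloc[:, 0].to_numpy() == 1
        tot = (ph["minutes_mel"] + ph["minutes_cyd"]).to_numpy(dtype=float)
        y = ph["minutes_mel"].to_numpy(dtype=float)
        contrast = y[het].sum() / tot[het].sum() - y[~het].sum() / tot[~het].sum()
        assert 100 * contrast / 0.9 == pytest.approx(30.0, abs=1.0)

    def test_pure_binomial_when_overdispersion_zero(self):
        # replicate males with identical genotype: var(y/n) ~ p(1-p)/n
        cfg = _two_marker_config(20_000, 0.0, seed=14)
        lmap, _, truth = simulate_backcross(cfg)
        nt = 12
        ph = simulate_preference_phenotypes(
            truth, lmap, [], parental_means=(0.3, 0.9), overdispersion_sd=0.0,
            trials_spec=CountSpec("fixed", value=2),
            minutes_per_trial_spec=CountSpec("fixed", value=nt // 2),
            seed=15,
        )
        prop = (ph["minutes_mel"] / nt).to_numpy()
        assert prop.var() == pytest.approx(0.3 * 0.7 / nt, rel=0.05)

    def test_unknown_qtl_rejected(self):
        cfg = _two_marker_config(10, 10.0, seed=16)
        lmap, _, truth = simulate_backcross(cfg)
        with pytest.raises(KeyError):
            simulate_preference_phenotypes(truth, lmap, [QtlSpec("nope", 0.0, 10.0)])
        with pytest.raises(ValueError):
            simulate_preference_phenotypes(truth, lmap, [QtlSpec("c1", 99.0, 10.0)])

    def test_trial_count_median_is_five(self):
        cfg = SimulationConfig(n_individuals=2000, seed=17)
        lmap, _, truth = simulate_backcross(cfg)
        ph = simulate_preference_phenotypes(truth, lmap, [], seed=18)
        assert np.median(ph["n_trials"]) == 5

    def test_determinism(self):
        cfg = _two_marker_config(50, 10.0, seed=19)
        lmap, _, truth = simulate_backcross(cfg)
        a = simulate_preference_phenotypes(truth, lmap, [], seed=20)
        b = simulate_preference_phenotypes(truth, lmap, [], seed=20)
        pd.testing.assert_frame_equal(a, b)


class TestSolveLogitForMean:
    @pytest.mark.parametrize("target", [0.05, 0.3, 0.6, 0.95])
    @pytest.mark.parametrize("sigma", [0.0, 0.5, 1.5])
    def test_marginal_mean_hits_target(self, target, sigma, rng):
        b = solve_logit_for_mean(target, sigma)
        mean = (1 / (1 + np.exp(-(b + sigma * rng.standard_normal(400_000))))).mean()
        assert mean == pytest.approx(target, abs=0.003)


class TestFourPopulationFrequencies:
    def test_no_introgression_fd_near_zero(self):
        freqs = simulate_four_population_frequencies(50_000, 0.0, seed=21)
        win = windowed_fd(freqs, width=100_000, step=100_000)
        med = win.loc[win["defined"], "fd"].median()
        assert abs(med) < 0.05

    def test_complete_introgression_fd_one(self):
        freqs = simulate_four_population_frequencies(5_000, 1.0, seed=22)
        win = windowed_fd(freqs, width=100_000, step=100_000)
        assert np.allclose(win.loc[win["defined"], "fd"], 1.0)

    def test_half_introgression_fd_near_half(self):
        freqs = simulate_four_population_frequencies(100_000, 0.5, seed=23)
        win = windowed_fd(freqs, width=10_000_000, step=10_000_000)
        vals = win.loc[win["defined"], "fd"]
        assert vals.mean() == pytest.approx(0.5, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_four_population_frequencies(0, 0.5)
        with pytest.raises(ValueError):
            simulate_four_population_frequencies(10, 1.5)

    def test_determinism(self):
        a = simulate_four_population_frequencies(100, 0.3, seed=24)
        b = simulate_four_population_frequencies(100, 0.3, seed=24)
        pd.testing.assert_frame_equal(a, b)
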