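"""Occupancy-normalised tuning profiles and the SSG condition statistics."""

import numpy as np
import pandas as pd
import pytest

from echospace import tuning
from echospace.errors import FitError
from echospace.simulate import PlantedRF, synthetic_first_echoes
from echospace.tuning import (associate_spikes, compare_first_last_ssg,
                              compare_ssg_nonssg, permutation_power_screen,
                              selectivity_anova, stability_split,
                              tuning_profile)
from echospace.sonar import SonarSoundGroup

from conftest import RECOVERY_BOX, RECOVERY_RF, planted_samples


class TestAssociateSpikes:
    def echo_table(self):
        return synthetic_first_echoes(5, seed=0, spacing=0.2)

    def test_spike_in_window_counts(self):
        ech = self.echo_table()
        spikes = [ech["t_arrival"].iloc[2] + 0.006]
        s = associate_spikes(spikes, ech)
        assert s["response"].tolist() == [0, 0, 1, 0, 0]

    def test_spike_below_window_ignored(self):
        ech = self.echo_table()
        spikes = [ech["t_arrival"].iloc[2] + 0.001]
        s = associate_spikes(spikes, ech)
        assert s["response"].sum() == 0

    def test_overlapping_windows_assign_to_nearest_preceding(self):
        ech = synthetic_first_echoes(3, seed=0, spacing=0.012)
        # windows overlap; a spike in the overlap belongs to the later echo
        t1 = ech["t_arrival"].iloc[1]
        s = associate_spikes([t1 + 0.004], ech)
        assert s["overlap"].any()
        assert s["response"].iloc[1] == 1
        assert s["response"].iloc[0] == 0

    def test_response_probability_tracks_planted_gaussian(self):
        samples, rf = planted_samples(4000, 11, rf=PlantedRF(**RECOVERY_RF),
                                      **RECOVERY_BOX)
        # near the center the response rate approaches baseline + peak
        z = (((samples["azimuth"] - rf.mu_az) / rf.sigma_az) ** 2
             + ((samples["elevation"] - rf.mu_el) / rf.sigma_el) ** 2
             + ((samples["range"] - rf.mu_range) / rf.sigma_range) ** 2)
        core = samples[z < 0.5 ** 2]
        far = samples[z > 3.0 ** 2]
        p_core = core["response"].mean()
        n = len(core)
        expect = rf.baseline_p + rf.peak_p * np.exp(-0.5 * 0.25)
        assert abs(p_core - expect) < 3 * np.sqrt(expect * (1 - expect) / n) + 0.05
        assert far["response"].mean() < 0.08


class TestSelectivityANOVA:
    def test_planted_tuned_unit_detected(self):
        hits = 0
        for s in range(20):
            samples, _ = planted_samples(500, 300 + s, rf=PlantedRF(**RECOVERY_RF),
                                         **RECOVERY_BOX)
            p = selectivity_anova(samples, "range")
            hits += (p < 0.05)
        assert hits >= 19

    def test_all_zero_responses_undefined(self):
        ech = synthetic_first_echoes(100, seed=1)
        samples = associate_spikes([], ech)
        assert np.isnan(selectivity_anova(samples, "range"))

    def test_too_few_bins_undefined(self):
        ech = synthetic_first_echoes(50, seed=2, r_range=(1.0, 1.05))
        samples = associate_spikes([], ech)
        samples["response"] = 1
        assert np.isnan(selectivity_anova(samples, "range"))


class TestTuningProfile:
    def test_probability_arithmetic(self):
        # one bin with 10 events, 5 responses -> probability 0.5
        df = pd.DataFrame(dict(range=np.full(10, 1.05),
                               response=[1] * 5 + [0] * 5))
        tp = tuning_profile(df, "range", fit=False)
        b = np.digitize(1.05, tp.edges) - 1
        assert tp.event_counts[b] == 10
        assert tp.probability[b] == pytest.approx(0.5)

    def test_low_coverage_bins_masked_but_not_uniform_peak(self):
        rng = np.random.default_rng(3)
        # exactly equal coverage: 30 events in each of 12 bins
        xs = np.repeat(np.arange(0.55, 1.75, 0.1), 30)
        resp = (np.abs(xs - 1.15) < 0.15).astype(int)
        df = pd.DataFrame(dict(range=xs, response=resp))
        tp = tuning_profile(df, "range", fit=False)
        occupied = tp.event_counts > 0
        assert tp.included[occupied].all()          # uniform coverage: none masked
        # starving two flank bins masks them and only them
        xs2 = np.concatenate([np.repeat(np.arange(0.55, 1.75, 0.1), 30),
                              [0.15, 0.15, 0.15, 2.35, 2.35]])
        df2 = pd.DataFrame(dict(range=xs2, response=0))
        tp2 = tuning_profile(df2, "range", fit=False)
        starved = (tp2.event_counts > 0) & (tp2.event_counts < 10)
        assert not tp2.included[starved].any()
        assert tp2.included[tp2.event_counts == 30].all()

    def test_planted_parameters_recovered(self):
        samples, rf = planted_samples(600, 42, rf=PlantedRF(**RECOVERY_RF),
                                      **RECOVERY_BOX)
        tp = tuning_profile(samples, "range")
        assert abs(tp.mu - rf.mu_range) < 0.05
        assert abs(tp.sigma / rf.sigma_range - 1) < 0.35
        assert tp.fwhm == pytest.approx(tuning.GAUSS_FWHM * tp.sigma, rel=1e-9)

    def test_flat_profile_flagged(self):
        ech = synthetic_first_echoes(800, seed=5)
        rng = np.random.default_rng(5)
        samples = associate_spikes([], ech)
        samples["response"] = rng.uniform(size=len(samples)) < 0.2
        try:
            tp = tuning_profile(samples, "range")
            assert not np.isfinite(tp.r2) or tp.r2 < 0.5
        except FitError:
            pass

    def test_too_few_bins_raise(self):
        df = pd.DataFrame(dict(range=np.full(50, 1.0), response=1))
        with pytest.raises(FitError):
            tuning_profile(df, "range")


class TestStability:
    def test_stationary_field_rarely_flags_change(self):
        flagged = 0
        usable = 0
        for s in range(15):
            samples, _ = planted_samples(1600, 600 + s, rf=PlantedRF(**RECOVERY_RF),
                                         **RECOVERY_BOX)
            out = stability_split(samples)
            if out["indeterminate"]:
                continue
            usable += 1
            flagged += any(out["changed"].values())
        assert usable >= 8
        assert flagged <= 0.35 * usable

    def test_large_mid_session_shift_flagged(self):
        rf1 = PlantedRF(mu_range=1.1, **RECOVERY_RF)
        rf2 = PlantedRF(mu_range=1.6, **RECOVERY_RF)
        a, _ = planted_samples(900, 77, rf=rf1, **RECOVERY_BOX)
        b, _ = planted_samples(900, 78, rf=rf2, **RECOVERY_BOX)
        b = b.copy()
        b["t_emit"] += a["t_emit"].max() + 0.1
        b["voc_id"] += 10_000
        out = stability_split(pd.concat([a, b], ignore_index=True))
        assert not out["indeterminate"]
        assert out["changed"]["range"]

    def test_starved_half_indeterminate(self):
        samples, _ = planted_samples(80, 9, rf=PlantedRF(**RECOVERY_RF),
                                     **RECOVERY_BOX)
        out = stability_split(samples)
        assert out["indeterminate"]


class TestSSGComparison:
    @staticmethod
    def response_frame(seed, n_ssg=200, n_non=200, mu_ssg=1.1, mu_non=1.3,
                       sd_ssg=0.12, sd_non=0.20):
        """Per-condition response samples drawn at the planted dispersions."""
        rng = np.random.default_rng(seed)
        return pd.DataFrame(dict(
            range=np.concatenate([rng.normal(mu_ssg, sd_ssg, n_ssg),
                                  rng.normal(mu_non, sd_non, n_non)]),
            response=1,
            ssg=np.r_[np.ones(n_ssg, bool), np.zeros(n_non, bool)]))

    def test_planted_sharpening_detected_with_high_power(self):
        hits = 0
        for s in range(20):
            samples = self.response_frame(s, mu_ssg=1.3, sd_ssg=0.12, sd_non=0.20)
            out = compare_ssg_nonssg(samples, rng=np.random.default_rng(s))
            hits += bool(out.included and out.sharpened)
        assert hits >= 16    # >= 80% power at sigma ratio 0.6, n = 200/200

    def test_planted_shift_detected_with_negative_sign(self):
        out = compare_ssg_nonssg(self.response_frame(55, sd_ssg=0.2),
                                 rng=np.random.default_rng(0))
        assert out.included
        assert out.ranksum_p < 0.05
        assert out.mu_ssg < out.mu_nonssg
        assert out.shifted_closer

    def test_null_rarely_rejects(self):
        rejects = 0
        for s in range(12):
            samples = self.response_frame(3000 + s, mu_ssg=1.3, sd_ssg=0.2)
            out = compare_ssg_nonssg(samples, rng=np.random.default_rng(s))
            rejects += bool(out.included and (out.sharpened or out.shifted_closer))
        assert rejects <= 3

    def test_full_chain_modulation_detected(self):
        """Through echoes -> spikes -> samples, SSG modulation still shows."""
        rf = PlantedRF(ssg_sigma_ratio=0.6, ssg_mu_shift=-0.2, **RECOVERY_RF)
        samples, _ = planted_samples(4000, 1234, rf=rf, ssg_fraction=0.5,
                                     **RECOVERY_BOX)
        out = compare_ssg_nonssg(samples, rng=np.random.default_rng(1))
        assert out.included
        assert out.mu_ssg < out.mu_nonssg
        assert out.sigma_ssg < out.sigma_nonssg

    def test_insufficient_samples_excluded(self):
        out = compare_ssg_nonssg(self.response_frame(1, n_ssg=5, n_non=200),
                                 n_min=50)
        assert not out.included and out.reason == "insufficient responses"


class TestPermutationScreen:
    def test_separated_groups_pass(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, 40)
        b = rng.normal(1.6, 0.1, 40)
        p = permutation_power_screen(a, b, rng=1)
        assert p < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            permutation_power_screen([], [1.0, 2.0])

    def test_low_reps_warn(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning):
            permutation_power_screen(rng.normal(size=20), rng.normal(size=20),
                                     reps=50, rng=2)

    def test_bf_and_ranksum_statistics_agree_on_separated_dispersion(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.3, 0.05, 60)
        b = rng.normal(1.3, 0.30, 60)
        assert permutation_power_screen(a, b, statistic="bf", reps=500, rng=3) < 0.05


class TestFirstLastSSG:
    def make(self, p_first, p_last, n_groups=60, seed=0):
        rng = np.random.default_rng(seed)
        rows, groups, voc_ids = [], [], []
        vid = 0
        for g in range(n_groups):
            calls = (3 * g, 3 * g + 1, 3 * g + 2)
            groups.append(SonarSoundGroup(calls=calls, mean_pi=0.03))
            for j, c in enumerate(calls):
                p = p_first if j == 0 else (p_last if j == 2 else 0.4)
                rows.append(dict(voc_id=vid, response=int(rng.uniform() < p)))
                voc_ids.append(vid)
                vid += 1
        return pd.DataFrame(rows), groups, np.array(voc_ids)

    def test_last_call_gain_detected(self):
        samples, groups, ids = self.make(0.3, 0.7)
        out = compare_first_last_ssg(samples, groups, ids)
        assert out["included"] and out["p"] < 0.05
        assert out["p_last"] > out["p_first"]

    def test_equal_gains_not_flagged(self):
        rejects = 0
        for s in range(10):
            samples, groups, ids = self.make(0.4, 0.4, seed=s)
            out = compare_first_last_ssg(samples, groups, ids)
            rejects += out["p"] < 0.05
        assert rejects <= 2

    def test_two_call_groups_still_defined(self):
        rng = np.random.default_rng(3)
        rows, groups, ids = [], [], []
        for g in range(30):
            calls = (2 * g, 2 * g + 1)
            groups.append(SonarSoundGroup(calls=calls, mean_pi=0.03))
            for j, c in enumerate(calls):
                rows.append(dict(voc_id=c, response=int(rng.uniform() < (0.2, 0.8)[j])))
                ids.append(c)
        out = compare_first_last_ssg(pd.DataFrame(rows), groups, np.array(ids))
        assert out["included"] and out["n"] == 30
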