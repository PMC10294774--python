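"""Cohort simulation: phase locking, noise calibration, design resolution."""

import math

import numpy as np
import pytest

import freqtag as ft
from freqtag.cohort import _one_over_f_noise, resolve_kappa
from freqtag.errors import InsufficientTrialsError, InvalidParameterError
from freqtag.pipeline import subject_itpcz


class TestExpectedItpc:
    def test_limits(self):
        assert ft.expected_itpc(0.0) == 0.0
        assert ft.expected_itpc(math.inf) == 1.0

    def test_bessel_ratio_against_high_precision_oracle(self):
        import sympy

        for kappa in (0.5, 1.0, 2.0, 4.0):
            exact = float(sympy.besseli(1, kappa) / sympy.besseli(0, kappa))
            assert ft.expected_itpc(kappa) == pytest.approx(exact, abs=1e-12)

    def test_monotone_in_kappa(self):
        grid = np.linspace(0, 50, 200)
        vals = [ft.expected_itpc(k) for k in grid]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] < 1.0

    def test_negative_kappa_rejected(self):
        with pytest.raises(InvalidParameterError):
            ft.expected_itpc(-0.5)


class TestSimulateEpochs:
    def test_perfect_locking_without_noise_gives_identical_trials_and_unit_itpc(self):
        spec = ft.PhaseLockSpec(freq=4.0, amplitude=0.5, mean_phase=0.7, locked=True)
        noise = ft.NoiseModel(sd=0.0, channel_gain_sd=0.0)
        ep = ft.simulate_epochs([spec], noise, n_trials=8, n_channels=2,
                                fs_eeg=250.0, seed=0)
        np.testing.assert_array_equal(ep.data[0], ep.data[1])
        z = ft.rayleigh_z(ft.compute_itpc(ft.fft_phase(ep, fmax=5.0)))
        idx = z.bin_index(4.0)
        assert z.values[:, idx] == pytest.approx(8.0)  # ITPC = 1 -> Z = n

    def test_uniform_phases_recover_the_small_sample_null_mean(self):
        # E[resultant length] under uniform phases ~ sqrt(pi) / (2 sqrt(n))
        n = 48
        spec = ft.PhaseLockSpec(freq=4.0, amplitude=0.5, kappa=0.0)
        noise = ft.NoiseModel(sd=0.0, channel_gain_sd=0.0)
        vals = []
        for rep in range(200):
            ep = ft.simulate_epochs([spec], noise, n_trials=n, n_channels=1,
                                    fs_eeg=250.0, seed=rep)
            itpc = ft.compute_itpc(ft.fft_phase(ep, fmax=5.0))
            vals.append(itpc.values[0, itpc.freqs.searchsorted(4.0 - 1e-9)])
        expected = math.sqrt(math.pi) / (2.0 * math.sqrt(n))
        assert np.mean(vals) == pytest.approx(expected, abs=0.015)

    def test_epoch_geometry_and_determinism(self):
        spec = ft.PhaseLockSpec(freq=2.0, amplitude=0.5, kappa=1.0)
        noise = ft.NoiseModel()
        a = ft.simulate_epochs([spec], noise, 4, 3, 250.0, (-1.0, 10.0), seed=3)
        b = ft.simulate_epochs([spec], noise, 4, 3, 250.0, (-1.0, 10.0), seed=3)
        assert a.data.shape == (4, 3, 2750)
        np.testing.assert_array_equal(a.data, b.data)

    def test_fewer_than_two_trials_rejected(self):
        spec = ft.PhaseLockSpec(freq=2.0, amplitude=0.5, kappa=1.0)
        with pytest.raises(InsufficientTrialsError):
            ft.simulate_epochs([spec], ft.NoiseModel(), 1, 3, 250.0, seed=0)

    def test_components_start_at_stimulus_onset(self):
        spec = ft.PhaseLockSpec(freq=4.0, amplitude=0.5, locked=True)
        noise = ft.NoiseModel(sd=0.0, channel_gain_sd=0.0)
        ep = ft.simulate_epochs([spec], noise, 2, 1, 250.0, seed=0)
        pre = ep.data[:, :, ep.times < 0]
        assert np.all(pre == 0.0)

    def test_channel_shared_phase_matches_channel_average(self):
        # trial phases are shared across channels, so single-channel ITPC
        # equals ITPC of the channel-averaged (noise-free) signal
        spec = ft.PhaseLockSpec(freq=2.0, amplitude=0.5, kappa=1.5)
        noise = ft.NoiseModel(sd=0.0, channel_gain_sd=0.3)
        ep = ft.simulate_epochs([spec], noise, 16, 4, 250.0, seed=4)
        itpc = ft.compute_itpc(ft.fft_phase(ep, fmax=5.0))
        avg = ft.EpochArray(
            data=ep.data.mean(axis=1, keepdims=True), fs=ep.fs,
            window=ep.window, channel_labels=("AVG",),
        )
        itpc_avg = ft.compute_itpc(ft.fft_phase(avg, fmax=5.0))
        idx = itpc.freqs.searchsorted(2.0 - 1e-9)
        np.testing.assert_allclose(itpc.values[:, idx],
                                   itpc_avg.values[0, idx], atol=1e-5)


def test_noise_variance_matches_requested_sd():
    rng = np.random.default_rng(1)
    x = _one_over_f_noise(rng, (64,), 2750, 250.0, 1.0, 1.5)
    assert float(x.std()) == pytest.approx(1.5, rel=0.05)


def test_noise_spectrum_is_low_frequency_weighted():
    rng = np.random.default_rng(2)
    x = _one_over_f_noise(rng, (200,), 2750, 250.0, 1.0, 1.0).astype(np.float64)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    f = np.fft.rfftfreq(2750, 1 / 250.0)
    low = spec[:, (f > 0.5) & (f < 2.0)].mean()
    high = spec[:, (f > 50) & (f < 80)].mean()
    assert low > 5 * high


class TestMontage:
    def test_analysis_montage_has_62_channels(self):
        full = ft.quickcap_montage()
        assert len(full) == 64
        assert len(ft.analysis_montage()) == 62
        assert "CB1" not in ft.analysis_montage()
        assert "CB2" not in ft.analysis_montage()

    def test_hemisphere_split_partitions_montage(self):
        labels = ft.analysis_montage()
        left, right, midline = ft.hemisphere_split(labels)
        assert set(left) | set(right) | set(midline) == set(labels)
        assert len(left) == len(right)  # symmetric cap
        assert all(lbl.endswith("Z") for lbl in midline)


class TestDesign:
    def test_default_design_matches_study_dimensions(self, default_design):
        assert default_design.n_per_group == 24
        assert default_design.n_trials == 48
        assert default_design.conditions == ("active", "passive")
        assert default_design.window == (-1.0, 10.0)

    def test_proficiency_coupling_is_monotone(self, default_design):
        k0 = resolve_kappa(default_design, "L2", "active", 2.0, proficiency=0.0)
        k30 = resolve_kappa(default_design, "L2", "active", 2.0, proficiency=30.0)
        assert k30 > k0 >= 0.0

    def test_l2_untracked_cells_have_zero_kappa(self, default_design):
        assert resolve_kappa(default_design, "L2", "active", 1.0, 20.0) == 0.0
        assert resolve_kappa(default_design, "L2", "passive", 2.0, 20.0) == 0.0

    def test_unknown_condition_rejected(self, default_design):
        profiles = ft.make_profiles(ft.CohortDesign(n_per_group=2, seed=1))
        with pytest.raises(InvalidParameterError):
            ft.simulate_subject(profiles[0], default_design, "sleeping", seed=0)


class TestCohort:
    def test_minimal_cohort_counts_and_profiles(self, tiny_design):
        cohort = ft.simulate_cohort(tiny_design)
        assert len(cohort.profiles) == 4
        assert len(cohort.epochs) == 8  # 4 subjects x 2 conditions
        df = cohort.profile_frame()
        l2 = df[df.group == "L2"]
        assert l2.proficiency.between(0, 30).all()
        assert df[df.group == "L1"].proficiency.isna().all()

    def test_profile_table_reproducible_from_seed(self, tiny_design):
        a = ft.make_profiles(tiny_design)
        b = ft.make_profiles(tiny_design)
        assert a == b

    def test_epoch_stream_reproducible_from_seed(self, tiny_design):
        first = {(p.subject_id, c): e.data for p, c, e in ft.iter_cohort(tiny_design)}
        second = {(p.subject_id, c): e.data for p, c, e in ft.iter_cohort(tiny_design)}
        for key in first:
            np.testing.assert_array_equal(first[key], second[key])

    def test_absent_component_is_null_at_its_bin(self, tiny_design):
        # L2 passive has no 1-Hz component: its bin must look like background
        profiles = [p for p in ft.make_profiles(tiny_design) if p.group == "L2"]
        zs = []
        for rep, p in enumerate(12 * profiles):
            ep = ft.simulate_subject(p, tiny_design, "passive", seed=rep)
            z = subject_itpcz(ep)
            zs.append(float(z.channel_mean[z.bin_index(1.0)])
                      - ft.neighbor_mean(z, 1.0))
        res = ft.peak_test([v for v in zs], [0.0] * len(zs), m_tests=1)
        assert res.p_raw > 0.01
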