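"""Synthetic generator: carriers, coupled modulators, subjects, empty room."""

import numpy as np
import pytest

from envconn import (
    ALPHA,
    CouplingSpec,
    FrequencyBand,
    SimulationConfig,
    generate_band_carrier,
    generate_coupled_envelopes,
    generate_empty_room,
    grid_source_space,
    realized_envelope_correlation,
    simulate_dataset,
    synthesize_subject,
)
from envconn.bands import BandError
from envconn.simulate import _latent_rho, _link


class TestCarrier:
    def test_spectral_energy_confined_to_band(self):
        x = generate_band_carrier(10.0, 200.0, ALPHA, np.random.default_rng(1))
        spec = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x), d=1 / 200.0)
        in_band = spec[(f >= 8) & (f < 13)].sum()
        assert in_band >= 0.99 * spec.sum()

    def test_unit_variance(self):
        x = generate_band_carrier(10.0, 200.0, ALPHA, np.random.default_rng(2))
        assert abs(x.var() - 1.0) < 0.05

    def test_nyquist_violation(self):
        with pytest.raises(BandError):
            generate_band_carrier(
                10.0, 200.0, FrequencyBand("hi", 90.0, 110.0), np.random.default_rng(0)
            )

    def test_flattened_carrier_has_small_modulus_fluctuation(self):
        from envconn.spectral import analytic_signal

        rng = np.random.default_rng(3)
        x = generate_band_carrier(30.0, 200.0, ALPHA, rng, n_series=5, n_flatten=2)
        mag = np.abs(analytic_signal(x))
        cv2 = mag.var(axis=-1) / mag.mean(axis=-1) ** 2
        assert cv2.max() < 0.1  # vs ~0.27 for raw Gaussian band noise


class TestCoupledEnvelopes:
    def test_rho_one_gives_identical_modulators(self):
        m1, m2 = generate_coupled_envelopes(4000, 100.0, 1.0, np.random.default_rng(1))
        assert np.allclose(m1, m2)
        assert (m1 > 0).all()

    def test_rho_zero_null_bound(self):
        n_eff = 2 * 300  # ~2 x duration x 1-Hz modulator bandwidth
        for seed in (1, 2, 3):
            m1, m2 = generate_coupled_envelopes(
                300 * 100, 100.0, 0.0, np.random.default_rng(seed)
            )
            assert abs(np.corrcoef(m1, m2)[0, 1]) < 3 / np.sqrt(n_eff)

    def test_calibration_against_link_oracle(self):
        # oracle: direct simulation of the log-normal link at 1e6 samples
        rho = 0.6
        z = np.random.default_rng(9).standard_normal((3, 10**6))
        a = np.sqrt(_latent_rho(rho))
        o1 = _link(a * z[0] + np.sqrt(1 - a * a) * z[1])
        o2 = _link(a * z[0] + np.sqrt(1 - a * a) * z[2])
        oracle = np.corrcoef(o1, o2)[0, 1]

        vals = []
        for rep in range(200):
            m1, m2 = generate_coupled_envelopes(
                300 * 200, 200.0, rho, np.random.default_rng(1000 + rep)
            )
            vals.append(np.corrcoef(m1, m2)[0, 1])
        assert abs(np.mean(vals) - oracle) < 0.1

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            generate_coupled_envelopes(1000, 100.0, 1.2, np.random.default_rng(0))


@pytest.fixture(scope="module")
def coupled_setup(small_forward):
    config = SimulationConfig(
        n_subjects=2,
        duration_s=60.0,
        fs_hz=100.0,
        n_sensors=24,
        grid_shape=(3, 3, 3),
        sensor_snr=np.inf,
        bands=("alpha",),
        rng_seed=5,
    )
    coupling = CouplingSpec(3, "alpha", 7, "alpha", 0.9)
    sigs, rec = synthesize_subject(
        config, small_forward, [coupling], np.random.default_rng(5)
    )
    return config, coupling, sigs, rec


class TestSynthesizeSubject:
    def test_planted_coupling_on_true_sources(self, coupled_setup):
        config, coupling, sigs, _ = coupled_setup
        r = realized_envelope_correlation(
            sigs["alpha"][3], sigs["alpha"][7], config.fs_hz
        )
        assert r >= 0.8

    def test_infinite_snr_is_noiseless_projection(self, coupled_setup, small_forward):
        config, coupling, sigs, rec = coupled_setup
        proj = small_forward.leadfield @ sum(sigs.values())
        assert np.array_equal(rec.data, proj)

    def test_uninvolved_pairs_null_by_shift_surrogates(self, coupled_setup):
        config, _, sigs, _ = coupled_setup
        r_obs = realized_envelope_correlation(
            sigs["alpha"][0], sigs["alpha"][12], config.fs_hz
        )
        rng = np.random.default_rng(17)
        n = sigs["alpha"].shape[1]
        null = []
        for _ in range(100):
            shifted = np.roll(sigs["alpha"][12], rng.integers(n // 4, 3 * n // 4))
            null.append(
                realized_envelope_correlation(sigs["alpha"][0], shifted, config.fs_hz)
            )
        assert abs(r_obs) <= np.quantile(np.abs(null), 0.99) + 0.05

    def test_missing_node_raises(self, small_forward):
        config = SimulationConfig(
            n_subjects=2, duration_s=10.0, fs_hz=100.0, n_sensors=24,
            grid_shape=(3, 3, 3), bands=("alpha",),
        )
        with pytest.raises(IndexError):
            synthesize_subject(
                config,
                small_forward,
                [CouplingSpec(0, "alpha", 99, "alpha", 0.5)],
                np.random.default_rng(0),
            )

    def test_sensor_snr_scaling(self, small_forward):
        config = SimulationConfig(
            n_subjects=2, duration_s=30.0, fs_hz=100.0, n_sensors=24,
            grid_shape=(3, 3, 3), sensor_snr=5.0, noise_std=2.0,
            bands=("alpha",), rng_seed=8,
        )
        sigs, rec = synthesize_subject(config, small_forward, [], np.random.default_rng(8))
        proj = small_forward.leadfield @ sum(sigs.values())
        scale = config.sensor_snr * config.noise_std / np.sqrt((proj**2).mean())
        noise = rec.data - scale * proj
        ratio = np.sqrt(((scale * proj) ** 2).mean()) / noise.std()
        assert abs(ratio - config.sensor_snr) / config.sensor_snr < 0.05
        assert abs(noise.std() - config.noise_std) / config.noise_std < 0.05


class TestEmptyRoom:
    def test_moments_and_determinism(self):
        config = SimulationConfig(
            n_subjects=2, duration_s=60.0, fs_hz=100.0, n_sensors=20,
            grid_shape=(3, 3, 3), noise_std=1.5,
        )
        room = generate_empty_room(config, np.random.default_rng(4))
        again = generate_empty_room(config, np.random.default_rng(4))
        assert np.array_equal(room.data, again.data)
        assert abs(room.data.mean()) < 0.05
        per_sensor_var = room.data.var(axis=1)
        assert np.abs(per_sensor_var - config.noise_std**2).max() < 0.1 * config.noise_std**2

    def test_covariance_convergence(self):
        config = SimulationConfig(
            n_subjects=2, duration_s=120.0, fs_hz=100.0, n_sensors=20,
            grid_shape=(3, 3, 3),
        )
        room = generate_empty_room(config, np.random.default_rng(6))
        c = room.data @ room.data.T / room.data.shape[1]
        target = np.eye(20)
        err = np.linalg.norm(c - target) / np.linalg.norm(target)
        assert err < 0.1


class TestDataset:
    def test_bit_identical_reproducibility(self, tiny_config):
        a = simulate_dataset(tiny_config)
        b = simulate_dataset(tiny_config)
        for ra, rb in zip(a.recordings, b.recordings):
            assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(a.empty_room.data, b.empty_room.data)
        assert np.array_equal(a.forward.leadfield, b.forward.leadfield)

    def test_planted_correlation_recovered_within_tolerance(self):
        # spec'd generator contract: realized envelope correlation on true
        # source signals within +-0.1 of the planted value for >= 300 s
        for rho in (0.5, 0.9):
            config = SimulationConfig(
                n_subjects=2,
                duration_s=300.0,
                fs_hz=100.0,
                n_sensors=10,
                grid_shape=(2, 2, 2),
                couplings=(CouplingSpec(0, "alpha", 7, "alpha", rho),),
                bands=("alpha",),
                rng_seed=21,
            )
            ds = simulate_dataset(config)
            realized = ds.ground_truth.realized[:, 0]
            assert np.abs(realized.mean() - rho) < 0.1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=1)
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(sensor_snr=0.0)
        with pytest.raises(ValueError):
            CouplingSpec(2, "alpha", 2, "alpha", 0.5)
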