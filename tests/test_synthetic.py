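"""Generator-level checks: Markov-chain statistics, envelope construction,
planted connectome effects and keypress streams, against closed-form or
counting oracles."""

import numpy as np
import pandas as pd
import pytest

import restdyn as rd
from restdyn.synthetic import FTT_SEQUENCE


def _chain_cfg(K, A, pi, T, seed=0, **kw):
    return rd.SimulationConfig(
        n_subjects=1,
        n_sessions=1,
        n_nodes=K,
        n_states=K,
        samples_per_session=T,
        transition_matrix=A,
        initial_probs=pi,
        seed=seed,
        **kw,
    )


class TestStatePaths:
    def test_absorbing_chain_stays_in_state_one(self):
        cfg = _chain_cfg(2, np.eye(2), [1.0, 0.0], 500)
        path = rd.simulate_state_paths(cfg)[("sub001", "RS1")]
        assert np.all(path == 0)

    def test_uniform_two_state_occupancy(self):
        cfg = _chain_cfg(2, np.full((2, 2), 0.5), [0.5, 0.5], 100_000)
        path = rd.simulate_state_paths(cfg)[("sub001", "RS1")]
        fo = np.mean(path == 0)
        assert abs(fo - 0.5) < 0.01

    def test_geometric_dwell_time(self):
        # self-transition 0.9 -> geometric mean lifetime 1/(1-0.9) = 10 samples
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        cfg = _chain_cfg(2, A, [0.5, 0.5], 100_000, fs=40.0)
        path = rd.simulate_state_paths(cfg)[("sub001", "RS1")]
        vals, lens = rd.run_lengths(path == 0)
        mean_len = lens[vals].mean()
        assert abs(mean_len - 10.0) / 10.0 < 0.05
        tp = rd.temporal_params(path, fs=40.0, K=2)
        assert abs(tp.loc[0, "MLT_s"] - 0.25) / 0.25 < 0.05

    def test_invalid_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            _chain_cfg(2, np.array([[0.5, 0.6], [0.5, 0.5]]), [0.5, 0.5], 10)

    def test_reproducible_and_seed_sensitive(self):
        cfg = rd.SimulationConfig(
            n_subjects=2, n_sessions=2, n_nodes=4, n_states=3, samples_per_session=300, seed=5
        )
        a = rd.simulate_state_paths(cfg)
        b = rd.simulate_state_paths(cfg)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        cfg2 = rd.SimulationConfig(
            n_subjects=2, n_sessions=2, n_nodes=4, n_states=3, samples_per_session=300, seed=6
        )
        c = rd.simulate_state_paths(cfg2)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_recordings_use_distinct_streams(self):
        cfg = rd.SimulationConfig(
            n_subjects=2, n_sessions=2, n_nodes=4, n_states=2, samples_per_session=1000, seed=7
        )
        paths = rd.simulate_state_paths(cfg)
        keys = list(paths)
        assert not np.array_equal(paths[keys[0]], paths[keys[1]])


class TestEnvelopes:
    def test_noiseless_limit_reproduces_patterns(self):
        cfg = rd.SimulationConfig(
            n_subjects=1, n_sessions=1, n_nodes=4, n_states=2,
            samples_per_session=200, noise_sd=1e-12, baseline=1.5, seed=3,
        )
        paths = rd.simulate_state_paths(cfg)
        ds = rd.simulate_envelopes(paths, cfg)
        env = ds.data[("sub001", "RS1")]
        path = paths[("sub001", "RS1")]
        expected = 1.5 + cfg.state_patterns[path].T
        np.testing.assert_allclose(env, expected, atol=1e-9)

    def test_identity_mixing_is_a_no_op(self):
        base = dict(n_subjects=1, n_sessions=1, n_nodes=4, n_states=2,
                    samples_per_session=2000, seed=9)
        ds_none, _ = rd.simulate_dataset(rd.SimulationConfig(**base))
        ds_eye, _ = rd.simulate_dataset(rd.SimulationConfig(**base, mixing=np.eye(4)))
        np.testing.assert_allclose(
            ds_none.data[("sub001", "RS1")], ds_eye.data[("sub001", "RS1")]
        )

    def test_shared_slow_component_raises_envelope_correlation(self):
        cfg = rd.SimulationConfig(
            n_subjects=1, n_sessions=1, n_nodes=4, n_states=1,
            samples_per_session=10_000, noise_sd=0.1, seed=4,
            coupling=[((0, 1), 1.0, 1.0)],
        )
        ds, _ = rd.simulate_dataset(cfg)
        env = ds.data[("sub001", "RS1")]
        r = np.corrcoef(env[0], env[1])[0, 1]
        assert r > 0.9
        assert abs(np.corrcoef(env[2], env[3])[0, 1]) < 0.1

    def test_shape_mismatch_rejected(self):
        cfg = rd.SimulationConfig(
            n_subjects=1, n_sessions=1, n_nodes=4, n_states=2, samples_per_session=100, seed=1
        )
        bad = {("sub001", "RS1"): np.array([0, 1, 5])}
        with pytest.raises(ValueError):
            rd.simulate_envelopes(bad, cfg)


class TestPlantedEffects:
    def test_zero_delta_is_identity(self, rng):
        mats = rd.simulate_connectome_set(5, 6, seed=1)
        out = rd.plant_connectome_effect(mats, [(0, 1)], 0.0)
        np.testing.assert_array_equal(out, mats)

    def test_effect_added_and_symmetric(self):
        mats = rd.simulate_connectome_set(4, 6, seed=2)
        out = rd.plant_connectome_effect(mats, [(0, 1), (1, 2)], 0.1)
        diff = out - mats
        assert np.allclose(out, np.swapaxes(out, -1, -2))
        np.testing.assert_allclose(diff[..., 0, 1], 0.1, atol=1e-12)
        np.testing.assert_allclose(diff[..., 3, 4], 0.0, atol=1e-12)

    def test_clipping_at_one(self):
        base = np.full((1, 3, 3), 0.9)
        np.fill_diagonal(base[0], 1.0)
        out = rd.plant_connectome_effect(base, [(0, 1)], 0.3)
        assert out[0, 0, 1] == 1.0

    def test_out_of_range_edge_rejected(self):
        mats = rd.simulate_connectome_set(2, 4, seed=3)
        with pytest.raises(IndexError):
            rd.plant_connectome_effect(mats, [(0, 7)], 0.1)

    def test_group_mask_limits_effect(self):
        mats = rd.simulate_connectome_set(1, 4, seed=4, n_conditions=1)[0]
        mask = np.array([False])
        out = rd.plant_connectome_effect(mats, [(0, 1)], 0.2, group_mask=mask)
        np.testing.assert_array_equal(out, mats)


class TestKeypressStreams:
    def test_noiseless_stream_follows_sequence(self):
        ev = rd.simulate_ftt_blocks(n_blocks=3, mean_rate=4, error_rate=0.0, seed=1)
        for _, grp in ev.groupby("block"):
            keys = grp.sort_values("t_ms")["key"].to_numpy()
            expected = [FTT_SEQUENCE[i % 5] for i in range(keys.size)]
            np.testing.assert_array_equal(keys, expected)

    def test_press_count_matches_poisson_rate(self):
        ev = rd.simulate_ftt_blocks(n_blocks=40, mean_rate=3.0, error_rate=0.0, seed=2)
        counts = ev.groupby("block").size()
        # total over 40 blocks ~ Poisson(3600); 3 SD band
        total = counts.sum()
        assert abs(total - 40 * 90) < 3 * np.sqrt(40 * 90)

    def test_error_fraction_binomial(self):
        ev = rd.simulate_ftt_blocks(n_blocks=40, mean_rate=10.0, error_rate=0.5, seed=3)
        # intended key at press i of a block is seq[i % 5] by construction
        n_err = 0
        for _, grp in ev.groupby("block"):
            keys = grp.sort_values("t_ms")["key"].to_numpy()
            intended = np.array([FTT_SEQUENCE[i % 5] for i in range(keys.size)])
            n_err += int((keys != intended).sum())
        frac = n_err / len(ev)
        assert len(ev) > 10_000
        assert abs(frac - 0.5) < 0.02

    def test_learning_curve_increases_rate(self):
        ev = rd.simulate_ftt_blocks(n_blocks=20, mean_rate=2.0, seed=4, learning_gain=1.0)
        counts = ev.groupby("block").size()
        assert counts.iloc[15:].mean() > counts.iloc[:5].mean()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            rd.simulate_ftt_blocks(mean_rate=0.0)
        with pytest.raises(ValueError):
            rd.simulate_ftt_blocks(error_rate=1.0)


def test_occupancy_consistency_with_state_metrics(small_dataset):
    """Generator truth and state_metrics agree exactly via run-length counts."""
    cfg, paths, _ = small_dataset
    import itertools

    for path in paths.values():
        tp = rd.temporal_params(path, fs=cfg.fs, K=cfg.n_states)
        for k in range(cfg.n_states):
            runs = [
                (v, len(list(g)))
                for v, g in itertools.groupby(path == k)
            ]
            act = [n for v, n in runs if v]
            assert tp.loc[k, "NO"] == len(act)
            assert tp.loc[k, "FO"] == pytest.approx(sum(act) / len(path), abs=0)
            if act:
                assert tp.loc[k, "MLT_s"] == pytest.approx(np.mean(act) / cfg.fs)
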