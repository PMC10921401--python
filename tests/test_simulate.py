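import numpy as np
import pytest

from rhpmap.simulate import (DeadChainSpec, FeedState, SimulationConfig, binarize,
                             conversion_profile, mayo_lewis_binary,
                             positional_frequency, segment_histogram, simulate_batch)

from conftest import make_binary_matrix


def propagated_composition(ensemble, warmup=10):
    """Monomer-1 fraction among units added by terminal-model propagation
    (excludes each chain's first `warmup` feed-seeded/transient units)."""
    n1 = n = 0
    for ch in ensemble.chains:
        tail = ch.sequence[warmup:]
        n1 += int((tail == 0).sum())
        n += len(tail)
    return n1 / n, n


class TestMayoLewis:
    @pytest.mark.parametrize("f1,r12,r21,expected", [
        (0.5, 1.0, 1.0, 0.5),
        (1.0, 2.0, 0.5, 1.0),
        (0.0, 2.0, 0.5, 0.0),
        (0.5, 2.0, 0.5, 0.75 / 1.125),
    ])
    def test_closed_form_values(self, f1, r12, r21, expected):
        assert mayo_lewis_binary(f1, r12, r21) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mayo_lewis_binary(1.2, 1, 1)
        with pytest.raises(ValueError):
            mayo_lewis_binary(0.5, 0, 1)


class TestConservation:
    def test_full_conversion_composition_equals_feed_exactly(self, registry, ratios):
        feed = FeedState(np.array([0.1, 0.2, 0.45, 0.25]))
        cfg = SimulationConfig(n_chains=150, target_conversion=1.0,
                               mean_dp_target=30, seed=5)
        ens = simulate_batch(feed, ratios, cfg, registry=registry)
        assert ens.global_conversion == 1.0
        # exact equality, not statistical: every pool monomer was consumed
        assert np.array_equal(ens.composition(), ens.feed0.fractions)

    def test_integer_mass_balance(self, small_ensemble):
        total_in_chains = sum(len(ch) for ch in small_ensemble.chains)
        assert total_in_chains == int(small_ensemble.consumed.sum())
        assert np.array_equal(small_ensemble.monomer_counts(), small_ensemble.consumed)

    def test_same_seed_bit_identical(self, registry, ratios):
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        cfg = SimulationConfig(n_chains=100, target_conversion=0.5,
                               mean_dp_target=20, seed=42,
                               dead_chain=DeadChainSpec(fraction=0.1))
        e1 = simulate_batch(feed, ratios, cfg, registry=registry)
        e2 = simulate_batch(feed, ratios, cfg, registry=registry)
        assert all(np.array_equal(a.sequence, b.sequence)
                   and a.living == b.living
                   and a.termination_conversion == b.termination_conversion
                   for a, b in zip(e1.chains, e2.chains))

    def test_mean_chain_length_tracks_target(self, registry, ratios):
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        cfg = SimulationConfig(n_chains=500, target_conversion=0.8,
                               mean_dp_target=50, seed=3)
        ens = simulate_batch(feed, ratios, cfg, registry=registry)
        expected = 50 * ens.global_conversion / 0.8
        assert ens.lengths().mean() == pytest.approx(expected, rel=0.02)


class TestTerminalModel:
    def test_binary_low_conversion_matches_mayo_lewis(self, binary_registry):
        mat = make_binary_matrix(binary_registry, 2.0, 0.5)
        feed = FeedState(np.array([0.5, 0.5]))
        cfg = SimulationConfig(n_chains=3000, target_conversion=0.02,
                               mean_dp_target=60, seed=9)
        ens = simulate_batch(feed, mat, cfg, registry=binary_registry)
        F1, n = propagated_composition(ens)
        # drift correction: closed form evaluated at the mid-window feed
        resid = ens.pool0 - ens.consumed
        f1_mid = 0.5 * (ens.feed0.fractions[0] + resid[0] / resid.sum())
        expect = mayo_lewis_binary(f1_mid, 2.0, 0.5)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(F1 - expect) < 3 * se

    def test_early_segments_richer_in_mma(self, registry, ratios):
        # all cross-ratios toward MMA are < 1, so MMA converts fastest and
        # early-added chain segments are MMA-enriched relative to late ones
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        cfg = SimulationConfig(n_chains=1500, target_conversion=0.9,
                               mean_dp_target=50, seed=21)
        ens = simulate_batch(feed, ratios, cfg, registry=registry)
        prof = conversion_profile(ens)
        x = prof["global_conversion"].to_numpy()
        xm = prof["x_M"].to_numpy()
        first_decile = np.searchsorted(x, 0.09)
        # incremental MMA share in the first vs last tenth of conversion
        share_first = xm[first_decile] * ens.pool0[0] / (x[first_decile] * ens.pool0.sum())
        share_last = ((xm[-1] - xm[-1 - first_decile]) * ens.pool0[0]
                      / ((x[-1] - x[-1 - first_decile]) * ens.pool0.sum()))
        assert share_first > share_last


class TestConversionProfile:
    def test_monotone_and_final_row(self, small_ensemble):
        prof = conversion_profile(small_ensemble)
        for col in prof.columns:
            assert (np.diff(prof[col].to_numpy()) >= -1e-12).all()
        np.testing.assert_allclose(
            prof.iloc[-1, 1:].to_numpy(),
            small_ensemble.conversion_per_monomer)
        assert small_ensemble.global_conversion >= 0.7  # loop contract

    def test_preferential_monomer_always_ahead(self, binary_registry):
        mat = make_binary_matrix(binary_registry, 5.0, 0.2)
        feed = FeedState(np.array([0.5, 0.5]))
        cfg = SimulationConfig(n_chains=800, target_conversion=0.9,
                               mean_dp_target=40, seed=13)
        ens = simulate_batch(feed, mat, cfg, registry=binary_registry)
        prof = conversion_profile(ens)
        assert (prof["x_A"].to_numpy() >= prof["x_B"].to_numpy()).all()

    def test_trace_disabled_raises(self, registry, ratios):
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        cfg = SimulationConfig(n_chains=50, target_conversion=0.5,
                               mean_dp_target=10, seed=1)
        ens = simulate_batch(feed, ratios, cfg, registry=registry, trace=False)
        with pytest.raises(ValueError, match="trace"):
            conversion_profile(ens)


class TestDeadChains:
    def test_dead_fraction_near_requested(self, registry, ratios):
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        cfg = SimulationConfig(n_chains=4000, target_conversion=0.7,
                               mean_dp_target=50, seed=7,
                               dead_chain=DeadChainSpec(fraction=0.15))
        ens = simulate_batch(feed, ratios, cfg, registry=registry)
        dead = sum(not ch.living for ch in ens.chains) / len(ens.chains)
        assert dead == pytest.approx(0.15, abs=0.04)

    def test_dead_chains_stop_growing_and_keep_metadata(self, small_ensemble):
        for ch in small_ensemble.chains:
            if not ch.living:
                assert ch.termination_conversion is not None
                assert ch.termination_conversion >= ch.birth_conversion


class TestPositionalFrequency:
    def test_rows_sum_to_one_and_flat_for_ideal(self, binary_registry):
        mat = make_binary_matrix(binary_registry, 1.0, 1.0)
        feed = FeedState(np.array([0.3, 0.7]))
        cfg = SimulationConfig(n_chains=2000, target_conversion=1.0,
                               mean_dp_target=40, seed=2)
        ens = simulate_batch(feed, mat, cfg, registry=binary_registry)
        freq = positional_frequency(ens)
        np.testing.assert_allclose(freq.sum(axis=1), 1.0)
        # exchangeable additions: no positional gradient beyond noise
        assert freq["A"].to_numpy().std() < 0.01

    def test_drift_direction_with_preferential_monomer(self, binary_registry):
        mat = make_binary_matrix(binary_registry, 5.0, 0.2)
        feed = FeedState(np.array([0.5, 0.5]))
        cfg = SimulationConfig(n_chains=2000, target_conversion=0.95,
                               mean_dp_target=40, seed=4)
        ens = simulate_batch(feed, mat, cfg, registry=binary_registry)
        freq = positional_frequency(ens)
        assert freq["A"].iloc[0] > freq["A"].iloc[-1]

    def test_homopolymer_trivial(self, registry, ratios):
        from conftest import hand_built_ensemble
        ens = hand_built_ensemble(registry, [("M" * 40, True)])
        freq = positional_frequency(ens)
        np.testing.assert_allclose(freq["M"], 1.0)


class TestBinarizeAndSegments:
    def test_binarize_default_set(self, registry):
        seq = registry.encode("MOEN")
        np.testing.assert_array_equal(binarize(seq, registry=registry), [1, 0, 1, 0])

    def test_binarize_edge_sets(self, registry):
        seq = registry.encode("MOEN")
        np.testing.assert_array_equal(binarize(seq, hydrophobic_set=[]), [0, 0, 0, 0])
        np.testing.assert_array_equal(binarize(seq, hydrophobic_set=[0, 1, 2, 3]),
                                      [1, 1, 1, 1])

    def test_alternating_and_homopolymer_runs(self, registry):
        alt = registry.encode("MOMOMOMOMO")
        hist1 = segment_histogram([alt], cls=1, registry=registry)
        hist0 = segment_histogram([alt], cls=0, registry=registry)
        assert hist1.to_dict() == {1: 5} and hist0.to_dict() == {1: 5}
        homo = registry.encode("M" * 10)
        assert segment_histogram([homo], cls=1, registry=registry).to_dict() == {10: 1}

    def test_bernoulli_mean_run_length_geometric(self, registry):
        # iid hydrophobic labels with p=0.3: mean run length 1/(1-p)
        rng = np.random.default_rng(8)
        seqs = [np.where(rng.random(200) < 0.3, 0, 2).astype(np.int8)
                for _ in range(400)]
        hist = segment_histogram(seqs, cls=1, registry=registry)
        mean_run = (hist.index.to_numpy() * hist.to_numpy()).sum() / hist.sum()
        assert mean_run == pytest.approx(1 / 0.7, rel=0.02)
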