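import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhpmap.chemistry import chain_molar_mass
from rhpmap.composition import (ConversionRecord, IntegralTable,
                                compare_compositions, composition_from_conversions,
                                conversions_from_integrals, depolymerization_readout,
                                loss_correct, purification_filter, split_living_dead)
from rhpmap.simulate import FeedState

from conftest import hand_built_ensemble


class TestLossCorrect:
    def test_twenty_percent_mma_loss(self):
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        out = loss_correct(feed, [0.2, 0, 0, 0])
        np.testing.assert_allclose(
            out.fractions, [0.2 / 0.95, 0.25 / 0.95, 0.25 / 0.95, 0.25 / 0.95])

    def test_zero_loss_identity(self):
        feed = FeedState(np.array([0.1, 0.2, 0.45, 0.25]))
        np.testing.assert_array_equal(loss_correct(feed, [0, 0, 0, 0]).fractions,
                                      feed.fractions)

    def test_total_loss_rejected(self):
        feed = FeedState(np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            loss_correct(feed, [1.0, 0.0])

    @given(st.lists(st.floats(0, 0.9), min_size=4, max_size=4))
    def test_result_always_normalized(self, losses):
        feed = FeedState(np.array([0.1, 0.2, 0.45, 0.25]))
        out = loss_correct(feed, losses)
        assert out.fractions.sum() == pytest.approx(1.0)


class TestCompositionFromConversions:
    def test_uniform_conversion_returns_feed(self):
        feed = FeedState(np.array([0.1, 0.2, 0.45, 0.25]))
        conv = ConversionRecord(x=np.full(4, 0.6), feed0=feed)
        np.testing.assert_allclose(composition_from_conversions(feed, conv),
                                   feed.fractions)

    def test_worked_example(self):
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        conv = ConversionRecord(x=np.array([0.8, 0.6, 0.6, 0.6]), feed0=feed)
        np.testing.assert_allclose(
            composition_from_conversions(feed, conv),
            [0.8 / 2.6, 0.6 / 2.6, 0.6 / 2.6, 0.6 / 2.6])

    def test_zero_conversion_component(self):
        feed = FeedState(np.array([0.5, 0.5]))
        conv = ConversionRecord(x=np.array([0.0, 0.5]), feed0=feed)
        out = composition_from_conversions(feed, conv)
        assert out[0] == 0.0 and out[1] == 1.0

    def test_all_zero_rejected(self):
        feed = FeedState(np.array([0.5, 0.5]))
        conv = ConversionRecord(x=np.zeros(2), feed0=feed)
        with pytest.raises(ValueError):
            composition_from_conversions(feed, conv)

    def test_matches_simulated_sequence_counts_exactly(self, small_ensemble):
        conv = ConversionRecord.from_ensemble(small_ensemble)
        via_conv = composition_from_conversions(small_ensemble.feed0, conv)
        direct = small_ensemble.composition()
        np.testing.assert_allclose(via_conv, direct, rtol=0, atol=1e-15)


class TestConversionsFromIntegrals:
    def test_no_consumption(self):
        t = IntegralTable(pre=np.array([100.0, 50.0]), post=np.array([100.0, 50.0]),
                          codes=("A", "B"))
        np.testing.assert_array_equal(conversions_from_integrals(t).x, [0.0, 0.0])

    def test_loss_corrected_worked_example(self):
        t = IntegralTable(pre=np.array([100.0]), post=np.array([40.0]),
                          codes=("A",), loss_fractions=np.array([0.2]))
        assert conversions_from_integrals(t).x[0] == pytest.approx(0.5)

    def test_full_conversion(self):
        t = IntegralTable(pre=np.array([100.0]), post=np.array([0.0]), codes=("A",))
        assert conversions_from_integrals(t).x[0] == 1.0

    def test_post_above_pre_rejected(self):
        t = IntegralTable(pre=np.array([100.0]), post=np.array([110.0]), codes=("A",))
        with pytest.raises(ValueError, match="exceeds"):
            conversions_from_integrals(t)


class TestCompareCompositions:
    def test_identical_zero(self):
        out = compare_compositions([0.5, 0.5], [0.5, 0.5])
        assert out["max"] == 0.0

    def test_four_point_difference(self):
        out = compare_compositions([0.50, 0.50], [0.46, 0.54])
        assert out["max"] == pytest.approx(4.0)

    def test_misaligned_codes_rejected(self):
        with pytest.raises(ValueError, match="align"):
            compare_compositions([0.5, 0.5], [0.5, 0.5],
                                 codes_a=("M", "E"), codes_b=("E", "M"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compare_compositions([0.5, 0.5], [1.0])


class TestPurificationFilter:
    def test_noop_filter(self, small_ensemble, registry):
        retained, removed, shift = purification_filter(
            small_ensemble, registry, mwco=0.0, hlb_window=(0.0, 20.0))
        assert len(removed.chains) == 0
        assert shift["max"] == 0.0

    def test_partition_matches_brute_force_enumeration(self, small_ensemble, registry):
        mwco = 3000.0
        retained, removed, _ = purification_filter(small_ensemble, registry, mwco=mwco)
        expected_removed = {
            i for i, ch in enumerate(small_ensemble.chains)
            if len(ch.sequence) == 0 or chain_molar_mass(ch.sequence, registry) < mwco
        }
        assert len(removed.chains) == len(expected_removed)
        # exact partition: counts and monomer balance conserved
        assert len(retained.chains) + len(removed.chains) == len(small_ensemble.chains)
        total = retained.monomer_counts() + removed.monomer_counts()
        np.testing.assert_array_equal(total, small_ensemble.monomer_counts())

    def test_hlb_window_filter(self, registry):
        ens = hand_built_ensemble(registry, [("MMMM", True), ("OOOO", True)])
        retained, removed, _ = purification_filter(
            ens, registry, hlb_window=(10.0, 20.0))
        assert len(retained.chains) == 1 and len(removed.chains) == 1
        assert registry.decode(retained.chains[0].sequence) == "OOOO"

    def test_everything_removed_rejected(self, registry):
        ens = hand_built_ensemble(registry, [("MM", True), ("ME", True)])
        with pytest.raises(ValueError, match="every chain"):
            purification_filter(ens, registry, mwco=1e6)

    def test_no_criterion_rejected(self, small_ensemble, registry):
        with pytest.raises(ValueError, match="criterion"):
            purification_filter(small_ensemble, registry)


class TestLivingDead:
    def test_hand_built_split(self, registry):
        ens = hand_built_ensemble(registry, [("MM", True), ("OO", False)])
        living, dead, diff = split_living_dead(ens)
        np.testing.assert_array_equal(living, [1, 0, 0, 0])
        np.testing.assert_array_equal(dead, [0, 0, 1, 0])
        assert diff["M"] == 100.0 and diff["O"] == -100.0

    def test_all_living_rejected(self, registry):
        ens = hand_built_ensemble(registry, [("MM", True), ("OO", True)])
        with pytest.raises(ValueError, match="dead"):
            split_living_dead(ens)

    def test_subpopulations_recombine_exactly(self, small_ensemble):
        living = small_ensemble.monomer_counts("living")
        dead = small_ensemble.monomer_counts("dead")
        np.testing.assert_array_equal(living + dead, small_ensemble.monomer_counts())
        f_liv, f_dead, _ = split_living_dead(small_ensemble)
        w = living.sum() / (living.sum() + dead.sum())
        np.testing.assert_allclose(w * f_liv + (1 - w) * f_dead,
                                   small_ensemble.composition(), atol=1e-15)

    def test_early_terminated_chains_are_mma_rich(self, registry, ratios):
        # early-biased hazard + cross-propagation favouring MMA: dead chains
        # sample the MMA-rich early conversions
        from rhpmap.simulate import DeadChainSpec, SimulationConfig, simulate_batch
        feed = FeedState(np.array([0.25, 0.25, 0.25, 0.25]))
        cfg = SimulationConfig(n_chains=3000, target_conversion=0.7,
                               mean_dp_target=57, seed=17,
                               dead_chain=DeadChainSpec(fraction=0.1, hazard_decay=5.0))
        ens = simulate_batch(feed, ratios, cfg, registry=registry)
        f_liv, f_dead, _ = split_living_dead(ens)
        assert f_dead[0] > f_liv[0]


class TestDepolymerization:
    def test_all_living_equals_overall(self, registry):
        ens = hand_built_ensemble(registry, [("MEON", True), ("MMOO", True)])
        np.testing.assert_allclose(depolymerization_readout(ens), ens.composition())

    def test_mixed_matches_brute_force_living_count(self, registry):
        ens = hand_built_ensemble(registry, [("MEON", True), ("MMMM", False),
                                             ("OONN", True)])
        out = depolymerization_readout(ens)
        counts = np.zeros(4)
        for s in ("MEON", "OONN"):
            for c in s:
                counts[registry.index(c)] += 1
        np.testing.assert_allclose(out, counts / counts.sum())
        f_liv, _, _ = split_living_dead(ens)
        np.testing.assert_array_equal(out, f_liv)

    def test_no_living_chains_rejected(self, registry):
        ens = hand_built_ensemble(registry, [("MM", False)])
        with pytest.raises(ValueError, match="living"):
            depolymerization_readout(ens)
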