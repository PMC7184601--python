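"""Unit tests for the delayed stochastic simulation engine."""

import numpy as np
import pytest
from scipy import stats

from silentsnp.ssa import (
    DelayedProduct,
    DelayedSSA,
    NetworkConfigError,
    Reaction,
    ReactionNetwork,
    Species,
    compute_propensities,
    simulate,
)


def _net(species, reactions):
    return ReactionNetwork(species, reactions)


class TestPropensities:
    @pytest.mark.parametrize(
        "counts, reactants, rate, expected",
        [
            ({"A": 0, "B": 5}, ("A", "B"), 1.0, 0.0),  # empty reactant pool
            ({"Rib": 100, "mRNA1": 50}, ("Rib", "mRNA1"), 0.01, 50.0),
            ({"C": 7}, ("C",), 1.0, 7.0),  # unimolecular
        ],
    )
    def test_mass_action(self, counts, reactants, rate, expected):
        r = Reaction(reactants, (), rate)
        assert compute_propensities(counts, [r]) == pytest.approx([expected])

    def test_unknown_species_is_config_error(self):
        r = Reaction(("ghost",), (), 1.0)
        with pytest.raises(NetworkConfigError):
            compute_propensities({"A": 1}, [r])


class TestNetworkValidation:
    def test_rejects_three_reactants(self):
        with pytest.raises(NetworkConfigError):
            Reaction(("A", "B", "C"), (), 1.0)

    def test_rejects_homodimer(self):
        with pytest.raises(NetworkConfigError):
            Reaction(("A", "A"), (), 1.0)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(NetworkConfigError):
            Reaction(("A",), (), 0.0)

    def test_rejects_negative_delay(self):
        with pytest.raises(NetworkConfigError):
            DelayedProduct("A", -1.0)

    def test_rejects_duplicate_species(self):
        with pytest.raises(NetworkConfigError):
            _net([Species("A", 1), Species("A", 2)], [])

    def test_rejects_unknown_reactant(self):
        with pytest.raises(NetworkConfigError):
            _net([Species("A", 1)], [Reaction(("B",), (), 1.0)])

    def test_from_dict_roundtrip(self):
        net = ReactionNetwork.from_dict(
            {
                "species": [{"name": "A", "initial_count": 3}, {"name": "B"}],
                "reactions": [
                    {
                        "reactants": ["A"],
                        "products": [{"species": "B", "delay": 2.0}],
                        "rate": 0.5,
                    }
                ],
            }
        )
        assert net.species_names == ("A", "B")
        assert net.reactions[0].products[0].delay == 2.0


class TestStep:
    def test_release_is_only_event_when_propensity_zero(self):
        # dead propensity, one scheduled release at t=12: clock jumps there
        net = _net([Species("A", 0)], [Reaction(("A",), (), 1.0)])
        engine = DelayedSSA(net, seed=0)
        engine.schedule(net.index["A"], 12.0)
        ev = engine.step()
        assert ev.kind == "release" and ev.time == 12.0
        assert engine.time == 12.0 and engine.counts[net.index["A"]] == 1

    def test_dead_system_terminates_not_raises(self):
        net = _net([Species("A", 0)], [Reaction(("A",), (), 1.0)])
        assert DelayedSSA(net, seed=0).step() is None

    def test_codon_step_sequesters_complex_and_trna(self):
        # analogue of the codon-decoding reaction: both products are delayed,
        # so complex and tRNA vanish immediately and reappear only after tau
        tau = 7.0
        net = _net(
            [Species("C1", 1), Species("tRNA", 1), Species("C2", 0)],
            [
                Reaction(
                    ("C1", "tRNA"),
                    (DelayedProduct("C2", tau), DelayedProduct("tRNA", tau)),
                    5.0,
                )
            ],
        )
        engine = DelayedSSA(net, seed=3)
        ev = engine.step()
        assert ev.kind == "reaction"
        i = net.index
        assert engine.counts[i["C1"]] == 0 and engine.counts[i["tRNA"]] == 0
        assert engine.counts[i["C2"]] == 0
        assert engine.pending[i["C2"]] == 1 and engine.pending[i["tRNA"]] == 1
        # both releases happen exactly tau after the firing
        for _ in range(2):
            rel = engine.step()
            assert rel.kind == "release"
            assert rel.time == pytest.approx(ev.time + tau)
        assert engine.counts[i["C2"]] == 1 and engine.counts[i["tRNA"]] == 1

    def test_equal_release_times_drain_fifo(self):
        net = _net([Species("A", 0), Species("B", 0)], [Reaction(("A",), (), 1.0)])
        engine = DelayedSSA(net, seed=0)
        engine.schedule(net.index["B"], 5.0)
        engine.schedule(net.index["A"], 5.0)
        assert engine.step().species == "B"
        assert engine.step().species == "A"


class TestSimulate:
    def test_step_and_simulate_share_the_draw_sequence(self, toys):
        net = toys["cascade"].network
        t_end, dt = 200.0, 5.0
        traj = simulate(net, t_end=t_end, sample_interval=dt, seed=99)

        engine = DelayedSSA(net, seed=99)
        grid = traj.times
        counts = np.empty_like(traj.counts)
        k = 0
        while True:
            before = list(engine.counts)
            ev = engine.step()
            t_ev = ev.time if ev is not None else np.inf
            while k < len(grid) and grid[k] < min(t_ev, t_end + 1):
                counts[k] = before
                k += 1
            if ev is None or ev.time > t_end:
                break
        while k < len(grid):
            counts[k] = engine.counts
            k += 1
        np.testing.assert_array_equal(traj.counts, counts)

    def test_same_seed_bitwise_identical(self, toys):
        net = toys["birth_death"].network
        a = simulate(net, t_end=100, seed=7)
        b = simulate(net, t_end=100, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = simulate(net, t_end=100, seed=8)
        assert (a.counts != c.counts).any()

    def test_t_end_before_first_event_keeps_initial_counts(self):
        net = _net([Species("A", 1)], [Reaction(("A",), (), 1e-9)])
        traj = simulate(net, t_end=10, sample_interval=1, seed=0)
        assert (traj.series("A") == 1).all()

    def test_dead_after_single_delayed_conversion(self, toys):
        # A -> B(tau): one firing, one release, then the system is dead;
        # the trajectory still extends to t_end
        traj = simulate(toys["delayed_conversion"].network, t_end=1000,
                        sample_interval=1.0, seed=4)
        assert traj.series("A")[-1] == 0 and traj.series("B")[-1] == 1
        assert traj.times[-1] == 1000.0
        # B appears exactly `delay` seconds after A disappears
        t_fire = traj.times[np.argmax(traj.series("A") == 0)]
        t_appear = traj.times[np.argmax(traj.series("B") == 1)]
        assert t_appear - t_fire == pytest.approx(5.0, abs=2.0)

    def test_interevent_times_are_exponential(self):
        # pure-death A -> 0: each waiting time scaled by the current total
        # propensity is a standard exponential draw
        k = 0.5
        net = _net([Species("A", 12000)], [Reaction(("A",), (), k)])
        engine = DelayedSSA(net, seed=2024)
        scaled = []
        t_prev = 0.0
        for _ in range(10_000):
            a0 = k * engine.counts[0]
            ev = engine.step()
            scaled.append((ev.time - t_prev) * a0)
            t_prev = ev.time
        ks = stats.kstest(scaled, "expon")
        assert ks.pvalue > 0.01

    def test_invalid_arguments(self, toys):
        net = toys["birth_death"].network
        with pytest.raises(ValueError):
            simulate(net, t_end=0, seed=0)
        with pytest.raises(ValueError):
            simulate(net, t_end=10, sample_interval=0, seed=0)
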