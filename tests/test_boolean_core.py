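import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchscape import (
    BooleanNetwork,
    NetworkState,
    find_attractors,
    network_from_dict,
    network_to_dict,
    load_network,
    save_network,
    synchronous_update,
    trajectory_to_attractor,
)
from switchscape.errors import CapacityError, DimensionError, NetworkValidationError

from conftest import random_network


def S(bits):
    return NetworkState.from_bits(bits)


class TestStateCodec:
    def test_node0_is_least_significant_bit(self):
        assert NetworkState.from_bits((1, 0)).int_code == 1
        assert NetworkState.from_bits((0, 1)).int_code == 2

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=50)
    def test_bits_int_bijection(self, bits):
        s = NetworkState.from_bits(bits)
        assert NetworkState.from_int(s.int_code, s.n).bits == s.bits

    def test_out_of_range_code_rejected(self):
        with pytest.raises(DimensionError):
            NetworkState.from_int(4, 2)


class TestSynchronousUpdate:
    def test_toggle_fixed_point(self, toggle):
        assert synchronous_update(toggle, S((0, 1))).bits == (0, 1)
        assert synchronous_update(toggle, S((1, 0))).bits == (1, 0)

    def test_toggle_two_cycle(self, toggle):
        assert synchronous_update(toggle, S((0, 0))).bits == (1, 1)
        assert synchronous_update(toggle, S((1, 1))).bits == (0, 0)

    def test_identity_net(self, identity_net):
        assert synchronous_update(identity_net, S((0,))).bits == (0,)
        assert synchronous_update(identity_net, S((1,))).bits == (1,)

    def test_dimension_mismatch(self, toggle):
        with pytest.raises(DimensionError):
            synchronous_update(toggle, S((0, 1, 1)))

    def test_update_is_deterministic(self, toggle):
        results = {synchronous_update(toggle, S((0, 0))).int_code for _ in range(5)}
        assert results == {3}


class TestTrajectory:
    def test_start_on_fixed_point(self, toggle):
        cycle, transient = trajectory_to_attractor(toggle, S((0, 1)))
        assert set(cycle) == {2} and transient == 0

    def test_start_on_cycle(self, toggle):
        cycle, transient = trajectory_to_attractor(toggle, S((0, 0)))
        assert set(cycle) == {0, 3} and transient == 0

    def test_identity(self, identity_net):
        cycle, transient = trajectory_to_attractor(identity_net, S((1,)))
        assert cycle == (1,) and transient == 0

    def test_transient_counted(self):
        # g0' = 1 (constant), g1' = g0: state 00 -> 10 -> 11 (fixed)
        net = BooleanNetwork(("g0", "g1"), ((0,), (0,)), ((1, 1), (0, 1)))
        cycle, transient = trajectory_to_attractor(net, S((0, 0)))
        assert set(cycle) == {3} and transient == 2


class TestFindAttractors:
    def test_toggle_attractor_structure(self, toggle):
        atts = find_attractors(toggle)
        summary = {a.states: (a.kind, a.basin_size) for a in atts.attractors}
        assert summary == {
            (0, 3): ("cyclic", 2),
            (1,): ("point", 1),
            (2,): ("point", 1),
        }

    def test_identity_two_point_attractors(self, identity_net):
        atts = find_attractors(identity_net)
        assert [a.kind for a in atts.attractors] == ["point", "point"]
        assert [a.basin_size for a in atts.attractors] == [1, 1]

    def test_canonical_ordering_by_min_member(self, toggle):
        atts = find_attractors(toggle)
        assert [a.min_state for a in atts.attractors] == [0, 1, 2]

    def test_capacity_error_above_cap(self, toggle):
        with pytest.raises(CapacityError, match="max_n"):
            find_attractors(toggle, max_n=1)

    @pytest.mark.parametrize("seed", range(8))
    def test_basins_partition_state_space(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n=int(rng.integers(3, 8)))
        atts = find_attractors(net)
        assert sum(a.basin_size for a in atts.attractors) == 1 << net.n
        assert len(atts.basin_map) == 1 << net.n
        all_states = [s for a in atts.attractors for s in a.states]
        assert len(all_states) == len(set(all_states))  # disjoint cycles

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_per_state_trajectories(self, seed):
        """The pointer-doubling enumeration matches naive iteration from
        every start state (independent oracle)."""
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, n=5)
        atts = find_attractors(net)
        for code in range(1 << net.n):
            cycle, _ = trajectory_to_attractor(net, NetworkState.from_int(code, net.n))
            idx = atts.attractor_of(code)
            assert set(atts.attractors[idx].states) == set(cycle)

    @pytest.mark.parametrize("seed", range(4))
    def test_cycle_states_map_to_successor(self, seed):
        net = random_network(np.random.default_rng(200 + seed), n=6)
        atts = find_attractors(net)
        for a in atts.attractors:
            for k, s in enumerate(a.states):
                assert net.step_int(s) == a.states[(k + 1) % len(a.states)]


class TestValidation:
    def test_truth_table_length_checked(self):
        with pytest.raises(NetworkValidationError):
            BooleanNetwork(("a",), ((0,),), ((0, 1, 1),))

    def test_input_index_range_checked(self):
        with pytest.raises(NetworkValidationError):
            BooleanNetwork(("a",), ((1,),), ((0, 1),))

    def test_non_binary_entries_rejected(self):
        with pytest.raises(NetworkValidationError):
            BooleanNetwork(("a",), ((0,),), ((0, 2),))


class TestJsonDialect:
    def test_dict_keys_and_values(self, toggle):
        d = network_to_dict(toggle)
        assert d == {
            "nodes": ["a", "b"],
            "inputs": [[1], [0]],
            "truth_tables": [[1, 0], [1, 0]],
        }

    @pytest.mark.parametrize("seed", range(4))
    def test_file_round_trip_bit_exact(self, seed, tmp_path):
        net = random_network(np.random.default_rng(300 + seed), n=6)
        path = tmp_path / "net.json"
        save_network(net, path)
        assert load_network(path) == net

    def test_missing_key_rejected(self):
        with pytest.raises(NetworkValidationError):
            network_from_dict({"nodes": ["a"]})
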