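"""Binding-funnel networks: CAPRI classes, landscape probabilities, paths."""

import io
import math

import networkx as nx
import pandas as pd
import pytest

import mfptnet as M
from mfptnet import generators as G
from mfptnet.funnel import (
    FunnelState,
    assign_transition_probabilities,
    capri_classify,
    load_mfpt_matrix,
    load_states,
    mfpt_weighted_graph,
    shortest_path,
)


def _state(id, energy=0.0, lrmsd=2.0, irmsd=1.5, fnat=0.4, fnonnat=0.3):
    return FunnelState(id, energy, lrmsd, irmsd, fnat, fnonnat)


class TestCapriClassification:
    @pytest.mark.parametrize(
        "fnat,lrmsd,irmsd,expected",
        [
            (0.8, 0.5, 3.0, "high"),        # fnat >= 0.5, LRMSD <= 1
            (0.8, 4.0, 0.9, "high"),        # fnat >= 0.5, IRMSD <= 1
            (0.8, 4.0, 3.0, "medium"),      # fnat >= 0.5 but both RMSDs large
            (0.4, 4.0, 3.0, "medium"),      # 0.3 <= fnat < 0.5, LRMSD <= 5
            (0.4, 8.0, 1.5, "medium"),      # 0.3 <= fnat < 0.5, IRMSD <= 2
            (0.4, 8.0, 3.0, "acceptable"),  # fnat >= 0.3 but both RMSDs large
            (0.2, 8.0, 3.5, "acceptable"),  # 0.1 <= fnat < 0.3, LRMSD <= 10
            (0.2, 12.0, 3.5, "acceptable"),  # 0.1 <= fnat < 0.3, IRMSD <= 4
            (0.05, 2.0, 1.0, "incorrect"),  # fnat < 0.1
            (0.2, 12.0, 5.0, "incorrect"),  # both RMSDs too large
        ],
    )
    def test_clause_boundaries(self, fnat, lrmsd, irmsd, expected):
        assert capri_classify(fnat, lrmsd, irmsd) == expected

    def test_labels(self):
        assert _state(21, fnat=0.4, lrmsd=4.0, irmsd=3.0).label == "M21"
        assert _state(3, fnat=0.8, lrmsd=0.5).label == "H3"
        assert _state(7, fnat=0.05).label == "I7"
        assert _state(9, fnat=0.35, lrmsd=8.0, irmsd=3.0).label == "A9"

    def test_invalid_metadata_rejected(self):
        with pytest.raises(M.ValidationError):
            _state(0, fnat=1.5)
        with pytest.raises(M.ValidationError):
            _state(0, lrmsd=-1.0)


class TestLoadStates:
    def test_plain_table(self):
        text = "0 -5.0 1.2 0.8 0.6 0.2\n1 -3.5 7.0 3.0 0.2 0.5\n"
        states = load_states(io.StringIO(text))
        assert [s.id for s in states] == [0, 1]
        assert states[0].capri_class == "high"
        assert states[1].energy == -3.5

    def test_header_and_comments_skipped(self):
        text = "# docking states\nid energy lrmsd irmsd fnat fnonnat\n" \
               "0 -5.0 1.2 0.8 0.6 0.2\n"
        states = load_states(io.StringIO(text))
        assert len(states) == 1 and states[0].id == 0


class TestTransitionProbabilities:
    def test_downhill_favoured_boltzmann_uphill(self):
        states = [_state(0, energy=0.0), _state(1, energy=-2.0),
                  _state(2, energy=1.0)]
        net = assign_transition_probabilities(states, [(0, 1), (0, 2)])
        u = {e.target: float(e.u) for e in net.edges[0]}
        # downhill to 1 has raw weight 1, uphill to 2 weight exp(-1)
        z = 1.0 + math.exp(-1.0)
        assert u[1] == pytest.approx(1.0 / z)
        assert u[2] == pytest.approx(math.exp(-1.0) / z)
        # each row is a probability distribution with unit local times
        for out in net.edges:
            if out:
                assert math.fsum(float(e.u) for e in out) == pytest.approx(1.0)
                assert all(e.tau == 1 for e in out)

    def test_transitions_into_high_lrmsd_blocked(self):
        states = [_state(0), _state(1, lrmsd=9.0), _state(2)]
        net = assign_transition_probabilities(states, [(0, 1), (0, 2), (1, 2)])
        assert [e.target for e in net.edges[0]] == [2]
        # the far state keeps its outgoing transitions in the default rule
        assert {e.target for e in net.edges[1]} == {0, 2}

    def test_block_outgoing_variant(self):
        states = [_state(0), _state(1, lrmsd=9.0), _state(2)]
        net = assign_transition_probabilities(
            states, [(0, 1), (0, 2), (1, 2)], block_outgoing=True
        )
        assert {e.target for e in net.edges[0]} == {1, 2}
        assert net.edges[1] == []  # far state becomes a dead end

    def test_pruning_removes_tiny_edges_and_renormalizes(self):
        states = [_state(0, energy=0.0), _state(1, energy=-1.0),
                  _state(2, energy=20.0)]
        net = assign_transition_probabilities(states, [(0, 1), (0, 2)])
        # exp(-20) / Z is far below the 1e-6 pruning threshold
        assert [e.target for e in net.edges[0]] == [1]
        assert float(net.edges[0][0].u) == pytest.approx(1.0)

    def test_gapped_ids_rejected(self):
        with pytest.raises(M.ValidationError):
            assign_transition_probabilities([_state(0), _state(2)], [(0, 2)])

    def test_funnel_mfpts_agree_between_solvers(self):
        # small rugged landscape: MFPT into the native basin must agree
        # between the combinatorial solver and the linear oracle
        rng_energy = [0.0, -1.0, 0.5, -3.0, -0.5, -4.0]
        states = [_state(i, energy=e) for i, e in enumerate(rng_energy)]
        adjacency = [(0, 1), (1, 2), (1, 3), (2, 4), (3, 5), (4, 5)]
        net = assign_transition_probabilities(states, adjacency)
        q = M.MfptQuery(0, {5})
        assert M.mfpt_hill(net, q) == pytest.approx(M.mfpt_linear(net, q),
                                                    rel=1e-9)


class TestMfptWeightedGraph:
    def test_dataframe_with_missing_entries(self):
        df = pd.DataFrame(
            [[0.0, 2.5, math.nan], [1.0, 0.0, math.inf], [4.0, 1.5, 0.0]],
            index=range(3), columns=range(3),
        )
        g = mfpt_weighted_graph(df)
        assert set(g.nodes) == {0, 1, 2}
        assert g[0][1]["weight"] == 2.5
        assert not g.has_edge(0, 2) and not g.has_edge(1, 2)
        assert not g.has_edge(0, 0)  # diagonal ignored

    def test_negative_weight_rejected(self):
        with pytest.raises(M.ValidationError):
            mfpt_weighted_graph({(0, 1): -1.0})

    def test_load_matrix_with_missing_tokens(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("# times\n0 2.5 -\n1.0 0 NA\n4.0 1.5 0\n")
        g = load_mfpt_matrix(p)
        assert g[2][0]["weight"] == 4.0
        assert not g.has_edge(0, 2)

    def test_non_square_matrix_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 1\n2 0 3\n")
        with pytest.raises(M.ValidationError):
            load_mfpt_matrix(p)


class TestShortestPath:
    def test_two_hop_beats_direct(self):
        g = mfpt_weighted_graph({(0, 1): 10.0, (0, 2): 2.0, (2, 1): 3.0})
        path, total = shortest_path(g, 0, 1)
        assert path == [0, 2, 1]
        assert total == pytest.approx(5.0)

    def test_lexicographic_tie_break(self):
        # two equal-cost routes 0-1-3 and 0-2-3: the smaller middle node wins
        g = mfpt_weighted_graph(
            {(0, 1): 1.0, (1, 3): 1.0, (0, 2): 1.0, (2, 3): 1.0}
        )
        path, total = shortest_path(g, 0, 3)
        assert path == [0, 1, 3]
        assert total == pytest.approx(2.0)

    def test_unreachable_target(self):
        g = mfpt_weighted_graph({(0, 1): 1.0, (2, 1): 1.0})
        path, total = shortest_path(g, 0, 2)
        assert path is None and total is M.NOT_ACCESSIBLE

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        import itertools
        import numpy as np

        rng = np.random.default_rng(seed)
        n = 6
        weights = {}
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.5:
                    weights[(i, j)] = float(rng.uniform(0.5, 10.0))
        g = mfpt_weighted_graph(weights)
        path, total = shortest_path(g, 0, n - 1)
        # brute force over all simple paths
        best = math.inf
        for r in range(n):
            for mids in itertools.permutations(range(1, n - 1), r):
                seq = (0, *mids, n - 1)
                try:
                    cost = sum(weights[(a, b)] for a, b in zip(seq, seq[1:]))
                except KeyError:
                    continue
                best = min(best, cost)
        if best == math.inf:
            assert path is None
        else:
            assert total == pytest.approx(best, rel=1e-12)

    def test_funnel_pipeline_end_to_end(self):
        # states -> landscape network -> pairwise MFPTs -> favourable path
        energies = [0.0, -1.5, -0.5, -3.0, -2.0]
        states = [_state(i, energy=e) for i, e in enumerate(energies)]
        adjacency = [(0, 1), (1, 2), (2, 3), (1, 4), (4, 3)]
        net = assign_transition_probabilities(states, adjacency)
        mat = {}
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                t = M.mfpt_linear(net, M.MfptQuery(i, {j}))
                if t is not M.NOT_ACCESSIBLE and t != math.inf:
                    mat[(i, j)] = t
        g = mfpt_weighted_graph(mat)
        path, total = shortest_path(g, 0, 3)
        assert path is not None and path[0] == 0 and path[-1] == 3
        assert total <= mat[(0, 3)] + 1e-12  # never worse than the direct hop
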