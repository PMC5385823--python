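"""Signed network construction, propagation and p53 response-element scanning."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_scan
from tp53mir import network_model as nm
from tp53mir.errors import ConflictError, FormatError, LookupError_, ParameterError

MIRNA_DIRECTIONS = {
    "miR-107": "down",
    "miR-215": "down",
    "miR-34b/c": "down",
    "miR-125b": "down",  # via the AKT1 feedback override
    "miR-155": "up",
}


@pytest.fixture(scope="module")
def net():
    return nm.bundled_network("tp53_normal")


class TestLoadAndCount:
    def test_curated_network_has_three_activation_two_repression_tp53_edges(self, net):
        assert nm.count_edges_by_sign(net, "TP53") == (3, 2)

    def test_empty_file_gives_empty_network(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("source\tsource_kind\ttarget\ttarget_kind\tsign\n")
        assert len(nm.load_edges(path)) == 0

    def test_unknown_sign_token_is_format_error_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "source\tsource_kind\ttarget\ttarget_kind\tsign\n"
            "TP53\tTF\tmiR-1\tmiRNA\t±\n"
        )
        with pytest.raises(FormatError, match=":2"):
            nm.load_edges(path)

    def test_duplicate_edge_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "source\tsource_kind\ttarget\ttarget_kind\tsign\n"
            "TP53\tTF\tmiR-1\tmiRNA\tactivation\n"
            "TP53\tTF\tmiR-1\tmiRNA\trepression\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            nm.load_edges(path)

    def test_leaf_node_has_no_out_edges(self, net):
        assert nm.count_edges_by_sign(net, "BAK1") == (0, 0)

    def test_adding_repression_edge_increments_count(self, net):
        import copy

        net2 = copy.deepcopy(net)
        net2.add_node("miR-999", "miRNA")
        net2.add_edge("TP53", "miR-999", -1)
        assert nm.count_edges_by_sign(net2, "TP53") == (3, 3)

    def test_unknown_source_raises(self, net):
        with pytest.raises(LookupError_):
            nm.count_edges_by_sign(net, "NOSUCH")

    def test_self_loop_rejected(self):
        net = nm.SignedNetwork()
        net.add_node("A", "gene")
        with pytest.raises(ParameterError, match="self-loop"):
            net.add_edge("A", "A", 1)


class TestPropagation:
    def test_tp53_loss_reproduces_reported_mirna_and_target_directions(self, net):
        state = nm.propagate(
            net, {"TP53": "down"}, [("miR-125b", "down", "AKT1 feedback")]
        )
        for mir, direction in MIRNA_DIRECTIONS.items():
            assert state[mir] == direction, mir
        # miR-155 up silences AGTR1 and MEIS1; miR-125b loss boosts BAK1
        assert state["AGTR1"] == "down"
        assert state["MEIS1"] == "down"
        assert state["BAK1"] == "up"
        assert state.override_reasons["miR-125b"] == "AKT1 feedback"

    def test_unchanged_clamp_propagates_unchanged(self, net):
        state = nm.propagate(net, {"TP53": "unchanged"})
        assert all(
            state[n] in ("unchanged", "unknown") for n in net.nodes
        )
        assert state["BAK1"] == "unchanged"

    def test_involution_flipping_clamp_flips_all_propagated_states(self, net):
        down = nm.propagate(net, {"TP53": "down"}, [("miR-125b", "down", "x")])
        up = nm.propagate(net, {"TP53": "up"}, [("miR-125b", "up", "x")])
        flip = {"up": "down", "down": "up"}
        for node in net.nodes:
            if down[node] in flip:
                assert up[node] == flip[down[node]], node

    def test_unreachable_nodes_are_unknown(self, net):
        state = nm.propagate(net, {"miR-155": "up"})
        assert state["miR-107"] == "unknown"
        assert state["TP53"] == "unknown"
        assert state["AGTR1"] == "down"

    def test_feedback_network_without_override_conflicts_on_mir125b(self):
        # TP53-down implies miR-125b up directly but down via PHLDA3/AKT1
        net = nm.bundled_network("tp53_feedback")
        with pytest.raises(ConflictError, match="miR-125b"):
            nm.propagate(net, {"TP53": "down"})

    def test_feedback_network_with_override_resolves(self):
        net = nm.bundled_network("tp53_feedback")
        state = nm.propagate(
            net, {"TP53": "down"}, [("miR-125b", "down", "AKT1 feedback")]
        )
        assert state["AKT1"] == "up"
        assert state["BAK1"] == "up"

    def test_cycle_without_clamp_on_loop_raises(self):
        net = nm.SignedNetwork()
        for n in ("A", "B", "C"):
            net.add_node(n, "gene")
        net.add_edge("A", "B", 1)
        net.add_edge("B", "C", 1)
        net.add_edge("C", "A", 1)
        with pytest.raises(ParameterError, match="cyclic"):
            nm.propagate(net, {}, [])
        # clamping a node on the loop breaks it
        state = nm.propagate(net, {"A": "up"})
        assert state["C"] == "up"

    def test_unknown_clamp_node_raises(self, net):
        with pytest.raises(LookupError_):
            nm.propagate(net, {"NOSUCH": "down"})


class TestScanner:
    def test_two_adjacent_decamers_spacer_zero(self):
        hits = nm.scan_p53_re("AAACATGTTTAAACATGTTT")
        assert len(hits) == 1
        assert (hits[0].first_start, hits[0].second_start, hits[0].spacer) == (0, 10, 0)

    @pytest.mark.parametrize("spacer,expected", [(0, 1), (13, 1), (14, 0)])
    def test_spacer_boundary(self, spacer, expected):
        seq = "AAACATGTTT" + "C" * spacer + "AAACATGTTT"
        assert len(nm.scan_p53_re(seq)) == expected

    def test_pure_pyrimidine_background_has_no_hits(self):
        assert nm.scan_p53_re("T" * 200) == []

    def test_n_never_matches(self):
        assert nm.scan_p53_re("AAACATGTTTNAACATGTTTAAACATGTTT".replace("N", "N")) == \
            nm.scan_p53_re("AAACATGTTTNAACATGTTTAAACATGTTT")
        # N inside the second decamer kills the adjacent pair
        hits = nm.scan_p53_re("AAACATGTTTAANCATGTTT")
        assert hits == []

    def test_non_nucleotide_raises_with_offset(self):
        with pytest.raises(FormatError, match="offset 3"):
            nm.scan_p53_re("AAAXATGTTT")

    def test_matches_brute_force_oracle_on_random_long_sequences(self):
        rng = np.random.default_rng(123)
        for _ in range(3):
            seq = "".join(rng.choice(list("ACGT"), size=10_000))
            got = [(h.first_start, h.second_start, h.spacer) for h in nm.scan_p53_re(seq)]
            assert got == brute_force_scan(seq)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_matches_brute_force_oracle_exhaustively_small(self, seq):
        got = [(h.first_start, h.second_start, h.spacer) for h in nm.scan_p53_re(seq)]
        assert got == brute_force_scan(seq)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=20, max_size=60))
    def test_hit_arithmetic_invariants(self, seq):
        for h in nm.scan_p53_re(seq, both_strands=True):
            assert h.second_start - h.first_start - 10 == h.spacer
            assert 0 <= h.spacer <= 13
            first, second = h.matched.split("+")
            assert brute_force_scan(first + second, max_spacer=0) == [(0, 10, 0)]

    def test_reverse_strand_hits_reported_in_forward_coordinates(self):
        seq = "AAACATGTTTAAACATGTTT"
        rc = "AAACATGTTT"  # motif is not its own reverse complement
        from tp53mir.network_model import _COMPLEMENT

        rev = seq.translate(_COMPLEMENT)[::-1]
        hits = nm.scan_p53_re(rev, both_strands=True)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert (minus[0].first_start, minus[0].second_start) == (0, 10)

    def test_overlapping_pairs_all_reported(self):
        seq = "AAACATGTTT" * 3  # decamers at 0, 10, 20: pairs (0,10), (10,20), (0,20)
        got = {(h.first_start, h.second_start) for h in nm.scan_p53_re(seq)}
        assert got == {(0, 10), (10, 20), (0, 20)}


class TestHitOutput:
    def test_bed_spans_full_tandem_element(self):
        hits = nm.scan_p53_re("AAACATGTTT" + "CC" + "AAACATGTTT", seq_id="chrP")
        bed = nm.hits_to_bed(hits)
        assert bed.loc[0, ["chrom", "start", "end", "name"]].tolist() == ["chrP", 0, 22, "2"]
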