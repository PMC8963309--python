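"""Transitive breakpoint detection: traversal geometry and chain recovery."""

import pytest

from svbreaks import (
    TransitiveParams,
    find_transitive_calls,
    find_transitive_calls_bruteforce,
    make_breakpoint_set,
    plant_transitive,
    simulate_truth,
    traverse_step,
)

from conftest import bnd, make_pair


def chain_fixture(insert_len=100):
    """A=(chr1:1000,+)<->(chr2:5000,-), B=(chr2:5100,+)<->(chr3:2000,-),
    candidate T joining chr1:1000 to chr3:2000 with `insert_len` inserted bases."""
    bes = (make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-")
           + make_pair("B", "chr2", 5100, "+", "chr3", 2000, "-")
           + make_pair("T", "chr1", 1000, "+", "chr3", 2000, "-",
                       insert="G" * insert_len))
    return make_breakpoint_set(bes, contig_order=["chr1", "chr2", "chr3"])


class TestTraverseStep:
    def setup_method(self):
        self.bset = chain_fixture()

    def test_forward_facing_junction_found(self):
        # landed on (chr2:5000,'-'): walk rightward, B presents (chr2:5100,'+')
        nxt = traverse_step(self.bset, self.bset.get("A_2"), 1000)
        assert [(be.id, d) for be, d in nxt] == [("B_1", 100)]

    def test_junction_behind_traversal_ignored(self):
        bes = (make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-")
               + make_pair("B", "chr2", 4900, "+", "chr3", 2000, "-"))
        bset = make_breakpoint_set(bes)
        assert traverse_step(bset, bset.get("A_2"), 1000) == []

    def test_wrong_facing_orientation_ignored(self):
        bes = (make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-")
               + make_pair("B", "chr2", 5100, "-", "chr3", 2000, "-"))
        bset = make_breakpoint_set(bes)
        assert traverse_step(bset, bset.get("A_2"), 1000) == []

    def test_distance_bound_enforced(self):
        assert traverse_step(self.bset, self.bset.get("A_2"), 99) == []

    def test_leftward_walk_from_plus_breakend(self):
        bes = (make_pair("A", "chr1", 1000, "-", "chr2", 5000, "+")
               + make_pair("B", "chr2", 4950, "-", "chr3", 2000, "-"))
        bset = make_breakpoint_set(bes)
        nxt = traverse_step(bset, bset.get("A_2"), 1000)
        assert [(be.id, d) for be, d in nxt] == [("B_1", 50)]


class TestFindTransitive:
    def test_candidate_explained_when_insert_length_agrees(self):
        bset = chain_fixture(insert_len=100)
        chains = find_transitive_calls(bset)
        assert len(chains) == 1
        c = chains[0]
        assert c.candidate_id == "T_1"
        assert set(c.constituent_ids) == {"A_1", "B_1"}
        assert sum(c.segment_distances) == 100
        assert c.total_traversed == 100
        assert c.classification == "precise-insert-explained"

    def test_insert_length_mismatch_rejected(self):
        bset = chain_fixture(insert_len=400)
        assert find_transitive_calls(
            bset, TransitiveParams(insert_tolerance_bp=25)) == []

    def test_tolerance_window(self):
        bset = chain_fixture(insert_len=120)
        assert find_transitive_calls(
            bset, TransitiveParams(insert_tolerance_bp=25)) != []
        assert find_transitive_calls(
            bset, TransitiveParams(insert_tolerance_bp=19)) == []

    def test_single_junction_duplicate_is_not_transitive(self):
        # a candidate identical to one real junction: chains need >= 2 parts
        bes = (make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-")
               + make_pair("T", "chr1", 1000, "+", "chr2", 5000, "-"))
        assert find_transitive_calls(make_breakpoint_set(bes)) == []

    def test_imprecise_candidate_gated_by_flag(self):
        bes = (make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-")
               + make_pair("B", "chr2", 5100, "+", "chr3", 2000, "-")
               + [bnd("T_1", "chr1", 1000, "+", partner="T_2", lo=900, hi=1100,
                      precise=False),
                  bnd("T_2", "chr3", 2000, "-", partner="T_1", lo=1900, hi=2100,
                      precise=False)])
        bset = make_breakpoint_set(bes, contig_order=["chr1", "chr2", "chr3"])
        got = find_transitive_calls(bset, TransitiveParams(allow_imprecise=True))
        assert len(got) == 1 and got[0].classification == "imprecise-explained"
        assert find_transitive_calls(
            bset, TransitiveParams(allow_imprecise=False)) == []

    def test_two_set_mode_draws_constituents_separately(self):
        cand = make_breakpoint_set(
            make_pair("T", "chr1", 1000, "+", "chr3", 2000, "-", insert="G" * 100),
            contig_order=["chr1", "chr2", "chr3"])
        cons = make_breakpoint_set(
            make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-")
            + make_pair("B", "chr2", 5100, "+", "chr3", 2000, "-"),
            contig_order=["chr1", "chr2", "chr3"])
        chains = find_transitive_calls(cand, constituents=cons)
        assert len(chains) == 1 and set(chains[0].constituent_ids) == {"A_1", "B_1"}

    def test_constituent_inserts_count_toward_traversal(self):
        bes = (make_pair("A", "chr1", 1000, "+", "chr2", 5000, "-", insert="T" * 30)
               + make_pair("B", "chr2", 5100, "+", "chr3", 2000, "-")
               + make_pair("T", "chr1", 1000, "+", "chr3", 2000, "-",
                           insert="G" * 130))
        bset = make_breakpoint_set(bes, contig_order=["chr1", "chr2", "chr3"])
        chains = find_transitive_calls(bset)
        assert len(chains) == 1 and chains[0].total_traversed == 130


def _planted(seed, n2=4, n3=2, negatives=True):
    truth = simulate_truth(0, seed=seed)
    plant_transitive(truth, n2, 2, seed=seed + 1)
    plant_transitive(truth, n3, 3, seed=seed + 2)
    if negatives:
        plant_transitive(truth, 2, 2, seed=seed + 3, negative="insert-off")
        plant_transitive(truth, 2, 2, seed=seed + 4, negative="gap-too-big")
    return truth


def _check_recovery(truth, chains):
    by_cand = {}
    for c in chains:
        by_cand.setdefault(c.candidate_id, []).append(c)
    for label in truth.chains:
        cid = truth.pair_id_of_event(label.candidate_event)
        want = [truth.pair_id_of_event(e) for e in label.constituent_events]
        got = by_cand.get(cid, [])
        if label.negative:
            assert got == [], f"negative control {cid} was explained"
        else:
            lists = [list(c.constituent_ids) for c in got]
            assert want in lists or want[::-1] in lists, \
                f"candidate {cid}: wanted {want}, got {lists}"


class TestPlantedRecovery:
    def test_planted_chains_recovered_and_negatives_rejected(self):
        truth = _planted(41)
        bset = truth.breakpoint_set()
        chains = find_transitive_calls(bset)
        _check_recovery(truth, chains)

    def test_structural_invariants_of_reported_chains(self):
        truth = _planted(43)
        bset = truth.breakpoint_set()
        params = TransitiveParams()
        for c in find_transitive_calls(bset, params):
            assert 2 <= len(c.constituent_ids) <= params.max_chain
            assert len(set(c.constituent_ids)) == len(c.constituent_ids)
            assert c.candidate_id not in c.constituent_ids
            assert all(0 <= d <= params.max_segment_bp
                       for d in c.segment_distances)
            assert len(c.segment_distances) == len(c.constituent_ids) - 1

    def test_search_equals_bruteforce_enumeration(self):
        truth = _planted(47, n2=3, n3=2)
        bset = truth.breakpoint_set()
        assert len(bset.breakpoint_pairs()) <= 50
        key = lambda cs: sorted((c.candidate_id, c.constituent_ids,
                                 c.segment_distances, c.total_traversed,
                                 c.classification) for c in cs)
        assert key(find_transitive_calls(bset)) == \
            key(find_transitive_calls_bruteforce(bset))
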