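import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from phycodelim.cbc_barcode import AnalysisConfig
from phycodelim.haplotype_network import (Haplotype, NetworkError,
                                          assign_query, build_network,
                                          collapse_haplotypes,
                                          mutational_steps, parsimony_limit,
                                          parsimony_probability)
from phycodelim.io_formats import MetadataRecord, SequenceRecord


class TestCollapse:
    def test_identical_inputs_merge(self):
        seqs = [SequenceRecord(f"s{i}", "ACGU") for i in range(5)]
        (hap,) = collapse_haplotypes(seqs)
        assert hap.multiplicity == 5

    def test_two_haplotypes_with_multiplicities(self):
        seqs = [SequenceRecord("a", "ACGU"), SequenceRecord("b", "ACGA"),
                SequenceRecord("c", "ACGU")]
        haps = collapse_haplotypes(seqs)
        assert [h.multiplicity for h in haps] == [2, 1]

    def test_metadata_categories_retained(self):
        seqs = [SequenceRecord("a", "ACGU"), SequenceRecord("b", "ACGU")]
        md = [MetadataRecord(strain="a", habitat="marine"),
              MetadataRecord(strain="b", habitat="terrestrial")]
        (hap,) = collapse_haplotypes(seqs, md)
        assert hap.habitat_counts() == {"marine": 1, "terrestrial": 1}

    def test_multiplicity_conserved(self):
        rng = random.Random(5)
        seqs = [SequenceRecord(f"s{i}",
                               "".join(rng.choice("AC") for _ in range(6)))
                for i in range(20)]
        haps = collapse_haplotypes(seqs)
        assert sum(h.multiplicity for h in haps) == 20

    def test_unequal_ungapped_lengths_rejected(self):
        seqs = [SequenceRecord("a", "ACGU"), SequenceRecord("b", "ACG")]
        with pytest.raises(NetworkError):
            collapse_haplotypes(seqs)


class TestMutationalSteps:
    def test_simple_hamming(self):
        assert mutational_steps("ACGU", "ACGA") == 1
        assert mutational_steps("ACGU", "UGCA") == 4

    def test_contiguous_gap_run_is_one_step(self):
        assert mutational_steps("AC--GU", "ACUUGU") == 1
        assert mutational_steps("A--C-U", "AGGCAU") == 2


class TestParsimonyLimit:
    def test_full_confidence_gives_single_steps_only(self):
        assert parsimony_limit(300, 1.0) == 1

    def test_monotone_in_sequence_length(self):
        limits = [parsimony_limit(m) for m in range(40, 1200, 40)]
        assert limits == sorted(limits)

    def test_matches_independent_oracle_table(self):
        """Frozen values from a 50-digit independent evaluation of the
        documented probability-of-parsimony estimator."""
        oracle = {50: 2, 100: 3, 118: 3, 124: 3, 150: 3, 200: 4,
                  250: 5, 300: 5, 360: 6, 600: 7, 1000: 10}
        assert {m: parsimony_limit(m) for m in oracle} == oracle

    def test_probability_values_match_oracle(self):
        oracle = {(1, 100): 0.994973403202, (3, 124): 0.963686000884,
                  (5, 250): 0.950475117445, (8, 360): 0.913511438134,
                  (13, 600): 0.86653045162}
        for (j, m), val in oracle.items():
            assert parsimony_probability(j, m) == pytest.approx(val,
                                                                abs=1e-9)

    def test_probability_decreasing_in_steps(self):
        vals = [parsimony_probability(j, 200) for j in range(0, 60)]
        assert vals == sorted(vals, reverse=True)
        assert vals[0] == 1.0


def _hap(hid, seq, mult=1):
    return Haplotype(id=hid, sequence=seq,
                     members=[(f"{hid}.{k}", None) for k in range(mult)])


def brute_force_min_steps(haps):
    """Minimum total unit steps over all spanning trees of the complete
    step-distance graph (independent of the construction path)."""
    n = len(haps)
    dist = {(i, j): mutational_steps(haps[i].sequence, haps[j].sequence)
            for i in range(n) for j in range(i + 1, n)}
    best = None
    for edges in itertools.combinations(sorted(dist), n - 1):
        g = nx.Graph(edges)
        if g.number_of_nodes() == n and nx.is_connected(g):
            total = sum(dist[e] for e in edges)
            best = total if best is None else min(best, total)
    return best


class TestBuildNetwork:
    def test_chain_without_medians(self):
        haps = [_hap("A", "AAAA"), _hap("B", "AAAC"), _hap("C", "AACC")]
        net = build_network(haps, limit=5)
        assert net.total_steps == 2
        assert set(net.graph.edges()) == {("A", "B"), ("B", "C")}

    def test_distance_two_inserts_one_median(self):
        haps = [_hap("A", "AAAA"), _hap("B", "AACC")]
        net = build_network(haps, limit=5)
        kinds = nx.get_node_attributes(net.graph, "kind")
        medians = [n for n, k in kinds.items() if k == "median"]
        assert len(medians) == 1 and net.total_steps == 2
        assert all(mutational_steps(net.graph.nodes[u]["sequence"],
                                    net.graph.nodes[v]["sequence"]) == 1
                   for u, v in net.graph.edges())

    def test_pair_beyond_limit_stays_apart(self):
        haps = [_hap("A", "AAAA"), _hap("B", "CCCC")]
        net = build_network(haps, limit=3)
        assert len(net.components) == 2

    def test_matches_brute_force_minimum_on_random_instances(self):
        rng = random.Random(17)
        for _ in range(15):
            n = rng.randrange(3, 7)
            haps = []
            seen = set()
            while len(haps) < n:
                seq = "".join(rng.choice("ACGU") for _ in range(10))
                if seq not in seen:
                    seen.add(seq)
                    haps.append(_hap(f"H{len(haps)}", seq,
                                     rng.randrange(1, 4)))
            net = build_network(haps, limit=10)
            assert net.total_steps == brute_force_min_steps(haps)

    def test_invariant_under_input_order(self):
        rng = random.Random(23)
        haps = [_hap(f"H{i}", "".join(rng.choice("ACGU") for _ in range(8)))
                for i in range(5)]
        net1 = build_network(haps, limit=8)
        net2 = build_network(list(reversed(haps)), limit=8)

        def canonical(net):
            seq = nx.get_node_attributes(net.graph, "sequence")
            return {frozenset((seq[u], seq[v])) for u, v in net.graph.edges()}

        assert canonical(net1) == canonical(net2)

    def test_node_table_reports_multiplicities(self):
        haps = [_hap("A", "AAAA", 3), _hap("B", "AAAC", 1)]
        net = build_network(haps, limit=2)
        table = net.node_table().set_index("id")
        assert table.loc["A", "multiplicity"] == 3
        assert table.loc["B", "kind"] == "observed"


class TestAssignQuery:
    def _refs(self):
        seq = "ACGU" * 50  # 200 nt reference
        md = [MetadataRecord(strain="r1", species_label="SpeciesX")]
        return [Haplotype(id="R", sequence=seq, members=[("r1", md[0])])]

    def test_identical_query_assigned(self):
        refs = self._refs()
        a = assign_query(SequenceRecord("q", refs[0].sequence), refs)
        assert a.assigned and a.species == "SpeciesX"
        assert a.identity == 1.0 and a.coverage == 1.0

    def test_identity_below_threshold_rejected(self):
        refs = self._refs()
        seq = list(refs[0].sequence)
        for i in range(0, 32, 4):  # 8 mismatches / 200 = 96% identity
            seq[i] = "C" if seq[i] != "C" else "G"
        a = assign_query(SequenceRecord("q", "".join(seq)), refs)
        assert not a.assigned and a.identity == pytest.approx(0.96)

    def test_identity_above_threshold_accepted(self):
        refs = self._refs()
        seq = list(refs[0].sequence)
        for i in range(0, 20, 4):  # 5 mismatches / 200 = 97.5%
            seq[i] = "C" if seq[i] != "C" else "G"
        a = assign_query(SequenceRecord("q", "".join(seq)), refs)
        assert a.assigned and a.identity == pytest.approx(0.975)

    def test_partial_coverage_rejected_despite_identity(self):
        refs = self._refs()
        half = refs[0].sequence[:100]
        a = assign_query(SequenceRecord("q", half), refs)
        assert not a.assigned and a.coverage == pytest.approx(0.5)
        assert a.identity == 1.0

    def test_thresholds_configurable(self):
        refs = self._refs()
        half = refs[0].sequence[:100]
        cfg = AnalysisConfig(coverage_required=0.5, identity_min=0.9)
        a = assign_query(SequenceRecord("q", half), refs, cfg)
        assert a.assigned

    def test_empty_reference_list_is_error(self):
        with pytest.raises(NetworkError):
            assign_query(SequenceRecord("q", "ACGU"), [])
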