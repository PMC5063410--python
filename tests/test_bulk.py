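"""Bulk pipeline: demultiplexing, clustering, anchoring, breakpoints,
junction counting and paired-end conditional quantification."""

import numpy as np
import pandas as pd
import pytest

import oracles
from circamp import (
    IsoformDefinition,
    Junction,
    JunctionProbe,
    ReadPair,
    SimulationConfig,
    anchor_align,
    build_probe,
    bulk_study_config,
    call_breakpoints,
    cluster_reads,
    count_junctions,
    demultiplex_by_primer,
    filter_clusters,
    paired_3prime_quantification,
    simulate_bulk_amplicons,
    simulate_plasmid_amplicons,
)
from circamp import primers
from circamp.bulk import AMBIGUOUS, ReadCluster, sequence_identity
from circamp.locus import FORWARD, LINEAR, reverse_complement


def _pair(seq1, seq2="T" * 50, name="r"):
    return ReadPair(name=name, seq1=seq1, seq2=seq2)


class TestDemultiplex:
    def test_circle_primer_assigns_circular_channel(self):
        read = "T" * 40 + primers.CIRCLE_F + "A" * 40
        out = demultiplex_by_primer([_pair(read)])
        assert len(out[primers.CIRCULAR]) == 1

    def test_one_substitution_leaves_read_unassigned(self):
        mutated = "A" + primers.CIRCLE_F[1:]
        assert mutated != primers.CIRCLE_F
        out = demultiplex_by_primer([_pair("T" * 40 + mutated + "A" * 40)])
        assert len(out[primers.UNASSIGNED]) == 1

    def test_primers_of_two_channels_flag_chimeric(self):
        read = primers.SHORT_F + "T" * 10 + primers.CIRCLE_F
        out = demultiplex_by_primer([_pair(read)])
        assert len(out["chimeric"]) == 1

    def test_empty_primer_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            demultiplex_by_primer([_pair("ACGT" * 30)], primer_set={})

    def test_error_free_assignment_matches_ground_truth(self, locus):
        cfg = SimulationConfig(
            isoform_mixture={"canonical": 0.5, "circle-3-2": 0.5},
            n_reads=1000, substitution_rate=0.0, seed=21,
        )
        pairs, truth = simulate_bulk_amplicons(locus, cfg)
        out = demultiplex_by_primer(pairs)
        by_channel = {p.name: ch for ch in (primers.LINEAR, primers.CIRCULAR)
                      for p in out[ch]}
        for row in truth.reads.itertuples():
            assert by_channel[row.name] == row.channel


class TestClusterReads:
    def test_identical_reads_form_one_cluster(self):
        clusters = cluster_reads(["ACGT" * 30] * 10)
        assert len(clusters) == 1
        assert clusters[0].count == 10

    def test_three_mismatches_split_at_99_percent(self):
        a = "ACGT" * 38  # 152 nt
        b = a[:10] + "T" + a[11:70] + "A" + a[71:130] + "C" + a[131:]
        assert sequence_identity(a, b) < 0.99
        assert len(cluster_reads([a, b])) == 2

    def test_single_mismatch_merges_at_99_percent(self):
        a = "ACGT" * 38
        b = a[:75] + ("A" if a[75] != "A" else "C") + a[76:]
        assert len(cluster_reads([a, a, b])) == 1

    def test_partition_matches_quadratic_oracle(self, locus):
        cfg = bulk_study_config(n_reads=50, seed=31, substitution_rate=0.01)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        seqs = [p.seq1 for p in pairs]
        names = [p.name for p in pairs]
        ours = {(c.representative, tuple(sorted(c.member_names)))
                for c in cluster_reads(seqs, names)}
        theirs = set(oracles.greedy_cluster(seqs, names))
        assert ours == theirs

    def test_invariant_under_permutation_of_identical_reads(self):
        seqs = ["A" * 150, "C" * 150, "A" * 150]
        a = cluster_reads(seqs, ["x", "y", "z"])
        b = cluster_reads(seqs[::-1], ["z", "y", "x"])
        assert {(c.representative, c.count) for c in a} == \
               {(c.representative, c.count) for c in b}

    def test_empty_input_gives_empty_output(self):
        assert cluster_reads([]) == []


class TestFilterClusters:
    def test_minimum_read_support(self):
        clusters = [ReadCluster("A", n, []) for n in (12, 5, 4, 1)]
        assert [c.count for c in filter_clusters(clusters, 5)] == [12, 5]
        assert filter_clusters(clusters, 1) == clusters

    def test_small_artifact_clone_removed(self, locus):
        cfg = SimulationConfig(isoform_mixture={"canonical": 1.0}, n_reads=40,
                               substitution_rate=0.0, seed=1)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        seqs = [p.seq1 for p in pairs] + ["ACGT" * 38] * 3  # 3-read artifact
        kept = filter_clusters(cluster_reads(seqs), min_reads=5)
        assert len(kept) == 1 and kept[0].count == 40


class TestAnchorAlign:
    def test_exact_exon_slice_gives_one_covering_anchor(self, locus):
        e2 = locus.exon("2")
        rep = locus.sequence[e2.start: e2.start + 60]
        anchors = [a for a in anchor_align(rep, locus) if a.strand == "+"]
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.query_start, a.query_end) == (0, 60)
        assert (a.ref_start, a.ref_end) == (e2.start, e2.start + 60)

    def test_junction_spanning_read_yields_adjacent_anchors(self, locus):
        e1, e4 = locus.exon("1"), locus.exon("4")
        rep = locus.exon_sequence("1") + locus.exon_sequence("4")
        anchors = sorted(
            (a for a in anchor_align(rep, locus) if a.strand == "+"),
            key=lambda a: a.query_start,
        )
        assert len(anchors) == 2
        # maximal exact matches may chance-extend a base or two across the
        # junction when flanking genomic bases coincide
        assert abs(anchors[0].ref_end - e1.end) <= 2
        assert abs(anchors[1].ref_start - e4.start) <= 2

    def test_match_below_threshold_is_dropped(self, locus):
        rep = "T" * 30 + locus.sequence[200:217] + "G" * 30  # 17 bp shared
        assert all(
            not (a.ref_start <= 200 < a.ref_end) or a.length >= 18
            for a in anchor_align(rep, locus)
        )
        # a 17-mer cannot seed an anchor at min_anchor=18 unless extended
        plus = [a for a in anchor_align(rep, locus, min_anchor=18)
                if a.strand == "+"]
        assert all(a.length >= 18 for a in plus)

    def test_matches_naive_mem_oracle(self, locus):
        rng = np.random.default_rng(5)
        e2 = locus.exon("2")
        reps = [
            locus.exon_sequence("1") + locus.exon_sequence("2")[:40],
            locus.sequence[e2.start - 20: e2.end + 20],
            "".join(rng.choice(list("ACGT"), 80)),  # unanchored
        ]
        for rep in reps:
            ours = {(a.query_start, a.query_end, a.ref_start, a.ref_end)
                    for a in anchor_align(rep, locus) if a.strand == "+"}
            assert ours == set(oracles.naive_mems(rep, locus.sequence, 18))


class TestCallBreakpoints:
    def _breakpoints(self, locus, mixture, n_reads, seed, min_fraction=0.01,
                     isoforms=None):
        cfg = SimulationConfig(isoform_mixture=mixture, n_reads=n_reads,
                               substitution_rate=0.002, seed=seed)
        pairs, _ = simulate_bulk_amplicons(locus, cfg, isoforms=isoforms)
        seqs = [p.seq1 for p in pairs] + [p.seq2 for p in pairs]
        clusters = filter_clusters(cluster_reads(seqs), 5)
        return call_breakpoints(clusters, locus, channel_total=len(seqs),
                                min_fraction=min_fraction)

    def test_canonical_library_yields_consecutive_exon_breakpoints(self, locus):
        bp = self._breakpoints(locus, {"canonical": 1.0}, 400, seed=41)
        exons = {x: locus.exon(x) for x in "1234"}
        expected = {
            (exons["1"].end, exons["2"].start),
            (exons["2"].end, exons["3"].start),
            (exons["3"].end, exons["4"].start),
        }
        assert set(zip(bp["left"], bp["right"])) == expected
        assert (bp["topology"] == "forward").all()

    def test_low_frequency_spike_in_falls_below_threshold(self, locus):
        isoforms = dict(
            canonical=IsoformDefinition("canonical", ("1", "2", "3", "4"), LINEAR),
            skip=IsoformDefinition("skip", ("1", "3*", "4"), LINEAR),
            spike=IsoformDefinition("spike", ("1", "3", "4"), LINEAR),
        )
        mixture = {"canonical": 0.895, "skip": 0.10, "spike": 0.005}
        bp = self._breakpoints(locus, mixture, 2000, seed=42, isoforms=isoforms)
        arcs = set(zip(bp["left"], bp["right"]))
        skip_arc = (locus.exon("1").end, locus.exon("3*").start)
        spike_arc = (locus.exon("1").end, locus.exon("3").start)
        assert skip_arc in arcs
        assert spike_arc not in arcs
        # with no threshold the spike's breakpoint is visible
        bp0 = self._breakpoints(locus, mixture, 2000, seed=42,
                                min_fraction=0.0, isoforms=isoforms)
        assert spike_arc in set(zip(bp0["left"], bp0["right"]))

    def test_zero_channel_total_is_an_error(self, locus):
        with pytest.raises(ValueError, match="total"):
            call_breakpoints([], locus, channel_total=0)

    def test_plasmid_control_shows_no_spliced_breakpoints(self, locus,
                                                          five_probes,
                                                          three_probes):
        cfg = SimulationConfig(n_reads=300, substitution_rate=0.002, seed=43)
        pairs, _ = simulate_plasmid_amplicons(locus, cfg)
        seqs = [p.seq1 for p in pairs] + [p.seq2 for p in pairs]
        clusters = filter_clusters(cluster_reads(seqs), 5)
        bp = call_breakpoints(clusters, locus, channel_total=len(seqs))
        assert bp.empty
        # no spliced-junction probe matches the unspliced template ...
        res = count_junctions(seqs, five_probes + three_probes)
        assert sum(res.counts.values()) == 0
        # ... while the contiguous intron-exon boundary 20-mer does
        e2 = locus.exon("2")
        boundary = JunctionProbe(
            junction=Junction("intron1", "2", FORWARD),
            donor_flank=locus.sequence[e2.start - 10: e2.start],
            acceptor_flank=locus.sequence[e2.start: e2.start + 10],
        )
        hits = count_junctions(seqs, [boundary])
        assert hits.counts["intron1-2"] > 0


class TestCountJunctions:
    def test_exact_probe_match_is_counted(self, locus, five_probes):
        p12 = next(p for p in five_probes if p.name == "1-2")
        read = "T" * 30 + p12.probe + "C" * 30
        res = count_junctions([read], five_probes)
        assert res.counts["1-2"] == 1

    def test_reverse_complement_match_is_counted(self, five_probes):
        p12 = next(p for p in five_probes if p.name == "1-2")
        read = "T" * 30 + reverse_complement(p12.probe) + "C" * 30
        assert count_junctions([read], five_probes).counts["1-2"] == 1

    def test_two_mismatches_exceed_the_allowance(self, five_probes):
        p12 = next(p for p in five_probes if p.name == "1-2")
        probe = p12.probe
        mutated = ("A" if probe[3] != "A" else "C").join(
            [probe[:3], probe[4:]]
        )
        mutated = mutated[:15] + ("A" if mutated[15] != "A" else "C") + mutated[16:]
        read = "T" * 30 + mutated + "C" * 30
        res = count_junctions([read], five_probes, max_mismatch=1)
        assert res.counts["1-2"] == 0 and res.unassigned == 1

    def test_duplicate_probe_strings_rejected(self, five_probes):
        dup = JunctionProbe(
            junction=Junction("9", "9", FORWARD),
            donor_flank=five_probes[0].donor_flank,
            acceptor_flank=five_probes[0].acceptor_flank,
        )
        with pytest.raises(ValueError, match="not identifying"):
            count_junctions(["ACGT" * 10], five_probes + [dup])

    def test_equal_distance_hits_are_ambiguous(self, five_probes):
        a, b = five_probes[0], five_probes[1]
        read = "T" * 5 + a.probe + "T" * 5 + b.probe + "T" * 5
        res = count_junctions([read], five_probes)
        assert res.assignments == [AMBIGUOUS]
        assert res.ambiguous == 1

    def test_counts_match_naive_hamming_oracle(self, locus, five_probes):
        cfg = bulk_study_config(n_reads=400, seed=51)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        seqs = [p.seq1 for p in pairs]
        res = count_junctions(seqs, five_probes, max_mismatch=1)
        assert res.assignments == oracles.naive_assignments(seqs, five_probes, 1)

    def test_conservation_and_permutation_invariance(self, locus, five_probes):
        cfg = bulk_study_config(n_reads=300, seed=52)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        seqs = [p.seq1 for p in pairs]
        res = count_junctions(seqs, five_probes)
        assert res.assigned + res.ambiguous + res.unassigned == len(seqs)
        rev = count_junctions(seqs[::-1], five_probes)
        assert res.counts == rev.counts


class TestPairedQuantification:
    def test_canonical_only_mass_on_consecutive_junction(self, locus,
                                                         five_probes,
                                                         three_probes):
        cfg = SimulationConfig(isoform_mixture={"canonical": 1.0}, n_reads=200,
                               substitution_rate=0.0, seed=61)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        res = paired_3prime_quantification(pairs, five_probes, three_probes, "1-2")
        assert res.counts["2-3"] == res.n_pairs
        assert res.counts["2-4"] == res.counts["2-3*"] == 0

    def test_bins_sum_to_pair_total(self, locus, five_probes, three_probes):
        cfg = bulk_study_config(n_reads=2000, seed=62)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        res = paired_3prime_quantification(pairs, five_probes, three_probes, "1-2")
        assert res.resolved + res.unresolved + res.ambiguous == res.n_pairs

    def test_recovers_known_conditional_mixture(self, locus, five_probes,
                                                three_probes):
        cfg = bulk_study_config(n_reads=20_000, seed=63)
        pairs, _ = simulate_bulk_amplicons(locus, cfg)
        res = paired_3prime_quantification(pairs, five_probes, three_probes, "1-2")
        frac = res.counts["2-4"] / res.resolved
        se = np.sqrt(0.129 * (1 - 0.129) / res.resolved)
        assert abs(frac - 0.129) <= 3 * se

    def test_missing_five_prime_junction_is_an_error(self, locus, five_probes,
                                                     three_probes):
        with pytest.raises(ValueError, match="9-9"):
            paired_3prime_quantification([], five_probes, three_probes, "9-9")
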