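"""Mapping, window excision, duplex calling, signature scoring, filters,
and planted-truth recovery of the assembled discovery pipeline."""

import math

import numpy as np
import pytest

from mirforge import discovery
from mirforge.discovery import (Anchor, DiscoveryParams, HairpinCandidate,
                                call_duplex, contaminant_filter, excise_windows,
                                map_reads, merge_loci, signature_score)
from mirforge.profiling import CollapsedRead
from mirforge.seqio import revcomp_dna, to_rna


def _random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestMapReads:
    def test_forward_and_reverse_anchors(self, rng):
        genome = {"g": _random_dna(rng, 2000)}
        fwd = CollapsedRead(to_rna(genome["g"][100:122]), 3, "x")
        rev = CollapsedRead(to_rna(revcomp_dna(genome["g"][300:322])), 2, "x")
        anchors = map_reads([fwd, rev], genome)
        spans = {(a.strand, a.start, a.end) for a in anchors}
        assert ("+", 100, 122) in spans
        assert ("-", 300, 322) in spans

    def test_equivalence_with_brute_force_scan(self, rng):
        genome = {"g": _random_dna(rng, 10_000)}
        g = genome["g"]
        reads = []
        for _ in range(30):
            p = int(rng.integers(0, 9950))
            ln = int(rng.integers(20, 24))
            reads.append(g[p:p + ln])
        for _ in range(10):
            p = int(rng.integers(0, 9950))
            reads.append(revcomp_dna(g[p:p + 22]))
        reads += [_random_dna(rng, 22) for _ in range(10)]
        collapsed = [CollapsedRead(to_rna(r), 1, "x") for r in set(reads)]
        anchors = map_reads(collapsed, genome)
        got = {(a.read.sequence, a.strand, a.start) for a in anchors}

        expected = set()
        for rec in collapsed:
            dna = rec.sequence.replace("U", "T")
            for strand, probe in (("+", dna), ("-", revcomp_dna(dna))):
                p = g.find(probe)
                while p != -1:
                    expected.add((rec.sequence, strand, p))
                    p = g.find(probe, p + 1)
        assert got == expected

    def test_multimapper_cap(self):
        unit = "ACGTACGGATCCAGTACGGATC"
        genome = {"m": ("TTTTT" + unit) * 16}
        read = CollapsedRead(to_rna(unit), 5, "x")
        assert map_reads([read], genome, max_genomic_hits=15) == []
        kept = map_reads([read], genome, max_genomic_hits=16)
        assert len(kept) == 16 and all(a.n_genomic_hits == 16 for a in kept)


class TestExciseWindows:
    def _anchor(self, start, end):
        return Anchor(read=CollapsedRead("A" * (end - start), 1, "x"),
                      contig_id="g", strand="+", start=start, end=end)

    def test_three_windows(self):
        genome = {"g": "A" * 1300}
        wins = excise_windows(self._anchor(1000, 1022), genome, flank=150)
        assert wins == [(850, 1172), (850, 1052), (970, 1172)]

    def test_clipped_at_contig_start(self):
        genome = {"g": "A" * 500}
        wins = excise_windows(self._anchor(10, 32), genome, flank=150)
        assert wins[0] == (0, 182)

    def test_minus_strand_window_sequence_is_revcomp(self, rng):
        g = _random_dna(rng, 400)
        seq = discovery.window_sequence({"g": g}, "g", 100, 200, "-")
        assert seq == to_rna(revcomp_dna(g[100:200]))


class TestCallDuplex:
    def _perfect_stem_pairing(self, stem=30, loop=6, tail=4):
        n = 2 * stem + loop
        pairing = [-1] * (n + tail)
        for i in range(stem):
            pairing[i] = n - 1 - i
            pairing[n - 1 - i] = i
        return pairing, n - 1

    def test_mature_on_five_prime_arm(self):
        pairing, t = self._perfect_stem_pairing()
        star = call_duplex(pairing, 0, 22)
        assert star == (t - 22 + 3, t - 0 + 3)  # (46, 68)
        s0, s1 = star
        # inner star boundary pairs the last non-overhang mature position
        assert pairing[s0] == 19

    def test_mature_on_three_prime_arm_mirrored(self):
        pairing, t = self._perfect_stem_pairing()
        star = call_duplex(pairing, 44, 66)
        assert star == (t - 66 + 3, t - 44 + 3)  # (2, 24)

    def test_mature_centered_on_loop_rejected(self):
        pairing, _ = self._perfect_stem_pairing()
        assert call_duplex(pairing, 25, 47) is None

    def test_entirely_unpaired_mature_rejected(self):
        pairing = [-1] * 80
        assert call_duplex(pairing, 10, 32) is None

    def test_unpaired_terminus_resolved_toward_loop(self):
        pairing, t = self._perfect_stem_pairing()
        # fray the outermost two pairs: mature 5' terminus now unpaired
        for i in (0, 1):
            pairing[pairing[i]] = -1
            pairing[i] = -1
        star = call_duplex(pairing, 0, 22)
        assert star is not None
        s0, s1 = star
        assert s0 == t - 22 + 3  # inner boundary unchanged
        assert s1 == (t - 2) + 1 + 2  # outermost paired partner + extension


class TestSignatureScore:
    def _candidate(self):
        return HairpinCandidate(
            contig_id="g", strand="+", window_start=0, window_end=200,
            precursor_seq="A" * 200, structure="." * 200, pairing=[-1] * 200,
            mature_start=50, mature_end=72, star_start=100, star_end=122)

    def _anchor(self, start, end, count):
        return Anchor(read=CollapsedRead("A" * (end - start), count, "x"),
                      contig_id="g", strand="+", start=start, end=end)

    def test_mature_stack_with_scatter(self):
        anchors = [self._anchor(50, 72, 100), self._anchor(130, 152, 10)]
        score, star = signature_score(self._candidate(), anchors, jitter=2)
        assert score == pytest.approx(math.log2(101 / 11), abs=1e-6)
        assert star is False

    def test_empty_window_scores_zero(self):
        score, star = signature_score(self._candidate(), [], jitter=2)
        assert score == 0.0 and star is False

    def test_star_bonus(self):
        anchors = [self._anchor(50, 72, 100), self._anchor(100, 122, 5)]
        score, star = signature_score(self._candidate(), anchors, jitter=2)
        assert score == pytest.approx(math.log2(106 / 1) + 2, abs=1e-6)
        assert star is True

    def test_read_crossing_window_boundary_is_inconsistent(self):
        anchors = [self._anchor(190, 212, 7)]
        score, _ = signature_score(self._candidate(), anchors, jitter=2)
        assert score == pytest.approx(math.log2(1 / 8), abs=1e-6)


class TestContaminantFilter:
    def test_exact_trna_copy_fails(self, rng):
        trna = _random_dna(rng, 90)
        assert contaminant_filter(to_rna(trna), {"trna": trna}) is False

    def test_unrelated_precursor_passes(self, rng):
        precursor = to_rna(_random_dna(rng, 100))
        db = {f"c{i}": _random_dna(rng, 120) for i in range(5)}
        assert contaminant_filter(precursor, db) is True

    def test_threshold_case_fails(self, rng):
        precursor = _random_dna(rng, 100)
        frag = list(precursor[5:90])  # 85% coverage of the precursor
        for pos in (20, 40, 60, 70):  # 81/85 identical = 95.3%
            frag[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[pos]]
        assert contaminant_filter(to_rna(precursor),
                                  {"x": "".join(frag)}) is False

    def test_empty_db_auto_passes(self):
        assert contaminant_filter("ACGU" * 20, {}) is True

    def test_reverse_complement_copy_fails(self, rng):
        rrna = _random_dna(rng, 150)
        assert contaminant_filter(to_rna(revcomp_dna(rrna)), {"r": rrna}) is False


class TestDiscoverPipeline:
    def test_planted_recovery_with_exact_mature_ends(self, small_sim,
                                                     small_discovery):
        truth = small_sim["truth"]
        records = small_discovery
        found = {(r.strand, r.mature_five_prime) for r in records}
        expressed = [h for h in truth if h.max_rpm >= 50]
        recovered = sum(
            1 for h in expressed
            if any(s == h.strand and abs(fp - h.mature_five_prime) <= 1
                   for s, fp in found))
        assert recovered / len(expressed) >= 0.9

    def test_low_abundance_hairpins_absent(self, small_sim, small_discovery):
        truth = small_sim["truth"]
        low = [h for h in truth if h.max_rpm < 10]
        found = {(r.strand, r.mature_five_prime) for r in small_discovery}
        for h in low:
            assert not any(s == h.strand and abs(fp - h.mature_five_prime) <= 2
                           for s, fp in found)

    def test_five_rpm_hairpin_absent_at_reference_depth(self):
        from mirforge import profiling, synthetic

        cfg = synthetic.SimulationConfig(
            genome_len=20_000, n_hairpins=1, stages=[("egg", 1)],
            pirna_fraction_by_stage={"egg": 0.4}, read_depth=300_000,
            seed=21, contaminant_count=0, frac_low_abundance=1.0, low_rpm=5.0)
        genome, truth, cont = synthetic.plant_genome(cfg)
        libs, _ = synthetic.simulate_reads(genome, truth, cfg, cont)
        collapsed = {lib: profiling.length_filter(
            profiling.collapse_reads(reads, lib)) for lib, reads in libs.items()}
        records = discovery.discover(collapsed, genome, DiscoveryParams(),
                                     lib_sizes={"egg_r1": cfg.read_depth})
        assert records == []

    def test_dicer_overhangs_on_recovered_duplexes(self, small_sim,
                                                   small_discovery):
        truth_by_5p = {(h.strand, h.mature_five_prime): h
                       for h in small_sim["truth"]}
        checked = 0
        for rec in small_discovery:
            key = (rec.strand, rec.mature_five_prime)
            if key in truth_by_5p:
                h = truth_by_5p[key]
                (s0, s1) = rec.candidate.star_genomic
                assert (s0, s1) == (h.star_start, h.star_end)
                checked += 1
        assert checked >= 5

    def test_output_sorted_and_star_supported(self, small_discovery):
        keys = [(r.contig_id, r.candidate.window_start) for r in small_discovery]
        assert keys == sorted(keys)
        assert all(r.candidate.flags["star_supported"] for r in small_discovery)

    def test_locus_merging_idempotent(self, small_discovery):
        candidates = [r.candidate for r in small_discovery]
        merged = merge_loci(candidates)
        assert {id(c) for c in merge_loci(merged)} == {id(c) for c in merged}
        assert len(merged) == len(candidates)

    def test_gff3_round_trip_coordinates(self, small_discovery, tmp_path):
        path = tmp_path / "out.gff3"
        discovery.write_gff3(small_discovery, path)
        lines = [l.split("\t") for l in path.read_text().splitlines()
                 if not l.startswith("#")]
        pre = [l for l in lines if l[2] == "pre_miRNA"]
        assert len(pre) == len(small_discovery)
        for rec, row in zip(small_discovery, pre):
            assert int(row[3]) == rec.candidate.window_start + 1
            assert int(row[4]) == rec.candidate.window_end
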