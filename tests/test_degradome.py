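"""PARE tag mapping, duplex scoring, category assignment, empirical p-values,
and assembled target calling."""

import numpy as np
import pytest

from mirforge import degradome, synthetic
from mirforge.degradome import (DegradomeParams, DegradomeProfile, call_targets,
                                categorize, dinucleotide_shuffle, duplex_score,
                                find_sites, map_tags, site_pvalue)
from mirforge.seqio import revcomp_dna, revcomp_rna, to_rna


def _random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


def perfect_site(mirna_rna):
    """Transcript-sense site perfectly complementary to the miRNA."""
    return revcomp_rna(mirna_rna)


class TestMapTags:
    def test_exact_sense_match_counts_at_five_prime(self, rng):
        tx = {"t1": _random_rna(rng, 300).replace("U", "T")}
        tag = tx["t1"][50:70]
        profiles = map_tags([tag, tag, tag], tx)
        counts = profiles["t1"].five_prime_counts
        assert counts[50] == 3 and counts.sum() == 3

    def test_antisense_tag_ignored(self, rng):
        tx = {"t1": _random_rna(rng, 300).replace("U", "T")}
        profiles = map_tags([revcomp_dna(tx["t1"][50:70])], tx)
        assert profiles["t1"].total_tags == 0

    def test_off_length_tags_dropped(self, rng):
        tx = {"t1": _random_rna(rng, 300).replace("U", "T")}
        profiles = map_tags([tx["t1"][50:69], tx["t1"][50:71]], tx)
        assert profiles["t1"].total_tags == 0

    def test_noise_free_simulation_maps_only_to_planted_sites(self):
        tx, _, truth = synthetic.make_pare_dataset(n_transcripts=4,
                                                   transcript_len=400,
                                                   n_mirnas=3, seed=5)
        tags = synthetic.simulate_pare(tx, truth, seed=5, signal_fraction=1.0)
        profiles = map_tags(tags, tx)
        planted = {(s.transcript_id, s.position) for s in truth}
        occupied = {(tid, int(p)) for tid, prof in profiles.items()
                    for p in np.flatnonzero(prof.five_prime_counts)}
        assert occupied == planted

    def test_empty_transcriptome_errors(self):
        with pytest.raises(ValueError):
            map_tags(["A" * 20], {})


class TestDuplexScore:
    MIRNA = "UGGAAUGUAAAGAAGUAUGGA"  # 21 nt

    def test_perfect_complement_scores_zero(self):
        assert duplex_score(self.MIRNA, perfect_site(self.MIRNA)) == 0.0

    def test_gu_wobble_in_seed_scores_one(self):
        m = len(self.MIRNA)
        assert self.MIRNA[4] == "A"
        mirna = self.MIRNA[:4] + "G" + self.MIRNA[5:]
        site = list(perfect_site(mirna))
        site[m - 5] = "U"  # G:U wobble opposite miRNA position 5
        assert duplex_score(mirna, "".join(site)) == pytest.approx(1.0)

    def test_mismatch_outside_seed_scores_one(self):
        m = len(self.MIRNA)
        site = list(perfect_site(self.MIRNA))
        site[m - 20] = self.MIRNA[19]  # identity = guaranteed mismatch
        assert duplex_score(self.MIRNA, "".join(site)) == pytest.approx(1.0)

    def test_mismatch_inside_seed_doubled(self):
        m = len(self.MIRNA)
        site = list(perfect_site(self.MIRNA))
        site[m - 5] = self.MIRNA[4]
        assert duplex_score(self.MIRNA, "".join(site)) == pytest.approx(2.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            duplex_score(self.MIRNA, "ACGU")


class TestFindSites:
    def test_planted_perfect_site_located(self, rng):
        mirna = _random_rna(rng, 21)
        tx = _random_rna(rng, 800)
        pos = 300
        tx = tx[:pos] + perfect_site(mirna) + tx[pos + 21:]
        sites = find_sites(mirna, tx, max_score=2.0)
        perfect = [s for s in sites if s.duplex_score == 0.0]
        assert len(perfect) == 1
        assert perfect[0].cleavage_pos == pos + 21 - 10

    def test_random_transcripts_rarely_hit_at_low_threshold(self, rng):
        total = sum(len(find_sites(_random_rna(rng, 21), _random_rna(rng, 1000),
                                   max_score=2.0))
                    for _ in range(20))
        assert total <= 2

    def test_threshold_inclusive_at_exactly_seven(self, rng):
        mirna = _random_rna(rng, 21)
        site = list(perfect_site(mirna))
        m = len(mirna)
        for i in range(14, 21):  # seven singly-weighted mismatches
            site[m - i] = mirna[i - 1]
        tx = _random_rna(rng, 200) + "".join(site) + _random_rna(rng, 200)
        assert duplex_score(mirna, "".join(site)) == pytest.approx(7.0)
        hits = find_sites(mirna, tx, max_score=7.0)
        assert any(s.duplex_score == pytest.approx(7.0) for s in hits)
        hits_strict = find_sites(mirna, tx, max_score=6.5)
        assert not any(s.duplex_score == pytest.approx(7.0) for s in hits_strict)


def categorize_oracle(counts, pos):
    """Independent brute-force categorizer."""
    site = counts[pos]
    if site == 0:
        return None
    if site == 1:
        return 4
    occupied = sorted(c for c in counts if c >= 1)
    mx = max(counts)
    n_at_max = sum(1 for c in counts if c == mx)
    k = len(occupied)
    med = (occupied[k // 2] if k % 2 == 1
           else (occupied[k // 2 - 1] + occupied[k // 2]) / 2)
    if site == mx:
        return 0 if n_at_max == 1 else 1
    if site > med:
        return 2
    return 3


def make_profile(counts):
    arr = np.asarray(counts, dtype=np.int64)
    return DegradomeProfile("t", len(arr), arr)


class TestCategorize:
    @pytest.mark.parametrize("counts,pos,expected", [
        ([9, 1, 1], 0, 0),      # unique maximum
        ([5, 5, 1], 1, 1),      # shared maximum
        ([1, 0, 0], 0, 4),      # single read
        ([10, 3, 1, 1], 1, 2),  # above median, below maximum
        ([10, 9, 8, 2], 3, 3),  # at/below median
    ])
    def test_reference_cases(self, counts, pos, expected):
        assert categorize(make_profile(counts), pos) == expected

    def test_unoccupied_position_has_no_category(self):
        assert categorize(make_profile([5, 0, 2]), 1) is None

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            categorize(make_profile([1, 1]), 5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 30))
            counts = rng.integers(0, 12, n)
            if counts.sum() == 0:
                counts[0] = 1
            pos = int(rng.integers(0, n))
            got = categorize(make_profile(counts), pos)
            assert got == categorize_oracle(list(counts), pos)

    def test_monotone_in_site_reads(self, rng):
        counts = list(rng.integers(1, 10, 15))
        profile = make_profile(counts)
        cats = [categorize(profile, i) for i in range(15)]
        order = np.argsort(counts)
        ranked = [cats[i] for i in order if cats[i] is not None]
        # higher site reads never yield a strictly worse (higher) category,
        # except the dedicated single-read class 4
        ranked = [c for c in ranked if c != 4]
        assert all(a >= b for a, b in zip(ranked, ranked[1:]))


class TestSitePvalue:
    def test_deterministic(self, rng):
        mirna = _random_rna(rng, 21)
        tx = {"t": _random_rna(rng, 500)}
        hit = find_sites(mirna, tx["t"], max_score=40.0, transcript_id="t")[0]
        hit.category = 2
        p1 = site_pvalue(hit, mirna, tx, n_shuffles=30, seed=9)
        p2 = site_pvalue(hit, mirna, tx, n_shuffles=30, seed=9)
        assert p1 == p2

    def test_planted_site_significant(self, rng):
        mirna = _random_rna(rng, 21)
        tx_seq = _random_rna(rng, 800)
        tx_seq = tx_seq[:400] + perfect_site(mirna) + tx_seq[421:]
        hit = [s for s in find_sites(mirna, tx_seq, 0.0, transcript_id="t")][0]
        hit.category = 0
        p = site_pvalue(hit, mirna, {"t": tx_seq}, n_shuffles=100, seed=3)
        assert p <= 0.05

    def test_degenerate_homopolymer_null_is_powerless(self):
        mirna = "A" * 21
        tx_seq = "U" * 21 + "GCGC" * 50  # perfect poly(U) target site
        hit = find_sites(mirna, tx_seq, 0.0, transcript_id="t")[0]
        hit.category = 4
        # every dinucleotide shuffle of a homopolymer is the homopolymer
        p = site_pvalue(hit, mirna, {"t": tx_seq}, n_shuffles=50, seed=1)
        assert p == pytest.approx(1.0)

    def test_dinucleotide_composition_preserved(self, rng):
        seq = _random_rna(rng, 21)
        shuffled = dinucleotide_shuffle(seq, np.random.default_rng(5))
        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert len(shuffled) == len(seq)
        assert dinucs(shuffled) == dinucs(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestCallTargets:
    def test_shared_and_private_targets_across_libraries(self):
        tx, mirnas, truth = synthetic.make_pare_dataset(
            n_transcripts=16, transcript_len=500, n_mirnas=16, seed=8,
            tags_per_site=40)
        shared, only_a, only_b = truth[:10], truth[10:13], truth[13:16]
        tags_a = synthetic.simulate_pare(tx, shared + only_a, seed=8,
                                         signal_fraction=1.0)
        tags_b = synthetic.simulate_pare(tx, shared + only_b, seed=9,
                                         signal_fraction=1.0)
        profiles = {"libA": map_tags(tags_a, tx), "libB": map_tags(tags_b, tx)}
        params = DegradomeParams(max_score=3.0, n_shuffles=50, seed=4)
        hits, venn = call_targets(mirnas, tx, profiles, params)
        assert venn is not None
        assert venn.shared == 10
        assert venn.private == {"libA": 3, "libB": 3}
        assert all(h.category <= 2 and h.p_value < 0.05 for h in hits)

    def test_category_three_site_excluded(self, rng):
        mirna = _random_rna(rng, 21)
        tx_seq = _random_rna(rng, 300)
        tx_seq = tx_seq[:100] + perfect_site(mirna) + tx_seq[121:]
        cleavage = 100 + 21 - 10
        counts = np.zeros(300, dtype=np.int64)
        counts[cleavage] = 2
        counts[[5, 10, 15]] = [10, 9, 8]
        profile = DegradomeProfile("t", 300, counts)
        assert categorize(profile, cleavage) == 3
        hits, _ = call_targets({"m": mirna}, {"t": tx_seq},
                               {"lib": {"t": profile}},
                               DegradomeParams(max_score=3.0, seed=2))
        assert hits == []

    def test_p_exactly_alpha_excluded(self, rng):
        mirna = _random_rna(rng, 21)
        tx_seq = _random_rna(rng, 300)
        tx_seq = tx_seq[:100] + perfect_site(mirna) + tx_seq[121:]
        cleavage = 100 + 21 - 10
        counts = np.zeros(300, dtype=np.int64)
        counts[cleavage] = 20
        profile = DegradomeProfile("t", 300, counts)
        # with 19 shuffles and no shuffle success, p = 1/20 = alpha exactly
        hits, _ = call_targets({"m": mirna}, {"t": tx_seq},
                               {"lib": {"t": profile}},
                               DegradomeParams(max_score=0.0, n_shuffles=19,
                                               seed=2))
        assert hits == []

    def test_simulated_tag_length_mode_is_twenty(self):
        tx, _, truth = synthetic.make_pare_dataset(seed=3)
        tags = synthetic.simulate_pare(tx, truth, seed=3)
        lengths, counts = np.unique([len(t) for t in tags], return_counts=True)
        assert lengths[np.argmax(counts)] == 20
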