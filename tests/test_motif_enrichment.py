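"""Region geometry, Markov backgrounds, and the pentamer enrichment test."""

import numpy as np
import pytest

from smnsplice.genomic_model import (
    GenomicInterval,
    SplicingEvent,
    derive_introns,
    reverse_complement,
)
from smnsplice.motif_enrichment import (
    ALL_PENTAMERS,
    MarkovBackground,
    all_kmer_probabilities,
    assign_gc_bins,
    bh_adjust,
    binomial_enrichment,
    count_kmers,
    enrich_stratum,
    extract_regions,
    fit_markov,
    kmer_probability,
    region_intervals,
)
from smnsplice.synthetic_data import plant_motifs, random_sequence


def make_se_event(exon_len=200, intron_len=1000, cassette_len=150,
                  strand="+", start=1000):
    lens = [exon_len, intron_len, cassette_len, intron_len, exon_len]
    bounds = np.cumsum([start] + lens)
    spans = [(bounds[0], bounds[1]), (bounds[2], bounds[3]),
             (bounds[4], bounds[5])]
    if strand == "-":
        spans = spans[::-1]
    exons = tuple(GenomicInterval("chr1", a, b, strand) for a, b in spans)
    return SplicingEvent("ev", "SE", exons, derive_introns(exons))


class TestRegionGeometry:
    def test_seven_regions_with_stated_window_sizes(self):
        ev = make_se_event(exon_len=200, intron_len=1000, cassette_len=150)
        regions = region_intervals(ev)
        lengths = {label: len(iv) for label, iv in regions.items()}
        assert lengths == {
            "up_exon_150": 150, "up_intron_5p_300": 300,
            "up_intron_3p_300": 300, "cassette_exon_full": 150,
            "down_intron_5p_300": 300, "down_intron_3p_300": 300,
            "down_exon_150": 150,
        }

    def test_short_intron_split_halves_are_disjoint(self):
        ev = make_se_event(intron_len=400)
        regions = region_intervals(ev)
        i5, i3 = regions["up_intron_5p_300"], regions["up_intron_3p_300"]
        assert len(i5) == 200 and len(i3) == 200
        assert not i5.overlaps(i3)
        assert i5.end == i3.start  # + strand: contiguous halves

    def test_total_length_conservation(self):
        ev = make_se_event(exon_len=400, intron_len=1000, cassette_len=123)
        total = sum(len(iv) for iv in region_intervals(ev).values())
        assert total == 150 + 300 + 300 + 123 + 300 + 300 + 150

    def test_minus_strand_vs_brute_force(self):
        """− strand up_exon_150 equals revcomp of the genomically leftmost
        150 bp of the genomically rightmost exon (its transcript 3' end)."""
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=6000))}
        ev = make_se_event(strand="-", start=500)
        seqs = extract_regions(ev, genome).sequences
        up_exon = ev.exons[0]  # genomically rightmost
        expected = reverse_complement(
            genome["chr1"][up_exon.start : up_exon.start + 150]
        )
        assert seqs["up_exon_150"] == expected
        # 5' intron window of the upstream intron hugs that exon's left edge
        intron = ev.introns[0]
        expected_i5 = reverse_complement(
            genome["chr1"][intron.end - 300 : intron.end]
        )
        assert seqs["up_intron_5p_300"] == expected_i5

    def test_ri_event_four_regions(self):
        exons = tuple(
            GenomicInterval("chr1", a, b, "+")
            for a, b in [(100, 300), (500, 700)]
        )
        ev = SplicingEvent("ri", "RI", exons, derive_introns(exons))
        labels = set(region_intervals(ev))
        assert labels == {
            "up_exon_150", "intron_5p_300", "intron_3p_300", "down_exon_150"
        }


class TestGcBins:
    def test_equal_occupancy(self):
        seqs = ["G" * i + "A" * (10 - i) for i in range(1, 11)]  # GC .1 … 1.0
        bins = assign_gc_bins(seqs, n_bins=5)
        assert sorted(np.bincount(bins)) == [2, 2, 2, 2, 2]

    def test_identical_gc_single_bin(self):
        bins = assign_gc_bins(["ACGT"] * 8, n_bins=5)
        assert set(bins) == {0}

    def test_fewer_sequences_than_bins(self):
        bins = assign_gc_bins(["AAAA", "ACGT", "GGGG"], n_bins=5)
        assert len(set(bins)) == 3


class TestMarkovBackground:
    def test_uniform_model_pentamer_probability(self):
        m = MarkovBackground(0, np.full(4, 0.25), np.full((4, 4), 0.25), 0)
        assert kmer_probability(m, "ACGTA") == pytest.approx(4 ** -5)

    def test_probabilities_sum_to_one(self):
        m = fit_markov([random_sequence(np.random.default_rng(1), 2000, 0.4)])
        total = all_kmer_probabilities(m).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_vectorized_matches_scalar(self):
        m = fit_markov(["ACGTACGGTTACAGTACCAGT", "GGGTTTACAGTTTT"])
        probs = all_kmer_probabilities(m)
        for i in (0, 17, 555, 1023):
            assert probs[i] == pytest.approx(kmer_probability(m, ALL_PENTAMERS[i]))

    def test_homopolymer_hand_count(self):
        """100 A's: 99 AA pairs + pseudocount over 99 + 4 smoothing."""
        m = fit_markov(["A" * 100], pseudocount=1.0)
        assert m.transitions[0, 0] == pytest.approx(100 / 103)
        p_a = 101 / 104  # (100 + 1) / (100 + 4) initial frequency
        assert kmer_probability(m, "AAAAA") == pytest.approx(
            p_a * (100 / 103) ** 4
        )

    def test_n_breaks_training_pairs(self):
        m_clean = fit_markov(["AAAA", "CCCC"])
        m_split = fit_markov(["AANNAA", "CCNNCC"])
        # N-split segments contribute the same pairs as separate sequences
        m_ref = fit_markov(["AA", "AA", "CC", "CC"])
        assert np.allclose(m_split.transitions, m_ref.transitions)
        assert not np.allclose(m_split.transitions, m_clean.transitions)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fit_markov(["N"])


class TestKmerCounting:
    def test_overlapping_windows(self):
        counts, positions = count_kmers(["ACGTACGT"])
        assert positions == 4
        assert all(v == 1 for v in counts.values())
        counts, positions = count_kmers(["AAAAAA"])
        assert counts["AAAAA"] == 2 and positions == 2

    def test_n_windows_excluded_from_both_sides(self):
        counts, positions = count_kmers(["ACGTNAAAAAA"])
        # windows touching the N are dropped from numerator and denominator
        assert positions == 2
        assert counts["AAAAA"] == 2 and len(counts) == 1


class TestBinomialAndBH:
    def test_zero_observed_p_one(self):
        assert binomial_enrichment(0, 100, 0.01) == 1.0

    def test_exact_tail(self):
        # 1 - P(0) - P(1) at n=10, p=0.01
        expected = 1 - 0.99**10 - 10 * 0.01 * 0.99**9
        assert binomial_enrichment(2, 10, 0.01) == pytest.approx(expected)

    def test_all_successes(self):
        assert binomial_enrichment(10, 10, 0.5) == pytest.approx(2.0 ** -10)

    def test_monotone_in_observed(self):
        ps = [binomial_enrichment(k, 50, 0.1) for k in range(0, 51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bad_expected_p(self):
        with pytest.raises(ValueError):
            binomial_enrichment(1, 10, 0.0)

    def test_bh_step_up(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        # independent step-up implementation
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(bh_adjust(p), adj)

    def test_bh_trivial_cases(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


class TestEnrichStratum:
    def test_expected_counts_conserved(self):
        rng = np.random.default_rng(3)
        seqs = [random_sequence(rng, 300, 0.45) for _ in range(30)]
        records = enrich_stratum(seqs, "r", "up", n_bins=3)
        positions = records[0].positions
        total_expected = sum(r.expected_p for r in records) * positions
        assert total_expected == pytest.approx(positions, rel=1e-9)

    def test_planted_motif_is_top_hit(self):
        rng = np.random.default_rng(11)
        seqs = [random_sequence(rng, 300, 0.45) for _ in range(100)]
        planted, _pos = plant_motifs(seqs, "ACGCA", 5.0, rng)
        records = enrich_stratum(planted, "r", "up")
        best = min(records, key=lambda r: (r.q_value, r.p_value))
        assert best.pentamer == "ACGCA"
        assert best.q_value <= 0.05

    def test_no_planting_controls_false_positives(self):
        rng = np.random.default_rng(12)
        seqs = [random_sequence(rng, 300, 0.45) for _ in range(100)]
        records = enrich_stratum(seqs, "r", "up")
        frac_sig = np.mean([r.q_value <= 0.05 for r in records])
        assert frac_sig <= 0.05


class TestPlantMotifs:
    def test_fold_one_no_insertions(self):
        rng = np.random.default_rng(1)
        seqs = [random_sequence(rng, 300, 0.5) for _ in range(10)]
        edited, planted = plant_motifs(seqs, "ACGTA", 1.0, rng)
        assert planted == [] and edited == seqs

    def test_fold_five_expectation(self):
        """Planted count ≈ (fold−1) × positions × P_bg, by direct counting."""
        rng = np.random.default_rng(2)
        seqs = [random_sequence(rng, 300, 0.5) for _ in range(100)]
        edited, planted = plant_motifs(seqs, "ACGCA", 5.0, rng)
        expected = 4 * 100 * 296 * kmer_probability(fit_markov(seqs), "ACGCA")
        assert len(planted) == int(round(expected))
        observed_after = count_kmers(edited)[0]["ACGCA"]
        assert observed_after >= len(planted)  # plants plus background hits

    def test_positions_inside_sequences(self):
        rng = np.random.default_rng(3)
        seqs = [random_sequence(rng, 50, 0.5) for _ in range(20)]
        edited, planted = plant_motifs(seqs, "TTTTT", 10.0, rng)
        for i, off in planted:
            assert edited[i][off : off + 5] == "TTTTT"
            assert 0 <= off <= len(seqs[i]) - 5

    def test_invalid_pentamer(self):
        from smnsplice.synthetic_data import ConfigError

        with pytest.raises(ConfigError):
            plant_motifs(["ACGTACGT"], "ACGNN", 2.0, np.random.default_rng(0))
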