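"""Retention splicing, PTC scanning, and the NMD 50-nt prediction rule."""

import numpy as np
import pytest

from smnsplice.consequence_annotation import (
    annotate_group3,
    annotate_retention,
    scan_consequence,
    splice_with_retention,
    spliced_mrna,
)
from smnsplice.genomic_model import (
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
)
from smnsplice.synthetic_data import SimConfig, simulate_genome_and_events


def two_exon_model(exon1, intron, exon2, strand="+", cds=(0, None)):
    """Build a toy genome + transcript from sense-strand piece sequences."""
    sense = exon1 + intron + exon2
    genomic = sense if strand == "+" else reverse_complement(sense)
    genome = {"chrT": genomic}
    L = len(sense)

    def place(a, b):
        if strand == "+":
            return GenomicInterval("chrT", a, b, strand)
        return GenomicInterval("chrT", L - b, L - a, strand)

    exons = (
        place(0, len(exon1)),
        place(len(exon1) + len(intron), L),
    )
    cds_start, cds_end = cds
    if cds_end is None:
        cds_end = len(exon1) + len(exon2)
    model = TranscriptModel("t", exons, cds_start, cds_end)
    return genome, model


class TestSpliceWithRetention:
    def test_retention_inserts_intron(self):
        genome, model = two_exon_model("ATGAAA", "AAA", "TAA")
        assert splice_with_retention(genome=genome, model=model,
                                     retained_intron_index=0) == "ATGAAAAAATAA"
        assert splice_with_retention(genome=genome, model=model,
                                     retained_intron_index=None) == "ATGAAATAA"

    def test_minus_strand_matches_hand_construction(self):
        genome, model = two_exon_model("ATGCCC", "GTTTAG", "TGA", strand="-")
        assert spliced_mrna(model, genome) == "ATGCCCTGA"
        assert splice_with_retention(genome=genome, model=model,
                                     retained_intron_index=0) == "ATGCCCGTTTAGTGA"

    def test_index_out_of_range(self):
        genome, model = two_exon_model("ATGAAA", "AAA", "TAA")
        with pytest.raises(IndexError):
            splice_with_retention(genome=genome, model=model,
                                  retained_intron_index=1)


class TestScanConsequence:
    def test_intronic_stop_truncates(self):
        # CDS "ATG AAA TAA" with intron "TAGTAG" retained after codon 1
        mrna = "ATG" + "TAGTAG" + "AAATAA"
        call = scan_consequence(
            mrna, cds_start=0, reference_protein_length=2,
            last_junction_pos=len(mrna), retained_intron_length=6,
        )
        assert call.ptc_present
        assert call.ptc_codon_index == 1
        assert call.truncated_protein_length == 1
        assert call.lost_cterm_length == 1

    def test_frame_preserving_intron(self):
        mrna = "ATG" + "GGCGGCGGC" + "AAATAA"  # 9 nt, no stop
        call = scan_consequence(
            mrna, cds_start=0, reference_protein_length=2,
            last_junction_pos=len(mrna), retained_intron_length=9,
        )
        assert not call.ptc_present
        assert call.frame_preserving
        assert call.nmd_candidate is False

    @pytest.mark.parametrize("junction_gap, expected", [(60, True), (10, False)])
    def test_nmd_distance_rule(self, junction_gap, expected):
        stop_free = "GGC" * 40
        mrna = "ATG" + "TAA" + stop_free
        stop_end = 6
        call = scan_consequence(
            mrna, cds_start=0, reference_protein_length=30,
            last_junction_pos=stop_end + junction_gap,
            retained_intron_length=10,
        )
        assert call.ptc_present and call.nmd_candidate is expected

    def test_nmd_monotone_in_threshold(self):
        mrna = "ATG" + "TAA" + "GGC" * 40
        flags = [
            scan_consequence(
                mrna, 0, 30, last_junction_pos=66, retained_intron_length=10,
                nmd_distance=d,
            ).nmd_candidate
            for d in (10, 30, 50, 60, 100)
        ]
        # raising the distance threshold never adds candidates
        assert flags == sorted(flags, reverse=True)

    def test_independent_codon_walk_oracle(self):
        """Full agreement with a naive codon-walk on random transcripts."""
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(200):
            mrna = "".join(rng.choice(bases, size=rng.integers(30, 120)))
            ref_len = int(rng.integers(1, 20))
            call = scan_consequence(
                mrna, 0, ref_len, last_junction_pos=len(mrna),
                retained_intron_length=int(rng.integers(1, 30)),
            )
            first_stop = None
            for i in range(0, len(mrna) - 2, 3):
                if mrna[i : i + 3] in stops:
                    first_stop = i // 3
                    break
            expect_ptc = first_stop is not None and first_stop < ref_len
            assert call.ptc_present == expect_ptc
            if expect_ptc:
                assert call.ptc_codon_index == first_stop
                assert call.truncated_protein_length == first_stop


class TestAnnotateRetention:
    def test_utr_intron_is_not_ptc(self):
        # intron after the stop codon: Vps33b-style 3' UTR retention
        exon1 = "ATGAAATAA" + "CCC"
        intron = "TAGTAGTAG"
        exon2 = "GGGG"
        genome, model = two_exon_model(exon1, intron, exon2, cds=(0, 9))
        call = annotate_retention(model, genome, 0)
        assert call.utr_retention
        assert not call.ptc_present and not call.nmd_candidate

    def test_ground_truth_recovery(self):
        cfg = SimConfig(seed=21, n_se_events=0, n_ri_events=30)
        genome, models, events, truth = simulate_genome_and_events(cfg)
        df = annotate_group3(events, models, genome)
        assert len(df) == 30
        for r in df.itertuples():
            t = truth.consequence[r.event_id]
            if t["ptc_codon_index"] is None:
                assert not r.ptc_present and r.frame_preserving
            else:
                assert r.ptc_present
                assert r.ptc_codon_index == t["ptc_codon_index"]
                assert r.truncated_protein_length == t["truncated_protein_length"]

    def test_empty_event_set(self):
        cfg = SimConfig(seed=1, n_se_events=0, n_ri_events=2)
        genome, models, _events, _truth = simulate_genome_and_events(cfg)
        df = annotate_group3([], models, genome)
        assert len(df) == 0

    def test_unmappable_event_skipped(self, caplog):
        cfg = SimConfig(seed=1, n_se_events=0, n_ri_events=2)
        genome, models, events, _truth = simulate_genome_and_events(cfg)
        from smnsplice.genomic_model import parse_miso_event

        orphan = parse_miso_event("chr1:1:10:+@chr1:21:30:+")
        df = annotate_group3([orphan], models, genome)
        assert len(df) == 0

    def test_length_conservation(self):
        cfg = SimConfig(seed=4, n_se_events=0, n_ri_events=5)
        genome, models, events, _truth = simulate_genome_and_events(cfg)
        for model in models:
            base = len(spliced_mrna(model, genome))
            for i, intron in enumerate(model.introns):
                edited = splice_with_retention(model, genome, i)
                assert len(edited) == base + len(intron)
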