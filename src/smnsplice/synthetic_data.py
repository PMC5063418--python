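"""Ground-truth simulator for the whole pipeline.

Generates a genome with SE (exon trio) and RI (exon–intron–exon) genes,
matching GTF annotation and event strings, two-condition three-replicate
junction counts with known true Ψ per condition, pentamer-planted region
sequences for the motif analysis, and ΔΔCt-style qPCR Ct tables — so every
downstream stage can be tested against known truth without any external
download.

Everything is driven by one integer seed; per-stage generators are derived
deterministically with :class:`numpy.random.SeedSequence` spawning, so
stages can be re-run independently and two runs with the same config are
byte-identical.

Default shape mirrors the experimental design being emulated: two
conditions (control vs SMN-depleted), three biological replicates, ~100
informative junction reads per event per replicate, mouse-like 45% GC
background, and |ΔΨ| = 0.5 between conditions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_model import (
    COUNTS_COLUMNS,
    GenomicInterval,
    SplicingEvent,
    TranscriptModel,
    derive_introns,
    fetch_sequence,
    format_miso_event,
    reverse_complement,
)
from .motif_enrichment import K, count_kmers, fit_markov, kmer_probability

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = sorted(
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOPS
)


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """All knobs of the simulator; ``seed`` fixes every random stream."""

    seed: int = 0
    n_se_events: int = 20
    n_ri_events: int = 10
    # None = study-shaped mixture populating all four groups: SE events
    # alternate between inclusion loss (0.75 -> 0.25) and gain, RI events
    # are mostly intron-retained on depletion (spliced fraction 0.9 -> 0.4)
    psi_control: float | Sequence[float] | None = None
    psi_depleted: float | Sequence[float] | None = None
    coverage: int = 100                      # informative reads/event/replicate
    n_replicates: int = 3
    gc_content: float = 0.45
    planted_motif: str | None = None
    plant_region: str = "up_intron_3p_300"
    plant_fold: float = 5.0
    ct_noise_sd: float = 0.1
    # gene geometry (bp); SE introns >= 600 admit the full 150/300 windows
    se_exon_length: int = 200
    cassette_length: int = 150
    se_intron_length: int = 900
    ri_intron_ptc_offset: int = 10           # codons before the planted stop
    utr_length: int = 60
    spacer_length: int = 100
    ptc_fraction: float = 0.7                # RI introns carrying an in-frame stop

    def __post_init__(self) -> None:
        if self.coverage < 0 or self.n_replicates < 1:
            raise ConfigError("coverage must be >= 0 and n_replicates >= 1")
        if not 0 < self.gc_content < 1:
            raise ConfigError("gc_content must lie in (0, 1)")
        for given in (self.psi_control, self.psi_depleted):
            if given is None:
                continue
            for psi in np.atleast_1d(given):
                if not 0 <= psi <= 1:
                    raise ConfigError(f"true psi {psi} outside [0, 1]")
        if self.plant_fold < 1:
            raise ConfigError("plant_fold must be >= 1")
        if self.planted_motif is not None and (
            len(self.planted_motif) != K
            or not set(self.planted_motif) <= set(BASES)
        ):
            raise ConfigError(
                f"planted motif {self.planted_motif!r} is not an ACGT pentamer"
            )
        if min(self.se_exon_length, self.cassette_length) < K:
            raise ConfigError("exons shorter than a pentamer are infeasible")
        if self.se_intron_length < 2:
            raise ConfigError("SE introns need length >= 2")

    def stage_rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the run seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    psi_control: dict[str, float]
    psi_depleted: dict[str, float]
    delta_psi: dict[str, float]
    consequence: dict[str, dict] = field(default_factory=dict)
    planted_positions: list[tuple[str, int]] = field(default_factory=list)
    true_folds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "psi_control": self.psi_control,
            "psi_depleted": self.psi_depleted,
            "delta_psi": self.delta_psi,
            "consequence": self.consequence,
            "planted_positions": self.planted_positions,
            "true_folds": self.true_folds,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# sequence primitives

def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def _codons(rng: np.random.Generator, n: int) -> str:
    """n stop-free codons (uniform over the 61 sense codons)."""
    return "".join(rng.choice(NONSTOP_CODONS, size=n))


# --------------------------------------------------------------------------
# gene construction

def _place(offset: int, gene_len: int, strand: str, a: int, b: int,
           chrom: str) -> GenomicInterval:
    """Map a sense-coordinate span [a, b) of a gene to genomic coordinates."""
    if strand == "+":
        return GenomicInterval(chrom, offset + a, offset + b, strand)
    return GenomicInterval(chrom, offset + gene_len - b, offset + gene_len - a,
                           strand)


def _build_se_gene(
    cfg: SimConfig, rng: np.random.Generator, chrom: str, offset: int,
    strand: str, gene_id: str,
) -> tuple[str, SplicingEvent, TranscriptModel | None]:
    gc = cfg.gc_content
    parts = [
        random_sequence(rng, cfg.se_exon_length, gc),
        random_sequence(rng, cfg.se_intron_length, gc),
        random_sequence(rng, cfg.cassette_length, gc),
        random_sequence(rng, cfg.se_intron_length, gc),
        random_sequence(rng, cfg.se_exon_length, gc),
    ]
    sense = "".join(parts)
    bounds = np.cumsum([0] + [len(p) for p in parts])
    exon_spans = [(bounds[0], bounds[1]), (bounds[2], bounds[3]),
                  (bounds[4], bounds[5])]
    exons = tuple(
        _place(offset, len(sense), strand, a, b, chrom) for a, b in exon_spans
    )
    event = SplicingEvent(
        event_id="", event_type="SE", exons=exons,
        introns=derive_introns(exons), gene=gene_id,
    )
    event = SplicingEvent(
        event_id=format_miso_event(event), event_type="SE", exons=exons,
        introns=event.introns, gene=gene_id,
    )
    genomic = sense if strand == "+" else reverse_complement(sense)
    return genomic, event, None


def _build_ri_gene(
    cfg: SimConfig, rng: np.random.Generator, chrom: str, offset: int,
    strand: str, gene_id: str, with_ptc: bool,
) -> tuple[str, SplicingEvent, TranscriptModel, dict]:
    """Three-exon gene whose first intron is the candidate retained intron.

    Retaining intron 1 leaves the exon2–exon3 junction downstream, so the
    NMD 50-nt rule has a junction to compare against.  The first in-frame
    stop codon of a PTC intron sits at a generator-known codon offset.
    """
    gc = cfg.gc_content
    u5 = cfg.utr_length
    c1 = int(rng.integers(10, 30))
    c2 = int(rng.integers(10, 30))
    c3 = int(rng.integers(10, 30))
    exon1 = random_sequence(rng, u5, gc) + "ATG" + _codons(rng, c1)
    j = cfg.ri_intron_ptc_offset
    if with_ptc:
        tail = random_sequence(rng, int(rng.integers(40, 80)), gc)
        intron1 = _codons(rng, j) + "TAA" + tail
        truth = {
            "ptc_codon_index": 1 + c1 + j,
            "truncated_protein_length": 1 + c1 + j,
            "frame_preserving": False,
        }
    else:
        m = int(rng.integers(15, 40))
        intron1 = _codons(rng, m)
        truth = {
            "ptc_codon_index": None,
            "truncated_protein_length": None,
            "frame_preserving": True,
        }
    exon2 = _codons(rng, c2)
    intron2 = random_sequence(rng, int(rng.integers(80, 160)), gc)
    exon3 = _codons(rng, c3) + "TAA" + random_sequence(rng, cfg.utr_length, gc)
    parts = [exon1, intron1, exon2, intron2, exon3]
    sense = "".join(parts)
    bounds = np.cumsum([0] + [len(p) for p in parts])
    exon_spans = [(bounds[0], bounds[1]), (bounds[2], bounds[3]),
                  (bounds[4], bounds[5])]
    exons = tuple(
        _place(offset, len(sense), strand, a, b, chrom) for a, b in exon_spans
    )
    cds_start = u5
    cds_end = u5 + 3 + 3 * (c1 + c2 + c3) + 3
    model = TranscriptModel(
        id=f"{gene_id}_t1", exons=exons,
        cds_start=cds_start, cds_end=cds_end, gene=gene_id,
    )
    ev_exons = exons[:2]
    event = SplicingEvent(
        event_id="", event_type="RI", exons=ev_exons,
        introns=derive_introns(ev_exons), gene=gene_id,
    )
    event = SplicingEvent(
        event_id=format_miso_event(event), event_type="RI", exons=ev_exons,
        introns=event.introns, gene=gene_id,
    )
    genomic = sense if strand == "+" else reverse_complement(sense)
    return genomic, event, model, truth


def _default_psi_mixture(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Study-shaped true Ψ: all four classification groups populated.

    SE events alternate between inclusion loss (G1) and gain (G2); RI
    events are mostly retained-on-depletion (G3, spliced fraction drops)
    with the remainder spliced-on-depletion (G4).
    """
    psi_c, psi_d = [], []
    for i in range(cfg.n_se_events):
        if i % 2 == 0:
            psi_c.append(0.75), psi_d.append(0.25)
        else:
            psi_c.append(0.25), psi_d.append(0.75)
    for i in range(cfg.n_ri_events):
        if i % 4 != 3:
            psi_c.append(0.90), psi_d.append(0.40)
        else:
            psi_c.append(0.40), psi_d.append(0.90)
    return np.array(psi_c), np.array(psi_d)


def simulate_genome_and_events(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], list[SplicingEvent], GroundTruth]:
    """Genome, annotation models, parseable events, and the ground truth."""
    rng = cfg.stage_rng(0)
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    events: list[SplicingEvent] = []
    models: list[TranscriptModel] = []
    consequence: dict[str, dict] = {}

    def spacer() -> None:
        nonlocal cursor
        s = random_sequence(rng, cfg.spacer_length, cfg.gc_content)
        pieces.append(s)
        cursor += len(s)

    spacer()
    for i in range(cfg.n_se_events):
        strand = "+" if rng.random() < 0.5 else "-"
        seq, event, _ = _build_se_gene(
            cfg, rng, chrom, cursor, strand, f"se_gene_{i:04d}"
        )
        pieces.append(seq)
        cursor += len(seq)
        events.append(event)
        spacer()
    for i in range(cfg.n_ri_events):
        strand = "+" if rng.random() < 0.5 else "-"
        with_ptc = rng.random() < cfg.ptc_fraction
        seq, event, model, truth = _build_ri_gene(
            cfg, rng, chrom, cursor, strand, f"ri_gene_{i:04d}", with_ptc
        )
        pieces.append(seq)
        cursor += len(seq)
        events.append(event)
        models.append(model)
        consequence[event.event_id] = truth
        spacer()
    genome = {chrom: "".join(pieces)}

    if cfg.psi_control is None or cfg.psi_depleted is None:
        psi_c, psi_d = _default_psi_mixture(cfg)
    else:
        psi_c = np.broadcast_to(np.atleast_1d(cfg.psi_control), (len(events),))
        psi_d = np.broadcast_to(np.atleast_1d(cfg.psi_depleted), (len(events),))
    truth = GroundTruth(
        psi_control={e.event_id: float(p) for e, p in zip(events, psi_c)},
        psi_depleted={e.event_id: float(p) for e, p in zip(events, psi_d)},
        delta_psi={
            e.event_id: float(d - c)
            for e, c, d in zip(events, psi_c, psi_d)
        },
        consequence=consequence,
    )
    return genome, models, events, truth


# --------------------------------------------------------------------------
# junction counts

def simulate_counts(
    events: Sequence[SplicingEvent],
    truth: GroundTruth,
    cfg: SimConfig,
    length_model: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Binomial inclusion/exclusion reads per event, condition, replicate.

    The inclusion-read probability is the length-adjusted
    θ = Ψ·l_inc / (Ψ·l_inc + (1−Ψ)·l_exc); with the default equal effective
    lengths θ = Ψ.
    """
    rng = cfg.stage_rng(1)
    rows = []
    for event in events:
        l_inc, l_exc = (length_model or {}).get(event.event_id, (1.0, 1.0))
        for condition, psi_map in (
            ("control", truth.psi_control),
            ("depleted", truth.psi_depleted),
        ):
            psi = psi_map[event.event_id]
            num = psi * l_inc
            theta = num / (num + (1 - psi) * l_exc) if (num or (1 - psi)) else 0.5
            for rep in range(1, cfg.n_replicates + 1):
                k = int(rng.binomial(cfg.coverage, theta))
                rows.append(
                    {
                        "event_id": event.event_id,
                        "condition": condition,
                        "replicate": rep,
                        "inclusion_reads": k,
                        "exclusion_reads": cfg.coverage - k,
                    }
                )
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


# --------------------------------------------------------------------------
# motif planting

def plant_motifs(
    sequences: Sequence[str],
    pentamer: str,
    fold: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Raise a pentamer's expected count to ``fold`` × its Markov expectation.

    (fold − 1) × positions × P_bg(w) copies are written at uniform random
    non-overlapping offsets (overwriting in place, so lengths and
    coordinates are unchanged).  Returns edited sequences and the
    (sequence index, offset) of every plant.
    """
    if len(pentamer) != K or not set(pentamer) <= set(BASES):
        raise ConfigError(f"pentamer {pentamer!r} must be 5 ACGT bases")
    if fold < 1:
        raise ConfigError("fold must be >= 1")
    _, positions = count_kmers(sequences)
    p_bg = kmer_probability(fit_markov(sequences), pentamer)
    n_insert = int(round((fold - 1) * positions * p_bg))
    edited = [bytearray(s, "ascii") for s in sequences]
    slots = [
        (i, off)
        for i, s in enumerate(sequences)
        for off in range(0, len(s) - K + 1)
    ]
    planted: list[tuple[int, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    order = rng.permutation(len(slots))
    for idx in order:
        if len(planted) >= n_insert:
            break
        i, off = slots[idx]
        if any(a < off + K and off < b for a, b in occupied.get(i, [])):
            continue
        edited[i][off : off + K] = pentamer.encode("ascii")
        occupied.setdefault(i, []).append((off, off + K))
        planted.append((i, off))
    return [e.decode("ascii") for e in edited], planted


def plant_in_genome(
    genome: dict[str, str],
    events: Sequence[SplicingEvent],
    region_label: str,
    pentamer: str,
    fold: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Plant a motif inside one labelled region of every given event.

    Sequence-level planting is mapped back through the strand so that
    re-extracting the region recovers the planted pentamer.  Returns the
    edited genome and genomic (chrom, position) plants.
    """
    from .motif_enrichment import region_intervals

    intervals = []
    seqs = []
    for ev in events:
        iv = region_intervals(ev)[region_label]
        intervals.append(iv)
        seqs.append(fetch_sequence(genome, iv))
    edited, planted = plant_motifs(seqs, pentamer, fold, rng)
    chrom_seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    genomic_positions = []
    for i, off in planted:
        iv = intervals[i]
        if iv.strand == "+":
            gpos = iv.start + off
            chunk = pentamer
        else:
            gpos = iv.end - off - K
            chunk = reverse_complement(pentamer)
        chrom_seqs[iv.chrom][gpos : gpos + K] = chunk.encode("ascii")
        genomic_positions.append((iv.chrom, int(gpos)))
    return {c: s.decode("ascii") for c, s in chrom_seqs.items()}, genomic_positions


# --------------------------------------------------------------------------
# qPCR Ct tables

def simulate_ct_table(
    true_folds: Mapping[str, float],
    cfg: SimConfig,
    reference_gene: str = "rna5s",
    control_condition: str = "control",
    treated_condition: str = "treated",
    baseline_ct: float = 20.0,
) -> pd.DataFrame:
    """Ct = baseline − log2(expression) + N(0, ct_noise_sd).

    Control expression is 1 for every gene; treated expression is the true
    fold.  The reference gene's fold is fixed at 1 in both conditions, so a
    noiseless table inverts exactly under ΔΔCt.
    """
    for gene, f in true_folds.items():
        if f <= 0:
            raise ConfigError(f"non-positive fold {f} for {gene}")
    rng = cfg.stage_rng(3)
    genes = [reference_gene] + sorted(g for g in true_folds if g != reference_gene)
    baselines = {g: baseline_ct + 2.0 * i for i, g in enumerate(genes)}
    rows = []
    for condition in (control_condition, treated_condition):
        for rep in range(1, cfg.n_replicates + 1):
            for gene in genes:
                if gene == reference_gene or condition == control_condition:
                    expr = 1.0
                else:
                    expr = float(true_folds[gene])
                noise = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd else 0.0
                rows.append(
                    {
                        "sample": f"{condition}_{rep}",
                        "condition": condition,
                        "gene": gene,
                        "ct": baselines[gene] - np.log2(expr) + noise,
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])


# --------------------------------------------------------------------------
# writers

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def transcript_cds_intervals(model: TranscriptModel) -> list[GenomicInterval]:
    """Genomic CDS pieces of a transcript (for GTF export)."""
    out = []
    pos = 0
    for exon in model.exons:
        lo = max(model.cds_start, pos)
        hi = min(model.cds_end, pos + len(exon))
        if lo < hi:
            if exon.strand == "+":
                out.append(GenomicInterval(
                    exon.chrom, exon.start + (lo - pos), exon.start + (hi - pos),
                    exon.strand,
                ))
            else:
                out.append(GenomicInterval(
                    exon.chrom, exon.end - (hi - pos), exon.end - (lo - pos),
                    exon.strand,
                ))
        pos += len(exon)
    return out


def write_gtf(
    models: Sequence[TranscriptModel],
    events: Sequence[SplicingEvent],
    path: str | Path,
) -> None:
    """GTF (1-based inclusive) for transcripts plus exon-only event genes."""

    def line(chrom, feature, iv, strand, gene, tx):
        return (
            f"{chrom}\tsmnsplice\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{strand}\t.\tgene_id \"{gene}\"; transcript_id \"{tx}\";\n"
        )

    with open(path, "w") as fh:
        for model in models:
            exons = sorted(model.exons, key=lambda e: e.start)
            span = GenomicInterval(
                exons[0].chrom, exons[0].start, exons[-1].end, model.strand
            )
            fh.write(line(span.chrom, "transcript", span, model.strand,
                          model.gene or model.id, model.id))
            for e in exons:
                fh.write(line(e.chrom, "exon", e, model.strand,
                              model.gene or model.id, model.id))
            for c in sorted(transcript_cds_intervals(model),
                            key=lambda i: i.start):
                fh.write(line(c.chrom, "CDS", c, model.strand,
                              model.gene or model.id, model.id))
        covered = {m.gene for m in models}
        for ev in events:
            if ev.gene in covered:
                continue
            exons = sorted(ev.exons, key=lambda e: e.start)
            tx = f"{ev.gene}_t1"
            span = GenomicInterval(
                exons[0].chrom, exons[0].start, exons[-1].end, ev.strand
            )
            fh.write(line(span.chrom, "transcript", span, ev.strand, ev.gene, tx))
            for e in exons:
                fh.write(line(e.chrom, "exon", e, ev.strand, ev.gene, tx))


def write_events(events: Sequence[SplicingEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tevent_type\tgene\n")
        for ev in events:
            fh.write(f"{ev.event_id}\t{ev.event_type}\t{ev.gene}\n")


def read_events(path: str | Path) -> list[SplicingEvent]:
    from .genomic_model import parse_miso_event

    df = pd.read_csv(path, sep="\t")
    return [
        parse_miso_event(r.event_id, gene=r.gene) for r in df.itertuples()
    ]
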