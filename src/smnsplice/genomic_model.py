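"""Coordinate system, splicing-event representation, and file I/O.

Conventions (one boundary per format, each tested by a round-trip):

* internal coordinates: 0-based half-open ``[start, end)``
* MISO-style event strings and GTF: 1-based inclusive
* BED: 0-based half-open

"Upstream"/"downstream" always mean transcript orientation.  Event strings
on the − strand print their exon blocks genomically descending, so the
first printed block is always the transcript-upstream exon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """A malformed event string, record or table."""


class BoundsError(ValueError):
    """Sequence access outside a chromosome or missing chromosome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ParseError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParseError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SplicingEvent:
    """An SE (exon trio) or RI (exon-intron-exon) alternative-splicing event.

    ``exons`` are ordered 5'→3' in transcript orientation: genomically
    ascending on +, descending on −.  ``introns`` are the gaps between
    consecutive exons, also in transcript order.
    """

    event_id: str
    event_type: str  # "SE" or "RI"
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...] = field(default=())
    gene: str | None = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def cassette(self) -> GenomicInterval:
        if self.event_type != "SE":
            raise ValueError("cassette exon is defined only for SE events")
        return self.exons[1]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain plus transcript-relative CDS coordinates.

    ``cds_start``/``cds_end`` are 0-based half-open offsets into the spliced
    mRNA; the CDS length is a positive multiple of 3 (stop codon included)
    before any retention edit.
    """

    id: str
    exons: tuple[GenomicInterval, ...]  # transcript orientation
    cds_start: int
    cds_end: int
    gene: str | None = None

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return derive_introns(self.exons)

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < self.cds_end <= self.spliced_length:
            raise ParseError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"spliced length {self.spliced_length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ParseError(f"{self.id}: CDS length not a multiple of 3")


_BLOCK_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+):(?P<end>\d+):(?P<strand>[+-])$")


def derive_introns(exons: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Gaps between consecutive transcript-ordered exons, in transcript order."""
    introns = []
    for a, b in zip(exons, exons[1:]):
        if a.strand == "+":
            lo, hi = a.end, b.start
        else:
            lo, hi = b.end, a.start
        if hi - lo < 1:
            raise ParseError(
                f"zero-length intron between exons {a} and {b}"
            )
        introns.append(GenomicInterval(a.chrom, lo, hi, a.strand))
    return tuple(introns)


def parse_miso_event(event_string: str, gene: str | None = None) -> SplicingEvent:
    """Parse an ``@``-joined ``chrom:start:end:strand`` event string.

    Printed coordinates are 1-based inclusive; 2 blocks make an RI event,
    3 blocks an SE event with the middle block as the cassette exon.
    """
    blocks = event_string.split("@")
    if len(blocks) not in (2, 3):
        raise ParseError(
            f"{event_string!r}: expected 2 or 3 blocks, got {len(blocks)}"
        )
    exons = []
    for block in blocks:
        m = _BLOCK_RE.match(block)
        if m is None:
            raise ParseError(f"malformed block {block!r} in {event_string!r}")
        start_1, end_1 = int(m["start"]), int(m["end"])
        if start_1 > end_1 or start_1 < 1:
            raise ParseError(f"block {block!r}: start >= end")
        exons.append(
            GenomicInterval(m["chrom"], start_1 - 1, end_1, m["strand"])
        )
    strands = {e.strand for e in exons}
    if len(strands) > 1:
        raise ParseError(f"{event_string!r}: mixed strands")
    if len({e.chrom for e in exons}) > 1:
        raise ParseError(f"{event_string!r}: mixed chromosomes")
    strand = exons[0].strand
    # transcript order as printed: ascending on +, descending on -
    for a, b in zip(exons, exons[1:]):
        ordered = a.end <= b.start if strand == "+" else b.end <= a.start
        if not ordered or a.overlaps(b):
            raise ParseError(
                f"{event_string!r}: blocks {a} and {b} overlap or are out of "
                "transcript order"
            )
    event_type = "SE" if len(exons) == 3 else "RI"
    return SplicingEvent(
        event_id=event_string,
        event_type=event_type,
        exons=tuple(exons),
        introns=derive_introns(exons),
        gene=gene,
    )


def format_miso_event(event: SplicingEvent) -> str:
    """Serialize back to the printed 1-based inclusive form (round-trip)."""
    return "@".join(
        f"{e.chrom}:{e.start + 1}:{e.end}:{e.strand}" for e in event.exons
    )


# --------------------------------------------------------------------------
# sequence access

def fetch_sequence(genome: Mapping[str, object], interval: GenomicInterval) -> str:
    """Strand-aware uppercase sequence of ``interval``.

    ``genome`` is any chrom → sliceable-sequence mapping (a plain dict of
    strings, or a ``pyfaidx.Fasta``).  The − strand returns the reverse
    complement of the + strand substring.
    """
    try:
        record = genome[interval.chrom]
    except KeyError:
        raise BoundsError(f"unknown chromosome {interval.chrom!r}") from None
    if interval.end > len(record):
        raise BoundsError(
            f"{interval.chrom}:{interval.start}-{interval.end} beyond "
            f"chromosome length {len(record)}"
        )
    seq = str(record[interval.start : interval.end]).upper()
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ParseError(f"invalid bases {bad} in {interval.chrom}")
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def load_genome(path: str | Path):
    """Open an indexed FASTA for random access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


# --------------------------------------------------------------------------
# annotation / BED / counts I/O

def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read transcripts (exon + CDS features) from a GTF file.

    GTF coordinates are 1-based inclusive.  CDS coordinates are converted to
    transcript-relative offsets; the stop codon is taken to be included in
    the annotated CDS span.  Transcripts without CDS features get a
    zero-length marker CDS rejected by ``TranscriptModel`` — such
    transcripts are skipped.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exon_feats = list(db.children(tx, featuretype="exon", order_by="start"))
        cds_feats = list(db.children(tx, featuretype="CDS", order_by="start"))
        if not exon_feats or not cds_feats:
            continue
        strand = tx.strand
        exons = [
            GenomicInterval(f.seqid, f.start - 1, f.end, strand)
            for f in exon_feats
        ]
        if strand == "-":
            exons = exons[::-1]  # transcript orientation
        cds_lo = min(f.start - 1 for f in cds_feats)
        cds_hi = max(f.end for f in cds_feats)
        cds_start = _genomic_to_transcript(exons, cds_lo, cds_hi, strand)[0]
        cds_end = _genomic_to_transcript(exons, cds_lo, cds_hi, strand)[1]
        gene = tx.attributes.get("gene_id", [None])[0]
        models.append(
            TranscriptModel(
                id=tx.id, exons=tuple(exons),
                cds_start=cds_start, cds_end=cds_end, gene=gene,
            )
        )
    return models


def _genomic_to_transcript(
    exons: Sequence[GenomicInterval], g_lo: int, g_hi: int, strand: str
) -> tuple[int, int]:
    """Map a genomic [g_lo, g_hi) span onto spliced-transcript offsets."""
    offsets = []
    pos = 0
    for e in exons:
        for g in (g_lo, g_hi):
            if e.start <= g <= e.end:
                if strand == "+":
                    offsets.append(pos + (g - e.start))
                else:
                    offsets.append(pos + (e.end - g))
        pos += len(e)
    if len(offsets) < 2:
        raise ParseError("CDS boundaries fall outside annotated exons")
    return min(offsets), max(offsets)


def write_bed(
    regions: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    """Write (interval, name) pairs as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for interval, name in regions:
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}\t"
                f"{name}\t0\t{interval.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"BED6 line with {len(fields)} fields: {line!r}")
            chrom, start, end, name, _score, strand = fields[:6]
            out.append(
                (GenomicInterval(chrom, int(start), int(end), strand), name)
            )
    return out


COUNTS_COLUMNS = [
    "event_id", "condition", "replicate", "inclusion_reads", "exclusion_reads",
]


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-event, per-replicate junction counts TSV.

    ``inclusion_reads`` support the Ψ-oriented isoform (exon inclusion for
    SE; intron-removed for RI); ``exclusion_reads`` the other isoform.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"counts table missing columns {missing}")
    return validate_counts(df)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("inclusion_reads", "exclusion_reads"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ParseError(f"{col} must be integer")
        if (df[col] < 0).any():
            raise ParseError(f"negative counts in {col}")
    key = ["event_id", "condition", "replicate"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key)].iloc[0]
        raise ParseError(
            f"duplicate counts row for {tuple(dup[key])}"
        )
    return df


def write_counts_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_counts(df)[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)
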