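"""Reading-frame consequences of intron retention.

A retained intron inserted into the mRNA either preserves the frame (length
divisible by 3, no in-frame stop) or introduces a premature termination
codon (PTC).  A PTC more than 50 nt upstream of the last exon–exon junction
of the edited transcript is flagged as a nonsense-mediated-decay candidate
— a prediction reported alongside the call, never used to filter, since
intron-retained transcripts in neurons are frequently stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genomic_model import SplicingEvent, TranscriptModel, fetch_sequence

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NMD_DISTANCE_NT = 50


@dataclass(frozen=True)
class ConsequenceCall:
    transcript_id: str
    retained_intron_index: int
    ptc_present: bool
    ptc_codon_index: int | None  # codon position of first in-frame stop
    truncated_protein_length: int | None  # aa before the PTC
    lost_cterm_length: int | None  # aa removed vs the reference protein
    frame_preserving: bool
    nmd_candidate: bool
    utr_retention: bool = False

    def __post_init__(self) -> None:
        if self.nmd_candidate and not self.ptc_present:
            raise ValueError("nmd_candidate requires ptc_present")
        if self.frame_preserving and self.ptc_present:
            raise ValueError("frame_preserving excludes ptc_present")


def spliced_mrna(model: TranscriptModel, genome) -> str:
    """Normal mRNA: transcript-ordered exon sequences concatenated."""
    return "".join(fetch_sequence(genome, e) for e in model.exons)


def splice_with_retention(
    model: TranscriptModel, genome, retained_intron_index: int | None
) -> str:
    """mRNA with one intron's sequence retained in place (None = no edit)."""
    introns = model.introns
    if retained_intron_index is None:
        return spliced_mrna(model, genome)
    if not 0 <= retained_intron_index < len(introns):
        raise IndexError(
            f"intron index {retained_intron_index} out of range "
            f"for {len(introns)} introns"
        )
    parts = []
    for i, exon in enumerate(model.exons):
        parts.append(fetch_sequence(genome, exon))
        if i == retained_intron_index:
            parts.append(fetch_sequence(genome, introns[i]))
    return "".join(parts)


def _first_stop(mrna: str, cds_start: int) -> int | None:
    """Codon index of the first stop when translating from cds_start."""
    for codon_index, pos in enumerate(range(cds_start, len(mrna) - 2, 3)):
        if mrna[pos : pos + 3] in STOP_CODONS:
            return codon_index
    return None


def scan_consequence(
    mrna: str,
    cds_start: int,
    reference_protein_length: int,
    last_junction_pos: int,
    retained_intron_length: int | None = None,
    transcript_id: str = "",
    retained_intron_index: int = 0,
    intron_in_utr: bool = False,
    nmd_distance: int = NMD_DISTANCE_NT,
) -> ConsequenceCall:
    """Translate the retention-edited mRNA and classify the outcome.

    ``reference_protein_length`` counts amino acids of the unedited protein
    (stop codon excluded).  ``last_junction_pos`` is the 0-based mRNA offset
    of the last exon–exon junction of the *edited* transcript.  A stop is
    premature when it falls strictly before the reference stop codon; the
    NMD rule compares the end of the stop codon with the last junction.
    """
    if cds_start >= len(mrna):
        raise ValueError("cds_start beyond mRNA length")
    stop_index = _first_stop(mrna, cds_start)
    ptc_present = stop_index is not None and stop_index < reference_protein_length
    if intron_in_utr:
        ptc_present = False
    if ptc_present:
        truncated = stop_index
        lost = reference_protein_length - truncated
        stop_end_nt = cds_start + 3 * stop_index + 3
        nmd = (last_junction_pos - stop_end_nt) > nmd_distance
        frame_preserving = False
    else:
        truncated = None
        lost = None
        nmd = False
        frame_preserving = (
            retained_intron_length is not None
            and retained_intron_length % 3 == 0
        )
    return ConsequenceCall(
        transcript_id=transcript_id,
        retained_intron_index=retained_intron_index,
        ptc_present=ptc_present,
        ptc_codon_index=stop_index if ptc_present else None,
        truncated_protein_length=truncated,
        lost_cterm_length=lost,
        frame_preserving=frame_preserving,
        nmd_candidate=nmd,
        utr_retention=intron_in_utr,
    )


def _match_transcript(
    event: SplicingEvent, models: Sequence[TranscriptModel]
) -> tuple[TranscriptModel, int] | None:
    """Longest-CDS transcript whose exon chain contains the event's intron."""
    (intron,) = event.introns
    key = (intron.chrom, intron.start, intron.end, intron.strand)
    best: tuple[TranscriptModel, int] | None = None
    for model in models:
        for idx, tx_intron in enumerate(model.introns):
            if (tx_intron.chrom, tx_intron.start, tx_intron.end,
                    tx_intron.strand) == key:
                if best is None or (
                    model.cds_end - model.cds_start
                    > best[0].cds_end - best[0].cds_start
                ):
                    best = (model, idx)
    return best


def annotate_retention(
    model: TranscriptModel,
    genome,
    retained_intron_index: int,
    nmd_distance: int = NMD_DISTANCE_NT,
) -> ConsequenceCall:
    """Consequence call for retaining one annotated intron of a transcript."""
    introns = model.introns
    intron_len = len(introns[retained_intron_index])
    mrna = splice_with_retention(model, genome, retained_intron_index)
    # transcript offset where the retained intron begins
    exon_cumsum = 0
    for e in model.exons[: retained_intron_index + 1]:
        exon_cumsum += len(e)
    intron_tx_start = exon_cumsum
    # CDS offsets shift by the intron length if the intron precedes them
    cds_start = model.cds_start
    intron_in_utr = intron_tx_start >= model.cds_end  # after the stop codon
    if intron_tx_start <= cds_start:
        cds_start += intron_len
    reference_protein_length = (model.cds_end - model.cds_start) // 3 - 1
    # last exon-exon junction of the edited transcript: the retained intron
    # fuses exons i and i+1, removing that junction
    junctions = []
    pos = 0
    for i, e in enumerate(model.exons[:-1]):
        pos += len(e)
        offset = intron_len if i >= retained_intron_index else 0
        if i != retained_intron_index:
            junctions.append(pos + offset)
    last_junction = max(junctions) if junctions else 0
    return scan_consequence(
        mrna,
        cds_start,
        reference_protein_length,
        last_junction,
        retained_intron_length=intron_len,
        transcript_id=model.id,
        retained_intron_index=retained_intron_index,
        intron_in_utr=intron_in_utr,
        nmd_distance=nmd_distance,
    )


def annotate_group3(
    events: Iterable[SplicingEvent],
    models: Sequence[TranscriptModel],
    genome,
    nmd_distance: int = NMD_DISTANCE_NT,
) -> pd.DataFrame:
    """Consequence calls for intron-retained-on-depletion (G3) events.

    Each event's intron is matched exactly against annotated introns; the
    longest CDS-bearing transcript wins.  Unmappable events are skipped
    with a warning.  Returns a table plus a ptc fraction in ``attrs``.
    """
    rows = []
    for event in events:
        hit = _match_transcript(event, models)
        if hit is None:
            log.warning("event %s matches no annotated intron; skipped",
                        event.event_id)
            continue
        model, idx = hit
        call = annotate_retention(model, genome, idx, nmd_distance=nmd_distance)
        rows.append({"event_id": event.event_id, **call.__dict__})
    df = pd.DataFrame(
        rows,
        columns=[
            "event_id", "transcript_id", "retained_intron_index",
            "ptc_present", "ptc_codon_index", "truncated_protein_length",
            "lost_cterm_length", "frame_preserving", "nmd_candidate",
            "utr_retention",
        ],
    )
    df.attrs["ptc_fraction"] = float(df["ptc_present"].mean()) if len(df) else 0.0
    return df
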