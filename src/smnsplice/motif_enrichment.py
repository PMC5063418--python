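"""Pentamer RBP-motif enrichment around differentially spliced events.

Each SE event is split into 7 transcript-oriented regions — the last 150 bp
of the upstream exon, the first and last 300 bp of the upstream intron, the
whole cassette exon, the first and last 300 bp of the downstream intron, and
the first 150 bp of the downstream exon.  RI events get the analogous
4-region partition (exon flanks plus both ends of the single intron).
Windows truncate to what is available; an intron shorter than 600 bp
contributes its disjoint first and second halves so no base is counted
twice.

Per (region label, ΔΨ direction) stratum, sequences are divided into GC
quantile bins, a smoothed first-order Markov chain is fitted per bin, and
each of the 1024 pentamers is tested for enrichment of its overlapping
occurrence count against the positions-weighted pooled Markov expectation
with a one-sided binomial test, Benjamini–Hochberg corrected within the
stratum.  Significant pentamers map to RBPs through a user-supplied
RBP → pentamer table; up- and down-regulated events are analyzed separately
and the RBPs shared by both directions are reported.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .genomic_model import GenomicInterval, SplicingEvent, fetch_sequence

log = logging.getLogger(__name__)

BASES = "ACGT"
K = 5
ALL_PENTAMERS = ["".join(p) for p in itertools.product(BASES, repeat=K)]
EXON_FLANK = 150
INTRON_FLANK = 300

SE_REGION_LABELS = (
    "up_exon_150", "up_intron_5p_300", "up_intron_3p_300",
    "cassette_exon_full", "down_intron_5p_300", "down_intron_3p_300",
    "down_exon_150",
)
RI_REGION_LABELS = (
    "up_exon_150", "intron_5p_300", "intron_3p_300", "down_exon_150",
)


# --------------------------------------------------------------------------
# region geometry

def _five_prime_window(iv: GenomicInterval, n: int) -> GenomicInterval:
    """First n bases of the interval in transcript orientation."""
    n = min(n, len(iv))
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start, iv.start + n, iv.strand)
    return GenomicInterval(iv.chrom, iv.end - n, iv.end, iv.strand)


def _three_prime_window(iv: GenomicInterval, n: int) -> GenomicInterval:
    """Last n bases of the interval in transcript orientation."""
    n = min(n, len(iv))
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.end - n, iv.end, iv.strand)
    return GenomicInterval(iv.chrom, iv.start, iv.start + n, iv.strand)


def intron_windows(
    intron: GenomicInterval, flank: int = INTRON_FLANK
) -> tuple[GenomicInterval, GenomicInterval]:
    """Transcript-5' and -3' windows of an intron, disjoint when short.

    A long intron yields its first and last ``flank`` bases; one shorter
    than 2×flank yields its first and second halves (first half gets the
    extra base when the length is odd at the 5' side boundary len//2).
    """
    if len(intron) >= 2 * flank:
        return _five_prime_window(intron, flank), _three_prime_window(intron, flank)
    half = len(intron) // 2
    return (
        _five_prime_window(intron, half),
        _three_prime_window(intron, len(intron) - half),
    )


def region_intervals(event: SplicingEvent) -> dict[str, GenomicInterval]:
    """Labelled genomic sub-intervals of an event's 7- or 4-region split."""
    if event.event_type == "SE":
        up_exon, cassette, down_exon = event.exons
        up_intron, down_intron = event.introns
        u5, u3 = intron_windows(up_intron)
        d5, d3 = intron_windows(down_intron)
        return {
            "up_exon_150": _three_prime_window(up_exon, EXON_FLANK),
            "up_intron_5p_300": u5,
            "up_intron_3p_300": u3,
            "cassette_exon_full": cassette,
            "down_intron_5p_300": d5,
            "down_intron_3p_300": d3,
            "down_exon_150": _five_prime_window(down_exon, EXON_FLANK),
        }
    if event.event_type == "RI":
        up_exon, down_exon = event.exons
        (intron,) = event.introns
        i5, i3 = intron_windows(intron)
        return {
            "up_exon_150": _three_prime_window(up_exon, EXON_FLANK),
            "intron_5p_300": i5,
            "intron_3p_300": i3,
            "down_exon_150": _five_prime_window(down_exon, EXON_FLANK),
        }
    raise ValueError(f"unknown event type {event.event_type!r}")


@dataclass(frozen=True)
class RegionSet:
    """Transcript-oriented labelled sequences around one event."""

    event_id: str
    sequences: dict[str, str]  # label -> sequence


def extract_regions(event: SplicingEvent, genome) -> RegionSet:
    seqs = {
        label: fetch_sequence(genome, iv)
        for label, iv in region_intervals(event).items()
    }
    return RegionSet(event.event_id, seqs)


# --------------------------------------------------------------------------
# GC binning and Markov background

def gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in BASES)
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


def assign_gc_bins(sequences: Sequence[str], n_bins: int = 5) -> np.ndarray:
    """GC-quantile bin id per sequence (equal-occupancy aim).

    Fewer sequences — or fewer distinct GC values — than requested bins
    collapse to the achievable number; identical GC lands in one bin.
    """
    gc = pd.Series([gc_fraction(s) for s in sequences])
    q = min(n_bins, len(gc))
    if q <= 1 or gc.nunique() == 1:
        if len(gc) and gc.nunique() == 1 and n_bins > 1:
            log.info("all %d sequences share one GC value; single bin", len(gc))
        return np.zeros(len(gc), dtype=int)
    bins = pd.qcut(gc, q=q, labels=False, duplicates="drop")
    if bins.nunique() < n_bins:
        log.info("GC bins collapsed to %d (requested %d)", bins.nunique(), n_bins)
    return bins.to_numpy(dtype=int)


@dataclass(frozen=True)
class MarkovBackground:
    """Smoothed first-order Markov chain over ACGT for one GC bin."""

    gc_bin: int
    initial: np.ndarray       # shape (4,)
    transitions: np.ndarray   # shape (4, 4), rows sum to 1
    training_positions: int


_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _clean_segments(seq: str) -> list[str]:
    """Maximal ACGT-only runs; anything else (N, ...) breaks training pairs."""
    out, cur = [], []
    for ch in seq:
        if ch in _BASE_INDEX:
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def fit_markov(
    sequences: Iterable[str], pseudocount: float = 1.0, gc_bin: int = 0
) -> MarkovBackground:
    """Fit initial and transition probabilities from adjacent-pair counts."""
    mono = np.zeros(4)
    pairs = np.zeros((4, 4))
    n_positions = 0
    for seq in sequences:
        for seg in _clean_segments(seq.upper()):
            idx = [_BASE_INDEX[c] for c in seg]
            n_positions += len(idx)
            np.add.at(mono, idx, 1)
            if len(idx) > 1:
                np.add.at(pairs, (idx[:-1], idx[1:]), 1)
    if n_positions < 2:
        raise ValueError("Markov training set must contain >= 2 usable bases")
    initial = (mono + pseudocount) / (mono.sum() + 4 * pseudocount)
    transitions = (pairs + pseudocount) / (
        pairs.sum(axis=1, keepdims=True) + 4 * pseudocount
    )
    return MarkovBackground(gc_bin, initial, transitions, n_positions)


def kmer_probability(model: MarkovBackground, kmer: str) -> float:
    idx = [_BASE_INDEX[c] for c in kmer]
    p = model.initial[idx[0]]
    for a, b in zip(idx, idx[1:]):
        p *= model.transitions[a, b]
    return float(p)


def all_kmer_probabilities(model: MarkovBackground, k: int = K) -> np.ndarray:
    """P(w) for every k-mer in lexicographic ACGT order, vectorized."""
    p = model.initial.copy()
    for _ in range(k - 1):
        # last base of each lexicographic prefix is its index mod 4
        last = np.arange(p.size) % 4
        p = (p[:, None] * model.transitions[last]).reshape(-1)
    return p


# --------------------------------------------------------------------------
# k-mer counting and the enrichment test

def count_kmers(
    sequences: Iterable[str], k: int = K
) -> tuple[Counter, int]:
    """Overlapping k-mer counts and the number of scanned (N-free) windows."""
    counts: Counter = Counter()
    positions = 0
    for seq in sequences:
        seq = seq.upper()
        for i in range(max(len(seq) - k + 1, 0)):
            w = seq[i : i + k]
            if set(w) <= set(BASES):
                counts[w] += 1
                positions += 1
    return counts, positions


def binomial_enrichment(observed: int, positions: int, expected_p: float) -> float:
    """One-sided upper-tail P(X >= observed), X ~ Binomial(positions, p)."""
    if not 0 <= observed <= positions:
        raise ValueError("observed outside [0, positions]")
    if not 0 < expected_p < 1:
        raise ValueError("expected_p must lie strictly in (0, 1)")
    return float(binom.sf(observed - 1, positions, expected_p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# the full per-stratum analysis

@dataclass(frozen=True)
class KmerEnrichment:
    pentamer: str
    region: str
    direction: str  # "up" or "down"
    observed: int
    positions: int
    expected_p: float
    p_value: float
    q_value: float


def read_motif_table(path: str | Path) -> dict[str, set[str]]:
    """TSV with columns rbp, pentamer → mapping RBP name → pentamer set."""
    df = pd.read_csv(path, sep="\t", comment="#")
    table: dict[str, set[str]] = {}
    for row in df.itertuples():
        w = str(row.pentamer).upper()
        if len(w) != K or not set(w) <= set(BASES):
            raise ValueError(f"invalid pentamer {w!r} for RBP {row.rbp}")
        table.setdefault(str(row.rbp), set()).add(w)
    return table


def enrich_stratum(
    sequences: Sequence[str],
    region: str,
    direction: str,
    n_bins: int = 5,
    pseudocount: float = 1.0,
    background_sequences: Sequence[str] | None = None,
) -> list[KmerEnrichment]:
    """Test all 1024 pentamers in one (region, direction) stratum.

    The Markov background is fitted per GC bin on the stratum's own
    sequences (self-background) unless an external control sequence set is
    supplied, in which case the GC bins and per-bin models come from the
    control set and the pooled expectation is its positions-weighted mean.
    """
    if not sequences:
        return []
    obs_counts, total_positions = count_kmers(sequences)
    if total_positions == 0:
        return []
    train = background_sequences if background_sequences is not None else sequences
    bins = assign_gc_bins(train, n_bins=n_bins)
    pooled = np.zeros(len(ALL_PENTAMERS))
    weight = 0
    for b in np.unique(bins):
        bin_train = [train[i] for i in np.where(bins == b)[0]]
        if background_sequences is None:
            _, bin_positions = count_kmers(bin_train)
        else:
            bin_positions = count_kmers(bin_train)[1]
        if bin_positions == 0:
            continue
        model = fit_markov(bin_train, pseudocount=pseudocount, gc_bin=int(b))
        pooled += bin_positions * all_kmer_probabilities(model)
        weight += bin_positions
    expected = pooled / weight
    observed = np.array([obs_counts.get(w, 0) for w in ALL_PENTAMERS])
    pvals = binom.sf(observed - 1, total_positions, expected)
    qvals = bh_adjust(pvals)
    return [
        KmerEnrichment(
            pentamer=w, region=region, direction=direction,
            observed=int(o), positions=total_positions,
            expected_p=float(e), p_value=float(p), q_value=float(q),
        )
        for w, o, e, p, q in zip(ALL_PENTAMERS, observed, expected, pvals, qvals)
    ]


def enrich(
    events_up: Sequence[SplicingEvent],
    events_down: Sequence[SplicingEvent],
    genome,
    motif_table: Mapping[str, set[str]] | None = None,
    q_cutoff: float = 0.05,
    n_bins: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Full enrichment over both ΔΨ directions.

    ``events_up``/``events_down`` are the foreground events with ΔΨ > 0 and
    ΔΨ < 0 (callers filter at BF ≥ 10 first).  Returns the per-stratum
    enrichment table and an RBP summary with per-RBP significant motif-site
    counts and the RBPs shared by both directions.
    """
    records: list[KmerEnrichment] = []
    for direction, events in (("up", events_up), ("down", events_down)):
        if not events:
            log.warning("no foreground events in %s direction; skipped", direction)
            continue
        region_seqs: dict[str, list[str]] = {}
        for ev in events:
            for label, seq in extract_regions(ev, genome).sequences.items():
                region_seqs.setdefault(label, []).append(seq)
        for label, seqs in region_seqs.items():
            records.extend(
                enrich_stratum(seqs, label, direction, n_bins=n_bins)
            )
    df = pd.DataFrame(
        [r.__dict__ for r in records],
        columns=[
            "pentamer", "region", "direction", "observed", "positions",
            "expected_p", "p_value", "q_value",
        ],
    )
    sig = df[df["q_value"] <= q_cutoff]
    summary: dict = {
        "n_significant_pentamers": int(sig["pentamer"].nunique()) if len(df) else 0,
    }
    if motif_table:
        rbp_rows = []
        for rbp, pentamers in sorted(motif_table.items()):
            hits = sig[sig["pentamer"].isin(pentamers)]
            if len(hits):
                rbp_rows.append(
                    {
                        "rbp": rbp,
                        "motif_sites": int(hits["observed"].sum()),
                        "directions": sorted(hits["direction"].unique()),
                    }
                )
        summary["rbps"] = rbp_rows
        summary["shared_rbps"] = sorted(
            r["rbp"] for r in rbp_rows if {"up", "down"} <= set(r["directions"])
        )
    return df, summary
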