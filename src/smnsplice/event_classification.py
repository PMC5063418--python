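"""Discovery/validation thresholds, four-group classification, U12 flagging.

ΔΨ is Ψ(SMN-depleted) − Ψ(control).  Ψ is oriented as exon inclusion for SE
events and as the spliced (intron-removed) fraction for RI events, so intron
retention upon depletion gives ΔΨ < 0.  The four groups:

* G1 — SE, ΔΨ < 0: exon skipped upon SMN depletion
* G2 — SE, ΔΨ > 0: exon retained (full-length favoured) upon depletion
* G3 — RI, ΔΨ < 0: intron retained upon depletion
* G4 — RI, ΔΨ > 0: intron retained at normal SMN (spliced out on depletion)

Discovery keeps BF ≥ 5 (boundary inclusive); validation is strict:
SE needs |ΔΨ| > 0.5 and BF > 10, RI needs BF > 5.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genomic_model import GenomicInterval, SplicingEvent, read_bed
from .psi_inference import PsiCall

BF_DISCOVERY = 5.0
BF_VALIDATION_SE = 10.0
DELTA_PSI_VALIDATION = 0.5
BF_VALIDATION_RI = 5.0


class GroupLabel(str, enum.Enum):
    G1_exon_skipped_on_depletion = "G1_exon_skipped_on_depletion"
    G2_exon_retained_on_depletion = "G2_exon_retained_on_depletion"
    G3_intron_retained_on_depletion = "G3_intron_retained_on_depletion"
    G4_intron_retained_at_normal_smn = "G4_intron_retained_at_normal_smn"
    unchanged = "unchanged"


def assign_group(event_type: str, delta_psi: float) -> GroupLabel:
    if not -1.0 <= delta_psi <= 1.0:
        raise ValueError(f"delta_psi {delta_psi} outside [-1, 1]")
    if delta_psi == 0:
        return GroupLabel.unchanged
    if event_type == "SE":
        return (
            GroupLabel.G1_exon_skipped_on_depletion
            if delta_psi < 0
            else GroupLabel.G2_exon_retained_on_depletion
        )
    if event_type == "RI":
        return (
            GroupLabel.G3_intron_retained_on_depletion
            if delta_psi < 0
            else GroupLabel.G4_intron_retained_at_normal_smn
        )
    raise ValueError(f"unknown event type {event_type!r}")


def filter_discovery(
    calls: Sequence[PsiCall], bf_cutoff: float = BF_DISCOVERY
) -> list[PsiCall]:
    """Keep calls with BF ≥ cutoff (inclusive boundary)."""
    return [c for c in calls if c.bayes_factor >= bf_cutoff]


def filter_validation(
    call: PsiCall,
    q_value: float | None = None,
    q_cutoff: float | None = None,
) -> bool:
    """Strict validation predicate; optional extra FDR predicate.

    SE: |ΔΨ| > 0.5 and BF > 10.  RI: BF > 5.  If a ``q_value`` column is
    supplied together with ``q_cutoff``, q < cutoff is additionally required
    (off by default).
    """
    if call.event_type == "SE":
        ok = (
            abs(call.delta_psi) > DELTA_PSI_VALIDATION
            and call.bayes_factor > BF_VALIDATION_SE
        )
    elif call.event_type == "RI":
        ok = call.bayes_factor > BF_VALIDATION_RI
    else:
        raise ValueError(f"unknown event type {call.event_type!r}")
    if ok and q_cutoff is not None and q_value is not None:
        ok = q_value < q_cutoff
    return ok


@dataclass(frozen=True)
class U12Flag:
    event_id: str
    is_u12: bool


def flag_u12(
    events: Iterable[SplicingEvent],
    u12_introns: Iterable[GenomicInterval] | str | Path,
) -> list[U12Flag]:
    """Exact-interval membership of any event intron in the U12 list."""
    if isinstance(u12_introns, (str, Path)):
        u12_introns = [iv for iv, _name in read_bed(u12_introns)]
    u12_set = {
        (iv.chrom, iv.start, iv.end, iv.strand) for iv in u12_introns
    }
    flags = []
    for ev in events:
        hit = any(
            (i.chrom, i.start, i.end, i.strand) in u12_set for i in ev.introns
        )
        flags.append(U12Flag(ev.event_id, hit))
    return flags


def classify_calls(
    calls: Sequence[PsiCall],
    bf_discovery: float = BF_DISCOVERY,
    u12_flags: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Classified table: group label, discovery/validation flags, U12."""
    from .psi_inference import calls_to_frame

    df = calls_to_frame(list(calls))
    df["group"] = [
        assign_group(c.event_type, c.delta_psi).value for c in calls
    ]
    df["passes_discovery"] = [
        c.bayes_factor >= bf_discovery for c in calls
    ]
    df["passes_validation"] = [filter_validation(c) for c in calls]
    df["is_u12"] = [
        (u12_flags or {}).get(c.event_id, False) for c in calls
    ]
    return df


def group_summary(classified: pd.DataFrame) -> dict[str, int]:
    kept = classified[classified["passes_discovery"]]
    counts = kept["group"].value_counts().to_dict()
    return {
        "n_discovery": int(len(kept)),
        "n_validation": int(kept["passes_validation"].sum()),
        "n_u12": int(kept["is_u12"].sum()),
        "per_group": {g.value: int(counts.get(g.value, 0)) for g in GroupLabel},
    }


# --------------------------------------------------------------------------
# packaged corpus: curated SE/RI differential-splicing calls from an
# SMN-depletion RNA-seq screen in motor-neuron-like NSC-34 cells
# (mm9 coordinates), grouped by published category.

CATEGORY_TO_GROUP = {
    "exon_skipping": GroupLabel.G1_exon_skipped_on_depletion,
    "exon_retention": GroupLabel.G2_exon_retained_on_depletion,
    "intron_skipping": GroupLabel.G4_intron_retained_at_normal_smn,
    "intron_retention": GroupLabel.G3_intron_retained_on_depletion,
}


def load_reference_event_tables() -> pd.DataFrame:
    """The packaged NSC-34 SMN-depletion event corpus.

    Columns: category, gene, delta_psi, bayes_factor, event, event_type.
    """
    ref = importlib.resources.files("smnsplice") / "data" / "smn_event_tables.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["event_type"] = [
        "SE" if cat.startswith("exon") else "RI" for cat in df["category"]
    ]
    return df
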