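"""Stage orchestration: simulate → infer → classify → enrich → consequences → quant.

Each stage reads only its predecessor's files, writes TSV/JSON outputs into
the run directory, and records itself in ``manifest.json`` (parameters,
seed, sha256 checksums), so any stage can be re-run in isolation and two
runs with the same seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import consequence_annotation, event_classification, motif_enrichment
from . import genomic_model as gm
from . import psi_inference, quantification_utils, synthetic_data

log = logging.getLogger(__name__)

STAGES = ("simulate", "infer", "classify", "enrich", "consequences", "quant")


@dataclass
class PipelineConfig:
    out_dir: str = "smnsplice_run"
    seed: int = 0
    # inputs; empty string means "use the simulate stage's output"
    genome: str = ""
    annotation: str = ""
    counts: str = ""
    events: str = ""
    motif_table: str = ""
    u12_bed: str = ""
    ct_table: str = ""
    # thresholds (per the validated study design)
    bf_discovery: float = 5.0
    bf_validation_se: float = 10.0
    delta_psi_validation: float = 0.5
    bf_validation_ri: float = 5.0
    bf_motif: float = 10.0
    q_cutoff: float = 0.05
    min_reads: int = 20
    gc_bins: int = 5
    nmd_distance: int = 50
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)

    def __post_init__(self) -> None:
        for name in ("bf_discovery", "bf_validation_se", "bf_validation_ri",
                     "bf_motif", "q_cutoff", "delta_psi_validation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.min_reads < 0 or self.gc_bins < 1 or self.nmd_distance < 0:
            raise ValueError("min_reads/gc_bins/nmd_distance out of range")
        self.sim.seed = self.seed

    def path(self, name: str) -> Path:
        return Path(self.out_dir) / name


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(cfg: PipelineConfig, stage: str, outputs: list[Path]) -> None:
    # timings go to the log, not the manifest, so manifests are reproducible
    manifest_path = cfg.path("manifest.json")
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists()
        else {"seed": cfg.seed, "parameters": _params(cfg), "stages": []}
    )
    manifest["stages"] = [s for s in manifest["stages"] if s["stage"] != stage]
    manifest["stages"].append(
        {
            "stage": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    )
    manifest["stages"].sort(key=lambda s: STAGES.index(s["stage"]))
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _params(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["sim"] = asdict(cfg.sim)
    return d


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    sim = cfg.sim
    genome, models, events, truth = synthetic_data.simulate_genome_and_events(sim)
    up_events = [
        e for e in events
        if truth.delta_psi[e.event_id] > 0 and e.event_type == "SE"
    ]
    if sim.planted_motif and up_events:
        genome, positions = synthetic_data.plant_in_genome(
            genome, up_events, sim.plant_region, sim.planted_motif,
            sim.plant_fold, sim.stage_rng(2),
        )
        truth.planted_positions = positions
    counts = synthetic_data.simulate_counts(events, truth, sim)
    truth.true_folds = {"target_a": 0.3, "target_b": 2.0, "target_c": 1.0}
    ct = synthetic_data.simulate_ct_table(truth.true_folds, sim)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synthetic_data.write_fasta(genome, out / "genome.fa")
    synthetic_data.write_gtf(models, events, out / "annotation.gtf")
    synthetic_data.write_events(events, out / "events.tsv")
    gm.write_counts_table(counts, out / "counts.tsv")
    ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
    # a small U12 list: the first two RI-event introns
    ri = [e for e in events if e.event_type == "RI"][:2]
    gm.write_bed(
        [(e.introns[0], f"u12_{i}") for i, e in enumerate(ri)],
        out / "u12.bed",
    )
    return [
        out / n
        for n in ("genome.fa", "annotation.gtf", "events.tsv", "counts.tsv",
                  "ct_table.tsv", "ground_truth.json", "u12.bed")
    ]


def _input(cfg: PipelineConfig, override: str, default_name: str) -> Path:
    path = Path(override) if override else cfg.path(default_name)
    if not path.exists():
        raise FileNotFoundError(f"required input {path} is missing")
    return path


def stage_infer(cfg: PipelineConfig) -> list[Path]:
    counts = gm.read_counts_table(_input(cfg, cfg.counts, "counts.tsv"))
    events = synthetic_data.read_events(_input(cfg, cfg.events, "events.tsv"))
    calls = psi_inference.call_events(
        counts,
        {e.event_id: e.event_type for e in events},
        min_reads=cfg.min_reads,
    )
    df = psi_inference.calls_to_frame(calls)
    out = cfg.path("calls.tsv")
    df.to_csv(out, sep="\t", index=False, float_format="%.6g")
    return [out]


def _calls_from_frame(df: pd.DataFrame) -> list[psi_inference.PsiCall]:
    calls = []
    for r in df.itertuples():
        calls.append(
            psi_inference.PsiCall(
                event_id=r.event_id,
                event_type=r.event_type,
                psi_control=psi_inference.PsiPosterior(
                    "control", r.psi_control, r.psi_control_lo, r.psi_control_hi
                ),
                psi_depleted=psi_inference.PsiPosterior(
                    "depleted", r.psi_depleted, r.psi_depleted_lo,
                    r.psi_depleted_hi,
                ),
                bayes_factor=float(r.bayes_factor),
                low_coverage=bool(r.low_coverage),
            )
        )
    return calls


def stage_classify(cfg: PipelineConfig) -> list[Path]:
    df = pd.read_csv(cfg.path("calls.tsv"), sep="\t")
    calls = _calls_from_frame(df)
    events = synthetic_data.read_events(_input(cfg, cfg.events, "events.tsv"))
    u12_path = _input(cfg, cfg.u12_bed, "u12.bed")
    flags = {
        f.event_id: f.is_u12
        for f in event_classification.flag_u12(events, u12_path)
    }
    classified = event_classification.classify_calls(
        calls, bf_discovery=cfg.bf_discovery, u12_flags=flags
    )
    out = cfg.path("classified.tsv")
    classified.to_csv(out, sep="\t", index=False, float_format="%.6g")
    summary = event_classification.group_summary(classified)
    cfg.path("classification_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return [out, cfg.path("classification_summary.json")]


def stage_enrich(cfg: PipelineConfig) -> list[Path]:
    classified = pd.read_csv(cfg.path("classified.tsv"), sep="\t")
    events = {
        e.event_id: e
        for e in synthetic_data.read_events(_input(cfg, cfg.events, "events.tsv"))
    }
    genome = gm.load_genome(_input(cfg, cfg.genome, "genome.fa"))
    fg = classified[classified["bayes_factor"] >= cfg.bf_motif]
    ups = [events[i] for i in fg[fg["delta_psi"] > 0]["event_id"]]
    downs = [events[i] for i in fg[fg["delta_psi"] < 0]["event_id"]]
    if cfg.motif_table:
        motif_table = motif_enrichment.read_motif_table(cfg.motif_table)
    else:
        ref = (importlib.resources.files("smnsplice") / "data"
               / "rbp_pentamers_example.tsv")
        with importlib.resources.as_file(ref) as path:
            motif_table = motif_enrichment.read_motif_table(path)
    enr, summary = motif_enrichment.enrich(
        ups, downs, genome, motif_table,
        q_cutoff=cfg.q_cutoff, n_bins=cfg.gc_bins,
    )
    out = cfg.path("enrichment.tsv")
    enr.to_csv(out, sep="\t", index=False, float_format="%.6g")
    cfg.path("rbp_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    regions = [
        (iv, f"{label}")
        for ev in (*ups, *downs)
        for label, iv in motif_enrichment.region_intervals(ev).items()
    ]
    gm.write_bed(regions, cfg.path("regions.bed"))
    return [out, cfg.path("rbp_summary.json"), cfg.path("regions.bed")]


def stage_consequences(cfg: PipelineConfig) -> list[Path]:
    classified = pd.read_csv(cfg.path("classified.tsv"), sep="\t")
    events = {
        e.event_id: e
        for e in synthetic_data.read_events(_input(cfg, cfg.events, "events.tsv"))
    }
    genome = gm.load_genome(_input(cfg, cfg.genome, "genome.fa"))
    models = gm.read_annotation(_input(cfg, cfg.annotation, "annotation.gtf"))
    g3 = classified[
        classified["group"]
        == event_classification.GroupLabel.G3_intron_retained_on_depletion.value
    ]
    df = consequence_annotation.annotate_group3(
        [events[i] for i in g3["event_id"]], models, genome,
        nmd_distance=cfg.nmd_distance,
    )
    out = cfg.path("consequences.tsv")
    df.to_csv(out, sep="\t", index=False)
    return [out]


def stage_quant(cfg: PipelineConfig) -> list[Path]:
    ct = pd.read_csv(_input(cfg, cfg.ct_table, "ct_table.tsv"), sep="\t")
    reference = "rna5s"
    targets = sorted(set(ct["gene"]) - {reference})
    frames = [
        quantification_utils.delta_delta_ct(ct, t, reference, "control")
        for t in targets
    ]
    out = cfg.path("fold_changes.tsv")
    pd.concat(frames, ignore_index=True).to_csv(
        out, sep="\t", index=False, float_format="%.6g"
    )
    return [out]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "infer": stage_infer,
    "classify": stage_classify,
    "enrich": stage_enrich,
    "consequences": stage_consequences,
    "quant": stage_quant,
}


def run_stage(stage: str, cfg: PipelineConfig) -> list[Path]:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    t0 = time.monotonic()
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    outputs = _STAGE_FUNCS[stage](cfg)
    elapsed = time.monotonic() - t0
    _record(cfg, stage, outputs)
    log.info("stage %s finished in %.2fs", stage, elapsed)
    return outputs


def run_all(cfg: PipelineConfig) -> dict:
    for stage in STAGES:
        run_stage(stage, cfg)
    return json.loads(cfg.path("manifest.json").read_text())
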