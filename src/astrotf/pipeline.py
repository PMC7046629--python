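"""End-to-end orchestration: normalize -> gate -> DE -> DEGs -> pool ->
enrich -> classify TFs -> predict targets, with a structured config, stage
outputs on disk and a machine-readable run report.

The in-memory entry point is :func:`analyze`; the file-based stages wrap it
for the CLI.  Every threshold actually applied is echoed into the report so
there are no silent defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .discovery import (find_region_tfs, find_universal_tfs, region_calls_frame,
                        select_top_tf, universal_calls_frame)
from .evaluate import (deg_recovery, region_tf_recovery, target_recovery,
                       universal_recovery)
from .expression import (CountMatrix, call_degs, deg_direction_fractions, deg_sets,
                         normalize_rpm, pool_degs, sample_pca)
from .motifs import Pwm, library_hits, parse_homer_motifs
from .promoters import extract_promoters, read_bed6, write_bed6
from .simulate import GroundTruth, SimConfig, simulate_dataset, write_dataset
from .targets import (predict_targets, primer_windows, primer_windows_bed,
                      primer_windows_fasta, targets_frame)

log = logging.getLogger("astrotf")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""


class PipelineConfig(BaseModel):
    """Paths, thresholds and mode flags for a pipeline run.

    All thresholds default to the study's printed values: DEGs need
    |FC| > 1.5 at p < 0.01 behind an RPM > 5 gate in >= 2 replicates;
    region TFs need FC > 2 at p < 0.01; targets need FC > 2.5 at p < 0.01
    with a zero-mismatch motif within 2 kb of the TSS; universal motifs
    need presence in >= 50% of every region's DEGs.
    """

    # paths (any may be filled in by the simulate stage)
    counts: Optional[str] = None
    samples: Optional[str] = None
    genome: Optional[str] = None
    tss: Optional[str] = None
    motifs: Optional[str] = None
    motif_tf_map: Optional[str] = None
    ground_truth: Optional[str] = None
    outdir: str = "results/run"

    # thresholds
    deg_fc: float = 1.5
    deg_p: float = 0.01
    rpm: float = 5.0
    min_reps: int = 2
    tf_fc: float = 2.0
    tf_p: float = 0.01
    target_fc: float = 2.5
    target_p: Optional[float] = 0.01      # None = fold-change-only rule
    freq_min: float = 0.5
    enrich_p: float = 0.01
    window_enrich: int = 2000
    window_freq: int = 10000

    # mode flags
    scan_mode: Literal["consensus", "pwm"] = "consensus"
    use_bh: bool = True
    up_only: bool = True
    compute_wide_profile: bool = True

    seed: int = 42
    sim: dict = Field(default_factory=dict)   # SimConfig overrides for `simulate`

    @field_validator("deg_fc", "deg_p", "rpm", "tf_fc", "tf_p", "target_fc",
                     "freq_min", "enrich_p")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be positive")
        return v

    @field_validator("window_enrich", "window_freq", "min_reps")
    @classmethod
    def _positive_int(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def threshold_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("deg_fc", "deg_p", "rpm", "min_reps", "tf_fc", "tf_p", "target_fc",
                 "target_p", "freq_min", "enrich_p", "window_enrich", "window_freq")}


class RunReport(BaseModel):
    """Machine-readable summary of one pipeline run (no timestamps, so two
    identical runs produce byte-identical reports)."""

    tool_version: str
    python_version: str
    seed: int
    scan_mode: str
    use_bh: bool
    thresholds: dict
    stages: list[str]
    deg_counts: dict[str, int]
    deg_direction: dict[str, dict]
    pooled_raw: int
    pooled_dedup: int
    pca_variance_fractions: list[float]
    universal_tfs: list[dict]
    region_tf_calls: dict[str, int]
    region_top_tfs: dict[str, Optional[str]]
    target_counts: dict[str, int]
    ground_truth_comparison: Optional[dict] = None


def report_schema() -> dict:
    return RunReport.model_json_schema()


@dataclass
class PipelineResult:
    cm: CountMatrix
    rpm: pd.DataFrame
    deg_table: pd.DataFrame
    deg_sets: dict
    pooled: list
    pooled_raw: int
    universal_calls: list
    region_calls: dict
    targets_by_region: dict
    pca_coords: pd.DataFrame
    pca_fractions: list
    promoters: object
    contigs: dict
    motifs: list
    report: RunReport | None = None


def analyze(cm: CountMatrix, contigs: dict, tss_bed: pd.DataFrame, motifs: list[Pwm],
            cfg: PipelineConfig, truth: GroundTruth | None = None) -> PipelineResult:
    """Run the full analysis chain in memory and assemble the run report."""
    rpm = normalize_rpm(cm)
    deg_table = call_degs(cm, fc_threshold=cfg.deg_fc, p_threshold=cfg.deg_p,
                          rpm_threshold=cfg.rpm, min_reps=cfg.min_reps)
    sets = deg_sets(deg_table)
    pooled, raw, dedup = pool_degs(sets)

    promoters = extract_promoters(contigs, tss_bed, half_width=cfg.window_enrich)
    promoters_wide = None
    if cfg.compute_wide_profile and cfg.window_freq != cfg.window_enrich:
        promoters_wide = extract_promoters(contigs, tss_bed, half_width=cfg.window_freq)
    hits = library_hits(motifs, promoters, mode=cfg.scan_mode)

    universal_calls = []
    if pooled:
        universal_calls = find_universal_tfs(
            pooled, sets, motifs, promoters, cm, rpm, mode=cfg.scan_mode,
            enrich_p=cfg.enrich_p, use_bh=cfg.use_bh, freq_min=cfg.freq_min,
            rpm_threshold=cfg.rpm, min_reps=cfg.min_reps,
            promoters_wide=promoters_wide, hits=hits)
    region_calls = find_region_tfs(
        deg_table, sets, motifs, promoters, cm, rpm, mode=cfg.scan_mode,
        enrich_p=cfg.enrich_p, use_bh=cfg.use_bh, tf_fc=cfg.tf_fc, tf_p=cfg.tf_p,
        rpm_threshold=cfg.rpm, min_reps=cfg.min_reps, hits=hits)

    by_name = {m.name: m for m in motifs}
    targets_by_region = {}
    for region, calls in region_calls.items():
        top = select_top_tf(calls)
        if top is None:
            targets_by_region[region] = []
            continue
        targets_by_region[region] = predict_targets(
            top.tf_gene, by_name[top.motif], region, deg_table, promoters,
            fc_threshold=cfg.target_fc, p_threshold=cfg.target_p,
            up_only=cfg.up_only, hits=hits[top.motif])

    coords, fractions = sample_pca(rpm)

    direction = {row["region"]: {k: row[k] for k in
                                 ("n_degs", "n_up", "n_down", "frac_up", "frac_down")}
                 for _, row in deg_direction_fractions(deg_table).iterrows()}
    gt_cmp = None
    if truth is not None:
        gt_cmp = {
            "deg_jaccard": deg_recovery(truth, sets),
            "universal": universal_recovery(truth, universal_calls),
            "region_tfs": region_tf_recovery(truth, region_calls),
            "targets": target_recovery(truth, targets_by_region),
        }
    report = RunReport(
        tool_version=__version__,
        python_version=platform.python_version(),
        seed=cfg.seed,
        scan_mode=cfg.scan_mode,
        use_bh=cfg.use_bh,
        thresholds=cfg.threshold_dict(),
        stages=["normalize", "gate", "de", "degs", "pool", "enrich", "classify",
                "targets"],
        deg_counts={r: len(s) for r, s in sets.items()},
        deg_direction=direction,
        pooled_raw=raw,
        pooled_dedup=dedup,
        pca_variance_fractions=[float(f) for f in fractions],
        universal_tfs=[{
            "tf_gene": c.tf_gene, "motif": c.motif, "pvalue": c.pvalue,
            "padj": c.padj,
            "min_region_frequency": min(c.region_frequency.values()),
            "region_frequency": c.region_frequency,
            "region_frequency_10kb": c.region_frequency_wide,
        } for c in universal_calls],
        region_tf_calls={r: len(c) for r, c in region_calls.items()},
        region_top_tfs={r: (select_top_tf(c).tf_gene if c else None)
                        for r, c in region_calls.items()},
        target_counts={r: len(t) for r, t in targets_by_region.items()},
        ground_truth_comparison=gt_cmp,
    )
    return PipelineResult(
        cm=cm, rpm=rpm, deg_table=deg_table, deg_sets=sets, pooled=pooled,
        pooled_raw=raw, universal_calls=universal_calls, region_calls=region_calls,
        targets_by_region=targets_by_region, pca_coords=coords,
        pca_fractions=list(fractions), promoters=promoters, contigs=contigs,
        motifs=motifs, report=report,
    )


# ---------------------------------------------------------------------------
# File-based stages


def _require(cfg: PipelineConfig, *names: str) -> None:
    for name in names:
        path = getattr(cfg, name)
        if path is None or not os.path.exists(path):
            raise PipelineError(f"required input {name!r} missing"
                                f"{': ' + str(path) if path else ''}")


def _load_inputs(cfg: PipelineConfig):
    _require(cfg, "counts", "samples", "genome", "tss", "motifs")
    cm = CountMatrix.from_tsv(cfg.counts, cfg.samples)
    from .promoters import _load_contigs
    contigs = _load_contigs(cfg.genome)
    bed = read_bed6(cfg.tss)
    tf_map: dict = {}
    if cfg.motif_tf_map and os.path.exists(cfg.motif_tf_map):
        mapping = pd.read_csv(cfg.motif_tf_map, sep="\t")
        for motif, group in mapping.groupby("motif"):
            tfs = list(group["tf_gene"])
            tf_map[motif] = tfs[0] if len(tfs) == 1 else tfs
    with open(cfg.motifs) as fh:
        motifs = parse_homer_motifs(fh.read(), tf_map=tf_map)
    truth = None
    if cfg.ground_truth and os.path.exists(cfg.ground_truth):
        truth = GroundTruth.from_json(cfg.ground_truth)
    return cm, contigs, bed, motifs, truth


def stage_simulate(cfg: PipelineConfig) -> PipelineConfig:
    """Generate the synthetic dataset and point the config paths at it."""
    sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
    simdir = os.path.join(cfg.outdir, "sim")
    cm, annotation, contigs, motifs, truth = simulate_dataset(sim_cfg)
    paths = write_dataset(simdir, sim_cfg, cm, annotation, contigs, motifs, truth)
    updates = {"counts": paths["counts"], "samples": paths["samples"],
               "genome": paths["genome"], "tss": paths["tss"],
               "motifs": paths["motifs"], "motif_tf_map": paths["motif_tf_map"],
               "ground_truth": paths["ground_truth"]}
    log.info("simulated dataset written to %s", simdir)
    return cfg.model_copy(update=updates)


def _run_and_write(cfg: PipelineConfig) -> PipelineResult:
    cm, contigs, bed, motifs, truth = _load_inputs(cfg)
    result = analyze(cm, contigs, bed, motifs, cfg, truth=truth)
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)

    result.deg_table.to_csv(os.path.join(outdir, "deg_table.tsv"), sep="\t", index=False)
    result.pca_coords.to_csv(os.path.join(outdir, "pca.tsv"), sep="\t",
                             index_label="sample")
    universal_calls_frame(result.universal_calls).to_csv(
        os.path.join(outdir, "universal_tfs.tsv"), sep="\t", index=False)
    region_calls_frame(result.region_calls).to_csv(
        os.path.join(outdir, "region_tfs.tsv"), sep="\t", index=False)
    all_targets = [t for ts in result.targets_by_region.values() for t in ts]
    targets_frame(all_targets).to_csv(os.path.join(outdir, "targets.tsv"),
                                      sep="\t", index=False)
    windows = primer_windows(all_targets, result.promoters, contigs)
    if windows:
        write_bed6(primer_windows_bed(windows),
                   os.path.join(outdir, "primer_windows.bed"))
        primer_windows_fasta(windows, os.path.join(outdir, "primer_windows.fa"))

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        fh.write(result.report.model_dump_json(indent=1))
    with open(os.path.join(outdir, "report.schema.json"), "w") as fh:
        json.dump(report_schema(), fh, indent=1, sort_keys=True)
    return result


def run_pipeline(cfg: PipelineConfig, simulate_first: bool = False) -> PipelineResult:
    """Run every stage; any failure aborts with the stage name and cause."""
    os.makedirs(cfg.outdir, exist_ok=True)
    stage = "simulate" if simulate_first or cfg.counts is None else "inputs"
    try:
        if stage == "simulate":
            cfg = stage_simulate(cfg)
        stage = "analysis"
        result = _run_and_write(cfg)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    log.info("pipeline complete; report at %s", os.path.join(cfg.outdir, "report.json"))
    return result


def _deg_table_path(cfg: PipelineConfig) -> str:
    return os.path.join(cfg.outdir, "deg_table.tsv")


def _read_deg_table(cfg: PipelineConfig) -> pd.DataFrame:
    path = _deg_table_path(cfg)
    if not os.path.exists(path):
        raise PipelineError(f"DEG table not found at {path}; run `degs` first")
    return pd.read_csv(path, sep="\t")


def stage_degs(cfg: PipelineConfig) -> pd.DataFrame:
    """DEG calling + PCA QC, written to the output directory."""
    _require(cfg, "counts", "samples")
    cm = CountMatrix.from_tsv(cfg.counts, cfg.samples)
    deg_table = call_degs(cm, fc_threshold=cfg.deg_fc, p_threshold=cfg.deg_p,
                          rpm_threshold=cfg.rpm, min_reps=cfg.min_reps)
    os.makedirs(cfg.outdir, exist_ok=True)
    deg_table.to_csv(_deg_table_path(cfg), sep="\t", index=False)
    rpm = normalize_rpm(cm)
    coords, fractions = sample_pca(rpm)
    coords.to_csv(os.path.join(cfg.outdir, "pca.tsv"), sep="\t", index_label="sample")
    sets = deg_sets(deg_table)
    pooled, raw, dedup = pool_degs(sets)
    summary = {
        "deg_counts": {r: len(s) for r, s in sets.items()},
        "pooled_raw": raw, "pooled_dedup": dedup,
        "direction": deg_direction_fractions(deg_table).to_dict(orient="records"),
        "pca_variance_fractions": [float(f) for f in fractions],
    }
    with open(os.path.join(cfg.outdir, "deg_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return deg_table


def stage_enrich(cfg: PipelineConfig) -> pd.DataFrame:
    """Per-motif enrichment table for each region's DEGs and the pooled list."""
    from .discovery import _enrich_library, expressed_background

    deg_table = _read_deg_table(cfg)
    cm, contigs, bed, motifs, _ = _load_inputs(cfg)
    rpm = normalize_rpm(cm)
    promoters = extract_promoters(contigs, bed, half_width=cfg.window_enrich)
    hits = library_hits(motifs, promoters, mode=cfg.scan_mode)
    background = expressed_background(cm, rpm, promoters, cfg.rpm, cfg.min_reps)
    sets = deg_sets(deg_table)
    pooled, _, _ = pool_degs(sets)
    rows = []
    for label, genes in [("pooled", pooled)] + list(sets.items()):
        fg = [g for g in genes if g in set(background)]
        if not fg:
            continue
        for res in _enrich_library(motifs, fg, background, promoters,
                                   cfg.scan_mode, None, hits):
            rows.append({"gene_set": label, "motif": res.motif, "pvalue": res.pvalue,
                         "padj": res.padj, "k": res.k, "n": res.n, "K": res.K,
                         "N": res.N, "fold": res.fold})
    table = pd.DataFrame(rows)
    os.makedirs(cfg.outdir, exist_ok=True)
    table.to_csv(os.path.join(cfg.outdir, "enrichment.tsv"), sep="\t", index=False)
    return table


def stage_discover(cfg: PipelineConfig):
    """Universal and region-specific TF classification from existing DEG calls."""
    deg_table = _read_deg_table(cfg)
    cm, contigs, bed, motifs, _ = _load_inputs(cfg)
    rpm = normalize_rpm(cm)
    promoters = extract_promoters(contigs, bed, half_width=cfg.window_enrich)
    promoters_wide = None
    if cfg.compute_wide_profile and cfg.window_freq != cfg.window_enrich:
        promoters_wide = extract_promoters(contigs, bed, half_width=cfg.window_freq)
    hits = library_hits(motifs, promoters, mode=cfg.scan_mode)
    sets = deg_sets(deg_table)
    pooled, _, _ = pool_degs(sets)
    universal = []
    if pooled:
        universal = find_universal_tfs(
            pooled, sets, motifs, promoters, cm, rpm, mode=cfg.scan_mode,
            enrich_p=cfg.enrich_p, use_bh=cfg.use_bh, freq_min=cfg.freq_min,
            rpm_threshold=cfg.rpm, min_reps=cfg.min_reps,
            promoters_wide=promoters_wide, hits=hits)
    region_calls = find_region_tfs(
        deg_table, sets, motifs, promoters, cm, rpm, mode=cfg.scan_mode,
        enrich_p=cfg.enrich_p, use_bh=cfg.use_bh, tf_fc=cfg.tf_fc, tf_p=cfg.tf_p,
        rpm_threshold=cfg.rpm, min_reps=cfg.min_reps, hits=hits)
    universal_calls_frame(universal).to_csv(
        os.path.join(cfg.outdir, "universal_tfs.tsv"), sep="\t", index=False)
    region_calls_frame(region_calls).to_csv(
        os.path.join(cfg.outdir, "region_tfs.tsv"), sep="\t", index=False)
    return universal, region_calls


def stage_targets(cfg: PipelineConfig) -> pd.DataFrame:
    """Target prediction for each region's top TF from existing discovery output."""
    region_path = os.path.join(cfg.outdir, "region_tfs.tsv")
    if not os.path.exists(region_path):
        raise PipelineError(f"region TF table not found at {region_path}; "
                            "run `discover` first")
    deg_table = _read_deg_table(cfg)
    calls = pd.read_csv(region_path, sep="\t")
    cm, contigs, bed, motifs, _ = _load_inputs(cfg)
    promoters = extract_promoters(contigs, bed, half_width=cfg.window_enrich)
    by_name = {m.name: m for m in motifs}
    all_targets = []
    for row in calls[calls.get("is_top", pd.Series(dtype=bool)) == True].itertuples():  # noqa: E712
        all_targets += predict_targets(
            row.tf_gene, by_name[row.motif], row.region, deg_table, promoters,
            fc_threshold=cfg.target_fc, p_threshold=cfg.target_p, up_only=cfg.up_only)
    frame = targets_frame(all_targets)
    frame.to_csv(os.path.join(cfg.outdir, "targets.tsv"), sep="\t", index=False)
    windows = primer_windows(all_targets, promoters, contigs)
    if windows:
        write_bed6(primer_windows_bed(windows),
                   os.path.join(cfg.outdir, "primer_windows.bed"))
        primer_windows_fasta(windows, os.path.join(cfg.outdir, "primer_windows.fa"))
    return frame


def load_report(outdir: str) -> RunReport:
    path = os.path.join(outdir, "report.json")
    if not os.path.exists(path):
        raise PipelineError(f"no report at {path}; run the pipeline first")
    with open(path) as fh:
        return RunReport.model_validate_json(fh.read())
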