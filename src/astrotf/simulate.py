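"""Synthetic region-labeled RNA-seq data with planted regulatory ground truth.

The generator emulates a FACS-sorted astrocyte bulk RNA-seq study design:
four brain regions (OB, HC, CX, BS) with a few replicates each, a
region-restricted differential-expression program per region, one
"universal" transcription factor whose motif is planted in nearly all DEG
promoters of every region, one region-specific TF per region whose motif
marks its planted targets, and decoy motifs planted at low background
frequency.  Counts are negative-binomial with log-normal gene baselines,
per-sample library-size scaling and multiplicative region effects.

Ground truth is exact: because differential expression is defined by a
one-vs-rest contrast, a gene planted k-fold up in one region truly shows a
fold change below 1 in every *other* region's contrast (the rest-mean is
inflated).  The manifest therefore derives true DEG membership from the
expected one-vs-rest fold of the full effect model, not just from the
planting labels.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .motifs import IUPAC, Pwm, revcomp, write_homer_motifs
from .promoters import BED6_COLUMNS

DEFAULT_REGIONS = ("OB", "HC", "CX", "BS")

# fixed spawn keys: one RNG stream per artifact, so e.g. changing the
# replicate count never perturbs the promoter sequences
_STREAMS = {"assignment": 0, "sequences": 1, "motifs": 2, "planting": 3, "counts": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))
    )


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Planted fold changes must strictly exceed the pipeline thresholds they
    are meant to trip: DEGs 1.5, region TFs 2, targets 2.5.
    """

    n_genes: int = 1200
    n_regions: int = 4
    reps_per_region: int = 3
    promoter_len: int = 4000           # interpreted as +/- promoter_len/2 around TSS
    scan_half_width: int = 2000
    background_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    n_decoy_motifs: int = 8
    planted_universal_tfs: int = 1
    planted_region_tfs: int = 1
    deg_per_region: int = 100
    frac_up: float = 0.6
    targets_per_region: int = 30
    deg_fold_change: float = 1.8
    tf_fold_change: float = 4.0
    target_fold_change: float = 4.0
    deg_call_fold: float = 1.5         # the DEG threshold the pipeline applies
    universal_motif_frequency: float = 0.96
    decoy_frequency: float = 0.05
    dispersion: float = 0.02
    mean_log_expression: tuple = (5.0, 1.2)   # natural-log location / scale
    library_size_range: tuple = (1.5e6, 2.5e6)
    seed: int = 42

    def __post_init__(self):
        for name in ("n_genes", "n_regions", "reps_per_region", "promoter_len",
                     "scan_half_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not math.isclose(sum(self.background_freqs), 1.0, abs_tol=1e-9):
            raise ValueError("background_freqs must sum to 1 within 1e-9")
        if any(p < 0 for p in self.background_freqs):
            raise ValueError("background_freqs must be non-negative")
        if self.promoter_len < 2 * self.scan_half_width:
            raise ValueError("promoter_len must be at least twice the scan half-width")
        if self.deg_per_region > 0 and not self.deg_fold_change > 1.5:
            raise ValueError("deg_fold_change must exceed the 1.5 DEG threshold")
        if self.planted_region_tfs > 0 and not self.tf_fold_change > 2.0:
            raise ValueError("tf_fold_change must exceed the 2-fold TF threshold")
        if self.targets_per_region > 0 and not self.target_fold_change > 2.5:
            raise ValueError("target_fold_change must exceed the 2.5-fold target threshold")
        if not 0.0 <= self.universal_motif_frequency <= 1.0:
            raise ValueError("universal_motif_frequency must lie in [0, 1]")
        up = int(round(self.deg_per_region * self.frac_up))
        if self.targets_per_region > up and self.deg_per_region > 0:
            raise ValueError("targets_per_region exceeds the up-DEG program size")

    @property
    def region_labels(self) -> list[str]:
        if self.n_regions == len(DEFAULT_REGIONS):
            return list(DEFAULT_REGIONS)
        return [f"R{i+1}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """Planted-truth manifest for one synthetic dataset."""

    deg_sets: dict            # region -> {"up": [genes], "down": [genes]}
    universal_tfs: list       # TF gene ids
    region_tfs: dict          # region -> TF gene id
    targets: dict             # TF gene id -> [target gene ids]
    planted_hits: dict        # gene -> [{"motif","offset","strand","instance"}]
    motif_tf: dict            # motif name -> TF gene id
    effects: dict             # gene -> {region: fold} for non-unit effects

    def region_deg_union(self, region: str) -> set[str]:
        d = self.deg_sets[region]
        return set(d["up"]) | set(d["down"])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Gene models and promoter sequences


def make_gene_models(cfg: SimConfig):
    """Random gene annotation and promoter contigs.

    One contig per gene (contig id = gene id) of length ``promoter_len``
    with the TSS at the midpoint; strand +/- with probability 0.5; bases
    i.i.d. from ``background_freqs``.
    """
    rng = _rng(cfg.seed, "sequences")
    genes = [f"g{i+1:05d}" for i in range(cfg.n_genes)]
    tss = cfg.promoter_len // 2
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs: dict[str, str] = {}
    for g in genes:
        codes = rng.choice(4, size=cfg.promoter_len, p=np.asarray(cfg.background_freqs))
        contigs[g] = base_arr[codes].tobytes().decode("ascii")
    annotation = pd.DataFrame({
        "contig": genes, "start": tss, "end": tss + 1,
        "name": genes, "score": 0, "strand": strands,
    })[BED6_COLUMNS]
    return annotation, contigs


# ---------------------------------------------------------------------------
# Motif library


def _random_pwm(rng: np.random.Generator, name: str, length: int,
                dominant: float, tf_gene: str | None) -> Pwm:
    matrix = np.full((length, 4), (1.0 - dominant) / 3.0)
    tops = rng.integers(0, 4, size=length)
    matrix[np.arange(length), tops] = dominant
    pwm = Pwm(name=name, matrix=matrix, tf_gene=tf_gene)
    pwm.logodds_threshold = 0.8 * pwm.max_logodds()
    return pwm


def make_motif_library(cfg: SimConfig, universal_tf_genes, region_tf_genes: dict,
                       decoy_tf_genes) -> list[Pwm]:
    """Planted TF motifs plus decoys.

    Planted motifs (universal and region TFs) are near-deterministic
    (dominant column probability 0.97, lengths 8-12) so their consensus is a
    concrete word whose zero-mismatch background rate is low; decoys span
    lengths 6-12 with dominant probabilities down to 0.6, giving degenerate
    consensus letters when the top two columns are within 0.1.
    """
    rng = _rng(cfg.seed, "motifs")
    motifs: list[Pwm] = []
    for i, tf in enumerate(universal_tf_genes):
        motifs.append(_random_pwm(rng, f"M_UNIV{i+1}", int(rng.integers(8, 13)), 0.97, tf))
    for region, tfs in region_tf_genes.items():
        for j, tf in enumerate(tfs):
            motifs.append(_random_pwm(rng, f"M_{region}{j+1 if len(tfs) > 1 else ''}",
                                      int(rng.integers(8, 13)), 0.97, tf))
    for i, tf in enumerate(decoy_tf_genes):
        dominant = float(rng.uniform(0.6, 0.97))
        motifs.append(_random_pwm(rng, f"M_DECOY{i+1}", int(rng.integers(6, 13)), dominant, tf))
    return motifs


# ---------------------------------------------------------------------------
# Planting


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Concrete ACGT word compatible with a degenerate consensus."""
    return "".join(c if c in "ACGT" else rng.choice(list(IUPAC[c])) for c in consensus)


def plant_motifs(contigs: dict, annotation: pd.DataFrame, motif: Pwm, gene_set,
                 frequency: float, rng, half_width: int = 2000,
                 occupied: dict | None = None):
    """Overwrite promoter sequence with motif instances in a random subset.

    ``ceil(frequency * |gene_set|)`` genes receive one instance each at a
    random strand and random TSS offset within +/- half_width; instances
    never straddle the contig boundary and never overlap previously planted
    instances (tracked via ``occupied``).  Returns the list of planted hit
    records; ``contigs`` is modified in place.
    """
    if not 0.0 <= frequency <= 1.0:
        raise ValueError("frequency must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.PCG64(rng))
    genes = sorted(gene_set)
    if not genes:
        return []
    L = len(motif.consensus)
    ann = annotation.set_index("name")
    if L > min(len(contigs[g]) for g in genes):
        raise ValueError(f"motif {motif.name} longer than a promoter sequence")
    # guard against float error: ceil(0.96 * 50) must be 48, not 49
    n_plant = math.ceil(frequency * len(genes) - 1e-9)
    chosen = list(rng.choice(genes, size=n_plant, replace=False)) if n_plant else []
    occupied = occupied if occupied is not None else {}
    hits = []
    for gene in chosen:
        row = ann.loc[gene]
        tss, gene_strand = int(row["start"]), row["strand"]
        clen = len(contigs[gene])
        if gene_strand == "+":
            lo = max(-(half_width - 1), -tss)
            hi = min(half_width - L - 1, clen - tss - L)
        else:
            lo = max(-(half_width - 1), tss - clen + 1)
            hi = min(half_width - L - 1, tss - L + 1)
        if hi < lo:
            raise ValueError(f"no room to plant {motif.name} in {gene}")
        taken = occupied.setdefault(gene, [])
        for _ in range(200):
            d = int(rng.integers(lo, hi + 1))
            if all(d + L <= a or d >= b for a, b in taken):
                break
        else:
            continue  # promoter too crowded; skip rather than clobber
        taken.append((d, d + L))
        hit_strand = rng.choice(["+", "-"])
        instance = _realize_consensus(motif.consensus, rng)
        oriented = instance if hit_strand == "+" else revcomp(instance)
        seq = contigs[gene]
        if gene_strand == "+":
            start = tss + d
            contigs[gene] = seq[:start] + oriented + seq[start + L:]
        else:
            start = tss - d - L + 1
            contigs[gene] = seq[:start] + revcomp(oriented) + seq[start + L:]
        hits.append({"gene": gene, "motif": motif.name, "offset": d,
                     "strand": hit_strand, "instance": instance})
    return hits


# ---------------------------------------------------------------------------
# Ground-truth effect model


def _true_deg_sets(effects: np.ndarray, genes, regions, call_fold: float) -> dict:
    """Expected one-vs-rest fold per gene/region -> true DEG membership.

    With equal replicate counts per region, the rest-mean is the average of
    the other regions' effects, so the true contrast fold of gene g in
    region r is effects[g, r] / mean(effects[g, not r]).
    """
    k = effects.shape[1]
    out = {}
    for j, region in enumerate(regions):
        rest = effects[:, [i for i in range(k) if i != j]].mean(axis=1)
        fold = effects[:, j] / rest
        up = [genes[i] for i in np.where(fold > call_fold)[0]]
        down = [genes[i] for i in np.where(fold < 1.0 / call_fold)[0]]
        out[region] = {"up": sorted(up), "down": sorted(down)}
    return out


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(cfg: SimConfig, effects, genes=None,
                    baselines: np.ndarray | None = None) -> CountMatrix:
    """Negative-binomial counts under the planted multiplicative model.

    ``effects`` is either a (n_genes x n_regions) fold-change array or a
    :class:`GroundTruth` (whose sparse effect map is expanded; planted TF
    genes get their baseline raised so they clear the RPM expression gate).
    Gene baselines are log-normal; each sample's expected totals are drawn
    uniformly from ``library_size_range`` and gene means rescaled to match;
    region effects multiply the baseline.  ``dispersion`` -> 0 reduces to
    Poisson sampling.
    """
    rng = _rng(cfg.seed, "counts")
    loc, scale = cfg.mean_log_expression
    if genes is None:
        genes = [f"g{i+1:05d}" for i in range(cfg.n_genes)]
    boost: list[str] = []
    if isinstance(effects, GroundTruth):
        truth = effects
        gidx = {g: i for i, g in enumerate(genes)}
        effects = np.ones((cfg.n_genes, cfg.n_regions))
        for g, per_region in truth.effects.items():
            for region, fold in per_region.items():
                effects[gidx[g], cfg.region_labels.index(region)] = fold
        boost = list(truth.universal_tfs)
        for tfs in truth.region_tfs.values():
            boost += tfs if isinstance(tfs, list) else [tfs]
    if baselines is None:
        baselines = rng.lognormal(loc, scale, size=cfg.n_genes)
        if boost:
            gidx = {g: i for i, g in enumerate(genes)}
            for tf in boost:
                baselines[gidx[tf]] = max(baselines[gidx[tf]], 100.0)
    regions = cfg.region_labels
    columns, data = [], []
    for j, region in enumerate(regions):
        for rep in range(1, cfg.reps_per_region + 1):
            total = rng.uniform(*cfg.library_size_range)
            mean = baselines * effects[:, j]
            mean = mean * (total / mean.sum())
            if cfg.dispersion <= 1e-12:
                col = rng.poisson(mean)
            else:
                r_nb = 1.0 / cfg.dispersion
                p = r_nb / (r_nb + mean)
                col = rng.negative_binomial(r_nb, p)
            columns.append(f"{region}_rep{rep}")
            data.append(col)
    counts = pd.DataFrame(np.column_stack(data), index=list(genes), columns=columns)
    sample_region = {c: c.rsplit("_rep", 1)[0] for c in columns}
    sample_replicate = {c: int(c.rsplit("_rep", 1)[1]) for c in columns}
    return CountMatrix(counts=counts, sample_region=sample_region,
                       sample_replicate=sample_replicate)


# ---------------------------------------------------------------------------
# Full dataset


def simulate_dataset(cfg: SimConfig, outdir: str | None = None):
    """Generate a complete synthetic study and optional on-disk copy.

    Returns ``(cm, annotation, contigs, motifs, truth)``.  When ``outdir``
    is given, writes genome.fa, tss.bed, counts.tsv, samples.tsv,
    motifs.txt, motif_tf_map.tsv and ground_truth.json.
    """
    regions = cfg.region_labels
    rng_assign = _rng(cfg.seed, "assignment")
    genes = [f"g{i+1:05d}" for i in range(cfg.n_genes)]

    # ---- assign planted roles to disjoint gene subsets
    n_special = (cfg.n_regions * cfg.deg_per_region + cfg.planted_universal_tfs
                 + cfg.n_regions * cfg.planted_region_tfs + cfg.n_decoy_motifs)
    if n_special > cfg.n_genes:
        raise ValueError("n_genes too small for the planted programs")
    shuffled = list(rng_assign.permutation(genes))
    cursor = 0

    def take(n):
        nonlocal cursor
        out = shuffled[cursor:cursor + n]
        cursor += n
        return out

    planted_up, planted_down, region_targets = {}, {}, {}
    n_up = int(round(cfg.deg_per_region * cfg.frac_up))
    for region in regions:
        block = take(cfg.deg_per_region)
        planted_up[region] = block[:n_up]
        planted_down[region] = block[n_up:]
        region_targets[region] = planted_up[region][:cfg.targets_per_region]
    universal_tfs = take(cfg.planted_universal_tfs)
    region_tfs = {region: take(cfg.planted_region_tfs) for region in regions}
    decoy_tfs = take(cfg.n_decoy_motifs)

    # ---- multiplicative effect matrix
    effects = np.ones((cfg.n_genes, cfg.n_regions))
    gidx = {g: i for i, g in enumerate(genes)}
    for j, region in enumerate(regions):
        for g in planted_up[region]:
            effects[gidx[g], j] = cfg.deg_fold_change
        for g in region_targets[region]:
            effects[gidx[g], j] = cfg.target_fold_change
        for g in planted_down[region]:
            effects[gidx[g], j] = 1.0 / cfg.deg_fold_change
        for g in region_tfs[region]:
            effects[gidx[g], j] = cfg.tf_fold_change

    deg_truth = _true_deg_sets(effects, genes, regions, cfg.deg_call_fold)

    # ---- sequences and motifs
    annotation, contigs = make_gene_models(cfg)
    motifs = make_motif_library(cfg, universal_tfs, region_tfs, decoy_tfs)

    # ---- planting
    rng_plant = _rng(cfg.seed, "planting")
    occupied: dict[str, list] = {}
    planted_hits: list[dict] = []
    by_name = {m.name: m for m in motifs}
    for i in range(cfg.planted_universal_tfs):
        motif = by_name[f"M_UNIV{i+1}"]
        covered: set[str] = set()
        for region in regions:
            rset = set(deg_truth[region]["up"]) | set(deg_truth[region]["down"])
            need = math.ceil(cfg.universal_motif_frequency * len(rset)) - len(rset & covered)
            pool = sorted(rset - covered)
            if need <= 0 or not pool:
                continue
            hits = plant_motifs(contigs, annotation, motif, pool,
                                min(1.0, need / len(pool)), rng_plant,
                                half_width=cfg.scan_half_width, occupied=occupied)
            covered |= {h["gene"] for h in hits}
            planted_hits += hits
    target_map: dict[str, list[str]] = {}
    for region in regions:
        for j, tf in enumerate(region_tfs[region]):
            motif = by_name[f"M_{region}{j+1 if len(region_tfs[region]) > 1 else ''}"]
            planted_hits += plant_motifs(contigs, annotation, motif, region_targets[region],
                                         1.0, rng_plant, half_width=cfg.scan_half_width,
                                         occupied=occupied)
            target_map[tf] = sorted(region_targets[region])
    for i, tf in enumerate(decoy_tfs):
        motif = by_name[f"M_DECOY{i+1}"]
        planted_hits += plant_motifs(contigs, annotation, motif, genes, cfg.decoy_frequency,
                                     rng_plant, half_width=cfg.scan_half_width,
                                     occupied=occupied)

    # ---- counts: TF genes get a raised baseline so expression gates are meaningful
    rng_counts_aux = _rng(cfg.seed, "counts")
    loc, scale = cfg.mean_log_expression
    baselines = rng_counts_aux.lognormal(loc, scale, size=cfg.n_genes)
    for tf in universal_tfs + [t for ts in region_tfs.values() for t in ts]:
        baselines[gidx[tf]] = max(baselines[gidx[tf]], 100.0)
    cm = simulate_counts(cfg, effects, genes, baselines=baselines)

    hit_index: dict[str, list[dict]] = {}
    for h in planted_hits:
        hit_index.setdefault(h["gene"], []).append(
            {k: (int(v) if k == "offset" else v) for k, v in h.items() if k != "gene"})
    truth = GroundTruth(
        deg_sets=deg_truth,
        universal_tfs=universal_tfs,
        region_tfs={r: (tfs[0] if len(tfs) == 1 else tfs) for r, tfs in region_tfs.items()
                    if tfs},
        targets=target_map,
        planted_hits=hit_index,
        motif_tf={m.name: m.tf_gene for m in motifs},
        effects={genes[i]: {regions[j]: float(effects[i, j])
                            for j in range(cfg.n_regions) if effects[i, j] != 1.0}
                 for i in np.where((effects != 1.0).any(axis=1))[0]},
    )

    if outdir is not None:
        write_dataset(outdir, cfg, cm, annotation, contigs, motifs, truth)
    return cm, annotation, contigs, motifs, truth


def write_dataset(outdir, cfg, cm, annotation, contigs, motifs, truth) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("genome", "genome.fa"), ("tss", "tss.bed"), ("counts", "counts.tsv"),
        ("samples", "samples.tsv"), ("motifs", "motifs.txt"),
        ("motif_tf_map", "motif_tf_map.tsv"), ("ground_truth", "ground_truth.json"),
        ("sim_config", "sim_config.json"),
    ]}
    with open(paths["genome"], "w") as fh:
        for gene in sorted(contigs):
            fh.write(f">{gene}\n")
            seq = contigs[gene]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    annotation.to_csv(paths["tss"], sep="\t", header=False, index=False)
    cm.to_tsv(paths["counts"], paths["samples"])
    with open(paths["motifs"], "w") as fh:
        fh.write(write_homer_motifs(motifs))
    pd.DataFrame(
        [(m.name, m.tf_gene) for m in motifs if m.tf_gene], columns=["motif", "tf_gene"]
    ).to_csv(paths["motif_tf_map"], sep="\t", index=False)
    truth.to_json(paths["ground_truth"])
    with open(paths["sim_config"], "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, sort_keys=True)
    return paths
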