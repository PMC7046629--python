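"""Prediction of direct targets of region-specific transcription factors.

A region DEG is a predicted target of its region's TF when its one-vs-rest
fold change exceeds 2.5 at p < 0.01 and the TF's consensus motif matches its
promoter with zero mismatches within 2 kb of the TSS (both strands, IUPAC
degeneracy honored).  Candidate ChIP-qPCR amplicon windows around predicted
binding sites are emitted as BED + FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import MotifHit, Pwm, match_consensus
from .promoters import PromoterSet


@dataclass
class PredictedTarget:
    tf_gene: str
    target_gene: str
    region: str
    offset: int               # nearest-to-TSS hit offset (signed, transcription-oriented)
    strand: str
    log2fc: float
    pvalue: float
    hits: list[MotifHit] = field(default_factory=list)   # all retained hits


def _strict_consensus(consensus: str) -> str:
    if any(c not in "ACGT" for c in consensus):
        raise ValueError("consensus contains degenerate letters; strict ACGT mode refused")
    return consensus


def predict_targets(tf_gene: str, motif: Pwm, region: str, deg_table: pd.DataFrame,
                    promoters: PromoterSet, fc_threshold: float = 2.5,
                    p_threshold: float | None = 0.01, up_only: bool = True,
                    max_mismatch: int = 0, strict_acgt: bool = False,
                    hits=None) -> list[PredictedTarget]:
    """Targets of one TF in one region.

    ``p_threshold=None`` gives the fold-change-only rule.  ``up_only=False``
    admits downregulated DEGs (exploratory).  ``hits`` may supply a
    precomputed {gene: [MotifHit]} map for this motif's promoter scan.
    """
    consensus = _strict_consensus(motif.consensus) if strict_acgt else motif.consensus
    sub = deg_table[(deg_table["region"] == region) & deg_table["is_deg"]]
    if up_only:
        sub = sub[sub["direction"] == "up"]
    sub = sub[sub["log2fc"].abs() > np.log2(fc_threshold)]
    if p_threshold is not None:
        sub = sub[sub["pvalue"] < p_threshold]
    out: list[PredictedTarget] = []
    for row in sub.itertuples(index=False):
        gene = row.gene
        if gene not in promoters:
            continue
        rec = promoters[gene]
        if hits is not None:
            gene_hits = list(hits.get(gene, []))
        else:
            gene_hits = match_consensus(rec.seq, consensus, max_mismatch=max_mismatch)
            for h in gene_hits:
                h.gene, h.motif, h.offset = gene, motif.name, h.pos - rec.tss_index
        gene_hits = [h for h in gene_hits if abs(h.offset) <= 2000]
        if not gene_hits:
            continue
        nearest = min(gene_hits, key=lambda h: (abs(h.offset), h.offset, h.strand))
        out.append(PredictedTarget(
            tf_gene=tf_gene, target_gene=gene, region=region,
            offset=int(nearest.offset), strand=nearest.strand,
            log2fc=float(row.log2fc), pvalue=float(row.pvalue), hits=gene_hits,
        ))
    return rank_targets(out)


def rank_targets(targets: list[PredictedTarget], k: int | None = None) -> list[PredictedTarget]:
    """Order by fold change descending, ties by p ascending then gene id."""
    ranked = sorted(targets, key=lambda t: (-t.log2fc, t.pvalue, t.target_gene))
    return ranked if k is None else ranked[:k]


def targets_frame(targets: list[PredictedTarget]) -> pd.DataFrame:
    return pd.DataFrame([{
        "tf_gene": t.tf_gene, "target_gene": t.target_gene, "region": t.region,
        "offset": t.offset, "strand": t.strand, "log2fc": t.log2fc,
        "pvalue": t.pvalue, "n_hits": len(t.hits),
    } for t in targets], columns=["tf_gene", "target_gene", "region", "offset",
                                  "strand", "log2fc", "pvalue", "n_hits"])


# ---------------------------------------------------------------------------
# ChIP-qPCR candidate windows


@dataclass
class PrimerWindow:
    gene: str
    contig: str
    start: int                # genomic, 0-based
    end: int                  # half-open
    motif: str
    clipped: bool
    seq: str = ""


def primer_windows(targets: list[PredictedTarget], promoters: PromoterSet,
                   contigs: dict[str, str], flank: int = 150) -> list[PrimerWindow]:
    """Candidate amplicon windows: each retained hit span +/- flank, clipped
    to the contig.  Window sequences are sliced from the genome (forward
    strand)."""
    out = []
    for t in targets:
        rec = promoters[t.target_gene]
        contig_seq = contigs[rec.contig]
        for h in t.hits:
            gstart, gend = rec.genomic_span(h.pos, h.length)
            lo = max(0, gstart - flank)
            hi = min(len(contig_seq), gend + flank)
            out.append(PrimerWindow(
                gene=t.target_gene, contig=rec.contig, start=lo, end=hi,
                motif=h.motif, clipped=(gstart - flank < 0 or gend + flank > len(contig_seq)),
                seq=contig_seq[lo:hi],
            ))
    return out


def primer_windows_bed(windows: list[PrimerWindow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": w.contig, "start": w.start, "end": w.end,
        "name": f"{w.gene}|{w.motif}", "score": 0, "strand": "+",
    } for w in windows])


def primer_windows_fasta(windows: list[PrimerWindow], path: str) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.gene}|{w.motif}|{w.contig}:{w.start}-{w.end}\n{w.seq}\n")
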