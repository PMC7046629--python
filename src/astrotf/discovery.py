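"""Classification of transcription factors as universal or region-specific.

A *universal* TF has a motif significantly enriched in the pooled DEG list,
present in at least half of every region's DEGs, and its gene clears the RPM
expression gate in every region.  A *region-specific* TF has a motif
enriched in one region's DEGs and is itself upregulated more than 2-fold
(p < 0.01) in that region; the most upregulated qualifying TF per region is
flagged as the top call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix, expression_gate
from .motifs import EnrichmentResult, Pwm, bh_adjust, enrichment_test, library_hits


@dataclass
class UniversalTfCall:
    tf_gene: str
    motif: str
    pvalue: float
    padj: float
    region_frequency: dict[str, float]       # 2 kb-window motif frequency per region
    expression_pass: bool
    enrichment: EnrichmentResult | None = None
    region_frequency_wide: dict[str, float] | None = None  # 10 kb profile when available


@dataclass
class RegionTfCall:
    tf_gene: str
    motif: str
    region: str
    enrichment_p: float
    enrichment_padj: float
    tf_log2fc: float
    tf_pvalue: float
    is_top: bool = False


def _tf_genes(pwm: Pwm) -> list[str]:
    if pwm.tf_gene is None:
        return []
    return pwm.tf_gene if isinstance(pwm.tf_gene, list) else [pwm.tf_gene]


def _enrich_library(motifs, foreground, background_genes, promoters, mode, bg_freqs, hits):
    results = []
    for pwm in motifs:
        results.append(enrichment_test(pwm, foreground, background_genes, promoters,
                                       mode=mode, background_freqs=bg_freqs,
                                       hits=hits[pwm.name]))
    padj = bh_adjust([r.pvalue for r in results])
    for r, a in zip(results, padj):
        r.padj = float(a)
    return results


def expressed_background(cm: CountMatrix, rpm: pd.DataFrame, promoters,
                         rpm_threshold: float = 5.0, min_reps: int = 2) -> list[str]:
    """Genes passing the RPM gate in at least one region and having a promoter."""
    gate = pd.Series(False, index=rpm.index)
    for region in cm.regions:
        gate |= expression_gate(rpm, cm, region, threshold=rpm_threshold, min_reps=min_reps)
    return [g for g in rpm.index[gate] if g in promoters]


def find_universal_tfs(pooled_degs, region_deg_sets: dict, motifs: list[Pwm],
                       promoters, cm: CountMatrix, rpm: pd.DataFrame,
                       mode: str = "consensus", background_freqs=None,
                       enrich_p: float = 0.01, use_bh: bool = True,
                       freq_min: float = 0.5, rpm_threshold: float = 5.0,
                       min_reps: int = 2, promoters_wide=None,
                       hits=None, wide_hits=None) -> list[UniversalTfCall]:
    """Universal-TF calls: pooled enrichment + per-region frequency + gate.

    ``promoters`` is the 2 kb-half-width window set used for enrichment and
    the 50%-per-region frequency rule; ``promoters_wide`` (optionally the
    10 kb windows) only adds a reported wide-window frequency profile.
    Motifs with no TF gene mapping are excluded.  Calls are sorted by pooled
    enrichment p ascending.
    """
    if not pooled_degs:
        raise ValueError("pooled DEG list is empty")
    background = expressed_background(cm, rpm, promoters, rpm_threshold, min_reps)
    fg = [g for g in pooled_degs if g in set(background)]
    if hits is None:
        hits = library_hits(motifs, promoters, mode=mode, background=background_freqs)
    results = _enrich_library(motifs, fg, background, promoters, mode, background_freqs, hits)

    if promoters_wide is not None and wide_hits is None:
        # if the wide windows clipped down to the same sequences (short
        # contigs), the narrow-window scan already covers them
        same = all(promoters_wide[g].seq == promoters[g].seq
                   and promoters_wide[g].tss_index == promoters[g].tss_index
                   for g in promoters) and set(promoters_wide) == set(promoters)
        wide_hits = hits if same else library_hits(motifs, promoters_wide, mode=mode,
                                                   background=background_freqs)
    gates = {region: expression_gate(rpm, cm, region, threshold=rpm_threshold,
                                     min_reps=min_reps)
             for region in cm.regions}

    calls: list[UniversalTfCall] = []
    for pwm, res in zip(motifs, results):
        p_eff = res.padj if use_bh else res.pvalue
        if p_eff >= enrich_p:
            continue
        freqs = {}
        ok = True
        for region, genes in region_deg_sets.items():
            genes = [g for g in genes if g in promoters]
            if not genes:
                ok = False
                break
            freqs[region] = sum(bool(hits[pwm.name].get(g)) for g in genes) / len(genes)
        if not ok or min(freqs.values()) < freq_min:
            continue
        wide = None
        if wide_hits is not None:
            wide = {region: (sum(bool(wide_hits[pwm.name].get(g))
                                 for g in genes_r if g in promoters_wide)
                             / max(1, sum(g in promoters_wide for g in genes_r)))
                    for region, genes_r in region_deg_sets.items()}
        for tf in _tf_genes(pwm):
            gate_all = all(bool(gates[region].get(tf, False)) for region in cm.regions)
            if not gate_all:
                continue
            calls.append(UniversalTfCall(
                tf_gene=tf, motif=pwm.name, pvalue=res.pvalue, padj=res.padj,
                region_frequency=freqs, expression_pass=True, enrichment=res,
                region_frequency_wide=wide,
            ))
    calls.sort(key=lambda c: (c.pvalue, c.tf_gene))
    return calls


def find_region_tfs(deg_table: pd.DataFrame, region_deg_sets: dict, motifs: list[Pwm],
                    promoters, cm: CountMatrix, rpm: pd.DataFrame,
                    mode: str = "consensus", background_freqs=None,
                    enrich_p: float = 0.01, use_bh: bool = True,
                    tf_fc: float = 2.0, tf_p: float = 0.01,
                    rpm_threshold: float = 5.0, min_reps: int = 2,
                    hits=None) -> dict[str, list[RegionTfCall]]:
    """Region-specific TF calls per region.

    For each region, motifs enriched in that region's DEGs (BH within the
    library) are kept when their TF gene is upregulated with fold change
    > ``tf_fc`` at p < ``tf_p`` in the one-vs-rest contrast of that region.
    Regions with no qualifying TF return an empty list.
    """
    background = expressed_background(cm, rpm, promoters, rpm_threshold, min_reps)
    if hits is None:
        hits = library_hits(motifs, promoters, mode=mode, background=background_freqs)
    de = deg_table.set_index(["region", "gene"])
    lfc_cut = np.log2(tf_fc)
    out: dict[str, list[RegionTfCall]] = {}
    for region, genes in region_deg_sets.items():
        fg = [g for g in genes if g in set(background)]
        calls: list[RegionTfCall] = []
        if fg:
            results = _enrich_library(motifs, fg, background, promoters, mode,
                                      background_freqs, hits)
            for pwm, res in zip(motifs, results):
                p_eff = res.padj if use_bh else res.pvalue
                if p_eff >= enrich_p:
                    continue
                for tf in _tf_genes(pwm):
                    try:
                        row = de.loc[(region, tf)]
                    except KeyError:
                        continue
                    if row["log2fc"] > lfc_cut and row["pvalue"] < tf_p:
                        calls.append(RegionTfCall(
                            tf_gene=tf, motif=pwm.name, region=region,
                            enrichment_p=res.pvalue, enrichment_padj=res.padj,
                            tf_log2fc=float(row["log2fc"]),
                            tf_pvalue=float(row["pvalue"]),
                        ))
        top = select_top_tf(calls)
        for c in calls:
            c.is_top = top is not None and c is top
        out[region] = sorted(calls, key=lambda c: (-c.tf_log2fc, c.enrichment_p, c.tf_gene))
    return out


def select_top_tf(calls: list[RegionTfCall]) -> RegionTfCall | None:
    """The most upregulated call; ties broken by smaller enrichment p, then
    lexicographic TF gene id.  None for an empty list."""
    if not calls:
        return None
    return min(calls, key=lambda c: (-c.tf_log2fc, c.enrichment_p, c.tf_gene))


def universal_calls_frame(calls: list[UniversalTfCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"tf_gene": c.tf_gene, "motif": c.motif, "pvalue": c.pvalue,
               "padj": c.padj, "expression_pass": c.expression_pass,
               "min_region_frequency": min(c.region_frequency.values())}
        row.update({f"freq_{r}": f for r, f in c.region_frequency.items()})
        if c.region_frequency_wide:
            row.update({f"freq10kb_{r}": f for r, f in c.region_frequency_wide.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def region_calls_frame(calls_by_region: dict[str, list[RegionTfCall]]) -> pd.DataFrame:
    rows = [{
        "region": c.region, "tf_gene": c.tf_gene, "motif": c.motif,
        "enrichment_p": c.enrichment_p, "enrichment_padj": c.enrichment_padj,
        "tf_log2fc": c.tf_log2fc, "tf_pvalue": c.tf_pvalue, "is_top": c.is_top,
    } for calls in calls_by_region.values() for c in calls]
    return pd.DataFrame(rows, columns=["region", "tf_gene", "motif", "enrichment_p",
                                       "enrichment_padj", "tf_log2fc", "tf_pvalue",
                                       "is_top"])
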