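"""Strand-aware promoter window extraction from a genome FASTA + TSS BED.

Coordinates are 0-based half-open throughout.  For a gene on the minus
strand the extracted window is reverse-complemented so that positions run in
transcription orientation (negative offsets upstream of the TSS).  Windows
are clipped at contig ends and carry clip flags.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
from pyfaidx import Fasta

from .motifs import revcomp


@dataclass
class PromoterRecord:
    """A transcription-oriented promoter window.

    ``seq`` is the extracted (possibly reverse-complemented) sequence.
    ``tss_index`` is the index within ``seq`` corresponding to TSS offset 0,
    so a hit starting at index i sits at offset ``i - tss_index``.
    ``window_start``/``window_end`` are genomic coordinates of the window on
    the forward genomic strand.
    """

    gene: str
    contig: str
    tss: int
    strand: str
    seq: str
    tss_index: int
    window_start: int
    window_end: int
    clipped_left: bool = False
    clipped_right: bool = False

    def genomic_span(self, pos: int, length: int, hit_strand: str = "+") -> tuple[int, int]:
        """Genomic [start, end) of a window occupying seq[pos:pos+length]."""
        if self.strand == "+":
            start = self.window_start + pos
        else:
            start = self.window_end - pos - length
        return start, start + length


class PromoterSet(dict):
    """gene id -> PromoterRecord, with FASTA round-trip helpers."""

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for gene, rec in self.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(rec.seq), 80):
                    fh.write(rec.seq[i:i + 80] + "\n")


BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_bed6(path: str) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    bad = ~bed["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"BED strand must be + or -; offending rows: {bed.index[bad].tolist()[:5]}")
    return bed


def write_bed6(records: pd.DataFrame, path: str) -> None:
    records[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _load_contigs(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    if isinstance(genome, (str, os.PathLike)):
        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        return {name: str(fa[name][:]) for name in fa.keys()}
    raise TypeError("genome must be a FASTA path or a {contig: sequence} dict")


def extract_promoters(genome, tss_bed, half_width: int = 2000) -> PromoterSet:
    """Extract [TSS - half_width, TSS + half_width) windows per gene.

    ``genome`` is a FASTA path or contig dict; ``tss_bed`` a BED6 path or
    DataFrame whose name column provides gene ids and whose start column is
    the TSS.  Minus-strand windows are reverse-complemented; windows
    reaching past a contig end are clipped and flagged.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    contigs = _load_contigs(genome)
    bed = tss_bed if isinstance(tss_bed, pd.DataFrame) else read_bed6(tss_bed)
    out = PromoterSet()
    for row in bed.itertuples(index=False):
        if row.contig not in contigs:
            raise KeyError(f"TSS contig {row.contig!r} absent from genome FASTA")
        contig_seq = contigs[row.contig]
        tss = int(row.start)
        lo = max(0, tss - half_width)
        hi = min(len(contig_seq), tss + half_width)
        window = contig_seq[lo:hi]
        if row.strand == "+":
            seq = window
            tss_index = tss - lo
        else:
            seq = revcomp(window)
            tss_index = hi - 1 - tss
        out[row.name] = PromoterRecord(
            gene=row.name,
            contig=row.contig,
            tss=tss,
            strand=row.strand,
            seq=seq,
            tss_index=tss_index,
            window_start=lo,
            window_end=hi,
            clipped_left=(tss - half_width < 0),
            clipped_right=(tss + half_width > len(contig_seq)),
        )
    return out
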