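"""Position weight matrices, promoter scanning, and motif enrichment.

Motifs are represented as position probability matrices (A,C,G,T column
order) with an IUPAC consensus string.  Two scanning modes are provided:

* ``scan_pwm`` — log-odds scoring (bits) against a background base
  composition, both strands, threshold cutoff.  This mirrors how HOMER-style
  known-motif scanning works.
* ``match_consensus`` — exact IUPAC-compatible matching with at most
  ``max_mismatch`` incompatible bases (default zero mismatches), both
  strands.  This is the rule used for transcription-factor target calls.

Enrichment of a motif in a gene set is tested with the upper hypergeometric
tail under ZOOPS counting (a gene counts once regardless of how many hits
its promoter carries).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

# ---------------------------------------------------------------------------
# Alphabet helpers

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT (anything else, incl. N, -> 4) as int8."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = idx
    return out


def iupac_letter(probs, tie_margin: float = 0.1) -> str:
    """Consensus letter for one PWM column.

    The letter covers the top base plus every base whose probability is
    within ``tie_margin`` of it; the base set is mapped back to IUPAC.
    """
    order = np.argsort(probs)[::-1]
    top = probs[order[0]]
    bases = frozenset(BASES[i] for i in range(4) if probs[i] >= top - tie_margin)
    for letter, cover in IUPAC.items():
        if frozenset(cover) == bases:
            return letter
    return "N"


def consensus_from_matrix(matrix: np.ndarray, tie_margin: float = 0.1) -> str:
    return "".join(iupac_letter(col, tie_margin) for col in matrix)


# ---------------------------------------------------------------------------
# PWM type and HOMER-style I/O


@dataclass
class Pwm:
    """A TF-linked motif: L x 4 probability matrix plus consensus.

    ``matrix`` rows are positions, columns are A,C,G,T probabilities.
    ``logodds_threshold`` is the score cutoff (bits) for PWM-mode scanning;
    when None, 80% of the maximum attainable log-odds is used at scan time.
    """

    name: str
    matrix: np.ndarray
    consensus: str = ""
    logodds_threshold: float | None = None
    tf_gene: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.name}: matrix must be L x 4")
        if not self.consensus:
            self.consensus = consensus_from_matrix(self.matrix)
        if len(self.consensus) != len(self.matrix):
            raise ValueError(f"motif {self.name}: consensus length != matrix length")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def max_logodds(self, background=None) -> float:
        bg = _as_background(background)
        return float(np.sum(np.log2(self.matrix.max(axis=1) / bg[np.argmax(self.matrix, axis=1)])))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        m = np.clip(self.matrix, 1e-12, 1.0)
        return float(np.sum(2.0 + np.sum(m * np.log2(m), axis=1)))


def _as_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies summing to 1")
    return bg


def parse_homer_motifs(text: str, tf_map: dict[str, str | list[str]] | None = None,
                       pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse HOMER-style motif text into Pwm objects.

    Records start with ``>CONSENSUS<TAB>name<TAB>threshold`` followed by one
    row of four tab- or space-separated probabilities (A C G T) per
    position.  A pseudocount is added and each row renormalized.  ``tf_map``
    assigns a TF gene id (or several) to a motif name; motifs absent from
    the map get ``tf_gene=None``.
    """
    motifs: list[Pwm] = []
    header = None
    rows: list[list[float]] = []
    header_line = 0

    def _flush(lineno):
        if header is None:
            return
        if not rows:
            raise ValueError(f"line {header_line}: motif record with no matrix rows")
        consensus, name, thresh = header
        matrix = np.array(rows, dtype=float)
        sums = matrix.sum(axis=1)
        bad = np.where((sums < 0.9) | (sums > 1.1))[0]
        if bad.size:
            raise ValueError(
                f"line {header_line + 1 + int(bad[0])}: probabilities sum to "
                f"{sums[bad[0]]:.4f}, outside [0.9, 1.1]"
            )
        matrix = matrix + pseudocount
        matrix /= matrix.sum(axis=1, keepdims=True)
        tf = None
        if tf_map and name in tf_map:
            tf = tf_map[name]
        motifs.append(Pwm(name=name, matrix=matrix, consensus=consensus,
                          logodds_threshold=thresh, tf_gene=tf))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush(lineno)
            parts = line[1:].split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: header needs >CONSENSUS<TAB>name")
            consensus = parts[0].upper()
            for letter in consensus:
                if letter not in IUPAC:
                    raise ValueError(f"line {lineno}: illegal consensus letter {letter!r}")
            thresh = float(parts[2]) if len(parts) > 2 and parts[2] else None
            header = (consensus, parts[1], thresh)
            header_line = lineno
            rows = []
        else:
            fields = re.split(r"[\t ]+", line)
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 probability fields, got {len(fields)}")
            rows.append([float(x) for x in fields])
    _flush(None)
    return motifs


def write_homer_motifs(motifs: list[Pwm]) -> str:
    """Serialize motifs back to HOMER-style text (inverse of the parser)."""
    out = []
    for m in motifs:
        thresh = m.logodds_threshold if m.logodds_threshold is not None else m.max_logodds() * 0.8
        out.append(f">{m.consensus}\t{m.name}\t{thresh:.6g}")
        for row in m.matrix:
            out.append("\t".join(f"{p:.10f}" for p in row))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Scanning


@dataclass
class MotifHit:
    """A motif occurrence on a scanned sequence.

    ``pos`` is the 0-based start of the occupied window on the *forward*
    orientation of the scanned sequence, for both strands.  ``score`` is the
    log-odds score in bits (consensus mode: number of mismatches is stored
    in ``mismatches`` and score is 0).
    """

    pos: int
    strand: str
    score: float = 0.0
    mismatches: int = 0
    motif: str = ""
    gene: str = ""
    offset: int | None = None  # signed bases from TSS, set by promoter-aware wrappers
    length: int = 0            # bases occupied by the hit window


def _logodds_table(pwm: Pwm, bg: np.ndarray) -> np.ndarray:
    # 5th row handles N: contributes log2(1) = 0
    lom = np.zeros((5, len(pwm)))
    lom[:4] = np.log2(pwm.matrix.T / bg[:, None])
    return lom


def _scan_scores(enc: np.ndarray, lom: np.ndarray) -> np.ndarray:
    L = lom.shape[1]
    n = enc.size
    if n < L:
        return np.empty(0)
    scores = np.zeros(n - L + 1)
    for i in range(L):
        scores += lom[enc[i:n - L + 1 + i], i]
    return scores


def _rc_logodds(lom: np.ndarray) -> np.ndarray:
    """Log-odds table of the reverse-complement motif: scanning the forward
    strand with it is equivalent to scanning the reverse strand, with hits
    reported at the same forward window start."""
    out = np.zeros_like(lom)
    out[:4] = lom[[3, 2, 1, 0]][:, ::-1]
    return out


def scan_pwm(seq: str, pwm: Pwm, background=None, threshold: float | None = None) -> list[MotifHit]:
    """Log-odds scan of both strands; hits are windows scoring >= threshold.

    Threshold resolution order: explicit argument, the motif's own
    ``logodds_threshold``, else 80% of the maximum attainable log-odds.
    Overlapping hits are all reported; windows containing N score the N
    positions as 0 bits.
    """
    bg = _as_background(background)
    if threshold is None:
        threshold = pwm.logodds_threshold
    if threshold is None:
        threshold = 0.8 * pwm.max_logodds(bg)
    L = len(pwm)
    n = len(seq)
    if n < L:
        return []
    lom = _logodds_table(pwm, bg)
    hits = []
    fwd = _scan_scores(encode(seq), lom)
    for pos in np.where(fwd >= threshold)[0]:
        hits.append(MotifHit(pos=int(pos), strand="+", score=float(fwd[pos]), motif=pwm.name, length=L))
    rev = _scan_scores(encode(revcomp(seq)), lom)
    for j in np.where(rev >= threshold)[0]:
        # window [j, j+L) on the reverse strand occupies [n-L-j, n-j) forward
        hits.append(MotifHit(pos=int(n - L - j), strand="-", score=float(rev[j]), motif=pwm.name, length=L))
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def _iupac_compat_table(consensus: str) -> np.ndarray:
    """Bool table: compat[i, b] — base code b satisfies consensus position i.

    Sequence code 4 (N or unknown) is compatible with nothing, so an N in
    the scanned sequence always counts as a mismatch.
    """
    table = np.zeros((len(consensus), 5), dtype=bool)
    for i, letter in enumerate(consensus):
        if letter not in IUPAC:
            raise ValueError(f"illegal IUPAC letter {letter!r} in consensus")
        for b in IUPAC[letter]:
            table[i, _BASE_INDEX[b]] = True
    return table


def _match_one_strand(enc: np.ndarray, table: np.ndarray, max_mismatch: int) -> np.ndarray:
    L = table.shape[0]
    n = enc.size
    if n < L:
        return np.empty(0, dtype=int)
    mism = np.zeros(n - L + 1, dtype=np.int16)
    for i in range(L):
        mism += ~table[i, enc[i:n - L + 1 + i]]
    return np.where(mism <= max_mismatch)[0]


def match_consensus(seq: str, consensus: str, max_mismatch: int = 0) -> list[MotifHit]:
    """IUPAC-compatible matching of a consensus on both strands.

    A position matches when every base is compatible with its IUPAC letter,
    allowing at most ``max_mismatch`` incompatibilities.  Positions are
    forward-strand starts for both orientations.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    consensus = consensus.upper()
    table = _iupac_compat_table(consensus)
    rc_table = _iupac_compat_table(revcomp(consensus))
    enc = encode(seq)
    L = len(consensus)
    hits = [MotifHit(pos=int(p), strand="+", length=L)
            for p in _match_one_strand(enc, table, max_mismatch)]
    hits += [MotifHit(pos=int(p), strand="-", length=L)
             for p in _match_one_strand(enc, rc_table, max_mismatch)]
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Set-level scanning, frequency and enrichment


def library_hits(motifs: list[Pwm], promoters, mode: str = "consensus",
                 background=None, max_mismatch: int = 0,
                 threshold: float | None = None) -> dict[str, dict[str, list[MotifHit]]]:
    """Scan a whole motif library over a promoter set in one pass per motif.

    All promoter sequences are concatenated and scanned once per
    motif/strand; windows straddling two promoters are discarded by
    construction.  Returns ``{motif name: {gene: [MotifHit, ...]}}`` with
    TSS-relative offsets on every hit.  Equivalent to calling
    :func:`promoter_hits` per motif, but much faster on large sets.
    """
    if mode not in ("pwm", "consensus"):
        raise ValueError(f"unknown scan mode {mode!r}")
    genes = list(promoters.keys())
    lengths = np.array([len(promoters[g].seq) for g in genes])
    starts = np.concatenate([[0], np.cumsum(lengths)])
    enc = encode("".join(promoters[g].seq for g in genes))
    tss_idx = np.array([promoters[g].tss_index for g in genes])
    bg = _as_background(background)

    out: dict[str, dict[str, list[MotifHit]]] = {}
    for pwm in motifs:
        L = len(pwm)
        found: list[tuple[int, str, float, int]] = []  # (concat pos, strand, score, mism)
        if mode == "pwm":
            thr = threshold if threshold is not None else pwm.logodds_threshold
            if thr is None:
                thr = 0.8 * pwm.max_logodds(bg)
            lom = _logodds_table(pwm, bg)
            for strand, table in (("+", lom), ("-", _rc_logodds(lom))):
                scores = _scan_scores(enc, table)
                for pos in np.where(scores >= thr)[0]:
                    found.append((int(pos), strand, float(scores[pos]), 0))
        else:
            tables = (("+", _iupac_compat_table(pwm.consensus)),
                      ("-", _iupac_compat_table(revcomp(pwm.consensus))))
            for strand, table in tables:
                for pos in _match_one_strand(enc, table, max_mismatch):
                    found.append((int(pos), strand, 0.0, 0))
        per_gene: dict[str, list[MotifHit]] = {}
        for pos, strand, score, mism in found:
            gi = int(np.searchsorted(starts, pos, side="right")) - 1
            if pos + L > starts[gi + 1]:
                continue  # straddles a promoter boundary: not a real window
            local = pos - int(starts[gi])
            hit = MotifHit(pos=local, strand=strand, score=score, mismatches=mism,
                           motif=pwm.name, gene=genes[gi],
                           offset=local - int(tss_idx[gi]), length=L)
            per_gene.setdefault(genes[gi], []).append(hit)
        for hits in per_gene.values():
            hits.sort(key=lambda h: (h.pos, h.strand))
        out[pwm.name] = per_gene
    return out


def promoter_hits(pwm: Pwm, promoters, mode: str = "consensus", background=None,
                  threshold: float | None = None, max_mismatch: int = 0) -> dict[str, list[MotifHit]]:
    """Scan every promoter in a PromoterSet; hits carry TSS-relative offsets."""
    if mode not in ("pwm", "consensus"):
        raise ValueError(f"unknown scan mode {mode!r}")
    out: dict[str, list[MotifHit]] = {}
    for gene, rec in promoters.items():
        if mode == "pwm":
            hits = scan_pwm(rec.seq, pwm, background=background, threshold=threshold)
        else:
            hits = match_consensus(rec.seq, pwm.consensus, max_mismatch=max_mismatch)
        for h in hits:
            h.gene = gene
            h.motif = pwm.name
            h.offset = h.pos - rec.tss_index
        if hits:
            out[gene] = hits
    return out


def motif_frequency(pwm: Pwm, gene_set, promoters, mode: str = "consensus",
                    background=None, hits: dict[str, list[MotifHit]] | None = None):
    """Fraction of genes in the set whose promoter carries >= 1 hit.

    Returns ``(fraction, per_gene)`` where ``per_gene`` maps gene -> bool.
    Precomputed ``hits`` (from :func:`promoter_hits`) may be supplied to
    avoid rescanning.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    missing = [g for g in gene_set if g not in promoters]
    if missing:
        raise KeyError(f"genes without promoters: {missing[:5]}")
    if hits is None:
        sub = {g: promoters[g] for g in gene_set}
        hits = promoter_hits(pwm, sub, mode=mode, background=background)
    per_gene = {g: bool(hits.get(g)) for g in gene_set}
    return sum(per_gene.values()) / len(gene_set), per_gene


@dataclass
class EnrichmentResult:
    motif: str
    pvalue: float
    k: int   # foreground genes with the motif
    n: int   # foreground size
    K: int   # background genes with the motif
    N: int   # background size
    fold: float | None
    padj: float | None = None


def enrichment_test(pwm: Pwm, foreground, background_genes, promoters,
                    mode: str = "consensus", background_freqs=None,
                    hits: dict[str, list[MotifHit]] | None = None) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of a motif in a gene set.

    ZOOPS counting: each gene counts once if its promoter has >= 1 hit.
    ``p = P(X >= k)`` for X ~ Hypergeom(N, K, n).  ``foreground`` must be a
    subset of ``background_genes``.
    """
    fg = set(foreground)
    bg = set(background_genes)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background gene set")
    if hits is None:
        sub = {g: promoters[g] for g in bg}
        hits = promoter_hits(pwm, sub, mode=mode, background=background_freqs)
    with_motif = {g for g in bg if hits.get(g)}
    N, K, n, k = len(bg), len(with_motif), len(fg), len(fg & with_motif)
    if K == 0:
        return EnrichmentResult(pwm.name, 1.0, k, n, K, N, None)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if n else None
    return EnrichmentResult(pwm.name, min(p, 1.0), k, n, K, N, fold)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
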