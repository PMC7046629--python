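"""Motif parsing, scanning, frequency and enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest

from astrotf.motifs import (
    MotifHit,
    Pwm,
    bh_adjust,
    consensus_from_matrix,
    encode,
    enrichment_test,
    iupac_letter,
    library_hits,
    match_consensus,
    motif_frequency,
    parse_homer_motifs,
    promoter_hits,
    revcomp,
    scan_pwm,
    write_homer_motifs,
)
from astrotf.promoters import PromoterRecord, PromoterSet


def make_prom(gene, seq, tss_index=0):
    return PromoterRecord(gene=gene, contig=gene, tss=tss_index, strand="+", seq=seq,
                          tss_index=tss_index, window_start=0, window_end=len(seq))


def prom_set(seqs: dict) -> PromoterSet:
    ps = PromoterSet()
    for gene, seq in seqs.items():
        ps[gene] = make_prom(gene, seq)
    return ps


# ---------------------------------------------------------------------------
# Alphabet helpers


def test_revcomp_basic_and_degenerate():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AAGG") == "CCTT"
    assert revcomp("ARG") == "CYT"        # R<->Y under complement
    assert revcomp(revcomp("ACGTRYSWKMBDHVN")) == "ACGTRYSWKMBDHVN"


def test_encode_maps_unknowns_to_4():
    assert encode("ACGTNX").tolist() == [0, 1, 2, 3, 4, 4]


def test_consensus_letter_argmax():
    assert iupac_letter(np.array([0.97, 0.01, 0.01, 0.01])) == "A"


def test_consensus_letter_full_degeneracy():
    assert iupac_letter(np.array([0.25, 0.25, 0.25, 0.25])) == "N"


def test_consensus_letter_two_way_tie_within_margin():
    # A and G within 0.1 of the top -> R
    assert iupac_letter(np.array([0.45, 0.05, 0.40, 0.10])) == "R"


def test_consensus_from_matrix():
    m = np.array([[1, 0, 0, 0], [0, 0, 0, 1]], dtype=float)
    assert consensus_from_matrix(m) == "AT"


# ---------------------------------------------------------------------------
# Pwm type


def test_pwm_autoconsensus_and_length():
    m = np.array([[1, 0, 0, 0], [0, 0, 0, 1]], dtype=float)
    pwm = Pwm(name="m", matrix=m)
    assert pwm.consensus == "AT"
    assert len(pwm) == 2


def test_pwm_rejects_bad_shape():
    with pytest.raises(ValueError):
        Pwm(name="m", matrix=np.ones((4, 3)))


def test_pwm_rejects_consensus_length_mismatch():
    with pytest.raises(ValueError):
        Pwm(name="m", matrix=np.full((3, 4), 0.25), consensus="AC")


def test_information_content_matches_entropy_formula(sharp_pwm):
    # per column: 2 - H(0.97, 0.01, 0.01, 0.01) bits
    h = -(0.97 * math.log2(0.97) + 3 * 0.01 * math.log2(0.01))
    expected = 8 * (2.0 - h)
    assert sharp_pwm.information_content() == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(14.1, abs=0.05)


def test_max_logodds_is_score_of_consensus(sharp_pwm):
    expected = 8 * math.log2(0.97 / 0.25)
    assert sharp_pwm.max_logodds() == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# HOMER-style I/O


HOMER_TEXT = """\
>AT\tm_at\t1.5
1\t0\t0\t0
0\t0\t0\t1
>ACGT\tm_acgt
0.97\t0.01\t0.01\t0.01
0.01\t0.97\t0.01\t0.01
0.01\t0.01\t0.97\t0.01
0.01\t0.01\t0.01\t0.97
"""


def test_parse_homer_basic():
    motifs = parse_homer_motifs(HOMER_TEXT)
    assert [m.name for m in motifs] == ["m_at", "m_acgt"]
    assert motifs[0].consensus == "AT"
    assert motifs[0].logodds_threshold == 1.5
    assert motifs[1].logodds_threshold is None
    # rows renormalized after pseudocount
    assert np.allclose(motifs[0].matrix.sum(axis=1), 1.0, atol=1e-9)
    assert motifs[0].matrix[0, 0] == pytest.approx((1 + 1e-3) / (1 + 4e-3))


def test_parse_homer_tf_map():
    motifs = parse_homer_motifs(HOMER_TEXT, tf_map={"m_at": "gene7"})
    assert motifs[0].tf_gene == "gene7"
    assert motifs[1].tf_gene is None


def test_parse_homer_roundtrip_matrices_equal():
    first = parse_homer_motifs(HOMER_TEXT)
    # the pseudocount was applied once at the first parse; re-parsing the
    # serialized (already-smoothed) matrices must not re-smooth them
    second = parse_homer_motifs(write_homer_motifs(first), pseudocount=0.0)
    for a, b in zip(first, second):
        assert a.consensus == b.consensus
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)


def test_parse_homer_malformed_row_names_line():
    bad = ">AT\tm\n1\t0\t0\n"
    with pytest.raises(ValueError, match="line 2"):
        parse_homer_motifs(bad)


def test_parse_homer_bad_probability_sum_names_line():
    bad = ">AT\tm\n1\t0\t0\t0\n0.5\t0.1\t0.1\t0.1\n"
    with pytest.raises(ValueError, match="line 3"):
        parse_homer_motifs(bad)


def test_parse_homer_illegal_consensus_letter():
    with pytest.raises(ValueError, match="line 1"):
        parse_homer_motifs(">AXT\tm\n1\t0\t0\t0\n")


def test_parse_homer_header_without_rows():
    with pytest.raises(ValueError, match="no matrix rows"):
        parse_homer_motifs(">AT\tm\n")


# ---------------------------------------------------------------------------
# PWM scanning


def test_scan_consensus_single_forward_hit(sharp_pwm):
    hits = scan_pwm("AACGTGAC", sharp_pwm)
    assert len(hits) == 1
    h = hits[0]
    assert (h.pos, h.strand, h.length) == (0, "+", 8)
    assert h.score == pytest.approx(sharp_pwm.max_logodds(), rel=1e-12)


def test_scan_revcomp_gives_minus_hit_same_score(sharp_pwm):
    fwd = scan_pwm("AACGTGAC", sharp_pwm)
    rev = scan_pwm(revcomp("AACGTGAC"), sharp_pwm)
    assert len(rev) == 1
    assert rev[0].strand == "-"
    assert rev[0].pos == 0
    assert rev[0].score == pytest.approx(fwd[0].score, rel=1e-12)


def test_scan_sequence_shorter_than_motif(sharp_pwm):
    assert scan_pwm("ACGT", sharp_pwm) == []


def test_scan_n_positions_score_zero_bits(sharp_pwm):
    # one N drops exactly one column's contribution
    full = sharp_pwm.max_logodds()
    per_col = math.log2(0.97 / 0.25)
    hits = scan_pwm("AACGNGAC", sharp_pwm, threshold=full - per_col - 1e-9)
    assert [h.strand for h in hits] == ["+"]
    assert hits[0].score == pytest.approx(full - per_col, rel=1e-9)


def naive_scan(seq, pwm, background, threshold):
    """Independent O(n*L) scorer used as the oracle."""
    bg = np.asarray(background, dtype=float)
    L = len(pwm)
    found = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for i in range(len(s) - L + 1):
            score = 0.0
            for j, base in enumerate(s[i:i + L]):
                if base in "ACGT":
                    score += math.log2(pwm.matrix[j, "ACGT".index(base)] / bg["ACGT".index(base)])
            if score >= threshold:
                pos = i if strand == "+" else len(s) - L - i
                found.add((pos, strand))
    return found


def test_scan_matches_naive_oracle_small():
    rng = np.random.default_rng(11)
    for trial in range(3):
        length = int(rng.integers(6, 11))
        matrix = rng.dirichlet(np.ones(4) * 0.5, size=length)
        pwm = Pwm(name=f"r{trial}", matrix=matrix)
        thr = 0.6 * pwm.max_logodds()
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            got = {(h.pos, h.strand) for h in scan_pwm(seq, pwm, threshold=thr)}
            assert got == naive_scan(seq, pwm, (0.25,) * 4, thr)


def test_scan_nonuniform_background():
    pwm = Pwm(name="m", matrix=np.array([[0.97, 0.01, 0.01, 0.01]] * 4))
    bg = (0.4, 0.1, 0.1, 0.4)
    expected = 4 * math.log2(0.97 / 0.4)
    hits = scan_pwm("AAAA", pwm, background=bg, threshold=expected - 1e-9)
    assert hits and hits[0].score == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# Consensus matching


def test_match_consensus_spec_example():
    # "ARG" against "AAGCAGG": windows AAG (pos 0) and AGG (pos 4) satisfy
    # A,[AG],G; reverse complement CYT matches nowhere
    hits = match_consensus("AAGCAGG", "ARG")
    assert [(h.pos, h.strand) for h in hits] == [(0, "+"), (4, "+")]


def test_match_consensus_reverse_strand():
    hits = match_consensus(revcomp("AAGCAGG"), "ARG")
    # mirrored positions: length 7, L 3 -> 7-0-3=4 and 7-4-3=0
    assert [(h.pos, h.strand) for h in hits] == [(0, "-"), (4, "-")]


def test_match_consensus_empty_consensus_rejected():
    with pytest.raises(ValueError):
        match_consensus("ACGT", "")


def test_match_consensus_illegal_letter_rejected():
    with pytest.raises(ValueError):
        match_consensus("ACGT", "AXG")


def test_match_consensus_absent_both_strands():
    assert match_consensus("AAAAAAAA", "CCG") == []


def test_match_consensus_n_in_sequence_never_matches():
    assert match_consensus("ANG", "AAG") == []
    # even a fully degenerate consensus letter rejects sequence N at 0 mismatches
    assert match_consensus("N", "N") == []
    # ... but one allowed mismatch admits it
    assert [h.pos for h in match_consensus("ANG", "ARG", max_mismatch=1)] == [0]


def test_match_consensus_max_mismatch():
    assert match_consensus("ACGTT", "ACGAA") == []
    hits = match_consensus("ACGTT", "ACGAA", max_mismatch=2)
    assert any(h.pos == 0 and h.strand == "+" for h in hits)


# ---------------------------------------------------------------------------
# Set-level scanning


def _random_promoters(rng, n, length=200):
    return prom_set({f"g{i}": "".join(rng.choice(list("ACGT"), size=length))
                     for i in range(n)})


def test_library_hits_equals_per_promoter_scan():
    rng = np.random.default_rng(3)
    proms = _random_promoters(rng, 8)
    motifs = [Pwm(name="a", matrix=np.tile([0.97, 0.01, 0.01, 0.01], (5, 1))),
              Pwm(name="b", matrix=rng.dirichlet([0.4] * 4, size=7))]
    for mode in ("consensus", "pwm"):
        lib = library_hits(motifs, proms, mode=mode)
        for pwm in motifs:
            single = promoter_hits(pwm, proms, mode=mode)
            got = {(g, h.pos, h.strand) for g, hs in lib[pwm.name].items() for h in hs}
            want = {(g, h.pos, h.strand) for g, hs in single.items() for h in hs}
            assert got == want


def test_library_hits_rejects_boundary_straddling_windows():
    # the word only exists across the junction of the two concatenated promoters
    proms = prom_set({"g1": "AAAAAACC", "g2": "GGAAAAAA"})
    lib = library_hits([Pwm(name="m", matrix=np.array(
        [[0.01, 0.97, 0.01, 0.01]] * 2 + [[0.01, 0.01, 0.97, 0.01]] * 2))],
        proms, mode="consensus")
    assert lib["m"] == {}


def test_library_hits_offsets_are_tss_relative():
    ps = PromoterSet()
    ps["g"] = PromoterRecord(gene="g", contig="g", tss=5, strand="+",
                             seq="AAAAACCGGTTT", tss_index=5,
                             window_start=0, window_end=12)
    lib = library_hits([Pwm(name="m", matrix=np.array(
        [[0.01, 0.97, 0.01, 0.01]] * 2 + [[0.01, 0.01, 0.97, 0.01]] * 2))], ps)
    offs = {(h.offset, h.strand) for h in lib["m"]["g"]}
    # CCGG starts at index 5 -> offset 0; its revcomp CCGG (palindrome) too
    assert offs == {(0, "+"), (0, "-")}


def test_motif_frequency_all_planted(sharp_pwm):
    proms = prom_set({f"g{i}": "TT" + "AACGTGAC" + "TT" for i in range(5)})
    frac, per_gene = motif_frequency(sharp_pwm, list(proms), proms)
    assert frac == 1.0
    assert all(per_gene.values())


def test_motif_frequency_disjoint_alphabet():
    pwm = Pwm(name="c", matrix=np.tile([0.01, 0.97, 0.01, 0.01], (6, 1)))
    proms = prom_set({f"g{i}": "A" * 50 for i in range(4)})
    frac, per_gene = motif_frequency(pwm, list(proms), proms)
    assert frac == 0.0
    assert not any(per_gene.values())


def test_motif_frequency_empty_set_rejected(sharp_pwm):
    with pytest.raises(ValueError):
        motif_frequency(sharp_pwm, [], prom_set({"g": "ACGT"}))


def test_motif_frequency_missing_promoter_rejected(sharp_pwm):
    with pytest.raises(KeyError):
        motif_frequency(sharp_pwm, ["absent"], prom_set({"g": "ACGT"}))


# ---------------------------------------------------------------------------
# Enrichment


def _enrichment_setup(n_with, n_without):
    word = "AAACCGGG"   # non-palindromic
    seqs = {}
    for i in range(n_with):
        seqs[f"p{i:02d}"] = "A" * 10 + word + "A" * 12
    for i in range(n_without):
        seqs[f"q{i:02d}"] = "A" * 30
    pwm = Pwm(name="m", matrix=np.array(
        [[0.97, 0.01, 0.01, 0.01]] * 3 + [[0.01, 0.97, 0.01, 0.01]] * 2
        + [[0.01, 0.01, 0.97, 0.01]] * 3))
    assert pwm.consensus == word
    return pwm, prom_set(seqs)


def test_enrichment_exact_tail_example():
    # N=20, K=10, n=5, k=5 -> C(10,5)/C(20,5) = 252/15504
    pwm, proms = _enrichment_setup(10, 10)
    fg = [f"p{i:02d}" for i in range(5)]
    res = enrichment_test(pwm, fg, list(proms), proms)
    assert (res.N, res.K, res.n, res.k) == (20, 10, 5, 5)
    assert res.pvalue == pytest.approx(252 / 15504, rel=1e-9)
    assert res.fold == pytest.approx((5 / 5) / (10 / 20))


def test_enrichment_saturation_foreground_equals_background():
    pwm, proms = _enrichment_setup(10, 10)
    res = enrichment_test(pwm, list(proms), list(proms), proms)
    assert res.k == res.K
    assert res.pvalue == pytest.approx(1.0)


def test_enrichment_k_zero_p_near_one():
    pwm, proms = _enrichment_setup(10, 10)
    fg = [f"q{i:02d}" for i in range(5)]
    res = enrichment_test(pwm, fg, list(proms), proms)
    assert res.k == 0
    assert 0 < res.pvalue <= 1.0


def test_enrichment_motif_absent_everywhere():
    pwm, proms = _enrichment_setup(0, 10)
    res = enrichment_test(pwm, list(proms)[:3], list(proms), proms)
    assert res.K == 0 and res.pvalue == 1.0 and res.fold is None


def test_enrichment_p_nonincreasing_in_k():
    # same (N, K, n), k swept by choosing more motif-bearing foreground genes
    pwm, proms = _enrichment_setup(10, 10)
    ps = []
    for k in range(6):
        fg = [f"p{i:02d}" for i in range(k)] + [f"q{i:02d}" for i in range(5 - k)]
        ps.append(enrichment_test(pwm, fg, list(proms), proms).pvalue)
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_enrichment_requires_subset():
    pwm, proms = _enrichment_setup(2, 2)
    with pytest.raises(ValueError):
        enrichment_test(pwm, ["nope"], list(proms), proms)


def exact_hypergeom_tail(N, K, n, k):
    total = Fraction(math.comb(N, n))
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j))
    return acc / total


def test_enrichment_against_exact_rational_tail_spot_checks():
    from scipy import stats
    rng = np.random.default_rng(5)
    for _ in range(200):
        N = int(rng.integers(2, 31))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        got = float(stats.hypergeom.sf(k - 1, N, K, n))
        want = float(exact_hypergeom_tail(N, K, n, k))
        assert got == pytest.approx(want, abs=1e-12)


def test_bh_adjust_known_example():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_adjust_preserves_order_and_bounds():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    adj = bh_adjust(p)
    assert ((adj >= p - 1e-15) & (adj <= 1.0 + 1e-15)).all()
    # adjusted values keep the ordering of the raw ones
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# Strand-flip invariance


def test_strand_flip_leaves_hit_counts_invariant(sharp_pwm):
    rng = np.random.default_rng(9)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = match_consensus(seq, sharp_pwm.consensus)
        rev = match_consensus(revcomp(seq), sharp_pwm.consensus)
        assert len(fwd) == len(rev)
        # each + hit maps to a - hit at the mirrored position and vice versa
        mirrored = {(len(seq) - h.pos - h.length, {"+": "-", "-": "+"}[h.strand])
                    for h in fwd}
        assert mirrored == {(h.pos, h.strand) for h in rev}
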