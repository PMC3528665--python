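import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haloriscan.genome_io import GeneFeature, Replicon
from haloriscan.orb_discovery import (
    IntergenicRegion,
    at_rich_segment,
    detect_g_string,
    discover_motifs,
    extract_flanking_irs,
    pair_inverted,
    scan_motif,
    _revcomp_str,
)
from haloriscan.synthetic_data import SHARED_ORB, mutate_sequence, random_dna


def _ir(seq, start=0, rid="r", gene="g", side="upstream"):
    return IntergenicRegion(rid, gene, side, start, start + len(seq), seq)


# ---------------------------------------------------------------------------
# IR extraction
# ---------------------------------------------------------------------------

def _two_gene_replicon(strand="+"):
    seq = random_dna(600, 0.6, np.random.default_rng(1))
    feats = [GeneFeature("g1", "CDS", 100, 200, strand),
             GeneFeature("g2", "CDS", 400, 500, "+")]
    return Replicon(id="r", sequence=seq, topology="linear", features=feats)


def test_ir_between_adjacent_genes_plus_strand():
    rep = _two_gene_replicon("+")
    irs = extract_flanking_irs(rep, rep.features[0])
    by_side = {ir.side: ir for ir in irs}
    assert (by_side["downstream"].start, by_side["downstream"].end) == (200, 400)
    assert by_side["upstream"].start == 0 and by_side["upstream"].end == 100


def test_ir_side_flips_with_gene_strand():
    rep = _two_gene_replicon("-")
    irs = extract_flanking_irs(rep, rep.features[0])
    by_side = {ir.side: ir for ir in irs}
    assert (by_side["upstream"].start, by_side["upstream"].end) == (200, 400)


def test_ir_wraps_circular_origin_with_rotation_oracle():
    rng = np.random.default_rng(2)
    seq = random_dna(1000, 0.6, rng)
    feats = [GeneFeature("a", "CDS", 850, 950, "+"),
             GeneFeature("b", "CDS", 100, 300, "+")]
    rep = Replicon(id="c", sequence=seq, topology="circular", features=feats)
    irs = extract_flanking_irs(rep, feats[0])
    down = {ir.side: ir for ir in irs}["downstream"]
    assert down.wraps
    assert len(down) == 150  # 50 to the origin + 100 beyond
    # rotation oracle: rotate so no wrap occurs, recompute, compare sequence
    rot = 500
    rep2 = Replicon(id="c2", sequence=seq[rot:] + seq[:rot], topology="circular",
                    features=[GeneFeature("a", "CDS", 350, 450, "+"),
                              GeneFeature("b", "CDS", 600, 800, "+")])
    irs2 = extract_flanking_irs(rep2, rep2.features[0])
    down2 = {ir.side: ir for ir in irs2}["downstream"]
    assert down2.sequence == down.sequence


def test_ir_capped_at_max_span_keeps_gene_proximal_part():
    seq = random_dna(12_000, 0.6, np.random.default_rng(3))
    feats = [GeneFeature("a", "CDS", 100, 400, "+"),
             GeneFeature("b", "CDS", 11_000, 11_500, "+")]
    rep = Replicon(id="r", sequence=seq, topology="linear", features=feats)
    down = {ir.side: ir for ir in extract_flanking_irs(rep, feats[0], max_span=5000)}["downstream"]
    assert (down.start, down.end) == (400, 5400)


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------

def _planted_irs(consensus, n_with=8, n_without=2, length=250, mutation=0.0,
                 seed=0, reverse=False):
    rng = np.random.default_rng(seed)
    irs = []
    for i in range(n_with + n_without):
        seq = random_dna(length, 0.6, rng)
        if i < n_with:
            inst = mutate_sequence(consensus, mutation, rng)
            if reverse:
                inst = _revcomp_str(inst)
            pos = int(rng.integers(0, length - len(consensus)))
            seq = seq[:pos] + inst + seq[pos + len(inst):]
        irs.append(_ir(seq, rid=f"r{i}", gene=f"g{i}"))
    return irs


PLANTED = "TTACGATCAGGCATTACGGATTCAGCTAGT"  # 30-mer, no G-string


def _strand_hamming(consensus: str, planted: str) -> int:
    """Hamming distance to a planted motif, either strand form (a ZOOPS
    model over both strands is defined only up to reverse complement)."""
    fwd = sum(a != b for a, b in zip(consensus, planted))
    rev = sum(a != b for a, b in zip(consensus, _revcomp_str(planted)))
    return min(fwd, rev)


def test_discover_recovers_planted_consensus():
    irs = _planted_irs(PLANTED, seed=5)
    models = discover_motifs(irs, width_min=30, width_max=30, n_restarts=6, seed=1)
    assert _strand_hamming(models[0].consensus, PLANTED) <= 1


def test_discover_recovers_reverse_strand_motif():
    irs = _planted_irs(PLANTED, seed=6, reverse=True)
    models = discover_motifs(irs, width_min=30, width_max=30, n_restarts=6, seed=1)
    cons = models[0].consensus
    d_fwd = sum(a != b for a, b in zip(cons, PLANTED))
    d_rev = sum(a != b for a, b in zip(cons, _revcomp_str(PLANTED)))
    assert min(d_fwd, d_rev) <= 1
    # occurrences are reported with the matching orientation
    els = scan_motif(irs[0], models[0], min_bits=10)
    assert len(els) == 1


def test_discover_null_scores_below_planted_signal():
    irs_null = _planted_irs(PLANTED, n_with=0, n_without=10, seed=7)
    irs_sig = _planted_irs(PLANTED, seed=7)
    m_null = discover_motifs(irs_null, width_min=30, width_max=30, n_restarts=6, seed=2)
    m_sig = discover_motifs(irs_sig, width_min=30, width_max=30, n_restarts=6, seed=2)
    assert m_sig[0].llr > 2 * m_null[0].llr


def test_discover_deterministic_given_seed():
    irs = _planted_irs(PLANTED, seed=8)
    a = discover_motifs(irs, width_min=30, width_max=30, n_restarts=4, seed=9)
    b = discover_motifs(irs, width_min=30, width_max=30, n_restarts=4, seed=9)
    assert np.array_equal(a[0].pfm, b[0].pfm)
    assert a[0].llr == b[0].llr


def test_discover_input_validation():
    with pytest.raises(ValueError):
        discover_motifs([_ir("ACGT" * 20)])
    with pytest.raises(ValueError):
        discover_motifs([_ir("ACGTACGT"), _ir("ACGTACGT")], width_min=20)


def test_pfm_columns_sum_to_one():
    irs = _planted_irs(PLANTED, seed=10)
    m = discover_motifs(irs, width_min=20, width_max=40, n_restarts=3, seed=0)[0]
    assert np.allclose(m.pfm.sum(axis=1), 1.0, atol=1e-9)
    # scoring pure background sequence averages at or below zero
    rng = np.random.default_rng(0)
    bg_ir = _ir(random_dna(4000, 0.6, rng))
    scores = []
    codes_lo = m.log_odds
    for off in range(0, 4000 - m.width, m.width):
        window = bg_ir.sequence[off:off + m.width]
        scores.append(sum(codes_lo[i, "ACGT".index(c)] for i, c in enumerate(window)))
    assert np.mean(scores) < 0


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def test_scan_finds_planted_position_exactly_once():
    rng = np.random.default_rng(11)
    irs = _planted_irs(PLANTED, seed=11)
    model = discover_motifs(irs, width_min=30, width_max=30, n_restarts=6, seed=0)[0]
    seq = random_dna(400, 0.6, rng)
    target = seq[:200] + model.consensus + seq[200:]
    els = scan_motif(_ir(target), model, min_bits=10)
    assert [e.offset for e in els] == [200]
    assert els[0].sequence == model.consensus


def test_scan_unsatisfiable_threshold_returns_empty():
    irs = _planted_irs(PLANTED, seed=12)
    model = discover_motifs(irs, width_min=30, width_max=30, n_restarts=4, seed=0)[0]
    assert scan_motif(irs[0], model, min_bits=model.max_bits + 1) == []


def test_scan_invariant_under_reverse_complement():
    irs = _planted_irs(PLANTED, seed=13)
    model = discover_motifs(irs, width_min=30, width_max=30, n_restarts=6, seed=0)[0]
    ir = irs[0]
    els = scan_motif(ir, model, min_bits=10)
    rc = _ir(_revcomp_str(ir.sequence))
    els_rc = scan_motif(rc, model, min_bits=10)
    remapped = sorted((len(ir) - e.offset - e.length,
                       "reverse" if e.orientation == "forward" else "forward",
                       round(e.score, 6)) for e in els)
    direct = sorted((e.offset, e.orientation, round(e.score, 6)) for e in els_rc)
    assert remapped == direct


# ---------------------------------------------------------------------------
# G-string detection
# ---------------------------------------------------------------------------

def test_g_string_on_shared_orb_element():
    g = detect_g_string(SHARED_ORB)
    assert g is not None
    assert g.run_length == 7
    # the run ends one base before the 3' end
    assert g.offset + g.run_length == len(SHARED_ORB) - 1


def test_g_string_absent_without_g():
    assert detect_g_string("AAAA") is None
    assert detect_g_string("ATATGGGATAT" * 3, min_run=5) is None


def test_g_string_interior_run_is_ignored():
    seq = "AT" * 8 + "G" * 6 + "AT" * 8  # run ends 16 bp from the 3' end
    assert detect_g_string(seq, min_run=5, terminal_window=10) is None


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(min_value=5, max_value=12), st.integers(min_value=0, max_value=6))
def test_g_string_run_grows_by_one_when_g_appended(run, pad):
    seq = "ATCTA" + "C" * pad + "G" * run
    base = detect_g_string(seq, min_run=5, terminal_window=10)
    plus = detect_g_string(seq + "G", min_run=5, terminal_window=10)
    assert base is not None and plus is not None
    assert plus.run_length == base.run_length + 1


def test_g_string_invariant_to_bases_outside_terminal_windows():
    rng = np.random.default_rng(14)
    core = random_dna(20, 0.6, rng).replace("G", "A")
    seq = "GGGGGT" + core + "TGGGGGGG"
    ref = detect_g_string(seq)
    mutated = seq[:10] + random_dna(len(seq) - 20, 0.5, rng).replace("G", "C") + seq[-10:]
    assert detect_g_string(mutated) == ref


# ---------------------------------------------------------------------------
# Inverted-repeat pairing
# ---------------------------------------------------------------------------

def _el(offset, orientation, score, length=30):
    from haloriscan.orb_discovery import ORBElement

    return ORBElement(ir=_ir("A" * 600), offset=offset, length=length,
                      orientation=orientation, sequence="G" * length, score=score)


def test_pairing_unique_match():
    f, r = _el(10, "forward", 20.0), _el(160, "reverse", 18.0)
    pairs, singles = pair_inverted([f, r], max_gap=400)
    assert len(pairs) == 1 and singles == []
    assert pairs[0].gap == 120
    assert pairs[0].interval == (10, 190)


def test_pairing_same_orientation_yields_singletons():
    a, b = _el(10, "forward", 20.0), _el(200, "forward", 15.0)
    pairs, singles = pair_inverted([a, b])
    assert pairs == [] and len(singles) == 2


def _assignment_oracle(fwd, rev, max_gap=400):
    def feasible(f, r):
        left, right = (f, r) if f.offset <= r.offset else (r, f)
        return 0 <= right.offset - (left.offset + left.length) <= max_gap

    best = 0.0
    for k in range(min(len(fwd), len(rev)) + 1):
        for fs in itertools.permutations(fwd, k):
            for rs in itertools.permutations(rev, k):
                if all(feasible(f, r) for f, r in zip(fs, rs)):
                    best = max(best, sum(f.score + r.score for f, r in zip(fs, rs)))
    return best


def test_pairing_matches_exhaustive_assignment_oracle_on_planted_layout():
    """Three well-separated planted inverted pairs: greedy matching attains
    the exhaustive-assignment optimum exactly."""
    rng = np.random.default_rng(15)
    for _ in range(20):
        fwd, rev = [], []
        for k in range(3):
            base = 900 * k  # blocks far enough apart that no cross-block pair is feasible
            gap = int(rng.integers(40, 200))
            fwd.append(_el(base, "forward", float(rng.uniform(8, 30))))
            rev.append(_el(base + 30 + gap, "reverse", float(rng.uniform(8, 30))))
        pairs, singles = pair_inverted(fwd + rev, max_gap=400)
        got = sum(p.forward.score + p.reverse.score for p in pairs)
        assert len(pairs) == 3 and singles == []
        assert got == pytest.approx(_assignment_oracle(fwd, rev))


def test_pairing_never_exceeds_assignment_oracle_random_layouts():
    rng = np.random.default_rng(16)
    for _ in range(10):
        fwd = [_el(int(o), "forward", float(s))
               for o, s in zip(rng.integers(0, 300, 3), rng.uniform(8, 30, 3))]
        rev = [_el(int(o) + 320, "reverse", float(s))
               for o, s in zip(rng.integers(0, 300, 3), rng.uniform(8, 30, 3))]
        pairs, _ = pair_inverted(fwd + rev, max_gap=400)
        got = sum(p.forward.score + p.reverse.score for p in pairs)
        assert got <= _assignment_oracle(fwd, rev) + 1e-9


def test_pairing_respects_max_gap():
    f, r = _el(0, "forward", 20.0), _el(500, "reverse", 20.0)
    pairs, singles = pair_inverted([f, r], max_gap=400)
    assert pairs == [] and len(singles) == 2


# ---------------------------------------------------------------------------
# AT-rich segments
# ---------------------------------------------------------------------------

def test_at_rich_all_at_ir():
    ir = _ir("AT" * 100)
    seg = at_rich_segment(ir, background_gc=0.62)
    assert seg.at_fraction == 1.0
    assert (seg.start, seg.end) == (0, 200)


def test_at_rich_absent_at_background_composition():
    rng = np.random.default_rng(16)
    ir = _ir(random_dna(400, 0.62, rng))
    assert at_rich_segment(ir, background_gc=0.62) is None


def test_at_rich_planted_island_reciprocal_overlap():
    rng = np.random.default_rng(17)
    island = random_dna(80, 0.12, rng)
    seq = random_dna(150, 0.62, rng) + island + random_dna(150, 0.62, rng)
    seg = at_rich_segment(_ir(seq), background_gc=0.62)
    assert seg is not None
    inter = max(0, min(seg.end, 230) - max(seg.start, 150))
    assert inter / 80 >= 0.8
    assert inter / (seg.end - seg.start) >= 0.8


def test_at_rich_requires_window_length():
    with pytest.raises(ValueError):
        at_rich_segment(_ir("ATAT"), background_gc=0.6, window=50)
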