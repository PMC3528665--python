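"""ORB (origin recognition box) element discovery in intergenic regions.

Archaeal replication origins carry ~20-40 bp ORB repeats, typically as an
inverted pair flanking an AT-rich duplex-unwinding element, and in
haloarchaea the ORB ends in a "G-string" (a long G run).  This module

* extracts the intergenic regions (IRs) flanking initiator genes,
* learns an ORB motif from a set of IRs with a ZOOPS ("zero or one
  occurrence per sequence") EM mixture model over both strands,
* scans IRs with the learned position weight matrix,
* detects terminal G-strings, pairs inverted occurrences, and finds
  AT-rich segments against the high-GC (~62%) genomic background.

The EM is the classic two-component ZOOPS mixture: each sequence either
contains no occurrence (probability 1-gamma) or exactly one occurrence at
a uniformly chosen position/strand (probability gamma/m_i per placement).
The E-step computes posterior placement responsibilities from the
motif/background likelihood ratio; the M-step re-estimates the position
frequency matrix from responsibility-weighted window counts and gamma
from the expected number of motif-bearing sequences.  The log likelihood
is expressed relative to the all-background model, so the converged value
is directly the likelihood-ratio score of the motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import GeneFeature, Replicon, gc_fraction

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}  # A<->T, C<->G, N->N
DEFAULT_WIDTH_GRID = (20, 25, 30, 35, 40)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IntergenicRegion:
    replicon_id: str
    gene_ref: str
    side: str  # upstream | downstream (relative to the gene's orientation)
    start: int  # replicon coordinate, 0-based
    end: int  # exclusive; < start when the IR wraps a circular origin
    sequence: str
    wraps: bool = False
    gene_at: str = "left"  # which IR end abuts the anchoring gene

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GString:
    offset: int  # run start within the element (motif orientation)
    run_length: int


@dataclass
class MotifModel:
    width: int
    pfm: np.ndarray  # (width, 4) column-stochastic
    background: np.ndarray  # (4,)
    pseudo_count: float
    llr: float  # converged ZOOPS log likelihood ratio (nats)
    score: float  # width-penalized ranking score
    gamma: float
    n_expected_sites: float
    motif_id: int = 0
    g_tier: int = 0  # 2: consensus G-run at 3' end; 1: at 5' end; 0: none

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 odds of the smoothed PFM against the background."""
        return np.log2(self.pfm / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=1))

    @property
    def max_bits(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class ORBElement:
    ir: IntergenicRegion
    offset: int  # forward-strand offset within the IR
    length: int
    orientation: str  # forward | reverse (motif orientation)
    sequence: str  # in motif orientation
    score: float  # log-odds bits
    g_string: GString | None = None
    motif_id: int = 0

    @property
    def replicon_interval(self) -> tuple[int, int]:
        return (self.ir.start + self.offset, self.ir.start + self.offset + self.length)


@dataclass
class InvertedPair:
    forward: ORBElement
    reverse: ORBElement
    gap: int

    @property
    def interval(self) -> tuple[int, int]:
        """Enclosed interval in IR coordinates (outer span of the pair)."""
        s = min(self.forward.offset, self.reverse.offset)
        e = max(self.forward.offset + self.forward.length,
                self.reverse.offset + self.reverse.length)
        return (s, e)


@dataclass
class ATRichSegment:
    start: int  # IR coordinates
    end: int
    at_fraction: float
    background_gc: float


# ---------------------------------------------------------------------------
# IR extraction
# ---------------------------------------------------------------------------

def extract_flanking_irs(
    replicon: Replicon, gene: GeneFeature, max_span: int = 5000
) -> list[IntergenicRegion]:
    """The annotation-free intervals on each side of a gene, capped at
    ``max_span`` bp measured from the gene boundary.  On circular replicons
    the interval wraps through the coordinate origin.  A side whose nearest
    neighbour abuts or overlaps the gene yields no IR.
    """
    genes = sorted(
        (f for f in replicon.features if f.kind in {"CDS", "rRNA", "tRNA"}),
        key=lambda f: (f.start, f.locus_tag),
    )
    try:
        idx = next(i for i, f in enumerate(genes) if f.locus_tag == gene.locus_tag)
    except StopIteration:
        raise ValueError(f"gene {gene.locus_tag} not on replicon {replicon.id}") from None
    L = len(replicon)
    circular = replicon.topology == "circular"
    n = len(genes)
    out: list[IntergenicRegion] = []

    def _emit(start: int, gap: int, anchored_left: bool) -> tuple[int, int] | None:
        # region of length `gap` beginning at `start` (mod L); truncate to
        # max_span keeping the gene-adjacent side
        if gap <= 0:
            return None
        if gap > max_span:
            if anchored_left:
                gap = max_span
            else:
                start = (start + (gap - max_span)) % L
                gap = max_span
        return start, (start + gap) % L if circular else start + gap

    # right side: from gene.end to next gene's start
    if circular:
        nxt = genes[(idx + 1) % n]
        right_gap = (nxt.start - gene.end) % L if n > 1 else L - gene.length(L)
    else:
        right_gap = (genes[idx + 1].start if idx + 1 < n else L) - gene.end
    right = _emit(gene.end % L, right_gap, anchored_left=True)
    # left side: from previous gene's end to gene.start
    if circular:
        prv = genes[(idx - 1) % n]
        left_gap = (gene.start - prv.end) % L if n > 1 else 0 if n == 1 and right is not None else 0
    else:
        left_gap = gene.start - (genes[idx - 1].end if idx > 0 else 0)
    left_start = (gene.start - left_gap) % L if circular else gene.start - left_gap
    left = _emit(left_start, left_gap, anchored_left=False)

    for region, is_left in ((left, True), (right, False)):
        if region is None:
            continue
        s, e = region
        side = "upstream" if (is_left == (gene.strand == "+")) else "downstream"
        wraps = e < s or (e == s and circular)
        seq = replicon.fetch(s, e) if not (e == s) else ""
        if not seq:
            continue
        out.append(IntergenicRegion(replicon.id, gene.locus_tag, side, s, e, seq,
                                    wraps, gene_at="right" if is_left else "left"))
    out.sort(key=lambda ir: 0 if ir.side == "upstream" else 1)
    return out


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery
# ---------------------------------------------------------------------------

def trim_ir_proximal(ir: IntergenicRegion, limit: int, replicon_length: int) -> IntergenicRegion:
    """Keep the ``limit`` bp of an IR nearest its anchoring gene.

    ORB elements sit directly adjacent to the initiator gene, so the distal
    part of a long IR only adds scan noise and EM cost.
    """
    if limit <= 0 or len(ir) <= limit:
        return ir
    if ir.gene_at == "right":
        seq = ir.sequence[-limit:]
        start = (ir.end - limit) % replicon_length
        end = ir.end
    else:
        seq = ir.sequence[:limit]
        start = ir.start
        end = (ir.start + limit) % replicon_length
    return IntergenicRegion(ir.replicon_id, ir.gene_ref, ir.side, start, end,
                            seq, wraps=end < start, gene_at=ir.gene_at)


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.array([_COMP[int(c)] for c in codes[::-1]], dtype=np.int8)


def background_composition(seqs: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        codes = encode(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    return counts / total if total else np.full(4, 0.25)


class _Placements:
    """Precomputed window index matrix for one width over an IR set.

    Rows are every placement (position x strand) of every sequence; entries
    are base codes (0..3, 4 for N).  Reverse-strand windows are stored in
    motif orientation so one PWM scores both strands.
    """

    def __init__(self, seqs: list[str], width: int):
        self.width = width
        windows = []
        seq_index = []
        meta = []  # (seq_i, forward_offset, orientation)
        for si, s in enumerate(seqs):
            codes = encode(s)
            L = len(codes)
            if L < width:
                continue
            fwd = sliding_window_view(codes, width)
            rc = sliding_window_view(revcomp_codes(codes), width)
            for j in range(L - width + 1):
                meta.append((si, j, "forward"))
            for j in range(L - width + 1):
                meta.append((si, L - width - j, "reverse"))
            windows.append(np.vstack([fwd, rc]))
            seq_index.extend([si] * 2 * (L - width + 1))
        if not windows:
            raise ValueError(f"no sequence admits width {width}")
        self.W = np.vstack(windows).astype(np.int64)
        # flattened indices into a row-major (width, 5) matrix, one gather per scan
        self.Wflat = self.W + (np.arange(width) * 5)[None, :]
        self.seq_index = np.array(seq_index)
        self.meta = meta
        self.n_seqs = int(self.seq_index.max()) + 1
        self.m = np.bincount(self.seq_index, minlength=self.n_seqs).astype(float)

    def window_scores(self, M: np.ndarray) -> np.ndarray:
        """Sum M[i, base_i] over window columns; M is (width, 5)."""
        return M.ravel()[self.Wflat].sum(axis=1)

    def weighted_counts(self, z: np.ndarray) -> np.ndarray:
        """(width, 5) responsibility-weighted base counts."""
        flat = np.bincount(
            self.Wflat.ravel(),
            weights=np.repeat(z, self.width),
            minlength=self.width * 5,
        )
        return flat.reshape(self.width, 5)


def _g_run_arrays(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """run_end[i]: length of the G run ending at i; run_start[i]: starting at i."""
    g = codes == 2
    run_end = np.zeros(len(codes), dtype=int)
    acc = 0
    for i, flag in enumerate(g):
        acc = acc + 1 if flag else 0
        run_end[i] = acc
    run_start = np.zeros(len(codes), dtype=int)
    acc = 0
    for i in range(len(g) - 1, -1, -1):
        acc = acc + 1 if g[i] else 0
        run_start[i] = acc
    return run_end, run_start


def _gstring_seed_mask(pl: _Placements, min_run: int = 5, terminal_window: int = 10) -> np.ndarray:
    """Placements whose window carries a long G run near either end -- used
    only to bias EM restarts toward ORB-like (G-string bearing) windows."""
    w = pl.width
    tw = min(terminal_window, w)
    mask = np.zeros(len(pl.W), dtype=bool)
    run_end = np.zeros_like(pl.W)
    acc = np.zeros(len(pl.W), dtype=np.int64)
    for i in range(w):
        acc = np.where(pl.W[:, i] == 2, acc + 1, 0)
        run_end[:, i] = acc
    tail = run_end[:, w - tw:].max(axis=1)
    head = run_end[:, :tw].max(axis=1)
    mask = (tail >= min_run) | (head >= min_run)
    return mask


def _pfm_from_window(window: np.ndarray, background: np.ndarray) -> np.ndarray:
    w = len(window)
    pfm = np.full((w, 4), 0.15 / 3)
    for i in range(w):
        b = int(window[i])
        if b < 4:
            pfm[i, b] = 0.85
        else:
            pfm[i] = background
    return pfm / pfm.sum(axis=1, keepdims=True)


def _zoops_em(
    pl: _Placements,
    background: np.ndarray,
    init_pfm: np.ndarray,
    pseudo: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, float]:
    """Run ZOOPS EM from an initial PFM; returns (pfm, gamma, llr)."""
    w = pl.width
    pfm = np.array(init_pfm, dtype=float)
    gamma = 0.5
    prev_ll = -np.inf
    n = pl.n_seqs
    bg5 = np.append(background, 1.0)
    for _ in range(max_iter):
        M = np.zeros((w, 5))
        M[:, :4] = np.log(pfm / background[None, :])
        scores = pl.window_scores(M)
        lr = np.exp(np.clip(scores, -700, 700))
        S = np.bincount(pl.seq_index, weights=lr, minlength=n)
        denom = (1.0 - gamma) + (gamma / pl.m) * S
        ll = float(np.log(denom).sum())
        z = (gamma / pl.m)[pl.seq_index] * lr / denom[pl.seq_index]
        Q = np.bincount(pl.seq_index, weights=z, minlength=n)
        gamma = float(np.clip(Q.mean(), 1.0 / (2 * n), 1 - 1.0 / (2 * n)))
        counts = pl.weighted_counts(z)
        counts[:, :4] += counts[:, 4:5] * background[None, :]  # N mass -> background
        pfm = (counts[:, :4] + pseudo * background[None, :])
        pfm /= pfm.sum(axis=1, keepdims=True)
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return pfm, gamma, prev_ll


def _gstring_tier(consensus: str, min_run: int, terminal_window: int) -> int:
    """Rank a consensus by where its G-string sits: 2 when a qualifying run
    ends within the terminal window of the 3' end (the canonical ORB form,
    in the orientation the scanner reports elements), 1 when it begins near
    the 5' end, 0 when absent or interior."""
    g = detect_g_string(consensus, min_run=min_run, terminal_window=terminal_window)
    if g is None:
        return 0
    if len(consensus) - (g.offset + g.run_length) < terminal_window:
        return 2
    return 1


def _refine_register(pl, background, pfm, gamma, ll, pseudo, tol, max_iter):
    """Try shifted registers of a converged model (columns rolled left or
    right, vacated columns reset to background) and keep the best fit; EM
    register is a local optimum and commonly lands a few columns off."""
    best = (pfm, gamma, ll)
    w = pl.width
    for _round in range(4):  # hill-climb: registers can be several columns off
        improved = False
        base = best[0]
        for shift in (-3, -2, -1, 1, 2, 3):
            shifted = np.tile(background, (w, 1)).astype(float)
            if shift > 0:
                shifted[shift:] = base[:w - shift]
            else:
                shifted[:w + shift] = base[-shift:]
            p2, g2, ll2 = _zoops_em(pl, background, shifted, pseudo, tol, max_iter)
            if ll2 > best[2] + 1e-9:
                best = (p2, g2, ll2)
                improved = True
        if not improved:
            break
    return best


def discover_motifs(
    irs: list[IntergenicRegion],
    width_min: int = 20,
    width_max: int = 40,
    width_step: int = 5,
    n_restarts: int = 20,
    seed: int = 0,
    pseudo_count: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 200,
    background: np.ndarray | None = None,
    g_string_rank: tuple[int, int] | None = None,
) -> list[MotifModel]:
    """ZOOPS EM motif discovery over both strands of an IR set.

    For each width in the grid, ``n_restarts`` seeded starts are run to
    convergence and the best model kept; models are returned ranked by a
    BIC-penalized likelihood-ratio score (the penalty stops wider windows
    from absorbing uninformative flanking columns).

    When ``g_string_rank=(min_run, terminal_window)`` is given, converged
    models whose consensus carries a terminal G-string outrank those that
    do not.  The origin pipeline uses this to keep the search aimed at
    ORBs rather than at the AT-rich unwinding element -- itself a strong
    positional signal in origin IRs -- and to pin the reported motif to
    the G-form strand so element sequences carry the G-string rather than
    its complement.  With the default ``None`` the search is purely
    likelihood-driven.  Deterministic for a fixed seed and IR order.
    """
    if len(irs) < 2:
        raise ValueError("motif discovery requires at least 2 intergenic regions")
    seqs = [ir.sequence for ir in irs]
    if max(len(s) for s in seqs) < width_min:
        raise ValueError(f"all IRs shorter than minimum motif width {width_min}")
    if background is None:
        background = background_composition(seqs)
    background = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    models: list[MotifModel] = []
    placements: dict[int, _Placements] = {}
    widths = [w for w in range(width_min, width_max + 1, width_step)
              if any(len(s) >= w for s in seqs)]
    for w in widths:
        pl = _Placements(seqs, w)
        g_candidates = np.flatnonzero(_gstring_seed_mask(pl))
        n_cand = max(12 * n_restarts, 80)
        pools = []
        if len(g_candidates):
            pools.append(rng.choice(g_candidates, size=n_cand // 2))
        pools.append(rng.choice(len(pl.W), size=n_cand - (len(pools) and n_cand // 2)))
        candidates = np.unique(np.concatenate(pools))
        # seed triage (MEME-style): a window sitting inside a genuine motif
        # occurrence has near-identical windows in many other sequences;
        # converge full EM only from the most enriched candidates
        triage = []
        for idx in candidates:
            ident = (pl.W == pl.W[idx]).sum(axis=1) / w
            per_seq = np.zeros(pl.n_seqs)
            np.maximum.at(per_seq, pl.seq_index, ident)
            n_sharing = int((per_seq >= 0.75).sum())
            triage.append((n_sharing, float(ident.sum()), int(idx)))
        triage.sort(key=lambda t: (-t[0], -t[1]))
        starts = [idx for _n, _s, idx in triage[:n_restarts]]
        best = None
        best_key = None
        for start_idx in starts:
            init = _pfm_from_window(pl.W[start_idx], background)
            pfm, gamma, ll = _zoops_em(pl, background, init, pseudo_count, tol, max_iter)
            if g_string_rank is not None:
                cons = "".join(BASES[i] for i in pfm.argmax(axis=1))
                tier = _gstring_tier(cons, *g_string_rank)
            else:
                tier = 0
            key = (tier, ll)
            if best_key is None or key > best_key:
                best, best_key = (pfm, gamma, ll, tier), key
        pfm, gamma, ll, tier = best
        nsites = max(gamma * pl.n_seqs, 2.0)
        penalty = 1.5 * w * np.log(nsites)
        models.append(MotifModel(
            width=w, pfm=pfm, background=background, pseudo_count=pseudo_count,
            llr=ll, score=ll - penalty, gamma=gamma, n_expected_sites=gamma * pl.n_seqs,
            g_tier=tier,
        ))
        placements[w] = pl

    def rank(ms):
        ms.sort(key=lambda m: (-m.g_tier, -m.score) if g_string_rank is not None
                else (-m.score,))

    rank(models)
    # register hill-climb on the ranking winner only (EM register is a local
    # optimum and commonly lands a few columns off); the tier is recomputed
    # from the refined consensus, and if refinement demotes the winner the
    # next-ranked model gets its turn
    refined: set[int] = set()
    for _ in range(min(3, len(models))):
        top = models[0]
        if top.width in refined:
            break
        refined.add(top.width)
        pl = placements[top.width]
        pfm, gamma, ll = _refine_register(
            pl, background, top.pfm, top.gamma, top.llr, pseudo_count, tol,
            min(max_iter, 60))
        top.pfm, top.gamma, top.llr = pfm, gamma, ll
        top.n_expected_sites = gamma * pl.n_seqs
        top.score = ll - 1.5 * top.width * np.log(max(gamma * pl.n_seqs, 2.0))
        if g_string_rank is not None:
            top.g_tier = _gstring_tier(top.consensus, *g_string_rank)
        rank(models)
        if models[0] is top:
            break
    for i, m in enumerate(models):
        m.motif_id = i
    return models


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def scan_motif(ir: IntergenicRegion, motif: MotifModel, min_bits: float = 8.0) -> list[ORBElement]:
    """All non-overlapping occurrences with log-odds >= ``min_bits``.

    Both strands are scanned; overlaps are resolved greedily, highest score
    first with ties broken leftmost then forward-strand first.
    """
    w = motif.width
    if w > len(ir):
        raise ValueError(f"motif width {w} exceeds IR length {len(ir)}")
    codes = encode(ir.sequence)
    M = np.zeros((w, 5))
    M[:, :4] = motif.log_odds
    hits: list[tuple[float, int, int, str]] = []
    for orientation, arr in (("forward", codes), ("reverse", revcomp_codes(codes))):
        win = sliding_window_view(arr, w)
        scores = np.zeros(len(win))
        for i in range(w):
            scores += M[i, win[:, i]]
        for j in np.flatnonzero(scores >= min_bits):
            fwd_off = int(j) if orientation == "forward" else len(ir) - w - int(j)
            hits.append((float(scores[j]), fwd_off, 0 if orientation == "forward" else 1, orientation))
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    chosen: list[ORBElement] = []
    occupied: list[tuple[int, int]] = []
    for score, off, _t, orientation in hits:
        if any(off < e and off + w > s for s, e in occupied):
            continue
        occupied.append((off, off + w))
        subseq = ir.sequence[off:off + w]
        if orientation == "reverse":
            subseq = _revcomp_str(subseq)
        chosen.append(ORBElement(
            ir=ir, offset=off, length=w, orientation=orientation,
            sequence=subseq, score=round(score, 3), motif_id=motif.motif_id,
        ))
    chosen.sort(key=lambda e: e.offset)
    return chosen


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# G-string detection
# ---------------------------------------------------------------------------

def detect_g_string(element_seq: str, min_run: int = 5, terminal_window: int = 10) -> GString | None:
    """Longest G run of length >= ``min_run`` ending within
    ``terminal_window`` of either end of the element; ``None`` otherwise.
    The caller passes the element in motif orientation.
    """
    L = len(element_seq)
    runs = []
    i = 0
    while i < L:
        if element_seq[i] == "G":
            j = i
            while j < L and element_seq[j] == "G":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    best: GString | None = None
    for s, e in runs:
        if (L - e) >= terminal_window and s >= terminal_window:
            continue  # confined to the interior
        length = e - s
        if length < min_run:
            continue
        if best is None or length > best.run_length:
            best = GString(offset=s, run_length=length)
    return best


def annotate_g_strings(elements: list[ORBElement], min_run: int = 5, terminal_window: int = 10) -> None:
    for el in elements:
        el.g_string = detect_g_string(el.sequence, min_run, terminal_window)


# ---------------------------------------------------------------------------
# Inverted-repeat pairing
# ---------------------------------------------------------------------------

def pair_inverted(
    elements: list[ORBElement], max_gap: int = 400
) -> tuple[list[InvertedPair], list[ORBElement]]:
    """Pair forward with reverse occurrences of one motif within an IR.

    Candidate pairs (one forward, one reverse element, non-overlapping,
    inner gap <= ``max_gap``) are taken greedily in order of decreasing
    combined score without element reuse; leftovers are singletons.
    """
    fwd = [e for e in elements if e.orientation == "forward"]
    rev = [e for e in elements if e.orientation == "reverse"]
    candidates = []
    for f in fwd:
        for r in rev:
            left, right = (f, r) if f.offset <= r.offset else (r, f)
            gap = right.offset - (left.offset + left.length)
            if 0 <= gap <= max_gap:
                candidates.append((f.score + r.score, min(f.offset, r.offset), f, r, gap))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    used: set[int] = set()
    pairs: list[InvertedPair] = []
    for total, _left, f, r, gap in candidates:
        if id(f) in used or id(r) in used:
            continue
        used.add(id(f))
        used.add(id(r))
        pairs.append(InvertedPair(forward=f, reverse=r, gap=gap))
    singletons = [e for e in elements if id(e) not in used]
    return pairs, singletons


# ---------------------------------------------------------------------------
# AT-rich (duplex unwinding) segment detection
# ---------------------------------------------------------------------------

def at_rich_segment(
    ir: IntergenicRegion,
    background_gc: float,
    window: int = 50,
    margin: float = 0.25,
) -> ATRichSegment | None:
    """AT-rich (duplex unwinding) segment against the replicon background.

    Presence requires at least one ``window``-bp stretch whose AT fraction
    reaches ``(1 - background_gc) + margin``; the reported interval is the
    maximum-sum subarray under AT-vs-threshold weights (Kadane), which
    tightens the qualifying window chain to the actual AT island.
    """
    if len(ir) < window:
        raise ValueError(f"IR length {len(ir)} below window {window}")
    threshold = min((1.0 - background_gc) + margin, 1.0)
    codes = encode(ir.sequence)
    is_at = ((codes == 0) | (codes == 3)).astype(float)
    cat = np.concatenate([[0.0], np.cumsum(is_at)])
    starts = np.arange(len(ir) - window + 1)
    frac = (cat[starts + window] - cat[starts]) / window
    if frac.max() < threshold:
        return None
    # Kadane max-sum subarray: +(1-t) per A/T base, -t per G/C base, so any
    # positive-sum interval has AT fraction above the threshold t
    weights = np.where(is_at > 0, 1.0 - threshold, -threshold)
    best_sum = cur = 0.0
    best = (0, 0)
    seg_start = 0
    for i, wgt in enumerate(weights):
        if cur <= 0:
            cur = 0.0
            seg_start = i
        cur += wgt
        if cur > best_sum:
            best_sum = cur
            best = (seg_start, i + 1)
    s, e = best
    if e <= s:
        return None
    at = float((cat[e] - cat[s]) / (e - s))
    return ATRichSegment(start=int(s), end=int(e), at_fraction=at,
                         background_gc=background_gc)


def chunk_irs(irs: list[IntergenicRegion], size: int = 260, overlap: int = 40) -> list[IntergenicRegion]:
    """Cut IRs into overlapping chunks so a motif occurring twice within one
    IR (e.g. an inverted pair) contributes two sequences to a ZOOPS model,
    which credits at most one occurrence per sequence."""
    out = []
    step = max(size - overlap, 1)
    for ir in irs:
        if len(ir) <= size:
            out.append(ir)
            continue
        for s in range(0, len(ir) - overlap, step):
            sub = ir.sequence[s:s + size]
            if len(sub) < overlap:
                continue
            out.append(IntergenicRegion(ir.replicon_id, f"{ir.gene_ref}:{s}", ir.side,
                                        ir.start + s, ir.start + s + len(sub), sub))
    return out


def mask_occurrences(
    irs: list[IntergenicRegion],
    elements: list[ORBElement],
    seed: int = 0,
    background: np.ndarray | None = None,
) -> list[IntergenicRegion]:
    """Replace discovered occurrences with background-sampled bases so a
    second, independent motif can be searched for (MEME-style masking)."""
    rng = np.random.default_rng(seed)
    if background is None:
        background = background_composition([ir.sequence for ir in irs])
    by_ir: dict[int, list[ORBElement]] = {}
    for el in elements:
        by_ir.setdefault(id(el.ir), []).append(el)
    out = []
    for ir in irs:
        seq = list(ir.sequence)
        for el in by_ir.get(id(ir), []):
            for k in range(el.offset, min(el.offset + el.length, len(seq))):
                seq[k] = BASES[rng.choice(4, p=background)]
        out.append(IntergenicRegion(ir.replicon_id, ir.gene_ref, ir.side,
                                    ir.start, ir.end, "".join(seq), ir.wraps))
    return out
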