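"""Screen proteomes for origin-associated Orc/Cdc6 replication initiators.

The screen is an explicit, deterministic stand-in for a BLASTP/PSI-BLAST
search: a candidate CDS product must align to a seed initiator at or above
a percent-identity / aligned-length floor (default 30% over >=150 residues,
Smith-Waterman local alignment, BLOSUM62, affine gaps 11/1), exceed a
length floor (default 300 aa), and carry a Walker-A (P-loop) box in its
N-terminal region -- the sequence signature of the AAA+ ATPase domain that,
with the C-terminal winged-helix DNA-binding domain, defines this initiator
family.  A winged-helix composition score is reported but never gates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import GeneFeature, ProteinRecord, PseudogeneError, Replicon, translate_cds

log = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Walker-A / P-loop motif of AAA+ ATPases
WALKER_A = re.compile(r"[AG].{4}GK[ST]")
#: fraction of the sequence (from the N-terminus) where Walker-A must occur
WALKER_A_NTERM_FRACTION = 0.6


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    aligned_length: int  # alignment columns, gaps included
    identities: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_length if self.aligned_length else 0.0


@dataclass
class OrcCdc6Hit:
    protein: ProteinRecord
    gene: GeneFeature
    replicon_id: str
    best_seed_identity_pct: float
    best_seed_id: str
    best_aligned_length: int
    aaa_motif_found: bool
    wh_score: float
    passes: bool
    via_profile: bool = False
    notes: list[str] = field(default_factory=list)


from functools import lru_cache


@lru_cache(maxsize=8)
def _make_aligner(gap_open: float, gap_extend: float, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment under BLOSUM62 affine scoring.

    Identity is counted over alignment columns including gap columns, the
    convention BLAST reports.
    """
    if not a.aa_sequence or not b.aa_sequence:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a.aa_sequence, b.aa_sequence)[0]
    identities = 0
    columns = 0
    qa, qb = aln.aligned  # matched segment coordinates in a and b
    prev_qa_end = prev_qb_end = None
    for (sa, ea), (sb, eb) in zip(qa, qb):
        if prev_qa_end is not None:
            columns += (sa - prev_qa_end) + (sb - prev_qb_end)  # gap columns
        seg_a = a.aa_sequence[sa:ea]
        seg_b = b.aa_sequence[sb:eb]
        identities += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += ea - sa
        prev_qa_end, prev_qb_end = ea, eb
    qspan = (int(qa[0][0]), int(qa[-1][1])) if len(qa) else (0, 0)
    sspan = (int(qb[0][0]), int(qb[-1][1])) if len(qb) else (0, 0)
    return AlignmentResult(
        query_id=a.id, subject_id=b.id, score=float(aln.score),
        aligned_length=columns, identities=identities,
        query_span=qspan, subject_span=sspan,
    )


def local_align_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score-only fast path (no traceback)."""
    return float(_make_aligner(gap_open, gap_extend).score(a, b))


def detect_aaa_walker(protein: ProteinRecord) -> tuple[bool, int | None]:
    """First Walker-A match within the N-terminal 60% of the sequence."""
    limit = int(WALKER_A_NTERM_FRACTION * protein.length_aa)
    m = WALKER_A.search(protein.aa_sequence)
    if m is not None and m.start() < limit:
        return True, m.start()
    return False, None


# Kyte-Doolittle hydropathy, used by the winged-helix composition score
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}


def winged_helix_score(protein: ProteinRecord, window: int = 60) -> float:
    """Soft [0,1] winged-helix plausibility score over the C-terminal third.

    Combines basic-residue enrichment (DNA contact) with alpha-helical
    hydrophobic periodicity (~3.6 residues) of the best C-terminal window.
    Reported for review; never used as a gate.
    """
    seq = protein.aa_sequence
    tail = seq[-max(window, len(seq) // 3):]
    if len(tail) < 20:
        return 0.0
    basic = sum(tail.count(r) for r in "RK") / len(tail)
    basic_score = min(basic / 0.18, 1.0)  # ~18% R+K saturates
    kd = np.array([_KD.get(c, 0.0) for c in tail])
    kd = kd - kd.mean()
    freqs = np.fft.rfftfreq(len(kd))
    power = np.abs(np.fft.rfft(kd)) ** 2
    helical = (freqs > 1 / 4.2) & (freqs < 1 / 3.2)  # 100 deg/residue band
    total = power[1:].sum()
    period_score = float(power[helical].sum() / total) if total > 0 else 0.0
    period_score = min(period_score / 0.3, 1.0)
    return round(0.5 * basic_score + 0.5 * period_score, 4)


def iter_proteome(replicons: list[Replicon]) -> list[tuple[str, GeneFeature, ProteinRecord]]:
    """Translate every CDS; pseudogenes are logged and skipped."""
    out = []
    for rep in replicons:
        for feat in rep.features:
            if feat.kind != "CDS":
                continue
            try:
                prot = translate_cds(rep, feat)
            except PseudogeneError as exc:
                log.warning("skipping pseudogene: %s", exc)
                continue
            out.append((rep.id, feat, prot))
    return out


def screen_proteome(
    replicons: list[Replicon],
    seeds: list[ProteinRecord],
    min_len: int = 300,
    min_identity_pct: float = 30.0,
    min_aligned: int = 150,
) -> list[OrcCdc6Hit]:
    """Screen all CDS products against the seed panel.

    A CDS enters the hit list when its best seed alignment reaches both the
    identity and aligned-length floors; ``passes`` additionally requires the
    length floor and the Walker-A box.  Hits are ordered by replicon then
    coordinate.
    """
    if not seeds:
        raise ValueError("empty seed panel")
    hits: list[OrcCdc6Hit] = []
    for rid, feat, prot in iter_proteome(replicons):
        if prot.length_aa < min_aligned:
            continue  # cannot reach the aligned-length floor
        best: AlignmentResult | None = None
        best_score = -np.inf
        for seed in seeds:
            s = local_align_score(prot.aa_sequence, seed.aa_sequence)
            if s > best_score:
                best_score = s
                best_seed = seed
        aln = local_align(prot, best_seed)
        if aln.identity_pct < min_identity_pct or aln.aligned_length < min_aligned:
            continue
        best = aln
        aaa_found, _ = detect_aaa_walker(prot)
        length_ok = prot.length_aa > min_len
        hit = OrcCdc6Hit(
            protein=prot, gene=feat, replicon_id=rid,
            best_seed_identity_pct=round(best.identity_pct, 2),
            best_seed_id=best.subject_id,
            best_aligned_length=best.aligned_length,
            aaa_motif_found=aaa_found,
            wh_score=winged_helix_score(prot),
            passes=length_ok and aaa_found,
        )
        if not length_ok:
            hit.notes.append(f"length {prot.length_aa} aa below floor {min_len}")
        if not aaa_found:
            hit.notes.append("Walker-A box not found in N-terminal region")
        hits.append(hit)
    hits.sort(key=lambda h: (h.replicon_id, h.gene.start))
    return hits


# ---------------------------------------------------------------------------
# Profile rescreen (iterative, PSI-BLAST-style)
# ---------------------------------------------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_BG_AA = np.full(20, 1 / 20)


def build_profile(members: list[ProteinRecord], anchor: ProteinRecord,
                  pseudo_weight: float = 5.0) -> np.ndarray:
    """Position-specific log-odds (bits) over the anchor's coordinates.

    Member residues are mapped onto the anchor through pairwise local
    alignments; columns are smoothed with a background pseudocount mass of
    ``pseudo_weight`` so that sparse columns fall back to zero log-odds.
    """
    L = len(anchor.aa_sequence)
    counts = np.zeros((L, 20))
    for m in members:
        aln = _make_aligner(11, 1).align(anchor.aa_sequence, m.aa_sequence)[0]
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            for i in range(ea - sa):
                aa = m.aa_sequence[sb + i]
                if aa in _AA_INDEX:
                    counts[sa + i, _AA_INDEX[aa]] += 1
    n = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudo_weight * _BG_AA) / (n + pseudo_weight)
    return np.log2(probs / _BG_AA)


def profile_score(pssm: np.ndarray, protein: ProteinRecord,
                  min_overlap: int = 150) -> float:
    """Best ungapped sliding-window fit of a protein to the profile.

    Returns the maximum per-column mean log-odds (bits/column) over all
    offsets with at least ``min_overlap`` aligned columns; ``-inf`` when the
    protein is too short.
    """
    idx = np.array([_AA_INDEX.get(c, -1) for c in protein.aa_sequence])
    L, n = len(pssm), len(idx)
    if min(L, n) < min_overlap:
        return float("-inf")
    best = float("-inf")
    for offset in range(-(n - min_overlap), L - min_overlap + 1):
        p0, p1 = max(0, offset), min(L, offset + n)
        cols = np.arange(p0, p1)
        res = idx[cols - offset]
        valid = res >= 0
        if valid.sum() < min_overlap:
            continue
        score = pssm[cols[valid], res[valid]].mean()
        best = max(best, float(score))
    return best


def profile_rescreen(
    hits: list[OrcCdc6Hit],
    all_cds: list[tuple[str, GeneFeature, ProteinRecord]],
    iterations: int = 2,
    min_profile_bits: float = 0.0,
    min_len: int = 300,
    min_overlap: int = 150,
) -> list[OrcCdc6Hit]:
    """Iterative profile search recovering divergent family members.

    A PSSM built from the passing hits (anchored on the longest member) is
    slid over every CDS product not already in the hit list; products whose
    best mean log-odds exceeds ``min_profile_bits`` join as profile hits.
    The procedure is repeated ``iterations`` times and is a fixed point
    thereafter whenever no new member appears.
    """
    passing = [h for h in hits if h.passes]
    if not passing:
        raise ValueError("profile rescreen requires at least one passing hit")
    hits = list(hits)
    known = {h.protein.id for h in hits}
    for _ in range(iterations):
        members = [h.protein for h in hits if h.passes]
        anchor = max(members, key=lambda p: p.length_aa)
        pssm = build_profile(members, anchor)
        added = False
        for rid, feat, prot in all_cds:
            if prot.id in known:
                continue
            s = profile_score(pssm, prot, min_overlap=min_overlap)
            if s > min_profile_bits:
                aaa_found, _ = detect_aaa_walker(prot)
                length_ok = prot.length_aa > min_len
                hit = OrcCdc6Hit(
                    protein=prot, gene=feat, replicon_id=rid,
                    best_seed_identity_pct=0.0, best_seed_id=anchor.id,
                    best_aligned_length=min(prot.length_aa, len(pssm)),
                    aaa_motif_found=aaa_found, wh_score=winged_helix_score(prot),
                    passes=length_ok and aaa_found, via_profile=True,
                    notes=[f"profile score {s:.2f} bits/col"],
                )
                hits.append(hit)
                known.add(prot.id)
                added = True
        if not added:
            break
    hits.sort(key=lambda h: (h.replicon_id, h.gene.start))
    return hits
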