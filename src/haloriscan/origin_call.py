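"""Classify the ORB evidence around each initiator gene into an origin call.

The decision rules, in the order they are evaluated:

* **dual** -- two ORB element sets from clearly distinct motif families
  (consensus Hamming distance above width/4 at the best ungapped offset),
  each independently satisfying the candidate rule.
* **candidate** -- at least two G-string-bearing ORBs associated with the
  gene, arranged either as an inverted pair within one IR (the classical
  ORB / DUE / ORB origin architecture) or spread over both flanking IRs
  with more than one element on at least one side.
* **deficient** -- qualifying ORBs are present but never reach the
  candidate arrangement; the canonical case is exactly one ORB-like
  element in each flanking IR with no inverted pair, which is recorded as
  a deficient origin rather than a functional one.
* **none** -- no G-string-bearing ORB in either IR.

A "qualifying" ORB is a scanned motif occurrence carrying a terminal
G-string, the haloarchaeal ORB signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cdc6_screen import OrcCdc6Hit
from .genome_io import GeneFeature
from .orb_discovery import (
    ATRichSegment,
    IntergenicRegion,
    InvertedPair,
    MotifModel,
    ORBElement,
    pair_inverted,
)

STATUSES = ("candidate", "deficient", "dual", "none")


@dataclass
class OriginCall:
    gene_ref: str
    replicon_id: str
    status: str
    orbs: list[ORBElement] = field(default_factory=list)
    pairs: list[InvertedPair] = field(default_factory=list)
    at_rich: ATRichSegment | None = None
    layout: str | None = None  # upstream | downstream | both
    origin_interval: tuple[int, int] | None = None
    genome_id: str | None = None
    name: str | None = None
    family: str | None = None
    later_acquired: bool = False
    notes: list[str] = field(default_factory=list)


def consensus_hamming(a: str, b: str) -> int:
    """Hamming distance at the best ungapped offset (shorter inside longer)."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        d = sum(x != y for x, y in zip(a, b[off:off + len(a)]))
        best = min(best, d)
    return best


def _qualifying(elements: list[ORBElement]) -> list[ORBElement]:
    return [e for e in elements if e.g_string is not None]


def _candidate_arrangement(
    orbs_by_ir: dict[str, list[ORBElement]], max_gap: int
) -> tuple[bool, list[InvertedPair]]:
    """Candidate rule on one motif family's qualifying ORBs.

    True for an inverted pair of qualifying elements within a single IR, or
    for qualifying elements in both IRs provided the layout is richer than
    one lone element per side (that exact pattern is the deficient case).
    """
    pairs_all: list[InvertedPair] = []
    has_pair = False
    for elements in orbs_by_ir.values():
        qual = _qualifying(elements)
        pairs, _ = pair_inverted(qual, max_gap=max_gap)
        if pairs:
            has_pair = True
            pairs_all.extend(pairs)
    sides = {side: len(_qualifying(els)) for side, els in orbs_by_ir.items()}
    occupied = [n for n in sides.values() if n > 0]
    both_sides_rich = len(occupied) == 2 and max(occupied) >= 2
    return (has_pair or both_sides_rich), pairs_all


def call_origin(
    gene: OrcCdc6Hit,
    orb_results: dict[str, list[ORBElement]],
    at_results: dict[str, ATRichSegment | None],
    irs: dict[str, IntergenicRegion],
    motifs: list[MotifModel] | None = None,
    max_gap: int = 400,
    genome_id: str | None = None,
) -> OriginCall:
    """Apply the dual -> candidate -> deficient -> none decision cascade.

    ``orb_results``/``at_results``/``irs`` are keyed by IR side
    (``upstream``/``downstream``).  ``motifs`` supplies the motif models so
    dual calls can verify the two families are genuinely distinct.
    """
    call = OriginCall(gene_ref=gene.gene.locus_tag, replicon_id=gene.replicon_id,
                      status="none", genome_id=genome_id)
    all_orbs = [e for els in orb_results.values() for e in els]
    qual_all = _qualifying(all_orbs)
    if not qual_all:
        call.notes.append("no G-string-bearing ORB element in flanking IRs")
        return call

    motif_widths = {m.motif_id: m.width for m in (motifs or [])}
    motif_consensus = {m.motif_id: m.consensus for m in (motifs or [])}
    families = sorted({e.motif_id for e in qual_all})
    satisfied: dict[int, list[InvertedPair]] = {}
    for fam in families:
        by_ir = {side: [e for e in els if e.motif_id == fam]
                 for side, els in orb_results.items()}
        ok, pairs = _candidate_arrangement(by_ir, max_gap)
        if ok:
            satisfied[fam] = pairs

    status = None
    chosen: list[int] = []
    if len(satisfied) >= 2:
        fams = sorted(satisfied)
        for i, fa in enumerate(fams):
            for fb in fams[i + 1:]:
                ca, cb = motif_consensus.get(fa), motif_consensus.get(fb)
                if ca is None or cb is None:
                    continue
                wmin = min(motif_widths[fa], motif_widths[fb])
                if consensus_hamming(ca, cb) > wmin / 4:
                    status, chosen = "dual", [fa, fb]
                    break
            if status:
                break
    if status is None and satisfied:
        best = max(satisfied, key=lambda f: sum(e.score for e in qual_all if e.motif_id == f))
        status, chosen = "candidate", [best]
    if status is None:
        status = "deficient"
        chosen = families
        call.notes.append("qualifying ORBs present but no candidate arrangement")

    call.status = status
    call.orbs = [e for e in qual_all if e.motif_id in chosen]
    for fam in chosen:
        call.pairs.extend(satisfied.get(fam, []))
    at_sides = [(side, a) for side, a in at_results.items() if a is not None]
    at_span = None
    if at_sides:
        side, seg = max(at_sides, key=lambda sa: sa[1].at_fraction)
        call.at_rich = seg
        ir = irs.get(side)
        if ir is not None:
            at_span = (ir.start + seg.start, ir.start + seg.end)
    call.layout = layout_classify(call, gene.gene, irs)
    call.origin_interval = _origin_interval(call, at_span)
    return call


def layout_classify(
    call: OriginCall, gene: GeneFeature, irs: dict[str, IntergenicRegion]
) -> str | None:
    """Which side(s) of the gene, in coding orientation, carry the ORBs."""
    if call.status == "none" or not call.orbs:
        return None
    sides = set()
    for el in call.orbs:
        sides.add(el.ir.side)
    if sides == {"upstream", "downstream"}:
        return "both"
    return sides.pop() if sides else None


def _origin_interval(call: OriginCall, at_span: tuple[int, int] | None) -> tuple[int, int] | None:
    """Minimal replicon-coordinate span covering the qualifying ORBs and the
    AT-rich segment."""
    if not call.orbs:
        return None
    points = []
    for el in call.orbs:
        s, e = el.replicon_interval
        points.extend([s, e])
    if at_span is not None:
        points.extend(at_span)
    return (min(points), max(points))


def summarize_replicon(calls: list[OriginCall]) -> tuple[int, int, int | None]:
    """Per-replicon tally: (n initiator genes, n with an associated origin,
    integer percentage).  Origin-associated means status candidate or dual;
    with no initiators the percentage is undefined (None).
    """
    n_cdc6 = len(calls)
    n_ori = sum(1 for c in calls if c.status in {"candidate", "dual"})
    if n_cdc6 == 0:
        return 0, 0, None
    return n_cdc6, n_ori, round(100.0 * n_ori / n_cdc6)


def assign_origin_names(calls: list[OriginCall], replicon_classes: dict[str, str]) -> None:
    """Name origins oriC1..oriCn on chromosomal replicons and oriP1..oriPn on
    plasmid-class replicons, in replicon-coordinate order."""
    counters: dict[tuple[str, str], int] = {}
    for call in sorted(calls, key=lambda c: (c.replicon_id, c.origin_interval or (0, 0))):
        if call.status not in {"candidate", "dual", "deficient"}:
            continue
        cls = replicon_classes.get(call.replicon_id, "unknown")
        prefix = "oriC" if cls in {"chromosome", "minichromosome", "unknown"} else "oriP"
        key = (call.genome_id or "", prefix)
        counters[key] = counters.get(key, 0) + 1
        call.name = f"{prefix}{counters[key]}"
        if call.status == "deficient":
            call.name += "*"
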