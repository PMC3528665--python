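"""Origin families, initiator phylogeny, and later-acquired flags.

Origins are grouped into families by the pairwise identity of their
Orc/Cdc6 initiators (single-linkage components at an 80% identity floor),
named by the conventions of the field (oriC1 for the family present in
every genome, oriCa/oriCb for the next two largest, F<k> for the rest),
checked for initiator-ORB linkage consistency, and flagged as
later-acquired when a transposase or integrase gene sits near the origin
interval.  Trees are neighbour-joining over Poisson-corrected protein
distances (and, for species trees, any externally supplied distance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix
from skbio.tree import nj

from .cdc6_screen import OrcCdc6Hit, _make_aligner, local_align
from .genome_io import GeneFeature, ProteinRecord
from .orb_discovery import _revcomp_str
from .origin_call import OriginCall

log = logging.getLogger(__name__)

MOBILE_KEYWORDS = ("transposase", "integrase", "insertion sequence", "ish")


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, percent identity, diagonal 100


@dataclass
class OriginFamily:
    name: str
    members: list[tuple[str, OriginCall, OrcCdc6Hit]]  # (genome_id, call, hit)
    orb_consensus: str = ""
    genome_coverage: float = 0.0
    notes: list[str] = field(default_factory=list)


@dataclass
class MobilityAnnotation:
    origin_ref: str
    mobile_genes: list[tuple[str, str, int]]  # (locus_tag, class, distance bp)
    later_acquired: bool
    window_bp: int


@dataclass
class PhyloTree:
    newick: str
    ids: list[str]
    notes: list[str] = field(default_factory=list)


def identity_matrix(proteins: list[ProteinRecord], min_aligned: int = 100) -> IdentityMatrix:
    """Pairwise local-alignment percent identity over the aligned span.

    Local alignments shorter than ``min_aligned`` columns score 0%: a short
    high-identity segment between otherwise unrelated proteins must not
    chain families together.
    """
    if len(proteins) < 2:
        raise ValueError("identity matrix requires at least 2 proteins")
    n = len(proteins)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(proteins[i], proteins[j])
            pct = aln.identity_pct if aln.aligned_length >= min_aligned else 0.0
            values[i, j] = values[j, i] = pct
    return IdentityMatrix(ids=[p.id for p in proteins], values=values)


def cluster_families(matrix: IdentityMatrix, threshold_pct: float = 80.0) -> list[list[str]]:
    """Single-linkage components of the identity >= threshold graph,
    members ordered by input position, components by smallest member."""
    adj = csr_matrix(matrix.values >= threshold_pct)
    n_comp, labels = connected_components(adj, directed=False)
    comps: dict[int, list[str]] = {}
    for idx, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(matrix.ids[idx])
    out = sorted(comps.values(), key=lambda c: (matrix.ids.index(c[0])))
    for comp in out:
        mn = _min_pairwise(matrix, comp)
        if mn is not None and mn < threshold_pct:
            log.warning(
                "family %s chained below threshold: min pairwise identity %.1f%%",
                comp[0], mn,
            )
    return out


def _min_pairwise(matrix: IdentityMatrix, members: list[str]) -> float | None:
    if len(members) < 2:
        return None
    idx = [matrix.ids.index(m) for m in members]
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].min())


def name_families(
    families: list[list[tuple[str, OriginCall, OrcCdc6Hit]]],
    genome_ids: list[str],
) -> list[OriginFamily]:
    """Apply the field's family-naming convention.

    The family represented in every input genome is oriC1 (largest wins a
    tie, then lexicographically smallest member); of the remainder, the two
    largest by member count become oriCa and oriCb; the rest are numbered
    F3, F4, ... in size order.
    """
    n_genomes = max(len(set(genome_ids)), 1)
    wrapped = []
    for members in families:
        coverage = len({g for g, _c, _h in members}) / n_genomes
        fam = OriginFamily(name="", members=list(members), genome_coverage=coverage)
        fam.orb_consensus = _family_orb_consensus(members)
        wrapped.append(fam)

    def size_key(f: OriginFamily):
        first = min(h.protein.id for _g, _c, h in f.members)
        return (-len(f.members), first)

    universal = [f for f in wrapped if f.genome_coverage >= 1.0]
    rest = [f for f in wrapped if f.genome_coverage < 1.0]
    named: list[OriginFamily] = []
    if universal:
        universal.sort(key=size_key)
        universal[0].name = "oriC1"
        if n_genomes == 1:
            universal[0].notes.append("single-genome input: coverage trivially 1")
        named.append(universal[0])
        rest.extend(universal[1:])
    else:
        log.warning("no origin family present in every genome; oriC1 not assigned")
    rest.sort(key=size_key)
    letters = ["oriCa", "oriCb"]
    for i, fam in enumerate(rest):
        fam.name = letters[i] if i < 2 else f"F{i + 1}"
        named.append(fam)
    return named


def _family_orb_consensus(members) -> str:
    """Majority-vote consensus of member ORB sequences at modal width."""
    seqs = []
    for _g, call, _h in members:
        for el in call.orbs:
            seqs.append(el.sequence)
    if not seqs:
        return ""
    widths = [len(s) for s in seqs]
    modal = max(set(widths), key=widths.count)
    seqs = [s for s in seqs if len(s) == modal]
    cols = []
    for i in range(modal):
        col = [s[i] for s in seqs]
        cols.append(max(set(col), key=col.count))
    return "".join(cols)


def orb_linkage_check(family: OriginFamily) -> tuple[float, list[tuple[str, str, float]]]:
    """Mean pairwise similarity of member ORB consensi.

    Similarity is 1 minus the normalized Hamming distance at equal width,
    or at the best ungapped offset when widths differ (normalized by the
    overlap).  Members without ORB elements are skipped with a note.
    """
    consensi = []
    for gid, call, hit in family.members:
        if call.orbs:
            consensi.append((hit.protein.id, _member_consensus(call)))
        else:
            family.notes.append(f"{hit.protein.id}: no ORB elements, skipped in linkage check")
    if len(consensi) < 2:
        raise ValueError("linkage check requires >=2 members with ORBs")
    detail = []
    for i in range(len(consensi)):
        for j in range(i + 1, len(consensi)):
            (ida, a), (idb, b) = consensi[i], consensi[j]
            detail.append((ida, idb, _orb_similarity(a, b)))
    score = float(np.mean([d[2] for d in detail]))
    return score, detail


def _member_consensus(call: OriginCall) -> str:
    seqs = [el.sequence for el in call.orbs]
    widths = [len(s) for s in seqs]
    modal = max(set(widths), key=widths.count)
    seqs = [s for s in seqs if len(s) == modal]
    return "".join(
        max(set(col), key=col.count) for col in zip(*seqs)
    )


def _orb_similarity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for candidate in (b, _revcomp_str(b)):
        for off in range(len(candidate) - len(a) + 1):
            matches = sum(x == y for x, y in zip(a, candidate[off:off + len(a)]))
            best = max(best, matches / len(a))
    return best


def annotate_mobility(
    call: OriginCall,
    features: list[GeneFeature],
    window_bp: int = 10000,
    replicon_length: int | None = None,
    circular: bool = True,
) -> MobilityAnnotation:
    """Flag an origin as later-acquired when a mobile-element gene
    (transposase / integrase / insertion sequence, by product annotation)
    lies within ``window_bp`` of the origin interval."""
    if call.origin_interval is None:
        return MobilityAnnotation(call.gene_ref, [], False, window_bp)
    os_, oe = call.origin_interval
    mobile = []
    for feat in features:
        product = (feat.product or "").lower()
        klass = None
        if "transposase" in product:
            klass = "transposase"
        elif "integrase" in product:
            klass = "integrase"
        elif "insertion sequence" in product or product.startswith("ish") or " ish" in product:
            klass = "transposase"
        if klass is None:
            continue
        d = _interval_distance(os_, oe, feat.start, feat.end, replicon_length, circular)
        if d <= window_bp:
            mobile.append((feat.locus_tag, klass, int(d)))
    mobile.sort(key=lambda m: m[2])
    return MobilityAnnotation(call.gene_ref, mobile, bool(mobile), window_bp)


def _interval_distance(
    s1: int, e1: int, s2: int, e2: int,
    length: int | None, circular: bool,
) -> int:
    if e1 >= s2 and e2 >= s1:
        return 0
    d = max(s2 - e1, s1 - e2)
    if circular and length:
        d = min(d, length - max(e1, e2) + min(s1, s2))
    return max(d, 0)


# ---------------------------------------------------------------------------
# Trees and distances
# ---------------------------------------------------------------------------

def nj_tree(matrix: np.ndarray, ids: list[str]) -> PhyloTree:
    """Saitou-Nei neighbour joining over a symmetric distance matrix.

    Negative branch lengths (a known NJ artefact) are clamped to zero with
    a note; the tree is serialized as newick.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    if not np.allclose(matrix, matrix.T, atol=1e-9) or (matrix < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    dm = DistanceMatrix(matrix, ids)
    tree = nj(dm)
    notes = []
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            notes.append(f"negative branch at {node.name or 'internal'} clamped to 0")
            node.length = 0.0
    newick = str(tree).strip()
    return PhyloTree(newick=newick, ids=list(ids), notes=notes)


def protein_distance(aligned_a: str, aligned_b: str, max_distance: float = 10.0) -> float:
    """Poisson-corrected distance -ln(1 - p) between two aligned sequences.

    Gap-containing columns are removed first (the explicit counterpart of
    manual gappy-column stripping before tree building); p is the
    proportion of differing residues among the remaining columns.  p >= 1
    (or no comparable column) caps the distance with a warning.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"]
    if not pairs:
        log.warning("no ungapped columns; distance capped at %.1f", max_distance)
        return max_distance
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= 1.0:
        log.warning("p-distance %.3f >= 1; Poisson distance capped at %.1f", p, max_distance)
        return max_distance
    return float(-np.log(1.0 - p))


def pairwise_protein_distances(proteins: list[ProteinRecord]) -> tuple[np.ndarray, list[str]]:
    """Distance matrix from global pairwise alignments + Poisson correction."""
    n = len(proteins)
    aligner = _make_aligner(11, 1, mode="global")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(proteins[i].aa_sequence, proteins[j].aa_sequence)[0]
            a, b = str(aln[0]), str(aln[1])
            D[i, j] = D[j, i] = protein_distance(a, b)
    return D, [p.id for p in proteins]


def bootstrap_nj(
    aligned: dict[str, str], n_replicates: int = 100, seed: int = 0
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """NJ tree with column-resampling bootstrap support on bipartitions.

    ``aligned`` maps taxon id to rows of one multiple alignment (equal
    length).  Returns the tree on the full alignment and the bootstrap
    fraction of each non-trivial bipartition (as frozensets of taxon ids).
    """
    ids = list(aligned)
    L = len(next(iter(aligned.values())))
    if any(len(s) != L for s in aligned.values()):
        raise ValueError("alignment rows differ in length")

    def tree_from_columns(cols: np.ndarray) -> PhyloTree:
        n = len(ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a = "".join(aligned[ids[i]][c] for c in cols)
                b = "".join(aligned[ids[j]][c] for c in cols)
                D[i, j] = D[j, i] = protein_distance(a, b)
        return nj_tree(D, ids)

    full = tree_from_columns(np.arange(L))
    ref_parts = _bipartitions(full.newick, set(ids))
    counts = {p: 0 for p in ref_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = tree_from_columns(cols)
        for p in _bipartitions(rep.newick, set(ids)):
            if p in counts:
                counts[p] += 1
    support = {p: c / n_replicates for p, c in counts.items()}
    return full, support


def _bipartitions(newick: str, all_ids: set[str]) -> set[frozenset]:
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    parts = set()
    for node in tree.non_tips():
        tips = frozenset(t.name for t in node.tips())
        if 1 < len(tips) < len(all_ids) - 1:
            parts.add(min(tips, key=len) if False else tips)
    # normalize: a bipartition equals its complement
    normed = set()
    for p in parts:
        comp = frozenset(all_ids - p)
        normed.add(min((p, comp), key=lambda s: (len(s), sorted(s))))
    return normed
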