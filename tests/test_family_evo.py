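import itertools

import numpy as np
import pytest

from haloriscan.cdc6_screen import OrcCdc6Hit
from haloriscan.family_evo import (
    IdentityMatrix,
    OriginFamily,
    annotate_mobility,
    cluster_families,
    identity_matrix,
    name_families,
    nj_tree,
    orb_linkage_check,
    pairwise_protein_distances,
    protein_distance,
)
from haloriscan.genome_io import GeneFeature, ProteinRecord
from haloriscan.origin_call import OriginCall
from haloriscan.synthetic_data import make_seed_panel, mutate_protein_to_identity

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_prot(rng, n=300, pid="p"):
    return ProteinRecord(pid, "".join(AA[i] for i in rng.integers(0, 20, n)))


# ---------------------------------------------------------------------------
# Identity matrix
# ---------------------------------------------------------------------------

def test_identity_matrix_identical_and_symmetry(rng):
    prots = [_rand_prot(rng, 250, f"p{i}") for i in range(6)]
    prots.append(ProteinRecord("dup", prots[0].aa_sequence))
    m = identity_matrix(prots)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 100.0)
    i, j = m.ids.index("p0"), m.ids.index("dup")
    assert m.values[i, j] == 100.0


def test_identity_tracks_mutation_rate(rng):
    panel = make_seed_panel()
    for _ in range(15):
        mutant = ProteinRecord("m", mutate_protein_to_identity(panel[0], 0.90, rng))
        m = identity_matrix([panel[0], mutant])
        assert 85.0 <= m.values[0, 1] <= 95.0


# ---------------------------------------------------------------------------
# Family clustering
# ---------------------------------------------------------------------------

def _matrix(ids, pairs):
    n = len(ids)
    v = np.zeros((n, n))
    np.fill_diagonal(v, 100.0)
    for (a, b), val in pairs.items():
        i, j = ids.index(a), ids.index(b)
        v[i, j] = v[j, i] = val
    return IdentityMatrix(ids=list(ids), values=v)


def test_single_linkage_chain():
    m = _matrix("abc", {("a", "b"): 85, ("b", "c"): 82, ("a", "c"): 60})
    assert cluster_families(m, 80) == [["a", "b", "c"]]
    assert cluster_families(m, 90) == [["a"], ["b"], ["c"]]
    assert cluster_families(m, 100) == [["a"], ["b"], ["c"]]


def union_find_oracle(values, threshold):
    n = len(values)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


def test_clustering_equals_union_find_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(2, 13))
        v = rng.uniform(0, 100, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        ids = [f"x{i}" for i in range(n)]
        got = cluster_families(IdentityMatrix(ids, v), 80)
        got_idx = sorted(sorted(ids.index(m) for m in fam) for fam in got)
        assert got_idx == union_find_oracle(v, 80)


# ---------------------------------------------------------------------------
# Family naming
# ---------------------------------------------------------------------------

def _member(gid, tag, orb_seq="G" * 30):
    call = OriginCall(gene_ref=tag, replicon_id=f"{gid}_chr", status="candidate",
                      genome_id=gid)
    if orb_seq:
        from haloriscan.orb_discovery import GString, IntergenicRegion, ORBElement

        ir = IntergenicRegion(f"{gid}_chr", tag, "upstream", 0, 500, "A" * 500)
        call.orbs = [ORBElement(ir, 10, len(orb_seq), "forward", orb_seq, 20.0,
                                GString(len(orb_seq) - 7, 7))]
    gene = GeneFeature(tag, "CDS", 0, 900, "+")
    hit = OrcCdc6Hit(ProteinRecord(tag, "M" * 310), gene, f"{gid}_chr",
                     90.0, "s", 300, True, 0.5, True)
    return (gid, call, hit)


def test_universal_family_named_oric1_and_top_two_lettered():
    genomes = [f"g{i}" for i in range(4)]
    fam_u = [_member(g, f"{g}_u") for g in genomes]
    fam_a = [_member(g, f"{g}_a") for g in genomes[:3]]
    fam_b = [_member(g, f"{g}_b") for g in genomes[:2]]
    single = [_member("g0", "g0_s")]
    named = name_families([fam_u, fam_a, fam_b, single], genomes)
    by_name = {f.name: f for f in named}
    assert {m[1].gene_ref for m in by_name["oriC1"].members} == {f"{g}_u" for g in genomes}
    assert {m[1].gene_ref for m in by_name["oriCa"].members} == {f"{g}_a" for g in genomes[:3]}
    assert {m[1].gene_ref for m in by_name["oriCb"].members} == {f"{g}_b" for g in genomes[:2]}
    assert by_name["F3"].members[0][1].gene_ref == "g0_s"  # remainder numbered F3, F4, ...


def test_equal_size_families_tie_break_deterministic():
    genomes = ["g0", "g1", "g2"]
    fam1 = [_member("g0", "aaa"), _member("g1", "aab")]
    fam2 = [_member("g0", "bbb"), _member("g1", "bbc")]
    named = name_families([fam2, fam1], genomes)
    by_name = {f.name: f for f in named}
    # no universal family -> no oriC1; tie broken by smallest member id
    assert "oriC1" not in by_name
    assert {m[1].gene_ref for m in by_name["oriCa"].members} == {"aaa", "aab"}


def test_single_genome_coverage_edge_case():
    named = name_families([[_member("g0", "x")]], ["g0"])
    assert named[0].name == "oriC1"
    assert any("single-genome" in n for n in named[0].notes)


# ---------------------------------------------------------------------------
# ORB linkage
# ---------------------------------------------------------------------------

def test_orb_linkage_identical_and_arithmetic():
    fam = OriginFamily("oriC1", [_member("g0", "a"), _member("g1", "b")])
    score, detail = orb_linkage_check(fam)
    assert score == 1.0
    seq_b = "G" * 27 + "TTT"
    fam2 = OriginFamily("oriC1", [_member("g0", "a"), _member("g1", "b", seq_b)])
    score2, _ = orb_linkage_check(fam2)
    assert score2 == pytest.approx(0.9)


def test_orb_linkage_same_family_beats_cross_family(rng):
    from haloriscan.synthetic_data import SHARED_ORB, mutate_sequence

    other = "CATTGACCTTAAGCTACACTATGGGGGGT"
    wins = 0
    for s in range(20):
        a = mutate_sequence(SHARED_ORB, 0.05, 1000 + s)
        b = mutate_sequence(SHARED_ORB, 0.05, 2000 + s)
        c = mutate_sequence(other, 0.05, 3000 + s)
        same = OriginFamily("f", [_member("g0", "a", a), _member("g1", "b", b)])
        cross = OriginFamily("f", [_member("g0", "a", a), _member("g1", "c", c)])
        if orb_linkage_check(same)[0] > orb_linkage_check(cross)[0]:
            wins += 1
    assert wins >= 19


def test_orb_linkage_skips_members_without_orbs():
    fam = OriginFamily("f", [_member("g0", "a"), _member("g1", "b", orb_seq="")])
    with pytest.raises(ValueError):
        orb_linkage_check(fam)
    assert any("no ORB" in n for n in fam.notes)


# ---------------------------------------------------------------------------
# Mobility
# ---------------------------------------------------------------------------

def _call_with_interval(start, end):
    return OriginCall(gene_ref="g", replicon_id="chr", status="candidate",
                      origin_interval=(start, end))


def test_transposase_within_window_flags_later_acquired():
    call = _call_with_interval(10_000, 11_000)
    feats = [GeneFeature("tnp", "CDS", 14_000, 14_800, "+", product="ISH3 family transposase")]
    ann = annotate_mobility(call, feats, window_bp=10_000, replicon_length=100_000)
    assert ann.later_acquired
    assert ann.mobile_genes[0] == ("tnp", "transposase", 3000)


def test_distant_mobile_gene_outside_window():
    call = _call_with_interval(10_000, 11_000)
    feats = [GeneFeature("int", "CDS", 36_000, 36_900, "+", product="phage integrase")]
    ann = annotate_mobility(call, feats, window_bp=10_000, replicon_length=500_000)
    assert not ann.later_acquired


def test_mobility_window_monotonicity(rng):
    call = _call_with_interval(50_000, 51_000)
    feats = [GeneFeature(f"t{i}", "CDS", int(p), int(p) + 600, "+",
                         product="transposase")
             for i, p in enumerate(rng.integers(0, 200_000, 15))]
    prev = False
    for window in (1000, 5000, 10_000, 50_000, 200_000):
        got = annotate_mobility(call, feats, window_bp=window,
                                replicon_length=200_000).later_acquired
        assert got or not prev  # enlarging the window never flips true->false
        prev = prev or got


# ---------------------------------------------------------------------------
# Trees and distances
# ---------------------------------------------------------------------------

def test_nj_three_taxon_closed_form():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = nj_tree(d, ["A", "B", "C"])
    import dendropy

    t = dendropy.Tree.get(data=tree.newick, schema="newick")
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def _random_tree_distance_matrix(rng, n):
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
        rng=__import__("random").Random(int(rng.integers(1 << 30))))
    for e in tree.preorder_edge_iter():
        if e.length is None or e.length <= 0:
            e.length = 0.1
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    labels = [f"t{i}" for i in range(n)]
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = pdm.patristic_distance(
                    taxa.get_taxon(a), taxa.get_taxon(b))
    return tree, D, labels


def test_nj_recovers_additive_trees_exactly():
    import dendropy

    rng = np.random.default_rng(5)
    for n in (5, 7, 10):
        true_tree, D, labels = _random_tree_distance_matrix(rng, n)
        out = nj_tree(D, labels)
        tns = true_tree.taxon_namespace
        got = dendropy.Tree.get(data=out.newick, schema="newick",
                                taxon_namespace=tns)
        true_tree.deroot()  # NJ trees are unrooted; compare as such
        got.deroot()
        got.encode_bipartitions()
        true_tree.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(true_tree, got)
        assert rf == 0
        # path distances reproduced
        pdm = got.phylogenetic_distance_matrix()
        for i, j in itertools.combinations(range(n), 2):
            d = pdm.patristic_distance(tns.get_taxon(labels[i]), tns.get_taxon(labels[j]))
            assert d == pytest.approx(D[i, j], abs=1e-6)


def test_nj_label_permutation_invariance():
    import dendropy

    rng = np.random.default_rng(6)
    _t, D, labels = _random_tree_distance_matrix(rng, 6)
    perm = rng.permutation(6)
    D2 = D[np.ix_(perm, perm)]
    labels2 = [labels[i] for i in perm]
    tns = dendropy.TaxonNamespace(labels)
    a = dendropy.Tree.get(data=nj_tree(D, labels).newick, schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=nj_tree(D2, labels2).newick, schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])
    bad = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], dtype=float)
    with pytest.raises(ValueError):
        nj_tree(bad, list("abc"))


def test_protein_distance_closed_form():
    assert protein_distance("MKLV", "MKLV") == 0.0
    a = "A" * 100
    b = "C" * 10 + "A" * 90  # p = 0.1
    assert protein_distance(a, b) == pytest.approx(0.10536, abs=1e-5)
    # gap columns removed first
    assert protein_distance("MK-LV", "MKXLV") == 0.0


def test_protein_distance_monotone_in_divergence(rng):
    panel = make_seed_panel()
    prev = -1.0
    for ident in (0.95, 0.85, 0.7, 0.55, 0.4):
        mutant = ProteinRecord("m", mutate_protein_to_identity(panel[0], ident, rng))
        D, _ = pairwise_protein_distances([panel[0], mutant])
        assert D[0, 1] > prev
        prev = D[0, 1]
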