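"""Synthetic multi-replicon haloarchaeal genomes with planted ground truth.

The generator emulates the genome architecture the pipeline targets:
high-GC (~62%) circular replicons (chromosome, minichromosome,
megaplasmid), each carrying planted *orc/cdc6* initiator genes whose
flanking intergenic regions contain -- depending on the planted origin
status -- an inverted ORB pair with terminal G-strings around an AT-rich
unwinding element (candidate), exactly one lone ORB per flanking IR
(deficient), two unrelated ORB motif sets (dual), or nothing (none).
Mobile-element (transposase) genes are planted near a configurable
fraction of origins, and decoy genes plus shuffled-ORB decoy IRs stress
the screen and the motif stage.

Every random draw flows from a single integer seed, so generated genomes
(and the emitted GenBank/GFF3/TSV files) are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome_io import GeneFeature, ProteinRecord, Replicon

#: the ORB element shared by the two dual-origin loci, used as the master
#: consensus from which planted ORB families diverge (terminal run of 7 Gs)
SHARED_ORB = "TAACAGCGGAAACAGTGGGGTGGGGGGGT"
#: an unrelated second consensus for dual origins (terminal G-string kept)
DUAL_SECOND_ORB = "CATTGACCTTAAGCTACACTATGGGGGGT"

BASES = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# NCBI translation table 11, built once: aa -> synonymous codons
from Bio.Data import CodonTable

_T11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _T11.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort."""

    n_genomes: int = 5
    replicons: tuple = (
        ("chromosome", 500_000, "circular"),
        ("minichromosome", 300_000, "circular"),
        ("megaplasmid", 200_000, "circular"),
    )
    background_gc: float = 0.62
    n_cdc6: tuple = (4, 2, 1)  # per replicon, mirrors multi-replicon counts
    orb_master_consensus: str = SHARED_ORB
    dual_second_consensus: str = DUAL_SECOND_ORB
    orb_family_divergence: float = 0.12  # family consensus vs master, core only
    orb_mutation_rate: float = 0.05  # instance vs its family consensus
    protein_identity_range: tuple = (0.40, 0.90)  # singleton initiators vs seed
    family_protein_divergence: float = 0.05  # member vs family ancestor
    deficient_fraction: float = 0.15
    dual_fraction: float = 0.10
    none_fraction: float = 0.25
    mobile_fraction: float = 0.40  # fraction of origins with a mobile gene nearby
    decoy_gene_count: int = 40  # per genome
    seed: int = 0
    # which genomes carry the partial families; "U" is always universal
    family_plan: dict = field(default_factory=dict)

    def resolved_family_plan(self) -> dict[str, list[int]]:
        if self.family_plan:
            return {k: list(v) for k, v in self.family_plan.items()}
        n = self.n_genomes
        plan = {"U": list(range(n))}
        if n >= 2:
            plan["A"] = list(range(0, max(2, (2 * n) // 3)))
            plan["B"] = list(range(n - max(2, (2 * n) // 3), n))
        return plan


@dataclass
class TruthRecord:
    genome_id: str
    replicon_id: str
    locus_tag: str
    is_cdc6: bool
    family_id: str | None
    origin_status: str | None  # candidate | deficient | dual | none
    orb_intervals: list = field(default_factory=list)  # replicon coords
    at_rich_interval: tuple | None = None
    mobile_nearby: bool = False
    seed_identity: float | None = None


@dataclass
class GroundTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def cdc6(self) -> list[TruthRecord]:
        return [r for r in self.records if r.is_cdc6]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = asdict(r)
            d["orb_intervals"] = ";".join(f"{s}-{e}" for s, e in r.orb_intervals)
            d["at_rich_interval"] = (
                f"{r.at_rich_interval[0]}-{r.at_rich_interval[1]}" if r.at_rich_interval else ""
            )
            rows.append(d)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join("ACGT"[c] for c in codes)


def mutate_sequence(seq: str, rate: float, seed: int | np.random.Generator,
                    protect: set[int] | None = None) -> str:
    """i.i.d. per-base substitution to a uniformly chosen *different* base.

    ``protect`` positions are never touched (used for functionally
    constrained positions such as terminal G-strings).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        if protect and i in protect:
            continue
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def mutate_protein(aa: str, divergence: float, rng: np.random.Generator,
                   protect: set[int] | None = None) -> str:
    out = list(aa)
    hit = rng.random(len(aa)) < divergence
    for i in np.flatnonzero(hit):
        if protect and i in protect:
            continue
        choices = [a for a in AA_ALPHABET if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def reverse_translate(aa: str, rng: np.random.Generator, gc: float) -> str:
    """Codon choice weighted toward the background GC so planted CDSs do not
    form composition islands."""
    p = _base_probs(gc)
    idx = {b: i for i, b in enumerate(BASES)}
    codons = []
    for residue in aa:
        options = _CODONS_BY_AA[residue]
        w = np.array([p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] for c in options])
        codons.append(options[rng.choice(len(options), p=w / w.sum())])
    return "".join(codons) + "TGA"


def _walker_positions(aa: str) -> set[int]:
    import re

    m = re.search(r"[AG].{4}GK[ST]", aa)
    if not m:
        return set()
    return set(range(m.start(), m.end()))


def _orb_protect(consensus: str) -> set[int]:
    """Positions of the terminal G run (functionally constrained)."""
    from .orb_discovery import detect_g_string

    g = detect_g_string(consensus, min_run=5, terminal_window=10)
    if g is None:
        return set()
    return set(range(g.offset, g.offset + g.run_length))


def make_seed_panel(n: int = 8, length: int = 420, seed: int = 20120911) -> list[ProteinRecord]:
    """Deterministic synthetic stand-in panel of origin-associated Orc/Cdc6
    initiator proteins (AAA+ Walker-A box in the N-terminal region)."""
    rng = np.random.default_rng(seed)
    panel = []
    for k in range(n):
        aa = ["M"] + [AA_ALPHABET[rng.integers(20)] for _ in range(length - 1)]
        pos = int(rng.integers(40, 80))
        walker = "G" + "".join(AA_ALPHABET[rng.integers(20)] for _ in range(4)) + "GKT"
        aa[pos:pos + 8] = list(walker)
        panel.append(ProteinRecord(id=f"seed_cdc6_{k:02d}", aa_sequence="".join(aa)))
    return panel


def mutate_protein_to_identity(
    seed_protein: ProteinRecord, identity: float, rng: np.random.Generator
) -> str:
    """Substitution-only divergence to approximately the target identity,
    preserving the Walker-A box and the initial Met."""
    protect = _walker_positions(seed_protein.aa_sequence) | {0}
    return mutate_protein(seed_protein.aa_sequence, 1.0 - identity, rng, protect=protect)


def shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = list(seq)
    rng.shuffle(arr)
    return "".join(arr)


# ---------------------------------------------------------------------------
# Study plan shared across genomes of one cohort
# ---------------------------------------------------------------------------

@dataclass
class _FamilySpec:
    family_id: str
    genomes: list[int]
    consensus: str
    ancestor: ProteinRecord


def study_plan(spec: SyntheticSpec) -> dict[str, _FamilySpec]:
    """Family consensi and ancestor proteins, identical for every genome of
    the cohort (drawn from the cohort seed only)."""
    rng = np.random.default_rng([spec.seed, 0xFA])
    panel = make_seed_panel()
    plan = spec.resolved_family_plan()
    protect = _orb_protect(spec.orb_master_consensus)
    out: dict[str, _FamilySpec] = {}
    for i, (fid, genomes) in enumerate(sorted(plan.items())):
        if fid == "U":
            consensus = spec.orb_master_consensus
        else:
            consensus = mutate_sequence(
                spec.orb_master_consensus, spec.orb_family_divergence, rng, protect=protect
            )
        seedp = panel[i % len(panel)]
        ancestor = ProteinRecord(
            id=f"fam{fid}_ancestor",
            aa_sequence=mutate_protein_to_identity(seedp, 0.70, rng),
        )
        out[fid] = _FamilySpec(fid, list(genomes), consensus, ancestor)
    return out


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    locus_tag: str
    kind: str  # cdc6 | decoy | mobile
    protein: str
    product: str
    strand: str
    status: str | None = None  # for cdc6
    family_id: str | None = None
    orb_consensus: str | None = None
    seed_identity: float | None = None
    mobile_nearby: bool = False


def _draw_status(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    u = rng.random()
    if u < spec.dual_fraction:
        return "dual"
    if u < spec.dual_fraction + spec.deficient_fraction:
        return "deficient"
    if u < spec.dual_fraction + spec.deficient_fraction + spec.none_fraction:
        return "none"
    return "candidate"


def generate_genome(spec: SyntheticSpec, genome_index: int) -> tuple[list[Replicon], GroundTruth]:
    """Build one genome of the cohort with its ground truth."""
    if genome_index >= spec.n_genomes:
        raise ValueError("genome_index beyond spec.n_genomes")
    rng = np.random.default_rng([spec.seed, 1 + genome_index])
    families = study_plan(spec)
    panel = make_seed_panel()
    gid = f"g{genome_index}"
    truth = GroundTruth()
    replicons: list[Replicon] = []

    # which family genes this genome carries; family genes live on replicon 0
    family_genes = [f for f in families.values() if genome_index in f.genomes]

    gene_counter = 0

    def next_tag(prefix: str) -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"{gid}_{prefix}{gene_counter:04d}"

    n_decoys_left = spec.decoy_gene_count
    n_reps = len(spec.replicons)
    for ri, (rclass, length, topology) in enumerate(spec.replicons):
        rid = f"{gid}_r{ri}_{rclass}"
        n_cdc6 = spec.n_cdc6[ri] if ri < len(spec.n_cdc6) else 0
        plans: list[_GenePlan] = []
        fam_here = family_genes if ri == 0 else []
        for fam in fam_here[:n_cdc6]:
            member = mutate_protein(
                fam.ancestor.aa_sequence, spec.family_protein_divergence, rng,
                protect=_walker_positions(fam.ancestor.aa_sequence) | {0},
            )
            plans.append(_GenePlan(
                locus_tag=next_tag("cdc6_"), kind="cdc6", protein=member,
                product="orc/cdc6 family replication initiator",
                strand="+" if rng.random() < 0.5 else "-",
                status="candidate", family_id=fam.family_id,
                orb_consensus=fam.consensus,
            ))
        protect_orb = _orb_protect(spec.orb_master_consensus)
        for k in range(n_cdc6 - len(plans)):
            status = _draw_status(rng, spec)
            seedp = panel[int(rng.integers(len(panel)))]
            ident = float(rng.uniform(*spec.protein_identity_range))
            member = mutate_protein_to_identity(seedp, ident, rng)
            consensus = mutate_sequence(
                spec.orb_master_consensus, spec.orb_family_divergence, rng,
                protect=protect_orb,
            )
            plans.append(_GenePlan(
                locus_tag=next_tag("cdc6_"), kind="cdc6", protein=member,
                product="orc/cdc6 family replication initiator",
                strand="+" if rng.random() < 0.5 else "-",
                status=status, family_id=None,
                orb_consensus=consensus, seed_identity=ident,
            ))
        for p in plans:
            if p.status in {"candidate", "deficient", "dual"}:
                p.mobile_nearby = bool(rng.random() < spec.mobile_fraction)
        n_decoy_here = max(n_decoys_left // (n_reps - ri), 2)
        n_decoys_left -= n_decoy_here
        sequence, feats, records = _assemble_replicon(
            rid, gid, length, topology, plans, n_decoy_here, spec, rng, next_tag
        )
        rep = Replicon(id=rid, sequence=sequence, topology=topology,
                       replicon_class=rclass, features=feats)
        replicons.append(rep)
        truth.records.extend(records)
    return replicons, truth


def _orb_instance(consensus: str, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    return mutate_sequence(consensus, spec.orb_mutation_rate, rng,
                           protect=_orb_protect(consensus))


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _candidate_block(consensus: str, spec: SyntheticSpec, rng) -> tuple[str, list, tuple]:
    """[pad][ORB >][AT-rich][< ORB][pad]; returns (seq, orb spans, at span)."""
    pad_a = random_dna(int(rng.integers(30, 60)), spec.background_gc, rng)
    pad_b = random_dna(int(rng.integers(30, 60)), spec.background_gc, rng)
    orb_f = _orb_instance(consensus, spec, rng)
    orb_r = _revcomp(_orb_instance(consensus, spec, rng))
    at = random_dna(int(rng.integers(60, 121)), 0.15, rng)
    seq = pad_a + orb_f + at + orb_r + pad_b
    o1 = (len(pad_a), len(pad_a) + len(orb_f))
    at_span = (o1[1], o1[1] + len(at))
    o2 = (at_span[1], at_span[1] + len(orb_r))
    return seq, [o1, o2], at_span


def _single_orb_block(consensus: str, spec: SyntheticSpec, rng) -> tuple[str, list]:
    pad_a = random_dna(int(rng.integers(40, 80)), spec.background_gc, rng)
    pad_b = random_dna(int(rng.integers(40, 80)), spec.background_gc, rng)
    orb = _orb_instance(consensus, spec, rng)  # forward on both sides: no pair
    seq = pad_a + orb + pad_b
    return seq, [(len(pad_a), len(pad_a) + len(orb))]


def _plain_ir(spec: SyntheticSpec, rng, lo: int = 120, hi: int = 260,
              decoy_orb: str | None = None) -> str:
    seq = random_dna(int(rng.integers(lo, hi)), spec.background_gc, rng)
    if decoy_orb is not None:
        # same composition, destroyed order: stresses the motif stage
        sh = shuffled(decoy_orb, rng)
        k = int(rng.integers(0, max(len(seq) - len(sh), 1)))
        seq = seq[:k] + sh + seq[k + len(sh):]
    return seq


def _assemble_replicon(rid, gid, length, topology, plans, n_decoys, spec, rng, next_tag):
    """Sequential block construction: blocks cannot overlap by design."""
    segments: list[str] = []
    feats: list[GeneFeature] = []
    records: list[TruthRecord] = []
    cursor = 0

    def append(seq: str) -> tuple[int, int]:
        nonlocal cursor
        segments.append(seq)
        s = cursor
        cursor += len(seq)
        return s, cursor

    def add_gene(plan: _GenePlan) -> GeneFeature:
        nt = reverse_translate(plan.protein, rng, spec.background_gc)
        if plan.strand == "-":
            nt = _revcomp(nt)
        s, e = append(nt)
        feat = GeneFeature(locus_tag=plan.locus_tag, kind="CDS", start=s, end=e,
                           strand=plan.strand, product=plan.product)
        feats.append(feat)
        return feat

    blocks_needed = []
    for plan in plans:
        blocks_needed.append(plan)
    decoy_plans = []
    for _ in range(n_decoys):
        L = int(rng.integers(150, 451))
        aa = "M" + "".join(AA_ALPHABET[rng.integers(20)] for _ in range(L - 1))
        decoy_plans.append(_GenePlan(
            locus_tag=next_tag("gene_"), kind="decoy", protein=aa,
            product="hypothetical protein",
            strand="+" if rng.random() < 0.5 else "-",
        ))

    est_block = 3500
    total_est = len(plans) * est_block + len(decoy_plans) * 1800
    if total_est > length:
        raise ValueError(f"replicon {rid} too short ({length}) for planned content")
    n_blocks = len(plans) + len(decoy_plans)
    spacer_len = max((length - total_est) // max(n_blocks, 1), 50)

    decoy_iter = iter(decoy_plans)
    for plan in plans:
        append(random_dna(max(spacer_len + int(rng.integers(-spacer_len // 4, spacer_len // 4 + 1)), 50),
                          spec.background_gc, rng))
        orb_spans_abs: list[tuple[int, int]] = []
        at_abs: tuple | None = None
        consensus = plan.orb_consensus or spec.orb_master_consensus
        # upstream IR content (to the left for +, but planted relative to
        # coding orientation: build left-side IR, then gene, then right IR)
        left_seq = right_seq = None
        left_spans: list = []
        right_spans: list = []
        left_at = right_at = None
        if plan.status == "candidate":
            block, spans, at_span = _candidate_block(consensus, spec, rng)
            if plan.strand == "+":
                left_seq, left_spans, left_at = block, spans, at_span
                right_seq = _plain_ir(spec, rng)
            else:
                right_seq, right_spans, right_at = block, spans, at_span
                left_seq = _plain_ir(spec, rng)
        elif plan.status == "deficient":
            left_seq, left_spans = _single_orb_block(consensus, spec, rng)
            right_seq, right_spans = _single_orb_block(consensus, spec, rng)
        elif plan.status == "dual":
            b1, s1, a1 = _candidate_block(consensus, spec, rng)
            b2, s2, a2 = _candidate_block(spec.dual_second_consensus, spec, rng)
            left_seq, left_spans, left_at = b1, s1, a1
            right_seq, right_spans, right_at = b2, s2, a2
        elif plan.status == "none":
            left_seq = _plain_ir(spec, rng, decoy_orb=shuffled(consensus, rng))
            right_seq = _plain_ir(spec, rng)
        else:  # decoy-style gene among cdc6 plans (not used)
            left_seq = _plain_ir(spec, rng)
            right_seq = _plain_ir(spec, rng)

        ls, le = append(left_seq)
        orb_spans_abs.extend((ls + a, ls + b) for a, b in left_spans)
        if left_at:
            at_abs = (ls + left_at[0], ls + left_at[1])
        add_gene(plan)
        rs, re_ = append(right_seq)
        orb_spans_abs.extend((rs + a, rs + b) for a, b in right_spans)
        if right_at and at_abs is None:
            at_abs = (rs + right_at[0], rs + right_at[1])
        # bounding decoy gene; carries the mobile annotation when planted
        try:
            nxt = next(decoy_iter)
        except StopIteration:
            nxt = None
        if plan.mobile_nearby:
            mob = _GenePlan(
                locus_tag=next_tag("tnp_"), kind="mobile",
                protein="M" + "".join(AA_ALPHABET[rng.integers(20)] for _ in range(249)),
                product="ISH3 family transposase" if rng.random() < 0.7 else "integrase",
                strand="+" if rng.random() < 0.5 else "-",
            )
            add_gene(mob)
        elif nxt is not None:
            add_gene(nxt)
        records.append(TruthRecord(
            genome_id=gid, replicon_id=rid, locus_tag=plan.locus_tag, is_cdc6=True,
            family_id=plan.family_id, origin_status=plan.status,
            orb_intervals=orb_spans_abs, at_rich_interval=at_abs,
            mobile_nearby=plan.mobile_nearby, seed_identity=plan.seed_identity,
        ))

    for plan in decoy_iter:
        append(random_dna(max(spacer_len, 50), spec.background_gc, rng))
        # occasional decoy IR with a shuffled ORB
        if rng.random() < 0.25:
            append(_plain_ir(spec, rng, decoy_orb=shuffled(spec.orb_master_consensus, rng)))
        add_gene(plan)
        records.append(TruthRecord(
            genome_id=gid, replicon_id=rid, locus_tag=plan.locus_tag, is_cdc6=False,
            family_id=None, origin_status=None,
        ))

    tail = length - cursor
    if tail > 0:
        append(random_dna(tail, spec.background_gc, rng))
    return "".join(segments), feats, records


def generate_cohort(spec: SyntheticSpec) -> tuple[dict[str, list[Replicon]], GroundTruth]:
    genomes: dict[str, list[Replicon]] = {}
    truth = GroundTruth()
    for gi in range(spec.n_genomes):
        reps, t = generate_genome(spec, gi)
        genomes[f"g{gi}"] = reps
        truth.records.extend(t.records)
    return genomes, truth


# ---------------------------------------------------------------------------
# File emission (GenBank + GFF3 + truth TSV), byte-stable for a fixed seed
# ---------------------------------------------------------------------------

def write_genome(replicons: list[Replicon], outdir: str | Path, genome_id: str,
                 truth: GroundTruth | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gb_path = outdir / f"{genome_id}.gbk"
    gff_path = outdir / f"{genome_id}.gff3"
    records = []
    for rep in replicons:
        rec = SeqRecord(Seq(rep.sequence), id=rep.id, name=rep.id[:16],
                        description=f"synthetic {rep.replicon_class}")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        rec.annotations["date"] = "01-JAN-1980"  # fixed for byte-stable output
        for f in rep.features:
            loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
            sf = SeqFeature(loc, type=f.kind)
            sf.qualifiers["locus_tag"] = [f.locus_tag]
            if f.product:
                sf.qualifiers["product"] = [f.product]
            rec.features.append(sf)
        records.append(rec)
    with open(gb_path, "w") as fh:
        SeqIO.write(records, fh, "genbank")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in replicons:
            for f in rep.features:
                attrs = f"locus_tag={f.locus_tag}"
                if f.product:
                    attrs += f";product={f.product}"
                fh.write(f"{rep.id}\thaloriscan_sim\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                         f"{f.strand}\t.\t{attrs}\n")
    paths = {"genbank": gb_path, "gff3": gff_path}
    if truth is not None:
        truth_path = outdir / f"{genome_id}.truth.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

@dataclass
class TruthComparison:
    confusion: pd.DataFrame  # rows: truth status, cols: called status
    precision: dict
    recall: dict
    family_rand_index: float | None


def truth_compare(calls, truth: GroundTruth) -> TruthComparison:
    """Confusion table of called vs planted origin status plus the Rand
    index of the family assignment against the planted families.

    Truth initiator genes with no call (missed by the screen) count as
    called "none".
    """
    from sklearn.metrics import rand_score

    statuses = ["candidate", "deficient", "dual", "none"]
    call_by_tag = {c.gene_ref: c for c in calls}
    conf = pd.DataFrame(0, index=statuses, columns=statuses)
    fam_true, fam_pred = [], []
    for rec in truth.cdc6():
        call = call_by_tag.get(rec.locus_tag)
        called = call.status if call is not None else "none"
        conf.loc[rec.origin_status, called] += 1
        if rec.origin_status in {"candidate", "dual"}:
            fam_true.append(rec.family_id or f"singleton:{rec.locus_tag}")
            if call is not None and call.family:
                fam_pred.append(call.family)
            else:
                fam_pred.append(f"unassigned:{rec.locus_tag}")
    precision, recall = {}, {}
    for st in statuses:
        tp = int(conf.loc[st, st])
        called_total = int(conf[st].sum())
        truth_total = int(conf.loc[st].sum())
        precision[st] = tp / called_total if called_total else None
        recall[st] = tp / truth_total if truth_total else None
    rand = rand_score(fam_true, fam_pred) if len(set(fam_true)) > 1 else None
    return TruthComparison(confusion=conf, precision=precision, recall=recall,
                           family_rand_index=rand)
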