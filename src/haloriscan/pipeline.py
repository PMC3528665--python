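"""End-to-end orchestration: screen -> IRs -> ORBs -> calls -> families.

One :class:`RunConfig` centralizes every threshold of the pipeline; a run
is deterministic given the config (motif seed included) and records a
machine-readable manifest with the per-stage funnel counts
(CDS -> initiator hits -> origin-associated genes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cdc6_screen, family_evo, genome_io, orb_discovery, origin_call

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # screen
    min_identity_pct: float = 30.0
    min_len: int = 300
    min_aligned: int = 150
    use_profile_rescreen: bool = True
    # motif discovery
    width_min: int = 20
    width_max: int = 40
    width_step: int = 5
    n_restarts: int = 20
    motif_seed: int = 17
    second_motif: bool = True
    # ORB qualification
    min_bits: float = 8.0
    min_g_run: int = 5
    terminal_window: int = 10
    max_gap: int = 400
    at_window: int = 50
    at_margin: float = 0.25
    ir_max_span: int = 5000
    motif_ir_trim: int = 800  # gene-proximal bp of each IR used for motif work; 0 = full IR
    # families / evolution
    family_threshold_pct: float = 80.0
    mobility_window_bp: int = 10000
    build_tree: bool = True
    # I/O
    genome_paths: list = field(default_factory=list)
    seeds_path: str | None = None
    outdir: str | None = None

    def validate(self) -> None:
        checks = [
            (0 <= self.min_identity_pct <= 100, "min_identity_pct in [0,100]"),
            (self.min_len > 0, "min_len positive"),
            (20 <= self.width_min <= self.width_max <= 40, "width grid within [20,40]"),
            (self.n_restarts >= 1, "n_restarts >= 1"),
            (self.min_g_run >= 1, "min_g_run >= 1"),
            (0 <= self.at_margin <= 1, "at_margin in [0,1]"),
            (self.family_threshold_pct > 0, "family threshold positive"),
            (self.mobility_window_bp >= 0, "mobility window non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    hits: dict  # genome_id -> list[OrcCdc6Hit]
    calls: list  # all OriginCall
    families: list  # named OriginFamily
    tree: object | None  # PhyloTree of ori-associated initiators
    manifest: dict
    motifs: dict  # genome_id -> list[MotifModel]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage '{stage}' failed: {detail}")
        self.stage = stage


def _stage_seed(motif_seed: int, label: str) -> int:
    """Stable per-stage RNG seed below 2**31."""
    return (motif_seed * 2654435761 ^ zlib.crc32(label.encode())) % (2**31)


def run_pipeline(
    config: RunConfig,
    genomes: dict[str, list] | None = None,
    seeds: list | None = None,
) -> PipelineResult:
    """Run the full prediction pipeline over one or more genomes.

    ``genomes`` maps genome id to its replicon list; when omitted they are
    loaded from ``config.genome_paths`` (one GenBank file per genome).
    """
    config.validate()
    if genomes is None:
        genomes = {}
        for p in config.genome_paths:
            p = Path(p)
            genomes[p.stem] = genome_io.read_replicons(p, format="genbank")
    if not genomes:
        raise StageError("input", "no input replicons")
    if seeds is None:
        seeds = genome_io.read_seed_panel(config.seeds_path)

    hits_by_genome: dict[str, list] = {}
    calls: list = []
    motifs_by_genome: dict[str, list] = {}
    counts: dict[str, dict] = {}
    masked_pool: list = []
    per_gene_ctx: list = []  # (genome_id, hit, irs-by-side, elements1-by-side)

    for gid, replicons in sorted(genomes.items()):
        try:
            hits = cdc6_screen.screen_proteome(
                replicons, seeds, min_len=config.min_len,
                min_identity_pct=config.min_identity_pct, min_aligned=config.min_aligned,
            )
            if config.use_profile_rescreen and any(h.passes for h in hits):
                all_cds = cdc6_screen.iter_proteome(replicons)
                hits = cdc6_screen.profile_rescreen(
                    hits, all_cds, min_len=config.min_len, min_overlap=config.min_aligned)
        except Exception as exc:
            raise StageError("screen", f"{gid}: {exc}") from exc
        hits_by_genome[gid] = hits
        passing = [h for h in hits if h.passes]
        n_cds = sum(1 for r in replicons for f in r.features if f.kind == "CDS")
        counts[gid] = {"n_cds": n_cds, "n_hits": len(hits), "n_passing_cdc6": len(passing)}

        rep_by_id = {r.id: r for r in replicons}
        gene_irs = []
        for hit in passing:
            irs = orb_discovery.extract_flanking_irs(
                rep_by_id[hit.replicon_id], hit.gene, max_span=config.ir_max_span)
            L = len(rep_by_id[hit.replicon_id])
            irs = [orb_discovery.trim_ir_proximal(ir, config.motif_ir_trim, L) for ir in irs]
            gene_irs.append((hit, {ir.side: ir for ir in irs}))
        pooled = [ir for _h, by_side in gene_irs for ir in by_side.values()]
        if len(pooled) < 2:
            for hit, by_side in gene_irs:
                calls.append(origin_call.OriginCall(
                    gene_ref=hit.gene.locus_tag, replicon_id=hit.replicon_id,
                    status="none", genome_id=gid, notes=["too few IRs for motif discovery"]))
            motifs_by_genome[gid] = []
            continue
        try:
            models = orb_discovery.discover_motifs(
                pooled, width_min=config.width_min, width_max=config.width_max,
                width_step=config.width_step, n_restarts=config.n_restarts,
                seed=_stage_seed(config.motif_seed, f"motifs:{gid}"),
                g_string_rank=(config.min_g_run, config.terminal_window),
            )
        except Exception as exc:
            raise StageError("motif_discovery", f"{gid}: {exc}") from exc
        top = models[0]
        top.motif_id = 0
        motifs_by_genome[gid] = [top]

        elements_by_gene = []
        all_elements = []
        for hit, by_side in gene_irs:
            el_by_side = {}
            for side, ir in by_side.items():
                if len(ir) < top.width:
                    el_by_side[side] = []
                    continue
                els = orb_discovery.scan_motif(ir, top, min_bits=config.min_bits)
                orb_discovery.annotate_g_strings(
                    els, min_run=config.min_g_run, terminal_window=config.terminal_window)
                el_by_side[side] = els
                all_elements.extend(els)
            elements_by_gene.append((hit, by_side, el_by_side))
        per_gene_ctx.append((gid, elements_by_gene))
        masked_pool.extend(orb_discovery.mask_occurrences(
            pooled, all_elements,
            seed=_stage_seed(config.motif_seed, f"mask:{gid}")))

    # Second motif family, searched cohort-wide on masked IRs (dual origins
    # carry an unrelated second ORB set that is rare within any one genome).
    second_model = None
    if config.second_motif and len(masked_pool) >= 2:
        chunks = orb_discovery.chunk_irs(masked_pool)
        try:
            models2 = orb_discovery.discover_motifs(
                chunks, width_min=config.width_min, width_max=config.width_max,
                width_step=config.width_step, n_restarts=config.n_restarts,
                seed=_stage_seed(config.motif_seed, "motifs:second"),
                g_string_rank=(config.min_g_run, config.terminal_window),
            )
        except ValueError:
            models2 = []
        for m2 in models2[:1]:
            if m2.n_expected_sites < 2:
                continue
            distinct = all(
                origin_call.consensus_hamming(m2.consensus, m1.consensus)
                > min(m2.width, m1.width) / 4
                for ms in motifs_by_genome.values() for m1 in ms
            )
            if distinct:
                second_model = m2
                second_model.motif_id = 1

    for gid, elements_by_gene in per_gene_ctx:
        if second_model is not None:
            motifs_by_genome[gid] = motifs_by_genome[gid][:1] + [second_model]
        for hit, irs_by_side, el_by_side in elements_by_gene:
            if second_model is not None:
                els2_by_side = {}
                for side, ir in irs_by_side.items():
                    if len(ir) < second_model.width:
                        continue
                    els2 = orb_discovery.scan_motif(ir, second_model, min_bits=config.min_bits)
                    orb_discovery.annotate_g_strings(
                        els2, min_run=config.min_g_run,
                        terminal_window=config.terminal_window)
                    els2_by_side[side] = els2
                # only admit the second family where it independently forms a
                # candidate-grade arrangement (dual-origin evidence); lone
                # second-family hits must not perturb the primary call
                ok2, _ = origin_call._candidate_arrangement(els2_by_side, config.max_gap)
                if ok2:
                    for side, els2 in els2_by_side.items():
                        existing = el_by_side.get(side, [])
                        for e2 in els2:
                            if not any(e2.offset < e.offset + e.length and
                                       e2.offset + e2.length > e.offset
                                       for e in existing):
                                existing.append(e2)
                        el_by_side[side] = sorted(existing, key=lambda e: e.offset)
            at_by_side = {}
            for side, ir in irs_by_side.items():
                if len(ir) >= config.at_window:
                    at_by_side[side] = orb_discovery.at_rich_segment(
                        ir, background_gc=_replicon_gc(ir, genomes, gid),
                        window=config.at_window, margin=config.at_margin)
                else:
                    at_by_side[side] = None
            call = origin_call.call_origin(
                hit, el_by_side, at_by_side, irs_by_side,
                motifs=motifs_by_genome[gid], max_gap=config.max_gap, genome_id=gid)
            calls.append(call)

    for gid in genomes:
        counts[gid]["n_ori_associated"] = sum(
            1 for c in calls if c.genome_id == gid and c.status in {"candidate", "dual"})

    # mobility flags
    rep_features = {}
    rep_meta = {}
    for gid, replicons in genomes.items():
        for r in replicons:
            rep_features[r.id] = r.features
            rep_meta[r.id] = (len(r), r.topology == "circular", r.replicon_class)
    for call in calls:
        if call.status in {"candidate", "dual"} and call.origin_interval:
            L, circ, _cls = rep_meta[call.replicon_id]
            ann = family_evo.annotate_mobility(
                call, rep_features[call.replicon_id],
                window_bp=config.mobility_window_bp, replicon_length=L, circular=circ)
            call.later_acquired = ann.later_acquired
            if ann.mobile_genes:
                tag, klass, dist = ann.mobile_genes[0]
                call.notes.append(f"mobile gene {tag} ({klass}) at {dist} bp")

    origin_call.assign_origin_names(
        calls, {rid: meta[2] for rid, meta in rep_meta.items()})

    # families over origin-associated initiators
    hit_by_tag = {h.gene.locus_tag: (gid, h)
                  for gid, hs in hits_by_genome.items() for h in hs}
    assoc = [c for c in calls if c.status in {"candidate", "dual"}]
    families = []
    tree = None
    if len(assoc) >= 2:
        proteins = [hit_by_tag[c.gene_ref][1].protein for c in assoc]
        matrix = family_evo.identity_matrix(proteins)
        member_sets = family_evo.cluster_families(matrix, config.family_threshold_pct)
        call_by_tag = {c.gene_ref: c for c in assoc}
        fam_members = []
        for members in member_sets:
            fam_members.append([
                (hit_by_tag[tag][0], call_by_tag[tag], hit_by_tag[tag][1])
                for tag in members
            ])
        families = family_evo.name_families(fam_members, sorted(genomes))
        for fam in families:
            for _gid, call, _hit in fam.members:
                call.family = fam.name
        if config.build_tree and len(assoc) >= 3:
            D, ids = family_evo.pairwise_protein_distances(proteins)
            tree = family_evo.nj_tree(D, ids)

    manifest = {
        "config_hash": config.config_hash,
        "n_genomes": len(genomes),
        "per_genome": counts,
        "totals": {
            "n_cds": sum(c["n_cds"] for c in counts.values()),
            "n_passing_cdc6": sum(c["n_passing_cdc6"] for c in counts.values()),
            "n_ori_associated": sum(c.get("n_ori_associated", 0) for c in counts.values()),
            "n_deficient": sum(1 for c in calls if c.status == "deficient"),
            "n_none": sum(1 for c in calls if c.status == "none"),
            "n_dual": sum(1 for c in calls if c.status == "dual"),
            "n_families": len(families),
            "n_later_acquired": sum(1 for c in calls if c.later_acquired),
        },
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]

    result = PipelineResult(hits=hits_by_genome, calls=calls, families=families,
                            tree=tree, manifest=manifest, motifs=motifs_by_genome)
    if config.outdir:
        _write_outputs(result, config, genomes)
    return result


def _replicon_gc(ir, genomes, gid) -> float:
    for r in genomes[gid]:
        if r.id == ir.replicon_id:
            return genome_io.gc_fraction(r.sequence)
    return 0.5


def _write_outputs(result: PipelineResult, config: RunConfig, genomes: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    replicons = [r for reps in genomes.values() for r in reps]
    genome_io.write_origin_report(result.calls, result.families, outdir, replicons)
    rows = []
    for fam in result.families:
        for gid, call, hit in fam.members:
            rows.append({
                "family": fam.name, "member": hit.protein.id, "genome": gid,
                "replicon": call.replicon_id, "status": call.status,
                "later_acquired": call.later_acquired,
            })
    import pandas as pd

    pd.DataFrame(rows, columns=["family", "member", "genome", "replicon",
                                "status", "later_acquired"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False)
    if result.tree is not None:
        (outdir / "initiators.nwk").write_text(result.tree.newick + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    (outdir / "config.yaml").write_text(config.to_yaml())
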