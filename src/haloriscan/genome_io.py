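"""Replicon I/O, the coordinate model, and shared sequence statistics.

All internal coordinates are 0-based half-open on the forward strand.
GenBank and GFF3 use 1-based inclusive coordinates; conversion happens at
the I/O boundary and nowhere else.  Haloarchaeal replicons are circular:
a feature crossing the coordinate origin is stored with ``start > end``
and ``wraps_origin=True``; its length is ``(L - start) + end``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
_KIND_MAP = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}

#: replicon classes recognised throughout the pipeline
REPLICON_CLASSES = ("chromosome", "minichromosome", "megaplasmid", "plasmid", "unknown")


class ParseError(ValueError):
    """Malformed input record."""


class PseudogeneError(ValueError):
    """CDS translation hit an internal stop codon (likely pseudogene)."""


@dataclass
class GeneFeature:
    locus_tag: str
    kind: str = "CDS"  # CDS | rRNA | tRNA | other
    start: int = 0  # 0-based inclusive
    end: int = 0  # 0-based exclusive
    strand: str = "+"
    product: str = ""
    wraps_origin: bool = False

    def length(self, replicon_length: int | None = None) -> int:
        if self.wraps_origin:
            if replicon_length is None:
                raise ValueError("replicon length required for wrapped feature")
            return (replicon_length - self.start) + self.end
        return self.end - self.start

    def midpoint(self, replicon_length: int | None = None) -> int:
        if self.wraps_origin:
            return (self.start + self.length(replicon_length) // 2) % replicon_length
        return (self.start + self.end) // 2


@dataclass
class Replicon:
    id: str
    sequence: str
    topology: str = "linear"  # circular | linear
    replicon_class: str = "unknown"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"replicon {self.id}: empty sequence")
        self.sequence = _normalize_sequence(self.sequence, self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence with circular wrap: ``end < start`` wraps through 0."""
        if end >= start:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError(f"wrapped fetch on linear replicon {self.id}")
        return self.sequence[start:] + self.sequence[:end]

    def feature_sequence(self, feat: GeneFeature) -> str:
        raw = self.fetch(feat.start, feat.end)  # fetch handles wrapped features
        if feat.strand == "-":
            return str(Seq(raw).reverse_complement())
        return raw


@dataclass
class ProteinRecord:
    id: str
    aa_sequence: str

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


def _normalize_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq
    bad = sorted(set(seq) - VALID_BASES)
    warnings.warn(
        f"replicon {name}: residues {bad} outside A/C/G/T/N mapped to N",
        stacklevel=3,
    )
    table = str.maketrans({c: "N" for c in bad})
    return seq.translate(table)


def _guess_replicon_class(description: str) -> str:
    d = description.lower()
    if "megaplasmid" in d:
        return "megaplasmid"
    if "minichromosome" in d or "chromosome ii" in d or "chromosome 2" in d:
        return "minichromosome"
    if "chromosome" in d:
        return "chromosome"
    if "plasmid" in d:
        return "plasmid"
    return "unknown"


def read_replicons(path: str | Path, format: str | None = None) -> list[Replicon]:
    """Read FASTA or GenBank into :class:`Replicon` objects.

    GenBank feature coordinates (1-based inclusive) are converted to the
    internal 0-based half-open convention; ``join`` locations crossing the
    coordinate origin of a circular record become wrapped features.
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    if format not in {"fasta", "genbank"}:
        raise ValueError(f"unsupported format: {format}")
    replicons: list[Replicon] = []
    try:
        with open(path) as fh:
            records = list(SeqIO.parse(fh, format))
    except Exception as exc:  # noqa: BLE001 - surface the offending file
        raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise ParseError(f"no records parsed from {path} (format={format})")
    for rec in records:
        topology = "linear"
        if format == "genbank":
            topology = rec.annotations.get("topology", "linear")
        rep = Replicon(
            id=rec.id,
            sequence=str(rec.seq),
            topology=topology if topology in {"circular", "linear"} else "linear",
            replicon_class=_guess_replicon_class(rec.description or ""),
        )
        if format == "genbank":
            rep.features = _features_from_genbank(rec, len(rep))
        replicons.append(rep)
    return replicons


def _features_from_genbank(rec, length: int) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    n_anon = 0
    for f in rec.features:
        kind = _KIND_MAP.get(f.type)
        if kind is None:
            continue
        quals = f.qualifiers
        locus = quals.get("locus_tag", [None])[0]
        if locus is None:
            n_anon += 1
            locus = f"{rec.id}_f{n_anon}"
        product = quals.get("product", [""])[0]
        strand = "-" if f.location.strand == -1 else "+"
        start = int(f.location.start)
        end = int(f.location.end)
        wraps = False
        parts = f.location.parts
        if len(parts) > 1 and int(parts[0].end) == length and int(parts[-1].start) == 0:
            # join(x..L, 1..y) across the origin of a circular record
            start, end, wraps = int(parts[0].start), int(parts[-1].end), True
        feats.append(
            GeneFeature(locus_tag=locus, kind=kind, start=start, end=end,
                        strand=strand, product=product, wraps_origin=wraps)
        )
    feats.sort(key=lambda g: g.start)
    return feats


def read_annotations(
    path: str | Path,
    replicons: Sequence[Replicon] | None = None,
    format: str = "gff3",
) -> dict[str, list[GeneFeature]]:
    """Parse GFF3 gene features grouped by replicon id.

    1-based inclusive GFF coordinates become 0-based half-open.  When
    ``replicons`` is supplied, seqids are validated against it and a
    feature whose end runs past a circular replicon's length is wrapped
    (``wraps_origin=True``).
    """
    if format != "gff3":
        raise ValueError(f"unsupported annotation format: {format}")
    by_rep: dict[str, Replicon] = {r.id: r for r in (replicons or [])}
    grouped: dict[str, list[GeneFeature]] = {}
    unmatched: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"GFF3 line with {len(cols)} columns: {line[:80]}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            kind = _KIND_MAP.get(ftype)
            if kind is None and ftype != "gene":
                continue
            attrd = _parse_gff_attributes(attrs)
            locus = attrd.get("locus_tag") or attrd.get("ID") or f"{seqid}:{start}-{end}"
            s, e = int(start) - 1, int(end)
            wraps = False
            if replicons is not None:
                if seqid not in by_rep:
                    unmatched.add(seqid)
                    continue
                rep = by_rep[seqid]
                if e > len(rep):
                    if rep.topology == "circular":
                        e = e % len(rep)
                        wraps = True
                    else:
                        raise ParseError(
                            f"feature {locus} ends at {e} beyond linear replicon "
                            f"{seqid} of length {len(rep)}"
                        )
            grouped.setdefault(seqid, []).append(
                GeneFeature(locus_tag=locus, kind=kind or "other", start=s, end=e,
                            strand=strand if strand in "+-" else "+",
                            product=attrd.get("product", ""), wraps_origin=wraps)
            )
    if unmatched:
        raise ParseError(f"GFF3 seqids not matching any replicon: {sorted(unmatched)}")
    for feats in grouped.values():
        feats.sort(key=lambda g: g.start)
    return grouped


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def attach_annotations(replicons: Sequence[Replicon], grouped: dict[str, list[GeneFeature]]) -> None:
    for rep in replicons:
        if rep.id in grouped:
            rep.features = grouped[rep.id]


def translate_cds(replicon: Replicon, feature: GeneFeature) -> ProteinRecord:
    """Translate a CDS with the bacterial/archaeal code (NCBI table 11).

    Minus-strand features are reverse-complemented first; the terminal stop
    is removed.  An internal stop raises :class:`PseudogeneError`.
    """
    if feature.kind != "CDS":
        raise ValueError(f"{feature.locus_tag}: not a CDS")
    nt = replicon.feature_sequence(feature)
    if len(nt) % 3 != 0:
        raise ParseError(f"{feature.locus_tag}: CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise PseudogeneError(f"{feature.locus_tag}: internal stop codon at aa {aa.index('*')}")
    return ProteinRecord(id=feature.locus_tag, aa_sequence=aa)


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from numerator and denominator."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = int(np.sum((arr == ord("G")) | (arr == ord("C"))))
    n = int(np.sum(arr == ord("N")))
    denom = len(seq) - n
    return gc / denom if denom else 0.0


def gc_profile(replicon: Replicon, window: int = 50000, step: int = 1000) -> pd.DataFrame:
    """Sliding-window GC content, columns ``midpoint`` and ``gc``.

    Circular replicons wrap; on linear replicons the window must fit.
    """
    L = len(replicon)
    if window > L:
        if replicon.topology != "circular":
            raise ValueError(f"window {window} exceeds linear replicon length {L}")
        window = L
    arr = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    if replicon.topology == "circular":
        starts = np.arange(0, L, step)
        is_gc = np.concatenate([is_gc, is_gc[: window - 1]]) if window > 1 else is_gc
        is_n = np.concatenate([is_n, is_n[: window - 1]]) if window > 1 else is_n
    else:
        starts = np.arange(0, L - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    cn = np.concatenate([[0], np.cumsum(is_n)])
    gc_counts = cg[starts + window] - cg[starts]
    n_counts = cn[starts + window] - cn[starts]
    denom = np.maximum(window - n_counts, 1)
    values = gc_counts / denom
    midpoints = (starts + window // 2) % L
    return pd.DataFrame({"midpoint": midpoints, "gc": values})


# ---------------------------------------------------------------------------
# Origin report output (BED / GFF3 / TSV summaries)
# ---------------------------------------------------------------------------

def write_origin_report(calls, families, outdir: str | Path, replicons: Sequence[Replicon] | None = None) -> dict[str, Path]:
    """Write the origin call set as BED6 + GFF3 + per-replicon TSV summaries.

    ``origins.bed``: one interval per called origin (0-based half-open).
    ``origins.gff3``: origin features with their ORB elements as children.
    ``replicon_summary.tsv``: per-replicon initiator/origin counts and the
    percentage of initiators with an associated origin.
    ``mobility_summary.tsv``: per-genome predicted vs later-acquired counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": outdir / "origins.bed",
        "gff3": outdir / "origins.gff3",
        "summary": outdir / "replicon_summary.tsv",
        "mobility": outdir / "mobility_summary.tsv",
    }
    called = [c for c in calls if c.status in {"candidate", "dual", "deficient"} and c.origin_interval]
    with open(paths["bed"], "w") as bed:
        bed.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for c in called:
            s, e = c.origin_interval
            name = c.name or f"ori_{c.gene_ref}"
            bed.write(f"{c.replicon_id}\t{s}\t{e}\t{name}\t0\t.\n")
    with open(paths["gff3"], "w") as gff:
        gff.write("##gff-version 3\n")
        for i, c in enumerate(called, 1):
            s, e = c.origin_interval
            oid = c.name or f"origin{i}"
            gff.write(
                f"{c.replicon_id}\thaloriscan\tregion\t{s + 1}\t{e}\t.\t.\t.\t"
                f"ID={oid};status={c.status};gene={c.gene_ref}\n"
            )
            for j, orb in enumerate(c.orbs, 1):
                os_, oe = orb.replicon_interval
                strand = "+" if orb.orientation == "forward" else "-"
                gff.write(
                    f"{c.replicon_id}\thaloriscan\tmisc_feature\t{os_ + 1}\t{oe}\t"
                    f"{orb.score:.2f}\t{strand}\t.\tID={oid}.orb{j};Parent={oid}\n"
                )
    # Table-1-style per-replicon summary
    from .origin_call import summarize_replicon  # local import avoids cycle

    rep_ids = [r.id for r in (replicons or [])] or sorted({c.replicon_id for c in calls})
    rows = []
    for rid in rep_ids:
        sub = [c for c in calls if c.replicon_id == rid]
        n_cdc6, n_ori, pct = summarize_replicon(sub)
        rows.append({"replicon": rid, "n_cdc6": n_cdc6, "n_ori_associated": n_ori,
                     "percentage": "" if pct is None else pct})
    pd.DataFrame(rows, columns=["replicon", "n_cdc6", "n_ori_associated", "percentage"]).to_csv(
        paths["summary"], sep="\t", index=False)
    # Table-2-style per-genome later-acquired summary
    rows = []
    by_genome: dict[str, list] = {}
    for c in calls:
        by_genome.setdefault(c.genome_id or "genome", []).append(c)
    for gid in sorted(by_genome):
        sub = [c for c in by_genome[gid] if c.status in {"candidate", "dual"}]
        n_later = sum(1 for c in sub if c.later_acquired)
        rows.append({"genome": gid, "n_predicted": len(sub), "n_later_acquired": n_later})
    pd.DataFrame(rows, columns=["genome", "n_predicted", "n_later_acquired"]).to_csv(
        paths["mobility"], sep="\t", index=False)
    return paths


def read_seed_panel(path: str | Path | None = None) -> list[ProteinRecord]:
    """Load the packaged initiator seed panel (FASTA of protein sequences)."""
    if path is None:
        from importlib.resources import files

        path = files("haloriscan.data") / "synthetic_orc_cdc6_seeds.faa"
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no seed proteins in {path}")
    return [ProteinRecord(id=r.id, aa_sequence=str(r.seq)) for r in records]
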