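"""GFF3/BED/FASTA writers and a minimal GFF3 reader.

Internal coordinates are 0-based half-open; GFF3 is written 1-based
inclusive and BED 0-based half-open. All writers are deterministic:
features are emitted in (seqid, start, type) order and floats with fixed
precision, so identical inputs give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .seqs import SequenceRecord


@dataclass
class Gff3Feature:
    seqid: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    strand: str = "."
    score: str = "."
    source: str = "tas3scan"
    attributes: dict = field(default_factory=dict)

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return "\t".join([
            self.seqid, self.source, self.type,
            str(self.start + 1), str(self.end), str(self.score),
            self.strand, ".", attrs or ".",
        ])


def write_gff3(features: list[Gff3Feature], path: str | Path) -> None:
    ordered = sorted(features, key=lambda f: (f.seqid, f.start, f.end, f.type,
                                              f.attributes.get("ID", "")))
    lines = ["##gff-version 3"] + [f.line() for f in ordered]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, source, ftype, start, end, score, strand, _, attrs = \
            line.split("\t")
        attributes = {}
        if attrs != ".":
            for kv in attrs.split(";"):
                k, v = kv.split("=", 1)
                attributes[k] = v
        feats.append(Gff3Feature(seqid, ftype, int(start) - 1, int(end),
                                 strand, score, source, attributes))
    return feats


def write_bed(intervals: list[tuple], path: str | Path) -> None:
    """BED6 rows from (seqid, start, end, name, score, strand) tuples."""
    rows = sorted(intervals)
    lines = ["\t".join(str(x) for x in row) for row in rows]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
           for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq),
                           rec.description.removeprefix(rec.id).strip())
            for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# feature builders


def precursor_features(cand) -> list[Gff3Feature]:
    pid = f"pre_{cand.sequence_id}_{cand.start}"

    def genome_arm(rel):
        if cand.strand == "+":
            return cand.start + rel[0], cand.start + rel[1]
        return cand.end - rel[1], cand.end - rel[0]

    mir = genome_arm(cand.mir_arm)
    star = genome_arm(cand.star_arm)
    parent = Gff3Feature(
        cand.sequence_id, "pre_miRNA", cand.start, cand.end, cand.strand,
        attributes={
            "ID": pid,
            "mfe": f"{cand.fold.mfe:.2f}",
            "stem_bp": cand.fold.stem_bp,
            "lower_stem_bp": cand.lower_stem_bp,
            "passes": str(cand.passes).lower(),
            "criteria": ",".join(k for k, v in cand.criteria.items()
                                 if k != "pass" and v),
        })
    return [
        parent,
        Gff3Feature(cand.sequence_id, "miRNA", mir[0], mir[1], cand.strand,
                    attributes={"ID": f"{pid}_miR", "Parent": pid}),
        Gff3Feature(cand.sequence_id, "miRNA_star", star[0], star[1],
                    cand.strand,
                    attributes={"ID": f"{pid}_miR_star", "Parent": pid}),
    ]


def target_site_feature(hit) -> Gff3Feature:
    return Gff3Feature(
        hit.sequence_id, "miRNA_target_site", hit.start, hit.end, hit.strand,
        score=f"{hit.penalty:.2f}",
        attributes={
            "ID": f"site_{hit.sequence_id}_{hit.start}_{hit.strand.replace('-', 'm')}",
            "guide": hit.guide_name,
            "penalty": f"{hit.penalty:.2f}",
            "cleavable": str(hit.cleavable).lower(),
        })


def locus_features(locus, idx: int) -> list[Gff3Feature]:
    lid = f"TAS3_{locus.sequence_id}_{idx}"
    feats = [Gff3Feature(
        locus.sequence_id, "TAS3_locus", locus.start, locus.end, locus.strand,
        attributes={"ID": lid, "architecture": locus.architecture.value,
                    "length": locus.length})]
    for name, site in (("site5", locus.site5), ("site3", locus.site3)):
        feats.append(Gff3Feature(
            locus.sequence_id, "miR390_target_site", site.start, site.end,
            site.strand, score=f"{site.penalty:.2f}",
            attributes={"ID": f"{lid}_{name}", "Parent": lid,
                        "cleavable": str(site.cleavable).lower()}))
    for i, h in enumerate(locus.tasi_hits):
        attrs = {"ID": f"{lid}_tasi{i}", "Parent": lid,
                 "identity": f"{h.identity:.4f}",
                 "phase_register": h.phase_register}
        if h.functional is not None:
            attrs["functional"] = str(h.functional).lower()
        feats.append(Gff3Feature(
            locus.sequence_id, f"tasi{h.kind}", h.start, h.end,
            h.strand_of_match, attributes=attrs))
    return feats


def truth_features(truths) -> list[Gff3Feature]:
    feats = []
    for t in truths:
        attrs = {"ID": t.feature_id, "kind": t.kind.value}
        if t.architecture is not None:
            attrs["architecture"] = t.architecture.value
        feats.append(Gff3Feature(t.sequence_id, t.kind.value, t.start, t.end,
                                 t.strand, source="tas3scan_truth",
                                 attributes=attrs))
        for name, el in sorted(t.elements.items()):
            e_attrs = {"ID": f"{t.feature_id}_{name}", "Parent": t.feature_id}
            if "phase_register" in el:
                e_attrs["phase_register"] = el["phase_register"]
            feats.append(Gff3Feature(
                t.sequence_id, el.get("kind", name), el["start"], el["end"],
                el["strand"], source="tas3scan_truth", attributes=e_attrs))
    return feats
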