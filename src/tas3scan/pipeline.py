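"""End-to-end scan orchestration and planted-truth recovery scoring.

``run_scan`` chains the stages — precursor discovery, in-silico PCR, dual
target-site locus scanning with element classification, TAS6-TAS3 complex
detection and (when at least three loci are found) NJ clustering — over a
set of FASTA inputs, writes GFF3/BED/FASTA/JSON outputs and returns a
per-stage count report. All outputs are deterministic for fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

from .config import PipelineConfig, default_config
from .compare import distance_matrix, nj_tree
from .gff import (Gff3Feature, locus_features, precursor_features,
                  read_fasta, target_site_feature, truth_features,
                  write_bed, write_fasta, write_gff3)
from .pcr import predict_amplicons
from .precursor import scan_precursors
from .seqs import SequenceRecord
from .targets import find_target_sites
from .taslocus import (ArchitectureClass, Tas3Locus, detect_tas6_tas3_complex,
                       scan_tas_loci)


def scan_record(record: SequenceRecord, cfg: PipelineConfig) -> dict:
    """All stages over one sequence; returns the per-record result bundle."""
    precursors = scan_precursors(
        record, cfg.guide_variants("miR390"), cfg.star_variants("miR390"),
        cfg.criteria, None, cfg.max_mm_per_arm, cfg.duplex_span_range,
        cfg.flank)

    amplicons = []
    for pset in cfg.primer_sets:
        amplicons.extend(predict_amplicons(record, pset))

    mir390_hits = []
    for guide in cfg.guide_variants("miR390"):
        mir390_hits.extend(find_target_sites(
            record, guide, cfg.max_penalty, cfg.weights, "miR390"))
    loci = scan_tas_loci(record, mir390_hits, cfg.tasi_refs,
                         cfg.tas3_span_range, cfg.min_identity,
                         cfg.adjacency_gap, cfg.ap2_target_ref,
                         cfg.max_breaking_subs)

    tas6_hits = []
    for name in ("miR156", "miR529"):
        if name not in cfg.guides:
            continue
        for guide in cfg.guide_variants(name):
            tas6_hits.extend(find_target_sites(
                record, guide, cfg.max_penalty, cfg.weights, name))
    from .taslocus import pair_dual_sites, resolve_locus_overlaps
    tas6_loci = resolve_locus_overlaps(
        pair_dual_sites(tas6_hits, cfg.tas6_span_range))
    complexes = detect_tas6_tas3_complex(tas6_loci, loci, cfg.tas6_max_gap)
    upgraded = {id(c.tas3) for c in complexes}
    for locus in loci:
        if id(locus) in upgraded:
            locus.architecture = ArchitectureClass.TAS6_TAS3

    return {
        "record": record,
        "precursors": precursors,
        "amplicons": amplicons,
        "mir390_hits": mir390_hits,
        "loci": loci,
        "tas6_loci": tas6_loci,
        "complexes": complexes,
    }


def run_scan(cfg: PipelineConfig, records: list[SequenceRecord] | None = None,
             write: bool = True) -> dict:
    """Scan every input record; optionally write the output bundle.

    Returns the run report (per-stage counts plus per-record results under
    the ``results`` key, which is not serialized)."""
    if records is None:
        records = []
        for path in cfg.inputs:
            records.extend(read_fasta(path))

    results = [scan_record(rec, cfg) for rec in records]

    counts = {
        "sequences": len(records),
        "arm_pair_candidates": sum(len(r["precursors"]) for r in results),
        "passing_precursors": sum(
            sum(1 for c in r["precursors"] if c.passes) for r in results),
        "amplicons": sum(len(r["amplicons"]) for r in results),
        "mir390_target_sites": sum(len(r["mir390_hits"]) for r in results),
        "tas3_loci": sum(len(r["loci"]) for r in results),
        "tas6_loci": sum(len(r["tas6_loci"]) for r in results),
        "tas6_tas3_complexes": sum(len(r["complexes"]) for r in results),
    }
    arch_counts: dict = {}
    for r in results:
        for locus in r["loci"]:
            arch_counts[locus.architecture.value] = \
                arch_counts.get(locus.architecture.value, 0) + 1

    newick = None
    loci_seqs = {}
    for r in results:
        for i, locus in enumerate(r["loci"]):
            lid = f"{locus.sequence_id}_L{i}"
            loci_seqs[lid] = r["record"].seq[locus.start:locus.end]
    if len(loci_seqs) >= 3:
        newick = nj_tree(distance_matrix(loci_seqs))

    report = {"counts": counts, "architectures": arch_counts,
              "seed": cfg.seed, "newick": newick, "results": results}
    if write:
        _write_outputs(cfg, report)
    return report


def _write_outputs(cfg: PipelineConfig, report: dict) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats: list[Gff3Feature] = []
    bed_rows = []
    passing_windows = []
    for r in report["results"]:
        rec = r["record"]
        for c in r["precursors"]:
            feats.extend(precursor_features(c))
            if c.passes:
                passing_windows.append(SequenceRecord(
                    f"{rec.id}_{c.start}_{c.end}",
                    rec.seq[c.start:c.end],
                    f"passing precursor window mfe={c.fold.mfe:.2f}"))
        for h in r["mir390_hits"]:
            feats.append(target_site_feature(h))
        for i, locus in enumerate(r["loci"]):
            feats.extend(locus_features(locus, i))
            bed_rows.append((rec.id, locus.start, locus.end,
                             f"TAS3_{i}_{locus.architecture.value}", 0,
                             locus.strand))
        for a in r["amplicons"]:
            bed_rows.append((rec.id, a.start, a.end,
                             f"amplicon_{a.length}nt", a.total_mismatches,
                             "+"))
    write_gff3(feats, out / "features.gff3")
    write_bed(bed_rows, out / "features.bed")
    write_fasta(passing_windows, out / "passing_precursors.fasta")
    if report["newick"]:
        (out / "loci_nj.nwk").write_text(report["newick"] + "\n")
    serial = {k: v for k, v in report.items() if k != "results"}
    (out / "report.json").write_text(json.dumps(serial, indent=2,
                                                sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Monte-Carlo recovery experiments


def locus_recovery_experiment(seed: int, n_loci: int = 60,
                              divergence: float = 0.0,
                              cfg: PipelineConfig | None = None,
                              genome_len: int | None = None) -> dict:
    """Plant `n_loci` TAS3 loci cycling through all six architecture
    classes (TAS6_TAS3 planted as genomic complexes), scan the genome, and
    score coordinate-exact recovery and class accuracy."""
    from .simulate import FeatureKind, FeatureSpec, plant_features

    cfg = cfg or default_config()
    defaults = {
        "guide390": cfg.guide_variants("miR390")[0],
        "guide156": cfg.guide_variants("miR156")[0],
        "guide529": cfg.guide_variants("miR529")[0],
        "tasi_refs": cfg.tasi_refs,
    }
    classes = [ArchitectureClass.ONE_TASIAP2_ONLY,
               ArchitectureClass.ONE_TASIAP2_ONE_TASIARF,
               ArchitectureClass.TAS6_TAS3,
               ArchitectureClass.ONE_TASIARF_ONLY,
               ArchitectureClass.TWO_TASIARF_TANDEM,
               ArchitectureClass.TWO_TASIARF_SPACER]
    specs = []
    for i in range(n_loci):
        arch = classes[i % len(classes)]
        strand = "+" if (i // len(classes)) % 2 == 0 else "-"
        if arch is ArchitectureClass.TAS6_TAS3:
            specs.append(FeatureSpec(FeatureKind.TAS6_TAS3_COMPLEX,
                                     strand=strand, divergence=divergence))
        else:
            specs.append(FeatureSpec(FeatureKind.TAS3_LOCUS,
                                     architecture=arch, strand=strand,
                                     divergence=divergence))
    # features are spaced beyond the locus span range so that cross-feature
    # site pairs can never form candidate loci (the paper's loci are sparse
    # single-copy regions, not tandem arrays)
    genome_len = genome_len or max(8000, n_loci * 2600)
    genome, truths = plant_features(genome_len, specs, seed=seed,
                                    margin=500, defaults=defaults)
    result = scan_record(genome, cfg)
    score = score_locus_recovery(truths, result)
    score["seed"] = seed
    score["divergence"] = divergence
    score["genome_len"] = genome_len
    return score


# ---------------------------------------------------------------------------
# planted-truth recovery scoring


def score_locus_recovery(truths, result: dict) -> dict:
    """Compare detected TAS3 loci against planted truth.

    A truth is *recovered* when a detected locus matches its exact
    coordinates and strand; *class-correct* when the architecture also
    matches. Returns counts plus per-truth outcomes.
    """
    from .simulate import FeatureKind
    loci = result["loci"]
    outcomes = []
    for t in truths:
        if t.kind not in (FeatureKind.TAS3_LOCUS,):
            continue
        if t.architecture is None:
            continue
        match = next((l for l in loci
                      if l.start == t.start and l.end == t.end
                      and l.strand == t.strand), None)
        outcomes.append({
            "feature_id": t.feature_id,
            "recovered": match is not None,
            "class_correct": (match is not None
                              and match.architecture == t.architecture),
            "truth_class": t.architecture.value,
            "detected_class": match.architecture.value if match else None,
        })
    n = len(outcomes)
    return {
        "n_truth": n,
        "n_recovered": sum(o["recovered"] for o in outcomes),
        "n_class_correct": sum(o["class_correct"] for o in outcomes),
        "recall": sum(o["recovered"] for o in outcomes) / n if n else 1.0,
        "class_accuracy": (sum(o["class_correct"] for o in outcomes) / n
                           if n else 1.0),
        "outcomes": outcomes,
    }


def score_precursor_recovery(truths, result: dict) -> dict:
    """A planted hairpin is recovered when a criteria-passing candidate
    reports the planted miR/miR* arms at their exact genome coordinates."""
    from .simulate import FeatureKind

    def genome_arm(c, rel):
        if c.strand == "+":
            return c.start + rel[0], c.start + rel[1]
        return c.end - rel[1], c.end - rel[0]

    passing = [c for c in result["precursors"] if c.passes]
    outcomes = []
    for t in truths:
        if t.kind is not FeatureKind.MIR390_HAIRPIN:
            continue
        mir = (t.elements["miR"]["start"], t.elements["miR"]["end"])
        star = (t.elements["miR_star"]["start"], t.elements["miR_star"]["end"])
        hit = any(
            {genome_arm(c, c.mir_arm), genome_arm(c, c.star_arm)}
            == {mir, star} and c.strand == t.strand
            for c in passing)
        outcomes.append({"feature_id": t.feature_id, "recovered": hit})
    n = len(outcomes)
    return {
        "n_truth": n,
        "n_recovered": sum(o["recovered"] for o in outcomes),
        "recall": sum(o["recovered"] for o in outcomes) / n if n else 1.0,
        "outcomes": outcomes,
    }
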