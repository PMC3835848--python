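"""Pipeline configuration: defaults, YAML loading and validation.

The effective configuration is the shipped defaults overlaid with the
user's YAML. Unknown keys are reported, never silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO

from .pcr import PrimerSet
from .precursor import StrictCriteriaParams
from .targets import PenaltyWeights


@dataclass
class PipelineConfig:
    inputs: list = field(default_factory=list)
    output_dir: str = "tas3scan_out"
    seed: int = 1
    guides: dict = field(default_factory=dict)  # name -> {mature, star}
    primer_sets: list = field(default_factory=list)  # of PrimerSet
    criteria: StrictCriteriaParams = field(default_factory=StrictCriteriaParams)
    weights: PenaltyWeights = field(default_factory=PenaltyWeights)
    max_penalty: float = 4.0
    max_mm_per_arm: int = 3
    duplex_span_range: tuple = (40, 400)
    flank: int = 20
    tas3_span_range: tuple = (150, 400)
    tas6_span_range: tuple = (100, 500)
    adjacency_gap: int = 10
    min_identity: float = 0.75
    tas6_max_gap: int = 1500
    max_breaking_subs: int = 3
    tasi_refs: list = field(default_factory=list)  # (name, kind, seq)
    ap2_target_ref: str | None = None

    def guide_variants(self, name: str) -> list:
        return self.guides[name]["mature"]

    def star_variants(self, name: str) -> list:
        return self.guides[name]["star"]


def _load_yaml_resource(name: str) -> dict:
    text = resources.files("tas3scan.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_tasi_refs(path: str | None = None) -> tuple[list, str | None]:
    """(name, kind, seq) triples plus the AP2 target reference, from a
    FASTA whose headers carry ``kind=ARF|AP2|AP2_TARGET``."""
    if path is None:
        src = resources.files("tas3scan.data").joinpath(
            "tasi_refs_synthetic.fasta")
        records = list(SeqIO.parse(src.open("r"), "fasta"))
    else:
        records = list(SeqIO.parse(path, "fasta"))
    refs, ap2_target = [], None
    for rec in records:
        kind = None
        for tok in rec.description.split():
            if tok.startswith("kind="):
                kind = tok.split("=", 1)[1]
        if kind == "AP2_TARGET":
            ap2_target = str(rec.seq)
        elif kind in ("ARF", "AP2"):
            refs.append((rec.id, kind, str(rec.seq)))
    return refs, ap2_target


def default_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.guides = _load_yaml_resource("guides.yaml")["guides"]
    cfg.primer_sets = [
        PrimerSet(p["name"], p["forward"], p["reverse"],
                  p.get("max_mm", 2), p.get("three_prime_exact", 3),
                  tuple(p.get("product_range", (80, 1500))))
        for p in _load_yaml_resource("primers.yaml")["primer_sets"]]
    cfg.tasi_refs, cfg.ap2_target_ref = load_tasi_refs()
    return cfg


_KNOWN_KEYS = {
    "inputs", "output_dir", "seed", "guides", "primer_sets", "criteria",
    "weights", "max_penalty", "max_mm_per_arm", "duplex_span_range", "flank",
    "tas3_span_range", "tas6_span_range", "adjacency_gap", "min_identity",
    "tas6_max_gap", "max_breaking_subs", "tasi_refs_fasta",
}
_CRITERIA_KEYS = {"min_precursor_len", "min_stem_bp", "max_mfe",
                  "forbid_multibranch"}
_WEIGHT_KEYS = {"mismatch", "gu", "bulge", "core_range", "core_factor",
                "cleavable_positions"}


def validate_config(path: str) -> tuple[PipelineConfig | None, list]:
    """Load + schema-check a YAML config; returns (config, errors).

    The config is None whenever errors is non-empty. Missing keys fall back
    to the shipped defaults; unknown keys are listed as errors.
    """
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]

    for k in sorted(set(raw) - _KNOWN_KEYS):
        errors.append(f"unknown key: {k}")
    crit_raw = raw.get("criteria", {})
    for k in sorted(set(crit_raw) - _CRITERIA_KEYS):
        errors.append(f"unknown key: criteria.{k}")
    w_raw = raw.get("weights", {})
    for k in sorted(set(w_raw) - _WEIGHT_KEYS):
        errors.append(f"unknown key: weights.{k}")

    cfg = default_config()
    if "max_mfe" in crit_raw and crit_raw["max_mfe"] >= 0:
        errors.append("criteria.max_mfe must be negative")
    if not 0 < raw.get("min_identity", cfg.min_identity) <= 1:
        errors.append("min_identity must lie in (0, 1]")
    if raw.get("max_penalty", cfg.max_penalty) < 0:
        errors.append("max_penalty must be non-negative")
    for p in raw.get("inputs", []):
        if not Path(p).exists():
            errors.append(f"input not found: {p}")
    if "tasi_refs_fasta" in raw and not Path(raw["tasi_refs_fasta"]).exists():
        errors.append(f"tasi reference FASTA not found: {raw['tasi_refs_fasta']}")
    if errors:
        return None, errors

    cfg.inputs = list(raw.get("inputs", []))
    cfg.output_dir = raw.get("output_dir", cfg.output_dir)
    cfg.seed = int(raw.get("seed", cfg.seed))
    if "guides" in raw:
        cfg.guides = raw["guides"]
    if "primer_sets" in raw:
        cfg.primer_sets = [
            PrimerSet(p["name"], p["forward"], p["reverse"],
                      p.get("max_mm", 2), p.get("three_prime_exact", 3),
                      tuple(p.get("product_range", (80, 1500))))
            for p in raw["primer_sets"]]
    if crit_raw:
        base = asdict(cfg.criteria)
        base.update(crit_raw)
        cfg.criteria = StrictCriteriaParams(**base)
    if w_raw:
        w = dict(w_raw)
        if "core_range" in w:
            w["core_range"] = tuple(w["core_range"])
        if "cleavable_positions" in w:
            w["cleavable_positions"] = tuple(w["cleavable_positions"])
        cfg.weights = PenaltyWeights(**w)
    for key in ("max_penalty", "max_mm_per_arm", "flank", "adjacency_gap",
                "min_identity", "tas6_max_gap", "max_breaking_subs"):
        if key in raw:
            setattr(cfg, key, raw[key])
    for key in ("duplex_span_range", "tas3_span_range", "tas6_span_range"):
        if key in raw:
            setattr(cfg, key, tuple(raw[key]))
    if "tasi_refs_fasta" in raw:
        cfg.tasi_refs, cfg.ap2_target_ref = load_tasi_refs(
            raw["tasi_refs_fasta"])
    return cfg, []
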