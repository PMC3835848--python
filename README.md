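# tas3scan

Discovery of **miR390 precursor hairpins** and **miR390-guided TAS3/TAS6
trans-acting siRNA loci** in plant genomic or transcript sequence.

In land plants, the deeply conserved microRNA miR390 triggers production of
trans-acting siRNAs from *TAS3* loci: a non-coding transcript carries two
miR390 target sites (a 5′ site and a cleaved 3′ site) flanking 21-nt
tasiARF and/or tasiAP2 source elements that are processed in a 21-nt phased
register from the 3′-site cleavage point. The internal organization of these
loci varies across lineages — from liverwort loci carrying a single tasiAP2
element, through moss loci with one tasiAP2 and one tasiARF (sometimes in a
genomic cluster with an upstream miR156/miR529-dependent *TAS6* locus), to
fern and seed-plant loci with one or two tasiARFs, tandem or
spacer-separated. `tas3scan` turns that body of locus anatomy into a
testable scanning pipeline for comparative genomics of the miR390/TAS3
pathway:

* **Hairpin folding** (`tas3scan.fold`): minimum-free-energy folding
  restricted to single stem-loops (no multibranch loops) under a
  nearest-neighbor energy model, with an exhaustive-enumeration reference
  folder for validation.
* **Precursor detection** (`tas3scan.precursor`): imperfect inverted-repeat
  search seeded from a miR390/miR390\* variant set, followed by four strict
  structural criteria — window ≥ 60 nt, ≥ 22 stem base pairs (G:U wobble
  included), MFE ≤ −35 kcal/mol, no multibranch loop — plus duplex 2-nt
  3′-overhang geometry and lower-stem accounting.
* **In-silico PCR** (`tas3scan.pcr`): IUPAC degenerate primer matching with
  3′-end fidelity and combinatorial amplicon prediction.
* **Target-site scanning** (`tas3scan.targets`): plant-style
  position-weighted complementarity scoring (mismatch 1, G:U 0.5, bulge 2,
  doubled at guide positions 2–13), cleavability from Watson-Crick pairing
  at guide position 10, and the cleavage coordinate between the bases
  opposite guide positions 10/11.
* **Locus assembly** (`tas3scan.taslocus`): dual-site pairing, tasiARF /
  tasiAP2 element detection on both strands, 21-nt phase registers,
  architecture classification, tasiAP2 functionality calls and TAS6–TAS3
  genomic cluster detection.
* **Locus comparison** (`tas3scan.compare`): affine-gap pairwise distances,
  canonical neighbor joining, and reference-group cluster assignment on
  outgroup-rooted trees.
* **Synthetic genomes** (`tas3scan.simulate`): planted hairpins and loci of
  every architecture class with machine-readable ground truth, so each
  detector is scored against known coordinates without downloads.

## Worked example

Simulate a genome with planted features, then scan it:

```bash
tas3scan simulate --seed 3 --genome-len 8000 --n-precursors 1 --n-loci 1 \
    --out sim
tas3scan scan sim/genome.fasta --out scan_out
```

The scan prints its per-stage counts:

```json
{
  "architectures": {
    "ONE_TASIAP2_ONLY": 1
  },
  "counts": {
    "amplicons": 0,
    "arm_pair_candidates": 2,
    "mir390_target_sites": 8,
    "passing_precursors": 2,
    "sequences": 1,
    "tas3_loci": 1,
    "tas6_loci": 0,
    "tas6_tas3_complexes": 0
  }
}
```

One planted hairpin yields two arm-pair candidates (an inverted repeat is
detected on both strands of the same window; both fold and pass the strict
criteria). Eight miR390 target-site hits come from the locus borders and
the hairpin arms (a precursor's miR\* arm is itself near-complementary to
the guide), each found by both configured guide variants. The planted TAS3
locus is assembled from its two border sites paired within the span
window, classified from its internal elements (here a single tasiAP2 —
the liverwort-type organization), and written to `scan_out/features.gff3`
together with BED intervals, passing precursor windows in FASTA and a JSON
report. With ≥ 3 loci the scan also writes an NJ tree (`loci_nj.nwk`).

The same stages are importable as a library (`find_target_sites`,
`scan_tas_loci`, `fold_best_hairpin`, …) returning plain dataclasses.

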