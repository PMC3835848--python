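# Methods

## Scope and model of a TAS3-like locus

`tas3scan` operationalizes the comparative anatomy of miR390-dependent
trans-acting siRNA loci. A locus is modelled as two miR390 target sites on
one strand bounding an internal region that carries 21-nt tasiARF and/or
tasiAP2 source elements; locus length is always reported as the inclusive
span counting both border sites. TAS6 loci are modelled the same way with
miR529 (5′) and miR156 (3′) sites; a TAS6–TAS3 genomic cluster is a
same-strand TAS6 upstream of a TAS3 within a configurable gap, each TAS6
joined only to its nearest downstream TAS3 (the pair transcribed as one
precursor). Classification of internal organization:

| class | rule |
|---|---|
| ONE_TASIAP2_ONLY | ≥1 AP2, 0 ARF |
| ONE_TASIAP2_ONE_TASIARF | ≥1 AP2, ≥1 ARF |
| ONE_TASIARF_ONLY | 1 ARF, 0 AP2 |
| TWO_TASIARF_TANDEM | 2 ARF, gap < `adjacency_gap` (10 nt) |
| TWO_TASIARF_SPACER | 2 ARF, gap ≥ `adjacency_gap` |
| TAS6_TAS3 | any of the above upgraded by complex membership |
| UNCLASSIFIED | anything else |

The tandem/spacer cut needs a numeric threshold the source material leaves
qualitative; 10 nt separates "adjacent phased segments" from a genuine
spacer (the generator's spacer is 42 nt, two phase cycles) and is exposed
in the config.

## Hairpin folding

`fold_best_hairpin` minimizes free energy over all non-crossing structures
containing **no multibranch loop** — chains of nested pairs separated by
stacks, bulges or internal loops, ending in one hairpin loop. The energy
model is a small Turner-style nearest-neighbor parameterisation (37 °C,
kcal/mol) shipped as `data/energy_params.json`: stacking energies over
adjacent pairs (G:U wobble included), loop-initiation tables extrapolated
as ΔG(n) = ΔG(n_max) + 1.079·ln(n/n_max), a 0.5 kcal/mol terminal AU/GU
penalty on the outermost pair, and single-nucleotide bulges retaining the
flanking stack. There are no dangling ends, coaxial stacks or
sequence-specific loop bonuses; the unfolded state is 0, so reported MFE is
never positive. Energies are reported at 2 decimals and criteria compare
the reported value.

The DP is O(n²·c²) with interior loops capped at c = 30 unpaired
nucleotides (the cap standard folders use), vectorized across window
positions. Ties are resolved deterministically: interior candidates are
preferred over terminating the hairpin (more base pairs), stacking and
smaller loops first, and the outermost pair at the smallest start
coordinate. `exhaustive_hairpin_mfe` enumerates the same structure space
top-down and is the validation reference for windows ≤ ~30 nt.

Two symmetry caveats are deliberate properties of the model, not bugs:
reverse-complement mirror symmetry of the MFE holds exactly only for
Watson-Crick-restricted folding (a G:U pair maps to unpairable A:C under
reverse complement), which is how the property is tested
(`load_default_model(allow_gu=False)`); and the "stem ≥ 22 bp" criterion
counts *total* pairs in the structure, not the longest contiguous helix —
the whole-stem reading of pair counting with wobble included.

## Strict precursor criteria

Candidate windows come from an imperfect inverted-repeat search: a guide
match and a star match on the same strand, each within
`max_mm_per_arm` (default 3) mismatches of *any* configured variant, with
inclusive span in 40–400 nt (mosses place the miR390/miR390\* arms roughly
100 nt apart; the assay products run ~80–270 bp). Windows are the arm span
± 20 nt flank, truncated at sequence ends (recorded). Criteria are
inclusive comparisons — length ≥ 60 nt, stem ≥ 22 bp, MFE ≤ −35.0 — plus
the multibranch prohibition; candidates overlapping ≥ 50% merge to the
lowest-MFE representative per strand. A physical hairpin is usually
detected on both strands (the reverse complement of an inverted repeat is
an inverted repeat); both are reported, each on its own strand.

Duplex geometry is read off the fold: 3′ overhangs at each duplex end
(canonical = 2 nt at both, the DCL excision signature) and the lower-stem
extension, the count of pairs below both arms.

## Target-site scoring

The de facto plant complementarity scheme: WC 0, G:U 0.5, mismatch 1,
bulged base 2, all doubled at guide positions 2–13; default acceptance
threshold 4.0. Alignment is global and banded (±3 nt) against the site's
antiparallel reading; a bulged site base between guide positions p and p+1
is charged at the weight of position max(1, p). Scanning uses a multi-start
formulation of the same DP vectorized over template positions (exact, not
heuristic — the test suite compares it window-by-window with a scalar
brute force). Overlapping hits are deduplicated to local penalty minima,
ties to the leftmost.

Cleavability requires WC pairing at guide position 10 (configurable to
9–11); the cleavage coordinate is the template boundary between the bases
opposite guide positions 10 and 11, flagged approximate when a bulge
disrupts that neighbourhood. Phase registers are signed distances from the
3′-site cleavage coordinate toward the 5′ site, modulo the 21-nt DCL4
cycle.

## tasi element detection and AP2 functionality

Reference tasiARF/tasiAP2 21-mers are matched on both strands of the
inter-site region, ungapped or with one indel; identity is matches over
alignment columns, threshold 0.75 (16/21 for a 21-mer). Overlapping
same-kind hits keep the best identity. A tasiAP2 element is called
functional against the configured AP2 target reference when at most
`max_breaking_subs` (default 3) positions can form neither a Watson-Crick
nor a G:U pair — wobbles are tolerated, so only pairing-breaking
substitutions count.

## Locus comparison

Distances are 1 − identity from global affine-gap alignment (match +1,
mismatch −1, gap open −4 on the first gap residue, extend −1; Biopython's
`PairwiseAligner` behind the module surface). Trees are canonical
neighbor joining (Studier–Keppler update) with deterministic tie-breaks
and negative branch estimates clamped to 0 — a stated substitution for the
original server-side minimal-evolution tree, which is why only
topology-level properties (additive-matrix recovery, family monophyly,
cluster membership) are asserted, never branch lengths of real data.
Cluster assignment roots on a designated outgroup and labels a query with
group A when the smallest clade containing the A references plus the query
excludes every B reference.

## Synthetic data: what it emulates and what it does not

The generator plants, on either strand of an i.i.d. background of
configurable GC: MIR390 stem-loops (guide + star arms, 2-nt 3′ overhangs
or blunt, a lower stem of exact pair count, G/C lower-stem composition so
short extensions are thermodynamically committed), TAS3 loci of every
architecture (perfect target sites, elements planted on the processing
grid of the 3′-site cleavage register, tasiARFs on the minus strand as in
mosses), TAS6–TAS3 complexes, and decoys. Generators verify their own
postconditions by running the relevant detector on the fresh construct and
resampling filler on failure, so zero-divergence truth is clean by
construction; a 1-bp lower stem under canonical overhangs is rejected as
unrealizable (see folding). Divergence is i.i.d. per-site substitution
only, keeping truth coordinates exact; indels are out of scope.

What passing recovery tests therefore show: the detectors invert the
generative model exactly at zero noise and degrade gracefully under
substitution noise. What they do not show: robustness to indel divergence,
repetitive genomes, transcript fragmentation, or divergence of real tasi
element families beyond the shipped references — the default
guide/star/tasi sequences beyond the canonical conserved miR390/miR156
21-/20-mers are synthetic stand-ins (flagged in the data files), and real
screens should configure curated sets.

## Problem sizes and numerical choices

The shipped validation runs at desk scale: 200 random windows ≤ 30 nt for
the folding oracle; 50 (tests) / 10 (acceptance script) random 5-kb
templates for the PCR oracle; 20 / 4 random 10-kb sequences for the
target-scan oracle; 60 planted loci cycling all six classes at divergence
0 and 10 seeds × 50 loci at 5%; 100 replicates of the two-family
clustering simulation. Recovery genomes space features ≥ 500 nt apart —
cross-feature site pairs would otherwise form shorter equal-penalty
chimeric candidates, and real TAS3 loci are sparse single-copy regions,
not tandem arrays. The 5%-divergence assertions are regression floors set
below the observed seed-to-seed range (recall ≥ 0.85, class accuracy
≥ 0.78 per seed), not claims about the attainable maximum.

## Known limitations

* The energy parameterisation is Turner-style but minimal; absolute MFEs
  of real precursors will deviate from full-featured folders by a few
  kcal/mol (the −35 criterion is threshold-like, so calls are less
  sensitive than energies).
* Dual-site pairing assumes non-overlapping loci; nested or overlapping
  TAS arrays resolve to one representative by (penalty, span) and the
  alternatives are dropped.
* PCR prediction is combinatorial only — no melting temperature, dimers,
  or nonspecific amplification.
* Cluster assignment depends on a correct outgroup choice; there is no
  automatic outgroup inference.
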