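# Methods

This note documents the models and numerical choices behind `satcen`: what
each stage computes, which parameters matter, what the synthetic data do
and do not emulate, and where the design was genuinely open.

## Read mapping to a consensus panel

Reads are placed semi-globally (read fully contained in the target) on
every panel target, both strands.  Identity is substitution-only:
matching positions / read length, with `N` never matching.  A hit is
reported when the best identity reaches `min_identity` (default 0.80,
i.e. 20 % mismatches tolerated — the conventional stringency for mapping
short reads to diverged satellite monomers).

*Dimer trick.*  A tandem monomer is mapped as its head-to-tail dimer.  Any
window of an infinite tandem array is a window of the dimer, so error-free
array reads always attain identity 1.0 — there is no junction blind spot.
Hits landing entirely in the second monomer copy are exact duplicates of a
first-copy placement and are canonicalised to `offset mod monomer_length`.

*Exactness and speed.*  The scorer evaluates **every** offset: match
counts for all placements come from one matrix product between
one-hot-encoded reads and a matrix with one one-hot column per (target,
strand, offset).  Columns are ordered (panel order, `+` before `-`,
offset ascending), so a first-occurrence argmax realises the tie-breaking
rules exactly: equal best identity across entries → earliest panel entry
wins and the hit is flagged ambiguous (the summary exposes the ambiguous
count so users can exclude such reads); within an entry → forward strand,
then smallest offset.  Match counts are far below 2²⁴ and therefore exact
in float32.  The test suite checks the scorer against an independently
written exhaustive sliding-window aligner, including tie-breaks and flags.

An optional edit-distance mode (`allow_indels=True`, via edlib, infix
alignment) scores `1 − edit_distance/read_length`.  It is slower, and its
offset on indel-containing alignments follows edlib's first reported
location; substitution-only is the default because it admits an exact,
fast oracle.

## Enrichment

`norm = raw / (total_reads × ref_length) × 10⁹`.  The 10⁹ constant is
cosmetic (per-billion, RPKM-like): enrichment ratios are scale-free, which
the suite verifies exactly under per-sample rescaling.  `ref_length` of a
tandem family is the monomer length — the dimer is a mapping artifice.
Zero input counts yield a flagged *undefined* ratio, never a sentinel
number.  A delta-method standard error,
`SE/ratio = sqrt((1−p_ip)/x_ip + (1−p_in)/x_in)`, supports the
3-SE recovery checks.

RNA counting deliberately avoids normalisation: all mapping targets share
one window length (default 442 bp — conveniently exactly a dimer of a
221 bp monomer), so raw best-hit counts are directly comparable between
the satellite and gene transcripts.

## Consensus and logo

Aligned read bases fold onto monomer coordinates
(`(monomer_offset + i) mod monomer_length`, minus-strand reads
reverse-complemented first).  Information content is the unadjusted
`2 − H` bits (deep coverage makes small-sample correction irrelevant
here); consensus is per-position argmax with alphabetical tie-breaking
(flagged) and `N` at zero coverage.  GC content excludes `N` from both
numerator and denominator.  The logo drawing is a report artefact; the
matrix is the tested object.

## Tandem structure

The period estimator maximises the self-match fraction between `s[i]` and
`s[i+p]` over lags (autocorrelation of the one-hot encoding), requiring a
fraction above 0.7 — comfortably above the 0.25 expected for i.i.d.
bases — and returning the smallest lag within 0.02 of the best, so the
fundamental period beats its multiples.  These three numbers (lag range,
0.7, 0.02) are this package's operationalisation of a qualitative
observation; they are exposed as arguments.

Head-to-tail verification finds greedy non-overlapping monomer placements
on both strands (identity ≥ 0.8) and requires co-orientation with
gaps/overlaps ≤ 5 bp.  Region classification tiles a region into windows
of the panel's shortest tandem monomer length, assigns each window its
best-identity family with the same scoring as read mapping, and labels
the region by majority (ties flagged *mixed*, resolved toward higher mean
identity; unclassified below the identity floor).  Majority-by-length
with the 0.80 floor is this package's criterion for a region "consisting
of" a family; the choice is deliberate and configurable.

## Peak filtering and the domain caller

The stringent selection applies **strict** inequalities exactly as
stated — fold enrichment > 5, pile-up > 100, −log10 p > 100,
−log10 q > 100 — so boundary values fail; the suite checks brute-force
equality, monotonicity under relaxation and idempotence.  The importer
reads MACS-style TSV with case-insensitive alias matching and an optional
column map.

The window caller is labelled plumbing: depth-normalised IP/input window
ratios (0.5 pseudocount), centred 3-window smoothing, runs ≥ `min_ratio`
merged into domains; −log10 p from a one-sided binomial tail on the
domain's read counts against the genome-wide IP share, q by
Benjamini–Hochberg computed on the −log10 scale (exact far below float
underflow).  It exists so the synthetic pipeline runs end-to-end; users
with real peak-caller output bypass it via the importer.  Note that
pile-up scales with sequencing depth: at the default desk-scale depth
(200k reads) true domains reach pile-up ≈ 45, so the stringent filter
only passes domains in deeper designs — a faithful consequence of scale,
not a defect.

## Fibre profiles and slot blots

Per channel, signal-positive intervals are maximal runs strictly above
the channel median + k·MAD (k = 3): robust because background occupies
the majority of a scanned fibre.  Runs are merged across gaps ≤ 2
samples, and blocks are kept only if ≥ 3 samples long *and* their mean
intensity itself clears the threshold (guards against stitching isolated
noise spikes into pseudo-blocks).  The longest red run is the satellite
stretch; green blocks are clipped to it; coverage fraction =
green-covered length / stretch length.  Pattern classification — III if
coverage ≤ 0.05, I if ≥ 0.90, II otherwise — is this package's numeric
operationalisation of the three qualitative binding patterns; the cutoffs
are configurable and echoed in reports.  Classification is invariant to
rescaling both channels (threshold is background-relative).

Slot-blot ratios are background-subtracted IP/input IDV quotients;
background defaults to 0.  The ratio is scale-invariant only at zero
background — both behaviours are asserted in the suite.

## Synthetic data: what it emulates

The generator builds one chromosome from shuffled segments: head-to-tail
tandem arrays (monomer copies with per-copy substitution divergence,
default 2 %), scattered interspersed-element copies, 442 bp genes, and
i.i.d. background; annotations tile the genome exactly and every read id
encodes its true source.

*IP model.*  Two-state chromatin: sampling weight 1 for unbound and
`1 + α·occupancy` for CENP-A-bound regions; input weight 1 everywhere.
The expected length-normalised ratio has the closed form
`R_f = (1 + α·occ_f) / (1 + α·q)` with `q` the genome's length-weighted
mean occupancy, so `α` is solvable for any attainable target ratio
(`alpha_for_ratio`).  Two study designs are provided and used throughout:

* **default design** — the centromeric family is ~0.26 % of a 2.9 Mb
  genome (a centromeric satellite is a small genome fraction), occupancy
  1 on it alone, α = 5.593 giving expected centromeric ratio 6.5 while
  unbound families stay at `1/(1+αq) ≈ 0.99` — this is what makes an
  interspersed control element "equally represented" in both fractions;
* **`ratio_grid` design** — the focal family is ~2.5 % of a 300 kb
  genome, giving ~5,000 input reads on it at 200k reads/sample and hence
  ~2 % relative SE on the estimated ratio; used for ratio-recovery
  experiments across true ratios {1, 2, 6.5, 10}.

Reads are single-end, fixed length (default 100 bp — read length and
fragment size are free choices here), uniform-start within the weighted
regions, with i.i.d. substitution errors (default 1 %) and constant
quality strings.  Not emulated: indels, quality models, PCR duplicates,
fragment-size distributions, GC bias, paired ends.  Passing tests
therefore demonstrate correctness of the estimators under this sampling
model, not robustness to every artefact of real libraries.

Monomers without explicit sequences are synthetic stand-ins generated
with *exactly* `round(gc·length)` G/C bases — the default centromeric
monomer is 221 bp with 117 G+C, i.e. 52.94 % ≈ 53 % GC by construction.
A real monomer sequence can be supplied verbatim via
`MonomerSpec(sequence=...)`.

Fibre traces place a red stretch covering 25–45 % of the scan (fibres
extend beyond the satellite array, and a sub-majority signal keeps the
median-based background estimate valid), with green coverage ≥ 96 %
(pattern I), 2–4 blocks totalling 25–60 % (pattern II) or absent
(pattern III), amplitude ~100 over background ~4, Gaussian noise σ = 3.
The slot-blot generator applies a saturating film response
`IDV_IP ∝ R^γ` with γ = 0.45 and 3 % multiplicative noise, so a 6.5-fold
sequence enrichment appears as a ≈ 2.3-fold densitometric ratio, in the
1.8–2.5 range typical of saturating blot signals.

*Determinism.*  All randomness flows from one integer seed through
per-channel `SeedSequence` spawns; identical config + seed reproduces
FASTQ bytes, annotations, fibres and slot values exactly.

## Problem sizes

The acceptance computations use 200k reads per sample for enrichment
(four grid designs plus the default design), 1,000 reads × 5 entries for
mapper-oracle parity, ~90× monomer coverage for consensus recovery,
1,705 regions for classification, 1,000 random records for the peak
filter, and 25 fibres (15/7/3); unit tests use smaller seeded designs of
the same shape.

## Known limitations

* Substitution-only identity underestimates similarity for
  indel-diverged monomers; the edlib mode mitigates but with looser
  tie-break guarantees.
* The domain caller is not a production peak caller (no local background
  model, no duplicate handling).
* Fibre analysis is strictly 1-D; spot detection in micrographs is out of
  scope.
* The equal-length RNA windows compare transcript abundance per window,
  not transcription per genomic copy.
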