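# satcen

Tools for asking a classic question in centromere biology: **of the several
satellite DNA families packed into a genome's (peri)centromeres, which one
actually carries centromeric function** — i.e. binds CENP-A, the
centromere-specific histone H3 variant?

The package implements the computational side of a CENP-A ChIP-seq study of
a satellite-rich genome as a tested, reusable pipeline:

* **mismatch-tolerant read mapping** against a panel of repeat consensus
  sequences (default: ≥ 80 % identity, substitution-only scoring, both
  strands).  Tandem monomers are mapped as head-to-tail **dimers**, so reads
  straddling the monomer junction are never lost;
* **depth- and length-normalised enrichment**: for family *f* with raw
  count *c*, sample total *N* and reference (monomer) length *L*,

  `norm(f) = c / (N · L) × 10⁹`,  `ratio(f) = norm_IP(f) / norm_input(f)`,

  so ratio = 1 means "equally represented in immunoprecipitated and input
  chromatin" and the CENP-A-bound family stands out as a several-fold ratio;
* **consensus / logo derivation** from mapped reads (per-position base
  frequencies, information content `2 − H` bits, majority consensus, GC
  content);
* **tandem-structure analysis**: fundamental repeat-unit length from the
  lagged self-match profile, head-to-tail verification, and
  majority-family classification of enriched regions;
* **stringent peak filtering** (strictly: fold enrichment > 5, pile-up
  > 100, −log10 p > 100, −log10 q > 100) plus a minimal window/binomial
  domain caller so the synthetic pipeline runs end-to-end;
* **satellite transcription counting** on equal-length transcript windows
  (no normalisation needed when all windows share one length);
* **chromatin-fibre immuno-FISH quantification**: robust segmentation of
  two-channel line profiles and classification of CENP-A binding patterns
  (I — CENP-A covers the whole satellite stretch; II — CENP-A in blocks;
  III — no CENP-A), and slot-blot densitometric IDV ratios.

Because data of this kind are rarely deposited at read level, the package
ships a first-class **synthetic-data generator** (`satcen.simulate`): a
seeded toy genome with head-to-tail satellite arrays, an interspersed
control element, genes, differential CENP-A occupancy, IP/input/RNA read
sampling with substitution errors, fibre profiles and slot blots — all with
exact ground truth, so every stage is testable offline.

## Worked example

```bash
satcen run --out demo/ --seed 1
```

or equivalently from Python:

```python
from satcen.simulate import SimConfig
from satcen.pipeline import run_pipeline

cfg = SimConfig(seed=1, n_reads_ip=50_000, n_reads_input=50_000,
                n_reads_rna=5_000, fibre_counts=(15, 7, 3))
run_pipeline(cfg, "demo/")
```

`demo/summary.json` then contains (values from this exact run):

```
"estimated_ratios": { "cen_sat": 6.076, "ere_like": 1.021,
                      "peri_satA": 0.792, "peri_satB": 1.085 }
"expected_ratios":  { "cen_sat": 6.499, "ere_like": 0.986, ... }
"consensus_gc_percent": 52.94
"consensus_matches_monomer": true
"fibre_percentages": { "I": 60, "II": 28, "III": 12 }
"slot_ratios": { "cen_sat": 2.311, "ere_like": 1.048, ... }
```

Reading: the centromeric satellite (`cen_sat`, a 221 bp GC-rich monomer) is
~6-fold enriched in the IP fraction (closed-form expectation 6.5 for this
design; the estimate tightens with read depth), the interspersed control
element sits at ratio ≈ 1, the consensus rebuilt from noisy mapped reads
matches the true monomer exactly (GC 53 %), 60 %/28 %/12 % of the simulated
fibres show binding patterns I/II/III, and the saturating slot-blot model
compresses the 6.5-fold sequence enrichment to a ~2.3 densitometric ratio.
`demo/` also holds every intermediate table (hits, enrichment, matrix,
classifications, peak tables, fibre traces), figures (enrichment bars,
sequence logo, RNA counts, fibre line charts) and a `manifest.json` with
per-output SHA-256 checksums — rerunning with the same seed reproduces all
non-image outputs byte-identically.

Individual stages are available as subcommands
(`satcen simulate|map|enrich|consensus|classify|filter-peaks|fibres|run`)
and as plain library functions.

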