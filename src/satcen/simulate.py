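"""Seeded synthetic data: toy genome, IP/input/RNA reads, fibres, slot blots.

The generator emulates the experimental design of a centromeric ChIP-seq
study on a satellite-rich genome: a small genome carrying head-to-tail
tandem arrays of several satellite monomer families plus an interspersed
retroelement and random background; differential CENP-A occupancy across
families; immunoprecipitated (IP) versus input read sampling with
substitution errors; satellite and gene transcripts; and two-channel
chromatin-fibre intensity traces in three binding patterns.  Every output
is deterministic in the configuration seed and every read identifier
encodes its true source region, so downstream estimates can be checked
against exact ground truth.

IP sampling model (two-state chromatin): a fragment starting in region
``r`` is drawn with weight ``1`` in the input channel and
``1 + alpha * occupancy_r`` in the IP channel.  The expected
length-normalised IP/input count ratio of family ``f`` is then the closed
form

    R_f = (1 + alpha * occ_f) / wbar,
    wbar = sum_r len_r * (1 + alpha * occ_r) / sum_r len_r,

so ``alpha`` can be solved for any attainable target ratio
(:func:`alpha_for_ratio`).  In a realistic design the centromeric family is
a tiny fraction of the genome, ``wbar`` is close to 1, and unbound
families keep ratios near 1 — mirroring an interspersed control element
being equally represented in the two fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from satcen import _seq
from satcen.fibres import FibreProfile
from satcen.panel import PanelEntry, ReferencePanel

_CHANNELS = {"genome": 0, "ip": 1, "input": 2, "rna": 3, "fibres": 4, "slot": 5, "monomers": 6}


# --------------------------------------------------------------------- config


@dataclass
class MonomerSpec:
    """A repeat family to simulate.

    ``sequence`` may be given explicitly; otherwise a synthetic monomer of
    the requested length is generated with *exactly*
    ``round(gc * length)`` G/C bases, so the GC content is a design
    parameter, not a random outcome.
    """

    name: str
    length: int = 221
    gc: float = 0.5
    sequence: str | None = None
    is_tandem: bool = True
    expression: float = 0.0  # per-base transcription weight (RNA channel)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.strip().upper()
            self.length = len(self.sequence)
        if self.length <= 0:
            raise ValueError(f"monomer {self.name!r}: length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"monomer {self.name!r}: gc must be in [0, 1]")


@dataclass
class GeneSpec:
    name: str
    length: int = 442
    expression: float = 1.0


def _default_monomers() -> list[MonomerSpec]:
    return [
        # centromeric satellite: 221 bp GC-rich monomer, transcribed
        MonomerSpec("cen_sat", length=221, gc=0.53, expression=0.1),
        # two pericentromeric satellites, CENP-A negative
        MonomerSpec("peri_satA", length=145, gc=0.45),
        MonomerSpec("peri_satB", length=137, gc=0.40),
        # interspersed retroelement control, CENP-A negative
        MonomerSpec("ere_like", length=700, gc=0.42, is_tandem=False),
    ]


def _default_genes() -> list[GeneSpec]:
    return [GeneSpec(f"gene{c}", 442, 1.0) for c in "ABCD"]


@dataclass
class SimConfig:
    """Full study design for one synthetic experiment.

    The defaults describe a genome-realistic design: the centromeric
    family occupies ~0.26 % of the genome (as a centromeric satellite is a
    small fraction of a real genome), occupancy 1 on the centromeric
    family only, and ``ip_enrichment_alpha`` chosen so the expected
    centromeric enrichment ratio is 6.5 while unbound families stay near
    ratio 1.
    """

    seed: int = 0
    monomers: list[MonomerSpec] = field(default_factory=_default_monomers)
    # per tandem family: copies per array (one int per array)
    array_copies: dict[str, list[int]] = field(
        default_factory=lambda: {
            "cen_sat": [12, 12, 10],
            "peri_satA": [25, 25],
            "peri_satB": [25, 25],
        }
    )
    interspersed_copies: dict[str, int] = field(default_factory=lambda: {"ere_like": 400})
    occupancy: dict[str, float] = field(default_factory=lambda: {"cen_sat": 1.0})
    ip_enrichment_alpha: float = 5.593  # expected cen_sat ratio 6.5 on the default genome
    read_length: int = 100
    substitution_error_rate: float = 0.01
    per_copy_mutation_rate: float = 0.02
    n_reads_ip: int = 200_000
    n_reads_input: int = 200_000
    n_reads_rna: int = 20_000
    genes: list[GeneSpec] = field(default_factory=_default_genes)
    background_length: int = 2_600_000
    min_background_gap: int = 200
    # fibre simulation
    fibre_counts: tuple[int, int, int] = (15, 7, 3)
    fibre_points: tuple[int, int] = (150, 400)
    fibre_red_fraction: tuple[float, float] = (0.25, 0.45)
    fibre_full_coverage: float = 0.95
    fibre_signal: float = 100.0
    fibre_background: float = 4.0
    fibre_noise_sd: float = 3.0
    # slot-blot densitometry: film response is sublinear, IDV ~ abundance^gamma
    slot_gamma: float = 0.45
    slot_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if not self.monomers:
            raise ValueError("empty panel")
        for frac in (self.substitution_error_rate, self.per_copy_mutation_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for fam, occ in self.occupancy.items():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy[{fam!r}] must be in [0, 1]")
        if self.ip_enrichment_alpha < 0:
            raise ValueError("ip_enrichment_alpha must be >= 0")
        for n in (self.n_reads_ip, self.n_reads_input, self.n_reads_rna):
            if n < 0:
                raise ValueError("read counts must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if any(c < 0 for c in self.fibre_counts):
            raise ValueError("fibre_counts must be >= 0")
        known = {m.name: m for m in self.monomers}
        for fam in list(self.array_copies) + list(self.interspersed_copies):
            if fam not in known:
                raise ValueError(f"unknown family {fam!r}")
        region_lens = [g.length for g in self.genes] + [self.min_background_gap]
        for fam, copies in self.array_copies.items():
            region_lens += [known[fam].length * c for c in copies]
        for fam in self.interspersed_copies:
            region_lens.append(known[fam].length)
        if region_lens and self.read_length > min(region_lens):
            raise ValueError("read_length must not exceed the shortest simulated fragment")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fibre_counts"] = list(self.fibre_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "monomers" in d:
            d["monomers"] = [MonomerSpec(**m) if isinstance(m, dict) else m for m in d["monomers"]]
        if "genes" in d:
            d["genes"] = [GeneSpec(**g) if isinstance(g, dict) else g for g in d["genes"]]
        for key in ("fibre_counts", "fibre_points", "fibre_red_fraction"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def rng(self, channel: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_CHANNELS[channel],))
        )

    @classmethod
    def ratio_grid(cls, true_ratio: float, seed: int = 0, **overrides) -> "SimConfig":
        """A focal design for ratio-recovery experiments.

        The centromeric family is set to ~2.5 % of a 300 kb genome so its
        input read count at 200k reads/sample is ~5,000, giving ~2 %
        relative standard error on the estimated ratio; ``alpha`` is
        solved so the expected centromeric ratio equals ``true_ratio``.
        """
        cfg = cls(
            seed=seed,
            interspersed_copies={"ere_like": 12},
            background_length=268_000,
            ip_enrichment_alpha=0.0,
            **overrides,
        )
        cfg.ip_enrichment_alpha = alpha_for_ratio(cfg, "cen_sat", true_ratio)
        return cfg


# ---------------------------------------------------------------- sequences


def synthetic_monomer(length: int, gc: float, rng: np.random.Generator) -> str:
    """A synthetic random monomer with exactly ``round(gc*length)`` G/C bases."""
    n_gc = int(round(gc * length))
    codes = np.empty(length, dtype=np.int8)
    is_gc = np.zeros(length, dtype=bool)
    is_gc[rng.choice(length, size=n_gc, replace=False)] = True
    codes[is_gc] = rng.choice([_seq.C, _seq.G], size=n_gc)
    codes[~is_gc] = rng.choice([_seq.A, _seq.T], size=length - n_gc)
    return _seq.decode(codes)


def build_panel(cfg: SimConfig) -> ReferencePanel:
    """The reference panel of true family consensus monomers for ``cfg``.

    Monomers without an explicit sequence are synthetic stand-ins drawn
    from the config's dedicated monomer stream, so the panel is
    reproducible from the seed alone.
    """
    rng = cfg.rng("monomers")
    entries = []
    for m in cfg.monomers:
        seq = m.sequence if m.sequence is not None else synthetic_monomer(m.length, m.gc, rng)
        entries.append(PanelEntry(m.name, seq, is_tandem=m.is_tandem))
    return ReferencePanel(entries)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = rng.random(len(codes)) < rate
    # substitution to a uniformly chosen *different* base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


# ------------------------------------------------------------------- genome


def simulate_genome(cfg: SimConfig) -> tuple[str, pd.DataFrame]:
    """Build the toy genome and its complete, non-overlapping annotation.

    Tandem arrays are head-to-tail concatenations of (optionally mutated)
    monomer copies.  The annotation tiles the genome exactly: every base
    belongs to one region (tandem array, interspersed copy, gene or
    background).  Coordinates are 0-based half-open.
    """
    panel = build_panel(cfg)
    rng = cfg.rng("genome")
    exp = {m.name: m.expression for m in cfg.monomers}

    segments: list[tuple[str, str, np.ndarray]] = []  # (family, kind, codes)
    for fam, copy_lists in cfg.array_copies.items():
        mono = _seq.encode(panel[fam].sequence)
        for n_copies in copy_lists:
            copies = [_mutate(mono, cfg.per_copy_mutation_rate, rng) for _ in range(n_copies)]
            segments.append((fam, "tandem_array", np.concatenate(copies)))
    for fam, n_copies in cfg.interspersed_copies.items():
        mono = _seq.encode(panel[fam].sequence)
        for _ in range(n_copies):
            segments.append((fam, "interspersed", _mutate(mono, cfg.per_copy_mutation_rate, rng)))
    for gene in cfg.genes:
        segments.append((gene.name, "gene", rng.integers(0, 4, size=gene.length).astype(np.int8)))

    order = rng.permutation(len(segments))
    segments = [segments[i] for i in order]

    # background split into len(segments)+1 gaps of at least min_background_gap
    k = len(segments) + 1
    spare = cfg.background_length - k * cfg.min_background_gap
    if spare < 0:
        raise ValueError("background_length too small for the number of segments")
    gaps = rng.multinomial(spare, np.full(k, 1.0 / k)) + cfg.min_background_gap

    pieces: list[np.ndarray] = []
    rows = []
    pos = 0
    gene_exp = {g.name: g.expression for g in cfg.genes}

    def add(family: str, kind: str, codes: np.ndarray) -> None:
        nonlocal pos
        occ = cfg.occupancy.get(family, 0.0) if kind in ("tandem_array", "interspersed") else 0.0
        if kind == "gene":
            expression = gene_exp[family]
        elif kind == "tandem_array":
            expression = exp.get(family, 0.0)
        else:
            expression = 0.0
        rows.append((len(rows), "chrS", pos, pos + len(codes), family, kind, occ, expression))
        pieces.append(codes)
        pos += len(codes)

    for i, (fam, kind, codes) in enumerate(segments):
        add("background", "background", rng.integers(0, 4, size=int(gaps[i])).astype(np.int8))
        add(fam, kind, codes)
    add("background", "background", rng.integers(0, 4, size=int(gaps[-1])).astype(np.int8))

    genome = _seq.decode(np.concatenate(pieces))
    annotations = pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "family", "kind", "occupancy", "expression"],
    )
    return genome, annotations


# -------------------------------------------------------------------- truth


def expected_ratios(annotations: pd.DataFrame, alpha: float) -> dict[str, float]:
    """Closed-form expected normalised IP/input ratio per family."""
    lens = (annotations.end - annotations.start).to_numpy(dtype=float)
    w = 1.0 + alpha * annotations.occupancy.to_numpy(dtype=float)
    wbar = float((lens * w).sum() / lens.sum())
    out: dict[str, float] = {}
    for fam in annotations.family.unique():
        sel = annotations.family == fam
        fam_w = float((lens[sel.to_numpy()] * w[sel.to_numpy()]).sum() / lens[sel.to_numpy()].sum())
        out[fam] = fam_w / wbar
    return out


def alpha_for_ratio(cfg: SimConfig, family: str, target_ratio: float) -> float:
    """Solve the IP weight ``alpha`` giving ``target_ratio`` for ``family``.

    From R = (1 + alpha*occ_f) / (1 + alpha*q), q the length-weighted mean
    occupancy: alpha = (R - 1) / (occ_f - R*q).  Raises if the design
    cannot attain the ratio (needs occ_f > R*q).
    """
    _, ann = simulate_genome(dataclasses.replace(cfg, ip_enrichment_alpha=0.0))
    lens = (ann.end - ann.start).to_numpy(dtype=float)
    occ = ann.occupancy.to_numpy(dtype=float)
    q = float((lens * occ).sum() / lens.sum())
    sel = (ann.family == family).to_numpy()
    occ_f = float((lens[sel] * occ[sel]).sum() / lens[sel].sum())
    if target_ratio == 1.0:
        return 0.0
    denom = occ_f - target_ratio * q
    if denom <= 0:
        raise ValueError(
            f"ratio {target_ratio} unattainable for {family!r}: "
            f"family occupancy {occ_f:.3f} vs genome mean {q:.4f}"
        )
    return (target_ratio - 1.0) / denom


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    expected_ratios: dict[str, float]
    regions: pd.DataFrame
    fibre_classes: list[str] = field(default_factory=list)

    @classmethod
    def from_config(cls, cfg: SimConfig, annotations: pd.DataFrame) -> "SimTruth":
        classes = ["I"] * cfg.fibre_counts[0] + ["II"] * cfg.fibre_counts[1] + ["III"] * cfg.fibre_counts[2]
        return cls(expected_ratios(annotations, cfg.ip_enrichment_alpha), annotations, classes)

    def to_json(self, path: str | Path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "expected_ratios": self.expected_ratios,
                    "fibre_classes": self.fibre_classes,
                    "regions": self.regions.to_dict(orient="list"),
                },
                fh,
                indent=1,
            )


# --------------------------------------------------------------------- reads


def _region_weights(annotations: pd.DataFrame, cfg: SimConfig, channel: str) -> np.ndarray:
    lens = (annotations.end - annotations.start).to_numpy(dtype=float)
    if channel == "input":
        w = np.ones(len(annotations))
    elif channel == "ip":
        w = 1.0 + cfg.ip_enrichment_alpha * annotations.occupancy.to_numpy(dtype=float)
    elif channel == "rna":
        w = annotations.expression.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return lens * w


def simulate_reads(
    genome: str,
    annotations: pd.DataFrame,
    cfg: SimConfig,
    channel: str,
    n_reads: int | None = None,
) -> list[tuple[str, str]]:
    """Draw ``n_reads`` single-end reads for one channel.

    Fragment starts are sampled region-by-region with the channel's weight
    model; DNA channels may cross region boundaries, RNA reads stay inside
    their transcript.  Substitution errors are applied per base at the
    configured rate.  Identifiers encode channel, index, source region,
    family, 0-based start and strand, e.g. ``ip:7:r12:cen_sat:10432:-``.
    """
    if n_reads is None:
        n_reads = {"ip": cfg.n_reads_ip, "input": cfg.n_reads_input, "rna": cfg.n_reads_rna}[channel]
    m = cfg.read_length
    if not genome:
        raise ValueError("genome is empty")
    if m > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = cfg.rng(channel)
    weights = _region_weights(annotations, cfg, channel)
    if channel == "rna":
        # reads must fit inside the transcript
        lens = (annotations.end - annotations.start).to_numpy()
        weights = np.where(lens >= m, weights, 0.0)
    if weights.sum() <= 0:
        raise ValueError(f"no sampleable regions for channel {channel!r}")
    p = weights / weights.sum()

    region_idx = rng.choice(len(annotations), size=n_reads, p=p)
    starts_all = annotations.start.to_numpy()
    ends_all = annotations.end.to_numpy()
    u = rng.random(n_reads)
    if channel == "rna":
        span = ends_all[region_idx] - starts_all[region_idx] - m + 1
    else:
        span = ends_all[region_idx] - starts_all[region_idx]
    starts = starts_all[region_idx] + np.floor(u * span).astype(np.int64)
    starts = np.minimum(starts, len(genome) - m)
    strands = rng.integers(0, 2, size=n_reads)

    gcodes = _seq.encode(genome)
    reads: list[tuple[str, str]] = []
    fams = annotations.family.to_numpy()
    chunk = 50_000
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        idx = starts[lo:hi, None] + np.arange(m)[None, :]
        codes = gcodes[idx]
        if cfg.substitution_error_rate > 0:
            err = rng.random(codes.shape) < cfg.substitution_error_rate
            n_err = int(err.sum())
            codes[err] = (codes[err] + rng.integers(1, 4, size=n_err)) % 4
        minus = strands[lo:hi] == 1
        codes[minus] = _seq.revcomp_codes(codes[minus])
        text = _seq.decode(codes.ravel())
        for j in range(hi - lo):
            i = lo + j
            rid = (
                f"{channel}:{i}:r{region_idx[i]}:{fams[region_idx[i]]}:"
                f"{starts[i]}:{'-' if strands[i] else '+'}"
            )
            reads.append((rid, text[j * m : (j + 1) * m]))
    return reads


def parse_read_id(read_id: str) -> dict:
    """Recover the ground truth encoded in a simulated read identifier."""
    channel, idx, region, family, start, strand = read_id.split(":")
    return {
        "channel": channel,
        "index": int(idx),
        "region_id": int(region[1:]),
        "family": family,
        "start": int(start),
        "strand": strand,
    }


def write_fastq(reads, path: str | Path) -> None:
    """Write reads as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path):
    """Parse FASTQ lazily; malformed records raise naming the record index."""
    with open(path) as fh:
        rec = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if not header.startswith("@") or not lines[2].startswith("+") or not lines[3].strip():
                raise ValueError(f"malformed FASTQ record at index {rec}")
            seq = lines[1].strip()
            if len(seq) != len(lines[3].strip()):
                raise ValueError(f"malformed FASTQ record at index {rec}: sequence/quality length differ")
            yield header[1:].split()[0], seq
            rec += 1


# ------------------------------------------------------------------- fibres


def simulate_fibres(cfg: SimConfig) -> list[FibreProfile]:
    """Two-channel chromatin-fibre traces in the three binding patterns.

    Pattern I: the green (CENP-A) channel covers at least
    ``fibre_full_coverage`` of the red (satellite) stretch; pattern II: two
    or more disjoint green blocks inside the red stretch; pattern III:
    green at background level only.  Gaussian noise is added and
    intensities clipped at zero; the true class travels with each profile.
    """
    rng = cfg.rng("fibres")
    profiles: list[FibreProfile] = []
    classes = ["I"] * cfg.fibre_counts[0] + ["II"] * cfg.fibre_counts[1] + ["III"] * cfg.fibre_counts[2]
    for k, true_class in enumerate(classes):
        n = int(rng.integers(cfg.fibre_points[0], cfg.fibre_points[1] + 1))
        red = np.full(n, cfg.fibre_background)
        green = np.full(n, cfg.fibre_background)
        frac = rng.uniform(*cfg.fibre_red_fraction)
        stretch_len = max(int(round(frac * n)), 30)
        lo = int(rng.integers(5, n - stretch_len - 4))
        hi = lo + stretch_len
        red[lo:hi] += cfg.fibre_signal * rng.uniform(0.8, 1.2)
        true_blocks: list[tuple[int, int]] = []
        if true_class == "I":
            cov = rng.uniform(max(cfg.fibre_full_coverage, 0.96), 1.0)
            glen = int(round(cov * stretch_len))
            g0 = lo + int(rng.integers(0, stretch_len - glen + 1))
            green[g0 : g0 + glen] += cfg.fibre_signal * rng.uniform(0.8, 1.2)
            true_blocks.append((g0, g0 + glen))
        elif true_class == "II":
            min_w, min_gap = 6, 6
            n_blocks = int(min(2 + stretch_len // 80, 4))
            budget = int(rng.uniform(0.25, 0.60) * stretch_len)
            budget = max(budget, n_blocks * min_w)
            widths = np.full(n_blocks, min_w)
            extra = budget - n_blocks * min_w
            if extra > 0:
                widths = widths + rng.multinomial(extra, np.full(n_blocks, 1.0 / n_blocks))
            slack = stretch_len - int(widths.sum()) - (n_blocks - 1) * min_gap
            gaps = rng.multinomial(max(slack, 0), np.full(n_blocks + 1, 1.0 / (n_blocks + 1)))
            cursor = lo + int(gaps[0])
            for b in range(n_blocks):
                if b > 0:
                    cursor += min_gap + int(gaps[b])
                end = min(cursor + int(widths[b]), hi)
                green[cursor:end] += cfg.fibre_signal * rng.uniform(0.8, 1.2)
                true_blocks.append((cursor, end))
                cursor = end
        if cfg.fibre_noise_sd > 0:
            red = red + rng.normal(0.0, cfg.fibre_noise_sd, size=n)
            green = green + rng.normal(0.0, cfg.fibre_noise_sd, size=n)
        profiles.append(
            FibreProfile(
                fibre_id=f"fibre{k:03d}",
                positions=np.arange(n, dtype=float),
                red=np.clip(red, 0.0, None),
                green=np.clip(green, 0.0, None),
                true_class=true_class,
                true_red_stretch=(lo, hi),
                true_green_blocks=true_blocks,
            )
        )
    return profiles


# ---------------------------------------------------------------- slot blot


def simulate_slot_blot(cfg: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Synthetic densitometric IDV pairs per probe.

    Film densitometry compresses abundance sublinearly; the IP-side IDV
    scales with the family's true enrichment ratio raised to
    ``slot_gamma`` (< 1), so a several-fold sequence-level enrichment
    shows up as a ~2-fold densitometric ratio, as is typical of
    saturating blot signals.
    """
    rng = cfg.rng("slot")
    rows = []
    base = 1000.0
    for fam in [m.name for m in cfg.monomers]:
        r = truth.expected_ratios.get(fam, 1.0)
        idv_input = base * (1.0 + rng.normal(0, cfg.slot_noise_sd))
        idv_ip = base * (r ** cfg.slot_gamma) * (1.0 + rng.normal(0, cfg.slot_noise_sd))
        rows.append((fam, idv_ip, idv_input, 0.0))
    return pd.DataFrame(rows, columns=["probe", "idv_ip", "idv_input", "background"])
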