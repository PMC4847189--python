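"""Normalised abundances and IP/input enrichment ratios.

Raw per-family read counts are normalised for sequencing depth and
reference length:

    normalized = raw_count / (total_reads * ref_length) * 1e9

(a per-billion, RPKM-like scale; the constant is cosmetic since the
IP/input ratio is scale-free).  ``ref_length`` of a tandem family is its
monomer length — the dimer used as mapping target is an artifice, not a
reference.  The enrichment ratio IP.normalized / input.normalized equals 1
when a family is equally represented in the immunoprecipitated and input
fractions.

The module also performs the equal-length-window RNA counting: satellite
transcription is compared with gene transcripts by mapping RNA reads to
windows that all share one length, so raw counts are directly comparable
without normalisation (the satellite window being a monomer dimer of that
same length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from satcen.mapping import MapperConfig, MappingSummary, ReadMapper
from satcen.panel import PanelEntry, ReferencePanel

SCALE = 1e9


def normalize(raw_count: float, total_reads: int, ref_length: int) -> float:
    """Depth- and length-normalised abundance (per-billion scale)."""
    if total_reads <= 0 or ref_length <= 0:
        raise ValueError("empty sample/reference")
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    return raw_count / (total_reads * ref_length) * SCALE


@dataclass(frozen=True)
class CountRow:
    entry: str
    raw_count: int
    total_reads: int
    ref_length: int

    @property
    def normalized(self) -> float:
        return normalize(self.raw_count, self.total_reads, self.ref_length)


def enrichment_ratio(ip: CountRow, input_row: CountRow) -> float | None:
    """IP/input normalised-count ratio; None (undefined) on zero input."""
    if ip.entry != input_row.entry:
        raise ValueError(f"entry mismatch: {ip.entry!r} vs {input_row.entry!r}")
    if ip.ref_length != input_row.ref_length:
        raise ValueError("IP and input rows must share ref_length")
    if input_row.raw_count == 0:
        return None
    return ip.normalized / input_row.normalized


@dataclass
class EnrichmentTable:
    """Per-family IP and input counts with normalised values and ratios."""

    frame: pd.DataFrame

    @classmethod
    def from_summaries(
        cls,
        ip: MappingSummary,
        input_summary: MappingSummary,
        panel: ReferencePanel,
    ) -> "EnrichmentTable":
        rows = []
        for e in panel:
            r_ip = CountRow(e.name, ip.per_entry.get(e.name, 0), ip.total_reads, e.ref_length)
            r_in = CountRow(
                e.name, input_summary.per_entry.get(e.name, 0), input_summary.total_reads, e.ref_length
            )
            ratio = enrichment_ratio(r_ip, r_in)
            rows.append(
                (
                    e.name,
                    r_ip.raw_count,
                    r_in.raw_count,
                    r_ip.total_reads,
                    r_in.total_reads,
                    e.ref_length,
                    r_ip.normalized,
                    r_in.normalized,
                    np.nan if ratio is None else ratio,
                    ratio is None,
                )
            )
        return cls(
            pd.DataFrame(
                rows,
                columns=[
                    "entry",
                    "raw_ip",
                    "raw_input",
                    "total_ip",
                    "total_input",
                    "ref_len",
                    "norm_ip",
                    "norm_input",
                    "ratio",
                    "undefined",
                ],
            )
        )

    def ratio(self, entry: str) -> float | None:
        row = self.frame.loc[self.frame.entry == entry]
        if row.empty:
            raise KeyError(entry)
        if bool(row.undefined.iloc[0]):
            return None
        return float(row.ratio.iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def ratio_standard_error(raw_ip: int, total_ip: int, raw_input: int, total_input: int) -> float:
    """Approximate relative-scale standard error of an enrichment ratio.

    Delta-method propagation of the two binomial counting errors:
    SE(ratio)/ratio = sqrt((1-p_ip)/x_ip + (1-p_in)/x_in).  Returned on
    the ratio scale (multiply a ratio estimate by ± this relative error).
    """
    if raw_ip <= 0 or raw_input <= 0:
        raise ValueError("counts must be positive for an SE estimate")
    rel = np.sqrt(
        (1 - raw_ip / total_ip) / raw_ip + (1 - raw_input / total_input) / raw_input
    )
    return float(rel)


# ----------------------------------------------------------- RNA counting


@dataclass
class RnaWindowPanel:
    """Equal-length transcript windows plus satellite dimer targets.

    All mapping targets share one length ``window_length`` so raw read
    counts are comparable without normalisation.  A tandem satellite
    contributes a dimer window (monomer doubled, trimmed to the window
    length if needed) but is reported under its monomer name.
    """

    windows: list[PanelEntry]
    window_length: int

    @classmethod
    def build(
        cls,
        gene_windows: Sequence[tuple[str, str]],
        satellites: Sequence[PanelEntry] = (),
        window_length: int | None = None,
    ) -> "RnaWindowPanel":
        entries = [PanelEntry(n, s, is_tandem=False) for n, s in gene_windows]
        lengths = {e.monomer_length for e in entries}
        if window_length is None:
            if len(lengths) != 1:
                raise ValueError("windows must share one length")
            window_length = lengths.pop()
        elif lengths - {window_length}:
            raise ValueError("windows must share one length")
        sat_entries = []
        for sat in satellites:
            dimer = (sat.sequence * (window_length // sat.monomer_length + 2))[:window_length]
            sat_entries.append(PanelEntry(sat.name, dimer, is_tandem=True))
        return cls(sat_entries + entries, window_length)

    def as_reference(self) -> ReferencePanel:
        # windows are already cut to the common length; map them as-is
        return ReferencePanel([PanelEntry(e.name, e.sequence, is_tandem=False) for e in self.windows])


def count_rna_windows(
    reads: Iterable[tuple[str, str]],
    windows: RnaWindowPanel,
    config: MapperConfig | None = None,
) -> pd.DataFrame:
    """Best-hit read counts per window, reported without normalisation."""
    mapper = ReadMapper(windows.as_reference(), config)
    _, summary = mapper.map_reads(reads)
    rows = [(e.name, summary.per_entry.get(e.name, 0)) for e in windows.windows]
    df = pd.DataFrame(rows, columns=["window", "raw_count"])
    df["window_length"] = windows.window_length
    df["total_reads"] = summary.total_reads
    return df
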