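"""ChIP peak records, stringent filtering and a minimal domain caller.

The stringent selection keeps only peaks *strictly* exceeding all four
thresholds — fold enrichment > 5, pile-up > 100, −log10(p) > 100,
−log10(q) > 100 by default — so boundary values fail.  Records arrive
from MACS-style tab-separated tables (header line, case-insensitive
column matching with an optional rename mapping) or from the built-in
window-based domain caller, which exists so the synthetic pipeline runs
end-to-end without external peak software: it merges adjacent windows of
elevated depth-normalised IP/input coverage ratio and scores each domain
with a one-sided binomial tail plus Benjamini–Hochberg conversion of p
to q.  The caller is deliberately simple plumbing, not a reimplementation
of a production peak caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class PeakRecord:
    contig: str
    start: int
    end: int
    fold_enrichment: float
    pileup: float
    neg_log10_p: float
    neg_log10_q: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.contig}:{self.start}-{self.end}: start must be < end")
        for name in ("fold_enrichment", "pileup", "neg_log10_p", "neg_log10_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"peak {self.contig}:{self.start}-{self.end}: {name} must be >= 0")


@dataclass(frozen=True)
class PeakFilterCriteria:
    """Strict lower bounds a peak must exceed on all four statistics."""

    min_fold_enrichment: float = 5.0
    min_pileup: float = 100.0
    min_neg_log10_p: float = 100.0
    min_neg_log10_q: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "min_fold_enrichment",
            "min_pileup",
            "min_neg_log10_p",
            "min_neg_log10_q",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def passes(self, p: PeakRecord) -> bool:
        return (
            p.fold_enrichment > self.min_fold_enrichment
            and p.pileup > self.min_pileup
            and p.neg_log10_p > self.min_neg_log10_p
            and p.neg_log10_q > self.min_neg_log10_q
        )


def filter_peaks(
    records: Sequence[PeakRecord], criteria: PeakFilterCriteria | None = None
) -> tuple[list[PeakRecord], dict]:
    """Keep records strictly exceeding every threshold, preserving order.

    Returns (kept, summary) where the summary reports kept/dropped counts.
    """
    criteria = criteria or PeakFilterCriteria()
    kept = [p for p in records if criteria.passes(p)]
    summary = {"total": len(records), "kept": len(kept), "dropped": len(records) - len(kept)}
    return kept, summary


def tally_by_family(
    kept: Sequence[PeakRecord], classifications: dict[tuple[str, int, int], str | None]
) -> dict[str, int]:
    """Per-family counts of surviving regions, joined on (contig, start, end)."""
    tally: dict[str, int] = {}
    for p in kept:
        fam = classifications.get((p.contig, p.start, p.end)) or "unclassified"
        tally[fam] = tally.get(fam, 0) + 1
    return tally


# ---------------------------------------------------------------- import/export

_COLUMN_ALIASES = {
    "contig": {"contig", "chr", "chrom", "chromosome", "seqnames"},
    "start": {"start", "chromstart"},
    "end": {"end", "chromend"},
    "fold_enrichment": {"fold_enrichment", "fe", "fold-enrichment", "foldchange", "fold"},
    "pileup": {"pileup", "pile-up", "pile_up"},
    "neg_log10_p": {"neg_log10_p", "-log10(pvalue)", "log10p", "-log10pvalue", "neglog10p"},
    "neg_log10_q": {"neg_log10_q", "-log10(qvalue)", "log10q", "-log10qvalue", "neglog10q"},
}


def read_peak_table(path: str | Path, column_map: dict[str, str] | None = None) -> list[PeakRecord]:
    """Parse a MACS-style TSV peak table.

    Column names are matched case-insensitively against common aliases;
    ``column_map`` maps canonical field names to the file's column names
    for dialect drift.  Malformed rows raise with their line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for want, aliases in _COLUMN_ALIASES.items():
        if column_map and want in column_map:
            resolved[want] = column_map[want]
        else:
            found = [lower[a] for a in aliases if a in lower]
            if not found:
                raise ValueError(f"peak table {path}: missing column for {want!r}")
            resolved[want] = found[0]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        vals = dict(zip(df.columns, row))
        try:
            records.append(
                PeakRecord(
                    contig=str(vals[resolved["contig"]]),
                    start=int(vals[resolved["start"]]),
                    end=int(vals[resolved["end"]]),
                    fold_enrichment=float(vals[resolved["fold_enrichment"]]),
                    pileup=float(vals[resolved["pileup"]]),
                    neg_log10_p=float(vals[resolved["neg_log10_p"]]),
                    neg_log10_q=float(vals[resolved["neg_log10_q"]]),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"peak table {path}: malformed row at line {line_no}: {e}") from None
    return records


def peaks_to_frame(records: Iterable[PeakRecord]) -> pd.DataFrame:
    cols = ["contig", "start", "end", "fold_enrichment", "pileup", "neg_log10_p", "neg_log10_q"]
    return pd.DataFrame([[getattr(p, c) for c in cols] for p in records], columns=cols)


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    peaks_to_frame(records).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- domain caller


def coverage_track(starts: np.ndarray, read_length: int, genome_length: int) -> np.ndarray:
    """Per-base coverage from read start positions (0-based)."""
    track = np.zeros(genome_length + 1, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    np.add.at(track, starts, 1)
    np.add.at(track, np.minimum(starts + read_length, genome_length), -1)
    return np.cumsum(track)[:genome_length]


def call_domains(
    ip_track: np.ndarray,
    input_track: np.ndarray,
    window: int = 100,
    min_ratio: float = 2.0,
    contig: str = "chrS",
    smooth_windows: int = 3,
    read_length: int | None = None,
) -> list[PeakRecord]:
    """Merge windows of elevated depth-normalised IP/input ratio into domains.

    Per window the coverage ratio is depth-normalised ((ip/total_ip) /
    (input/total_input), with a 0.5 pseudocount against empty windows) and
    smoothed by a centred moving average over ``smooth_windows`` windows.
    Runs of windows with smoothed ratio >= ``min_ratio`` become domains;
    each reports the mean windowed ratio as fold enrichment, the maximum
    IP coverage as pile-up, a one-sided binomial tail on the window read
    mass as −log10 p, and Benjamini–Hochberg q-values.  When
    ``read_length`` is given, coverage mass is converted back to read
    counts before the binomial test so each read is one trial.
    """
    ip_track = np.asarray(ip_track, dtype=float)
    input_track = np.asarray(input_track, dtype=float)
    if ip_track.shape != input_track.shape:
        raise ValueError("IP and input tracks must have the same length")
    if window <= 0:
        raise ValueError("window must be positive")
    total_ip, total_in = ip_track.sum(), input_track.sum()
    if total_in == 0:
        raise ValueError("cannot form ratio: input track is all zero")
    n_win = len(ip_track) // window
    if n_win == 0:
        return []
    ip_w = ip_track[: n_win * window].reshape(n_win, window).sum(axis=1)
    in_w = input_track[: n_win * window].reshape(n_win, window).sum(axis=1)
    ratio = ((ip_w + 0.5) / total_ip) / ((in_w + 0.5) / total_in)
    if smooth_windows > 1:
        kernel = np.ones(smooth_windows) / smooth_windows
        smoothed = np.convolve(ratio, kernel, mode="same")
    else:
        smoothed = ratio

    records: list[tuple[int, int]] = []
    above = smoothed >= min_ratio
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            records.append((start, i))
            start = None
    if start is not None:
        records.append((start, n_win))
    if not records:
        return []

    # read mass per domain, scored against the genome-wide IP share
    p0 = total_ip / (total_ip + total_in)
    log10p = []
    domains = []
    scale = float(read_length) if read_length else 1.0
    for w0, w1 in records:
        x = float(ip_w[w0:w1].sum()) / scale
        n = x + float(in_w[w0:w1].sum()) / scale
        # coverage mass in read-length units is fractional; round for the test
        xi, ni = int(round(x)), int(round(n))
        logp = stats.binom.logsf(max(xi - 1, 0), max(ni, 1), p0) / _LN10
        log10p.append(-logp)
        domains.append((w0 * window, w1 * window, float(smoothed[w0:w1].mean()), float(ip_track[w0 * window : w1 * window].max())))

    neg_p = np.array(log10p)
    neg_q = _bh_neg_log10(neg_p)
    out = []
    for (start_bp, end_bp, fe, pileup), nlp, nlq in zip(domains, neg_p, neg_q):
        out.append(
            PeakRecord(
                contig=contig,
                start=start_bp,
                end=end_bp,
                fold_enrichment=fe,
                pileup=pileup,
                neg_log10_p=float(max(nlp, 0.0)),
                neg_log10_q=float(max(nlq, 0.0)),
            )
        )
    return out


def _bh_neg_log10(neg_log10_p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg on −log10 scale (handles p far below float range)."""
    n = len(neg_log10_p)
    order = np.argsort(-neg_log10_p)  # most significant first
    ranked = neg_log10_p[order]
    # q_(i) = p_(i) * n / i, then enforce monotonicity from the least
    # significant end; on the −log10 scale subtract log10(n/i).
    adj = ranked - np.log10(n / np.arange(1, n + 1))
    # step-up: -log10 q_(i) = max over less-significant j >= i of adj_(j)
    adj = np.maximum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.maximum(adj, 0.0)
    return out
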