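"""Percent-identity read mapping against a repeat consensus panel.

Short reads are placed semi-globally (read fully contained in the target)
on every panel target, on both strands, and the single best placement is
reported when its identity reaches the configured threshold.  Identity is
substitution-only by default: matching positions divided by read length,
with N counting as a mismatch.  The mapper scores *every* offset exactly:
match counts for all placements are obtained in one dense matrix product
between one-hot-encoded reads and a matrix of one-hot-encoded target
windows (one column per target, strand and offset), so its output is
identical to an exhaustive sliding-window aligner by construction while
running at BLAS speed.  Counts are far below 2^24, hence exact in float32.

Tie-breaking is deterministic and documented:

* equal best identity across panel entries → the entry earliest in panel
  order wins and the hit is flagged ``ambiguous``;
* equal best identity at several offsets within one target → the smallest
  offset wins;
* equal best identity on both strands → forward wins.

Tandem entries are mapped against their head-to-tail dimer; a hit landing
entirely in the second monomer copy is an exact duplicate of one in the
first and is canonicalised to ``offset mod monomer_length``.

An optional edit-distance mode (``allow_indels=True``, via edlib) scores
``1 − edit_distance / read_length`` instead; it is slower and its offset
tie-breaking follows edlib's first-reported location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from satcen import _seq
from satcen.panel import ReferencePanel

_CHUNK = 4096  # reads scored per matrix-product batch


@dataclass(frozen=True)
class MapperConfig:
    """Mapping parameters.

    min_identity : minimum fraction of matching positions (default 0.80,
        i.e. up to 20 % mismatches are tolerated).
    allow_indels : score with edit distance (edlib) instead of
        substitution-only identity.
    """

    min_identity: float = 0.80
    allow_indels: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class AlignmentHit:
    """Best placement of one read on the panel."""

    read_id: str
    entry: str
    offset: int  # 0-based start on the mapping target (dimer for tandem)
    strand: str  # '+' or '-'
    identity: float
    monomer_offset: int  # offset mod monomer_length for tandem entries
    ambiguous: bool = False


@dataclass
class MappingSummary:
    total_reads: int = 0
    mapped: int = 0
    unmapped: int = 0
    ambiguous: int = 0
    per_entry: dict[str, int] = field(default_factory=dict)


class ReadMapper:
    """Reusable mapper holding per-panel precomputations."""

    def __init__(self, panel: ReferencePanel, config: MapperConfig | None = None):
        self.panel = panel
        self.config = config or MapperConfig()
        self._targets = [(e, _seq.encode(e.target)) for e in panel]
        self._max_target_len = max(len(e.target) for e in panel)
        self._window_cache: dict[int, tuple] = {}

    # ------------------------------------------------------------------ core

    def _window_matrix(self, m: int) -> tuple:
        """Window matrix for read length m: one column per placement.

        Columns are ordered (entry in panel order, '+' strand before '-',
        offset ascending), so a first-occurrence argmax over columns
        realises the documented tie-breaking exactly.
        """
        if m in self._window_cache:
            return self._window_cache[m]
        blocks, entry_of, offset_of, strand_of, bounds = [], [], [], [], [0]
        for idx, (entry, tcodes) in enumerate(self._targets):
            n_off = len(tcodes) - m + 1
            if n_off > 0:
                wins = np.lib.stride_tricks.sliding_window_view(tcodes, m)
                for strand, w in ((0, wins), (1, _seq.revcomp_codes(wins))):
                    blocks.append(_seq.onehot(w).reshape(n_off, 4 * m))
                    entry_of.append(np.full(n_off, idx))
                    offset_of.append(np.arange(n_off))
                    strand_of.append(np.full(n_off, strand))
            bounds.append(bounds[-1] + max(n_off, 0) * 2)
        if not blocks:
            out = (None,) * 5
        else:
            # (4m, n_cols) for a single GEMM per read chunk
            out = (
                np.ascontiguousarray(np.concatenate(blocks).T),
                np.concatenate(entry_of),
                np.concatenate(offset_of),
                np.concatenate(strand_of),
                np.asarray(bounds),
            )
        self._window_cache[m] = out
        return out

    def _score_chunk(self, codes: np.ndarray) -> tuple[np.ndarray, ...] | None:
        """Score a (B, m) chunk of equal-length reads against all targets.

        Returns per-read arrays: best match count, entry index, offset,
        strand (0 fwd / 1 rev), ambiguous flag; or None if no target can
        contain a read of this length.
        """
        b, m = codes.shape
        wmat, entry_of, offset_of, strand_of, bounds = self._window_matrix(m)
        if wmat is None:
            return None
        reads = _seq.onehot(codes).reshape(b, 4 * m)
        scores = reads @ wmat  # (B, n_cols) exact match counts
        best_col = scores.argmax(axis=1)
        best = scores[np.arange(b), best_col]
        # ambiguity: does a second entry reach the same best identity?
        starts = bounds[:-1]
        widths = np.diff(bounds)
        nonempty = widths > 0
        per_entry_max = np.full((b, len(self._targets)), -1.0, dtype=scores.dtype)
        per_entry_max[:, nonempty] = np.maximum.reduceat(scores, starts[nonempty], axis=1)[:, : nonempty.sum()]
        n_top = (per_entry_max == best[:, None]).sum(axis=1)
        return (
            best.astype(np.int64),
            entry_of[best_col],
            offset_of[best_col],
            strand_of[best_col],
            n_top > 1,
        )

    def _score_chunk_edlib(self, seqs: Sequence[str]) -> tuple[np.ndarray, ...]:
        import edlib

        b = len(seqs)
        best = np.full(b, -1, dtype=np.int64)
        best_entry = np.full(b, -1, dtype=np.int64)
        best_off = np.zeros(b, dtype=np.int64)
        best_strand = np.zeros(b, dtype=np.int64)
        ambiguous = np.zeros(b, dtype=bool)
        for i, seq in enumerate(seqs):
            m = len(seq)
            rc = _seq.revcomp(seq)
            for idx, (entry, tcodes) in enumerate(self._targets):
                target = entry.target
                if m > len(target):
                    continue
                for strand, s in ((0, seq), (1, rc)):
                    res = edlib.align(s, target, mode="HW", task="locations")
                    score = m - res["editDistance"]
                    if score > best[i]:
                        best[i] = score
                        best_entry[i] = idx
                        best_off[i] = res["locations"][0][0]
                        best_strand[i] = strand
                        ambiguous[i] = False
                    elif score == best[i] and best_entry[i] not in (-1, idx):
                        ambiguous[i] = True
        return best, best_entry, best_off, best_strand, ambiguous

    # ------------------------------------------------------------- interface

    def map_reads(
        self, reads: Iterable[tuple[str, str]]
    ) -> tuple[list[AlignmentHit], MappingSummary]:
        """Map an iterable of ``(read_id, sequence)`` pairs.

        Reads are buffered into equal-length batches; each read yields at
        most one hit.  All-N reads are valid no-hits; any symbol outside
        ACGTN raises.
        """
        summary = MappingSummary(per_entry={e.name: 0 for e in self.panel})
        hits: list[AlignmentHit] = []
        by_len: dict[int, tuple[list[str], list[str]]] = {}

        def flush(length: int) -> None:
            ids, seqs = by_len.pop(length)
            if self.config.allow_indels:
                res = self._score_chunk_edlib(seqs)
            elif length > self._max_target_len:
                for s in seqs:
                    _seq.encode(s)  # alphabet check; read cannot fit any target
                return
            else:
                codes = np.array([_seq.encode(s) for s in seqs], dtype=np.int8)
                res = self._score_chunk(codes)
            self._collect(ids, length, res, hits, summary)

        for read_id, seq in reads:
            summary.total_reads += 1
            if self.config.allow_indels:
                _seq.encode(seq)  # alphabet check
            ids, seqs = by_len.setdefault(len(seq), ([], []))
            ids.append(read_id)
            seqs.append(seq)
            if len(ids) >= _CHUNK:
                flush(len(seq))
        for length in list(by_len):
            flush(length)
        summary.unmapped = summary.total_reads - summary.mapped
        return hits, summary

    def _collect(self, ids, m, res, hits, summary) -> None:
        best, entry_idx, off, strand, ambiguous = res
        min_matches = self.config.min_identity * m - 1e-9
        for i, read_id in enumerate(ids):
            if entry_idx[i] < 0 or best[i] < min_matches:
                continue
            entry = self.panel.entries[entry_idx[i]]
            offset = int(off[i])
            if entry.is_tandem:
                offset %= entry.monomer_length
            mono_off = offset % entry.monomer_length
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    entry=entry.name,
                    offset=offset,
                    strand="-" if strand[i] else "+",
                    identity=float(best[i]) / m,
                    monomer_offset=mono_off,
                    ambiguous=bool(ambiguous[i]),
                )
            )
            summary.mapped += 1
            summary.ambiguous += int(ambiguous[i])
            summary.per_entry[entry.name] += 1


def align_read(
    read: str, panel: ReferencePanel, config: MapperConfig | None = None
) -> AlignmentHit | None:
    """Best placement of a single read, or None if below threshold."""
    hits, _ = ReadMapper(panel, config).map_reads([("read", read)])
    return hits[0] if hits else None


def map_readset(
    reads: Iterable[tuple[str, str]],
    panel: ReferencePanel,
    config: MapperConfig | None = None,
) -> tuple[list[AlignmentHit], MappingSummary]:
    """Map a read set; see :meth:`ReadMapper.map_reads`."""
    return ReadMapper(panel, config).map_reads(reads)


def hits_to_frame(hits: Sequence[AlignmentHit]):
    """Tabulate hits as a DataFrame (column per hit field)."""
    import pandas as pd

    cols = ["read_id", "entry", "offset", "strand", "identity", "monomer_offset", "ambiguous"]
    return pd.DataFrame([[getattr(h, c) for c in cols] for h in hits], columns=cols)


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[AlignmentHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentHit(
            read_id=str(r.read_id),
            entry=str(r.entry),
            offset=int(r.offset),
            strand=str(r.strand),
            identity=float(r.identity),
            monomer_offset=int(r.monomer_offset),
            ambiguous=bool(r.ambiguous),
        )
        for r in df.itertuples()
    ]
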