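"""Tandem-repeat structure: period estimation, head-to-tail checks and
family classification of enriched-region sequences.

The repeat unit length of a sequence is estimated from its self-match
profile: the lag maximising the average per-base match fraction between
``s[i]`` and ``s[i+p]`` (the autocorrelation of the one-hot encoding).
Among near-equal maxima the smallest lag wins, so the fundamental period
is returned rather than one of its multiples.  Head-to-tail organisation
is verified by locating every monomer placement on both strands and
requiring co-orientation and adjacency.  Region classification tiles a
sequence into monomer-sized windows, assigns each window its best-identity
family with the same scoring as read mapping, and labels the region by
majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from satcen import _seq
from satcen.mapping import MapperConfig, ReadMapper
from satcen.panel import ReferencePanel


def window_identity(query: str | np.ndarray, target: str | np.ndarray) -> np.ndarray:
    """Exact identity of ``query`` at every offset of ``target`` (one strand).

    Returns an array of length ``len(target) - len(query) + 1``; N matches
    nothing.  This sliding-window scan is the brute-force scoring primitive
    used for placement finding (and, in the test suite, as the oracle for
    the FFT mapper).
    """
    q = _seq.encode(query) if isinstance(query, str) else query
    t = _seq.encode(target) if isinstance(target, str) else target
    if len(q) > len(t):
        return np.empty(0, dtype=float)
    wins = np.lib.stride_tricks.sliding_window_view(t, len(q))
    match = (wins == q[None, :]) & (wins < 4) & (q[None, :] < 4)
    return match.mean(axis=1)


def estimate_period(
    sequence: str,
    min_lag: int = 10,
    max_lag: int | None = None,
    threshold: float = 0.7,
    near_tol: float = 0.02,
) -> int | None:
    """Fundamental tandem period of a sequence, or None.

    Searches lags in ``[min_lag, max_lag]`` (default up to half the
    sequence, capped at 600 bp); a lag qualifies when its self-match
    fraction exceeds ``threshold`` (0.7 by default — far above the 0.25
    expected for i.i.d. bases); the smallest lag within ``near_tol`` of
    the best qualifying fraction is returned.
    """
    codes = _seq.encode(sequence)
    if max_lag is None:
        max_lag = min(len(codes) // 2, 600)
    if len(codes) < 2 * min_lag:
        return None
    lags = np.arange(min_lag, max_lag + 1)
    if len(lags) == 0:
        return None
    fracs = np.empty(len(lags))
    for i, p in enumerate(lags):
        a, b = codes[:-p], codes[p:]
        fracs[i] = float(((a == b) & (a < 4)).mean())
    best = fracs.max()
    if best < threshold:
        return None
    winner = lags[np.argmax(fracs >= best - near_tol)]
    return int(winner)


def find_placements(
    sequence: str, monomer: str, min_identity: float = 0.8, overlap_tol: int = 5
) -> list[tuple[int, str, float]]:
    """Greedy non-overlapping monomer placements on both strands.

    Candidate offsets (identity >= ``min_identity``) are accepted in
    decreasing identity order, skipping any candidate overlapping an
    accepted placement by more than ``overlap_tol`` bases.  Returns
    (offset, strand, identity) sorted by offset.
    """
    m = len(monomer)
    fwd = window_identity(monomer, sequence)
    rev = window_identity(_seq.revcomp(monomer), sequence)
    cands = []
    for strand, ident in (("+", fwd), ("-", rev)):
        for off in np.nonzero(ident >= min_identity)[0]:
            cands.append((float(ident[off]), int(off), strand))
    # best identity first; ties: smaller offset, then forward strand
    cands.sort(key=lambda c: (-c[0], c[1], c[2] != "+"))
    accepted: list[tuple[int, str, float]] = []
    for ident, off, strand in cands:
        if all(min(off + m, a + m) - max(off, a) <= overlap_tol for a, _, _ in accepted):
            accepted.append((off, strand, ident))
    accepted.sort()
    return accepted


def is_head_to_tail(
    sequence: str, monomer: str, min_identity: float = 0.8, gap_tol: int = 5
) -> bool:
    """True iff monomer placements are co-oriented and adjacent.

    Adjacent means the gap (or overlap) between consecutive placements is
    at most ``gap_tol`` bases; a head-to-head arrangement (alternating
    strands) or interrupted array returns False.  Raises if the monomer
    is not found at all.
    """
    placements = find_placements(sequence, monomer, min_identity, overlap_tol=gap_tol)
    if not placements:
        raise ValueError("family absent")
    strands = {s for _, s, _ in placements}
    if len(strands) > 1:
        return False
    m = len(monomer)
    for (o1, _, _), (o2, _, _) in zip(placements, placements[1:]):
        if abs(o2 - (o1 + m)) > gap_tol:
            return False
    return True


@dataclass
class RegionClassification:
    region_id: str
    family: str | None  # None = unclassified
    mean_identity: float
    head_to_tail: bool
    period: int | None
    mixed: bool = False
    window_families: dict[str, int] | None = None


def classify_region(
    sequence: str,
    panel: ReferencePanel,
    config: MapperConfig | None = None,
    region_id: str = "region",
    window: int | None = None,
    mapper: ReadMapper | None = None,
) -> RegionClassification:
    """Label a region by the majority repeat family of its windows.

    The region is tiled into non-overlapping windows of the panel's
    shortest tandem monomer length (so every window can fit every mapping
    target); each window is assigned its best-identity family exactly as
    a read would be.  The region takes the majority family and the mean
    identity of that family's windows; it is unclassified when the best
    mean identity falls below the mapping threshold.  A majority tie is
    flagged ``mixed`` and resolved toward the higher mean identity.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if mapper is not None:
        panel, config = mapper.panel, mapper.config
    config = config or MapperConfig()
    if window is None:
        tandem_lens = [e.monomer_length for e in panel if e.is_tandem]
        window = min(tandem_lens or [e.monomer_length for e in panel])
    window = min(window, len(sequence))
    tiles = [(f"w{i}", sequence[i * window : (i + 1) * window]) for i in range(len(sequence) // window)]
    if not tiles:
        tiles = [("w0", sequence)]
    hits, _ = (mapper or ReadMapper(panel, config)).map_reads(tiles)

    per_family: dict[str, list[float]] = {}
    for h in hits:
        per_family.setdefault(h.entry, []).append(h.identity)
    if not per_family:
        return RegionClassification(region_id, None, 0.0, False, estimate_period(sequence))

    def rank(fam: str) -> tuple[int, float]:
        idents = per_family[fam]
        return (len(idents), float(np.mean(idents)))

    ordered = sorted(per_family, key=lambda f: (-rank(f)[0], -rank(f)[1], panel.names.index(f)))
    best = ordered[0]
    n_best, mean_ident = rank(best)
    mixed = len(ordered) > 1 and rank(ordered[1])[0] == n_best
    if mean_ident < config.min_identity:
        return RegionClassification(region_id, None, mean_ident, False, estimate_period(sequence))

    entry = panel[best]
    head_to_tail = False
    if entry.is_tandem:
        try:
            head_to_tail = is_head_to_tail(sequence, entry.sequence, config.min_identity)
        except ValueError:
            head_to_tail = False
    return RegionClassification(
        region_id,
        best,
        mean_ident,
        head_to_tail,
        estimate_period(sequence),
        mixed=mixed,
        window_families={f: len(v) for f, v in per_family.items()},
    )
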