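"""Independent brute-force aligner used as the mapping oracle.

Deliberately naive: explicit loops over targets, strands and offsets,
counting matching positions at each placement.  Shares nothing with the
production scoring path beyond the alphabet.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _codes(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    return np.array([table[b] for b in seq], dtype=np.int8)


def brute_force_align(read: str, panel, min_identity: float):
    """Best placement of a read over every offset/strand of every target.

    Tie-breaks mirror the documented rules: entry order, then '+' strand,
    then smallest offset.  Returns None or a dict with entry, offset,
    strand, identity, ambiguous.
    """
    m = len(read)
    best = None  # (matches, entry_idx, strand_rank, offset)
    entry_best: dict[int, int] = {}
    for e_idx, entry in enumerate(panel):
        target = _codes(entry.target)
        for strand_rank, seq in enumerate((read, revcomp(read))):
            q = _codes(seq)
            for off in range(len(target) - m + 1):
                w = target[off : off + m]
                matches = int(((w == q) & (w < 4) & (q < 4)).sum())
                key = (-matches, e_idx, strand_rank, off)
                if best is None or key < best:
                    best = key
                if matches > entry_best.get(e_idx, -1):
                    entry_best[e_idx] = matches
    if best is None:
        return None
    matches, e_idx, strand_rank, off = -best[0], best[1], best[2], best[3]
    if matches < min_identity * m - 1e-9:
        return None
    entry = panel.entries[e_idx]
    if entry.is_tandem:
        off %= entry.monomer_length
    ambiguous = sum(1 for v in entry_best.values() if v == matches) > 1
    return {
        "entry": entry.name,
        "offset": off,
        "strand": "-" if strand_rank else "+",
        "identity": matches / m,
        "ambiguous": ambiguous,
    }
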