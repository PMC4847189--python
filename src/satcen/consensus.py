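"""Per-position base frequencies, consensus calling and logo material.

Reads mapped to a tandem monomer are folded onto monomer coordinates:
an aligned read base at offset ``i`` of a hit starting at ``monomer_offset``
contributes to position ``(monomer_offset + i) mod monomer_length``
(minus-strand hits are reverse-complemented first).  The resulting
position × base count matrix yields per-position frequencies, an
information content in bits (2 − Shannon entropy of the frequency vector,
the usual sequence-logo scaling for a 4-letter alphabet) and a
majority-vote consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from satcen import _seq
from satcen.mapping import AlignmentHit

_BASES = "ACGT"


@dataclass
class BaseFrequencyMatrix:
    """Monomer-position base counts with derived logo quantities."""

    counts: np.ndarray  # (monomer_length, 4) float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (monomer_length, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def monomer_length(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-position base frequencies; zero-coverage rows are NaN."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts / cov[:, None]
        freq[cov == 0] = np.nan
        return freq

    @property
    def information_bits(self) -> np.ndarray:
        """2 − H (Shannon entropy, bits) per position, in [0, 2].

        No small-sample correction is applied: the intended use is
        deep-coverage satellite consensus building.  Zero-coverage
        positions report 0 bits.
        """
        freq = self.frequencies
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
        info = 2.0 + np.nansum(plogp, axis=1)
        info[self.coverage == 0] = 0.0
        return np.clip(info, 0.0, 2.0)

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies
        cons, ambiguous = consensus_call(self, with_flags=True)
        df = pd.DataFrame(self.counts.astype(int), columns=list(_BASES))
        df.insert(0, "position", np.arange(self.monomer_length))
        for i, b in enumerate(_BASES):
            df[f"freq{b}"] = freq[:, i]
        df["info_bits"] = self.information_bits
        df["consensus_base"] = list(cons)
        df["ambiguous"] = ambiguous
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_matrix(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, str] | Sequence[tuple[str, str]],
    monomer_length: int,
) -> BaseFrequencyMatrix:
    """Accumulate aligned read bases onto monomer positions.

    ``hits`` must all reference one tandem entry; ``reads`` maps read ids
    to sequences.  N bases are skipped (they carry no base call).
    """
    if monomer_length <= 0:
        raise ValueError("monomer_length must be positive")
    if not isinstance(reads, Mapping):
        reads = dict(reads)
    entries = {h.entry for h in hits}
    if len(entries) > 1:
        raise ValueError(f"hits reference several entries: {sorted(entries)}")
    counts = np.zeros((monomer_length, 4), dtype=float)
    for h in hits:
        if not 0 <= h.monomer_offset < monomer_length:
            raise ValueError(f"hit offset {h.monomer_offset} out of range for read {h.read_id!r}")
        codes = _seq.encode(reads[h.read_id])
        if h.strand == "-":
            codes = _seq.revcomp_codes(codes)
        pos = (h.monomer_offset + np.arange(len(codes))) % monomer_length
        keep = codes < 4
        np.add.at(counts, (pos[keep], codes[keep]), 1.0)
    return BaseFrequencyMatrix(counts)


def consensus_call(matrix: BaseFrequencyMatrix, with_flags: bool = False):
    """Majority-vote consensus of a base-frequency matrix.

    Per position the base with maximal count wins; ties break
    alphabetically (A < C < G < T) and are flagged; zero-coverage
    positions emit N.
    """
    counts = matrix.counts
    best = counts.argmax(axis=1)  # argmax takes the first max → alphabetical
    seq = np.frombuffer(_BASES.encode(), dtype=np.uint8)[best].tobytes().decode()
    cov = matrix.coverage
    n_best = (counts == counts.max(axis=1, keepdims=True)).sum(axis=1)
    chars = list(seq)
    ambiguous = np.zeros(matrix.monomer_length, dtype=bool)
    for i in range(matrix.monomer_length):
        if cov[i] == 0:
            chars[i] = "N"
        elif n_best[i] > 1:
            ambiguous[i] = True
    consensus = "".join(chars)
    if with_flags:
        return consensus, ambiguous
    return consensus


def gc_content(sequence: str) -> float:
    """Percent G+C among informative (non-N) bases."""
    if not sequence:
        raise ValueError("empty sequence")
    codes = _seq.encode(sequence.upper())
    informative = codes < 4
    if not informative.any():
        raise ValueError("no informative bases")
    gc = np.isin(codes, (_seq.G, _seq.C)).sum()
    return 100.0 * float(gc) / float(informative.sum())
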