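"""Reference panels of repeat consensus sequences.

A panel holds the consensus monomer of each repeat family together with a
flag saying whether the family is tandemly organised.  For tandem families
the *mapping target* is the monomer concatenated head-to-tail with itself
(a dimer): a read sampled anywhere from an arbitrarily long tandem array —
including reads straddling the monomer junction — then always has a full
placement on the target, so the dimer trick leaves no blind spot.
Interspersed elements map against their plain consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from satcen import _seq


def sanitize(sequence: str) -> str:
    """Uppercase a sequence, fold U onto T, and reject anything outside ACGTN."""
    seq = sequence.strip().upper().replace("U", "T")
    _seq.encode(seq)  # validates alphabet
    return seq


@dataclass(frozen=True)
class PanelEntry:
    """One repeat family: a named consensus and its tandem/interspersed flag."""

    name: str
    sequence: str
    is_tandem: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", sanitize(self.sequence))
        if not self.sequence:
            raise ValueError(f"panel entry {self.name!r} has an empty sequence")

    @property
    def monomer_length(self) -> int:
        return len(self.sequence)

    @property
    def target(self) -> str:
        """The sequence reads are actually placed on (dimer for tandem entries)."""
        return self.sequence * 2 if self.is_tandem else self.sequence

    @property
    def ref_length(self) -> int:
        """Length used for abundance normalisation: always the monomer, the
        dimer being a mapping artifice only."""
        return self.monomer_length


@dataclass
class ReferencePanel:
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty panel")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("panel entry names must be unique")

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @classmethod
    def from_fasta(cls, path: str | Path, interspersed: Iterable[str] = ()) -> "ReferencePanel":
        """Load a panel from FASTA.

        Entries named in ``interspersed`` (or whose FASTA description
        contains the token ``interspersed``) are flagged non-tandem;
        everything else is treated as a tandem satellite monomer.
        """
        interspersed = set(interspersed)
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            tandem = rec.id not in interspersed and "interspersed" not in rec.description.lower()
            entries.append(PanelEntry(rec.id, str(rec.seq), is_tandem=tandem))
        return cls(entries)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                tag = "tandem" if e.is_tandem else "interspersed"
                fh.write(f">{e.name} {tag}\n{e.sequence}\n")

    @classmethod
    def from_sequences(
        cls, items: Sequence[tuple[str, str]] | dict[str, str], interspersed: Iterable[str] = ()
    ) -> "ReferencePanel":
        if isinstance(items, dict):
            items = list(items.items())
        interspersed = set(interspersed)
        return cls([PanelEntry(n, s, is_tandem=n not in interspersed) for n, s in items])
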