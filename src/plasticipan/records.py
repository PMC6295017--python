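"""Basic sequence record types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GenomeRecord:
    """One nucleotide genome (a chromosome or a concatenated draft).

    ``gc`` is mol% G+C computed over unambiguous A/C/G/T only; it is ``None``
    when the sequence contains no unambiguous base.
    """

    id: str
    sequence: str
    gc: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        if self.gc is None:
            acgt = sum(self.sequence.count(b) for b in "ACGT")
            if acgt:
                gc = self.sequence.count("G") + self.sequence.count("C")
                self.gc = 100.0 * gc / acgt

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """One protein sequence belonging to a genome."""

    id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
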