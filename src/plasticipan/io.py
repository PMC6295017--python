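"""FASTA reading/writing and output formatting helpers.

All writers use a fixed column order and 6-significant-digit floats so that
reruns of the same configuration diff clean.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from plasticipan.records import GenomeRecord, ProteinRecord

FASTA_WIDTH = 70


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a (multi-)FASTA of nucleotide records.

    Record ids are the header token up to the first whitespace; sequences are
    upper-cased.  Raises on an empty file or duplicate ids.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_genome(path: str | os.PathLike) -> GenomeRecord:
    """Read one genome, concatenating multi-contig drafts in file order.

    The concatenated record keeps the first contig's id and records contig
    boundaries (0-based start offsets) in ``record.contig_starts`` so that
    downstream fragmenting can drop fragments spanning a boundary.
    """
    contigs = read_fasta(path)
    if len(contigs) == 1:
        genome = contigs[0]
        genome.contig_starts = [0]  # type: ignore[attr-defined]
        return genome
    seq = "".join(c.sequence for c in contigs)
    genome = GenomeRecord(id=contigs[0].id, sequence=seq)
    starts, pos = [], 0
    for c in contigs:
        starts.append(pos)
        pos += c.length
    genome.contig_starts = starts  # type: ignore[attr-defined]
    return genome


def read_proteins(path: str | os.PathLike, genome_id: str) -> list[ProteinRecord]:
    recs = read_fasta(path)
    return [ProteinRecord(id=r.id, genome_id=genome_id, sequence=r.sequence) for r in recs]


def write_fasta(records: Iterable[GenomeRecord | ProteinRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(seq_records)


def fmt(x: float) -> str:
    """Format a float with 6 significant digits (deterministic output)."""
    if x != x:  # NaN
        return "NA"
    return f"{x:.6g}"


def write_matrix_tsv(path: str | os.PathLike, ids: Sequence[str], matrix, header_lines: Sequence[str] = ()) -> None:
    """Write a square labelled matrix as TSV with ids as header row/column."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, gid in enumerate(ids):
            row = "\t".join(fmt(float(v)) for v in matrix[i])
            fh.write(f"{gid}\t{row}\n")
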