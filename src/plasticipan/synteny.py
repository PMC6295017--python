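"""Locally collinear blocks and the block-order synteny score.

A pair of genomes is compared through the homologous blocks (LCBs) they
share, e.g. the rows of a Mauve ``.backbone`` file.  Blocks shorter than a
minimum length in the reference genome are discarded; the survivors are
ordered along genome 0 and ranked by their position in genome 1.  A block is
*syntenic* when its rank is consecutive (offset 1) with its neighbour's, and
the score is the fraction of genome 0 covered by syntenic blocks:

    synteny = 100 * sum(l_i for syntenic blocks i) / L0

The score is asymmetric: the denominator and the block lengths are taken
from the first genome of the ordered pair.

Conventions for block coordinates follow Mauve backbone files: 1-based
inclusive intervals, negative coordinates mean the reverse strand, and
``(0, 0)`` means the block is absent from that genome.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class CollinearBlock:
    """A homologous block with a signed 1-based interval per genome.

    ``intervals[genome_id] = (start, end)`` with ``|start| <= |end|``; a
    negative sign on both coordinates marks the reverse strand.  Genomes
    without the block are simply missing from the mapping.
    """

    block_id: str
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)

    def present_in(self, genome_id: str) -> bool:
        iv = self.intervals.get(genome_id)
        return iv is not None and iv != (0, 0)

    def length_in(self, genome_id: str) -> int:
        s, e = self.intervals[genome_id]
        return abs(e) - abs(s) + 1

    def start_in(self, genome_id: str) -> int:
        return abs(self.intervals[genome_id][0])

    def strand_in(self, genome_id: str) -> int:
        return -1 if self.intervals[genome_id][0] < 0 else 1


@dataclass
class BackboneTable:
    """An ordered genome list plus the collinear blocks relating them."""

    genome_ids: list[str]
    blocks: list[CollinearBlock]

    def for_pair(self, g0: str, g1: str) -> list[CollinearBlock]:
        return [b for b in self.blocks if b.present_in(g0) and b.present_in(g1)]


@dataclass
class SyntenyScore:
    genome0_id: str
    genome1_id: str
    L0: int
    n_blocks: int
    syntenic_length: int
    score: float  # percent of genome 0 in syntenic blocks


def read_backbone(path: str | os.PathLike, genome_ids: Sequence[str] | None = None) -> BackboneTable:
    """Parse a Mauve ``.backbone`` file (or the generic block-table dialect).

    The Mauve dialect has a header ``seq0_leftend seq0_rightend seq1_leftend
    ...`` and one row per block with signed coordinates, ``0 0`` marking
    absence.  The generic dialect written by :func:`write_block_table` adds a
    leading ``block_id`` column and ``#`` comment lines.  ``genome_ids``
    overrides the default names ``seq0, seq1, ...``.
    """
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: empty backbone file")

    has_id = header[0] == "block_id"
    coord_cols = header[1:] if has_id else header
    if len(coord_cols) % 2 != 0 or not coord_cols:
        raise ValueError(f"{path}: odd coordinate column count in header ({len(coord_cols)})")
    n_genomes = len(coord_cols) // 2
    for i in range(n_genomes):
        expected = (f"seq{i}_leftend", f"seq{i}_rightend")
        got = (coord_cols[2 * i], coord_cols[2 * i + 1])
        if got != expected:
            raise ValueError(f"{path}: malformed header, expected {expected}, got {got}")
    if genome_ids is None:
        genome_ids = [f"seq{i}" for i in range(n_genomes)]
    elif len(genome_ids) != n_genomes:
        raise ValueError(f"{path}: {len(genome_ids)} genome ids given for {n_genomes} genomes")

    blocks = []
    for row_idx, (lineno, fields) in enumerate(rows):
        vals = fields[1:] if has_id else fields
        if len(vals) != 2 * n_genomes:
            raise ValueError(f"{path}:{lineno}: expected {2 * n_genomes} coordinates, got {len(vals)}")
        try:
            coords = [int(v) for v in vals]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate: {exc}") from exc
        block_id = fields[0] if has_id else f"block{row_idx}"
        block = CollinearBlock(block_id=block_id)
        for i, gid in enumerate(genome_ids):
            s, e = coords[2 * i], coords[2 * i + 1]
            if (s, e) == (0, 0):
                continue
            if abs(e) < abs(s):
                s, e = e, s
            block.intervals[gid] = (s, e)
        blocks.append(block)
    return BackboneTable(genome_ids=list(genome_ids), blocks=blocks)


def write_block_table(table: BackboneTable, path: str | os.PathLike, comments: Sequence[str] = ()) -> None:
    """Write the generic block-table dialect (Mauve columns + block_id)."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        cols = ["block_id"]
        for i in range(len(table.genome_ids)):
            cols += [f"seq{i}_leftend", f"seq{i}_rightend"]
        fh.write("\t".join(cols) + "\n")
        for b in table.blocks:
            row = [b.block_id]
            for gid in table.genome_ids:
                s, e = b.intervals.get(gid, (0, 0))
                row += [str(s), str(e)]
            fh.write("\t".join(row) + "\n")


def pair_blocks(table: BackboneTable, g0: str, g1: str, min_length: int = 1000) -> list[tuple[CollinearBlock, int]]:
    """Blocks shared by ``g0``/``g1``, ordered along g0, with g1 ranks.

    A block survives the filter when its length in g0 is strictly greater
    than ``min_length``.  The returned rank ``i_k`` (1-based) is the block's
    position in g1 by absolute start coordinate among the survivors.
    """
    if g0 == g1:
        raise ValueError("pair_blocks requires two distinct genomes")
    for g in (g0, g1):
        if g not in table.genome_ids:
            raise ValueError(f"genome {g!r} not present in backbone table")
    shared = [b for b in table.for_pair(g0, g1) if b.length_in(g0) > min_length]
    shared.sort(key=lambda b: b.start_in(g0))
    # rank in g1 by absolute start; ties (invalid input) broken by end coordinate
    by_g1 = sorted(shared, key=lambda b: (b.start_in(g1), abs(b.intervals[g1][1])))
    starts = [b.start_in(g1) for b in by_g1]
    if len(set(starts)) < len(starts):
        log.warning("tied g1 start coordinates between blocks of pair (%s, %s); ties broken by end", g0, g1)
    rank = {id(b): k + 1 for k, b in enumerate(by_g1)}
    return [(b, rank[id(b)]) for b in shared]


def syntenic_flags(ranks: Sequence[int]) -> list[bool]:
    """Which blocks of a g0-ordered rank sequence are syntenic.

    Block k (k >= 2) is syntenic iff ``|i_k - i_{k-1}| == 1``; the first
    block is syntenic iff it is adjacent to the second; a single surviving
    block counts as syntenic (so identical genomes score 100).
    """
    n = len(ranks)
    if n == 0:
        return []
    if n == 1:
        return [True]
    flags = [abs(ranks[k] - ranks[k - 1]) == 1 for k in range(1, n)]
    return [flags[0]] + flags


def synteny_score(blocks: Sequence[tuple[CollinearBlock, int]], L0: int, g0: str, g1: str) -> SyntenyScore:
    """Score a filtered, g0-ordered block list against genome length ``L0``."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    ranks = [r for _, r in blocks]
    flags = syntenic_flags(ranks)
    syntenic_bp = sum(b.length_in(g0) for (b, _), f in zip(blocks, flags) if f)
    return SyntenyScore(
        genome0_id=g0,
        genome1_id=g1,
        L0=L0,
        n_blocks=len(blocks),
        syntenic_length=syntenic_bp,
        score=100.0 * syntenic_bp / L0,
    )


def score_pair(table: BackboneTable, g0: str, g1: str, L0: int, min_length: int = 1000) -> SyntenyScore:
    return synteny_score(pair_blocks(table, g0, g1, min_length=min_length), L0, g0, g1)


@dataclass
class SyntenySummary:
    scores: list[SyntenyScore]
    mean: float
    sd: float
    sem: float


def synteny_matrix(table: BackboneTable, genome_lengths: Mapping[str, int], min_length: int = 1000) -> SyntenySummary:
    """Score every ordered genome pair and summarize mean, sd and sem.

    The score is asymmetric (the denominator is the first genome's length),
    so both directions of each pair are reported and enter the summary.
    """
    ids = table.genome_ids
    if len(ids) < 2:
        raise ValueError("need at least two genomes")
    for gid in ids:
        if gid not in genome_lengths:
            raise ValueError(f"genome length missing for {gid!r}")
    scores = []
    for g0, g1 in combinations(ids, 2):
        scores.append(score_pair(table, g0, g1, genome_lengths[g0], min_length))
        scores.append(score_pair(table, g1, g0, genome_lengths[g1], min_length))
    vals = np.array([s.score for s in scores])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return SyntenySummary(scores=scores, mean=float(vals.mean()), sd=sd, sem=sd / np.sqrt(len(vals)))


def write_scores_tsv(summary: SyntenySummary, path: str | os.PathLike, header_lines: Sequence[str] = ()) -> None:
    from plasticipan.io import fmt

    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("g0\tg1\tL0\tn_blocks\tsyntenic_bp\tscore_pct\n")
        for s in summary.scores:
            fh.write(f"{s.genome0_id}\t{s.genome1_id}\t{s.L0}\t{s.n_blocks}\t{s.syntenic_length}\t{fmt(s.score)}\n")
        fh.write(f"# mean={fmt(summary.mean)} sd={fmt(summary.sd)} sem={fmt(summary.sem)}\n")


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    """k-mers occurring exactly once in ``seq`` -> their position."""
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1}


_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def find_collinear_blocks(
    genome0, genome1, min_anchor: int = 20, max_gap: int = 200, min_block: int = 0
) -> BackboneTable:
    """Anchor-based collinear block finder for alignment-free input.

    Unique exact matches of length ``min_anchor`` (both strands) are chained
    into runs on a common diagonal; runs on the same diagonal and strand
    separated by at most ``max_gap`` bp (mismatch islands) are merged.  On
    indel-free synthetic genomes whose planted blocks exceed the anchor
    length the recovered table equals the planted block map.  This is not a
    general-purpose aligner: it assumes rearrangement without insertion or
    deletion inside blocks.
    """
    s0, s1 = genome0.sequence, genome0.sequence if genome1 is genome0 else genome1.sequence
    k = min_anchor
    u0 = _unique_kmer_positions(s0, k)
    u1_f = _unique_kmer_positions(s1, k)
    s1_rc = revcomp(s1)
    u1_r = _unique_kmer_positions(s1_rc, k)

    # anchors: (pos0, pos1 on forward genome1 coords, strand)
    anchors: list[tuple[int, int, int]] = []
    L1 = len(s1)
    for km, p0 in u0.items():
        in_f = km in u1_f
        in_r = km in u1_r
        if in_f == in_r:  # absent, or ambiguous across strands
            continue
        if in_f:
            anchors.append((p0, u1_f[km], 1))
        else:
            # position of the k-mer start on the forward strand of genome1
            anchors.append((p0, L1 - u1_r[km] - k, -1))
    anchors.sort()

    # chain anchors sharing a diagonal and strand, allowing gaps <= max_gap
    chains: list[list[int]] = []  # [p0_start, p0_end, p1_start, strand]
    open_chains: dict[tuple[int, int], list[int]] = {}
    for p0, p1, strand in anchors:
        diag = p1 - p0 if strand == 1 else p1 + p0
        key = (diag, strand)
        ch = open_chains.get(key)
        if ch is not None and p0 - ch[1] <= max_gap + k:
            ch[1] = p0 + k - 1
        else:
            ch = [p0, p0 + k - 1, p1, strand]
            chains.append(ch)
            open_chains[key] = ch

    g0_id, g1_id = genome0.id, genome1.id
    blocks = []
    chains.sort(key=lambda c: c[0])
    for idx, (p0s, p0e, p1s, strand) in enumerate(chains):
        length = p0e - p0s + 1
        if length < max(min_block, k):
            continue
        b = CollinearBlock(block_id=f"lcb{idx}")
        b.intervals[g0_id] = (p0s + 1, p0e + 1)
        if strand == 1:
            b.intervals[g1_id] = (p1s + 1, p1s + length)
        else:
            # on the reverse strand the chain's first anchor (smallest p0)
            # carries the largest forward coordinate; the block's forward
            # span is [p1s - (length - k), p1s + k - 1]
            start_fwd = p1s - (length - k)
            b.intervals[g1_id] = (-(start_fwd + 1), -(start_fwd + length))
        blocks.append(b)
    return BackboneTable(genome_ids=[g0_id, g1_id], blocks=blocks)
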