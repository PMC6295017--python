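"""Synthetic genome collections with planted, fully known truth.

The generator emulates a collection of related bacterial strains derived
from a common ancestor:

* the ancestor is tiled by homologous blocks; each descendant genome
  carries the same blocks, reordered by random inversions and
  translocations (so the planted block map is the exact collinear-block
  truth for the synteny stage);
* point substitutions are applied i.i.d. per site and per genome, with no
  indels, so ancestral coordinates align exactly between genomes and
  pairwise nucleotide identity has a closed-form oracle;
* gene content consists of a core set present in every genome, an
  accessory pool present in random proper subsets, and two planted
  "genomogroups" each carrying a group-exclusive set of gene families of
  unequal size;
* proteins are random sequences shared within a family, with per-genome
  substitutions, so ortholog recovery is non-trivial but unambiguous.

Each genome draws from its own RNG stream derived from the master seed, so
enlarging the collection never perturbs already-generated genomes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from plasticipan.records import GenomeRecord, ProteinRecord
from plasticipan.synteny import BackboneTable, CollinearBlock
from plasticipan import io as pio

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass
class EvolutionConfig:
    """Parameters of the simulated collection.

    Defaults describe a small two-group collection: 10 genomes of 100 kb in
    40 blocks, 2% per-site divergence from the ancestor, 10 rearrangement
    moves per genome, 200 core families, 100 accessory families, and two
    groups of 5 genomes with 8 and 3 exclusive families respectively
    (unequal on purpose, mirroring asymmetric group-specific gene sets seen
    in real species splits).
    """

    n_genomes: int = 10
    ancestor_length: int = 100_000
    n_blocks: int = 40
    block_length_range: tuple[int, int] = (1_200, 5_000)
    substitution_rate: float = 0.02
    n_rearrangements: int = 10
    core_size: int = 200
    accessory_pool: int = 100
    group_sizes: tuple[int, int] = (5, 5)
    group_specific_counts: tuple[int, int] = (8, 3)
    # accessory families are gained/lost along lineages, so genomes of one
    # group share accessory content: each family has a "home" group where
    # carriage is common and is only sporadically found outside it
    accessory_in_prob: float = 0.9
    accessory_out_prob: float = 0.05
    paralog_families: int = 0  # core families duplicated in one random genome
    protein_length_range: tuple[int, int] = (80, 200)
    protein_substitution_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genomes, self.ancestor_length, self.n_blocks, self.n_rearrangements,
            self.core_size, self.accessory_pool, *self.group_sizes,
            *self.group_specific_counts, self.paralog_families,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if not (0.0 <= self.substitution_rate < 0.5):
            raise ValueError("substitution_rate must be in [0, 0.5)")
        if sum(self.group_sizes) != self.n_genomes:
            raise ValueError("group sizes must sum to n_genomes")
        lo, hi = self.block_length_range
        if self.n_blocks * lo > self.ancestor_length or self.n_blocks * hi < self.ancestor_length:
            raise ValueError(
                f"{self.n_blocks} blocks of {lo}-{hi} bp cannot tile {self.ancestor_length} bp"
            )
        if self.paralog_families > self.core_size:
            raise ValueError("paralog_families cannot exceed core_size")


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`evolve_collection`."""

    genome_ids: list[str]
    block_lengths: dict[str, int]
    # per genome: ordered (block_id, strand) with strand in {+1, -1}
    block_orders: dict[str, list[tuple[str, int]]]
    orthogroups: pd.DataFrame  # families x genomes, integer copy counts
    labels: dict[str, str]  # genome -> "I" | "II"
    pairwise_divergence: dict[tuple[str, str], float]
    # per-genome substituted ancestor arrays, in ancestral coordinates
    mutated: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def block_table(self) -> BackboneTable:
        """The planted block map as a backbone-style table."""
        blocks = {bid: CollinearBlock(block_id=bid) for bid in self.block_lengths}
        for gid in self.genome_ids:
            pos = 1
            for bid, strand in self.block_orders[gid]:
                length = self.block_lengths[bid]
                iv = (pos, pos + length - 1)
                blocks[bid].intervals[gid] = iv if strand == 1 else (-iv[0], -iv[1])
                pos += length
        return BackboneTable(genome_ids=list(self.genome_ids), blocks=list(blocks.values()))

    def pair_lcbs(self, g0: str, g1: str) -> BackboneTable:
        """The planted block map projected onto one genome pair.

        Orientation is re-expressed relative to ``g0`` (whose intervals come
        out positive) and maximal runs of blocks that are contiguous and
        collinear in *both* genomes are merged, since no alignment-based
        block finder can see the internal boundaries of such runs.
        """
        starts: dict[str, dict[str, int]] = {}
        for gid in (g0, g1):
            pos, d = 1, {}
            for bid, _ in self.block_orders[gid]:
                d[bid] = pos
                pos += self.block_lengths[bid]
            starts[gid] = d
        strand1 = {bid: s for bid, s in self.block_orders[g1]}
        runs: list[list[tuple[str, int]]] = []
        for bid, s0 in self.block_orders[g0]:
            rel = s0 * strand1[bid]
            if runs:
                prev_bid, prev_rel = runs[-1][-1]
                prev_end1 = starts[g1][prev_bid] + self.block_lengths[prev_bid]
                if rel == prev_rel:
                    if rel == 1 and starts[g1][bid] == prev_end1:
                        runs[-1].append((bid, rel))
                        continue
                    if rel == -1 and starts[g1][bid] + self.block_lengths[bid] == starts[g1][prev_bid]:
                        runs[-1].append((bid, rel))
                        continue
            runs.append([(bid, rel)])
        blocks = []
        for i, run in enumerate(runs):
            length = sum(self.block_lengths[b] for b, _ in run)
            s0 = starts[g0][run[0][0]]
            rel = run[0][1]
            s1 = min(starts[g1][b] for b, _ in run)
            b = CollinearBlock(block_id=f"run{i}")
            b.intervals[g0] = (s0, s0 + length - 1)
            iv1 = (s1, s1 + length - 1)
            b.intervals[g1] = iv1 if rel == 1 else (-iv1[0], -iv1[1])
            blocks.append(b)
        return BackboneTable(genome_ids=[g0, g1], blocks=blocks)

    def strict_single_copy(self) -> list[str]:
        m = self.orthogroups
        return list(m.index[(m == 1).all(axis=1)])

    def group_specific(self, label: str) -> list[str]:
        ingroup = [g for g, l in self.labels.items() if l == label]
        outgroup = [g for g, l in self.labels.items() if l != label]
        m = self.orthogroups
        mask = (m[ingroup] >= 1).all(axis=1) & (m[outgroup] == 0).all(axis=1)
        return list(m.index[mask])


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _tile_lengths(cfg: EvolutionConfig, rng: np.random.Generator) -> np.ndarray:
    """Block lengths summing exactly to the ancestor length."""
    lo, hi = cfg.block_length_range
    raw = rng.integers(lo, hi + 1, size=cfg.n_blocks).astype(float)
    lengths = np.clip(np.round(raw * cfg.ancestor_length / raw.sum()), lo, hi).astype(int)
    # settle the remainder while keeping every block inside [lo, hi]
    deficit = cfg.ancestor_length - int(lengths.sum())
    while deficit != 0:
        if deficit > 0:
            room = np.flatnonzero(lengths < hi)[: deficit]
            lengths[room] += 1
            deficit -= len(room)
        else:
            room = np.flatnonzero(lengths > lo)[: -deficit]
            lengths[room] -= 1
            deficit += len(room)
    return lengths


def invert(blocks: list[tuple[str, int]], i: int, j: int) -> list[tuple[str, int]]:
    """Invert the contiguous run ``blocks[i:j+1]`` (order and orientation)."""
    run = [(bid, -s) for bid, s in reversed(blocks[i : j + 1])]
    return blocks[:i] + run + blocks[j + 1 :]


def translocate(blocks: list[tuple[str, int]], i: int, j: int, dest: int) -> list[tuple[str, int]]:
    """Move the run ``blocks[i:j+1]`` so it starts at index ``dest`` of the remainder."""
    run = blocks[i : j + 1]
    rest = blocks[:i] + blocks[j + 1 :]
    if not 0 <= dest <= len(rest):
        raise ValueError("destination outside remaining block list")
    return rest[:dest] + run + rest[dest:]


def apply_rearrangements(
    blocks: list[tuple[str, int]], n_moves: int, seed: int | np.random.Generator
) -> list[tuple[str, int]]:
    """Apply ``n_moves`` random whole-block inversions/translocations.

    Moves never split a block, so the planted block map stays exact.  The
    multiset of block identities is preserved.
    """
    if n_moves < 0:
        raise ValueError("n_moves must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(blocks)
    n = len(out)
    if n < 2:
        return out
    for _ in range(n_moves):
        i, j = sorted(rng.integers(0, n, size=2))
        if rng.random() < 0.5:
            out = invert(out, i, j)
        else:
            dest = int(rng.integers(0, n - (j - i + 1) + 1))
            out = translocate(out, i, j, dest)
    return out


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator, alphabet_size: int) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different symbol."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, alphabet_size, size=n_hit)) % alphabet_size
    return out


def _gene_content(cfg: EvolutionConfig, genome_ids: list[str], labels: dict[str, str]) -> pd.DataFrame:
    rng = _rng(cfg.seed, 2)
    n = cfg.n_genomes
    families: list[str] = []
    rows: list[np.ndarray] = []

    for f in range(cfg.core_size):
        families.append(f"core{f:04d}")
        rows.append(np.ones(n, dtype=int))
    group_of = np.array([labels[g] for g in genome_ids])
    for f in range(cfg.accessory_pool):
        home = "I" if rng.random() < 0.5 else "II"
        p = np.where(group_of == home, cfg.accessory_in_prob, cfg.accessory_out_prob)
        row = (rng.random(n) < p).astype(int)
        if row.sum() == 0:  # keep the family in the pan-genome
            row[int(rng.integers(0, n))] = 1
        if row.sum() == n:  # accessory by construction: never universal
            row[int(rng.integers(0, n))] = 0
        families.append(f"acc{f:04d}")
        rows.append(row)
    for label, count in zip(("I", "II"), cfg.group_specific_counts):
        member_mask = np.array([labels[g] == label for g in genome_ids])
        for f in range(count):
            row = np.zeros(n, dtype=int)
            row[member_mask] = 1
            families.append(f"grp{label}_{f:03d}")
            rows.append(row)

    matrix = pd.DataFrame(np.vstack(rows) if rows else np.zeros((0, n), int),
                          index=families, columns=genome_ids)
    # duplicate the first paralog_families core families in one random genome each
    for f in range(cfg.paralog_families):
        g = genome_ids[int(rng.integers(0, n))]
        matrix.loc[f"core{f:04d}", g] = 2
    return matrix


def _make_proteins(cfg: EvolutionConfig, matrix: pd.DataFrame) -> dict[str, list[ProteinRecord]]:
    fam_rng = _rng(cfg.seed, 3)
    lo, hi = cfg.protein_length_range
    ancestral: dict[str, np.ndarray] = {}
    for fam in matrix.index:
        length = int(fam_rng.integers(lo, hi + 1))
        ancestral[fam] = fam_rng.integers(0, len(_AA), size=length).astype(np.uint8)

    proteins: dict[str, list[ProteinRecord]] = {}
    for gi, gid in enumerate(matrix.columns):
        rng = _rng(cfg.seed, 4, gi)
        recs = []
        for fam, count in matrix[gid].items():
            for c in range(int(count)):
                mutated = _mutate(ancestral[fam], cfg.protein_substitution_rate, rng, len(_AA))
                seq = _AA[mutated].tobytes().decode()
                recs.append(ProteinRecord(id=f"{gid}|{fam}_{c}", genome_id=gid, sequence=seq))
        proteins[gid] = recs
    return proteins


def evolve_collection(
    cfg: EvolutionConfig,
) -> tuple[list[GenomeRecord], dict[str, list[ProteinRecord]], SyntheticTruth]:
    """Simulate the collection; deterministic under a fixed seed."""
    genome_ids = [f"g{i:02d}" for i in range(cfg.n_genomes)]
    labels = {
        gid: ("I" if i < cfg.group_sizes[0] else "II") for i, gid in enumerate(genome_ids)
    }

    anc_rng = _rng(cfg.seed, 0)
    lengths = _tile_lengths(cfg, anc_rng)
    ancestor = anc_rng.integers(0, 4, size=cfg.ancestor_length).astype(np.uint8)
    block_ids = [f"b{i:03d}" for i in range(cfg.n_blocks)]
    block_lengths = dict(zip(block_ids, (int(x) for x in lengths)))
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    anc_slices = {bid: (int(s), int(s + l)) for bid, s, l in zip(block_ids, starts, lengths)}
    anc_order = [(bid, 1) for bid in block_ids]

    genomes: list[GenomeRecord] = []
    block_orders: dict[str, list[tuple[str, int]]] = {}
    mutated: dict[str, np.ndarray] = {}
    for gi, gid in enumerate(genome_ids):
        rng = _rng(cfg.seed, 1, gi)
        mut = _mutate(ancestor, cfg.substitution_rate, rng, 4)
        order = apply_rearrangements(anc_order, cfg.n_rearrangements, rng)
        parts = []
        for bid, strand in order:
            s, e = anc_slices[bid]
            piece = mut[s:e]
            if strand == -1:
                piece = (3 - piece)[::-1]  # reverse complement in 2-bit coding
            parts.append(piece)
        seq = _NUC[np.concatenate(parts)].tobytes().decode()
        genomes.append(GenomeRecord(id=gid, sequence=seq))
        block_orders[gid] = order
        mutated[gid] = mut

    divergence = {
        (a, b): float(np.mean(mutated[a] != mutated[b]))
        for a, b in combinations(genome_ids, 2)
    }

    matrix = _gene_content(cfg, genome_ids, labels)
    proteins = _make_proteins(cfg, matrix)

    truth = SyntheticTruth(
        genome_ids=genome_ids,
        block_lengths=block_lengths,
        block_orders=block_orders,
        orthogroups=matrix,
        labels=labels,
        pairwise_divergence=divergence,
        mutated=mutated,
    )
    return genomes, proteins, truth


def write_collection(
    genomes: list[GenomeRecord],
    proteins: dict[str, list[ProteinRecord]],
    truth: SyntheticTruth,
    out_dir: str | os.PathLike,
) -> None:
    """Write genomes, proteins and truth tables as plain text files.

    Produces ``<id>.fna`` and ``<id>.faa`` per genome, ``labels.tsv``,
    ``orthogroups.tsv``, ``divergence.tsv`` and the planted block map
    ``blocks.tsv`` in the block-table dialect read by the synteny stage.
    """
    if not genomes:
        raise ValueError("refusing to write an empty collection")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        for g in genomes:
            pio.write_fasta([g], out / f"{g.id}.fna")
            pio.write_fasta(proteins.get(g.id, []), out / f"{g.id}.faa")
        with open(out / "labels.tsv", "w") as fh:
            fh.write("genome\tlabel\n")
            for gid in truth.genome_ids:
                fh.write(f"{gid}\t{truth.labels[gid]}\n")
        truth.orthogroups.to_csv(out / "orthogroups.tsv", sep="\t", index_label="group_id")
        with open(out / "divergence.tsv", "w") as fh:
            fh.write("genome_a\tgenome_b\tdivergence\n")
            for (a, b), d in truth.pairwise_divergence.items():
                fh.write(f"{a}\t{b}\t{pio.fmt(d)}\n")
        from plasticipan.synteny import write_block_table

        write_block_table(truth.block_table(), out / "blocks.tsv",
                          comments=[f"genomes: {','.join(truth.genome_ids)}"])
    except OSError as exc:
        raise OSError(f"failed writing collection to {out}: {exc}") from exc
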