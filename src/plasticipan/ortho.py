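"""Ortholog graph construction, Markov clustering and pan-genome structure.

Pairwise protein similarities (reciprocal BLASTP-style hits at E <= 1e-5)
are turned into a weighted undirected graph: inter-genome edges require
reciprocity; intra-genome edges are kept only for proteins that also have
inter-genome orthologs or that hit each other better than anything in
another genome (recent paralogs).  Edge weights are mean -log10(E) capped
at 200, then normalized by the incident nodes' average weight — a
simplification of OrthoMCL's inter-species rescaling that preserves
presence/absence structure.  Markov clustering (inflation 1.5 by default)
partitions the graph into orthogroups; unconnected proteins become
singletons.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from plasticipan.records import ProteinRecord

log = logging.getLogger(__name__)

EVALUE_THRESHOLD = 1e-5
WEIGHT_CAP = 200.0

BLAST_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
              "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass(frozen=True)
class SimilarityEdge:
    """A directed protein hit; nodes are (genome, protein id) pairs."""

    protein_a: tuple[str, str]
    protein_b: tuple[str, str]
    evalue: float
    bitscore: float

    @property
    def weight(self) -> float:
        if self.evalue <= 0:
            return WEIGHT_CAP
        return min(WEIGHT_CAP, -np.log10(self.evalue))


@dataclass
class OrthoGroup:
    group_id: str
    members: list[tuple[str, str]]  # (genome, protein)

    def copy_counts(self, genomes: Sequence[str]) -> dict[str, int]:
        counts = dict.fromkeys(genomes, 0)
        for g, _ in self.members:
            counts[g] = counts.get(g, 0) + 1
        return counts


def _default_genome_of(protein_id: str) -> str:
    return protein_id.split("|", 1)[0]


def read_hits(path: str | os.PathLike, evalue_threshold: float = EVALUE_THRESHOLD,
              genome_of: Mapping[str, str] | None = None) -> list[SimilarityEdge]:
    """Read BLAST tabular (outfmt-6) hits, keeping E <= threshold.

    Self-hits (identical protein id) are dropped; duplicate directed pairs
    keep the best (lowest) E-value.  The owning genome of each protein is
    taken from ``genome_of`` or parsed from ids of the form
    ``<genome>|<protein>``.
    """
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST_COLS, comment="#",
                         dtype={"qseqid": str, "sseqid": str})
    except Exception as exc:
        raise ValueError(f"cannot parse BLAST tabular file {path}: {exc}") from exc
    if df[["evalue", "bitscore"]].isna().any().any():
        bad = int(df[["evalue", "bitscore"]].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}:{bad}: malformed line (missing evalue/bitscore)")

    def genome(pid: str) -> str:
        return genome_of[pid] if genome_of is not None else _default_genome_of(pid)

    best: dict[tuple[str, str], SimilarityEdge] = {}
    for row in df.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q == s or float(row.evalue) > evalue_threshold:
            continue
        key = (q, s)
        prev = best.get(key)
        if prev is None or float(row.evalue) < prev.evalue:
            best[key] = SimilarityEdge(
                protein_a=(genome(q), q), protein_b=(genome(s), s),
                evalue=float(row.evalue), bitscore=float(row.bitscore),
            )
    return list(best.values())


def build_graph(edges: Iterable[SimilarityEdge],
                proteins: Iterable[tuple[str, str]] | None = None) -> nx.Graph:
    """Reciprocal ortholog graph with normalized weights.

    ``proteins`` optionally lists every (genome, protein) so that proteins
    without any retained edge still appear as isolated nodes (future
    singletons).
    """
    directed: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for e in edges:
        key = (e.protein_a, e.protein_b)
        directed[key] = max(directed.get(key, 0.0), e.weight)

    raw: dict[tuple, float] = {}
    inter_partner: set[tuple[str, str]] = set()
    best_inter: dict[tuple[str, str], float] = {}
    for (a, b), w_ab in directed.items():
        if a[0] != b[0]:
            best_inter[a] = max(best_inter.get(a, 0.0), w_ab)
        w_ba = directed.get((b, a))
        if w_ba is None or a >= b:
            continue
        weight = 0.5 * (w_ab + w_ba)
        raw[(a, b)] = weight
        if a[0] != b[0]:
            inter_partner.add(a)
            inter_partner.add(b)

    g = nx.Graph()
    if proteins is not None:
        g.add_nodes_from(proteins)
    for (a, b), w in raw.items():
        if a[0] == b[0]:
            both_orthologed = a in inter_partner and b in inter_partner
            recent_paralogs = w > best_inter.get(a, 0.0) and w > best_inter.get(b, 0.0)
            if not (both_orthologed or recent_paralogs):
                continue
        g.add_edge(a, b, weight=w)

    # per-node average-weight normalization
    avg = {
        n: (sum(d["weight"] for d in g[n].values()) / deg if deg else 1.0)
        for n, deg in g.degree()
    }
    for a, b, d in g.edges(data=True):
        d["weight"] = d["weight"] / (0.5 * (avg[a] + avg[b]))
    return g


def mcl(graph: nx.Graph, inflation: float = 1.5, max_iter: int = 100,
        tol: float = 1e-6, prune_threshold: float = 1e-5) -> list[OrthoGroup]:
    """Markov clustering of the weighted ortholog graph.

    The column-stochastic adjacency (with unit self-loops) is iterated
    through expansion (matrix square) and inflation (entrywise power then
    column renormalization), pruning entries below ``prune_threshold``,
    until the maximum entry change falls below ``tol``.  Clusters are the
    connected components of the limit matrix; isolated nodes come out as
    singletons.  The procedure involves no randomness.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return []
    idx = {node: i for i, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for a, b, d in graph.edges(data=True):
        i, j = idx[a], idx[b]
        rows += [i, j]
        cols += [j, i]
        vals += [d["weight"], d["weight"]]
    M = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=float)
    M = M + sparse.identity(n, format="csr")

    def normalize(m: sparse.csr_matrix) -> sparse.csr_matrix:
        colsum = np.asarray(m.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return (m @ sparse.diags(1.0 / colsum)).tocsr()

    M = normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M.copy()
        M = M @ M
        M = M.power(inflation)
        M.data[M.data < prune_threshold] = 0.0
        M.eliminate_zeros()
        M = normalize(M)
        delta = abs(M - prev)
        if delta.nnz == 0 or delta.max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations; "
                      "returning the current interpretation")

    n_comp, labels = sparse.csgraph.connected_components(M + M.T, directed=False)
    clusters: dict[int, list] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), []).append(node)
    # deterministic group ids: order clusters by size desc, then first member
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), ms[0]))
    return [OrthoGroup(group_id=f"og{i:05d}", members=ms) for i, ms in enumerate(ordered)]


def cluster_proteins(edges: Iterable[SimilarityEdge],
                     proteins: Iterable[tuple[str, str]],
                     inflation: float = 1.5) -> list[OrthoGroup]:
    """Convenience wrapper: graph construction followed by MCL."""
    return mcl(build_graph(edges, proteins=proteins), inflation=inflation)


def to_matrix(groups: Sequence[OrthoGroup], genomes: Sequence[str]) -> pd.DataFrame:
    """Orthogroup x genome copy-count matrix (singletons included)."""
    data = {g.group_id: g.copy_counts(genomes) for g in groups}
    m = pd.DataFrame.from_dict(data, orient="index", dtype=int)
    if m.empty:
        return pd.DataFrame(index=pd.Index([], name="group_id"), columns=genomes, dtype=int)
    return m.reindex(columns=genomes, fill_value=0)


@dataclass
class PanPartition:
    core: list[str]
    accessory: list[str]
    single_copy_core: list[str]
    # per-genome counts of member genes (not groups), which differ from the
    # group counts when paralogs are present
    core_genes_per_genome: dict[str, int]
    accessory_genes_per_genome: dict[str, int]


def core_accessory(matrix: pd.DataFrame) -> PanPartition:
    """Split orthogroups into core (present in every genome) and accessory."""
    if matrix.shape[1] < 1:
        raise ValueError("matrix has no genomes")
    core_mask = (matrix >= 1).all(axis=1)
    single_mask = (matrix == 1).all(axis=1)
    core = list(matrix.index[core_mask])
    return PanPartition(
        core=core,
        accessory=list(matrix.index[~core_mask]),
        single_copy_core=list(matrix.index[single_mask]),
        core_genes_per_genome=matrix.loc[core_mask].sum(axis=0).astype(int).to_dict(),
        accessory_genes_per_genome=matrix.loc[~core_mask].sum(axis=0).astype(int).to_dict(),
    )


def select_phylo_markers(matrix: pd.DataFrame) -> list[str]:
    """Orthogroups with exactly one member in every genome and no paralogs.

    The strict single-copy contract of the core set, exposed separately
    because marker selection is typically run on a wider taxon set to feed
    concatenated-alignment phylogenetics.
    """
    return list(matrix.index[(matrix == 1).all(axis=1)])


@dataclass
class AccumulationCurve:
    k: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k, "core_mean": self.core_mean, "core_sd": self.core_sd,
            "pan_mean": self.pan_mean, "pan_sd": self.pan_sd,
        })


def accumulation(matrix: pd.DataFrame, n_permutations: int = 100,
                 seed: int = 0) -> AccumulationCurve:
    """Core- and pan-genome accumulation curves over random genome orderings.

    For each permutation of genome order, core(k) counts groups present in
    all of the first k genomes and pan(k) groups present in any of them.
    When the number of distinct orderings does not exceed ``n_permutations``
    every ordering is enumerated exactly once instead of sampled, so small
    collections get the exact permutation average.
    """
    import math
    from itertools import permutations as iter_permutations

    n = matrix.shape[1]
    if n < 2:
        raise ValueError("need at least two genomes")
    present = (matrix.values >= 1)
    if math.factorial(n) <= n_permutations:
        orders = [np.array(p) for p in iter_permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_permutations)]
    n_permutations = len(orders)
    cores = np.empty((n_permutations, n), dtype=int)
    pans = np.empty((n_permutations, n), dtype=int)
    for p, order in enumerate(orders):
        cum_core = np.ones(present.shape[0], dtype=bool)
        cum_pan = np.zeros(present.shape[0], dtype=bool)
        for ki, gi in enumerate(order):
            cum_core &= present[:, gi]
            cum_pan |= present[:, gi]
            cores[p, ki] = cum_core.sum()
            pans[p, ki] = cum_pan.sum()
    return AccumulationCurve(
        k=np.arange(1, n + 1),
        core_mean=cores.mean(axis=0), core_sd=cores.std(axis=0, ddof=1),
        pan_mean=pans.mean(axis=0), pan_sd=pans.std(axis=0, ddof=1),
        n_permutations=n_permutations,
    )


class KmerProteinSearch:
    """All-vs-all protein hit generator for alignment-free synthetic tests.

    Candidate pairs share at least ``min_shared`` exact k-mers (inverted
    index); each candidate pair is scored by ungapped identity (the
    synthetic families are indel-free) and emitted as a symmetric pair of
    directed hits with an identity-derived E-value.  Real analyses should
    use external BLASTP/DIAMOND tabular output instead.
    """

    def __init__(self, k: int = 4, min_shared: int = 3, min_identity: float = 0.5):
        self.k = k
        self.min_shared = min_shared
        self.min_identity = min_identity

    def __call__(self, proteins: Sequence[ProteinRecord]) -> list[SimilarityEdge]:
        index: dict[str, list[int]] = {}
        for i, p in enumerate(proteins):
            for j in range(0, len(p.sequence) - self.k + 1, self.k):
                index.setdefault(p.sequence[j : j + self.k], []).append(i)
        shared: dict[tuple[int, int], int] = {}
        for hits in index.values():
            if len(hits) < 2 or len(hits) > 50:
                continue
            for a, b in combinations(sorted(set(hits)), 2):
                shared[(a, b)] = shared.get((a, b), 0) + 1
        edges = []
        for (ia, ib), count in shared.items():
            if count < self.min_shared:
                continue
            a, b = proteins[ia], proteins[ib]
            if len(a.sequence) != len(b.sequence):
                continue
            sa = np.frombuffer(a.sequence.encode(), dtype=np.uint8)
            sb = np.frombuffer(b.sequence.encode(), dtype=np.uint8)
            matches = int((sa == sb).sum())
            ident = matches / len(sa)
            if ident < self.min_identity:
                continue
            evalue = 10.0 ** (-min(WEIGHT_CAP, 0.5 * matches))
            for x, y in ((a, b), (b, a)):
                edges.append(SimilarityEdge(
                    protein_a=(x.genome_id, x.id), protein_b=(y.genome_id, y.id),
                    evalue=evalue, bitscore=float(matches),
                ))
        return edges


def write_membership_tsv(groups: Sequence[OrthoGroup], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgenome\tprotein_id\n")
        for g in groups:
            for genome, pid in g.members:
                fh.write(f"{g.group_id}\t{genome}\t{pid}\n")
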