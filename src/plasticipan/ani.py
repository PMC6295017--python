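"""Fragment-based reciprocal average nucleotide identity (ANIb).

The query genome is cut into consecutive non-overlapping fragments
(1020 bp by default, the standard ANIb choice) and each fragment's best
local alignment against the subject genome is collected.  Fragments whose
best hit has identity > 30% and covers > 70% of the fragment contribute
their identity to the ANI mean and their aligned length to the coverage;
fragments without a qualifying hit contribute to neither.

The alignment provider is pluggable: :class:`KmerAligner` is a
k-mer-seeded, ungapped local aligner that is exact on indel-free synthetic
genomes; :class:`BlastTabAligner` ingests externally produced BLASTN
tabular output (outfmt 6) for real genomes, where published ANIb values
come from.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from plasticipan.records import GenomeRecord
from plasticipan.synteny import revcomp

log = logging.getLogger(__name__)

DEFAULT_FRAGMENT = 1020
MIN_IDENTITY_PCT = 30.0
MIN_FRAGMENT_COVERAGE = 0.70


@dataclass
class Fragment:
    index: int
    start: int  # 0-based offset in the query genome
    sequence: str


@dataclass
class FragmentHit:
    """Best local alignment of one fragment against the subject."""

    fragment_index: int
    identity: float  # percent
    aligned_length: int


@dataclass
class ANIResult:
    query_id: str
    subject_id: str
    ani: float | None  # percent; None when no fragment qualifies
    coverage: float  # percent of query length aligned by counted fragments
    n_fragments: int
    n_counted: int


@dataclass
class ANIMatrix:
    genome_ids: list[str]
    ani: np.ndarray  # directed, percent; NaN = missing
    coverage: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ids = self.genome_ids
        return (
            pd.DataFrame(self.ani, index=ids, columns=ids),
            pd.DataFrame(self.coverage, index=ids, columns=ids),
        )


def fragment_genome(genome: GenomeRecord, fragment_length: int = DEFAULT_FRAGMENT) -> list[Fragment]:
    """Cut the genome into consecutive fragments; the final short one is kept.

    If the genome is a concatenated draft with recorded ``contig_starts``,
    fragments spanning a contig boundary are dropped.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    seq = genome.sequence
    if not seq:
        raise ValueError(f"genome {genome.id!r} is empty")
    boundaries = set(getattr(genome, "contig_starts", [])[1:])
    fragments = []
    for idx, start in enumerate(range(0, len(seq), fragment_length)):
        end = min(start + fragment_length, len(seq))
        if any(start < b < end for b in boundaries):
            continue
        fragments.append(Fragment(index=idx, start=start, sequence=seq[start:end]))
    return fragments


class Aligner(Protocol):
    """Best-local-hit provider: fragments vs one subject genome."""

    def __call__(self, fragments: Sequence[Fragment], subject: GenomeRecord) -> list[FragmentHit]:
        ...


class KmerAligner:
    """Ungapped local aligner seeded by exact k-mer matches.

    For each fragment, seed k-mers are looked up in an index of the subject
    (both strands); each seed fixes a diagonal, along which the fragment is
    compared base-by-base and the maximal-scoring ungapped segment
    (match +1, mismatch -2) is taken as the local alignment.  Exact for
    substitution-only divergence; not suitable for indel-rich genomes.
    """

    def __init__(self, k: int = 16, seed_stride: int = 8, mismatch_penalty: int = 2):
        self.k = k
        self.seed_stride = seed_stride
        self.mismatch_penalty = mismatch_penalty
        self._index_cache: dict[int, dict[str, list[int]]] = {}

    def _index(self, subject: GenomeRecord) -> dict[str, list[int]]:
        key = id(subject)
        if key not in self._index_cache:
            idx: dict[str, list[int]] = {}
            seq = subject.sequence
            for i in range(len(seq) - self.k + 1):
                idx.setdefault(seq[i : i + self.k], []).append(i)
            self._index_cache = {key: idx}  # keep only the latest subject
        return self._index_cache[key]

    def _best_on_diagonal(self, frag: str, subject: str, offset: int) -> tuple[float, int] | None:
        """Best ungapped segment aligning frag[i] to subject[i + offset]."""
        lo = max(0, -offset)
        hi = min(len(frag), len(subject) - offset)
        if hi - lo < self.k:
            return None
        f = np.frombuffer(frag[lo:hi].encode(), dtype=np.uint8)
        s = np.frombuffer(subject[lo + offset : hi + offset].encode(), dtype=np.uint8)
        match = f == s
        score = np.where(match, 1, -self.mismatch_penalty)
        # maximal-scoring contiguous segment (Kadane)
        best, cur, start, best_span = -1, 0, 0, (0, 0)
        for i, v in enumerate(score):
            if cur <= 0:
                cur, start = int(v), i
            else:
                cur += int(v)
            if cur > best:
                best, best_span = cur, (start, i + 1)
        a, b = best_span
        seg_len = b - a
        if seg_len == 0:
            return None
        ident = 100.0 * float(match[a:b].sum()) / seg_len
        return ident, seg_len

    def __call__(self, fragments: Sequence[Fragment], subject: GenomeRecord) -> list[FragmentHit]:
        index = self._index(subject)
        sub_f = subject.sequence
        sub_r = revcomp(sub_f)
        hits = []
        for frag in fragments:
            seen_offsets: set[tuple[int, int]] = set()
            best: tuple[float, int] | None = None
            for i in range(0, len(frag.sequence) - self.k + 1, self.seed_stride):
                kmer = frag.sequence[i : i + self.k]
                for pos in index.get(kmer, ())[:4]:
                    key = (1, pos - i)
                    if key in seen_offsets:
                        continue
                    seen_offsets.add(key)
                    res = self._best_on_diagonal(frag.sequence, sub_f, pos - i)
                    if res and (best is None or res[0] * res[1] > best[0] * best[1]):
                        best = res
                for pos in index.get(revcomp(kmer), ())[:4]:
                    # k-mer at frag offset i matches reverse strand; on the
                    # reverse-complemented subject it sits at rc position
                    rc_pos = len(sub_f) - pos - self.k
                    key = (-1, rc_pos - i)
                    if key in seen_offsets:
                        continue
                    seen_offsets.add(key)
                    res = self._best_on_diagonal(frag.sequence, sub_r, rc_pos - i)
                    if res and (best is None or res[0] * res[1] > best[0] * best[1]):
                        best = res
            if best is not None:
                hits.append(FragmentHit(fragment_index=frag.index, identity=best[0], aligned_length=best[1]))
        return hits


class BlastTabAligner:
    """Adapter turning BLASTN outfmt-6 rows into per-fragment best hits.

    Expects fragment query ids of the form ``<genome>|frag<index>`` (as
    written by :func:`write_fragment_fasta`) and one tabular file per
    genome pair, provided through ``path_for(query_id, subject_id)``.
    """

    COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

    def __init__(self, query_id: str, path_for: Callable[[str, str], str | os.PathLike]):
        self.query_id = query_id
        self.path_for = path_for

    def __call__(self, fragments: Sequence[Fragment], subject: GenomeRecord) -> list[FragmentHit]:
        path = self.path_for(self.query_id, subject.id)
        df = pd.read_csv(path, sep="\t", names=self.COLS, comment="#")
        best: dict[int, FragmentHit] = {}
        for row in df.itertuples(index=False):
            try:
                frag_idx = int(str(row.qseqid).rsplit("|frag", 1)[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: cannot parse fragment index from {row.qseqid!r}") from exc
            score = (row.bitscore, row.pident)
            prev = best.get(frag_idx)
            if prev is None or score > (getattr(prev, "_score", (-1, -1))):
                hit = FragmentHit(fragment_index=frag_idx, identity=float(row.pident),
                                  aligned_length=int(row.length))
                hit._score = score  # type: ignore[attr-defined]
                best[frag_idx] = hit
        return list(best.values())


def write_fragment_fasta(genome: GenomeRecord, path: str | os.PathLike,
                         fragment_length: int = DEFAULT_FRAGMENT) -> None:
    """Write fragments as FASTA with ids ``<genome>|frag<i>`` for BLASTN runs."""
    from plasticipan.io import write_fasta

    frags = fragment_genome(genome, fragment_length)
    write_fasta(
        [GenomeRecord(id=f"{genome.id}|frag{f.index}", sequence=f.sequence) for f in frags],
        path,
    )


def anib_pair(query: GenomeRecord, fragments: Sequence[Fragment],
              hits: Sequence[FragmentHit], subject_id: str) -> ANIResult:
    """Combine per-fragment best hits into one directed ANI value."""
    frag_len = {f.index: len(f.sequence) for f in fragments}
    counted = [
        h for h in hits
        if h.identity > MIN_IDENTITY_PCT
        and h.aligned_length > MIN_FRAGMENT_COVERAGE * frag_len[h.fragment_index]
    ]
    if not counted:
        warnings.warn(f"no qualifying fragment for {query.id} vs {subject_id}; ANI undefined")
        return ANIResult(query.id, subject_id, None, 0.0, len(fragments), 0)
    ani = float(np.mean([h.identity for h in counted]))
    coverage = 100.0 * sum(h.aligned_length for h in counted) / query.length
    return ANIResult(query.id, subject_id, ani, min(coverage, 100.0), len(fragments), len(counted))


def ani_pair(query: GenomeRecord, subject: GenomeRecord, aligner: Aligner | None = None,
             fragment_length: int = DEFAULT_FRAGMENT) -> ANIResult:
    aligner = aligner or KmerAligner()
    fragments = fragment_genome(query, fragment_length)
    hits = aligner(fragments, subject)
    return anib_pair(query, fragments, hits, subject.id)


def ani_matrix(genomes: Sequence[GenomeRecord], aligner: Aligner | None = None,
               aligner_factory: Callable[[str], Aligner] | None = None,
               fragment_length: int = DEFAULT_FRAGMENT) -> ANIMatrix:
    """All ordered-pair ANIb values.

    ``aligner_factory(query_id)`` supports per-query providers (needed by the
    BLAST adapter); otherwise one shared ``aligner`` is used.  A failing pair
    is flagged missing (NaN) and the run continues.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.id for g in genomes]
    n = len(ids)
    ani = np.full((n, n), np.nan)
    cov = np.zeros((n, n))
    np.fill_diagonal(ani, 100.0)
    np.fill_diagonal(cov, 100.0)
    for qi, q in enumerate(genomes):
        prov = aligner_factory(q.id) if aligner_factory else (aligner or KmerAligner())
        fragments = fragment_genome(q, fragment_length)
        for si, s in enumerate(genomes):
            if qi == si:
                continue
            try:
                hits = prov(fragments, s)
                res = anib_pair(q, fragments, hits, s.id)
            except Exception as exc:  # pair-level failure must not kill the run
                log.error("ANI pair (%s, %s) failed: %s", q.id, s.id, exc)
                continue
            if res.ani is not None:
                ani[qi, si] = res.ani
            cov[qi, si] = res.coverage
    return ANIMatrix(genome_ids=ids, ani=ani, coverage=cov)


@dataclass
class ANISummary:
    median_ani: float
    median_coverage: float
    median_ani_pair_averaged: float
    components: list[list[str]]
    n_missing: int


def summarize_ani(matrix: ANIMatrix, species_cutoff: float = 95.0) -> ANISummary:
    """Medians over directed off-diagonal entries and components at a cutoff.

    Two genomes fall in one component when *both* directed ANI values reach
    the cutoff (the conventional species boundary is 95%).  The median of
    per-pair direction-averaged values is reported alongside the default
    directed-entry median.
    """
    a = matrix.ani
    n = len(matrix.genome_ids)
    off = ~np.eye(n, dtype=bool)
    vals = a[off]
    missing = int(np.isnan(vals).sum())
    pair_avg = []
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if not (np.isnan(a[i, j]) or np.isnan(a[j, i])):
                pair_avg.append(0.5 * (a[i, j] + a[j, i]))
                if a[i, j] >= species_cutoff and a[j, i] >= species_cutoff:
                    adj[i, j] = adj[j, i] = True
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    components = [[matrix.genome_ids[i] for i in range(n) if comp[i] == c] for c in range(n_comp)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = float(np.nanmedian(vals)) if vals.size else float("nan")
        med_cov = float(np.nanmedian(matrix.coverage[off])) if vals.size else float("nan")
    return ANISummary(
        median_ani=med,
        median_coverage=med_cov,
        median_ani_pair_averaged=float(np.median(pair_avg)) if pair_avg else float("nan"),
        components=components,
        n_missing=missing,
    )


def cluster_ward(data: np.ndarray | pd.DataFrame, symmetrize: bool = False) -> np.ndarray:
    """Ward.D2 agglomerative clustering on Euclidean row distances.

    Returns a scipy linkage matrix.  With ``symmetrize=True`` (for directed
    ANI matrices) the matrix is first averaged with its transpose.
    """
    X = np.asarray(data, dtype=float)
    if symmetrize:
        X = 0.5 * (X + X.T)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in clustering input")
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    return sch.linkage(pdist(X, metric="euclidean"), method="ward")
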