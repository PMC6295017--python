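"""End-to-end pipeline: ANI -> synteny -> orthogroups -> genomogroups.

Every stage is also runnable standalone from files produced by upstream
stages; this module wires them together for a genome collection laid out
as ``<id>.fna`` / ``<id>.faa`` files plus optional block/hit tables, and
stamps every output with the tool version, a configuration hash and the
seed so reruns diff clean.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from plasticipan import __version__, io as pio
from plasticipan import ani as ani_mod
from plasticipan import groups as grp
from plasticipan import ortho
from plasticipan import synteny as syn

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genomes_dir: str
    out_dir: str
    proteins_dir: str | None = None
    hits_path: str | None = None  # BLAST tabular with all-vs-all protein hits
    backbone_path: str | None = None  # Mauve backbone or generic block table
    evalue: float = 1e-5
    min_block: int = 1000
    fragment_length: int = 1020
    ani_cutoff: float = 95.0
    inflation: float = 1.5
    alpha: float = 0.05
    n_permutations: int = 100
    gap_B: int = 50
    min_anchor: int = 20
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("evalue", "min_block", "fragment_length", "ani_cutoff",
                     "inflation", "n_permutations", "gap_B", "min_anchor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    def digest(self) -> str:
        """Hash of the analytic parameters (paths and log level excluded,
        so reruns on relocated inputs still diff clean)."""
        params = {k: v for k, v in asdict(self).items()
                  if k not in ("genomes_dir", "out_dir", "proteins_dir",
                               "hits_path", "backbone_path", "log_level")}
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"plasticipan {__version__}", f"config {self.digest()}", f"seed {self.seed}"]


@dataclass
class StageReport:
    name: str
    ok: bool
    seconds: float
    detail: str = ""


@dataclass
class PipelineReport:
    stages: list[StageReport] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s.ok for s in self.stages)

    def failed(self) -> list[str]:
        return [s.name for s in self.stages if not s.ok]


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage in dependency order; failures are reported, not raised."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()
    report = PipelineReport()

    gdir = Path(config.genomes_dir)
    fna = sorted(gdir.glob("*.fna")) + sorted(gdir.glob("*.fasta"))
    if not fna:
        raise FileNotFoundError(f"no genome FASTA files (*.fna, *.fasta) in {gdir}")
    genomes = [pio.read_genome(p) for p in fna]
    lengths = {g.id: g.length for g in genomes}

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                detail = fn() or ""
                report.stages.append(StageReport(name, True, time.monotonic() - t0, detail))
            except Exception as exc:
                log.exception("stage %s failed", name)
                report.stages.append(StageReport(name, False, time.monotonic() - t0, str(exc)))
        return wrap

    matrix_holder: dict[str, pd.DataFrame] = {}

    @stage("ani")
    def _ani():
        m = ani_mod.ani_matrix(genomes, fragment_length=config.fragment_length)
        pio.write_matrix_tsv(out / "ani.tsv", m.genome_ids, m.ani, header)
        pio.write_matrix_tsv(out / "ani_coverage.tsv", m.genome_ids, m.coverage, header)
        s = ani_mod.summarize_ani(m, species_cutoff=config.ani_cutoff)
        with open(out / "ani_summary.txt", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write(f"median_ani\t{pio.fmt(s.median_ani)}\n")
            fh.write(f"median_coverage\t{pio.fmt(s.median_coverage)}\n")
            fh.write(f"median_ani_pair_averaged\t{pio.fmt(s.median_ani_pair_averaged)}\n")
            fh.write(f"n_components\t{len(s.components)}\n")
            for i, comp in enumerate(s.components):
                fh.write(f"component_{i}\t{','.join(comp)}\n")
        return f"median ANI {s.median_ani:.2f}"

    @stage("synteny")
    def _synteny():
        if config.backbone_path:
            table = syn.read_backbone(config.backbone_path, genome_ids=[g.id for g in genomes])
        else:
            blocks = []
            for i in range(len(genomes)):
                for j in range(i + 1, len(genomes)):
                    t = syn.find_collinear_blocks(genomes[i], genomes[j],
                                                  min_anchor=config.min_anchor)
                    blocks.extend(t.blocks)
            table = syn.BackboneTable(genome_ids=[g.id for g in genomes], blocks=blocks)
        summary = syn.synteny_matrix(table, lengths, min_length=config.min_block)
        syn.write_scores_tsv(summary, out / "synteny.tsv", header)
        return f"mean synteny {summary.mean:.1f}%"

    @stage("ortho")
    def _ortho():
        if config.hits_path:
            edges = ortho.read_hits(config.hits_path, evalue_threshold=config.evalue)
            proteins = []
            if config.proteins_dir:
                for g in genomes:
                    faa = Path(config.proteins_dir) / f"{g.id}.faa"
                    proteins.extend(pio.read_proteins(faa, g.id))
        else:
            if not config.proteins_dir:
                raise FileNotFoundError("ortho stage needs --proteins or --hits")
            proteins = []
            for g in genomes:
                faa = Path(config.proteins_dir) / f"{g.id}.faa"
                proteins.extend(pio.read_proteins(faa, g.id))
            edges = ortho.KmerProteinSearch()(proteins)
        node_list = [(p.genome_id, p.id) for p in proteins]
        groups_list = ortho.cluster_proteins(edges, node_list, inflation=config.inflation)
        matrix = ortho.to_matrix(groups_list, [g.id for g in genomes])
        matrix_holder["matrix"] = matrix
        ortho.write_membership_tsv(groups_list, out / "orthogroups_members.tsv")
        matrix.to_csv(out / "ortho_matrix.tsv", sep="\t", index_label="group_id")
        part = ortho.core_accessory(matrix)
        curve = ortho.accumulation(matrix, n_permutations=config.n_permutations,
                                   seed=config.seed)
        curve.to_frame().to_csv(out / "accumulation.tsv", sep="\t", index=False,
                                float_format="%.6g")
        with open(out / "pangenome_summary.txt", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write(f"n_orthogroups\t{matrix.shape[0]}\n")
            fh.write(f"n_core\t{len(part.core)}\n")
            fh.write(f"n_single_copy_core\t{len(part.single_copy_core)}\n")
            fh.write(f"n_accessory\t{len(part.accessory)}\n")
        return f"{matrix.shape[0]} orthogroups, {len(part.core)} core"

    @stage("groups")
    def _groups():
        matrix = matrix_holder.get("matrix")
        if matrix is None:
            raise RuntimeError("ortho stage did not produce a matrix")
        ordn = grp.ordinate(matrix)
        pd.DataFrame(ordn.coordinates, index=ordn.genome_ids).to_csv(
            out / "ordination.tsv", sep="\t", float_format="%.6g")
        gap = grp.gap_statistic(matrix, B=config.gap_B, seed=config.seed)
        pd.DataFrame({"k": gap.k, "gap": gap.gap, "se": gap.se}).to_csv(
            out / "gap.tsv", sep="\t", index=False, float_format="%.6g")
        k = max(gap.optimal_k, 1)
        assignment = grp.assign_groups(matrix, max(k, 2) if k >= 2 else 1)
        with open(out / "groups.tsv", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write("genome\tlabel\n")
            for g, lab in assignment.labels.items():
                fh.write(f"{g}\t{lab}\n")
        if assignment.k == 2:
            diff = grp.differential(matrix, assignment.labels, alpha=config.alpha)
            diff.table.to_csv(out / "differential.tsv", sep="\t", index=False,
                              float_format="%.6g")
            return f"k={gap.optimal_k}, {len(diff.significant)} differential orthogroups"
        return f"k={gap.optimal_k}"

    if not report.ok:
        log.error("failed stages: %s", ", ".join(report.failed()))
    return report
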