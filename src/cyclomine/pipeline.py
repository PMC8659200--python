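"""End-to-end orchestration: mine -> physchem -> SSN -> logos/cleavage ->
tree, with deterministic outputs and a machine-readable run report.

Identical inputs and configuration produce byte-identical outputs: all
stages are deterministic and every table is written in sorted order.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from .align import AlignmentParams, SearchThresholds, align_local
from .io import (
    load_annotated_genome,
    load_cleavage_table,
    load_seed_set,
    write_edge_list,
    write_protein_fasta,
    write_results_tables,
)
from .mining import CandidateBGC, MiningParams, mine_genome
from .models import GenomeRecord, ProteinRecord, SeedSet
from .msa import align_msa, logo_matrix, transfer_cleavage, write_logo_tsv
from .phylo import distance_matrix, nj_tree, write_leaf_annotations
from .physchem import ClassifierThresholds, PkaTable, profile_peptide
from .ssn import GroupAssignment, SSNNode, assign_groups, build_ssn, dedupe_sequences

logger = logging.getLogger("cyclomine")


@dataclass
class RunConfig:
    genome_fastas: list = field(default_factory=list)      # paths; parallel to gff3s
    genome_gff3s: list = field(default_factory=list)       # entries may be None
    seed_fasta: Optional[str] = None
    seed_roles: Optional[str] = None
    cleavage_table: Optional[str] = None
    out_dir: str = "cyclomine_out"
    window_k: int = 10
    min_precursor_len: int = 25
    max_precursor_len: int = 150
    min_identity_pct: float = 30.0
    min_query_coverage: float = 0.5
    min_raw_score: float = 50.0
    ssn_identity_pct: float = 50.0
    ssn_min_score: float = 60.0
    anchor_min_identity_pct: float = 50.0
    profile_on_core: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if len(self.genome_gff3s) not in (0, len(self.genome_fastas)):
            raise ValueError("genome_gff3s must be empty or parallel to genome_fastas")
        for p in list(self.genome_fastas) + [q for q in self.genome_gff3s if q]:
            if not os.path.exists(str(p)):
                raise FileNotFoundError(p)

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams()

    def thresholds(self) -> SearchThresholds:
        return SearchThresholds(self.min_identity_pct, self.min_query_coverage,
                                self.min_raw_score)

    def mining_params(self) -> MiningParams:
        return MiningParams(self.window_k, self.min_precursor_len,
                            self.max_precursor_len)


@dataclass
class RunReport:
    genomes_scanned: int = 0
    transporter_hits: int = 0
    windows: int = 0
    passing_bgcs: int = 0
    failing_windows: int = 0
    unique_precursors: int = 0
    n_groups: int = 0
    n_singletons: int = 0
    subgroup_counts: dict = field(default_factory=dict)
    clamped_branches: int = 0

    def to_dict(self) -> dict:
        return {
            "genomes_scanned": self.genomes_scanned,
            "transporter_hits": self.transporter_hits,
            "windows": self.windows,
            "passing_bgcs": self.passing_bgcs,
            "failing_windows": self.failing_windows,
            "unique_precursors": self.unique_precursors,
            "n_groups": self.n_groups,
            "n_singletons": self.n_singletons,
            "subgroup_counts": dict(sorted(self.subgroup_counts.items())),
            "clamped_branches": self.clamped_branches,
        }


@dataclass
class PipelineResult:
    report: RunReport
    bgcs: list
    nodes: list
    groups: list
    profiles: dict      # node id -> PhyschemProfile
    cores: dict         # node id -> inferred core sequence
    cleavage: dict      # group_id -> CleavageAnnotation
    tree_newick: Optional[str] = None


def _group_anchor(members: list[SSNNode], seeds: SeedSet, cleavage_table: dict,
                  params: AlignmentParams, min_identity: float):
    """Best characterized precursor matching any group member, if any."""
    best = None
    for entry in seeds.by_role("precursor"):
        if entry.bacteriocin_name not in cleavage_table:
            continue
        for node in members:
            res = align_local(entry.record.sequence, node.sequence, params)
            if res.identity_pct >= min_identity and res.raw_score >= 60:
                if best is None or res.raw_score > best[2]:
                    best = (entry, cleavage_table[entry.bacteriocin_name], res.raw_score)
    return best


def analyze_mined_precursors(
    bgcs: list[CandidateBGC],
    seeds: SeedSet,
    config: RunConfig,
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Everything downstream of mining: dedupe, SSN, groups, cleavage
    transfer, physicochemical profiles, logos, tree."""
    params = config.alignment_params()
    cleavage_table = load_cleavage_table(config.cleavage_table)
    report = RunReport()
    passing = [b for b in bgcs if b.verdict == "pass"]
    report.windows = len(bgcs)
    report.passing_bgcs = len(passing)
    report.failing_windows = len(bgcs) - len(passing)

    records: list[ProteinRecord] = []
    seen_ids = set()
    for b in passing:
        for cand in b.precursor_candidates():
            if cand.id in seen_ids:
                continue
            seen_ids.add(cand.id)
            records.append(ProteinRecord(id=cand.id, sequence=cand.sequence,
                                         description=b.window.genome_id))
    result = PipelineResult(report=report, bgcs=bgcs, nodes=[], groups=[],
                            profiles={}, cores={}, cleavage={})
    if not records:
        return result

    nodes = dedupe_sequences(records)
    graph = build_ssn(nodes, params, config.ssn_identity_pct, config.ssn_min_score)
    groups = assign_groups(graph)
    result.nodes = nodes
    result.groups = groups
    report.unique_precursors = len(nodes)
    report.n_groups = sum(1 for g in groups if not g.is_singleton)
    report.n_singletons = sum(1 for g in groups if g.is_singleton)

    node_by_id = {n.id: n for n in nodes}
    # leader/core segmentation by cleavage transfer from characterized anchors
    for g in groups:
        members = [node_by_id[m] for m in g.members]
        anchor = _group_anchor(members, seeds, cleavage_table, params,
                               config.anchor_min_identity_pct)
        if anchor is None:
            continue
        entry, leader_len, _score = anchor
        ids = [n.id for n in members] + [entry.record.id]
        seqs = [n.sequence for n in members] + [entry.record.sequence]
        if len(seqs) < 2:
            continue
        msa = align_msa(ids, seqs, params)
        ann = transfer_cleavage(msa, entry.record.id, leader_len)
        result.cleavage[g.group_id] = ann
        for n in members:
            site = ann.transferred[n.id]
            if 0 <= site < len(n.sequence):
                result.cores[n.id] = n.sequence[site:]

    for n in nodes:
        core = result.cores.get(n.id, n.sequence) if config.profile_on_core else n.sequence
        result.cores.setdefault(n.id, core)
        prof = profile_peptide(core)
        result.profiles[n.id] = prof
        report.subgroup_counts[prof.subgroup_call] = (
            report.subgroup_counts.get(prof.subgroup_call, 0) + 1
        )
        graph.node_attrs[n.id] = {
            "group_id": next(g.group_id for g in groups if n.id in g.members),
            "subgroup": prof.subgroup_call,
            "gravy": round(prof.gravy, 4),
            "pI": round(prof.pI_cyclic, 3) if prof.pI_cyclic is not None else "NA",
        }

    tree = None
    if len(nodes) >= 3:
        dm = distance_matrix([n.id for n in nodes], [n.sequence for n in nodes], params)
        tree = nj_tree(dm)
        tree.leaf_annotations = graph.node_attrs
        result.tree_newick = tree.root.newick()
        report.clamped_branches = tree.clamped_branches

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_edge_list(graph, os.path.join(out_dir, "ssn_"))
        write_results_tables(passing, groups, result.profiles, out_dir)
        write_protein_fasta(
            [ProteinRecord(id=n.id, sequence=n.sequence) for n in nodes],
            os.path.join(out_dir, "unique_precursors.faa"),
        )
        for g in groups:
            if len(g.members) < 3:
                continue
            members = [node_by_id[m] for m in g.members]
            msa = align_msa([n.id for n in members], [n.sequence for n in members], params)
            with open(os.path.join(out_dir, f"group{g.group_id}_msa.afa"), "w") as fh:
                for sid, row in zip(msa.ids, msa.rows):
                    fh.write(f">{sid}\n{row}\n")
            write_logo_tsv(logo_matrix(msa),
                           os.path.join(out_dir, f"group{g.group_id}_logo.tsv"))
        if tree is not None:
            with open(os.path.join(out_dir, "precursors_nj.nwk"), "w") as fh:
                fh.write(result.tree_newick + "\n")
            write_leaf_annotations(tree, os.path.join(out_dir, "tree_annotations.tsv"))
    return result


def run_pipeline_on_genomes(
    genomes: list[GenomeRecord],
    seeds: SeedSet,
    config: RunConfig,
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Mine a set of in-memory genomes and run every downstream stage."""
    params = config.alignment_params()
    thresholds = config.thresholds()
    mining = config.mining_params()
    all_bgcs = []
    n_hits = 0
    for genome in genomes:
        hits, bgcs = mine_genome(genome, seeds, params, thresholds, mining)
        logger.info("genome %s: %d transporter hits, %d windows",
                    genome.genome_id, len(hits), len(bgcs))
        n_hits += len(hits)
        all_bgcs.extend(bgcs)
    result = analyze_mined_precursors(all_bgcs, seeds, config, out_dir)
    result.report.genomes_scanned = len(genomes)
    result.report.transporter_hits = n_hits
    return result


def run_pipeline(config: RunConfig) -> RunReport:
    """File-driven full run: load genomes and seeds, execute all stages,
    write every intermediate plus report.json under config.out_dir."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = load_seed_set(config.seed_fasta, config.seed_roles)
    gffs = config.genome_gff3s or [None] * len(config.genome_fastas)
    genomes = [load_annotated_genome(f, g) for f, g in zip(config.genome_fastas, gffs)]
    os.makedirs(config.out_dir, exist_ok=True)
    result = run_pipeline_on_genomes(genomes, seeds, config, config.out_dir)
    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result.report
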