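"""Synthetic annotated genomes with implanted, ground-truthed circular
bacteriocin gene clusters and decoys.

The generator emulates the cluster architectures seen in characterized
producers: 1-3 precursor gene copies, a SpoIIM gene, 1-3 transporters,
and optional Yip1 / transposase / peptidase accessories, implanted into
a background of random genes at a controlled protein identity to the
seed proteins. Decoy neighborhoods omit one required role and are the
specificity oracle. Everything is deterministic under the configured
seed; the manifest records the truth the mining stages must recover.

Codon choice is uniform over synonymous codons (no codon-usage model):
nothing downstream reads codon bias, so realism there would be unused.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .align import AlignmentParams, global_identity_fraction, load_matrix
from .models import GeneFeature, GenomeRecord, ProteinRecord, SeedSet

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _BACK_TABLE.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_TABLE.stop_codons)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def mutate_to_identity(protein: str, target_identity_pct: float,
                       rng: np.random.Generator,
                       params: AlignmentParams = AlignmentParams()) -> str:
    """Substitute residues to reach a target global identity (length kept).

    Substitution positions are sampled without replacement; replacement
    residues are drawn proportionally to substitution-matrix
    exchangeability 2^S(orig, repl), never equal to the original. For
    very short sequences the identity grid is coarse; if the attainable
    value misses the target by more than 3 points a warning is issued
    and the best effort returned.
    """
    if not (20.0 <= target_identity_pct <= 100.0):
        raise ValueError("target identity must be in [20, 100]")
    L = len(protein)
    k = int(round(L * (1.0 - target_identity_pct / 100.0)))
    attainable = 100.0 * (1.0 - k / L)
    if abs(attainable - target_identity_pct) > 3.0:
        warnings.warn(
            f"length-{L} sequence cannot reach {target_identity_pct}% identity "
            f"within 3 points (best {attainable:.1f}%)"
        )
    if k == 0:
        return protein
    S = load_matrix(params.substitution_matrix_name)
    positions = rng.choice(L, size=k, replace=False)
    seq = list(protein)
    for pos in sorted(positions):
        orig = seq[pos]
        if orig == "X":
            choices, weights = list(AMINO_ACIDS), np.ones(20)
        else:
            choices = [a for a in AMINO_ACIDS if a != orig]
            weights = np.array([2.0 ** S[orig, a] for a in choices])
        seq[pos] = choices[rng.choice(len(choices), p=weights / weights.sum())]
    return "".join(seq)


def reverse_translate(protein: str, rng: np.random.Generator,
                      add_stop: bool = True) -> str:
    """Back-translate with uniformly random synonymous codons (table 11).

    The first residue, when M, is encoded as ATG so the CDS carries a
    canonical start; X is encoded as NNN.
    """
    codons = []
    for i, aa in enumerate(protein):
        if aa == "X":
            codons.append("NNN")
        elif i == 0 and aa == "M":
            codons.append("ATG")
        else:
            opts = _BACK_TABLE[aa]
            codons.append(opts[rng.integers(len(opts))])
    if add_stop:
        codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@dataclass
class ClusterSpec:
    """One implanted cluster (or decoy) on one genome."""

    genome_index: int
    bacteriocin: str                    # seed family supplying the proteins
    identity_pct: float = 70.0          # target identity of every gene to its seed
    n_precursor_copies: int = 1
    n_transporters: int = 1
    include_spoiim: bool = True
    include_yip1: bool = False
    include_transposase: bool = False
    include_peptidase: bool = False
    precursor_annotated: bool = True
    omit_role: Optional[str] = None     # 'precursor' | 'spoIIM' | 'transporter' -> decoy

    def __post_init__(self) -> None:
        if not (1 <= self.n_precursor_copies <= 3 and 1 <= self.n_transporters <= 3):
            raise ValueError("precursor and transporter copy numbers must be 1-3")
        if self.omit_role not in (None, "precursor", "spoIIM", "transporter"):
            raise ValueError(f"cannot omit role {self.omit_role!r}")

    @property
    def is_decoy(self) -> bool:
        return self.omit_role is not None


@dataclass
class SimConfig:
    seed: int
    n_genomes: int = 5
    background_genes: int = 25
    background_len_range: tuple[int, int] = (80, 350)
    spacer_range: tuple[int, int] = (20, 200)
    clusters: list[ClusterSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for c in self.clusters:
            if not (0 <= c.genome_index < self.n_genomes):
                raise ValueError(f"cluster genome_index {c.genome_index} out of range")
            if not (20.0 <= c.identity_pct <= 100.0):
                raise ValueError("cluster identity must be in [20, 100]")


@dataclass
class ImplantedGene:
    genome_id: str
    contig_id: str
    cluster_id: str
    role: str
    seed_name: str
    seed_id: str
    start: int
    end: int
    strand: str
    realized_identity_pct: float
    annotated: bool
    protein: str
    identity_warning: bool = False


@dataclass
class ClusterTruth:
    cluster_id: str
    genome_id: str
    contig_id: str
    spec: ClusterSpec
    genes: list[ImplantedGene]

    @property
    def span(self) -> tuple[int, int]:
        return min(g.start for g in self.genes), max(g.end for g in self.genes)


@dataclass
class SyntheticManifest:
    contig_lengths: dict[str, dict[str, int]]  # genome -> contig -> length
    clusters: list[ClusterTruth]

    def complete_clusters(self) -> list[ClusterTruth]:
        return [c for c in self.clusters if not c.spec.is_decoy]

    def decoys(self) -> list[ClusterTruth]:
        return [c for c in self.clusters if c.spec.is_decoy]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for g in c.genes:
                rows.append(
                    {
                        "genome_id": g.genome_id,
                        "contig_id": g.contig_id,
                        "cluster_id": c.cluster_id,
                        "decoy_omits": c.spec.omit_role or "",
                        "role": g.role,
                        "seed_name": g.seed_name,
                        "start": g.start,
                        "end": g.end,
                        "strand": g.strand,
                        "realized_identity_pct": round(g.realized_identity_pct, 2),
                        "annotated": g.annotated,
                        "protein": g.protein,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["genome_id", "contig_id", "cluster_id", "decoy_omits", "role",
                     "seed_name", "start", "end", "strand", "realized_identity_pct",
                     "annotated", "protein"],
        )


def _seed_record(seeds: SeedSet, bacteriocin: str, role: str) -> ProteinRecord:
    for e in seeds.entries:
        if e.role == role and (e.bacteriocin_name == bacteriocin or role in ("yip1", "peptidase")):
            return e.record
    raise ValueError(f"seed set has no {role!r} entry for {bacteriocin!r}")


@dataclass
class _PendingGene:
    role: str
    seed_name: str
    seed_id: str
    protein: str
    realized_identity: float
    annotated: bool
    product: str
    identity_warning: bool = False


def _cluster_genes(spec: ClusterSpec, seeds: SeedSet, rng: np.random.Generator,
                   params: AlignmentParams) -> list[_PendingGene]:
    order: list[tuple[str, str]] = []  # (role, product)
    if spec.omit_role != "precursor":
        order += [("precursor", "putative circular bacteriocin precursor")] * spec.n_precursor_copies
    if spec.include_transposase:
        order += [("transposase", "transposase")]
    if spec.omit_role != "transporter":
        order += [("transporter", "ABC transporter ATP-binding protein")] * spec.n_transporters
    if spec.include_spoiim and spec.omit_role != "spoIIM":
        order += [("spoIIM", "SpoIIM family membrane protein")]
    if spec.include_yip1:
        order += [("yip1", "Yip1 family membrane protein")]
    if spec.include_peptidase:
        order += [("peptidase", "zinc metallopeptidase")]

    genes: list[_PendingGene] = []
    base_mutant: dict[str, str] = {}  # role -> first-copy sequence
    for role, product in order:
        if role == "transposase":
            prot = random_protein(rng, int(rng.integers(120, 250)))
            genes.append(_PendingGene("transposase", "", "", prot, 0.0, True, product))
            continue
        seed = _seed_record(seeds, spec.bacteriocin, role)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if role in base_mutant:
                # additional copies are near-identical paralogs of the first
                mutated = mutate_to_identity(base_mutant[role], 98.0, rng, params)
            else:
                mutated = mutate_to_identity(seed.sequence, spec.identity_pct, rng, params)
                base_mutant[role] = mutated
            warned = len(caught) > 0
        realized = 100.0 * global_identity_fraction(mutated, seed.sequence, params)
        annotated = not (role == "precursor" and not spec.precursor_annotated)
        genes.append(_PendingGene(role, spec.bacteriocin, seed.id, mutated,
                                  realized, annotated, product, warned))
    return genes


def generate_genomes(config: SimConfig, seeds: SeedSet,
                     params: AlignmentParams = AlignmentParams()
                     ) -> tuple[list[GenomeRecord], SyntheticManifest]:
    """Emit synthetic genomes plus the ground-truth manifest.

    Each genome is one contig of background genes with the configured
    clusters implanted between them; intergenic spacers are 20-200 nt of
    random sequence. An in-frame stop codon is written immediately
    upstream of every precursor CDS so the true ORF boundary is the one
    an ORF scan recovers. Unannotated-precursor mode leaves the
    precursor out of the feature table but records it in the manifest.
    """
    rng = np.random.default_rng(config.seed)
    genomes: list[GenomeRecord] = []
    truths: list[ClusterTruth] = []
    contig_lengths: dict[str, dict[str, int]] = {}
    cluster_counter = 0

    for gi in range(config.n_genomes):
        genome_id = f"synthgenome{gi:03d}"
        contig_id = f"{genome_id}_c1"
        specs = [c for c in config.clusters if c.genome_index == gi]

        # plan: background genes as single-gene blocks, clusters as multi-gene blocks
        blocks: list[tuple[str, object]] = [("bg", None)] * config.background_genes
        for spec in specs:
            pos = int(rng.integers(0, len(blocks) + 1))
            blocks.insert(pos, ("cluster", spec))

        seq_parts: list[str] = []
        cursor = 0  # length emitted so far
        features: list[GeneFeature] = []
        gene_idx = 0

        def emit_spacer(force_stop_next: bool = False, strand: str = "+") -> None:
            nonlocal cursor
            lo, hi = config.spacer_range
            spacer = random_dna(rng, int(rng.integers(lo, hi + 1)))
            if force_stop_next:
                # in-frame stop immediately upstream of the next CDS start
                if strand == "+":
                    spacer = spacer[:-3] + "TAA"
                else:
                    spacer = "TTA" + spacer[3:]
            seq_parts.append(spacer)
            cursor += len(spacer)

        def emit_cds(protein: str, strand: str, annotated: bool, product: str,
                     protein_id: str) -> tuple[int, int]:
            nonlocal cursor, gene_idx
            cds = reverse_translate(protein, rng)
            if strand == "-":
                cds = reverse_complement(cds)
            start = cursor + 1
            end = cursor + len(cds)
            seq_parts.append(cds)
            cursor = end
            if annotated:
                features.append(
                    GeneFeature(
                        genome_id=genome_id, contig_id=contig_id,
                        start=start, end=end, strand=strand,
                        feature_kind="CDS", protein_id=protein_id,
                        product=product, translation=protein,
                    )
                )
            gene_idx += 1
            return start, end

        emit_spacer()
        for kind, payload in blocks:
            if kind == "bg":
                prot = random_protein(rng, int(rng.integers(*config.background_len_range)))
                strand = "+" if rng.integers(2) else "-"
                emit_cds(prot, strand, True, "hypothetical protein",
                         f"{genome_id}_g{gene_idx:04d}")
                emit_spacer()
            else:
                spec = payload
                cluster_id = f"cluster{cluster_counter:03d}"
                cluster_counter += 1
                strand = "+" if rng.integers(2) else "-"
                pending = _cluster_genes(spec, seeds, rng, params)
                if strand == "-":
                    pending = pending[::-1]
                implanted: list[ImplantedGene] = []
                for pg in pending:
                    if pg.role == "precursor":
                        # rewrite the upstream spacer to carry an in-frame stop
                        if strand == "+":
                            seq_parts[-1] = seq_parts[-1][:-3] + "TAA"
                        else:
                            pass  # handled after emission for '-' strand
                    pid = f"{genome_id}_g{gene_idx:04d}"
                    start, end = emit_cds(pg.protein, strand, pg.annotated,
                                          pg.product, pid)
                    if pg.role != "transposase":
                        implanted.append(
                            ImplantedGene(
                                genome_id=genome_id, contig_id=contig_id,
                                cluster_id=cluster_id, role=pg.role,
                                seed_name=pg.seed_name, seed_id=pg.seed_id,
                                start=start, end=end, strand=strand,
                                realized_identity_pct=pg.realized_identity,
                                annotated=pg.annotated, protein=pg.protein,
                                identity_warning=pg.identity_warning,
                            )
                        )
                    emit_spacer(force_stop_next=False)
                    if pg.role == "precursor" and strand == "-":
                        # in-frame stop downstream on the contig = upstream of the
                        # reverse-strand ORF
                        seq_parts[-1] = "TTA" + seq_parts[-1][3:]
                truths.append(
                    ClusterTruth(cluster_id=cluster_id, genome_id=genome_id,
                                 contig_id=contig_id, spec=spec, genes=implanted)
                )

        genome = GenomeRecord(genome_id=genome_id,
                              contigs={contig_id: "".join(seq_parts)},
                              features=features)
        genome.validate()
        genomes.append(genome)
        contig_lengths[genome_id] = {contig_id: len(genome.contigs[contig_id])}

    return genomes, SyntheticManifest(contig_lengths=contig_lengths, clusters=truths)


def standard_recovery_simulation(seed: int, seeds: SeedSet) -> SimConfig:
    """The default recovery benchmark: 20 genomes, 6 complete clusters
    spanning 60-90% seed identity with varied architectures, and 4
    decoys each missing one required role."""
    clusters = [
        ClusterSpec(0, "amylocyclicin", identity_pct=60.0, n_precursor_copies=3,
                    n_transporters=1, include_yip1=True),
        ClusterSpec(1, "uberolysin", identity_pct=66.0, n_precursor_copies=3,
                    n_transporters=2, include_transposase=True),
        ClusterSpec(2, "enterocin AS-48", identity_pct=72.0, n_precursor_copies=1,
                    n_transporters=3),
        ClusterSpec(3, "gassericin A", identity_pct=78.0, n_precursor_copies=1,
                    n_transporters=1, include_peptidase=True),
        ClusterSpec(4, "circularin A", identity_pct=84.0, n_precursor_copies=2,
                    n_transporters=1, precursor_annotated=False),
        ClusterSpec(5, "carnocyclin A", identity_pct=90.0, n_precursor_copies=1,
                    n_transporters=2, include_yip1=True),
        ClusterSpec(6, "pumilarin", identity_pct=75.0, omit_role="precursor"),
        ClusterSpec(7, "plantaricyclin A", identity_pct=75.0, omit_role="precursor"),
        ClusterSpec(8, "enterocin NKR-5-3B", identity_pct=75.0, omit_role="spoIIM"),
        ClusterSpec(9, "butyrovibriocin AR10", identity_pct=75.0, omit_role="spoIIM"),
    ]
    return SimConfig(seed=seed, n_genomes=20, clusters=clusters)


def write_simulation(genomes: list[GenomeRecord], manifest: SyntheticManifest,
                     out_dir) -> None:
    import os

    from .io import write_genome_fasta, write_genome_gff3

    os.makedirs(out_dir, exist_ok=True)
    for g in genomes:
        write_genome_fasta(g, os.path.join(out_dir, f"{g.genome_id}.fna"))
        write_genome_gff3(g, os.path.join(out_dir, f"{g.genome_id}.gff3"))
    manifest.to_dataframe().to_csv(os.path.join(out_dir, "manifest.tsv"),
                                   sep="\t", index=False)
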