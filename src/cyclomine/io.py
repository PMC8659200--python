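"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, GFF3 via gffutils; TSV outputs are plain pandas
tables sorted deterministically so reruns are byte-identical.
"""
from __future__ import annotations

import os
from importlib import resources
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .models import (
    CrossReferenceError,
    FormatError,
    GeneFeature,
    GenomeRecord,
    ProteinRecord,
    SeedEntry,
    SeedSet,
    SourceLocation,
)

BACTERIAL_CODON_TABLE = 11


def read_protein_fasta(path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FormatError(f"no FASTA records parsed from {path}")
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            desc = f" {r.description}" if r.description else ""
            fh.write(f">{r.id}{desc}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def translate_cds(dna: str, strand: str = "+") -> str:
    """Translate one CDS with the bacterial code (table 11), honoring strand.

    A trailing stop is trimmed; ambiguous codons (any N) yield X.
    """
    seq = Seq(dna)
    if strand == "-":
        seq = seq.reverse_complement()
    prot = str(seq.translate(table=BACTERIAL_CODON_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot.replace("J", "X")


def load_annotated_genome(fasta_path, gff3_path=None, genome_id: Optional[str] = None) -> GenomeRecord:
    """Load a genome from nucleotide FASTA plus optional GFF3 annotation.

    CDS features without a supplied translation are translated with the
    bacterial code; a premature internal stop flags the feature (kept,
    but excluded from proteome searches).
    """
    gid = genome_id or os.path.splitext(os.path.basename(str(fasta_path)))[0]
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise FormatError(f"no contigs parsed from {fasta_path}")
    genome = GenomeRecord(genome_id=gid, contigs=contigs)

    if gff3_path is not None:
        try:
            db = gffutils.create_db(
                str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
                merge_strategy="create_unique",
            )
        except Exception as exc:  # gffutils raises assorted parse errors
            raise FormatError(f"malformed GFF3 {gff3_path}: {exc}") from exc
        for f in db.all_features():
            if f.seqid not in contigs:
                raise CrossReferenceError(
                    f"GFF3 feature references contig {f.seqid!r} absent from FASTA"
                )
            kind = "CDS" if f.featuretype == "CDS" else "other"
            translation = None
            internal_stop = False
            if kind == "CDS":
                dna = contigs[f.seqid][f.start - 1 : f.end]
                translation = translate_cds(dna, f.strand)
                internal_stop = "*" in translation
                if internal_stop:
                    translation = translation.replace("*", "X")
            attrs = f.attributes
            genome.features.append(
                GeneFeature(
                    genome_id=gid,
                    contig_id=f.seqid,
                    start=f.start,
                    end=f.end,
                    strand=f.strand if f.strand in ("+", "-") else "+",
                    feature_kind=kind,
                    protein_id=(attrs.get("ID") or attrs.get("protein_id") or [None])[0],
                    product=(attrs.get("product") or [""])[0],
                    translation=translation,
                    internal_stop=internal_stop,
                )
            )
    genome.validate()
    return genome


def write_genome_fasta(genome: GenomeRecord, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for cid in sorted(genome.contigs):
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome_gff3(genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in sorted(genome.contigs):
            fh.write(f"##sequence-region {cid} 1 {len(genome.contigs[cid])}\n")
        for i, f in enumerate(sorted(genome.features, key=lambda f: (f.contig_id, f.start))):
            attrs = [f"ID={f.protein_id or f'gene{i:04d}'}"]
            if f.product:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "cyclomine",
                        f.feature_kind if f.feature_kind == "CDS" else "gene",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Seed set


def load_seed_set(fasta_path=None, roles_path=None) -> SeedSet:
    """Load a seed set from protein FASTA + role-annotation TSV.

    With no arguments, loads the bundled synthetic stand-in for the 19
    characterized circular bacteriocins (precursor, transporter, SpoIIM
    and accessory families).
    """
    if fasta_path is None or roles_path is None:
        pkg = resources.files("cyclomine.data")
        fasta_path = pkg / "seeds_synthetic.faa"
        roles_path = pkg / "seed_roles_synthetic.tsv"
        provenance = "bundled synthetic stand-in seed set"
    else:
        provenance = f"user seed set: {fasta_path}"
    records = {r.id: r for r in read_protein_fasta(fasta_path)}
    roles = pd.read_csv(roles_path, sep="\t", dtype=str)
    required = {"seq_id", "bacteriocin_name", "role", "subgroup"}
    if not required.issubset(roles.columns):
        raise FormatError(f"roles TSV must have columns {sorted(required)}")
    entries = []
    for row in roles.itertuples(index=False):
        if row.seq_id not in records:
            raise CrossReferenceError(f"roles TSV names {row.seq_id!r} absent from seed FASTA")
        entries.append(
            SeedEntry(
                bacteriocin_name=row.bacteriocin_name,
                role=row.role,
                subgroup=row.subgroup,
                record=records[row.seq_id],
            )
        )
    return SeedSet(entries=entries, provenance=provenance)


def load_cleavage_table(path=None) -> dict[str, int]:
    """Bacteriocin name -> leader length (residues before the cleavage site).

    The bundled default is the synthetic fixture accompanying the seed
    set; 0 means leaderless.
    """
    if path is None:
        path = resources.files("cyclomine.data") / "cleavage_sites_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"bacteriocin_name": str, "leader_length": int})
    return dict(zip(df["bacteriocin_name"], df["leader_length"]))


# ---------------------------------------------------------------------------
# Result tables


def write_edge_list(graph, out_prefix) -> tuple[str, str]:
    """Write an SSN as edge-list + node-attribute TSVs (network-viewer friendly).

    Returns (edges_path, nodes_path).
    """
    edges_path = f"{out_prefix}edges.tsv"
    nodes_path = f"{out_prefix}nodes.tsv"
    erows = [
        {
            "node_a": a,
            "node_b": b,
            "percent_identity": round(ident, 4),
            "alignment_score": score,
        }
        for (a, b, ident, score) in graph.edges
    ]
    edf = pd.DataFrame(erows, columns=["node_a", "node_b", "percent_identity", "alignment_score"])
    edf = edf.sort_values(["node_a", "node_b"]).reset_index(drop=True)
    edf.to_csv(edges_path, sep="\t", index=False)

    nrows = []
    for node in graph.nodes:
        attrs = graph.node_attrs.get(node.id, {})
        nrows.append(
            {
                "id": node.id,
                "multiplicity": node.multiplicity,
                "group_id": attrs.get("group_id", ""),
                "subgroup": attrs.get("subgroup", ""),
                "GRAVY": attrs.get("gravy", ""),
                "pI": attrs.get("pI", ""),
            }
        )
    ndf = pd.DataFrame(nrows, columns=["id", "multiplicity", "group_id", "subgroup", "GRAVY", "pI"])
    ndf = ndf.sort_values("id").reset_index(drop=True)
    ndf.to_csv(nodes_path, sep="\t", index=False)
    return edges_path, nodes_path


HIT_COLUMNS = [
    "genome_id", "contig_id", "window_start", "window_end", "anchor_id",
    "verdict", "roles_found", "accessory_flags", "precursor_id",
    "precursor_sequence", "group_id", "subgroup",
]
GROUP_COLUMNS = ["group_id", "is_singleton", "n_unique", "n_genomes", "members"]


def write_results_tables(bgcs, groups, profiles, out_dir) -> tuple[str, str]:
    """Write the per-hit and per-group summary tables.

    ``bgcs``: CandidateBGC list; ``groups``: GroupAssignment list;
    ``profiles``: dict precursor node id -> PhyschemProfile.
    Output is fully sorted so regeneration is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    group_of: dict[str, object] = {}
    for g in groups:
        for m in g.members:
            group_of[m] = g.group_id

    missing = [m for g in groups for m in g.members if m not in profiles]
    if missing:
        raise ValueError(f"group members without physicochemical profiles: {sorted(missing)}")

    hit_rows = []
    for bgc in bgcs:
        w = bgc.window
        roles_found = ",".join(sorted(r for r, hits in bgc.roles.items() if hits))
        accessory = ",".join(sorted(k for k, v in bgc.accessory_flags.items() if v))
        precs = bgc.roles.get("precursor", [])
        base = {
            "genome_id": w.genome_id,
            "contig_id": w.contig_id,
            "window_start": w.span[0],
            "window_end": w.span[1],
            "anchor_id": w.anchor.protein_id or "",
            "verdict": bgc.verdict,
            "roles_found": roles_found,
            "accessory_flags": accessory,
        }
        if not precs:
            hit_rows.append({**base, "precursor_id": "", "precursor_sequence": "",
                             "group_id": "", "subgroup": ""})
        for cand, _hit in precs:
            pid = cand.id
            prof = profiles.get(pid)
            hit_rows.append(
                {
                    **base,
                    "precursor_id": pid,
                    "precursor_sequence": cand.sequence,
                    "group_id": group_of.get(pid, ""),
                    "subgroup": prof.subgroup_call if prof is not None else "",
                }
            )
    hdf = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)
    hdf = hdf.sort_values(["genome_id", "contig_id", "window_start", "precursor_id"]).reset_index(drop=True)
    hits_path = os.path.join(out_dir, "hits.tsv")
    hdf.to_csv(hits_path, sep="\t", index=False)

    grows = []
    for g in sorted(groups, key=lambda g: (g.is_singleton, g.group_id)):
        genomes = set()
        for m in g.members:
            for bgc in bgcs:
                for cand, _hit in bgc.roles.get("precursor", []):
                    if cand.id == m:
                        genomes.add(bgc.window.genome_id)
        grows.append(
            {
                "group_id": g.group_id,
                "is_singleton": g.is_singleton,
                "n_unique": len(g.members),
                "n_genomes": len(genomes),
                "members": ",".join(sorted(g.members)),
            }
        )
    gdf = pd.DataFrame(grows, columns=GROUP_COLUMNS)
    groups_path = os.path.join(out_dir, "groups.tsv")
    gdf.to_csv(groups_path, sep="\t", index=False)
    return hits_path, groups_path
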