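"""Core domain types shared by every pipeline stage.

Coordinates are 1-based inclusive (GFF3 convention) throughout; any
half-open arithmetic is internal to the functions that need it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file (FASTA/GFF3/TSV)."""


class CrossReferenceError(ValueError):
    """Inconsistent references between inputs (e.g. GFF3 contig not in FASTA)."""


@dataclass(frozen=True)
class SourceLocation:
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional genomic provenance."""

    id: str
    sequence: str
    description: str = ""
    source: Optional[SourceLocation] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)!r} "
                "(expected the 20 canonical amino acids plus X, uppercase)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene (usually CDS) located on a contig; start/end 1-based inclusive."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_kind: str = "CDS"
    protein_id: Optional[str] = None
    product: str = ""
    translation: Optional[str] = None
    internal_stop: bool = False  # miscalled gene: kept but excluded from searches

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    features: list[GeneFeature] = field(default_factory=list)

    def validate(self) -> None:
        for cid, seq in self.contigs.items():
            bad = set(seq) - NUCLEOTIDE_ALPHABET
            if bad:
                raise ValueError(f"contig {cid!r}: invalid nucleotides {sorted(bad)!r}")
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise CrossReferenceError(
                    f"feature on contig {f.contig_id!r} not present in genome "
                    f"{self.genome_id!r}"
                )
            if f.end > len(self.contigs[f.contig_id]):
                raise ValueError(
                    f"feature {f.protein_id or f.product!r} extends past contig "
                    f"{f.contig_id!r} ({f.end} > {len(self.contigs[f.contig_id])})"
                )
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end))

    def contig_features(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]

    def proteome(self) -> list[ProteinRecord]:
        """Translated CDS records usable as search targets.

        Features flagged with internal stops are excluded (tolerated as
        miscalled genes rather than aborting the run).
        """
        out = []
        for i, f in enumerate(self.features):
            if f.feature_kind != "CDS" or f.translation is None or f.internal_stop:
                continue
            pid = f.protein_id or f"{self.genome_id}|{f.contig_id}|{f.start}..{f.end}|{f.strand}"
            out.append(
                ProteinRecord(
                    id=pid,
                    sequence=f.translation,
                    description=f.product,
                    source=SourceLocation(self.genome_id, f.contig_id, f.start, f.end, f.strand),
                )
            )
        return out


SEED_ROLES = ("precursor", "transporter", "spoIIM", "yip1", "peptidase", "immunity")
SUBGROUPS = ("i", "ii", "unknown")


@dataclass(frozen=True)
class SeedEntry:
    bacteriocin_name: str
    role: str
    subgroup: str
    record: ProteinRecord

    def __post_init__(self) -> None:
        if self.role not in SEED_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {SEED_ROLES}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")


@dataclass
class SeedSet:
    """Characterized reference proteins, keyed by biosynthetic role.

    The bundled default is a synthetic stand-in emulating the 19
    characterized circular bacteriocins (see data/ fixtures); any
    user-supplied protein FASTA + role TSV can replace it.
    """

    entries: list[SeedEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        roles = {e.role for e in self.entries}
        if "transporter" not in roles or "spoIIM" not in roles:
            raise ValueError("seed set must contain at least one transporter and one spoIIM entry")
        ids = [e.record.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids in seed set")

    def by_role(self, role: str) -> list[SeedEntry]:
        return [e for e in self.entries if e.role == role]

    def records_for_role(self, role: str) -> list[ProteinRecord]:
        return [e.record for e in self.by_role(role)]

    def subgroup_of(self, bacteriocin_name: str) -> str:
        for e in self.entries:
            if e.bacteriocin_name == bacteriocin_name:
                return e.subgroup
        raise KeyError(bacteriocin_name)


def check_unique_ids(records: list[ProteinRecord], what: str = "collection") -> None:
    seen: set[str] = set()
    dups: set[str] = set()
    for r in records:
        (dups if r.id in seen else seen).add(r.id)
    if dups:
        raise ValueError(f"duplicate ids in {what}: {sorted(dups)}")
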