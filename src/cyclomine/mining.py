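"""Neighborhood extraction, small-ORF scanning, role annotation, and the
co-occurrence filter that turns transporter hits into candidate BGCs.

A candidate biosynthetic gene cluster passes the filter iff the
neighborhood around a transporter hit contains a precursor peptide, a
SpoIIM-family gene, and the transporter itself — the minimal gene
content shared by every characterized circular-bacteriocin cluster.
Accessory genes (Yip1, peptidases, transposases) are reported as flags
and never influence the verdict.

Precursor evidence: a small protein (annotated CDS or window-local ORF)
supported by homology to a seed precursor. Candidates that only satisfy
the physicochemical heuristic (GRAVY >= -0.5, length within bounds) are
reported with a ``heuristic_only`` flag but do not by themselves satisfy
the filter — window-local ORF scans produce spurious small ORFs freely,
and homology support is what keeps decoy neighborhoods out.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import AlignmentParams, AlignmentResult, SearchThresholds, align_local, search_proteome
from .io import translate_cds
from .models import GeneFeature, GenomeRecord, ProteinRecord, SeedSet
from .physchem import gravy
from .simulate import reverse_complement

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

ROLE_PRIORITY = {"precursor": 0, "spoIIM": 1, "transporter": 2, "yip1": 3, "peptidase": 4}


@dataclass
class ClusterWindow:
    genome_id: str
    contig_id: str
    anchor: GeneFeature
    genes: list[GeneFeature]
    span: tuple[int, int]  # 1-based inclusive on the contig
    dna: str

    def validate(self) -> None:
        if self.anchor not in self.genes:
            raise ValueError("anchor feature must be part of the window")
        if any(self.genes[i].start > self.genes[i + 1].start for i in range(len(self.genes) - 1)):
            raise ValueError("window genes must be sorted by start")


def extract_window(genome: GenomeRecord, anchor: GeneFeature, k: int = 10) -> ClusterWindow:
    """Up to k genes each side of the anchor on its contig, truncated at
    contig ends; the DNA slice covers the full span."""
    if k < 1:
        raise ValueError("k must be >= 1")
    contig_feats = genome.contig_features(anchor.contig_id)
    try:
        idx = contig_feats.index(anchor)
    except ValueError:
        raise LookupError(
            f"anchor {anchor.protein_id!r} is not a feature of genome {genome.genome_id!r}"
        ) from None
    genes = contig_feats[max(0, idx - k) : idx + k + 1]
    start = min(f.start for f in genes)
    end = max(f.end for f in genes)
    # pad into the flanking intergenic space so an unannotated precursor
    # adjacent to the outermost window gene (up to ~150 aa CDS plus its
    # intergenic spacer) is still inside the scannable span
    contig = genome.contigs[anchor.contig_id]
    pad = 1000
    start = max(1, start - pad)
    end = min(len(contig), end + pad)
    window = ClusterWindow(
        genome_id=genome.genome_id,
        contig_id=anchor.contig_id,
        anchor=anchor,
        genes=genes,
        span=(start, end),
        dna=contig[start - 1 : end],
    )
    window.validate()
    return window


@dataclass
class PrecursorCandidate:
    id: str
    sequence: str
    start: int
    end: int
    strand: str
    origin: str  # 'annotated_cds' | 'orf_scan'
    best_seed_identity_pct: float = 0.0
    heuristic_only: bool = False
    profile: Optional[object] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _orfs_in_frame(dna: str, frame: int) -> list[tuple[int, int]]:
    """(start, end) 0-based half-open ORF spans (incl. stop codon) in one
    forward frame; longest ORF per stop (earliest start after the
    previous stop)."""
    orfs = []
    start: Optional[int] = None
    pos = frame
    while pos + 3 <= len(dna):
        codon = dna[pos : pos + 3]
        if codon in STOP_CODONS:
            if start is not None:
                orfs.append((start, pos + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = pos
        pos += 3
    return orfs


def scan_orfs(window: ClusterWindow, min_len_aa: int = 25, max_len_aa: int = 150
              ) -> list[PrecursorCandidate]:
    """Six-frame ORF scan of the window DNA.

    ORFs start at ATG/GTG/TTG and end at the first in-frame stop;
    translated length (stop excluded) must fall in [min_len, max_len].
    ORFs wholly contained inside an annotated CDS on the same strand are
    suppressed (they are annotation shadows, not novel genes).
    """
    if not (10 <= min_len_aa < max_len_aa):
        raise ValueError("require 10 <= min_len_aa < max_len_aa")
    span_start, span_end = window.span
    out: list[PrecursorCandidate] = []
    rc = reverse_complement(window.dna)
    for strand, seq in (("+", window.dna), ("-", rc)):
        for frame in range(3):
            for s, e in _orfs_in_frame(seq, frame):
                aa_len = (e - s) // 3 - 1
                if not (min_len_aa <= aa_len <= max_len_aa):
                    continue
                if strand == "+":
                    c_start, c_end = span_start + s, span_start + e - 1
                else:
                    c_start, c_end = span_end - e + 1, span_end - s
                if any(
                    f.strand == strand and f.start <= c_start and c_end <= f.end
                    for f in window.genes
                    if f.feature_kind == "CDS"
                ):
                    continue
                prot = translate_cds(seq[s:e], "+")
                if prot and prot[0] != "M":
                    prot = "M" + prot[1:]  # alternative start codons read as Met
                out.append(
                    PrecursorCandidate(
                        id=f"{window.genome_id}|{window.contig_id}|{c_start}..{c_end}|{strand}|orf",
                        sequence=prot,
                        start=c_start,
                        end=c_end,
                        strand=strand,
                        origin="orf_scan",
                    )
                )
    out.sort(key=lambda c: (c.start, c.end, c.strand))
    return out


@dataclass
class CandidateBGC:
    window: ClusterWindow
    roles: dict = field(default_factory=dict)  # role -> list of (carrier, AlignmentResult)
    accessory_flags: dict = field(default_factory=dict)
    verdict: str = "fail"
    fail_reasons: tuple[str, ...] = ()

    @property
    def has_precursor(self) -> bool:
        return bool(self.roles.get("precursor"))

    @property
    def has_spoiim(self) -> bool:
        return bool(self.roles.get("spoIIM"))

    @property
    def has_transporter(self) -> bool:
        return bool(self.roles.get("transporter"))

    def precursor_candidates(self) -> list[PrecursorCandidate]:
        return [cand for cand, _hit in self.roles.get("precursor", [])]


@dataclass(frozen=True)
class MiningParams:
    window_k: int = 10
    min_precursor_len: int = 25
    max_precursor_len: int = 150
    precursor_min_identity_pct: float = 30.0
    heuristic_min_gravy: float = -0.5


def _feature_protein(window: ClusterWindow, f: GeneFeature, genome_id: str) -> Optional[ProteinRecord]:
    if f.feature_kind != "CDS" or f.translation is None or f.internal_stop:
        return None
    pid = f.protein_id or f"{genome_id}|{f.contig_id}|{f.start}..{f.end}|{f.strand}"
    return ProteinRecord(id=pid, sequence=f.translation, description=f.product)


def classify_roles(
    window: ClusterWindow,
    seeds: SeedSet,
    params: AlignmentParams = AlignmentParams(),
    thresholds: SearchThresholds = SearchThresholds(),
    mining: MiningParams = MiningParams(),
) -> CandidateBGC:
    """Assign one biosynthetic role per window gene and apply the
    co-occurrence filter.

    Role conflicts resolve by highest raw alignment score, ties by role
    priority (precursor > spoIIM > transporter > accessories): the
    precursor is the scarce signal.
    """
    searchable_roles = [r for r in ("precursor", "transporter", "spoIIM", "yip1", "peptidase")
                        if seeds.by_role(r)]
    if "transporter" not in searchable_roles or "spoIIM" not in searchable_roles:
        raise ValueError("seed set lacks transporter or spoIIM entries")

    annotated: list[tuple[GeneFeature, ProteinRecord]] = []
    for f in window.genes:
        rec = _feature_protein(window, f, window.genome_id)
        if rec is not None:
            annotated.append((f, rec))

    orf_candidates = scan_orfs(window, mining.min_precursor_len, mining.max_precursor_len)

    # best passing hit per (carrier, role)
    best: dict[str, dict[str, AlignmentResult]] = {}
    carriers: dict[str, object] = {}
    for f, rec in annotated:
        carriers[rec.id] = (f, rec)
        for role in searchable_roles:
            if role == "precursor" and not (
                mining.min_precursor_len <= len(rec.sequence) <= mining.max_precursor_len
            ):
                continue
            for seed in seeds.records_for_role(role):
                res = align_local(seed.sequence, rec.sequence, params,
                                  query_id=seed.id, subject_id=rec.id)
                if thresholds.passes(res):
                    cur = best.setdefault(rec.id, {}).get(role)
                    if cur is None or res.raw_score > cur.raw_score:
                        best[rec.id][role] = res
    for cand in orf_candidates:
        carriers[cand.id] = cand
        for seed in seeds.records_for_role("precursor"):
            res = align_local(seed.sequence, cand.sequence, params,
                              query_id=seed.id, subject_id=cand.id)
            if thresholds.passes(res):
                cur = best.setdefault(cand.id, {}).get("precursor")
                if cur is None or res.raw_score > cur.raw_score:
                    best[cand.id]["precursor"] = res

    roles: dict[str, list] = {r: [] for r in searchable_roles}
    for carrier_id, role_hits in best.items():
        role, hit = min(
            role_hits.items(),
            key=lambda kv: (-kv[1].raw_score, ROLE_PRIORITY[kv[0]]),
        )
        carrier = carriers[carrier_id]
        if role == "precursor":
            if isinstance(carrier, tuple):
                f, rec = carrier
                cand = PrecursorCandidate(
                    id=rec.id, sequence=rec.sequence, start=f.start, end=f.end,
                    strand=f.strand, origin="annotated_cds",
                    best_seed_identity_pct=hit.identity_pct,
                )
            else:
                cand = carrier
                cand.best_seed_identity_pct = hit.identity_pct
            if hit.identity_pct >= mining.precursor_min_identity_pct:
                roles["precursor"].append((cand, hit))
        else:
            roles[role].append((carrier, hit))

    # heuristic-only precursor candidates: reported, never decisive
    supported = {cand.id for cand, _h in roles["precursor"]}
    heuristic: list[PrecursorCandidate] = []
    for cand in orf_candidates:
        if cand.id in supported:
            continue
        try:
            g = gravy(cand.sequence)
        except ValueError:
            continue
        if g >= mining.heuristic_min_gravy:
            cand.heuristic_only = True
            heuristic.append(cand)

    transposase = any(
        "transposase" in (f.product or "").lower() for f in window.genes
    )
    accessory = {
        "yip1": bool(roles.get("yip1")),
        "peptidase": bool(roles.get("peptidase")),
        "transposase": transposase,
    }

    bgc = CandidateBGC(window=window, roles=roles, accessory_flags=accessory)
    bgc.roles["heuristic_precursor"] = [(c, None) for c in heuristic]
    reasons = []
    if not bgc.has_precursor:
        reasons.append("no_precursor")
    if not bgc.has_spoiim:
        reasons.append("no_spoiim")
    if not bgc.has_transporter:
        reasons.append("no_transporter")
    bgc.fail_reasons = tuple(reasons)
    bgc.verdict = "pass" if not reasons else "fail"
    return bgc


def mine_genome(
    genome: GenomeRecord,
    seeds: SeedSet,
    params: AlignmentParams = AlignmentParams(),
    thresholds: SearchThresholds = SearchThresholds(),
    mining: MiningParams = MiningParams(),
) -> tuple[list[AlignmentResult], list[CandidateBGC]]:
    """Transporter-seeded mining of one genome.

    Seed transporters are searched against the annotated proteome; each
    hit anchors a neighborhood window; overlapping windows collapse to
    the best-scoring anchor; every surviving window is role-annotated
    and filtered. Returns (transporter hits, candidate BGCs).
    """
    proteome = genome.proteome()
    if not proteome:
        return [], []
    transporter_seeds = seeds.records_for_role("transporter")
    hits = search_proteome(transporter_seeds, proteome, params, thresholds)
    if not hits:
        return [], []

    by_feature: dict[str, GeneFeature] = {}
    for f in genome.features:
        rec = _feature_protein(None, f, genome.genome_id) if f.feature_kind == "CDS" else None
        if rec is not None:
            by_feature[rec.id] = f

    best_by_anchor: dict[str, AlignmentResult] = {}
    for h in hits:
        cur = best_by_anchor.get(h.subject_id)
        if cur is None or h.raw_score > cur.raw_score:
            best_by_anchor[h.subject_id] = h

    windows: list[tuple[AlignmentResult, ClusterWindow]] = []
    for sid, h in sorted(best_by_anchor.items()):
        anchor = by_feature.get(sid)
        if anchor is None:
            continue
        windows.append((h, extract_window(genome, anchor, mining.window_k)))

    # merge overlapping windows: keep the best-scoring anchor per overlap group
    windows.sort(key=lambda t: (t[1].contig_id, t[1].span))
    merged: list[tuple[AlignmentResult, ClusterWindow]] = []
    for h, w in windows:
        if merged:
            ph, pw = merged[-1]
            if pw.contig_id == w.contig_id and w.span[0] <= pw.span[1]:
                if h.raw_score > ph.raw_score:
                    merged[-1] = (h, w)
                continue
        merged.append((h, w))

    bgcs = [classify_roles(w, seeds, params, thresholds, mining) for _h, w in merged]
    return hits, bgcs
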