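"""Window extraction, six-frame ORF scanning, role classification, and
the co-occurrence filter, checked against the simulation manifest."""
import numpy as np
import pytest

from cyclomine.mining import (
    ClusterWindow,
    MiningParams,
    classify_roles,
    extract_window,
    mine_genome,
    scan_orfs,
)
from cyclomine.models import GeneFeature, GenomeRecord
from cyclomine.simulate import reverse_complement


def make_genome(n_genes, contig_len=None, gene_len=60, gap=40):
    feats = []
    pos = 1
    for i in range(n_genes):
        feats.append(GeneFeature("g", "c1", pos, pos + gene_len - 1, "+",
                                 protein_id=f"p{i}", translation="M" * 20))
        pos += gene_len + gap
    length = contig_len or (pos + 100)
    return GenomeRecord("g", {"c1": "A" * length}, feats)


class TestExtractWindow:
    def test_single_gene_contig_truncates_to_one(self):
        genome = make_genome(1)
        w = extract_window(genome, genome.features[0], k=10)
        assert len(w.genes) == 1

    def test_k10_on_21_gene_contig_takes_all(self):
        genome = make_genome(21)
        w = extract_window(genome, genome.features[10], k=10)
        assert len(w.genes) == 21

    def test_anchor_not_in_genome_is_lookup_error(self):
        genome = make_genome(3)
        stray = GeneFeature("g", "c1", 5000, 5059, "+", protein_id="zz")
        with pytest.raises(LookupError):
            extract_window(genome, stray)

    def test_dna_slice_matches_span(self, small_simulation):
        genomes, _ = small_simulation
        g = genomes[0]
        w = extract_window(g, g.features[5], k=3)
        s, e = w.span
        assert w.dna == g.contigs[w.contig_id][s - 1 : e]

    def test_window_spans_every_implanted_cluster_gene(self, seed_set, small_simulation):
        genomes, manifest = small_simulation
        for cluster in manifest.complete_clusters():
            genome = next(g for g in genomes if g.genome_id == cluster.genome_id)
            # anchor on the implanted transporter's annotated feature
            t = next(g for g in cluster.genes if g.role == "transporter")
            anchor = next(f for f in genome.features
                          if (f.start, f.end) == (t.start, t.end))
            w = extract_window(genome, anchor, k=10)
            lo, hi = cluster.span
            assert w.span[0] <= lo and hi <= w.span[1]


class TestScanOrfs:
    def window_of(self, dna, genes=()):
        return ClusterWindow("g", "c1", genes[0] if genes else
                             GeneFeature("g", "c1", 1, max(3, len(dna)), "+"),
                             list(genes) or [GeneFeature("g", "c1", 1, max(3, len(dna)), "+",
                                                         feature_kind="other")],
                             (1, len(dna)), dna)

    def test_no_stop_codons_no_orfs(self):
        w = self.window_of("A" * 300)
        assert scan_orfs(w, 10, 50) == []

    def test_hand_built_orf_translated(self):
        # pad so the 4-codon ORF meets a min length of 10 via a longer insert
        core = "ATGAAATGT" + "GCA" * 10 + "TAA"  # M K C A*10
        w = self.window_of("C" * 30 + core + "C" * 30)
        orfs = scan_orfs(w, 10, 50)
        assert len(orfs) == 1
        assert orfs[0].sequence == "MKC" + "A" * 10
        assert orfs[0].strand == "+"
        assert orfs[0].start == 31 and orfs[0].end == 30 + len(core)

    def test_scan_is_strand_symmetric(self):
        rng = np.random.default_rng(17)
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1200))
        fwd = scan_orfs(self.window_of(dna), 20, 120)
        rev = scan_orfs(self.window_of(reverse_complement(dna)), 20, 120)
        assert sorted(o.sequence for o in fwd) == sorted(o.sequence for o in rev)
        # coordinates mirror: start/end swap through L - x + 1
        L = len(dna)
        mapped = sorted((L - o.end + 1, L - o.start + 1, o.sequence) for o in rev)
        assert mapped == sorted((o.start, o.end, o.sequence) for o in fwd)

    def test_orf_inside_annotated_cds_same_strand_suppressed(self):
        core = "ATGAAATGT" + "GCA" * 10 + "TAA"
        dna = "C" * 30 + core + "C" * 30
        cds = GeneFeature("g", "c1", 31, 30 + len(core), "+", feature_kind="CDS")
        w = ClusterWindow("g", "c1", cds, [cds], (1, len(dna)), dna)
        assert scan_orfs(w, 10, 50) == []

    def test_unannotated_precursor_recovered_with_exact_coordinates(
            self, seed_set, small_simulation):
        genomes, manifest = small_simulation
        cluster = next(c for c in manifest.complete_clusters()
                       if any(not g.annotated for g in c.genes))
        genome = next(g for g in genomes if g.genome_id == cluster.genome_id)
        _hits, bgcs = mine_genome(genome, seed_set)
        passing = [b for b in bgcs if b.verdict == "pass"]
        assert len(passing) == 1
        found = {(c.start, c.end, c.strand, c.sequence)
                 for c in passing[0].precursor_candidates()}
        truth = {(g.start, g.end, g.strand, g.protein)
                 for g in cluster.genes if g.role == "precursor"}
        assert truth <= found

    def test_bad_length_bounds_rejected(self):
        with pytest.raises(ValueError):
            scan_orfs(self.window_of("A" * 100), 5, 50)


class TestClassifyRoles:
    def test_transporter_only_window_fails_with_both_reasons(self, seed_set):
        rng = np.random.default_rng(1)
        from cyclomine.simulate import mutate_to_identity

        t = mutate_to_identity(seed_set.records_for_role("transporter")[0].sequence,
                               80.0, rng)
        f = GeneFeature("g", "c1", 101, 100 + 3 * len(t), "+", protein_id="t1",
                        translation=t)
        dna = "C" * 2000
        w = ClusterWindow("g", "c1", f, [f], (1, len(dna)), dna)
        bgc = classify_roles(w, seed_set)
        assert bgc.verdict == "fail"
        assert set(bgc.fail_reasons) == {"no_precursor", "no_spoiim"}

    def test_complete_cluster_passes_and_decoy_fails(self, seed_set, small_simulation):
        genomes, manifest = small_simulation
        verdicts = {}
        for genome in genomes:
            _hits, bgcs = mine_genome(genome, seed_set)
            for b in bgcs:
                verdicts[genome.genome_id] = (b.verdict, b.fail_reasons)
        reason_of = {"precursor": "no_precursor", "spoIIM": "no_spoiim",
                     "transporter": "no_transporter"}
        for cluster in manifest.complete_clusters():
            assert verdicts[cluster.genome_id][0] == "pass"
        for decoy in manifest.decoys():
            verdict, reasons = verdicts[decoy.genome_id]
            assert verdict == "fail"
            assert reason_of[decoy.spec.omit_role] in reasons

    def test_multi_copy_precursors_all_reported_in_one_bgc(self, seed_set, small_simulation):
        genomes, manifest = small_simulation
        multi = next(c for c in manifest.complete_clusters()
                     if c.spec.n_precursor_copies > 1)
        genome = next(g for g in genomes if g.genome_id == multi.genome_id)
        _hits, bgcs = mine_genome(genome, seed_set)
        passing = [b for b in bgcs if b.verdict == "pass"]
        assert len(passing) == 1  # one cluster stays one candidate BGC
        assert len(passing[0].precursor_candidates()) == multi.spec.n_precursor_copies

    def test_accessory_yip1_flag_from_homology(self, seed_set, small_simulation):
        genomes, manifest = small_simulation
        with_yip = next(c for c in manifest.complete_clusters() if c.spec.include_yip1)
        genome = next(g for g in genomes if g.genome_id == with_yip.genome_id)
        _hits, bgcs = mine_genome(genome, seed_set)
        b = next(b for b in bgcs if b.verdict == "pass")
        assert b.accessory_flags["yip1"]
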