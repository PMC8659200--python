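"""Domain types, genome loading/translation, and deterministic tables."""
import os

import pytest

from cyclomine.io import (
    load_annotated_genome,
    load_seed_set,
    read_protein_fasta,
    translate_cds,
    write_edge_list,
    write_genome_fasta,
    write_genome_gff3,
    write_protein_fasta,
)
from cyclomine.models import (
    CrossReferenceError,
    GeneFeature,
    GenomeRecord,
    ProteinRecord,
    SeedEntry,
    SeedSet,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestModels:
    def test_protein_record_rejects_bad_residues_and_empty(self):
        with pytest.raises(ValueError):
            ProteinRecord(id="x", sequence="")
        with pytest.raises(ValueError):
            ProteinRecord(id="x", sequence="MKU")

    def test_gene_feature_coordinate_and_strand_invariants(self):
        with pytest.raises(ValueError):
            GeneFeature("g", "c", 5, 3, "+")
        with pytest.raises(ValueError):
            GeneFeature("g", "c", 1, 3, "?")

    def test_seed_set_requires_transporter_and_spoiim(self):
        prec = SeedEntry("x", "precursor", "i", ProteinRecord(id="p", sequence="MK"))
        with pytest.raises(ValueError, match="transporter"):
            SeedSet(entries=[prec])

    def test_bundled_seed_set_contents(self, seed_set):
        names = {e.bacteriocin_name for e in seed_set.by_role("precursor")}
        assert len(names) == 19
        assert sum(1 for e in seed_set.by_role("precursor") if e.subgroup == "i") == 13
        assert sum(1 for e in seed_set.by_role("precursor") if e.subgroup == "ii") == 6
        # circularin A and thermocin 485 are identical peptides
        seqs = {e.bacteriocin_name: e.record.sequence for e in seed_set.by_role("precursor")}
        assert seqs["circularin A"] == seqs["thermocin 485"]


class TestTranslation:
    def test_simple_cds_translates_and_trims_stop(self):
        assert translate_cds("ATGAAATAA", "+") == "MK"

    def test_strands_agree_through_reverse_complement(self):
        from cyclomine.simulate import reverse_complement

        cds = "ATGAAATGTTGGTAA"
        assert translate_cds(reverse_complement(cds), "-") == translate_cds(cds, "+")

    def test_ambiguous_codon_yields_x(self):
        assert translate_cds("ATGNNATAA", "+").startswith("M")
        assert "X" in translate_cds("ATGNNATAA", "+")


class TestLoadAnnotatedGenome:
    def test_fasta_without_gff_has_no_features(self, tmp_path):
        fa = write(tmp_path, "g.fna", ">c1\nATGAAATAA\n")
        genome = load_annotated_genome(fa)
        assert genome.features == []
        assert genome.contigs["c1"] == "ATGAAATAA"

    def test_cds_feature_translated_with_bacterial_code(self, tmp_path):
        fa = write(tmp_path, "g.fna", ">c1\nATGAAATAA\n")
        gff = write(tmp_path, "g.gff3",
                    "##gff-version 3\nc1\t.\tCDS\t1\t9\t.\t+\t0\tID=gene1\n")
        genome = load_annotated_genome(fa, gff)
        assert len(genome.features) == 1
        assert genome.features[0].translation == "MK"

    def test_gff_contig_absent_from_fasta_is_cross_reference_error(self, tmp_path):
        fa = write(tmp_path, "g.fna", ">c1\nATGAAATAA\n")
        gff = write(tmp_path, "g.gff3",
                    "##gff-version 3\nc2\t.\tCDS\t1\t9\t.\t+\t0\tID=gene1\n")
        with pytest.raises(CrossReferenceError):
            load_annotated_genome(fa, gff)

    def test_internal_stop_flagged_and_excluded_from_proteome(self, tmp_path):
        fa = write(tmp_path, "g.fna", ">c1\nATGTAAAAATAA\n")
        gff = write(tmp_path, "g.gff3",
                    "##gff-version 3\nc1\t.\tCDS\t1\t12\t.\t+\t0\tID=gene1\n")
        genome = load_annotated_genome(fa, gff)
        assert genome.features[0].internal_stop
        assert genome.proteome() == []

    def test_round_trip_preserves_contigs_and_coordinates(self, tmp_path, small_simulation):
        genomes, _manifest = small_simulation
        g = genomes[0]
        fa = str(tmp_path / "rt.fna")
        gff = str(tmp_path / "rt.gff3")
        write_genome_fasta(g, fa)
        write_genome_gff3(g, gff)
        loaded = load_annotated_genome(fa, gff, genome_id=g.genome_id)
        assert loaded.contigs == g.contigs
        assert [(f.contig_id, f.start, f.end, f.strand) for f in loaded.features] == [
            (f.contig_id, f.start, f.end, f.strand) for f in g.features
        ]
        # translations re-derived from DNA match the originals
        by_coord = {(f.start, f.end): f.translation for f in loaded.features}
        for f in g.features:
            assert by_coord[(f.start, f.end)] == f.translation


class TestProteinFastaRoundTrip:
    def test_write_then_read(self, tmp_path):
        recs = [ProteinRecord(id="a", sequence="MKWLV", description="x"),
                ProteinRecord(id="b", sequence="M" * 100)]
        path = tmp_path / "p.faa"
        write_protein_fasta(recs, path)
        back = read_protein_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in recs]


class TestResultTables:
    @pytest.fixture()
    def analysis(self, seed_set, small_simulation):
        from cyclomine.mining import mine_genome
        from cyclomine.pipeline import RunConfig, analyze_mined_precursors

        genomes, _ = small_simulation
        bgcs = []
        for g in genomes:
            bgcs.extend(mine_genome(g, seed_set)[1])
        return bgcs, analyze_mined_precursors(bgcs, seed_set, RunConfig())

    def test_tables_regenerate_byte_identically(self, tmp_path, analysis):
        from cyclomine.io import write_results_tables

        bgcs, result = analysis
        passing = [b for b in bgcs if b.verdict == "pass"]
        d1, d2 = tmp_path / "one", tmp_path / "two"
        for d in (d1, d2):
            write_results_tables(passing, result.groups, result.profiles, str(d))
        for name in ("hits.tsv", "groups.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_group_summary_counts_unique_and_genomes(self, tmp_path, analysis):
        import pandas as pd

        from cyclomine.io import write_results_tables

        bgcs, result = analysis
        passing = [b for b in bgcs if b.verdict == "pass"]
        _hits, groups_path = write_results_tables(
            passing, result.groups, result.profiles, str(tmp_path))
        gdf = pd.read_csv(groups_path, sep="\t")
        assert gdf["n_unique"].sum() == result.report.unique_precursors

    def test_edge_list_round_trip(self, tmp_path, seed_set):
        import pandas as pd

        from cyclomine.ssn import build_ssn, dedupe_sequences

        nodes = dedupe_sequences([e.record for e in seed_set.by_role("precursor")])
        graph = build_ssn(nodes)
        edges_path, nodes_path = write_edge_list(graph, str(tmp_path) + os.sep)
        edf = pd.read_csv(edges_path, sep="\t")
        back = {frozenset((a, b)) for a, b in zip(edf["node_a"], edf["node_b"])}
        assert back == {frozenset((a, b)) for a, b, *_ in graph.edges}
        ndf = pd.read_csv(nodes_path, sep="\t")
        assert sorted(ndf["id"]) == sorted(n.id for n in graph.nodes)

    def test_empty_inputs_give_header_only_tables(self, tmp_path):
        from cyclomine.io import write_results_tables

        hits_path, groups_path = write_results_tables([], [], {}, str(tmp_path))
        assert len(open(hits_path).readlines()) == 1
        assert len(open(groups_path).readlines()) == 1
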