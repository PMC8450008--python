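"""Metadata validation, quality filtering, Kraken renaming, and library export."""

from __future__ import annotations

import gzip

import numpy as np
import pytest

from struoforge.genomes import (
    ContigSet,
    GenomeRecord,
    MetadataError,
    export_kraken_library,
    filter_genomes,
    load_metadata,
    read_fasta,
    rename_contigs_for_kraken,
    write_fasta,
    write_metadata,
)
from struoforge.taxonomy import build_taxdump, parse_gtdb_lineage


def _record(name, species="s__Sp a", completeness=99.0, contamination=1.0,
            accession="ACC", taxid=2):
    return GenomeRecord(
        taxon_name=name, accession=accession, fasta_path="unused.fna",
        taxid=taxid, genus="g__G", species=species,
        completeness=completeness, contamination=contamination,
    )


class TestMetadata:
    def _write_table(self, tmp_path, rows):
        fasta = tmp_path / "g.fna"
        write_fasta([("c1", "ACGT" * 10)], fasta)
        lines = ["taxon_name\taccession\tfasta_path\ttaxid\tgenus\tspecies"]
        for r in rows:
            lines.append("\t".join([r[0], "ACC", str(fasta), "5", "g__G", r[1]]))
        path = tmp_path / "meta.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_valid_table_loads_all_rows(self, tmp_path):
        path = self._write_table(tmp_path, [("a", "s1"), ("b", "s2"), ("c", "s3")])
        assert len(load_metadata(path)) == 3

    def test_duplicate_taxon_name_rejected(self, tmp_path):
        path = self._write_table(tmp_path, [("a", "s1"), ("a", "s2")])
        with pytest.raises(MetadataError, match="duplicate"):
            load_metadata(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("taxon_name\taccession\n x\ty\n")
        with pytest.raises(MetadataError, match="missing required columns"):
            load_metadata(path)

    def test_unreadable_fasta_path_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "taxon_name\taccession\tfasta_path\ttaxid\tgenus\tspecies\n"
            "a\tACC\t/nonexistent/g.fna\t5\tg__G\ts__S\n"
        )
        with pytest.raises(MetadataError, match="unreadable"):
            load_metadata(path)

    def test_round_trip_through_writer(self, tmp_path):
        path = self._write_table(tmp_path, [("a", "s1")])
        records = load_metadata(path)
        out = write_metadata(records, tmp_path / "copy.tsv")
        assert load_metadata(out) == records


class TestFilter:
    def test_thresholds_are_half_open(self):
        records = [
            _record("low_comp", completeness=49.9),
            _record("edge_comp", species="s__b", completeness=50.0),
            _record("edge_cont", species="s__c", contamination=5.0),
            _record("ok_cont", species="s__d", contamination=4.99),
        ]
        kept = {r.taxon_name for r in filter_genomes(records)}
        assert kept == {"edge_comp", "ok_cont"}

    def test_one_genome_per_species_by_completeness_then_contamination(self):
        records = [
            _record("a", completeness=99.0, contamination=1.0),
            _record("b", completeness=98.0, contamination=0.1),
        ]
        assert [r.taxon_name for r in filter_genomes(records)] == ["a"]

    def test_empty_input_gives_empty_output(self):
        assert filter_genomes([]) == []

    def test_missing_quality_fields_listed(self):
        with pytest.raises(MetadataError, match="nociq"):
            filter_genomes([_record("nociq", completeness=None)])

    def test_selection_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            records = [
                _record(
                    f"t{i}",
                    species=f"s__{rng.integers(5)}",
                    completeness=float(rng.uniform(30, 100)),
                    contamination=float(rng.uniform(0, 10)),
                    accession=f"A{i}",
                )
                for i in range(rng.integers(1, 25))
            ]
            kept = filter_genomes(records)
            passing = [
                r for r in records
                if r.completeness >= 50 and r.contamination < 5
            ]
            expected_species = {r.species for r in passing}
            assert {r.species for r in kept} == expected_species
            assert len(kept) == len(expected_species)
            for r in kept:  # no passing candidate strictly better
                for other in passing:
                    if other.species == r.species:
                        assert (-other.completeness, other.contamination,
                                other.accession) >= (
                            -r.completeness, r.contamination, r.accession)


class TestKrakenRename:
    def test_header_scheme_and_sequence_identity(self):
        cs = ContigSet("g", [("c1", "ACGTACGT")])
        renamed = rename_contigs_for_kraken(cs, 7)
        assert renamed.contigs == [("kraken:taxid|7|c1", "ACGTACGT")]

    def test_double_rename_guarded(self):
        renamed = rename_contigs_for_kraken(ContigSet("g", [("c1", "ACGT")]), 7)
        with pytest.raises(ValueError, match="already"):
            rename_contigs_for_kraken(renamed, 7)

    def test_nonpositive_taxid_rejected(self):
        with pytest.raises(ValueError):
            rename_contigs_for_kraken(ContigSet("g", [("c1", "ACGT")]), 0)


class TestLibraryExport:
    @staticmethod
    def _setup(tmp_path):
        lin1 = parse_gtdb_lineage("d__B;p__P;c__C;o__O;f__F;g__G1;s__G1 a")
        lin2 = parse_gtdb_lineage("d__B;p__P;c__C;o__O;f__F;g__G2;s__G2 b")
        dump = build_taxdump([lin1, lin2])
        t1 = dump.taxid_of("s__G1 a", "s")
        t2 = dump.taxid_of("s__G2 b", "s")
        cs1 = ContigSet("g1", [("c1", "ACGT" * 100), ("c2", "GGCC" * 50)])
        cs2 = ContigSet("g2", [("c1", "TTAA" * 80)])
        records = [
            GenomeRecord("g1", "A1", tmp_path / "g1.fna", t1, "g__G1", "s__G1 a"),
            GenomeRecord("g2", "A2", tmp_path / "g2.fna", t2, "g__G2", "s__G2 b"),
        ]
        return dump, records, {"g1": cs1, "g2": cs2}

    def test_contig_count_and_base_conservation(self, tmp_path):
        dump, records, contig_sets = self._setup(tmp_path)
        manifest = export_kraken_library(records, dump, tmp_path / "out",
                                         contig_sets=contig_sets)
        lib = read_fasta(manifest["library"][0])
        assert len(lib.contigs) == 3
        assert lib.total_length == sum(c.total_length for c in contig_sets.values())
        # per-genome concatenation preserved exactly
        by_header = dict(lib.contigs)
        for rec in records:
            joined = "".join(
                by_header[f"kraken:taxid|{rec.taxid}|{cid}"]
                for cid, _ in contig_sets[rec.taxon_name].contigs
            )
            original = "".join(s for _, s in contig_sets[rec.taxon_name].contigs)
            assert joined == original

    def test_taxid_absent_from_taxdump_names_the_genome(self, tmp_path):
        dump, records, contig_sets = self._setup(tmp_path)
        bad = records[0].__class__(**{**records[0].__dict__, "taxid": 999})
        with pytest.raises(ValueError, match="g1"):
            export_kraken_library([bad], dump, tmp_path / "out",
                                  contig_sets=contig_sets)


def test_gzip_detected_by_magic_bytes_not_extension(tmp_path):
    path = tmp_path / "genome.txt"  # misleading extension
    with gzip.open(path, "wt") as fh:
        fh.write(">c1\nACGTACGT\n")
    cs = read_fasta(path)
    assert cs.contigs == [("c1", "ACGTACGT")]
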