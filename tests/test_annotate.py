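"""Reference search, propagation, 90->50 mapping, HUMAnN export, update path."""

from __future__ import annotations

import numpy as np
import pytest

from struoforge._align import align_aa
from struoforge.annotate import (
    AnnotationError,
    Annotation,
    ReferenceDB,
    batch_queries,
    export_humann_fastas,
    format_humann_header,
    map_uniref50,
    propagate_annotations,
    search_reference,
    update_annotations,
)
from struoforge.cluster import cluster_genes, update_clusters
from struoforge.genecat import GeneRecord, GenesDB

AA = "ACDEFGHIKLMNPQRSTVWY"


def aa_gene(gene_id, aa_seq, genus="g__Synth", species="s__Synth sp"):
    nt = "ATG" + "GCT" * len(aa_seq) + "TAA"
    return GeneRecord(
        gene_id=gene_id, genome_id="g", contig_id="c", start=0, end=len(nt),
        strand="+", nt_seq=nt, aa_seq=aa_seq, genus=genus, species=species,
    )


def random_protein(rng, n=100):
    return "".join(rng.choice(list(AA), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestBatching:
    @pytest.mark.parametrize(
        "n_reps, n_batches, sizes",
        [(10, 3, [4, 3, 3]), (5, 1, [5]), (2, 5, [1, 1, 0, 0, 0])],
    )
    def test_balanced_partition(self, rng, n_reps, n_batches, sizes):
        reps = [aa_gene(f"g{i}", random_protein(rng)) for i in range(n_reps)]
        batches = batch_queries(reps, n_batches)
        assert [len(b) for b in batches] == sizes
        flat = [g.gene_id for b in batches for g in b]
        assert sorted(flat) == sorted(g.gene_id for g in reps)

    def test_invalid_batch_count(self, rng):
        with pytest.raises(ValueError):
            batch_queries([], 0)


class TestSearch:
    def test_identical_protein_scores_identity_one(self, rng):
        seq = random_protein(rng)
        ref = ReferenceDB(proteins={"U90_A": seq, "U90_B": random_protein(rng)})
        hits = search_reference([aa_gene("q", seq)], ref)
        assert len(hits) == 1
        assert (hits[0].ref_id, hits[0].identity) == ("U90_A", 1.0)

    def test_unrelated_reference_gives_no_hit(self, rng):
        ref = ReferenceDB(proteins={"U90_A": random_protein(rng)})
        assert search_reference([aa_gene("q", random_protein(rng))], ref) == []

    def test_best_hit_matches_bruteforce_scoring_oracle(self, rng):
        query = aa_gene("q", random_protein(rng, 120))
        ref = ReferenceDB(
            proteins={
                f"U90_{i}": _blend(rng, query.aa_seq, keep)
                for i, keep in enumerate([0.95, 0.9, 0.85, 0.8])
            }
        )
        hits = search_reference([query], ref, min_identity=0.5, min_coverage=0.8)
        assert len(hits) == 1
        # oracle: score every pair exhaustively and take the maximum
        scored = {
            rid: align_aa(query.aa_seq, seq).score
            for rid, seq in ref.proteins.items()
        }
        assert hits[0].ref_id == max(sorted(scored), key=lambda r: scored[r])

    def test_result_independent_of_batching(self, rng):
        reps = [aa_gene(f"g{i}", random_protein(rng)) for i in range(7)]
        ref = ReferenceDB(proteins={"U90_A": reps[0].aa_seq, "U90_B": reps[3].aa_seq})
        assert search_reference(reps, ref, n_batches=1) == search_reference(
            reps, ref, n_batches=4
        )


def _blend(rng, seq, keep_fraction):
    out = list(seq)
    for p in rng.choice(len(seq), size=int(len(seq) * (1 - keep_fraction)),
                        replace=False):
        out[p] = AA[int(rng.integers(len(AA)))]
    return "".join(out)


class TestPropagation:
    def _cluster_of_five(self, rng):
        base = random_protein(rng)
        genes = [aa_gene(f"m{i}", _blend(rng, base, 0.97)) for i in range(5)]
        return genes, cluster_genes(genes)

    def test_annotated_cluster_propagates_to_all_members(self, rng):
        genes, db = self._cluster_of_five(rng)
        assert db.n_clusters() == 1
        rep = db.rep_order[0]
        ref = ReferenceDB(proteins={"U90_X": db.sequences[rep]})
        hits = search_reference([g for g in genes if g.gene_id == rep], ref)
        anns = propagate_annotations(db, hits)
        assert len(anns) == 5
        assert {a.uniref90_id for a in anns} == {"U90_X"}
        assert sum(a.source == "searched" for a in anns) == 1
        assert sum(a.source == "propagated" for a in anns) == 4

    def test_unannotated_cluster_yields_nothing(self, rng):
        _, db = self._cluster_of_five(rng)
        assert propagate_annotations(db, []) == []

    def test_hit_for_nonrepresentative_rejected(self, rng):
        genes, db = self._cluster_of_five(rng)
        non_rep = next(g for g in genes if g.gene_id != db.rep_order[0])
        ref = ReferenceDB(proteins={"U90_X": non_rep.aa_seq})
        bad_hits = search_reference([non_rep], ref)
        with pytest.raises(AnnotationError):
            propagate_annotations(db, bad_hits)


class TestUniref50:
    def test_mapping_fills_flags_and_is_idempotent(self):
        ref = ReferenceDB(proteins={}, id_map={"U90_A": "U50_X"})
        anns = [Annotation("g1", "U90_A"), Annotation("g2", "U90_B")]
        mapped, unmapped = map_uniref50(anns, ref)
        assert mapped[0].uniref50_id == "U50_X"
        assert mapped[1].uniref50_id == ""
        assert unmapped == 1
        again, unmapped2 = map_uniref50(mapped, ref)
        assert again == mapped and unmapped2 == 1


class TestHumannExport:
    def test_header_format_and_round_trip(self):
        gene = aa_gene("g1", "M" * 101, genus="g__Escherichia",
                       species="s__Escherichia coli")
        ann = Annotation("g1", "UniRef90_Q6GZX4")
        header = format_humann_header(gene, ann)
        assert header == (
            f"UniRef90_Q6GZX4|{len(gene.nt_seq)}|g__Escherichia;s__Escherichia coli"
        )
        uniref, length, taxon = header.split("|")
        assert (uniref, int(length)) == ("UniRef90_Q6GZX4", len(gene.nt_seq))
        assert taxon.split(";") == ["g__Escherichia", "s__Escherichia coli"]

    def test_unannotated_gene_rejected(self):
        with pytest.raises(AnnotationError):
            format_humann_header(aa_gene("g1", "MKLV"), Annotation("g1", ""))

    def test_export_counts_and_matching_headers(self, rng, tmp_path):
        genes = [aa_gene(f"g{i}", random_protein(rng)) for i in range(10)]
        db = GenesDB(genes=genes)
        anns = [Annotation(f"g{i}", f"U90_{i}") for i in range(7)]
        paths = export_humann_fastas(db, anns, tmp_path)
        nt_headers = [l[1:] for l in paths["nt"].read_text().splitlines()
                      if l.startswith(">")]
        aa_headers = [l[1:] for l in paths["aa"].read_text().splitlines()
                      if l.startswith(">")]
        assert len(nt_headers) == len(aa_headers) == 7
        assert nt_headers == aa_headers

    def test_zero_annotated_warns_and_writes_empty(self, rng, tmp_path):
        db = GenesDB(genes=[aa_gene("g0", random_protein(rng))])
        with pytest.warns(UserWarning, match="no annotated"):
            paths = export_humann_fastas(db, [], tmp_path)
        assert paths["nt"].read_text() == ""


class TestUpdatePath:
    def _setup(self, rng):
        old = [aa_gene(f"a{i}", random_protein(rng, 120)) for i in range(4)]
        ref = ReferenceDB(
            proteins={f"U90_{i}": g.aa_seq for i, g in enumerate(old)},
            id_map={f"U90_{i}": f"U50_{i // 2}" for i in range(5)},
        )
        db = cluster_genes(old)
        hits = search_reference(old, ref)
        anns, _ = map_uniref50(propagate_annotations(db, hits), ref)
        return old, ref, db, anns

    def test_only_new_representatives_searched(self, rng):
        old, ref, db, anns = self._setup(rng)
        new = [aa_gene("b0", random_protein(rng, 110))]
        db2, new_reps = update_clusters(db, new)
        assert new_reps == {"b0"}
        searched: list[str] = []

        def instrumented(reps, *args, **kwargs):
            searched.extend(g.gene_id for g in reps)
            return search_reference(reps, *args, **kwargs)

        genes = {g.gene_id: g for g in old + new}
        update_annotations(db2, new_reps, anns, ref, genes,
                           search_fn=instrumented)
        assert searched == ["b0"]

    def test_untouched_cluster_annotations_are_byte_identical(self, rng):
        old, ref, db, anns = self._setup(rng)
        new = [aa_gene("b0", random_protein(rng, 110))]
        db2, new_reps = update_clusters(db, new)
        genes = {g.gene_id: g for g in old + new}
        out = update_annotations(db2, new_reps, anns, ref, genes)
        old_ids = {a.gene_id for a in anns}
        assert [a for a in out if a.gene_id in old_ids] == sorted(
            anns, key=lambda a: a.gene_id
        )

    def test_gene_added_to_old_cluster_inherits_annotation(self, rng):
        old, ref, db, anns = self._setup(rng)
        joiner = aa_gene("b0", _blend(rng, old[0].aa_seq, 0.97)[:115])
        db2, new_reps = update_clusters(db, [joiner])
        assert new_reps == set()
        genes = {g.gene_id: g for g in old + [joiner]}
        out = update_annotations(db2, new_reps, anns, ref, genes)
        b0 = next(a for a in out if a.gene_id == "b0")
        rep_ann = next(a for a in anns if a.gene_id == db2.members["b0"])
        assert b0.uniref90_id == rep_ann.uniref90_id
        assert b0.source == "propagated"

    def test_unknown_new_cluster_rejected(self, rng):
        old, ref, db, anns = self._setup(rng)
        with pytest.raises(AnnotationError, match="unknown"):
            update_annotations(db, {"ghost"}, anns, ref,
                               {g.gene_id: g for g in old})
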