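"""End-to-end database build and update workflows with manifest tracking.

``build_all`` runs metadata loading -> gene calling/dereplication ->
amino-acid clustering -> reference search/propagation/50%-mapping ->
export of the Kraken2 library+taxonomy, the genes database (nt/aa FASTA +
metadata), the cluster table and the HUMAnN input FASTAs.  ``update_all``
extends an existing output directory with new genomes (full per-genome gene
pipeline) or standalone amino-acid genes, re-searching only representatives
of newly formed clusters.

Every run writes a manifest recording content digests of all inputs and
outputs plus the full parameter set; identical inputs and parameters
reproduce identical output digests.  Orchestration is plain in-process
sequencing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    Annotation,
    ReferenceDB,
    export_humann_fastas,
    map_uniref50,
    propagate_annotations,
    read_annotations,
    search_reference,
    update_annotations,
    write_annotations,
)
from .cluster import cluster_genes, read_cluster_db, update_clusters, write_cluster_db
from .genecat import (
    GeneRecord,
    GenesDB,
    build_genes_db,
    genes_from_genome,
    read_genes_db,
    write_genes_db,
)
from .genomes import GenomeRecord, export_kraken_library, load_metadata
from .taxonomy import build_taxdump, parse_gtdb_lineage

DEFAULT_CONFIG: dict[str, float | int] = {
    "min_gene_len": 300,
    "derep_identity": 0.97,
    "cluster_identity": 0.9,
    "cluster_coverage": 0.8,
    "search_min_identity": 0.5,
    "search_min_coverage": 0.8,
    "n_batches": 1,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class BuildManifest:
    version: str
    params: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> Path:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "params": self.params,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "timings": self.timings,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        return path

    @classmethod
    def read(cls, path: Path) -> "BuildManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(version=d["version"], params=d["params"], inputs=d["inputs"],
                   outputs=d["outputs"], timings=d.get("timings", {}))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path | None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(config)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    return config


def _taxdump_from_records(records: Sequence[GenomeRecord]):
    """Build the taxdump for a genome collection and remap record taxids.

    Taxid assignment is deterministic but collection-relative (breadth-first
    over the lineage set), so the taxdump built from this run's sample table
    is authoritative: each record's taxid is reassigned to its species node.
    Returns (taxdump, records-with-remapped-taxids).
    """
    lineages = []
    for r in records:
        if not r.gtdb_taxonomy:
            raise PipelineError(
                f"genome {r.taxon_name!r} lacks a gtdb_taxonomy lineage string"
            )
        lineages.append(parse_gtdb_lineage(r.gtdb_taxonomy))
    taxdump = build_taxdump(lineages)
    species_taxids = taxdump.species_taxids()
    remapped = [
        dataclasses.replace(r, taxid=species_taxids[lin.species])
        for r, lin in zip(records, lineages)
    ]
    return taxdump, remapped


def _digest_outputs(out_dir: Path) -> dict[str, str]:
    digests = {}
    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            digests[str(p.relative_to(out_dir))] = sha256_file(p)
    return digests


def _annotate(
    genes_db: GenesDB, cluster_db, ref: ReferenceDB, config: dict
) -> list[Annotation]:
    by_id = genes_db.by_id()
    reps = [by_id[r] for r in cluster_db.rep_order]
    hits = search_reference(
        reps, ref,
        min_identity=config["search_min_identity"],
        min_coverage=config["search_min_coverage"],
        n_batches=int(config["n_batches"]),
    )
    annotations = propagate_annotations(cluster_db, hits)
    annotations, _ = map_uniref50(annotations, ref)
    return annotations


def build_all(
    samples: str | Path,
    reference: str | Path,
    config: str | Path | dict | None,
    out_dir: str | Path,
    id_map: str | Path | None = None,
) -> BuildManifest:
    """Run the full database build and write all output groups.

    ``reference`` is the annotation protein FASTA; ``id_map`` the two-column
    UniRef90->UniRef50 TSV (defaults to ``<reference dir>/uniref90_to_uniref50.tsv``
    when present).
    """
    samples = Path(samples)
    reference = Path(reference)
    if not reference.is_file():
        raise PipelineError(f"reference protein FASTA not found: {reference}")
    out_dir = Path(out_dir)
    cfg = config if isinstance(config, dict) else load_config(config)
    if id_map is None:
        cand = reference.parent / "uniref90_to_uniref50.tsv"
        id_map = cand if cand.is_file() else None

    manifest = BuildManifest(version=__version__, params=dict(cfg))
    manifest.inputs[str(samples)] = sha256_file(samples)
    manifest.inputs[str(reference)] = sha256_file(reference)
    if id_map is not None:
        manifest.inputs[str(id_map)] = sha256_file(id_map)

    t0 = time.monotonic()
    records = load_metadata(samples)
    for r in records:
        manifest.inputs[str(r.fasta_path)] = sha256_file(r.fasta_path)
    taxdump, records = _taxdump_from_records(records)
    manifest.timings["load"] = time.monotonic() - t0

    t0 = time.monotonic()
    genes_db = build_genes_db(
        records,
        min_len=int(cfg["min_gene_len"]),
        derep_identity=cfg["derep_identity"],
    )
    manifest.timings["genes"] = time.monotonic() - t0

    t0 = time.monotonic()
    cluster_db = cluster_genes(
        genes_db, identity=cfg["cluster_identity"], coverage=cfg["cluster_coverage"]
    )
    manifest.timings["cluster"] = time.monotonic() - t0

    t0 = time.monotonic()
    ref = ReferenceDB.from_files(reference, id_map)
    annotations = _annotate(genes_db, cluster_db, ref, cfg)
    manifest.timings["annotate"] = time.monotonic() - t0

    t0 = time.monotonic()
    export_kraken_library(records, taxdump, out_dir / "kraken2")
    write_genes_db(genes_db, out_dir / "genes")
    write_cluster_db(cluster_db, out_dir / "cluster")
    write_annotations(annotations, out_dir / "annotations" / "annotations.tsv")
    export_humann_fastas(genes_db, annotations, out_dir / "humann")
    manifest.timings["export"] = time.monotonic() - t0

    manifest.outputs = _digest_outputs(out_dir)
    manifest.write(out_dir / "manifest.json")
    return manifest


def _load_existing(existing: Path):
    manifest = BuildManifest.read(existing / "manifest.json")
    for rel, digest in manifest.outputs.items():
        p = existing / rel
        if not p.is_file() or sha256_file(p) != digest:
            raise PipelineError(f"existing database is corrupt: digest mismatch for {rel}")
    genes_db = read_genes_db(existing / "genes")
    sequences = {g.gene_id: g.aa_seq for g in genes_db.genes}
    cluster_db = read_cluster_db(existing / "cluster", sequences)
    annotations = read_annotations(existing / "annotations" / "annotations.tsv")
    return manifest, genes_db, cluster_db, annotations


def _load_standalone_genes(gene_dir: Path) -> list[GeneRecord]:
    """Standalone aa gene input: genes.faa + genes_metadata.tsv (+ genes.fna)."""
    from Bio import SeqIO

    faa = gene_dir / "genes.faa"
    meta_path = gene_dir / "genes_metadata.tsv"
    if not faa.is_file():
        raise PipelineError(f"standalone gene input lacks genes.faa: {gene_dir}")
    if not meta_path.is_file():
        raise PipelineError(
            "standalone gene input lacks per-gene taxonomy metadata "
            f"(genes_metadata.tsv): {gene_dir}"
        )
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("gene_id", "genus", "species"):
        if col not in meta.columns:
            raise PipelineError(f"standalone gene metadata lacks column {col!r}")
    meta_by_id = meta.set_index("gene_id")
    nt: dict[str, str] = {}
    fna = gene_dir / "genes.fna"
    if fna.is_file():
        with open(fna) as fh:
            nt = {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}
    genes = []
    with open(faa) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id not in meta_by_id.index:
                raise PipelineError(f"standalone gene {rec.id!r} missing from metadata")
            row = meta_by_id.loc[rec.id]
            aa = str(rec.seq)
            genes.append(
                GeneRecord(
                    gene_id=rec.id,
                    genome_id=str(row.get("genome_id", "standalone")),
                    contig_id="standalone",
                    start=0,
                    end=3 * (len(aa) + 1),
                    strand="+",
                    nt_seq=nt.get(rec.id, ""),
                    aa_seq=aa,
                    genus=str(row["genus"]),
                    species=str(row["species"]),
                )
            )
    return genes


def update_all(
    existing: str | Path,
    new_input: str | Path,
    config: str | Path | dict | None,
    out_dir: str | Path,
    reference: str | Path | None = None,
    id_map: str | Path | None = None,
) -> BuildManifest:
    """Update an existing database directory with new genomes or genes.

    ``new_input`` is either a genome metadata TSV (full per-genome gene
    pipeline) or a directory of standalone amino-acid genes with per-gene
    taxonomy metadata (enters directly at cluster update).  Only
    representatives of newly formed clusters are searched against the
    reference; all prior annotations are carried over verbatim.
    """
    existing = Path(existing)
    new_input = Path(new_input)
    out_dir = Path(out_dir)
    cfg = config if isinstance(config, dict) else load_config(config)

    manifest_old, genes_db, cluster_db, annotations = _load_existing(existing)
    if reference is None:
        ref_inputs = [p for p in manifest_old.inputs if p.endswith(".faa")]
        if not ref_inputs:
            raise PipelineError("cannot locate the reference FASTA; pass reference=")
        reference = Path(ref_inputs[0])
    reference = Path(reference)
    if id_map is None:
        cand = reference.parent / "uniref90_to_uniref50.tsv"
        id_map = cand if cand.is_file() else None
    ref = ReferenceDB.from_files(reference, id_map)

    manifest = BuildManifest(version=__version__, params=dict(cfg))
    manifest.inputs[str(new_input)] = (
        sha256_file(new_input) if new_input.is_file() else "directory"
    )

    new_records: list[GenomeRecord] = []
    t0 = time.monotonic()
    if new_input.is_file():  # genome metadata table
        new_records = load_metadata(new_input)
        existing_genomes = {g.genome_id for g in genes_db.genes}
        clash = [r.taxon_name for r in new_records if r.taxon_name in existing_genomes]
        if clash:
            raise PipelineError(f"new genomes already present in catalog: {clash}")
        new_genes: list[GeneRecord] = []
        for r in new_records:
            new_genes.extend(
                genes_from_genome(
                    r,
                    min_len=int(cfg["min_gene_len"]),
                    derep_identity=cfg["derep_identity"],
                )
            )
    else:
        new_genes = _load_standalone_genes(new_input)
    manifest.timings["genes"] = time.monotonic() - t0

    t0 = time.monotonic()
    merged_genes = GenesDB(genes=list(genes_db.genes) + new_genes)
    cluster_new, new_rep_ids = update_clusters(cluster_db, new_genes)
    manifest.timings["cluster"] = time.monotonic() - t0

    t0 = time.monotonic()
    merged_by_id = merged_genes.by_id()
    new_annotations = update_annotations(
        cluster_new, new_rep_ids, annotations, ref, merged_by_id,
        min_identity=cfg["search_min_identity"],
        min_coverage=cfg["search_min_coverage"],
    )
    new_annotations, _ = map_uniref50(new_annotations, ref)
    manifest.timings["annotate"] = time.monotonic() - t0

    t0 = time.monotonic()
    # Kraken library/taxonomy: all genomes, old lineages re-read from the old
    # metadata input when available, new genomes appended
    old_meta_paths = [
        p for p in manifest_old.inputs
        if p.endswith(".tsv") and "uniref" not in Path(p).name
    ]
    all_records: list[GenomeRecord] = []
    for p in old_meta_paths:
        if Path(p).is_file():
            try:
                all_records.extend(load_metadata(p))
            except Exception:
                continue
    all_records.extend(new_records)
    if all_records:
        taxdump, all_records = _taxdump_from_records(all_records)
        export_kraken_library(all_records, taxdump, out_dir / "kraken2")
    write_genes_db(merged_genes, out_dir / "genes")
    write_cluster_db(cluster_new, out_dir / "cluster")
    write_annotations(new_annotations, out_dir / "annotations" / "annotations.tsv")
    export_humann_fastas(merged_genes, new_annotations, out_dir / "humann")
    manifest.timings["export"] = time.monotonic() - t0

    manifest.outputs = _digest_outputs(out_dir)
    manifest.write(out_dir / "manifest.json")
    return manifest
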