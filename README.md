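# struoforge

Tools for building and updating custom metagenome-profiling databases from
collections of microbial genomes (isolates or MAGs), for researchers who run
taxonomic profiling with Kraken2/Bracken and functional profiling with
HUMAnN3 against reference sets of their own choosing — typically GTDB-style
genome collections rather than the default NCBI-derived databases.

## What it does

Given a genome metadata table (taxon name, assembly FASTA, GTDB lineage,
optional CheckM completeness/contamination) and a reference protein set
with a UniRef90→UniRef50 identifier index, `struoforge` builds:

* **Kraken2 inputs** — contigs renamed to `kraken:taxid|<taxid>|<seqid>`
  plus NCBI-dialect taxdump files (`nodes.dmp`/`names.dmp`) generated from
  the GTDB lineage strings (root = taxid 1; remaining taxids assigned
  breadth-first with lexicographic sibling order, so the assignment is
  deterministic and independent of input order).
* **A genes database** — ORFs called per genome, dereplicated at 97%
  nucleotide identity (greedy centroid, longest first), pooled with
  per-gene provenance metadata, kept in both nucleotide and amino-acid
  alphabets.
* **A cluster database** — greedy centroid clustering of amino-acid
  sequences (global alignment identity ≥ 0.9 and short-sequence coverage
  ≥ 0.8 by default). Incremental update adds new genes without touching
  existing representatives or memberships.
* **HUMAnN3 inputs** — cluster representatives are searched against the
  reference proteins, the best hit is propagated to every cluster member,
  UniRef90 ids are mapped to UniRef50 through the index (no second
  annotation round), and annotated genes are exported with headers
  `<uniref90_id>|<nt_length>|g__<genus>;s__<species>`.

Updating an existing database with new genomes (or standalone amino-acid
genes with per-gene taxonomy) re-searches **only** the representatives of
newly formed clusters; everything else is carried over verbatim.

Two companion components quantify database quality:

* `missim` — a misassembly simulator introducing breakpoints (contig
  splits), rearrangements (intra-genome fragment relocation) and chimerisms
  (inter-genome relocation), with uniform breakpoint placement, fragment
  sizes uniform on 1–10 kb, and a complete, replayable event log.
* `evaluate` — annotation recovery versus a ground-truth catalog
  (percent annotated, percent with the correct UniRef90 id), Bray–Curtis
  dissimilarity BC(p,q) = Σ|pᵢ−qᵢ| / Σ(pᵢ+qᵢ), Mantel tests (Pearson
  correlation of distance-matrix upper triangles, permutation p-value with
  the +1 correction, optional exhaustive enumeration), and OLS R².

A `fixtures` module generates complete synthetic inputs — genomes with
planted gene families in start-codon-free background, matching reference
proteins with a known 90→50 index, and log-normal community profiles — so
the whole pipeline runs and is tested without any downloads.

## Worked example

```bash
struoforge fixtures --preset small --seed 5 --outdir fx
struoforge build --samples fx/metadata.tsv --reference fx/reference.faa --outdir db
```

which prints:

```
metadata: fx/metadata.tsv
truth: fx/truth_genes.tsv
reference: fx/reference.faa
id_map: fx/uniref90_to_uniref50.tsv
genome_dir: fx/genomes
wrote 11 files to db
```

`db/` now holds `kraken2/library/library.fna` (taxid-tagged contigs) and
`kraken2/taxonomy/{nodes,names}.dmp`, the genes database
(`genes/genes.{fna,faa}` + `genes_metadata.tsv`), the cluster table
(`cluster/clusters.tsv`, one `gene_id → representative_id` row per gene),
per-gene annotations (`annotations/annotations.tsv`) and the HUMAnN input
FASTAs (`humann/humann_genes.{fna,faa}`). `manifest.json` records SHA-256
digests of every input and output; rerunning the same command reproduces
identical digests.

Simulate misassemblies and compare profiles:

```bash
struoforge missim --genomes fx/genomes --breakpoints 2 --rearrangements 1 \
    --chimerisms 1 --seed 3 --outdir mis
struoforge evaluate recovery --truth db/annotations/annotations.tsv \
    --test db_mis/annotations/annotations.tsv
```

The recovery command prints `{"pct_annotated": ..., "pct_correct": ...}` —
the share of ground-truth-annotated genes that the degraded database still
annotates, and the share that keep the correct UniRef90 identifier.

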