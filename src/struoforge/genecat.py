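"""Gene catalog construction: ORF calling, per-genome dereplication, pooling.

Gene calling here is a deliberately simple, deterministic ORF scanner (a
documented stand-in for a dedicated gene caller): maximal open reading
frames from a start codon (ATG/GTG/TTG) to the next in-frame stop, on both
strands and all three frames, kept when the nucleotide length (stop codon
included) reaches ``min_len``.  Within one stop-codon/frame combination only
the longest ORF is reported.  Per genome, called genes are dereplicated at
97% nucleotide identity by greedy centroid selection (longest first), then
pooled across genomes into a genes database carrying both nucleotide and
amino-acid sequences plus per-gene provenance metadata.

Coordinates are 0-based, half-open, always on the forward strand; for a
minus-strand gene the stored nucleotide sequence is the reverse complement
of the forward-strand slice.  Amino-acid sequences are the direct
translation of the coding sequence with the stop codon trimmed (alternative
start codons are not rewritten to methionine).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from ._align import align_nt
from .genomes import ContigSet, GenomeRecord, read_fasta

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
MIN_GENE_LEN = 300
DEREP_IDENTITY = 0.97


@dataclass(frozen=True)
class GeneRecord:
    """A called gene with provenance, coordinates and both sequence alphabets."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    nt_seq: str
    aa_seq: str
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene end must exceed start (half-open coordinates)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GenesDB:
    """Pooled, dereplicated gene catalog with per-gene metadata."""

    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_ids in a GenesDB must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "contig_id": g.contig_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "nt_length": len(g.nt_seq),
                "genus": g.genus,
                "species": g.species,
            }
            for g in self.genes
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "genome_id", "contig_id", "start", "end",
                "strand", "nt_length", "genus", "species",
            ],
        )


def translate_orf(nt_seq: str) -> str:
    """Translate a coding sequence (stop codon trimmed from the output)."""
    if len(nt_seq) % 3 != 0:
        raise ValueError("coding sequence length must be a multiple of 3")
    aa = str(Seq(nt_seq).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in coding sequence")
    return aa


def _scan_frame(seq: str, frame: int, min_len: int) -> list[tuple[int, int]]:
    """Maximal ORFs [start, end) in one frame of one strand of ``seq``.

    For each stop codon, the earliest start codon after the previous stop is
    used, giving the longest ORF per stop per frame.
    """
    orfs = []
    first_start: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if first_start is not None and (pos + 3 - first_start) >= min_len:
                orfs.append((first_start, pos + 3))
            first_start = None
        elif first_start is None and codon in START_CODONS:
            first_start = pos
    return orfs


def call_genes(
    contigs: ContigSet, min_len: int = MIN_GENE_LEN
) -> list[GeneRecord]:
    """Call maximal ORFs of nucleotide length >= ``min_len`` on both strands.

    Returned genes are sorted by (contig, start, end, strand) and carry ids
    ``<contig>|<start>-<end>|<strand>`` unique within the genome.
    """
    genes: list[GeneRecord] = []
    for contig_id, seq in contigs.contigs:
        length = len(seq)
        rc = str(Seq(seq).reverse_complement())
        for strand, scan_seq in (("+", seq), ("-", rc)):
            for frame in range(3):
                for s, e in _scan_frame(scan_seq, frame, min_len):
                    if strand == "+":
                        start, end = s, e
                        nt = seq[start:end]
                    else:
                        start, end = length - e, length - s
                        nt = rc[s:e]
                    genes.append(
                        GeneRecord(
                            gene_id=f"{contig_id}|{start}-{end}|{strand}",
                            genome_id=contigs.genome_id,
                            contig_id=contig_id,
                            start=start,
                            end=end,
                            strand=strand,
                            nt_seq=nt,
                            aa_seq=translate_orf(nt),
                        )
                    )
    genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.strand))
    return genes


def dereplicate(
    genes: Sequence[GeneRecord], identity: float = DEREP_IDENTITY
) -> list[GeneRecord]:
    """Greedy centroid dereplication of one genome's genes on nucleotides.

    Candidates are processed longest-first (ties by gene_id); a gene is
    discarded iff its global-alignment identity to an already retained gene
    reaches ``identity``.  Output preserves the processing order, making the
    operation deterministic and idempotent.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    ordered = sorted(genes, key=lambda g: (-len(g.nt_seq), g.gene_id))
    retained: list[GeneRecord] = []
    for gene in ordered:
        redundant = any(
            gene.nt_seq == kept.nt_seq
            or align_nt(gene.nt_seq, kept.nt_seq).identity >= identity
            for kept in retained
        )
        if not redundant:
            retained.append(gene)
    return retained


def genes_from_genome(
    record: GenomeRecord,
    contigs: ContigSet | None = None,
    min_len: int = MIN_GENE_LEN,
    derep_identity: float = DEREP_IDENTITY,
) -> list[GeneRecord]:
    """Call and dereplicate genes for one genome, namespaced by taxon name."""
    if contigs is None:
        contigs = read_fasta(record.fasta_path, genome_id=record.taxon_name)
    called = call_genes(contigs, min_len=min_len)
    kept = dereplicate(called, identity=derep_identity)
    return [
        replace(
            g,
            gene_id=f"{record.taxon_name}|{g.gene_id}",
            genome_id=record.taxon_name,
            genus=record.genus,
            species=record.species,
        )
        for g in kept
    ]


def build_genes_db(
    records: Sequence[GenomeRecord],
    contig_sets: dict[str, ContigSet] | None = None,
    min_len: int = MIN_GENE_LEN,
    derep_identity: float = DEREP_IDENTITY,
) -> GenesDB:
    """Per-genome call + dereplicate, then pool into one catalog.

    A genome yielding zero genes is kept in the run (warning semantics: it
    simply contributes no rows).
    """
    pooled: list[GeneRecord] = []
    for record in records:
        contigs = None if contig_sets is None else contig_sets.get(record.taxon_name)
        pooled.extend(
            genes_from_genome(
                record, contigs=contigs, min_len=min_len, derep_identity=derep_identity
            )
        )
    return GenesDB(genes=pooled)


def write_genes_db(db: GenesDB, out_dir: str | Path) -> dict[str, Path]:
    """Write the catalog as nt FASTA + aa FASTA + metadata TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nt_path = out_dir / "genes.fna"
    aa_path = out_dir / "genes.faa"
    meta_path = out_dir / "genes_metadata.tsv"
    with open(nt_path, "w") as nt_fh, open(aa_path, "w") as aa_fh:
        for g in db.genes:
            nt_fh.write(f">{g.gene_id}\n{g.nt_seq}\n")
            aa_fh.write(f">{g.gene_id}\n{g.aa_seq}\n")
    db.metadata().to_csv(meta_path, sep="\t", index=False)
    return {"nt": nt_path, "aa": aa_path, "metadata": meta_path}


def read_genes_db(out_dir: str | Path) -> GenesDB:
    """Read a catalog previously written by :func:`write_genes_db`."""
    out_dir = Path(out_dir)
    meta = pd.read_csv(out_dir / "genes_metadata.tsv", sep="\t")
    nt = {c.id: str(c.seq) for c in _iter_fasta(out_dir / "genes.fna")}
    aa = {c.id: str(c.seq) for c in _iter_fasta(out_dir / "genes.faa")}
    genes = []
    for _, row in meta.iterrows():
        gid = row["gene_id"]
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome_id=row["genome_id"],
                contig_id=row["contig_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                nt_seq=nt[gid],
                aa_seq=aa[gid],
                genus="" if pd.isna(row["genus"]) else str(row["genus"]),
                species="" if pd.isna(row["species"]) else str(row["species"]),
            )
        )
    return GenesDB(genes=genes)


def _iter_fasta(path: Path):
    from Bio import SeqIO

    with open(path) as fh:
        yield from SeqIO.parse(fh, "fasta")
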