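"""Genome metadata tables, FASTA I/O, quality filtering, and Kraken2 export.

The input is a tab-delimited sample table with one genome per row: a unique
taxon name, an accession, the path to a (optionally gzipped) assembly FASTA,
the species taxid, genus and species names, and optional CheckM-style
completeness/contamination estimates.  Genomes passing quality filters are
exported as a Kraken2-ready library: contigs renamed to
``kraken:taxid|<taxid>|<seqid>`` plus taxdump files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import Taxdump, write_taxdump

KRAKEN_PREFIX = "kraken:taxid|"

REQUIRED_COLUMNS = ("taxon_name", "accession", "fasta_path", "taxid", "genus", "species")
QUALITY_COLUMNS = ("completeness", "contamination")


class MetadataError(ValueError):
    """Raised on schema violations in the genome metadata table."""


@dataclass(frozen=True)
class GenomeRecord:
    """One genome of the input collection."""

    taxon_name: str
    accession: str
    fasta_path: Path
    taxid: int
    genus: str
    species: str
    completeness: float | None = None
    contamination: float | None = None
    gtdb_taxonomy: str | None = None
    ncbi_taxonomy: str | None = None


@dataclass
class ContigSet:
    """Contigs of one genome, as (contig_id, uppercase sequence) pairs."""

    genome_id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in genome {self.genome_id!r}")
        for cid, seq in self.contigs:
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def copy(self) -> "ContigSet":
        return ContigSet(self.genome_id, list(self.contigs))


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def read_fasta(path: str | Path, genome_id: str | None = None) -> ContigSet:
    """Read a plain or gzipped FASTA into a :class:`ContigSet`.

    Gzip is detected by magic bytes, not file extension.
    """
    path = Path(path)
    opener = gzip.open if _is_gzip(path) else open
    contigs: list[tuple[str, str]] = []
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fasta"):
            contigs.append((record.id, str(record.seq).upper()))
    return ContigSet(genome_id=genome_id or path.stem, contigs=contigs)


def write_fasta(contigs: ContigSet | Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    items = contigs.contigs if isinstance(contigs, ContigSet) else list(contigs)
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in items
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def load_metadata(table_path: str | Path, check_paths: bool = True) -> list[GenomeRecord]:
    """Load and validate the genome metadata TSV.

    Raises :class:`MetadataError` on a missing required column, duplicate
    taxon names, or an unreadable FASTA path.
    """
    table_path = Path(table_path)
    df = pd.read_csv(table_path, sep="\t", dtype={"accession": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table is missing required columns: {missing}")
    dupes = df["taxon_name"][df["taxon_name"].duplicated()].tolist()
    if dupes:
        raise MetadataError(f"duplicate taxon names in metadata: {sorted(set(dupes))}")

    records: list[GenomeRecord] = []
    for _, row in df.iterrows():
        fasta = Path(row["fasta_path"])
        if not fasta.is_absolute():
            fasta = table_path.parent / fasta
        if check_paths and not fasta.is_file():
            raise MetadataError(
                f"FASTA path for genome {row['taxon_name']!r} is unreadable: {fasta}"
            )

        def _opt(col: str) -> float | None:
            if col in df.columns and pd.notna(row[col]):
                return float(row[col])
            return None

        def _opt_str(col: str) -> str | None:
            if col in df.columns and pd.notna(row[col]):
                return str(row[col])
            return None

        records.append(
            GenomeRecord(
                taxon_name=str(row["taxon_name"]),
                accession="" if pd.isna(row["accession"]) else str(row["accession"]),
                fasta_path=fasta,
                taxid=int(row["taxid"]),
                genus=str(row["genus"]),
                species=str(row["species"]),
                completeness=_opt("completeness"),
                contamination=_opt("contamination"),
                gtdb_taxonomy=_opt_str("gtdb_taxonomy"),
                ncbi_taxonomy=_opt_str("ncbi_taxonomy"),
            )
        )
    return records


def write_metadata(records: Sequence[GenomeRecord], path: str | Path) -> Path:
    """Write genome records back to a metadata TSV (inverse of load_metadata)."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "taxon_name": r.taxon_name,
                "accession": r.accession,
                "fasta_path": str(r.fasta_path),
                "taxid": r.taxid,
                "genus": r.genus,
                "species": r.species,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "gtdb_taxonomy": r.gtdb_taxonomy,
                "ncbi_taxonomy": r.ncbi_taxonomy,
            }
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def filter_genomes(
    records: Sequence[GenomeRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 5.0,
) -> list[GenomeRecord]:
    """Apply assembly-quality filters and keep one genome per species.

    A record passes when completeness >= ``min_completeness`` and
    contamination is strictly below ``max_contamination``.  Among passing
    candidates of the same species, the one with the highest completeness is
    kept, ties resolved by lowest contamination, then by lexicographically
    smallest accession.
    """
    missing = [
        r.taxon_name for r in records
        if r.completeness is None or r.contamination is None
    ]
    if missing:
        raise MetadataError(
            f"records lack completeness/contamination estimates: {missing}"
        )
    passing = [
        r for r in records
        if r.completeness >= min_completeness and r.contamination < max_contamination
    ]
    by_species: dict[str, list[GenomeRecord]] = {}
    for r in passing:
        by_species.setdefault(r.species, []).append(r)
    selected = []
    for species in sorted(by_species):
        best = min(
            by_species[species],
            key=lambda r: (-r.completeness, r.contamination, r.accession),
        )
        selected.append(best)
    return selected


def rename_contigs_for_kraken(contigs: ContigSet, taxid: int) -> ContigSet:
    """Rename contig ids to ``kraken:taxid|<taxid>|<seqid>``; sequences untouched."""
    if taxid <= 0:
        raise ValueError(f"taxid must be positive, got {taxid}")
    renamed = []
    for cid, seq in contigs.contigs:
        if cid.startswith(KRAKEN_PREFIX):
            raise ValueError(
                f"contig {cid!r} already carries a kraken taxid prefix"
            )
        renamed.append((f"{KRAKEN_PREFIX}{taxid}|{cid}", seq))
    return ContigSet(genome_id=contigs.genome_id, contigs=renamed)


def export_kraken_library(
    records: Sequence[GenomeRecord],
    taxdump: Taxdump,
    out_dir: str | Path,
    contig_sets: dict[str, ContigSet] | None = None,
) -> dict[str, list[Path]]:
    """Write the Kraken2 build inputs: ``library/`` and ``taxonomy/``.

    ``library/library.fna`` holds all contigs of all genomes with taxid-tagged
    names; ``taxonomy/`` holds the taxdump files.  Returns a manifest of
    written files.  Sequences may be supplied pre-loaded via ``contig_sets``
    (keyed by taxon name); otherwise they are read from each record's path.
    """
    out_dir = Path(out_dir)
    for r in records:
        if r.taxid not in taxdump.nodes:
            raise ValueError(
                f"genome {r.taxon_name!r} has taxid {r.taxid} absent from the taxdump"
            )
    library_dir = out_dir / "library"
    library_dir.mkdir(parents=True, exist_ok=True)
    all_contigs: list[tuple[str, str]] = []
    for r in records:
        if contig_sets is not None and r.taxon_name in contig_sets:
            cs = contig_sets[r.taxon_name]
        else:
            cs = read_fasta(r.fasta_path, genome_id=r.taxon_name)
        all_contigs.extend(rename_contigs_for_kraken(cs, r.taxid).contigs)
    library_path = write_fasta(all_contigs, library_dir / "library.fna")
    tax_files = write_taxdump(taxdump, out_dir / "taxonomy")
    return {"library": [library_path], "taxonomy": tax_files}
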