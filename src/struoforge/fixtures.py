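"""Synthetic inputs for the whole pipeline: genomes with planted genes,
reference protein sets with a known identifier index, and community
abundance profiles.

The genome generator plants protein-coding genes (shared gene families,
lightly diverged per genome) into intergenic background that is free of
start codons on either strand, so the ORF caller recovers exactly the
planted genes; every contig is verified against the caller at generation
time and re-drawn if a spurious ORF slipped in.  Truth tables record every
planted gene with exact coordinates, strand, sequences, family, and its
ground-truth UniRef90/UniRef50 identifiers.  All generators are
deterministic under their seed.

These fixtures emulate gene content and taxonomy structure only — uniform
base composition, uniform gene spacing, no pseudogenes, no real codon-usage
bias — which is sufficient to exercise catalog construction, clustering,
annotation, misassembly and evaluation logic, but says nothing about caller
sensitivity on real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import ReferenceDB
from .evaluate import AbundanceProfile
from .genecat import MIN_GENE_LEN, STOP_CODONS, call_genes, translate_orf
from .genomes import ContigSet, GenomeRecord, write_fasta, write_metadata
from .taxonomy import Lineage, build_taxdump, parse_gtdb_lineage

_BASES = "ACGT"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# trigrams that would put a start codon on either strand of the background
_FORBIDDEN = {"ATG", "GTG", "TTG", "CAT", "CAC", "CAA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Size and noise parameters of the synthetic genome collection."""

    n_genomes: int = 10
    contigs_per_genome: int = 2
    contig_len: int = 10_000
    genes_per_genome: int = 5
    gene_len: int = 900
    family_divergence: float = 0.02  # per-site nt divergence of genome copies
    reference_mutation_rate: float = 0.0
    n_taxa_profiles: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genomes, self.contigs_per_genome, self.contig_len,
               self.gene_len) <= 0:
            raise FixtureError("all fixture sizes must be positive")
        if self.genes_per_genome < 0:
            raise FixtureError("genes_per_genome must be >= 0")
        if self.gene_len % 3 != 0 or self.gene_len < MIN_GENE_LEN:
            raise FixtureError(
                f"gene_len must be a multiple of 3 and >= {MIN_GENE_LEN}"
            )
        if not 0 <= self.reference_mutation_rate < 1:
            raise FixtureError("reference_mutation_rate must be in [0, 1)")


def safe_background(rng: np.random.Generator, n: int) -> str:
    """Random sequence containing no start codon on either strand."""
    out: list[str] = []
    for _ in range(n):
        last2 = "".join(out[-2:])
        allowed = [b for b in _BASES if (last2 + b)[-3:] not in _FORBIDDEN]
        out.append(allowed[int(rng.integers(len(allowed)))])
    return "".join(out)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random sense codons + TAA, ``length`` nt total."""
    n_interior = length // 3 - 2
    interior = "".join(
        _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        for _ in range(n_interior)
    )
    return "ATG" + interior + "TAA"


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Point-mutate a coding sequence, preserving start/stop and sense codons."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for ci in range(1, len(codons) - 1):
        codon = list(codons[ci])
        for pi in range(3):
            if rng.random() < rate:
                codon[pi] = _BASES[int(rng.integers(4))]
        mutated = "".join(codon)
        if mutated in STOP_CODONS:
            mutated = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        codons[ci] = mutated
    return "".join(codons)


def _clean_cds(rng: np.random.Generator, length: int, max_tries: int = 50) -> str:
    """A CDS that, embedded in safe background, yields exactly one called ORF."""
    for _ in range(max_tries):
        cds = _random_cds(rng, length)
        pad = safe_background(rng, 300)
        test = ContigSet("probe", [("c", pad + cds + pad)])
        called = call_genes(test)
        if len(called) == 1 and (called[0].start, called[0].end) == (300, 300 + length):
            return cds
    raise FixtureError("could not generate a clean coding sequence")


def _lineage_for(i: int) -> Lineage:
    return parse_gtdb_lineage(
        f"d__Bacteria;p__Synthphyla;c__Synthclassia;o__Synthales;"
        f"f__Synthaceae;g__Synthgenus{i:03d};s__Synthgenus{i:03d} synthii"
    )


def synth_genomes(
    spec: FixtureSpec,
) -> tuple[list[ContigSet], pd.DataFrame, list[GenomeRecord]]:
    """Generate genomes with planted genes plus truth and metadata tables.

    Gene families are shared across genomes: every genome carries one copy
    of each of ``genes_per_genome`` families, diverged from the family base
    sequence at ``family_divergence`` per site, strand chosen at random.
    Returns (contig sets, truth table, genome records); the truth table has
    one row per planted gene with the gene_id the catalog builder will
    assign, exact coordinates, both sequences, and the family's ground-truth
    reference identifiers.
    """
    rng = np.random.default_rng(spec.seed)
    n_fam = spec.genes_per_genome
    families = [_clean_cds(rng, spec.gene_len) for _ in range(n_fam)]

    # distribute families round-robin over the contigs of a genome
    per_contig: list[list[int]] = [[] for _ in range(spec.contigs_per_genome)]
    for k in range(n_fam):
        per_contig[k % spec.contigs_per_genome].append(k)
    margin = 50
    for fam_ids in per_contig:
        if fam_ids:
            slot = spec.contig_len // len(fam_ids)
            if slot < spec.gene_len + 2 * margin:
                raise FixtureError(
                    f"infeasible packing: {len(fam_ids)} genes of {spec.gene_len} bp "
                    f"do not fit a {spec.contig_len} bp contig"
                )

    genomes: list[ContigSet] = []
    truth_rows: list[dict] = []
    lineages = [_lineage_for(i) for i in range(1, spec.n_genomes + 1)]
    taxdump = build_taxdump(lineages)
    species_taxids = taxdump.species_taxids()

    for gi in range(1, spec.n_genomes + 1):
        genome_id = f"G{gi:03d}"
        lineage = lineages[gi - 1]
        contigs: list[tuple[str, str]] = []
        for ci, fam_ids in enumerate(per_contig, start=1):
            contig_id = f"{genome_id}_c{ci}"
            for _attempt in range(50):
                planted: list[tuple[int, int, str, str, int]] = []
                parts: list[str] = []
                pos = 0
                ok = True
                slot = spec.contig_len // len(fam_ids) if fam_ids else spec.contig_len
                for si, fam in enumerate(fam_ids):
                    copy = _mutate_cds(rng, families[fam], spec.family_divergence)
                    strand = "+" if rng.random() < 0.5 else "-"
                    lo = si * slot + margin
                    hi = (si + 1) * slot - spec.gene_len - margin
                    start = int(rng.integers(lo, hi + 1))
                    parts.append(safe_background(rng, start - pos))
                    if strand == "+":
                        parts.append(copy)
                    else:
                        parts.append(_revcomp(copy))
                    planted.append((start, start + spec.gene_len, strand, copy, fam))
                    pos = start + spec.gene_len
                parts.append(safe_background(rng, spec.contig_len - pos))
                seq = "".join(parts)
                called = call_genes(ContigSet(genome_id, [(contig_id, seq)]))
                want = {(s, e, st) for s, e, st, _, _ in planted}
                got = {(g.start, g.end, g.strand) for g in called}
                if got == want:
                    break
                ok = False
            if not ok and got != want:
                raise FixtureError(
                    f"could not build a clean contig for {contig_id} in 50 attempts"
                )
            contigs.append((contig_id, seq))
            for start, end, strand, copy, fam in planted:
                truth_rows.append(
                    {
                        "gene_id": f"{genome_id}|{contig_id}|{start}-{end}|{strand}",
                        "genome_id": genome_id,
                        "contig_id": contig_id,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "family": f"FAM{fam:03d}",
                        "nt_seq": copy,
                        "aa_seq": translate_orf(copy),
                        "uniref90_id": f"U90_{fam:03d}",
                        "uniref50_id": f"U50_{fam // 2:03d}",
                    }
                )
        genomes.append(ContigSet(genome_id, contigs))

    records = [
        GenomeRecord(
            taxon_name=g.genome_id,
            accession=f"SYN_{g.genome_id}",
            fasta_path=Path(f"{g.genome_id}.fna"),
            taxid=species_taxids[lineages[i].species],
            genus=lineages[i].name_at("g"),
            species=lineages[i].species,
            completeness=100.0,
            contamination=0.0,
            gtdb_taxonomy=str(lineages[i]),
            ncbi_taxonomy=str(lineages[i]),
        )
        for i, g in enumerate(genomes)
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "genome_id", "contig_id", "start", "end", "strand",
            "family", "nt_seq", "aa_seq", "uniref90_id", "uniref50_id",
        ],
    )
    return genomes, truth, records


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def synth_reference(
    truth: pd.DataFrame, mutation_rate: float, seed: int
) -> ReferenceDB:
    """One reference protein per planted gene family, plus the 90->50 index.

    At ``mutation_rate`` 0 each reference protein is the amino-acid sequence
    of the family's first planted copy, so every planted gene has a
    ground-truth best hit; higher rates degrade the reference away from the
    catalog.  Families map 2:1 onto 50%-level identifiers.
    """
    if not 0 <= mutation_rate < 1:
        raise FixtureError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    id_map: dict[str, str] = {}
    for u90, grp in truth.sort_values("gene_id").groupby("uniref90_id", sort=True):
        aa = grp.iloc[0]["aa_seq"]
        mutated = "".join(
            _AA20[int(rng.integers(len(_AA20)))] if rng.random() < mutation_rate else c
            for c in aa
        )
        proteins[u90] = mutated
        id_map[u90] = grp.iloc[0]["uniref50_id"]
    return ReferenceDB(proteins=proteins, id_map=id_map)


def synth_profiles(
    n_samples: int, n_taxa: int, effect: float, seed: int
) -> list[AbundanceProfile]:
    """Log-normal community profiles with a planted two-group shift.

    Samples split into two equal groups; the first fifth of taxa are scaled
    by ``1 + effect`` in the second group.  Per-sample multiplicative noise
    (log-normal, sigma 0.5) is applied throughout.
    """
    if n_samples < 3:
        raise FixtureError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_taxa)
    n_shift = max(1, n_taxa // 5)
    profiles = []
    for s in range(n_samples):
        group2 = s >= n_samples // 2
        noise = rng.lognormal(mean=0.0, sigma=0.5, size=n_taxa)
        counts = base * noise
        if group2:
            counts[:n_shift] *= 1.0 + effect
        profiles.append(
            AbundanceProfile(
                sample_id=f"S{s + 1:03d}",
                counts={f"taxon_{t + 1:03d}": float(counts[t]) for t in range(n_taxa)},
            )
        )
    return profiles


def write_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Materialize a fixture on disk in the formats the pipeline consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes, truth, records = synth_genomes(spec)
    genome_dir = out_dir / "genomes"
    updated_records = []
    for g, rec in zip(genomes, records):
        write_fasta(g, genome_dir / f"{g.genome_id}.fna")
        # paths are stored relative to the metadata table for relocatability
        rel = Path("genomes") / f"{g.genome_id}.fna"
        updated_records.append(
            GenomeRecord(**{**rec.__dict__, "fasta_path": rel})
        )
    meta_path = write_metadata(updated_records, out_dir / "metadata.tsv")
    truth_path = out_dir / "truth_genes.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    ref = synth_reference(truth, spec.reference_mutation_rate, spec.seed + 1)
    ref_fasta = out_dir / "reference.faa"
    ref_map = out_dir / "uniref90_to_uniref50.tsv"
    ref.write(ref_fasta, ref_map)
    return {
        "metadata": meta_path,
        "truth": truth_path,
        "reference": ref_fasta,
        "id_map": ref_map,
        "genome_dir": genome_dir,
    }
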