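"""Annotation of cluster representatives against a reference protein set,
propagation to cluster members, UniRef90->UniRef50 mapping, and export of
HUMAnN-ready sequence files.

Only cluster representatives are searched (exact global alignment against
every reference protein; best hit by alignment score, ties by higher
identity then lexicographic reference id, accepted when identity and
coverage reach the configured thresholds).  The representative's annotation
is then propagated to every member of its cluster, and UniRef90 identifiers
are mapped to UniRef50 through a two-column index, which avoids a second
round of annotation at the 50% level.  On update, only representatives of
newly formed clusters are searched; prior annotations are kept verbatim and
propagated to any genes newly added to old clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._align import align_aa
from .cluster import ClusterDB
from .genecat import GeneRecord, GenesDB

MIN_IDENTITY_DEFAULT = 0.5
MIN_COVERAGE_DEFAULT = 0.8
UNMAPPED = ""


class AnnotationError(ValueError):
    pass


@dataclass
class ReferenceDB:
    """Reference proteins plus the UniRef90->UniRef50 identifier index."""

    proteins: dict[str, str]  # ref_id -> aa sequence
    id_map: dict[str, str] = field(default_factory=dict)  # ref_id -> uniref50 id

    @classmethod
    def from_files(cls, fasta_path: str | Path, map_path: str | Path | None) -> "ReferenceDB":
        proteins: dict[str, str] = {}
        with open(fasta_path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in proteins:
                    raise AnnotationError(f"duplicate reference id {rec.id!r}")
                proteins[rec.id] = str(rec.seq)
        id_map: dict[str, str] = {}
        if map_path is not None:
            df = pd.read_csv(map_path, sep="\t")
            id_map = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return cls(proteins=proteins, id_map=id_map)

    def write(self, fasta_path: str | Path, map_path: str | Path) -> None:
        Path(fasta_path).parent.mkdir(parents=True, exist_ok=True)
        with open(fasta_path, "w") as fh:
            for rid in sorted(self.proteins):
                fh.write(f">{rid}\n{self.proteins[rid]}\n")
        pd.DataFrame(
            sorted(self.id_map.items()), columns=["uniref90_id", "uniref50_id"]
        ).to_csv(map_path, sep="\t", index=False)


@dataclass(frozen=True)
class Annotation:
    gene_id: str
    uniref90_id: str
    uniref50_id: str = UNMAPPED
    identity: float = 0.0
    coverage: float = 0.0
    source: str = "searched"  # searched | propagated | preexisting


@dataclass(frozen=True)
class Hit:
    """Best reference hit for one representative."""

    gene_id: str
    ref_id: str
    identity: float
    coverage: float
    score: float


def batch_queries(
    reps: Sequence[GeneRecord], n_batches: int
) -> list[list[GeneRecord]]:
    """Deterministic balanced partition of representatives into batches.

    Representatives are ordered by gene_id and split into contiguous chunks
    whose sizes differ by at most one; trailing batches may be empty when
    ``n_batches`` exceeds the number of representatives.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    ordered = sorted(reps, key=lambda g: g.gene_id)
    n = len(ordered)
    base, extra = divmod(n, n_batches)
    batches: list[list[GeneRecord]] = []
    pos = 0
    for i in range(n_batches):
        size = base + (1 if i < extra else 0)
        batches.append(ordered[pos : pos + size])
        pos += size
    return batches


def search_reference(
    reps: Sequence[GeneRecord],
    ref: ReferenceDB,
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_coverage: float = MIN_COVERAGE_DEFAULT,
    n_batches: int = 1,
) -> list[Hit]:
    """Best reference hit per representative, thresholded.

    For each representative the reference protein maximizing the global
    alignment score among hits meeting both thresholds is reported; ties go
    to the higher identity, then the lexicographically smaller reference id.
    Representatives without an accepted hit are omitted (unannotated).
    Batching is a parallelism seam only; results are merged in a fixed
    order and do not depend on ``n_batches``.
    """
    if not ref.proteins:
        raise AnnotationError("reference protein set is empty")
    hits: list[Hit] = []
    for batch in batch_queries(reps, n_batches):
        for rep in batch:
            best: Hit | None = None
            for ref_id in sorted(ref.proteins):
                stats = align_aa(rep.aa_seq, ref.proteins[ref_id])
                if stats.identity < min_identity or stats.coverage < min_coverage:
                    continue
                cand = Hit(rep.gene_id, ref_id, stats.identity, stats.coverage,
                           stats.score)
                if (
                    best is None
                    or cand.score > best.score
                    or (cand.score == best.score and cand.identity > best.identity)
                ):
                    best = cand
            if best is not None:
                hits.append(best)
    hits.sort(key=lambda h: h.gene_id)
    return hits


def propagate_annotations(
    db: ClusterDB, hits: Sequence[Hit]
) -> list[Annotation]:
    """Give every member of an annotated cluster its representative's id.

    The representative keeps source ``searched``; other members are
    ``propagated`` and inherit the representative's identifiers verbatim.
    """
    by_rep = {}
    for h in hits:
        if h.gene_id not in db.rep_order:
            raise AnnotationError(
                f"hit for {h.gene_id!r}, which is not a cluster representative"
            )
        by_rep[h.gene_id] = h
    annotations: list[Annotation] = []
    for rep, members in db.clusters().items():
        hit = by_rep.get(rep)
        if hit is None:
            continue
        for gid in members:
            annotations.append(
                Annotation(
                    gene_id=gid,
                    uniref90_id=hit.ref_id,
                    identity=hit.identity,
                    coverage=hit.coverage,
                    source="searched" if gid == rep else "propagated",
                )
            )
    annotations.sort(key=lambda a: a.gene_id)
    return annotations


def map_uniref50(
    annotations: Sequence[Annotation], ref: ReferenceDB
) -> tuple[list[Annotation], int]:
    """Fill uniref50 ids from the identifier index; count unmapped ids.

    Ids absent from the index stay unannotated at the 50% level.  The
    operation is idempotent.
    """
    out: list[Annotation] = []
    unmapped = 0
    for ann in annotations:
        u50 = ref.id_map.get(ann.uniref90_id, UNMAPPED)
        if u50 == UNMAPPED:
            unmapped += 1
        out.append(replace(ann, uniref50_id=u50))
    return out, unmapped


def format_humann_header(gene: GeneRecord, ann: Annotation) -> str:
    """``<uniref90_id>|<nt_length>|g__<genus>;s__<species>``."""
    if not ann.uniref90_id:
        raise AnnotationError(f"gene {gene.gene_id!r} is unannotated")
    genus = gene.genus if gene.genus.startswith("g__") else f"g__{gene.genus}"
    species = gene.species if gene.species.startswith("s__") else f"s__{gene.species}"
    return f"{ann.uniref90_id}|{len(gene.nt_seq)}|{genus};{species}"


def export_humann_fastas(
    genes: GenesDB,
    annotations: Sequence[Annotation],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the annotated-gene nt and aa FASTAs with HUMAnN-style headers.

    The nucleotide file is the bowtie2-build input, the amino-acid file the
    diamond-makedb input; both carry identical headers per gene and exactly
    one record per annotated gene.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = genes.by_id()
    nt_path = out_dir / "humann_genes.fna"
    aa_path = out_dir / "humann_genes.faa"
    n = 0
    with open(nt_path, "w") as nt_fh, open(aa_path, "w") as aa_fh:
        for ann in sorted(annotations, key=lambda a: a.gene_id):
            gene = by_id.get(ann.gene_id)
            if gene is None:
                raise AnnotationError(f"annotation for unknown gene {ann.gene_id!r}")
            header = format_humann_header(gene, ann)
            nt_fh.write(f">{header}\n{gene.nt_seq}\n")
            aa_fh.write(f">{header}\n{gene.aa_seq}\n")
            n += 1
    if n == 0:
        warnings.warn("no annotated genes; HUMAnN FASTAs are empty", stacklevel=2)
    return {"nt": nt_path, "aa": aa_path}


def update_annotations(
    db: ClusterDB,
    new_cluster_ids: set[str],
    existing: Sequence[Annotation],
    ref: ReferenceDB,
    genes: Mapping[str, GeneRecord],
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_coverage: float = MIN_COVERAGE_DEFAULT,
    search_fn: Callable[..., list[Hit]] | None = None,
) -> list[Annotation]:
    """Annotate after an incremental cluster update.

    Searches only the representatives of ``new_cluster_ids``.  Annotations
    of previously annotated clusters are retained verbatim
    and propagated to any genes newly added to those clusters.  A prior
    annotation for a cluster that no longer exists is an error.

    ``search_fn`` defaults to :func:`search_reference`; tests may inject an
    instrumented version to assert which representatives were searched.
    """
    unknown = new_cluster_ids - set(db.rep_order)
    if unknown:
        raise AnnotationError(f"unknown new cluster representatives: {sorted(unknown)}")
    prior_by_gene = {a.gene_id: a for a in existing}
    # representative -> prior annotation, via the representative's own row
    prior_rep_ann: dict[str, Annotation] = {}
    for rep in db.rep_order:
        if rep in new_cluster_ids:
            continue
        ann = prior_by_gene.get(rep)
        if ann is not None:
            prior_rep_ann[rep] = ann
    annotated_old_reps = {
        a.gene_id for a in existing if a.gene_id in db.members
        and db.members[a.gene_id] == a.gene_id
    }
    missing = annotated_old_reps - set(prior_rep_ann) - new_cluster_ids
    if missing:
        raise AnnotationError(f"missing prior annotation for clusters: {sorted(missing)}")

    search = search_fn or search_reference
    new_reps = [genes[rep] for rep in sorted(new_cluster_ids)]
    new_hits = search(new_reps, ref, min_identity=min_identity,
                      min_coverage=min_coverage)
    hits_by_rep = {h.gene_id: h for h in new_hits}

    annotations: list[Annotation] = []
    for rep, members in db.clusters().items():
        if rep in new_cluster_ids:
            hit = hits_by_rep.get(rep)
            if hit is None:
                continue
            for gid in members:
                annotations.append(
                    Annotation(
                        gene_id=gid,
                        uniref90_id=hit.ref_id,
                        identity=hit.identity,
                        coverage=hit.coverage,
                        source="searched" if gid == rep else "propagated",
                    )
                )
        else:
            ann = prior_rep_ann.get(rep)
            if ann is None:
                continue
            for gid in members:
                prior = prior_by_gene.get(gid)
                if prior is not None:
                    # carried over verbatim so untouched clusters stay
                    # byte-identical across updates
                    annotations.append(prior)
                else:  # gene newly added to an old cluster
                    annotations.append(
                        Annotation(
                            gene_id=gid,
                            uniref90_id=ann.uniref90_id,
                            uniref50_id=ann.uniref50_id,
                            identity=ann.identity,
                            coverage=ann.coverage,
                            source="propagated",
                        )
                    )
    annotations.sort(key=lambda a: a.gene_id)
    return annotations


def annotations_to_table(annotations: Sequence[Annotation]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": a.gene_id,
            "uniref90_id": a.uniref90_id,
            "uniref50_id": a.uniref50_id,
            "identity": round(a.identity, 6),
            "coverage": round(a.coverage, 6),
            "source": a.source,
        }
        for a in sorted(annotations, key=lambda a: a.gene_id)
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "uniref90_id", "uniref50_id", "identity", "coverage",
                 "source"],
    )


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotations_to_table(annotations).to_csv(path, sep="\t", index=False)
    return path


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(Path(path), sep="\t", keep_default_na=False)
    return [
        Annotation(
            gene_id=row["gene_id"],
            uniref90_id=row["uniref90_id"],
            uniref50_id=row["uniref50_id"],
            identity=float(row["identity"]),
            coverage=float(row["coverage"]),
            source=row["source"],
        )
        for _, row in df.iterrows()
    ]
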