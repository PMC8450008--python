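"""Greedy centroid clustering of amino-acid gene sequences, with incremental
update of an existing clustering.

The build is a deterministic, exact-alignment analogue of linear-time
protein clustering: candidates are processed longest-first (ties by
gene_id); each gene joins the first representative — in founding order —
whose global-alignment identity and coverage both reach the configured
thresholds, otherwise it founds a new cluster with itself as
representative.  The update path leaves every existing representative and
membership untouched: new genes first try the existing representatives,
then cluster among themselves by the same greedy rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._align import align_aa
from .genecat import GeneRecord, GenesDB

IDENTITY_DEFAULT = 0.9
COVERAGE_DEFAULT = 0.8


class ClusterError(ValueError):
    pass


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) of a global amino-acid alignment.

    Identity is matching columns over all alignment columns; coverage is the
    number of mutually aligned columns over the length of the shorter
    sequence.  BLOSUM62 with gap open 11 / extend 1.
    """
    stats = align_aa(a, b)
    return stats.identity, stats.coverage


@dataclass
class ClusterDB:
    """A partition of gene ids into clusters keyed by representative id."""

    members: dict[str, str]  # gene_id -> representative gene_id
    sequences: dict[str, str]  # gene_id -> aa sequence
    rep_order: list[str] = field(default_factory=list)  # founding order
    identity: float = IDENTITY_DEFAULT
    coverage: float = COVERAGE_DEFAULT

    def __post_init__(self) -> None:
        reps = set(self.members.values())
        for rep in reps:
            if self.members.get(rep) != rep:
                raise ClusterError(
                    f"representative {rep!r} is not a member of its own cluster"
                )
        if set(self.rep_order) != reps:
            raise ClusterError("rep_order inconsistent with membership table")

    def clusters(self) -> dict[str, list[str]]:
        """Representative -> sorted member list."""
        out: dict[str, list[str]] = {rep: [] for rep in self.rep_order}
        for gid, rep in self.members.items():
            out[rep].append(gid)
        for rep in out:
            out[rep].sort()
        return out

    def n_clusters(self) -> int:
        return len(self.rep_order)

    def __len__(self) -> int:
        return len(self.members)

    def validate(self) -> None:
        """Re-check that every member meets the thresholds to its representative."""
        for gid, rep in self.members.items():
            if gid == rep:
                continue
            ident, cov = pairwise_identity(self.sequences[gid], self.sequences[rep])
            if ident < self.identity or cov < self.coverage:
                raise ClusterError(
                    f"member {gid!r} fails thresholds to representative {rep!r}: "
                    f"identity={ident:.3f}, coverage={cov:.3f}"
                )


def _candidate_order(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    return sorted(genes, key=lambda g: (-len(g.aa_seq), g.gene_id))


def _assign(
    gene: GeneRecord,
    rep_order: Sequence[str],
    sequences: Mapping[str, str],
    identity: float,
    coverage: float,
) -> str | None:
    """First representative (founding order) meeting both thresholds, or None."""
    for rep in rep_order:
        ident, cov = pairwise_identity(gene.aa_seq, sequences[rep])
        if ident >= identity and cov >= coverage:
            return rep
    return None


def cluster_genes(
    genes: GenesDB | Sequence[GeneRecord],
    identity: float = IDENTITY_DEFAULT,
    coverage: float = COVERAGE_DEFAULT,
) -> ClusterDB:
    """Greedy centroid clustering of amino-acid sequences."""
    records = list(genes.genes) if isinstance(genes, GenesDB) else list(genes)
    if not records:
        raise ClusterError("cannot cluster an empty gene set")
    members: dict[str, str] = {}
    sequences: dict[str, str] = {}
    rep_order: list[str] = []
    for gene in _candidate_order(records):
        sequences[gene.gene_id] = gene.aa_seq
        rep = _assign(gene, rep_order, sequences, identity, coverage)
        if rep is None:
            rep = gene.gene_id
            rep_order.append(rep)
        members[gene.gene_id] = rep
    return ClusterDB(
        members=members, sequences=sequences, rep_order=rep_order,
        identity=identity, coverage=coverage,
    )


def update_clusters(
    db: ClusterDB, new_genes: Sequence[GeneRecord]
) -> tuple[ClusterDB, set[str]]:
    """Extend an existing clustering with new genes.

    Existing representatives and memberships are untouched.  Each new gene
    (longest-first) joins the first representative — existing ones first,
    then clusters newly founded during this update — meeting the thresholds,
    else founds a new cluster.  Returns the enlarged ClusterDB and the set
    of representatives of clusters formed by this update.
    """
    collisions = [g.gene_id for g in new_genes if g.gene_id in db.members]
    if collisions:
        raise ClusterError(f"gene_id collision with existing catalog: {collisions}")
    members = dict(db.members)
    sequences = dict(db.sequences)
    rep_order = list(db.rep_order)
    new_reps: list[str] = []
    for gene in _candidate_order(list(new_genes)):
        sequences[gene.gene_id] = gene.aa_seq
        rep = _assign(gene, rep_order, sequences, db.identity, db.coverage)
        if rep is None:
            rep = gene.gene_id
            rep_order.append(rep)
            new_reps.append(rep)
        members[gene.gene_id] = rep
    out = ClusterDB(
        members=members, sequences=sequences, rep_order=rep_order,
        identity=db.identity, coverage=db.coverage,
    )
    return out, set(new_reps)


def write_cluster_db(db: ClusterDB, out_dir: str | Path) -> dict[str, Path]:
    """Serialize as a member->representative TSV plus a params file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "clusters.tsv"
    rows = [
        {"gene_id": gid, "representative_id": rep}
        for gid, rep in sorted(db.members.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "representative_id"]).to_csv(
        tsv, sep="\t", index=False
    )
    params = out_dir / "cluster_params.tsv"
    with open(params, "w") as fh:
        fh.write("identity\t%s\n" % db.identity)
        fh.write("coverage\t%s\n" % db.coverage)
        fh.write("rep_order\t%s\n" % ",".join(db.rep_order))
    return {"clusters": tsv, "params": params}


def read_cluster_db(out_dir: str | Path, sequences: Mapping[str, str]) -> ClusterDB:
    """Read a serialized clustering; aa sequences are supplied from the catalog."""
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "clusters.tsv", sep="\t")
    members = dict(zip(df["gene_id"], df["representative_id"]))
    params: dict[str, str] = {}
    with open(out_dir / "cluster_params.tsv") as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            params[key] = value
    rep_order = params["rep_order"].split(",") if params.get("rep_order") else []
    seqs = {gid: sequences[gid] for gid in members}
    return ClusterDB(
        members=members, sequences=seqs, rep_order=rep_order,
        identity=float(params["identity"]), coverage=float(params["coverage"]),
    )
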