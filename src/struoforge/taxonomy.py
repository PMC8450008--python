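"""GTDB lineage parsing, NCBI-style taxdump construction, and NCBI<->GTDB mapping.

A GTDB lineage is a 7-rank, semicolon-separated string with rank prefixes::

    d__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus;s__Lactobacillus crispatus

This module converts collections of such lineages into taxdump tables
(``nodes.dmp`` / ``names.dmp`` in the NCBI dump dialect) consumed by Kraken2
and related tools, and maps taxon names between the NCBI and GTDB taxonomies
by plurality vote over genomes that carry both labels.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

RANK_CODES = ("d", "p", "c", "o", "f", "g", "s")

#: rank-code -> NCBI dump rank label
RANK_LABELS = {
    "d": "superkingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

ROOT_TAXID = 1
ROOT_NAME = "root"


class LineageParseError(ValueError):
    """Raised when a lineage string violates the 7-rank prefixed format."""


class TaxdumpError(ValueError):
    """Raised on inconsistent lineage sets or invalid taxdump lookups."""


@dataclass(frozen=True)
class Lineage:
    """Ordered (rank-code, prefixed-name) pairs from domain to species."""

    ranks: tuple[tuple[str, str], ...]
    source: Literal["gtdb", "ncbi"] = "gtdb"

    def __post_init__(self) -> None:
        codes = tuple(code for code, _ in self.ranks)
        if codes != RANK_CODES:
            raise LineageParseError(
                f"lineage must have exactly the ranks {RANK_CODES}, got {codes}"
            )

    def name_at(self, rank_code: str) -> str:
        for code, name in self.ranks:
            if code == rank_code:
                return name
        raise KeyError(rank_code)

    @property
    def species(self) -> str:
        return self.ranks[-1][1]

    def __str__(self) -> str:
        return ";".join(name for _, name in self.ranks)


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


@dataclass
class Taxdump:
    """Node table keyed by taxid; NCBI dump-file compatible.

    The root node has ``taxid == parent_taxid == 1`` and rank ``"no rank"``.
    """

    nodes: dict[int, TaxNode] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxdump):
            return NotImplemented
        return self.nodes == other.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def taxid_of(self, name: str, rank_code: str | None = None) -> int:
        """Return the taxid of a node by (prefixed) name, optionally checking rank."""
        want_rank = RANK_LABELS[rank_code] if rank_code else None
        for node in self.nodes.values():
            if node.name == name and (want_rank is None or node.rank == want_rank):
                return node.taxid
        raise TaxdumpError(f"name not found in taxdump: {name!r}")

    def species_taxids(self) -> dict[str, int]:
        """Map prefixed species name -> taxid for every species node."""
        return {
            n.name: n.taxid for n in self.nodes.values() if n.rank == "species"
        }


@dataclass(frozen=True)
class TaxMapResult:
    """Result of a plurality-vote taxonomy mapping query."""

    query: str
    target: str
    rank: str
    agreement: float
    tie: bool = False
    found: bool = True


def parse_gtdb_lineage(
    lineage_string: str, source: Literal["gtdb", "ncbi"] = "gtdb"
) -> Lineage:
    """Parse a 7-rank, prefix-coded lineage string.

    Raises :class:`LineageParseError` on wrong field count, malformed or
    out-of-order prefixes, or empty names.
    """
    fields = [f.strip() for f in lineage_string.split(";")]
    if len(fields) != len(RANK_CODES):
        raise LineageParseError(
            f"expected {len(RANK_CODES)} semicolon-separated fields, "
            f"got {len(fields)}: {lineage_string!r}"
        )
    ranks: list[tuple[str, str]] = []
    for expected, fld in zip(RANK_CODES, fields):
        if len(fld) < 3 or fld[1:3] != "__":
            raise LineageParseError(f"malformed rank prefix in field {fld!r}")
        code = fld[0]
        if code != expected:
            raise LineageParseError(
                f"rank order violated: expected {expected!r}__ but found {fld!r}"
            )
        if fld[3:] == "":
            raise LineageParseError(f"empty name at rank {code!r}__ in {lineage_string!r}")
        ranks.append((code, fld))
    return Lineage(ranks=tuple(ranks), source=source)


def build_taxdump(lineages: Iterable[Lineage]) -> Taxdump:
    """Build a taxdump from parsed lineages.

    One node is created per unique root-anchored path prefix plus the root.
    Taxids are deterministic and input-order independent: root = 1, then
    breadth-first from the root with siblings sorted lexicographically by
    name, numbering consecutively from 2.

    Raises :class:`TaxdumpError` if the same name occurs at the same rank
    under two different parent paths (GTDB names are unique per rank, so a
    collision signals corrupt input).
    """
    # children[path_prefix] = set of child names; path keyed by tuple of names
    children: dict[tuple[str, ...], set[str]] = {(): set()}
    seen_name_at_rank: dict[tuple[int, str], tuple[str, ...]] = {}
    for lin in lineages:
        path: tuple[str, ...] = ()
        for depth, (_, name) in enumerate(lin.ranks):
            prior = seen_name_at_rank.get((depth, name))
            if prior is not None and prior != path:
                raise TaxdumpError(
                    f"name {name!r} at rank {RANK_CODES[depth]!r} occurs under two "
                    f"parent paths: {'/'.join(prior) or 'root'} and "
                    f"{'/'.join(path) or 'root'}"
                )
            seen_name_at_rank[(depth, name)] = path
            children.setdefault(path, set()).add(name)
            path = path + (name,)
            children.setdefault(path, set())

    dump = Taxdump()
    dump.nodes[ROOT_TAXID] = TaxNode(ROOT_TAXID, ROOT_TAXID, "no rank", ROOT_NAME)
    next_id = ROOT_TAXID + 1
    queue: deque[tuple[tuple[str, ...], int]] = deque([((), ROOT_TAXID)])
    while queue:
        path, parent_id = queue.popleft()
        for name in sorted(children.get(path, ())):
            node_path = path + (name,)
            rank = RANK_LABELS[RANK_CODES[len(path)]]
            dump.nodes[next_id] = TaxNode(next_id, parent_id, rank, name)
            queue.append((node_path, next_id))
            next_id += 1
    return dump


def lineage_from_taxid(taxdump: Taxdump, taxid: int) -> Lineage:
    """Reconstruct the full lineage of a species-rank node by walking parents."""
    node = taxdump.nodes.get(taxid)
    if node is None:
        raise TaxdumpError(f"unknown taxid: {taxid}")
    if node.rank != "species":
        raise TaxdumpError(
            f"taxid {taxid} has rank {node.rank!r}, expected 'species'"
        )
    names: list[str] = []
    while node.taxid != node.parent_taxid:
        names.append(node.name)
        node = taxdump.nodes[node.parent_taxid]
    names.reverse()
    if len(names) != len(RANK_CODES):
        raise TaxdumpError(
            f"taxid {taxid} sits at depth {len(names)}, expected {len(RANK_CODES)}"
        )
    return Lineage(ranks=tuple(zip(RANK_CODES, names)))


def write_taxdump(taxdump: Taxdump, directory: str | Path) -> list[Path]:
    """Write ``nodes.dmp`` and ``names.dmp`` in the NCBI dump dialect.

    Fields are separated by ``\\t|\\t`` and lines terminated by ``\\t|``;
    every name is recorded with name class ``scientific name``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes_path = directory / "nodes.dmp"
    names_path = directory / "names.dmp"
    sep = "\t|\t"
    with open(nodes_path, "w") as nodes_fh, open(names_path, "w") as names_fh:
        for taxid in sorted(taxdump.nodes):
            n = taxdump.nodes[taxid]
            nodes_fh.write(sep.join([str(n.taxid), str(n.parent_taxid), n.rank]) + "\t|\n")
            names_fh.write(
                sep.join([str(n.taxid), n.name, "", "scientific name"]) + "\t|\n"
            )
    return [nodes_path, names_path]


def read_taxdump(directory: str | Path) -> Taxdump:
    """Read ``nodes.dmp`` / ``names.dmp`` back into a :class:`Taxdump`."""
    directory = Path(directory)
    dump = Taxdump()
    ranks: dict[int, tuple[int, str]] = {}
    with open(directory / "nodes.dmp") as fh:
        for line in fh:
            parts = line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")
            taxid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
            ranks[taxid] = (parent, rank)
    with open(directory / "names.dmp") as fh:
        for line in fh:
            parts = line.rstrip("\n").rstrip("|").rstrip("\t").split("\t|\t")
            taxid, name = int(parts[0]), parts[1]
            parent, rank = ranks[taxid]
            dump.nodes[taxid] = TaxNode(taxid, parent, rank, name)
    return dump


def map_taxonomies(
    records: pd.DataFrame,
    query_name: str,
    direction: Literal["ncbi_to_gtdb", "gtdb_to_ncbi"],
    rank: str,
) -> TaxMapResult:
    """Map a taxon name between the NCBI and GTDB taxonomies by plurality vote.

    ``records`` must carry ``gtdb_taxonomy`` and ``ncbi_taxonomy`` lineage
    strings, one row per genome.  The target is the name, at the same rank in
    the destination taxonomy, held by the plurality of genomes labelled with
    the query; ``agreement`` is the plurality fraction.  Ties are broken by
    the lexicographically smallest target and flagged.
    """
    if rank not in RANK_CODES:
        raise ValueError(f"unknown rank code {rank!r}; expected one of {RANK_CODES}")
    if direction == "ncbi_to_gtdb":
        src_col, dst_col, src_kind, dst_kind = (
            "ncbi_taxonomy", "gtdb_taxonomy", "ncbi", "gtdb")
    elif direction == "gtdb_to_ncbi":
        src_col, dst_col, src_kind, dst_kind = (
            "gtdb_taxonomy", "ncbi_taxonomy", "gtdb", "ncbi")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if records.empty:
        raise ValueError("records table is empty")

    votes: dict[str, int] = {}
    for _, row in records.iterrows():
        src = parse_gtdb_lineage(row[src_col], source=src_kind)
        if src.name_at(rank) != query_name:
            continue
        dst = parse_gtdb_lineage(row[dst_col], source=dst_kind)
        target = dst.name_at(rank)
        votes[target] = votes.get(target, 0) + 1

    if not votes:
        return TaxMapResult(query=query_name, target="", rank=RANK_LABELS[rank],
                            agreement=float("nan"), found=False)
    total = sum(votes.values())
    best = max(votes.values())
    winners = sorted(t for t, c in votes.items() if c == best)
    return TaxMapResult(
        query=query_name,
        target=winners[0],
        rank=RANK_LABELS[rank],
        agreement=best / total,
        tie=len(winners) > 1,
    )
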