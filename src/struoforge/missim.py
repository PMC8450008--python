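"""Misassembly simulation for genome assemblies, with a replayable event log.

Three structural error types are introduced into assemblies:

* **breakpoint** — a contig is split into two pieces at a position drawn
  uniformly from the interior of the contig;
* **rearrangement** — a genomic fragment (uniform length, 1-10 kb by
  default) is excised from one contig and re-inserted at a uniform position
  on a contig of the same genome;
* **chimerism** — a fragment is relocated from a contig of a donor genome
  into a contig of a different (recipient) genome.

Every event records the genome/contig ids, coordinates (0-based, half-open)
and fragment length actually used, so the simulation can be audited and
replayed deterministically.  All randomness flows through one seeded
generator in a fixed draw order, making outputs byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomes import ContigSet

FRAG_MIN_DEFAULT = 1_000
FRAG_MAX_DEFAULT = 10_000


class SimulationError(ValueError):
    """Raised when a simulation is infeasible for a genome."""


@dataclass(frozen=True)
class MisassemblyEvent:
    """Ground-truth record of a single introduced misassembly."""

    kind: str  # breakpoint | rearrangement | chimerism
    genome_id: str
    contig_id: str
    position: int
    # rearrangement/chimerism only:
    fragment_length: int | None = None
    target_genome_id: str | None = None
    target_contig_id: str | None = None
    target_position: int | None = None
    # new contig ids produced by a breakpoint:
    new_contig_ids: tuple[str, str] | None = None


@dataclass(frozen=True)
class SimConfig:
    """Per-genome misassembly counts and fragment-size bounds."""

    n_breakpoints: int = 0
    n_rearrangements: int = 0
    n_chimerisms: int = 0
    frag_min: int = FRAG_MIN_DEFAULT
    frag_max: int = FRAG_MAX_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_breakpoints, self.n_rearrangements, self.n_chimerisms) < 0:
            raise ValueError("misassembly counts must be non-negative")
        if self.frag_min > self.frag_max:
            raise ValueError("frag_min must be <= frag_max")

    @property
    def label(self) -> str:
        return f"b{self.n_breakpoints}-r{self.n_rearrangements}-c{self.n_chimerisms}"


def _contig_index(genome: ContigSet, contig_id: str) -> int:
    for i, (cid, _) in enumerate(genome.contigs):
        if cid == contig_id:
            return i
    raise SimulationError(f"contig {contig_id!r} not found in genome {genome.genome_id!r}")


def sim_breakpoint(
    genome: ContigSet, rng: np.random.Generator
) -> tuple[ContigSet, MisassemblyEvent]:
    """Split one contig into two at a uniformly drawn interior position."""
    eligible = [cid for cid, seq in genome.contigs if len(seq) >= 2]
    if not eligible:
        raise SimulationError(
            f"genome {genome.genome_id!r} has no contig of length >= 2"
        )
    contig_id = eligible[int(rng.integers(len(eligible)))]
    return apply_breakpoint(genome, contig_id, None, rng)


def apply_breakpoint(
    genome: ContigSet,
    contig_id: str,
    position: int | None,
    rng: np.random.Generator | None = None,
) -> tuple[ContigSet, MisassemblyEvent]:
    """Split ``contig_id`` at ``position`` (drawn uniformly when None)."""
    idx = _contig_index(genome, contig_id)
    cid, seq = genome.contigs[idx]
    if position is None:
        position = int(rng.integers(1, len(seq)))  # uniform on [1, len-1]
    if not 1 <= position <= len(seq) - 1:
        raise SimulationError(f"breakpoint position {position} outside (0, {len(seq)})")
    left_id, right_id = f"{cid}_1", f"{cid}_2"
    new_contigs = list(genome.contigs)
    new_contigs[idx : idx + 1] = [(left_id, seq[:position]), (right_id, seq[position:])]
    event = MisassemblyEvent(
        kind="breakpoint",
        genome_id=genome.genome_id,
        contig_id=cid,
        position=position,
        new_contig_ids=(left_id, right_id),
    )
    return ContigSet(genome.genome_id, new_contigs), event


def _draw_fragment(
    genome: ContigSet, rng: np.random.Generator, frag_min: int, frag_max: int
) -> tuple[str, int, int]:
    """Pick (contig_id, start, length) for an excision.

    The source contig is drawn uniformly among contigs long enough to lose a
    fragment of at least ``frag_min`` bases without being emptied; the
    fragment length is uniform on [frag_min, min(frag_max, len-1)] and the
    start uniform among valid offsets.
    """
    eligible = [cid for cid, seq in genome.contigs if len(seq) >= frag_min + 1]
    if not eligible:
        raise SimulationError(
            f"genome {genome.genome_id!r} has no contig of length >= {frag_min + 1}"
        )
    contig_id = eligible[int(rng.integers(len(eligible)))]
    seq = genome.contigs[_contig_index(genome, contig_id)][1]
    max_len = min(frag_max, len(seq) - 1)
    length = int(rng.integers(frag_min, max_len + 1))
    start = int(rng.integers(0, len(seq) - length + 1))
    return contig_id, start, length


def apply_relocation(
    source: ContigSet,
    target: ContigSet,
    contig_id: str,
    start: int,
    length: int,
    target_contig_id: str,
    target_position: int,
) -> tuple[ContigSet, ContigSet]:
    """Excise [start, start+length) from source contig and insert into target.

    ``source`` and ``target`` may be the same object (intra-genome
    rearrangement); the insertion position refers to the target contig state
    *after* the excision.
    """
    src_idx = _contig_index(source, contig_id)
    cid, seq = source.contigs[src_idx]
    if start + length > len(seq) or length >= len(seq):
        raise SimulationError("fragment exceeds or empties the source contig")
    fragment = seq[start : start + length]
    new_src = list(source.contigs)
    new_src[src_idx] = (cid, seq[:start] + seq[start + length :])
    source_after = ContigSet(source.genome_id, new_src)

    tgt_set = source_after if target is source else target.copy()
    tgt_idx = _contig_index(tgt_set, target_contig_id)
    tcid, tseq = tgt_set.contigs[tgt_idx]
    if not 0 <= target_position <= len(tseq):
        raise SimulationError(
            f"insertion position {target_position} outside [0, {len(tseq)}]"
        )
    new_tgt = list(tgt_set.contigs)
    new_tgt[tgt_idx] = (tcid, tseq[:target_position] + fragment + tseq[target_position:])
    target_after = ContigSet(tgt_set.genome_id, new_tgt)
    if target is source:
        return target_after, target_after
    return source_after, target_after


def sim_rearrangement(
    genome: ContigSet,
    rng: np.random.Generator,
    frag_min: int = FRAG_MIN_DEFAULT,
    frag_max: int = FRAG_MAX_DEFAULT,
) -> tuple[ContigSet, MisassemblyEvent]:
    """Relocate a fragment within a genome (same or another contig)."""
    contig_id, start, length = _draw_fragment(genome, rng, frag_min, frag_max)
    target_ids = [cid for cid, _ in genome.contigs]
    target_contig_id = target_ids[int(rng.integers(len(target_ids)))]
    # length of the insertion target after excision
    tgt_len = len(genome.contigs[_contig_index(genome, target_contig_id)][1])
    if target_contig_id == contig_id:
        tgt_len -= length
    target_position = int(rng.integers(0, tgt_len + 1))
    _, genome_after = apply_relocation(
        genome, genome, contig_id, start, length, target_contig_id, target_position
    )
    event = MisassemblyEvent(
        kind="rearrangement",
        genome_id=genome.genome_id,
        contig_id=contig_id,
        position=start,
        fragment_length=length,
        target_genome_id=genome.genome_id,
        target_contig_id=target_contig_id,
        target_position=target_position,
    )
    return genome_after, event


def sim_chimerism(
    donor: ContigSet,
    recipient: ContigSet,
    rng: np.random.Generator,
    frag_min: int = FRAG_MIN_DEFAULT,
    frag_max: int = FRAG_MAX_DEFAULT,
) -> tuple[ContigSet, ContigSet, MisassemblyEvent]:
    """Relocate a fragment from a donor genome into a recipient genome."""
    if donor.genome_id == recipient.genome_id:
        raise SimulationError("donor and recipient genomes must differ")
    contig_id, start, length = _draw_fragment(donor, rng, frag_min, frag_max)
    target_ids = [cid for cid, _ in recipient.contigs]
    target_contig_id = target_ids[int(rng.integers(len(target_ids)))]
    tgt_len = len(recipient.contigs[_contig_index(recipient, target_contig_id)][1])
    target_position = int(rng.integers(0, tgt_len + 1))
    donor_after, recipient_after = apply_relocation(
        donor, recipient, contig_id, start, length, target_contig_id, target_position
    )
    event = MisassemblyEvent(
        kind="chimerism",
        genome_id=donor.genome_id,
        contig_id=contig_id,
        position=start,
        fragment_length=length,
        target_genome_id=recipient.genome_id,
        target_contig_id=target_contig_id,
        target_position=target_position,
    )
    return donor_after, recipient_after, event


def simulate_dataset(
    genomes: Sequence[ContigSet], config: SimConfig
) -> tuple[list[ContigSet], list[MisassemblyEvent]]:
    """Apply the configured per-genome misassembly counts to a genome set.

    Events are applied in a fixed order — per genome (sorted by id) all
    breakpoints, then all rearrangements; then per donor genome all
    chimerisms, with the recipient drawn uniformly among the other genomes.
    The whole run is driven by one generator seeded from ``config.seed``.
    """
    if config.n_chimerisms > 0 and len(genomes) < 2:
        raise SimulationError("chimerism simulation needs at least 2 genomes")
    rng = np.random.default_rng(config.seed)
    state = {g.genome_id: g.copy() for g in genomes}
    order = sorted(state)
    events: list[MisassemblyEvent] = []

    for gid in order:
        for _ in range(config.n_breakpoints):
            state[gid], ev = sim_breakpoint(state[gid], rng)
            events.append(ev)
        for _ in range(config.n_rearrangements):
            state[gid], ev = sim_rearrangement(
                state[gid], rng, config.frag_min, config.frag_max
            )
            events.append(ev)
    for gid in order:
        others = [o for o in order if o != gid]
        for _ in range(config.n_chimerisms):
            recipient_id = others[int(rng.integers(len(others)))]
            donor_after, recipient_after, ev = sim_chimerism(
                state[gid], state[recipient_id], rng, config.frag_min, config.frag_max
            )
            state[gid] = donor_after
            state[recipient_id] = recipient_after
            events.append(ev)

    # preserve the caller's genome order
    return [state[g.genome_id] for g in genomes], events


def replay_events(
    genomes: Sequence[ContigSet], events: Iterable[MisassemblyEvent]
) -> list[ContigSet]:
    """Deterministically re-apply a logged event sequence to the input genomes."""
    state = {g.genome_id: g.copy() for g in genomes}
    for ev in events:
        if ev.kind == "breakpoint":
            state[ev.genome_id], _ = apply_breakpoint(
                state[ev.genome_id], ev.contig_id, ev.position
            )
        elif ev.kind == "rearrangement":
            _, state[ev.genome_id] = apply_relocation(
                state[ev.genome_id], state[ev.genome_id],
                ev.contig_id, ev.position, ev.fragment_length,
                ev.target_contig_id, ev.target_position,
            )
        elif ev.kind == "chimerism":
            donor_after, recipient_after = apply_relocation(
                state[ev.genome_id], state[ev.target_genome_id],
                ev.contig_id, ev.position, ev.fragment_length,
                ev.target_contig_id, ev.target_position,
            )
            state[ev.genome_id] = donor_after
            state[ev.target_genome_id] = recipient_after
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return [state[g.genome_id] for g in genomes]


def events_to_table(events: Sequence[MisassemblyEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "kind": ev.kind,
                "genome_id": ev.genome_id,
                "contig_id": ev.contig_id,
                "position": ev.position,
                "fragment_length": ev.fragment_length,
                "target_genome_id": ev.target_genome_id,
                "target_contig_id": ev.target_contig_id,
                "target_position": ev.target_position,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "genome_id", "contig_id", "position", "fragment_length",
            "target_genome_id", "target_contig_id", "target_position",
        ],
    )


def write_event_log(events: Sequence[MisassemblyEvent], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events_to_table(events).to_csv(path, sep="\t", index=False)
    return path
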