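"""Database-quality evaluation: annotation recovery versus ground truth,
Bray-Curtis beta diversity, Mantel tests, and ordinary least squares.

Recovery compares the annotation table built from a perturbed (e.g.
misassembled) genome set against the table built from the unaltered
genomes.  Genes are paired across the two catalogs primarily by exact
nucleotide sequence; genes whose sequence was disrupted are paired by
reciprocal best global identity above a floor, and genes with no
counterpart stay unpaired (they can only lower the correctness score).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from skbio import DistanceMatrix

from ._align import align_nt
from .genecat import GeneRecord


@dataclass(frozen=True)
class AbundanceProfile:
    """Taxon -> count table for one sample."""

    sample_id: str
    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("abundances must be non-negative")


def bray_curtis(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Bray-Curtis dissimilarity sum|p-q| / sum(p+q) over the taxon union."""
    taxa = sorted(set(p.counts) | set(q.counts))
    if not taxa:
        raise ValueError("taxon union is empty")
    pv = np.array([p.counts.get(t, 0.0) for t in taxa])
    qv = np.array([q.counts.get(t, 0.0) for t in taxa])
    denom = (pv + qv).sum()
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(pv - qv).sum() / denom)


def bray_curtis_matrix(profiles: Sequence[AbundanceProfile]) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances for a set of samples."""
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = bray_curtis(profiles[i], profiles[j])
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    The statistic is the Pearson correlation of the vectorized upper
    triangles; significance comes from jointly permuting the rows and
    columns of ``d2``, with the one-sided (greater) p-value
    ``(1 + #{rho* >= rho}) / (1 + n_perm)`` so it can never be exactly zero.
    With ``exhaustive=True`` all n! label permutations are enumerated
    instead and ``p = #{rho* >= rho} / n!`` (the identity permutation makes
    this >= 1/n!); feasible only for small n.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share identical sample ids")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("mantel requires at least 3 samples")
    iu = np.triu_indices(n, k=1)
    x = d1.data[iu]
    m2 = d2.data
    rho = float(sp_stats.pearsonr(x, m2[iu])[0])
    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        exceed = sum(
            1
            for perm in _perms(range(n))
            if float(sp_stats.pearsonr(x, m2[np.ix_(perm, perm)][iu])[0])
            >= rho - 1e-12
        )
        return rho, exceed / factorial(n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rho_star = float(sp_stats.pearsonr(x, m2[np.ix_(perm, perm)][iu])[0])
        if rho_star >= rho:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return rho, p


def ols_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares line fit: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sp_stats.linregress(x, y)
    y_hat = res.intercept + res.slope * x
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(res.slope), float(res.intercept), r2


def match_genes(
    truth_genes: Sequence[GeneRecord],
    test_genes: Sequence[GeneRecord],
    min_identity: float = 0.9,
) -> dict[str, str]:
    """Pair test genes with truth genes: test gene_id -> truth gene_id.

    Exact nucleotide sequence matches are paired first (within the same
    genome when possible, one-to-one).  Remaining test genes are paired with
    the remaining truth gene of highest global nucleotide identity when it
    reaches ``min_identity`` and the choice is reciprocal.
    """
    truth_free = {g.gene_id: g for g in truth_genes}
    mapping: dict[str, str] = {}
    # exact-sequence pass, preferring the same source genome
    by_seq: dict[str, list[GeneRecord]] = {}
    for g in truth_genes:
        by_seq.setdefault(g.nt_seq, []).append(g)
    unmatched_test: list[GeneRecord] = []
    for t in sorted(test_genes, key=lambda g: g.gene_id):
        cands = [c for c in by_seq.get(t.nt_seq, []) if c.gene_id in truth_free]
        if cands:
            same = [c for c in cands if c.genome_id == t.genome_id]
            chosen = sorted(same or cands, key=lambda c: c.gene_id)[0]
            mapping[t.gene_id] = chosen.gene_id
            del truth_free[chosen.gene_id]
        else:
            unmatched_test.append(t)
    # reciprocal best-identity pass for sequence-disrupted genes
    if unmatched_test and truth_free:
        best_for_test: dict[str, tuple[str, float]] = {}
        best_for_truth: dict[str, tuple[str, float]] = {}
        for t in unmatched_test:
            for tid, tr in truth_free.items():
                ident = align_nt(t.nt_seq, tr.nt_seq).identity
                if ident < min_identity:
                    continue
                if tid not in best_for_truth or ident > best_for_truth[tid][1]:
                    best_for_truth[tid] = (t.gene_id, ident)
                cur = best_for_test.get(t.gene_id)
                if cur is None or ident > cur[1]:
                    best_for_test[t.gene_id] = (tid, ident)
        for test_id, (truth_id, _) in sorted(best_for_test.items()):
            if best_for_truth.get(truth_id, (None,))[0] == test_id:
                mapping[test_id] = truth_id
    return mapping


def annotation_recovery(
    truth: pd.DataFrame,
    test: pd.DataFrame,
    gene_map: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """(pct_annotated, pct_correct) of a test catalog versus ground truth.

    Both tables need columns ``gene_id`` and ``uniref90_id``; rows with an
    empty id are unannotated.  ``pct_annotated`` is 100 x the number of
    annotated test genes over the number of annotated truth genes;
    ``pct_correct`` additionally requires the test gene's identifier to
    equal its paired truth gene's.  ``gene_map`` maps test gene ids to truth
    gene ids (identity mapping when omitted, for tables sharing a key).
    """

    def _annotated(df: pd.DataFrame) -> dict[str, str]:
        out = {}
        for _, row in df.iterrows():
            u90 = row["uniref90_id"]
            if pd.notna(u90) and str(u90) != "":
                out[str(row["gene_id"])] = str(u90)
        return out

    truth_ann = _annotated(truth)
    if not truth_ann:
        raise ValueError("truth table has no annotated genes")
    test_ann = _annotated(test)
    pct_annotated = 100.0 * len(test_ann) / len(truth_ann)
    if gene_map is None:
        gene_map = {gid: gid for gid in test_ann}
    correct = sum(
        1
        for test_id, u90 in test_ann.items()
        if truth_ann.get(gene_map.get(test_id, "")) == u90
    )
    pct_correct = 100.0 * correct / len(truth_ann)
    return pct_annotated, pct_correct


def profiles_from_table(df: pd.DataFrame) -> list[AbundanceProfile]:
    """Sample x taxon count table (samples as rows, index = sample id)."""
    return [
        AbundanceProfile(sample_id=str(idx), counts=row.to_dict())
        for idx, row in df.iterrows()
    ]
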