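"""Genomic clustering of miRNA loci, cluster statistics, cross-species
cluster conservation/fragmentation, paralog groups and co-expression.

Clusters are single-linkage chains per chromosome: two loci join when the gap
between their precursor intervals is at most the cutoff (inclusive; 0 when
they overlap). Singletons are excluded from the cluster list but counted in
the statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .armprofile import ArmUsageRecord
from .mirio import MiRNALocus

__all__ = [
    "MiRNACluster",
    "cluster_loci",
    "ClusterStats",
    "cluster_stats",
    "same_arm_proportion",
    "ClusterConservation",
    "compare_clusters",
    "ParalogGroup",
    "detect_paralogs",
    "clustered_expression_correlation",
]


@dataclass
class MiRNACluster:
    cluster_id: str
    chrom: str
    members: list[str]
    span: int
    cutoff: int
    same_strand: bool


def _gap(a: MiRNALocus, b: MiRNALocus) -> int:
    """Gap between precursor intervals; 0 if they overlap."""
    lo = max(a.precursor_iv[0], b.precursor_iv[0])
    hi = min(a.precursor_iv[1], b.precursor_iv[1])
    return max(0, lo - hi) if lo > hi else 0


def cluster_loci(loci: Sequence[MiRNALocus], cutoff_bp: int
                 ) -> list[MiRNACluster]:
    """Single-linkage clusters at a genomic distance cutoff (gap <= cutoff)."""
    clusters: list[MiRNACluster] = []
    by_chrom: dict[str, list[MiRNALocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    n = 0
    for chrom in sorted(by_chrom):
        chain: list[MiRNALocus] = []
        max_end = -1
        for loc in sorted(by_chrom[chrom], key=lambda l: l.precursor_iv):
            if chain and max(0, loc.precursor_iv[0] - max_end) <= cutoff_bp:
                chain.append(loc)
                max_end = max(max_end, loc.precursor_iv[1])
            else:
                if len(chain) >= 2:
                    n += 1
                    clusters.append(_make_cluster(n, chrom, chain, cutoff_bp))
                chain = [loc]
                max_end = loc.precursor_iv[1]
        if len(chain) >= 2:
            n += 1
            clusters.append(_make_cluster(n, chrom, chain, cutoff_bp))
    return clusters


def _make_cluster(n: int, chrom: str, chain: list[MiRNALocus], cutoff: int
                  ) -> MiRNACluster:
    return MiRNACluster(
        cluster_id=f"cluster_{cutoff}_{n}", chrom=chrom,
        members=[l.locus_id for l in chain],
        span=chain[-1].precursor_iv[1] - chain[0].precursor_iv[0],
        cutoff=cutoff,
        same_strand=len({l.strand for l in chain}) == 1)


@dataclass
class ClusterStats:
    cutoff: int
    n_clusters: int
    fraction_clustered: float
    mean_cluster_size: float
    same_strand_fraction: float
    per_chrom: dict[str, int]


def cluster_stats(clusters: Sequence[MiRNACluster],
                  all_loci: Sequence[MiRNALocus]) -> ClusterStats:
    clustered = sum(len(c.members) for c in clusters)
    sizes = [len(c.members) for c in clusters]
    per_chrom: dict[str, int] = {}
    for c in clusters:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + len(c.members)
    return ClusterStats(
        cutoff=clusters[0].cutoff if clusters else 0,
        n_clusters=len(clusters),
        fraction_clustered=clustered / len(all_loci) if all_loci else 0.0,
        mean_cluster_size=sum(sizes) / len(sizes) if sizes else 0.0,
        same_strand_fraction=(sum(c.same_strand for c in clusters) / len(clusters)
                              if clusters else 0.0),
        per_chrom=per_chrom)


def same_arm_proportion(clusters: Sequence[MiRNACluster],
                        arm_records: Mapping[str, ArmUsageRecord],
                        all_loci: Sequence[MiRNALocus],
                        rng: np.random.Generator | None = None,
                        ) -> tuple[float, float]:
    """Arm-selection concordance of clustered vs non-clustered miRNAs.

    The clustered proportion counts each clustered miRNA as concordant when
    its predominant-arm call matches its cluster's majority arm (balanced and
    no-data calls are skipped). The non-clustered baseline is the pairwise
    agreement probability among singleton loci: the chance that two randomly
    chosen non-clustered miRNAs produce their dominant product from the same
    arm.
    """
    concordant = total = 0
    clustered_ids: set[str] = set()
    for c in clusters:
        calls = [arm_records[m].call for m in c.members
                 if m in arm_records and arm_records[m].call in ("5p", "3p")]
        clustered_ids.update(c.members)
        if len(calls) < 2:
            continue
        majority = max(("5p", "3p"), key=lambda a: (calls.count(a), a == "5p"))
        concordant += sum(1 for x in calls if x == majority)
        total += len(calls)
    clustered_prop = concordant / total if total else math.nan

    single_calls = [arm_records[l.locus_id].call for l in all_loci
                    if l.locus_id not in clustered_ids
                    and l.locus_id in arm_records
                    and arm_records[l.locus_id].call in ("5p", "3p")]
    if len(single_calls) < 2:
        return clustered_prop, math.nan
    n5 = single_calls.count("5p")
    n3 = single_calls.count("3p")
    n = n5 + n3
    # probability that a random pair of singletons agrees
    pair_agree = (n5 * (n5 - 1) + n3 * (n3 - 1)) / (n * (n - 1))
    return clustered_prop, pair_agree


@dataclass
class ClusterConservation:
    cluster_a_id: str
    cluster_b_id: str | None
    shared_families: list[str]
    status: str  # conserved | fragmented | species_specific


def compare_clusters(clusters_a: Sequence[MiRNACluster],
                     clusters_b: Sequence[MiRNACluster],
                     family_of_a: Mapping[str, str],
                     family_of_b: Mapping[str, str],
                     ) -> list[ClusterConservation]:
    """Conservation status of each cluster of species A against species B.

    conserved: every orthologous family of the A-cluster co-clusters in one
    B-cluster; fragmented: a proper non-empty subset does; species_specific:
    none do.
    """
    fam_to_bcluster: dict[str, str] = {}
    for c in clusters_b:
        for m in c.members:
            fam = family_of_b.get(m)
            if fam:
                fam_to_bcluster[fam] = c.cluster_id
    out = []
    for c in clusters_a:
        fams = [family_of_a.get(m) for m in c.members]
        fams = [f for f in fams if f]
        hits: dict[str, list[str]] = {}
        for f in fams:
            bc = fam_to_bcluster.get(f)
            if bc:
                hits.setdefault(bc, []).append(f)
        if not hits:
            out.append(ClusterConservation(c.cluster_id, None, [], "species_specific"))
            continue
        best_bc, shared = max(hits.items(), key=lambda kv: (len(kv[1]), kv[0]))
        status = "conserved" if len(shared) == len(fams) else "fragmented"
        out.append(ClusterConservation(c.cluster_id, best_bc, sorted(shared), status))
    return out


@dataclass
class ParalogGroup:
    family_label: str
    member_loci: list[str]
    evidence: set[str] = field(default_factory=set)


def _identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="distance", mode="NW")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def detect_paralogs(loci: Sequence[MiRNALocus],
                    precursor_identity: float = 0.70) -> list[ParalogGroup]:
    """Group loci that share an identical mature sequence or precursors with
    at least ``precursor_identity`` global identity (single linkage)."""
    n = len(loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    def mature(loc: MiRNALocus) -> set[str]:
        out = set()
        for arm in ("5p", "3p"):
            iv = loc.arm_iv(arm)
            if iv:
                a, b = loc.to_precursor_coords(*iv)
                out.add(loc.precursor_seq[a:b])
        return out

    evidence: dict[tuple[int, int], set[str]] = {}
    for i, j in itertools.combinations(range(n), 2):
        ev = set()
        if mature(loci[i]) & mature(loci[j]):
            ev.add("identical_mature")
        if _identity(loci[i].precursor_seq, loci[j].precursor_seq) >= precursor_identity:
            ev.add("precursor_similarity")
        if ev:
            union(i, j)
            evidence[(i, j)] = ev
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for root, idxs in sorted(groups.items()):
        if len(idxs) < 2:
            continue
        ev: set[str] = set()
        for i, j in itertools.combinations(idxs, 2):
            ev |= evidence.get((i, j), set())
        members = sorted(loci[i].locus_id for i in idxs)
        label = loci[idxs[0]].family or members[0]
        out.append(ParalogGroup(label, members, ev))
    return out


def clustered_expression_correlation(clusters: Sequence[MiRNACluster],
                                     counts, size_factors=None,
                                     ) -> dict[str, float]:
    """Mean pairwise squared Pearson correlation of log normalized counts
    between cluster members across libraries (requires >= 3 libraries).

    ``counts`` is a locus x library DataFrame; members with all-zero counts
    are excluded.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 libraries")
    norm = counts / size_factors if size_factors is not None else counts
    logc = np.log2(norm + 1.0)
    out: dict[str, float] = {}
    for c in clusters:
        members = [m for m in c.members
                   if m in logc.index and counts.loc[m].sum() > 0]
        if len(members) < 2:
            continue
        r2s = []
        for a, b in itertools.combinations(members, 2):
            x, y = logc.loc[a].values, logc.loc[b].values
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2s.append(r * r)
        if r2s:
            out[c.cluster_id] = float(np.mean(r2s))
    return out
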