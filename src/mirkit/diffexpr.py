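"""Count matrices, normalization, fold changes and differential expression.

Differential calls follow a declared decision rule (|log2 fold change| > 1.5
and p < 0.05). P-values come from a permutation test on normalized counts;
with very few replicates per condition (the common small RNA-seq design) the
within-locus label permutations are too few to resolve p < 0.05, so the null
distribution is then pooled across loci (SAM-style). Knockdown validation
normalizes against an invariant reference gene (U2 snRNA by default);
condition contrasts default to median-of-ratios size factors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .armprofile import assign_arm
from .isomir import build_stack
from .mirio import GenomeSequence, MiRNALocus

__all__ = [
    "CountMatrix",
    "build_count_matrix",
    "normalize",
    "fold_changes",
    "DEResult",
    "differential_expression",
    "SpeciesPartition",
    "partition_species",
    "LFC_THRESHOLD",
    "ALPHA",
]

LFC_THRESHOLD = 1.5
ALPHA = 0.05
PSEUDOCOUNT = 0.5
MIN_LABEL_PERMS = 40  # below this, pool permutation nulls across loci

RNA_CLASSES = ("miRNA", "tRNA_rRNA_snoRNA", "other")


@dataclass
class CountMatrix:
    counts: pd.DataFrame                 # loci x libraries, weighted counts
    row_classes: pd.Series               # locus -> RNA class
    library_meta: dict[str, dict]        # library -> {condition, replicate, experiment}
    size_factors: pd.Series | None = None

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("normalize() has not been run")
        return self.counts / self.size_factors

    def libraries_for(self, condition: str) -> list[str]:
        return [lib for lib, m in self.library_meta.items()
                if m.get("condition") == condition]


def build_count_matrix(loci: Sequence[MiRNALocus],
                       alignments_by_library: Mapping[str, Sequence],
                       library_meta: Mapping[str, dict],
                       genome: GenomeSequence,
                       locus_classes: Mapping[str, str] | None = None,
                       arm_mode: str = "both") -> CountMatrix:
    """Locus x library weighted count matrix.

    Per-locus counts sum the iso-miR stack of each arm (non-template-tailed
    and internally mismatched mature reads included; loop-derived and
    beyond-window degradation reads excluded). ``arm_mode='predominant'``
    keeps only the more abundant arm.
    """
    for lib in alignments_by_library:
        if lib not in library_meta:
            raise ValueError(f"library {lib!r} has no metadata")
    libs = list(alignments_by_library)
    data = np.zeros((len(loci), len(libs)))
    for j, lib in enumerate(libs):
        reads = alignments_by_library[lib]
        by_locus_arm: dict[tuple[str, str], list] = {}
        for r in reads:
            for loc in loci:
                if (r.chrom == loc.chrom
                        and r.start < loc.precursor_iv[1] + 3
                        and r.end > loc.precursor_iv[0] - 3):
                    arm = assign_arm(r, loc)
                    if arm != "unassigned":
                        by_locus_arm.setdefault((loc.locus_id, arm), []).append(r)
        for i, loc in enumerate(loci):
            arm_totals = {}
            for arm in ("5p", "3p"):
                rs = by_locus_arm.get((loc.locus_id, arm), [])
                if not rs:
                    arm_totals[arm] = 0.0
                    continue
                stack = build_stack(loc, arm, rs, genome)
                arm_totals[arm] = stack.total + sum(
                    r.weighted_count for r, _ in stack.internal_mismatch)
            if arm_mode == "predominant":
                data[i, j] = max(arm_totals.values())
            else:
                data[i, j] = sum(arm_totals.values())
    counts = pd.DataFrame(data, index=[l.locus_id for l in loci], columns=libs)
    classes = pd.Series({l.locus_id: (locus_classes or {}).get(l.locus_id, "miRNA")
                         for l in loci})
    return CountMatrix(counts, classes, {k: dict(v) for k, v in library_meta.items()})


def normalize(matrix: CountMatrix, mode: str = "median_of_ratios",
              reference_gene: str = "U2") -> pd.Series:
    """Compute and attach per-library size factors.

    median_of_ratios: median of per-locus ratios to the geometric-mean
    reference library (rows with any zero are skipped). reference_gene: size
    factors proportional to the reference gene's counts (relative to the
    first library). total_mapped: proportional to library totals (relative to
    their geometric mean).
    """
    c = matrix.counts
    if c.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    if mode == "median_of_ratios":
        positive = c[(c > 0).all(axis=1)]
        if positive.empty:
            raise ValueError("no locus with all-positive counts")
        log_geo = np.log(positive).mean(axis=1)
        sf = np.exp(np.median(np.log(positive).sub(log_geo, axis=0), axis=0))
        sf = pd.Series(sf, index=c.columns)
    elif mode == "reference_gene":
        if reference_gene not in c.index:
            raise ValueError(f"reference gene {reference_gene!r} not in matrix")
        ref = c.loc[reference_gene]
        if (ref == 0).any():
            raise ValueError(f"reference gene {reference_gene!r} has a zero count")
        sf = ref / ref.iloc[0]
    elif mode == "total_mapped":
        totals = c.sum(axis=0)
        sf = totals / np.exp(np.log(totals).mean())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    matrix.size_factors = sf
    return sf


def fold_changes(matrix: CountMatrix, contrast: tuple[str, str],
                 pseudocount: float = PSEUDOCOUNT,
                 ) -> tuple[pd.Series, dict[str, float]]:
    """Per-locus log2 fold change of condition a over b on normalized means,
    plus per-class medians."""
    cond_a, cond_b = contrast
    libs_a = matrix.libraries_for(cond_a)
    libs_b = matrix.libraries_for(cond_b)
    if not libs_a or not libs_b:
        raise ValueError(f"contrast {contrast} matches no libraries")
    norm = matrix.normalized()
    mean_a = norm[libs_a].mean(axis=1)
    mean_b = norm[libs_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    medians = {klass: float(lfc[matrix.row_classes == klass].median())
               for klass in sorted(matrix.row_classes.unique())}
    return lfc, medians


@dataclass
class DEResult:
    locus_id: str
    log2fc: float
    p_value: float
    significant: bool
    direction: str


def _distinct_label_assignments(libs: list[str], n_a: int, cap: int,
                                rng: np.random.Generator):
    combos = list(itertools.combinations(range(len(libs)), n_a))
    if len(combos) <= cap:
        return combos
    idx = rng.choice(len(combos), size=cap, replace=False)
    return [combos[i] for i in idx]


def differential_expression(matrix: CountMatrix, contrast: tuple[str, str],
                            lfc_threshold: float = LFC_THRESHOLD,
                            alpha: float = ALPHA,
                            max_permutations: int = 1000,
                            seed: int = 0) -> list[DEResult]:
    """Permutation-based differential expression with the declared decision
    rule (|log2fc| > threshold and p < alpha).

    The test statistic is the per-locus log2 fold change on normalized
    counts. Labels are permuted over the contrast's libraries; when fewer
    than ``MIN_LABEL_PERMS`` distinct relabelings exist the permutation
    statistics are pooled across loci to form the null. With fewer than two
    replicates per condition p-values are NA and nothing is called.
    """
    cond_a, cond_b = contrast
    libs_a = matrix.libraries_for(cond_a)
    libs_b = matrix.libraries_for(cond_b)
    if not libs_a or not libs_b:
        raise ValueError(f"contrast {contrast} matches no libraries")
    lfc, _ = fold_changes(matrix, contrast)
    if min(len(libs_a), len(libs_b)) < 2:
        return [DEResult(loc, float(lfc[loc]), math.nan, False,
                         "up" if lfc[loc] >= 0 else "down")
                for loc in matrix.counts.index]
    rng = np.random.default_rng(seed)
    libs = libs_a + libs_b
    norm = matrix.normalized()[libs].values
    n_a = len(libs_a)
    combos = _distinct_label_assignments(libs, n_a, max_permutations, rng)
    identity = tuple(range(n_a))
    null_stats = []  # rows: loci, cols: non-identity relabelings
    for combo in combos:
        if tuple(combo) == identity:
            continue
        a_idx = list(combo)
        b_idx = [i for i in range(len(libs)) if i not in combo]
        ma = norm[:, a_idx].mean(axis=1)
        mb = norm[:, b_idx].mean(axis=1)
        null_stats.append(np.abs(np.log2((ma + PSEUDOCOUNT) / (mb + PSEUDOCOUNT))))
    null = np.array(null_stats)  # (n_perm, n_loci)
    obs = np.abs(lfc.values)
    pooled = null.shape[0] + 1 < MIN_LABEL_PERMS
    results = []
    if pooled:
        flat = np.sort(null.ravel())
        n_null = flat.size
        for i, loc in enumerate(matrix.counts.index):
            ge = n_null - np.searchsorted(flat, obs[i], side="left")
            p = (1.0 + ge) / (1.0 + n_null)
            results.append(_make_result(loc, float(lfc[loc]), float(p),
                                        lfc_threshold, alpha))
    else:
        for i, loc in enumerate(matrix.counts.index):
            ge = int((null[:, i] >= obs[i]).sum())
            p = (1.0 + ge) / (1.0 + null.shape[0])
            results.append(_make_result(loc, float(lfc[loc]), float(p),
                                        lfc_threshold, alpha))
    return results


def _make_result(loc: str, lfc: float, p: float, thr: float, alpha: float
                 ) -> DEResult:
    sig = abs(lfc) > thr and p < alpha
    return DEResult(loc, lfc, p, sig, "up" if lfc >= 0 else "down")


# ---------------------------------------------------------------------------
# host/vector partition of shared-sequence miRNAs
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPartition:
    family_label: str
    vector_count: float
    host_count: float
    ambiguous_count: float
    unmatched_count: float

    @property
    def exogenous_fraction(self) -> float:
        assigned = self.vector_count + self.host_count + self.ambiguous_count
        return self.host_count / assigned if assigned else math.nan


def partition_species(reads: Iterable[tuple[str, float]],
                      vector_isoforms: Sequence[str],
                      host_isoforms: Sequence[str],
                      family_label: str = "") -> SpeciesPartition:
    """Assign reads by exact sequence match to vector vs host isoform sets.

    Reads matching both sets land in the ambiguous bucket; identical
    sequences listed in both isoform sets are a configuration error.
    """
    from .mirio import dna

    vec = {dna(s) for s in vector_isoforms}
    host = {dna(s) for s in host_isoforms}
    overlap = vec & host
    if overlap:
        raise ValueError(f"isoform sequences listed for both species: {overlap}")
    part = SpeciesPartition(family_label, 0.0, 0.0, 0.0, 0.0)
    for seq, count in reads:
        s = dna(seq)
        if s in vec:
            part.vector_count += count
        elif s in host:
            part.host_count += count
        else:
            part.unmatched_count += count
    return part
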