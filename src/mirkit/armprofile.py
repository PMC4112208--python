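"""Arm usage: 5p/3p read assignment, proportions and ratios, predominant-arm
calls, shifts against annotation and switches between conditions or species.

The predominant-arm call uses a declared balanced band: ratio > 1.25 calls
5p, ratio < 0.8 calls 3p, anything between is balanced ("5p~3p"). Ratios with
an empty arm are computed with a 0.5 pseudocount on both arms and flagged;
proportions stay raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mirio import AlignedRead, MiRNALocus

__all__ = [
    "assign_arm",
    "ArmUsageRecord",
    "arm_usage",
    "arm_usage_from_reads",
    "ArmSwitchCall",
    "detect_arm_shift_vs_annotation",
    "detect_arm_switch_between",
    "pair_orthologs",
    "global_arm_bias",
    "RATIO_5P",
    "RATIO_3P",
]

RATIO_5P = 1.25   # ratio above which the 5p arm is called predominant
RATIO_3P = 0.80   # ratio below which the 3p arm is called predominant
ARM_SLOP = 3      # nt of slack around the annotated mature interval
MIN_OVERLAP_FRACTION = 0.5


def assign_arm(read: AlignedRead, locus: MiRNALocus) -> str:
    """Assign a read to the 5p or 3p arm of its locus, or ``unassigned``.

    The read must be on the locus strand and put at least half of its length
    on one arm's mature interval (extended by 3 nt); the arm with the larger
    overlap wins. Loop-centred and degradation reads stay unassigned.
    """
    if read.chrom != locus.chrom or read.strand != locus.strand:
        return "unassigned"
    best_arm, best_ov = "unassigned", 0
    for arm in ("5p", "3p"):
        iv = locus.arm_iv(arm)
        if iv is None:
            continue
        lo, hi = iv[0] - ARM_SLOP, iv[1] + ARM_SLOP
        ov = min(read.end, hi) - max(read.start, lo)
        if ov > best_ov:
            best_arm, best_ov = arm, ov
    if best_ov < MIN_OVERLAP_FRACTION * len(read.seq):
        return "unassigned"
    return best_arm


@dataclass
class ArmUsageRecord:
    locus_id: str
    library_id: str
    count5p: float
    count3p: float
    proportion5p: float = math.nan
    ratio: float = math.nan
    call: str = "no_data"          # 5p | 3p | balanced | no_data
    zero_adjusted: bool = False

    def __post_init__(self) -> None:
        total = self.count5p + self.count3p
        if total <= 0:
            return
        self.proportion5p = self.count5p / total
        if self.count5p == 0 or self.count3p == 0:
            self.ratio = (self.count5p + 0.5) / (self.count3p + 0.5)
            self.zero_adjusted = True
        else:
            self.ratio = self.count5p / self.count3p
        self.call = call_from_ratio(self.ratio)


def call_from_ratio(ratio: float) -> str:
    if ratio > RATIO_5P:
        return "5p"
    if ratio < RATIO_3P:
        return "3p"
    return "balanced"


def arm_usage(locus_id: str, count5p: float, count3p: float,
              library_id: str = "") -> ArmUsageRecord:
    """Arm-usage record from weighted 5p/3p counts (tailed reads included
    upstream, at counting time)."""
    return ArmUsageRecord(locus_id, library_id, count5p, count3p)


def arm_usage_from_reads(locus: MiRNALocus, reads: Iterable[AlignedRead],
                         library_id: str = "") -> ArmUsageRecord:
    c5 = c3 = 0.0
    for r in reads:
        arm = assign_arm(r, locus)
        if arm == "5p":
            c5 += r.weighted_count
        elif arm == "3p":
            c3 += r.weighted_count
    return arm_usage(locus.locus_id, c5, c3, library_id)


@dataclass
class ArmSwitchCall:
    locus_id: str
    context: str                  # annotation_vs_observed | condition_pair | species_pair
    ratio_a: float
    ratio_b: float
    fold_difference: float
    switched: bool
    observed_call: str = ""
    flagged: bool = False


def detect_arm_shift_vs_annotation(record: ArmUsageRecord, annotated_arm: str
                                   ) -> ArmSwitchCall:
    """Compare the observed predominant arm with a declared annotation.

    switched only when the observed call is the *opposite* arm; a balanced
    observation is reported as "5p~3p" without counting as a switch.
    """
    observed = record.call
    opposite = {"5p": "3p", "3p": "5p"}.get(annotated_arm)
    switched = observed == opposite
    shown = "5p~3p" if observed == "balanced" else observed
    return ArmSwitchCall(record.locus_id, "annotation_vs_observed",
                         math.nan, record.ratio, math.nan, switched,
                         observed_call=shown)


def detect_arm_switch_between(a: ArmUsageRecord, b: ArmUsageRecord,
                              fold_threshold: float = 10.0,
                              context: str = "condition_pair") -> ArmSwitchCall:
    """Fold difference in relative arm usage between two paired records."""
    if a.call == "no_data" or b.call == "no_data":
        raise ValueError("both records must carry data")
    ra, rb = a.ratio, b.ratio
    fold = max(ra / rb, rb / ra)
    return ArmSwitchCall(a.locus_id, context, ra, rb, fold,
                         switched=fold >= fold_threshold,
                         flagged=a.zero_adjusted or b.zero_adjusted)


def pair_orthologs(set_a: Sequence[MiRNALocus], set_b: Sequence[MiRNALocus],
                   ) -> tuple[list[tuple[MiRNALocus, MiRNALocus]], list[str]]:
    """1:1 ortholog pairs by family label; families with paralogs in either
    species (or present in only one) are excluded and reported."""
    def by_family(loci):
        fam: dict[str, list[MiRNALocus]] = {}
        for loc in loci:
            fam.setdefault(loc.family or loc.locus_id, []).append(loc)
        return fam

    fa, fb = by_family(set_a), by_family(set_b)
    pairs, excluded = [], []
    for family in sorted(set(fa) | set(fb)):
        in_a, in_b = fa.get(family, []), fb.get(family, [])
        if len(in_a) == 1 and len(in_b) == 1:
            pairs.append((in_a[0], in_b[0]))
        else:
            excluded.append(family)
    return pairs, excluded


def global_arm_bias(records: Iterable[ArmUsageRecord]
                    ) -> tuple[float, float]:
    """Mean per-locus 5p proportion (each locus weighted equally) and the
    pooled-read variant (total 5p reads over total reads)."""
    props, c5, tot = [], 0.0, 0.0
    for r in records:
        if r.call == "no_data":
            continue
        props.append(r.proportion5p)
        c5 += r.count5p
        tot += r.count5p + r.count3p
    if not props:
        raise ValueError("no records with data")
    return sum(props) / len(props), c5 / tot
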