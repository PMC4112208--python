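"""Iso-miR analysis: per-arm read stacks, 5'/3' heterogeneity, 3'-extension
classification (template vs non-template tailing) and the editing scan.

The most abundant perfectly matching read of an arm is the reference isoform;
every other read is described by its 5' and 3' offsets from that reference
(negative offset5 = 5' end upstream of the reference, i.e. extended; positive
offset3 = 3' end downstream, i.e. extended). Reads further than 3 nt from the
reference at either end are tallied as degradation/other; reads with internal
mismatches are routed to the editing scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import binomtest

from .mirio import AlignedRead, GenomeSequence, MiRNALocus, rna

__all__ = [
    "StackEntry",
    "ReadStack",
    "build_stack",
    "FivePrimeProfile",
    "five_prime_profile",
    "ExtensionCall",
    "classify_extension",
    "IsomirProfile",
    "isomir_profile",
    "TailingSummary",
    "tailing_composition",
    "EditingScan",
    "editing_scan",
    "precursor_context",
]

WINDOW = 3  # max |offset| at either end for stack membership
NUCLEOTIDES = ("A", "U", "C", "G")


@dataclass
class StackEntry:
    seq: str
    weighted_count: float
    offset5: int
    offset3: int
    mismatch_positions: tuple[int, ...] = ()


@dataclass
class ReadStack:
    locus_id: str
    arm: str
    reference_seq: str = ""
    reference_read: AlignedRead | None = None
    entries: list[StackEntry] = field(default_factory=list)
    beyond_window: float = 0.0
    internal_mismatch: list[tuple[AlignedRead, tuple[int, ...]]] = field(
        default_factory=list)

    @property
    def total(self) -> float:
        return sum(e.weighted_count for e in self.entries)

    @property
    def is_empty(self) -> bool:
        return self.reference_read is None


def _mismatch_positions(read: AlignedRead, genome: GenomeSequence
                        ) -> tuple[int, ...]:
    """Read-local (transcript-orientation) positions differing from genome."""
    ref = genome.fetch(read.chrom, read.start, read.end, read.strand)
    return tuple(i for i, (a, b) in enumerate(zip(read.seq, ref)) if a != b)


def _offsets(read: AlignedRead, ref: AlignedRead) -> tuple[int, int]:
    if read.strand == "+":
        return read.start - ref.start, read.end - ref.end
    return ref.end - read.end, ref.start - read.start


def build_stack(locus: MiRNALocus, arm: str, reads: Sequence[AlignedRead],
                genome: GenomeSequence) -> ReadStack:
    """Assemble the iso-miR stack of one locus arm.

    The reference is the highest-count perfectly matching read (ties broken
    by length, then most-5' start, then sequence). Reads with any internal
    mismatch (excluding the 3'-terminal position, which may be a tail) are
    excluded from the stack and kept for the editing scan.
    """
    stack = ReadStack(locus_id=locus.locus_id, arm=arm)
    if not reads:
        return stack
    perfect = [r for r in reads if r.n_mismatch == 0]
    if not perfect:
        stack.beyond_window = 0.0
        for r in reads:
            mm = _mismatch_positions(r, genome)
            internal = tuple(p for p in mm if p < len(r.seq) - 1)
            if internal:
                stack.internal_mismatch.append((r, internal))
            else:
                stack.beyond_window += r.weighted_count
        return stack

    def ref_key(r: AlignedRead):
        five = r.five_prime if r.strand == "+" else -r.five_prime
        return (-r.weighted_count, -len(r.seq), five, r.seq)

    ref = min(perfect, key=ref_key)
    stack.reference_read = ref
    stack.reference_seq = ref.seq
    for r in reads:
        mm = _mismatch_positions(r, genome)
        internal = tuple(p for p in mm if p < len(r.seq) - 1)
        if internal:
            stack.internal_mismatch.append((r, internal))
            continue
        off5, off3 = _offsets(r, ref)
        if abs(off5) > WINDOW or abs(off3) > WINDOW:
            stack.beyond_window += r.weighted_count
            continue
        stack.entries.append(StackEntry(
            seq=r.seq, weighted_count=r.weighted_count,
            offset5=off5, offset3=off3, mismatch_positions=mm))
    stack.entries.sort(key=lambda e: (-e.weighted_count, e.seq))
    return stack


# ---------------------------------------------------------------------------
# 5' heterogeneity
# ---------------------------------------------------------------------------


@dataclass
class FivePrimeProfile:
    hist: dict[int, float]
    seed_shift_fraction: float
    dominant_classes: list[int]


def five_prime_profile(stack: ReadStack, dominant_threshold: float = 0.10
                       ) -> FivePrimeProfile:
    """Weighted 5'-offset histogram; any non-zero offset shifts the seed."""
    if not stack.entries:
        raise ValueError("empty stack")
    total = stack.total
    hist: dict[int, float] = {}
    for e in stack.entries:
        hist[e.offset5] = hist.get(e.offset5, 0.0) + e.weighted_count / total
    shift = sum(f for off, f in hist.items() if off != 0)
    dominant = sorted(off for off, f in hist.items() if f >= dominant_threshold)
    return FivePrimeProfile(hist=hist, seed_shift_fraction=shift,
                            dominant_classes=dominant)


# ---------------------------------------------------------------------------
# 3' extension classification
# ---------------------------------------------------------------------------


@dataclass
class ExtensionCall:
    kind: str            # untailed | trimmed | template | nontemplate | complex
    k: int = 0           # number of added nucleotides (template)
    nt: str | None = None  # RNA letter of a single addition
    ambiguous: bool = False


def precursor_context(stack: ReadStack, genome: GenomeSequence, n: int = WINDOW
                      ) -> str:
    """Genomic sequence immediately downstream of the reference 3' end
    (transcript orientation)."""
    ref = stack.reference_read
    if ref is None:
        raise ValueError("empty stack has no reference")
    if ref.strand == "+":
        return genome.fetch(ref.chrom, ref.end, ref.end + n, "+")
    return genome.fetch(ref.chrom, ref.start - n, ref.start, "-")


def classify_extension(entry: StackEntry, context: str) -> ExtensionCall:
    """Classify the 3' state of a stack entry against the downstream genome.

    All added nucleotides matching the adjacent genomic bases -> template
    extension (imprecise processing). A single mismatching addition -> a
    non-template tail of that nucleotide. A single A/U addition that matches
    the genome is counted template but flagged ambiguous, since tailing and
    imprecise processing cannot be distinguished. Multi-nucleotide additions
    whose bases do not all match are reported as complex tails.
    """
    off3 = entry.offset3
    if off3 > WINDOW:
        raise ValueError(f"offset3 {off3} beyond the stack window")
    if off3 == 0:
        return ExtensionCall("untailed")
    if off3 < 0:
        return ExtensionCall("trimmed", k=off3)
    if len(context) < off3:
        raise ValueError("precursor context shorter than the extension")
    added = entry.seq[-off3:]
    templ = context[:off3]
    if added == templ:
        nt = rna(added[-1]) if off3 == 1 else None
        ambiguous = off3 == 1 and nt in ("A", "U")
        return ExtensionCall("template", k=off3, nt=nt, ambiguous=ambiguous)
    if off3 == 1:
        return ExtensionCall("nontemplate", k=1, nt=rna(added))
    return ExtensionCall("complex", k=off3)


@dataclass
class IsomirProfile:
    locus_id: str
    arm: str
    five_prime_hist: dict[int, float]
    three_prime_hist: dict[int, float]
    seed_shift_fraction: float
    trim_gt1_fraction: float
    template_ext_fraction: float
    nontemplate_ext_by_nt: dict[str, float]
    ambiguous_ext_fraction: float
    complex_ext_fraction: float
    untailed_fraction: float
    dominant_classes: list[int]


def isomir_profile(stack: ReadStack, genome: GenomeSequence) -> IsomirProfile:
    """Full per-arm iso-miR profile (5' and 3' histograms plus the 3'-end
    classification partition, all as weighted fractions of the stack)."""
    if not stack.entries:
        raise ValueError("empty stack")
    fp = five_prime_profile(stack)
    total = stack.total
    ctx = precursor_context(stack, genome)
    hist3: dict[int, float] = {}
    parts = {"untailed": 0.0, "template": 0.0, "ambiguous": 0.0,
             "complex": 0.0}
    by_nt = {nt: 0.0 for nt in NUCLEOTIDES}
    trim_gt1 = 0.0
    for e in stack.entries:
        f = e.weighted_count / total
        hist3[e.offset3] = hist3.get(e.offset3, 0.0) + f
        call = classify_extension(e, ctx)
        if call.kind in ("untailed", "trimmed"):
            parts["untailed"] += f
            if e.offset3 < -1:
                trim_gt1 += f
        elif call.kind == "template":
            if call.ambiguous:
                parts["ambiguous"] += f
            else:
                parts["template"] += f
        elif call.kind == "nontemplate":
            by_nt[call.nt] += f
        else:
            parts["complex"] += f
    return IsomirProfile(
        locus_id=stack.locus_id, arm=stack.arm,
        five_prime_hist=fp.hist, three_prime_hist=hist3,
        seed_shift_fraction=fp.seed_shift_fraction,
        trim_gt1_fraction=trim_gt1,
        template_ext_fraction=parts["template"],
        nontemplate_ext_by_nt=by_nt,
        ambiguous_ext_fraction=parts["ambiguous"],
        complex_ext_fraction=parts["complex"],
        untailed_fraction=parts["untailed"],
        dominant_classes=fp.dominant_classes)


# ---------------------------------------------------------------------------
# tail composition across loci
# ---------------------------------------------------------------------------


@dataclass
class TailingSummary:
    arm: str
    nontemplate_by_nt: dict[str, float | None]
    per_locus_share: dict[str, dict[str, float]]
    total_nontemplate: float
    total_template: float
    total_ambiguous: float


def tailing_composition(stacks: Iterable[ReadStack], genome: GenomeSequence,
                        arm: str | None = None) -> TailingSummary:
    """Global A/U/C/G composition of single-nucleotide non-template tails,
    with each locus's share of every tail class."""
    nt_totals = {nt: 0.0 for nt in NUCLEOTIDES}
    per_locus: dict[str, dict[str, float]] = {nt: {} for nt in NUCLEOTIDES}
    total_template = total_ambiguous = 0.0
    for stack in stacks:
        if stack.is_empty or (arm and stack.arm != arm):
            continue
        ctx = precursor_context(stack, genome)
        for e in stack.entries:
            call = classify_extension(e, ctx)
            if call.kind == "nontemplate":
                nt_totals[call.nt] += e.weighted_count
                d = per_locus[call.nt]
                d[stack.locus_id] = d.get(stack.locus_id, 0.0) + e.weighted_count
            elif call.kind == "template":
                total_template += e.weighted_count
                if call.ambiguous:
                    total_ambiguous += e.weighted_count
    grand = sum(nt_totals.values())
    if grand == 0:
        fracs: dict[str, float | None] = {nt: None for nt in NUCLEOTIDES}
        shares: dict[str, dict[str, float]] = {nt: {} for nt in NUCLEOTIDES}
    else:
        fracs = {nt: nt_totals[nt] / grand for nt in NUCLEOTIDES}
        shares = {nt: {loc: v / nt_totals[nt] for loc, v in per_locus[nt].items()}
                  if nt_totals[nt] > 0 else {}
                  for nt in NUCLEOTIDES}
    return TailingSummary(arm=arm or "both", nontemplate_by_nt=fracs,
                          per_locus_share=shares, total_nontemplate=grand,
                          total_template=total_template,
                          total_ambiguous=total_ambiguous)


# ---------------------------------------------------------------------------
# editing scan
# ---------------------------------------------------------------------------

_SUBSTITUTIONS = [(a, b) for a in "ACGU" for b in "ACGU" if a != b]


@dataclass
class EditingScan:
    mismatch_rate: float
    transition_counts: dict[tuple[str, str], float]
    ag_cu_enrichment: float
    p_value: float


def editing_scan(stacks: Iterable[ReadStack], genome: GenomeSequence,
                 ) -> EditingScan:
    """Substitution spectrum of internally mismatched reads.

    Deamination editing would enrich A->G (ADAR) and C->U (APOBEC-like)
    transitions; the enrichment statistic compares the observed joint
    fraction of those two cells against the uniform expectation of 2/12 with
    a two-sided binomial test on rounded weighted counts.
    """
    counts = {sub: 0.0 for sub in _SUBSTITUTIONS}
    mm_weight = total_weight = 0.0
    for stack in stacks:
        total_weight += stack.total + stack.beyond_window
        for read, internal in stack.internal_mismatch:
            ref = genome.fetch(read.chrom, read.start, read.end, read.strand)
            mm_weight += read.weighted_count
            total_weight += read.weighted_count
            for pos in internal:
                sub = (rna(ref[pos]), rna(read.seq[pos]))
                if sub in counts:
                    counts[sub] += read.weighted_count
    n_subs = sum(counts.values())
    if n_subs == 0:
        return EditingScan(0.0 if total_weight else 0.0, {}, 1.0, 1.0)
    observed = counts[("A", "G")] + counts[("C", "U")]
    expected_frac = 2.0 / 12.0
    enrichment = (observed / n_subs) / expected_frac
    test = binomtest(round(observed), round(n_subs), expected_frac,
                     alternative="two-sided")
    rate = mm_weight / total_weight if total_weight else 0.0
    return EditingScan(mismatch_rate=rate, transition_counts=counts,
                       ag_cu_enrichment=enrichment, p_value=test.pvalue)
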