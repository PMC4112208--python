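"""Short-read mapping, hairpin folding and novel-miRNA candidate filtering.

The filtering rules mirror a conservative small RNA-seq discovery protocol:
a candidate hairpin must attract at least ``min_reads`` reads per library in
at least two libraries from two biological experiments, fold into a single
stem-loop below an energy threshold (default -15 kcal/mol), show a consistent
5' start, sit on a placed chromosome, and not be supported exclusively by
multi-mapping or mismatched reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .mirio import AlignedRead, GenomeSequence, MiRNALocus, dna, revcomp

__all__ = [
    "GenomeIndex",
    "map_reads",
    "quantify_locus_shifted",
    "HairpinFold",
    "fold_hairpin",
    "DuplexOverhangs",
    "call_duplex_overhangs",
    "DiscoveryConfig",
    "CandidateLocus",
    "filter_candidates",
    "ConservationCall",
    "classify_conservation",
    "five_prime_consistency",
]


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


class GenomeIndex:
    """Lazy exact k-mer indexes over a genome, one per needed k."""

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self._idx: dict[int, dict[str, dict[str, list[int]]]] = {}

    def _build(self, k: int) -> None:
        per_chrom: dict[str, dict[str, list[int]]] = {}
        for chrom in self.genome.chrom_names:
            seq = self.genome.sequences[chrom]
            d: dict[str, list[int]] = {}
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                d.setdefault(kmer, []).append(i)
            per_chrom[chrom] = d
        self._idx[k] = per_chrom

    def occurrences(self, chrom: str, kmer: str) -> list[int]:
        k = len(kmer)
        if k not in self._idx:
            self._build(k)
        return self._idx[k][chrom].get(kmer, [])


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


MIN_CHUNK = 4


def map_reads(reads: Sequence[tuple[str, int]], genome: GenomeSequence,
              max_mismatch: int = 2, seed_k: int = 12,
              index: GenomeIndex | None = None) -> list[AlignedRead]:
    """Map collapsed reads to the genome, reporting every alignment with at
    most ``max_mismatch`` substitutions on either strand.

    Each read is partitioned into ``max_mismatch + 1`` seed chunks (chunk
    length capped at ``seed_k``); by pigeonhole, every alignment within the
    mismatch budget contains at least one exact chunk, so the search is
    complete. Multi-mapping reads receive weight ``1 / n_mapped_loci``. Reads
    too short to seed produce no alignments.
    """
    idx = index or GenomeIndex(genome)
    out: list[AlignedRead] = []
    for seq, count in reads:
        q = dna(seq)
        hits: set[tuple[str, int, str]] = set()
        n_parts = max_mismatch + 1
        chunk = min(seed_k, len(q) // n_parts)
        if chunk < MIN_CHUNK:
            continue  # unmappable: too short to seed
        for strand in "+-":
            target = q if strand == "+" else revcomp(q)
            offsets = [p * chunk for p in range(n_parts)]
            for off in offsets:
                kmer = target[off:off + chunk]
                for chrom in genome.chrom_names:
                    for pos in idx.occurrences(chrom, kmer):
                        start = pos - off
                        end = start + len(q)
                        ref = genome.sequences[chrom]
                        if start < 0 or end > len(ref):
                            continue
                        if _hamming(target, ref[start:end], max_mismatch) <= max_mismatch:
                            hits.add((chrom, start, strand))
        if not hits:
            continue
        n = len(hits)
        for chrom, start, strand in sorted(hits):
            target = q if strand == "+" else revcomp(q)
            nm = _hamming(target, genome.sequences[chrom][start:start + len(q)],
                          len(q))
            out.append(AlignedRead(
                seq=q, count=count, chrom=chrom, strand=strand,
                start=start, end=start + len(q),
                n_mismatch=nm, n_mapped_loci=n, weight=1.0 / n))
    out.sort(key=lambda r: (r.chrom, r.start, r.strand, r.seq))
    return out


def quantify_locus_shifted(locus: MiRNALocus, reads: Iterable[AlignedRead],
                           shift: int = 2, max_mismatch: int = 2,
                           ) -> tuple[float, float]:
    """Weighted 5p/3p read counts under a shifted mapping window.

    A read contributes to an arm when its 5' start lies within ``±shift`` of
    that arm's annotated 5' start and the read is contained in the precursor
    interval extended by ``shift`` on both sides.
    """
    if locus.mature5p_iv is None and locus.mature3p_iv is None:
        raise ValueError(f"{locus.locus_id}: arms undefined")
    p0, p1 = locus.precursor_iv
    counts = {"5p": 0.0, "3p": 0.0}
    arm_starts = {}
    for arm in ("5p", "3p"):
        iv = locus.arm_iv(arm)
        if iv is not None:
            arm_starts[arm] = iv[0] if locus.strand == "+" else iv[1] - 1
    for r in reads:
        if r.chrom != locus.chrom or r.strand != locus.strand:
            continue
        if r.n_mismatch > max_mismatch:
            continue
        if r.start < p0 - shift or r.end > p1 + shift:
            continue
        for arm, a5 in arm_starts.items():
            if abs(r.five_prime - a5) <= shift:
                counts[arm] += r.weighted_count
                break
    return counts["5p"], counts["3p"]


# ---------------------------------------------------------------------------
# hairpin folding (reduced nearest-neighbour model; pluggable backend)
# ---------------------------------------------------------------------------

_PAIR_STRENGTH = {("G", "C"): 3, ("C", "G"): 3,
                  ("A", "T"): 2, ("T", "A"): 2,
                  ("G", "T"): 1, ("T", "G"): 1}

_MAX_INTERIOR = 10  # per-side cap on bulge/interior loop size in the DP
_MIN_HAIRPIN = 3


def _stack_energy(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    # reduced nearest-neighbour stack: scales with the product of pair
    # strengths, calibrated so GC/GC ~ -3.4 and AU/AU ~ -1.7 kcal/mol
    return -(_PAIR_STRENGTH[p1] * _PAIR_STRENGTH[p2]) * 0.33 - 0.4


def _hairpin_penalty(n: int) -> float:
    table = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    if n in table:
        return table[n]
    return 6.4 + 1.1 * math.log(n / 9.0)


def _loop_penalty(n1: int, n2: int) -> float:
    if n1 == 0 or n2 == 0:  # bulge
        n = n1 + n2
        return 3.3 + 0.6 * (n - 1)
    return 2.0 + 0.5 * (n1 + n2)


@dataclass
class HairpinFold:
    sequence: str
    structure: str
    energy: float
    n_stems: int
    loop_len: int
    backend: str = "builtin"


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIR_STRENGTH


def _fold_builtin(seq: str) -> tuple[str, float]:
    n = len(seq)
    INF = float("inf")
    V = [[INF] * n for _ in range(n)]
    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not _pairable(seq[i], seq[j]):
                continue
            best = _hairpin_penalty(j - i - 1)
            kmax = min(i + 1 + _MAX_INTERIOR, j - 1)
            for k in range(i + 1, kmax + 1):
                lmin = max(j - 1 - _MAX_INTERIOR, k + 1)
                for l in range(lmin, j):
                    vkl = V[k][l]
                    if vkl == INF:
                        continue
                    n1, n2 = k - i - 1, j - l - 1
                    if n1 == 0 and n2 == 0:
                        cand = vkl + _stack_energy((seq[i], seq[j]),
                                                   (seq[k], seq[l]))
                    else:
                        cand = vkl + _loop_penalty(n1, n2)
                    if cand < best:
                        best = cand
            V[i][j] = best
    # external loop: optimal decomposition into stems
    W = [0.0] * (n + 1)
    choice: list[tuple[int, int] | None] = [None] * (n + 1)
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        choice[j] = None
        for i in range(0, j):
            if V[i][j - 1] < INF and W[i] + V[i][j - 1] < W[j]:
                W[j] = W[i] + V[i][j - 1]
                choice[j] = (i, j - 1)
    # traceback
    struct = ["."] * n
    stack = []
    j = n
    while j > 0:
        if choice[j] is None:
            j -= 1
        else:
            i, jj = choice[j]
            stack.append((i, jj))
            j = i
    def trace_v(i: int, j: int) -> None:
        struct[i], struct[j] = "(", ")"
        best = V[i][j]
        if abs(best - _hairpin_penalty(j - i - 1)) < 1e-9:
            return
        kmax = min(i + 1 + _MAX_INTERIOR, j - 1)
        for k in range(i + 1, kmax + 1):
            lmin = max(j - 1 - _MAX_INTERIOR, k + 1)
            for l in range(lmin, j):
                if V[k][l] == float("inf"):
                    continue
                n1, n2 = k - i - 1, j - l - 1
                if n1 == 0 and n2 == 0:
                    cand = V[k][l] + _stack_energy((seq[i], seq[j]),
                                                   (seq[k], seq[l]))
                else:
                    cand = V[k][l] + _loop_penalty(n1, n2)
                if abs(cand - best) < 1e-9:
                    trace_v(k, l)
                    return
    for i, j in stack:
        trace_v(i, j)
    return "".join(struct), (W[n] if W[n] < 0 else 0.0)


def _fold_vienna(seq: str) -> tuple[str, float]:
    import RNA  # ViennaRNA python bindings

    structure, mfe = RNA.fold(seq.replace("T", "U"))
    return structure, float(mfe)


def _count_stems(structure: str) -> int:
    # number of hairpin (innermost) loops == number of stem-loops
    n = 0
    prev = ""
    for ch in structure:
        if ch == ")" and prev == "(":
            n += 1
        if ch in "()":
            prev = ch
    return n


def fold_hairpin(seq: str, backend: str = "builtin") -> HairpinFold:
    """Minimum-free-energy single-structure prediction for a precursor.

    ``backend='builtin'`` uses the reduced nearest-neighbour model (stack
    energies plus loop penalties, no multiloops beyond external-loop
    decomposition); ``backend='vienna'`` delegates to ViennaRNA when its
    python bindings are available.
    """
    s = dna(seq)
    if not 40 <= len(s) <= 200:
        raise ValueError(f"sequence length {len(s)} outside [40, 200]")
    if s.count("N") > 0.10 * len(s):
        raise ValueError("sequence contains more than 10% N")
    s = s.replace("N", "A")
    if backend == "builtin":
        structure, energy = _fold_builtin(s)
    elif backend == "vienna":
        structure, energy = _fold_vienna(s)
    else:
        raise ValueError(f"unknown folding backend {backend!r}")
    n_stems = _count_stems(structure)
    # loop length of the (first) hairpin loop
    loop_len = 0
    if "(" in structure:
        close = structure.index(")") if ")" in structure else -1
        if close > 0:
            open_ = structure.rfind("(", 0, close)
            loop_len = close - open_ - 1
    return HairpinFold(sequence=s, structure=structure, energy=energy,
                       n_stems=n_stems, loop_len=loop_len, backend=backend)


# ---------------------------------------------------------------------------
# duplex overhangs
# ---------------------------------------------------------------------------


def _pair_table(structure: str) -> dict[int, int]:
    stack, pt = [], {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pt[i], pt[j] = j, i
    return pt


def _partner(pt: dict[int, int], pos: int, max_scan: int = 5) -> int | None:
    """Helix-implied pairing partner of ``pos``; scans inward over unpaired
    positions and extrapolates along the helix."""
    for d in range(max_scan + 1):
        if pos + d in pt:
            return pt[pos + d] + d
    return None


@dataclass
class DuplexOverhangs:
    overhang5p: int | None
    overhang3p: int | None
    classification: str  # canonical | atypical | undefined
    low_confidence: bool = False


def call_duplex_overhangs(locus: MiRNALocus,
                          iv5p: tuple[int, int] | None,
                          iv3p: tuple[int, int] | None,
                          fold: HairpinFold | None = None,
                          backend: str = "builtin") -> DuplexOverhangs:
    """3'-overhang lengths of the miR/miR* duplex implied by the hairpin fold.

    ``iv5p``/``iv3p`` are the predominant-read intervals of each arm in
    strand-oriented precursor coordinates. RNase III processing leaves 1-2 nt
    3' overhangs on both strands; duplexes outside that range are atypical,
    and extreme overhangs flag the candidate low-confidence. A missing arm
    leaves the overhangs undefined without penalizing the candidate.
    """
    if iv5p is None or iv3p is None:
        return DuplexOverhangs(None, None, "undefined")
    fold = fold or fold_hairpin(locus.precursor_seq, backend=backend)
    pt = _pair_table(fold.structure)
    a5, b5 = iv5p
    a3, b3 = iv3p
    p_a5 = _partner(pt, a5)
    p_a3 = _partner(pt, a3)
    if p_a5 is None or p_a3 is None:
        return DuplexOverhangs(None, None, "undefined")
    over3 = (b3 - 1) - p_a5   # 3' overhang of the 3p strand
    over5 = (b5 - 1) - p_a3   # 3' overhang of the 5p strand
    canonical = over3 in (1, 2) and over5 in (1, 2)
    low_conf = not canonical and (abs(over3) > 4 or abs(over5) > 4
                                  or over3 < -2 or over5 < -2)
    return DuplexOverhangs(over5, over3,
                           "canonical" if canonical else "atypical", low_conf)


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------


def five_prime_consistency(reads: Iterable[AlignedRead]) -> tuple[float, float]:
    """Weighted fraction of reads sharing the modal 5' start, and the joint
    fraction of the top two 5' positions (the alternative-processing case)."""
    by_pos: dict[int, float] = {}
    for r in reads:
        by_pos[r.five_prime] = by_pos.get(r.five_prime, 0.0) + r.weighted_count
    total = sum(by_pos.values())
    if total == 0:
        return 0.0, 0.0
    fracs = sorted((v / total for v in by_pos.values()), reverse=True)
    return fracs[0], sum(fracs[:2])


@dataclass
class DiscoveryConfig:
    min_reads: float = 10.0
    min_libraries: int = 2
    min_experiments: int = 2
    max_energy: float = -15.0
    five_prime_threshold: float = 0.66
    two_mode_threshold: float = 0.90
    shift: int = 2
    max_mismatch: int = 2
    seed_k: int = 12
    fold_backend: str = "builtin"


@dataclass
class CandidateLocus:
    locus: MiRNALocus
    per_library_reads: dict[str, float] = field(default_factory=dict)
    five_prime_consistency: float = 0.0
    top2_consistency: float = 0.0
    overhang5p: int | None = None
    overhang3p: int | None = None
    fold: HairpinFold | None = None
    n_libraries_detected: int = 0
    n_experiments_detected: int = 0
    exclusively_mismatched: bool = False
    exclusively_multimapped: bool = False
    filter_flags: set[str] = field(default_factory=set)


def filter_candidates(candidates: Iterable[CandidateLocus],
                      config: DiscoveryConfig | None = None,
                      library_experiments: Mapping[str, str] | None = None,
                      ) -> tuple[list[CandidateLocus], list[CandidateLocus]]:
    """Classify candidates into accepted / rejected-with-reasons.

    Pure and order-independent: each candidate is judged on its own fields;
    rejected candidates carry every reason that applies in ``filter_flags``.
    """
    cfg = config or DiscoveryConfig()
    accepted, rejected = [], []
    for c in candidates:
        flags: set[str] = set()
        libs_ok = [lib for lib, n in c.per_library_reads.items()
                   if n >= cfg.min_reads]
        if library_experiments:
            exps = {library_experiments.get(lib, lib) for lib in libs_ok}
        else:
            exps = set(libs_ok)
        if len(libs_ok) < cfg.min_libraries or len(exps) < cfg.min_experiments:
            flags.add("insufficient read support")
        if c.fold is None or not c.fold.energy < cfg.max_energy:
            flags.add("fold energy")
        if c.fold is not None and c.fold.n_stems != 1:
            flags.add("multiple stems")
        if (c.five_prime_consistency < cfg.five_prime_threshold
                and c.top2_consistency < cfg.two_mode_threshold):
            flags.add("5prime inconsistency")
        if c.locus.chrom_class != "placed":
            flags.add("unplaced contig")
        if c.exclusively_mismatched:
            flags.add("inexact mapping only")
        if c.exclusively_multimapped:
            flags.add("multimapped only")
        c.filter_flags = flags
        (accepted if not flags else rejected).append(c)
    return accepted, rejected


# ---------------------------------------------------------------------------
# homology classification
# ---------------------------------------------------------------------------


@dataclass
class ConservationCall:
    conservation_class: str     # full_homolog | seed_only | none
    best_match_id: str | None
    identity: float


def _identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="distance", mode="NW")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def classify_conservation(mature: str,
                          known_sets: Mapping[str, Sequence[tuple[str, str]]],
                          ) -> ConservationCall:
    """Classify a mature sequence against known miRNA sets.

    full_homolog: some known mature shares the exact seed (nt 2-8) and global
    identity > 0.70. seed_only: exact seed match plus agreement of the first
    10 nt up to one substitution outside the seed. Ties resolve to the
    highest identity, then the lexicographically smallest id.
    """
    q = dna(mature)
    if len(q) < 10:
        raise ValueError("mature sequence shorter than 10 nt")
    seed = q[1:8]
    full_hits, seed_hits = [], []
    for species in sorted(known_sets):
        for known_id, known_seq in sorted(known_sets[species]):
            k = dna(known_seq)
            if len(k) < 10 or k[1:8] != seed:
                continue
            ident = _identity(q, k)
            if ident > 0.70:
                full_hits.append((ident, known_id))
            if _hamming(q[:10], k[:10], 10) <= 1:
                seed_hits.append((ident, known_id))
    for hits, klass in ((full_hits, "full_homolog"), (seed_hits, "seed_only")):
        if hits:
            top = max(h[0] for h in hits)
            best = min(hid for ident, hid in hits if ident == top)
            return ConservationCall(klass, best, top)
    return ConservationCall("none", None, 0.0)
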