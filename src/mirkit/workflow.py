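"""Convenience pipeline glue: map libraries, build per-arm stacks, assemble
candidates and count matrices from a simulated or loaded dataset."""

from __future__ import annotations

from typing import Mapping, Sequence

from . import armprofile, discovery, isomir
from .mirio import AlignedRead, GenomeSequence, MiRNALocus

__all__ = [
    "map_libraries",
    "reads_by_locus_arm",
    "build_stacks",
    "build_candidates",
]


def map_libraries(libraries: Mapping[str, Sequence[tuple[str, int]]],
                  genome: GenomeSequence, max_mismatch: int = 2,
                  seed_k: int = 12) -> dict[str, list[AlignedRead]]:
    """Map every library against the genome with a shared k-mer index."""
    index = discovery.GenomeIndex(genome)
    return {lib: discovery.map_reads(reads, genome, max_mismatch=max_mismatch,
                                     seed_k=seed_k, index=index)
            for lib, reads in libraries.items()}


def reads_by_locus_arm(loci: Sequence[MiRNALocus],
                       alignments: Sequence[AlignedRead],
                       ) -> dict[tuple[str, str], list[AlignedRead]]:
    """Assign alignments to locus arms (loop/degradation reads dropped)."""
    by_chrom: dict[str, list[MiRNALocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    out: dict[tuple[str, str], list[AlignedRead]] = {}
    for r in alignments:
        for loc in by_chrom.get(r.chrom, []):
            if (r.start < loc.precursor_iv[1] + 3
                    and r.end > loc.precursor_iv[0] - 3):
                arm = armprofile.assign_arm(r, loc)
                if arm != "unassigned":
                    out.setdefault((loc.locus_id, arm), []).append(r)
    return out


def build_stacks(loci: Sequence[MiRNALocus], alignments: Sequence[AlignedRead],
                 genome: GenomeSequence) -> dict[tuple[str, str], isomir.ReadStack]:
    """Per locus-arm iso-miR stacks for one library."""
    assigned = reads_by_locus_arm(loci, alignments)
    by_id = {l.locus_id: l for l in loci}
    return {(lid, arm): isomir.build_stack(by_id[lid], arm, reads, genome)
            for (lid, arm), reads in sorted(assigned.items())}


def build_candidates(loci: Sequence[MiRNALocus],
                     alignments_by_library: Mapping[str, Sequence[AlignedRead]],
                     genome: GenomeSequence,
                     config: discovery.DiscoveryConfig | None = None,
                     ) -> list[discovery.CandidateLocus]:
    """Quantify candidate loci across libraries and attach every field the
    filter inspects (shifted-window support, fold, 5' consistency, duplex
    overhangs, mapping-quality exclusivity)."""
    cfg = config or discovery.DiscoveryConfig()
    candidates = []
    for loc in loci:
        cand = discovery.CandidateLocus(locus=loc)
        pooled: list[AlignedRead] = []
        for lib, alns in alignments_by_library.items():
            c5, c3 = discovery.quantify_locus_shifted(
                loc, alns, shift=cfg.shift, max_mismatch=cfg.max_mismatch)
            cand.per_library_reads[lib] = c5 + c3
            pooled.extend(r for r in alns
                          if r.chrom == loc.chrom and r.strand == loc.strand
                          and r.start >= loc.precursor_iv[0] - cfg.shift
                          and r.end <= loc.precursor_iv[1] + cfg.shift)
        cand.n_libraries_detected = sum(
            1 for v in cand.per_library_reads.values() if v >= cfg.min_reads)
        if pooled:
            cand.exclusively_mismatched = all(r.n_mismatch > 0 for r in pooled)
            cand.exclusively_multimapped = all(r.n_mapped_loci > 1 for r in pooled)
            arm_reads = {arm: [] for arm in ("5p", "3p")}
            for r in pooled:
                arm = armprofile.assign_arm(r, loc)
                if arm in arm_reads:
                    arm_reads[arm].append(r)
            counts = {arm: sum(r.weighted_count for r in rs)
                      for arm, rs in arm_reads.items()}
            main_arm = max(counts, key=lambda a: (counts[a], a))
            if arm_reads[main_arm]:
                top, top2 = discovery.five_prime_consistency(arm_reads[main_arm])
                cand.five_prime_consistency = top
                cand.top2_consistency = top2
            cand.fold = discovery.fold_hairpin(loc.precursor_seq,
                                               backend=cfg.fold_backend)
            ivs = {}
            for arm in ("5p", "3p"):
                rs = [r for r in arm_reads[arm] if r.n_mismatch == 0]
                if rs:
                    ref = max(rs, key=lambda r: (r.weighted_count, -r.start))
                    ivs[arm] = loc.to_precursor_coords(ref.start, ref.end)
            over = discovery.call_duplex_overhangs(
                loc, ivs.get("5p"), ivs.get("3p"), fold=cand.fold)
            cand.overhang5p, cand.overhang3p = over.overhang5p, over.overhang3p
        candidates.append(cand)
    return candidates
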