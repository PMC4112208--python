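"""Iso-miR stacks, 5' heterogeneity, 3'-extension classification, tail
composition and the editing scan."""

import itertools

import numpy as np
import pytest

from mirkit import isomir
from mirkit.isomir import (StackEntry, build_stack,
                           classify_extension, editing_scan,
                           five_prime_profile, isomir_profile,
                           tailing_composition)
from mirkit.mirio import AlignedRead, GenomeSequence

from conftest import make_locus

REF = "ACGTTGCACGGTTAACCGGATC"  # 22-mer planted at chr position 10


@pytest.fixture
def stack_genome():
    return GenomeSequence(["c"], {"c": "T" * 10 + REF + "GAC" + "T" * 40})


def _locus(genome):
    return make_locus(chrom="c", start=7, length=70, genome=genome)


def _read(genome, start, end, seq=None, count=1):
    seq = seq if seq is not None else genome.sequences["c"][start:end]
    ref = genome.sequences["c"][start:end]
    nm = sum(a != b for a, b in zip(seq, ref))
    return AlignedRead(seq=seq, count=count, chrom="c", strand="+",
                       start=start, end=end, n_mismatch=nm)


class TestBuildStack:
    def test_reference_is_most_abundant(self, stack_genome):
        g = stack_genome
        reads = [_read(g, 10, 32, count=100), _read(g, 11, 32, count=40)]
        stack = build_stack(_locus(g), "5p", reads, g)
        assert stack.reference_seq == REF

    def test_tie_breaks_to_longer_read(self, stack_genome):
        g = stack_genome
        reads = [_read(g, 11, 32, count=50), _read(g, 10, 32, count=50)]
        stack = build_stack(_locus(g), "5p", reads, g)
        assert stack.reference_seq == REF  # one nt longer at the 5' end

    def test_beyond_window_tallied_separately(self, stack_genome):
        g = stack_genome
        reads = [_read(g, 10, 32, count=10), _read(g, 10, 28, count=3)]
        stack = build_stack(_locus(g), "5p", reads, g)
        assert stack.beyond_window == 3.0
        assert len(stack.entries) == 1

    def test_internal_mismatch_routed_to_editing(self, stack_genome):
        g = stack_genome
        edited = REF[:5] + ("G" if REF[5] != "G" else "C") + REF[6:]
        reads = [_read(g, 10, 32, count=10), _read(g, 10, 32, seq=edited, count=2)]
        stack = build_stack(_locus(g), "5p", reads, g)
        assert len(stack.entries) == 1
        assert len(stack.internal_mismatch) == 1
        assert stack.internal_mismatch[0][1] == (5,)

    def test_terminal_mismatch_stays_in_stack(self, stack_genome):
        """A 3'-terminal mismatching addition is a tail, not an edit."""
        g = stack_genome
        tailed = REF + "T"  # genome continues G at position 32
        reads = [_read(g, 10, 32, count=10), _read(g, 10, 33, seq=tailed, count=4)]
        stack = build_stack(_locus(g), "5p", reads, g)
        assert stack.internal_mismatch == []
        offs = {(e.offset5, e.offset3) for e in stack.entries}
        assert (0, 1) in offs

    def test_empty_arm_gives_empty_stack(self, stack_genome):
        stack = build_stack(_locus(stack_genome), "3p", [], stack_genome)
        assert stack.is_empty and stack.entries == []

    def test_partition_conserves_counts(self, stack_genome):
        g = stack_genome
        edited = REF[:5] + ("G" if REF[5] != "G" else "C") + REF[6:]
        reads = [_read(g, 10, 32, count=7), _read(g, 10, 28, count=3),
                 _read(g, 10, 32, seq=edited, count=2), _read(g, 12, 32, count=5)]
        stack = build_stack(_locus(g), "5p", reads, g)
        total = (stack.total + stack.beyond_window
                 + sum(r.weighted_count for r, _ in stack.internal_mismatch))
        assert total == pytest.approx(sum(r.weighted_count for r in reads))


class TestFivePrime:
    def test_homogeneous_stack(self, stack_genome):
        g = stack_genome
        stack = build_stack(_locus(g), "5p", [_read(g, 10, 32, count=10)], g)
        prof = five_prime_profile(stack)
        assert prof.hist == {0: 1.0}
        assert prof.seed_shift_fraction == 0.0

    def test_two_dominant_classes(self, stack_genome):
        """An 87/12 split between the annotated 5' end and an upstream
        extension yields two dominant classes and a 12% seed shift."""
        g = stack_genome
        reads = [_read(g, 10, 32, count=87), _read(g, 9, 32, count=12),
                 _read(g, 11, 32, count=1)]
        stack = build_stack(_locus(g), "5p", reads, g)
        prof = five_prime_profile(stack)
        assert prof.dominant_classes == [-1, 0]
        assert prof.seed_shift_fraction == pytest.approx(0.13)

    def test_halved_weight_duplication_invariance(self, stack_genome):
        g = stack_genome
        reads = [_read(g, 10, 32, count=8), _read(g, 9, 32, count=2)]
        stack = build_stack(_locus(g), "5p", reads, g)
        dup = [AlignedRead(r.seq, r.count, r.chrom, r.strand, r.start, r.end,
                           r.n_mismatch, 2, 0.5)
               for r in reads for _ in range(2)]
        stack_dup = build_stack(_locus(g), "5p", dup, g)
        assert five_prime_profile(stack).hist == pytest.approx(
            five_prime_profile(stack_dup).hist)


class TestExtensionClassifier:
    # reference ends ...GATC; genome continues GAC
    @pytest.mark.parametrize("suffix, kind, nt, ambiguous", [
        ("", "untailed", None, False),
        ("G", "template", "G", False),
        ("T", "nontemplate", "U", False),
        ("C", "nontemplate", "C", False),
        ("GA", "template", None, False),
        ("GAC", "template", None, False),
        ("GT", "complex", None, False),
    ])
    def test_against_context(self, suffix, kind, nt, ambiguous):
        entry = StackEntry(REF + suffix, 1.0, 0, len(suffix))
        call = classify_extension(entry, "GAC")
        assert (call.kind, call.nt, call.ambiguous) == (kind, nt, ambiguous)

    def test_matching_a_or_u_is_ambiguous_template(self):
        entry = StackEntry(REF + "A", 1.0, 0, 1)
        call = classify_extension(entry, "ACC")
        assert call.kind == "template" and call.ambiguous and call.nt == "A"

    def test_beyond_window_extension_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            classify_extension(StackEntry(REF + "AAAA", 1.0, 0, 4), "AAAA")

    def test_matches_suffix_enumeration_oracle(self):
        """Exhaustive comparison against a literal re-statement of the rule
        over every 1-3 nt suffix and every 3-nt genomic context."""
        def oracle(added, ctx):
            if added == ctx[:len(added)]:
                if len(added) == 1 and added in "AT":
                    return ("template", True)
                return ("template", False)
            if len(added) == 1:
                return ("nontemplate", False)
            return ("complex", False)

        for k in (1, 2, 3):
            for added in map("".join, itertools.product("ACGT", repeat=k)):
                for ctx in map("".join, itertools.product("ACGT", repeat=3)):
                    call = classify_extension(
                        StackEntry(REF + added, 1.0, 0, k), ctx)
                    assert (call.kind, call.ambiguous) == oracle(added, ctx)


class TestTailing:
    def test_composition_fractions(self, stack_genome):
        g = stack_genome
        reads = [_read(g, 10, 32, count=10),
                 _read(g, 10, 33, seq=REF + "A", count=4),
                 _read(g, 10, 33, seq=REF + "T", count=6)]
        stack = build_stack(_locus(g), "5p", reads, g)
        summary = tailing_composition([stack], g, arm="5p")
        assert summary.nontemplate_by_nt["A"] == pytest.approx(0.4)
        assert summary.nontemplate_by_nt["U"] == pytest.approx(0.6)

    def test_per_locus_share(self, stack_genome):
        g = stack_genome
        big = build_stack(_locus(g), "5p",
                          [_read(g, 10, 32, count=10),
                           _read(g, 10, 33, seq=REF + "T", count=80)], g)
        big.locus_id = "mir-8-like"
        small = build_stack(_locus(g), "5p",
                            [_read(g, 10, 32, count=10),
                             _read(g, 10, 33, seq=REF + "T", count=20)], g)
        small.locus_id = "other"
        summary = tailing_composition([big, small], g)
        assert summary.per_locus_share["U"]["mir-8-like"] == pytest.approx(0.8)

    def test_no_tails_reported_as_na(self, stack_genome):
        g = stack_genome
        stack = build_stack(_locus(g), "5p", [_read(g, 10, 32, count=5)], g)
        summary = tailing_composition([stack], g)
        assert all(v is None for v in summary.nontemplate_by_nt.values())


class TestEditingScan:
    def test_no_mismatches(self, stack_genome):
        g = stack_genome
        stack = build_stack(_locus(g), "5p", [_read(g, 10, 32, count=5)], g)
        scan = editing_scan([stack], g)
        assert scan.mismatch_rate == 0.0 and scan.transition_counts == {}

    def test_uniform_substitutions_are_unenriched(self, stack_genome):
        g = stack_genome
        reads = [_read(g, 10, 32, count=60)]
        for pos in range(4, 16):  # 12 internal positions, one sub each
            base = REF[pos]
            alt = "ACGT"[("ACGT".index(base) + 1) % 4]
            reads.append(_read(g, 10, 32, seq=REF[:pos] + alt + REF[pos + 1:]))
        stack = build_stack(_locus(g), "5p", reads, g)
        scan = editing_scan([stack], g)
        assert sum(scan.transition_counts.values()) == 12
        assert scan.p_value > 0.2

    def test_planted_ag_editing_is_enriched(self):
        """A simulated dataset with A->G-biased editing shows enrichment."""
        from mirkit import simdata, workflow
        cfg = simdata.scenario_presets()["ago_knockdown"]
        cfg.reads_per_library = 10_000
        for spec in cfg.loci:
            if spec.rna_class == "miRNA" and spec.editing_rate:
                spec.editing_rate = 0.3
                spec.editing_bias = "AG"
        cfg.conditions = cfg.conditions[:1]
        cfg.conditions[0].n_replicates = 1
        res = simdata.generate(cfg, seed=5)
        aln = workflow.map_libraries(res.libraries, res.genome)
        loci = [l for l in res.loci if l.chrom in res.genome.sequences]
        stacks = workflow.build_stacks(loci, aln["control_rep1"], res.genome)
        scan = editing_scan(stacks.values(), res.genome)
        assert scan.ag_cu_enrichment > 1.5
        assert scan.p_value < 0.01
        assert scan.mismatch_rate > 0.1


def test_isomir_profile_partition_sums_to_one(ago_sim):
    from mirkit import workflow
    res, aln = ago_sim
    loci = [l for l in res.loci if l.chrom in res.genome.sequences]
    stacks = workflow.build_stacks(loci, aln["control_rep1"], res.genome)
    checked = 0
    for stack in stacks.values():
        if not stack.entries:
            continue
        p = isomir_profile(stack, res.genome)
        partition = (p.untailed_fraction + p.template_ext_fraction
                     + p.ambiguous_ext_fraction + p.complex_ext_fraction
                     + sum(p.nontemplate_ext_by_nt.values()))
        assert partition == pytest.approx(1.0, abs=1e-9)
        assert sum(p.five_prime_hist.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(p.three_prime_hist.values()) == pytest.approx(1.0, abs=1e-9)
        checked += 1
    assert checked > 10
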