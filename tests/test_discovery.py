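"""Mapper correctness against a brute-force oracle, shifted-window
quantification, hairpin folding, duplex overhangs, candidate filtering and
homology classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirkit import discovery
from mirkit.discovery import (CandidateLocus, HairpinFold,
                              call_duplex_overhangs, classify_conservation,
                              filter_candidates, fold_hairpin, map_reads,
                              quantify_locus_shifted)
from mirkit.mirio import AlignedRead, GenomeSequence, revcomp

from conftest import make_locus


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def brute_force_map(seq, genome, max_mismatch):
    """All-positions Hamming scan on both strands: the mapping oracle."""
    hits = set()
    for strand in "+-":
        target = seq if strand == "+" else revcomp(seq)
        for chrom in genome.chrom_names:
            ref = genome.sequences[chrom]
            for start in range(len(ref) - len(seq) + 1):
                window = ref[start:start + len(seq)]
                if sum(a != b for a, b in zip(target, window)) <= max_mismatch:
                    hits.add((chrom, start, strand))
    return hits


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


def test_mapper_equals_brute_force_oracle():
    rng = np.random.default_rng(0)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
    genome = GenomeSequence(["c1"], {"c1": ref})
    reads = []
    for _ in range(30):
        start = int(rng.integers(0, 5000 - 22))
        seq = ref[start:start + 22]
        n_mut = int(rng.integers(0, 4))  # 0-3 substitutions
        pos = rng.choice(22, size=n_mut, replace=False)
        seq = _mutate(seq, pos, rng)
        if rng.integers(0, 2):
            seq = revcomp(seq)
        reads.append((seq, 1))
    alignments = map_reads(reads, genome, max_mismatch=2)
    by_seq = {}
    for a in alignments:
        by_seq.setdefault(a.seq, set()).add((a.chrom, a.start, a.strand))
    for seq, _ in reads:
        assert by_seq.get(seq, set()) == brute_force_map(seq, genome, 2)


def test_multimapping_weights():
    unit = "ACGTTGCACGGTTAACCGGATCAA"
    genome = GenomeSequence(["c"], {"c": unit + "T" * 30 + unit})
    alns = map_reads([(unit[:22], 5)], genome)
    plus = [a for a in alns if a.strand == "+"]
    assert len(plus) == 2
    assert all(a.weight == pytest.approx(1 / a.n_mapped_loci) for a in plus)
    assert all(a.n_mapped_loci == len(alns) for a in alns)


def test_three_substitutions_stay_unmapped():
    rng = np.random.default_rng(1)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    genome = GenomeSequence(["c"], {"c": ref})
    seq = _mutate(ref[100:122], [2, 9, 17], rng)
    assert brute_force_map(seq, genome, 2) == set()
    assert map_reads([(seq, 1)], genome, max_mismatch=2) == []


# ---------------------------------------------------------------------------
# shifted-window quantification
# ---------------------------------------------------------------------------


def _read_at(start, length=22, chrom="chr1", strand="+", count=1):
    return AlignedRead(seq="A" * length, count=count, chrom=chrom,
                       strand=strand, start=start, end=start + length)


def test_shifted_window_boundaries():
    locus = make_locus(start=100, length=70)
    assert locus.mature5p_iv[0] == 100
    for offset, counted in [(0, True), (-2, True), (2, True), (-3, False)]:
        c5, _ = quantify_locus_shifted(locus, [_read_at(100 + offset)], shift=2)
        assert (c5 == 1.0) is counted, offset


def test_shifted_window_requires_arms():
    locus = make_locus()
    locus.mature5p_iv = locus.mature3p_iv = None
    with pytest.raises(ValueError, match="arms undefined"):
        quantify_locus_shifted(locus, [])


@given(shift=st.integers(min_value=0, max_value=4))
@settings(derandomize=True, deadline=None)
def test_shifted_window_monotone_in_shift(shift):
    locus = make_locus(start=100, length=70)
    reads = [_read_at(100 + d) for d in range(-5, 6)]
    small = sum(quantify_locus_shifted(locus, reads, shift=shift))
    large = sum(quantify_locus_shifted(locus, reads, shift=shift + 1))
    assert small <= large


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------


def make_perfect_hairpin(rng=None, stem=25, loop=6):
    rng = rng or np.random.default_rng(4)
    comp = dict(zip("ACGT", "TGCA"))
    arm = "".join("ACGT"[i] for i in rng.integers(0, 4, stem))
    return arm + "".join("ACAC"[i % 4] for i in range(loop)) + revcomp(arm)


def test_perfect_inverted_repeat_folds_as_single_stem():
    seq = make_perfect_hairpin()
    fold = fold_hairpin(seq)
    assert fold.energy < -15.0
    assert fold.n_stems == 1
    assert len(fold.structure) == len(seq)
    assert fold.structure.count("(") == fold.structure.count(")")


def test_builtin_energy_tracks_established_folder():
    """The reduced model agrees with ViennaRNA within 20%, or both sit below
    the stem-loop acceptance threshold."""
    pytest.importorskip("RNA")
    rng = np.random.default_rng(8)
    for stem in (20, 25, 30):
        seq = make_perfect_hairpin(rng, stem=stem)
        ours = fold_hairpin(seq)
        vienna = fold_hairpin(seq, backend="vienna")
        below = ours.energy < -15 and vienna.energy < -15
        close = abs(ours.energy - vienna.energy) <= 0.2 * abs(vienna.energy)
        assert below or close
        assert vienna.n_stems == ours.n_stems == 1


def test_homopolymer_rejected_as_hairpin():
    fold = fold_hairpin("A" * 60)
    assert fold.energy >= 0.0
    assert fold.n_stems == 0


def test_fold_input_validation():
    with pytest.raises(ValueError, match="length"):
        fold_hairpin("ACGT")
    with pytest.raises(ValueError, match="N"):
        fold_hairpin("N" * 20 + "ACGT" * 10)


# ---------------------------------------------------------------------------
# duplex overhangs
# ---------------------------------------------------------------------------


def _overhang_locus():
    """Designed hairpin with known 2-nt 3' overhangs (pairs i <-> 49-i)."""
    from mirkit.simdata import _build_hairpin
    rng = np.random.default_rng(2)
    _, pre = _build_hairpin("ACGTTGCACGGTTAACCGGATC", rng)
    genome = GenomeSequence(["c"], {"c": "T" * 10 + pre + "CCC" + "T" * 10})
    locus = make_locus(chrom="c", start=10, length=len(pre), genome=genome)
    locus.precursor_seq = pre
    return locus


@pytest.mark.parametrize("iv5, iv3, expect, low", [
    ((0, 22), (30, 52), "canonical", False),   # designed 2-nt overhangs
    ((0, 22), (30, 50), "atypical", False),    # blunt-ish on one end
    ((0, 22), (30, 55), "atypical", True),     # 5-nt overhang
])
def test_duplex_overhang_classification(iv5, iv3, expect, low):
    locus = _overhang_locus()
    call = call_duplex_overhangs(locus, iv5, iv3)
    assert call.classification == expect
    assert call.low_confidence == low
    if expect == "canonical":
        assert call.overhang5p == call.overhang3p == 2


def test_missing_arm_leaves_overhangs_undefined():
    locus = _overhang_locus()
    call = call_duplex_overhangs(locus, (0, 22), None)
    assert call.classification == "undefined"
    assert call.overhang5p is None and call.overhang3p is None


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------


def _candidate(**kw):
    locus = make_locus()
    fold = HairpinFold("A", "(((...)))", energy=-20.0, n_stems=1, loop_len=3)
    base = dict(locus=locus, fold=fold, five_prime_consistency=0.9,
                per_library_reads={"l1": 50.0, "l2": 40.0})
    base.update(kw)
    c = CandidateLocus(**{k: v for k, v in base.items()
                          if k in CandidateLocus.__dataclass_fields__})
    for k, v in base.items():
        setattr(c, k, v) if hasattr(c, k) else None
    return c


@pytest.mark.parametrize("override, reason", [
    ({"per_library_reads": {"l1": 9.0, "l2": 5.0}}, "insufficient read support"),
    ({"per_library_reads": {"l1": 50.0}}, "insufficient read support"),
    ({"fold": HairpinFold("A", ".", -14.2, 1, 3)}, "fold energy"),
    ({"fold": HairpinFold("A", ".", -20.0, 2, 3)}, "multiple stems"),
    ({"five_prime_consistency": 0.5}, "5prime inconsistency"),
    ({"exclusively_mismatched": True}, "inexact mapping only"),
    ({"exclusively_multimapped": True}, "multimapped only"),
])
def test_filter_rejects_with_reason(override, reason):
    cand = _candidate(**override)
    accepted, rejected = filter_candidates([cand])
    assert accepted == [] and reason in rejected[0].filter_flags


def test_filter_accepts_and_unplaced_rejection():
    good = _candidate()
    accepted, rejected = filter_candidates([good])
    assert rejected == [] and accepted[0].filter_flags == set()
    bad = _candidate()
    bad.locus.chrom_class = "unplaced_contig"
    _, rej = filter_candidates([bad])
    assert "unplaced contig" in rej[0].filter_flags
    bad.locus.chrom_class = "placed"


def test_filter_two_mode_exception():
    """Loci with two abundant alternative 5' ends pass via the joint rule."""
    cand = _candidate(five_prime_consistency=0.55, top2_consistency=0.95)
    accepted, _ = filter_candidates([cand])
    assert accepted


def test_filter_idempotent_and_order_independent():
    cands = [_candidate(), _candidate(five_prime_consistency=0.5),
             _candidate(per_library_reads={"l1": 9.0})]
    a1, r1 = filter_candidates(cands)
    a2, r2 = filter_candidates(list(reversed(cands)))
    assert {c.locus.locus_id for c in a1} == {c.locus.locus_id for c in a2}
    a3, r3 = filter_candidates(a1 + r1)
    assert {id(c) for c in a3} == {id(c) for c in a1}


def test_filter_requires_two_experiments():
    cand = _candidate(per_library_reads={"l1": 50.0, "l2": 40.0})
    _, rej = filter_candidates([cand],
                               library_experiments={"l1": "e1", "l2": "e1"})
    assert "insufficient read support" in rej[0].filter_flags


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

KNOWN = {
    "aae": [("aae-miR-2940", "GUCGACAGAGAGAUAAAUCACU")],
    "hsa": [("hsa-miR-561", "CAAAGUUUAAGAUCCUUGAAGU")],
}


def test_identical_sequence_is_full_homolog():
    call = classify_conservation("GUCGACAGAGAGAUAAAUCACU", KNOWN)
    assert call.conservation_class == "full_homolog"
    assert call.best_match_id == "aae-miR-2940"
    assert call.identity == pytest.approx(1.0)


def test_first_ten_nt_only_is_seed_only():
    known_mature = KNOWN["hsa"][0][1]
    query = known_mature[:10] + "GGGGCCCCGGGG"  # shares only nt 1-10
    call = classify_conservation(query, KNOWN)
    assert call.conservation_class == "seed_only"
    assert call.best_match_id == "hsa-miR-561"


def test_unrelated_sequence_is_none():
    call = classify_conservation("UUUUUUUUUUUUGGGGGGGGGG", KNOWN)
    assert call.conservation_class == "none"
    assert call.best_match_id is None


def test_short_mature_raises():
    with pytest.raises(ValueError, match="10 nt"):
        classify_conservation("ACGUACGUA", KNOWN)
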