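"""Shared fixtures: small deterministic datasets built at test time."""

import pytest

from mirkit import simdata, workflow
from mirkit.mirio import GenomeSequence, MiRNALocus


@pytest.fixture(scope="session")
def toy_genome():
    """A 200-bp two-chromosome genome with a hand-placed hairpin-free layout."""
    seq1 = ("ACGTAC" * 40)[:200]
    seq2 = "TTTTACGTACGTACGTACGTTTTT" * 4
    return GenomeSequence(["chr1", "chr2"], {"chr1": seq1, "chr2": seq2})


def make_locus(locus_id="locus1", chrom="chr1", strand="+", start=100,
               genome=None, length=70, arm_len=22, gap3p=4):
    """A precursor of ``length`` nt with mature arms at both ends."""
    end = start + length
    if strand == "+":
        iv5 = (start, start + arm_len)
        iv3 = (end - arm_len, end)
    else:
        iv5 = (end - arm_len, end)
        iv3 = (start, start + arm_len)
    seq = genome.fetch(chrom, start, end, strand) if genome else "A" * length
    return MiRNALocus(locus_id=locus_id, chrom=chrom, strand=strand,
                      precursor_iv=(start, end), mature5p_iv=iv5,
                      mature3p_iv=iv3, precursor_seq=seq)


@pytest.fixture(scope="session")
def ago_sim():
    """Knockdown scenario at reduced depth, mapped once for the session."""
    cfg = simdata.scenario_presets()["ago_knockdown"]
    cfg.reads_per_library = 20_000
    res = simdata.generate(cfg, seed=42)
    aln = workflow.map_libraries(res.libraries, res.genome)
    return res, aln


@pytest.fixture(scope="session")
def feeding_sim():
    cfg = simdata.scenario_presets()["feeding"]
    cfg.reads_per_library = 20_000
    res = simdata.generate(cfg, seed=42)
    aln = workflow.map_libraries(res.libraries, res.genome)
    return res, aln
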