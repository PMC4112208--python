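"""Synthetic small RNA-seq data with machine-readable truth tables.

The generator emulates the structure of a mosquito small RNA-seq study: a
small multi-chromosome genome with embedded designed miRNA hairpins (perfect
Watson-Crick stems with 2-nt 3' duplex overhangs), non-miRNA small RNA loci
(a tRNA/rRNA/snoRNA class and an invariant U2 reference gene), an unplaced
decoy contig, an optional host genome supplying blood-meal contaminant reads,
and libraries laid out as replicated conditions (e.g. sugar-fed / blood-fed /
infected plus single-replicate knockdown libraries).

Reads are drawn per locus from declared iso-miR category probabilities
(5' offsets, 3' trims, template extensions, single-nucleotide non-template
tails, internal editing) so that every downstream statistic has a planted
truth. Identical config and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mirio import GenomeSequence, MiRNALocus, dna, revcomp

__all__ = [
    "LocusSpec",
    "ConditionSpec",
    "SimulationConfig",
    "SimResult",
    "generate_genome",
    "simulate_reads",
    "generate",
    "scenario_presets",
    "write_scenario",
]

ARM_LEN = 22
LOOP_LEN = 6
PRECURSOR_LEN = 2 * ARM_LEN + LOOP_LEN + 2  # 22 + 6 + 22 + 2-nt 3p overhang


@dataclass
class LocusSpec:
    """Declared truth for one simulated locus."""

    name: str
    chrom: str
    pos: int
    strand: str = "+"
    family: str | None = None
    rna_class: str = "miRNA"
    is_hairpin: bool = True
    arm_ratio: float = 0.25                 # planted 5p proportion
    arm_ratio_by_condition: dict[str, float] = field(default_factory=dict)
    expression: float = 1.0
    expression_group: str | None = None
    fold: dict[str, float] = field(default_factory=dict)   # condition -> multiplier
    fiveprime_offset_probs: dict[int, float] = field(default_factory=dict)
    threeprime_trim_probs: dict[int, float] = field(default_factory=dict)
    template_ext_probs: dict[int, float] = field(default_factory=dict)
    nontemplate_tail_probs: dict[str, float] = field(default_factory=dict)
    editing_rate: float = 0.0
    editing_bias: str = "uniform"           # uniform | AG
    copy_arms_from: str | None = None       # paralog: reuse another spec's arms
    diverge_positions: tuple[int, ...] = () # arm positions mutated vs the source
    alphabet: str = "ACGT"                  # decoys use a pair-free alphabet


@dataclass
class ConditionSpec:
    name: str
    n_replicates: int = 2
    host_contamination: float = 0.0
    class_scaling: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    chroms: dict[str, int]
    loci: list[LocusSpec]
    conditions: list[ConditionSpec]
    host_chrom_len: int = 0
    host_loci: list[LocusSpec] = field(default_factory=list)
    unplaced_contig_len: int = 3000
    reads_per_library: int = 50_000
    error_rate: float = 0.001


@dataclass
class SimResult:
    genome: GenomeSequence
    host_genome: GenomeSequence | None
    loci: list[MiRNALocus]
    specs: dict[str, LocusSpec]
    classes: dict[str, str]
    library_meta: dict[str, dict]
    libraries: dict[str, list[tuple[str, int]]]
    truth: pd.DataFrame
    config: SimulationConfig


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


_WOBBLE_POSITIONS = (2, 6, 10, 14, 18)


def _build_hairpin(arm5: str, rng: np.random.Generator) -> tuple[str, str]:
    """52-nt precursor: positions [0,22) are the 5p mature, [30,52) the 3p
    mature; stem pairs i <-> 49-i leave 2-nt 3' overhangs on both duplex
    ends. Five evenly spaced G-U wobble pairs keep the stem folding while
    making the two arms non-complementary at >2 positions, as in real
    precursors (otherwise every arm read would also map to the opposite arm
    as its exact reverse complement). The first loop base is fixed to C so
    single A/U/G additions after the 5p arm are never template-matched.

    Returns (possibly adjusted arm5, precursor)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    wobble = {"T": "G", "G": "T"}  # partner base giving a G-U pair
    a5 = list(arm5)
    for i in _WOBBLE_POSITIONS:  # guarantee a wobble-capable base
        if a5[i] not in wobble:
            a5[i] = "T" if rng.integers(0, 2) else "G"
    arm5 = "".join(a5)
    partners = [comp[b] for b in a5]
    for i in _WOBBLE_POSITIONS:
        partners[i] = wobble[a5[i]]
    seq = list(arm5)
    loop = "C" + _rand_seq(rng, LOOP_LEN - 1, "AC")
    seq += list(loop)
    seq += partners[::-1]   # positions 28..49 pair i <-> 49-i
    seq += list("AA")       # 3p 3' overhang tail (positions 50, 51)
    return arm5, "".join(seq)


def generate_genome(config: SimulationConfig, seed: int = 0
                    ) -> tuple[GenomeSequence, GenomeSequence | None,
                               list[MiRNALocus], dict[str, str]]:
    """Build the reference (and optional host) genome with embedded loci.

    Returns (genome, host_genome, loci, class map). Hairpin loci get designed
    precursors; non-hairpin loci (non-miRNA classes, decoys) get plain
    windows. The three bases 3'-ward of every hairpin precursor are fixed to
    C (transcript orientation) so planted A/U/G tails are never ambiguous.
    """
    rng = np.random.default_rng([seed, 7])
    chroms = dict(config.chroms)
    chroms["contig_un"] = config.unplaced_contig_len
    seqs = {name: list(_rand_seq(rng, n)) for name, n in chroms.items()}
    arm_cache: dict[str, tuple[str, str]] = {}
    loci: list[MiRNALocus] = []
    classes: dict[str, str] = {}

    def embed(spec: LocusSpec, seqs_map, genome_name: str) -> MiRNALocus:
        target = seqs_map[spec.chrom]
        if spec.is_hairpin:
            if spec.copy_arms_from and spec.copy_arms_from in arm_cache:
                arm5 = arm_cache[spec.copy_arms_from][0]
            else:
                arm5 = _rand_seq(rng, ARM_LEN)
            if spec.diverge_positions:
                rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
                a = list(arm5)
                for p in spec.diverge_positions:
                    a[p] = rot[a[p]]
                arm5 = "".join(a)
            arm5, pre = _build_hairpin(arm5, rng)
            arm_cache[spec.name] = (arm5, pre[30:52])
            iv5_t, iv3_t = (0, ARM_LEN), (30, PRECURSOR_LEN)
        else:
            pre = _rand_seq(rng, PRECURSOR_LEN, spec.alphabet)
            iv5_t, iv3_t = (0, ARM_LEN), (30, PRECURSOR_LEN)
        g0 = spec.pos
        g1 = g0 + PRECURSOR_LEN
        if g1 + 3 > len(target) or g0 < 3:
            raise ValueError(f"locus {spec.name} does not fit on {spec.chrom}")
        if spec.strand == "+":
            target[g0:g1] = list(pre)
            target[g1:g1 + 3] = list("CCC")
            iv5 = (g0 + iv5_t[0], g0 + iv5_t[1])
            iv3 = (g0 + iv3_t[0], g0 + iv3_t[1])
        else:
            target[g0:g1] = list(revcomp(pre))
            target[g0 - 3:g0] = list("GGG")
            iv5 = (g1 - iv5_t[1], g1 - iv5_t[0])
            iv3 = (g1 - iv3_t[1], g1 - iv3_t[0])
        placed = spec.chrom != "contig_un"
        return MiRNALocus(
            locus_id=spec.name, chrom=spec.chrom, strand=spec.strand,
            precursor_iv=(g0, g1), mature5p_iv=iv5, mature3p_iv=iv3,
            precursor_seq=pre,
            source="novel_candidate" if spec.rna_class == "miRNA" else "known",
            chrom_class="placed" if placed else "unplaced_contig",
            family=spec.family)

    for spec in config.loci:
        loci.append(embed(spec, seqs, "vector"))
        classes[spec.name] = spec.rna_class
    genome = GenomeSequence(list(chroms), {k: "".join(v) for k, v in seqs.items()})

    host_genome = None
    host_loci: list[MiRNALocus] = []
    if config.host_chrom_len:
        hseqs = {"host_chr1": list(_rand_seq(rng, config.host_chrom_len))}
        for spec in config.host_loci:
            host_loci.append(embed(spec, hseqs, "host"))
            classes[spec.name] = spec.rna_class
        host_genome = GenomeSequence(["host_chr1"],
                                     {"host_chr1": "".join(hseqs["host_chr1"])})
    loci.sort(key=lambda l: (l.chrom, l.precursor_iv))
    return genome, host_genome, loci + host_loci, classes


def _mature_seq(locus: MiRNALocus, arm: str) -> str:
    iv = locus.arm_iv(arm)
    a, b = locus.to_precursor_coords(*iv)
    return locus.precursor_seq[a:b]


def _context(genome: GenomeSequence, locus: MiRNALocus, arm: str,
             upstream: bool, n: int) -> str:
    """Genomic bases adjacent to an arm in transcript orientation."""
    iv = locus.arm_iv(arm)
    if locus.strand == "+":
        if upstream:
            return genome.fetch(locus.chrom, iv[0] - n, iv[0], "+")
        return genome.fetch(locus.chrom, iv[1], iv[1] + n, "+")
    if upstream:
        return genome.fetch(locus.chrom, iv[1], iv[1] + n, "-")
    return genome.fetch(locus.chrom, iv[0] - n, iv[0], "-")


def _apply_category(mature: str, up: str, down: str, category: str,
                    rng: np.random.Generator) -> str:
    """Construct the read sequence for one planted iso-miR category."""
    kind, _, arg = category.partition(":")
    if kind == "canonical":
        return mature
    if kind == "off5":
        k = int(arg)
        if k < 0:
            return up[len(up) + k:] + mature
        return mature[k:]
    if kind == "trim":
        return mature[:int(arg)]
    if kind == "tmpl":
        k = int(arg)
        return mature + down[:k]
    if kind == "tail":
        return mature + dna(arg)
    if kind == "edited":
        pos = int(rng.integers(1, len(mature) - 1))
        base = mature[pos]
        choices = [b for b in "ACGT" if b != base]
        return mature[:pos] + choices[int(rng.integers(0, 3))] + mature[pos + 1:]
    if kind == "edited_ag":
        a_pos = [i for i, b in enumerate(mature[1:-1], 1) if b == "A"]
        if not a_pos:
            return _apply_category(mature, up, down, "edited", rng)
        pos = a_pos[int(rng.integers(0, len(a_pos)))]
        return mature[:pos] + "G" + mature[pos + 1:]
    raise ValueError(f"unknown category {category!r}")


def _category_table(spec: LocusSpec) -> tuple[list[str], list[float]]:
    cats, probs = [], []
    for k, p in sorted(spec.fiveprime_offset_probs.items()):
        cats.append(f"off5:{k}"), probs.append(p)
    for k, p in sorted(spec.threeprime_trim_probs.items()):
        cats.append(f"trim:{k}"), probs.append(p)
    for k, p in sorted(spec.template_ext_probs.items()):
        cats.append(f"tmpl:{k}"), probs.append(p)
    for nt, p in sorted(spec.nontemplate_tail_probs.items()):
        cats.append(f"tail:{nt}"), probs.append(p)
    if spec.editing_rate:
        cats.append("edited_ag" if spec.editing_bias == "AG" else "edited")
        probs.append(spec.editing_rate)
    total = sum(probs)
    if total > 1.0 + 1e-9:
        raise ValueError(f"{spec.name}: category probabilities exceed 1")
    cats.append("canonical")
    probs.append(1.0 - total)
    return cats, probs


def simulate_reads(genome: GenomeSequence, host_genome: GenomeSequence | None,
                   loci: Sequence[MiRNALocus], config: SimulationConfig,
                   seed: int = 0) -> tuple[dict[str, list[tuple[str, int]]],
                                           dict[str, dict], pd.DataFrame]:
    """Draw per-library collapsed reads and the completed truth table.

    Returns (libraries, library_meta, truth). Truth rows carry the planted
    category counts per locus x library x arm, before sequencing-error
    injection; errors never touch the terminal base of a planted tail.
    """
    rng = np.random.default_rng([seed, 13])
    specs = {}
    for spec in config.loci + config.host_loci:
        specs[spec.name] = spec
    by_id = {l.locus_id: l for l in loci}
    vector_ids = [s.name for s in config.loci]
    host_ids = [s.name for s in config.host_loci]

    library_meta: dict[str, dict] = {}
    libraries: dict[str, list[tuple[str, int]]] = {}
    truth_rows = []

    # per-library expression-group multipliers (shared within a group)
    groups = sorted({s.expression_group for s in config.loci
                     if s.expression_group})

    for cond in config.conditions:
        for rep in range(1, cond.n_replicates + 1):
            lib = f"{cond.name}_rep{rep}"
            library_meta[lib] = {"condition": cond.name, "replicate": rep,
                                 "experiment": f"exp{rep}"}
            group_mult = {g: float(rng.lognormal(0.0, 0.8)) for g in groups}
            weights = []
            for s in config.loci:
                w = s.expression * s.fold.get(cond.name, 1.0)
                w *= cond.class_scaling.get(s.rna_class, 1.0)
                if s.expression_group:
                    w *= group_mult[s.expression_group]
                weights.append(w)
            weights = np.array(weights, dtype=float)
            n_vector = config.reads_per_library
            n_host = 0
            if cond.host_contamination and host_ids:
                n_host = int(round(config.reads_per_library * cond.host_contamination))
                n_vector = config.reads_per_library - n_host
            locus_counts = rng.multinomial(n_vector, weights / weights.sum())
            entries: dict[str, int] = {}

            def emit(locus_id: str, n_total: int, gen: GenomeSequence):
                spec = specs[locus_id]
                locus = by_id[locus_id]
                prop5 = spec.arm_ratio_by_condition.get(cond.name, spec.arm_ratio)
                n5 = rng.binomial(n_total, prop5)
                for arm, n_arm in (("5p", n5), ("3p", n_total - n5)):
                    if n_arm == 0:
                        continue
                    mature = _mature_seq(locus, arm)
                    up = _context(gen, locus, arm, upstream=True, n=3)
                    down = _context(gen, locus, arm, upstream=False, n=3)
                    cats, probs = _category_table(spec)
                    cat_counts = rng.multinomial(n_arm, probs)
                    for cat, n_cat in zip(cats, cat_counts):
                        if n_cat == 0:
                            continue
                        seq = _apply_category(mature, up, down, cat, rng)
                        truth_rows.append((locus_id, lib, arm, cat, int(n_cat)))
                        # sequencing errors: substitution-only thinning
                        protect_last = cat.startswith("tail")
                        L = len(seq) - (1 if protect_last else 0)
                        p_err = 1.0 - (1.0 - config.error_rate) ** L
                        n_err = rng.binomial(n_cat, p_err)
                        entries[seq] = entries.get(seq, 0) + int(n_cat - n_err)
                        for _ in range(n_err):
                            pos = int(rng.integers(0, L))
                            base = seq[pos]
                            alts = [b for b in "ACGT" if b != base]
                            mutated = (seq[:pos] + alts[int(rng.integers(0, 3))]
                                       + seq[pos + 1:])
                            entries[mutated] = entries.get(mutated, 0) + 1

            for locus_id, n_total in zip(vector_ids, locus_counts):
                if n_total:
                    emit(locus_id, int(n_total), genome)
            if n_host:
                hw = np.array([specs[h].expression for h in host_ids])
                host_counts = rng.multinomial(n_host, hw / hw.sum())
                for locus_id, n_total in zip(host_ids, host_counts):
                    if n_total:
                        emit(locus_id, int(n_total), host_genome)
            libraries[lib] = sorted(entries.items())

    truth = pd.DataFrame(truth_rows,
                         columns=["locus", "library", "arm", "category", "count"])
    return libraries, library_meta, truth


def generate(config: SimulationConfig, seed: int = 0) -> SimResult:
    """One-call generation: genome, loci, libraries and truth."""
    genome, host_genome, loci, classes = generate_genome(config, seed)
    libraries, meta, truth = simulate_reads(genome, host_genome, loci, config, seed)
    return SimResult(genome=genome, host_genome=host_genome, loci=loci,
                     specs={s.name: s for s in config.loci + config.host_loci},
                     classes=classes, library_meta=meta, libraries=libraries,
                     truth=truth, config=config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_ISOMIR_DEFAULTS = dict(
    fiveprime_offset_probs={-1: 0.04, 1: 0.04},
    threeprime_trim_probs={-2: 0.05, -1: 0.08},
    template_ext_probs={1: 0.08, 2: 0.02},
    nontemplate_tail_probs={"A": 0.04, "U": 0.05},
    editing_rate=0.01,
)

# arm ratios across the base locus panel average to a 3'-biased 0.40
_BASE_ARM_RATIOS = [0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.35, 0.50,
                    0.55, 0.60, 0.65, 0.80]


def _base_mirna_loci(n: int = 12, spacing: int = 3000) -> list[LocusSpec]:
    loci = []
    for i in range(n):
        chrom = f"chr{i % 3 + 1}"
        strand = "-" if i % 5 == 4 else "+"
        loci.append(LocusSpec(
            name=f"mir-sim{i + 1}", chrom=chrom,
            pos=1000 + (i // 3) * spacing, strand=strand,
            family=f"mir-sim{i + 1}",
            arm_ratio=_BASE_ARM_RATIOS[i % len(_BASE_ARM_RATIOS)],
            expression=1.0 + (i % 4),
            **_ISOMIR_DEFAULTS))
    return loci


def _support_loci() -> list[LocusSpec]:
    """Non-miRNA small RNA classes, the U2 reference gene and decoys."""
    out = [
        LocusSpec(name="tRNA-1", chrom="chr1", pos=20_000, is_hairpin=False,
                  rna_class="tRNA_rRNA_snoRNA", arm_ratio=1.0, expression=3.0),
        LocusSpec(name="rRNA-1", chrom="chr2", pos=20_000, is_hairpin=False,
                  rna_class="tRNA_rRNA_snoRNA", arm_ratio=1.0, expression=2.0),
        LocusSpec(name="snoRNA-1", chrom="chr3", pos=20_000, is_hairpin=False,
                  rna_class="tRNA_rRNA_snoRNA", arm_ratio=1.0, expression=1.5),
        LocusSpec(name="U2", chrom="chr1", pos=24_000, is_hairpin=False,
                  rna_class="other", arm_ratio=1.0, expression=2.0),
        # decoys: AC-only precursors cannot base-pair -> never fold as hairpins
        LocusSpec(name="decoy-flat", chrom="chr2", pos=24_000, is_hairpin=False,
                  rna_class="miRNA", arm_ratio=0.5, expression=0.5,
                  alphabet="AC"),
        LocusSpec(name="decoy-contig", chrom="contig_un", pos=500,
                  is_hairpin=False, rna_class="miRNA", arm_ratio=0.5,
                  expression=0.5, alphabet="AC"),
    ]
    return out


def _chroms() -> dict[str, int]:
    return {"chr1": 30_000, "chr2": 30_000, "chr3": 30_000}


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study designs with documented planted parameters."""
    presets: dict[str, SimulationConfig] = {}

    # --- feeding: sugar vs blood, host contamination, miR-92a-style sharing
    loci = _base_mirna_loci() + _support_loci()
    mir7 = LocusSpec(name="mir-7", chrom="chr1", pos=11_000, family="mir-7",
                     arm_ratio=0.3, expression=2.0, fold={"blood": 5.0},
                     **_ISOMIR_DEFAULTS)
    mirN3 = LocusSpec(name="mir-N3", chrom="chr2", pos=11_000, family="mir-N3",
                      arm_ratio=0.2, expression=1.0, fold={"blood": 4.0},
                      **_ISOMIR_DEFAULTS)
    # the shared-family locus: the host copy reuses the vector arms with three
    # diverged positions per arm, so its reads are distinguishable by exact
    # sequence and never map to the vector genome within 2 mismatches.
    # Host/vector weights put 90% of the family's blood-library reads on the
    # host isoforms (0.26*0.47 = 9 x 0.74 * 1/54.5).
    mir92a = LocusSpec(name="mir-92a", chrom="chr3", pos=11_000,
                       family="mir-92a", arm_ratio=0.3, expression=1.0)
    host92 = LocusSpec(name="host-mir-92a", chrom="host_chr1", pos=1_000,
                       rna_class="miRNA", arm_ratio=0.3, expression=0.47,
                       copy_arms_from="mir-92a",
                       diverge_positions=(4, 12, 19))
    host_other = LocusSpec(name="host-other", chrom="host_chr1", pos=3_000,
                           rna_class="miRNA", arm_ratio=0.5, expression=0.53)
    presets["feeding"] = SimulationConfig(
        chroms=_chroms(), loci=loci + [mir7, mirN3, mir92a],
        conditions=[ConditionSpec("sugar", 2),
                    ConditionSpec("blood", 2, host_contamination=0.26)],
        host_chrom_len=8_000, host_loci=[host92, host_other])

    # --- infection: blood vs infected, 6 planted responders
    loci = _base_mirna_loci() + _support_loci()
    responders = [
        LocusSpec(name="mir-317", chrom="chr1", pos=11_000, family="mir-317",
                  arm_ratio=0.3, expression=2.0, fold={"infected": 5.0},
                  **_ISOMIR_DEFAULTS),
        LocusSpec(name="mir-2940", chrom="chr2", pos=11_000, family="mir-2940",
                  arm_ratio=0.2, expression=2.0, fold={"infected": 3.0},
                  **_ISOMIR_DEFAULTS),
    ] + [
        LocusSpec(name=f"mir-inf{i}", chrom=f"chr{i % 3 + 1}",
                  pos=12_000 + 600 * (i // 3), family=f"mir-inf{i}",
                  arm_ratio=0.4, expression=0.5, fold={"infected": 4.0},
                  **_ISOMIR_DEFAULTS)
        for i in range(4)
    ]
    presets["infection"] = SimulationConfig(
        chroms=_chroms(), loci=loci + responders,
        conditions=[ConditionSpec("blood", 2), ConditionSpec("infected", 2)])

    # --- ago_knockdown: class-specific global depletion
    loci = _base_mirna_loci() + _support_loci()
    presets["ago_knockdown"] = SimulationConfig(
        chroms=_chroms(), loci=loci,
        conditions=[
            ConditionSpec("control", 2),
            ConditionSpec("ago1", 1, class_scaling={
                "miRNA": 0.35, "tRNA_rRNA_snoRNA": 0.91}),
            ConditionSpec("ago2", 1, class_scaling={
                "miRNA": 2 ** 0.54, "tRNA_rRNA_snoRNA": 2 ** 0.16}),
        ])

    # --- arm_switch: condition-dependent arm usage, >=10-fold for two loci
    loci = _base_mirna_loci() + _support_loci()
    switchers = [
        LocusSpec(name="mir-1175", chrom="chr1", pos=11_000, family="mir-1175",
                  arm_ratio=0.9, arm_ratio_by_condition={"aedes": 0.3},
                  expression=2.0, **_ISOMIR_DEFAULTS),
        LocusSpec(name="mir-31", chrom="chr2", pos=11_000, family="mir-31",
                  arm_ratio=0.1, arm_ratio_by_condition={"aedes": 0.6},
                  expression=2.0, **_ISOMIR_DEFAULTS),
        LocusSpec(name="mir-305", chrom="chr3", pos=11_000, family="mir-305",
                  arm_ratio=0.5, expression=2.0, **_ISOMIR_DEFAULTS),
    ]
    presets["arm_switch"] = SimulationConfig(
        chroms=_chroms(), loci=loci + switchers,
        conditions=[ConditionSpec("anopheles", 2), ConditionSpec("aedes", 2)])

    # --- cluster_conservation: clusters, paralogs, co-expression groups
    clustered = []
    # conserved cluster (gap 800 bp, same strand), co-expressed
    for i, fam in enumerate(["mir-2", "mir-13", "mir-71"]):
        clustered.append(LocusSpec(
            name=fam, chrom="chr1", pos=2_000 + i * (PRECURSOR_LEN + 800),
            family=fam, arm_ratio=0.3, expression=2.0,
            expression_group="cl1", **_ISOMIR_DEFAULTS))
    # fragmented-in-B cluster
    for i, fam in enumerate(["mir-2944", "mir-309", "mir-286"]):
        clustered.append(LocusSpec(
            name=fam, chrom="chr2", pos=2_000 + i * (PRECURSOR_LEN + 900),
            family=fam, arm_ratio=0.3, expression=2.0,
            expression_group="cl2", **_ISOMIR_DEFAULTS))
    # species-specific cluster (< 1 kb apart) with a shared arm preference
    for i, fam in enumerate(["mir-285", "mir-11"]):
        clustered.append(LocusSpec(
            name=fam, chrom="chr3", pos=2_000 + i * (PRECURSOR_LEN + 700),
            family=fam, arm_ratio=0.2, expression=2.0,
            expression_group="cl3", **_ISOMIR_DEFAULTS))
    # paralogs: identical mature pair + a 2944-style trio member
    clustered.append(LocusSpec(
        name="mir-965-1", chrom="chr1", pos=12_000, family="mir-965",
        arm_ratio=0.8, expression=1.5, **_ISOMIR_DEFAULTS))
    clustered.append(LocusSpec(
        name="mir-965-2", chrom="chr1", pos=12_600, family="mir-965",
        arm_ratio=0.8, expression=1.5, copy_arms_from="mir-965-1",
        **_ISOMIR_DEFAULTS))
    singles = [LocusSpec(
        name=f"mir-single{i}", chrom=f"chr{i % 3 + 1}",
        pos=18_000 + (i // 3) * 4_000, family=f"mir-single{i}",
        arm_ratio=0.25 if i % 2 else 0.75, expression=1.0,
        expression_group=f"solo{i}", **_ISOMIR_DEFAULTS) for i in range(6)]
    presets["cluster_conservation"] = SimulationConfig(
        chroms=_chroms(), loci=clustered + singles + _support_loci(),
        conditions=[ConditionSpec("adult", 4)])

    # --- species B counterpart for cluster-conservation comparisons:
    # mir-2/13/71 stay clustered; mir-286/mir-309 cluster without mir-2944;
    # mir-285 and mir-11 are unlinked; mir-965 is single-copy.
    b_loci = []
    for i, fam in enumerate(["mir-2", "mir-13", "mir-71"]):
        b_loci.append(LocusSpec(
            name=f"b-{fam}", chrom="chr1", pos=2_000 + i * (PRECURSOR_LEN + 850),
            family=fam, arm_ratio=0.3, expression=2.0, **_ISOMIR_DEFAULTS))
    for i, fam in enumerate(["mir-286", "mir-309"]):
        b_loci.append(LocusSpec(
            name=f"b-{fam}", chrom="chr2", pos=2_000 + i * (PRECURSOR_LEN + 900),
            family=fam, arm_ratio=0.3, expression=2.0, **_ISOMIR_DEFAULTS))
    b_loci.append(LocusSpec(name="b-mir-2944", chrom="chr2", pos=15_000,
                            family="mir-2944", arm_ratio=0.3, expression=2.0,
                            **_ISOMIR_DEFAULTS))
    b_loci.append(LocusSpec(name="b-mir-285", chrom="chr3", pos=2_000,
                            family="mir-285", arm_ratio=0.2, expression=2.0,
                            **_ISOMIR_DEFAULTS))
    b_loci.append(LocusSpec(name="b-mir-11", chrom="chr3", pos=15_000,
                            family="mir-11", arm_ratio=0.2, expression=2.0,
                            **_ISOMIR_DEFAULTS))
    b_loci.append(LocusSpec(name="b-mir-965", chrom="chr1", pos=15_000,
                            family="mir-965", arm_ratio=0.8, expression=1.5,
                            **_ISOMIR_DEFAULTS))
    presets["cluster_conservation_b"] = SimulationConfig(
        chroms=_chroms(), loci=b_loci + _support_loci(),
        conditions=[ConditionSpec("adult", 2)])

    return presets


def write_scenario(result: SimResult, out_dir: str | Path) -> None:
    """Write genome.fa, host.fa, annotations.gff3, per-library FASTQ and
    truth tables; byte-deterministic for a given config and seed."""
    from .mirio import write_genome, write_mirna_gff

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(result.genome, out / "genome.fa")
    if result.host_genome is not None:
        write_genome(result.host_genome, out / "host.fa")
    write_mirna_gff([l for l in result.loci if l.chrom in result.genome.sequences],
                    out / "annotations.gff3")
    for lib in sorted(result.libraries):
        with open(out / f"lib_{lib}.fastq", "w") as fh:
            i = 0
            for seq, count in result.libraries[lib]:
                for _ in range(count):
                    i += 1
                    fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    result.truth.to_csv(truth_dir / "categories.tsv", sep="\t", index=False)
    rows = [{"locus": s.name, "class": s.rna_class, "arm_ratio": s.arm_ratio,
             "expression": s.expression}
            for s in result.specs.values()]
    pd.DataFrame(rows).to_csv(truth_dir / "loci.tsv", sep="\t", index=False)
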