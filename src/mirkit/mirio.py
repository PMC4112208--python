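"""Data model and readers/writers for the small-RNA pipeline.

Conventions used throughout the package:

* genomic intervals are 0-based half-open tuples ``(start, end)``; GFF3 I/O
  converts from/to the 1-based inclusive convention at the boundary;
* sequences are stored in the DNA alphabet (``U`` is normalized to ``T`` on
  read); reports that print mature miRNA sequences emit RNA;
* collapsed read multiplicities use the common ``_x<count>`` FASTA header
  suffix.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "MiRNALocus",
    "AlignedRead",
    "NovelMiRNATableRecord",
    "ReadCollection",
    "FormatError",
    "read_genome",
    "write_genome",
    "read_mirna_gff",
    "write_mirna_gff",
    "read_small_rna_reads",
    "read_alignments",
    "parse_novel_table",
    "load_table1_fixture",
    "load_table2_fixture",
    "revcomp",
    "rna",
    "dna",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = set("ACGTN")

# Paper-style length windows: reads shorter than 15 nt or longer than 35 nt are
# rejected outright; reads outside [17, 30] nt are kept but flagged.
MIN_READ_LEN = 15
MAX_READ_LEN = 35
FLAG_READ_RANGE = (17, 30)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def dna(seq: str) -> str:
    """Normalize a nucleotide string to the uppercase DNA alphabet."""
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    """Render a DNA-alphabet sequence as RNA (for reports)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A reference genome: ordered chromosome names and DNA sequences."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate identifier among chromosome names")
        for name in self.chrom_names:
            bad = set(self.sequences[name]) - _VALID_NT
            if bad:
                raise FormatError(
                    f"non-nucleotide characters {sorted(bad)} in sequence {name!r}"
                )

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-oriented slice of ``chrom[start:end)`` (0-based half-open)."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        s = self.sequences[chrom][max(start, 0):end]
        return revcomp(s) if strand == "-" else s

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class MiRNALocus:
    """A precursor hairpin with optional annotated 5p/3p mature arms.

    ``mature5p_iv`` is the arm 5'-ward in strand orientation (on the minus
    strand this is the genomically *rightmost* arm).
    """

    locus_id: str
    chrom: str
    strand: str
    precursor_iv: tuple[int, int]
    mature5p_iv: tuple[int, int] | None = None
    mature3p_iv: tuple[int, int] | None = None
    precursor_seq: str = ""
    source: str = "known"          # known | novel_candidate
    chrom_class: str = "placed"    # placed | unplaced_contig
    family: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be + or -")
        p0, p1 = self.precursor_iv
        if not 50 <= p1 - p0 <= 200:
            raise ValueError(
                f"{self.locus_id}: precursor length {p1 - p0} outside [50, 200]"
            )
        for iv in (self.mature5p_iv, self.mature3p_iv):
            if iv is not None and not (p0 <= iv[0] < iv[1] <= p1):
                raise ValueError(f"{self.locus_id}: mature interval {iv} not nested "
                                 f"in precursor {self.precursor_iv}")
        if self.mature5p_iv and self.mature3p_iv:
            five, three = self.mature5p_iv, self.mature3p_iv
            ok = five[0] < three[0] if self.strand == "+" else five[1] > three[1]
            if not ok:
                raise ValueError(f"{self.locus_id}: 5p arm is not 5'-ward of 3p arm")

    def arm_iv(self, arm: str) -> tuple[int, int] | None:
        return self.mature5p_iv if arm == "5p" else self.mature3p_iv

    def to_precursor_coords(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic interval into strand-oriented precursor coordinates."""
        p0, p1 = self.precursor_iv
        if self.strand == "+":
            return start - p0, end - p0
        return p1 - end, p1 - start


@dataclass
class AlignedRead:
    """A collapsed read aligned to the genome.

    ``seq`` is the read sequence as sequenced (i.e. equal to the genome slice
    on ``+``, to its reverse complement on ``-``, up to mismatches).
    """

    seq: str
    count: float
    chrom: str
    strand: str
    start: int
    end: int
    n_mismatch: int = 0
    n_mapped_loci: int = 1
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("alignment span does not match read length")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read 5' end (position of first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def weighted_count(self) -> float:
        return self.count * self.weight


CONSERVATION_CLASSES = ("full_homolog", "seed_only", "none")

_MIR_ID = re.compile(r"\b(?:aae|dme|bmo|tca|hsa|cqu|aga)-mir-\S+", re.IGNORECASE)


def classify_conservation_note(note: str) -> str:
    """Map a free-text conservation note to its three-way class.

    ``No``-prefixed notes mean no detectable homology; notes containing the
    word ``seed`` (and notes claiming conservation only of the candidate's own
    newly named miR) mean similarity restricted to the seed; notes naming a
    known miRNA of another species mean a full homolog.
    """
    if note.startswith("No"):
        return "none"
    if "seed" in note:
        return "seed_only"
    if note.startswith("miR conserved"):
        return "seed_only"
    if _MIR_ID.search(note):
        return "full_homolog"
    raise FormatError(f"cannot classify conservation note {note!r}")


@dataclass
class NovelMiRNATableRecord:
    """One row of the packaged novel-miRNA table fixture."""

    mature_seq: str                 # RNA alphabet, as printed
    seed: str                       # 7-mer, nucleotides 2-8
    predominant_arm: str            # 5p | 3p | 5p~3p
    reads_5p: int
    reads_3p: int
    conservation_note: str
    conservation_class: str = ""
    low_confidence: bool = False
    fields_ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.conservation_class:
            self.conservation_class = classify_conservation_note(self.conservation_note)
        if not self.fields_ambiguous and self.mature_seq[1:8] != self.seed:
            raise FormatError(
                f"seed {self.seed} != mature[2..8] for row {self.mature_seq}"
            )


@dataclass
class ReadCollection:
    """Collapsed small-RNA reads plus bookkeeping of flagged/rejected input."""

    entries: list[tuple[str, int]] = field(default_factory=list)
    flagged: dict[str, str] = field(default_factory=dict)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.entries)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA reference; U->T and lowercase are normalized."""
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate identifier {rec.id!r}")
        seq = dna(str(rec.seq))
        bad = set(seq) - _VALID_NT
        if bad:
            raise FormatError(
                f"non-nucleotide characters {sorted(bad)} in record {rec.id!r}"
            )
        names.append(rec.id)
        seqs[rec.id] = seq
    if not names:
        raise FormatError(f"no records in {path}")
    return GenomeSequence(names, seqs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            s = genome.sequences[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


_COLLAPSED = re.compile(r"_x(\d+)$")


def read_small_rna_reads(path: str | Path) -> ReadCollection:
    """Read adapter-trimmed small-RNA reads (FASTQ, or collapsed FASTA whose
    headers carry ``_x<count>`` multiplicities) and collapse identical
    sequences.

    Reads outside [15, 35] nt are rejected with a reason; reads outside
    [17, 30] nt are kept but flagged, mirroring the read-length window the
    size-distribution summaries use.
    """
    path = Path(path)
    fmt = "fastq"
    with open(path) as fh:
        first = fh.read(1)
        if first == ">":
            fmt = "fasta"
        elif first != "@":
            raise FormatError(f"{path}: neither FASTA nor FASTQ")
    counts: dict[str, int] = {}
    coll = ReadCollection()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq = dna(str(rec.seq))
            mult = 1
            if fmt == "fasta":
                m = _COLLAPSED.search(rec.id)
                if m:
                    mult = int(m.group(1))
            if len(seq) < MIN_READ_LEN:
                coll.rejected.append((seq, "below minimum length"))
                continue
            if len(seq) > MAX_READ_LEN:
                coll.rejected.append((seq, "above maximum length"))
                continue
            if not FLAG_READ_RANGE[0] <= len(seq) <= FLAG_READ_RANGE[1]:
                coll.flagged[seq] = "outside 17-30 nt window"
            counts[seq] = counts.get(seq, 0) + mult
    except ValueError as exc:  # Biopython raises on truncated FASTQ records
        raise FormatError(f"{path}: truncated record near index {len(counts)}: {exc}")
    coll.entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return coll


# ---------------------------------------------------------------------------
# GFF3 (miRBase dialect)
# ---------------------------------------------------------------------------


def _gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_mirna_gff(path: str | Path, genome: GenomeSequence,
                   placed_chroms: set[str] | None = None) -> list[MiRNALocus]:
    """Parse a miRBase-style GFF3 (``miRNA_primary_transcript`` parents with
    child ``miRNA`` features linked by ``Derives_from``).

    Coordinates are converted to 0-based half-open; the precursor sequence is
    extracted strand-oriented from ``genome``. ``placed_chroms`` (default: all
    genome chromosomes not named like contigs) marks loci on unplaced contigs.
    """
    parents: dict[str, dict] = {}
    children: list[dict] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = f
            a = _gff_attrs(attrs)
            rec = dict(chrom=chrom, start=int(start) - 1, end=int(end),
                       strand=strand, attrs=a, line=ln)
            if ftype == "miRNA_primary_transcript":
                parents[a.get("ID", a.get("Name", str(ln)))] = rec
            elif ftype == "miRNA":
                children.append(rec)
    loci: list[MiRNALocus] = []
    kids_of: dict[str, list[dict]] = {pid: [] for pid in parents}
    for c in children:
        pid = c["attrs"].get("Derives_from")
        if pid not in kids_of:
            raise FormatError(f"line {c['line']}: Derives_from={pid!r} has no parent")
        kids_of[pid].append(c)
    for pid, p in parents.items():
        if p["chrom"] not in genome:
            raise FormatError(f"unknown chrom {p['chrom']!r} for locus {pid}")
        iv5 = iv3 = None
        for c in kids_of[pid]:
            if not (p["start"] <= c["start"] < c["end"] <= p["end"]):
                raise FormatError(f"child of {pid} outside parent interval")
            name = c["attrs"].get("Name", "")
            iv = (c["start"], c["end"])
            if name.endswith("-5p"):
                iv5 = iv
            elif name.endswith("-3p"):
                iv3 = iv
            else:
                # unannotated suffix: orient by position relative to strand
                if p["strand"] == "+":
                    mid = (p["start"] + p["end"]) / 2
                    if (iv[0] + iv[1]) / 2 < mid:
                        iv5 = iv
                    else:
                        iv3 = iv
                else:
                    mid = (p["start"] + p["end"]) / 2
                    if (iv[0] + iv[1]) / 2 > mid:
                        iv5 = iv
                    else:
                        iv3 = iv
        if placed_chroms is None:
            placed = not p["chrom"].lower().startswith(("contig", "scaffold", "unkn"))
        else:
            placed = p["chrom"] in placed_chroms
        loci.append(MiRNALocus(
            locus_id=p["attrs"].get("Name", pid),
            chrom=p["chrom"], strand=p["strand"],
            precursor_iv=(p["start"], p["end"]),
            mature5p_iv=iv5, mature3p_iv=iv3,
            precursor_seq=genome.fetch(p["chrom"], p["start"], p["end"], p["strand"]),
            source=p["attrs"].get("source_class", "known"),
            chrom_class="placed" if placed else "unplaced_contig",
            family=p["attrs"].get("family"),
        ))
    loci.sort(key=lambda l: (l.chrom, l.precursor_iv, l.locus_id))
    return loci


def write_mirna_gff(loci: Iterable[MiRNALocus], path: str | Path) -> None:
    """Deterministic miRBase-dialect GFF3 writer (round-trips read_mirna_gff)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in sorted(loci, key=lambda l: (l.chrom, l.precursor_iv, l.locus_id)):
            attrs = f"ID={loc.locus_id};Name={loc.locus_id};source_class={loc.source}"
            if loc.family:
                attrs += f";family={loc.family}"
            fh.write("\t".join([
                loc.chrom, "mirkit", "miRNA_primary_transcript",
                str(loc.precursor_iv[0] + 1), str(loc.precursor_iv[1]),
                ".", loc.strand, ".", attrs]) + "\n")
            for arm, iv in (("5p", loc.mature5p_iv), ("3p", loc.mature3p_iv)):
                if iv is None:
                    continue
                fh.write("\t".join([
                    loc.chrom, "mirkit", "miRNA",
                    str(iv[0] + 1), str(iv[1]), ".", loc.strand, ".",
                    f"ID={loc.locus_id}-{arm};Name={loc.locus_id}-{arm};"
                    f"Derives_from={loc.locus_id}"]) + "\n")


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    n_mapped: int = 0
    n_unmapped: int = 0


def read_alignments(path: str | Path, require_nh: bool = True,
                    counts: Mapping[str, int] | None = None,
                    ) -> tuple[list[AlignedRead], AlignmentReport]:
    """Load SAM/BAM alignments; NM -> n_mismatch, NH -> multi-map weighting.

    ``counts`` optionally supplies collapsed multiplicities by read sequence
    (as sequenced). Unmapped records are skipped and tallied.
    """
    report = AlignmentReport()
    out: list[AlignedRead] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                report.n_unmapped += 1
                continue
            if not rec.has_tag("NH"):
                if require_nh:
                    raise FormatError(
                        "alignment lacks NH tag required for multi-map weighting; "
                        "use the built-in mapper instead")
                nh = 1
            else:
                nh = int(rec.get_tag("NH"))
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            strand = "-" if rec.is_reverse else "+"
            # pysam reports the reference-strand sequence; store as sequenced
            seq = dna(rec.query_sequence or "")
            if strand == "-":
                seq = revcomp(seq)
            count = counts.get(seq, 1) if counts else 1
            out.append(AlignedRead(
                seq=seq, count=count, chrom=rec.reference_name, strand=strand,
                start=rec.reference_start, end=rec.reference_end,
                n_mismatch=nm, n_mapped_loci=nh, weight=1.0 / nh))
            report.n_mapped += 1
    out.sort(key=lambda r: (r.chrom, r.start, r.strand, r.seq))
    return out, report


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def parse_novel_table(path: str | Path) -> list[NovelMiRNATableRecord]:
    """Parse the novel-miRNA TSV fixture and validate the seed rule."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                records.append(NovelMiRNATableRecord(
                    mature_seq=row["mature_seq"], seed=row["seed"],
                    predominant_arm=row["predominant_arm"],
                    reads_5p=int(row["reads_5p"]), reads_3p=int(row["reads_3p"]),
                    conservation_note=row["conservation_note"],
                    low_confidence=row["low_confidence"] == "1",
                    fields_ambiguous=row["fields_ambiguous"] == "1"))
            except FormatError as exc:
                raise FormatError(f"{path}:{ln}: {exc}")
    return records


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("mirkit").joinpath("data", name)))


def load_table1_fixture() -> list[NovelMiRNATableRecord]:
    """The packaged transcription of the published novel-miRNA table."""
    return parse_novel_table(_data_path("table1_novel_mirnas.tsv"))


def load_table2_fixture():
    """The packaged arm-shift table (annotated vs detected arm, 5p/3p ratios).

    Returns a list of dicts with keys mirna, annotated_arm, detected_arm,
    ratio_sf, ratio_bf.
    """
    rows = []
    with open(_data_path("table2_arm_shifts.tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                row["ratio_sf"] = float(row["ratio_sf"])
                row["ratio_bf"] = float(row["ratio_bf"])
                rows.append(row)
    return rows
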