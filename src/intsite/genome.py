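"""Reference genome and transcript-annotation containers.

Coordinates are 0-based half-open throughout, matching BED. A transcript's
TSS is ``tx_start`` on the + strand and ``tx_end - 1`` on the − strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRef:
    """Named chromosomes with upper-case DNA sequences.

    The coordinate frame for every downstream position in the package.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has zero length")
            if seq != seq.upper():
                raise ValueError(f"chromosome {name!r} is not upper-case")
            if not set(seq) <= _DNA:
                bad = sorted(set(seq) - _DNA)
                raise ValueError(f"chromosome {name!r} has non-ACGTN bases: {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(chroms)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class Transcript:
    """One transcript model: span, strand and exon blocks."""

    id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"transcript {self.id}: tx_start must be < tx_end")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"transcript {self.id}: empty exon ({start},{end})")
            if start < self.tx_start or end > self.tx_end:
                raise ValueError(
                    f"transcript {self.id}: exon ({start},{end}) outside span"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons unsorted or overlapping"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class AnnotationSet:
    """A set of transcript models; TSS positions and context classes derive
    from it."""

    transcripts: list[Transcript] = field(default_factory=list)

    def validate_against(self, genome: GenomeRef) -> None:
        lengths = genome.lengths
        for t in self.transcripts:
            if t.chrom not in lengths:
                raise ValueError(f"transcript {t.id}: unknown chromosome {t.chrom}")
            if t.tx_end > lengths[t.chrom]:
                raise ValueError(
                    f"transcript {t.id}: span exceeds {t.chrom} length"
                )

    @classmethod
    def from_bed12(cls, path: str | Path) -> "AnnotationSet":
        transcripts = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 12:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 12 BED columns, "
                        f"got {len(fields)}"
                    )
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
                transcripts.append(
                    Transcript(name, chrom, strand, start, end, exons)
                )
        return cls(transcripts)

    def to_bed12(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                sizes = ",".join(str(e - s) for s, e in t.exons)
                starts = ",".join(str(s - t.tx_start) for s, _ in t.exons)
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            str(t.tx_start),
                            str(t.tx_end),
                            t.id,
                            "0",
                            t.strand,
                            str(t.tx_start),
                            str(t.tx_end),
                            "0",
                            str(len(t.exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )

    def transcript_spans(self, chrom: str) -> list[tuple[int, int]]:
        return [
            (t.tx_start, t.tx_end) for t in self.transcripts if t.chrom == chrom
        ]

    def tss_positions(self, chrom: str) -> list[int]:
        return [t.tss for t in self.transcripts if t.chrom == chrom]
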