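"""Junction-read processing: trimming, length calibration and mapping.

Reads are accepted only when they carry the expected barcode followed by
the transposon end sequence; the remaining genomic fragment is mapped by
exact full-length search on both strands and kept only when it has a
single genome-wide hit. The mapped position is the coordinate of the
fragment base adjacent to the vector/genome junction: the leftmost
fragment base on +, the rightmost on −.

Mismatch-tolerant alignment of real data is delegated to external
aligners; their SAM/BED output is ingested with :func:`load_alignments`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pysam

from .genome import GenomeRef, revcomp

log = logging.getLogger(__name__)

REJECT_NO_BARCODE = "no_barcode"
REJECT_NO_JUNCTION = "no_junction"
REJECT_TOO_SHORT = "too_short"

STATUS_MAPPED = "mapped"
STATUS_UNMAPPED = "unmapped"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_TOO_SHORT = "too_short"

# the empirically calibrated minimum fragment length for human-genome-scale
# datasets; calibrate_min_length recomputes it for synthetic genomes
DEFAULT_MIN_LEN = 25


class CalibrationError(RuntimeError):
    """No fragment length eliminated all random mappings."""

    def __init__(self, message: str, counts: dict[int, int]):
        super().__init__(message)
        self.counts = counts  # candidate length -> number of random hits


@dataclass
class TrimSpec:
    barcode_seq: str
    transposon_end_seq: str
    min_len: int = DEFAULT_MIN_LEN

    def __post_init__(self) -> None:
        if not self.barcode_seq or not self.transposon_end_seq:
            raise ValueError("barcode and transposon end must be non-empty")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class JunctionRead:
    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"read {self.id}: non-ACGTN bases in sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality length mismatch")


@dataclass(frozen=True)
class MappedSite:
    chrom: str
    position: int  # 0-based insertion point
    strand: str
    read_id: str


@dataclass
class TrimResult:
    fragment: Optional[str]
    rejection: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.fragment is not None


@dataclass
class MapResult:
    site: Optional[MappedSite]
    status: str


def read_fastq(path: str | Path) -> Iterator[JunctionRead]:
    """Iterate Phred+33 FASTQ records as :class:`JunctionRead`."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record near {header!r}")
            yield JunctionRead(header[1:].split()[0], seq, qual or None)


def trim_read(read: JunctionRead, spec: TrimSpec) -> TrimResult:
    """Strip exact barcode + transposon-end prefix; reject otherwise.

    Rejections: ``no_barcode`` (barcode prefix absent), ``no_junction``
    (transposon end absent after the barcode), ``too_short`` (genomic
    fragment below ``spec.min_len``).
    """
    if not read.sequence.startswith(spec.barcode_seq):
        return TrimResult(None, REJECT_NO_BARCODE)
    rest = read.sequence[len(spec.barcode_seq):]
    if not rest.startswith(spec.transposon_end_seq):
        return TrimResult(None, REJECT_NO_JUNCTION)
    fragment = rest[len(spec.transposon_end_seq):]
    if len(fragment) < spec.min_len:
        return TrimResult(None, REJECT_TOO_SHORT)
    return TrimResult(fragment)


def _count_hits(fragment: str, genome: GenomeRef, limit: int = 2):
    """Exact occurrences of fragment (either strand); stops after `limit`."""
    hits = []  # (chrom, start, strand)
    rc = revcomp(fragment)
    for chrom, seq in genome.chromosomes.items():
        for probe, strand in ((fragment, "+"), (rc, "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append((chrom, start, strand))
                if len(hits) >= limit:
                    return hits
                start = seq.find(probe, start + 1)
    return hits


def map_fragment(
    fragment: str,
    genome: GenomeRef,
    min_len: int = DEFAULT_MIN_LEN,
    read_id: str = "",
) -> MapResult:
    """Exact full-length mapping with a unique-hit requirement.

    A fragment containing N never matches (N is not a wildcard). The
    reported position is the junction-adjacent fragment base: leftmost
    matched base for a + hit, rightmost for a − hit.
    """
    if not fragment:
        raise ValueError("fragment must be non-empty")
    if len(fragment) < min_len:
        return MapResult(None, STATUS_TOO_SHORT)
    if "N" in fragment:
        return MapResult(None, STATUS_UNMAPPED)
    hits = _count_hits(fragment, genome)
    if len(hits) == 0:
        return MapResult(None, STATUS_UNMAPPED)
    if len(hits) > 1:
        return MapResult(None, STATUS_AMBIGUOUS)
    chrom, start, strand = hits[0]
    pos = start if strand == "+" else start + len(fragment) - 1
    return MapResult(MappedSite(chrom, pos, strand, read_id), STATUS_MAPPED)


def calibrate_min_length(
    genome: GenomeRef,
    length_profile,
    n_random: int = 1000,
    seed: int = 0,
) -> int:
    """Smallest length L at which no random fragment maps to the genome.

    ``length_profile`` is the empirical fragment-length distribution,
    given either as a sequence of observed lengths or as a mapping
    length → count. For each candidate L (ascending over profile lengths),
    ``n_random`` fragments are drawn with lengths from the profile
    conditioned on ≥ L and uniform random bases; L is returned when zero
    of them map (unique or ambiguous hits both count as mapping). Each
    candidate uses a seed derived from (seed, L), so re-simulation at the
    returned L reproduces the zero-hit draw exactly.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    if isinstance(length_profile, dict):
        lengths = np.array(sorted(length_profile), dtype=int)
        counts = np.array([length_profile[l] for l in lengths], dtype=float)
    else:
        lengths, counts = np.unique(
            np.asarray(length_profile, dtype=int), return_counts=True
        )
        counts = counts.astype(float)
    if lengths.size == 0 or np.any(lengths < 1):
        raise ValueError("length profile must contain positive lengths")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    hit_counts: dict[int, int] = {}
    for L in lengths:
        L = int(L)
        mask = lengths >= L
        p = counts[mask] / counts[mask].sum()
        rng = np.random.default_rng([seed, L])
        draw_lengths = rng.choice(lengths[mask], size=n_random, p=p)
        n_hits = 0
        for flen in draw_lengths:
            frag = rng.choice(bases, size=int(flen)).tobytes().decode("ascii")
            result = map_fragment(frag, genome, min_len=1)
            if result.status in (STATUS_MAPPED, STATUS_AMBIGUOUS):
                n_hits += 1
        hit_counts[L] = n_hits
        log.debug("calibration: L=%d -> %d/%d random hits", L, n_hits, n_random)
        if n_hits == 0:
            return L
    raise CalibrationError(
        f"no candidate length up to {int(lengths.max())} eliminated random "
        f"mappings",
        hit_counts,
    )


def load_alignments(
    path: str | Path, genome: Optional[GenomeRef] = None
) -> list[MappedSite]:
    """Ingest external alignments (SAM or BED6) as mapped sites.

    SAM: primary mapped records only; the site is the leftmost aligned
    reference base for forward alignments and the rightmost for reverse
    (0-based). BED: chromStart is the site, strand from column 6.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        sites = _load_sam(path)
    else:
        sites = _load_bed(path)
    if genome is not None:
        known = set(genome.lengths)
        for s in sites:
            if s.chrom not in known:
                raise ValueError(
                    f"{path}: alignment on unknown chromosome {s.chrom!r}"
                )
    return sites


def _load_sam(path: Path) -> list[MappedSite]:
    sites = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_reverse:
                site = MappedSite(
                    rec.reference_name, rec.reference_end - 1, "-",
                    rec.query_name,
                )
            else:
                site = MappedSite(
                    rec.reference_name, rec.reference_start, "+", rec.query_name
                )
            sites.append(site)
    return sites


def _load_bed(path: Path) -> list[MappedSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 requires 6 columns, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer chromStart"
                ) from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: bad strand {strand!r}"
                )
            sites.append(MappedSite(fields[0], start, strand, fields[3]))
    return sites


def write_sites_tsv(sites: list[MappedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos0\tstrand\tread_id\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.strand}\t{s.read_id}\n")
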