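"""Synthetic data generator for integration-site analysis.

Emulates the statistical structure the downstream pipeline assumes: a
multi-chromosome genome, non-overlapping transcript models, a skewed
clone-abundance profile (Dirichlet), integration-site placement with
optional TA-dinucleotide and transcript bias, and junction reads of the
form barcode + transposon end + genomic flank with substitution errors.

All randomness flows from explicit integer seeds; identical inputs yield
byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeRef, AnnotationSet, Transcript, revcomp

log = logging.getLogger(__name__)

# Defaults for the junction-library structure. The barcode and transposon-end
# sequences are synthetic stand-ins with the right shape (sample index +
# vector terminus); any non-degenerate sequences work.
DEFAULT_BARCODE = "ACGTACGT"
DEFAULT_TRANSPOSON_END = "TGACGTTGGAGTCA"


class CapacityError(ValueError):
    """The genome cannot accommodate the requested gene models."""


@dataclass
class CloneProfile:
    """Relative abundances of engineered-cell clones (sum to 1)."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or self.abundances.size < 1:
            raise ValueError("abundances must be a non-empty 1-D vector")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if abs(self.abundances.sum() - 1.0) > 1e-12:
            raise ValueError("abundances must sum to 1 within 1e-12")

    @property
    def n_clones(self) -> int:
        return self.abundances.size


@dataclass
class TruthSite:
    clone_id: int
    chrom: str
    position: int  # 0-based insertion point
    strand: str


@dataclass
class IntegrationTruth:
    """Ground-truth clone → integration-site map (one site per clone)."""

    sites: list[TruthSite]
    abundances: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": [s.clone_id for s in self.sites],
                "chrom": [s.chrom for s in self.sites],
                "pos0": [s.position for s in self.sites],
                "strand": [s.strand for s in self.sites],
                "abundance": np.asarray(self.abundances, dtype=float),
            }
        )


@dataclass
class SimConfig:
    """Knobs for junction-read simulation; one seed drives everything."""

    seed: int = 0
    reads_total: int = 2000
    read_len: int = 60
    error_rate: float = 0.0
    barcode_seq: str = DEFAULT_BARCODE
    transposon_end_seq: str = DEFAULT_TRANSPOSON_END
    motif_weight: float = 1.0
    transcript_bias: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.motif_weight < 0 or self.transcript_bias < 0:
            raise ValueError("bias weights must be >= 0")


def generate_genome(
    n_chrom: int,
    chrom_lengths: list[int],
    gc_fraction: float = 0.41,
    seed: int = 0,
) -> GenomeRef:
    """Generate i.i.d. random chromosomes named chr1..chrN.

    ``gc_fraction`` is split evenly between G and C (and 1−gc between A
    and T); the default approximates the human genome's GC content.
    """
    if len(chrom_lengths) != n_chrom:
        raise ValueError("chrom_lengths must have n_chrom entries")
    if any(length <= 0 for length in chrom_lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,  # C
        gc_fraction / 2,  # G
        (1 - gc_fraction) / 2,  # T
    ]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chroms = {}
    for i, length in enumerate(chrom_lengths, start=1):
        draw = rng.choice(bases, size=length, p=p)
        chroms[f"chr{i}"] = draw.tobytes().decode("ascii")
    return GenomeRef(chroms)


def generate_annotation(
    genome: GenomeRef,
    n_genes: int,
    mean_exons: float = 4.0,
    exon_len: int = 150,
    intron_len: int = 800,
    seed: int = 0,
    max_attempts_per_gene: int = 1000,
) -> AnnotationSet:
    """Place non-overlapping multi-exon gene models on the genome.

    Exon counts are 1 + Poisson(mean_exons − 1); both strands are drawn
    uniformly. Raises :class:`CapacityError` when a gene cannot be placed
    without overlap.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    chrom_names = list(lengths)
    chrom_p = np.array([lengths[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    transcripts: list[Transcript] = []
    for gi in range(n_genes):
        n_ex = 1 + int(rng.poisson(max(mean_exons - 1.0, 0.0)))
        gene_len = n_ex * exon_len + (n_ex - 1) * intron_len
        placed = False
        for _ in range(max_attempts_per_gene):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
            L = lengths[chrom]
            if L < gene_len:
                continue
            start = int(rng.integers(0, L - gene_len + 1))
            end = start + gene_len
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [
                (start + k * (exon_len + intron_len),
                 start + k * (exon_len + intron_len) + exon_len)
                for k in range(n_ex)
            ]
            transcripts.append(
                Transcript(f"gene{gi + 1}", chrom, strand, start, end, exons)
            )
            occupied[chrom].append((start, end))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place gene {gi + 1}/{n_genes} (length {gene_len} bp) "
                f"without overlap"
            )
    ann = AnnotationSet(transcripts)
    frac = transcript_fraction(ann, genome)
    log.info("annotation: %d genes, transcript-bp fraction %.4f", n_genes, frac)
    return ann


def transcript_fraction(annotation: AnnotationSet, genome: GenomeRef) -> float:
    """Fraction of genome bases covered by the union of transcript spans."""
    total = sum(genome.lengths.values())
    covered = 0
    for chrom in genome.chromosomes:
        spans = sorted(annotation.transcript_spans(chrom))
        cur_s = cur_e = None
        for s, e in spans:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
    return covered / total


def exon_fraction(annotation: AnnotationSet, genome: GenomeRef) -> float:
    """Fraction of genome bases covered by the union of exon intervals."""
    total = sum(genome.lengths.values())
    covered = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in annotation.transcripts:
        by_chrom.setdefault(t.chrom, []).extend(t.exons)
    for spans in by_chrom.values():
        spans.sort()
        cur_s = cur_e = None
        for s, e in spans:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
    return covered / total


def sample_clone_abundances(
    n_clones: int, concentration: float = 5.0, seed: int = 0
) -> CloneProfile:
    """Clone abundances ~ Dirichlet(concentration / n_clones, ...).

    One knob spans the clonality spectrum: small ``concentration`` gives an
    oligoclonal (outgrowth-like) profile, large gives near-even clones.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if n_clones == 1:
        return CloneProfile(np.array([1.0]))
    rng = np.random.default_rng(seed)
    alpha = np.full(n_clones, concentration / n_clones)
    ab = rng.dirichlet(alpha)
    # guard against numerically-zero normalisation drift
    ab = ab / ab.sum()
    return CloneProfile(ab)


def _position_weights(
    genome: GenomeRef,
    annotation: AnnotationSet,
    motif_weight: float,
    transcript_bias: float,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-position sampling weights over the concatenated genome.

    Weight = 1, × motif_weight when the two bases flanking the insertion
    point (positions p−1 and p) are 'TA', × transcript_bias when p lies in
    any transcript span.
    """
    names = list(genome.chromosomes)
    weights = []
    offsets = [0]
    for name in names:
        seq = np.frombuffer(genome.chromosomes[name].encode("ascii"), dtype="S1")
        L = seq.size
        w = np.ones(L, dtype=float)
        ta = np.zeros(L, dtype=bool)
        ta[1:] = (seq[:-1] == b"T") & (seq[1:] == b"A")
        w[ta] *= motif_weight
        in_tx = np.zeros(L, dtype=bool)
        for s, e in annotation.transcript_spans(name):
            in_tx[s:e] = True
        w[in_tx] *= transcript_bias
        weights.append(w)
        offsets.append(offsets[-1] + L)
    return names, np.concatenate(weights), np.asarray(offsets)


def place_integrations(
    genome: GenomeRef,
    annotation: AnnotationSet,
    profile: CloneProfile,
    motif_weight: float = 1.0,
    transcript_bias: float = 1.0,
    seed: int = 0,
    min_separation: int = 0,
) -> IntegrationTruth:
    """Sample one integration site per clone, biased by motif and context.

    Positions are sampled without replacement from the genome-wide weight
    pool; ``min_separation`` additionally enforces a minimum distance
    between any two sites on the same chromosome (0 disables it).
    """
    if motif_weight < 0 or transcript_bias < 0:
        raise ValueError("bias weights must be >= 0")
    if not np.isfinite(motif_weight) or not np.isfinite(transcript_bias):
        raise ValueError("bias weights must be finite")
    rng = np.random.default_rng(seed)
    names, w, offsets = _position_weights(
        genome, annotation, motif_weight, transcript_bias
    )
    n = profile.n_clones
    total = w.sum()
    if total <= 0 or np.count_nonzero(w) < n:
        raise ValueError(
            f"not enough eligible positions ({np.count_nonzero(w)}) "
            f"for {n} clones"
        )
    w = w.copy()
    chosen: list[int] = []
    # batch-sample, then blank out accepted sites (and their exclusion
    # windows) and redraw the shortfall; terminates because each accepted
    # site only ever removes a bounded window of the pool
    while len(chosen) < n:
        need = n - len(chosen)
        p = w / w.sum()
        if np.count_nonzero(w) < need:
            raise ValueError("min_separation leaves too few eligible positions")
        batch = rng.choice(w.size, size=min(need, np.count_nonzero(w)),
                           replace=False, p=p)
        for g in batch:
            if w[g] <= 0:
                continue
            chosen.append(int(g))
            lo = max(0, g - max(min_separation, 0))
            hi = g + max(min_separation, 0) + 1
            w[lo:hi] = 0.0
            if len(chosen) == n:
                break
    sites = []
    for clone_id, g in enumerate(chosen):
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        pos = g - int(offsets[ci])
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(TruthSite(clone_id, names[ci], pos, strand))
    return IntegrationTruth(sites, profile.abundances.copy())


def write_junction_fastq(
    truth: IntegrationTruth,
    genome: GenomeRef,
    cfg: SimConfig,
    out_dir: str | Path,
    prefix: str = "sim",
) -> tuple[Path, Path]:
    """Write junction reads (FASTQ) and the truth table (TSV).

    Each read is barcode + transposon end + the genomic flank starting at
    the clone's insertion point on its strand, with i.i.d. substitution
    errors at ``cfg.error_rate`` over the whole read. Read counts per clone
    are a single multinomial(reads_total, abundances) draw, recorded in the
    truth table's ``n_reads`` column. Qualities are constant 'I' (Q40).
    """
    prefix_len = len(cfg.barcode_seq) + len(cfg.transposon_end_seq)
    if cfg.read_len <= prefix_len:
        raise ValueError(
            f"read_len ({cfg.read_len}) must exceed barcode+transposon end "
            f"({prefix_len})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    flank_len = cfg.read_len - prefix_len
    counts = rng.multinomial(cfg.reads_total, truth.abundances)

    reads: list[tuple[str, str]] = []
    for site, n_reads in zip(truth.sites, counts):
        if n_reads == 0:
            continue
        seq = genome.chromosomes[site.chrom]
        p = site.position
        if site.strand == "+":
            flank = seq[p : p + flank_len]
        else:
            flank = revcomp(seq[max(0, p - flank_len + 1) : p + 1])
        template = cfg.barcode_seq + cfg.transposon_end_seq + flank
        for _ in range(n_reads):
            reads.append((f"clone{site.clone_id}", template))

    order = rng.permutation(len(reads))
    bases = "ACGT"
    fastq_path = out_dir / f"{prefix}.fastq"
    with open(fastq_path, "w") as fh:
        for out_i, ri in enumerate(order):
            clone_tag, template = reads[ri]
            if cfg.error_rate > 0:
                arr = list(template)
                hits = np.nonzero(rng.random(len(arr)) < cfg.error_rate)[0]
                for h in hits:
                    alts = bases.replace(arr[h], "") if arr[h] in bases else bases
                    arr[h] = alts[int(rng.integers(len(alts)))]
                template = "".join(arr)
            fh.write(f"@read{out_i}_{clone_tag}\n{template}\n+\n")
            fh.write("I" * len(template) + "\n")

    truth_path = out_dir / f"{prefix}_truth.tsv"
    frame = truth.to_frame()
    frame["n_reads"] = counts
    frame.to_csv(truth_path, sep="\t", index=False)
    log.info(
        "wrote %d reads for %d clones to %s", len(reads), len(truth.sites),
        fastq_path,
    )
    return fastq_path, truth_path
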