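"""Genomic-context classification, TSS distances, random controls, motifs.

Each integration event is classified once, at its representative
position, into exactly one of three classes (exon > transcript
precedence): inside an exon (``exon_transcript``), inside a transcript
span but not an exon (``nonexon_transcript``), or outside all
transcripts (``non_transcript``). Distances to the nearest transcription
start site are unsigned, restricted to the event's own chromosome.
A matched in-silico random control resamples each event's position
uniformly on its own chromosome, preserving per-chromosome event counts
and read tallies — the null model against which integration preferences
are judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomeRef, AnnotationSet
from .clonality import IntegrationEvent
from .junctions import MappedSite

EXON_TRANSCRIPT = "exon_transcript"
NONEXON_TRANSCRIPT = "nonexon_transcript"
NON_TRANSCRIPT = "non_transcript"
CONTEXT_CLASSES = (EXON_TRANSCRIPT, NONEXON_TRANSCRIPT, NON_TRANSCRIPT)


@dataclass
class ContextSummary:
    fractions: dict[str, float]
    median_tss_distance: Optional[float]
    n_sites: int


class AnnotationIndex:
    """Interval trees and sorted TSS arrays per chromosome."""

    def __init__(self, annotation: AnnotationSet):
        self.exons: dict[str, IntervalTree] = {}
        self.transcripts: dict[str, IntervalTree] = {}
        self.tss: dict[str, np.ndarray] = {}
        for t in annotation.transcripts:
            self.transcripts.setdefault(t.chrom, IntervalTree()).addi(
                t.tx_start, t.tx_end
            )
            tree = self.exons.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                tree.addi(s, e)
        by_chrom: dict[str, list[int]] = {}
        for t in annotation.transcripts:
            by_chrom.setdefault(t.chrom, []).append(t.tss)
        self.tss = {c: np.array(sorted(v)) for c, v in by_chrom.items()}


def _as_index(annotation: Union[AnnotationSet, AnnotationIndex]) -> AnnotationIndex:
    if isinstance(annotation, AnnotationIndex):
        return annotation
    return AnnotationIndex(annotation)


def classify_position(
    chrom: str, position: int, index: AnnotationIndex
) -> str:
    if chrom in index.exons and index.exons[chrom].overlaps_point(position):
        return EXON_TRANSCRIPT
    if chrom in index.transcripts and index.transcripts[chrom].overlaps_point(
        position
    ):
        return NONEXON_TRANSCRIPT
    return NON_TRANSCRIPT


def classify_site(
    site: MappedSite,
    annotation: Union[AnnotationSet, AnnotationIndex],
    genome: Optional[GenomeRef] = None,
) -> str:
    """Context class of one mapped site (exon > transcript precedence)."""
    if genome is not None and site.chrom not in genome.lengths:
        raise ValueError(f"unknown chromosome {site.chrom!r}")
    return classify_position(site.chrom, site.position, _as_index(annotation))


def context_fractions(
    events: list[IntegrationEvent],
    annotation: Union[AnnotationSet, AnnotationIndex],
) -> dict[str, float]:
    """Per-event class fractions, classified at representative positions."""
    if not events:
        raise ValueError("no events to classify")
    index = _as_index(annotation)
    counts = dict.fromkeys(CONTEXT_CLASSES, 0)
    for e in events:
        counts[classify_position(e.chrom, e.representative_position, index)] += 1
    n = len(events)
    return {cls: counts[cls] / n for cls in CONTEXT_CLASSES}


def nearest_tss_distance(
    site: Union[MappedSite, IntegrationEvent],
    annotation: Union[AnnotationSet, AnnotationIndex],
) -> Optional[int]:
    """Unsigned bp distance to the nearest TSS on the same chromosome.

    Returns None when the chromosome carries no transcripts (the caller's
    default policy excludes such sites from medians).
    """
    index = _as_index(annotation)
    chrom = site.chrom
    pos = (
        site.representative_position
        if isinstance(site, IntegrationEvent)
        else site.position
    )
    if chrom not in index.tss or index.tss[chrom].size == 0:
        return None
    tss = index.tss[chrom]
    i = int(np.searchsorted(tss, pos))
    best = min(
        abs(pos - int(tss[j])) for j in (i - 1, i) if 0 <= j < tss.size
    )
    return best


def median_tss_distance(
    events: list[IntegrationEvent],
    annotation: Union[AnnotationSet, AnnotationIndex],
) -> Optional[float]:
    """Median nearest-TSS distance over events (transcript-less chromosomes
    excluded)."""
    index = _as_index(annotation)
    dists = [
        d
        for e in events
        if (d := nearest_tss_distance(e, index)) is not None
    ]
    if not dists:
        return None
    return float(np.median(dists))


def summarize_context(
    events: list[IntegrationEvent],
    annotation: Union[AnnotationSet, AnnotationIndex],
) -> ContextSummary:
    index = _as_index(annotation)
    return ContextSummary(
        fractions=context_fractions(events, index),
        median_tss_distance=median_tss_distance(events, index),
        n_sites=len(events),
    )


def random_control(
    events: list[IntegrationEvent],
    chrom_lengths: dict[str, int],
    seed: int = 0,
) -> list[IntegrationEvent]:
    """Matched in-silico random control.

    Each event keeps its chromosome and read tally but gets a fresh
    position drawn uniformly on that chromosome, so per-chromosome event
    counts and read counts are preserved exactly.
    """
    for e in events:
        if e.chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {e.chrom!r} in events")
    rng = np.random.default_rng(seed)
    out = []
    for e in events:
        pos = int(rng.integers(0, chrom_lengths[e.chrom]))
        out.append(IntegrationEvent(e.chrom, pos, e.read_count, [pos]))
    return out


def flank_matrix(
    events: list[IntegrationEvent],
    genome: GenomeRef,
    window: int = 10,
) -> pd.DataFrame:
    """Position-frequency matrix of bases around insertion points.

    Rows A/C/G/T, columns are offsets in [−window, +window) relative to
    the insertion point (offset 0 is the first genomic base of the
    flank). Events whose window is truncated by a chromosome end, or
    contains N, are excluded; every remaining column sums to the number
    of contributing events.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    offsets = list(range(-window, window))
    counts = pd.DataFrame(
        0, index=list("ACGT"), columns=offsets, dtype=int
    )
    n_used = 0
    for e in events:
        seq = genome.chromosomes[e.chrom]
        p = e.representative_position
        lo, hi = p - window, p + window
        if lo < 0 or hi > len(seq):
            continue
        flank = seq[lo:hi]
        if "N" in flank:
            continue
        for off, base in zip(offsets, flank):
            counts.at[base, off] += 1
        n_used += 1
    if n_used == 0 and events:
        warnings.warn(
            "flank_matrix: all events excluded (window truncated at "
            "chromosome ends or N-containing flanks)"
        )
    return counts
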