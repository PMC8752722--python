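"""Clonal clustering and outgrowth statistics.

Reads mapping to the same position ±1 nt (a tolerance for sequencing
error) are grouped into one integration event — one engineered-cell
clone. Grouping is single-linkage chaining of positions within each
chromosome, collapsed over strand, which is the only order-independent
closure of the pairwise ±1 rule. Read tallies per event estimate relative
clone abundance; the outgrowth statistics are the frequency of the top
clone and the cumulative frequency of the top-k (default 10) clones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .junctions import MappedSite


@dataclass
class IntegrationEvent:
    """A ±tolerance cluster of mapped positions: one clone."""

    chrom: str
    representative_position: int
    read_count: int
    member_positions: list[int]


@dataclass
class ClonalSummary:
    n_events: int
    top1_freq: float
    topk_cum_freq: float
    k: int = 10


def cluster_sites(
    sites: list[MappedSite], tolerance: int = 1
) -> list[IntegrationEvent]:
    """Single-linkage chaining of positions with gap ≤ tolerance.

    Strand-collapsed (insertion is a locus property). The representative
    is the modal member position, ties broken by the smaller coordinate.
    Output sorted by (chrom, representative).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_chrom: dict[str, Counter] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, Counter())[s.position] += 1
    events: list[IntegrationEvent] = []
    for chrom in by_chrom:
        tallies = by_chrom[chrom]
        positions = sorted(tallies)
        cluster: list[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > tolerance:
                events.append(_make_event(chrom, cluster, tallies))
                cluster = []
            cluster.append(pos)
        if cluster:
            events.append(_make_event(chrom, cluster, tallies))
    events.sort(key=lambda e: (e.chrom, e.representative_position))
    return events


def _make_event(chrom: str, members: list[int], tallies: Counter) -> IntegrationEvent:
    rep = max(members, key=lambda p: (tallies[p], -p))
    count = sum(tallies[p] for p in members)
    return IntegrationEvent(chrom, rep, count, list(members))


def clone_frequencies(events: list[IntegrationEvent]) -> np.ndarray:
    """Relative clone abundances from read tallies (order preserved)."""
    if not events:
        raise ValueError("no integration events: cannot compute frequencies")
    counts = np.array([e.read_count for e in events], dtype=float)
    return counts / counts.sum()


def outgrowth_stats(events: list[IntegrationEvent], k: int = 10) -> ClonalSummary:
    """Top-clone and cumulative top-k clone frequencies."""
    if not events:
        raise ValueError("no integration events: cannot compute outgrowth")
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = np.sort(clone_frequencies(events))[::-1]
    return ClonalSummary(
        n_events=len(events),
        top1_freq=float(freqs[0]),
        topk_cum_freq=float(freqs[: min(k, freqs.size)].sum()),
        k=k,
    )


def write_clones_tsv(events: list[IntegrationEvent], path) -> None:
    freqs = clone_frequencies(events) if events else []
    with open(path, "w") as fh:
        fh.write("chrom\trep_pos0\tread_count\tfreq\n")
        for e, f in zip(events, freqs):
            fh.write(
                f"{e.chrom}\t{e.representative_position}\t{e.read_count}\t"
                f"{f:.6g}\n"
            )
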