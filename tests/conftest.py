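import numpy as np
import pytest

from intsite import (
    GenomeRef,
    AnnotationSet,
    generate_genome,
    generate_annotation,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeRef:
    return generate_genome(2, [50_000, 30_000], gc_fraction=0.41, seed=101)


@pytest.fixture(scope="session")
def small_annotation(small_genome) -> AnnotationSet:
    return generate_annotation(small_genome, n_genes=12, seed=102)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)


def per_base_masks(genome: GenomeRef, annotation: AnnotationSet):
    """Mark every base as exon / transcript by direct interval painting."""
    exon = {c: np.zeros(L, dtype=bool) for c, L in genome.lengths.items()}
    tx = {c: np.zeros(L, dtype=bool) for c, L in genome.lengths.items()}
    for t in annotation.transcripts:
        tx[t.chrom][t.tx_start : t.tx_end] = True
        for s, e in t.exons:
            exon[t.chrom][s:e] = True
    return exon, tx


def genome_composition(genome: GenomeRef, annotation: AnnotationSet):
    """Brute-force (exon, non-exon transcript, non-transcript) base fractions."""
    exon, tx = per_base_masks(genome, annotation)
    total = sum(genome.lengths.values())
    n_exon = sum(m.sum() for m in exon.values())
    n_tx = sum(m.sum() for m in tx.values())
    return n_exon / total, (n_tx - n_exon) / total, 1 - n_tx / total


def brute_force_scan(fragment: str, genome: GenomeRef):
    """All exact occurrences of fragment on either strand, O(G x F)."""
    from intsite import revcomp

    hits = []
    rc = revcomp(fragment)
    k = len(fragment)
    for chrom, seq in genome.chromosomes.items():
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if window == fragment:
                hits.append((chrom, i, "+"))
            if window == rc:
                hits.append((chrom, i, "-"))
    return hits


def brute_force_clusters(positions, tolerance):
    """Connected components of the pairwise |pi - pj| <= tolerance graph,
    via an explicit adjacency matrix — independent of the chaining code."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    pos = np.asarray(positions)
    n = pos.size
    if n == 0:
        return []
    adj = np.abs(pos[:, None] - pos[None, :]) <= tolerance
    _, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = {}
    for p, lab in zip(pos, labels):
        clusters.setdefault(lab, []).append(int(p))
    return sorted(sorted(c) for c in clusters.values())
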