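"""Synthetic-data generator: determinism, composition, bias recovery."""

import numpy as np
import pytest

from intsite import (
    CloneProfile,
    SimConfig,
    TrimSpec,
    generate_annotation,
    generate_genome,
    place_integrations,
    sample_clone_abundances,
    transcript_fraction,
    trim_read,
    write_junction_fastq,
    read_fastq,
)
from intsite.simulate import CapacityError

from conftest import per_base_masks


class TestGenerateGenome:
    def test_basic_shape_and_alphabet(self):
        g = generate_genome(1, [10_000], gc_fraction=0.5, seed=42)
        assert list(g.lengths.values()) == [10_000]
        assert set(g.chromosomes["chr1"]) <= set("ACGT")

    def test_gc_zero_is_at_only(self):
        g = generate_genome(2, [5_000, 3_000], gc_fraction=0.0, seed=7)
        for seq in g.chromosomes.values():
            assert set(seq) <= set("AT")

    def test_seed_determinism(self, tmp_path):
        paths = []
        for i in (1, 2):
            g = generate_genome(2, [4_000, 2_000], gc_fraction=0.4, seed=42)
            p = tmp_path / f"g{i}.fasta"
            g.to_fasta(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, [0], 0.5, seed=0)


class TestGenerateAnnotation:
    def test_empty(self, small_genome):
        ann = generate_annotation(small_genome, n_genes=0, seed=0)
        assert ann.transcripts == []
        assert transcript_fraction(ann, small_genome) == 0.0

    def test_transcript_fraction_matches_per_base_oracle(
        self, small_genome, small_annotation
    ):
        _, tx_mask = per_base_masks(small_genome, small_annotation)
        expected = sum(m.sum() for m in tx_mask.values()) / sum(
            small_genome.lengths.values()
        )
        assert transcript_fraction(small_annotation, small_genome) == pytest.approx(
            expected, abs=1e-12
        )

    def test_genes_do_not_overlap_and_both_strands(self, small_annotation):
        by_chrom = {}
        for t in small_annotation.transcripts:
            by_chrom.setdefault(t.chrom, []).append((t.tx_start, t.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
        assert {t.strand for t in small_annotation.transcripts} == {"+", "-"}

    def test_capacity_error(self):
        tiny = generate_genome(1, [500], 0.5, seed=1)
        with pytest.raises(CapacityError):
            generate_annotation(tiny, n_genes=5, seed=1)


class TestCloneAbundances:
    def test_single_clone(self):
        assert sample_clone_abundances(1, 0.1, seed=0).abundances.tolist() == [1.0]

    def test_sums_to_one(self):
        for seed in range(5):
            prof = sample_clone_abundances(100, 2.0, seed=seed)
            assert abs(prof.abundances.sum() - 1.0) < 1e-12

    def test_even_limit_matches_monte_carlo_reference(self):
        """At very large concentration the max abundance concentrates near
        1/n; our single draw must fall within 3 sigma of a 10^4-replicate
        Monte-Carlo reference of the same Dirichlet."""
        n, conc = 1000, 1e6 * 1000
        rng = np.random.default_rng(2024)
        gammas = rng.gamma(conc / n, size=(10_000, n))
        ref_max = (gammas / gammas.sum(axis=1, keepdims=True)).max(axis=1)
        mu, sigma = ref_max.mean(), ref_max.std()
        ours = sample_clone_abundances(n, conc, seed=5).abundances.max()
        assert abs(ours - mu) < 3 * sigma
        assert ours == pytest.approx(1 / n, rel=0.01)

    def test_n_clones_validated(self):
        with pytest.raises(ValueError):
            sample_clone_abundances(0, 1.0, seed=0)


class TestPlaceIntegrations:
    def _uniform_profile(self, n):
        return CloneProfile(np.full(n, 1.0 / n))

    def test_neutral_matches_transcript_fraction(
        self, small_genome, small_annotation
    ):
        n = 2000
        truth = place_integrations(
            small_genome, small_annotation, self._uniform_profile(n),
            motif_weight=1.0, transcript_bias=1.0, seed=9,
        )
        _, tx_mask = per_base_masks(small_genome, small_annotation)
        inside = sum(
            tx_mask[s.chrom][s.position] for s in truth.sites
        )
        f = sum(m.sum() for m in tx_mask.values()) / sum(
            small_genome.lengths.values()
        )
        half_width = 2.576 * np.sqrt(f * (1 - f) / n)
        assert abs(inside / n - f) < half_width

    def test_zero_bias_excludes_transcripts(self, small_genome, small_annotation):
        truth = place_integrations(
            small_genome, small_annotation, self._uniform_profile(300),
            transcript_bias=0.0, seed=3,
        )
        _, tx_mask = per_base_masks(small_genome, small_annotation)
        assert all(not tx_mask[s.chrom][s.position] for s in truth.sites)

    def test_huge_motif_weight_forces_ta_flanks(
        self, small_genome, small_annotation
    ):
        truth = place_integrations(
            small_genome, small_annotation, self._uniform_profile(500),
            motif_weight=1e6, seed=4,
        )
        n_ta = sum(
            small_genome.chromosomes[s.chrom][s.position - 1 : s.position + 1]
            == "TA"
            for s in truth.sites
        )
        assert n_ta / 500 > 0.99

    def test_bias_recovery_is_monotone(self, small_genome, small_annotation):
        """Estimated transcript and TA-flank fractions are monotone in the
        corresponding weights (fixed-seed grid)."""
        prof = self._uniform_profile(500)
        _, tx_mask = per_base_masks(small_genome, small_annotation)
        tx_fracs = []
        for bias in (0.5, 1.0, 2.0, 5.0):
            t = place_integrations(
                small_genome, small_annotation, prof,
                transcript_bias=bias, seed=7,
            )
            tx_fracs.append(
                sum(tx_mask[s.chrom][s.position] for s in t.sites) / 500
            )
        assert tx_fracs == sorted(tx_fracs)
        ta_fracs = []
        for mw in (1.0, 5.0, 50.0, 1e6):
            t = place_integrations(
                small_genome, small_annotation, prof,
                motif_weight=mw, seed=7,
            )
            ta_fracs.append(
                sum(
                    small_genome.chromosomes[s.chrom][
                        s.position - 1 : s.position + 1
                    ]
                    == "TA"
                    for s in t.sites
                )
                / 500
            )
        assert ta_fracs == sorted(ta_fracs)

    def test_min_separation(self, small_genome, small_annotation):
        truth = place_integrations(
            small_genome, small_annotation, self._uniform_profile(200),
            seed=8, min_separation=2,
        )
        by_chrom = {}
        for s in truth.sites:
            by_chrom.setdefault(s.chrom, []).append(s.position)
        for positions in by_chrom.values():
            positions.sort()
            assert all(b - a > 2 for a, b in zip(positions, positions[1:]))


@pytest.fixture(scope="module")
def sim_outputs(small_genome, small_annotation, tmp_path_factory):
    prof = sample_clone_abundances(20, 50.0, seed=21)
    truth = place_integrations(
        small_genome, small_annotation, prof, seed=22, min_separation=2
    )
    cfg = SimConfig(seed=23, reads_total=800)
    out = tmp_path_factory.mktemp("fastq")
    fq, tt = write_junction_fastq(truth, small_genome, cfg, out)
    return truth, cfg, fq, tt


class TestJunctionFastq:

    def test_record_count(self, sim_outputs):
        _, cfg, fq, _ = sim_outputs
        assert sum(1 for _ in read_fastq(fq)) == cfg.reads_total

    def test_error_free_reads_are_exact_genome_substrings(
        self, small_genome, sim_outputs
    ):
        truth, cfg, fq, _ = sim_outputs
        by_clone = {f"clone{s.clone_id}": s for s in truth.sites}
        spec = TrimSpec(cfg.barcode_seq, cfg.transposon_end_seq, min_len=1)
        from intsite import revcomp

        for read in read_fastq(fq):
            site = by_clone[read.id.split("_")[1]]
            frag = trim_read(read, spec).fragment
            seq = small_genome.chromosomes[site.chrom]
            if site.strand == "+":
                assert seq[site.position : site.position + len(frag)] == frag
            else:
                expected = revcomp(
                    seq[site.position - len(frag) + 1 : site.position + 1]
                )
                assert expected == frag

    def test_clone_counts_within_binomial_3sigma(
        self, small_genome, small_annotation, tmp_path
    ):
        prof = CloneProfile(np.array([0.9, 0.1]))
        truth = place_integrations(
            small_genome, small_annotation, prof, seed=31, min_separation=2
        )
        cfg = SimConfig(seed=32, reads_total=10_000)
        _, tt = write_junction_fastq(truth, small_genome, cfg, tmp_path)
        import pandas as pd

        counts = pd.read_csv(tt, sep="\t").set_index("clone_id")["n_reads"]
        sigma = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(counts.loc[0] - 9000) < 3 * sigma

    def test_byte_identical_under_same_seed(
        self, small_genome, small_annotation, tmp_path
    ):
        prof = sample_clone_abundances(10, 5.0, seed=41)
        truth = place_integrations(
            small_genome, small_annotation, prof, seed=42
        )
        cfg = SimConfig(seed=43, reads_total=300, error_rate=0.01)
        fq1, tt1 = write_junction_fastq(
            truth, small_genome, cfg, tmp_path / "a"
        )
        fq2, tt2 = write_junction_fastq(
            truth, small_genome, cfg, tmp_path / "b"
        )
        assert fq1.read_bytes() == fq2.read_bytes()
        assert tt1.read_bytes() == tt2.read_bytes()

    def test_read_len_too_short_rejected(self, small_genome, small_annotation):
        prof = sample_clone_abundances(3, 5.0, seed=1)
        truth = place_integrations(small_genome, small_annotation, prof, seed=2)
        with pytest.raises(ValueError):
            write_junction_fastq(
                truth, small_genome, SimConfig(read_len=10), "/tmp/never"
            )
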