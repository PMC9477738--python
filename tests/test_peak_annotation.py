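"""Peak-gene assignment geometry, metagene profiles and the randomized null."""

import numpy as np
import pytest

from cobind.io_formats import GeneModel, GenomicInterval, Peak
from cobind.peak_annotation import (
    AnnotationConfig,
    assign_peaks_to_genes,
    metagene_profile,
    random_peak_null,
    sample_uniform_peaks,
)


def _peak(pid, center, length=100, chrom="c"):
    start = center - length // 2
    return Peak(pid, GenomicInterval(chrom, start, start + length))


def _gene(gid, start, end, strand, chrom="c"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


class TestAssignment:
    def test_upstream_boundary_inclusive(self):
        genes = [_gene("g", 5000, 7000, "+")]
        (link,) = assign_peaks_to_genes([_peak("p", 2000)], genes)
        assert link.category == "upstream" and link.signed_distance == -3000

    def test_just_outside_window_not_linked(self):
        genes = [_gene("g", 5000, 7000, "+")]
        assert assign_peaks_to_genes([_peak("p", 1999)], genes) == []

    def test_minus_strand_upstream_lies_right_of_gene(self):
        genes = [_gene("g", 5000, 7000, "-")]  # TSS at 6999
        (link,) = assign_peaks_to_genes([_peak("p", 7500)], genes)
        assert link.category == "upstream" and link.signed_distance == -501

    def test_genic_and_downstream_categories(self):
        genes = [_gene("g", 5000, 7000, "+")]
        (genic,) = assign_peaks_to_genes([_peak("p1", 6000)], genes)
        (down,) = assign_peaks_to_genes([_peak("p2", 7500)], genes)
        assert genic.category == "genic" and down.category == "downstream"
        assert down.signed_distance == 2500  # anchor -> TSS, positive inside/3'

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        genes = [_gene("g", 5000, 7000, "+")]
        with caplog.at_level("WARNING"):
            links = assign_peaks_to_genes([_peak("p", 6000, chrom="other")], genes)
        assert links == [] and "skipped 1" in caplog.text

    def test_invariant_under_list_permutations(self):
        rng = np.random.default_rng(0)
        genes = [
            _gene(f"g{i}", s, s + 1500, "+" if i % 2 else "-")
            for i, s in enumerate(range(0, 90_000, 9000))
        ]
        peaks = [_peak(f"p{i}", int(rng.integers(100, 95_000))) for i in range(60)]
        ref = {(l.peak_id, l.gene_id, l.category, l.signed_distance)
               for l in assign_peaks_to_genes(peaks, genes)}
        rng.shuffle(peaks)
        rng.shuffle(genes)
        perm = {(l.peak_id, l.gene_id, l.category, l.signed_distance)
                for l in assign_peaks_to_genes(peaks, genes)}
        assert ref == perm

    def test_reflection_preserves_categories_and_distances(self):
        rng = np.random.default_rng(1)
        L = 100_000
        genes = [
            _gene(f"g{i}", s, s + 1200, "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(range(500, 90_000, 6000))
        ]
        # odd peak length: the center is a reflection fixed point, so the
        # mirror invariant is exact
        peaks = [_peak(f"p{i}", int(rng.integers(200, L - 200)), length=101)
                 for i in range(80)]

        def reflect_gene(g):
            iv = g.interval
            return GeneModel(
                g.id,
                GenomicInterval(iv.chrom, L - iv.end, L - iv.start,
                                "-" if iv.strand == "+" else "+"),
            )

        def reflect_peak(p):
            iv = p.interval
            return Peak(p.id, GenomicInterval(iv.chrom, L - iv.end, L - iv.start))

        fwd = {(l.peak_id, l.gene_id): (l.category, abs(l.signed_distance))
               for l in assign_peaks_to_genes(peaks, genes)}
        mirrored = {(l.peak_id, l.gene_id): (l.category, abs(l.signed_distance))
                    for l in assign_peaks_to_genes(
                        [reflect_peak(p) for p in peaks],
                        [reflect_gene(g) for g in genes])}
        assert fwd == mirrored

    def test_matches_bruteforce_window_logic(self):
        rng = np.random.default_rng(7)
        cfg = AnnotationConfig()
        genes = [
            _gene(f"g{i}", int(s), int(s) + int(rng.integers(500, 2500)),
                  "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(range(1000, 80_000, 5000))
        ]
        peaks = [_peak(f"p{i}", int(rng.integers(100, 90_000))) for i in range(150)]
        expected = set()
        for p in peaks:
            a = p.center
            for g in genes:
                sign = 1 if g.interval.strand == "+" else -1
                d_tss = (a - g.tss) * sign
                d_tes = (a - g.tes) * sign
                if -cfg.upstream_window <= d_tss and d_tes <= cfg.downstream_window:
                    cat = "upstream" if d_tss < 0 else ("downstream" if d_tes > 0 else "genic")
                    expected.add((p.id, g.id, cat, d_tss))
        got = {(l.peak_id, l.gene_id, l.category, l.signed_distance)
               for l in assign_peaks_to_genes(peaks, genes, cfg)}
        assert got == expected


class TestMetagene:
    def test_peak_at_tss_lands_in_bin_containing_zero(self):
        genes = [_gene("g", 5000, 7000, "+")]
        prof = metagene_profile([_peak("p", 5000)], genes, bins=50)
        idx = np.digitize(0.0, prof.bin_edges) - 1
        assert prof.observed_density[idx] == 1.0
        assert prof.observed_density.sum() == 1.0

    def test_multi_linked_peak_counted_once_per_link(self):
        # divergent promoters flanking one peak
        genes = [_gene("gl", 1000, 2000, "-"), _gene("gr", 4000, 5000, "+")]
        prof = metagene_profile([_peak("p", 3000)], genes)
        assert prof.n_links == 2
        assert prof.observed_density.sum() == pytest.approx(2.0)

    def test_no_links_warns_and_returns_zeros(self, caplog):
        genes = [_gene("g", 50_000, 52_000, "+")]
        with caplog.at_level("WARNING"):
            prof = metagene_profile([_peak("p", 1000)], genes)
        assert prof.n_links == 0 and prof.observed_density.sum() == 0.0


class TestNullEnvelope:
    def _setup(self):
        rng = np.random.default_rng(2)
        genes = [
            _gene(f"g{i}", s, s + 1500, "+" if i % 2 else "-")
            for i, s in enumerate(range(2000, 180_000, 9000))
        ]
        peaks = [_peak(f"p{i}", int(rng.integers(300, 195_000)),
                       length=int(rng.integers(80, 400))) for i in range(150)]
        return peaks, {"c": 200_000}, genes

    def test_deterministic_given_seed(self):
        peaks, cs, genes = self._setup()
        a = random_peak_null(peaks, cs, genes, n_sets=5, seed=42)
        b = random_peak_null(peaks, cs, genes, n_sets=5, seed=42)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.hi95, b.hi95)
        c = random_peak_null(peaks, cs, genes, n_sets=5, seed=43)
        assert not np.array_equal(a.mean, c.mean)

    def test_envelope_orders_lo_mean_hi(self):
        peaks, cs, genes = self._setup()
        env = random_peak_null(peaks, cs, genes, n_sets=200, seed=3)
        assert (env.lo95 <= env.mean + 1e-12).all()
        assert (env.mean <= env.hi95 + 1e-12).all()

    def test_placements_keep_length_multiset_and_fit(self):
        rng = np.random.default_rng(0)
        lengths = [100, 250, 4000, 60]
        cs = {"a": 5000, "b": 3000}
        for _ in range(50):
            placed = sample_uniform_peaks(lengths, cs, rng)
            assert sorted(p.length for p in placed) == sorted(lengths)
            for p in placed:
                assert 0 <= p.interval.start and p.interval.end <= cs[p.interval.chrom]

    def test_peak_longer_than_every_chromosome_rejected(self):
        with pytest.raises(ValueError, match="longer than every chromosome"):
            sample_uniform_peaks([10_000], {"a": 5000}, np.random.default_rng(0))
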