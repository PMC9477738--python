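"""Generator contracts: determinism, degenerate configs, planted-truth fidelity."""

import numpy as np
import pytest

from cobind.io_formats import GenomicInterval, Peak
from cobind.motif_architecture import MotifSpec, scan_motif
from cobind.synthetic_data import (
    DEGPlan,
    MotifPlan,
    SimConfig,
    TruthBundle,
    generate_genome,
    generate_peaks,
    plant_motifs,
    simulate_all,
    simulate_counts,
    simulate_deg_tables,
    verify_truth,
    _rng_streams,
)


def _streams(cfg):
    return _rng_streams(cfg.seed)


class TestGenome:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_length=30_000, n_genes=20, n_peaks=30,
                n_cooperative=3, n_shared_degs=5,
                deg_plans={"pif4": DEGPlan(n_deg=8), "cdfq": DEGPlan(n_deg=8)})
        a = simulate_all(cfg)
        b = simulate_all(cfg)
        assert a.genome == b.genome
        assert a.genes == b.genes
        assert a.counts.counts.equals(b.counts.counts)
        assert a.truth.to_json() == b.truth.to_json()

    def test_degenerate_composition_gives_monobase_genome(self):
        cfg = SimConfig(
            seed=0, n_chrom=1, chrom_length=5000, n_genes=3,
            base_composition=(1.0, 0.0, 0.0, 0.0),
        )
        genome, _ = generate_genome(cfg)
        assert set(genome["chr1"]) == {"A"}

    def test_overfull_genome_raises_placement_error(self):
        cfg = SimConfig(
            seed=0, n_chrom=1, chrom_length=3000, n_genes=10,
            gene_length_range=(500, 800),
        )
        with pytest.raises(ValueError, match="longer chromosomes"):
            generate_genome(cfg)

    def test_genes_do_not_overlap(self, default_sim):
        by_chrom = {}
        for g in default_sim.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


class TestPeaks:
    def test_promoter_fraction_one_puts_every_center_upstream(self):
        cfg = SimConfig(seed=2, n_peaks=100, promoter_fraction=1.0)
        streams = _streams(cfg)
        genome, genes = generate_genome(cfg, streams["genome"], streams["genes"])
        cs = {c: len(s) for c, s in genome.items()}
        peaks, prom = generate_peaks(cfg, genes, cs, streams["peaks"])
        assert set(prom) == {p.id for p in peaks}
        gene_by_id = {g.id: g for g in genes}
        for p in peaks:
            g = gene_by_id[prom[p.id]]
            sign = 1 if g.interval.strand == "+" else -1
            d = (p.center - g.tss) * sign
            assert -cfg.promoter_window <= d <= -1

    def test_promoter_fraction_zero_centers_look_uniform(self):
        from scipy import stats

        cfg = SimConfig(seed=4, n_peaks=1000, promoter_fraction=0.0)
        streams = _streams(cfg)
        genome, genes = generate_genome(cfg, streams["genome"], streams["genes"])
        cs = {c: len(s) for c, s in genome.items()}
        peaks, prom = generate_peaks(cfg, genes, cs, streams["peaks"])
        assert prom == {}
        rel = [p.center / cs[p.interval.chrom] for p in peaks]
        assert stats.kstest(rel, "uniform").pvalue > 0.01

    def test_zero_length_sd_gives_constant_lengths(self):
        cfg = SimConfig(seed=1, n_peaks=40, peak_length_sd=0.0)
        streams = _streams(cfg)
        genome, genes = generate_genome(cfg, streams["genome"], streams["genes"])
        cs = {c: len(s) for c, s in genome.items()}
        peaks, _ = generate_peaks(cfg, genes, cs, streams["peaks"])
        assert {p.length for p in peaks} == {int(cfg.peak_length_mean)}


class TestPlanting:
    def test_exact_plan_constant_spacing(self):
        plan = MotifPlan("gbox", "CACGTG", (0.0, 0.0, 1.0, 0.0), 25.0, 0.0)
        cfg = SimConfig(
            seed=9, n_chrom=1, chrom_length=60_000, n_genes=10, n_peaks=20,
            motif_plans=(plan,), n_cooperative=2, n_shared_degs=3,
            deg_plans={"pif4": DEGPlan(n_deg=5), "cdfq": DEGPlan(n_deg=5)},
        )
        sim = simulate_all(cfg)
        spec = MotifSpec("gbox", "CACGTG")
        for p in sim.peaks:
            iv = p.interval
            seq = sim.genome[iv.chrom][iv.start : iv.end]
            offs = sorted(h.offset for h in scan_motif(seq, spec, p.id))
            assert len(offs) == 2 and offs[1] - offs[0] == 25

    def test_zero_count_plan_leaves_no_hits(self):
        plan = MotifPlan("dof", "AAAAG", (1.0, 0.0, 0.0, 0.0), 15.0, 4.0)
        cfg = SimConfig(
            seed=9, n_chrom=1, chrom_length=50_000, n_genes=10, n_peaks=15,
            motif_plans=(plan,), base_composition=(0.0, 1.0, 0.0, 0.0),
        )
        streams = _streams(cfg)
        genome, genes = generate_genome(cfg, streams["genome"], streams["genes"])
        cs = {c: len(s) for c, s in genome.items()}
        peaks, _ = generate_peaks(cfg, genes, cs, streams["peaks"])
        genome, truth = plant_motifs(genome, peaks, cfg, streams["motifs"])
        for p in peaks:
            iv = p.interval
            seq = genome[iv.chrom][iv.start : iv.end]
            assert scan_motif(seq, MotifSpec("dof", "AAAAG"), p.id) == []

    def test_truth_matches_rescan_on_default_dataset(self, default_sim):
        assert verify_truth(default_sim) == []

    def test_impossible_plan_names_the_peak(self):
        plan = MotifPlan("wide", "CACGTG" * 20, (0.0, 0.0, 0.0, 1.0), 130.0, 0.0)
        cfg = SimConfig(
            seed=3, n_chrom=1, chrom_length=50_000, n_genes=5, n_peaks=5,
            peak_length_mean=100.0, peak_length_sd=0.0, motif_plans=(plan,),
        )
        streams = _streams(cfg)
        genome, genes = generate_genome(cfg, streams["genome"], streams["genes"])
        cs = {c: len(s) for c, s in genome.items()}
        peaks, _ = generate_peaks(cfg, genes, cs, streams["peaks"])
        with pytest.raises(ValueError, match="peak_0001"):
            plant_motifs(genome, peaks, cfg, streams["motifs"])


def _manual_peaks(n, length=5, gap=10):
    return [
        Peak(f"p{i}", GenomicInterval("c", i * (length + gap), i * (length + gap) + length))
        for i in range(n)
    ]


class TestCounts:
    def test_dispersion_zero_is_poisson_like(self):
        peaks = _manual_peaks(10_000)
        truth = TruthBundle()
        cfg = SimConfig(seed=6, affected_fraction=0.0, nb_dispersion=0.0)
        cm = simulate_counts(peaks, cfg, truth)
        for s in cm.col_ids[:2]:
            col = cm.counts[s].to_numpy()
            assert 0.9 < col.var() / col.mean() < 1.15

    def test_positive_dispersion_is_overdispersed(self):
        peaks = _manual_peaks(10_000)
        cfg = SimConfig(seed=6, affected_fraction=0.0, nb_dispersion=0.1)
        cm = simulate_counts(peaks, cfg, TruthBundle())
        col = cm.counts[cm.col_ids[0]].to_numpy()
        # var/mean for NB is 1 + dispersion * mean ~ 11 at mean 100
        assert col.var() / col.mean() > 5

    def test_zero_effect_equals_zero_affected_fraction(self):
        peaks = _manual_peaks(500)
        truth = TruthBundle()
        for p in peaks:
            truth.gbox_count[p.id] = 1
        cfg_a = SimConfig(seed=8, affected_fraction=0.0)
        cfg_b = SimConfig(seed=8, affected_fraction=0.3, effect_log2fc=0.0)
        cm_a = simulate_counts(peaks, cfg_a, TruthBundle(), np.random.default_rng(5))
        cm_b = simulate_counts(peaks, cfg_b, truth, np.random.default_rng(5))
        assert cm_a.counts.equals(cm_b.counts)

    def test_affected_peaks_prefer_gbox_carriers(self):
        peaks = _manual_peaks(1000)
        truth = TruthBundle()
        for i, p in enumerate(peaks):
            truth.gbox_count[p.id] = 1 if i < 300 else 0
        cfg = SimConfig(seed=2, affected_fraction=0.1)
        simulate_counts(peaks, cfg, truth)
        assert all(truth.gbox_count[pid] >= 1 for pid in truth.affected_peaks)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_counts(_manual_peaks(5), SimConfig(n_replicates=1), TruthBundle())


class TestDEGTables:
    def _genes(self, n):
        from cobind.io_formats import GeneModel

        return [
            GeneModel(f"g{i:03d}", GenomicInterval("c", i * 100, i * 100 + 50, "+"))
            for i in range(n)
        ]

    def test_requested_overlap_larger_than_set_rejected(self):
        genes = self._genes(100)
        cfg = SimConfig(
            n_shared_degs=30,
            deg_plans={"a": DEGPlan(n_deg=20), "b": DEGPlan(n_deg=40)},
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_deg_tables(genes, cfg, TruthBundle(), set())

    def test_all_up_no_opposition(self):
        genes = self._genes(200)
        cfg = SimConfig(
            n_shared_degs=20,
            frac_opposite=0.0,
            deg_plans={"a": DEGPlan(n_deg=40, frac_up=1.0), "b": DEGPlan(n_deg=40, frac_up=1.0)},
        )
        truth = TruthBundle()
        simulate_deg_tables(genes, cfg, truth, set())
        da, db = truth.deg_sets["a"], truth.deg_sets["b"]
        shared = set(da) & set(db)
        assert len(shared) == 20
        assert all(da[g] == db[g] for g in shared)
        assert all(d == 1 for d in da.values())

    def test_planted_opposite_fraction_recovered(self):
        from cobind.coregulation import direction_consistency

        genes = self._genes(600)
        cfg = SimConfig(
            seed=13,
            n_shared_degs=200,
            frac_opposite=0.1,
            deg_plans={"a": DEGPlan(n_deg=250), "b": DEGPlan(n_deg=250)},
        )
        truth = TruthBundle()
        simulate_deg_tables(genes, cfg, truth, set())
        dc = direction_consistency(truth.deg_sets["a"], truth.deg_sets["b"])
        # binomial 99% interval around 0.1 at n=200
        assert abs(dc.fraction_opposite - 0.1) < 2.6 * np.sqrt(0.1 * 0.9 / 200)

    def test_zero_cooperative_plan_gives_empty_truth(self):
        cfg = SimConfig(seed=3, n_cooperative=0, n_chrom=1, chrom_length=200_000,
                        n_genes=100, n_peaks=150, n_shared_degs=10,
                        deg_plans={"pif4": DEGPlan(n_deg=25), "cdfq": DEGPlan(n_deg=25)})
        sim = simulate_all(cfg)
        assert sim.truth.cooperative_genes == []

    def test_deg_tables_honor_the_filter_boundary(self, default_sim):
        from cobind.coregulation import DEGFilterConfig, filter_degs

        for gt, table in default_sim.deg_tables.items():
            recovered = filter_degs(table, DEGFilterConfig())
            assert set(recovered) == set(default_sim.truth.deg_sets[gt])
            assert recovered == default_sim.truth.deg_sets[gt]


class TestOutputs:
    def test_written_files_reload_identically(self, default_sim, tmp_path):
        from cobind.io_formats import (
            read_count_matrix,
            read_fasta,
            read_genes,
            read_peaks,
        )
        from cobind.synthetic_data import write_outputs

        paths = write_outputs(default_sim, tmp_path)
        assert read_fasta(paths["genome"]) == default_sim.genome
        assert read_genes(paths["genes"]) == default_sim.genes
        back = read_peaks(paths["peaks"], "narrowPeak")
        assert [(p.id, p.interval, p.summit_offset) for p in back] == [
            (p.id, p.interval, p.summit_offset) for p in default_sim.peaks
        ]
        assert np.allclose(
            [p.score for p in back], [p.score for p in default_sim.peaks], rtol=1e-5
        )
        cm = read_count_matrix(paths["counts"])
        assert cm.counts.equals(default_sim.counts.counts)
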