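"""Synthetic-data generator: determinism, composition, segregation models."""

import numpy as np
import pytest

from panelforge import io
from panelforge.genome import KmerIndex
from panelforge.models import SourceClass
from panelforge.simulate import (
    IntensityModel,
    PopulationSpec,
    SimScenario,
    simulate_genome,
    simulate_intensities,
    simulate_population_calls,
    simulate_variants,
)


class TestGenome:
    def test_same_seed_identical_fasta(self, tmp_path):
        sc = SimScenario(rng_seed=9, n_contigs=20)
        g1, g2 = simulate_genome(sc), simulate_genome(sc)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        io.write_fasta(g1, p1)
        io.write_fasta(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gc_matches_background(self):
        sc = SimScenario(rng_seed=3, n_contigs=40, gc_background=0.5,
                         repeat_fraction=0.0)
        g = simulate_genome(sc)
        seq = "".join(c.seq for c in g.contigs.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(0.25 / len(seq))
        assert abs(gc - 0.5) <= 3 * se

    def test_no_repeats_means_unique_kmers(self):
        sc = SimScenario(rng_seed=4, n_contigs=20, repeat_fraction=0.0)
        g = simulate_genome(sc)
        idx = KmerIndex.from_genome(g, 16)
        dup_rate = sum(1 for v in idx.counts.values() if v > 1) / len(idx.counts)
        assert dup_rate < 0.01

    def test_repeat_fraction_masks_duplicated_segments(self):
        sc = SimScenario(rng_seed=4, n_contigs=20, repeat_fraction=0.05)
        g = simulate_genome(sc)
        masked = sum(int(c.mask.sum()) for c in g.contigs.values())
        total = g.total_length()
        assert masked / total == pytest.approx(0.05, rel=0.4)


class TestVariants:
    def test_density_within_poisson_error(self):
        sc = SimScenario(rng_seed=6, n_contigs=100, snp_density_per_kb=1.0,
                         repeat_fraction=0.0)
        g = simulate_genome(sc)
        cands, _, _ = simulate_variants(g, sc)
        lam = g.total_length() / 1000.0
        assert abs(len(cands) - lam) <= 3 * np.sqrt(lam)

    def test_tstv_ratio_recovered(self):
        sc = SimScenario(rng_seed=7, n_contigs=120, snp_density_per_kb=5.0,
                         tstv_ratio=1.85)
        g = simulate_genome(sc)
        cands, _, truth = simulate_variants(g, sc)
        assert len(cands) > 1500
        n_ts = int(truth["is_transition"].sum())
        n_tv = len(truth) - n_ts
        p = 1.85 / 2.85
        se = np.sqrt(p * (1 - p) / len(truth))
        assert abs(n_ts / len(truth) - p) <= 3 * se
        assert n_ts / n_tv == pytest.approx(1.85, rel=0.15)

    def test_truth_table_matches_candidates(self):
        sc = SimScenario(rng_seed=8, n_contigs=30)
        g = simulate_genome(sc)
        cands, others, truth = simulate_variants(g, sc)
        assert len(truth) == len(cands)
        for c, row in zip(cands, truth.itertuples(index=False)):
            assert c.snp_id == row.snp_id
            assert g[c.contig_id].seq[c.pos] == c.ref_allele
            assert c.is_transition == row.is_transition

    def test_indels_exercise_exclusion_filter(self):
        """A candidate within the exclusion window of an indel fails the
        nearby-variant rule downstream."""
        from panelforge.filtering import FilterRule, run_filters

        sc = SimScenario(rng_seed=12, n_contigs=40, indel_density_per_kb=0.5)
        g = simulate_genome(sc)
        cands, others, _ = simulate_variants(g, sc)
        near = [
            c for c in cands
            if any(ctg == c.contig_id and abs(pos - c.pos) <= 30
                   for ctg, pos, _, _ in others)
        ]
        assert near, "scenario should place some candidate near an indel"
        outcomes = {o.snp_id: o for o in run_filters(
            cands, [(ctg, pos) for ctg, pos, _, _ in others], g
        )}
        for c in near:
            assert FilterRule.NEARBY_VARIANT in outcomes[c.snp_id].failed_rules


class TestPopulations:
    def _scenario(self, pop):
        return SimScenario(rng_seed=13, populations=[pop])

    def _snps(self, n=300, source=SourceClass.ANONYMOUS):
        from panelforge.models import SnpCandidate

        return [SnpCandidate(f"m{i}", "c", 100 + i, "A", "G", source_class=source)
                for i in range(n)]

    def test_backcross_interspecific_has_no_minor_hom(self):
        pop = PopulationSpec(name="bc", model="backcross_like",
                             fixed_diff_fraction=1.0, n_samples=200)
        snps = self._snps(source=SourceClass.GENE_INTERSPECIFIC)
        geno, truth = simulate_population_calls(snps, pop, self._scenario(pop))
        assert truth["is_fixed_diff"].all()
        assert (geno.to_numpy() != 0).all()  # dosage 0 = minor homozygote
        het = (geno.to_numpy() == 1).mean()
        assert het == pytest.approx(0.5, abs=0.02)  # 1:1 AA/AB segregation

    def test_random_mating_het_fraction_at_half(self):
        pop = PopulationSpec(name="w", model="random_mating",
                             maf_min=0.5, maf_max=0.5, n_samples=1000)
        snps = self._snps(n=50)
        geno, _ = simulate_population_calls(snps, pop, self._scenario(pop))
        het = (geno.to_numpy() == 1).mean()
        se = np.sqrt(0.25 / geno.size)
        assert abs(het - 0.5) <= 4 * se

    def test_monomorphic_override(self):
        pop = PopulationSpec(
            name="w", model="random_mating", n_samples=100,
            class_monomorphic_fraction={SourceClass.GENE_BLUE.value: 1.0},
        )
        snps = self._snps(n=80, source=SourceClass.GENE_BLUE)
        geno, truth = simulate_population_calls(snps, pop, self._scenario(pop))
        assert (geno.to_numpy() == 2).all()
        assert (truth["freq_a"] == 1.0).all()


class TestIntensities:
    def test_zero_noise_recovers_truth_exactly(self):
        from panelforge.genotyping import transform_intensities

        pop = PopulationSpec(name="w", n_samples=40, bad_sample_fraction=0.0)
        sc = SimScenario(
            rng_seed=14, populations=[pop],
            intensity=IntensityModel(cluster_sd=1e-6, strength_sd=1e-6,
                                     nc_rate=0.0, otv_fraction=0.0),
        )
        from panelforge.pipeline import make_recovery_inputs

        manifest, intensity, geno, _, _ = make_recovery_inputs(
            seed=14, n_snps=30, n_samples=40, cluster_sd=1e-6, nc_rate=0.0
        )
        contrast, _ = transform_intensities(intensity["signal_a"],
                                            intensity["signal_b"])
        intensity = intensity.assign(contrast=contrast)
        mu = sc.intensity.contrast_mu
        for snp in manifest.snps:
            rows = intensity[intensity.probe_id == f"{snp.snp_id}_F"]
            expected = mu * (geno[snp.snp_id].loc[rows.sample_id].to_numpy() - 1.0)
            assert np.allclose(rows.contrast.to_numpy(), expected, atol=1e-3)

    def test_bad_sample_fraction_fails_dqc(self):
        from panelforge.genotyping import call_dataset
        from panelforge.pipeline import make_recovery_inputs

        manifest, _, _, scenario, _ = make_recovery_inputs(
            seed=15, n_snps=30, n_samples=192
        )
        pop = PopulationSpec(name="w", n_samples=192, bad_sample_fraction=0.06)
        geno, _ = simulate_population_calls(manifest.snps, pop, scenario)
        intensity, truth = simulate_intensities(geno, manifest, pop, scenario)
        n_bad = len(truth["bad_samples"])
        se = np.sqrt(192 * 0.06 * 0.94)
        assert abs(n_bad - 192 * 0.06) <= 3 * se
        cs = call_dataset(intensity, manifest)
        qc = cs.sample_qc.set_index("sample_id")
        assert (qc.loc[truth["bad_samples"], "dqc"] < 0.82).all()
        good = qc.drop(index=truth["bad_samples"])
        assert (good["dqc"] >= 0.9).all()

    def test_nc_rate_drops_rows(self):
        from panelforge.pipeline import make_recovery_inputs

        m0, full, _, _, _ = make_recovery_inputs(seed=16, n_snps=50,
                                                 n_samples=50, nc_rate=0.0)
        m1, dropped, _, _, _ = make_recovery_inputs(seed=16, n_snps=50,
                                                    n_samples=50, nc_rate=0.1)
        n_snp_rows_full = (~full.probe_id.str.startswith("rqc")).sum()
        n_snp_rows_drop = (~dropped.probe_id.str.startswith("rqc")).sum()
        frac = 1 - n_snp_rows_drop / n_snp_rows_full
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_otv_fraction_flagged_within_3se(self):
        """Closed loop: ~5% of probesets carry the off-target signature and
        the classifier flags them (recall is high, false positives rare)."""
        from panelforge.genotyping import call_dataset
        from panelforge.models import SnpCategory
        from panelforge.pipeline import make_recovery_inputs

        manifest, intensity, _, _, truth = make_recovery_inputs(
            seed=17, n_snps=300, n_samples=120, otv_fraction=0.05
        )
        cs = call_dataset(intensity, manifest)
        flagged = {s for s, c in cs.snp_category.items() if c is SnpCategory.OTV}
        expected = 0.05 * 300
        se = np.sqrt(300 * 0.05 * 0.95)
        assert abs(len(flagged) - expected) <= 3 * se
        assert len(flagged - truth["otv_snps"]) <= 3  # few false positives


class TestEndToEndDeterminism:
    def test_same_seed_reproduces_scenario_run(self, tmp_path):
        from panelforge.pipeline import run_scenario
        from panelforge.reports import render_reports

        sc = SimScenario(rng_seed=21, n_contigs=25, qc_probes_per_class=20,
                         populations=[PopulationSpec(name="w", n_samples=24,
                                                     bad_sample_fraction=0.0)])
        paths1 = render_reports(run_scenario(sc), tmp_path / "r1")
        paths2 = render_reports(run_scenario(sc), tmp_path / "r2")
        assert set(paths1) == set(paths2)
        for name in paths1:
            assert paths1[name].read_bytes() == paths2[name].read_bytes(), name
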