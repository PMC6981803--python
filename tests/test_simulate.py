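"""Synthetic-data generator: determinism, structure, planted truth."""

import numpy as np
import pandas as pd
import pytest

from soyqtl.genome import ConfigError, PlantedQtl, default_genome
from soyqtl.simulate import (select_bulks, simulate_germplasm,
                             simulate_phenotypes, simulate_pools,
                             simulate_population)


class TestSimulatePopulation:
    def test_line_and_segment_counts(self, default_population):
        pop = default_population
        assert pop.n_lines == 208
        for line_id in pop.line_ids:
            assert 1 <= len(pop.segments(line_id)) <= 3

    def test_deterministic_for_fixed_seed(self, small_genome):
        kw = dict(segment_length=(2_000_000, 8_000_000), seed=5)
        a = simulate_population(small_genome, 20, **kw)
        b = simulate_population(small_genome, 20, **kw)
        assert a.to_dict() == b.to_dict()
        c = simulate_population(small_genome, 20,
                                segment_length=(2_000_000, 8_000_000),
                                seed=6)
        assert a.to_dict() != c.to_dict()

    def test_single_line_dosage_only_inside_segment(self, small_genome):
        pop = simulate_population(small_genome, 2, segments_per_line=(1, 1),
                                  segment_length=(2_000_000, 2_000_000),
                                  seed=0)
        line = pop.line_ids[0]
        (seg,) = pop.segments(line)
        assert pop.dosage(line, seg.chrom, seg.start) == 1
        assert pop.dosage(line, seg.chrom, seg.end) == 1
        if seg.start > 1:
            assert pop.dosage(line, seg.chrom, seg.start - 1) == 0
        other = [c for c in small_genome.names if c != seg.chrom][0]
        assert pop.dosage(line, other, 1_000_000) == 0

    def test_segment_bounds_validation(self, small_genome):
        with pytest.raises(ConfigError):
            simulate_population(small_genome, 10,
                                segment_length=(1_000, 40_000_000), seed=0)
        with pytest.raises(ConfigError):
            simulate_population(small_genome, 1, seed=0)

    def test_dosage_matrix_matches_brute_force(self, small_population):
        pop = small_population
        positions = {"Gm01": [5_000_000, 15_000_000],
                     "Gm03": [1, 29_999_999]}
        dm = pop.dosage_matrix(positions)
        for col in dm.columns:
            chrom, pos = col.split(":")
            expected = [pop.dosage(l, chrom, int(pos))
                        for l in pop.line_ids]
            assert list(dm[col]) == expected


class TestSimulatePhenotypes:
    def test_noise_free_values_are_exact(self, small_population):
        # carrier class differs from non-carriers by 2a (additive convention)
        pop = small_population
        q = PlantedQtl("Gm01", 10_000_000, 2.0, "T")
        ph = simulate_phenotypes(pop, [q], years=2, reps=2, year_sd=0.0,
                                 resid_sd=0.0, grand_mean=50.0, seed=1)
        means = ph.groupby("line_id")["value"].mean()
        for line in pop.line_ids:
            dose = pop.dosage(line, q.chrom, q.pos)
            assert means[line] == pytest.approx(50.0 + 2.0 * 2.0 * dose)

    def test_two_qtl_effects_are_additive(self, small_population):
        pop = small_population
        qa = PlantedQtl("Gm01", 10_000_000, 3.0, "T")
        qb = PlantedQtl("Gm02", 10_000_000, -1.0, "T")
        ph = simulate_phenotypes(pop, [qa, qb], years=1, reps=1,
                                 grand_mean=0.0, seed=1)
        vals = ph.set_index("line_id")["value"]
        for line in pop.line_ids:
            expect = (2 * 3.0 * pop.dosage(line, qa.chrom, qa.pos)
                      + 2 * -1.0 * pop.dosage(line, qb.chrom, qb.pos))
            assert vals[line] == pytest.approx(expect)

    def test_deterministic_and_shapes(self, small_population):
        q = [PlantedQtl("Gm01", 10_000_000, 1.0, "T")]
        a = simulate_phenotypes(small_population, q, 4, 3, 1.0, 2.0, 10.0,
                                seed=9)
        b = simulate_phenotypes(small_population, q, 4, 3, 1.0, 2.0, 10.0,
                                seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == small_population.n_lines * 4 * 3
        assert set(a.columns) == {"line_id", "year", "replicate", "trait",
                                  "value"}

    def test_rejects_negative_sd(self, small_population):
        with pytest.raises(ConfigError):
            simulate_phenotypes(small_population, [], year_sd=-1.0)


class TestSelectBulks:
    def test_disjoint_bulks_of_requested_size(self, default_population):
        ph = simulate_phenotypes(
            default_population, [PlantedQtl("Gm16", 32_000_000, -7.65, "PH")],
            years=4, reps=3, year_sd=3.0, resid_sd=5.0, grand_mean=80.0,
            seed=2)
        high, low = select_bulks(ph, "PH", 30)
        assert len(high) == len(low) == 30
        assert not set(high) & set(low)

    def test_noise_free_selection_partitions_by_genetic_value(
            self, small_population):
        pop = small_population
        q = PlantedQtl("Gm01", 10_000_000, 2.0, "T")
        ph = simulate_phenotypes(pop, [q], years=2, reps=2, year_sd=0.0,
                                 resid_sd=0.0, grand_mean=0.0, seed=1)
        carriers = {l for l in pop.line_ids
                    if pop.dosage(l, q.chrom, q.pos)}
        n = min(len(carriers), pop.n_lines - len(carriers))
        assert n >= 1, "fixture population must have a polymorphic QTL"
        high, low = select_bulks(ph, "T", n)
        assert set(high) <= carriers
        if n == len(carriers):
            assert set(high) == carriers
        assert not set(low) & carriers

    def test_n_extreme_one_is_argmax_argmin(self, small_population):
        ph = simulate_phenotypes(
            small_population, [PlantedQtl("Gm01", 10_000_000, 1.0, "T")],
            years=1, reps=1, resid_sd=1.0, seed=3)
        means = ph.groupby("line_id")["value"].mean()
        high, low = select_bulks(ph, "T", 1)
        assert means[high[0]] == means.max()
        assert means[low[0]] == means.min()

    def test_infeasible_bulk_size_raises(self, small_population):
        ph = simulate_phenotypes(small_population, [], years=1, reps=1,
                                 trait="T")
        with pytest.raises(ValueError):
            select_bulks(ph, "T", small_population.n_lines)


class TestSimulatePools:
    def test_binomial_parameter_equals_bulk_mean_dosage(
            self, small_population):
        pop = small_population
        ids = list(pop.line_ids)
        high, low = ids[:10], ids[10:20]
        sim = simulate_pools(pop, high, low, snp_spacing=1_000_000, seed=4)
        grid = sim.truth[sim.truth.variant_type == "snp"]
        for row in grid.sample(25, random_state=0).itertuples():
            ph = np.mean([pop.dosage(l, row.chrom, row.pos) for l in high])
            pl = np.mean([pop.dosage(l, row.chrom, row.pos) for l in low])
            assert row.p_high == pytest.approx(ph)
            assert row.p_low == pytest.approx(pl)

    def test_high_depth_concentrates_on_truth(self, small_population):
        pop = small_population
        ids = list(pop.line_ids)
        sim = simulate_pools(pop, ids[:5], ids[5:10],
                             snp_spacing=5_000_000, depth_mean=1e6, seed=5)
        truth = sim.truth.set_index(["chrom", "pos"])
        for v in sim.variants[:30]:
            p = truth.loc[(v.chrom, v.pos), "p_high"]
            ad = v.allele_depths_high
            assert ad[1] / sum(ad) == pytest.approx(p, abs=0.01)

    def test_fixed_site_in_single_carrier_bulk(self, small_genome):
        pop = simulate_population(small_genome, 4,
                                  segments_per_line=(1, 1),
                                  segment_length=(5_000_000, 5_000_000),
                                  seed=8)
        line = pop.line_ids[0]
        (seg,) = pop.segments(line)
        pos = (seg.start // 1_000_000 + 1) * 1_000_000
        if not seg.contains(seg.chrom, pos):
            pytest.skip("grid point missed the segment")
        sim = simulate_pools(pop, [line], [pop.line_ids[1]],
                             snp_spacing=1_000_000, seed=9)
        row = sim.truth[(sim.truth.chrom == seg.chrom)
                        & (sim.truth.pos == pos)].iloc[0]
        assert row.p_high == 1.0

    def test_injected_clusters_and_indels_present(self, small_population):
        pop = small_population
        ids = list(pop.line_ids)
        sim = simulate_pools(pop, ids[:8], ids[8:16],
                             snp_spacing=1_000_000, inject_clusters=5,
                             inject_indels=4, seed=6)
        snp_pos = {}
        for v in sim.variants:
            if v.variant_type == "snp":
                snp_pos.setdefault(v.chrom, []).append(v.pos)
        pairs = sum(1 for c, ps in snp_pos.items()
                    for a, b in zip(ps, ps[1:]) if b - a < 5)
        assert pairs >= 5
        indels = [v for v in sim.variants if v.variant_type == "indel"]
        assert len(indels) == 4

    def test_empty_bulk_raises(self, small_population):
        with pytest.raises(ValueError):
            simulate_pools(small_population, [], ["L001"], seed=0)

    def test_byte_identical_vcf_for_fixed_seed(self, small_population,
                                               tmp_path):
        from soyqtl.variants import write_vcf

        ids = list(small_population.line_ids)
        paths = []
        for name in ("a.vcf", "b.vcf"):
            sim = simulate_pools(small_population, ids[:6], ids[6:12],
                                 snp_spacing=2_000_000, seed=42)
            write_vcf(sim.variants, tmp_path / name,
                      genome=small_population.genome)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSimulateGermplasm:
    def test_panel_shape_and_determinism(self):
        a = simulate_germplasm(seed=3)
        b = simulate_germplasm(seed=3)
        pd.testing.assert_frame_equal(a.calls, b.calls)
        assert a.calls.shape == (92, 12)
        assert set(np.unique(a.calls)) <= {-1, 0, 1}
        assert a.causal_site in a.calls.columns

    def test_causal_effect_visible_in_trait(self):
        g = simulate_germplasm(effect=50.0, trait_sd=1.0, seed=4)
        carriers = g.calls[g.causal_site] == 1
        non = g.calls[g.causal_site] == 0
        assert (g.trait[carriers.values].mean()
                - g.trait[non.values].mean()) == pytest.approx(50.0, abs=2.0)
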