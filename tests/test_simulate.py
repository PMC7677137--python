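"""Synthetic population generator: pools, individuals, registry, calibration."""

import dataclasses

import numpy as np
import pytest

from hlamatch.nomenclature import LOCI, AlleleCode
from hlamatch.simulate import (
    CHROM_ORDER,
    SEGMENT_WEIGHTS,
    CalibrationError,
    GeneratorConfig,
    _draw_mhc_track,
    calibrate_self_id,
    generate_cohort,
    generate_individual,
    generate_pools,
    generate_registry,
    generate_scd_cohort,
    generate_snp_panel,
)


class TestPools:
    def test_seeded_reproducibility(self, small_config):
        a1, e1 = generate_pools(small_config, np.random.default_rng(3))
        a2, e2 = generate_pools(small_config, np.random.default_rng(3))
        assert a1.haplotypes == a2.haplotypes
        assert np.array_equal(a1.frequencies, a2.frequencies)
        assert e1.haplotypes == e2.haplotypes

    def test_african_pool_more_diverse(self, small_pools):
        afr, eur = small_pools
        assert len(afr) > len(eur)
        for locus in LOCI:
            assert afr.expected_heterozygosity(locus) > eur.expected_heterozygosity(locus)

    def test_frequencies_normalized(self, small_pools):
        for pool in small_pools:
            assert pool.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
            assert (pool.frequencies > 0).all()

    def test_no_sharing_gives_disjoint_pools(self, small_config):
        cfg = dataclasses.replace(small_config, shared_group_fraction=0.0)
        afr, eur = generate_pools(cfg, np.random.default_rng(4))
        afr_alleles = {a for h in afr.haplotypes for a in h}
        eur_alleles = {a for h in eur.haplotypes for a in h}
        assert not afr_alleles & eur_alleles

    def test_degenerate_size_rejected(self, small_config):
        with pytest.raises(ValueError):
            dataclasses.replace(small_config, afr_pool_size=0)


class TestIndividuals:
    def test_ancestry_vector_on_simplex(self, small_config, small_pools, rng):
        ind = generate_individual(small_config, small_pools, "merged", rng, sigma=0.16)
        assert ind.q.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ind.q >= 0).all()

    def test_pure_african_ancestry_boundary(self, small_config, rng):
        track = _draw_mhc_track(small_config, 1.0, rng)
        assert all(track)

    def test_block_inheritance_without_recombination(self, small_config, small_pools, rng):
        for _ in range(20):
            ind = generate_individual(small_config, small_pools, "merged", rng, sigma=0.16)
            assert set(ind.mhc_afr) <= {0.0, 1.0}

    def test_mhc_fraction_consistent_with_track(self, small_config, small_pools, rng):
        cfg = dataclasses.replace(small_config, mhc_recombination=True)
        for _ in range(50):
            ind = generate_individual(cfg, small_pools, "merged", rng, sigma=0.16)
            for frac, track in zip(ind.mhc_afr, ind.mhc_tracks):
                expected = float(np.dot(SEGMENT_WEIGHTS, np.asarray(track, float)))
                assert frac == pytest.approx(expected, abs=1e-12)

    def test_high_admixture_cohort_mean(self, small_config, small_pools):
        rng = np.random.default_rng(11)
        inds = generate_cohort(small_config, small_pools, 5000, "high_admixture",
                               rng, sigma=0.16)
        mean_afr = np.mean([i.q[0] for i in inds])
        assert mean_afr == pytest.approx(0.497, abs=0.01)

    def test_snp_dosages_in_range(self, small_config, small_pools, rng):
        freqs = generate_snp_panel(small_config, rng)
        ind = generate_individual(small_config, small_pools, "merged", rng,
                                  sigma=0.16, snp_freqs=freqs)
        assert ind.snps.shape == (small_config.n_snps,)
        assert set(np.unique(ind.snps)) <= {0, 1, 2}

    def test_diversity_premise_distinct_genotypes(self, small_config, small_pools):
        # at equal sample size, African-only individuals carry more distinct
        # five-locus genotypes than European-only ones
        cfg = dataclasses.replace(
            small_config,
            cohort_beta={"afr_only": (1e7, 1e-7), "eur_only": (1e-7, 1e7)},
        )
        def distinct(cohort_name, seed):
            inds = generate_cohort(cfg, small_pools, 300, cohort_name,
                                   np.random.default_rng(seed), sigma=0.16)
            keys = set()
            for ind in inds:
                keys.add(tuple(
                    tuple(sorted(a.name for a in ind.genotypes[l].alleles))
                    for l in LOCI
                ))
            return len(keys)
        assert distinct("afr_only", 21) > distinct("eur_only", 21)


class TestRegistry:
    def test_single_category_composition(self, small_config, small_pools):
        cfg = dataclasses.replace(
            small_config, registry_size=100,
            registry_composition={"White": 1.0},
        )
        reg = generate_registry(cfg, small_pools, np.random.default_rng(5))
        assert len(reg) == 100
        assert all(d.self_id == "White" for d in reg)

    def test_core_loci_always_typed_and_partial_extended(self, small_registry, small_config):
        for d in small_registry:
            assert d.typed_at(("A", "B", "DRB1"))
        frac_c = np.mean([d.genotypes["C"].typed for d in small_registry])
        p = small_config.c_typed_fraction
        se = np.sqrt(p * (1 - p) / len(small_registry))
        assert abs(frac_c - p) < 4 * se

    def test_composition_converges(self, small_config, small_pools):
        cfg = dataclasses.replace(small_config, registry_size=10000)
        reg = generate_registry(cfg, small_pools, np.random.default_rng(6))
        cats = np.array([d.self_id for d in reg])
        for cat, p in cfg.registry_composition.items():
            frac = np.mean(cats == cat)
            se = np.sqrt(p * (1 - p) / len(reg))
            assert abs(frac - p) <= 3 * se, cat

    def test_low_resolution_donors_report_one_field(self, small_registry):
        saw_low = False
        for d in small_registry:
            if d.typing_resolution != "low":
                continue
            saw_low = True
            for locus in LOCI:
                g = d.genotypes[locus]
                if g.typed:
                    assert all(a.field2 is None for a in g.alleles)
        assert saw_low

    def test_allele_codes_only_on_medium_donors_and_cover_truth(self, small_registry):
        n_codes = 0
        for d in small_registry:
            for locus in LOCI:
                g = d.genotypes[locus]
                for a in (g.alleles if g.typed else ()):
                    if isinstance(a, AlleleCode):
                        n_codes += 1
                        assert d.typing_resolution == "medium"
                        assert len(a.expansion) >= 1
        assert n_codes > 0

    def test_byte_identical_csv_on_rerun(self, small_config, small_pools, tmp_path):
        for run in (1, 2):
            reg = generate_registry(small_config, small_pools, np.random.default_rng(13))
            reg.to_csv(tmp_path / f"reg{run}.csv", tmp_path / f"codes{run}.json")
        assert (tmp_path / "reg1.csv").read_bytes() == (tmp_path / "reg2.csv").read_bytes()
        assert (tmp_path / "codes1.json").read_bytes() == (tmp_path / "codes2.json").read_bytes()

    def test_bad_composition_rejected(self, small_config):
        with pytest.raises(ValueError):
            dataclasses.replace(small_config,
                                registry_composition={"White": 0.5, "Black": 0.2})


class TestSelfIdCalibration:
    def test_less_noise_explains_more_variance(self, small_config):
        rng = np.random.default_rng(31)
        res = calibrate_self_id(small_config, 0.5, rng=rng)
        # zero-noise limit is the deterministic-threshold maximum
        assert res.bracket[1] > res.achieved_r2 > res.bracket[0]

    def test_unattainable_target_reports_bracket(self, small_config):
        with pytest.raises(CalibrationError, match="bracket"):
            calibrate_self_id(small_config, 0.99, rng=np.random.default_rng(32))


class TestScdCohort:
    def test_flags_and_mean_ancestry(self, small_config, small_pools):
        inds = generate_scd_cohort(small_config, small_pools, 417,
                                   np.random.default_rng(14), sigma=0.16)
        assert all(i.scd for i in inds)
        assert np.mean([i.q[0] for i in inds]) == pytest.approx(0.52, abs=0.02)

    def test_single_member(self, small_config, small_pools):
        inds = generate_scd_cohort(small_config, small_pools, 1,
                                   np.random.default_rng(15), sigma=0.16)
        assert len(inds) == 1 and inds[0].scd

    def test_non_scd_cohorts_unflagged(self, small_cohort):
        assert not any(i.scd for i in small_cohort)
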