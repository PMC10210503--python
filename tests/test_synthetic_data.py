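import math

import numpy as np
import pytest

from pirnakit import (
    SimulationConfig,
    annotate_library,
    density_per_kb,
    expected_density,
    fold_enrichment,
    make_references,
    map_library,
    normalize_to_region,
    rt_ratio,
    simulate_egg_chambers,
    simulate_library,
    simulate_qpcr,
)
from pirnakit.sequence_io import trim_library
from pirnakit.synthetic_data import RegionSpec


def small_cfg(**kw) -> SimulationConfig:
    """Study-structured config at reduced sequencing depth for fast tests."""
    return SimulationConfig(**kw).scaled(0.05)


def run_pipeline_on(cfg, generation, lineage):
    reads, truth, refs = simulate_library(cfg, generation, lineage)
    kept, rejected = trim_library(reads, cfg.adapter)
    assert sum(rejected.values()) == 0  # every simulated read carries the adapter
    mult = [int(m) for m in truth["multiplicity"]]
    result = map_library(kept, refs, max_mm=0, multiplicities=mult)
    ann = annotate_library(kept, refs, multiplicities=mult)
    return result.hits, ann, refs, truth


class TestReferences:
    def test_lengths_and_determinism(self):
        cfg = small_cfg(seed=3)
        refs1, bed1 = make_references(cfg)
        refs2, bed2 = make_references(cfg)
        assert refs1["T3"].seq == refs2["T3"].seq
        assert len(refs1["T3"].seq) == 900
        assert len(refs1["PlArB"].seq) == 18000
        assert len(refs1["white"].seq) == 4100
        assert bed1.equals(bed2)

    def test_different_seed_different_sequence(self):
        refs1, _ = make_references(small_cfg(seed=1))
        refs2, _ = make_references(small_cfg(seed=2))
        assert refs1["T3"].seq != refs2["T3"].seq

    def test_bed_within_parent(self):
        cfg = small_cfg()
        refs, bed = make_references(cfg)
        for row in bed.itertuples():
            assert 0 <= row.start < row.end <= len(refs[row.region].seq)

    def test_carved_categories_map_to_genome(self):
        refs, _ = make_references(small_cfg())
        assert refs["miscRNA"].seq in refs["genome"].seq
        assert refs["tRNA"].seq in refs["genome"].seq
        assert refs["miRNA"].seq in refs["genome"].seq

    def test_overlapping_subregions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSpec("bad", 1000, subregions=(("a", 0, 500), ("b", 400, 800)))

    def test_subregion_outside_parent_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            RegionSpec("bad", 100, subregions=(("a", 0, 200),))


class TestSimulateLibrary:
    def test_determinism(self):
        cfg = small_cfg(seed=5)
        r1, t1, _ = simulate_library(cfg, 1, "paternal")
        r2, t2, _ = simulate_library(cfg, 1, "paternal")
        assert [(x.id, x.seq) for x in r1] == [(x.id, x.seq) for x in r2]
        assert t1.equals(t2)

    def test_instant_conversion_at_c_one(self):
        """c = 1 makes paternal G1 density equal the plateau."""
        cfg = small_cfg(conversion_probability=1.0)
        for region in ("PlArB", "T3", "white"):
            assert expected_density(cfg, region, 1, "paternal", 1.0) == pytest.approx(
                cfg.plateau_density[region]
            )

    def test_density_approach_to_plateau_over_seeds(self):
        """Sampled 0-mm densities track D_max*(1-(1-c)^g) within binomial noise.

        Reads carrying simulated mismatches are excluded from the target
        since 0-mm mapping drops them.
        """
        c = 0.45
        region, kb = "white", 4.1
        for g in (1, 4):
            rel_errs = []
            for seed in range(8):
                cfg = small_cfg(
                    seed=seed, conversion_probability=c, mismatch_read_fraction=0.0
                )
                _, truth, _ = simulate_library(cfg, g, "paternal")
                n = len(truth[(truth.kind == "piRNA") & (truth.region == region)])
                denom = (
                    cfg.background_counts["genome"] + cfg.background_counts["miRNA"]
                )
                density = n * 1e6 / denom / kb
                target = cfg.plateau_density[region] * (1 - (1 - c) ** g)
                rel_errs.append(density / target - 1)
            # mean over seeds unbiased; per-seed noise ~ 1/sqrt(n)
            assert abs(np.mean(rel_errs)) < 0.1

    def test_pingpong_and_one_u_by_construction(self):
        """pingpong_fraction=1, one_u_bias=1: every read starts with T and
        paired antisense 5' ends sit exactly 9 nt downstream of a sense 5'."""
        cfg = small_cfg(pingpong_fraction=1.0, one_u_bias=1.0,
                        mismatch_read_fraction=0.0, seed=2)
        _, truth, refs = simulate_library(cfg, 4, "paternal")
        pir = truth[truth.kind == "piRNA"]
        assert (pir.first_nt == "T").all()
        paired = pir[pir.paired]
        assert len(paired) > 0
        for region, grp in paired.groupby("region"):
            sense5 = set(pir[(pir.region == region) & (pir.strand == "+")].five_prime)
            for a5 in grp.five_prime:
                assert (a5 - 9) in sense5

    def test_sirna_only_in_paternal(self):
        cfg = small_cfg(seed=4)
        _, t_pat, _ = simulate_library(cfg, 2, "paternal")
        _, t_mat, _ = simulate_library(cfg, 2, "maternal")
        assert (t_pat.kind == "siRNA").sum() > 0
        assert (t_mat.kind == "siRNA").sum() == 0
        assert (t_pat[t_pat.kind == "siRNA"].length == 21).all()

    def test_background_totals_match_config(self):
        cfg = small_cfg(seed=6)
        _, truth, _ = simulate_library(cfg, 1, "maternal")
        for cat, total in cfg.background_counts.items():
            got = truth[truth.kind == f"background_{cat}"].multiplicity.sum()
            assert got == total

    def test_truth_pipeline_agreement(self):
        """Pipeline-estimated 1U bias and strand fraction match the generator."""
        cfg = small_cfg(seed=9, pingpong_fraction=0.0, mismatch_read_fraction=0.0)
        hits, ann, refs, truth = run_pipeline_on(cfg, 4, "maternal")
        for region in ("PlArB", "white"):
            d = density_per_kb(hits, ann, region, refs[region].length_kb)
            n = len(truth[(truth.kind == "piRNA") & (truth.region == region)])
            # binomial 99% CI around the generating 1U bias
            p = cfg.one_u_bias
            half = 2.576 * math.sqrt(p * (1 - p) / n)
            assert abs(d.one_u_fraction - p) < half + 0.02
            from pirnakit import coverage_profile, strand_asymmetry

            prof = coverage_profile(hits, ann, region, len(refs[region].seq))
            frac, _ = strand_asymmetry(prof)
            s = cfg.strand_ratio[region]
            assert abs(frac - s) < 3 * math.sqrt(s * (1 - s) / n) + 0.02


class TestEggChambers:
    def test_zero_conversion_zero_repression(self):
        cfg = small_cfg(conversion_probability=0.0)
        for g in (1, 4):
            for c in simulate_egg_chambers(cfg, g, "paternal"):
                assert c.n_repressed == 0

    def test_maternal_plateau(self):
        cfg = small_cfg(maternal_repression=0.95, chambers_per_subline=400)
        pct = []
        for seed in range(5):
            for c in simulate_egg_chambers(cfg.with_(seed=seed), 1, "maternal"):
                pct.append(100 * c.n_repressed / c.n_total)
        se = 100 * math.sqrt(0.95 * 0.05 / 400)
        assert abs(np.mean(pct) - 95.0) < 3 * se

    def test_paternal_expectation_non_decreasing(self):
        cfg = small_cfg(conversion_probability=0.45)
        means = []
        for g in range(1, 5):
            vals = [
                100 * c.n_repressed / c.n_total
                for seed in range(5)
                for c in simulate_egg_chambers(cfg.with_(seed=seed), g, "paternal")
            ]
            means.append(np.mean(vals))
        assert all(b >= a - 2.0 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestQpcrSimulation:
    def test_zero_noise_round_trip_exact(self):
        cfg = small_cfg(ct_noise_sd=0.0)
        rt, chip = simulate_qpcr(cfg)
        by_sample = {}
        for s in rt:
            by_sample.setdefault(s.sample_id, {})[s.gene] = s
        for sid, genes in by_sample.items():
            for gene, true_ratio in cfg.true_rt_ratios.items():
                assert rt_ratio(genes[gene], genes["RpL32"]) == pytest.approx(
                    true_ratio, rel=1e-12
                )
        per_region = {}
        for s in chip:
            per_region.setdefault(s.target_region, []).append(fold_enrichment(s))
        for region, true_e in cfg.true_enrichments.items():
            for e in per_region[region]:
                assert e == pytest.approx(true_e, rel=1e-9)
        rel = normalize_to_region(
            {r: float(np.mean(v)) for r, v in per_region.items()}
        )
        assert rel["42AB"] == pytest.approx(1.0)

    def test_noisy_estimates_near_truth(self):
        """sigma=0.1, n=3: mean enrichment within 20% of truth in >=90% of seeds."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = small_cfg(seed=seed, ct_noise_sd=0.1)
            _, chip = simulate_qpcr(cfg)
            vals = [fold_enrichment(s) for s in chip if s.target_region == "42AB"]
            if abs(np.mean(vals) / cfg.true_enrichments["42AB"] - 1) < 0.2:
                ok += 1
        assert ok >= 0.9 * n_seeds
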