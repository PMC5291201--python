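"""Scan orchestration: planted-effect recovery, caching, Q-Q data,
multi-dataset evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtlcollapse.regions import GenomicInterval, build_regions, enumerate_pairs
from mqtlcollapse.scan import (
    ScanConfig,
    ScanData,
    followup_single_variants,
    multi_timepoint_evaluation,
    qq_points,
    run_scan,
)
from mqtlcollapse.simulate import (
    EffectSpec,
    SimConfig,
    default_study_config,
    simulate_dataset,
)
from mqtlcollapse.skat import skat_test


def scan_inputs(ds, tier="island_shore_shelf", cutoff=0.05):
    islands = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in ds.islands.itertuples()
    ]
    regions_list = build_regions(islands, ds.variants, tier, cutoff)
    data = ScanData(
        dosages=ds.dosages,
        variant_ids=ds.variants["id"].tolist(),
        variant_mafs=ds.variants["maf"].to_numpy(),
        methylation=ds.methylation,
        covariates=ds.covariates.to_numpy(float),
    )
    return regions_list, {r.region_id: r for r in regions_list}, data


@pytest.fixture(scope="module")
def single_effect_scan():
    """One collapsed cis effect among dozens of null pairs."""
    cfg = SimConfig(
        n_islands=12,
        seed=31,
        effect_scenarios=(EffectSpec(0, "collapsed", (0.7, -0.7, 0.7, -0.7, 0.7)),),
    )
    ds = simulate_dataset(cfg)
    regions_list, regions, data = scan_inputs(ds)
    pairs = [
        p for p in enumerate_pairs(regions_list, ds.probes) if p.relation == "cis"
    ]
    table = run_scan(pairs, regions, data, ScanConfig())
    return ds, regions, data, table


class TestRunScan:
    def test_planted_pair_uniquely_recovered(self, single_effect_scan):
        ds, regions, data, table = single_effect_scan
        assert len(table) >= 50
        bonferroni = 0.05 / len(table)
        hits = table[table["p_value"] < bonferroni]
        assert len(hits) == 1
        hit = hits.iloc[0]
        assert hit["probe_id"] == "cg00000000"
        planted = set(ds.truth.probes["cg00000000"]["variant_ids"])
        assert planted <= set(regions[hit["region_id"]].variant_ids)

    def test_rare_cutoff_removes_low_frequency_effects(self):
        # effects planted at MAF ~2.5-4.5%: at the <=1% tier nothing is left
        cfg = SimConfig(
            n_islands=6,
            maf_range=(0.025, 0.045),
            seed=32,
            effect_scenarios=(
                EffectSpec(0, "collapsed", (0.7, -0.7, 0.7, -0.7, 0.7)),
            ),
        )
        ds = simulate_dataset(cfg)
        regions_list, regions, data = scan_inputs(ds, cutoff=0.01)
        pairs = enumerate_pairs(regions_list, ds.probes)
        table = run_scan(pairs, regions, data, ScanConfig(maf_cutoff=0.01))
        assert not table["passes_threshold"].any()

    def test_empty_pair_list(self, single_effect_scan):
        _, regions, data, _ = single_effect_scan
        assert len(run_scan([], regions, data, ScanConfig())) == 0

    def test_cached_null_model_matches_fresh_fit(self, single_effect_scan):
        ds, regions, data, table = single_effect_scan
        cfg = ScanConfig()
        for _, row in table.head(10).iterrows():
            region = regions[row["region_id"]]
            G, mafs, _ = data.columns_for(region.variant_ids)
            y = data.methylation.loc[row["probe_id"]].to_numpy(float)
            fresh = skat_test(y, data.covariates, G, cfg.weight_spec, mafs=mafs)
            assert row["p_value"] == pytest.approx(fresh.p_value, rel=1e-12)

    def test_invariant_to_pair_order(self, single_effect_scan):
        ds, regions, data, table = single_effect_scan
        regions_list = list(regions.values())
        pairs = [
            p for p in enumerate_pairs(regions_list, ds.probes) if p.relation == "cis"
        ]
        rng = np.random.default_rng(0)
        shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
        table2 = run_scan(shuffled, regions, data, ScanConfig())
        pd.testing.assert_frame_equal(
            table.reset_index(drop=True), table2.reset_index(drop=True)
        )

    def test_missing_probe_skipped(self, single_effect_scan):
        ds, regions, data, _ = single_effect_scan
        trimmed = ScanData(
            data.dosages,
            data.variant_ids,
            data.variant_mafs,
            data.methylation.drop(index="cg00000001"),
            data.covariates,
        )
        regions_list = list(regions.values())
        pairs = [
            p for p in enumerate_pairs(regions_list, ds.probes) if p.relation == "cis"
        ]
        table = run_scan(pairs, regions, trimmed, ScanConfig())
        assert "cg00000001" not in set(table["probe_id"])

    def test_null_scan_tail_fraction_consistent(self):
        # on a fully null fixture P(p < 1e-3) should be ~1e-3
        ps = []
        for seed in range(25):
            ds = simulate_dataset(
                SimConfig(n_samples=300, n_islands=8, seed=900 + seed)
            )
            regions_list, regions, data = scan_inputs(ds)
            pairs = enumerate_pairs(regions_list, ds.probes)
            ps.extend(run_scan(pairs, regions, data, ScanConfig())["p_value"])
        frac = np.mean(np.asarray(ps) < 1e-3)
        # binomial 99% upper bound at ~2000 draws
        assert frac <= 1e-3 + 3 * np.sqrt(1e-3 / len(ps))


class TestFollowup:
    def test_collapsed_hit_has_no_single_driver(self, single_effect_scan):
        _, regions, data, table = single_effect_scan
        hit = table.loc[table["p_value"].idxmin()]
        effects, drivers = followup_single_variants(hit, regions, data, ScanConfig())
        assert not drivers
        assert len(effects) == regions[hit["region_id"]].variant_ids.__len__()

    def test_single_variant_hit_flags_driver(self, study_dataset, study_scan_data):
        regions_list, regions, data = scan_inputs(study_dataset)
        hit = pd.Series({"region_id": "region_0001", "probe_id": "cg00000001"})
        effects, drivers = followup_single_variants(hit, regions, data, ScanConfig())
        assert drivers
        best = effects.loc[effects["p"].idxmin(), "variant_id"]
        assert best == study_dataset.truth.probes["cg00000001"]["variant_ids"][0]


class TestQQPoints:
    def test_three_value_example(self):
        out = qq_points(np.array([0.5, 0.1, 0.9]))
        np.testing.assert_allclose(
            out["expected"], -np.log10([1 / 4, 2 / 4, 3 / 4])
        )
        np.testing.assert_allclose(out["observed"], -np.log10([0.1, 0.5, 0.9]))

    def test_single_point(self):
        out = qq_points(np.array([0.2]))
        assert out["expected"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_uniform_sample_near_identity(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=10_000)
        out = qq_points(p)
        # deviations bounded by the 1% KS band on the p scale
        obs_p = 10 ** (-out["observed"].to_numpy())
        exp_p = 10 ** (-out["expected"].to_numpy())
        assert np.max(np.abs(obs_p - exp_p)) < 1.63 / np.sqrt(10_000)

    def test_zero_p_floored_and_flagged(self):
        out = qq_points(np.array([0.0, 0.5]))
        assert out["floored"].any()
        assert np.isfinite(out["observed"]).all()


class TestMultiTimepoint:
    def test_refreshed_noise_replicates_hits(self, study_dataset, study_scan_data):
        # same genotypes and truth, new methylation noise (a second life
        # stage of the same cohort)
        regions_list, regions, data = scan_inputs(study_dataset)
        cfg_b = default_study_config(seed=0)
        cfg_b.noise_seed = 77
        ds_b = simulate_dataset(cfg_b)
        np.testing.assert_array_equal(ds_b.dosages, study_dataset.dosages)
        assert not np.allclose(
            ds_b.methylation.to_numpy(), study_dataset.methylation.to_numpy()
        )
        data_b = ScanData(
            ds_b.dosages,
            ds_b.variants["id"].tolist(),
            ds_b.variants["maf"].to_numpy(),
            ds_b.methylation,
            ds_b.covariates.to_numpy(float),
        )
        hits = pd.DataFrame(
            [
                {"region_id": "region_0000", "probe_id": "cg00000000"},
                {"region_id": "region_0001", "probe_id": "cg00000001"},
            ]
        )
        out = multi_timepoint_evaluation(
            hits, regions, {"timepoint_b": data_b}, ScanConfig()
        )
        assert out["testable"].all()
        assert (out["p_value"] < ScanConfig().evaluation_p).all()

    def test_missing_variant_decrements_nvars(self, study_dataset):
        regions_list, regions, data = scan_inputs(study_dataset)
        region = regions["region_0000"]
        drop = region.variant_ids[0]
        keep_cols = [j for j, v in enumerate(data.variant_ids) if v != drop]
        data_b = ScanData(
            data.dosages[:, keep_cols],
            [data.variant_ids[j] for j in keep_cols],
            data.variant_mafs[keep_cols],
            data.methylation,
            data.covariates,
        )
        hits = pd.DataFrame([{"region_id": "region_0000", "probe_id": "cg00000000"}])
        out = multi_timepoint_evaluation(hits, regions, {"b": data_b}, ScanConfig())
        assert out["n_variants"].iloc[0] == len(region.variant_ids) - 1
        assert out["testable"].iloc[0]

    def test_all_variants_missing_marks_untestable(self, study_dataset):
        regions_list, regions, data = scan_inputs(study_dataset)
        region = regions["region_0000"]
        keep_cols = [
            j
            for j, v in enumerate(data.variant_ids)
            if v not in set(region.variant_ids)
        ]
        data_b = ScanData(
            data.dosages[:, keep_cols],
            [data.variant_ids[j] for j in keep_cols],
            data.variant_mafs[keep_cols],
            data.methylation,
            data.covariates,
        )
        hits = pd.DataFrame([{"region_id": "region_0000", "probe_id": "cg00000000"}])
        out = multi_timepoint_evaluation(hits, regions, {"b": data_b}, ScanConfig())
        assert not out["testable"].iloc[0]
        assert np.isnan(out["p_value"].iloc[0])
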