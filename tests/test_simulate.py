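import dataclasses

import numpy as np
import pandas as pd
import pytest

import bloomclock as bc
from bloomclock import forecast as fc
from bloomclock import simulate as sim


class TestGenerateTimecourse:
    def test_seeded_reproducibility(self, small_config):
        m1, meta1, t1 = sim.generate_timecourse(small_config)
        m2, meta2, t2 = sim.generate_timecourse(small_config)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(meta1.table, meta2.table)
        assert t1.module_membership == t2.module_membership

    def test_different_seed_differs(self, small_config):
        m1, _, _ = sim.generate_timecourse(small_config)
        cfg2 = dataclasses.replace(small_config, seed=8)
        m2, _, _ = sim.generate_timecourse(cfg2)
        assert not np.allclose(m1.values.to_numpy(), m2.values.to_numpy())

    def test_zero_noise_trees_identical_for_module_genes(self, small_config):
        cfg = dataclasses.replace(small_config, replicate_noise_sd=0.0)
        matrix, meta, truth = sim.generate_timecourse(cfg)
        module_genes = [
            g for g, lab in truth.module_membership.items() if lab.startswith("module")
        ]
        by_tree = {}
        for tree, _, _ in cfg.trees:
            cols = meta.table.loc[meta.table["tree_id"] == tree, "sample_id"]
            by_tree[tree] = matrix.values.loc[module_genes, cols].to_numpy()
        trees = list(by_tree)
        for other in trees[1:]:
            np.testing.assert_allclose(by_tree[trees[0]], by_tree[other])

    def test_module_mean_peaks_at_nearest_sampled_day(self, small_config):
        cfg = dataclasses.replace(small_config, replicate_noise_sd=0.0)
        matrix, meta, truth = sim.generate_timecourse(cfg)
        days = meta.day_offsets(matrix.sample_ids)
        sampled = np.array(cfg.sampling_days, dtype=float)
        for mi, peak in enumerate(cfg.peak_days):
            genes = [
                g
                for g, lab in truth.module_membership.items()
                if lab == f"module{mi + 1}"
            ]
            prof = matrix.values.loc[genes].to_numpy().mean(axis=0)
            # mean expression per sampled day, argmax over days
            per_day = {d: prof[days == d].mean() for d in sampled}
            best = max(per_day, key=per_day.get)
            nearest = sampled[np.argmin(np.abs(sampled - peak))]
            assert best == nearest

    def test_values_nonnegative(self, small_config):
        matrix, _, _ = sim.generate_timecourse(small_config)
        assert (matrix.values.to_numpy() >= 0).all()

    def test_oversized_modules_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, module_sizes=[200, 200, 200])
        with pytest.raises(ValueError, match="exceed"):
            sim.generate_timecourse(cfg)

    def test_unsorted_days_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, sampling_days=[0, -5, 5])
        with pytest.raises(ValueError, match="sorted"):
            sim.generate_timecourse(cfg)

    def test_one_sample_per_tree_and_day(self, small_config):
        matrix, meta, _ = sim.generate_timecourse(small_config)
        assert matrix.n_samples == len(small_config.trees) * len(
            small_config.sampling_days
        )
        combos = meta.table.groupby(["tree_id", "day_offset"]).size()
        assert (combos == 1).all()


class TestGenerateCtSeries:
    def test_noiseless_quadratic_extremum_at_planted_day(self, small_config):
        _, _, truth = sim.generate_timecourse(small_config)
        truth.ct_noise_sd = 0.0
        ct, meta = sim.generate_ct_series(np.arange(-36, 1), truth)
        series = fc.build_delta_ct_series(ct, meta)
        t = series["days_to_flowering"].to_numpy()
        b = series["dct_b"].to_numpy()
        # vertex of the planted parabola: argmin over a fine fitted curve
        curve = fc.fit_stage_curve(t, b, degree=2)
        assert curve.extremum_day == pytest.approx(20.0, abs=1e-8)

    def test_control_ct_monotone_in_stage_when_noiseless(self, small_config):
        _, _, truth = sim.generate_timecourse(small_config)
        truth.ct_noise_sd = 0.0
        days = np.arange(-30, 6)  # increasing stage axis
        ct, _ = sim.generate_ct_series(days, truth)
        ctr = ct.loc[ct["role"] == "CBFr", "ct"].to_numpy()
        assert (np.diff(ctr) < 0).all()

    def test_ct_values_in_cycle_range(self, small_config):
        _, _, truth = sim.generate_timecourse(small_config)
        ct, _ = sim.generate_ct_series(np.arange(-36, 12), truth, seed=3)
        assert ct["ct"].between(10, 45).all()

    def test_noise_sd_recovered_from_residuals(self, small_config):
        _, _, truth = sim.generate_timecourse(small_config)
        truth.ct_noise_sd = 0.5
        days = np.linspace(-36, 11, 100)
        ct, _ = sim.generate_ct_series(days, truth, seed=11)
        noiseless_truth = dataclasses.replace(truth, ct_noise_sd=0.0)
        clean, _ = sim.generate_ct_series(days, noiseless_truth)
        resid = ct["ct"].to_numpy() - clean["ct"].to_numpy()
        assert 0.35 <= resid.std(ddof=1) <= 0.65

    def test_empty_days_error(self, small_config):
        _, _, truth = sim.generate_timecourse(small_config)
        with pytest.raises(ValueError, match="nonempty"):
            sim.generate_ct_series([], truth)

    def test_forecast_roundtrip_from_planted_coefficients(self, small_config):
        """Days built from the planted coefficients refit to them exactly."""
        _, _, truth = sim.generate_timecourse(small_config)
        train = sim.generate_forecast_training(truth)
        model = fc.fit_forecast_model(train)
        np.testing.assert_allclose(
            model.coefficients(), truth.forecast_coefficients, atol=1e-6
        )


class TestGenerateGoAnnotation:
    def test_planted_term_enrichment_detected(self, small_config):
        matrix, _, truth = sim.generate_timecourse(small_config)
        ann_map, term_meta = sim.generate_go_annotation(
            matrix.gene_ids, truth, planted_term_module=[("t", "module1")]
        )
        ann = bc.GOAnnotation(ann_map, term_meta)
        module_genes = [
            g for g, lab in truth.module_membership.items() if lab == "module1"
        ]
        results = bc.fisher_enrichment(module_genes, matrix.gene_ids, ann)
        planted = [r for r in results if r.term_id == "GO:0000001"]
        assert planted and planted[0].enriched and planted[0].fdr < 0.05

    def test_no_planted_pairs_no_forced_enrichment(self, small_config):
        matrix, _, truth = sim.generate_timecourse(small_config)
        ann_map, _ = sim.generate_go_annotation(matrix.gene_ids, truth, n_terms=10)
        module_genes = {
            g for g, lab in truth.module_membership.items() if lab == "module1"
        }
        for tid in {t for ts in ann_map.values() for t in ts}:
            in_mod = sum(1 for g in module_genes if tid in ann_map[g])
            rate_mod = in_mod / len(module_genes)
            assert rate_mod < 0.35  # ~5% background, generous ceiling

    def test_seeded_reproducibility(self, small_config):
        matrix, _, truth = sim.generate_timecourse(small_config)
        a1, _ = sim.generate_go_annotation(matrix.gene_ids, truth, seed=5)
        a2, _ = sim.generate_go_annotation(matrix.gene_ids, truth, seed=5)
        assert a1 == a2

    def test_too_few_terms_rejected(self, small_config):
        matrix, _, truth = sim.generate_timecourse(small_config)
        with pytest.raises(ValueError, match="n_terms"):
            sim.generate_go_annotation(
                matrix.gene_ids,
                truth,
                n_terms=1,
                planted_term_module=[("a", "module1"), ("b", "module2")],
            )
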