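"""Side merging, pooled-sample construction, and the distortion of diversity
summaries under alternative sampling strategies."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from biofilmgeo.core import SpatialCountTable
from biofilmgeo.resampling import (
    SamplingPlan,
    apply_plan,
    build_groups,
    merge_sides,
    strategy_sweep,
)
from biofilmgeo.synthetic import SyntheticConfig, environment_preset, generate_biofilm


def _paired_meta(n_pos):
    rows = []
    for j in range(n_pos):
        for s, side in enumerate(("side1", "side2")):
            rows.append(dict(section_id=f"S{j}{side[-1]}",
                             position_cm=(j + 0.5) * 1.2, side=side,
                             length_cm=1.2, area_cm2=1.5, environment="e"))
    return pd.DataFrame(rows)


class TestMergeSides:
    def test_counts_added_and_area_summed(self):
        meta = _paired_meta(2)
        t = SpatialCountTable(["a", "b"], meta.section_id.tolist(),
                              np.array([[1, 0, 2, 2], [0, 2, 1, 0]]))
        mt, mm = merge_sides(t, meta)
        assert mt.n_sections == 2
        np.testing.assert_array_equal(mt.counts[:, 0], [1, 2])
        assert (mm.side == "merged").all()
        assert mm.area_cm2.iloc[0] == pytest.approx(3.0)

    def test_halves_section_count(self, small_survey):
        table, meta, _ = small_survey
        mt, _ = merge_sides(table, meta)
        assert mt.n_sections == table.n_sections // 2

    def test_already_merged_identity(self):
        meta = _paired_meta(2)
        t = SpatialCountTable(["a"], meta.section_id.tolist(),
                              np.array([[1, 2, 3, 4]]))
        mt, mm = merge_sides(t, meta)
        again, _ = merge_sides(mt, mm)
        assert again == mt

    def test_orphan_section_rejected(self):
        meta = _paired_meta(2).iloc[:-1]
        t = SpatialCountTable(["a"], meta.section_id.tolist(),
                              np.array([[1, 2, 3]]))
        with pytest.raises(ValueError, match="unpaired"):
            merge_sides(t, meta)


class TestBuildGroups:
    meta = pd.DataFrame(dict(
        section_id=[f"s{i}" for i in range(6)],
        position_cm=np.arange(6) * 1.2, side="merged",
        length_cm=1.2, area_cm2=3.0, environment="e"))

    def test_k1_both_strategies_identical(self):
        a = build_groups(self.meta, "contiguous", 1)
        b = build_groups(self.meta, "discontiguous", 1, seed=3)
        assert a == b == [[f"s{i}"] for i in range(6)]

    def test_k_equals_n_single_group(self):
        a = build_groups(self.meta, "contiguous", 6)
        b = build_groups(self.meta, "discontiguous", 6, seed=1)
        assert len(a) == len(b) == 1
        assert sorted(a[0]) == sorted(b[0])

    def test_contiguous_axial_runs(self):
        groups = build_groups(self.meta, "contiguous", 2)
        assert groups == [["s0", "s1"], ["s2", "s3"], ["s4", "s5"]]

    def test_remainder_forms_smaller_group(self):
        groups = build_groups(self.meta, "contiguous", 4)
        assert [len(g) for g in groups] == [4, 2]

    def test_discontiguous_covers_all_once(self):
        groups = build_groups(self.meta, "discontiguous", 2, seed=7)
        flat = [s for g in groups for s in g]
        assert sorted(flat) == sorted(self.meta.section_id)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_groups(self.meta, "contiguous", 7)


class TestApplyPlan:
    def test_identity_configuration(self, small_survey):
        """k=1 without rarefaction reproduces the side-merged table."""
        table, meta, _ = small_survey
        plan = SamplingPlan(strategy="contiguous", sections_per_sample=1,
                            rarefaction_depth=0, rarefy_samples=False,
                            iterations=1, seed=0)
        ss = apply_plan(table, meta, plan)[0]
        mt, _ = merge_sides(table, meta)
        assert np.array_equal(
            ss.table.counts.sum(axis=0), mt.counts.sum(axis=0))
        assert ss.table.counts.sum() == mt.counts.sum()

    def test_columns_sum_to_depth_and_determinism(self, small_survey):
        table, meta, _ = small_survey
        plan = SamplingPlan(strategy="discontiguous", sections_per_sample=5,
                            rarefaction_depth=3000, iterations=3, seed=9)
        sets1 = apply_plan(table, meta, plan)
        sets2 = apply_plan(table, meta, plan)
        for a, b in zip(sets1, sets2):
            assert a.table == b.table
            assert (a.table.column_totals() == 3000).all()

    def test_pooled_totals_conserved_before_rarefaction(self, small_survey):
        table, meta, _ = small_survey
        plan = SamplingPlan(strategy="contiguous", sections_per_sample=4,
                            rarefy_samples=False, iterations=1, seed=0)
        ss = apply_plan(table, meta, plan)[0]
        assert ss.table.counts.sum() == table.counts.sum()

    def test_area_fractions_sum_to_one(self, small_survey):
        table, meta, _ = small_survey
        plan = SamplingPlan(strategy="contiguous", sections_per_sample=7,
                            rarefaction_depth=2000, iterations=1, seed=0)
        ss = apply_plan(table, meta, plan)[0]
        assert ss.sample_area_fraction.sum() == pytest.approx(1.0)

    def test_infeasible_depth_names_sample(self, small_survey):
        table, meta, _ = small_survey
        plan = SamplingPlan(strategy="contiguous", sections_per_sample=1,
                            rarefaction_depth=10**9, iterations=1, seed=0)
        with pytest.raises(ValueError, match="reads"):
            apply_plan(table, meta, plan)


def _gradient_table(seed, n_taxa=150, n_sections=80, depth=2000):
    cfg = SyntheticConfig(n_taxa=n_taxa, n_sections=n_sections, depth=depth,
                          frac_monotonic=0.35, frac_peaked=0.15,
                          gradient_strength=0.06, noise_overdispersion=1.0,
                          seed=seed)
    return generate_biofilm(cfg)


class TestStrategySweep:
    def test_k1_matches_diversity_module(self, small_survey):
        from biofilmgeo.diversity import alpha_table
        table, meta, _ = small_survey
        mt, _ = merge_sides(table, meta)
        sweep = strategy_sweep(table, meta, [1], ["contiguous"],
                               depth=0, iterations=1, seed=0,
                               rarefy_samples=False)
        direct = alpha_table(mt)
        merged = sweep["alpha"].sort_values("section_id").reset_index()
        direct = direct.sort_values("section_id").reset_index()
        np.testing.assert_allclose(merged.shannon, direct.shannon)

    def test_distortion_directions_on_gradient_data(self):
        """Pooling more sections per sample raises per-sample richness,
        lowers whole-environment richness at fixed depth, and lowers
        between-sample dissimilarity."""
        table, meta, _ = _gradient_table(seed=21)
        sweep = strategy_sweep(table, meta, [1, 4, 10], ["contiguous"],
                               depth=1500, iterations=3, seed=5)
        by_k = sweep["alpha"].groupby("k").richness.mean()
        assert by_k.loc[1] < by_k.loc[4] < by_k.loc[10]
        gamma = sweep["gamma"].groupby("k").richness.mean()
        assert gamma.loc[1] > gamma.loc[10]
        beta = sweep["beta"].groupby("k").bray_curtis.mean()
        assert beta.loc[1] > beta.loc[10]

    def test_discontiguous_destroys_distance_decay(self):
        """Group-centre distance correlates with dissimilarity for contiguous
        pooling but not after random (discontiguous) pooling."""
        wins = 0
        n_runs = 10
        for seed in range(n_runs):
            table, meta, _ = _gradient_table(seed=100 + seed)
            rhos = {}
            for strategy in ("contiguous", "discontiguous"):
                sweep = strategy_sweep(table, meta, [4], [strategy],
                                       depth=1500, iterations=1, seed=seed)
                beta = sweep["beta"]
                alpha = sweep["alpha"].set_index("section_id")
                # reconstruct group-centre distances from the sweep samples
                plan = SamplingPlan(strategy=strategy, sections_per_sample=4,
                                    rarefaction_depth=1500, iterations=1,
                                    seed=seed)
                ss = apply_plan(table, meta, plan)[0]
                pos = ss.meta.set_index("section_id").position_cm
                d = (beta.sample_a.map(pos) - beta.sample_b.map(pos)).abs()
                rhos[strategy] = spearmanr(d, beta.bray_curtis).statistic
            wins += rhos["discontiguous"] < rhos["contiguous"]
        assert wins >= 0.9 * n_runs

    def test_beta_dispersion_falls_without_rarefaction_too(self):
        table, meta, _ = _gradient_table(seed=33)
        sweep = strategy_sweep(table, meta, [1, 10], ["contiguous"],
                               depth=0, iterations=2, seed=3,
                               rarefy_samples=False)
        beta = sweep["beta"].groupby("k").bray_curtis.mean()
        assert beta.loc[1] > beta.loc[10]
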