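"""Paired-line exposure screen: normalization, ratios, regions, panel."""

import numpy as np
import pandas as pd
import pytest

from arecamir.ane import (
    CENTER,
    REGION_GRID,
    assign_region,
    build_ane_panel,
    classify_dysregulation,
    group_ratio,
    normalize_matrix,
)
from arecamir.io import ExpressionMatrix
from arecamir.simulate import SimConfig, simulate_ane_experiment


class TestNormalize:
    def test_idempotent(self, toy_paired_matrix):
        once = normalize_matrix(toy_paired_matrix)
        twice = normalize_matrix(once)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-9)

    def test_scale_invariance_of_downstream_ratios(self, toy_paired_matrix):
        scaled = toy_paired_matrix.values.copy()
        scaled["L1_exposed_0"] *= 10.0
        m = ExpressionMatrix(scaled, toy_paired_matrix.annotations.copy())
        r_orig = group_ratio(normalize_matrix(toy_paired_matrix), "L1")
        r_scaled = group_ratio(normalize_matrix(m), "L1")
        np.testing.assert_allclose(r_orig, r_scaled, rtol=1e-9)

    def test_recovers_planted_chip_scales(self):
        cfg = SimConfig(seed=3, noise_sigma=0.0, n_common_up=0, n_common_down=0,
                        n_discordant=0)
        m, truth = simulate_ane_experiment(cfg)
        normed = normalize_matrix(m)
        corr = normed.meta["scale_corrections"]
        # corrections should undo planted scales up to one global constant
        rel = np.array([corr[s] * truth.scale_factors[s] for s in m.samples])
        assert rel.max() / rel.min() < 1.01

    def test_all_zero_sample_rejected(self, toy_paired_matrix):
        vals = toy_paired_matrix.values.copy()
        vals["L1_parental_0"] = 0.0
        m = ExpressionMatrix(vals, toy_paired_matrix.annotations.copy())
        with pytest.raises(ValueError, match="all-zero"):
            normalize_matrix(m)


class TestGroupRatio:
    def test_identical_groups_give_unity(self, toy_paired_matrix):
        vals = toy_paired_matrix.values.copy()
        vals["L1_exposed_0"] = vals["L1_parental_0"]
        m = ExpressionMatrix(vals, toy_paired_matrix.annotations.copy())
        assert group_ratio(m, "L1").tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_singleton_direct_division(self, toy_paired_matrix):
        r = group_ratio(toy_paired_matrix, "L1")
        assert r["mirA"] == pytest.approx(2.0)
        assert r["mirB"] == pytest.approx(0.5)
        assert r["mirC"] == pytest.approx(1.0)

    def test_missing_group_names_the_condition(self, toy_paired_matrix):
        with pytest.raises(ValueError, match="L3"):
            group_ratio(toy_paired_matrix, "L3")

    def test_planted_effect_recovered_within_band(self):
        """2.5x planted effect, sigma=0.1, n=3: measured ratio near truth
        for the vast majority of seeds."""
        hits = total = 0
        for seed in range(50):
            cfg = SimConfig(
                seed=seed, n_mirnas=20, n_common_up=5, n_common_down=0,
                n_discordant=0, effect=2.5, noise_sigma=0.1, chip_scale_sigma=0.0,
            )
            m, truth = simulate_ane_experiment(cfg)
            r = group_ratio(m, "OECM1")
            for p in truth.planted_up:
                total += 1
                hits += 2.2 <= r[p] <= 2.8
        assert hits / total >= 0.78  # ~86% per-draw coverage expected


class TestClassifyAndRegions:
    @pytest.mark.parametrize(
        "r,expected",
        [(1.2, "up"), (1 / 1.2, "down"), (1.0, "none"), (1.19, "none"), (3.0, "up")],
    )
    def test_threshold_inclusive(self, r, expected):
        assert classify_dysregulation(r) == expected

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_dysregulation(1.5, threshold=1.0)

    def test_exhaustive_enumeration(self):
        """All 9 ordered call pairs yield 8 distinct regions plus CENTER."""
        labels = [
            assign_region(a, b)
            for a in ("up", "down", "none")
            for b in ("up", "down", "none")
        ]
        assert sorted(labels) == sorted([f"R{i}" for i in range(1, 9)] + [CENTER])
        assert assign_region("up", "up") == "R2"
        assert assign_region("down", "down") == "R6"
        assert assign_region("none", "none") == CENTER

    def test_direction_symmetry(self):
        """Swapping up<->down in both lines maps R1<->R5, R2<->R6, R3<->R7, R4<->R8."""
        flip = {"up": "down", "down": "up", "none": "none"}
        partner = {"R1": "R5", "R2": "R6", "R3": "R7", "R4": "R8",
                   "R5": "R1", "R6": "R2", "R7": "R3", "R8": "R4", CENTER: CENTER}
        for (a, b), label in REGION_GRID.items():
            assert assign_region(flip[a], flip[b]) == partner[label]


class TestBuildPanel:
    def test_toy_matrix_hand_calls(self, toy_paired_matrix):
        panel = build_ane_panel(toy_paired_matrix, normalize=False)
        assert panel.table.loc["mirA", "region"] == "R2"
        assert panel.table.loc["mirB", "region"] == "R6"
        assert panel.table.loc["mirC", "region"] == CENTER
        assert panel.singleton_groups

    def test_requires_two_lines(self, toy_paired_matrix):
        with pytest.raises(ValueError, match="two cell lines"):
            build_ane_panel(toy_paired_matrix, lines=["L1"])

    def test_partition_identity_and_recovery(self):
        """Planted 40 common-up / 40 common-down / 10 discordant in 500
        miRNAs at sigma=0.05: the region sets partition the features and
        the concordant sets are recovered nearly exactly."""
        cfg = SimConfig(seed=11, noise_sigma=0.05)
        m, truth = simulate_ane_experiment(cfg)
        panel = build_ane_panel(m)
        total = (
            len(panel.up_any) + len(panel.down_any)
            + len(panel.discordant) + len(panel.center)
        )
        assert total == len(panel.table) == cfg.n_mirnas
        assert len(panel.common_up & truth.planted_up) >= 38
        assert len(panel.common_down & truth.planted_down) >= 38
        assert panel.discordant >= truth.planted_discordant

    def test_all_null_center_dominant(self):
        cfg = SimConfig(seed=5, n_common_up=0, n_common_down=0, n_discordant=0,
                        noise_sigma=0.05)
        m, _ = simulate_ane_experiment(cfg)
        panel = build_ane_panel(m)
        assert len(panel.center) > 0.9 * cfg.n_mirnas

    def test_sample_scaling_leaves_calls_unchanged(self):
        cfg = SimConfig(seed=2, n_mirnas=100, n_common_up=10, n_common_down=10,
                        n_discordant=2)
        m, _ = simulate_ane_experiment(cfg)
        panel = build_ane_panel(m)
        scaled_vals = m.values.copy()
        scaled_vals.iloc[:, 0] *= 37.0
        scaled = ExpressionMatrix(scaled_vals, m.annotations.copy())
        panel2 = build_ane_panel(scaled)
        assert (panel.table["region"] == panel2.table["region"]).all()
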