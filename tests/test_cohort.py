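"""Cohort screen: admixture scoring, purity, de-mixing, t-test, panel."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arecamir.cohort import (
    PuritySignatures,
    build_cohort_panel,
    estimate_purity,
    purity_adjust,
    ssgsea_enrichment,
    unpaired_t,
)
from arecamir.simulate import SimConfig, simulate_cohort

GENES = [f"G{i:03d}" for i in range(120)]


def _sample(rng=None, values=None):
    if values is None:
        values = np.random.default_rng(0).lognormal(6, 1, len(GENES))
    return pd.Series(values, index=GENES)


class TestSsgsea:
    def test_directionality(self):
        expr = _sample(values=np.arange(len(GENES), dtype=float) + 1)
        top = GENES[-15:]  # highest expression
        bottom = GENES[:15]
        assert ssgsea_enrichment(expr, top) > 0
        assert ssgsea_enrichment(expr, bottom) < 0

    def test_monotone_transform_invariance(self):
        expr = _sample()
        gene_set = GENES[::7]
        squashed = np.log1p(expr) ** 0.5
        assert ssgsea_enrichment(expr, gene_set) == pytest.approx(
            ssgsea_enrichment(squashed, gene_set)
        )

    def test_random_set_mean_score_near_zero(self):
        rng = np.random.default_rng(42)
        expr = _sample()
        scores = []
        for _ in range(200):
            gene_set = rng.choice(GENES, size=20, replace=False)
            scores.append(ssgsea_enrichment(expr, gene_set))
        assert abs(np.mean(scores)) < 0.05

    def test_small_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ssgsea_enrichment(_sample(), GENES[:5])


def _admixture_cohort(contaminations):
    """Gene expression for samples mixed with stroma at given fractions."""
    sigs = PuritySignatures(frozenset(GENES[:20]), frozenset(GENES[20:40]))
    tumor = np.full(len(GENES), 500.0)
    tumor[:40] = 50.0  # malignant cells barely express the markers
    stroma = np.full(len(GENES), 500.0)
    stroma[:40] = 5000.0  # stromal/immune markers high in the admixture
    scores = []
    for c in contaminations:
        expr = pd.Series((1 - c) * tumor + c * stroma, index=GENES)
        scores.append(
            ssgsea_enrichment(expr, sigs.stromal_genes)
            + ssgsea_enrichment(expr, sigs.immune_genes)
        )
    return np.array(scores)


class TestPurity:
    def test_monotone_in_contamination(self):
        grid = np.linspace(0.0, 0.95, 20)
        scores = _admixture_cohort(grid)
        purity = estimate_purity(scores)
        assert (np.diff(purity) <= 1e-12).all()

    def test_pure_and_half_mixed_calibration(self):
        grid = np.linspace(0.0, 0.95, 20)
        purity = estimate_purity(_admixture_cohort(grid))
        assert purity[0] >= 0.95  # zero contamination
        half = np.argmin(np.abs(grid - 0.5))
        assert purity[half] == pytest.approx(0.5, abs=0.1)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            estimate_purity([0.1, np.nan])
        with pytest.raises(ValueError):
            estimate_purity([0.1, 0.2], purity_range=(0.0, 1.0))


class TestDemixing:
    def test_identity_at_full_purity(self):
        obs = np.array([10.0, 20.0, 30.0])
        ref = np.array([5.0, 5.0, 5.0])
        np.testing.assert_allclose(purity_adjust(obs, 1.0, ref), obs)

    def test_exact_algebraic_inverse(self):
        rng = np.random.default_rng(1)
        tumor = rng.lognormal(5, 1, 50)
        normal = rng.lognormal(5, 1, 50)
        observed = 0.6 * tumor + 0.4 * normal
        np.testing.assert_allclose(purity_adjust(observed, 0.6, normal), tumor, rtol=1e-9)

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            purity_adjust(np.ones(3), 0.0, np.ones(3))
        with pytest.raises(ValueError):
            purity_adjust(np.ones(3), 1.2, np.ones(3))

    def test_noisy_grid_error_reduction(self):
        """Across a purity grid with noise, de-mixed profiles are closer to
        the tumor-intrinsic truth than the raw observations."""
        rng = np.random.default_rng(9)
        tumor = rng.lognormal(5, 1, 200)
        normal = rng.lognormal(5, 1, 200)
        raw_err = adj_err = 0.0
        for p in np.linspace(0.3, 0.9, 7):
            noise = np.exp(rng.normal(0, 0.05, 200))
            observed = (p * tumor + (1 - p) * normal) * noise
            adjusted = purity_adjust(observed, p, normal)
            raw_err += np.abs(np.log(observed / tumor)).mean()
            adj_err += np.abs(np.log(np.maximum(adjusted, 1e-9) / tumor)).mean()
        assert adj_err < raw_err


class TestUnpairedT:
    def test_identical_groups(self):
        x = np.array([3.0, 4.0, 5.0])
        assert unpaired_t(x, x) == pytest.approx(1.0)

    def test_degenerate_equal_and_unequal(self):
        assert unpaired_t([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert unpaired_t([2.0, 2.0], [4.0, 4.0]) == 0.0

    @pytest.mark.parametrize("variant", ["welch", "student"])
    def test_matches_hand_computed_formula(self, variant):
        """Textbook two-sample case cross-checked against the explicit
        t-statistic and degrees-of-freedom formulas."""
        a = np.log2([120.0, 150.0, 98.0, 132.0, 141.0])
        b = np.log2([88.0, 95.0, 102.0, 79.0])
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        if variant == "welch":
            se2 = va / na + vb / nb
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
            df = na + nb - 2
        expected = 2 * stats.t.sf(abs(t), df)
        got = unpaired_t(2.0**a, 2.0**b, variant=variant)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [2.0, 3.0])


class TestBuildPanel:
    def test_planted_recovery_with_calibration(self):
        cfg = SimConfig(seed=21)
        m, truth = simulate_cohort(cfg)
        panel = build_cohort_panel(m)
        assert panel.calibrated
        planted_up = {k for k, v in truth.cohort_de.items() if v > 0}
        planted_down = {k for k, v in truth.cohort_de.items() if v < 0}
        planted = planted_up | planted_down
        sens = len(panel.selected & planted) / len(planted)
        fdr = (
            len(panel.selected - planted) / len(panel.selected)
            if panel.selected
            else 0.0
        )
        assert sens >= 0.9
        assert fdr <= 0.1
        assert panel.overexpressed >= planted_up & panel.selected
        assert panel.underexpressed >= planted_down & panel.selected

    def test_direction_sets_partition_selected(self, small_cohort_matrix):
        panel = build_cohort_panel(small_cohort_matrix, calibrate_purity=False)
        assert panel.overexpressed | panel.underexpressed == panel.selected
        assert not panel.overexpressed & panel.underexpressed

    def test_selection_monotone_in_thresholds(self):
        m, _ = simulate_cohort(SimConfig(seed=4))
        loose = build_cohort_panel(m, fr_threshold=1.2, alpha=0.05)
        tight_fr = build_cohort_panel(m, fr_threshold=1.5, alpha=0.05)
        tight_a = build_cohort_panel(m, fr_threshold=1.2, alpha=0.01)
        assert tight_fr.selected <= loose.selected
        assert tight_a.selected <= loose.selected

    def test_null_cohort_selects_few(self):
        cfg = SimConfig(seed=13, cohort_n_up=0, cohort_n_down=0)
        m, _ = simulate_cohort(cfg)
        panel = build_cohort_panel(m)
        assert len(panel.selected) <= 0.05 * cfg.cohort_n_mirnas

    def test_missing_tissue_class_rejected(self, small_cohort_matrix):
        vals = small_cohort_matrix.values[
            [c for c in small_cohort_matrix.samples if c.startswith("tumor")]
        ]
        from arecamir.io import ExpressionMatrix

        m = ExpressionMatrix(vals, small_cohort_matrix.annotations.loc[vals.columns])
        with pytest.raises(ValueError, match="normal"):
            build_cohort_panel(m)

    def test_bh_reported_alongside(self):
        m, _ = simulate_cohort(SimConfig(seed=2))
        panel = build_cohort_panel(m, bh=True)
        assert "q" in panel.table
        assert (panel.table["q"] >= panel.table["p"] - 1e-12).all()
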