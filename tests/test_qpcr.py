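"""qPCR arithmetic tests: Ct capping, molecule counts, ratios, Welch test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recurcna.config import QpcrConfig, SimConfig
from recurcna.probemap import build_probe_map
from recurcna.qpcr import (
    ct_to_molecules,
    folded_ratio,
    plate_allelic_ratios,
    preprocess_ct,
    region_group_comparison,
    region_summaries,
    sample_allelic_ratio,
    select_validation_snps,
    welch_test,
)
from recurcna.synthetic import TruthProfile, TruthSegment, build_snp_panel, simulate_ct_plate


class TestPreprocessCt:
    @pytest.mark.parametrize("ct,expected", [(33.0, 30.0), (np.nan, 30.0), (24.5, 24.5), (30.0, 30.0)])
    def test_cap_rule(self, ct, expected):
        assert preprocess_ct([ct])[0] == expected

    @given(st.lists(st.floats(0, 45, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        once = preprocess_ct(values)
        np.testing.assert_array_equal(preprocess_ct(once), once)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            preprocess_ct([-1.0])


class TestCtToMolecules:
    @pytest.mark.parametrize("ct,expected", [(26.0, 1.0), (25.0, 2.0), (30.0, 0.0625)])
    def test_anchor_values(self, ct, expected):
        assert ct_to_molecules(ct) == pytest.approx(expected)

    def test_halves_per_cycle_and_decreasing(self):
        grid = np.arange(10.0, 35.0, 0.5)
        m = ct_to_molecules(grid)
        np.testing.assert_allclose(m[2:] / m[:-2], 0.5, rtol=1e-12)
        assert np.all(np.diff(m) < 0)


class TestAllelicRatio:
    def test_balance_and_arithmetic(self):
        r, flag = sample_allelic_ratio(pd.Series([4.0]), pd.Series([4.0]), 10.0, 10.0)
        assert r[0] == pytest.approx(1.0) and not flag[0]
        r, _ = sample_allelic_ratio(pd.Series([8.0]), pd.Series([4.0]), 10.0, 10.0)
        assert r[0] == pytest.approx(2.0)

    def test_channel_bias_cancels(self):
        # A = 2B per SNP but the sample's A channel total is also doubled
        r, _ = sample_allelic_ratio(pd.Series([8.0]), pd.Series([4.0]), 20.0, 10.0)
        assert r[0] == pytest.approx(1.0)

    def test_global_scaling_invariance(self):
        a = pd.Series([3.0, 5.0, 1.0])
        b = pd.Series([2.0, 4.0, 6.0])
        r1, _ = sample_allelic_ratio(a, b, a.sum(), b.sum())
        r2, _ = sample_allelic_ratio(a * 7, b * 0.3, a.sum() * 7, b.sum() * 0.3)
        np.testing.assert_allclose(r1, r2)

    def test_zero_b_sentinel(self):
        r, flag = sample_allelic_ratio(pd.Series([1.0]), pd.Series([0.0]), 2.0, 1.0)
        assert flag[0] and r[0] == QpcrConfig().max_ratio_sentinel

    def test_plate_pipeline_replicate_average(self):
        ct = pd.DataFrame(
            {
                "sample_id": "S1",
                "snp_id": ["x"] * 4,
                "replicate": [1, 2, 1, 2],
                "channel": ["A", "A", "B", "B"],
                "ct": [25.0, 25.0, 26.0, 26.0],
            }
        )
        out = plate_allelic_ratios(ct)
        # one SNP: normalization divides by totals, ratio returns to 1
        assert out["ratio"].iloc[0] == pytest.approx(1.0)
        assert not out["zero_b_flag"].iloc[0]


class TestWelch:
    def test_textbook_hand_computation(self):
        x = np.array([19.8, 20.4, 19.6])
        y = np.array([28.2, 26.6, 20.1])
        t, df, p = welch_test(x, y)
        # hand computation of the Welch formulas
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 3 + vy / 3
        t_hand = (x.mean() - y.mean()) / np.sqrt(se2)
        df_hand = se2**2 / (vx**2 / (9 * 2) + vy**2 / (9 * 2))
        assert t == pytest.approx(t_hand, abs=1e-6)
        assert df == pytest.approx(df_hand, abs=1e-6)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df_hand), abs=1e-6)

    def test_identical_groups(self):
        t, _, p = welch_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_equal_constants(self):
        t, _, p = welch_test(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert t == 0.0 and p == 1.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            welch_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestPanelSelection:
    def _het_table(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "region", "het_fraction"])

    def test_threshold_and_ranking(self):
        rows = [(f"s{i:02d}", "7p", 0.30 + 0.01 * i) for i in range(30)]
        panel = select_validation_snps(self._het_table(rows))
        sel = panel[panel["region"] == "7p"]
        assert len(sel) == 16
        assert sel["het_fraction"].min() >= 0.40
        assert set(sel["snp_id"]) == {f"s{i:02d}" for i in range(14, 30)}

    def test_short_region_warns_and_returns_all(self):
        rows = [("a", "7q", 0.5), ("b", "7q", 0.45), ("c", "7q", 0.1)]
        with pytest.warns(UserWarning):
            panel = select_validation_snps(self._het_table(rows))
        assert set(panel[panel["region"] == "7q"]["snp_id"]) == {"a", "b"}

    def test_deterministic_tie_break(self):
        rows = [(s, "13", 0.44) for s in "zyxwvutsrqponmlkjihg"]
        panel = select_validation_snps(self._het_table(rows))
        sel = panel[panel["region"] == "13"]["snp_id"].tolist()
        assert sel == sorted(sel)


class TestRegionComparison:
    def test_identical_group_data_gives_p_one(self):
        summaries = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d", "e", "f"],
                "region": "7p",
                "mean_folded_ratio": [1.0, 1.2, 1.4, 1.0, 1.2, 1.4],
            }
        )
        groups = pd.Series(
            ["L", "L", "L", "C", "C", "C"], index=["a", "b", "c", "d", "e", "f"]
        )
        out = region_group_comparison(summaries, groups, "L-vs-C")
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_balanced_vs_imbalanced_end_to_end(self):
        """L tumors (balanced chr7) vs controls (imbalanced chr7) separate on
        the folded ratio through the full plate arithmetic."""
        pm = build_probe_map(8, 40, seed=2)
        panel_all = build_snp_panel(pm)
        het = panel_all.rename(columns={"population_het": "het_fraction"})
        panel = select_validation_snps(het).merge(
            panel_all[["snp_id", "chrom", "probe_idx"]], on="snp_id"
        )
        cfg = SimConfig(ct_noise_sd=0.10)

        def truth(c, b):
            return TruthProfile(
                {ch: [TruthSegment(0, len(pm.chrom_index(ch)), c, b)] for ch in pm.chromosomes}
            )

        truths = {f"L{i}": truth(2, 1) for i in range(6)}
        truths.update({f"C{i}": truth(3, 1) for i in range(8)})
        ct, geno = simulate_ct_plate(truths, panel, pm, 64.0, cfg, 5)
        ratios = plate_allelic_ratios(ct)
        summaries = region_summaries(ratios, panel, geno)
        groups = pd.Series(
            {**{f"L{i}": "L" for i in range(6)}, **{f"C{i}": "C" for i in range(8)}}
        )
        out = region_group_comparison(summaries, groups, "L-vs-C").set_index("region")
        assert out.loc["7p", "p"] < 0.05
        assert out.loc["7p", "t"] < 0  # L group has ratios nearer 1

    def test_folded_ratio_symmetry(self):
        r = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        np.testing.assert_allclose(folded_ratio(r), folded_ratio(1 / r))
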