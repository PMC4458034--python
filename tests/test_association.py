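"""Association tests: global test, BH, chromosome status, exact Fisher."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from _oracles import bh_oracle, fisher_oracle
from recurcna.association import (
    UndefinedTestError,
    bh_adjust,
    chromosome_status,
    combine_status,
    fisher_rxc,
    global_test,
    hierarchical_test,
    status_group_test,
)
from recurcna.config import AssociationConfig
from recurcna.probemap import build_probe_map


# ---------------------------------------------------------------------------
# global test


class TestGlobalTest:
    def test_constant_features_give_null_statistic(self):
        X = np.zeros((4, 10))
        y = np.r_[np.ones(5), np.zeros(5)]
        q, p = global_test(X, y, 100, 0)
        assert q == 0.0 and p == 1.0

    def test_single_feature_reduces_to_squared_score(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = np.r_[np.ones(12), np.zeros(18)]
        q, _ = global_test(x[None, :], y, 100, 0)
        z = (x - x.mean()) / x.std()
        assert q == pytest.approx(float((z @ (y - y.mean())) ** 2))
        # monotone in squared sample correlation
        qs = []
        for slope in (0.0, 0.5, 1.0, 2.0):
            feat = slope * (y - y.mean()) + rng.normal(size=30) * 0.5
            q_i, _ = global_test(feat[None, :], y, 100, 1)
            qs.append(q_i)
        assert qs == sorted(qs)

    def test_detects_strong_association(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(15), np.zeros(15)]
        X = y[None, :] * 2 + rng.normal(size=(20, 30)) * 0.3
        _, p = global_test(X, y, 2000, 2)
        assert p < 0.01

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            global_test(np.random.default_rng(0).normal(size=(3, 8)), np.ones(8), 10, 0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(UndefinedTestError):
            global_test(np.empty((0, 8)), np.r_[np.ones(4), np.zeros(4)], 10, 0)

    def test_null_calibration_quick(self):
        """Type-I error at alpha=0.05 over 300 null replicates (coarse check;
        the fine-grained calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            X = rng.normal(size=(10, 24))
            y = np.r_[np.ones(12), np.zeros(12)]
            rng.shuffle(y)
            _, p = global_test(X, y, 400, rng)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_permutation_p_valid_under_label_exchange(self):
        """Permutation p-values are stochastically >= uniform under the null."""
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            X = rng.normal(size=(5, 20))
            y = np.r_[np.ones(10), np.zeros(10)]
            rng.shuffle(y)
            ps.append(global_test(X, y, 200, rng)[1])
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        # one-sided: ECDF should not exceed uniform by more than sampling noise
        assert np.max(ecdf - ps) < 0.12


# ---------------------------------------------------------------------------
# BH adjustment


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.04, 0.03, 0.8], [0.02, 0.053333333, 0.053333333, 0.8]),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-6)

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40).map(np.array)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_and_statsmodels(self, p):
        ours = bh_adjust(p)
        np.testing.assert_allclose(ours, bh_oracle(p), atol=1e-12)
        np.testing.assert_allclose(
            ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        # order preserving in the sorted sense
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(ours[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.2])


# ---------------------------------------------------------------------------
# exact Fisher


class TestFisherRxc:
    def test_printed_status_tables(self):
        """The two chromosome-status tables anchor the exact test."""
        assert fisher_rxc([[9, 0, 0], [19, 25, 1]]) == pytest.approx(0.0025, abs=5e-5)
        assert fisher_rxc([[7, 1, 1], [5, 33, 7]]) <= 2e-4

    def test_tiny_table_by_hand(self):
        # margins (2,2)/(2,2): three tables, observed prob 1/6 each extreme
        assert fisher_rxc([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_matches_scipy_2x2(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_rxc(t) == pytest.approx(fisher_exact(t)[1], rel=1e-9)

    def test_oracle_all_2x2_small(self):
        for total in range(1, 8):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        t = [[a, b], [c, total - a - b - c]]
                        assert fisher_rxc(t) == pytest.approx(fisher_oracle(t), abs=1e-10)

    def test_oracle_random_2x3(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 30:
            t = rng.multinomial(rng.integers(2, 13), np.full(6, 1 / 6)).reshape(2, 3)
            if t.sum() == 0:
                continue
            assert fisher_rxc(t) == pytest.approx(fisher_oracle(t), abs=1e-10)
            checked += 1

    @pytest.mark.parametrize("bad", [[[1]], [[1, -2], [0, 3]], [[0.5, 1], [1, 1]], [[0, 0], [0, 0]]])
    def test_invalid_tables(self, bad):
        with pytest.raises(ValueError):
            fisher_rxc(bad)


# ---------------------------------------------------------------------------
# chromosome status


def _segments(chrom_classes):
    """Build a minimal segment-call frame: (chrom, class, n_het) triples."""
    rows = []
    for chrom, klass, n_het in chrom_classes:
        rows.append(
            {
                "chrom": chrom,
                "start_idx": 0,
                "end_idx": n_het,
                "n_probes": n_het,
                "n_het": n_het,
                "allelic_class": klass,
            }
        )
    df = pd.DataFrame(rows)
    df["allelic_class"] = df["allelic_class"].astype("Int64")
    return df


class TestChromosomeStatus:
    def test_unanimous(self):
        assert chromosome_status(_segments([(7, 1, 40), (7, 1, 30)]), 7) == 1

    def test_most_abundant_wins(self):
        assert chromosome_status(_segments([(7, 1, 40), (7, 2, 60)]), 7) == 2

    def test_tie_resolves_to_higher_class(self):
        assert chromosome_status(_segments([(7, 1, 50), (7, 3, 50)]), 7) == 3

    def test_missing_when_no_informative_segment(self):
        assert chromosome_status(_segments([(7, None, 0)]), 7) is None

    def test_probe_weighting_option(self):
        segs = _segments([(7, 1, 40), (7, 2, 60)])
        segs.loc[0, "n_probes"] = 100
        assert chromosome_status(segs, 7, "probes") == 1

    def test_combine_rule(self):
        assert combine_status(1, 2) == 2
        assert combine_status(3, 1) == 3
        assert combine_status(1, 1) == 1
        assert combine_status(None, 2) is None

    @given(st.integers(1, 3), st.integers(1, 3))
    @settings(max_examples=20, deadline=None)
    def test_combine_commutative_and_dominant(self, a, b):
        assert combine_status(a, b) == combine_status(b, a) == max(a, b)


class TestStatusGroupTest:
    def test_printed_table_reconstruction(self):
        statuses = pd.Series(
            [1] * 9 + [1] * 19 + [2] * 25 + [3] * 1,
            index=[f"P{i}" for i in range(54)],
        )
        groups = pd.Series(["L"] * 9 + ["C"] * 45, index=statuses.index)
        table, p = status_group_test(statuses, groups, "L-vs-C")
        assert table.values.tolist() == [[9, 0, 0], [19, 25, 1]]
        assert p == pytest.approx(0.0025, abs=5e-5)

    def test_identical_distributions_give_p_one(self):
        statuses = pd.Series([1, 2, 3] * 8, index=[f"P{i}" for i in range(24)])
        groups = pd.Series(["L", "C"] * 12, index=statuses.index)
        # L and C both see statuses 1, 2, 3 equally often
        table, p = status_group_test(statuses, groups, "L-vs-C")
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        statuses = pd.Series([1, 2], index=["a", "b"])
        groups = pd.Series(["C", "C"], index=statuses.index)
        with pytest.raises(ValueError):
            status_group_test(statuses, groups, "L-vs-C")


# ---------------------------------------------------------------------------
# hierarchy gating


class TestHierarchy:
    def _matrices(self, effect: bool, seed=0):
        pm = build_probe_map(3, 20, seed=1)
        rng = np.random.default_rng(seed)
        patients = [f"L{i}" for i in range(8)] + [f"C{i}" for i in range(12)]
        groups = pd.Series(["L"] * 8 + ["C"] * 12, index=patients)
        cn = pd.DataFrame(
            rng.normal(1, 0.05, (20, len(pm))), index=patients, columns=pm.df["probe_id"]
        )
        cls = pd.DataFrame(1.0, index=patients, columns=pm.df["probe_id"])
        if effect:
            idx = pm.arm_index("2p")
            cls.iloc[8:, idx] = 3.0  # controls carry LOH on 2p
        return cn, cls, groups, pm

    def test_gated_hierarchy_silent_without_genome_signal(self):
        cn, cls, groups, pm = self._matrices(effect=False)
        cfg = AssociationConfig(n_perm_genome=300, n_perm_arm=300, n_perm_region=200)
        results = hierarchical_test(cn, cls, groups, pm, "L-vs-C", cfg, seed=3)
        genome = [r for r in results if r.level == "genome"]
        arms = [r for r in results if r.level == "arm"]
        assert len(genome) == 2
        for g in genome:
            if g.p_value >= cfg.alpha:
                assert not [a for a in arms if a.datatype == g.datatype]

    def test_effect_flags_the_right_arm(self):
        cn, cls, groups, pm = self._matrices(effect=True)
        cfg = AssociationConfig(n_perm_genome=500, n_perm_arm=500, n_perm_region=300)
        results = hierarchical_test(cn, cls, groups, pm, "L-vs-C", cfg, seed=3)
        arm_hits = [
            r.scope
            for r in results
            if r.level == "arm" and r.datatype == "allelic" and r.p_adjusted < 0.05
        ]
        assert "2p" in arm_hits
        # regions of the accepted arm were tested and BH-adjusted within the arm
        regions = [r for r in results if r.level == "region" and r.scope.startswith("2p")]
        assert regions and all(r.p_adjusted >= r.p_value for r in regions)

    def test_unknown_comparison_rejected(self):
        cn, cls, groups, pm = self._matrices(effect=False)
        with pytest.raises(ValueError):
            hierarchical_test(cn, cls, groups, pm, "X-vs-C", seed=0)
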