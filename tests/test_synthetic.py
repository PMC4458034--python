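"""Generator tests: probe maps, truth profiles, assay mixtures, cohorts, plates."""

import numpy as np
import pandas as pd
import pytest

from recurcna.config import SimConfig
from recurcna.probemap import build_probe_map
from recurcna.synthetic import (
    MatchingError,
    TruthProfile,
    TruthSegment,
    build_snp_panel,
    simulate_assay_pair,
    simulate_cohort,
    simulate_ct_plate,
    simulate_study_table,
    simulate_truth_profile,
)


class TestProbeMap:
    def test_construction_counts_and_order(self):
        pm = build_probe_map(n_chromosomes=1, probes_per_arm=10, seed=0)
        assert len(pm) == 20
        assert np.all(np.diff(pm.positions(1)) > 0)

    def test_determinism(self):
        a = build_probe_map(22, 20, seed=3)
        b = build_probe_map(22, 20, seed=3)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_full_genome_arm_counts(self):
        pm = build_probe_map(22, 120, seed=1)
        assert len(pm) == 5280
        counts = pm.df.groupby("arm_label").size()
        assert (counts == 120).all() and len(counts) == 44

    def test_empty_arm_support(self):
        pm = build_probe_map(22, 120, seed=1, empty_arms=("13p",))
        assert len(pm) == 5160
        assert "13p" not in pm.arm_labels

    @pytest.mark.parametrize("bad", [{"n_chromosomes": 0}, {"probes_per_arm": 1}])
    def test_invalid_sizes(self, bad):
        with pytest.raises(ValueError):
            build_probe_map(**{"n_chromosomes": 2, "probes_per_arm": 10, **bad})


class TestTruthProfile:
    def test_null_configuration_is_diploid_het(self, small_probe_map):
        cfg = SimConfig(
            chr7_imbalance_prob=dict.fromkeys("C L D LD".split(), 0.0),
            chr7_loh_prob=dict.fromkeys("C L D LD".split(), 0.0),
            chr13_imbalance_prob=dict.fromkeys("C L D LD".split(), 0.0),
            chr13_loh_prob=dict.fromkeys("C L D LD".split(), 0.0),
            background_gain_rate=dict.fromkeys("C L D LD".split(), 0.0),
            background_loss_rate=dict.fromkeys("C L D LD".split(), 0.0),
        )
        t = simulate_truth_profile("C", small_probe_map, cfg, 0)
        c, b = t.per_probe(small_probe_map)
        assert np.all(c == 2) and np.all(b == 1)

    def test_l_group_retains_chromosome_7(self):
        pm = build_probe_map(8, 30, seed=0)
        cfg = SimConfig()
        for seed in range(20):
            t = simulate_truth_profile("L", pm, cfg, seed)
            for seg in t.segments[7]:
                assert seg.total_copies == 2 * seg.b_copies

    def test_control_imbalance_prior_monte_carlo(self):
        pm = build_probe_map(8, 30, seed=0)
        cfg = SimConfig()
        cfg.chr7_imbalance_prob["C"] = 0.5
        cfg.chr7_loh_prob["C"] = 0.0
        rng = np.random.default_rng(0)
        frac = np.mean(
            [
                simulate_truth_profile("C", pm, cfg, rng).segments[7][0].total_copies == 3
                for _ in range(500)
            ]
        )
        # binomial(500, .5) 99.9% interval
        assert 0.5 - 3.3 * 0.5 / np.sqrt(500) < frac < 0.5 + 3.3 * 0.5 / np.sqrt(500)

    def test_unknown_group_rejected(self, small_probe_map):
        with pytest.raises(ValueError):
            simulate_truth_profile("X", small_probe_map, SimConfig(), 0)

    def test_tiling_validation(self, small_probe_map):
        n = len(small_probe_map.chrom_index(1))
        t = TruthProfile({1: [TruthSegment(0, n - 5, 2, 1)], 2: [TruthSegment(0, n, 2, 1)]})
        with pytest.raises(ValueError):
            t.validate(small_probe_map)


def _uniform_truth(probe_map, c, b):
    return TruthProfile(
        {
            chrom: [TruthSegment(0, len(probe_map.chrom_index(chrom)), c, b)]
            for chrom in probe_map.chromosomes
        }
    )


class TestAssayMixture:
    def _noise_free(self, **kw):
        return SimConfig(noise_sd_cn=0.0, noise_sd_baf=0.0, wave_amplitude=0.0, **kw)

    @pytest.mark.parametrize(
        "rho,c,b,exp_ratio,exp_baf",
        [
            (1.0, 2, 1, 1.0, 0.5),
            (1.0, 1, 0, 0.5, 0.0),
            (0.5, 3, 2, 1.25, 0.6),
        ],
    )
    def test_zero_noise_mixture_values(self, small_probe_map, rho, c, b, exp_ratio, exp_baf):
        cfg = self._noise_free(purity=rho)
        truth = _uniform_truth(small_probe_map, c, b)
        a = simulate_assay_pair(
            truth, small_probe_map, cfg, 0, randomize_parental_phase=False
        )
        assert a.tumor_cn == pytest.approx(exp_ratio, abs=1e-9)
        het = a.germline_genotype == 1
        assert het.any()
        assert a.tumor_baf[het] == pytest.approx(exp_baf, abs=1e-9)

    def test_mixture_grid_consistency(self, small_probe_map):
        """Zero-noise outputs equal the closed-form mixture on a (rho, c, b) grid."""
        for rho in (0.3, 0.6, 1.0):
            for c, b in [(1, 0), (2, 0), (2, 1), (3, 1), (4, 2)]:
                cfg = self._noise_free(purity=rho)
                truth = _uniform_truth(small_probe_map, c, b)
                a = simulate_assay_pair(
                    truth, small_probe_map, cfg, 1, randomize_parental_phase=False
                )
                denom = rho * c + (1 - rho) * 2
                assert a.tumor_cn == pytest.approx(denom / 2, abs=1e-9)
                het = a.germline_genotype == 1
                expected_baf = (rho * b + (1 - rho)) / denom
                assert a.tumor_baf[het] == pytest.approx(expected_baf, abs=1e-9)

    def test_invalid_purity(self, small_probe_map):
        truth = _uniform_truth(small_probe_map, 2, 1)
        with pytest.raises(ValueError):
            simulate_assay_pair(truth, small_probe_map, SimConfig(purity=0.0), 0)

    def test_determinism(self, small_probe_map):
        truth = _uniform_truth(small_probe_map, 3, 1)
        a = simulate_assay_pair(truth, small_probe_map, SimConfig(), 5)
        b = simulate_assay_pair(truth, small_probe_map, SimConfig(), 5)
        np.testing.assert_array_equal(a.tumor_cn, b.tumor_cn)
        np.testing.assert_array_equal(a.tumor_baf, b.tumor_baf)


class TestCohort:
    def test_requested_group_sizes(self):
        cohort = simulate_cohort(SimConfig(), 0)
        sizes = cohort.groupby("group").size()
        assert sizes["C"] == 46 and sizes["L"] == 10
        assert sizes["D"] == 41 and sizes["LD"] == 15
        assert len(cohort) == 112

    def test_controls_have_no_recurrence_events(self):
        cohort = simulate_cohort(SimConfig(), 1)
        controls = cohort[cohort["group"] == "C"]
        assert (controls["lrfp_event"] == 0).all()
        assert (controls["drfp_event"] == 0).all()

    def test_recurrence_groups_have_their_events(self):
        cohort = simulate_cohort(SimConfig(), 2)
        assert (cohort.loc[cohort["group"].isin(["L", "LD"]), "lrfp_event"] == 1).all()
        assert (cohort.loc[cohort["group"].isin(["D", "LD"]), "drfp_event"] == 1).all()
        assert (cohort.loc[cohort["group"] == "L", "drfp_event"] == 0).all()

    def test_matching_invariants_many_cohorts(self):
        """Exact covariate match, <=7y age gap, within-group uniqueness."""
        gaps = []
        for seed in range(25):
            cohort = simulate_cohort(SimConfig(), seed)
            by_id = cohort.set_index("patient_id")
            rec = cohort[cohort["group"] != "C"]
            for row in rec.itertuples():
                ctrl = by_id.loc[row.matched_control_id]
                assert ctrl["group"] == "C"
                assert ctrl["tnm"] == row.tnm
                assert bool(ctrl["crm"]) == bool(row.crm)
                assert ctrl["sex"] == row.sex
                gap = abs(ctrl["age"] - row.age)
                assert gap <= 7.0
                gaps.append(gap)
            for g in ("L", "D", "LD"):
                assert rec.loc[rec["group"] == g, "matched_control_id"].is_unique
        assert np.mean(gaps) <= 7.0

    def test_matching_failure_names_stratum(self):
        cfg = SimConfig(n_per_group={"C": 2, "L": 0, "D": 30, "LD": 0})
        with pytest.raises(MatchingError, match="tnm="):
            simulate_cohort(cfg, 0)

    def test_dss_events_subset_of_os_events(self):
        cohort = simulate_cohort(SimConfig(), 3)
        assert (cohort["dss_event"] <= cohort["os_event"]).all()
        for name in ("os", "dss", "lrfp", "drfp"):
            assert (cohort[f"{name}_time"] <= SimConfig().horizon_years + 1e-9).all()
            assert (cohort[f"{name}_time"] >= 0).all()


@pytest.fixture(scope="module")
def ct_setup():
    pm = build_probe_map(8, 30, seed=0)
    panel = build_snp_panel(pm).head(12)
    return pm, panel


class TestCtPlate:

    def _plate(self, pm, panel, truth, cfg, seed=0, molecules=64.0):
        return simulate_ct_plate({"S1": truth}, panel, pm, molecules, cfg, seed)

    def test_single_molecule_gives_ct_26(self, ct_setup):
        pm, panel = ct_setup
        cfg = SimConfig(ct_noise_sd=0.0, purity=1.0)
        truth = _uniform_truth(pm, 2, 1)
        # input 2 diploid-equivalents -> one molecule per allele at het SNPs
        ct, geno = self._plate(pm, panel, truth, cfg, molecules=2.0)
        het_snps = geno.loc[geno["genotype"] == "AB", "snp_id"]
        het_ct = ct[ct["snp_id"].isin(het_snps)]["ct"]
        assert het_ct.dropna().unique() == pytest.approx([26.0])

    def test_balanced_alleles_symmetric_channels(self, ct_setup):
        pm, panel = ct_setup
        cfg = SimConfig(ct_noise_sd=0.0, purity=1.0)
        truth = _uniform_truth(pm, 2, 1)
        ct, geno = self._plate(pm, panel, truth, cfg)
        het_snps = set(geno.loc[geno["genotype"] == "AB", "snp_id"])
        wide = (
            ct[ct["snp_id"].isin(het_snps)]
            .pivot_table(index=["snp_id", "replicate"], columns="channel", values="ct")
        )
        assert np.allclose(wide["A"], wide["B"])

    def test_doubling_input_lowers_ct_by_one(self, ct_setup):
        pm, panel = ct_setup
        cfg = SimConfig(ct_noise_sd=0.05, purity=1.0)
        truth = _uniform_truth(pm, 2, 1)
        ct1, _ = self._plate(pm, panel, truth, cfg, seed=1, molecules=32.0)
        ct2, _ = self._plate(pm, panel, truth, cfg, seed=1, molecules=64.0)
        diff = ct1["ct"].mean() - ct2["ct"].mean()
        assert diff == pytest.approx(1.0, abs=0.1)

    def test_empty_panel_rejected(self, ct_setup):
        pm, panel = ct_setup
        with pytest.raises(ValueError):
            simulate_ct_plate({"S1": _uniform_truth(pm, 2, 1)}, panel.iloc[:0], pm, 64.0, SimConfig(), 0)


class TestStudyTable:
    def test_shape_and_ranges(self):
        df = simulate_study_table(20, ["7p", "8q"], 0)
        assert df["study_id"].nunique() == 20
        assert df["gain_fraction"].between(0, 1).all()
        assert df["loss_fraction"].between(0, 1).all()

    def test_degenerate_beta_forces_zero_fractions(self):
        df = simulate_study_table(5, ["7p"], 0, gain_beta=(1e-4, 1e4), loss_beta=(1e-4, 1e4))
        assert (df["gain_fraction"] < 1e-6).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_study_table(0, ["7p"], 0)
        with pytest.raises(ValueError):
            simulate_study_table(3, [], 0)
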