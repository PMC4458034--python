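"""Validation experiments: truth recovery, power, calibration.

Recovery metrics compare called states with the simulator's latent truth.
Probe-level CN-state accuracy compares each probe's called state (from its
containing segment) with the latent copy number (loss < 2, neutral = 2,
gain > 2).  Chromosome-level allelic-class accuracy compares the called
overall chromosome status with the latent modal class; both sides weight
probes by the patient's germline heterozygosity, the abundance measure used
for status calling, so the comparison is like for like.

The replicate experiments at the bottom rerun the full discovery analysis on
freshly simulated cohorts and measure: how often the hierarchy flags the
chromosome-7 arms for the local-recurrence comparison, how often the
effect-free distant-recurrence comparison stays silent, the type-I error of
the permutation global test, de-waving fidelity, and Cox hazard-ratio
recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import chromosome_status
from .probemap import ProbeMap
from .synthetic import AssayPair, TruthProfile


def called_state_vector(segments: pd.DataFrame, probe_map: ProbeMap) -> np.ndarray:
    """Per-probe called CN state expanded from segment calls."""
    out = np.empty(len(probe_map), dtype=object)
    for seg in segments.itertuples():
        out[probe_map.chrom_index(seg.chrom)[seg.start_idx : seg.end_idx]] = seg.cn_state
    return out


def cn_state_accuracy(
    calls: dict[str, pd.DataFrame],
    truths: dict[str, TruthProfile],
    probe_map: ProbeMap,
) -> float:
    """Fraction of probes (over all patients) with the true CN state."""
    total = 0
    correct = 0
    for pid, segments in calls.items():
        true_state = truths[pid].per_probe_cn_state(probe_map)
        called = called_state_vector(segments, probe_map)
        total += len(called)
        correct += int(np.sum(called == true_state))
    return correct / total


def allelic_class_accuracy(
    calls: dict[str, pd.DataFrame],
    truths: dict[str, TruthProfile],
    assays: dict[str, AssayPair],
    probe_map: ProbeMap,
) -> float:
    """Fraction of (patient, chromosome) pairs with the true overall class.

    Chromosomes whose called status is missing (no informative segment) are
    counted as misses, so the metric cannot be inflated by refusing to call.
    """
    total = 0
    correct = 0
    for pid, segments in calls.items():
        het = assays[pid].germline_genotype == 1
        for chrom in probe_map.chromosomes:
            idx = probe_map.chrom_index(chrom)
            truth_class = truths[pid].chromosome_class(chrom, probe_weights=het[idx])
            called = chromosome_status(segments, chrom, "het")
            total += 1
            correct += int(called == truth_class)
    return correct / total


# ---------------------------------------------------------------------------
# replicate experiments


def discovery_replicate(
    seed: int,
    sim_config=None,
    calling_config=None,
    assoc_config=None,
) -> dict:
    """One full discovery-phase run on a fresh synthetic cohort.

    Simulates the local-recurrence, control and distant-recurrence groups,
    runs the array pipeline, and performs the hierarchical tests for the
    L-vs-C comparison (which carries the chromosome-7 retention effect) and
    the effect-free D-vs-C comparison.  Returns the recovery accuracies, the
    significant arms for L-vs-C allelic data, and whether D-vs-C produced any
    significant arm.
    """
    from .association import hierarchical_test, probe_matrices, results_frame
    from .config import AssociationConfig, SimConfig
    from .pipeline import run_cohort_pipeline
    from .synthetic import simulate_discovery_dataset

    sim_config = sim_config or SimConfig()
    assoc_config = assoc_config or AssociationConfig(
        n_perm_genome=10_000, n_perm_arm=10_000, n_perm_region=1_000
    )
    data = simulate_discovery_dataset(sim_config, seed=seed, groups=("L", "C", "D"))
    calls, qc = run_cohort_pipeline(data["assays"], data["probe_map"], calling_config, seed)
    cn, cls = probe_matrices(calls, data["probe_map"], data["assays"])
    groups = data["cohort"].set_index("patient_id")["group"]
    res_l = results_frame(
        hierarchical_test(cn, cls, groups, data["probe_map"], "L-vs-C", assoc_config, seed)
    )
    res_d = results_frame(
        hierarchical_test(cn, cls, groups, data["probe_map"], "D-vs-C", assoc_config, seed)
    )
    arms_l = res_l[(res_l.level == "arm") & (res_l.datatype == "allelic")]
    sig_arms = set(arms_l.loc[arms_l.p_BH < assoc_config.alpha, "scope"])
    d_arms = res_d[(res_d.level == "arm") & (res_d.p_BH < assoc_config.alpha)]
    return {
        "cn_accuracy": cn_state_accuracy(calls, data["truths"], data["probe_map"]),
        "class_accuracy": allelic_class_accuracy(
            calls, data["truths"], data["assays"], data["probe_map"]
        ),
        "l_significant_arms": sig_arms,
        "chr7_flagged": {"7p", "7q"} <= sig_arms,
        "d_null_clean": len(d_arms) == 0,
        "n_excluded": int(qc["excluded"].sum()),
    }


def global_test_type_i_error(
    n_replicates: int = 1000,
    n_permutations: int = 1000,
    n_features: int = 20,
    n_samples: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the permutation global test under label exchange."""
    from .association import global_test

    rng = np.random.default_rng(seed)
    rejections = 0
    y_base = np.r_[np.ones(n_samples // 2), np.zeros(n_samples - n_samples // 2)]
    for _ in range(n_replicates):
        X = rng.normal(size=(n_features, n_samples))
        y = rng.permutation(y_base)
        _, p = global_test(X, y, n_permutations, rng)
        rejections += p <= alpha
    return rejections / n_replicates


def dewave_fidelity(
    n_replicates: int = 5,
    amplitude: float = 0.1,
    period_bp: float = 30e6,
    step: float = 0.5,
    seed: int = 0,
) -> dict:
    """Residual wave amplitude and step recovery of the de-waving stage.

    Replicates use fresh probe positions and wave phases; the residual
    amplitude is the sinusoid amplitude fitted to the corrected profile of a
    wave-only chromosome, and step recovery is measured on a chromosome with
    a half-length copy-number step under the same wave.
    """
    from .pipeline import dewave

    rng = np.random.default_rng(seed)
    residuals = []
    step_errors = []
    for _ in range(n_replicates):
        pos = np.sort(rng.choice(120_000_000, 240, replace=False)).astype(float)
        phase = rng.uniform(0, 2 * np.pi)
        wave = amplitude * np.sin(2 * np.pi * pos / period_bp + phase)
        v = 1 + wave + rng.normal(0, 0.01, len(pos))
        out = dewave(v, pos, span=period_bp)
        X = np.c_[np.sin(2 * np.pi * pos / period_bp), np.cos(2 * np.pi * pos / period_bp)]
        coef, *_ = np.linalg.lstsq(X, out - out.mean(), rcond=None)
        residuals.append(float(np.hypot(*coef)))

        v2 = 1 + wave + rng.normal(0, 0.02, len(pos))
        v2[len(pos) // 2 :] += step
        out2 = dewave(v2, pos, span=period_bp)
        recovered = out2[len(pos) // 2 :].mean() - out2[: len(pos) // 2].mean()
        step_errors.append(abs(recovered - step) / step)
    return {
        "max_residual_amplitude": max(residuals),
        "mean_residual_amplitude": float(np.mean(residuals)),
        "mean_step_error": float(np.mean(step_errors)),
    }


def cox_recovery(
    n_replicates: int = 200,
    n: int = 112,
    true_hr: float = 3.0,
    seed: int = 0,
) -> dict:
    """Hazard-ratio recovery and null CI coverage of the Cox marker model.

    The effect arm simulates a marker with the given true hazard ratio on a
    recurrence-type endpoint (~25 events at n = 112); the null arm checks
    that the 95% CI covers 1 at about the nominal rate.
    """
    from .survival import fit_marker_model
    from .synthetic import simulate_marker_survival

    rng = np.random.default_rng(seed)
    log_hrs = []
    events = []
    for _ in range(n_replicates):
        df = simulate_marker_survival(n, true_hr, rng)
        fit = fit_marker_model(df[["time", "event"]], df["marker"], mode="univariate")
        log_hrs.append(fit["coef"])
        events.append(fit["n_events"])
    covered = 0
    for _ in range(n_replicates):
        df = simulate_marker_survival(n, 1.0, rng)
        fit = fit_marker_model(df[["time", "event"]], df["marker"], mode="univariate")
        covered += fit["ci_low"] <= 1.0 <= fit["ci_high"]
    return {
        "mean_log_hr": float(np.mean(log_hrs)),
        "true_log_hr": float(np.log(true_hr)),
        "mean_events": float(np.mean(events)),
        "null_ci_coverage": covered / n_replicates,
    }
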