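"""Run the array pipeline: QC, normalization, de-waving, segmentation, calls.

Reads the simulated probe-level data from step 01, processes every
tumor/normal pair, and writes the per-segment CN/allelic-class calls plus a
QC report.  Also plots the per-group gain/loss frequency profiles (the
genome-wide alteration landscape of each recurrence group) and reports how
well the calls recover the known simulation truth.

Outputs (results/): segments.bed, qc.tsv, frequency_profiles.png,
frequencies_arm.tsv.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from recurcna import io
from recurcna.config import CallingConfig, config_hash
from recurcna.evaluate import allelic_class_accuracy, cn_state_accuracy
from recurcna.pipeline import frequency_profile, run_cohort_pipeline
from recurcna.probemap import ProbeMap
from recurcna.synthetic import simulate_discovery_dataset
from recurcna.config import SimConfig

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    # regenerate in memory (identical seed) rather than re-parsing assay.tsv:
    # the truth objects and germline genotypes are needed for evaluation
    cfg = SimConfig()
    data = simulate_discovery_dataset(cfg, seed=SEED)
    probe_map = data["probe_map"]
    calling = CallingConfig()
    h = config_hash(calling)

    calls, qc = run_cohort_pipeline(data["assays"], probe_map, calling, SEED)
    io.write_segments_bed(calls, str(ROOT / "segments.bed"), SEED, h)
    io.write_table(qc, str(ROOT / "qc.tsv"), SEED, h)
    print(f"processed {len(calls)} pairs; {int(qc['excluded'].sum())} flagged by QC")

    acc_cn = cn_state_accuracy(calls, data["truths"], probe_map)
    acc_cls = allelic_class_accuracy(calls, data["truths"], data["assays"], probe_map)
    print(f"truth recovery: {acc_cn:.1%} of probes have the correct CN state")
    print(f"                {acc_cls:.1%} of chromosomes the correct allelic class")

    groups = data["cohort"].set_index("patient_id")["group"]
    fig, axes = plt.subplots(2, 1, figsize=(11, 6), sharex=True)
    arm_rows = []
    for group, color in (("C", "0.3"), ("L", "tab:red"), ("D", "tab:blue"), ("LD", "tab:cyan")):
        members = groups[groups == group].index.tolist()
        prof = frequency_profile(calls, members, probe_map, calling)
        x = range(len(prof["probe"]))
        axes[0].plot(x, prof["probe"]["gain_freq"], color=color, lw=0.8, label=group)
        axes[1].plot(x, prof["probe"]["loss_freq"], color=color, lw=0.8, label=group)
        arm = prof["arm"].copy()
        arm.insert(0, "group", group)
        arm_rows.append(arm)
    for ax, title in zip(axes, ("gains", "losses (segments >= 15 SNPs)")):
        ax.set_ylabel(f"fraction with {title}")
        ax.set_ylim(0, 1)
    bounds = [0]
    for chrom in probe_map.chromosomes:
        bounds.append(bounds[-1] + len(probe_map.chrom_index(chrom)))
    for ax in axes:
        for b in bounds[1:-1]:
            ax.axvline(b, color="0.85", lw=0.5, zorder=0)
    axes[1].set_xlabel("probe index (chromosomes 1-22)")
    axes[0].legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(ROOT / "frequency_profiles.png", dpi=120)

    import pandas as pd

    io.write_table(pd.concat(arm_rows, ignore_index=True), str(ROOT / "frequencies_arm.tsv"), SEED, h)
    print(f"wrote segments.bed, qc.tsv, frequencies_arm.tsv, frequency_profiles.png to {ROOT}")


if __name__ == "__main__":
    main()
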