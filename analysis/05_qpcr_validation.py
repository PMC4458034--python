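"""qPCR validation arithmetic on a simulated dynamic-array plate.

Selects the 48-SNP validation panel (the 16 most heterozygous SNPs on 7p,
7q and chromosome 13, heterozygosity >= 40% in the cohort's normal
genotype calls), simulates duplicate-well two-channel Ct plates for every
tumor, and runs the full arithmetic: cap Ct at 30, count template molecules
as 2^(26-Ct), normalize by channel totals, form per-SNP allelic ratios, fold
them symmetrically, and compare per-region means between recurrence groups
with Welch's t-test.

Outputs (results/): panel.tsv, ct.csv, qpcr_ratios.tsv, welch.tsv.
"""

from pathlib import Path

import numpy as np

from recurcna import io
from recurcna.config import QpcrConfig, SimConfig, config_hash
from recurcna.pipeline import GENOTYPE_CODES, run_cohort_pipeline
from recurcna.qpcr import (
    plate_allelic_ratios,
    region_group_comparison,
    region_summaries,
    select_validation_snps,
)
from recurcna.synthetic import build_snp_panel, simulate_ct_plate, simulate_discovery_dataset

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    sim = SimConfig()
    qcfg = QpcrConfig()
    h = config_hash(sim, qcfg)
    data = simulate_discovery_dataset(sim, seed=SEED)
    probe_map = data["probe_map"]
    run_cohort_pipeline(data["assays"], probe_map, seed=SEED)  # fills genotype calls

    # observed heterozygote fraction across the cohort's normals, per probe
    het_mask = np.stack(
        [a.genotype_calls == GENOTYPE_CODES["AB"] for a in data["assays"].values()]
    )
    het_fraction = het_mask.mean(axis=0)
    panel_all = build_snp_panel(probe_map)
    het_table = panel_all.assign(het_fraction=het_fraction[panel_all["probe_idx"]])
    panel = select_validation_snps(het_table, qcfg).merge(
        panel_all[["snp_id", "chrom", "probe_idx"]], on="snp_id"
    )
    io.write_table(panel, str(ROOT / "panel.tsv"), SEED, h)
    per_region = panel.groupby("region").size().to_dict()
    print(f"panel: {len(panel)} SNPs {per_region}, min het {panel['het_fraction'].min():.2f}")

    ct_df, geno_df = simulate_ct_plate(
        data["truths"], panel, probe_map, input_molecules=64.0, config=sim, seed_or_rng=SEED + 1
    )
    io.write_table(ct_df, str(ROOT / "ct.csv"), SEED, h)
    n_capped = int((ct_df["ct"].isna() | (ct_df["ct"] > qcfg.ct_cap)).sum())
    print(f"plate: {len(ct_df)} wells, {n_capped} capped to Ct = {qcfg.ct_cap:.0f}")

    ratios = plate_allelic_ratios(ct_df, qcfg)
    io.write_table(ratios, str(ROOT / "qpcr_ratios.tsv"), SEED, h)
    summaries = region_summaries(ratios, panel, geno_df)
    groups = data["cohort"].set_index("patient_id")["group"]
    welch = region_group_comparison(summaries, groups, "L-vs-C")
    io.write_table(welch, str(ROOT / "welch.tsv"), SEED, h)
    print("\nWelch t-tests of mean folded allelic ratio, L vs C:")
    for row in welch.itertuples():
        print(f"  {row.region}: t = {row.t:.2f}, df = {row.df:.1f}, p = {row.p:.3g}")
    print(f"\nwrote panel.tsv, ct.csv, qpcr_ratios.tsv, welch.tsv to {ROOT}")


if __name__ == "__main__":
    main()
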