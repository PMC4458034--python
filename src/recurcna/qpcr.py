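"""Dynamic-array (qPCR) validation arithmetic.

The validation assay types a panel of SNPs (16 each on chromosome 7p, 7q and
13, chosen for the highest heterozygosity, at least 40%, in the cohort's
normal tissues) in duplicate wells on two allele channels (VIC = A, FAM = B).
Cycle-threshold values above 30 or missing are set to 30; template molecule
counts follow ``molecules = 2**(26 - Ct)`` (Ct 26 corresponds to one
molecule).  Channel totals per sample normalize the molecule counts, the
per-SNP allelic ratio is normalized A over normalized B, and group
differences in per-region mean ratios are assessed with Welch's two-sample
t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import QpcrConfig

REGIONS = ("7p", "7q", "13")


def select_validation_snps(
    het_fractions: pd.DataFrame,
    config: QpcrConfig | None = None,
) -> pd.DataFrame:
    """Pick the SNP panel: most heterozygous SNPs per region.

    ``het_fractions`` needs columns ``snp_id``, ``region`` (7p/7q/13) and
    ``het_fraction`` (observed heterozygote fraction among the cohort's
    normal genotype calls).  Per region, SNPs with het_fraction >= 0.40 are
    ranked descending (ties broken by snp_id) and the top 16 kept; a region
    with fewer eligible SNPs returns all of them with a warning.
    """
    config = config or QpcrConfig()
    required = {"snp_id", "region", "het_fraction"}
    if not required.issubset(het_fractions.columns):
        raise ValueError(f"het table needs columns {sorted(required)}")
    panels = []
    for region in REGIONS:
        sub = het_fractions[het_fractions["region"] == region]
        eligible = sub[sub["het_fraction"] >= config.min_het_fraction]
        eligible = eligible.sort_values(
            ["het_fraction", "snp_id"], ascending=[False, True], kind="mergesort"
        )
        if len(eligible) < config.panel_size_per_region:
            warnings.warn(
                f"region {region}: only {len(eligible)} SNPs reach "
                f"heterozygosity {config.min_het_fraction:.0%}"
            )
        panels.append(eligible.head(config.panel_size_per_region))
    return pd.concat(panels, ignore_index=True)[["snp_id", "region", "het_fraction"]]


def preprocess_ct(ct_values, config: QpcrConfig | None = None) -> np.ndarray:
    """Cap rule: missing wells and Ct above 30 are set to Ct = 30. Idempotent."""
    config = config or QpcrConfig()
    ct = np.asarray(ct_values, dtype=float)
    if np.any(ct[np.isfinite(ct)] < 0):
        raise ValueError("negative Ct value")
    out = np.where(np.isnan(ct) | (ct > config.ct_cap), config.ct_cap, ct)
    return out


def ct_to_molecules(ct, config: QpcrConfig | None = None):
    """Template molecules implied by a cycle threshold: 2**(26 - Ct)."""
    config = config or QpcrConfig()
    return np.power(2.0, config.single_molecule_ct - np.asarray(ct, dtype=float))


def sample_allelic_ratio(
    molecules_a: pd.Series,
    molecules_b: pd.Series,
    total_a: float,
    total_b: float,
    config: QpcrConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-normalized allelic ratio per SNP for one sample.

    Each channel's molecule counts are divided by the sample's total molecule
    amount on that channel, and the ratio is normalized A over normalized B —
    so a global efficiency difference between the VIC and FAM channels
    cancels.  A zero B channel yields the configured max-ratio sentinel with
    a flag.  Returns (ratios, flagged).
    """
    config = config or QpcrConfig()
    if total_a <= 0 or total_b <= 0:
        raise ValueError("channel totals must be positive")
    a = np.asarray(molecules_a, dtype=float) / total_a
    b = np.asarray(molecules_b, dtype=float) / total_b
    flagged = b <= 0
    ratio = np.where(flagged, config.max_ratio_sentinel, a / np.where(flagged, 1.0, b))
    return ratio, flagged


def plate_allelic_ratios(
    ct_df: pd.DataFrame, config: QpcrConfig | None = None
) -> pd.DataFrame:
    """Full plate arithmetic: cap Cts, count molecules, average replicate
    wells, normalize by channel totals, form per-SNP ratios.

    ``ct_df`` is the long Ct table (sample_id, snp_id, replicate, channel,
    ct).  Returns one row per sample x SNP with the normalized ratio and the
    zero-B flag.
    """
    config = config or QpcrConfig()
    df = ct_df.copy()
    df["ct"] = preprocess_ct(df["ct"], config)
    df["molecules"] = ct_to_molecules(df["ct"], config)
    per_snp = (
        df.groupby(["sample_id", "snp_id", "channel"])["molecules"].mean().unstack("channel")
    )
    if not {"A", "B"}.issubset(per_snp.columns):
        raise ValueError("Ct table must contain both A and B channels")
    rows = []
    for sample_id, sub in per_snp.groupby(level="sample_id"):
        ratio, flagged = sample_allelic_ratio(
            sub["A"], sub["B"], float(sub["A"].sum()), float(sub["B"].sum()), config
        )
        for (_, snp_id), r, f in zip(sub.index, ratio, flagged):
            rows.append((sample_id, snp_id, float(r), bool(f)))
    return pd.DataFrame(rows, columns=["sample_id", "snp_id", "ratio", "zero_b_flag"])


def folded_ratio(r: np.ndarray) -> np.ndarray:
    """Symmetric allelic-deviation measure max(r, 1/r), invariant to allele labels."""
    r = np.asarray(r, dtype=float)
    return np.maximum(r, 1.0 / r)


def region_summaries(
    ratios: pd.DataFrame,
    panel: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample, per-region mean folded allelic ratio over panel SNPs.

    Raw A/B ratios depend on arbitrary allele labels, so the per-patient
    summary folds each ratio to max(r, 1/r) before averaging.  When a
    genotype table is given, only SNPs heterozygous in that sample inform the
    summary (homozygous SNPs carry no allelic-ratio information).
    """
    df = ratios.merge(panel[["snp_id", "region"]], on="snp_id")
    if genotypes is not None:
        df = df.merge(genotypes, on=["sample_id", "snp_id"])
        df = df[df["genotype"] == "AB"]
    df = df[~df["zero_b_flag"]]
    df["folded"] = folded_ratio(df["ratio"].to_numpy())
    out = df.groupby(["sample_id", "region"])["folded"].mean().reset_index()
    return out.rename(columns={"folded": "mean_folded_ratio"})


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t-test: statistic, Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return np.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2**2 / (vx**2 / (len(x) ** 2 * (len(x) - 1)) + vy**2 / (len(y) ** 2 * (len(y) - 1)))
    return float(res.statistic), float(df), float(res.pvalue)


def region_group_comparison(
    summaries: pd.DataFrame,
    groups: pd.Series,
    comparison: str = "L-vs-C",
) -> pd.DataFrame:
    """Welch t-test of per-region mean allelic ratios between two groups.

    ``summaries`` is the output of :func:`region_summaries`; ``groups`` maps
    sample_id to recurrence group.  Returns one row per region with t, df, p
    and group sizes.
    """
    from .association import COMPARISONS

    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    case, control = COMPARISONS[comparison]
    df = summaries.copy()
    df["group"] = df["sample_id"].map(groups)
    rows = []
    for region in sorted(df["region"].unique()):
        sub = df[df["region"] == region]
        x = sub.loc[sub["group"] == case, "mean_folded_ratio"].to_numpy()
        y = sub.loc[sub["group"] == control, "mean_folded_ratio"].to_numpy()
        t, dof, p = welch_test(x, y)
        rows.append((region, comparison, t, dof, p, len(x), len(y)))
    return pd.DataFrame(rows, columns=["region", "comparison", "t", "df", "p", "n_case", "n_control"])
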