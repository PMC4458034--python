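"""Tumor/normal SNP-array preprocessing, segmentation and state calling.

Stages, in order: sample QC on raw intensities (mean log2 >= 4), genotype
calling from normal BAF, tumor/normal genotype-concordance QC at germline
homozygous probes, normalization of the CN ratio to the sample mean,
de-waving (removal of the long-range sinusoidal intensity artifact),
mirrored-BAF computation at heterozygous probes, permutation-tested recursive
binary segmentation of the CN and mBAF signals, and per-segment calling of
the CN state (loss < 0.92 / gain > 1.08 relative to the sample mean, strict
inequalities) and the allelic-ratio class (1 retention, 2 imbalance, 3 LOH by
mean mBAF cutpoints).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import CallingConfig
from .probemap import ProbeMap
from .synthetic import AssayPair

GENOTYPE_CODES = {"AA": 0, "AB": 1, "BB": 2, "NoCall": 3}


class IndeterminateQCError(ValueError):
    """Raised when a QC statistic has no informative probes."""


# ---------------------------------------------------------------------------
# QC


def qc_mean_log2(raw_intensities: np.ndarray, config: CallingConfig | None = None) -> tuple[bool, float]:
    """Sample-level intensity QC: mean of log2(raw intensity).

    Fails (returns ``(False, stat)``) iff the mean is strictly below the
    configured minimum (default 4); failing samples are flagged by the caller,
    never deleted.
    """
    config = config or CallingConfig()
    x = np.asarray(raw_intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity vector")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("raw intensities must be positive and finite")
    stat = float(np.mean(np.log2(x)))
    return stat >= config.mean_log2_min, stat


def call_genotypes(
    normal_baf: np.ndarray, config: CallingConfig | None = None
) -> tuple[np.ndarray, float]:
    """Genotype calls from normal-tissue BAF.

    AA below 0.15, BB above 0.85, AB within [0.35, 0.65], NoCall in the gaps.
    Returns integer codes (0=AA, 1=AB, 2=BB, 3=NoCall) and the heterozygous
    fraction among called probes.
    """
    config = config or CallingConfig()
    baf = np.asarray(normal_baf, dtype=float)
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF outside [0, 1]")
    calls = np.full(baf.shape, GENOTYPE_CODES["NoCall"], dtype=np.int8)
    calls[baf < config.baf_aa_max] = GENOTYPE_CODES["AA"]
    calls[baf > config.baf_bb_min] = GENOTYPE_CODES["BB"]
    calls[(baf >= config.baf_ab_low) & (baf <= config.baf_ab_high)] = GENOTYPE_CODES["AB"]
    called = calls != GENOTYPE_CODES["NoCall"]
    het_fraction = float(np.mean(calls[called] == GENOTYPE_CODES["AB"])) if called.any() else 0.0
    return calls, het_fraction


def check_pair_concordance(
    tumor_calls: np.ndarray,
    normal_calls: np.ndarray,
    config: CallingConfig | None = None,
) -> tuple[float, bool]:
    """Tumor/normal identity check at germline homozygous probes.

    Homozygous probes are robust to somatic allelic imbalance, so a matching
    pair should agree there; a swapped pair agrees only at chance level.
    Fails iff concordance < 0.90 (default).
    """
    config = config or CallingConfig()
    tumor_calls = np.asarray(tumor_calls)
    normal_calls = np.asarray(normal_calls)
    if tumor_calls.shape != normal_calls.shape:
        raise ValueError("call vectors must be aligned")
    hom = (normal_calls == GENOTYPE_CODES["AA"]) | (normal_calls == GENOTYPE_CODES["BB"])
    informative = hom & (tumor_calls != GENOTYPE_CODES["NoCall"])
    if not informative.any():
        raise IndeterminateQCError("no informative homozygous probes")
    concordance = float(np.mean(tumor_calls[informative] == normal_calls[informative]))
    return concordance, concordance >= config.concordance_min


# ---------------------------------------------------------------------------
# normalization and de-waving


def normalize_to_sample_mean(cn_ratios: np.ndarray) -> np.ndarray:
    """Divide by the sample mean so the genome-wide mean ratio is exactly 1."""
    x = np.asarray(cn_ratios, dtype=float)
    mean = np.nanmean(x) if x.size else np.nan
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("cannot normalize: no finite positive values")
    return x / mean


def _plateau_bounds(base: np.ndarray, jump_thresh: float, k: int) -> list[int]:
    """Split a median-filtered baseline into plateaus at step-scale jumps.

    Jumps are detected on a lagged difference (a true step smeared over a few
    probes by the filter still accumulates its full height within the lag)
    and each jump region contributes one cut at its largest single-probe
    change.
    """
    n = len(base)
    lag = max(3, k // 10)
    d = np.abs(base[lag:] - base[:-lag])
    hot = d > jump_thresh
    bounds = [0]
    j = 0
    while j < len(hot):
        if hot[j]:
            end = j
            while end < len(hot) and hot[end]:
                end += 1
            seg = np.abs(np.diff(base[j : min(end + lag, n)]))
            cut = j + int(np.argmax(seg)) + 1
            if cut - bounds[-1] > 2:
                bounds.append(cut)
            j = end
        else:
            j += 1
    bounds.append(n)
    return bounds


def dewave(
    cn_ratios: np.ndarray,
    positions: np.ndarray,
    span: float = 30_000_000.0,
    min_probes: int = 10,
) -> np.ndarray:
    """Remove a smooth long-range wave from one chromosome's CN ratios.

    The segment-scale structure is captured first: a running median over
    ``span`` worth of probes (a full wave period averages out under the
    median while step edges survive) is split into plateaus at step-scale
    jumps, and each probe is assigned its plateau's median level.  The wave
    is then estimated by local regression of the residual (probe values minus
    plateau levels), constrained to zero mean within every plateau — so
    segment means are preserved by construction — and divided out.
    Chromosomes with fewer than ``min_probes`` probes are returned unchanged
    with a warning.
    """
    values = np.asarray(cn_ratios, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    n = len(values)
    if n < min_probes:
        warnings.warn(f"chromosome with {n} probes: de-waving skipped")
        return values.copy()
    pos_range = max(positions[-1] - positions[0], 1.0)
    k = max(5, int(round(span * n / pos_range)) | 1)
    base = median_filter(values, size=k, mode="nearest")
    dv = np.diff(values)
    noise_sd = 1.4826 * np.median(np.abs(dv - np.median(dv))) / np.sqrt(2.0)
    # jumps are read off the k-probe median baseline, whose noise scale is
    # ~ noise_sd / sqrt(k); the floor keeps sub-threshold CN wobble intact
    base_sd = noise_sd * 1.25 / np.sqrt(k)
    bounds = _plateau_bounds(base, jump_thresh=max(6.0 * base_sd, 0.08), k=k)
    level = np.empty(n)
    for a, b in zip(bounds[:-1], bounds[1:]):
        level[a:b] = np.median(values[a:b])
    # track the wave with a window of ~ a quarter period: wide enough to
    # average noise, narrow enough not to attenuate the sinusoid
    frac = float(np.clip((span / 4.0) / pos_range, 0.03, 0.67))
    est = lowess(values - level, positions, frac=frac, it=1, return_sorted=False)
    for a, b in zip(bounds[:-1], bounds[1:]):
        est[a:b] -= est[a:b].mean()
    return values / np.clip(1.0 + est, 0.1, None)


def dewave_genome(
    cn_ratios: np.ndarray, probe_map: ProbeMap, span: float = 30_000_000.0
) -> np.ndarray:
    """De-wave per chromosome and re-normalize to genome mean 1."""
    out = np.array(cn_ratios, dtype=float)
    for chrom in probe_map.chromosomes:
        idx = probe_map.chrom_index(chrom)
        out[idx] = dewave(out[idx], probe_map.positions(chrom), span=span)
    return normalize_to_sample_mean(out)


def mirrored_baf(baf: np.ndarray, het_mask: np.ndarray) -> np.ndarray:
    """Mirrored BAF, |BAF - 0.5| + 0.5, at heterozygous probes; NaN elsewhere."""
    baf = np.asarray(baf, dtype=float)
    out = np.full(baf.shape, np.nan)
    out[het_mask] = np.abs(baf[het_mask] - 0.5) + 0.5
    return out


# ---------------------------------------------------------------------------
# segmentation


def _t_profile(cs: np.ndarray, css: np.ndarray, min_seg: int) -> np.ndarray:
    """|t| for every split of one series given cumulative sums (axis -1)."""
    n = cs.shape[-1]
    k = np.arange(min_seg, n - min_seg + 1, dtype=float)  # left sizes
    total = cs[..., -1:]
    total_sq = css[..., -1:]
    sum_l = cs[..., min_seg - 1 : n - min_seg]
    sum_r = total - sum_l
    sq_l = css[..., min_seg - 1 : n - min_seg]
    sq_r = total_sq - sq_l
    mean_l = sum_l / k
    mean_r = sum_r / (n - k)
    sse = (sq_l - sum_l**2 / k) + (sq_r - sum_r**2 / (n - k))
    sp2 = np.maximum(sse / max(n - 2, 1), 1e-12)
    return np.abs(mean_r - mean_l) / np.sqrt(sp2 * (1.0 / k + 1.0 / (n - k)))


def segment_profile(
    values: np.ndarray,
    positions: np.ndarray,
    alpha: float = 0.01,
    min_seg_probes: int = 5,
    n_permutations: int = 200,
    seed_or_rng=0,
) -> list[int]:
    """Recursive binary segmentation with a permutation stopping rule.

    At each step the split maximizing the two-sample t statistic of the
    candidate segment means is tested against ``n_permutations`` within-
    segment permutations; it is accepted iff the permutation p-value
    ``(1 + #{perm max|t| >= observed}) / (1 + B)`` is below ``alpha`` and both
    children have at least ``min_seg_probes`` probes.  Returns sorted
    breakpoint indices (index of the first probe right of each cut).
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    breakpoints: list[int] = []

    def _recurse(lo: int, hi: int) -> None:
        v = values[lo:hi]
        n = hi - lo
        if n < 2 * min_seg_probes:
            return
        t_obs = _t_profile(np.cumsum(v), np.cumsum(v**2), min_seg_probes)
        k_best = int(np.argmax(t_obs)) + min_seg_probes
        t_best = float(t_obs[k_best - min_seg_probes])
        perms = rng.permuted(np.tile(v, (n_permutations, 1)), axis=1)
        t_perm = _t_profile(
            np.cumsum(perms, axis=1), np.cumsum(perms**2, axis=1), min_seg_probes
        ).max(axis=1)
        p = (1.0 + np.sum(t_perm >= t_best)) / (1.0 + n_permutations)
        if p < alpha:
            breakpoints.append(lo + k_best)
            _recurse(lo, lo + k_best)
            _recurse(lo + k_best, hi)

    _recurse(0, len(values))
    return sorted(breakpoints)


def _segment_masked(
    values: np.ndarray,
    positions: np.ndarray,
    alpha: float,
    min_seg_probes: int,
    n_permutations: int,
    rng,
) -> list[int]:
    """Segment a series with missing values; breakpoints in full-index space."""
    mask = np.isfinite(values)
    if mask.sum() < 2 * min_seg_probes:
        return []
    idx = np.flatnonzero(mask)
    bps = segment_profile(
        values[idx], positions[idx], alpha, min_seg_probes, n_permutations, rng
    )
    return [int(idx[b]) for b in bps]


# ---------------------------------------------------------------------------
# segment calling


def call_segments(
    assay: AssayPair,
    breakpoints: dict[int, list[int]],
    probe_map: ProbeMap,
    config: CallingConfig | None = None,
) -> pd.DataFrame:
    """Per-segment CN state and allelic class for one patient.

    ``breakpoints`` maps chromosome to sorted local probe indices (typically
    the union of the CN-signal and mBAF-signal segmentations).  CN state uses
    strict thresholds (loss < 0.92, gain > 1.08, boundary = neutral); the
    allelic class comes from the mean mirrored BAF over germline-heterozygous
    probes (1 below 0.60, 3 at or above the LOH cut, else 2) and is missing
    when a segment has fewer than ``min_het_per_segment`` informative probes.
    """
    config = config or CallingConfig()
    if assay.norm_cn is None or assay.mbaf is None or assay.het_mask is None:
        raise ValueError("assay must be preprocessed (norm_cn, mbaf, het_mask)")
    rows = []
    for chrom in probe_map.chromosomes:
        idx = probe_map.chrom_index(chrom)
        pos = probe_map.positions(chrom)
        n = len(idx)
        bounds = [0] + sorted(breakpoints.get(chrom, [])) + [n]
        for start, end in zip(bounds[:-1], bounds[1:]):
            if end <= start:
                raise ValueError(f"empty segment on chrom {chrom}")
            seg_idx = idx[start:end]
            cn = assay.norm_cn[seg_idx]
            mb = assay.mbaf[seg_idx]
            n_het = int(np.sum(np.isfinite(mb)))
            mean_cn = float(np.mean(cn))
            mean_mbaf = float(np.nanmean(mb)) if n_het else np.nan
            if mean_cn < config.loss_threshold:
                state = "loss"
            elif mean_cn > config.gain_threshold:
                state = "gain"
            else:
                state = "neutral"
            if n_het < config.min_het_per_segment or not np.isfinite(mean_mbaf):
                klass = pd.NA
            elif mean_mbaf < config.mbaf_imbalance_cut:
                klass = 1
            elif mean_mbaf >= config.mbaf_loh_cut:
                klass = 3
            else:
                klass = 2
            rows.append(
                {
                    "patient_id": assay.patient_id,
                    "chrom": chrom,
                    "start_idx": start,
                    "end_idx": end,
                    "start_bp": int(pos[start]),
                    "end_bp": int(pos[end - 1]) + 1,
                    "n_probes": end - start,
                    "n_het": n_het,
                    "mean_cn_ratio": mean_cn,
                    "mean_mbaf": mean_mbaf,
                    "cn_state": state,
                    "allelic_class": klass,
                }
            )
    df = pd.DataFrame(rows)
    df["allelic_class"] = df["allelic_class"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# orchestration


def process_pair(
    assay: AssayPair,
    probe_map: ProbeMap,
    config: CallingConfig | None = None,
    seed_or_rng=0,
) -> pd.DataFrame:
    """Run the full per-sample pipeline; fills the assay's derived fields.

    QC failures are recorded in ``assay.qc`` (``excluded`` flag) but the
    sample is still processed so nothing is silently dropped.
    """
    config = config or CallingConfig()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    t_pass, t_stat = qc_mean_log2(assay.tumor_raw, config)
    n_pass, n_stat = qc_mean_log2(assay.normal_raw, config)
    assay.genotype_calls, het_fraction = call_genotypes(assay.normal_baf, config)
    assay.het_mask = assay.genotype_calls == GENOTYPE_CODES["AB"]
    tumor_calls, _ = call_genotypes(assay.tumor_baf, config)
    concordance, conc_pass = check_pair_concordance(tumor_calls, assay.genotype_calls, config)
    assay.qc = {
        "mean_log2_tumor": t_stat,
        "mean_log2_normal": n_stat,
        "mean_log2_pass": bool(t_pass and n_pass),
        "het_fraction": het_fraction,
        "concordance": concordance,
        "concordance_pass": conc_pass,
        "excluded": not (t_pass and n_pass and conc_pass),
    }
    assay.norm_cn = dewave_genome(
        normalize_to_sample_mean(assay.tumor_cn), probe_map, span=config.dewave_span_bp
    )
    assay.mbaf = mirrored_baf(assay.tumor_baf, assay.het_mask)

    breakpoints: dict[int, list[int]] = {}
    for chrom in probe_map.chromosomes:
        idx = probe_map.chrom_index(chrom)
        pos = probe_map.positions(chrom)
        bp_cn = segment_profile(
            assay.norm_cn[idx],
            pos,
            config.segmentation_alpha,
            config.min_seg_probes,
            config.n_segmentation_permutations,
            rng,
        )
        bp_mb = _segment_masked(
            assay.mbaf[idx],
            pos,
            config.segmentation_alpha,
            config.min_seg_probes,
            config.n_segmentation_permutations,
            rng,
        )
        breakpoints[chrom] = sorted(set(bp_cn) | set(bp_mb))
    return call_segments(assay, breakpoints, probe_map, config)


def run_cohort_pipeline(
    assays: dict[str, AssayPair],
    probe_map: ProbeMap,
    config: CallingConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Process every patient; returns per-patient segment calls and a QC table."""
    config = config or CallingConfig()
    seeds = np.random.SeedSequence(seed).spawn(len(assays))
    calls: dict[str, pd.DataFrame] = {}
    qc_rows = []
    for ss, (pid, assay) in zip(seeds, sorted(assays.items())):
        calls[pid] = process_pair(assay, probe_map, config, np.random.default_rng(ss))
        qc_rows.append({"patient_id": pid, **assay.qc})
    return calls, pd.DataFrame(qc_rows)


def frequency_profile(
    calls: dict[str, pd.DataFrame],
    patients: list[str],
    probe_map: ProbeMap,
    config: CallingConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Gain/loss frequencies over a patient group, per probe and per arm.

    Loss frequencies only count segments with at least
    ``loss_report_min_probes`` probes (default 15); the arm summary is the
    maximum probe-level frequency on the arm.
    """
    config = config or CallingConfig()
    if not patients:
        raise ValueError("empty patient group")
    missing = [p for p in patients if p not in calls]
    if missing:
        raise ValueError(f"no calls for patients: {missing[:5]}")
    n = len(patients)
    n_probes = len(probe_map)
    gain_count = np.zeros(n_probes)
    loss_count = np.zeros(n_probes)
    for pid in patients:
        for seg in calls[pid].itertuples():
            idx = probe_map.chrom_index(seg.chrom)[seg.start_idx : seg.end_idx]
            if seg.cn_state == "gain":
                gain_count[idx] += 1
            elif seg.cn_state == "loss" and seg.n_probes >= config.loss_report_min_probes:
                loss_count[idx] += 1
    probe_df = probe_map.df[["probe_id", "chrom", "arm", "pos", "arm_label"]].copy()
    probe_df["gain_freq"] = gain_count / n
    probe_df["loss_freq"] = loss_count / n
    arm_df = (
        probe_df.groupby("arm_label", sort=False)[["gain_freq", "loss_freq"]]
        .max()
        .reset_index()
        .rename(columns={"arm_label": "arm"})
    )
    return {"probe": probe_df, "arm": arm_df}
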