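"""Synthetic data with known ground truth for every stage of the analysis.

Generates matched tumor/normal SNP-array cohorts emulating a rectal-cancer
recurrence study: four recurrence groups (no recurrence C, local L, distant D,
local & distant LD), covariate-matched controls, four survival endpoints over
a 12-year horizon, probe-level tumor/normal intensity-ratio and B-allele-
fraction data under a purity-mixture model, duplicate-well qPCR Ct plates for
a SNP panel, and per-study chromosome-arm alteration-frequency tables for the
literature counting rule.

The latent state of a tumor is a :class:`TruthProfile`: per chromosome, a
tiling of segments each carrying a total copy number ``c`` and a B-allele copy
number ``b``.  The observable signals follow the standard mixture with tumor
purity rho:

    CN ratio  = (rho * c + (1 - rho) * 2) / 2
    BAF (het) = (rho * b + (1 - rho) * 1) / (rho * c + (1 - rho) * 2)

plus Gaussian noise and, for the CN ratio, a sinusoidal "wave" artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RECURRENCE_GROUPS, SimConfig
from .probemap import ProbeMap, build_probe_map
from .survival import RawEvents, build_endpoints

__all__ = [
    "TruthSegment",
    "TruthProfile",
    "AssayPair",
    "MatchingError",
    "simulate_truth_profile",
    "simulate_assay_pair",
    "simulate_cohort",
    "simulate_ct_plate",
    "simulate_study_table",
    "simulate_marker_survival",
    "simulate_discovery_dataset",
    "build_snp_panel",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# truth profiles


@dataclass
class TruthSegment:
    """Half-open probe-index range (local to a chromosome) with latent state."""

    start: int
    end: int
    total_copies: int
    b_copies: int

    def __post_init__(self) -> None:
        if self.total_copies < 0:
            raise ValueError("total_copies must be non-negative")
        if not 0 <= self.b_copies <= max(self.total_copies, 0):
            raise ValueError("b_copies must be in [0, total_copies]")
        if self.end <= self.start:
            raise ValueError("empty truth segment")


def allelic_class_of(total_copies: int, b_copies: int) -> int:
    """Latent allelic-ratio class: 1 retention, 2 imbalance, 3 LOH."""
    c, b = total_copies, b_copies
    if c == 0 or b == 0 or b == c:
        return 3
    if 2 * b == c:
        return 1
    return 2


@dataclass
class TruthProfile:
    """Per-chromosome latent segment tiling for one tumor."""

    segments: dict[int, list[TruthSegment]]

    def validate(self, probe_map: ProbeMap) -> None:
        for chrom in probe_map.chromosomes:
            n = len(probe_map.chrom_index(chrom))
            segs = self.segments.get(chrom, [])
            cursor = 0
            for seg in segs:
                if seg.start != cursor:
                    raise ValueError(f"gap/overlap in truth tiling on chrom {chrom}")
                cursor = seg.end
            if cursor != n:
                raise ValueError(f"truth tiling does not cover chrom {chrom}")

    def per_probe(self, probe_map: ProbeMap) -> tuple[np.ndarray, np.ndarray]:
        """Global per-probe (total copies, B copies) arrays aligned to the map."""
        c = np.full(len(probe_map), 2, dtype=int)
        b = np.full(len(probe_map), 1, dtype=int)
        for chrom, segs in self.segments.items():
            idx = probe_map.chrom_index(chrom)
            for seg in segs:
                c[idx[seg.start : seg.end]] = seg.total_copies
                b[idx[seg.start : seg.end]] = seg.b_copies
        return c, b

    def per_probe_class(self, probe_map: ProbeMap) -> np.ndarray:
        c, b = self.per_probe(probe_map)
        out = np.empty(len(probe_map), dtype=int)
        for i in range(len(out)):
            out[i] = allelic_class_of(c[i], b[i])
        return out

    def per_probe_cn_state(self, probe_map: ProbeMap) -> np.ndarray:
        """True CN state per probe: 'loss' (<2), 'neutral' (2), 'gain' (>2)."""
        c, _ = self.per_probe(probe_map)
        return np.where(c < 2, "loss", np.where(c > 2, "gain", "neutral"))

    def chromosome_class(self, chrom: int, probe_weights: np.ndarray | None = None) -> int:
        """Most abundant latent allelic class on a chromosome (ties to the
        higher class).

        ``probe_weights`` (local to the chromosome) weights each probe's
        contribution — pass the germline heterozygosity mask to mirror the
        het-probe abundance measure used when calling chromosome status;
        default is plain probe counts.
        """
        weights: dict[int, float] = {}
        for seg in self.segments[chrom]:
            k = allelic_class_of(seg.total_copies, seg.b_copies)
            if probe_weights is None:
                w = float(seg.end - seg.start)
            else:
                w = float(np.sum(probe_weights[seg.start : seg.end]))
            weights[k] = weights.get(k, 0.0) + w
        best = max(weights.values())
        return max(k for k, w in weights.items() if w == best)

    def to_dict(self) -> dict:
        return {
            str(chrom): [
                [s.start, s.end, s.total_copies, s.b_copies] for s in segs
            ]
            for chrom, segs in self.segments.items()
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TruthProfile":
        return cls(
            {
                int(chrom): [TruthSegment(*row) for row in rows]
                for chrom, rows in data.items()
            }
        )


# copy-number states used by the generator
_RETENTION = (2, 1)
_IMBALANCED_GAIN = (3, 1)
_COPY_NEUTRAL_LOH = (2, 0)
_DELETION = (1, 0)


def simulate_truth_profile(
    group: str, probe_map: ProbeMap, config: SimConfig, seed_or_rng=0
) -> TruthProfile:
    """Draw a latent genome for one tumor of the given recurrence group.

    Chromosomes 7 and 13 get a chromosome-wide allelic state drawn from the
    group-specific priors (the local-recurrence group retains balanced
    heterozygosity on chromosome 7 with probability 1 at the defaults);
    every other arm independently receives an imbalanced gain, a mono-allelic
    deletion, or stays diploid at the group's background rates.
    """
    if group not in RECURRENCE_GROUPS:
        raise ValueError(f"unknown recurrence group {group!r}")
    rng = _rng(seed_or_rng)
    segments: dict[int, list[TruthSegment]] = {}
    for chrom in probe_map.chromosomes:
        idx = probe_map.chrom_index(chrom)
        n = len(idx)
        if chrom in (7, 13):
            if chrom == 7:
                p_imb = config.chr7_imbalance_prob[group]
                p_loh = config.chr7_loh_prob[group]
            else:
                p_imb = config.chr13_imbalance_prob[group]
                p_loh = config.chr13_loh_prob[group]
            u = rng.random()
            if u < p_imb:
                c, b = _IMBALANCED_GAIN
            elif u < p_imb + p_loh:
                c, b = _COPY_NEUTRAL_LOH
            else:
                c, b = _RETENTION
            segments[chrom] = [TruthSegment(0, n, c, b)]
        else:
            arms = probe_map.df.loc[
                probe_map.df["chrom"] == chrom, "arm"
            ].to_numpy()
            segs: list[TruthSegment] = []
            cursor = 0
            for arm in ("p", "q"):
                size = int(np.sum(arms == arm))
                if size == 0:
                    continue
                u = rng.random()
                if u < config.background_gain_rate[group]:
                    c, b = _IMBALANCED_GAIN
                elif u < config.background_gain_rate[group] + config.background_loss_rate[group]:
                    c, b = _DELETION
                else:
                    c, b = _RETENTION
                segs.append(TruthSegment(cursor, cursor + size, c, b))
                cursor += size
            segments[chrom] = segs
    return TruthProfile(segments)


# ---------------------------------------------------------------------------
# probe-level assays


@dataclass
class AssayPair:
    """Per-patient tumor and normal probe-level measurements aligned to a ProbeMap.

    ``germline_genotype`` codes the simulated germline B-allele dosage
    (0=AA, 1=AB, 2=BB).  Fields filled in by the array pipeline
    (genotype calls, normalized ratios, mirrored BAF, QC) start as ``None``.
    """

    patient_id: str
    tumor_cn: np.ndarray
    tumor_baf: np.ndarray
    normal_cn: np.ndarray
    normal_baf: np.ndarray
    tumor_raw: np.ndarray
    normal_raw: np.ndarray
    germline_genotype: np.ndarray
    truth: TruthProfile | None = None
    genotype_calls: np.ndarray | None = None
    het_mask: np.ndarray | None = None
    norm_cn: np.ndarray | None = None
    mbaf: np.ndarray | None = None
    qc: dict = field(default_factory=dict)


def simulate_assay_pair(
    truth: TruthProfile,
    probe_map: ProbeMap,
    config: SimConfig,
    seed_or_rng=0,
    patient_id: str = "P000",
    randomize_parental_phase: bool = True,
) -> AssayPair:
    """Emit noisy probe-level tumor/normal data for one patient.

    The tumor CN ratio follows the purity mixture plus a sinusoidal wave of
    configured amplitude/period (random phase per sample) and Gaussian noise;
    BAF values follow the mixture for the germline genotype drawn from each
    probe's population heterozygosity.  With
    ``randomize_parental_phase=False`` the B allele always sits on the
    retained/amplified haplotype, which makes the zero-noise BAF equal the
    closed-form mixture value exactly (useful for tests).
    """
    if not 0.0 < config.purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {config.purity}")
    rng = _rng(seed_or_rng)
    truth.validate(probe_map)
    rho = config.purity
    n = len(probe_map)
    c, b = truth.per_probe(probe_map)
    pos = probe_map.df["pos"].to_numpy()

    het = probe_map.df["population_het"].to_numpy()
    u = rng.random(n)
    geno = np.where(u < het, 1, np.where(u < het + (1 - het) / 2, 0, 2))

    # normal sample: diploid everywhere
    normal_cn = 1.0 + rng.normal(0.0, config.noise_sd_cn, n)
    normal_cn = np.clip(normal_cn, 1e-6, None)
    normal_baf = np.clip(geno / 2.0 + rng.normal(0.0, config.noise_sd_baf, n), 0.0, 1.0)

    # tumor sample: mixture of tumor cells (c, b) and normal cells (2, geno)
    denom = rho * c + (1 - rho) * 2.0
    phase = rng.uniform(0.0, 2.0 * np.pi)
    wave = config.wave_amplitude * np.sin(2.0 * np.pi * pos / config.wave_period_bp + phase)
    tumor_cn = denom / 2.0 + wave + rng.normal(0.0, config.noise_sd_cn, n)
    tumor_cn = np.clip(tumor_cn, 1e-6, None)

    if randomize_parental_phase:
        flip = rng.random(n) < 0.5
        b_eff = np.where(flip, c - b, b)
    else:
        b_eff = b
    tumor_b_copies = np.where(geno == 1, b_eff, np.where(geno == 0, 0, c))
    tumor_baf = (rho * tumor_b_copies + (1 - rho) * geno) / denom
    tumor_baf = np.clip(tumor_baf + rng.normal(0.0, config.noise_sd_baf, n), 0.0, 1.0)

    scale_t = 2.0 ** rng.normal(config.intensity_log2_scale, config.intensity_log2_sd)
    scale_n = 2.0 ** rng.normal(config.intensity_log2_scale, config.intensity_log2_sd)
    return AssayPair(
        patient_id=patient_id,
        tumor_cn=tumor_cn,
        tumor_baf=tumor_baf,
        normal_cn=normal_cn,
        normal_baf=normal_baf,
        tumor_raw=tumor_cn * scale_t,
        normal_raw=normal_cn * scale_n,
        germline_genotype=geno,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cohort with matched controls and survival endpoints


class MatchingError(RuntimeError):
    """Raised when a matched control cannot be found within a covariate stratum."""


_TNM_LEVELS = ("I", "II", "III")


def _sample_covariates(n: int, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    tnm = rng.choice(_TNM_LEVELS, size=n, p=[config.tnm_probs[t] for t in _TNM_LEVELS])
    crm = rng.random(n) < config.crm_prob
    sex = np.where(rng.random(n) < config.male_prob, "male", "female")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 30.0, 95.0)
    return pd.DataFrame({"tnm": tnm, "crm": crm, "sex": sex, "age": np.round(age, 1)})


def _stratum_key(row) -> tuple:
    return (row.tnm, bool(row.crm), row.sex)


def _greedy_match(
    recurrent: pd.DataFrame,
    controls: pd.DataFrame,
    rng: np.random.Generator,
    max_age_gap: float = 7.0,
    n_retries: int = 25,
) -> tuple[dict[str, str], list[str]]:
    """Greedy nearest-age matching within exact covariate strata.

    Patients are processed in random order; each takes the age-nearest unused
    control of its stratum within the age gap.  Several orderings are tried
    and the one matching the most patients is kept.  Returns the assignment
    and the ids of patients left unmatched.
    """
    ctrl_by_stratum: dict[tuple, list[tuple[str, float]]] = {}
    for row in controls.itertuples():
        ctrl_by_stratum.setdefault(_stratum_key(row), []).append((row.patient_id, row.age))
    rows = list(recurrent.itertuples())
    best: tuple[dict[str, str], list[str]] | None = None
    for _ in range(n_retries):
        used: set[str] = set()
        assignment: dict[str, str] = {}
        unmatched: list[str] = []
        for i in rng.permutation(len(rows)):
            row = rows[i]
            candidates = [
                (abs(age - row.age), cid)
                for cid, age in ctrl_by_stratum.get(_stratum_key(row), [])
                if cid not in used and abs(age - row.age) <= max_age_gap
            ]
            if not candidates:
                unmatched.append(row.patient_id)
                continue
            _, cid = min(candidates)
            used.add(cid)
            assignment[row.patient_id] = cid
        if best is None or len(unmatched) < len(best[1]):
            best = (assignment, unmatched)
        if not unmatched:
            break
    assert best is not None
    return best


def _simulate_survival(
    group: str, config: SimConfig, rng: np.random.Generator
) -> RawEvents:
    horizon = config.horizon_years
    death = rng.exponential(1.0 / config.death_rate[group])
    cause = "cancer" if rng.random() < config.cancer_death_prob[group] else "other"
    censor = rng.exponential(1.0 / config.censoring_rate) if config.censoring_rate > 0 else np.inf
    obs_end = min(death, censor, horizon)

    def _truncated_exp(rate: float) -> float:
        # event time conditioned to fall before obs_end (recurrence groups are
        # defined by an observed recurrence)
        cdf_end = 1.0 - np.exp(-rate * obs_end)
        return float(-np.log1p(-rng.random() * cdf_end) / rate)

    local = _truncated_exp(config.local_recurrence_rate[group]) if group in ("L", "LD") else None
    distant = (
        _truncated_exp(config.distant_recurrence_rate[group]) if group in ("D", "LD") else None
    )
    return RawEvents(
        death_time=death,
        death_cause=cause,
        local_recurrence_time=local,
        distant_recurrence_time=distant,
        censor_time=censor,
    )


def simulate_cohort(config: SimConfig, seed_or_rng=0) -> pd.DataFrame:
    """Simulate the matched discovery cohort.

    Returns one row per patient with recurrence group, matching covariates
    (TNM stage, CRM involvement, sex, age), the matched control's id for
    recurrent patients, and the four survival endpoints (OS, DSS, LRFP, DRFP)
    built from simulated event histories.  Controls are constructed so that
    each recurrence group can be matched exactly on (TNM, CRM, sex) with an
    age gap of at most 7 years; a control may serve one patient in each
    recurrence group but is unique within a group.  Raises
    :class:`MatchingError` if the control budget cannot cover the strata.
    """
    config.validate()
    rng = _rng(seed_or_rng)
    n_c = config.n_per_group.get("C", 0)
    rec_groups = [g for g in ("L", "D", "LD") if config.n_per_group.get(g, 0) > 0]

    def _clone_control(row) -> tuple:
        age = round(float(np.clip(row.age + rng.uniform(-2, 2), 30, 95)), 1)
        return (row.tnm, bool(row.crm), row.sex, age)

    last_failure: tuple | None = None
    controls = None
    match_of: dict[str, str] = {}
    for _attempt in range(30):
        frames = []
        for g in rec_groups:
            cov = _sample_covariates(config.n_per_group[g], config, rng)
            cov.insert(0, "group", g)
            frames.append(cov)
        recurrent = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["group", "tnm", "crm", "sex", "age"])
        )
        recurrent["patient_id"] = [f"P{i + 1:03d}" for i in range(len(recurrent))]

        # seed the control pool: one clone per patient of the group that
        # needs the most controls in each stratum (a control may serve one
        # patient per recurrence group, so the per-stratum maximum suffices
        # age structure permitting)
        ctrl_rows: list[tuple] = []
        # sorted iteration: set order is hash-randomized across processes
        strata = sorted({_stratum_key(r) for r in recurrent.itertuples()})
        for key in strata:
            counts = {
                g: sum(
                    1
                    for r in recurrent[recurrent["group"] == g].itertuples()
                    if _stratum_key(r) == key
                )
                for g in rec_groups
            }
            g_max = max(counts, key=counts.get)
            for r in recurrent[recurrent["group"] == g_max].itertuples():
                if _stratum_key(r) == key:
                    ctrl_rows.append(_clone_control(r))
        if len(ctrl_rows) > n_c:
            last_failure = max(strata, key=lambda k: sum(1 for r in recurrent.itertuples() if _stratum_key(r) == k))
            continue

        def _controls_frame(rows: list[tuple]) -> pd.DataFrame:
            df = pd.DataFrame(rows, columns=["tnm", "crm", "sex", "age"])
            df.insert(0, "group", "C")
            df["patient_id"] = [f"C{i + 1:03d}" for i in range(len(df))]
            return df

        # match each group; clone a control for any unmatched patient while
        # the control budget allows, else resample the cohort
        feasible = True
        for _round in range(2 * n_c + 2):
            controls = _controls_frame(ctrl_rows)
            match_of = {}
            unmatched_all: list[str] = []
            for g in rec_groups:
                sub = recurrent[recurrent["group"] == g]
                assignment, unmatched = _greedy_match(sub, controls, rng)
                match_of.update(assignment)
                unmatched_all.extend(unmatched)
            if not unmatched_all:
                break
            if len(ctrl_rows) >= n_c:
                row = recurrent[recurrent["patient_id"] == unmatched_all[0]].iloc[0]
                last_failure = (row.tnm, bool(row.crm), row.sex)
                feasible = False
                break
            for pid in unmatched_all[: n_c - len(ctrl_rows)]:
                row = next(recurrent[recurrent["patient_id"] == pid].itertuples())
                ctrl_rows.append(_clone_control(row))
        else:
            feasible = False
        if feasible:
            break
    else:
        key = last_failure or ("?", "?", "?")
        raise MatchingError(
            f"control group of size {n_c} cannot match stratum "
            f"(tnm={key[0]}, crm={key[1]}, sex={key[2]})"
        )

    # pad the control pool to the requested size with random covariates
    n_pad = n_c - len(controls)
    if n_pad > 0:
        pad = _sample_covariates(n_pad, config, rng)
        pad.insert(0, "group", "C")
        pad["patient_id"] = [f"C{i + 1:03d}" for i in range(len(controls), n_c)]
        controls = pd.concat([controls, pad], ignore_index=True)

    cohort = pd.concat([controls, recurrent], ignore_index=True)
    cohort["matched_control_id"] = cohort["patient_id"].map(match_of).fillna("")

    # survival endpoints
    endpoint_cols: dict[str, list] = {
        f"{name.lower()}_{kind}": []
        for name in ("OS", "DSS", "LRFP", "DRFP")
        for kind in ("time", "event")
    }
    for row in cohort.itertuples():
        raw = _simulate_survival(row.group, config, rng)
        endpoints = build_endpoints(raw, horizon=config.horizon_years)
        for name, ep in endpoints.items():
            endpoint_cols[f"{name.lower()}_time"].append(round(ep.time, 4))
            endpoint_cols[f"{name.lower()}_event"].append(ep.event)
    for col, values in endpoint_cols.items():
        cohort[col] = values

    cols = [
        "patient_id",
        "group",
        "tnm",
        "crm",
        "sex",
        "age",
        "matched_control_id",
        "os_time",
        "os_event",
        "dss_time",
        "dss_event",
        "lrfp_time",
        "lrfp_event",
        "drfp_time",
        "drfp_event",
    ]
    return cohort[cols]


# ---------------------------------------------------------------------------
# qPCR Ct plates


def build_snp_panel(probe_map: ProbeMap, snp_ids: pd.DataFrame | None = None) -> pd.DataFrame:
    """Panel table (snp_id, region, chrom, probe_idx) for chromosome 7p/7q/13 SNPs.

    When ``snp_ids`` is None, all probes on those regions are returned; the
    qpcr module's panel selection narrows this to the 16 most heterozygous per
    region.
    """
    df = probe_map.df.copy()
    df["probe_idx"] = np.arange(len(df))
    region = np.where(
        df["chrom"] == 13, "13", np.where(df["arm_label"] == "7p", "7p", np.where(df["arm_label"] == "7q", "7q", ""))
    )
    df["region"] = region
    panel = df.loc[df["region"] != "", ["probe_id", "region", "chrom", "probe_idx", "population_het"]]
    panel = panel.rename(columns={"probe_id": "snp_id"})
    if snp_ids is not None:
        panel = panel[panel["snp_id"].isin(snp_ids)]
    return panel.reset_index(drop=True)


def simulate_ct_plate(
    truth_profiles: dict[str, TruthProfile],
    snp_panel: pd.DataFrame,
    probe_map: ProbeMap,
    input_molecules: float,
    config: SimConfig,
    seed_or_rng=0,
    n_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate duplicate-well two-channel qPCR Ct values for a SNP panel.

    Per sample x SNP x replicate x channel: the number of template molecules
    is ``input_molecules`` times the per-cell copy number of that allele
    (purity mixture) divided by 2, and ``Ct = 26 - log2(molecules)`` plus
    Gaussian noise.  Wells beyond the detection limit (Ct > 40, including
    alleles absent from a homozygous genotype) drop out to missing with the
    configured probability.  Returns the Ct table and the germline genotype
    table for the same samples.
    """
    if len(snp_panel) == 0:
        raise ValueError("empty SNP panel")
    if input_molecules <= 0:
        raise ValueError("input_molecules must be positive")
    rng = _rng(seed_or_rng)
    rho = config.purity
    pop_het = probe_map.df["population_het"].to_numpy()
    ct_rows = []
    geno_rows = []
    for sample_id, truth in truth_profiles.items():
        c_all, b_all = truth.per_probe(probe_map)
        for snp in snp_panel.itertuples():
            c, b = int(c_all[snp.probe_idx]), int(b_all[snp.probe_idx])
            g = 1 if rng.random() < pop_het[snp.probe_idx] else int(rng.random() < 0.5) * 2
            geno_rows.append((sample_id, snp.snp_id, {0: "AA", 1: "AB", 2: "BB"}[g]))
            b_eff = (c - b) if rng.random() < 0.5 else b
            tum_b = b_eff if g == 1 else (0 if g == 0 else c)
            per_cell_b = rho * tum_b + (1 - rho) * g
            per_cell_a = rho * (c - tum_b) + (1 - rho) * (2 - g)
            for channel, per_cell in (("A", per_cell_a), ("B", per_cell_b)):
                molecules = input_molecules * per_cell / 2.0
                for rep in range(1, n_replicates + 1):
                    if molecules <= 0:
                        ct = np.inf
                    else:
                        ct = (
                            26.0
                            - np.log2(molecules)
                            + rng.normal(0.0, config.ct_noise_sd)
                        )
                    if ct > config.ct_missing_above and rng.random() < config.ct_missing_prob:
                        ct = np.nan
                    elif np.isinf(ct):
                        ct = np.nan
                    ct_rows.append((sample_id, snp.snp_id, rep, channel, ct))
    ct_df = pd.DataFrame(ct_rows, columns=["sample_id", "snp_id", "replicate", "channel", "ct"])
    geno_df = pd.DataFrame(geno_rows, columns=["sample_id", "snp_id", "genotype"])
    return ct_df, geno_df


# ---------------------------------------------------------------------------
# literature study tables


def simulate_study_table(
    n_studies: int,
    arms: list[str],
    seed_or_rng=0,
    site: str = "rectum",
    case_range: tuple[int, int] = (6, 120),
    gain_beta: tuple[float, float] = (1.2, 3.5),
    loss_beta: tuple[float, float] = (1.2, 4.0),
    arm_overrides: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-study chromosome-arm gain/loss case-fraction tables.

    Fractions are Beta-distributed per arm and direction; ``arm_overrides``
    maps ``(arm, "gain"|"loss")`` to alternative Beta parameters so particular
    arms can be given systematically high alteration frequencies.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if not arms:
        raise ValueError("empty arm list")
    rng = _rng(seed_or_rng)
    overrides = arm_overrides or {}
    rows = []
    for s in range(1, n_studies + 1):
        n_cases = int(rng.integers(case_range[0], case_range[1] + 1))
        for arm in arms:
            ga, gb = overrides.get((arm, "gain"), gain_beta)
            la, lb = overrides.get((arm, "loss"), loss_beta)
            rows.append(
                (
                    f"study{s:03d}",
                    n_cases,
                    site,
                    arm,
                    float(rng.beta(ga, gb)),
                    float(rng.beta(la, lb)),
                )
            )
    return pd.DataFrame(
        rows, columns=["study_id", "n_cases", "site", "arm", "gain_fraction", "loss_fraction"]
    )


# ---------------------------------------------------------------------------
# marker survival data for proportional-hazards recovery checks


def simulate_marker_survival(
    n: int,
    true_hr: float,
    seed_or_rng=0,
    marker_prevalence: float = 0.25,
    baseline_rate: float = 0.015,
    horizon: float = 12.0,
    censoring_rate: float = 0.0,
) -> pd.DataFrame:
    """Exponential event times under a proportional-hazards marker effect.

    Hazard is ``baseline_rate * true_hr**marker`` with administrative
    censoring at the horizon and optional exponential censoring, sized so a
    cohort of ~112 yields on the order of 25 events at the defaults.
    """
    rng = _rng(seed_or_rng)
    marker = (rng.random(n) < marker_prevalence).astype(int)
    rate = baseline_rate * np.power(true_hr, marker)
    event_time = rng.exponential(1.0 / rate)
    censor = (
        rng.exponential(1.0 / censoring_rate, n) if censoring_rate > 0 else np.full(n, np.inf)
    )
    obs = np.minimum.reduce([event_time, censor, np.full(n, horizon)])
    event = (event_time <= np.minimum(censor, horizon)).astype(int)
    return pd.DataFrame({"time": obs, "event": event, "marker": marker})


# ---------------------------------------------------------------------------
# one-call discovery dataset


def simulate_discovery_dataset(
    config: SimConfig | None = None, seed: int = 0, groups: tuple[str, ...] | None = None
) -> dict:
    """Simulate probe map, cohort, truth profiles and probe-level assays.

    ``groups`` restricts assay generation to a subset of recurrence groups
    (the cohort table always contains all groups).  Returns a dict with keys
    ``probe_map``, ``cohort``, ``truths`` and ``assays``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    probe_map = build_probe_map(
        n_chromosomes=config.n_chromosomes,
        probes_per_arm=config.probes_per_arm,
        arm_length_bp=config.arm_length_bp,
        seed=int(rng.integers(2**31)),
        empty_arms=config.empty_arms,
    )
    cohort = simulate_cohort(config, rng)
    truths: dict[str, TruthProfile] = {}
    assays: dict[str, AssayPair] = {}
    for row in cohort.itertuples():
        if groups is not None and row.group not in groups:
            continue
        truth = simulate_truth_profile(row.group, probe_map, config, rng)
        truths[row.patient_id] = truth
        assays[row.patient_id] = simulate_assay_pair(
            truth, probe_map, config, rng, patient_id=row.patient_id
        )
    return {"probe_map": probe_map, "cohort": cohort, "truths": truths, "assays": assays}
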