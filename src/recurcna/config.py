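"""Configuration objects for the simulator, the array pipeline and the qPCR arithmetic.

Every numeric constant of the analysis lives here with its default, so nothing
is buried in code: the copy-number thresholds (0.92 / 1.08 relative to the
sample mean), the allelic-ratio class cutpoints on mirrored BAF, the qPCR Ct
cap (30) and single-molecule anchor (26), the SNP-panel heterozygosity floor
(0.40), and the meta-analysis counting thresholds (25% of cases, 40% of
studies, 20% site contrast).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

RECURRENCE_GROUPS = ("C", "L", "D", "LD")


def _per_group(c: float, l: float, d: float, ld: float) -> dict[str, float]:
    return {"C": c, "L": l, "D": d, "LD": ld}


@dataclass
class SimConfig:
    """Study conditions for the synthetic discovery cohort.

    Defaults emulate the discovery cohort of the rectal-cancer recurrence
    study: 112 patients in four recurrence groups (no recurrence C=46, local
    L=10, distant D=41, local & distant LD=15), matched controls, ~12 years of
    follow-up, and an allelic effect structure in which the local-recurrence
    group retains heterozygosity on chromosome 7 (and largely on 13) while
    controls are enriched for allelic imbalance, with a genome-wide deficit of
    background aberrations in the L group.  D and LD share the control priors,
    so D-vs-C is effect-free by construction.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"C": 46, "L": 10, "D": 41, "LD": 15}
    )
    # genome scale (desk scale; real CytoSNP density is a config choice)
    n_chromosomes: int = 22
    probes_per_arm: int = 120
    arm_length_bp: int = 60_000_000
    empty_arms: tuple[str, ...] = ("13p",)  # chr13 is acrocentric

    # assay model
    purity: float = 0.75
    noise_sd_cn: float = 0.08
    noise_sd_baf: float = 0.03
    wave_amplitude: float = 0.05
    wave_period_bp: float = 30_000_000.0
    intensity_log2_scale: float = 5.0  # mean log2 raw intensity of a good sample
    intensity_log2_sd: float = 0.3

    # chromosome-7 status priors per group (retention = remainder)
    chr7_imbalance_prob: dict[str, float] = field(
        default_factory=lambda: _per_group(0.60, 0.0, 0.60, 0.60)
    )
    chr7_loh_prob: dict[str, float] = field(
        default_factory=lambda: _per_group(0.02, 0.0, 0.02, 0.02)
    )
    # chromosome-13 status priors per group
    chr13_imbalance_prob: dict[str, float] = field(
        default_factory=lambda: _per_group(0.60, 0.11, 0.60, 0.60)
    )
    chr13_loh_prob: dict[str, float] = field(
        default_factory=lambda: _per_group(0.13, 0.11, 0.13, 0.13)
    )
    # background arm-level aberration rates per group
    background_gain_rate: dict[str, float] = field(
        default_factory=lambda: _per_group(0.25, 0.08, 0.25, 0.25)
    )
    background_loss_rate: dict[str, float] = field(
        default_factory=lambda: _per_group(0.20, 0.08, 0.20, 0.20)
    )

    # cohort covariate marginals (discovery-cohort Table-1-like)
    tnm_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.10, "II": 0.21, "III": 0.69}
    )
    crm_prob: float = 0.27
    male_prob: float = 0.65
    age_mean: float = 64.0
    age_sd: float = 9.0

    # survival generator (exponential hazards, 1/years)
    horizon_years: float = 12.0
    death_rate: dict[str, float] = field(
        default_factory=lambda: _per_group(0.045, 0.09, 0.16, 0.20)
    )
    cancer_death_prob: dict[str, float] = field(
        default_factory=lambda: _per_group(0.25, 0.60, 0.75, 0.80)
    )
    local_recurrence_rate: dict[str, float] = field(
        default_factory=lambda: _per_group(0.0, 0.35, 0.0, 0.40)
    )
    distant_recurrence_rate: dict[str, float] = field(
        default_factory=lambda: _per_group(0.0, 0.0, 0.40, 0.45)
    )
    censoring_rate: float = 0.04

    # qPCR plate model
    ct_noise_sd: float = 0.15
    ct_missing_above: float = 40.0
    ct_missing_prob: float = 0.9  # probability a Ct beyond the detection limit drops out

    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        for name in (
            "chr7_imbalance_prob",
            "chr7_loh_prob",
            "chr13_imbalance_prob",
            "chr13_loh_prob",
            "background_gain_rate",
            "background_loss_rate",
        ):
            for g, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{g}] = {p} outside [0, 1]")
        for g in RECURRENCE_GROUPS:
            if self.chr7_imbalance_prob[g] + self.chr7_loh_prob[g] > 1.0:
                raise ValueError(f"chr7 priors for group {g} exceed 1")
            if self.chr13_imbalance_prob[g] + self.chr13_loh_prob[g] > 1.0:
                raise ValueError(f"chr13 priors for group {g} exceed 1")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("negative group size")


@dataclass
class CallingConfig:
    """Thresholds for QC, genotype calling, segmentation and state calling."""

    loss_threshold: float = 0.92  # CN ratio below -> loss (strict)
    gain_threshold: float = 1.08  # CN ratio above -> gain (strict)
    baf_aa_max: float = 0.15
    baf_ab_low: float = 0.35
    baf_ab_high: float = 0.65
    baf_bb_min: float = 0.85
    concordance_min: float = 0.90
    mean_log2_min: float = 4.0
    mbaf_imbalance_cut: float = 0.60
    # chosen so a mono-allelic deletion at purity 0.75 (mBAF 0.80) calls LOH
    # while a 3:1 gain (mBAF 0.64) calls imbalance
    mbaf_loh_cut: float = 0.78
    min_het_per_segment: int = 10
    segmentation_alpha: float = 0.01
    min_seg_probes: int = 5
    n_segmentation_permutations: int = 200
    dewave_span_bp: float = 30_000_000.0
    loss_report_min_probes: int = 15  # loss frequencies restricted to >=15-SNP segments

    def validate(self) -> None:
        if not self.loss_threshold < 1.0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 1 < gain_threshold")
        if not 0.5 < self.mbaf_imbalance_cut < self.mbaf_loh_cut <= 1.0:
            raise ValueError("need 0.5 < mbaf_imbalance_cut < mbaf_loh_cut <= 1")


@dataclass
class AssociationConfig:
    """Hierarchy gating and permutation counts for the group-association tests."""

    alpha: float = 0.05  # gate on adjusted values at each level
    n_perm_genome: int = 10_000
    n_perm_arm: int = 10_000
    n_perm_region: int = 2_000
    region_probes: int = 30  # sub-arm window size for region-level tests
    status_weight: str = "het"  # abundance measure: 'het' or 'probes'


@dataclass
class QpcrConfig:
    """Dynamic-array arithmetic constants."""

    ct_cap: float = 30.0  # Ct > 30 and missing wells set to 30
    single_molecule_ct: float = 26.0  # Ct 26 == one DNA molecule
    min_het_fraction: float = 0.40
    panel_size_per_region: int = 16  # 16 SNPs each on 7p, 7q and chr13
    max_ratio_sentinel: float = 256.0  # emitted when the B channel is empty

    def validate(self) -> None:
        if not self.ct_cap > self.single_molecule_ct:
            raise ValueError("ct_cap must exceed single_molecule_ct")


@dataclass
class MetaConfig:
    """Thresholds of the literature counting rule."""

    case_threshold: float = 0.25  # >=25% of a study's cases (inclusive)
    study_threshold: float = 0.40  # >=40% of studies (inclusive)
    site_delta: float = 0.20  # rectum-vs-colon contrast, strict >


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(*configs: Any) -> str:
    """Short stable digest of one or more config dataclasses, for provenance."""
    payload = json.dumps([_to_jsonable(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _update_dataclass(obj: Any, data: dict[str, Any]) -> None:
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise KeyError(f"unknown {type(obj).__name__} field: {key}")
        current = getattr(obj, key)
        if isinstance(current, dict) and isinstance(value, dict):
            current.update(value)
        elif isinstance(current, tuple) and isinstance(value, list):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)


def load_config(path: str) -> dict[str, Any]:
    """Load a YAML run configuration.

    Recognized top-level sections: ``sim``, ``calling``, ``association``,
    ``qpcr``, ``meta``.  Missing sections get defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {
        "sim": SimConfig(),
        "calling": CallingConfig(),
        "association": AssociationConfig(),
        "qpcr": QpcrConfig(),
        "meta": MetaConfig(),
    }
    for section, obj in out.items():
        if section in raw and raw[section]:
            _update_dataclass(obj, raw[section])
    out["sim"].validate()
    out["calling"].validate()
    out["qpcr"].validate()
    return out
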