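"""The SNP probe coordinate backbone.

A :class:`ProbeMap` is an ordered table of SNP probes (chromosome, arm,
base-pair position, expected population heterozygosity) to which every
per-probe vector in the package is aligned.  Coordinates are 0-based and
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ARM_ORDER = ("p", "q")


@dataclass
class ProbeMap:
    """Ordered SNP probes with genomic coordinates.

    Wraps a DataFrame with columns ``probe_id, chrom, arm, pos,
    population_het`` sorted by (chrom, pos); positions are strictly increasing
    within a chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "chrom", "arm", "pos", "population_het"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"probe map missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")
        het = self.df["population_het"].to_numpy()
        if np.any((het < 0) | (het > 1)):
            raise ValueError("population_het outside [0, 1]")
        if not self.df["arm"].isin(ARM_ORDER).all():
            raise ValueError("invalid arm labels")
        self.df["arm_label"] = self.df["chrom"].astype(str) + self.df["arm"]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.df["chrom"].unique().tolist())

    @property
    def arm_labels(self) -> list[str]:
        """Arm labels in genomic order (only arms that carry probes)."""
        seen: list[str] = []
        for label in self.df["arm_label"]:
            if label not in seen:
                seen.append(label)
        return seen

    def chrom_index(self, chrom: int) -> np.ndarray:
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def arm_index(self, arm_label: str) -> np.ndarray:
        return np.flatnonzero((self.df["arm_label"] == arm_label).to_numpy())

    def positions(self, chrom: int) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def to_tsv(self, path: str, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.df[["probe_id", "chrom", "arm", "pos", "population_het"]].to_csv(
                fh, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, path: str) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df.rename(columns={"chrom": "chrom", "pos": "pos"}))


def build_probe_map(
    n_chromosomes: int = 22,
    probes_per_arm: int = 120,
    arm_length_bp: int = 60_000_000,
    seed: int = 0,
    empty_arms: tuple[str, ...] = (),
) -> ProbeMap:
    """Construct a synthetic probe map with uniformly jittered probe positions.

    Each chromosome gets a p arm on [0, arm_length_bp) and a q arm on
    [arm_length_bp, 2*arm_length_bp), each carrying ``probes_per_arm`` probes
    at distinct sorted positions.  Arms named in ``empty_arms`` (e.g. ``"13p"``
    for the acrocentric chromosome 13) receive no probes.  Deterministic for a
    given seed.
    """
    if not 1 <= n_chromosomes <= 22:
        raise ValueError(f"n_chromosomes must be in [1, 22], got {n_chromosomes}")
    if probes_per_arm < 2:
        raise ValueError(f"probes_per_arm must be >= 2, got {probes_per_arm}")
    if arm_length_bp <= probes_per_arm:
        raise ValueError("arm_length_bp too small for the probe count")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in range(1, n_chromosomes + 1):
        for arm_i, arm in enumerate(ARM_ORDER):
            if f"{chrom}{arm}" in empty_arms:
                continue
            offset = arm_i * arm_length_bp
            pos = rng.choice(arm_length_bp, size=probes_per_arm, replace=False)
            pos.sort()
            het = rng.uniform(0.2, 0.55, size=probes_per_arm)
            for j in range(probes_per_arm):
                rows.append(
                    (
                        f"rs{chrom:02d}{arm}{j:05d}",
                        chrom,
                        arm,
                        int(offset + pos[j]),
                        float(het[j]),
                    )
                )
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "arm", "pos", "population_het"])
    return ProbeMap(df)
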