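"""Tabular I/O for every pipeline artifact, with provenance headers.

All files are plain text.  Provenance lines start with ``#`` and record the
package version, the config hash and the seed, so every output can be traced
to the run that produced it.  Formats:

- probes.tsv: probe_id, chrom, arm, pos, population_het
- assay.tsv (long): sample_id, patient_id, tissue (tumor|normal), probe_id,
  cn_ratio, baf
- cohort.csv: patient_id, group, tnm, crm, sex, age, matched_control_id and
  the eight endpoint columns
- segments.bed: BED6+5 (chrom, start, end, name=patient_id,
  score=round(100*mean_cn_ratio), strand '.', then n_probes, n_het,
  mean_mbaf, cn_state, allelic_class)
- ct.csv: sample_id, snp_id, replicate, channel, ct (empty = missing)
- studies.csv: study_id, n_cases, site, arm, gain_fraction, loss_fraction
- truth.json: serialized latent profiles per patient
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .probemap import ProbeMap
from .synthetic import AssayPair, TruthProfile


def provenance_lines(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    lines = [f"recurcna {__version__}"]
    if config_hash is not None:
        lines.append(f"config_hash {config_hash}")
    if seed is not None:
        lines.append(f"seed {seed}")
    return lines


def _write_with_header(df: pd.DataFrame, path: str, sep: str, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_table(
    df: pd.DataFrame,
    path: str,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".bed")) else ","
    _write_with_header(df, path, sep, provenance_lines(seed, config_hash))


def read_table(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".bed")) else ","
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# assays


def assays_to_frame(assays: dict[str, AssayPair], probe_map: ProbeMap) -> pd.DataFrame:
    """Long-format probe-level table for a set of tumor/normal pairs."""
    frames = []
    probe_ids = probe_map.df["probe_id"].to_numpy()
    for pid in sorted(assays):
        a = assays[pid]
        for tissue, cn, baf in (
            ("tumor", a.tumor_cn, a.tumor_baf),
            ("normal", a.normal_cn, a.normal_baf),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": f"{pid}_{tissue[0].upper()}",
                        "patient_id": pid,
                        "tissue": tissue,
                        "probe_id": probe_ids,
                        "cn_ratio": np.round(cn, 5),
                        "baf": np.round(baf, 5),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def frame_to_assays(df: pd.DataFrame, probe_map: ProbeMap) -> dict[str, AssayPair]:
    """Rebuild AssayPair objects from the long-format table.

    Raw intensities are not part of the interchange format; they are set to
    ``2**5 * cn_ratio`` (a passing intensity scale) so QC still runs.
    Germline genotypes are unknown for real data and set to -1; genotype
    calls come from the pipeline.
    """
    probe_ids = probe_map.df["probe_id"].to_numpy()
    out: dict[str, AssayPair] = {}
    for pid, sub in df.groupby("patient_id"):
        vectors: dict[str, dict[str, np.ndarray]] = {}
        for tissue, tsub in sub.groupby("tissue"):
            tsub = tsub.set_index("probe_id").reindex(probe_ids)
            if tsub["cn_ratio"].isna().any():
                raise ValueError(f"sample {pid}/{tissue} does not cover the probe map")
            vectors[tissue] = {
                "cn": tsub["cn_ratio"].to_numpy(float),
                "baf": tsub["baf"].to_numpy(float),
            }
        if set(vectors) != {"tumor", "normal"}:
            raise ValueError(f"patient {pid}: need exactly one tumor and one normal sample")
        out[pid] = AssayPair(
            patient_id=pid,
            tumor_cn=vectors["tumor"]["cn"],
            tumor_baf=vectors["tumor"]["baf"],
            normal_cn=vectors["normal"]["cn"],
            normal_baf=vectors["normal"]["baf"],
            tumor_raw=vectors["tumor"]["cn"] * 2.0**5,
            normal_raw=vectors["normal"]["cn"] * 2.0**5,
            germline_genotype=np.full(len(probe_map), -1, dtype=int),
        )
    return out


# ---------------------------------------------------------------------------
# segments (BED6+5)

_BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "n_probes",
    "n_het",
    "mean_mbaf",
    "cn_state",
    "allelic_class",
]


def segments_to_bed(calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for pid in sorted(calls):
        for seg in calls[pid].itertuples():
            rows.append(
                {
                    "chrom": f"chr{seg.chrom}",
                    "start": seg.start_bp,
                    "end": seg.end_bp,
                    "name": pid,
                    "score": int(round(100 * seg.mean_cn_ratio)),
                    "strand": ".",
                    "n_probes": seg.n_probes,
                    "n_het": seg.n_het,
                    "mean_mbaf": round(seg.mean_mbaf, 4) if np.isfinite(seg.mean_mbaf) else "",
                    "cn_state": seg.cn_state,
                    "allelic_class": seg.allelic_class if not pd.isna(seg.allelic_class) else "",
                }
            )
    return pd.DataFrame(rows, columns=_BED_COLUMNS)


def write_segments_bed(
    calls: dict[str, pd.DataFrame],
    path: str,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    df = segments_to_bed(calls)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, config_hash):
            fh.write(f"# {line}\n")
        fh.write("\t".join(_BED_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_segments_bed(path: str, probe_map: ProbeMap) -> dict[str, pd.DataFrame]:
    """Read a segments BED back into per-patient call tables.

    Probe index bounds are reconstructed from bp bounds against the probe
    map.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, pd.DataFrame] = {}
    for pid, sub in df.groupby("name"):
        rows = []
        for seg in sub.itertuples():
            chrom = int(str(seg.chrom).removeprefix("chr"))
            pos = probe_map.positions(chrom)
            start_idx = int(np.searchsorted(pos, seg.start, side="left"))
            end_idx = int(np.searchsorted(pos, seg.end - 1, side="right"))
            rows.append(
                {
                    "patient_id": pid,
                    "chrom": chrom,
                    "start_idx": start_idx,
                    "end_idx": end_idx,
                    "start_bp": seg.start,
                    "end_bp": seg.end,
                    "n_probes": seg.n_probes,
                    "n_het": seg.n_het,
                    "mean_cn_ratio": seg.score / 100.0,
                    "mean_mbaf": seg.mean_mbaf if seg.mean_mbaf == seg.mean_mbaf else np.nan,
                    "cn_state": seg.cn_state,
                    "allelic_class": int(seg.allelic_class)
                    if seg.allelic_class == seg.allelic_class
                    else pd.NA,
                }
            )
        calls = pd.DataFrame(rows)
        calls["allelic_class"] = calls["allelic_class"].astype("Int64")
        out[pid] = calls.sort_values(["chrom", "start_idx"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# truth profiles


def write_truth_json(truths: dict[str, TruthProfile], path: str, seed: int | None = None) -> None:
    payload = {
        "_provenance": {"version": __version__, "seed": seed},
        "profiles": {pid: t.to_dict() for pid, t in sorted(truths.items())},
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path: str) -> dict[str, TruthProfile]:
    payload = json.loads(Path(path).read_text())
    return {pid: TruthProfile.from_dict(d) for pid, d in payload["profiles"].items()}


# ---------------------------------------------------------------------------
# validation

_COHORT_COLUMNS = [
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


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema checks for declared input files; returns a list of violations.

    Recognized keys: probes, assay, cohort, segments, ct, studies.  Checks
    columns, value ranges, sortedness and (for segments) per-sample tiling.
    """
    violations: list[str] = []

    def _load(key: str, sep: str) -> pd.DataFrame | None:
        try:
            return pd.read_csv(paths[key], sep=sep, comment="#")
        except OSError as exc:
            raise OSError(f"cannot read {key} file {paths[key]}: {exc}") from exc
        except Exception as exc:  # malformed text
            violations.append(f"{key}: unparseable ({exc})")
            return None

    probe_map = None
    if "probes" in paths:
        df = _load("probes", "\t")
        if df is not None:
            try:
                probe_map = ProbeMap(df)
            except ValueError as exc:
                violations.append(f"probes: {exc}")

    if "assay" in paths:
        df = _load("assay", "\t")
        if df is not None:
            need = {"sample_id", "patient_id", "tissue", "probe_id", "cn_ratio", "baf"}
            if not need.issubset(df.columns):
                violations.append(f"assay: missing columns {sorted(need - set(df.columns))}")
            else:
                if not df["tissue"].isin(["tumor", "normal"]).all():
                    violations.append("assay: tissue must be tumor|normal")
                bad_baf = ((df["baf"] < 0) | (df["baf"] > 1)).sum()
                if bad_baf:
                    violations.append(f"assay: {bad_baf} baf values outside [0, 1]")
                if (df["cn_ratio"] < 0).any():
                    violations.append("assay: negative cn_ratio values")

    if "cohort" in paths:
        df = _load("cohort", ",")
        if df is not None:
            missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
            if missing:
                violations.append(f"cohort: missing columns {missing}")
            else:
                if not df["group"].isin(["C", "L", "D", "LD"]).all():
                    violations.append("cohort: invalid group labels")
                for col in ("os_time", "dss_time", "lrfp_time", "drfp_time"):
                    if (df[col] < 0).any():
                        violations.append(f"cohort: negative {col}")
                for col in ("os_event", "dss_event", "lrfp_event", "drfp_event"):
                    if not df[col].isin([0, 1]).all():
                        violations.append(f"cohort: {col} must be 0/1")

    if "segments" in paths:
        df = _load("segments", "\t")
        if df is not None:
            need = {"chrom", "start", "end", "name", "n_probes"}
            if not need.issubset(df.columns):
                violations.append(f"segments: missing columns {sorted(need - set(df.columns))}")
            else:
                if (df["end"] <= df["start"]).any():
                    violations.append("segments: empty or inverted intervals")
                for (pid, chrom), sub in df.groupby(["name", "chrom"]):
                    sub = sub.sort_values("start")
                    if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                        violations.append(f"segments: overlapping segments for {pid} on {chrom}")
                        break

    if "ct" in paths:
        df = _load("ct", ",")
        if df is not None:
            need = {"sample_id", "snp_id", "replicate", "channel", "ct"}
            if not need.issubset(df.columns):
                violations.append(f"ct: missing columns {sorted(need - set(df.columns))}")
            else:
                if not df["channel"].isin(["A", "B"]).all():
                    violations.append("ct: channel must be A|B")
                finite = df["ct"].dropna()
                if (finite < 0).any():
                    violations.append("ct: negative Ct values")

    if "studies" in paths:
        df = _load("studies", ",")
        if df is not None:
            need = {"study_id", "n_cases", "arm", "gain_fraction", "loss_fraction"}
            if not need.issubset(df.columns):
                violations.append(f"studies: missing columns {sorted(need - set(df.columns))}")
            else:
                for col in ("gain_fraction", "loss_fraction"):
                    vals = df[col].dropna()
                    if ((vals < 0) | (vals > 1)).any():
                        violations.append(f"studies: {col} outside [0, 1]")
                if (df["n_cases"] <= 0).any():
                    violations.append("studies: non-positive case counts")

    return violations
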