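"""Literature counting rule for common chromosome-arm copy-number alterations.

A study "frequently" reports an alteration on an arm when at least 25% of its
cases carry it; an alteration is "common with high frequency" when at least
40% of the studies (after site filtering) frequently report it.  Rectum-vs-
colon contrasts flag arms whose study fractions differ by strictly more than
20 percentage points.  Studies with unextractable percentages are represented
with missing fractions and excluded per arm, not per study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MetaConfig

CANONICAL_ARMS = tuple(
    f"{c}{a}" for c in range(1, 23) for a in ("p", "q") if f"{c}{a}" not in ("13p", "14p", "15p", "21p", "22p")
)

_STUDY_COLUMNS = {"study_id", "n_cases", "arm", "gain_fraction", "loss_fraction"}


def _check_studies(studies: pd.DataFrame) -> None:
    missing = _STUDY_COLUMNS - set(studies.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    for col in ("gain_fraction", "loss_fraction"):
        vals = studies[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")


def flag_frequent(studies: pd.DataFrame, case_threshold: float = 0.25) -> pd.DataFrame:
    """Per study and arm: does the study report the alteration frequently?

    The flag is inclusive (``fraction >= case_threshold``); missing fractions
    yield missing flags.
    """
    _check_studies(studies)
    out = studies.copy()
    for direction in ("gain", "loss"):
        frac = out[f"{direction}_fraction"]
        out[f"{direction}_frequent"] = pd.array(
            np.where(frac.isna(), pd.NA, frac >= case_threshold), dtype="boolean"
        )
    return out


def common_alterations(
    studies: pd.DataFrame,
    site_filter: str | None = None,
    study_threshold: float = 0.40,
    case_threshold: float = 0.25,
) -> pd.DataFrame:
    """Fraction of studies frequently reporting each arm alteration.

    Per arm and direction: the fraction of (site-filtered) studies whose
    case fraction reaches ``case_threshold``, computed over studies with a
    non-missing fraction for that arm; ``common`` is inclusive at
    ``study_threshold``.
    """
    _check_studies(studies)
    sub = studies
    if site_filter is not None:
        if "site" not in studies.columns:
            raise ValueError("study table has no 'site' column to filter on")
        sub = studies[studies["site"] == site_filter]
        if len(sub) == 0:
            raise ValueError(f"no studies left after site filter {site_filter!r}")
    flagged = flag_frequent(sub, case_threshold)
    rows = []
    for arm, arm_df in flagged.groupby("arm", sort=False):
        for direction in ("gain", "loss"):
            flags = arm_df[f"{direction}_frequent"].dropna()
            n = len(flags)
            frac = float(flags.sum() / n) if n else np.nan
            rows.append(
                {
                    "arm": arm,
                    "direction": direction,
                    "n_studies": n,
                    "fraction_of_studies": frac,
                    "common": bool(frac >= study_threshold) if n else False,
                }
            )
    return pd.DataFrame(rows)


def site_contrast(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    delta_threshold: float = 0.20,
    labels: tuple[str, str] = ("rectum", "colon"),
) -> pd.DataFrame:
    """Arms whose study fractions differ by strictly more than the threshold.

    Both inputs are :func:`common_alterations` summaries over the same
    arm/direction list.  The returned table notes which site shows the
    excess.
    """
    key = ["arm", "direction"]
    a = summary_a.set_index(key)
    b = summary_b.set_index(key)
    if not a.index.equals(b.index):
        raise ValueError("summaries cover different arm/direction lists")
    diff = a["fraction_of_studies"] - b["fraction_of_studies"]
    hit = diff.abs() > delta_threshold
    out = pd.DataFrame(
        {
            f"fraction_{labels[0]}": a["fraction_of_studies"],
            f"fraction_{labels[1]}": b["fraction_of_studies"],
            "difference": diff,
            "excess_site": np.where(diff > 0, labels[0], labels[1]),
        }
    )
    return out[hit].reset_index()
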