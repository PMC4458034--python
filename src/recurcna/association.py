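"""Group-association testing: hierarchical global tests, BH correction,
chromosome status and exact r x c Fisher tests.

The global test asks whether a set of per-probe features (continuous CN
ratios, or allelic-ratio class codes 1/2/3) is jointly associated with a
binary group label.  With features row-standardized to z_j and the centered
label vector y~, the statistic is

    Q = (1/m) * sum_j (z_j . y~)^2

and its p-value comes from seeded label permutations.  The hierarchy mirrors
the discovery analysis: a genome-wide test gates per-arm tests (BH-adjusted
across arms), and significant arms gate region-level tests (BH-adjusted
within the arm's family).

Chromosome status is the most abundant allelic class on the chromosome
(1 balanced, 2 imbalanced, 3 LOH); combinations of chromosomes take the
highest status number; group differences in status counts are assessed with
an exact Fisher test for r x c count data computed by full enumeration of
tables with the observed margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AssociationConfig
from .probemap import ProbeMap

COMPARISONS = {"L-vs-C": ("L", "C"), "D-vs-C": ("D", "C"), "LD-vs-C": ("LD", "C")}


class UndefinedTestError(ValueError):
    """Raised when no testable features remain."""


@dataclass
class TestResult:
    level: str  # genome | arm | region
    scope: str  # e.g. "genome", "7p", "7p:120-150"
    comparison: str
    datatype: str  # "cn" | "allelic"
    statistic: float
    p_value: float
    p_adjusted: float | None
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# global test


def global_test(
    feature_matrix: np.ndarray,
    binary_labels: np.ndarray,
    n_permutations: int = 10_000,
    seed_or_rng=0,
) -> tuple[float, float]:
    """Score-form global test of joint feature/label association.

    ``feature_matrix`` has one row per feature and one column per sample.
    Rows are standardized to mean 0, SD 1; zero-variance rows are dropped
    (if every row is constant the statistic is 0 and p is 1).  Returns
    ``(Q, p)`` with the permutation p-value ``(1 + #{Q_perm >= Q}) / (1 + B)``.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise UndefinedTestError("empty feature matrix")
    y = np.asarray(binary_labels, dtype=float)
    if X.shape[1] != y.size:
        raise ValueError("labels do not align with feature columns")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.any():
        return 0.0, 1.0
    Z = (X[keep] - mu[keep]) / sd[keep]
    y_c = y - y.mean()
    m = Z.shape[0]
    q_obs = float(np.mean((Z @ y_c) ** 2))
    perms = rng.permuted(np.tile(y_c, (n_permutations, 1)), axis=1)
    q_perm = np.mean((Z @ perms.T) ** 2, axis=0)
    p = float((1.0 + np.sum(q_perm >= q_obs)) / (1.0 + n_permutations))
    return q_obs, p


# ---------------------------------------------------------------------------
# probe-level matrices from segment calls


def probe_matrices(
    calls: dict[str, pd.DataFrame], probe_map: ProbeMap, assays: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe CN and allelic-class matrices (patients x probes).

    The CN matrix carries each patient's normalized, de-waved per-probe ratio
    when the assay objects are given, otherwise the segment-mean ratio spread
    over the segment's probes.  The class matrix expands segment classes to
    per-probe integer codes; probes in segments with a missing class are
    coded 1 (no evidence of aberration).
    """
    patients = sorted(calls)
    n_probes = len(probe_map)
    cn = np.empty((len(patients), n_probes))
    cls = np.empty((len(patients), n_probes))
    for i, pid in enumerate(patients):
        if assays is not None and assays[pid].norm_cn is not None:
            cn[i] = assays[pid].norm_cn
        for seg in calls[pid].itertuples():
            idx = probe_map.chrom_index(seg.chrom)[seg.start_idx : seg.end_idx]
            if assays is None or assays[pid].norm_cn is None:
                cn[i, idx] = seg.mean_cn_ratio
            cls[i, idx] = seg.allelic_class if not pd.isna(seg.allelic_class) else 1
    cols = probe_map.df["probe_id"]
    return (
        pd.DataFrame(cn, index=patients, columns=cols),
        pd.DataFrame(cls, index=patients, columns=cols),
    )


# ---------------------------------------------------------------------------
# BH adjustment


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# hierarchical testing


def _region_windows(n: int, size: int) -> list[tuple[int, int]]:
    """Split ``n`` probes into contiguous windows of about ``size`` probes."""
    k = max(1, round(n / size))
    edges = np.linspace(0, n, k + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def hierarchical_test(
    cn_matrix: pd.DataFrame,
    class_matrix: pd.DataFrame,
    groups: pd.Series,
    probe_map: ProbeMap,
    comparison: str = "L-vs-C",
    config: AssociationConfig | None = None,
    seed: int = 0,
) -> list[TestResult]:
    """Gated genome -> arm -> region global tests for one group comparison.

    Arm tests run only when the genome-wide test is significant at
    ``config.alpha``; arm p-values are BH-adjusted across all tested arms (one
    family per comparison and datatype), and region tests run within each
    accepted arm, BH-adjusted within that arm's family.  Both the continuous
    CN data and the per-probe allelic class codes are tested.
    """
    config = config or AssociationConfig()
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    case, control = COMPARISONS[comparison]
    groups = groups.loc[cn_matrix.index]
    sel = groups.isin([case, control]).to_numpy()
    if groups[sel].nunique() < 2:
        raise ValueError(f"comparison {comparison} needs both groups present")
    y = (groups[sel] == case).to_numpy(float)
    rng = np.random.default_rng(seed)
    results: list[TestResult] = []
    for datatype, matrix in (("cn", cn_matrix), ("allelic", class_matrix)):
        X = matrix.to_numpy(float)[sel].T  # probes x samples
        q, p = global_test(X, y, config.n_perm_genome, rng)
        genome = TestResult(
            "genome", "genome", comparison, datatype, q, p, p, config.n_perm_genome, seed
        )
        results.append(genome)
        if p >= config.alpha:
            continue
        arm_results = []
        for arm in probe_map.arm_labels:
            idx = probe_map.arm_index(arm)
            q_a, p_a = global_test(X[idx], y, config.n_perm_arm, rng)
            arm_results.append(
                TestResult(
                    "arm", arm, comparison, datatype, q_a, p_a, None, config.n_perm_arm, seed
                )
            )
        adj = bh_adjust([r.p_value for r in arm_results])
        for r, a in zip(arm_results, adj):
            r.p_adjusted = float(a)
        results.extend(arm_results)
        for r in arm_results:
            if r.p_adjusted >= config.alpha:
                continue
            idx = probe_map.arm_index(r.scope)
            region_results = []
            for a, b in _region_windows(len(idx), config.region_probes):
                q_r, p_r = global_test(X[idx[a:b]], y, config.n_perm_region, rng)
                region_results.append(
                    TestResult(
                        "region",
                        f"{r.scope}:{a}-{b}",
                        comparison,
                        datatype,
                        q_r,
                        p_r,
                        None,
                        config.n_perm_region,
                        seed,
                    )
                )
            adj = bh_adjust([x.p_value for x in region_results])
            for x, a in zip(region_results, adj):
                x.p_adjusted = float(a)
            results.extend(region_results)
    return results


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": r.level,
                "scope": r.scope,
                "comparison": r.comparison,
                "datatype": r.datatype,
                "Q": r.statistic,
                "p": r.p_value,
                "p_BH": r.p_adjusted,
                "n_perm": r.n_permutations,
                "seed": r.seed,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# chromosome status


def chromosome_status(
    segment_calls: pd.DataFrame, chromosome: int, abundance_measure: str = "het"
) -> int | None:
    """Most abundant allelic class on a chromosome for one patient.

    Abundance is the total number of heterozygous probes (default) or total
    probes carried by segments of each class; ties resolve to the more
    aberrant (higher) class.  Returns None when every segment's class is
    missing.
    """
    if abundance_measure not in ("het", "probes"):
        raise ValueError(f"unknown abundance measure {abundance_measure!r}")
    sub = segment_calls[segment_calls["chrom"] == chromosome]
    weights: dict[int, float] = {}
    col = "n_het" if abundance_measure == "het" else "n_probes"
    for seg in sub.itertuples():
        if pd.isna(seg.allelic_class):
            continue
        weights[int(seg.allelic_class)] = weights.get(int(seg.allelic_class), 0) + getattr(
            seg, col
        )
    if not weights:
        return None
    best = max(weights.values())
    return max(k for k, w in weights.items() if w == best)


def combine_status(status_a: int | None, status_b: int | None) -> int | None:
    """Combined status of two chromosomes: the highest status number."""
    if status_a is None or status_b is None:
        return None
    for s in (status_a, status_b):
        if s not in (1, 2, 3):
            raise ValueError(f"status must be 1, 2 or 3, got {s}")
    return max(status_a, status_b)


def status_table(
    calls: dict[str, pd.DataFrame], chromosomes: list[int], abundance_measure: str = "het"
) -> pd.DataFrame:
    """Per-patient overall status for each chromosome and their combination."""
    rows = []
    for pid in sorted(calls):
        statuses = {
            chrom: chromosome_status(calls[pid], chrom, abundance_measure)
            for chrom in chromosomes
        }
        combined: int | None = None
        for s in statuses.values():
            combined = s if combined is None else combine_status(combined, s)
        row = {"patient_id": pid}
        row.update({f"chr{c}": statuses[c] for c in chromosomes})
        if len(chromosomes) > 1:
            row["combined"] = combined
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact r x c Fisher test


def fisher_rxc(contingency_table) -> float:
    """Exact Fisher test for an r x c table of counts.

    Enumerates every table with the observed margins; the p-value is the
    total multivariate-hypergeometric probability of tables no more probable
    than the observed one (with a 1e-7 relative tolerance against rounding).
    Deterministic; practical for the small tables of status comparisons.
    """
    t = np.asarray(contingency_table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    total = int(t.sum())
    if total == 0:
        raise ValueError("table total is zero")

    n_rows, n_cols = t.shape
    p_sum = 0.0

    # log(k!) lookup, shared by the observed table and the enumeration
    lf = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, total + 1)))])
    const = sum(lf[r] for r in row_sums) + sum(lf[c] for c in col_sums) - lf[total]
    log_obs = const - sum(lf[int(x)] for x in t.ravel())
    threshold = log_obs + np.log1p(1e-7)

    def _recurse(row: int, col: int, rem_row: int, rem_cols: np.ndarray, log_acc: float) -> None:
        nonlocal p_sum
        if row == n_rows - 1:
            # last row forced by column margins
            log_p = const + log_acc - sum(lf[c] for c in rem_cols)
            if log_p <= threshold:
                p_sum += np.exp(log_p)
            return
        if col == n_cols - 1:
            if rem_row > rem_cols[col]:
                return
            new_cols = rem_cols.copy()
            new_cols[col] -= rem_row
            _recurse(row + 1, 0, int(row_sums[row + 1]), new_cols, log_acc - lf[rem_row])
            return
        max_here = min(rem_row, int(rem_cols[col]))
        for x in range(max_here + 1):
            new_cols = rem_cols.copy()
            new_cols[col] -= x
            _recurse(row, col + 1, rem_row - x, new_cols, log_acc - lf[x])

    _recurse(0, 0, int(row_sums[0]), col_sums.astype(int).copy(), 0.0)
    return float(min(p_sum, 1.0))


def status_group_test(
    statuses: pd.Series, groups: pd.Series, comparison: str = "L-vs-C"
) -> tuple[pd.DataFrame, float]:
    """Status-by-group contingency table and its exact Fisher p-value.

    ``statuses`` holds per-patient status codes (1/2/3, NA excluded with a
    warning-free drop) indexed by patient_id; ``groups`` the recurrence
    groups.  Builds the 2 x 3 table (rows: case group, control group; columns:
    status 1, 2, 3).
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    case, control = COMPARISONS[comparison]
    merged = pd.DataFrame({"status": statuses, "group": groups}).dropna(subset=["status"])
    table = np.zeros((2, 3), dtype=int)
    for i, g in enumerate((case, control)):
        sub = merged[merged["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"empty group {g} in comparison {comparison}")
        for j, s in enumerate((1, 2, 3)):
            table[i, j] = int((sub["status"] == s).sum())
    table_df = pd.DataFrame(
        table, index=[case, control], columns=["retention", "imbalance", "LOH"]
    )
    return table_df, fisher_rxc(table)
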