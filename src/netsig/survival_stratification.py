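"""Signature-based patient stratification and metastasis-free-survival testing.

The chain mirrors standard prognostic-signature practice on microarray
compendia: collapse probes to genes (keep the probe with the highest mean
expression), quantile-normalize patients, restrict to the signature
genes, cluster patients by complete linkage on Pearson-correlation
distance, detect clusters with a dynamic hybrid dendrogram cut governed
by a minimum cluster-size fraction, then compare the clusters'
Kaplan–Meier curves with a k-sample log-rank test.

Expression matrices are pandas DataFrames (rows = probes or genes,
columns = patient ids, log-scale values); survival annotation is a
DataFrame with columns ``patient``, ``time`` (years), ``event`` (0/1) and
an optional ``subtype``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "unknown")


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# I/O


def read_expression(path: str | Path) -> pd.DataFrame:
    """Rows = probes/genes (first column), header = patient ids; no missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        raise SurvivalError("duplicate row ids in expression matrix")
    if df.columns.duplicated().any():
        raise SurvivalError("duplicate patient ids in expression matrix")
    if df.isna().any().any():
        raise SurvivalError("expression matrix contains missing values")


def read_survival(path: str | Path, time_unit: str = "years") -> pd.DataFrame:
    """TSV with columns ``patient time event [subtype]``; months converted to years."""
    df = pd.read_csv(path, sep="\t")
    need = {"patient", "time", "event"}
    if not need <= set(df.columns):
        raise SurvivalError(f"survival table must have columns {sorted(need)}")
    if "subtype" not in df.columns:
        df["subtype"] = "unknown"
    if (df["time"] < 0).any():
        raise SurvivalError("negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise SurvivalError("event must be 0/1")
    if time_unit == "months":
        df = df.assign(time=df["time"] / 12.0)
    elif time_unit != "years":
        raise SurvivalError(f"unknown time unit {time_unit!r}")
    df["patient"] = df["patient"].astype(str)
    return df[["patient", "time", "event", "subtype"]]


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``probe TAB gene``; each probe at most once."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], comment="#")
    if df["probe"].duplicated().any():
        raise SurvivalError("probe mapped more than once in probe map")
    return dict(zip(df["probe"].astype(str), df["gene"].astype(str).str.upper()))


# ---------------------------------------------------------------------------
# Preprocessing


def collapse_probes(expr: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Represent each gene by its probe with the highest mean expression.

    Ties go to the lexicographically smallest probe id; probes absent from
    the map are dropped (count logged).
    """
    mapped = [p for p in expr.index if p in probe_map]
    dropped = expr.shape[0] - len(mapped)
    if not mapped:
        raise SurvivalError("no probe in the matrix maps to a gene")
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = expr.loc[mapped]
    means = sub.mean(axis=1)
    frame = pd.DataFrame(
        {"probe": mapped, "gene": [probe_map[p] for p in mapped], "mean": means.values}
    )
    # max mean wins; lexicographically smallest probe on ties
    frame = frame.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    best = frame.groupby("gene", sort=True).first()
    out = sub.loc[best["probe"]]
    out.index = best.index
    return out


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every patient column onto the common mean-of-sorted distribution.

    Ties within a column receive the average (linear interpolation at
    fractional ranks) of their target values; column rank orders are
    preserved.  A single-column matrix is returned unchanged with a
    warning.
    """
    if expr.shape[1] < 2:
        log.warning("quantile_normalize: single column, returning input unchanged")
        return expr.copy()
    values = expr.to_numpy(dtype=float)
    n = values.shape[0]
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, target)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def signature_matrix(
    expr: pd.DataFrame, signature: Iterable[str]
) -> tuple[pd.DataFrame, set[str]]:
    """Row-subset to the signature genes present; returns (matrix, unmapped genes)."""
    sig = {str(g).strip().upper() for g in signature}
    rows = {str(r).upper(): r for r in expr.index}
    mapped = sorted(sig & set(rows))
    unmapped = sig - set(rows)
    if len(mapped) < 2:
        raise SurvivalError(
            f"only {len(mapped)} signature genes found in the expression matrix (need >= 2)"
        )
    return expr.loc[[rows[g] for g in mapped]], unmapped


def pearson_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """Patient-by-patient distance d(i, j) = 1 - Pearson r over the matrix rows."""
    if expr.shape[0] < 3:
        raise SurvivalError("need at least 3 rows for a correlation distance")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise SurvivalError(
            f"zero-variance expression profile for patient(s): {list(expr.columns[flat])}"
        )
    r = np.corrcoef(values, rowvar=False)
    d = 1.0 - r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


# ---------------------------------------------------------------------------
# Clustering


def hclust_complete(dist: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomeration; returns a SciPy linkage matrix."""
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise SurvivalError("distance matrix must be square and symmetric")
    if d.shape[0] < 2:
        raise SurvivalError("need at least 2 observations to cluster")
    return linkage(squareform(d, checks=False), method="complete")


def dynamic_hybrid_cut(
    Z: np.ndarray, dist: pd.DataFrame, min_fraction: float = 0.125
) -> pd.Series:
    """Dendrogram-shape cluster detection with a minimum-size floor.

    Stage 1 cuts the dendrogram at 99% of the merge-height range
    (``h_min + 0.99 * (h_max - h_min)``): merges joining above that level
    are severed, and the resulting branches that meet the size floor
    max(2, floor(min_fraction * n)) become core clusters.  If fewer than
    two admissible cores detach there, the cut level descends through the
    distinct merge heights until an admissible split appears — this is
    what makes the cut *dynamic*: a dendrogram with one outlying join is
    split exactly there, while a shapeless dendrogram is split at
    whatever depth first yields two sufficiently large branches.  Stage 2
    assigns the remaining patients to the core cluster with the smallest
    average dissimilarity.  Labels are 1..k, ordered by decreasing
    cluster size; if no admissible split exists at any level everyone is
    labelled 1.
    """
    if not (0 < min_fraction <= 0.5):
        raise SurvivalError("min_fraction must lie in (0, 0.5]")
    patients = list(dist.index)
    n = len(patients)
    floor_size = max(2, math.floor(min_fraction * n))
    ones = pd.Series(1, index=patients, name="cluster")
    if n < 2 * floor_size:
        return ones

    heights = Z[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    levels = [h_min + 0.99 * (h_max - h_min)]
    levels += sorted({float(h) for h in heights if h < levels[0]}, reverse=True)
    branches = None
    core_ids: list = []
    for t in levels:
        cand = fcluster(Z, t=t, criterion="distance")
        sizes = pd.Series(cand).value_counts()
        cores = [b for b in sizes.index if sizes[b] >= floor_size]
        if len(cores) >= 2:
            branches, core_ids = cand, cores
            break
    if branches is None:
        return ones

    d = dist.to_numpy(dtype=float)
    labels = np.zeros(n, dtype=int)
    for new, b in enumerate(sorted(core_ids), start=1):
        labels[branches == b] = new
    # stage 2: nearest-core assignment of stragglers by mean dissimilarity
    for i in np.flatnonzero(labels == 0):
        means = [d[i, labels == c].mean() for c in range(1, len(core_ids) + 1)]
        labels[i] = int(np.argmin(means)) + 1  # argmin takes smallest label on ties

    # relabel by decreasing size; ties by smallest member position
    order = sorted(
        range(1, len(core_ids) + 1),
        key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c)[0])),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    return pd.Series([remap[c] for c in labels], index=patients, name="cluster")


# ---------------------------------------------------------------------------
# Survival statistics


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # event-time grid (includes 0)
    survival: np.ndarray  # S(t) at each grid time
    at_risk: np.ndarray
    display_horizon: float = 15.0

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise SurvivalError("time must be non-negative")
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    pvalue: float


def km_curve(times: Iterable[float], events: Iterable[int]) -> KMCurve:
    """Kaplan–Meier estimate; censored-at-t subjects remain in the risk set at t."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    if t.size == 0:
        raise SurvivalError("no subjects")
    if (t < 0).any():
        raise SurvivalError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def km_survival_at(curve: KMCurve, t: float) -> float:
    return curve.survival_at(t)


def logrank_test(
    times: Iterable[float], events: Iterable[int], groups: Iterable
) -> LogRankResult:
    """Unweighted k-sample log-rank chi-square test (k - 1 degrees of freedom)."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=int)
    g = np.asarray(list(groups))
    labels = np.unique(g)
    if labels.size < 2:
        raise SurvivalError("log-rank test needs at least 2 groups")
    if e.sum() == 0:
        raise SurvivalError("log-rank test needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=int(labels.size - 1),
        pvalue=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# End-to-end stratification


@dataclass
class StratifyResult:
    assignment: pd.Series  # patient -> cluster label
    logrank: LogRankResult | None
    curves: dict[int, KMCurve]
    survival_at_5y: dict[int, float]
    subtype_composition: pd.DataFrame
    n_signature_mapped: int
    unmapped_genes: set[str] = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max())


def stratify(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    signature: Iterable[str],
    probe_map: Mapping[str, str] | None = None,
    min_fraction: float = 0.125,
    subtype_filter: str | None = None,
    normalize: bool = True,
) -> StratifyResult:
    """Cluster patients on signature-gene expression and test MFS differences.

    ``subtype_filter`` restricts the cohort to one molecular subtype before
    clustering; callers following the per-subtype workflow should also
    raise ``min_fraction`` (0.25 rather than the whole-cohort 0.125).
    When only one cluster is detected the log-rank test is skipped and
    ``logrank`` is None.
    """
    validate_expression(expr)
    if probe_map is not None:
        expr = collapse_probes(expr, probe_map)
    surv = survival.set_index("patient")
    shared = [c for c in expr.columns if str(c) in surv.index]
    if len(shared) < 4:
        raise SurvivalError("fewer than 4 patients shared between expression and survival")
    expr = expr[shared]
    surv = surv.loc[[str(c) for c in shared]]
    if subtype_filter is not None:
        if subtype_filter not in set(surv["subtype"]):
            raise SurvivalError(f"subtype {subtype_filter!r} absent from annotations")
        keep = surv["subtype"] == subtype_filter
        surv = surv[keep]
        expr = expr[[c for c in expr.columns if str(c) in surv.index]]
    if normalize:
        expr = quantile_normalize(expr)
    sig_expr, unmapped = signature_matrix(expr, signature)
    dist = pearson_distance(sig_expr)
    Z = hclust_complete(dist)
    assignment = dynamic_hybrid_cut(Z, dist, min_fraction)

    curves: dict[int, KMCurve] = {}
    s5: dict[int, float] = {}
    comp_rows = []
    for label in sorted(assignment.unique()):
        members = assignment.index[assignment == label]
        sub = surv.loc[[str(m) for m in members]]
        curves[int(label)] = km_curve(sub["time"], sub["event"])
        s5[int(label)] = curves[int(label)].survival_at(5.0)
        counts = sub["subtype"].value_counts()
        comp_rows.append(
            {"cluster": int(label), "n": len(sub), **{s: int(counts.get(s, 0)) for s in SUBTYPES}}
        )
    composition = pd.DataFrame(comp_rows).set_index("cluster")

    lr = None
    if assignment.nunique() >= 2 and surv["event"].sum() > 0:
        lr = logrank_test(surv["time"], surv["event"], assignment.loc[surv.index].to_numpy())
    return StratifyResult(
        assignment=assignment,
        logrank=lr,
        curves=curves,
        survival_at_5y=s5,
        subtype_composition=composition,
        n_signature_mapped=sig_expr.shape[0],
        unmapped_genes=unmapped,
    )
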