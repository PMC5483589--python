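"""Stable-target derivation and gene-set enrichment testing.

Stable perturbation targets are the genes significant (FDR below a
threshold) in every one of several differential-expression comparisons,
with a consistent fold-change direction.  Enrichment of a gene set in a
target list is tested by one-sided over-representation (hypergeometric
tail / Fisher's exact test) or by a rank-based Wilcoxon rank-sum test on
the full vector of gene p-values; families of tests are adjusted with
Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "log2fc", "pvalue", "fdr"]


class EnrichmentError(ValueError):
    pass


@dataclass
class DEGTable:
    """Differential-expression results for one comparison."""

    records: pd.DataFrame  # columns: gene, log2fc, pvalue, fdr
    comparison_label: str = ""

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in DEG_COLUMNS if c not in df.columns]
        if missing:
            raise EnrichmentError(f"DEG table missing columns {missing}")
        df["gene"] = df["gene"].astype(str).str.strip().str.upper()
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
            raise EnrichmentError(f"duplicate genes in DEG table: {dups[:5]}")
        for col in ("pvalue", "fdr"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise EnrichmentError(f"{col} outside [0, 1]")
        self.records = df[DEG_COLUMNS].reset_index(drop=True)

    def significant(self, threshold: float = 0.05) -> pd.DataFrame:
        return self.records[self.records["fdr"] < threshold]

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])


def read_deg_table(path: str | Path, label: str | None = None) -> DEGTable:
    """Read a TSV with header ``gene log2fc pvalue fdr``."""
    df = pd.read_csv(path, sep="\t")
    return DEGTable(df, comparison_label=label or Path(path).stem)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


@dataclass
class TargetLists:
    """Targets split by fold-change direction; zero-fold-change genes stay in *all* only."""

    all: set[str]
    up: set[str]
    down: set[str]


@dataclass
class GeneSet:
    name: str
    members: set[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.members = {str(m).strip().upper() for m in self.members if str(m).strip()}
        if not self.members:
            raise EnrichmentError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise EnrichmentError("duplicate gene-set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...`` per line."""
    sets = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets.append(GeneSet(name=parts[0], description=parts[1], members=set(parts[2:])))
    return GeneSetCollection(sets=sets, name=Path(path).stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


@dataclass
class EnrichmentResult:
    set_name: str
    list_name: str
    pvalue: float
    overlap_count: int
    set_size: int
    list_size: int
    universe_size: int
    qvalue: float = float("nan")


def common_targets(
    tables: Sequence[DEGTable], threshold: float = 0.05
) -> dict[str, float]:
    """Genes significant in every table with a consistent fold-change sign.

    Returns gene -> consensus log2 fold-change (value from the first
    table).  Genes whose sign disagrees between tables are excluded and
    logged as discordant.
    """
    if len(tables) < 2:
        raise EnrichmentError("need at least 2 DEG tables to intersect")
    sig_fc: list[dict[str, float]] = []
    for t in tables:
        sig = t.significant(threshold)
        sig_fc.append(dict(zip(sig["gene"], sig["log2fc"])))
    common = set(sig_fc[0])
    for d in sig_fc[1:]:
        common &= set(d)
    out: dict[str, float] = {}
    discordant = []
    for g in sorted(common):
        signs = {np.sign(d[g]) for d in sig_fc}
        if len(signs) > 1:
            discordant.append(g)
            continue
        out[g] = sig_fc[0][g]
    if discordant:
        log.warning(
            "excluded %d discordant-sign genes from common targets: %s%s",
            len(discordant),
            discordant[:10],
            "..." if len(discordant) > 10 else "",
        )
    return out


def split_targets(targets: Mapping[str, float]) -> TargetLists:
    """Split targets into all/up/down by fold-change sign (zeros stay in all)."""
    up = {g for g, fc in targets.items() if fc > 0}
    down = {g for g, fc in targets.items() if fc < 0}
    return TargetLists(all=set(targets), up=up, down=down)


def fisher_ora(
    gene_list: Iterable[str], gset: GeneSet, universe: Iterable[str]
) -> EnrichmentResult:
    """One-sided over-representation test (upper hypergeometric tail).

    p = P(overlap >= observed) for a list of size n drawn from a universe
    of size N containing K set members.
    """
    uni = {str(g).strip().upper() for g in universe}
    lst = {str(g).strip().upper() for g in gene_list}
    if not uni:
        raise EnrichmentError("empty universe")
    if not lst:
        raise EnrichmentError("empty gene list")
    if not lst <= uni:
        raise EnrichmentError(f"gene list not contained in universe: {sorted(lst - uni)[:5]}")
    members = gset.members & uni
    k = len(lst & members)
    N, K, n = len(uni), len(members), len(lst)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        set_name=gset.name,
        list_name="",
        pvalue=min(p, 1.0),
        overlap_count=k,
        set_size=K,
        list_size=n,
        universe_size=N,
    )


def wilcoxon_rank_enrichment(pvalues: Mapping[str, float], gset: GeneSet) -> float:
    """Rank-based enrichment: are in-set gene p-values smaller than out-of-set?

    One-sided Wilcoxon rank-sum test; exact null distribution when both
    groups have <= 25 genes and no ties, normal approximation with tie
    correction otherwise.
    """
    inside = [p for g, p in pvalues.items() if g in gset.members]
    outside = [p for g, p in pvalues.items() if g not in gset.members]
    if not inside or not outside:
        raise EnrichmentError("rank test needs genes both inside and outside the set")
    exact = (
        len(inside) <= 25
        and len(outside) <= 25
        and len(set(inside) | set(outside)) == len(inside) + len(outside)
    )
    res = stats.mannwhitneyu(
        inside, outside, alternative="less", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_all(
    lists: TargetLists,
    collection: GeneSetCollection,
    universe: Iterable[str],
    mode: str = "ora",
    pvalues: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set against the all/up/down target lists.

    BH adjustment is applied across sets *within* each list.  ``mode`` is
    ``"ora"`` (overlap test against the universe) or ``"rank"`` (Wilcoxon
    on the supplied per-gene p-values, ignoring the up/down split
    direction — the same gene-level p vector is used for each list's
    family, so rank mode reports a single column).
    """
    uni = {str(g).strip().upper() for g in universe}
    rows = []
    if mode == "ora":
        for list_name, lst in (("all", lists.all), ("up", lists.up), ("down", lists.down)):
            if not lst:
                for gset in collection:
                    rows.append(
                        dict(
                            set_name=gset.name, list_name=list_name, pvalue=np.nan,
                            qvalue=np.nan, overlap_count=0,
                            set_size=len(gset.members & uni), list_size=0,
                            universe_size=len(uni), testable=False,
                        )
                    )
                continue
            sub = []
            for gset in collection:
                r = fisher_ora(lst, gset, uni)
                sub.append(
                    dict(
                        set_name=r.set_name, list_name=list_name, pvalue=r.pvalue,
                        overlap_count=r.overlap_count, set_size=r.set_size,
                        list_size=r.list_size, universe_size=r.universe_size,
                        testable=True,
                    )
                )
            q = bh_adjust([r["pvalue"] for r in sub])
            for r, qv in zip(sub, q):
                r["qvalue"] = float(qv)
            rows.extend(sub)
    elif mode == "rank":
        if pvalues is None:
            raise EnrichmentError("rank mode requires per-gene p-values")
        sub = []
        for gset in collection:
            p = wilcoxon_rank_enrichment(pvalues, gset)
            sub.append(
                dict(
                    set_name=gset.name, list_name="all", pvalue=p,
                    overlap_count=len(set(pvalues) & gset.members),
                    set_size=len(gset.members), list_size=len(pvalues),
                    universe_size=len(pvalues), testable=True,
                )
            )
        q = bh_adjust([r["pvalue"] for r in sub])
        for r, qv in zip(sub, q):
            r["qvalue"] = float(qv)
        rows.extend(sub)
    else:
        raise EnrichmentError(f"unknown mode {mode!r}")
    df = pd.DataFrame(rows)
    df["significant"] = df["qvalue"] < alpha
    return df
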