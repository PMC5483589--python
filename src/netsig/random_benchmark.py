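"""Random-signature resampling null for prognostic-signature calibration.

A gene signature's log-rank p-value is only meaningful relative to what
equally sized random signatures achieve on the same cohort: many random
transcriptional signatures are prognostic in breast cancer compendia.
This module draws random signatures from a pathway-gene pool (e.g. the
union of all KEGG gene sets restricted to measured genes), pushes each
through the identical stratification chain, and summarizes the fraction
significant and the fraction outperforming the original signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .survival_stratification import SurvivalError, stratify


class BenchmarkError(ValueError):
    pass


@dataclass
class SignaturePool:
    """Sorted, deduplicated gene pool restricted to measured genes."""

    genes: list[str]
    source_collection: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BenchmarkConfig:
    n_signatures: int = 1000
    signature_size: int = 76
    alpha: float = 0.05
    master_seed: int = 0
    min_fraction: float = 0.125


@dataclass
class BenchmarkResult:
    pvalues: np.ndarray
    frac_significant: float
    frac_outperforming: float | None
    original_p: float | None
    n_single_cluster: int
    config: BenchmarkConfig | None = None

    @property
    def neglog10(self) -> np.ndarray:
        return -np.log10(np.maximum(self.pvalues, np.finfo(float).tiny))


def build_gene_pool(
    collection: GeneSetCollection, expr_genes: Iterable[str]
) -> SignaturePool:
    """Union of all set members, intersected with measured genes, sorted."""
    measured = {str(g).strip().upper() for g in expr_genes}
    pool = sorted(collection.all_members() & measured)
    if not pool:
        raise BenchmarkError("gene pool is empty after intersecting with expression rows")
    return SignaturePool(genes=pool, source_collection=collection.name)


def _draw_rng(master_seed: int, index: int) -> np.random.Generator:
    # independent substream per draw; reproducible across runs and platforms
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def sample_signatures(pool: SignaturePool, config: BenchmarkConfig) -> list[list[str]]:
    """n_signatures uniform subsets (without replacement) of the stated size."""
    if config.signature_size > len(pool):
        raise BenchmarkError(
            f"signature size {config.signature_size} exceeds pool size {len(pool)}"
        )
    if config.n_signatures < 1:
        raise BenchmarkError("need at least one signature")
    out = []
    for i in range(config.n_signatures):
        rng = _draw_rng(config.master_seed, i)
        draw = rng.choice(len(pool), size=config.signature_size, replace=False)
        out.append([pool.genes[j] for j in sorted(draw)])
    return out


def run_benchmark(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    pool: SignaturePool,
    config: BenchmarkConfig,
    original_p: float | None = None,
    subtype_filter: str | None = None,
) -> BenchmarkResult:
    """Stratify the cohort with each random signature and collect log-rank p-values.

    Signatures for which only one cluster is detected (log-rank undefined)
    are scored p = 1 — dropping them would bias the significant fraction
    upward — and counted in ``n_single_cluster``.
    """
    signatures = sample_signatures(pool, config)
    pvals = np.empty(len(signatures))
    n_single = 0
    for i, sig in enumerate(signatures):
        try:
            res = stratify(
                expr,
                survival,
                sig,
                min_fraction=config.min_fraction,
                subtype_filter=subtype_filter,
            )
        except SurvivalError as exc:
            raise BenchmarkError(f"signature {i} (seed index {i}) failed: {exc}") from exc
        if res.logrank is None:
            pvals[i] = 1.0
            n_single += 1
        else:
            pvals[i] = res.logrank.pvalue
    frac_sig, frac_out = summarize(pvals, original_p, config.alpha)
    return BenchmarkResult(
        pvalues=pvals,
        frac_significant=frac_sig,
        frac_outperforming=frac_out,
        original_p=original_p,
        n_single_cluster=n_single,
        config=config,
    )


def summarize(
    pvalues: Iterable[float], original_p: float | None, alpha: float = 0.05
) -> tuple[float, float | None]:
    """(fraction p < alpha, fraction p strictly below the original signature's p)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise BenchmarkError("empty p-value list")
    frac_sig = float(np.mean(p < alpha))
    frac_out = None if original_p is None else float(np.mean(p < original_p))
    return frac_sig, frac_out
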