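"""Synthetic inputs with planted structure for every pipeline stage.

Each generator is a pure function of its spec (seed included), so outputs
are byte-identical across runs.  The generators plant exactly the
structure the downstream statistics assume:

* a random signed directed network containing a connected module whose
  genes later appear as differential targets;
* differential-expression tables whose shared significant genes are a
  chosen fraction of that module (plus table-specific background);
* gene-set collections with an optional planted enriched set;
* a patient cohort in which signature genes carry group-specific
  expression *patterns* (sign-flipped mean shifts — a uniform offset
  would be invisible to correlation distance) and survival times are
  exponential with group-specific hazards under independent exponential
  plus administrative censoring;
* probe-level matrices expanding a gene-level matrix many-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import DEGTable, GeneSet, GeneSetCollection
from .graph_core import SignalingNetwork


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Network + DEG tables


@dataclass
class NetworkSpec:
    n_nodes: int = 200
    edge_prob: float = 0.02
    module_size: int = 10
    inhibition_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.module_size <= self.n_nodes):
            raise SyntheticError("module_size must be between 1 and n_nodes")
        if not (0 <= self.edge_prob <= 1 and 0 <= self.inhibition_fraction <= 1):
            raise SyntheticError("probabilities must lie in [0, 1]")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def gen_network(spec: NetworkSpec) -> tuple[SignalingNetwork, list[str]]:
    """Random signed directed graph with a planted connected module.

    The module nodes are wired into a random spanning tree (hence
    connected in the undirected view) and joined to the largest remaining
    component by a single bridge edge.
    """
    rng = np.random.default_rng(spec.seed)
    names = _gene_names(spec.n_nodes)
    module = names[: spec.module_size]

    def sign() -> str:
        return "inhibition" if rng.random() < spec.inhibition_fraction else "activation"

    triples: dict[tuple[str, str], str] = {}

    def add(u: str, v: str) -> None:
        if u != v and (u, v) not in triples and (v, u) not in triples:
            triples[(u, v)] = sign()

    # background Erdős–Rényi edges
    for i in range(spec.n_nodes):
        for j in range(spec.n_nodes):
            if i != j and rng.random() < spec.edge_prob:
                add(names[i], names[j])
    # planted spanning tree over module nodes
    order = list(rng.permutation(spec.module_size))
    for k in range(1, spec.module_size):
        a = names[order[k]]
        b = names[order[int(rng.integers(0, k))]]
        if rng.random() < 0.5:
            a, b = b, a
        triples.pop((b, a), None)
        triples[(a, b)] = sign()
    # one bridge from the module to the largest outside component
    if spec.module_size < spec.n_nodes:
        import networkx as nx

        und = nx.Graph()
        und.add_nodes_from(names)
        und.add_edges_from(triples)
        outside = [c for c in nx.connected_components(und) if not (c & set(module))]
        if outside:
            biggest = max(outside, key=lambda c: (len(c), min(c)))
            u = module[int(rng.integers(0, len(module)))]
            v = sorted(biggest)[int(rng.integers(0, len(biggest)))]
            triples[(u, v)] = sign()
    net = SignalingNetwork.from_edges(
        [(u, s, v) for (u, v), s in sorted(triples.items())],
        extra_nodes=names,
        name=f"synthetic-{spec.seed}",
    )
    return net, module


def gen_deg_tables(
    network: SignalingNetwork,
    planted_module: Sequence[str],
    n_tables: int = 3,
    frac_module_significant: float = 1.0,
    n_background: int = 0,
    n_filler: int = 50,
    seed: int = 0,
) -> tuple[list[DEGTable], list[str]]:
    """Differential tables whose shared significant genes are a planted module subset.

    Every table marks the same ``frac_module_significant`` of the module
    genes significant (FDR < 0.05, consistent fold-change signs), plus
    ``n_background`` table-specific significant genes and ``n_filler``
    non-significant fillers.  Returns (tables, planted significant genes).
    """
    if not (0 <= frac_module_significant <= 1):
        raise SyntheticError("frac_module_significant must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    module = sorted(planted_module)
    n_sig = int(round(frac_module_significant * len(module)))
    sig_genes = [module[i] for i in sorted(rng.choice(len(module), n_sig, replace=False))]
    base_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in sig_genes}
    others = sorted(network.nodes - set(module))
    tables = []
    for t in range(n_tables):
        rows = []
        for g in sig_genes:
            rows.append(
                dict(
                    gene=g,
                    log2fc=base_sign[g] * rng.uniform(0.5, 3.0),
                    pvalue=rng.uniform(0, 1e-3),
                    fdr=rng.uniform(0, 0.049),
                )
            )
        pool = [x for x in others]
        n_bg = min(n_background, len(pool))
        bg = [pool[i] for i in sorted(rng.choice(len(pool), n_bg, replace=False))] if n_bg else []
        for g in bg:
            rows.append(
                dict(
                    gene=g,
                    log2fc=rng.uniform(-3, 3),
                    pvalue=rng.uniform(0, 1e-3),
                    fdr=rng.uniform(0, 0.049),
                )
            )
        filler_pool = [x for x in pool if x not in set(bg)]
        n_fill = min(n_filler, len(filler_pool))
        fillers = (
            [filler_pool[i] for i in sorted(rng.choice(len(filler_pool), n_fill, replace=False))]
            if n_fill
            else []
        )
        for g in fillers:
            rows.append(
                dict(gene=g, log2fc=rng.normal(0, 0.2), pvalue=rng.uniform(0.2, 1), fdr=rng.uniform(0.3, 1))
            )
        tables.append(DEGTable(pd.DataFrame(rows), comparison_label=f"comparison_{t + 1}"))
    return tables, sig_genes


# ---------------------------------------------------------------------------
# Gene sets


def gen_gmt(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: Sequence[str],
    planted_target_list: Sequence[str] | None = None,
    planted_overlap: int = 0,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set collection, optionally with one planted enriched set.

    The planted set (named ``PLANTED``) contains exactly
    ``planted_overlap`` genes of ``planted_target_list`` and fills up to
    the size range from the rest of the universe.
    """
    if n_sets < 1:
        raise SyntheticError("need at least one gene set")
    lo, hi = set_size_range
    uni = sorted({str(g).upper() for g in universe})
    if hi > len(uni):
        raise SyntheticError("set size range exceeds universe")
    rng = np.random.default_rng(seed)
    sets = []
    if planted_target_list is not None:
        targets = sorted({str(g).upper() for g in planted_target_list})
        size = int(rng.integers(lo, hi + 1))
        if planted_overlap > min(size, len(targets)):
            raise SyntheticError("requested overlap exceeds set size or target list")
        inside = [targets[i] for i in sorted(rng.choice(len(targets), planted_overlap, replace=False))]
        rest_pool = [g for g in uni if g not in set(targets)]
        n_rest = size - planted_overlap
        if n_rest > len(rest_pool):
            raise SyntheticError("universe too small for requested planted set")
        rest = [rest_pool[i] for i in sorted(rng.choice(len(rest_pool), n_rest, replace=False))]
        sets.append(GeneSet(name="PLANTED", members=set(inside) | set(rest)))
    for i in range(n_sets - len(sets)):
        size = int(rng.integers(lo, hi + 1))
        members = [uni[j] for j in sorted(rng.choice(len(uni), size, replace=False))]
        sets.append(GeneSet(name=f"RANDOM_SET_{i + 1:03d}", members=set(members)))
    return GeneSetCollection(sets=sets, name=f"synthetic-gmt-{seed}")


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class CohortSpec:
    """Planted-subgroup cohort: expression patterns plus exponential survival.

    Rates are per year; ``expression_effect`` is the between-group mean
    shift of each signature gene in residual-SD units (the shift's sign
    is drawn per gene and group, so groups differ in profile shape, which
    is what a correlation distance can see).
    """

    n_patients: int = 200
    n_genes: int = 500
    signature_genes: list[str] = field(default_factory=lambda: [f"G{i:04d}" for i in range(20)])
    n_groups: int = 2
    expression_effect: float = 2.0
    baseline_hazard: float = 0.1
    hazard_ratios: tuple = (1.0, 3.0)
    censoring_rate: float = 0.05
    admin_censor_time: float = 15.0
    subtype_labels: tuple = ("Basal", "Her2", "LumA", "LumB")
    subtype_proportions: tuple = (0.2, 0.1, 0.4, 0.3)
    balanced_groups: bool = False  # equal-size groups instead of equiprobable draws
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hazard_ratios) != self.n_groups:
            raise SyntheticError("hazard_ratios length must equal n_groups")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise SyntheticError("rates must be positive")
        if self.expression_effect < 0:
            raise SyntheticError("expression_effect must be non-negative")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise SyntheticError("duplicate signature genes")


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate (expression genes x patients, survival table, planted group labels)."""
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_patients, spec.n_genes
    sig = [str(s).upper() for s in spec.signature_genes]
    gene_names = list(sig) + [f"BG{i:04d}" for i in range(g - len(sig))]
    if len(gene_names) != g:
        raise SyntheticError("n_genes smaller than the signature")
    patients = [f"P{i:04d}" for i in range(n)]
    if spec.balanced_groups:
        groups = rng.permutation(np.resize(np.arange(spec.n_groups), n))
    else:
        groups = rng.integers(0, spec.n_groups, size=n)

    values = rng.normal(0.0, 1.0, size=(g, n))
    # per-(gene, group) sign pattern: groups differ in shape, not offset
    pattern = rng.choice([-1.0, 1.0], size=(len(sig), spec.n_groups))
    for gi in range(len(sig)):
        values[gi] += spec.expression_effect * pattern[gi, groups]

    hr = np.asarray(spec.hazard_ratios, dtype=float)
    rate = spec.baseline_hazard * hr[groups]
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, spec.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    subtype = rng.choice(
        list(spec.subtype_labels), size=n, p=list(spec.subtype_proportions)
    )
    expr = pd.DataFrame(values, index=gene_names, columns=patients)
    survival = pd.DataFrame(
        {"patient": patients, "time": time, "event": event, "subtype": subtype}
    )
    labels = pd.Series(groups + 1, index=patients, name="group")
    return expr, survival, labels


# ---------------------------------------------------------------------------
# Probe maps


def gen_probe_map(
    expr: pd.DataFrame,
    probes_per_gene_range: tuple[int, int] = (1, 3),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str]]:
    """Expand a gene-level matrix into probes (many probes per gene).

    Each probe copies its gene's row with a probe-specific baseline shift
    plus small noise.  Returns (probe map, probe matrix, ground-truth
    top probe per gene — the probe with the highest realized mean).
    """
    lo, hi = probes_per_gene_range
    if lo < 1:
        raise SyntheticError("need at least one probe per gene")
    rng = np.random.default_rng(seed)
    probe_rows = []
    probe_ids = []
    probe_map: dict[str, str] = {}
    for gi, gene in enumerate(expr.index):
        k = int(rng.integers(lo, hi + 1))
        # a single probe is the gene's own row (identity round-trip)
        shifts = rng.normal(0.0, 1.0, size=k) if k > 1 else np.zeros(1)
        for j in range(k):
            pid = f"{gene}_at{j + 1}"
            probe_ids.append(pid)
            probe_map[pid] = str(gene)
            probe_rows.append(
                expr.iloc[gi].to_numpy() + shifts[j] + rng.normal(0, noise_sd, expr.shape[1])
            )
    probe_expr = pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=expr.columns)
    top: dict[str, str] = {}
    means = probe_expr.mean(axis=1)
    for pid, gene in probe_map.items():
        if gene not in top or means[pid] > means[top[gene]] or (
            means[pid] == means[top[gene]] and pid < top[gene]
        ):
            top[gene] = pid
    return probe_map, probe_expr, top
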