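# netsig

Network-guided extraction of transcriptional response modules and
evaluation of their prognostic power in patient survival cohorts.

## The problem

A perturbation experiment (receptor overexpression, ligand stimulation,
…) yields several differential-expression comparisons.  The genes that
respond consistently across all comparisons — the *stable targets* — are
a long, flat list.  `netsig` turns that list into biology and then into
a clinical readout:

1. **Stable targets.** Intersect the significant genes (FDR < 0.05,
   Benjamini–Hochberg) of every comparison, requiring a consistent
   fold-change direction.
2. **Enrichment.** Test gene-set over-representation in the *all*, *up*
   and *down* target lists with the one-sided hypergeometric
   (Fisher) test, or rank-based enrichment of the full gene p-value
   vector with the Wilcoxon rank-sum test; adjust per list with BH.
3. **Module extraction.** Map targets onto a signed, directed signaling
   network (activation/inhibition edges).  Mapped nodes become
   *terminals* of a Steiner-tree search in the undirected network: the
   metric-closure heuristic finds a small connected subgraph spanning
   all terminals, introducing non-differential *Steiner nodes* where
   needed (heuristic cost ≤ 2(1 − 1/|T|) × optimal).  The induced
   subnetwork on all tree nodes — with every original signed directed
   edge — is the response module.
4. **Survival stratification.** Use the module genes as an expression
   signature: collapse probes (highest-mean probe per gene), quantile-
   normalize patients, cluster patients by complete linkage on Pearson
   correlation distance d(i,j) = 1 − r(i,j), detect clusters with a
   dynamic hybrid dendrogram cut governed by a minimum cluster-size
   fraction (12.5 % whole cohort, 25 % within a molecular subtype), and
   compare the clusters' Kaplan–Meier metastasis-free-survival curves
   with the k-sample log-rank test.
5. **Random-signature benchmark.** Draw equally sized random signatures
   from a pathway gene pool (union of the gene-set collection ∩ measured
   genes), push each through the identical stratification chain, and
   report the fraction with log-rank p < α and the fraction beating the
   original signature — the resampling null that decides whether the
   module is *better than a random pathway signature*, not merely
   significant.

A `synthetic_data` module generates every input with planted ground
truth (connected network modules, consistent DEG tables, cohorts with
known expression subgroups and exponential survival hazards), so the
whole chain can be exercised and validated without any download.

## Worked example

```python
from netsig.synthetic_data import (
    NetworkSpec, CohortSpec, gen_network, gen_deg_tables, gen_cohort)
from netsig.enrichment import common_targets
from netsig.module_extraction import build_module
from netsig.survival_stratification import stratify

net, module = gen_network(NetworkSpec(n_nodes=200, edge_prob=0.008,
                                      module_size=20, seed=1))
tables, _ = gen_deg_tables(net, module, frac_module_significant=0.5,
                           n_background=5, seed=1)
targets = common_targets(tables, threshold=0.05)
print(f"common targets: {len(targets)}")
mod = build_module(net, targets)
print(f"module: {len(mod.terminals)} terminals + "
      f"{len(mod.steiner_nodes)} Steiner nodes = {mod.n_nodes} genes")

expr, surv, groups = gen_cohort(CohortSpec(seed=1))
res = stratify(expr, surv, [f"G{i:04d}" for i in range(20)],
               min_fraction=0.125)
print(f"clusters: {res.n_clusters}")
print(f"log-rank chi2 = {res.logrank.chi_square:.2f}, "
      f"p = {res.logrank.pvalue:.3g}")
for k, s in sorted(res.survival_at_5y.items()):
    print(f"cluster {k}: 5-year MFS = {s:.3f}")
```

prints

```
common targets: 10
module: 10 terminals + 2 Steiner nodes = 12 genes
clusters: 2
log-rank chi2 = 21.37, p = 3.78e-06
cluster 1: 5-year MFS = 0.305
cluster 2: 5-year MFS = 0.539
```

Half of a planted 20-gene network module responds in all three
synthetic comparisons; the Steiner search reconnects those 10 terminals
through 2 non-differential genes.  On a 200-patient synthetic cohort
the 20-gene signature splits patients into two clusters whose
metastasis-free survival differs strongly (log-rank p ≈ 4 × 10⁻⁶; 5-year
MFS 0.31 vs 0.54) — matching the cohort's planted hazard ratio of 3.

The same stages are available from the shell:

```sh
netsig simulate cohort --seed 1 --out data/
netsig extract-module --network net.sif --deg a.tsv --deg b.tsv --out out/
netsig stratify --expr data/expression.tsv --surv data/survival.tsv \
    --signature sig.txt --min-frac 0.125 --out out/
netsig benchmark --expr data/expression.tsv --surv data/survival.tsv \
    --gmt sets.gmt --signature sig.txt --n 1000 --seed 1 --out out/
netsig run-all --config config.yaml
```

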