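# Methods

This note documents the models, algorithms and defaults implemented in
`netsig`, the reasoning behind the genuinely open design choices, and
what the synthetic-data validation does and does not demonstrate.

## Stable targets and enrichment

A differential comparison is a table `(gene, log2fc, pvalue, fdr)`.
The *stable targets* of a perturbation are the genes with FDR below a
threshold (default 0.05) in **every** comparison and a consistent
fold-change sign; sign-discordant genes are excluded with a warning
rather than silently kept, because a "stable target" with opposite
directions in two comparisons is a contradiction, not a consensus.  The
consensus fold-change is taken from the first table.  Targets are split
into *all* / *up* / *down* lists by fold-change sign; an exactly zero
fold-change stays in *all* only.

Over-representation of a gene set in a target list is the one-sided
upper hypergeometric tail P(overlap ≥ observed) for a list of size *n*
drawn from a universe of size *N* containing *K* set members — Fisher's
exact test in its over-representation direction.  The universe is
caller-supplied and defaults to the union of all genes measured in the
differential tables: enrichment against "all genes ever named" inflates
significance, while the measured-gene universe conditions on what the
experiment could have detected.  Rank-based enrichment applies the
Wilcoxon rank-sum test to in-set versus out-of-set gene p-values,
one-sided toward smaller in-set p-values (exact null distribution when
both groups hold ≤ 25 genes without ties, normal approximation with tie
correction otherwise).  Families of tests are adjusted with
Benjamini–Hochberg step-up *within each target list*, mirroring a
per-column q-value report; significance is called at q < 0.05.

## Steiner-tree module extraction

The signaling network is a signed directed graph (activation /
inhibition).  Target genes are mapped onto its nodes by exact symbol
match after uppercasing; mapped nodes are *terminals*.  The connected
module is found in the **undirected, unit-weight** view of the network
— signs and directions say nothing about whether two genes belong to
the same regulatory neighbourhood, so the search ignores them and the
final induced subnetwork restores every original signed directed edge.

The search is the classic metric-closure heuristic
(Kou–Markowsky–Berman): (1) build the complete graph on terminals
weighted by BFS distances; (2) take its minimum spanning tree; (3)
expand every MST edge into one shortest path; (4) take the MST of the
expanded union; (5) prune non-terminal leaves.  Edge counts of the
result are within 2(1 − 1/|T|) of the optimum; the test suite verifies
this bound on random instances against an exact oracle that enumerates
Steiner-node subsets (feasible to 16 nodes).  Every tie — in MST edge
selection and in shortest-path expansion — is broken lexicographically
on node names, so identical inputs give identical modules on any
platform.  Terminals falling in different network components are
spanned per component and unioned; an explicit error (with the
component partition) is raised only when a single-tree answer is
requested directly.

Non-terminal tree nodes are *Steiner nodes*: connector genes that are
not themselves differential.  Node fold-change annotations keep their
raw values; a ±2 clamp is applied only to the display copy used for
color scales.

## Patient stratification

Preprocessing follows standard microarray-compendium practice:

* **Probe collapse** — each gene is represented by its probe with the
  highest mean expression across patients (ties: lexicographically
  smallest probe id).
* **Quantile normalization** — every patient column is mapped onto the
  across-column mean of sorted values; ties receive interpolated target
  values; rank orders within a column are preserved and afterwards all
  column distributions are exactly identical.
* **Signature subset** — rows are restricted to the signature genes
  present; the mapped/unmapped split is reported, and fewer than two
  mapped genes is an error.

Patients are compared by Pearson correlation distance d(i, j) = 1 −
r(i, j) over the signature genes (range [0, 2]; a zero-variance patient
profile is an error naming the patient) and clustered by
complete-linkage agglomeration.

**Dynamic hybrid cut.**  The number of clusters is not fixed; clusters
are read off the dendrogram subject to one parameter, the minimum
cluster-size fraction (default 0.125 of the cohort; 0.25 when a single
molecular subtype is clustered, where cohorts are smaller), giving a
size floor of max(2, ⌊fraction × n⌋).  Stage 1 severs the merges that
join above a cut level set at 99 % of the merge-height *range*
(h_min + 0.99 (h_max − h_min)); branches at or below the level that
meet the size floor become cluster cores.  If fewer than two admissible
cores detach there, the cut level descends through the distinct merge
heights until a level yields at least two — the adaptive element that
makes the cut dynamic: a dendrogram with one outlying join is split
exactly there, while a gradually merging dendrogram is split at the
depth where two sufficiently large branches first coexist.  A
completely flat dendrogram (all merge heights equal) yields a single
cluster.  Stage 2 assigns every remaining patient to the core with the
smallest average dissimilarity (ties to the smaller label).  Labels are
renumbered 1..k by decreasing size.  The procedure is fully
deterministic.  The height-range criterion was chosen over a percentile
of the merge-height distribution: a percentile rule severs a fixed
*number* of top merges whatever the tree looks like, which on a cohort
with two clean groups forcibly splits one group in half; the range rule
responds to the shape of the tree instead.

**Survival comparison.**  Cluster survival is estimated with the
Kaplan–Meier product-limit estimator; subjects censored exactly at an
event time remain in that risk set (the standard convention, stated
here because it changes hand calculations).  Times are in years
(months accepted via a unit flag and divided by 12); the 5-year
metastasis-free-survival summary is S(5) evaluated right-continuously,
and the 15-year horizon stored on curves affects plotting only.
Clusters are compared with the unweighted k-sample log-rank chi-square
test on k − 1 degrees of freedom (one global test across all clusters,
not pairwise), implemented via `lifelines`; a single detected cluster
skips the test and is reported as such.

## Random-signature benchmark

The gene pool is the union of a gene-set collection's members
intersected with the measured genes, sorted.  Each of `n_signatures`
(default 1,000) draws is a uniform subset without replacement of
`signature_size` genes (default 76, the size of a typical mapped
module signature); the per-draw RNG derives from the master seed via
`SeedSequence(master_seed, spawn_key=(index,))`, so results are
bit-reproducible and independent of execution order.  Every signature
runs through the identical stratification chain; a signature for which
only one cluster is detected scores p = 1 (dropping it would bias the
significant fraction upward) and is counted separately.  Summaries:
`frac_significant` = #{p < α}/n and `frac_outperforming` =
#{p < p_original}/n with strict inequality, so ties count against the
original signature — the conservative reading of "more strongly
associated".

## Synthetic data

The generators are pure functions of their spec (seed included) and
emulate exactly the structure each stage assumes:

* `gen_network` — a directed Erdős–Rényi graph (default 200 nodes, edge
  probability 0.02) with random activation/inhibition signs (30 %
  inhibition) and a planted module (default 10 nodes) wired into a
  random spanning tree and bridged to the largest outside component.
* `gen_deg_tables` — three comparisons by default; a chosen fraction of
  module genes is significant in every table with consistent signs,
  plus table-specific significant background and non-significant
  fillers, so the cross-table intersection equals the planted subset up
  to reported background collisions.
* `gen_cohort` — default 200 patients, 500 genes.  Patients fall into
  prognosis groups (equiprobable by default; `balanced_groups` plants
  exact equal sizes for recovery experiments where a group below the
  cluster-size floor would be undetectable by construction).  Each
  signature gene takes a per-(gene, group) mean of ±effect (default
  2 SD): the sign pattern makes groups differ in profile *shape*, which
  is what a correlation distance can see — a uniform offset would be
  invisible to it.  Survival is exponential with baseline hazard
  0.1/year times a per-group hazard ratio (default (1, 3)), under
  independent exponential censoring (0.05/year) plus administrative
  censoring at 15 years; without the administrative cut the event
  fraction has the closed form h/(h + c) used as a generator check.
  Subtype labels (Basal/Her2/LumA/LumB at 0.2/0.1/0.4/0.3) are drawn
  independently of prognosis groups, so subtype structure and
  signature structure can be separated in tests.
* `gen_probe_map` — expands gene rows into 1–3 probes with
  probe-specific baseline shifts and small noise, recording the
  highest-mean probe as ground truth for the collapse step.

What passing tests on these data do **not** show: robustness to
microarray batch effects, RNA-Seq count noise, non-proportional
hazards, heteroscedastic expression, or subtype-confounded prognosis —
none of which the generators attempt to mimic.

## Validation problem sizes

The acceptance-style tests run at sizes chosen to keep the full suite
fast while leaving each check statistically meaningful: Steiner
heuristic vs exact oracle on 100 random graphs of ≤ 12 nodes;
hypergeometric tails checked exactly for every configuration with
universe ≤ 30; BH against the step-up definition on 1,000 random
vectors; log-rank null calibration with 1,000 simulations at n = 100;
clustering recovery on 100 cohorts of 40 patients; planted-prognosis
recovery on 100 cohorts of 200 patients; benchmark calibration with 200
signatures on a 200-patient null cohort.  `scripts/acceptance.py`
repeats the same measurements from scratch at the same sizes.

## Known limitations

* The Steiner heuristic is deterministic but not optimal; a different
  tie-breaking scheme (or another implementation of the same heuristic
  family) can return a different, equally valid module.
* The dynamic cut exposes only the size-floor parameter; dendrograms
  whose natural clusters differ hugely in size may be under-split
  because a true small cluster below the floor can never form a core.
* The log-rank test relies on the asymptotic chi-square null; at very
  small cluster sizes or very few events its p-values are approximate.
* Quantile normalization assumes patient columns are comparable after
  rank alignment; strong global shifts with biological meaning are
  erased by design.
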