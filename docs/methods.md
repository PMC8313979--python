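# Methods

## Input model

The unit of analysis is a TF→gene regulatory relationship within one tumor
cohort, scored by a regulatory potential RP ∈ [0, 1] (a decay-weighted
summary of ChIP-Seq binding near the target's TSS, computed upstream by the
database that exports the table) and a Spearman correlation ρ ∈ [−1, 1]
between TF and target expression across tumors. `glycoreg` never recomputes
RP or ρ; it consumes the (TF, gene, cohort, RP, ρ) table, validates it
(ranges, non-empty symbols, uniqueness of the (TF, gene, cohort) key — a
duplicate key is a hard error, surfacing upstream corruption rather than
silently averaging), and restricts targets to a glycogene universe list.

Positive regulatory edges are retained when RP ≥ 0.5 **and** ρ ≥ 0.4, both
inclusive. Negative-ρ (repressive) edges are excluded by the default
thresholds but the thresholds are plain parameters, so alternative regimes
can be explored. The binding potential BP = RP·ρ is attached to every edge;
it is used only as an export/layout weight (e.g. Cytoscape force-directed
layouts weighted by 1 − BP), never in the statistics.

## Pathway overrepresentation

For one cohort with N retained edges, a focal TF with n of them, and a
pathway hit by K of the N edges (an edge "hits" a pathway iff its target
gene's classification includes that pathway), the test statistic is the
count a of the focal TF's edges in the pathway. Under the null that the
TF's targets are exchangeable with everyone else's, a is hypergeometric,
and the one-sided Fisher exact p-value is the upper tail

    p = Σ_{j≥a} C(K, j) · C(N−K, n−j) / C(N, n),

evaluated with `scipy.stats.hypergeom.sf` (tested against exhaustive subset
enumeration for all margins N ≤ 12). Counting *edges* rather than unique
genes is deliberate: with the (TF, gene, cohort) key unique, a TF's edges
and its unique targets coincide, but the background margin N counts all
retained relationships of the cohort. Edges to glycogenes absent from the
classification stay in the background (they count as "not in pathway");
a `restrict_background` switch drops them for sensitivity analysis. Genes
belonging to several pathways count toward each pathway independently —
the tests are per-pathway marginals, not a partition.

Multiple testing uses Benjamini–Hochberg step-up adjusted p-values
(`statsmodels`, adj₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j capped at 1). The default
family is the single global pool of all (cohort, TF, pathway) tests, which
targets the strongest enrichments across cohorts; a per-cohort scope is
available. Two significance conventions coexist, mirroring how such screens
are used: a raw screen at p ≤ 0.05 feeding the network/alluvial views, and
a refined set at adjusted P < 0.05. The per-(cohort, pathway) degree of
regulation is Σ −log₁₀(p_adj) over significant TFs, with the TF count
alongside.

A note on BH: the adjusted-value map is *not* idempotent — for
p = (0.005, 0.04), adjustment gives (0.01, 0.04) and re-adjusting that
gives (0.02, 0.04). What does hold, and what the property tests assert, is
rank-monotonicity, adj ≥ p, the cap at 1, and exact agreement between
thresholding adjusted values at α and the classic step-up rejection rule.

## Communities

Each cohort's retained edges form a bipartite graph (TF nodes vs glycogene
nodes; a symbol appearing on both sides is rejected). The TF projection
connects two TFs iff they share ≥ 1 target, weighted by the shared-target
count (raw counts, not BP-weighted). Communities are detected on this
projection with an in-house Clauset–Newman–Moore greedy: start from
singletons and repeatedly merge the connected pair with the largest
modularity gain ΔQ = 2(e_ij − a_i a_j) while a strictly positive gain
exists; Q increases monotonically, so the stopping partition is the max-Q
cut of the merge path. Gain ties break on the lexicographically smallest
pair of community ids (a community's id is its smallest member label),
making the partition a pure function of the graph. The greedy is written
in-house rather than delegated precisely so that this tie-break is
specified; library implementations may legitimately differ on ties. Greedy
modularity is a heuristic: on small dense random graphs it lands strictly
below the exhaustive-search optimum a few percent of the time, which the
property tests acknowledge by asserting Q_greedy ≤ Q_exhaustive plus
dominance over the singleton and one-block baselines, alongside exact
recovery on separable structures (disconnected cliques, planted blocks).

Only TFs are clustered. Glycogenes are then attached to the community
holding the plurality of their regulators; ties go to the community with
the larger summed BP toward the gene, then to the smaller community id.
This attachment rule is this package's own convention (needed to report
gene membership of TF communities), not a property of the clustering.
Community ids are 1-based in descending TF-count order; singleton
communities are retained in output but excluded from "large community"
reporting (default ≥ 5 TFs). Per-community pathway overrepresentation
reuses the hypergeometric tail with the community's edges as the focal
margin and BH within that community's pathway family.

## Signaling annotation

TF groups are annotated against a local GMT collection with the same
hypergeometric tail (universe = the cohort's retained TFs by default,
members intersected with the universe before testing), BH across sets, and
strict filters FDR < 0.1 and set size < 30. The high FDR ceiling is
deliberate: the annotation is a high-level survey, not a discovery claim.
A live pathway-database query would use that database's own annotated
universe and release-specific sets, so absolute p-values from this local
variant are not comparable across releases; only relative behaviour is
tested. Flow tables (signaling set → TF → glyco-pathway, weight = the TF's
retained edge count into the pathway) feed alluvial plotting; TFs enriched
to a glyco-pathway but absent from every kept signaling set are emitted
under `(unassigned)` so the right-hand side of the plot stays complete.

## Synthetic cohorts

The generator emulates the table layer only — no reads, peaks or
expression matrices. Every (TF, gene) cell of a cohort is an edge with
probability 0.2 (the raw density implied by a few-×10⁴-row export over a
~570 TF × 341 gene grid); an edge is "true" with probability 0.08 and a
decoy otherwise. Scores are drawn independently given truth status:
RP ~ Beta(5, 2) for true edges vs Beta(2, 5) for decoys, and ρ scaled to
[−1, 1] from Beta(40, 10) (mean 0.6, sd ≈ 0.11 — most genuine TF–target
correlations between 0.4 and 0.8) vs Beta(5, 5) (mean 0) for decoys. Under
the default thresholds this retains ~86% of true edges and ~1% of decoys,
i.e. a background retained out-degree of ≈ 0.011 × n_genes per TF — about
2–4 targets in the 200-gene benchmark cohorts, matching the sparse
post-filter fan-out of real integrated tables. The raw→filtered retention
fraction is consequently lower than a real database export's, because the
model treats every TF–cohort pair as active with homogeneous background;
matching fan-out was preferred over matching retention because all
downstream statistics operate on the filtered graph.

Planted signal:

* a planted (TF, pathway, factor) pair sets the TF's edge probability into
  each of the pathway's genes to min(1, factor × 0.2) and the truth
  probability of those cells to 1 − (1 − 0.08)/factor. At factor 1 the
  cells are *exactly* background — the null-calibration experiments depend
  on this — and as factor grows the cells saturate toward all-true.
* a planted block (TF group × gene group) sets within-block edge
  probability (default 0.9) with all-true edges, creating a TF community
  with dense shared targets.

Determinism: one seed governs everything; per-cohort streams are
`default_rng([seed, cohort_index])`, and the signaling GMT draws from a
fixed offset stream. Generated tables round RP/ρ to 6 decimals so writes
are byte-stable; repeated runs at one seed are byte-identical.

Recovery metrics: planted-pair recall/precision at adjusted P < 0.05, and
for blocks the fraction recovered exactly (a block is recovered iff it is
one cell of the detected partition restricted to planted TFs) plus the
pairwise Rand index over planted TFs. Degenerate cases (nothing planted,
nothing detected) report null rather than 0/0.

Power, computed before any benchmark was run: a factor-5 plant saturates
its 10 pathway-gene edges and makes ~82% of them true, so after
thresholding the focal count a is roughly Binomial(10, 0.70); surviving a
global BH family of ~10³ tests needs a ≥ 6, giving an expected per-pair
recall around 0.85–0.93. The measured recall (~0.92 at factor 5) sits in
that band; recall ≥ 0.95 is reachable only at larger factors (the
factor-25 configuration in the unit tests detects with certainty). The
generator parameters were fixed by the realism considerations above and
not revisited against benchmark outcomes.

## Problem sizes and numerical conventions

The shipped study cohort is 4 cohorts × 120 TFs × 341 genes with 20
ten-gene pathways (200 classified genes, the rest unclassified), three
factor-5 planted pairs and three 8-TF blocks; replicate benchmarks use
50 × 200 (pairs, 200 + 500 replicates) and 40 × 160 (blocks, 50
replicates). These sizes keep every driver and the full test suite at
desk scale while leaving all margins large enough for the asymptotics-free
exact tests. p-values are clipped to (0, 1]; zero-edge graphs define
Q = 0; empty filter results, empty communities and empty annotation
queries are legal and return empty tables.

## Limitations

The generator's independence assumptions (RP ⊥ ρ given truth status,
i.i.d. cells) are simplifications; real exports have correlated TF
activity, shared targets between paralogous TFs, and cohort-specific TF
expression gating, none of which are modelled. Passing recovery benchmarks
therefore demonstrates correctness of the statistics and determinism of
the pipeline on tables with the assumed marginal structure — not
robustness to the full dependence structure of real data. Community
memberships depend on the greedy heuristic's merge order; alternative
algorithms (Louvain/Leiden) are deliberately out of scope in this version.
Repressive regulation (ρ < 0) is untested territory: the enrichment logic
would apply unchanged, but no benchmark covers it.
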