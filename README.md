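# glycoreg

Inference of transcription-factor (TF) control of glycosylation from
ChIP-Seq/RNA-Seq-derived regulatory tables.

Glycan biosynthesis is carried out by a few hundred glycogenes —
glycosyltransferases, glycosidases, sulfotransferases and transporters — yet
which transcription factors drive them, and thereby reshape the cellular
glycome in development and disease, is largely uncharted. `glycoreg` is an
analysis toolkit for mining TF→glycogene regulatory relationships from
integrated ChIP-Seq/RNA-Seq tables of the kind exported by tumor regulatory
databases: one row per (TF, target gene, tumor cohort) carrying a regulatory
potential RP ∈ [0, 1] (binding evidence near the TSS) and a Spearman
correlation ρ ∈ [−1, 1] between TF and target expression.

The pipeline, each step a library module under `src/glycoreg/` and a
numbered driver under `analysis/`:

1. **Filtering** — keep positive regulatory edges with RP ≥ 0.5 and ρ ≥ 0.4
   (inclusive) whose target lies in the glycogene universe; score each edge
   with the binding potential BP = RP·ρ.
2. **Pathway enrichment** — for every (cohort, TF, glyco-pathway) triple,
   test whether the TF's retained edges hit the pathway disproportionately
   often, against all retained edges of that cohort. The one-sided Fisher
   exact p-value of the 2×2 table is the hypergeometric upper tail
   P(X ≥ a) with X ~ Hypergeom(N, K, n); p-values are corrected with the
   Benjamini–Hochberg step-up over the global pool across cohorts. The
   per-(cohort, pathway) *degree of regulation* is Σ −log₁₀(p_adj) over the
   significant TFs.
3. **Communities** — each cohort's retained edges form a bipartite
   TF–glycogene graph; the TF projection connects TFs by their number of
   shared targets, and a deterministic Clauset–Newman–Moore greedy
   modularity maximization partitions it. Glycogenes join the community
   holding the plurality of their regulators (BP total, then community id,
   break ties). Networks export to GraphML/SIF for Cytoscape.
4. **Signaling annotation** — TF groups (the enrichment-screened TFs, or
   whole communities) are tested against a local GMT of signaling gene sets
   with the same hypergeometric tail; sets with FDR < 0.1 and fewer than 30
   members are kept, and a flow table *signaling set → TF → glyco-pathway*
   is emitted for alluvial plotting.
5. **Synthetic cohorts** — a generator emulates the whole input layer
   (tables, classification, GMT) with planted TF–pathway enrichments and
   planted TF co-regulation blocks, so every step can be benchmarked
   against known ground truth.

A packaged classification of glycogenes into 20 glycosylation pathways
(dolichol pathway, N-glycan branching, GalNAc-type O-glycans,
chondroitin/heparan sulfate assembly, sialylation, fucosylation, ...) ships
with the package for tests and examples.

## Worked example

Running the numbered drivers in order on the built-in synthetic study
cohort (4 cohorts × 120 TFs × 341 genes, three planted TF–pathway pairs at
enrichment factor 5 and three planted 8-TF co-regulation blocks):

```sh
python analysis/01_simulate.py
python analysis/02_filter.py
python analysis/03_enrich.py
python analysis/04_communities.py
python analysis/05_annotate_signaling.py
python analysis/06_recovery_benchmark.py
```

prints, among other things:

```
raw: 34341 edges, 120 TFs
retained (RP>=0.5, rho>=0.4): 4169 edges, 120 TFs, 341 glycogenes, 4 cancer types
mean TF out-degree: 8.70 (range 1–31)

tests performed: 9580
significant at raw p <= 0.05: 127
significant at adjusted P < 0.05 (global BH): 12

CAN_01: 5 communities (4 with >=5 TFs), Q = 0.434
  community 4: 20 TFs / 35 genes; top pathway PW13 (p_adj = 1.27e-07)
  community 1: SIGBLK01   hits=8/8   FDR=0.00042

planted-pair recall at adjusted P<0.05, factor 5: 0.920 (300 pairs)
null false-flag rate at raw p<=0.05, factor 1: 0.013 (400 cells)
planted-block exact recovery: 1.000, Rand index 1.000 (25 cohorts)
```

Reading these numbers: the RP/ρ thresholds strip ~88% of the raw edges;
of 9,580 Fisher tests only 127 pass the raw screen and 12 survive global
BH — and those 12 are dominated by the planted TF–pathway pairs (the
recovery benchmark quantifies this at ~92% recall, with a null false-flag
rate of ~1%, well under the nominal 5%). Community detection partitions
each cohort's TF projection at modularity Q ≈ 0.43 and recovers the
planted co-regulation blocks exactly; annotating the communities against
the signaling GMT retrieves each block's planted signaling set (`SIGBLK*`,
8/8 members, FDR < 10⁻³). Intermediate tables land under `results/`.

The same steps run on real exports via the `glycoreg` CLI
(`glycoreg filter|enrich|communities|annotate|alluvial --help`), with a
configurable column-name dialect for the tab-delimited input.

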