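"""TF–glycopathway overrepresentation with BH correction.

One one-sided Fisher test per (cancer, TF, pathway); BH over the global pool
and, for comparison, per cancer.  Writes the full result table and the
degree-of-regulation summary (number of significant TFs and summed
-log10 adjusted p per cancer–pathway pair).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import RESULTS, SIM_DIR

from glycoreg.enrichment import degree_of_regulation, enrich_tf_pathways
from glycoreg.ingest import read_pathway_classification, read_tf_gene_table


def main() -> None:
    kept = read_tf_gene_table(RESULTS / "filtered_edges.tsv")
    classification = read_pathway_classification(SIM_DIR / "pathway_classification.tsv")

    results = enrich_tf_pathways(kept, classification, bh_scope="global")
    results.to_csv(RESULTS / "tf_pathway_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    per_cancer = enrich_tf_pathways(kept, classification, bh_scope="per_cancer")

    print(f"tests performed: {len(results)}")
    print(f"significant at raw p <= 0.05: {int(results['significant_raw'].sum())}")
    print(f"significant at adjusted P < 0.05 (global BH): {int(results['significant_adj'].sum())}")
    print(f"significant at adjusted P < 0.05 (per-cancer BH): {int(per_cancer['significant_adj'].sum())}")

    degrees = degree_of_regulation(results)
    degrees.to_csv(RESULTS / "degree_of_regulation.tsv", sep="\t", index=False, float_format="%.6g")
    top = degrees.sort_values("degree", ascending=False).head(5)
    print("strongest cancer–pathway regulation (sum of -log10 adjusted p):")
    for row in top.itertuples(index=False):
        print(f"  {row.cancer}\t{row.pathway}\tn_tfs={row.n_tfs}\tdegree={row.degree:.2f}")


if __name__ == "__main__":
    main()
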