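"""Filter the raw relationship table to high-confidence positive edges.

Applies the RP >= 0.5, rho >= 0.4 thresholds within the glycogene universe
and reports edge/TF counts and the per-TF out-degree, the quantities that
characterise the retained regulatory network.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import RESULTS, SIM_DIR

from glycoreg.filtering import FilterConfig, filter_records, summarize_table
from glycoreg.ingest import GeneSet, read_tf_gene_table, write_tf_gene_table


def main() -> None:
    records = read_tf_gene_table(SIM_DIR / "tf_gene_table.tsv")
    universe = GeneSet("glycogenes", frozenset(r.gene for r in records))
    kept = filter_records(records, FilterConfig(universe=universe))
    write_tf_gene_table(kept, RESULTS / "filtered_edges.tsv")

    raw = summarize_table(records)
    s = summarize_table(kept)
    s.per_cancer.to_csv(RESULTS / "summary_per_cancer.tsv", sep="\t", index=False)
    print(f"raw: {raw.n_edges} edges, {raw.n_tfs} TFs")
    print(f"retained (RP>=0.5, rho>=0.4): {s.n_edges} edges, {s.n_tfs} TFs, "
          f"{s.n_genes} glycogenes, {s.n_cancers} cancer types")
    print(f"mean TF out-degree: {s.mean_out_degree:.2f} "
          f"(range {s.out_degrees['out_degree'].min()}–{s.out_degrees['out_degree'].max()})")


if __name__ == "__main__":
    main()
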