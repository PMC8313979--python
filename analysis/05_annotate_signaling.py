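"""Signaling-set annotation of enriched TFs and alluvial flow tables.

For each cancer, the TFs passing the raw enrichment screen are tested
against the signaling GMT (FDR < 0.1, set size < 30), and a flow table
signaling set -> TF -> glyco-pathway is emitted for alluvial plotting.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import RESULTS, SIM_DIR

from glycoreg.annotation import build_alluvial_flows, overrepresent
from glycoreg.ingest import read_annotation_gmt, read_pathway_classification, read_tf_gene_table
from glycoreg.network import detect_communities


def main() -> None:
    kept = read_tf_gene_table(RESULTS / "filtered_edges.tsv")
    classification = read_pathway_classification(SIM_DIR / "pathway_classification.tsv")
    gmt = read_annotation_gmt(SIM_DIR / "signaling_sets.gmt")
    enr = pd.read_csv(RESULTS / "tf_pathway_enrichment.tsv", sep="\t")

    for cancer in sorted(enr["cancer"].unique()):
        edges = [r for r in kept if r.cancer == cancer]
        universe = sorted({r.tf for r in edges})
        sig = enr[(enr["cancer"] == cancer) & enr["significant_raw"]]
        query = sorted(sig["tf"].unique())
        overrep = overrepresent(query, gmt, universe)
        overrep.to_csv(RESULTS / f"signaling_{cancer}.tsv", sep="\t", index=False, float_format="%.6g")
        flows = build_alluvial_flows(sig, overrep, edges, classification)
        flows.to_csv(RESULTS / f"flows_{cancer}.tsv", sep="\t", index=False)
        print(f"{cancer}: {len(query)} screened TFs, {len(overrep)} kept signaling sets, "
              f"{len(flows)} alluvial flows")

        # signaling annotation of the TF communities themselves
        for comm in detect_communities(edges).large(min_tfs=5):
            hits = overrepresent(sorted(comm.tfs), gmt, universe)
            for row in hits.itertuples(index=False):
                print(f"  community {comm.id}: {row.set_name}\t"
                      f"hits={row.n_hits}/{row.set_size}\tFDR={row.fdr:.3g}")


if __name__ == "__main__":
    main()
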