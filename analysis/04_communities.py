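"""TF–glycogene communities per cancer type.

Builds each cancer's bipartite network, projects it onto TFs (edge weight =
shared glycogene targets), detects communities by greedy modularity
maximization, attaches glycogenes, and tests each large community for
glyco-pathway overrepresentation.  Exports GraphML/SIF for Cytoscape.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study_config import RESULTS, SIM_DIR

from glycoreg import network
from glycoreg.ingest import read_pathway_classification, read_tf_gene_table


def main() -> None:
    kept = read_tf_gene_table(RESULTS / "filtered_edges.tsv")
    classification = read_pathway_classification(SIM_DIR / "pathway_classification.tsv")

    member_frames, enrich_frames = [], []
    for cancer in sorted({r.cancer for r in kept}):
        edges = [r for r in kept if r.cancer == cancer]
        bip = network.build_bipartite(edges)
        cs = network.detect_communities(edges)
        member_frames.append(cs.membership_frame())
        network.export_graphml(bip, RESULTS / f"network_{cancer}.graphml", community_set=cs)
        network.export_sif(bip, RESULTS / f"network_{cancer}.sif")
        large = cs.large(min_tfs=5)
        print(f"{cancer}: {len(cs.communities)} communities "
              f"({len(large)} with >=5 TFs), Q = {cs.modularity:.3f}")
        for comm in large:
            res = network.community_glyco_enrichment(comm, edges, classification)
            res.insert(0, "community", comm.id)
            res.insert(0, "cancer", cancer)
            enrich_frames.append(res)
            best = res.loc[res["p"].idxmin()]
            print(f"  community {comm.id}: {len(comm.tfs)} TFs / {len(comm.genes)} genes; "
                  f"top pathway {best['pathway']} (p_adj = {best['p_adj']:.3g})")

    pd.concat(member_frames, ignore_index=True).to_csv(
        RESULTS / "community_membership.tsv", sep="\t", index=False
    )
    if enrich_frames:
        pd.concat(enrich_frames, ignore_index=True).to_csv(
            RESULTS / "community_glyco_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )


if __name__ == "__main__":
    main()
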