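"""End-to-end driver: simulate -> filter -> enrich -> communities -> annotate.

Chains the library modules over a synthetic cohort (or a table read from
disk) and writes every intermediate as a plain-text artifact: the raw and
filtered edge tables, the enrichment and degree-of-regulation tables,
per-cancer community memberships with GraphML/SIF exports, signaling
overrepresentation tables, and alluvial flow tables.  All outputs are
deterministic for a fixed seed (files are byte-identical across runs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotation, enrichment, network, synthetic
from .filtering import FilterConfig, filter_records, summarize_table
from .ingest import records_to_frame, write_tf_gene_table


@dataclass
class PipelineResult:
    truth: synthetic.SyntheticTruth
    filtered: list
    enrichments: pd.DataFrame
    degrees: pd.DataFrame
    community_sets: dict[str, network.CommunitySet]
    flows: dict[str, pd.DataFrame]
    paths: dict[str, Path]


def run_pipeline(
    out_dir: str | Path,
    config: synthetic.SyntheticConfig,
    rp_min: float = 0.5,
    rho_min: float = 0.4,
    alpha_raw: float = 0.05,
    alpha_adj: float = 0.05,
    bh_scope: str = "global",
    fdr_max: float = 0.1,
    max_set_size: int = 30,
) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = synthetic.write_truth(truth := synthetic.generate(config), out)

    filt_cfg = FilterConfig(rp_min=rp_min, rho_min=rho_min, universe=truth.universe)
    filtered = filter_records(list(truth.table), filt_cfg)
    paths["filtered"] = out / "filtered_edges.tsv"
    write_tf_gene_table(filtered, paths["filtered"])
    summary = summarize_table(filtered)
    paths["summary"] = out / "summary_per_cancer.tsv"
    summary.per_cancer.to_csv(paths["summary"], sep="\t", index=False)

    results = enrichment.enrich_tf_pathways(
        filtered, truth.classification, alpha_raw=alpha_raw, alpha_adj=alpha_adj, bh_scope=bh_scope
    )
    paths["enrichment"] = out / "tf_pathway_enrichment.tsv"
    results.to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.6g")
    degrees = enrichment.degree_of_regulation(results, alpha_adj=alpha_adj)
    paths["degree"] = out / "degree_of_regulation.tsv"
    degrees.to_csv(paths["degree"], sep="\t", index=False, float_format="%.6g")

    df = records_to_frame(filtered)
    community_sets: dict[str, network.CommunitySet] = {}
    flows: dict[str, pd.DataFrame] = {}
    member_frames = []
    for cancer in sorted(df["cancer"].unique()):
        edges_c = [r for r in filtered if r.cancer == cancer]
        bip = network.build_bipartite(edges_c)
        cs = network.detect_communities(edges_c)
        community_sets[cancer] = cs
        member_frames.append(cs.membership_frame())
        network.export_graphml(bip, out / f"network_{cancer}.graphml", community_set=cs)
        network.export_sif(bip, out / f"network_{cancer}.sif")

        tfs_c = sorted({r.tf for r in edges_c})
        sig_rows = results[
            (results["cancer"] == cancer) & results["significant_raw"]
        ]
        query = sorted(sig_rows["tf"].unique())
        overrep = annotation.overrepresent(
            query, truth.gmt, tfs_c, fdr_max=fdr_max, max_set_size=max_set_size
        )
        overrep.to_csv(out / f"signaling_{cancer}.tsv", sep="\t", index=False, float_format="%.6g")
        flow = annotation.build_alluvial_flows(sig_rows, overrep, edges_c, truth.classification)
        flow.to_csv(out / f"flows_{cancer}.tsv", sep="\t", index=False)
        flows[cancer] = flow

    paths["communities"] = out / "community_membership.tsv"
    members = (
        pd.concat(member_frames, ignore_index=True)
        if member_frames
        else pd.DataFrame(columns=["cancer", "community", "symbol", "kind"])
    )
    members.to_csv(paths["communities"], sep="\t", index=False)

    return PipelineResult(
        truth=truth,
        filtered=filtered,
        enrichments=results,
        degrees=degrees,
        community_sets=community_sets,
        flows=flows,
        paths=paths,
    )
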