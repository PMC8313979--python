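"""Signaling gene-set overrepresentation for TF groups and alluvial flows.

Groups of pathway-enriched TFs are tested against a local GMT collection of
signaling gene sets with the same hypergeometric upper tail used for the
glyco-pathway tests, BH-corrected across sets.  Kept sets obey strict
filters: FDR < 0.1 and fewer than 30 members (after intersection with the
universe).  Flow tables link kept signaling sets -> TFs -> enriched
glycosylation pathways for alluvial-style plotting; TFs with no kept
signaling set are emitted under the "(unassigned)" source.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError
from .ingest import AnnotationCollection, PathwayClassification, TFGeneRecord, records_to_frame
from .enrichment import benjamini_hochberg, hypergeometric_tail

UNASSIGNED = "(unassigned)"

OVERREP_COLUMNS = ["set_name", "set_size", "n_hits", "hits", "p", "fdr"]


def overrepresent(
    query: Iterable[str],
    collection: AnnotationCollection,
    universe: Iterable[str],
    fdr_max: float = 0.1,
    max_set_size: int = 30,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each annotation set.

    Set members are intersected with the universe before testing; the test
    draws |query| symbols from the universe and counts hits in each set.
    Results are BH-corrected across all tested sets, then filtered to
    fdr < fdr_max and set_size < max_set_size (both strict) unless
    ``keep_all`` is set.
    """
    universe_set = set(universe)
    if not universe_set:
        raise DomainError("empty universe")
    query_set = set(query) & universe_set
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe_set
        if not members:
            continue
        hits = sorted(query_set & members)
        p = hypergeometric_tail(len(hits), len(members), len(query_set), len(universe_set))
        rows.append((name, len(members), len(hits), ";".join(hits), p))
    df = pd.DataFrame(rows, columns=OVERREP_COLUMNS[:-1])
    if df.empty:
        return pd.DataFrame(columns=OVERREP_COLUMNS)
    df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    if not keep_all:
        df = df[(df["fdr"] < fdr_max) & (df["set_size"] < max_set_size)]
    return df.sort_values(["p", "set_name"], ignore_index=True)


def build_alluvial_flows(
    glyco_enrichments: pd.DataFrame,
    signaling_results: pd.DataFrame,
    edges: Sequence[TFGeneRecord],
    classification: PathwayClassification,
) -> pd.DataFrame:
    """Flow table signaling set -> TF -> glyco-pathway for one cancer.

    ``glyco_enrichments`` holds the significant (TF, pathway) rows of one
    cancer; ``signaling_results`` the kept overrepresentation rows whose
    ``hits`` column names the member TFs.  Each flow's weight is the TF's
    retained edge count into the pathway.  TFs absent from every kept
    signaling set appear once per pathway under ``(unassigned)``.
    """
    cancers = set(glyco_enrichments.get("cancer", pd.Series(dtype=str)).unique())
    if len(cancers) > 1:
        raise DomainError(f"glyco enrichments span multiple cancers: {sorted(cancers)}")
    cancer = next(iter(cancers)) if cancers else (edges[0].cancer if edges else "")

    tf_sets: dict[str, list[str]] = {}
    if not signaling_results.empty:
        for row in signaling_results.itertuples(index=False):
            for tf in str(row.hits).split(";"):
                if tf:
                    tf_sets.setdefault(tf, []).append(row.set_name)

    counts = records_to_frame(edges) if edges else pd.DataFrame(columns=["tf", "gene"])
    rows = []
    for er in glyco_enrichments.itertuples(index=False):
        pw_genes = classification.genes_in(er.pathway)
        weight = int(((counts["tf"] == er.tf) & (counts["gene"].isin(pw_genes))).sum())
        if weight < 1:
            continue
        for set_name in sorted(tf_sets.get(er.tf, [])) or [UNASSIGNED]:
            rows.append((set_name, er.tf, er.pathway, weight, cancer))
    return pd.DataFrame(
        rows, columns=["signaling_set", "tf", "glyco_pathway", "weight", "cancer"]
    ).sort_values(["signaling_set", "tf", "glyco_pathway"], ignore_index=True)
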