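"""Overrepresentation of glycosylation pathways among a TF's targets.

For each cancer type, every (TF, pathway) pair is scored with a one-sided
Fisher's exact test on the 2x2 table

    a = focal TF's retained edges whose target is in the pathway
    b = focal TF's remaining retained edges
    c = other TFs' retained edges into the pathway
    d = other TFs' remaining retained edges

against the background of all retained TF–gene edges of that cancer.  For a
2x2 table with fixed margins the one-sided ("greater") Fisher p-value is the
upper tail of the hypergeometric distribution of a, which is how it is
computed here.  Raw p-values are corrected with the Benjamini–Hochberg
step-up procedure, by default in one global pool across all cancer types.

The degree-of-regulation summary condenses the corrected results per
(cancer, pathway): the number of significant TFs and the sum of their
-log10(adjusted p) values.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .ingest import PathwayClassification, TFGeneRecord, records_to_frame

RESULT_COLUMNS = [
    "cancer", "tf", "pathway", "a", "b", "c", "d",
    "p", "p_adj", "significant_raw", "significant_adj",
]


class ContingencyTable(NamedTuple):
    a: int
    b: int
    c: int
    d: int


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` items without replacement from a population of ``N``
    containing ``K`` successes, the probability of observing ``k`` or more
    successes.  Equals the one-sided (greater) Fisher p-value of the 2x2
    table (k, n-k; K-k, N-K-n+k).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise DomainError(f"k={k} outside [0, min(K={K}, n={n})]")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order.

    adj_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_contingency(
    tf: str,
    pathway: str,
    edges: Sequence[TFGeneRecord],
    classification: PathwayClassification,
    restrict_background: bool = False,
) -> ContingencyTable:
    """2x2 counts for one TF and one pathway within one cancer's edges.

    ``restrict_background=True`` drops edges to unclassified genes before
    counting, shrinking the background margin to classified targets only.
    """
    cancers = {e.cancer for e in edges}
    if len(cancers) > 1:
        raise DomainError(f"edges span multiple cancers: {sorted(cancers)}")
    if restrict_background:
        edges = [e for e in edges if classification.pathways_of(e.gene)]
    if tf not in {e.tf for e in edges}:
        raise DomainError(f"TF {tf!r} has no edges in this background")
    a = b = c = d = 0
    for e in edges:
        in_pw = pathway in classification.pathways_of(e.gene)
        if e.tf == tf:
            a, b = (a + 1, b) if in_pw else (a, b + 1)
        else:
            c, d = (c + 1, d) if in_pw else (c, d + 1)
    return ContingencyTable(a, b, c, d)


def enrich_tf_pathways(
    edges: Sequence[TFGeneRecord] | pd.DataFrame,
    classification: PathwayClassification,
    alpha_raw: float = 0.05,
    alpha_adj: float = 0.05,
    bh_scope: str = "global",
    restrict_background: bool = False,
) -> pd.DataFrame:
    """Test every (cancer, TF, pathway) triple for pathway overrepresentation.

    One test is performed for each TF with at least one retained edge in a
    cancer, against each classified pathway.  Returns a DataFrame with the
    2x2 counts, raw p, BH-adjusted p and significance flags at ``alpha_raw``
    (raw screen, p <= alpha) and ``alpha_adj`` (adjusted, p_adj < alpha).

    ``bh_scope`` is ``"global"`` (one pool across all cancer types, the
    default) or ``"per_cancer"``.
    """
    if bh_scope not in ("global", "per_cancer"):
        raise DomainError(f"unknown bh_scope {bh_scope!r}")
    df = edges if isinstance(edges, pd.DataFrame) else records_to_frame(edges)
    if restrict_background:
        classified = classification.genes
        df = df[df["gene"].isin(classified)]
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    membership = classification.membership_frame()
    pathways = sorted(classification.pathways)

    # Margins: per-cancer totals N, per-(cancer, tf) draw counts n,
    # per-(cancer, pathway) success counts K, and per-triple hits a.
    n_ct = df.groupby(["cancer", "tf"]).size().rename("n")
    N_c = df.groupby("cancer").size().rename("N")
    hits = df.merge(membership, on="gene")
    K_cp = hits.groupby(["cancer", "pathway"]).size().rename("K")
    a_ctp = hits.groupby(["cancer", "tf", "pathway"]).size().rename("a")

    grid = (
        n_ct.reset_index()
        .merge(pd.DataFrame({"pathway": pathways}), how="cross")
        .merge(N_c.reset_index(), on="cancer")
        .merge(K_cp.reset_index(), on=["cancer", "pathway"], how="left")
        .merge(a_ctp.reset_index(), on=["cancer", "tf", "pathway"], how="left")
    )
    grid[["K", "a"]] = grid[["K", "a"]].fillna(0).astype(int)
    grid["b"] = grid["n"] - grid["a"]
    grid["c"] = grid["K"] - grid["a"]
    grid["d"] = grid["N"] - grid["n"] - grid["c"]
    grid["p"] = hypergeom.sf(grid["a"] - 1, grid["N"], grid["K"], grid["n"])
    grid["p"] = grid["p"].clip(lower=np.nextafter(0.0, 1.0), upper=1.0)

    if bh_scope == "global":
        grid["p_adj"] = benjamini_hochberg(grid["p"].to_numpy())
    else:
        grid["p_adj"] = grid.groupby("cancer")["p"].transform(
            lambda s: benjamini_hochberg(s.to_numpy())
        )
    grid["significant_raw"] = grid["p"] <= alpha_raw
    grid["significant_adj"] = grid["p_adj"] < alpha_adj
    grid = grid.sort_values(["cancer", "tf", "pathway"], ignore_index=True)
    return grid[RESULT_COLUMNS]


def degree_of_regulation(results: pd.DataFrame, alpha_adj: float = 0.05) -> pd.DataFrame:
    """Per (cancer, pathway) regulation summary over significant TFs.

    ``n_tfs`` counts TFs with p_adj < alpha_adj; ``degree`` is the sum of
    their -log10(p_adj).  Pairs with no significant TF report (0, 0.0).
    """
    if results.empty:
        return pd.DataFrame(columns=["cancer", "pathway", "n_tfs", "degree"])
    sig = results[results["p_adj"] < alpha_adj].copy()
    sig["neglog"] = -np.log10(sig["p_adj"])
    agg = (
        sig.groupby(["cancer", "pathway"])
        .agg(n_tfs=("tf", "nunique"), degree=("neglog", "sum"))
        .reset_index()
    )
    base = results[["cancer", "pathway"]].drop_duplicates()
    out = base.merge(agg, on=["cancer", "pathway"], how="left")
    out["n_tfs"] = out["n_tfs"].fillna(0).astype(int)
    out["degree"] = out["degree"].fillna(0.0)
    return out.sort_values(["cancer", "pathway"], ignore_index=True)
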