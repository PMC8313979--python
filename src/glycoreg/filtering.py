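"""Thresholding of TF–gene edges and binding-potential scoring.

Positive regulatory relationships are kept when the ChIP-derived regulatory
potential and the expression correlation both clear their thresholds
(RP >= 0.5 and rho >= 0.4 by default, inclusive) and the target lies in the
glycogene universe.  Each edge additionally carries a binding potential
BP = RP * rho used downstream as an export/layout weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .ingest import GeneSet, TFGeneRecord, records_to_frame


@dataclass(frozen=True)
class FilterConfig:
    """Edge-retention thresholds plus the target-gene universe."""

    rp_min: float = 0.5
    rho_min: float = 0.4
    universe: GeneSet | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rp_min <= 1.0:
            raise ValidationError(f"rp_min out of [0, 1]: {self.rp_min}")
        if not -1.0 <= self.rho_min <= 1.0:
            raise ValidationError(f"rho_min out of [-1, 1]: {self.rho_min}")


@dataclass(frozen=True)
class ScoredEdge:
    record: TFGeneRecord
    bp: float


def binding_potential(rp: float, rho: float) -> float:
    """BP score of one edge: the exact product RP * rho."""
    return rp * rho


def score_edges(records: Iterable[TFGeneRecord]) -> list[ScoredEdge]:
    return [ScoredEdge(record=r, bp=binding_potential(r.rp, r.rho)) for r in records]


def filter_records(records: Sequence[TFGeneRecord], config: FilterConfig) -> list[TFGeneRecord]:
    """Keep records with gene in the universe and RP/rho at or above threshold.

    Comparisons are inclusive; order is preserved; the result may be empty.
    """
    universe = config.universe.members if config.universe is not None else None
    out = []
    for rec in records:
        if universe is not None and rec.gene not in universe:
            continue
        if rec.rp >= config.rp_min and rec.rho >= config.rho_min:
            out.append(rec)
    return out


@dataclass(frozen=True)
class TableSummary:
    """Edge/TF/gene counts, globally and per cancer, with per-TF out-degrees."""

    n_edges: int
    n_tfs: int
    n_genes: int
    n_cancers: int
    per_cancer: pd.DataFrame  # cancer, n_edges, n_tfs, n_genes
    out_degrees: pd.DataFrame  # cancer, tf, out_degree

    @property
    def mean_out_degree(self) -> float:
        if self.out_degrees.empty:
            return 0.0
        return float(self.out_degrees["out_degree"].mean())


def summarize_table(records: Sequence[TFGeneRecord]) -> TableSummary:
    """Count edges, unique TFs/genes/cancers, and per-TF out-degree per cancer."""
    if not records:
        empty_pc = pd.DataFrame(columns=["cancer", "n_edges", "n_tfs", "n_genes"])
        empty_od = pd.DataFrame(columns=["cancer", "tf", "out_degree"])
        return TableSummary(0, 0, 0, 0, empty_pc, empty_od)
    df = records_to_frame(records)
    per_cancer = (
        df.groupby("cancer")
        .agg(n_edges=("gene", "size"), n_tfs=("tf", "nunique"), n_genes=("gene", "nunique"))
        .reset_index()
        .sort_values("cancer", ignore_index=True)
    )
    out_degrees = (
        df.groupby(["cancer", "tf"])
        .size()
        .rename("out_degree")
        .reset_index()
        .sort_values(["cancer", "tf"], ignore_index=True)
    )
    return TableSummary(
        n_edges=len(df),
        n_tfs=df["tf"].nunique(),
        n_genes=df["gene"].nunique(),
        n_cancers=df["cancer"].nunique(),
        per_cancer=per_cancer,
        out_degrees=out_degrees,
    )
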