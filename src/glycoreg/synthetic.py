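"""Synthetic regulatory tables with planted enrichments and TF communities.

The generator emulates the statistical layer the pipeline consumes: a
tab-delimited TF–gene table per cancer type with (RP, rho) scores, a
gene→pathway classification, and a GMT of signaling sets over TFs.  Each
potential (TF, gene) cell is an edge with some probability; an edge is
either "true" (regulatory: high RP, positive rho) or a "decoy" (weak
ChIP/correlation evidence: low RP, rho centred on zero), so the default
RP >= 0.5, rho >= 0.4 thresholds retain most true edges and few decoys.

Signal is planted two ways:

* planted (TF, pathway, factor) pairs inflate that TF's edge probability
  into the pathway's genes by ``factor`` and make the excess edges true;
  at factor = 1 the cells are statistically identical to background, which
  is what null-calibration experiments rely on;
* planted (TF-group, gene-group) blocks add dense true co-regulation,
  producing TF communities recoverable from the projected graph.

Ground truth (planted pairs, planted blocks) is carried alongside the table
so recovery metrics can be computed after running the pipeline.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .errors import ConfigurationError
from .ingest import (
    AnnotationCollection,
    GeneSet,
    PathwayClassification,
    TFGeneRecord,
    write_annotation_gmt,
    write_tf_gene_table,
)


@dataclass(frozen=True)
class PlantedPair:
    """A TF whose edge probability into one pathway is scaled by ``factor``."""

    tf_index: int
    pathway_index: int
    factor: float

    def __post_init__(self) -> None:
        if self.factor < 1.0:
            raise ConfigurationError("enrichment factor must be >= 1")


@dataclass(frozen=True)
class PlantedBlock:
    """A co-regulation block: dense true edges between a TF and a gene group."""

    tf_indices: tuple[int, ...]
    gene_indices: tuple[int, ...]
    within_prob: float = 0.9


@dataclass(frozen=True)
class SyntheticConfig:
    """Dimensions, probabilities and score distributions of the generator.

    Defaults give each TF a raw out-degree of ~40 of which ~3 edges survive
    the default RP/rho thresholds, mirroring the sparse post-filter
    regulatory fan-out of real ChIP/expression integration tables.  Beta
    parameters: RP ~ Beta(5,2) for true edges vs Beta(2,5) for decoys; rho is
    a Beta on [-1, 1], mean 0.6 (sd ~0.11) for true edges and mean 0 for
    decoys.
    """

    n_cancers: int = 1
    n_tfs: int = 50
    n_genes: int = 200
    n_pathways: int = 20
    pathway_size: int = 10
    background_edge_prob: float = 0.2
    true_edge_fraction: float = 0.08
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_blocks: tuple[PlantedBlock, ...] = ()
    rp_true: tuple[float, float] = (5.0, 2.0)
    rp_decoy: tuple[float, float] = (2.0, 5.0)
    rho_true: tuple[float, float] = (40.0, 10.0)
    rho_decoy: tuple[float, float] = (5.0, 5.0)
    n_signaling_sets: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigurationError("background_edge_prob must be in [0, 1]")
        if not 0.0 <= self.true_edge_fraction <= 1.0:
            raise ConfigurationError("true_edge_fraction must be in [0, 1]")
        if self.n_pathways * self.pathway_size > self.n_genes:
            raise ConfigurationError("pathways require more genes than available")
        for pair in self.planted_pairs:
            if not 0 <= pair.tf_index < self.n_tfs:
                raise ConfigurationError(f"planted TF index {pair.tf_index} out of range")
            if not 0 <= pair.pathway_index < self.n_pathways:
                raise ConfigurationError(f"planted pathway index {pair.pathway_index} out of range")
        for block in self.planted_blocks:
            if any(not 0 <= i < self.n_tfs for i in block.tf_indices):
                raise ConfigurationError("block TF index out of range")
            if any(not 0 <= j < self.n_genes for j in block.gene_indices):
                raise ConfigurationError("block gene index out of range")
            if not 0.0 <= block.within_prob <= 1.0:
                raise ConfigurationError("within_prob must be in [0, 1]")

    # --- symbol naming -------------------------------------------------
    def tf_name(self, i: int) -> str:
        return f"TF{i + 1:03d}"

    def gene_name(self, j: int) -> str:
        return f"G{j + 1:04d}"

    def cancer_name(self, c: int) -> str:
        return f"CAN_{c + 1:02d}"

    def pathway_name(self, p: int) -> str:
        return f"PW{p + 1:02d}"


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated dataset plus the planted ground truth."""

    config: SyntheticConfig
    table: tuple[TFGeneRecord, ...]
    classification: PathwayClassification
    gmt: AnnotationCollection
    true_pairs: frozenset[tuple[str, str, str]]  # (cancer, tf, pathway)
    true_blocks: tuple[frozenset[str], ...]

    @property
    def universe(self) -> GeneSet:
        cfg = self.config
        return GeneSet(
            name="synthetic-glycogenes",
            members=frozenset(cfg.gene_name(j) for j in range(cfg.n_genes)),
        )


def _build_classification(config: SyntheticConfig) -> PathwayClassification:
    assignment: dict[str, frozenset[str]] = {}
    for p in range(config.n_pathways):
        name = config.pathway_name(p)
        for j in range(p * config.pathway_size, (p + 1) * config.pathway_size):
            gene = config.gene_name(j)
            assignment[gene] = assignment.get(gene, frozenset()) | {name}
    return PathwayClassification(
        pathways=tuple(config.pathway_name(p) for p in range(config.n_pathways)),
        assignment=assignment,
    )


def _build_gmt(config: SyntheticConfig, rng: np.random.Generator) -> AnnotationCollection:
    tf_names = [config.tf_name(i) for i in range(config.n_tfs)]
    sets: dict[str, frozenset[str]] = {}
    for b, block in enumerate(config.planted_blocks):
        sets[f"SIGBLK{b + 1:02d}"] = frozenset(config.tf_name(i) for i in block.tf_indices)
    for s in range(config.n_signaling_sets):
        size = int(rng.integers(5, min(26, config.n_tfs + 1)))
        members = rng.choice(config.n_tfs, size=size, replace=False)
        sets[f"SIG{s + 1:02d}"] = frozenset(tf_names[i] for i in sorted(members))
    return AnnotationCollection(sets=sets, source="synthetic")


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a dataset; deterministic for a fixed config (incl. seed)."""
    classification = _build_classification(config)
    gmt_rng = np.random.default_rng([int(config.seed) % (2**31), 9999])
    gmt = _build_gmt(config, gmt_rng)

    shape = (config.n_tfs, config.n_genes)
    records: list[TFGeneRecord] = []
    true_pairs: set[tuple[str, str, str]] = set()

    for c in range(config.n_cancers):
        rng = np.random.default_rng([int(config.seed) % (2**31), c])
        prob = np.full(shape, config.background_edge_prob)
        truth_prob = np.full(shape, config.true_edge_fraction)
        for block in config.planted_blocks:
            cell = np.ix_(list(block.tf_indices), list(block.gene_indices))
            prob[cell] = block.within_prob
            truth_prob[cell] = 1.0
        for pair in config.planted_pairs:
            lo = pair.pathway_index * config.pathway_size
            cols = slice(lo, lo + config.pathway_size)
            prob[pair.tf_index, cols] = min(1.0, pair.factor * config.background_edge_prob)
            truth_prob[pair.tf_index, cols] = 1.0 - (1.0 - config.true_edge_fraction) / pair.factor
            true_pairs.add(
                (
                    config.cancer_name(c),
                    config.tf_name(pair.tf_index),
                    config.pathway_name(pair.pathway_index),
                )
            )

        exists = rng.random(shape) < prob
        is_true = rng.random(shape) < truth_prob
        rp_true = rng.beta(*config.rp_true, size=shape)
        rp_decoy = rng.beta(*config.rp_decoy, size=shape)
        rho_true = 2.0 * rng.beta(*config.rho_true, size=shape) - 1.0
        rho_decoy = 2.0 * rng.beta(*config.rho_decoy, size=shape) - 1.0
        rp = np.round(np.where(is_true, rp_true, rp_decoy), 6)
        rho = np.round(np.where(is_true, rho_true, rho_decoy), 6)

        cancer = config.cancer_name(c)
        tf_idx, gene_idx = np.nonzero(exists)
        for i, j in zip(tf_idx.tolist(), gene_idx.tolist()):
            records.append(
                TFGeneRecord(
                    tf=config.tf_name(i),
                    gene=config.gene_name(j),
                    cancer=cancer,
                    rp=float(rp[i, j]),
                    rho=float(rho[i, j]),
                )
            )

    blocks = tuple(
        frozenset(config.tf_name(i) for i in block.tf_indices) for block in config.planted_blocks
    )
    return SyntheticTruth(
        config=config,
        table=tuple(records),
        classification=classification,
        gmt=gmt,
        true_pairs=frozenset(true_pairs),
        true_blocks=blocks,
    )


def retention_probability(params_rp: tuple[float, float], params_rho: tuple[float, float],
                          rp_min: float = 0.5, rho_min: float = 0.4) -> float:
    """P(RP >= rp_min and rho >= rho_min) for one edge class (RP, rho independent)."""
    p_rp = float(beta_dist.sf(rp_min, *params_rp))
    p_rho = float(beta_dist.sf((rho_min + 1.0) / 2.0, *params_rho))
    return p_rp * p_rho


def expected_retained(config: SyntheticConfig, rp_min: float = 0.5, rho_min: float = 0.4) -> tuple[float, float]:
    """Analytic (mean, sd) of the retained-edge count under the config.

    Sums the per-cell Bernoulli retention probabilities (edge exists AND its
    scores clear the thresholds) over all cells of all cancers.
    """
    ret_true = retention_probability(config.rp_true, config.rho_true, rp_min, rho_min)
    ret_decoy = retention_probability(config.rp_decoy, config.rho_decoy, rp_min, rho_min)

    shape = (config.n_tfs, config.n_genes)
    prob = np.full(shape, config.background_edge_prob)
    truth_prob = np.full(shape, config.true_edge_fraction)
    for block in config.planted_blocks:
        cell = np.ix_(list(block.tf_indices), list(block.gene_indices))
        prob[cell] = block.within_prob
        truth_prob[cell] = 1.0
    for pair in config.planted_pairs:
        lo = pair.pathway_index * config.pathway_size
        cols = slice(lo, lo + config.pathway_size)
        prob[pair.tf_index, cols] = min(1.0, pair.factor * config.background_edge_prob)
        truth_prob[pair.tf_index, cols] = 1.0 - (1.0 - config.true_edge_fraction) / pair.factor

    r = prob * (truth_prob * ret_true + (1.0 - truth_prob) * ret_decoy)
    mean = float(config.n_cancers * r.sum())
    var = float(config.n_cancers * (r * (1.0 - r)).sum())
    return mean, var**0.5


@dataclass(frozen=True)
class RecoveryMetrics:
    """Agreement between pipeline output and planted ground truth (all in [0, 1])."""

    pair_recall: float | None
    pair_precision: float | None
    block_exact_fraction: float | None
    rand_index: float | None


def recovery_report(
    truth: SyntheticTruth,
    enrich_results=None,
    community_sets: Mapping[str, "object"] | Sequence["object"] | None = None,
    alpha_adj: float = 0.05,
) -> RecoveryMetrics:
    """Planted-pair precision/recall and planted-block partition agreement.

    ``enrich_results`` is the DataFrame from ``enrich_tf_pathways`` run on
    ``truth.table`` after filtering; ``community_sets`` maps cancer code to a
    ``CommunitySet`` (a single set or sequence is accepted).  Degenerate
    cases (nothing planted, no detections) report ``None``.
    """
    pair_recall = pair_precision = None
    if enrich_results is not None and truth.true_pairs:
        sig = enrich_results[enrich_results["p_adj"] < alpha_adj]
        detected = {(r.cancer, r.tf, r.pathway) for r in sig.itertuples(index=False)}
        hits = truth.true_pairs & detected
        pair_recall = len(hits) / len(truth.true_pairs)
        pair_precision = (len(hits) / len(detected)) if detected else None

    block_exact = rand = None
    if community_sets is not None and truth.true_blocks:
        if hasattr(community_sets, "communities"):
            sets = [community_sets]
        elif isinstance(community_sets, Mapping):
            sets = [community_sets[k] for k in sorted(community_sets)]
        else:
            sets = list(community_sets)
        planted_tfs = sorted(set().union(*truth.true_blocks))
        block_of = {tf: b for b, block in enumerate(truth.true_blocks) for tf in block}
        exacts, rands = [], []
        for cs in sets:
            comm_of = {}
            for comm in cs.communities:
                for tf in comm.tfs:
                    comm_of[tf] = comm.id
            if any(tf not in comm_of for tf in planted_tfs):
                exacts.append(0.0)
                rands.append(0.0)
                continue
            # a planted block is recovered iff it is exactly one cell of the
            # detected partition restricted to planted TFs
            restricted: dict[int, set[str]] = {}
            for tf in planted_tfs:
                restricted.setdefault(comm_of[tf], set()).add(tf)
            cells = {frozenset(v) for v in restricted.values()}
            exacts.append(
                sum(1 for block in truth.true_blocks if block in cells) / len(truth.true_blocks)
            )
            agree = total = 0
            for u, v in itertools.combinations(planted_tfs, 2):
                total += 1
                same_truth = block_of[u] == block_of[v]
                same_found = comm_of[u] == comm_of[v]
                agree += int(same_truth == same_found)
            rands.append(agree / total if total else 1.0)
        block_exact = sum(exacts) / len(exacts)
        rand = sum(rands) / len(rands)

    return RecoveryMetrics(
        pair_recall=pair_recall,
        pair_precision=pair_precision,
        block_exact_fraction=block_exact,
        rand_index=rand,
    )


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write table TSV, classification TSV, signaling GMT and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "tf_gene_table.tsv",
        "classification": out / "pathway_classification.tsv",
        "gmt": out / "signaling_sets.gmt",
        "truth": out / "truth.json",
    }
    write_tf_gene_table(truth.table, paths["table"])
    truth.classification.membership_frame().to_csv(paths["classification"], sep="\t", index=False)
    write_annotation_gmt(truth.gmt, paths["gmt"])
    payload = {
        "true_pairs": sorted(list(t) for t in truth.true_pairs),
        "true_blocks": [sorted(b) for b in truth.true_blocks],
        "seed": truth.config.seed,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return paths
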