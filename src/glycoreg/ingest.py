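"""Readers and domain types for TF–gene regulatory tables and gene-set files.

The central input is a tab-delimited table of TF→target relationships in the
dialect exported by ChIP-Seq/RNA-Seq integration databases: one row per
(TF, gene, cancer type) with a regulatory potential RP in [0, 1] summarizing
binding evidence near the gene's TSS and a Spearman correlation rho in [-1, 1]
between TF and target expression across tumors.  Column names vary between
exports, so the reader takes a configurable dialect mapping.

Gene-set inputs are plain text (one symbol per line), two-column TSV
(gene, pathway) classifications, or GMT collections.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

#: Default column names of the tab-delimited export dialect.
DEFAULT_DIALECT: Mapping[str, str] = {
    "tf": "TF",
    "gene": "gene",
    "cancer": "cancer",
    "rp": "RP",
    "rho": "rho",
}


@dataclass(frozen=True)
class TFGeneRecord:
    """One TF→gene regulatory relationship within one cancer type."""

    tf: str
    gene: str
    cancer: str
    rp: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("tf", "gene", "cancer"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value.strip():
                raise ValidationError(f"{name} must be a non-empty string, got {value!r}")
        if not 0.0 <= self.rp <= 1.0:
            raise ValidationError(f"RP out of range [0, 1]: {self.rp!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho out of range [-1, 1]: {self.rho!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.tf, self.gene, self.cancer)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. the glycogene universe)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members


@dataclass(frozen=True)
class PathwayClassification:
    """Many-to-many assignment of glycogenes to glycosylation pathways.

    A gene may belong to several pathways (sialyltransferases, for instance,
    sit in both the ganglioside and the sialylation groups).
    """

    pathways: tuple[str, ...]
    assignment: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        known = set(self.pathways)
        if len(known) != len(self.pathways):
            raise ValidationError("pathway names are not unique")
        for gene, pws in self.assignment.items():
            if not pws:
                raise ValidationError(f"gene {gene!r} is assigned to no pathway")
            unknown = set(pws) - known
            if unknown:
                raise ValidationError(f"gene {gene!r} assigned to unknown pathways {sorted(unknown)}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def genes_in(self, pathway: str) -> frozenset[str]:
        return frozenset(g for g, pws in self.assignment.items() if pathway in pws)

    def pathways_of(self, gene: str) -> frozenset[str]:
        return self.assignment.get(gene, frozenset())

    @property
    def n_memberships(self) -> int:
        return sum(len(pws) for pws in self.assignment.values())

    def membership_frame(self) -> pd.DataFrame:
        """Long-format (gene, pathway) membership table, sorted for determinism."""
        rows = [(g, p) for g in sorted(self.assignment) for p in sorted(self.assignment[g])]
        return pd.DataFrame(rows, columns=["gene", "pathway"])


@dataclass(frozen=True)
class AnnotationCollection:
    """Named gene sets (GMT-style), e.g. signaling pathway annotations."""

    sets: Mapping[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"annotation set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    resolved = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect keys: {sorted(unknown)}")
        resolved.update(dialect)
    return resolved


def read_tf_gene_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    cancer: str | None = None,
) -> list[TFGeneRecord]:
    """Read a tab-delimited TF–gene relationship table.

    Supports either a pooled table with a cancer column or a per-cancer file;
    in the latter case pass ``cancer=`` explicitly (or name the file after the
    cancer code, e.g. ``BRCA_1.tsv``) and omit the cancer column.

    Raises
    ------
    ConfigurationError
        if a required column is missing.
    ValidationError
        if RP/rho fall outside their ranges or a (tf, gene, cancer) key repeats.
    """
    path = Path(path)
    cols = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("tf", "gene", "rp", "rho"):
        if cols[key] not in df.columns:
            raise ConfigurationError(f"missing column {cols[key]!r} in {path.name}")
    if cols["cancer"] in df.columns:
        cancers = df[cols["cancer"]]
    else:
        inferred = cancer if cancer is not None else path.stem
        cancers = pd.Series([inferred] * len(df), index=df.index)

    records: list[TFGeneRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row_d = dict(zip(df.columns, row))
        try:
            rp = float(row_d[cols["rp"]])
            rho = float(row_d[cols["rho"]])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path.name} line {i}: RP/rho not numeric") from exc
        try:
            rec = TFGeneRecord(
                tf=str(row_d[cols["tf"]]).strip(),
                gene=str(row_d[cols["gene"]]).strip(),
                cancer=str(cancers.iloc[i - 2]).strip(),
                rp=rp,
                rho=rho,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} line {i}: {exc}") from exc
        if rec.key in seen:
            raise ValidationError(f"{path.name} line {i}: duplicate (tf, gene, cancer) {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_tf_gene_table(
    records: Iterable[TFGeneRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records back to the tab-delimited dialect (round-trips with the reader)."""
    cols = _resolve_dialect(dialect)
    df = records_to_frame(records)
    df = df.rename(columns={k: cols[k] for k in ("tf", "gene", "cancer", "rp", "rho")})
    df.to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[TFGeneRecord]) -> pd.DataFrame:
    """Records as a DataFrame with canonical lower-case column names."""
    return pd.DataFrame(
        [(r.tf, r.gene, r.cancer, r.rp, r.rho) for r in records],
        columns=["tf", "gene", "cancer", "rp", "rho"],
    )


def frame_to_records(df: pd.DataFrame) -> list[TFGeneRecord]:
    return [
        TFGeneRecord(tf=r.tf, gene=r.gene, cancer=r.cancer, rp=float(r.rp), rho=float(r.rho))
        for r in df.itertuples(index=False)
    ]


def read_gene_list(path: str | Path, name: str | None = None, uppercase: bool = False) -> GeneSet:
    """Read a plain-text gene list (one symbol per line), deduplicated and trimmed."""
    path = Path(path)
    symbols: set[str] = set()
    for line in path.read_text().splitlines():
        sym = line.strip().split("\t")[0].strip()
        if sym:
            symbols.add(sym.upper() if uppercase else sym)
    if not symbols:
        raise ValidationError(f"{path.name}: empty gene list")
    return GeneSet(name=name or path.stem, members=frozenset(symbols))


def read_pathway_classification(path: str | Path) -> PathwayClassification:
    """Read a gene→pathway classification from a two-column TSV or a GMT file.

    The TSV form has a header ``gene<TAB>pathway`` (or no header) with one row
    per membership; the GMT form has one line per pathway.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        collection = read_annotation_gmt(path)
        assignment: dict[str, set[str]] = {}
        for pw, members in collection.sets.items():
            for gene in members:
                assignment.setdefault(gene, set()).add(pw)
        return PathwayClassification(
            pathways=tuple(sorted(collection.sets)),
            assignment={g: frozenset(p) for g, p in assignment.items()},
        )

    pairs: list[tuple[str, str]] = []
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path.name}: empty classification file")
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path.name} line {i}: expected 2 tab-separated columns")
        gene, pathway = parts[0].strip(), parts[1].strip()
        if i == 1 and (gene.lower(), pathway.lower()) == ("gene", "pathway"):
            continue
        if not gene or not pathway:
            raise ValidationError(f"{path.name} line {i}: empty gene or pathway name")
        pairs.append((gene, pathway))
    if not pairs:
        raise ValidationError(f"{path.name}: no (gene, pathway) rows")
    assignment2: dict[str, set[str]] = {}
    for gene, pathway in pairs:
        assignment2.setdefault(gene, set()).add(pathway)
    pathways = tuple(sorted({p for _, p in pairs}))
    return PathwayClassification(
        pathways=pathways,
        assignment={g: frozenset(p) for g, p in assignment2.items()},
    )


def read_annotation_gmt(path: str | Path, uppercase: bool = False, source: str = "") -> AnnotationCollection:
    """Read a standard GMT file: name, description, then tab-separated members."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise ValidationError(f"{path.name} line {i}: GMT line has no members")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"{path.name} line {i}: duplicate set name {name!r}")
        members = frozenset(m.upper() if uppercase else m for m in parts[2:] if m)
        if not members:
            raise ValidationError(f"{path.name} line {i}: GMT line has no members")
        sets[name] = members
    if not sets:
        raise ValidationError(f"{path.name}: empty GMT file")
    return AnnotationCollection(sets=sets, source=source or path.name)


def write_annotation_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.source or 'glycoreg'}\t{members}\n")


def load_pathway_fixture() -> PathwayClassification:
    """Packaged glycosylation-pathway classification.

    Twenty curated pathway groups (dolichol pathway, N-glycan branching,
    GalNAc-type O-glycans, glycosaminoglycan initiation/extension, sialylation,
    fucosylation, ...) with representative member enzymes; a reduced stand-in
    for a full curated classification, intended for tests and examples.
    """
    ref = importlib.resources.files("glycoreg").joinpath("data/glyco_pathways.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_pathway_classification(path)
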