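"""Readers and writers for the flat-file formats the tool touches.

Edge-list TSV for the interactome, two-column term→gene tables (the
``phenotype_to_genes`` style), GAF 2.x for GO annotations, and a gene×tissue
expression TSV.  All parsers are pure functions returning the package's
domain types; identifiers are kept as opaque strings — mapping between
identifier namespaces is the caller's job.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

#: High-confidence experimental/sequence evidence codes kept by default.
DEFAULT_GAF_EVIDENCE = frozenset(
    {"EXP", "IDA", "IMP", "IGI", "IEP", "ISS", "ISA", "ISM", "ISO"}
)
#: IPI (inferred from physical interaction) is excluded by default: using it
#: would leak the interactome into annotations meant to be independent of it.
DEFAULT_GAF_EXCLUDED = frozenset({"IPI"})


@dataclass(eq=False)
class ExpressionMatrix:
    """Gene × condition expression values.

    One row per unique gene; duplicate input rows are collapsed element-wise
    by maximum before construction (the multiple-transcript rule generalised
    to any duplicated gene identifier).
    """

    genes: list[str]
    conditions: list[str]
    values: np.ndarray
    _row_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers after collapsing")
        if len(self.genes) and np.isnan(self.values).all(axis=1).any():
            raise ValueError("all-missing expression row")
        self._row_of = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            genes=[str(g) for g in df.index],
            conditions=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._row_of[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._row_of

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


# ---------------------------------------------------------------------------
# interactome edge list
# ---------------------------------------------------------------------------

def read_network(
    path: str | PathLike, delimiter: str | None = None
) -> InteractionNetwork:
    """Read an undirected edge-list file into an :class:`InteractionNetwork`.

    Parameters
    ----------
    path:
        Two-or-more-column text file; the first two columns are the edge
        endpoints.  Lines starting with ``#`` are comments.
    delimiter:
        Column separator; ``None`` splits on any whitespace.

    Self-loops are dropped and duplicate / reversed-duplicate edges collapse;
    the number of dropped records is logged.
    """
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                n_comment += 1
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=2 columns, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            nodes.update((u, v))
            edges.append((u, v))
    net = InteractionNetwork.from_edges(edges, nodes)
    dropped = len(edges) - net.number_of_edges
    if n_comment:
        logger.info("read_network: skipped %d comment lines", n_comment)
    if dropped:
        logger.info(
            "read_network: collapsed %d duplicate/self-loop edge records", dropped
        )
    logger.info(
        "read_network: %d nodes, %d edges from %s",
        net.number_of_nodes, net.number_of_edges, path,
    )
    return net


def write_network(
    network: InteractionNetwork, path: str | PathLike, delimiter: str = "\t"
) -> None:
    """Write a network as a deterministic (sorted) edge list.

    Isolated nodes are written as single-column lines so the node set
    round-trips.
    """
    connected = set()
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in network.edge_list():
            fh.write(f"{u}{delimiter}{v}\n")
            connected.update((u, v))
        for v in sorted(set(network.nodes) - connected):
            fh.write(f"{v}{delimiter}{v}\n")  # self-loop form; dropped on read


# ---------------------------------------------------------------------------
# term -> gene tables
# ---------------------------------------------------------------------------

def read_term_gene_table(
    path: str | PathLike, header: bool = False
) -> dict[str, frozenset[str]]:
    """Read a two-column (term, gene) TSV into a term→gene-set mapping.

    Duplicate (term, gene) rows collapse to set membership.  ``header=True``
    skips the first non-comment line.
    """
    mapping: dict[str, set[str]] = defaultdict(set)
    n_comment = 0
    skipped_header = not header
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                n_comment += 1
                continue
            if not skipped_header:
                skipped_header = True
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            mapping[fields[0]].add(fields[1])
    if n_comment:
        logger.info("read_term_gene_table: skipped %d comment lines", n_comment)
    return {t: frozenset(gs) for t, gs in mapping.items()}


def write_term_gene_table(
    mapping: dict[str, frozenset[str]], path: str | PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(mapping):
            for gene in sorted(mapping[term]):
                fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# GAF 2.x
# ---------------------------------------------------------------------------

def read_gaf(
    path: str | PathLike,
    allowed_evidence: frozenset[str] | set[str] | None = None,
    excluded_evidence: frozenset[str] | set[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Read GO annotations from a GAF 2.x file into a term→gene mapping.

    Rows are kept when the evidence code is in ``allowed_evidence`` and not in
    ``excluded_evidence``, and the qualifier column (4) is empty — negated or
    otherwise qualified annotations are dropped.  Gene identifiers are taken
    from the DB-object-symbol column (3).
    """
    allowed = DEFAULT_GAF_EVIDENCE if allowed_evidence is None else frozenset(allowed_evidence)
    excluded = DEFAULT_GAF_EXCLUDED if excluded_evidence is None else frozenset(excluded_evidence)
    mapping: dict[str, set[str]] = defaultdict(set)
    n_comment = n_qualified = n_evidence = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            if raw.startswith("!"):
                n_comment += 1
                continue
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"{path}: line {lineno}: GAF row has {len(fields)} columns, "
                    "expected >=15"
                )
            qualifier = fields[3].strip()
            term = fields[4].strip()
            evidence = fields[6].strip()
            if qualifier:
                n_qualified += 1
                continue
            if evidence not in allowed or evidence in excluded:
                n_evidence += 1
                continue
            mapping[term].add(fields[2].strip())
    logger.info(
        "read_gaf: kept %d terms; dropped %d qualified rows, %d by evidence, "
        "%d comment lines",
        len(mapping), n_qualified, n_evidence, n_comment,
    )
    return {t: frozenset(gs) for t, gs in mapping.items()}


def write_gaf(
    mapping: dict[str, frozenset[str]],
    path: str | PathLike,
    evidence: str = "IDA",
) -> None:
    """Write a term→gene mapping as a minimal GAF 2.1 file that round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for term in sorted(mapping):
            for gene in sorted(mapping[term]):
                fields = [
                    "PN", gene, gene, "", term, "REF:0000000", evidence, "",
                    "P", "", "", "protein", "taxon:9606", "20170101", "PN",
                    "", "",
                ]
                fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | PathLike) -> ExpressionMatrix:
    """Read a gene × condition expression TSV (header row, gene id first).

    Duplicate gene rows are collapsed element-wise by maximum.  A non-numeric
    cell raises :class:`ParseError` naming the gene and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[converted.isna() & df[col].notna()]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric value {df.loc[bad[0], col]!r} "
                    f"for gene {bad[0]!r}, column {col!r}"
                )
            df[col] = converted
    n_dup = len(df) - df.index.nunique()
    if n_dup:
        logger.info("read_expression: collapsed %d duplicate gene rows by max", n_dup)
        df = df.groupby(level=0, sort=False).max()
    all_missing = df.index[df.isna().all(axis=1)] if len(df.columns) else df.index
    if len(df) and len(all_missing):
        logger.info("read_expression: dropped %d all-missing rows", len(all_missing))
        df = df.drop(index=all_missing)
    return ExpressionMatrix.from_frame(df)


def write_expression(expr: ExpressionMatrix, path: str | PathLike) -> None:
    df = expr.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")
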