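"""Readers, writers, and domain types for gene-set and cohort data.

Formats handled here are the plain-text lingua franca of gene-set analysis:

* GMT (MSigDB dialect): one functional gene set per line —
  ``name<TAB>description<TAB>gene1<TAB>gene2...``
* disease gene lists: one gene symbol per line, ``#`` comments allowed;
  or a two-column TSV mapping disease ids to genes.
* PPI networks: two-column whitespace-separated edge lists.
* cohort diagnosis matrices: TSV with a sample-id column, one 0/1 column
  per disease code.
* mapping tables: two-column TSV; only one-to-one rows are retained.

Gene identity is case-insensitive: every symbol is uppercased at ingest so
that downstream set operations never miss a match on case alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GeneSet",
    "GeneSetCollection",
    "DiseaseGeneSet",
    "CohortTable",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_disease_gene_table",
    "read_edge_list",
    "write_edge_list",
    "read_cohort",
    "write_cohort",
    "read_mapping",
    "filter_to_universe",
]


class ParseError(ValueError):
    """A file did not conform to its expected plain-text format."""


def _clean_symbol(raw: str) -> str:
    return raw.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named functional gene set (e.g., one GO term's member genes)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of functional gene sets over a gene universe.

    The order of ``sets`` is significant: it defines the index of each
    entry of a semantic profiling vector, so two profiles built on the
    same collection are comparable position by position.
    """

    sets: tuple[GeneSet, ...]
    universe: frozenset[str]
    collection_id: str = "collection"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene set name: {dup!r}")
        stray = set().union(*(s.genes for s in self.sets)) - self.universe if self.sets else set()
        if stray:
            raise ValueError(
                f"{len(stray)} member genes are outside the universe "
                f"(e.g. {sorted(stray)[:3]})"
            )

    @classmethod
    def from_sets(
        cls,
        sets: Iterable[GeneSet],
        universe: Iterable[str] | None = None,
        collection_id: str = "collection",
    ) -> "GeneSetCollection":
        sets = tuple(sets)
        if universe is None:
            uni: frozenset[str] = frozenset().union(*(s.genes for s in sets)) if sets else frozenset()
        else:
            uni = frozenset(_clean_symbol(g) for g in universe)
        return cls(sets=sets, universe=uni, collection_id=collection_id)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, i: int) -> GeneSet:
        return self.sets[i]


@dataclass(frozen=True)
class DiseaseGeneSet:
    """The known gene list of one disease."""

    disease_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease {self.disease_id!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CohortTable:
    """A binary sample x disease diagnosis matrix (1 = diagnosed)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate disease codes: {dups}")
        values = self.data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at sample {self.data.index[i]!r}, "
                f"disease {self.data.columns[j]!r}: {values[i, j]!r}"
            )
        self.data = self.data.astype(np.int8)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def diseases(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def status(self, disease: str) -> np.ndarray:
        """Boolean diagnosis vector for one disease code."""
        if disease not in self.data.columns:
            raise KeyError(f"disease code {disease!r} not in cohort")
        return self.data[disease].to_numpy(dtype=bool)

    def prevalence(self, disease: str) -> float:
        return float(self.status(disease).mean())


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, collection_id: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    The universe defaults to the union of all member genes; callers that
    have a broader background (e.g., all HGNC symbols) can rebuild the
    collection with :meth:`GeneSetCollection.from_sets`.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = frozenset(_clean_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, description=description))
    return GeneSetCollection.from_sets(
        sets, collection_id=collection_id if collection_id is not None else path.stem
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path: str | Path, disease_id: str | None = None) -> DiseaseGeneSet:
    """Read a one-symbol-per-line gene list; ``#`` lines are comments."""
    path = Path(path)
    genes: set[str] = set()
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(_clean_symbol(line))
    if not genes:
        raise ParseError(f"{path}: no genes")
    return DiseaseGeneSet(
        disease_id=disease_id if disease_id is not None else path.stem,
        genes=frozenset(genes),
    )


def write_gene_list(disease: DiseaseGeneSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(disease.genes):
            fh.write(g + "\n")


def read_disease_gene_table(path: str | Path) -> dict[str, DiseaseGeneSet]:
    """Read a two-column TSV (disease_id, gene) into disease gene sets."""
    path = Path(path)
    table: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            table.setdefault(parts[0].strip(), set()).add(_clean_symbol(parts[1]))
    if not table:
        raise ParseError(f"{path}: no rows")
    return {
        d: DiseaseGeneSet(disease_id=d, genes=frozenset(gs)) for d, gs in table.items()
    }


# ---------------------------------------------------------------------------
# PPI edge lists


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column edge list into an undirected simple graph.

    Self-loops and duplicate edges are dropped (a count is logged); node
    labels are uppercased gene symbols.
    """
    path = Path(path)
    graph: nx.Graph = nx.Graph()
    n_self, n_dup = 0, 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            u, v = _clean_symbol(parts[0]), _clean_symbol(parts[1])
            if u == v:
                n_self += 1
                continue
            if graph.has_edge(u, v):
                n_dup += 1
                continue
            graph.add_edge(u, v)
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, n_self, n_dup
        )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# cohort matrices


def read_cohort(path: str | Path) -> CohortTable:
    """Read a TSV diagnosis matrix (first column sample id, 0/1 cells)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise ParseError(f"{path}: duplicate disease code in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    values = numeric.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-binary cell at sample {df.index[i]!r}, "
            f"disease {df.columns[j]!r}: {values[i, j]!r}"
        )
    numeric.index = numeric.index.astype(str)
    return CohortTable(data=numeric.astype(np.int8))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# mapping tables


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV identifier mapping, keeping one-to-one rows only.

    Rows whose source or target identifier participates in more than one
    mapping are discarded, mirroring the usual conservative treatment of
    cross-reference tables between disease vocabularies.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pairs.append((parts[0].strip(), parts[1].strip()))
    from collections import Counter

    src_counts = Counter(p[0] for p in pairs)
    dst_counts = Counter(p[1] for p in pairs)
    kept = {a: b for a, b in pairs if src_counts[a] == 1 and dst_counts[b] == 1}
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("%s: dropped %d non one-to-one mapping rows", path, dropped)
    return kept


# ---------------------------------------------------------------------------
# universe filtering


def filter_to_universe(
    disease: DiseaseGeneSet, universe: Iterable[str]
) -> DiseaseGeneSet:
    """Restrict a disease gene set to the analysis universe.

    Genes outside the universe cannot contribute to any enrichment table,
    so they are dropped (with a warning). Raises if nothing survives.
    """
    uni = frozenset(universe)
    kept = disease.genes & uni
    dropped = len(disease.genes) - len(kept)
    if dropped:
        logger.warning(
            "disease %s: %d/%d genes outside universe dropped",
            disease.disease_id,
            dropped,
            len(disease.genes),
        )
    if not kept:
        raise ValueError(
            f"disease {disease.disease_id!r}: no testable genes after universe filtering"
        )
    return DiseaseGeneSet(disease_id=disease.disease_id, genes=kept)
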