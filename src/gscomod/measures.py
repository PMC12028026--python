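"""Comorbidity scores for a disease pair.

Four measures are provided:

* ``gs_sim`` — Pearson correlation between the two diseases' transformed
  semantic profiling vectors. This is the gene-set-based similarity
  score: it can detect comorbidity even when the disease gene lists
  share no genes, because it compares functional enrichment patterns
  rather than gene identities.
* ``jaccard`` — |A∩B| / |A∪B| on the raw gene sets.
* ``overlap_coefficient`` — |A∩B| / min(|A|, |B|).
* ``sab`` — network separation of the two gene sets on a PPI graph:
  mean shortest distance to the nearest gene of the other set, minus the
  average of the two within-set nearest-neighbour distances. Negative
  values mean the two disease modules overlap topologically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geneset_io import DiseaseGeneSet
from .ora import SemanticProfile, transform_profile

__all__ = [
    "ComorbidityScore",
    "SabResult",
    "gs_sim",
    "pearson",
    "jaccard",
    "overlap_coefficient",
    "sab",
    "score_all_pairs",
]


@dataclass(frozen=True)
class ComorbidityScore:
    disease_a: str
    disease_b: str
    measure: str  # gs_sim | jaccard | oc | sab
    value: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SabResult:
    """Components of the network-separation score s_ab = d_ab - (d_aa + d_bb)/2."""

    d_ab: float
    d_aa: float
    d_bb: float
    s_ab: float
    n_dropped_a: int = 0  # genes of A absent from the network or unreachable
    n_dropped_b: int = 0


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation by direct summation; NaN on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        return float("nan")
    return float((dx * dy).sum() / denom)


def gs_sim(
    profile_a: SemanticProfile,
    profile_b: SemanticProfile,
    transform: str = "exp",
) -> ComorbidityScore:
    """Gene-set-based similarity score of two semantic profiles.

    Both profiles must come from the same collection (same id, length,
    and set order), otherwise positions are not comparable. If either
    transformed vector is constant the correlation is undefined; the
    score is then 0 with a ``zero_variance`` flag, since a flat profile
    carries no similarity evidence.
    """
    if profile_a.collection_id != profile_b.collection_id:
        raise ValueError(
            f"profiles built on different collections: "
            f"{profile_a.collection_id!r} vs {profile_b.collection_id!r}"
        )
    if profile_a.set_names != profile_b.set_names:
        raise ValueError("profiles have mismatched functional set order")
    x = transform_profile(profile_a, transform)
    y = transform_profile(profile_b, transform)
    r = pearson(x, y)
    if np.isnan(r):
        return ComorbidityScore(
            profile_a.disease_id, profile_b.disease_id, "gs_sim", 0.0,
            flags=("zero_variance",),
        )
    return ComorbidityScore(profile_a.disease_id, profile_b.disease_id, "gs_sim", r)


def _require_nonempty(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> None:
    if not a or not b:
        raise ValueError("gene sets must be non-empty")


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Jaccard index |A∩B| / |A∪B|."""
    _require_nonempty(a, b)
    a, b = frozenset(a), frozenset(b)
    return len(a & b) / len(a | b)


def overlap_coefficient(
    a: frozenset[str] | set[str], b: frozenset[str] | set[str]
) -> float:
    """Overlap coefficient |A∩B| / min(|A|, |B|)."""
    _require_nonempty(a, b)
    a, b = frozenset(a), frozenset(b)
    return len(a & b) / min(len(a), len(b))


def _nearest_distance(
    net: nx.Graph, source: str, targets: frozenset[str]
) -> float:
    """Shortest hop distance from ``source`` to the nearest node in ``targets``.

    Returns inf when no target is reachable. A BFS from the source stops
    as soon as any target is reached.
    """
    if source in targets:
        return 0.0
    lengths = nx.single_source_shortest_path_length(net, source)
    best = min((d for n, d in lengths.items() if n in targets), default=float("inf"))
    return float(best)


def sab(
    a: DiseaseGeneSet | frozenset[str] | set[str],
    b: DiseaseGeneSet | frozenset[str] | set[str],
    net: nx.Graph,
) -> SabResult:
    """Network separation of two disease gene sets on a PPI graph.

    d_ab averages, over every mapped gene of both sets, the hop distance
    to the nearest mapped gene of the other set (0 when a gene belongs to
    both sets). d_aa / d_bb average, over the mapped genes of one set,
    the distance to the nearest *other* gene of the same set; a singleton
    set has within-set distance 0 by convention. Genes missing from the
    network, or unreachable from every relevant counterpart, are dropped
    from the corresponding mean and counted in ``n_dropped_*``.
    """
    genes_a = a.genes if isinstance(a, DiseaseGeneSet) else frozenset(a)
    genes_b = b.genes if isinstance(b, DiseaseGeneSet) else frozenset(b)
    nodes = frozenset(net.nodes)
    mapped_a = genes_a & nodes
    mapped_b = genes_b & nodes
    if not mapped_a or not mapped_b:
        raise ValueError("unmapped disease: no gene of one set is in the network")

    dropped_a = len(genes_a) - len(mapped_a)
    dropped_b = len(genes_b) - len(mapped_b)

    def _mean_nearest(sources: frozenset[str], targets: frozenset[str]) -> tuple[float, int]:
        dists = []
        unreachable = 0
        for g in sources:
            d = _nearest_distance(net, g, targets)
            if np.isinf(d):
                unreachable += 1
            else:
                dists.append(d)
        return (float(np.mean(dists)) if dists else float("nan")), unreachable

    # cross distances: every mapped gene of A to nearest of B and vice versa
    cross: list[float] = []
    unreach_ab = unreach_ba = 0
    for g in mapped_a:
        d = _nearest_distance(net, g, mapped_b)
        if np.isinf(d):
            unreach_ab += 1
        else:
            cross.append(d)
    for g in mapped_b:
        d = _nearest_distance(net, g, mapped_a)
        if np.isinf(d):
            unreach_ba += 1
        else:
            cross.append(d)
    if not cross:
        raise ValueError("unmapped disease: the two sets are mutually unreachable")
    d_ab = float(np.mean(cross))

    def _within(mapped: frozenset[str]) -> tuple[float, int]:
        if len(mapped) == 1:
            return 0.0, 0  # singleton convention
        dists = []
        unreachable = 0
        for g in mapped:
            d = _nearest_distance(net, g, mapped - {g})
            if np.isinf(d):
                unreachable += 1
            else:
                dists.append(d)
        return (float(np.mean(dists)) if dists else 0.0), unreachable

    d_aa, un_aa = _within(mapped_a)
    d_bb, un_bb = _within(mapped_b)

    s = d_ab - (d_aa + d_bb) / 2.0
    return SabResult(
        d_ab=d_ab,
        d_aa=d_aa,
        d_bb=d_bb,
        s_ab=s,
        n_dropped_a=dropped_a + unreach_ab + un_aa,
        n_dropped_b=dropped_b + unreach_ba + un_bb,
    )


def score_all_pairs(
    diseases: dict[str, DiseaseGeneSet],
    profiles: dict[str, SemanticProfile] | None = None,
    net: nx.Graph | None = None,
    measures: tuple[str, ...] = ("gs_sim", "jaccard", "oc", "sab"),
    transform: str = "exp",
) -> list[ComorbidityScore]:
    """Score every unordered disease pair with the requested measures.

    Output order is deterministic: lexicographic by (disease_a,
    disease_b, measure). Measures that need missing inputs (profiles for
    gs_sim, a network for sab) raise up front.
    """
    known = {"gs_sim", "jaccard", "oc", "sab"}
    unknown = set(measures) - known
    if unknown:
        raise ValueError(f"unknown measure(s): {sorted(unknown)}")
    if "gs_sim" in measures and profiles is None:
        raise ValueError("gs_sim requested but no profiles supplied")
    if "sab" in measures and net is None:
        raise ValueError("sab requested but no network supplied")

    out: list[ComorbidityScore] = []
    for ida, idb in itertools.combinations(sorted(diseases), 2):
        da, db = diseases[ida], diseases[idb]
        for m in sorted(measures):
            if m == "gs_sim":
                out.append(gs_sim(profiles[ida], profiles[idb], transform=transform))
            elif m == "jaccard":
                out.append(ComorbidityScore(ida, idb, "jaccard", jaccard(da.genes, db.genes)))
            elif m == "oc":
                out.append(
                    ComorbidityScore(ida, idb, "oc", overlap_coefficient(da.genes, db.genes))
                )
            elif m == "sab":
                try:
                    res = sab(da, db, net)
                    out.append(ComorbidityScore(ida, idb, "sab", res.s_ab))
                except ValueError:
                    out.append(
                        ComorbidityScore(ida, idb, "sab", float("nan"), flags=("unmapped",))
                    )
    return out
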